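# Methods

This note documents the models, parameter choices and numerical
decisions behind `normnet`, and what the synthetic-data validation does
and does not establish.

## Channel geometry and regions

The packaged montage is a 64-channel 10–20 extended layout on a
schematic 2-D grid (one unit ≈ one electrode spacing; only relative
distances are used).  Nine analysis regions partition 52 channels into
left/medial/right × frontal/central/parietal sets; CB1, CB2, M1 and M2
are excluded from network analysis, leaving 60 nodes.  Channel-neighbor
adjacency for cluster formation is Euclidean distance ≤ 1.45 grid
units, chosen so the median channel has ~6 neighbors and no channel
fewer than 2 — comparable to common 64-channel template neighborhoods.
The threshold is a configuration value (`neighbor_threshold`) because
no canonical adjacency exists for this cap; results of the cluster test
depend mildly on it.

Time windows are closed intervals in ms, inclusive of boundary
samples; sample 0 sits at `epoch_start_ms` (−200 by default).

## Synthetic-data generative model

The generator's defaults encode the study conditions the pipeline is
meant to analyze: a 43-person class network with 1–5 nominations per
person, 27-person EEG subsample, 60-trial sessions split 30/30 between
peer-feedback and non-feedback with offsets balanced over ±1/±2/±3, and
500 Hz epochs from −200 to +1000 ms.

**Social network.**  Each node draws an out-degree uniformly from
1…5 and selects targets without replacement with probability
proportional to a lognormal "attractiveness" (σ = 0.8), giving
heavy-tailed in-degree; a candidate who already nominated the chooser
has its weight multiplied by 5 (reciprocity).  Real-life network size
is `max(0, round(3 + 2·out_degree + N(0, 2.5)))`, which reproduces the
observed positive size/out-degree correlation (~0.6) and a size mean
near 9.

**Behavior.**  The displayed group rating is
`initial + offset`, reflected to `initial − offset` when it leaves
0–9.  On feedback trials the final rating moves 1–3 points toward the
shown rating with probability `conformity` (default 0.135); on any
trial still unchanged, a spontaneous ±1/±2 drift occurs with
probability `spontaneous_rate` (default 0.243).  These two defaults
were solved once from the reported influence scores (≈34.6% feedback,
≈24.3% non-feedback): `conformity + (1−conformity)·spontaneous ≈ 0.346`.
RTs are Gaussian (SD 250 ms) with means 1372/1204 ms.

**EEG.**  Each trial is the sum of
(a) 1/f^1 background noise, synthesized by spectral shaping of white
noise and scaled to 5 µV RMS per channel — a deliberately conservative
residual level for trial-pooled scalp EEG;
(b) band-limited oscillations: per coupled channel set a common
oscillator at the band's center frequency, each member channel offset
by a per-trial von Mises phase with concentration κ;
(c) ERP templates: raised-cosine bumps over the component window,
normalized so the *window mean* equals the specified amplitude, with a
condition difference added on feedback trials.

The κ ↔ PLV mapping is analytic: with independent von Mises offsets on
both channels the expected pair phasor modulus is `(I₁(κ)/I₀(κ))²`, so
κ is obtained by inverting `I₁/I₀ = √PLV` numerically (scaled Bessel
ratio, Brent's method).  Calibration holds when the oscillation
dominates in-band noise (amplitudes of ~10 µV against the ~1–3 µV
in-band share of the background); the slow delta oscillator uses 6 µV
as a compromise between phase fidelity and the residue its random
per-trial phase leaves in trial-averaged window means (that residue
scales as amplitude/√n_trials).

Because the phase lag is constant within a trial, a pooled PLV
estimate effectively has only n_trials independent draws: single-
subject PLV estimates scatter by ~0.05 at 30 trials.  Calibration
statements therefore refer to means over seeds/subjects.

**Condition effects (defaults).**  More-negative parietal N2
(−0.97 µV window-mean difference), more-positive broad P3 (+0.30 µV)
and frontal LPP (+0.52 µV); a fronto-parietal midline delta coupling
increase (0.45 → 0.60) and a beta within-module coupling decrease
(0.55 → 0.30) under feedback.  The beta oscillators are *modular* —
one independent oscillator per scalp region (plus one for the
remaining retained channels) — so every network node belongs to a
coupled module.  This geometry matters: weakening a single dense
clique *raises* measured local efficiency (weakly attached satellites
of a dense core acquire locally efficient neighborhoods), whereas
weakening within-module coupling everywhere reorganizes the top-K
binarized graph toward randomness and lowers clustering/local
efficiency, which is the segregation phenomenon the topology metrics
are meant to index.

**Centrality link.**  `centrality_link` maps an effect label (ERP
component or band) to a slope β; a subject with standardized
betweenness z receives condition-effect magnitude
`cond_diff · (1 + β·z)`.  The default links LPP with β = 0.6.

**What the generator does not emulate:** volume conduction and field
spread (channels carry independent noise), ocular/muscle artifact
morphology (only threshold-exceeding test pulses), latency jitter and
amplitude non-stationarity across trials, reference-dependent
topography, and 1/f knee structure.  Passing recovery tests therefore
demonstrates correctness of the *analysis chain*, not robustness to
these real-data complications; in particular, PLV on real data is
inflated by volume conduction, which the pipeline (by design, matching
its target analysis) does not correct.

## Statistical procedures

**RM-ANOVA.**  The 2 (feedback) × 3 (hemisphere) × 3 (lobe) within-
subject ANOVA projects each subject's 18 cell means onto orthonormal
contrast bases (Kronecker products of factor contrasts); for each
feedback-related effect, `F = (n·‖z̄‖²/q) / (SS_resid/(q(n−1)))` and the
Greenhouse–Geisser ε is `tr(Σ)²/(q·tr(Σ²))` on the contrast covariance,
clamped to [1/q, 1].  ε is applied to every effect's degrees of freedom
(a two-level factor has q = 1, hence ε = 1 exactly).  F values agree
with statsmodels' AnovaRM and ε with pingouin on shared cases (tested).
Simple effects after an interaction are paired F(1, n−1) tests within
each lobe level with hemispheres collapsed.

**FDR.**  BH step-up via statsmodels, verified against the literal
step-up definition.  The default family is all 36 tests (9 regions × 4
metrics) within a component; a per-metric family is available because
the appropriate family is a genuine judgment call.

**Cluster permutation.**  Two-sided thresholding at the critical t
(α = 0.05), polarity-pure clusters under (neighbor-channel ∨
adjacent-sample) adjacency, cluster mass = summed t, max-|mass| null
from within-subject sign flips, `p = (1+#{null ≥ mass})/(1+n_perm)`.
All permutation t-maps are computed in one matrix product (the sum of
squares is sign-invariant), which is what makes 1000-permutation
calibration studies affordable.  Exhaustive enumeration of all 2ⁿ sign
assignments is available for n ≤ 12.  Minimum cluster size is 1; no
minimum-neighbor constraint.

**PLV.**  The modulus of the pooled (trials × samples) mean phasor of
the phase difference over 0–1000 ms, consistent with the quantity's
[0, 1] range; a per-trial-then-average variant is provided
(`per_trial=True`) since pooling versus averaging is a genuine
convention choice.  Band filters are zero-phase Butterworth (N = 2
applied forward/backward) with 200 ms reflection padding before the
Hilbert transform.  Connectivity is computed on unreferenced epochs:
with a common average reference, the subtracted mean injects the
coupled oscillators into every channel and manufactures spurious
locking between unrelated sites.

**Graph topology.**  Binarization keeps the
`K = round(sparsity·N(N−1)/2)` strongest edges with deterministic
lexicographic tie-breaking.  GE is the mean of inverse distances with
1/∞ = 0 (the standard efficiency — the literal "inverse of the mean
path length" is undefined on the disconnected graphs that sparsity
0.05 on 60 nodes routinely produces; it remains available behind
`literal=True`).  CC is the mean of `2·triangles/(k(k−1))` with
degree-<2 nodes contributing 0; AC is the Newman estimator (both edge
orientations); LE is the mean neighbor-subgraph efficiency, computed
by batched boolean matrix-power BFS over zero-padded subgraph stacks.
AUC uses the trapezoidal rule on the sparsity grid (left-Riemann
variant available).  All four metrics are verified against brute-force
oracles and networkx.

**Effect sizes.**  Paired contrasts report both `d = 2t/√df` — the
convention that reproduces every printed effect size in the study line
this pipeline follows — and the conventional `d_z = mean(diff)/sd(diff)`,
so the non-standard formula is never propagated silently.

**ERP filter.**  Preprocessing is a zero-phase 0.1–30 Hz Butterworth
(N = 4 forward/backward) with maximal padding; at N = 2 the 50 Hz
attenuation of the zero-phase filter falls just short of 90% and the
0.1 Hz corner leaves visible slow transients on 1.2 s epochs.

## Problem sizes used in validation

The simulation-heavy checks run at reduced sizes chosen to keep the
whole suite comfortably re-runnable on a single core while preserving
every structural property under test: cluster-test calibration uses
200 null datasets of 20 subjects × 16 grid channels × 100 samples with
1000 permutations (family-wise error confirmed in [0.02, 0.09]) and
100 injected-effect datasets (352–430 ms, standardized amplitude 1);
end-to-end recovery uses 100 replicate cohorts of 27 subjects at 20
trials and 250 Hz.  Full-size defaults (60 trials, 500 Hz, 5000
permutations) remain the package defaults.

## Known limitations

* Betweenness is computed on the directed graph, unnormalized, by
  default; the survey tradition is ambiguous on both points, so both
  options are exposed.  Raw directed values on a 43-node network are
  an order of magnitude larger than the small values some survey
  tables print; rank-based analyses are unaffected.
* The conforming-rate denominator defaults to changed trials;
  an all-feedback-trials denominator is available.
* The cluster test assumes exchangeability of condition labels within
  subject (paired designs only); no between-subject variant.
* PLV leakage correction (imaginary coherence, wPLI) is out of scope.
* The GG ε estimator is the classical one; no Huynh–Feldt option.
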