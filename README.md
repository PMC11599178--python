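# normnet

**Social-network position and the neural processing of group norms — an
end-to-end EEG analysis pipeline with synthetic ground truth.**

`normnet` re-implements, as a tested and reusable Python package, the
analysis chain used to ask whether a person's position in their
real-world social network predicts how their brain processes group
norms.  The chain links four layers of data for the same cohort:

1. **Social network** — a directed friend-nomination graph (each person
   nominates 1–5 close classmates) and per-person real-life network
   size.  Metrics: in-degree, out-degree, directed betweenness
   centrality `C_B(v) = Σ_{s≠t≠v} σ_st(v)/σ_st`, and the real-life size
   count.
2. **Behavior** — an adaptive peer-feedback task: participants rate
   stimuli 0–9, then re-rate them with ("peer-feedback") or without
   ("non-feedback") a fabricated group rating set ±1/±2/±3 from their
   initial rating, with direction reversal at the scale boundary.
   Statistics: RT contrast, influence score (fraction of changed
   ratings), conforming rate (changes toward the group rating).
3. **ERPs** — windowed amplitudes (N2 180–280 ms, P3 300–500 ms,
   LPP 600–800 ms) over nine scalp regions; 2 × 3 × 3 repeated-measures
   ANOVA with Greenhouse–Geisser correction; Pearson correlations of
   condition differences with centrality, BH-FDR adjusted; and a
   spatiotemporal cluster-based permutation test (paired t maps,
   neighbor-channel ∨ adjacent-sample clusters, max-mass sign-flip
   null, Monte Carlo p).
4. **Functional brain networks** — phase-locking value
   `PLV_ij = |⟨e^{i(φ_i−φ_j)}⟩|` per band (delta/theta/alpha/beta) and
   condition over the 60 retained channels, binarized across a sparsity
   sweep (0.05…0.50); global efficiency, clustering coefficient,
   assortativity and local efficiency summarized by the area under the
   sparsity curve; edgewise ΔPLV–centrality associations with
   connected-component reporting.

Because the human data behind this design are not public, the package
ships a first-class **synthetic-data module** that generates all three
data types with known, configurable ground truth (nomination graphs
with popularity heterogeneity and reciprocity, behavioral sessions with
a conformity parameter, EEG with 1/f noise, calibrated phase-coupled
oscillations and ERP templates whose effects scale with a subject's
centrality), so every stage of the pipeline can be validated by
parameter recovery.  See `docs/methods.md` for the generative model and
its limitations.

## Worked example

```python
from normnet import montage, synth, erp, behavior, graph, connectivity

layout = montage.default_layout()
cohort = synth.generate_cohort(n_subjects=8, n_trials=40, srate=250.0, seed=7)

# behavior: feedback slows responses and increases rating changes
trials = [t for s in cohort.sessions.values() for t in s]
summary = behavior.summarize_subjects(trials)
print(behavior.group_contrasts(summary).round(3))
```

```
                 mean_feedback  mean_non_feedback      t  df     p      d    d_z
measure
rt_ms                 1372.655           1215.654  6.135   7  0.00  4.637  2.169
influence_score          0.344              0.250  1.488   7  0.18  1.125  0.526
```

The RT contrast recovers the generator's built-in ~170 ms feedback
slowing; `d` is the 2t/√df effect-size convention this study line
prints, `d_z` the conventional paired effect size.

```python
# ERP: preprocess, window/region table, 2x3x3 RM-ANOVA on the N2
processed = {}
for subj, ep in cohort.epochs.items():
    ep = erp.preprocess(ep, layout)
    ep = erp.baseline_correct(ep)
    ep, _ = erp.reject_artifacts(ep, layout=layout)
    processed[subj] = ep
table = erp.amplitude_table(processed, layout)
print(erp.rm_anova(table, "N2").round(4))
```

```
                F  df1  df2     eps   p_unc    p_gg  partial_eta_sq
effect
S          8.1892    1    7  1.0000  0.0243  0.0243          0.5391
S x R      4.0108    2   14  0.8094  0.0420  0.0549          0.3643
S x H      3.5405    2   14  0.8233  0.0570  0.0699          0.3359
S x R x H  1.4572    4   28  0.7104  0.2417  0.2568          0.1723
```

The feedback main effect (S) reflects the injected parietal N2
difference; ε = 1 for the two-level factor, and GG-corrected p is
reported for every effect.

```python
# brain networks: PLV -> sparsity sweep -> AUC -> paired contrasts
plv = {s: connectivity.plv_stack(ep, layout, bands=("delta", "beta")).matrices
       for s, ep in cohort.epochs.items()}
aucs = graph.auc_table(plv, metrics=("CC", "LE"))
print(graph.condition_contrast(aucs).round(3))
```

```
              mean_feedback  sd_feedback  mean_non_feedback  sd_non_feedback       t  df      p       d     d_z
band  metric
beta  CC              0.156        0.005              0.227            0.007 -27.065   7  0.000 -20.459  -9.569
      LE              0.258        0.003              0.319            0.005 -29.732   7  0.000 -22.476 -10.512
delta CC              0.142        0.003              0.138            0.002   2.253   7  0.059   1.703   0.797
      LE              0.239        0.004              0.236            0.003   2.012   7  0.084   1.521   0.711
```

The generator weakens within-module beta phase locking under feedback,
so clustering and local efficiency of the binarized beta network drop
in that condition — exactly what the negative t values recover.

A command-line interface mirrors these stages
(`normnet simulate / net-metrics / behavior / erp / cluster / plv /
graph`); run `normnet --help`.

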