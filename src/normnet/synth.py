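"""Synthetic cohorts with known ground truth.

Three generators emulate the statistical structure the analysis chain
assumes:

* a directed friend-nomination network (each person nominates 1–5
  classmates, with controllable popularity heterogeneity and
  reciprocity) plus real-life network sizes correlated with out-degree;
* adaptive peer-feedback sessions — half peer-feedback, half
  non-feedback trials, intended offsets balanced over ±1/±2/±3, displayed
  ratings produced by the boundary-reflecting feedback rule, final
  ratings that conform with a configurable probability on feedback
  trials and drift spontaneously at an independent rate on all trials;
* epoched EEG per session: spectrally shaped 1/f background noise,
  band-limited oscillations whose inter-channel phase lags follow a
  von Mises law with concentration calibrated to hit a target
  phase-locking value, and raised-cosine ERP templates (posterior N2,
  centro-parietal P3, frontal LPP) whose condition effects can scale
  with the subject's standardized social-network centrality.

ERP effect amplitudes are specified as *window-mean* condition
differences in µV (the raised-cosine template is normalized so its mean
over the component window is 1), so a −1.0 µV N2 effect produces a
−1.0 µV feedback-minus-non-feedback window mean up to noise.

All generators are deterministic given a seed (child streams are
spawned from a single ``SeedSequence``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize, special

from . import behavior
from .behavior import TrialRecord, make_group_rating
from .errors import ParameterError
from .montage import ChannelLayout, EpochSet

# ---------------------------------------------------------------------------
# Social network
# ---------------------------------------------------------------------------


def generate_social_network(n: int = 43, max_nominations: int = 5,
                            seed=None, heterogeneity: float = 0.8,
                            reciprocity_boost: float = 4.0,
                            size_base: float = 3.0,
                            size_per_nomination: float = 2.0,
                            size_sd: float = 2.5):
    """Directed nomination graph with 1–`max_nominations` nominations per node.

    Popularity heterogeneity is induced by lognormal node attractiveness
    (σ = *heterogeneity*); a nomination already received from a
    candidate multiplies that candidate's weight by
    (1 + *reciprocity_boost*), producing reciprocated ties.  Real-life
    network size is drawn as
    ``max(0, round(size_base + size_per_nomination·out_degree + N(0, size_sd)))``,
    giving the positive size/out-degree correlation observed in
    class-network surveys.
    """
    from .social import SocialGraph

    if n < 2:
        raise ParameterError(f"need at least 2 nodes, got {n}")
    if not 1 <= max_nominations <= n - 1:
        raise ParameterError(
            f"max_nominations must be in [1, {n - 1}], got {max_nominations}")
    rng = np.random.default_rng(seed)
    ids = [f"p{i:02d}" for i in range(n)]
    attract = rng.lognormal(mean=0.0, sigma=heterogeneity, size=n)
    out_deg = rng.integers(1, max_nominations + 1, size=n)
    received: dict[int, set[int]] = {i: set() for i in range(n)}
    edges: list[tuple[str, str]] = []
    order = rng.permutation(n)
    for i in order:
        w = attract.copy()
        w[i] = 0.0
        for j in received[i]:
            w[j] *= 1.0 + reciprocity_boost
        w /= w.sum()
        targets = rng.choice(n, size=out_deg[i], replace=False, p=w)
        for j in targets:
            edges.append((ids[i], ids[int(j)]))
            received[int(j)].add(int(i))
    sizes = {
        ids[i]: max(0, int(round(size_base + size_per_nomination * out_deg[i]
                                 + rng.normal(0.0, size_sd))))
        for i in range(n)
    }
    edges.sort()
    return SocialGraph(nodes=tuple(ids), edges=tuple(edges),
                       real_life_size=sizes)


# ---------------------------------------------------------------------------
# Behavioral sessions
# ---------------------------------------------------------------------------


def generate_session(n_trials: int = 60, conformity: float = 0.135,
                     spontaneous_rate: float = 0.243, seed=None,
                     subject: str = "s01", rt_mean_feedback: float = 1372.0,
                     rt_mean_non_feedback: float = 1204.0,
                     rt_sd: float = 250.0) -> list[TrialRecord]:
    """One behavioral session: ``n_trials/2`` trials per condition.

    Intended offsets on feedback trials are balanced over ±1/±2/±3 as
    far as divisibility allows.  The final rating moves 1–3 points
    toward the displayed group rating with probability *conformity*
    (feedback trials); independently of feedback, any trial drifts by a
    random ±1/±2 step with probability *spontaneous_rate* — needed
    because real participants also change ~a quarter of non-feedback
    ratings.  RTs are Gaussian with a positive feedback-minus-none mean
    shift.
    """
    if n_trials % 2:
        raise ParameterError(f"n_trials must be even, got {n_trials}")
    for name, p in (("conformity", conformity),
                    ("spontaneous_rate", spontaneous_rate)):
        if not 0.0 <= p <= 1.0:
            raise ParameterError(f"{name} must be in [0, 1], got {p}")
    rng = np.random.default_rng(seed)
    half = n_trials // 2
    conditions = np.array(["peer_feedback"] * half + ["non_feedback"] * half)
    rng.shuffle(conditions)
    offset_cycle = np.resize(np.array([1, -1, 2, -2, 3, -3]), half)
    rng.shuffle(offset_cycle)
    trials: list[TrialRecord] = []
    fb_i = 0
    for k, cond in enumerate(conditions):
        initial = int(rng.integers(0, 10))
        offset = shown = None
        final = initial
        if cond == "peer_feedback":
            offset = int(offset_cycle[fb_i])
            fb_i += 1
            shown = make_group_rating(initial, offset)
            if rng.random() < conformity:
                step = int(rng.integers(1, min(3, abs(shown - initial)) + 1))
                final = initial + int(np.sign(shown - initial)) * step
        if final == initial and rng.random() < spontaneous_rate:
            # spontaneous drift: random small step staying on the scale
            choices = [s for s in (-2, -1, 1, 2)
                       if behavior.RATING_MIN <= initial + s <= behavior.RATING_MAX]
            final = initial + int(rng.choice(choices))
        mean_rt = rt_mean_feedback if cond == "peer_feedback" else rt_mean_non_feedback
        rt = max(200.0, float(rng.normal(mean_rt, rt_sd)))
        trials.append(TrialRecord(
            subject=subject, stimulus=f"im{k:02d}", condition=str(cond),
            initial=initial, offset=offset, shown=shown, final=final,
            rt_ms=rt))
    return trials


# ---------------------------------------------------------------------------
# EEG generator
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ErpEffect:
    """One ERP component template.

    ``base_amp`` is the window-mean amplitude common to both conditions;
    ``cond_diff`` the feedback-minus-non-feedback window-mean difference
    (µV).  ``region_weights`` maps region labels to spatial weights.
    """

    label: str
    window_ms: tuple[float, float]
    region_weights: dict[str, float]
    base_amp: float
    cond_diff: float


@dataclass(frozen=True)
class BandCoupling:
    """Phase coupling of a channel set in one band.

    A common oscillator (at ``freq_hz``) drives every channel in
    ``channels`` with a per-trial, per-channel von Mises phase offset
    whose concentration is calibrated so the empirical pooled PLV of any
    pair in the set approaches ``plv[condition]``.
    """

    band: str
    freq_hz: float
    channels: tuple[str, ...]
    plv: dict[str, float]          # condition -> target PLV in [0, 1]
    amplitude: float = 10.0        # µV oscillation amplitude


@dataclass(frozen=True)
class EffectSpec:
    """Free parameters of the EEG generator."""

    erp_effects: tuple[ErpEffect, ...] = ()
    coupling: tuple[BandCoupling, ...] = ()
    #: label (ERP component or band) -> slope tying standardized
    #: centrality to the subject's condition-effect magnitude
    centrality_link: dict[str, float] = field(default_factory=dict)
    noise_rms: float = 5.0         # µV broadband background
    noise_exponent: float = 1.0    # 1/f^exponent spectral shape
    seed: int | None = None

    def __post_init__(self):
        if self.noise_rms <= 0:
            raise ParameterError("noise RMS must be positive")
        for c in self.coupling:
            for cond, p in c.plv.items():
                if not 0.0 <= p <= 1.0:
                    raise ParameterError(
                        f"target PLV {p} for {c.band}/{cond} outside [0, 1]")


def default_effect_spec(seed: int | None = None) -> EffectSpec:
    """Condition effects emulating the reported ERP/network pattern:
    a parietal N2 that is more negative under feedback, a broad P3 and a
    frontal LPP that are more positive, a fronto-parietal delta-band
    coupling increase under feedback, and a beta-band *within-module*
    coupling decrease under feedback that lowers functional segregation
    (clustering / local efficiency) of the binarized network.

    The beta oscillators are modular — one independent oscillator per
    scalp region (plus one for the remaining retained channels) — so
    that every network node belongs to a coupled module; weakening
    within-module phase locking then reorganizes the top-K binarized
    graph toward randomness instead of merely detaching satellites from
    a single clique.
    """
    from .montage import default_layout

    layout = default_layout()
    modules = [tuple(chs) for chs in layout.regions.values()]
    modules.append(tuple(c for c in layout.retained
                         if layout.region_of(c) is None))
    beta_plv = {"peer_feedback": 0.30, "non_feedback": 0.55}
    fronto_parietal_set = ("FZ", "FCZ", "F1", "F2", "PZ", "POZ", "P1", "P2")
    return EffectSpec(
        erp_effects=(
            ErpEffect("N2", (180.0, 280.0),
                      {"left parietal": 1.0, "medial parietal": 1.0,
                       "right parietal": 1.0},
                      base_amp=-2.5, cond_diff=-0.97),
            ErpEffect("P3", (300.0, 500.0),
                      {"medial central": 1.0, "medial parietal": 1.0,
                       "left central": 0.7, "right central": 0.7},
                      base_amp=1.8, cond_diff=0.30),
            ErpEffect("LPP", (600.0, 800.0),
                      {"left frontal": 1.0, "medial frontal": 1.0,
                       "right frontal": 1.0},
                      base_amp=1.0, cond_diff=0.52),
        ),
        coupling=(
            # the slow oscillation sits on a fronto-parietal midline set
            # (not the full LPP region) so its trial-average residue does
            # not swamp the frontal window-mean differences
            BandCoupling("delta", 2.0, fronto_parietal_set,
                         {"peer_feedback": 0.60, "non_feedback": 0.45},
                         amplitude=6.0),
        ) + tuple(
            BandCoupling("beta", 17.0, m, dict(beta_plv), amplitude=10.0)
            for m in modules
        ),
        centrality_link={"LPP": 0.6},
        seed=seed,
    )


def plv_to_kappa(target_plv: float) -> float:
    """Von Mises concentration whose two-channel pooled PLV equals the target.

    Each of the two channels carries an independent von Mises phase
    offset with concentration κ, so the expected pair phasor modulus is
    R(κ)² with R = I₁(κ)/I₀(κ); this inverts R(κ) = √target numerically.
    """
    if not 0.0 <= target_plv <= 1.0:
        raise ParameterError(f"target PLV {target_plv} outside [0, 1]")
    if target_plv < 1e-12:
        return 0.0
    r = math.sqrt(target_plv)
    if r > 0.9995:
        return 2000.0
    # scaled Bessel ratio i1e/i0e == I1/I0 without overflow at large kappa
    f = lambda k: special.i1e(k) / special.i0e(k) - r
    return float(optimize.brentq(f, 1e-9, 2000.0))


def _one_over_f_noise(rng, shape, n_samples, srate, exponent, rms):
    """Spectrally shaped Gaussian noise, unit-free then scaled to RMS µV."""
    white = rng.standard_normal(shape + (n_samples,))
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / srate)
    shaping = np.zeros_like(freqs)
    shaping[1:] = freqs[1:] ** (-exponent / 2.0)
    spec *= shaping
    x = np.fft.irfft(spec, n=n_samples, axis=-1)
    scale = x.std(axis=-1, keepdims=True)
    scale[scale == 0] = 1.0
    return x / scale * rms


def _raised_cosine(times_ms, window):
    a, b = window
    tmpl = np.zeros_like(times_ms)
    inside = (times_ms >= a) & (times_ms <= b)
    tmpl[inside] = 0.5 * (1.0 - np.cos(
        2.0 * np.pi * (times_ms[inside] - a) / (b - a)))
    mean_in_window = tmpl[inside].mean()
    return tmpl / mean_in_window   # unit window mean


def generate_eeg(session: list[TrialRecord], layout: ChannelLayout,
                 spec: EffectSpec, centrality_z: float = 0.0,
                 srate: float = 500.0, epoch_start_ms: float = -200.0,
                 epoch_end_ms: float = 1000.0, seed=None) -> EpochSet:
    """Epoched EEG for one subject's session.

    Each trial = 1/f background noise + per-band coupled oscillations +
    ERP templates.  ``centrality_z`` (the subject's standardized
    centrality) scales condition effects whose label appears in
    ``spec.centrality_link``: an effect with slope β has per-subject
    magnitude ``cond_diff · (1 + β·z)``.
    """
    if seed is None:
        seed = spec.seed
    rng = np.random.default_rng(seed)
    n_samples = int(round((epoch_end_ms - epoch_start_ms) / 1000.0 * srate)) + 1
    times = epoch_start_ms + np.arange(n_samples) * 1000.0 / srate
    t_sec = times / 1000.0
    n_tr, n_ch = len(session), len(layout.names)
    conditions = np.array([t.condition for t in session], dtype=object)

    data = _one_over_f_noise(rng, (n_tr, n_ch), n_samples, srate,
                             spec.noise_exponent, spec.noise_rms)

    for coup in spec.coupling:
        ch_idx = np.array([layout.index(c) for c in coup.channels])
        slope = spec.centrality_link.get(coup.band, 0.0)
        base = coup.plv.get("non_feedback", 0.0)
        kappas = {}
        for cond in np.unique(conditions):
            target = coup.plv.get(str(cond), 0.0)
            scaled = base + (target - base) * (1.0 + slope * centrality_z)
            kappas[str(cond)] = plv_to_kappa(float(np.clip(scaled, 0.0, 1.0)))
        common = rng.uniform(0.0, 2.0 * np.pi, size=n_tr)
        for i, trial_cond in enumerate(conditions):
            kappa = kappas[str(trial_cond)]
            if kappa <= 0:
                offs = rng.uniform(-np.pi, np.pi, size=len(ch_idx))
            else:
                offs = rng.vonmises(0.0, kappa, size=len(ch_idx))
            phases = common[i] + offs
            data[i, ch_idx, :] += coup.amplitude * np.cos(
                2.0 * np.pi * coup.freq_hz * t_sec[None, :] + phases[:, None])

    for eff in spec.erp_effects:
        a, b = eff.window_ms
        if a < times[0] or b > times[-1]:
            raise ParameterError(
                f"ERP window {eff.window_ms} outside epoch "
                f"[{times[0]}, {times[-1]}] ms")
        tmpl = _raised_cosine(times, eff.window_ms)
        weights = np.zeros(n_ch)
        for region, w in eff.region_weights.items():
            weights[layout.region_indices(region)] = w
        slope = spec.centrality_link.get(eff.label, 0.0)
        diff = eff.cond_diff * (1.0 + slope * centrality_z)
        amp = np.where(conditions == "peer_feedback",
                       eff.base_amp + diff, eff.base_amp)
        data += amp[:, None, None] * weights[None, :, None] * tmpl[None, None, :]

    return EpochSet(
        amplitudes=data.astype(np.float32), srate=srate,
        epoch_start_ms=epoch_start_ms, conditions=conditions,
        channels=layout.names,
        subject_id=session[0].subject if session else None,
    )


def inject_artifacts(epochs: EpochSet, fraction: float,
                     amplitude: float = 100.0, seed=None,
                     layout: ChannelLayout | None = None
                     ) -> tuple[EpochSet, list[int]]:
    """Contaminate a fraction of trials with a supra-threshold square pulse.

    Returns the contaminated epochs and the (sorted) ground-truth list
    of affected trial indices, for rejection-accuracy tests.  When a
    *layout* is given the pulse lands on a retained channel, so
    rejection restricted to retained channels can recover the list
    exactly.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ParameterError(f"fraction {fraction} outside [0, 1]")
    if amplitude <= 75.0:
        raise ParameterError(
            f"artifact amplitude must exceed the 75 µV threshold, "
            f"got {amplitude}")
    rng = np.random.default_rng(seed)
    n = epochs.n_trials
    k = int(round(fraction * n))
    ids = sorted(rng.choice(n, size=k, replace=False).tolist())
    data = epochs.amplitudes.astype(np.float64, copy=True)
    width = max(1, int(round(0.02 * epochs.srate)))   # 20 ms pulse
    if layout is not None:
        candidates = [i for i, c in enumerate(epochs.channels)
                      if c not in layout.excluded]
    else:
        candidates = list(range(data.shape[1]))
    for i in ids:
        ch = int(candidates[rng.integers(0, len(candidates))])
        s0 = int(rng.integers(0, max(1, data.shape[2] - width)))
        sign = 1.0 if rng.random() < 0.5 else -1.0
        # overwrite so the excursion is guaranteed to exceed ±amplitude
        data[i, ch, s0:s0 + width] = sign * (amplitude + 10.0)
    return replace(epochs, amplitudes=data.astype(epochs.amplitudes.dtype)), ids


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------


@dataclass
class Cohort:
    """A synthetic study: class network, EEG subsample, per-subject data."""

    graph: object                      # social.SocialGraph
    centrality: object                 # pandas DataFrame (EEG subjects only)
    centrality_z: dict[str, float]     # standardized betweenness per subject
    sessions: dict[str, list[TrialRecord]]
    epochs: dict[str, EpochSet]


def generate_cohort(n_subjects: int = 27, class_size: int = 43,
                    n_trials: int = 60, layout: ChannelLayout | None = None,
                    spec: EffectSpec | None = None, srate: float = 500.0,
                    conformity: float = 0.135,
                    spontaneous_rate: float = 0.243, seed=None) -> Cohort:
    """Full synthetic study: a class network, an EEG subsample of
    ``n_subjects``, and per-subject sessions + EEG whose linked effects
    scale with each subject's standardized betweenness centrality."""
    from . import social
    from .montage import default_layout

    if layout is None:
        layout = default_layout()
    if spec is None:
        spec = default_effect_spec()
    if n_subjects > class_size:
        raise ParameterError("n_subjects cannot exceed class_size")
    ss = np.random.SeedSequence(seed)
    net_seed, pick_seed, *subj_seeds = ss.spawn(2 + n_subjects)
    graph = generate_social_network(class_size, seed=net_seed)
    table = social.centrality_table(graph)
    rng = np.random.default_rng(pick_seed)
    chosen = sorted(rng.choice(list(graph.nodes), size=n_subjects,
                               replace=False).tolist())
    sub = table.loc[chosen]
    bc = sub["betweenness"].to_numpy(dtype=float)
    sd = bc.std(ddof=0)
    z = (bc - bc.mean()) / sd if sd > 0 else np.zeros_like(bc)
    zmap = dict(zip(chosen, z))
    sessions, epochs = {}, {}
    for subj, sseed in zip(chosen, subj_seeds):
        s1, s2 = sseed.spawn(2)
        sessions[subj] = generate_session(
            n_trials=n_trials, conformity=conformity,
            spontaneous_rate=spontaneous_rate, seed=s1, subject=subj)
        epochs[subj] = generate_eeg(sessions[subj], layout, spec,
                                    centrality_z=zmap[subj], srate=srate,
                                    seed=s2)
    return Cohort(graph=graph, centrality=sub, centrality_z=zmap,
                  sessions=sessions, epochs=epochs)
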