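"""ERP preprocessing, window/region amplitudes, repeated-measures ANOVA
with Greenhouse–Geisser correction, and centrality correlations with
BH-FDR adjustment.

Pipeline: zero-phase 0.1–30 Hz band-pass and average reference →
baseline correction over [−200, 0] ms → ±75 µV artifact rejection →
per-subject, per-condition trial-average ERPs → mean amplitude per
component window (N2 180–280 ms, P3 300–500 ms, LPP 600–800 ms) and
scalp region.  The 2 (feedback) × 3 (hemisphere) × 3 (lobe) within-
subject ANOVA is computed from orthonormal contrast projections, with
the Greenhouse–Geisser sphericity correction applied to every effect.
"""

from __future__ import annotations

from dataclasses import replace
from itertools import product

import numpy as np
import pandas as pd
from scipy import signal, stats
from statsmodels.stats.multitest import multipletests

from .errors import ParameterError, UndefinedValueError, NormnetError
from .montage import ChannelLayout, EpochSet, CONDITIONS

#: component label -> closed window [a, b] in ms
COMPONENTS = {"N2": (180.0, 280.0), "P3": (300.0, 500.0), "LPP": (600.0, 800.0)}

HEMISPHERES = ("left", "medial", "right")
LOBES = ("frontal", "central", "parietal")


def split_region(label: str) -> tuple[str, str]:
    """'left frontal' -> ('left', 'frontal')."""
    hemi, lobe = label.split()
    if hemi not in HEMISPHERES or lobe not in LOBES:
        raise ParameterError(f"region label {label!r} is not hemisphere+lobe")
    return hemi, lobe


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------


def preprocess(epochs: EpochSet, layout: ChannelLayout | None = None,
               l_freq: float = 0.1, h_freq: float = 30.0) -> EpochSet:
    """Zero-phase fourth-order Butterworth band-pass + average reference
    over retained scalp channels.

    Filtering runs forward and backward (no phase distortion) with
    maximal padding, which keeps the very low high-pass corner from
    leaving slow transients on short epochs.  Re-referencing is
    idempotent: applying it twice changes nothing.
    """
    nyq = epochs.srate / 2.0
    if not 0 < l_freq < h_freq < nyq:
        raise ParameterError(
            f"band edges ({l_freq}, {h_freq}) must satisfy "
            f"0 < low < high < Nyquist ({nyq})")
    sos = signal.butter(4, [l_freq, h_freq], btype="bandpass", fs=epochs.srate,
                        output="sos")
    data = np.asarray(epochs.amplitudes, dtype=float)
    data = signal.sosfiltfilt(sos, data, axis=-1,
                              padlen=max(0, data.shape[-1] - 1))
    if layout is not None:
        idx = layout.retained_indices()
    else:
        idx = np.arange(data.shape[1])
    data = data - data[:, idx, :].mean(axis=1, keepdims=True)
    return replace(epochs, amplitudes=data)


def baseline_correct(epochs: EpochSet,
                     window: tuple[float, float] = (-200.0, 0.0)) -> EpochSet:
    """Subtract the per-trial, per-channel mean over the baseline window."""
    idx = epochs.window_slice(*window)
    data = np.asarray(epochs.amplitudes, dtype=float)
    return replace(epochs,
                   amplitudes=data - data[:, :, idx].mean(-1, keepdims=True))


def reject_artifacts(epochs: EpochSet, threshold: float = 75.0,
                     layout: ChannelLayout | None = None
                     ) -> tuple[EpochSet, list[int]]:
    """Drop trials with any |sample| > threshold µV on any retained channel.

    Returns (clean epochs, rejected trial indices); raises if every
    trial is rejected.
    """
    if threshold <= 0:
        raise ParameterError("threshold must be positive")
    data = np.abs(np.asarray(epochs.amplitudes, dtype=float))
    if layout is not None:
        data = data[:, layout.retained_indices(), :]
    bad = np.nonzero(data.max(axis=(1, 2)) > threshold)[0]
    if len(bad) == epochs.n_trials and epochs.n_trials > 0:
        raise NormnetError("artifact rejection removed every trial")
    keep = np.setdiff1d(np.arange(epochs.n_trials), bad)
    return epochs.select_trials(keep), bad.tolist()


# ---------------------------------------------------------------------------
# Window/region amplitudes
# ---------------------------------------------------------------------------


def window_region_means(epochs: EpochSet, layout: ChannelLayout,
                        components: dict | None = None) -> pd.DataFrame:
    """Mean amplitude per condition × region × component for one subject.

    The trial-average ERP is computed per condition first, then averaged
    over window samples and region channels.  Long-format columns:
    ``subject, condition, region, component, amplitude``.
    """
    if components is None:
        components = COMPONENTS
    ch_map = {c: i for i, c in enumerate(epochs.channels)}
    rows = []
    for cond in CONDITIONS:
        sub = epochs.condition_trials(cond)
        if sub.n_trials == 0:
            raise UndefinedValueError(f"no trials in condition {cond!r}")
        erp = np.asarray(sub.amplitudes, dtype=float).mean(axis=0)
        for region, chans in layout.regions.items():
            idx = [ch_map[c] for c in chans
                   if c in ch_map and c not in layout.excluded]
            if not idx:
                raise NormnetError(f"region {region!r} has no retained channel")
            for comp, window in components.items():
                s = epochs.window_slice(*window)
                rows.append({
                    "subject": epochs.subject_id, "condition": cond,
                    "region": region, "component": comp,
                    "amplitude": float(erp[np.ix_(idx, s)].mean()),
                })
    return pd.DataFrame(rows)


def amplitude_table(epochs_by_subject: dict[str, EpochSet],
                    layout: ChannelLayout,
                    components: dict | None = None) -> pd.DataFrame:
    """Stack :func:`window_region_means` over subjects."""
    frames = []
    for subj, ep in epochs_by_subject.items():
        df = window_region_means(ep, layout, components)
        df["subject"] = subj
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def diff_table(table: pd.DataFrame) -> pd.DataFrame:
    """Feedback-minus-non-feedback difference per subject × region × component."""
    wide = table.pivot_table(index=["subject", "region", "component"],
                             columns="condition", values="amplitude")
    out = wide.reset_index()
    out["diff"] = out["peer_feedback"] - out["non_feedback"]
    return out[["subject", "region", "component", "diff"]]


# ---------------------------------------------------------------------------
# Repeated-measures ANOVA with Greenhouse–Geisser correction
# ---------------------------------------------------------------------------


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k, k-1) orthonormal contrast basis (columns sum to 0, unit norm)."""
    h = np.zeros((k, k - 1))
    for j in range(1, k):
        h[:j, j - 1] = 1.0
        h[j, j - 1] = -j
    return h / np.linalg.norm(h, axis=0)


def _effect_stats(z: np.ndarray) -> dict:
    """Univariate RM effect from orthonormal contrast scores z (n × q)."""
    n, q = z.shape
    mean = z.mean(axis=0)
    ss_eff = n * float(mean @ mean)
    resid = z - mean
    ss_err = float((resid ** 2).sum())
    df1, df2 = q, q * (n - 1)
    f = (ss_eff / df1) / (ss_err / df2) if ss_err > 0 else np.inf
    # Greenhouse–Geisser epsilon from the contrast covariance spectrum
    if q == 1:
        eps = 1.0
    else:
        cov = resid.T @ resid / (n - 1)
        tr, tr2 = np.trace(cov), np.trace(cov @ cov)
        eps = float(tr ** 2 / (q * tr2)) if tr2 > 0 else 1.0
        eps = min(1.0, max(eps, 1.0 / q))
    p_unc = float(stats.f.sf(f, df1, df2))
    p_gg = float(stats.f.sf(f, df1 * eps, df2 * eps))
    peta = ss_eff / (ss_eff + ss_err) if (ss_eff + ss_err) > 0 else np.nan
    return {"F": f, "df1": df1, "df2": df2, "eps": eps,
            "p_unc": p_unc, "p_gg": p_gg, "partial_eta_sq": peta}


def rm_anova(table: pd.DataFrame, component: str) -> pd.DataFrame:
    """2 (feedback S) × 3 (hemisphere H) × 3 (lobe R) within-subject ANOVA.

    Returns the four feedback-related effects (S, S×R, S×H, S×R×H) with
    F, dfs, Greenhouse–Geisser ε, GG-corrected p and partial η².
    Requires a complete design with n ≥ 5 subjects.
    """
    sub = table[table["component"] == component].copy()
    if sub.empty:
        raise ParameterError(f"component {component!r} not in table")
    sub[["hemisphere", "lobe"]] = [split_region(r) for r in sub["region"]]
    cells = [(c, h, l) for c in CONDITIONS for h in HEMISPHERES for l in LOBES]
    wide = sub.pivot_table(index="subject",
                           columns=["condition", "hemisphere", "lobe"],
                           values="amplitude")
    missing = [c for c in cells if c not in wide.columns]
    if missing or wide.isna().any().any():
        raise ParameterError(f"incomplete 2x3x3 design (missing cells: "
                             f"{missing[:4]}...)" if missing else
                             "incomplete design: missing values")
    y = wide[cells].to_numpy(dtype=float)      # n × 18, S-major ordering
    n = y.shape[0]
    if n < 5:
        raise ParameterError(f"need at least 5 subjects, got {n}")
    c_s = _orthonormal_contrasts(2)
    c_h = _orthonormal_contrasts(3)
    c_l = _orthonormal_contrasts(3)
    m_h = np.full((3, 1), 1.0 / np.sqrt(3))
    m_l = np.full((3, 1), 1.0 / np.sqrt(3))
    effects = {
        "S": np.kron(c_s, np.kron(m_h, m_l)),
        "S x R": np.kron(c_s, np.kron(m_h, c_l)),
        "S x H": np.kron(c_s, np.kron(c_h, m_l)),
        "S x R x H": np.kron(c_s, np.kron(c_h, c_l)),
    }
    rows = []
    for name, cmat in effects.items():
        st = _effect_stats(y @ cmat)
        st["effect"] = name
        rows.append(st)
    return pd.DataFrame(rows).set_index("effect")[
        ["F", "df1", "df2", "eps", "p_unc", "p_gg", "partial_eta_sq"]]


def simple_effects(table: pd.DataFrame, component: str) -> pd.DataFrame:
    """Feedback effect within each lobe level (hemispheres collapsed):
    paired F(1, n−1) per frontal/central/parietal."""
    sub = table[table["component"] == component].copy()
    sub[["hemisphere", "lobe"]] = [split_region(r) for r in sub["region"]]
    rows = []
    for lobe in LOBES:
        cell = sub[sub["lobe"] == lobe].pivot_table(
            index="subject", columns="condition", values="amplitude")
        d = cell["peer_feedback"] - cell["non_feedback"]
        n = len(d)
        sd = d.std(ddof=1)
        t = d.mean() / (sd / np.sqrt(n)) if sd > 0 else np.inf
        f = t ** 2
        rows.append({"lobe": lobe, "F": f, "df1": 1, "df2": n - 1,
                     "p": float(stats.f.sf(f, 1, n - 1)),
                     "partial_eta_sq": f / (f + (n - 1)),
                     "mean_feedback": cell["peer_feedback"].mean(),
                     "mean_non_feedback": cell["non_feedback"].mean()})
    return pd.DataFrame(rows).set_index("lobe")


# ---------------------------------------------------------------------------
# Centrality correlations with BH-FDR
# ---------------------------------------------------------------------------


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def centrality_correlations(diffs: pd.DataFrame, centrality: pd.DataFrame,
                            family: str = "component") -> pd.DataFrame:
    """Pearson correlations of per-subject condition differences with the
    four social-network metrics, BH-FDR adjusted.

    *diffs* is the output of :func:`diff_table`; *centrality* a DataFrame
    indexed by subject with metric columns.  ``family`` sets the BH
    adjustment family: ``"component"`` (default; all regions × metrics
    within a component) or ``"metric"`` (regions within a component ×
    metric pair).  Zero-variance inputs are flagged ``undefined`` and
    excluded from the family.
    """
    if family not in ("component", "metric"):
        raise ParameterError(f"unknown family {family!r}")
    merged = diffs.merge(centrality, left_on="subject", right_index=True)
    if merged["subject"].nunique() < 4:
        raise ParameterError("need at least 4 subjects with both measures")
    metrics = [c for c in centrality.columns]
    rows = []
    for (comp, region), grp in merged.groupby(["component", "region"]):
        for metric in metrics:
            x = grp["diff"].to_numpy(dtype=float)
            y = grp[metric].to_numpy(dtype=float)
            ok = np.isfinite(x) & np.isfinite(y)
            x, y = x[ok], y[ok]
            undefined = len(x) < 3 or x.std() == 0 or y.std() == 0
            if undefined:
                r = p = np.nan
            else:
                r, p = stats.pearsonr(x, y)
            rows.append({"component": comp, "region": region, "metric": metric,
                         "n": len(x), "r": r, "p": p, "undefined": undefined})
    out = pd.DataFrame(rows)
    out["p_fdr"] = np.nan
    group_cols = ["component"] if family == "component" else \
        ["component", "metric"]
    for _, idx in out.groupby(group_cols).groups.items():
        sel = out.loc[idx]
        valid = sel.index[~sel["undefined"]]
        if len(valid):
            out.loc[valid, "p_fdr"] = bh_adjust(out.loc[valid, "p"].to_numpy())
    return out
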