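"""Band-limited phase extraction and PLV functional connectivity.

For each frequency band (delta 0.5–4, theta 4–8, alpha 8–12, beta
14–20 Hz) epochs are zero-phase band-pass filtered (with reflection
padding to suppress filter/Hilbert edge artifacts), the instantaneous
phase is taken from the analytic signal, and the phase-locking value of
every retained channel pair is the modulus of the mean phasor of the
phase difference over the post-stimulus window (0–1000 ms):

    PLV_ij = | mean over trials and samples of exp(i(φ_i − φ_j)) |

PLV lies in [0, 1]; 1 means a fixed phase lag on every trial and
sample.  By default trials and samples are pooled into a single phasor
mean; a per-trial-then-average variant is available via ``per_trial``.

ΔPLV (peer-feedback minus non-feedback, edgewise) and its across-
subject association with a centrality measure (edges retained at raw
p < α, connected components reported) complete the module.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import networkx as nx
import numpy as np
from scipy import signal, stats

from .errors import ParameterError, UndefinedValueError
from .montage import ChannelLayout, EpochSet, CONDITIONS

#: band label -> passband (Hz)
BANDS = {"delta": (0.5, 4.0), "theta": (4.0, 8.0),
         "alpha": (8.0, 12.0), "beta": (14.0, 20.0)}


def band_passband(band) -> tuple[float, float]:
    if isinstance(band, str):
        try:
            return BANDS[band]
        except KeyError:
            raise ParameterError(f"unknown band {band!r}") from None
    low, high = band
    return float(low), float(high)


def band_filter(epochs: EpochSet, band, pad_ms: float = 200.0) -> EpochSet:
    """Zero-phase Butterworth band-pass with reflection padding."""
    low, high = band_passband(band)
    nyq = epochs.srate / 2.0
    if not 0 < low < high < nyq:
        raise ParameterError(
            f"passband ({low}, {high}) must lie below Nyquist ({nyq})")
    sos = signal.butter(2, [low, high], btype="bandpass", fs=epochs.srate,
                        output="sos")
    data = np.asarray(epochs.amplitudes, dtype=float)
    pad = int(round(pad_ms / 1000.0 * epochs.srate))
    padded = np.pad(data, [(0, 0), (0, 0), (pad, pad)], mode="reflect")
    out = signal.sosfiltfilt(sos, padded, axis=-1)[:, :, pad:-pad]
    return replace(epochs, amplitudes=out)


def instantaneous_phase(x: np.ndarray, axis: int = -1,
                        pad: int = 0) -> np.ndarray:
    """Phase (radians) of the analytic signal along *axis*.

    A constant trace has no defined phase and raises
    :class:`UndefinedValueError`.  Optional reflection padding of *pad*
    samples suppresses Hilbert edge effects.
    """
    x = np.asarray(x, dtype=float)
    if np.ptp(x) == 0:
        raise UndefinedValueError("constant signal has no defined phase")
    if pad:
        widths = [(0, 0)] * x.ndim
        widths[axis] = (pad, pad)
        xp = np.pad(x, widths, mode="reflect")
        ph = np.angle(signal.hilbert(xp, axis=axis))
        sl = [slice(None)] * x.ndim
        sl[axis] = slice(pad, -pad)
        return ph[tuple(sl)]
    return np.angle(signal.hilbert(x, axis=axis))


@dataclass
class PLVStack:
    """Per condition × band symmetric PLV matrices over retained channels."""

    matrices: dict[tuple[str, str], np.ndarray]  # (condition, band) -> (C, C)
    channels: tuple[str, ...]

    def get(self, condition: str, band: str) -> np.ndarray:
        key = (condition, band)
        if key not in self.matrices:
            raise ParameterError(f"no PLV matrix for {key}")
        return self.matrices[key]


def _check_plv(m: np.ndarray) -> np.ndarray:
    assert np.allclose(m, m.T, atol=1e-9), "PLV matrix must be symmetric"
    assert m.min() >= -1e-9 and m.max() <= 1 + 1e-9, "PLV outside [0, 1]"
    np.fill_diagonal(m, 1.0)
    return np.clip(m, 0.0, 1.0)


def plv_from_phases(phases: np.ndarray, per_trial: bool = False) -> np.ndarray:
    """PLV matrix from phases of shape (n_trials, n_channels, n_samples)."""
    z = np.exp(1j * np.asarray(phases))
    if per_trial:
        mats = []
        for trial in z:                          # (C, S)
            m = trial @ trial.conj().T / trial.shape[-1]
            mats.append(np.abs(m))
        plv = np.mean(mats, axis=0)
    else:
        flat = np.moveaxis(z, 1, 0).reshape(z.shape[1], -1)   # (C, T*S)
        plv = np.abs(flat @ flat.conj().T) / flat.shape[-1]
    return _check_plv(plv)


def plv_matrix(epochs: EpochSet, band, condition: str,
               layout: ChannelLayout, window_ms: tuple[float, float] = (0.0, 1000.0),
               per_trial: bool = False, pad_ms: float = 200.0) -> np.ndarray:
    """Symmetric PLV matrix over retained channels for one condition/band."""
    if condition not in CONDITIONS:
        raise ParameterError(f"unknown condition {condition!r}")
    sub = epochs.condition_trials(condition)
    if sub.n_trials == 0:
        raise ParameterError(f"no trials in condition {condition!r}")
    filtered = band_filter(sub, band, pad_ms=pad_ms)
    keep = [i for i, c in enumerate(epochs.channels)
            if c not in layout.excluded]
    data = np.asarray(filtered.amplitudes, dtype=float)[:, keep, :]
    pad = int(round(pad_ms / 1000.0 * epochs.srate))
    phases = instantaneous_phase(data, axis=-1, pad=pad)
    s = sub.window_slice(*window_ms)
    return plv_from_phases(phases[:, :, s], per_trial=per_trial)


def plv_stack(epochs: EpochSet, layout: ChannelLayout,
              bands=tuple(BANDS), conditions=CONDITIONS,
              window_ms: tuple[float, float] = (0.0, 1000.0),
              per_trial: bool = False, pad_ms: float = 200.0) -> PLVStack:
    """All condition × band PLV matrices for one subject.

    Equivalent to calling :func:`plv_matrix` per (condition, band) but
    filters and extracts phases only once per band.
    """
    keep = [i for i, c in enumerate(epochs.channels)
            if c not in layout.excluded]
    channels = tuple(epochs.channels[i] for i in keep)
    pad = int(round(pad_ms / 1000.0 * epochs.srate))
    s = epochs.window_slice(*window_ms)
    mats = {}
    for band in bands:
        filtered = band_filter(epochs, band, pad_ms=pad_ms)
        data = np.asarray(filtered.amplitudes, dtype=float)[:, keep, :]
        phases = instantaneous_phase(data, axis=-1, pad=pad)[:, :, s]
        for cond in conditions:
            mask = epochs.conditions == cond
            if not mask.any():
                raise ParameterError(f"no trials in condition {cond!r}")
            mats[(cond, band)] = plv_from_phases(phases[mask],
                                                 per_trial=per_trial)
    return PLVStack(matrices=mats, channels=channels)


def delta_plv(stack: PLVStack, bands=tuple(BANDS)) -> dict[str, np.ndarray]:
    """Edgewise peer-feedback minus non-feedback PLV, per band."""
    out = {}
    for band in bands:
        out[band] = stack.get("peer_feedback", band) - \
            stack.get("non_feedback", band)
    return out


@dataclass
class EdgeAssociation:
    """Edgewise centrality association: r/p maps, retained edges, components."""

    r: np.ndarray
    p: np.ndarray
    alpha: float
    edges: list[tuple[str, str]]                 # retained channel pairs
    components: list[list[str]]                  # connected channel sets
    regions: dict[str, str | None]               # channel -> region label


def edgewise_centrality_association(delta_plvs: np.ndarray,
                                    centrality: np.ndarray,
                                    channels: tuple[str, ...],
                                    layout: ChannelLayout | None = None,
                                    alpha: float = 0.01) -> EdgeAssociation:
    """Across-subject Pearson correlation of each edge's ΔPLV with a
    centrality measure; edges with raw p < *alpha* retained and grouped
    into connected components (network-based-statistic style, no
    correction at this stage).

    *delta_plvs*: (n_subjects, C, C); *centrality*: (n_subjects,).
    """
    x = np.asarray(delta_plvs, dtype=float)
    y = np.asarray(centrality, dtype=float)
    n = x.shape[0]
    if n < 4:
        raise ParameterError(f"need at least 4 subjects, got {n}")
    if y.shape != (n,):
        raise ParameterError("centrality must be one value per subject")
    if y.std() == 0:
        raise UndefinedValueError("centrality has zero variance")
    c = x.shape[1]
    zy = (y - y.mean()) / y.std()
    xm = x - x.mean(axis=0)
    xs = x.std(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.einsum("k,kij->ij", zy, xm) / (n * xs)
    r[~np.isfinite(r)] = 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r ** 2))
    t[~np.isfinite(t)] = np.inf
    p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    np.fill_diagonal(p, 1.0)
    iu, ju = np.triu_indices(c, 1)
    keep = p[iu, ju] < alpha
    edges = [(channels[i], channels[j])
             for i, j in zip(iu[keep], ju[keep])]
    g = nx.Graph(edges)
    components = [sorted(comp) for comp in nx.connected_components(g)]
    components.sort(key=len, reverse=True)
    regions = {ch: (layout.region_of(ch) if layout is not None else None)
               for comp in components for ch in comp}
    return EdgeAssociation(r=r, p=p, alpha=alpha, edges=edges,
                           components=components, regions=regions)
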