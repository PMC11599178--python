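"""Spatiotemporal cluster-based permutation test for paired ERP contrasts.

At every (channel, sample) point a paired t compares the two conditions
across subjects.  Supra-threshold points (|t| > two-sided critical t at
α = 0.05) are grouped into maximal connected components under the joint
adjacency "neighboring channel at the same sample OR adjacent sample on
the same channel", with clusters kept polarity-pure.  Each cluster's
mass is its summed t.  The null distribution is built by random
within-subject condition swaps (sign flips of the paired differences);
per permutation the maximum |cluster mass| is recorded (max-statistic,
family-wise control), and each observed cluster's Monte Carlo p is
(1 + #{null ≥ mass}) / (1 + n_permutations).

For small n an exhaustive sign-flip enumeration (all 2ⁿ assignments) is
available and the Monte Carlo p converges to it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np
from scipy import sparse, stats
from scipy.sparse.csgraph import connected_components

from .errors import ParameterError
from .montage import ChannelLayout


@dataclass
class Cluster:
    channels: np.ndarray     # channel indices of member points
    samples: np.ndarray      # sample indices (parallel to channels)
    polarity: int            # +1 or -1
    mass: float              # summed t over member points


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    tmap: np.ndarray
    t_critical: float
    p_values: np.ndarray | None = None          # per cluster, Monte Carlo
    null_distribution: np.ndarray | None = None  # per permutation max |mass|

    def significant(self, alpha: float = 0.05) -> list[Cluster]:
        if self.p_values is None:
            raise ParameterError("no permutation p-values computed")
        return [c for c, p in zip(self.clusters, self.p_values) if p < alpha]


def pointwise_t(cond_a: np.ndarray, cond_b: np.ndarray) -> np.ndarray:
    """Paired t at every (channel, sample) point.

    Inputs are per-subject trial-averaged ERPs, shape
    (n_subjects, n_channels, n_samples), with matching subject order.
    Zero-variance points with a nonzero mean give signed infinity.
    """
    a = np.asarray(cond_a, dtype=float)
    b = np.asarray(cond_b, dtype=float)
    if a.shape != b.shape:
        raise ParameterError(f"condition shapes differ: {a.shape} vs {b.shape}")
    n = a.shape[0]
    if n < 3:
        raise ParameterError(f"need at least 3 subjects, got {n}")
    d = a - b
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    t[np.isnan(t)] = 0.0          # 0/0: no difference, no evidence
    return t


def _point_adjacency(n_ch: int, n_samp: int,
                     neighbors: np.ndarray) -> sparse.csr_matrix:
    """Sparse adjacency over flattened (channel, sample) points."""
    rows, cols = [], []
    # temporal adjacency along each channel
    base = np.arange(n_ch)[:, None] * n_samp + np.arange(n_samp - 1)[None, :]
    rows.append(base.ravel())
    cols.append((base + 1).ravel())
    # spatial adjacency at each sample
    ci, cj = np.nonzero(np.triu(neighbors))
    if len(ci):
        s = np.arange(n_samp)
        rows.append((ci[:, None] * n_samp + s[None, :]).ravel())
        cols.append((cj[:, None] * n_samp + s[None, :]).ravel())
    r = np.concatenate(rows)
    c = np.concatenate(cols)
    n = n_ch * n_samp
    m = sparse.coo_matrix((np.ones(len(r), dtype=bool), (r, c)), shape=(n, n))
    return (m + m.T).tocsr()


def _clusters_from_mask(t_flat: np.ndarray, mask: np.ndarray,
                        adj: sparse.csr_matrix, n_samp: int,
                        polarity: int) -> list[Cluster]:
    idx = np.flatnonzero(mask)
    if not len(idx):
        return []
    sub = adj[idx][:, idx]
    _, labels = connected_components(sub, directed=False)
    out = []
    for lab in range(labels.max() + 1):
        members = idx[labels == lab]
        out.append(Cluster(
            channels=members // n_samp, samples=members % n_samp,
            polarity=polarity, mass=float(t_flat[members].sum())))
    return out


def form_clusters(tmap: np.ndarray, layout: ChannelLayout | None = None,
                  alpha: float = 0.05, df: int | None = None,
                  neighbors: np.ndarray | None = None,
                  t_critical: float | None = None) -> ClusterResult:
    """Partition supra-threshold |t| points into polarity-pure connected
    clusters; an empty cluster list is a valid outcome.

    Channel adjacency comes from *layout* (or an explicit boolean
    *neighbors* matrix); the threshold is the two-sided critical t at
    *alpha* for *df*, or an explicit *t_critical*.
    """
    tmap = np.asarray(tmap, dtype=float)
    n_ch, n_samp = tmap.shape
    if neighbors is None:
        if layout is None:
            raise ParameterError("need a layout or a neighbors matrix")
        neighbors = layout.neighbors
    if neighbors.shape != (n_ch, n_ch):
        raise ParameterError(
            f"neighbors matrix {neighbors.shape} does not match "
            f"{n_ch} channels")
    if t_critical is None:
        if df is None:
            raise ParameterError("need df (or explicit t_critical)")
        t_critical = float(stats.t.ppf(1.0 - alpha / 2.0, df))
    adj = _point_adjacency(n_ch, n_samp, neighbors)
    t_flat = tmap.ravel()
    clusters = (_clusters_from_mask(t_flat, t_flat > t_critical, adj,
                                    n_samp, +1)
                + _clusters_from_mask(t_flat, t_flat < -t_critical, adj,
                                      n_samp, -1))
    clusters.sort(key=lambda c: -abs(c.mass))
    return ClusterResult(clusters=clusters, tmap=tmap, t_critical=t_critical)


def _max_masses(tmaps_flat: np.ndarray, t_critical: float,
                adj: sparse.csr_matrix) -> np.ndarray:
    """Maximum |cluster mass| per permutation (rows of tmaps_flat)."""
    out = np.zeros(tmaps_flat.shape[0])
    for k, t_flat in enumerate(tmaps_flat):
        best = 0.0
        for sign in (1.0, -1.0):
            idx = np.flatnonzero(sign * t_flat > t_critical)
            if not len(idx):
                continue
            sub = adj[idx][:, idx]
            _, labels = connected_components(sub, directed=False)
            masses = np.bincount(labels, weights=np.abs(t_flat[idx]))
            best = max(best, float(masses.max()))
        out[k] = best
    return out


def permutation_test(cond_a: np.ndarray, cond_b: np.ndarray,
                     layout: ChannelLayout | None = None,
                     n_perm: int = 5000, seed=None, alpha: float = 0.05,
                     neighbors: np.ndarray | None = None,
                     exact: bool = False) -> ClusterResult:
    """Cluster-based permutation test for a paired two-condition contrast.

    *cond_a*, *cond_b*: per-subject trial-averaged ERPs,
    (n_subjects, n_channels, n_samples).  The null is built by random
    within-subject condition swaps; with ``exact=True`` (n ≤ 12) all 2ⁿ
    sign assignments are enumerated instead.
    """
    a = np.asarray(cond_a, dtype=float)
    b = np.asarray(cond_b, dtype=float)
    if a.shape != b.shape:
        raise ParameterError(f"condition shapes differ: {a.shape} vs {b.shape}")
    n, n_ch, n_samp = a.shape
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is very small; p-values are coarse")
    if n < 5:
        warnings.warn(f"only {n} subjects: at most 2^{n} distinct partitions")
    d = (a - b).reshape(n, -1)
    df = n - 1
    t_critical = float(stats.t.ppf(1.0 - alpha / 2.0, df))
    if neighbors is None:
        if layout is None:
            raise ParameterError("need a layout or a neighbors matrix")
        neighbors = layout.neighbors
    adj = _point_adjacency(n_ch, n_samp, neighbors)

    observed = form_clusters(pointwise_t(a, b), neighbors=neighbors,
                             t_critical=t_critical)

    if exact:
        if n > 12:
            raise ParameterError("exact enumeration limited to n <= 12")
        signs = np.array(list(product((1.0, -1.0), repeat=n)))
    else:
        rng = np.random.default_rng(seed)
        signs = rng.choice((1.0, -1.0), size=(n_perm, n))

    # all permutation t-maps at once: the sum of squares is sign-invariant
    ssq = (d ** 2).sum(axis=0)
    means = signs @ d / n
    with np.errstate(divide="ignore", invalid="ignore"):
        var = (ssq - n * means ** 2) / (n - 1)
        var[var < 0] = 0.0
        tmaps = means / np.sqrt(var / n)
    tmaps[~np.isfinite(tmaps)] = 0.0

    null = _max_masses(tmaps, t_critical, adj)
    masses = np.array([abs(c.mass) for c in observed.clusters])
    n_eff = len(null)
    pvals = np.array([
        (1.0 + float((null >= m).sum())) / (1.0 + n_eff) for m in masses])
    observed.p_values = pvals
    observed.null_distribution = null
    return observed
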