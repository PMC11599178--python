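"""Sparsity-thresholded binary brain graphs and topology metrics.

A weighted connectivity matrix (e.g. PLV) is binarized by keeping the
K = round(sparsity · N(N−1)/2) strongest edges (ties broken by a fixed
lexicographic pair order).  Four metrics summarize the binary graph:

* GE — global efficiency, the mean over ordered node pairs of 1/d(i,j)
  with 1/∞ = 0 for disconnected pairs (the standard efficiency; a
  literal "inverse of the mean path length over connected pairs"
  variant is available behind a flag);
* CC — mean clustering coefficient, 2·triangles/(k(k−1)) per node,
  nodes with degree < 2 contributing 0;
* AC — degree assortativity, the Pearson correlation of endpoint
  degrees over edges with both orientations counted (Newman);
* LE — mean local efficiency, the global efficiency of each node's
  neighbor-induced subgraph.

Each metric is traced over a sparsity sweep (default 0.05…0.50 in steps
of 0.05) and summarized by the area under the curve (trapezoidal rule
by default, left-Riemann available).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import behavior
from .errors import ParameterError, UndefinedValueError

DEFAULT_SPARSITIES = tuple(np.round(np.arange(0.05, 0.501, 0.05), 2))

METRICS = ("GE", "CC", "AC", "LE")


@dataclass(frozen=True)
class BinaryGraph:
    adjacency: np.ndarray    # symmetric bool, zero diagonal
    sparsity: float

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2


def binarize(weights: np.ndarray, sparsity: float) -> BinaryGraph:
    """Keep the top round(sparsity · N(N−1)/2) strongest edges.

    Ties are resolved deterministically by lexicographic (i, j) pair
    order.  K = 0 raises :class:`ParameterError`.
    """
    w = np.asarray(weights, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ParameterError("weights must be a square matrix")
    if not np.allclose(w, w.T, atol=1e-9):
        raise ParameterError("weights must be symmetric")
    if not 0.0 < sparsity < 1.0 + 1e-12:
        raise ParameterError(f"sparsity {sparsity} outside (0, 1]")
    n = w.shape[0]
    iu, ju = np.triu_indices(n, 1)
    k = int(round(sparsity * n * (n - 1) / 2))
    if k == 0:
        raise ParameterError(
            f"sparsity {sparsity} retains zero edges on {n} nodes")
    order = np.lexsort((ju, iu, -w[iu, ju]))   # by (-weight, i, j)
    keep = order[:k]
    adj = np.zeros((n, n), dtype=bool)
    adj[iu[keep], ju[keep]] = True
    return BinaryGraph(adjacency=adj | adj.T, sparsity=float(sparsity))


def _bfs_distances(adj: np.ndarray) -> np.ndarray:
    """All-pairs unweighted shortest-path distances (∞ if disconnected)."""
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import shortest_path

    return shortest_path(csr_matrix(adj), method="D", unweighted=True,
                         directed=False)


def _pairwise_inverse_distance_mean(adj: np.ndarray) -> float:
    """Mean of 1/d over ordered node pairs (1/∞ = 0); the efficiency core."""
    n = adj.shape[0]
    d = _bfs_distances(adj)
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d[off]
    inv[~np.isfinite(inv)] = 0.0
    return float(inv.mean())


def global_efficiency(g: BinaryGraph, literal: bool = False) -> float:
    """Mean of 1/d over ordered node pairs (1/∞ = 0).

    ``literal=True`` computes 1/mean(d) over *connected* pairs instead
    (undefined → NaN when no pair is connected).
    """
    n = g.n_nodes
    if n < 2:
        raise ParameterError("need at least 2 nodes")
    if literal:
        d = _bfs_distances(g.adjacency)
        finite = np.isfinite(d) & ~np.eye(n, dtype=bool)
        if not finite.any():
            return float("nan")
        return float(1.0 / d[finite].mean())
    return _pairwise_inverse_distance_mean(g.adjacency)


def clustering_coefficient(g: BinaryGraph) -> float:
    """Mean over nodes of 2·triangles/(k(k−1)); degree < 2 contributes 0."""
    a = g.adjacency.astype(np.float64)
    k = a.sum(axis=1)
    tri = np.diag(a @ a @ a) / 2.0
    denom = k * (k - 1)
    cc = np.zeros_like(k)
    ok = denom > 0
    cc[ok] = 2.0 * tri[ok] / denom[ok]
    return float(cc.mean()) if len(cc) else float("nan")


def assortativity(g: BinaryGraph) -> float:
    """Pearson correlation of endpoint degrees over edges (both
    orientations); NaN when degree variance is zero."""
    a = g.adjacency
    if g.n_edges < 2:
        raise ParameterError("need at least 2 edges")
    k = a.sum(axis=1).astype(float)
    i, j = np.nonzero(np.triu(a))
    x = np.concatenate([k[i], k[j]])
    y = np.concatenate([k[j], k[i]])
    if x.std() == 0 or y.std() == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def local_efficiency(g: BinaryGraph) -> float:
    """Mean over nodes of the global efficiency of the neighbor-induced
    subgraph; nodes with < 2 neighbors contribute 0.

    All neighbor subgraphs are zero-padded into one (m, k_max, k_max)
    stack and distances found by batched boolean matrix powers, so the
    whole sparsity sweep stays a handful of BLAS calls.
    """
    a = g.adjacency
    n = g.n_nodes
    if n < 1:
        raise ParameterError("need at least 1 node")
    blocks, sizes = [], []
    for v in range(n):
        nbrs = np.nonzero(a[v])[0]
        if len(nbrs) < 2:
            continue
        blocks.append(a[np.ix_(nbrs, nbrs)])
        sizes.append(len(nbrs))
    if not blocks:
        return 0.0
    m = len(blocks)
    kmax = max(sizes)
    batch = np.zeros((m, kmax, kmax), dtype=np.float32)
    for b, blk in enumerate(blocks):
        batch[b, :blk.shape[0], :blk.shape[0]] = blk
    eye = np.eye(kmax, dtype=bool)
    reach = np.broadcast_to(eye, batch.shape).copy()
    frontier = reach.copy()
    inv_sum = np.zeros(m)   # Σ 1/d over ordered in-block pairs
    d = 1
    while True:
        nxt = (np.matmul(frontier.astype(np.float32), batch) > 0) & ~reach
        if not nxt.any():
            break
        inv_sum += nxt.sum(axis=(1, 2)) / d
        reach |= nxt
        frontier = nxt
        d += 1
    sizes = np.array(sizes, dtype=float)
    return float((inv_sum / (sizes * (sizes - 1.0))).sum() / n)


_METRIC_FUNCS = {
    "GE": global_efficiency,
    "CC": clustering_coefficient,
    "AC": assortativity,
    "LE": local_efficiency,
}


@dataclass
class TopologyCurve:
    metric: str
    sparsities: tuple[float, ...]
    values: np.ndarray
    auc: float


def topology_curve(weights: np.ndarray, metric: str,
                   sparsities=DEFAULT_SPARSITIES,
                   auc_method: str = "trapezoid") -> TopologyCurve:
    """Metric value at each sparsity level plus the area under the curve.

    AUC uses the trapezoidal rule over the sparsity axis by default;
    ``auc_method="left"`` gives step-width × sum of left values.  A
    single-level sweep reports AUC = 0.
    """
    if metric not in _METRIC_FUNCS:
        raise ParameterError(f"unknown metric {metric!r}; choose from {METRICS}")
    if auc_method not in ("trapezoid", "left"):
        raise ParameterError(f"unknown auc_method {auc_method!r}")
    sp = tuple(float(s) for s in sparsities)
    vals = np.array([_METRIC_FUNCS[metric](binarize(weights, s)) for s in sp])
    if len(sp) < 2:
        auc = 0.0
    elif auc_method == "trapezoid":
        auc = float(np.trapezoid(vals, sp))
    else:
        auc = float(np.sum(vals[:-1] * np.diff(sp)))
    return TopologyCurve(metric=metric, sparsities=sp, values=vals, auc=auc)


def auc_table(plv_by_subject: dict[str, dict], metrics=METRICS,
              sparsities=DEFAULT_SPARSITIES) -> pd.DataFrame:
    """AUC per subject × condition × band × metric.

    *plv_by_subject*: subject -> {(condition, band) -> weight matrix}.
    """
    rows = []
    for subj, mats in plv_by_subject.items():
        for (cond, band), w in mats.items():
            for metric in metrics:
                curve = topology_curve(w, metric, sparsities)
                rows.append({"subject": subj, "condition": cond, "band": band,
                             "metric": metric, "auc": curve.auc})
    return pd.DataFrame(rows)


def condition_contrast(aucs: pd.DataFrame) -> pd.DataFrame:
    """Paired feedback vs non-feedback test of AUCs per band × metric.

    Input columns: ``subject, condition, band, metric, auc``.  Output:
    means, SDs, paired t, p and both effect-size conventions.
    """
    required = {"subject", "condition", "band", "metric", "auc"}
    if not required <= set(aucs.columns):
        raise ParameterError(f"AUC table needs columns {sorted(required)}")
    rows = []
    for (band, metric), grp in aucs.groupby(["band", "metric"]):
        wide = grp.pivot_table(index="subject", columns="condition",
                               values="auc")
        if wide.isna().any().any() or \
                not {"peer_feedback", "non_feedback"} <= set(wide.columns):
            raise ParameterError(
                f"unpaired subjects for band={band}, metric={metric}")
        fb = wide["peer_feedback"].to_numpy()
        nf = wide["non_feedback"].to_numpy()
        c = behavior.paired_contrast(fb, nf)
        rows.append({"band": band, "metric": metric,
                     "mean_feedback": fb.mean(), "sd_feedback": fb.std(ddof=1),
                     "mean_non_feedback": nf.mean(),
                     "sd_non_feedback": nf.std(ddof=1),
                     "t": c.t, "df": c.df, "p": c.p, "d": c.d, "d_z": c.d_z})
    return pd.DataFrame(rows).set_index(["band", "metric"])
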