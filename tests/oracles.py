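"""Independent brute-force oracles used by the test suite.

Everything here is written from the textbook definitions (path
enumeration, triangle counting, step-up rule) with no reliance on the
package's implementations, so agreement is meaningful.
"""

from itertools import combinations

import numpy as np


def enumerate_shortest_paths(nodes, edges, s, t):
    """All shortest s→t paths by breadth-limited DFS path enumeration."""
    adj = {n: [] for n in nodes}
    for a, b in edges:
        adj[a].append(b)
    best, paths = None, []
    stack = [(s, (s,))]
    while stack:
        v, path = stack.pop()
        if best is not None and len(path) - 1 > best:
            continue
        if v == t:
            d = len(path) - 1
            if best is None or d < best:
                best, paths = d, [path]
            elif d == best:
                paths.append(path)
            continue
        for w in adj[v]:
            if w not in path:
                stack.append((w, path + (w,)))
    return paths


def brute_betweenness(nodes, edges):
    """Raw directed betweenness: sum over (s,t) of sigma_st(v)/sigma_st."""
    bc = {n: 0.0 for n in nodes}
    for s in nodes:
        for t in nodes:
            if s == t:
                continue
            paths = enumerate_shortest_paths(nodes, edges, s, t)
            if not paths:
                continue
            for v in nodes:
                if v in (s, t):
                    continue
                through = sum(v in p for p in paths)
                bc[v] += through / len(paths)
    return bc


def bfs_distances_dict(adj_matrix):
    """Unweighted all-pairs distances by plain dict/queue BFS."""
    n = adj_matrix.shape[0]
    dist = {}
    for s in range(n):
        d = {s: 0}
        queue = [s]
        while queue:
            v = queue.pop(0)
            for w in range(n):
                if adj_matrix[v, w] and w not in d:
                    d[w] = d[v] + 1
                    queue.append(w)
        dist[s] = d
    return dist


def global_efficiency_oracle(adj_matrix):
    n = adj_matrix.shape[0]
    dist = bfs_distances_dict(adj_matrix)
    total = 0.0
    for s in range(n):
        for t in range(n):
            if s != t and t in dist[s]:
                total += 1.0 / dist[s][t]
    return total / (n * (n - 1))


def clustering_oracle(adj_matrix):
    n = adj_matrix.shape[0]
    vals = []
    for v in range(n):
        nbrs = [w for w in range(n) if adj_matrix[v, w]]
        k = len(nbrs)
        if k < 2:
            vals.append(0.0)
            continue
        links = sum(1 for a, b in combinations(nbrs, 2) if adj_matrix[a, b])
        vals.append(2.0 * links / (k * (k - 1)))
    return float(np.mean(vals))


def assortativity_oracle(adj_matrix):
    n = adj_matrix.shape[0]
    deg = adj_matrix.sum(axis=1)
    x, y = [], []
    for a in range(n):
        for b in range(a + 1, n):
            if adj_matrix[a, b]:
                x += [deg[a], deg[b]]
                y += [deg[b], deg[a]]
    if len(x) < 4 or np.std(x) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def local_efficiency_oracle(adj_matrix):
    n = adj_matrix.shape[0]
    vals = []
    for v in range(n):
        nbrs = [w for w in range(n) if adj_matrix[v, w]]
        if len(nbrs) < 2:
            vals.append(0.0)
            continue
        sub = adj_matrix[np.ix_(nbrs, nbrs)]
        vals.append(global_efficiency_oracle(sub))
    return float(np.mean(vals))


def bh_stepup_oracle(pvals):
    """Adjusted p by the literal step-up definition:
    p_adj(i) = min_{j >= rank(i)} ( p(j) * m / j ), capped at 1."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


def plv_pooled_oracle(phases):
    """PLV by explicit per-sample complex-mean loops (trials, C, S)."""
    n_tr, n_ch, n_s = phases.shape
    plv = np.zeros((n_ch, n_ch))
    for i in range(n_ch):
        for j in range(n_ch):
            acc = 0.0 + 0.0j
            for tr in range(n_tr):
                for s in range(n_s):
                    acc += np.exp(1j * (phases[tr, i, s] - phases[tr, j, s]))
            plv[i, j] = abs(acc / (n_tr * n_s))
    return plv


def grid_neighbors(rows, cols):
    """4-connected grid channel adjacency (rows*cols channels)."""
    n = rows * cols
    nb = np.zeros((n, n), dtype=bool)
    for r in range(rows):
        for c in range(cols):
            i = r * cols + c
            for dr, dc in ((0, 1), (1, 0)):
                rr, cc = r + dr, c + dc
                if rr < rows and cc < cols:
                    j = rr * cols + cc
                    nb[i, j] = nb[j, i] = True
    return nb
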