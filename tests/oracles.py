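"""Independent brute-force implementations of every topological measure.

These are written from the definitions (BFS distance tables, shortest-path
counting, iterative peeling, dense eigendecomposition, power iteration) and
deliberately share no code with the package's networkx-backed encoders.
"""

from __future__ import annotations

from collections import deque

import numpy as np


def adjacency(n: int, edges) -> np.ndarray:
    a = np.zeros((n, n))
    for u, v in edges:
        a[u, v] = a[v, u] = 1.0
    return a


def bfs_distances(n: int, edges, source: int) -> dict[int, int]:
    adj = [[] for _ in range(n)]
    for u, v in edges:
        adj[u].append(v)
        adj[v].append(u)
    dist = {source: 0}
    q = deque([source])
    while q:
        cur = q.popleft()
        for nb in adj[cur]:
            if nb not in dist:
                dist[nb] = dist[cur] + 1
                q.append(nb)
    return dist


def shortest_path_counts(n: int, edges, source: int):
    """(distances, number-of-shortest-paths) from source, by BFS DP."""
    dist = bfs_distances(n, edges, source)
    sigma = {v: 0.0 for v in range(n)}
    sigma[source] = 1.0
    order = sorted(dist, key=dist.get)
    adj = [[] for _ in range(n)]
    for u, v in edges:
        adj[u].append(v)
        adj[v].append(u)
    for v in order:
        for nb in adj[v]:
            if nb in dist and dist[nb] == dist[v] + 1:
                sigma[nb] += sigma[v]
    return dist, sigma


def degree(n, edges):
    d = np.zeros(n)
    for u, v in edges:
        d[u] += 1
        d[v] += 1
    return d


def closeness(n, edges):
    """Wasserman-Faust component-scaled closeness."""
    out = np.zeros(n)
    for u in range(n):
        dist = bfs_distances(n, edges, u)
        r = len(dist)
        s = sum(dist.values())
        if s > 0 and n > 1:
            out[u] = ((r - 1) / (n - 1)) * ((r - 1) / s)
    return out


def betweenness(n, edges):
    """Node betweenness, normalized by (n-1)(n-2)/2 (undirected)."""
    out = np.zeros(n)
    if n < 3:
        return out
    for s in range(n):
        ds, sig_s = shortest_path_counts(n, edges, s)
        for t in range(s + 1, n):
            if t not in ds or sig_s[t] == 0:
                continue
            dt, sig_t = shortest_path_counts(n, edges, t)
            for v in range(n):
                if v in (s, t) or v not in ds or v not in dt:
                    continue
                if ds[v] + dt[v] == ds[t]:
                    out[v] += sig_s[v] * sig_t[v] / sig_s[t]
    return out / ((n - 1) * (n - 2) / 2.0)


def edge_betweenness(n, edges):
    """Edge betweenness per undirected edge, normalized by n(n-1)/2."""
    out = {tuple(sorted(e)): 0.0 for e in edges}
    for s in range(n):
        ds, sig_s = shortest_path_counts(n, edges, s)
        for t in range(s + 1, n):
            if t not in ds or sig_s[t] == 0:
                continue
            dt, sig_t = shortest_path_counts(n, edges, t)
            for a, b in out:
                cnt = 0.0
                for x, y in ((a, b), (b, a)):
                    if x in ds and y in dt and ds[x] + 1 + dt[y] == ds[t]:
                        cnt += sig_s[x] * sig_t[y]
                out[(a, b)] += cnt / sig_s[t]
    return {e: v / (n * (n - 1) / 2.0) for e, v in out.items()}


def eigenvector_centrality(n, edges):
    """Perron vector of the adjacency matrix, L2-normalized (dense solve)."""
    a = adjacency(n, edges)
    w, v = np.linalg.eigh(a)
    vec = v[:, int(np.argmax(w))]
    if vec.sum() < 0:
        vec = -vec
    return np.abs(vec) / np.linalg.norm(vec)


def pagerank(n, edges, alpha=0.85, iters=2000):
    """Power iteration from the definition, dangling mass redistributed."""
    a = adjacency(n, edges)
    deg_ = a.sum(axis=1)
    p = np.full(n, 1.0 / n)
    for _ in range(iters):
        dangling = p[deg_ == 0].sum()
        contrib = np.zeros(n)
        nz = deg_ > 0
        contrib = (a[nz].T / deg_[nz]) @ p[nz]
        p_new = (1 - alpha) / n + alpha * (contrib + dangling / n)
        if np.abs(p_new - p).sum() < 1e-15:
            p = p_new
            break
        p = p_new
    return p


def clustering(n, edges):
    a = adjacency(n, edges)
    d = a.sum(axis=1)
    tri = np.diag(a @ a @ a) / 2.0
    out = np.zeros(n)
    mask = d >= 2
    out[mask] = 2.0 * tri[mask] / (d[mask] * (d[mask] - 1))
    return out


def k_core(n, edges):
    """Iterative peeling from the definition of the k-core."""
    adj = {v: set() for v in range(n)}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    core = np.zeros(n, dtype=int)
    alive = set(range(n))
    k = 0
    while alive:
        while True:
            peel = [v for v in alive if len(adj[v] & alive) < k + 1]
            if not peel:
                break
            for v in peel:
                core[v] = k
                alive.discard(v)
        k += 1
        for v in alive:
            core[v] = k
    return core


def harmonic(n, edges):
    out = np.zeros(n)
    for u in range(n):
        dist = bfs_distances(n, edges, u)
        out[u] = sum(1.0 / d for v, d in dist.items() if v != u)
    return out


def eccentricity(n, edges):
    out = np.zeros(n)
    for u in range(n):
        dist = bfs_distances(n, edges, u)
        out[u] = max(dist.values())
    return out


def jaccard(n, edges, u, v):
    nb = lambda x: {b for a, b in edges if a == x} | {a for a, b in edges if b == x}
    nu, nv = nb(u), nb(v)
    union = nu | nv
    return len(nu & nv) / len(union) if union else 0.0


def adamic_adar(n, edges, u, v):
    d = degree(n, edges)
    nb = lambda x: {b for a, b in edges if a == x} | {a for a, b in edges if b == x}
    return sum(1.0 / np.log(d[w]) for w in nb(u) & nb(v))


def preferential_attachment(n, edges, u, v):
    d = degree(n, edges)
    return d[u] * d[v]
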