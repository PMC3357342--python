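"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written from the definitions, deliberately avoiding the
package's own code paths (no shared helpers, no vectorized shortcuts), so a
test comparing the two is a genuine dual-route check.
"""

from __future__ import annotations

from typing import Dict, List, Sequence, Set, Tuple

import numpy as np


def es_walk(
    genes: Sequence[str],
    scores: Sequence[float],
    members: Set[str],
    weight: float,
) -> Tuple[float, int, List[float]]:
    """Naive O(N) running-sum walk; returns (ES, 1-based peak, full path)."""
    N = len(genes)
    hit = [g in members for g in genes]
    n_hit = sum(hit)
    assert 0 < n_hit < N
    total_w = sum(abs(s) ** weight for s, h in zip(scores, hit) if h)
    run = 0.0
    path: List[float] = []
    for s, h in zip(scores, hit):
        if h:
            if total_w == 0:
                run += 1.0 / n_hit
            else:
                run += abs(s) ** weight / total_w
        else:
            run -= 1.0 / (N - n_hit)
        path.append(run)
    best = 0
    for i in range(1, N):
        if abs(path[i]) > abs(path[best]):
            best = i
    return path[best], best + 1, path


def quantile_normalize_matrix(X: np.ndarray) -> np.ndarray:
    """Mean-of-order-statistics quantile normalization with tie averaging."""
    n, k = X.shape
    ref = np.zeros(n)
    for j in range(k):
        ref += np.sort(X[:, j])
    ref /= k
    out = np.zeros_like(X, dtype=float)
    for j in range(k):
        col = X[:, j]
        order = sorted(range(n), key=lambda i: col[i])
        # group tied values and share the mean of their rank-slot means
        i = 0
        while i < n:
            j2 = i
            while j2 + 1 < n and col[order[j2 + 1]] == col[order[i]]:
                j2 += 1
            block = np.mean([ref[t] for t in range(i, j2 + 1)])
            for t in range(i, j2 + 1):
                out[order[t], j] = block
            i = j2 + 1
    return out


def moderated_t_stats(
    X: np.ndarray, Y: np.ndarray, nu0: float, w: int
) -> Tuple[np.ndarray, np.ndarray]:
    """Loop-based recomputation of the moderated t and its posterior variance."""
    n1, n2 = X.shape[1], Y.shape[1]
    m = X.shape[0]
    s2p = np.empty(m)
    means = np.empty(m)
    delta = np.empty(m)
    for i in range(m):
        v1 = np.var(X[i], ddof=1)
        v2 = np.var(Y[i], ddof=1)
        s2p[i] = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        means[i] = np.mean(np.concatenate([X[i], Y[i]]))
        delta[i] = X[i].mean() - Y[i].mean()
    w = min(w, m)
    order = sorted(range(m), key=lambda i: means[i])
    rank_of = {idx: r for r, idx in enumerate(order)}
    t = np.empty(m)
    s2_post = np.empty(m)
    for i in range(m):
        r = rank_of[i]
        start = min(max(r - w // 2, 0), m - w)
        window = [order[j] for j in range(start, start + w)]
        s0sq = np.mean([s2p[j] for j in window])
        s2_post[i] = (nu0 * s0sq + (n1 + n2 - 2) * s2p[i]) / (nu0 + n1 + n2 - 2)
        t[i] = delta[i] / np.sqrt(s2_post[i] * (1 / n1 + 1 / n2))
    return t, s2_post


def bh_stepup(p: Sequence[float]) -> List[float]:
    """Hand application of the BH step-up rule: q_i = min_{p_j>=p_i} p_j*m/rank_j."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        q[i] = running
    return q


class UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb


def component_count(nodes: Sequence[str], edges: Sequence[Tuple[str, str]]) -> int:
    uf = UnionFind(nodes)
    for a, b in edges:
        uf.union(a, b)
    return len({uf.find(n) for n in nodes})


def enumerate_links(
    de_mirnas: Dict[str, str],          # mirna -> 'up' | 'down'
    targets: Dict[str, Set[str]],       # mirna -> target genes
    modules: Dict[str, Dict[str, str]], # module -> {gene: 'up'|'down'} (leading edge)
) -> Dict[Tuple[str, str], Set[str]]:
    """Exhaustive enumeration of (miRNA, module, gene) triples satisfying
    target AND leading-edge AND opposite-direction."""
    out: Dict[Tuple[str, str], Set[str]] = {}
    for mirna, mdir in de_mirnas.items():
        for module, gene_dirs in modules.items():
            genes = set()
            for gene, gdir in gene_dirs.items():
                if gene in targets.get(mirna, set()) and gdir != mdir:
                    genes.add(gene)
            if genes:
                out[(mirna, module)] = genes
    return out
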