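"""Gene set enrichment analysis with leading-edge extraction and module merging.

The enrichment statistic is the weighted Kolmogorov-Smirnov running sum:
walking down the list of genes ranked by a differential-expression metric,
the sum increases by |score|^p / sum_hits |score|^p at each gene-set member
("hit") and decreases by 1/(N - N_hit) at each non-member ("miss").  The
enrichment score (ES) is the deviation of maximal magnitude; a positive ES
means the set concentrates among genes up in the exposure group.  The null
distribution comes from rescoring randomly drawn gene sets of matched size
against the fixed ranked list (gene-set permutation); phenotype permutation
(relabelling samples) is available as an option.  NES normalizes ES by the
mean magnitude of same-sign null scores; FDR Q-values come from the pooled
null NES distribution per sign stratum.

The leading edge of a set is the subset of members at or before (positive
ES) / at or after (negative ES) the running-sum peak — the genes actually
driving the enrichment.  Significant sets with overlapping leading edges
and consistent direction can be merged into functional modules, either via
an explicit user mapping or automatically by leading-edge Jaccard overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import (
    Dict,
    FrozenSet,
    Iterable,
    List,
    Mapping,
    Optional,
    Sequence,
    Set,
    Tuple,
)

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, GeneSetCollection, GroupDesign

__all__ = [
    "RankedList",
    "EnrichmentScore",
    "EnrichmentResult",
    "ModuleResult",
    "rank_genes",
    "enrichment_score",
    "geneset_permutation_null",
    "nes_and_fdr",
    "leading_edge",
    "merge_modules",
    "GeneSetEnrichment",
    "EnrichmentResults",
]

UP_IN_EXPOSURE = "up_in_exposure"
DOWN_IN_EXPOSURE = "down_in_exposure"


@dataclass(frozen=True)
class RankedList:
    """Genes ordered best-to-worst for the exposure group with their scores.

    Scores are descending; ties are broken by gene ID ascending so the order
    is deterministic.  Positions are 1-based throughout the enrichment code.
    """

    genes: Tuple[str, ...]
    scores: np.ndarray

    def __post_init__(self):
        if len(self.genes) != len(self.scores):
            raise ValueError("genes and scores length mismatch")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("ranked list contains duplicate genes")
        if np.any(np.diff(self.scores) > 0):
            raise ValueError("scores must be non-increasing")
        object.__setattr__(self, "scores", np.asarray(self.scores, dtype=float))
        object.__setattr__(
            self, "_pos", {g: i + 1 for i, g in enumerate(self.genes)}
        )

    def __len__(self) -> int:
        return len(self.genes)

    def position(self, gene: str) -> int:
        """1-based rank of a gene."""
        return self._pos[gene]

    def __contains__(self, gene: str) -> bool:
        return gene in self._pos

    def score_of(self, gene: str) -> float:
        return float(self.scores[self._pos[gene] - 1])


def _snr_scores(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """GSEA signal-to-noise with the standard variance floor."""
    m1, m2 = X.mean(axis=1), Y.mean(axis=1)
    s1, s2 = X.std(axis=1, ddof=1), Y.std(axis=1, ddof=1)
    s1 = np.maximum(s1, np.maximum(0.2 * np.abs(m1), 0.2))
    s2 = np.maximum(s2, np.maximum(0.2 * np.abs(m2), 0.2))
    return (m1 - m2) / (s1 + s2)


def rank_genes(
    m: ExpressionMatrix,
    d: GroupDesign,
    metric: str = "signal_to_noise",
) -> RankedList:
    """Rank genes by a two-group differential metric, best-for-exposure first.

    Metrics: ``signal_to_noise`` (default; difference of group means over the
    sum of floored group standard deviations), ``t_stat`` (ordinary pooled
    t), ``log_fold`` (difference of log2 group means).
    """
    exp = [s for s in m.sample_ids if d.assignment.get(s) == "exposure"]
    ctl = [s for s in m.sample_ids if d.assignment.get(s) == "control"]
    if metric in ("signal_to_noise", "t_stat") and (len(exp) < 2 or len(ctl) < 2):
        raise ValueError(f"metric {metric!r} needs >=2 samples per group")
    if not exp or not ctl:
        raise ValueError("both groups must be represented among the samples")
    X = m.values[exp].to_numpy()
    Y = m.values[ctl].to_numpy()
    if metric == "signal_to_noise":
        scores = _snr_scores(X, Y)
    elif metric == "t_stat":
        n1, n2 = X.shape[1], Y.shape[1]
        sp2 = ((n1 - 1) * X.var(axis=1, ddof=1) + (n2 - 1) * Y.var(axis=1, ddof=1)) / (
            n1 + n2 - 2
        )
        se = np.sqrt(sp2 * (1 / n1 + 1 / n2))
        with np.errstate(divide="ignore", invalid="ignore"):
            scores = np.where(se > 0, (X.mean(1) - Y.mean(1)) / se, 0.0)
    elif metric == "log_fold":
        scores = X.mean(axis=1) - Y.mean(axis=1)
    else:
        raise ValueError(f"unknown ranking metric {metric!r}")
    order = sorted(range(len(scores)), key=lambda i: (-scores[i], m.feature_ids[i]))
    genes = tuple(m.feature_ids[i] for i in order)
    return RankedList(genes, scores[np.array(order)])


# ---------------------------------------------------------------------------
# enrichment score
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EnrichmentScore:
    es: float
    peak_index: int  # 1-based position of the running-sum extremum
    running_sum: np.ndarray


def _hit_weights(scores_at_hits: np.ndarray, weight: float) -> np.ndarray:
    w = np.abs(scores_at_hits) ** weight
    total = w.sum()
    if total == 0:
        # degenerate all-zero hit scores: fall back to uniform hit mass
        return np.full(len(w), 1.0 / len(w))
    return w / total


def enrichment_score(
    r: RankedList, members: Iterable[str], weight: float = 1.0
) -> EnrichmentScore:
    """Weighted-KS enrichment score of a gene set against a ranked list.

    The set is intersected with the list first; the intersection must be
    non-empty and proper (otherwise the miss increment is undefined).
    Returns the signed ES, the 1-based peak position (first occurrence on
    ties of the maximal deviation), and the full running sum.
    """
    N = len(r)
    hit_pos = sorted(r.position(g) for g in set(members) if g in r)
    k = len(hit_pos)
    if k == 0:
        raise ValueError("gene set does not intersect the ranked list")
    if k == N:
        raise ValueError("gene set covers the whole ranked list; ES undefined")
    inc = np.full(N, -1.0 / (N - k))
    hits = np.asarray(hit_pos) - 1
    inc[hits] = _hit_weights(r.scores[hits], weight)
    running = np.cumsum(inc)
    peak = int(np.argmax(np.abs(running)))  # first occurrence of the max |dev|
    es = float(np.clip(running[peak], -1.0, 1.0))  # guard accumulation round-off
    return EnrichmentScore(es, peak + 1, running)


def _es_from_positions(
    pos: np.ndarray, score_abs_w: np.ndarray, N: int
) -> np.ndarray:
    """Vectorized ES for many candidate sets given sorted 1-based hit positions.

    ``pos`` is (n_sets, k) ascending; ``score_abs_w`` are |score|^p values of
    the whole ranked list.  The running sum is piecewise linear between hits,
    so its extrema occur immediately after a hit (maximum candidates) or
    immediately before one (minimum candidates); the walk over all N
    positions is never materialized.
    """
    n_sets, k = pos.shape
    w = score_abs_w[pos - 1]
    W = w.sum(axis=1, keepdims=True)
    zero = (W == 0).ravel()
    if zero.any():
        w[zero] = 1.0
        W = w.sum(axis=1, keepdims=True)
    cumw = np.cumsum(w, axis=1)
    j = np.arange(1, k + 1)
    miss_term = (pos - j) / (N - k)
    val_after = cumw / W - miss_term
    val_before = val_after - w / W
    jmax = np.argmax(val_after, axis=1)
    jmin = np.argmin(val_before, axis=1)
    rows = np.arange(n_sets)
    best_pos_val = val_after[rows, jmax]
    best_neg_val = val_before[rows, jmin]
    pos_at_max = pos[rows, jmax]
    pos_at_min = pos[rows, jmin] - 1
    take_pos = (np.abs(best_pos_val) > np.abs(best_neg_val)) | (
        (np.abs(best_pos_val) == np.abs(best_neg_val)) & (pos_at_max < pos_at_min)
    )
    return np.clip(np.where(take_pos, best_pos_val, best_neg_val), -1.0, 1.0)


def geneset_permutation_null(
    r: RankedList,
    set_size: int,
    n_perm: int = 2000,
    seed: int | np.random.Generator | None = None,
    weight: float = 1.0,
) -> np.ndarray:
    """Null ES sample from uniformly drawn gene sets of the given size."""
    N = len(r)
    if not (0 < set_size < N):
        raise ValueError(f"set_size must be in (0, {N}), got {set_size}")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    u = rng.random((n_perm, N))
    idx = np.argpartition(u, set_size, axis=1)[:, :set_size]
    pos = np.sort(idx, axis=1) + 1
    score_abs_w = np.abs(r.scores) ** weight
    return _es_from_positions(pos, score_abs_w, N)


# ---------------------------------------------------------------------------
# NES / FDR
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentResult:
    """Per-set enrichment outcome; NES/p/Q filled by :func:`nes_and_fdr`."""

    set_name: str
    es: float
    peak_index: int
    leading_edge: Tuple[str, ...]
    size: int  # post-intersection member count
    nes: float = float("nan")
    p_value: float = 1.0
    q_value: float = 1.0

    @property
    def direction(self) -> str:
        return UP_IN_EXPOSURE if self.es >= 0 else DOWN_IN_EXPOSURE


def nes_and_fdr(
    observed: Sequence[EnrichmentResult],
    nulls: Mapping[str, np.ndarray],
) -> List[EnrichmentResult]:
    """Fill NES, permutation p and pooled-null FDR Q on the observed results.

    NES = ES / mean(|null ES| of the same sign); p uses add-one smoothing
    over same-sign nulls; Q compares, within each sign stratum, the fraction
    of pooled null NES at least as extreme with the fraction of observed NES
    at least as extreme, clipped to [0,1] and monotonized so Q never
    decreases as |NES| shrinks.
    """
    for r in observed:
        null = nulls.get(r.set_name)
        if null is None or len(null) == 0:
            raise ValueError(f"no null ES sample for set {r.set_name!r}")
    pooled_pos: List[np.ndarray] = []
    pooled_neg: List[np.ndarray] = []
    for r in observed:
        null = np.asarray(nulls[r.set_name], dtype=float)
        pos = null[null > 0]
        neg = null[null < 0]
        if len(pos):
            pooled_pos.append(pos / pos.mean())
        if len(neg):
            pooled_neg.append(neg / np.abs(neg).mean())
        if r.es >= 0:
            if len(pos) == 0:
                r.nes, r.p_value = float("nan"), 1.0
            else:
                r.nes = float(r.es / pos.mean())
                r.p_value = float((1 + (pos >= r.es).sum()) / (1 + len(pos)))
        else:
            if len(neg) == 0:
                r.nes, r.p_value = float("nan"), 1.0
            else:
                r.nes = float(r.es / np.abs(neg).mean())
                r.p_value = float((1 + (neg <= r.es).sum()) / (1 + len(neg)))
    pool_pos = np.concatenate(pooled_pos) if pooled_pos else np.empty(0)
    pool_neg = np.concatenate(pooled_neg) if pooled_neg else np.empty(0)

    for stratum, pool in ((1, pool_pos), (-1, pool_neg)):
        sub = [
            r
            for r in observed
            if np.isfinite(r.nes) and (r.es >= 0 if stratum == 1 else r.es < 0)
        ]
        if not sub:
            continue
        obs_mag = np.array([abs(r.nes) for r in sub])
        pool_mag = np.abs(pool)
        for r in sub:
            m = abs(r.nes)
            num = float((pool_mag >= m).mean()) if len(pool_mag) else 1.0
            den = float((obs_mag >= m).mean())
            r.q_value = float(min(max(num / den, 0.0), 1.0))
        # monotonize: Q non-increasing in |NES| within the stratum
        for_rank = sorted(sub, key=lambda r: -abs(r.nes))
        running = 1.0
        for r in reversed(for_rank):  # smallest |NES| first: running minimum
            running = min(running, r.q_value)
            r.q_value = running
    return list(observed)


# ---------------------------------------------------------------------------
# leading edge & modules
# ---------------------------------------------------------------------------

def leading_edge(
    r: RankedList, members: Iterable[str], es: float, peak_index: int
) -> Tuple[str, ...]:
    """Members at/before (ES>0) or at/after (ES<0) the peak, in rank order."""
    if es == 0:
        raise ValueError("leading edge undefined for ES = 0")
    pos = sorted((r.position(g), g) for g in set(members) if g in r)
    if es > 0:
        picked = [g for p, g in pos if p <= peak_index]
    else:
        picked = [g for p, g in pos if p >= peak_index]
    return tuple(picked)


@dataclass(frozen=True)
class ModuleResult:
    """A merged functional module: member sets, pooled leading edge, directions."""

    module_name: str
    member_sets: Tuple[str, ...]
    leading_edge: Tuple[str, ...]  # union, ordered by rank
    gene_directions: Mapping[str, str]  # gene -> 'up' | 'down'
    direction: str = UP_IN_EXPOSURE

    def __post_init__(self):
        if not self.leading_edge:
            raise ValueError(f"module {self.module_name!r} has empty leading edge")
        object.__setattr__(self, "gene_directions", dict(self.gene_directions))


def _module_from_sets(
    name: str, members: List[EnrichmentResult], ranked: RankedList
) -> ModuleResult:
    directions = {r.direction for r in members}
    if len(directions) > 1:
        raise ValueError(
            f"cannot merge sets of opposite enrichment direction into {name!r}: "
            f"{sorted(r.set_name for r in members)}"
        )
    union: Set[str] = set()
    for r in members:
        union.update(r.leading_edge)
    ordered = tuple(sorted(union, key=lambda g: ranked.position(g)))
    gene_dir = {
        g: ("up" if ranked.score_of(g) >= 0 else "down") for g in ordered
    }
    return ModuleResult(
        module_name=name,
        member_sets=tuple(sorted(r.set_name for r in members)),
        leading_edge=ordered,
        gene_directions=gene_dir,
        direction=directions.pop(),
    )


def merge_modules(
    results: Sequence[EnrichmentResult],
    ranked: RankedList,
    merge_spec: Optional[Mapping[str, str]] = None,
    q_threshold: float = 0.05,
    auto: bool = False,
    jaccard_threshold: float = 0.5,
) -> List[ModuleResult]:
    """Combine significant, same-direction gene sets into functional modules.

    With an explicit ``merge_spec`` (set name -> module name) the caller
    states which functionally similar sets belong together; unnamed
    significant sets each become their own module.  In ``auto`` mode sets
    whose leading edges overlap at Jaccard >= ``jaccard_threshold`` (and
    share direction) are merged transitively.  Merging sets of opposite
    direction via an explicit spec is an error.
    """
    sig = [r for r in results if r.q_value <= q_threshold and r.es != 0]
    modules: List[ModuleResult] = []
    if auto:
        parent = {r.set_name: r.set_name for r in sig}

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for i, a in enumerate(sig):
            for b in sig[i + 1 :]:
                if a.direction != b.direction:
                    continue
                sa, sb = set(a.leading_edge), set(b.leading_edge)
                jac = len(sa & sb) / len(sa | sb)
                if jac >= jaccard_threshold:
                    parent[find(a.set_name)] = find(b.set_name)
        groups: Dict[str, List[EnrichmentResult]] = {}
        for r in sig:
            groups.setdefault(find(r.set_name), []).append(r)
        for members in groups.values():
            name = "+".join(sorted(m.set_name for m in members))
            modules.append(_module_from_sets(name, members, ranked))
    else:
        spec = dict(merge_spec or {})
        groups = {}
        for r in sig:
            groups.setdefault(spec.get(r.set_name, r.set_name), []).append(r)
        for name, members in groups.items():
            modules.append(_module_from_sets(name, members, ranked))
    modules.sort(key=lambda m: m.module_name)
    return modules


# ---------------------------------------------------------------------------
# model / results interface
# ---------------------------------------------------------------------------

class GeneSetEnrichment:
    """Gene set enrichment model over a two-group expression contrast.

    Parameters
    ----------
    matrix : gene-level expression matrix (log2 scale)
    design : exposure/control sample assignment
    gene_sets : collection to test
    metric : ranking metric (see :func:`rank_genes`)
    weight : running-sum hit-weight exponent p (1.0 = standard weighted KS)
    n_perm : permutations for the null (2000 by default)
    min_size, max_size : post-intersection set-size bounds
    permutation : 'gene_set' (default) or 'phenotype'
    seed : RNG seed for the permutation null
    """

    def __init__(
        self,
        matrix: ExpressionMatrix,
        design: GroupDesign,
        gene_sets: GeneSetCollection,
        metric: str = "signal_to_noise",
        weight: float = 1.0,
        n_perm: int = 2000,
        min_size: int = 5,
        max_size: int = 500,
        permutation: str = "gene_set",
        seed: Optional[int] = None,
    ):
        if permutation not in ("gene_set", "phenotype"):
            raise ValueError(f"unknown permutation mode {permutation!r}")
        self.matrix = matrix
        self.design = design
        self.gene_sets = gene_sets
        self.metric = metric
        self.weight = weight
        self.n_perm = n_perm
        self.min_size = min_size
        self.max_size = max_size
        self.permutation = permutation
        self.seed = seed

    def fit(self) -> "EnrichmentResults":
        ranked = rank_genes(self.matrix, self.design, self.metric)
        N = len(ranked)
        observed: List[EnrichmentResult] = []
        kept_sizes: Dict[str, int] = {}
        for gs in self.gene_sets:
            inter = [g for g in gs.members if g in ranked]
            k = len(inter)
            if k < self.min_size or k > self.max_size or k >= N:
                continue
            sc = enrichment_score(ranked, inter, self.weight)
            le = (
                leading_edge(ranked, inter, sc.es, sc.peak_index)
                if sc.es != 0
                else tuple()
            )
            observed.append(
                EnrichmentResult(gs.name, sc.es, sc.peak_index, le, k)
            )
            kept_sizes[gs.name] = k
        if self.permutation == "gene_set":
            nulls = self._geneset_nulls(ranked, kept_sizes)
        else:
            nulls = self._phenotype_nulls(observed)
        if observed:
            nes_and_fdr(observed, nulls)
        observed.sort(key=lambda r: (r.p_value, r.set_name))
        return EnrichmentResults(self, ranked, observed)

    def _geneset_nulls(
        self, ranked: RankedList, kept_sizes: Dict[str, int]
    ) -> Dict[str, np.ndarray]:
        rng = np.random.default_rng(self.seed)
        by_size: Dict[int, np.ndarray] = {}
        for k in sorted(set(kept_sizes.values())):
            by_size[k] = geneset_permutation_null(
                ranked, k, self.n_perm, rng, self.weight
            )
        return {name: by_size[k] for name, k in kept_sizes.items()}

    def _phenotype_nulls(
        self, observed: Sequence[EnrichmentResult]
    ) -> Dict[str, np.ndarray]:
        rng = np.random.default_rng(self.seed)
        samples = self.matrix.sample_ids
        n_exp = len(
            [s for s in samples if self.design.assignment.get(s) == "exposure"]
        )
        members_of = {
            gs.name: gs.members for gs in self.gene_sets if gs.name in
            {r.set_name for r in observed}
        }
        nulls: Dict[str, List[float]] = {r.set_name: [] for r in observed}
        for _ in range(self.n_perm):
            perm = list(samples)
            rng.shuffle(perm)
            d = GroupDesign.from_samples(perm[:n_exp], perm[n_exp:])
            ranked = rank_genes(self.matrix, d, self.metric)
            for name, members in members_of.items():
                sc = enrichment_score(ranked, members, self.weight)
                nulls[name].append(sc.es)
        return {name: np.asarray(v) for name, v in nulls.items()}


class EnrichmentResults:
    """Fitted enrichment results plus the ranked list they were scored on."""

    def __init__(
        self,
        model: GeneSetEnrichment,
        ranked: RankedList,
        results: List[EnrichmentResult],
    ):
        self.model = model
        self.ranked = ranked
        self.results = results

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "set": [r.set_name for r in self.results],
                "ES": [r.es for r in self.results],
                "NES": [r.nes for r in self.results],
                "p": [r.p_value for r in self.results],
                "Q": [r.q_value for r in self.results],
                "size": [r.size for r in self.results],
                "leading_edge": [";".join(r.leading_edge) for r in self.results],
            }
        ).set_index("set")

    def significant(self, q: float = 0.05) -> List[EnrichmentResult]:
        return [r for r in self.results if r.q_value <= q]

    def merge_modules(
        self,
        merge_spec: Optional[Mapping[str, str]] = None,
        q_threshold: float = 0.05,
        auto: bool = False,
        jaccard_threshold: float = 0.5,
    ) -> List[ModuleResult]:
        return merge_modules(
            self.results,
            self.ranked,
            merge_spec=merge_spec,
            q_threshold=q_threshold,
            auto=auto,
            jaccard_threshold=jaccard_threshold,
        )

    def summary(self, q: float = 0.05) -> str:
        sig = self.significant(q)
        n_up = sum(1 for r in sig if r.es >= 0)
        lines = [
            "Gene set enrichment analysis",
            "============================",
            f"ranked genes:          {len(self.ranked)}",
            f"sets tested:           {len(self.results)}",
            f"permutations:          {self.model.n_perm} ({self.model.permutation})",
            f"metric / weight:       {self.model.metric} / p={self.model.weight}",
            f"significant at Q<={q}: {len(sig)} ({n_up} up, {len(sig) - n_up} down)",
            "",
        ]
        head = self.frame().drop(columns="leading_edge").head(10)
        lines.append(head.to_string(float_format=lambda x: f"{x:.4g}"))
        return "\n".join(lines)
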