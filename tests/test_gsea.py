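"""Enrichment score, permutation null, NES/FDR, leading edge, module merging."""

import numpy as np
import pytest
from scipy import stats

from mirlink.containers import GeneSet, GeneSetCollection
from mirlink.gsea import (
    EnrichmentResult,
    GeneSetEnrichment,
    RankedList,
    enrichment_score,
    geneset_permutation_null,
    leading_edge,
    merge_modules,
    nes_and_fdr,
    rank_genes,
)
from conftest import make_matrix
import oracles


def _ranked(n, seed=0, scores=None):
    genes = tuple(f"G{i:03d}" for i in range(n))
    if scores is None:
        rng = np.random.default_rng(seed)
        scores = np.sort(rng.normal(0, 1, n))[::-1]
    return RankedList(genes, np.asarray(scores, dtype=float))


class TestRankGenes:
    def test_shifted_gene_ranks_first(self, design2):
        m = make_matrix(
            [[10.0, 10.0, 8.0, 8.0], [8.0, 8.0, 8.0, 8.0]],
            samples=["e1", "e2", "c1", "c2"],
        )
        r = rank_genes(m, design2)
        assert r.genes[0] == "F0"

    def test_swapping_groups_negates_and_reverses(self, design8):
        rng = np.random.default_rng(4)
        samples = design8.exposure_samples + design8.control_samples
        m = make_matrix(rng.normal(8, 1, (30, 16)), samples=samples)
        r1 = rank_genes(m, design8)
        r2 = rank_genes(m, design8.swap())
        s1 = {g: r1.score_of(g) for g in r1.genes}
        for g in r2.genes:
            assert r2.score_of(g) == pytest.approx(-s1[g])
        assert list(r2.genes) == list(reversed(r1.genes))

    def test_matches_floored_signal_to_noise_formula(self, design2):
        rng = np.random.default_rng(10)
        X = rng.normal(8, 1, (10, 2))
        Y = rng.normal(8, 1, (10, 2))
        m = make_matrix(np.column_stack([X, Y]), samples=["e1", "e2", "c1", "c2"])
        r = rank_genes(m, design2)
        expected = {}
        for i in range(10):
            m1, m2 = X[i].mean(), Y[i].mean()
            s1 = max(X[i].std(ddof=1), max(0.2 * abs(m1), 0.2))
            s2 = max(Y[i].std(ddof=1), max(0.2 * abs(m2), 0.2))
            expected[f"F{i}"] = (m1 - m2) / (s1 + s2)
        order = sorted(expected, key=lambda g: (-expected[g], g))
        assert list(r.genes) == order
        for g in r.genes:
            assert r.score_of(g) == pytest.approx(expected[g])

    def test_variance_metric_needs_replicates(self):
        from mirlink.containers import GroupDesign

        d = GroupDesign.from_samples(["e1"], ["c1"])
        m = make_matrix([[1.0, 2.0]], samples=["e1", "c1"])
        with pytest.raises(ValueError, match=">=2 samples"):
            rank_genes(m, d)
        # log_fold works without replicates
        r = rank_genes(m, d, metric="log_fold")
        assert r.score_of("F0") == pytest.approx(-1.0)


class TestEnrichmentScore:
    def test_top_gene_set_gives_es_one_at_peak_one(self):
        r = _ranked(10, scores=np.linspace(5, 0.5, 10))
        sc = enrichment_score(r, {r.genes[0]}, weight=1.0)
        assert sc.es == pytest.approx(1.0)
        assert sc.peak_index == 1

    def test_bottom_gene_set_unweighted_hand_walk(self):
        # N=4, set = {bottom gene}, p=0: three misses of -1/3, then the hit;
        # the extreme deviation is -1.0 just before the hit
        r = _ranked(4, scores=np.array([3.0, 2.0, 1.0, 0.5]))
        sc = enrichment_score(r, {r.genes[-1]}, weight=0.0)
        es_o, peak_o, _ = oracles.es_walk(r.genes, r.scores, {r.genes[-1]}, 0.0)
        assert sc.es == pytest.approx(es_o) == pytest.approx(-1.0)
        assert sc.peak_index == peak_o == 3

    def test_unweighted_equals_classic_ks(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            n = int(rng.integers(10, 80))
            r = _ranked(n, seed=rng.integers(1 << 30))
            k = int(rng.integers(2, n // 2))
            members = set(rng.choice(r.genes, size=k, replace=False))
            sc = enrichment_score(r, members, weight=0.0)
            hit_pos = [r.position(g) for g in members]
            miss_pos = [p for p in range(1, n + 1) if p not in set(hit_pos)]
            ks = stats.ks_2samp(hit_pos, miss_pos).statistic
            assert abs(sc.es) == pytest.approx(ks, abs=1e-12)

    def test_matches_walk_oracle_random(self):
        rng = np.random.default_rng(77)
        for _ in range(100):
            n = int(rng.integers(5, 150))
            r = _ranked(n, seed=rng.integers(1 << 30))
            k = int(rng.integers(1, n))
            members = set(rng.choice(r.genes, size=k, replace=False))
            w = float(rng.choice([0.0, 0.5, 1.0, 2.0]))
            sc = enrichment_score(r, members, w)
            es_o, peak_o, path = oracles.es_walk(r.genes, r.scores, members, w)
            assert sc.es == pytest.approx(es_o, abs=1e-12)
            assert sc.peak_index == peak_o
            assert -1.0 <= sc.es <= 1.0
            assert np.allclose(sc.running_sum, path, atol=1e-12)
            # conservation: the walk returns to zero at the end
            assert sc.running_sum[-1] == pytest.approx(0.0, abs=1e-9)

    def test_degenerate_sets_rejected(self):
        r = _ranked(5)
        with pytest.raises(ValueError, match="does not intersect"):
            enrichment_score(r, {"absent"})
        with pytest.raises(ValueError, match="whole ranked list"):
            enrichment_score(r, set(r.genes))

    def test_agrees_with_independent_gsea_tool(self):
        # cross-check the weighted statistic against gseapy's prerank ES
        gseapy = pytest.importorskip("gseapy")
        import pandas as pd

        rng = np.random.default_rng(0)
        genes = [f"G{i:03d}" for i in range(100)]
        scores = np.sort(rng.normal(0, 1, 100))[::-1]
        gs = {
            "MID": genes[5:25],
            "SPREAD": [genes[i] for i in range(0, 100, 7)],
            "TAIL": genes[80:95],
        }
        res = gseapy.prerank(
            rnk=pd.DataFrame({"gene": genes, "score": scores}),
            gene_sets=gs,
            permutation_num=4,
            min_size=3,
            max_size=500,
            seed=1,
            outdir=None,
            weight=1.0,
            threads=1,
        ).res2d.set_index("Term")
        r = RankedList(tuple(genes), scores)
        for name, members in gs.items():
            ours = enrichment_score(r, members, 1.0).es
            assert ours == pytest.approx(float(res.loc[name, "ES"]), abs=1e-6)


class TestPermutationNull:
    def test_same_seed_reproducible(self):
        r = _ranked(50)
        a = geneset_permutation_null(r, 10, 200, seed=42)
        b = geneset_permutation_null(r, 10, 200, seed=42)
        assert np.array_equal(a, b)

    def test_null_mean_near_zero_for_symmetric_scores(self):
        scores = np.sort(np.concatenate([np.linspace(0.1, 3, 50), -np.linspace(0.1, 3, 50)]))[::-1]
        r = _ranked(100, scores=scores)
        null = geneset_permutation_null(r, 15, 3000, seed=0)
        assert abs(null.mean()) < 3 * null.std() / np.sqrt(len(null))

    def test_vectorized_es_matches_single_set_walk(self):
        r = _ranked(80, seed=5)
        rng = np.random.default_rng(9)
        null = geneset_permutation_null(r, 12, 50, seed=9, weight=1.0)
        # recompute the same draws with the per-set walk
        rng2 = np.random.default_rng(9)
        u = rng2.random((50, 80))
        idx = np.argpartition(u, 12, axis=1)[:, :12]
        for row in range(50):
            members = {r.genes[i] for i in idx[row]}
            es = enrichment_score(r, members, 1.0).es
            assert null[row] == pytest.approx(es, abs=1e-12)

    def test_size_bounds_checked(self):
        r = _ranked(10)
        with pytest.raises(ValueError):
            geneset_permutation_null(r, 0, 10)
        with pytest.raises(ValueError):
            geneset_permutation_null(r, 10, 10)


class TestNesAndFdr:
    def test_observed_above_all_nulls_hits_p_floor(self):
        res = [EnrichmentResult("S", 0.9, 3, ("g",), 5)]
        null = np.concatenate([np.linspace(0.1, 0.5, 100), -np.linspace(0.1, 0.5, 100)])
        nes_and_fdr(res, {"S": null})
        assert res[0].p_value == pytest.approx(1 / 101)

    def test_nes_of_null_mean_magnitude_is_one(self):
        null = np.array([0.2, 0.4, -0.3, -0.1])
        res = [EnrichmentResult("S", 0.3, 3, ("g",), 5)]  # 0.3 = mean(pos null)
        nes_and_fdr(res, {"S": null})
        assert res[0].nes == pytest.approx(1.0)

    def test_toy_q_matches_pooled_null_recomputation(self):
        rng = np.random.default_rng(21)
        names = [f"S{i}" for i in range(5)]
        obs_es = [0.8, 0.5, -0.6, 0.3, -0.2]
        res = [
            EnrichmentResult(n, e, 3, ("g",), 5) for n, e in zip(names, obs_es)
        ]
        nulls = {n: rng.normal(0, 0.3, 20) for n in names}
        nes_and_fdr(res, nulls)
        # brute-force recomputation from the definition
        pooled = {1: [], -1: []}
        nes_exp = {}
        for n, e in zip(names, obs_es):
            null = nulls[n]
            pos, neg = null[null > 0], null[null < 0]
            pooled[1].extend(pos / pos.mean())
            pooled[-1].extend(neg / np.abs(neg).mean())
            nes_exp[n] = e / pos.mean() if e >= 0 else e / np.abs(neg).mean()
        for stratum in (1, -1):
            sub = [n for n, e in zip(names, obs_es) if (e >= 0) == (stratum == 1)]
            mags = {n: abs(nes_exp[n]) for n in sub}
            pool = np.abs(np.array(pooled[stratum]))
            raw = {}
            for n in sub:
                num = (pool >= mags[n]).mean()
                den = np.mean([mags[x] >= mags[n] for x in sub])
                raw[n] = min(max(num / den, 0.0), 1.0)
            # monotonize BH-style: q = min raw q over sets of smaller-or-equal |NES|
            expect = {}
            best = 1.0
            for n in sorted(sub, key=lambda x: mags[x]):
                best = min(best, raw[n])
                expect[n] = best
            for r in res:
                if r.set_name in sub:
                    assert r.nes == pytest.approx(nes_exp[r.set_name])
                    assert r.q_value == pytest.approx(expect[r.set_name])

    def test_q_monotone_in_abs_nes_per_stratum(self):
        rng = np.random.default_rng(33)
        res = [
            EnrichmentResult(f"S{i}", float(rng.uniform(-0.9, 0.9)), 3, ("g",), 5)
            for i in range(30)
        ]
        nulls = {r.set_name: rng.normal(0, 0.3, 50) for r in res}
        nes_and_fdr(res, nulls)
        for stratum in (1, -1):
            sub = sorted(
                (r for r in res if (r.es >= 0) == (stratum == 1)),
                key=lambda r: -abs(r.nes),
            )
            qs = [r.q_value for r in sub]
            assert all(a <= b + 1e-12 for a, b in zip(qs, qs[1:]))

    def test_missing_null_is_error(self):
        res = [EnrichmentResult("S", 0.5, 1, ("g",), 5)]
        with pytest.raises(ValueError, match="no null"):
            nes_and_fdr(res, {"S": np.array([])})


class TestLeadingEdge:
    def test_set_fully_before_positive_peak(self):
        r = _ranked(10, scores=np.linspace(5, 0.5, 10))
        members = set(r.genes[:3])
        sc = enrichment_score(r, members)
        le = leading_edge(r, members, sc.es, sc.peak_index)
        assert set(le) == members

    def test_single_top_gene(self):
        r = _ranked(10, scores=np.linspace(5, 0.5, 10))
        le = leading_edge(r, {r.genes[0]}, 1.0, 1)
        assert le == (r.genes[0],)

    def test_negative_es_mirror_returns_tail(self):
        scores = np.linspace(5, 0.5, 10)
        r = _ranked(10, scores=scores)
        members = set(r.genes[-3:])
        sc = enrichment_score(r, members)
        assert sc.es < 0
        le = leading_edge(r, members, sc.es, sc.peak_index)
        assert set(le) == members
        # mirror: negate scores, reverse the list -> positive ES, same genes
        r2 = RankedList(tuple(reversed(r.genes)), np.sort(-scores)[::-1])
        sc2 = enrichment_score(r2, members)
        assert sc2.es == pytest.approx(-sc.es)
        assert set(leading_edge(r2, members, sc2.es, sc2.peak_index)) == members

    def test_es_zero_is_error(self):
        r = _ranked(4)
        with pytest.raises(ValueError, match="ES = 0"):
            leading_edge(r, {r.genes[0]}, 0.0, 1)


class TestMergeModules:
    def _results(self):
        r = _ranked(20, scores=np.linspace(3, -3, 20))
        mk = lambda name, es, le, q: EnrichmentResult(
            name, es, 5, tuple(le), len(le), nes=es * 2, p_value=0.01, q_value=q
        )
        res = [
            mk("S1", 0.8, r.genes[:4], 0.01),
            mk("S2", 0.7, r.genes[2:6], 0.01),
            mk("S3", -0.6, r.genes[-4:], 0.01),
            mk("S4", 0.5, r.genes[6:9], 0.2),  # not significant
        ]
        return r, res

    def test_explicit_spec_unions_leading_edges(self):
        r, res = self._results()
        mods = merge_modules(res, r, merge_spec={"S1": "insulin", "S2": "insulin"})
        byname = {m.module_name: m for m in mods}
        assert set(byname) == {"insulin", "S3"}
        assert set(byname["insulin"].leading_edge) == set(r.genes[:6])
        assert byname["insulin"].member_sets == ("S1", "S2")
        # directions recorded from the ranked score sign
        for g in byname["insulin"].leading_edge:
            assert byname["insulin"].gene_directions[g] == (
                "up" if r.score_of(g) >= 0 else "down"
            )

    def test_empty_spec_one_module_per_significant_set(self):
        r, res = self._results()
        mods = merge_modules(res, r)
        assert sorted(m.module_name for m in mods) == ["S1", "S2", "S3"]

    def test_opposite_direction_merge_is_error(self):
        r, res = self._results()
        with pytest.raises(ValueError, match="opposite"):
            merge_modules(res, r, merge_spec={"S1": "X", "S3": "X"})

    def test_auto_mode_merges_by_jaccard(self):
        r, res = self._results()
        # S1/S2 leading edges: {0,1,2,3} vs {2,3,4,5}: Jaccard = 2/6 = 1/3
        mods = merge_modules(res, r, auto=True, jaccard_threshold=0.3)
        names = sorted(m.module_name for m in mods)
        assert names == ["S1+S2", "S3"]
        mods2 = merge_modules(res, r, auto=True, jaccard_threshold=0.5)
        assert sorted(m.module_name for m in mods2) == ["S1", "S2", "S3"]


class TestModelInterface:
    def test_fit_recovers_planted_set(self, design8):
        rng = np.random.default_rng(6)
        samples = design8.exposure_samples + design8.control_samples
        vals = rng.normal(8, 1, (200, 16))
        vals[:10, :8] += 2.0  # plant an up-shifted set
        m = make_matrix(vals, samples=samples)
        sets = GeneSetCollection(
            [
                GeneSet("PLANTED", "", frozenset(f"F{i}" for i in range(10))),
                GeneSet("NULL", "", frozenset(f"F{i}" for i in range(100, 115))),
            ]
        )
        enr = GeneSetEnrichment(m, design8, sets, n_perm=200, seed=0).fit()
        byname = {r.set_name: r for r in enr.results}
        assert byname["PLANTED"].q_value < 0.05
        assert byname["PLANTED"].es > 0
        assert byname["NULL"].q_value > 0.05
        assert "significant" in enr.summary()

    def test_phenotype_permutation_mode_runs(self, design2):
        rng = np.random.default_rng(1)
        m = make_matrix(rng.normal(8, 1, (30, 4)), samples=["e1", "e2", "c1", "c2"])
        sets = GeneSetCollection(
            [GeneSet("S", "", frozenset(f"F{i}" for i in range(8)))]
        )
        enr = GeneSetEnrichment(
            m, design2, sets, n_perm=20, seed=3, permutation="phenotype"
        ).fit()
        assert len(enr.results) == 1
        assert 0 < enr.results[0].p_value <= 1
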