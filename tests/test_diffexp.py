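"""Moderated t-test, BH q-values, fold conventions and 2^-ddCt."""

import numpy as np
import pytest
from scipy import stats

from mirlink.containers import GroupDesign
from mirlink.diffexp import (
    ModeratedTestConfig,
    ModeratedTTest,
    QPCRRecord,
    bh_qvalues,
    ddct_fold,
    moderated_t,
    signed_fold,
    storey_pi0,
)
from conftest import make_matrix
import oracles


def _matrix_for(design, X, Y, kind="mirna"):
    samples = design.exposure_samples + design.control_samples
    return make_matrix(np.column_stack([X, Y]), samples=samples, kind=kind)


class TestModeratedT:
    def test_equal_group_means_give_t0_p1(self, design2):
        m = _matrix_for(design2, np.array([[1.0, 2.0]]), np.array([[2.0, 1.0]]))
        recs = moderated_t(m, design2, ModeratedTestConfig(prior_df=1.0, window_size=1))
        assert recs[0].t_stat == pytest.approx(0.0)
        assert recs[0].p_value == pytest.approx(1.0)

    def test_nu0_zero_equals_ordinary_pooled_t(self, design8):
        rng = np.random.default_rng(11)
        X = rng.normal(8, 1, (60, 8))
        Y = rng.normal(8, 1, (60, 8))
        m = _matrix_for(design8, X, Y)
        recs = moderated_t(m, design8, ModeratedTestConfig(prior_df=0.0, window_size=11))
        by_id = {r.feature_id: r for r in recs}
        t_ref, p_ref = stats.ttest_ind(X, Y, axis=1, equal_var=True)
        for i, fid in enumerate(m.feature_ids):
            assert by_id[fid].t_stat == pytest.approx(t_ref[i], abs=1e-9)
            assert by_id[fid].p_value == pytest.approx(p_ref[i], abs=1e-9)

    def test_matches_bruteforce_oracle_small(self, design2):
        # 4v4-style toy: hand-set values, nu0=4, w=3
        rng = np.random.default_rng(5)
        d = GroupDesign.from_samples(["e1", "e2", "e3", "e4"], ["c1", "c2", "c3", "c4"])
        X = rng.normal(8, 1, (7, 4))
        Y = rng.normal(8, 1, (7, 4))
        m = _matrix_for(d, X, Y)
        recs = moderated_t(m, d, ModeratedTestConfig(prior_df=4.0, window_size=3))
        t_oracle, _ = oracles.moderated_t_stats(X, Y, 4.0, 3)
        by_id = {r.feature_id: r.t_stat for r in recs}
        for i, fid in enumerate(m.feature_ids):
            assert by_id[fid] == pytest.approx(t_oracle[i], abs=1e-9)

    def test_matches_bruteforce_oracle_random_50(self, design8):
        rng = np.random.default_rng(123)
        X = rng.normal(8, rng.uniform(0.5, 2), (50, 8))
        Y = rng.normal(8, 1, (50, 8))
        m = _matrix_for(design8, X, Y)
        recs = moderated_t(m, design8, ModeratedTestConfig(prior_df=10.0, window_size=21))
        t_oracle, _ = oracles.moderated_t_stats(X, Y, 10.0, 21)
        by_id = {r.feature_id: r.t_stat for r in recs}
        for i, fid in enumerate(m.feature_ids):
            assert by_id[fid] == pytest.approx(t_oracle[i], abs=1e-9)

    def test_shrinkage_limit_large_prior(self, design8):
        # as nu0 -> inf the posterior variance approaches the background s0^2
        rng = np.random.default_rng(9)
        X = rng.normal(8, 1, (30, 8))
        Y = rng.normal(8, 1, (30, 8))
        _, s2_small = oracles.moderated_t_stats(X, Y, 1e8, 29)
        _, s2_ref = oracles.moderated_t_stats(X, Y, 1e12, 29)
        assert np.allclose(s2_small, s2_ref, rtol=1e-3)
        recs_inf = moderated_t(
            _matrix_for(design8, X, Y), design8, ModeratedTestConfig(1e12, 29)
        )
        t_inf, _ = oracles.moderated_t_stats(X, Y, 1e12, 29)
        by_id = {r.feature_id: r.t_stat for r in recs_inf}
        for i in range(30):
            assert by_id[f"F{i}"] == pytest.approx(t_inf[i], rel=1e-9)

    def test_small_groups_rejected(self):
        d = GroupDesign.from_samples(["e1"], ["c1", "c2"])
        m = make_matrix([[1.0, 2.0, 3.0]], samples=["e1", "c1", "c2"])
        with pytest.raises(ValueError, match=">=2 samples"):
            moderated_t(m, d, ModeratedTestConfig(1.0, 1))

    def test_zero_variance_everywhere_with_nu0_zero(self, design2):
        m = _matrix_for(design2, np.ones((3, 2)), np.ones((3, 2)) * 2)
        with pytest.raises(ValueError, match="zero variance"):
            moderated_t(m, design2, ModeratedTestConfig(prior_df=0.0, window_size=1))

    def test_records_sorted_by_p(self, design8):
        rng = np.random.default_rng(2)
        X = rng.normal(8, 1, (20, 8))
        X[0] += 3  # one strong shift
        Y = rng.normal(8, 1, (20, 8))
        recs = moderated_t(_matrix_for(design8, X, Y), design8, ModeratedTestConfig(5, 5))
        ps = [r.p_value for r in recs]
        assert ps == sorted(ps)
        assert recs[0].feature_id == "F0"


class TestBHQvalues:
    def test_hand_stepup_example(self):
        assert bh_qvalues([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_qvalues([0.2]) == [pytest.approx(0.2)]

    def test_matches_hand_rule_and_is_monotone(self):
        rng = np.random.default_rng(8)
        p = list(rng.uniform(1e-6, 1, 200))
        q = bh_qvalues(p)
        assert q == pytest.approx(oracles.bh_stepup(p))
        for pi, qi in zip(p, q):
            assert qi >= pi - 1e-12
        order = np.argsort(p)
        assert np.all(np.diff(np.asarray(q)[order]) >= -1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_qvalues([0.0, 0.5])
        with pytest.raises(ValueError):
            bh_qvalues([0.5, 1.5])

    def test_storey_pi0_scaling(self):
        rng = np.random.default_rng(1)
        p = list(rng.uniform(0.5, 1.0, 100))  # clearly null-heavy
        pi0 = storey_pi0(p)
        assert pi0 == 1.0  # estimator clips at 1
        q = bh_qvalues(p, pi0=0.5)
        assert q == pytest.approx([min(1.0, x * 0.5) for x in bh_qvalues(p)])


class TestSignedFold:
    def test_ratio_conventions(self, design2):
        m = make_matrix(
            [[9.0, 9.0, 8.0, 8.0], [7.0, 7.0, 8.0, 8.0], [8.0, 8.0, 8.0, 8.0]],
            samples=["e1", "e2", "c1", "c2"],
        )
        folds = signed_fold(m, design2)
        assert folds["F0"] == pytest.approx(2.0)
        assert folds["F1"] == pytest.approx(-2.0)
        assert folds["F2"] == pytest.approx(1.0)  # ratio 1 reported as +1.0

    def test_negative_fold_means_decrease_under_exposure(self, design2):
        # a reported fold of -1.68 denotes a 1.68-fold decrease under exposure
        shift = -np.log2(1.68)
        m = make_matrix(
            [[8.0 + shift] * 2 + [8.0] * 2], samples=["e1", "e2", "c1", "c2"]
        )
        folds = signed_fold(m, design2)
        assert folds["F0"] == pytest.approx(-1.68)


class TestDdctFold:
    def _rec(self, exp_t, exp_r, ctl_t, ctl_r):
        d = GroupDesign.from_samples(["e"], ["c"])
        return QPCRRecord(
            ct_target={"e": exp_t, "c": ctl_t},
            ct_reference={"e": exp_r, "c": ctl_r},
            design=d,
        )

    @pytest.mark.parametrize(
        "ddct,expected", [(0, 1.0), (-1, 2.0), (1, 0.5), (-2, 4.0), (2, 0.25)]
    )
    def test_powers_of_two(self, ddct, expected):
        rec = self._rec([20.0 + ddct], [10.0], [20.0], [10.0])
        assert ddct_fold(rec) == pytest.approx(expected)

    def test_triplicates_averaged_symmetric_case(self):
        rec = self._rec([20.0] * 3, [10.0] * 3, [20.0] * 3, [10.0] * 3)
        assert ddct_fold(rec) == pytest.approx(1.0)

    def test_missing_reference_is_error(self):
        d = GroupDesign.from_samples(["e"], ["c"])
        rec = QPCRRecord(
            ct_target={"e": [20.0], "c": [20.0]},
            ct_reference={"e": [10.0]},
            design=d,
        )
        with pytest.raises(ValueError, match="reference"):
            ddct_fold(rec)


class TestModelInterface:
    def test_fit_returns_results_with_summary(self, design8):
        rng = np.random.default_rng(0)
        X = rng.normal(8, 1, (40, 16))
        samples = design8.exposure_samples + design8.control_samples
        m = make_matrix(X, samples=samples, kind="mirna")
        res = ModeratedTTest(m, design8, prior_df=5, window_size=9).fit()
        assert len(res.records) == 40
        frame = res.frame()
        assert list(frame.columns) == ["fold", "t", "p", "q", "direction"]
        text = res.summary()
        assert "prior_df" in text and "features tested" in text
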