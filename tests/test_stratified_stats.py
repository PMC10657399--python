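"""Stratified CMH and rank tests against independent oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from her2low.errors import DegenerateInputError
from her2low.stratified_stats import (
    baseline_tests,
    cmh_from_frame,
    cmh_general_association,
    stratified_kruskal_wallis,
    table_from_frame,
)


def _perm_p(table, n_draws, rng):
    """Within-stratum permutation p for the CMH statistic.

    Permuting group labels within a stratum makes group 1's category counts
    multivariate hypergeometric; the statistic's margins (hence E and V)
    are permutation-invariant, so only the count vector is redrawn.
    """
    table = np.asarray(table, dtype=float)
    K, S = table.shape[1], table.shape[2]
    obs = cmh_general_association(table).statistic
    d = np.zeros((n_draws, K - 1))
    V = np.zeros((K - 1, K - 1))
    for s in range(S):
        sub = table[:, :, s]
        N = sub.sum()
        r1 = int(sub[0].sum())
        c = sub.sum(axis=0).astype(int)
        d += rng.multivariate_hypergeometric(c, r1, size=n_draws)[:, : K - 1] - r1 * c[
            : K - 1
        ] / N
        V += (
            r1
            * sub[1].sum()
            / (N**2 * (N - 1))
            * (np.diag(c[: K - 1]) * N - np.outer(c[: K - 1], c[: K - 1]))
        )
    sp = np.einsum("ij,jk,ik->i", d, np.linalg.pinv(V), d)
    return float((sp >= obs - 1e-9).mean())


class TestCmh:
    def test_single_stratum_2x2_equals_hand_mh_chi_square(self):
        """[[10,20],[20,10]]: the (N-1)-scaled Mantel-Haenszel chi-square is
        (N-1)(ad-bc)^2/(r1 r2 c1 c2) = 59*300^2/30^4 = 59/9."""
        res = cmh_general_association(np.array([[10, 20], [20, 10]]))
        assert res.statistic == pytest.approx(59 / 9, abs=1e-9)
        assert res.df == 1

    def test_matches_r_mantelhaen_on_2x3x2(self):
        # frozen from R: mantelhaen.test(array(c(1,7,5,4,9,4, 4,4,7,6,4,5),
        #                                 dim=c(2,3,2))) -> M^2=3.056, p=0.217
        tbl = np.array([[[1, 4], [5, 7], [9, 4]], [[7, 4], [4, 6], [4, 5]]])
        res = cmh_general_association(tbl)
        assert res.statistic == pytest.approx(3.055971202710333, abs=1e-9)
        assert res.p_value == pytest.approx(0.217, abs=5e-4)

    def test_homogeneous_strata_give_zero_statistic(self):
        tbl = np.stack([np.array([[5, 10, 15], [5, 10, 15]])] * 2, axis=2)
        res = cmh_general_association(tbl)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == 1.0

    def test_invariant_to_stratum_order_and_category_relabeling(self):
        rng = np.random.default_rng(4)
        tbl = rng.integers(1, 12, size=(2, 3, 3))
        base = cmh_general_association(tbl).statistic
        assert cmh_general_association(tbl[:, :, ::-1]).statistic == pytest.approx(base)
        assert cmh_general_association(tbl[:, ::-1, :]).statistic == pytest.approx(base)

    def test_duplicating_every_stratum_doubles_the_statistic(self):
        rng = np.random.default_rng(9)
        tbl = rng.integers(1, 12, size=(2, 3, 2))
        base = cmh_general_association(tbl).statistic
        dup = np.concatenate([tbl, tbl], axis=2)
        assert cmh_general_association(dup).statistic == pytest.approx(2 * base, rel=1e-9)

    def test_asymptotic_p_converges_to_permutation_p(self):
        """At large per-stratum counts the chi-square reference matches the
        exact within-stratum permutation null."""
        rng = np.random.default_rng(0)
        checked = 0
        while checked < 5:
            p = rng.dirichlet(np.full(3, 12.0))
            tbl = np.stack(
                [np.stack([rng.multinomial(250, p) for _ in range(2)]) for _ in range(2)],
                axis=2,
            )
            res = cmh_general_association(tbl)
            if not 0.05 < res.p_value < 0.95:
                continue
            checked += 1
            assert abs(res.p_value - _perm_p(tbl, 50_000, rng)) < 0.02

    def test_correlation_variant_detects_ordered_trend(self):
        # group 0 shifted toward higher categories in both strata
        tbl = np.stack(
            [np.array([[2, 8, 20], [20, 8, 2]]), np.array([[3, 9, 18], [18, 9, 3]])],
            axis=2,
        )
        nominal = cmh_general_association(tbl)
        ordinal = cmh_general_association(tbl, kind="correlation")
        assert ordinal.df == 1
        assert ordinal.p_value < 0.001
        assert nominal.p_value < 0.001

    def test_all_zero_table_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            cmh_general_association(np.zeros((2, 3, 2)))

    def test_table_from_frame_round_trip(self):
        df = pd.DataFrame(
            {
                "g": ["a"] * 6 + ["b"] * 6,
                "c": ["x", "y", "z"] * 4,
                "s": ["s1", "s2"] * 6,
            }
        )
        tbl = table_from_frame(df, "g", "c", "s")
        assert tbl.sum() == 12
        res_frame = cmh_from_frame(df, "g", "c", "s")
        res_table = cmh_general_association(tbl)
        assert res_frame.statistic == pytest.approx(res_table.statistic)


def _wilcoxon_z_squared(x, y):
    """Independent oracle: tie-corrected normal-approximation rank-sum z^2."""
    n1, n2 = len(x), len(y)
    n = n1 + n2
    ranks = stats.rankdata(np.concatenate([x, y]))
    w = ranks[:n1].sum()
    e = n1 * (n + 1) / 2
    ss = ((ranks - ranks.mean()) ** 2).sum()
    var = n1 * n2 * ss / (n * (n - 1))
    return (w - e) ** 2 / var


class TestStratifiedKruskalWallis:
    def test_single_stratum_two_groups_equals_rank_sum_oracle(self):
        rng = np.random.default_rng(2)
        x = np.round(rng.normal(0, 1, 40), 1)  # ties via rounding
        g = rng.integers(0, 2, 40)
        res = stratified_kruskal_wallis(x, g, np.zeros(40))
        assert res.statistic == pytest.approx(
            _wilcoxon_z_squared(x[g == 0], x[g == 1]), abs=1e-9
        )

    def test_single_stratum_equals_unstratified_kruskal_wallis(self):
        rng = np.random.default_rng(1)
        v = np.round(rng.normal(0, 1, 60), 1)
        g = rng.integers(0, 3, 60)
        res = stratified_kruskal_wallis(v, g, np.zeros(60))
        ref = stats.kruskal(v[g == 0], v[g == 1], v[g == 2])
        assert res.statistic == pytest.approx(ref.statistic, abs=1e-9)
        assert res.df == 2

    def test_constant_values_give_zero_statistic(self):
        res = stratified_kruskal_wallis(np.ones(30), np.tile([0, 1], 15), np.zeros(30))
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_singleton_stratum_dropped_with_warning(self, caplog):
        v = np.concatenate([np.arange(20.0), [99.0]])
        g = np.concatenate([np.tile([0, 1], 10), [0]])
        s = np.concatenate([np.zeros(20), [1]])
        with caplog.at_level("WARNING"):
            res = stratified_kruskal_wallis(v, g, s)
        assert res.strata_used == 1
        assert "single sample" in caplog.text

    def test_null_type_one_error_calibrated(self):
        """Same distribution in both groups within each of 2 strata: empirical
        rejection at alpha=0.05 over 1000 replicates stays near nominal."""
        rng = np.random.default_rng(0)
        rej = 0
        n_rep = 1000
        for _ in range(n_rep):
            v = np.concatenate([rng.normal(0, 1, 100), rng.normal(2, 1.5, 100)])
            g = rng.integers(0, 2, 200)
            s = np.repeat([0, 1], 100)
            rej += stratified_kruskal_wallis(v, g, s).p_value < 0.05
        assert 0.035 < rej / n_rep < 0.065

    def test_detects_planted_shift(self):
        rng = np.random.default_rng(5)
        s = np.repeat([0, 1], 100)
        g = rng.integers(0, 2, 200)
        v = rng.normal(0, 1, 200) + 0.8 * g + 2.0 * s
        assert stratified_kruskal_wallis(v, g, s).p_value < 0.001


class TestBaselineTests:
    def test_planted_er_her2_dependence_detected(self, small_cohort):
        out = baseline_tests(
            small_cohort.clinical, categorical=["er_status"], continuous=["purity"]
        )
        er = out[out["variable"] == "er_status"].iloc[0]
        assert er["method"] == "chi_square"
        assert er["p_value"] < 0.05  # generator plants the ER imbalance

    def test_identical_duration_distribution_gives_large_p(self):
        df = pd.DataFrame(
            {
                "her2_class": np.repeat(["her2_low", "her2_0"], 30),
                "days": np.tile(np.arange(30.0), 2),
            }
        )
        out = baseline_tests(df, durations=["days"])
        assert out.iloc[0]["p_value"] > 0.9

    def test_single_level_column_skipped_with_note(self):
        df = pd.DataFrame(
            {"her2_class": ["her2_low", "her2_0"] * 5, "site": ["breast"] * 10}
        )
        out = baseline_tests(df, categorical=["site"])
        assert "skipped" in out.iloc[0]["note"]
        assert np.isnan(out.iloc[0]["p_value"])
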