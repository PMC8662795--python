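import numpy as np
import pandas as pd
import pytest

from bambusa import (
    aggregate_tissues,
    compute_tai,
    compute_tdi,
    expressed_fraction,
    expression_preference,
    flat_line_test,
    relative_expression,
    tissue_specificity_tau,
)


def frame(data, genes, samples):
    return pd.DataFrame(data, index=genes, columns=samples, dtype=float)


class TestTAI:
    def test_equal_expression_gives_unweighted_mean(self):
        e = frame([[1], [1], [1]], ["a", "b", "c"], ["s1"])
        ages = pd.Series({"a": 1, "b": 2, "c": 3})
        assert compute_tai(e, ages)["s1"] == pytest.approx(2.0)

    def test_single_expressed_gene(self):
        e = frame([[0], [7]], ["a", "b"], ["s1"])
        ages = pd.Series({"a": 3, "b": 11})
        assert compute_tai(e, ages)["s1"] == pytest.approx(11.0)

    def test_weighted_mean_hand_checked(self):
        e = frame([[3], [1]], ["a", "b"], ["s1"])
        ages = pd.Series({"a": 1, "b": 12})
        assert compute_tai(e, ages)["s1"] == pytest.approx(3.75)

    def test_all_zero_sample_flagged_nan(self):
        e = frame([[0, 1], [0, 2]], ["a", "b"], ["s1", "s2"])
        ages = pd.Series({"a": 1, "b": 2})
        tai = compute_tai(e, ages)
        assert np.isnan(tai["s1"]) and not np.isnan(tai["s2"])

    def test_expressed_gene_without_age_rejected(self):
        e = frame([[1]], ["a"], ["s1"])
        with pytest.raises(ValueError, match="without age"):
            compute_tai(e, pd.Series(dtype=float))

    def test_column_scaling_invariance(self, small_ages, rng):
        e = pd.DataFrame(rng.lognormal(1, 1, (600, 4)),
                         index=small_ages.index, columns=list("wxyz"))
        scaled = e.copy()
        scaled["x"] *= 37.5
        pd.testing.assert_series_equal(compute_tai(e, small_ages),
                                       compute_tai(scaled, small_ages))

    def test_monotone_in_age_relabeling(self, small_ages, rng):
        e = pd.DataFrame(rng.lognormal(1, 1, (600, 4)),
                         index=small_ages.index, columns=list("wxyz"))
        bumped = small_ages.copy()
        bumped.iloc[:100] += 1
        assert (compute_tai(e, bumped) >= compute_tai(e, small_ages)).all()


class TestTDI:
    def test_constant_omega(self):
        e = frame([[5], [1]], ["a", "b"], ["s1"])
        om = pd.Series({"a": 0.2, "b": 0.2})
        assert compute_tdi(e, om)["s1"] == pytest.approx(0.2)

    def test_equal_weights(self):
        e = frame([[1], [1]], ["a", "b"], ["s1"])
        om = pd.Series({"a": 0.1, "b": 0.9})
        assert compute_tdi(e, om)["s1"] == pytest.approx(0.5)

    def test_undefined_omega_excluded_from_both_sums(self):
        e = frame([[1], [1], [100]], ["a", "b", "c"], ["s1"])
        om = pd.Series({"a": 0.1, "b": 0.9, "c": np.nan})
        assert compute_tdi(e, om)["s1"] == pytest.approx(0.5)

    def test_no_defined_omega_rejected(self):
        e = frame([[1]], ["a"], ["s1"])
        with pytest.raises(ValueError, match="Ka/Ks"):
            compute_tdi(e, pd.Series({"a": np.nan}))


class TestRelativeExpression:
    def test_minmax_endpoints(self):
        e = frame([[1, 2, 4]], ["a"], ["s1", "s2", "s3"])
        ages = pd.Series({"a": 1})
        re = relative_expression(e, ages)
        row = re.loc[1]
        assert row["s1"] == 0.0 and row["s3"] == 1.0 and 0 < row["s2"] < 1

    def test_single_stage_stratum(self):
        e = frame([[0, 9, 0]], ["a"], ["s1", "s2", "s3"])
        re = relative_expression(e, pd.Series({"a": 2}))
        assert re.loc[2].tolist() == [0.0, 1.0, 0.0]

    def test_two_gene_stratum_hand_computed(self):
        e = frame([[2, 8], [4, 6]], ["a", "b"], ["s1", "s2"])
        re = relative_expression(e, pd.Series({"a": 5, "b": 5}))
        assert re.loc[5].tolist() == pytest.approx([0.0, 1.0])

    def test_constant_stratum_flagged_nan(self):
        e = frame([[3, 3]], ["a"], ["s1", "s2"])
        re = relative_expression(e, pd.Series({"a": 1}))
        assert re.loc[1].isna().all()

    def test_per_gene_scaling_invariance(self, small_ages, rng):
        e = pd.DataFrame(rng.lognormal(1, 1, (600, 5)),
                         index=small_ages.index,
                         columns=[f"s{i}" for i in range(5)])
        scaled = e.mul(rng.uniform(0.1, 10, 600), axis=0)
        pd.testing.assert_frame_equal(relative_expression(e, small_ages),
                                      relative_expression(scaled, small_ages))


class TestExpressionPreference:
    def test_neutral_stratum(self, rng):
        # 100 genes of stratum A holding exactly 10% of top-1000 expression
        ages = pd.Series([1] * 100 + [2] * 900,
                         index=[f"g{i}" for i in range(1000)])
        vals = np.ones(1000)
        e = frame(vals[:, None], ages.index, ["t"])
        ep = expression_preference(e, ages, k=1000)
        assert ep.loc[1, "t"] == pytest.approx(1.0)
        assert ep.loc[2, "t"] == pytest.approx(1.0)

    def test_enriched_stratum_direct_formula(self):
        ages = pd.Series([1] * 10 + [2] * 990,
                         index=[f"g{i}" for i in range(1000)])
        vals = np.ones(1000)
        vals[:10] = 24.75  # stratum 1: 247.5 of 1237.5 total = 20%
        e = frame(vals[:, None], ages.index, ["t"])
        ep = expression_preference(e, ages, k=1000)
        assert ep.loc[1, "t"] == pytest.approx(20.0)

    def test_absent_stratum_is_missing(self):
        ages = pd.Series([1] * 1000 + [2] * 5,
                         index=[f"g{i}" for i in range(1005)])
        vals = np.concatenate([np.full(1000, 10.0), np.full(5, 0.1)])
        e = frame(vals[:, None], ages.index, ["t"])
        ep = expression_preference(e, ages, k=1000)
        assert np.isnan(ep.loc[2, "t"])

    def test_k_larger_than_expressed_rejected(self):
        e = frame([[1], [0]], ["a", "b"], ["t"])
        with pytest.raises(ValueError, match="top"):
            expression_preference(e, pd.Series({"a": 1, "b": 1}), k=2)


class TestTau:
    def test_uniform_expression_zero(self):
        e = frame([[5, 5, 5]], ["a"], ["t1", "t2", "t3"])
        assert tissue_specificity_tau(e)["a"] == pytest.approx(0.0)

    def test_single_tissue_one(self):
        e = frame([[0, 7, 0, 0]], ["a"], list("wxyz"))
        assert tissue_specificity_tau(e)["a"] == pytest.approx(1.0)

    def test_hand_computed_value(self):
        e = frame([[8, 4, 0, 0]], ["a"], list("wxyz"))
        assert tissue_specificity_tau(e)["a"] == pytest.approx(5 / 6)

    def test_all_zero_gene_nan(self):
        e = frame([[0, 0]], ["a"], ["t1", "t2"])
        assert np.isnan(tissue_specificity_tau(e)["a"])

    def test_stage_columns_averaged_first(self):
        e = frame([[6, 2, 4]], ["a"], ["shoot_S1", "shoot_S2", "root"])
        tmap = {"shoot_S1": "shoot", "shoot_S2": "shoot", "root": "root"}
        # shoot mean 4 == root 4 -> uniform over tissues
        assert tissue_specificity_tau(e, tmap)["a"] == pytest.approx(0.0)

    def test_aggregate_requires_complete_map(self):
        e = frame([[1, 2]], ["a"], ["s1", "s2"])
        with pytest.raises(KeyError, match="s2"):
            aggregate_tissues(e, {"s1": "x"})


class TestExpressedFraction:
    def test_all_expressed(self):
        e = frame([[2], [5]], ["a", "b"], ["s"])
        assert expressed_fraction(e)["fraction"] == 1.0

    def test_genome_scale_fraction(self):
        vals = np.zeros((50936, 1))
        vals[:41307] = 2.0
        vals[41307:] = 0.2
        e = frame(vals, [f"g{i}" for i in range(50936)], ["s"])
        res = expressed_fraction(e, threshold=1.0)
        assert round(100 * res["fraction"], 2) == 81.10
        assert res["count"] == 41307

    def test_zero_threshold_counts_any_positive(self):
        e = frame([[0.01], [0.0]], ["a", "b"], ["s"])
        res = expressed_fraction(e, threshold=0)
        assert res["count"] == 1


class TestFlatLineBasics:
    def test_flat_profile_p_near_one(self):
        e = pd.DataFrame(np.tile([[1.0], [2.0], [3.0]], (1, 5)),
                         index=["a", "b", "c"],
                         columns=[f"s{i}" for i in range(5)])
        labels = pd.Series({"a": 1, "b": 5, "c": 9})
        res = flat_line_test(e, labels, n_perm=100, seed=0)
        assert res.p_value == pytest.approx(1.0)

    def test_reproducible_given_seed(self, small_ages, rng):
        e = pd.DataFrame(rng.lognormal(1, 1, (600, 6)),
                         index=small_ages.index,
                         columns=[f"s{i}" for i in range(6)])
        r1 = flat_line_test(e, small_ages, n_perm=150, seed=42)
        r2 = flat_line_test(e, small_ages, n_perm=150, seed=42)
        assert r1.p_value == r2.p_value
        pd.testing.assert_series_equal(r1.perm_mean, r2.perm_mean)

    def test_needs_two_samples(self):
        e = frame([[1]], ["a"], ["s"])
        with pytest.raises(ValueError, match="two samples"):
            flat_line_test(e, pd.Series({"a": 1}), n_perm=100)

    def test_band_length_matches_samples(self, small_ages, rng):
        e = pd.DataFrame(rng.lognormal(1, 1, (600, 7)),
                         index=small_ages.index,
                         columns=[f"s{i}" for i in range(7)])
        res = flat_line_test(e, small_ages, n_perm=120, seed=3)
        assert len(res.profile) == 7
        assert (res.perm_sd >= 0).all()
        assert 0 < res.p_value <= 1
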