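import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import comb
from scipy.stats import chi2_contingency

from bambusa import (
    ancestral_state_comparison,
    balanced_seg_census,
    call_segs,
    chi_square_yates,
    fisher_exact,
    seg_census,
    simulate_expression,
    tag_shoot_biased_wgd,
)


class TestChiSquareYates:
    def test_printed_enrichment_table(self):
        """New vs old genes among shoot SEGs: the published statistic."""
        stat, p = chi_square_yates([[225, 1397], [5557, 43757]])
        assert round(stat, 3) == 10.318
        assert p == pytest.approx(0.0013, abs=2e-4)

    def test_identical_proportions_near_zero(self):
        stat, p = chi_square_yates([[50, 100], [500, 1000]])
        assert stat < 0.05 and p > 0.8

    def test_balanced_small_table(self):
        stat, p = chi_square_yates([[10, 10], [10, 10]])
        # |O-E| = 0 for every cell; correction leaves ~0.05-scale value
        assert stat == pytest.approx(0.1, abs=0.2)
        assert p > 0.5

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            chi_square_yates([[0, 0], [5, 5]])

    @given(st.lists(st.integers(1, 200), min_size=4, max_size=4))
    @settings(max_examples=60, deadline=None)
    def test_matches_scipy_continuity_correction(self, cells):
        """Agrees with scipy whenever the correction is not clamped.

        scipy (like R) clamps the 0.5 correction so it never crosses the
        expectation; the closed form here applies it unconditionally, so
        comparison is restricted to tables with |O - E| >= 0.5.
        """
        table = np.array([[cells[0], cells[1]], [cells[2], cells[3]]])
        expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
        if np.abs(table - expected).min() < 0.5:
            return
        stat, p = chi_square_yates(table)
        ref_stat, ref_p, _, _ = chi2_contingency(table, correction=True)
        assert stat == pytest.approx(float(ref_stat))
        assert p == pytest.approx(float(ref_p))


def hypergeom_two_sided(table):
    """Full enumeration of the hypergeometric support (oracle)."""
    (a, b), (c, d) = table
    row1, col1, n = a + b, a + c, a + b + c + d

    def prob(x):
        return (comb(col1, x, exact=True)
                * comb(n - col1, row1 - x, exact=True)) / comb(n, row1,
                                                               exact=True)

    p_obs = prob(a)
    lo = max(0, row1 + col1 - n)
    hi = min(row1, col1)
    return sum(prob(x) for x in range(lo, hi + 1)
               if prob(x) <= p_obs * (1 + 1e-9))


class TestFisherExact:
    def test_fully_concentrated_table(self):
        assert fisher_exact([[5, 0], [0, 5]]) == pytest.approx(2 / 252)

    def test_independent_table_p_one(self):
        assert fisher_exact([[5, 5], [5, 5]]) == pytest.approx(1.0)

    @given(st.lists(st.integers(0, 15), min_size=4, max_size=4))
    @settings(max_examples=60, deadline=None)
    def test_matches_enumeration_for_small_margins(self, cells):
        table = [[cells[0], cells[1]], [cells[2], cells[3]]]
        if sum(cells) == 0:
            return
        assert fisher_exact(table) == pytest.approx(
            hypergeom_two_sided(table), rel=1e-6
        )

    def test_planted_enrichment_power(self):
        """Odds ratio 5 at n = 2,000: p < 0.05 in nearly every replicate."""
        rng = np.random.default_rng(17)
        hits = 0
        n_rep = 40
        for _ in range(n_rep):
            group = rng.random(2000) < 0.25
            p_hit = np.where(group, 0.25, 0.0625)  # OR = 5
            flag = rng.random(2000) < p_hit
            table = [[int((group & flag).sum()), int((group & ~flag).sum())],
                     [int((~group & flag).sum()), int((~group & ~flag).sum())]]
            hits += fisher_exact(table) < 0.05
        assert hits >= 0.95 * n_rep


def toy_expr():
    cols = ["root", "leaf", "shoot_S1", "shoot_S2"]
    tmap = {"root": "root", "leaf": "leaf",
            "shoot_S1": "shoot", "shoot_S2": "shoot"}
    data = {
        "specific": [100.0, 0.0, 0.0, 0.0],
        "uniform": [5.0, 5.0, 5.0, 5.0],
        "low": [0.5, 0.0, 0.0, 0.0],
        "shooty": [0.1, 0.2, 60.0, 80.0],
    }
    return pd.DataFrame.from_dict(data, orient="index", columns=cols), tmap


class TestCallSegs:
    def test_single_tissue_expression_called(self):
        expr, tmap = toy_expr()
        segs = call_segs(expr, tmap)
        assert segs.loc["specific", "tissue"] == "root"
        assert segs.loc["shooty", "tissue"] == "shoot"

    def test_uniform_expression_not_called(self):
        expr, tmap = toy_expr()
        assert pd.isna(call_segs(expr, tmap).loc["uniform", "tissue"])

    def test_expression_floor_enforced(self):
        expr, tmap = toy_expr()
        assert pd.isna(call_segs(expr, tmap).loc["low", "tissue"])

    def test_planted_seg_recovery(self, small_ages):
        expr, tmap, truth = simulate_expression(
            small_ages, n_seg_per_tissue=20, seed=9
        )
        segs = call_segs(expr, tmap)
        called = segs.dropna(subset=["tissue"])
        planted = truth.data["seg"]
        tp = sum(planted.get(g) == t for g, t in called["tissue"].items())
        assert tp / len(called) >= 0.95   # precision
        assert tp / len(planted) >= 0.95  # recall


class TestCensus:
    def test_totals_conserved(self, small_ages):
        expr, tmap, _ = simulate_expression(small_ages, n_seg_per_tissue=10,
                                            seed=4)
        segs = call_segs(expr, tmap)
        census = seg_census(segs, small_ages)
        n_called = segs["tissue"].notna().sum()
        assert census.loc["Total", "Total"] == n_called

    def test_published_table_margin(self):
        """The per-tissue totals of the published SEG census sum to 7,013."""
        per_tissue = pd.Series({"root": 574, "lateral_bud": 43, "leaf": 356,
                                "inflorescence": 194, "shoot_tip": 42,
                                "rhizome_tip": 22, "shoot": 5782})
        assert per_tissue.sum() == 7013
        assert round(100 * per_tissue["shoot"] / per_tissue.sum(), 2) == 82.45

    def test_balanced_census_touches_only_multistage_tissue(self, small_ages):
        expr, tmap, _ = simulate_expression(small_ages, n_seg_per_tissue=15,
                                            seed=6)
        full = seg_census(call_segs(expr, tmap), small_ages)
        bal = balanced_seg_census(expr, tmap, small_ages,
                                  multi_stage_tissue="shoot",
                                  stage="shoot_S3")
        other = [c for c in full.columns if c not in ("shoot", "Total")]
        for col in other:
            if col in bal.columns:
                pd.testing.assert_series_equal(full[col], bal[col],
                                               check_names=False)

    def test_unknown_stage_rejected(self, small_ages):
        expr, tmap, _ = simulate_expression(small_ages, seed=6)
        with pytest.raises(KeyError, match="shoot_S99"):
            balanced_seg_census(expr, tmap, small_ages,
                                multi_stage_tissue="shoot",
                                stage="shoot_S99")


def seg_frame(mapping):
    return pd.DataFrame(
        {"tissue": pd.Series(mapping, dtype=object),
         "tau": 0.9, "value": 10.0}
    )


def dup_frame(rows):
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "dup_class"])


class TestSBW:
    def test_wgd_seg_tagged(self):
        segs = seg_frame({"g1": "shoot", "g2": "root"})
        dup = dup_frame([("g1", "p1", "WGD")])
        res = tag_shoot_biased_wgd(segs, dup, "shoot")
        assert res["sbw_genes"] == ["g1"]

    def test_tandem_only_not_tagged(self):
        segs = seg_frame({"g1": "shoot"})
        dup = dup_frame([("g1", "p1", "tandem")])
        assert tag_shoot_biased_wgd(segs, dup, "shoot")["sbw_genes"] == []

    def test_monotone_in_wgd_pairs(self):
        segs = seg_frame({"g1": "shoot", "g2": "shoot", "g3": "shoot"})
        dup1 = dup_frame([("g1", "p1", "WGD")])
        dup2 = dup_frame([("g1", "p1", "WGD"), ("g2", "p2", "WGD")])
        s1 = set(tag_shoot_biased_wgd(segs, dup1, "shoot")["sbw_genes"])
        s2 = set(tag_shoot_biased_wgd(segs, dup2, "shoot")["sbw_genes"])
        assert s1 <= s2

    def test_high_omega_fraction(self):
        mapping = {f"g{i}": "shoot" for i in range(20)}
        segs = seg_frame(mapping)
        dup = dup_frame([(f"g{i}", f"p{i}", "WGD") for i in range(20)])
        omega = pd.Series({f"g{i}": (1.2 if i < 2 else 0.3)
                           for i in range(20)})
        res = tag_shoot_biased_wgd(segs, dup, "shoot", omega=omega)
        assert res["high_omega_fraction"] == pytest.approx(0.1)

    def test_unknown_class_rejected(self):
        segs = seg_frame({"g1": "shoot"})
        with pytest.raises(ValueError, match="retro"):
            tag_shoot_biased_wgd(segs, dup_frame([("g1", "p1", "retro")]),
                                 "shoot")


class TestAncestralState:
    def outgroup(self, small_ages, seed=12, n_seg=10):
        genes = [f"o{i}" for i in range(400)]
        ages = pd.Series(np.repeat(np.arange(1, 5), 100), index=genes)
        expr, tmap, truth = simulate_expression(
            ages, tissues=("root", "leaf", "inflorescence"),
            multi_stage_tissue="stem", n_stages=2, peak_stages=(0,),
            n_seg_per_tissue=n_seg, seed=seed,
        )
        return expr, tmap, truth

    def test_partition_conserved(self, small_ages):
        expr, tmap, _ = self.outgroup(small_ages)
        omap = pd.DataFrame({"focal": [f"g{i}" for i in range(120)],
                             "ortholog": [f"o{i}" for i in range(100)]
                             + [f"missing{i}" for i in range(20)]})
        res = ancestral_state_comparison(
            [f"g{i}" for i in range(120)], omap, expr, tmap
        )
        assert res["specific"] + res["broad"] + res["unassessed"] == res["mapped"]
        assert res["unassessed"] == 20

    def test_uniform_outgroup_no_specific(self, small_ages):
        genes = [f"o{i}" for i in range(50)]
        expr = pd.DataFrame(5.0, index=genes, columns=["root", "leaf", "stem"])
        tmap = {c: c for c in expr.columns}
        omap = pd.DataFrame({"focal": ["g1"] * 50, "ortholog": genes})
        res = ancestral_state_comparison(["g1"], omap, expr, tmap)
        assert res["specific"] == 0 and res["broad"] == 50

    def test_planted_specific_fraction_recovered(self, small_ages):
        expr, tmap, truth = self.outgroup(small_ages, seed=21, n_seg=15)
        planted = truth.data["seg"]
        # map every outgroup gene to a focal SBW gene
        omap = pd.DataFrame({"focal": [f"f{i}" for i in range(400)],
                             "ortholog": list(expr.index)})
        res = ancestral_state_comparison([f"f{i}" for i in range(400)],
                                         omap, expr, tmap)
        want = len(planted) / 400
        got = res["specific"] / res["mapped"]
        assert abs(got - want) <= 0.03
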