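"""Dye-swap pooling, per-gene t statistics, fold changes and DEG calling."""

import dataclasses
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import special

import dyeswap as ds

from test_preprocess import ratio_set_from


def pair_from_values(values_1: dict[str, list], values_2: dict[str, list]):
    def build(vals, orientation, slide_id):
        rows = []
        for gene, ms in vals.items():
            for i, m in enumerate(ms):
                rows.append({"CLONE_ID": gene, "GENE": gene, "BLOCK_ROW": 1,
                             "BLOCK_COL": 1, "REP": i + 1, "A": 10.0,
                             "M_raw": m, "M": m})
        return ds.RatioSet(slide_id=slide_id, condition_id="c1",
                           dye_orientation=orientation,
                           data=pd.DataFrame(rows), meta_grid=(12, 4),
                           stage="block_normalized")
    return (build(values_1, "test_ch2", "S01"),
            build(values_2, "test_ch1", "S02"))


class TestCombineDyeSwap:
    def test_six_plus_six_unit_spots_give_twelve_ones(self):
        r1, r2 = pair_from_values({"g": [1.0] * 6}, {"g": [1.0] * 6})
        matrix = ds.combine_dye_swap(r1, r2)
        assert np.array_equal(matrix.values["g"], np.ones(12))

    def test_gene_below_three_spots_on_either_slide_is_dropped(self):
        r1, r2 = pair_from_values({"g": [1.0] * 3, "h": [1.0] * 3},
                                  {"g": [1.0] * 2, "h": [1.0] * 3})
        matrix = ds.combine_dye_swap(r1, r2)
        assert "g" not in matrix.values
        assert len(matrix.values["h"]) == 6

    def test_same_orientation_pair_is_design_error(self):
        r1, r2 = pair_from_values({"g": [1.0] * 6}, {"g": [1.0] * 6})
        r2 = dataclasses.replace(r2, dye_orientation="test_ch2")
        with pytest.raises(ds.DesignError, match="orientation"):
            ds.combine_dye_swap(r1, r2)

    def test_different_conditions_are_a_design_error(self):
        r1, r2 = pair_from_values({"g": [1.0] * 6}, {"g": [1.0] * 6})
        r2 = dataclasses.replace(r2, condition_id="other")
        with pytest.raises(ds.DesignError, match="condition"):
            ds.combine_dye_swap(r1, r2)

    def test_planted_effect_is_recovered_within_clt_bound(
            self, fullsize_experiment, fullsize_stats):
        """Planted |log2 FC| = 1.25 with spot SD 0.3 and n = 12 spots:
        at least 99% of planted gene means land within 3 standard errors
        (3 * 0.3 / sqrt(12)) of the truth."""
        truth = fullsize_experiment.truth.log2_fc["cond_a"]
        st_ = fullsize_stats.set_index("gene")
        planted = sorted(fullsize_experiment.truth.de_genes("cond_a")
                         & set(st_.index))
        bound = 3 * 0.3 / math.sqrt(12)
        hits = [abs(st_.loc[g, "mean_log2er"] - truth[g]) <= bound
                for g in planted]
        assert np.mean(hits) >= 0.99


class TestGeneTTest:
    def test_all_zero_vector_is_degenerate_null(self):
        res = ds.gene_t_test(np.zeros(12))
        assert res.degenerate and res.p == 1.0

    def test_antisymmetric_pair_has_zero_t(self):
        res = ds.gene_t_test(np.array([1.0, -1.0]))
        assert res.t == 0.0 and res.p == 1.0

    def test_constant_nonzero_vector_is_degenerate_significant(self):
        res = ds.gene_t_test(np.full(5, 0.3))
        assert res.degenerate and res.p == 0.0

    def test_needs_two_values(self):
        with pytest.raises(ds.ParameterError):
            ds.gene_t_test(np.array([1.0]))

    def test_p_matches_incomplete_beta_oracle(self):
        """Two-sided p equals the textbook t CDF via the regularized
        incomplete beta function, to 1e-10, on seeded random vectors."""
        rng = np.random.default_rng(31)
        for _ in range(200):
            n = int(rng.integers(3, 15))
            x = rng.normal(rng.uniform(-1, 1), rng.uniform(0.1, 2.0), n)
            res = ds.gene_t_test(x)
            df = n - 1
            p_oracle = special.betainc(df / 2.0, 0.5,
                                       df / (df + res.t ** 2))
            assert res.p == pytest.approx(p_oracle, abs=1e-10)


class TestFoldChange:
    @pytest.mark.parametrize("m, fc", [
        (0.0, 1.0),
        (1.0, 2.0),
        (-1.0, -2.0),
        (2.0, 4.0),
    ])
    def test_exact_mappings(self, m, fc):
        assert ds.fold_change(m) == fc

    def test_deep_downregulation_uses_sign_magnitude_convention(self):
        """A 74.54-fold down-regulated gene reads -74.54 (linear magnitude
        with a sign), not a log2 value."""
        m = -math.log2(74.54)
        assert ds.fold_change(m) == pytest.approx(-74.54, abs=1e-12)

    @settings(derandomize=True, max_examples=200)
    @given(st.floats(min_value=-20, max_value=20,
                     allow_nan=False, allow_infinity=False))
    def test_round_trip_recovers_log_ratio(self, m):
        assert ds.log2er_from_fold_change(ds.fold_change(m)) == \
            pytest.approx(m, abs=1e-12)

    def test_magnitude_is_at_least_one(self):
        for m in np.linspace(-5, 5, 41):
            assert abs(ds.fold_change(m)) >= 1.0


class TestCallDegs:
    @staticmethod
    def stats_row(gene, p, fc):
        m = ds.log2er_from_fold_change(fc) if abs(fc) >= 1 else 0.0
        return {"gene": gene, "gene_name": gene, "n": 12, "mean_log2er": m,
                "t": 0.0, "p": p, "fc": fc,
                "direction": "up" if fc >= 0 else "down",
                "is_deg": False, "degenerate": False}

    def test_threshold_boundaries(self):
        stats = pd.DataFrame([
            self.stats_row("a", 0.005, 1.4),    # fails FC
            self.stats_row("b", 0.02, 3.0),     # fails p
            self.stats_row("c", 0.005, 1.5),    # boundary FC: called
            self.stats_row("d", 0.01, 1.6),     # boundary p: not called
            self.stats_row("e", 0.001, -2.0),   # down DEG
        ])
        table = ds.call_degs(stats, "c1")
        assert table.deg_genes == {"c", "e"}
        assert table.counts == (2, 1, 1)

    def test_counts_identity_holds(self, tiny_stats):
        table = ds.call_degs(tiny_stats, "cond_a")
        total, up, down = table.counts
        assert total == up + down == len(table.degs)

    def test_null_type_one_error_is_calibrated(self, fullsize_stats,
                                               fullsize_experiment):
        """Among null genes, the p < 0.01 fraction sits within 3 binomial
        SDs of 0.01 (no fold-change filter applied)."""
        nulls = fullsize_experiment.truth.null_genes("cond_a")
        sub = fullsize_stats[fullsize_stats["gene"].isin(nulls)]
        frac = (sub["p"] < 0.01).mean()
        tol = 3 * math.sqrt(0.01 * 0.99 / len(sub))
        assert abs(frac - 0.01) <= tol

    def test_power_on_planted_effects(self, fullsize_stats,
                                      fullsize_experiment):
        """Planted |log2 FC| = 1.25, spot SD 0.3, n = 12: at least 90% of
        planted genes are called under p < 0.01 and |FC| >= 1.5."""
        table = ds.call_degs(fullsize_stats, "cond_a")
        planted = fullsize_experiment.truth.de_genes("cond_a") \
            & set(fullsize_stats["gene"])
        sens = len(table.deg_genes & planted) / len(planted)
        assert sens >= 0.90

    def test_invalid_thresholds_are_parameter_errors(self, tiny_stats):
        with pytest.raises(ds.ParameterError):
            ds.call_degs(tiny_stats, "c1", p_threshold=0.0)
        with pytest.raises(ds.ParameterError):
            ds.call_degs(tiny_stats, "c1", fc_threshold=0.5)


class TestDyeSwapAntisymmetry:
    def test_relabeling_negates_means_and_preserves_p(self, tiny_experiment,
                                                      tiny_stats):
        """Exchanging test and control labels negates every gene's mean
        log2 ER and fold change exactly and leaves p values unchanged."""
        exp = tiny_experiment
        s1, s2 = (exp.slides[0], exp.slides[1])
        flipped = []
        for s in (s1, s2):
            other = "test_ch1" if s.dye_orientation == "test_ch2" \
                else "test_ch2"
            flipped.append(dataclasses.replace(s, dye_orientation=other))
        rs = [ds.preprocess_slide(s)[0] for s in flipped]
        matrix = ds.combine_dye_swap(rs[0], rs[1])
        neg = ds.gene_statistics(matrix).set_index("gene")
        orig = tiny_stats.set_index("gene")
        assert set(neg.index) == set(orig.index)
        assert (neg["mean_log2er"] + orig["mean_log2er"]).abs().max() == 0.0
        assert (neg["p"] - orig["p"]).abs().max() == 0.0
        assert (neg["fc"] + orig["fc"]).abs().max() == 0.0


class TestCompareConditions:
    @staticmethod
    def table_from(genes_all, degs, cond):
        rows = [TestCallDegs.stats_row(g, 0.001 if g in degs else 0.5,
                                       2.0 if g in degs else 1.1)
                for g in genes_all]
        return ds.call_degs(pd.DataFrame(rows), cond)

    def test_simple_partition(self):
        universe = ["g1", "g2", "g3", "g4", "g5"]
        a = self.table_from(universe, {"g1", "g2", "g3"}, "A")
        b = self.table_from(universe, {"g2", "g3", "g4"}, "B")
        venn = ds.compare_conditions(a, b)
        assert venn.only_a == {"g1"}
        assert venn.only_b == {"g4"}
        assert venn.common == {"g2", "g3"}

    def test_identical_tables_share_everything(self):
        universe = ["g1", "g2", "g3"]
        a = self.table_from(universe, {"g1", "g2"}, "A")
        venn = ds.compare_conditions(a, a)
        assert venn.only_a == venn.only_b == set()
        assert venn.common == {"g1", "g2"}

    def test_sum_identities(self):
        universe = [f"g{i}" for i in range(40)]
        a = self.table_from(universe, set(universe[:15]), "A")
        b = self.table_from(universe, set(universe[10:30]), "B")
        venn = ds.compare_conditions(a, b)
        na, nb, nc = venn.counts
        assert na + nc == len(a.deg_genes)
        assert nb + nc == len(b.deg_genes)
        assert not (venn.only_a & venn.only_b)
        assert not (venn.only_a & venn.common)

    def test_planted_tissue_specific_and_shared_degs_are_recovered(self):
        """Hand-planted condition-specific and shared effects at generous
        size come back as exactly the planted partition."""
        config = ds.GeneratorConfig(
            n_clones=150, category_scheme={},
            conditions=[("slow_24h", "slow", 24, "LPS"),
                        ("fast_24h", "fast", 24, "LPS")],
            de_fraction=0.0, low_quality_fraction=0.02, seed=17)
        clones = [f"clone_{i:04d}" for i in range(1, 151)]
        log2fc = pd.DataFrame(0.0, index=clones,
                              columns=["slow_24h", "fast_24h"])
        only_slow = clones[0:8]
        only_fast = clones[8:16]
        shared = clones[16:24]
        log2fc.loc[only_slow, "slow_24h"] = 2.0
        log2fc.loc[only_fast, "fast_24h"] = -2.0
        log2fc.loc[shared, ["slow_24h", "fast_24h"]] = 2.0
        truth = ds.TruthTable(log2_fc=log2fc, is_de=log2fc != 0.0,
                              low_quality=pd.DataFrame(
                                  columns=["SLIDE_ID", "CLONE_ID", "REP",
                                           "MECHANISM"]),
                              enriched_category="")
        exp = ds.simulate_experiment(config, truth=truth, seed=17)
        rs = {s.slide_id: ds.preprocess_slide(s)[0] for s in exp.slides}
        tables = {}
        for cond in ("slow_24h", "fast_24h"):
            a, b = exp.design.pairs[cond]
            stats = ds.gene_statistics(ds.combine_dye_swap(rs[a], rs[b]))
            tables[cond] = ds.call_degs(stats, cond)
        venn = ds.compare_conditions(tables["slow_24h"], tables["fast_24h"])
        assert venn.only_a == set(only_slow)
        assert venn.only_b == set(only_fast)
        assert venn.common == set(shared)
        assert venn.common_detail["same_direction"].all()
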