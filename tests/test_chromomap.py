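import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from genagephen import chromomap
from genagephen.config import AUTOSOMES
from genagephen.synthdata import SimulationConfig, simulate_tables
from genagephen.ingest import build_disease_profiles
from conftest import make_profiles


def records_frame(rows):
    return pd.DataFrame(rows, columns=["gene_id", "chromosome", "branch"])


class TestCountByChromosome:
    def test_simple_tally(self, framework):
        rec = records_frame([("G1", "1", "br0"), ("G2", "1", "br0"),
                             ("G3", "1", "br3")])
        prof = make_profiles([("G1", ["OP1"], "br0")])
        counts = chromomap.count_by_chromosome(rec, prof, framework)
        assert counts.loc["1", "total"] == 3
        assert counts.loc["1", "disease"] == 1

    def test_sex_classes_partition_disease_total(self, framework):
        rng = np.random.default_rng(0)
        rows, rec = [], []
        classes = ["none", "male_specific", "female_specific", "both"]
        for i in range(80):
            chrom = rng.choice(["1", "2", "X"])
            rec.append((f"G{i}", chrom, "br0"))
            rows.append((f"G{i}", ["OP7"], "br0", rng.choice(classes), chrom))
        counts = chromomap.count_by_chromosome(records_frame(rec),
                                               make_profiles(rows), framework)
        partition = (counts["male_specific"] + counts["female_specific"]
                     + counts["both"] + counts["sex_none"])
        assert (partition == counts["disease"]).all()
        assert (counts["reproductive"] + counts["non_reproductive"]
                == counts["disease"]).all()

    def test_matches_brute_force_group_by(self, framework):
        rng = np.random.default_rng(1)
        chroms = [str(c) for c in rng.integers(1, 23, size=200)]
        rec = records_frame([(f"G{i}", c, "br0") for i, c in enumerate(chroms)])
        sel = rng.random(200) < 0.3
        prof = make_profiles([(f"G{i}", ["OP1"], "br0", "none", chroms[i])
                              for i in np.flatnonzero(sel)])
        counts = chromomap.count_by_chromosome(rec, prof, framework)
        for c in set(chroms):
            assert counts.loc[c, "total"] == chroms.count(c)
            assert counts.loc[c, "disease"] == sum(
                1 for i in np.flatnonzero(sel) if chroms[i] == c)

    def test_age_split_partitions_disease(self, framework):
        rec = records_frame([("G1", "1", "br0"), ("G2", "1", "br5")])
        prof = make_profiles([("G1", ["OP1"], "br0"), ("G2", ["OP1"], "br5")])
        counts = chromomap.count_by_chromosome(rec, prof, framework)
        assert counts.loc["1", "ancient_disease"] == 1
        assert counts.loc["1", "young_disease"] == 1


def counts_from(totals, disease):
    idx = pd.Index([str(i) for i in range(1, len(totals) + 1)],
                   name="chromosome")
    return pd.DataFrame({"total": totals, "disease": disease}, index=idx)


class TestAutosomalOLS:
    def test_collinear_points(self):
        counts = counts_from([1, 2, 3], [2, 4, 6])
        reg = chromomap.fit_autosomal_ols(counts)
        assert reg.slope == pytest.approx(2.0)
        assert reg.intercept == pytest.approx(0.0, abs=1e-10)
        assert reg.r_squared == pytest.approx(1.0)

    def test_matches_normal_equation_oracle(self):
        x = np.array([10.0, 20.0, 30.0, 40.0, 50.0])
        y = np.array([3.0, 7.0, 6.0, 11.0, 12.0])
        counts = counts_from(x, y)
        reg = chromomap.fit_autosomal_ols(counts)
        X = np.column_stack([np.ones(5), x])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert reg.intercept == pytest.approx(beta[0])
        assert reg.slope == pytest.approx(beta[1])
        resid = y - (beta[0] + beta[1] * x)
        assert resid.sum() == pytest.approx(0.0, abs=1e-9)

    def test_recovers_planted_slope(self):
        rng = np.random.default_rng(6)
        totals = rng.integers(200, 2500, size=22).astype(float)
        disease = 0.23 * totals + rng.normal(0, 8, size=22)
        counts = counts_from(totals, np.maximum(disease, 0))
        reg = chromomap.fit_autosomal_ols(counts)
        se = 8 / np.sqrt(np.sum((totals - totals.mean()) ** 2))
        assert abs(reg.slope - 0.23) < 3 * se

    def test_sex_chromosomes_excluded_from_fit_but_evaluated(self, framework):
        idx = pd.Index([str(i) for i in range(1, 23)] + ["X", "Y"],
                       name="chromosome")
        totals = np.arange(1, 25, dtype=float) * 10
        disease = 2.0 * totals
        disease[-2:] = [900.0, 5.0]  # X wildly high, Y low; must not move fit
        counts = pd.DataFrame({"total": totals, "disease": disease}, index=idx)
        reg = chromomap.fit_autosomal_ols(counts)
        assert reg.slope == pytest.approx(2.0)
        assert reg.excess_pct["X"] == pytest.approx(
            100 * (900 - 2 * 230) / (2 * 230))

    def test_degenerate_x_variance_errors(self):
        with pytest.raises(ValueError, match="variance"):
            chromomap.fit_autosomal_ols(counts_from([5, 5, 5], [1, 2, 3]))


class TestExcessRate:
    @pytest.mark.parametrize("n,e,expected", [
        (99, 52.73, 87.75), (154, 156.59, -1.65)])
    def test_printed_observed_expected_pairs(self, n, e, expected):
        assert chromomap.excess_rate(n, e) == pytest.approx(expected, abs=0.005)

    def test_zero_when_observed_equals_expected(self):
        assert chromomap.excess_rate(52.73, 52.73) == 0.0

    @settings(max_examples=40, derandomize=True)
    @given(st.floats(0.1, 1e4), st.floats(0.1, 1e4))
    def test_antisymmetric_around_expectation(self, e, d):
        up = chromomap.excess_rate(e + d, e)
        down = chromomap.excess_rate(e - d, e)
        assert up == pytest.approx(-down)

    def test_nonpositive_expectation_rejected(self):
        with pytest.raises(ValueError):
            chromomap.excess_rate(10, 0)


class TestAlphaD:
    @pytest.mark.parametrize("m,f,expected", [(80, 9, 8.89), (38, 21, 1.81)])
    def test_printed_count_ratios(self, m, f, expected):
        assert chromomap.alpha_d(m, f) == pytest.approx(expected, abs=0.005)

    def test_equal_counts(self):
        assert chromomap.alpha_d(7, 7) == 1.0

    def test_zero_female_count_flagged(self):
        with pytest.raises(ValueError, match="undefined"):
            chromomap.alpha_d(5, 0)


class TestProportionRatio:
    def test_y_versus_autosome_printed_counts(self):
        pr = chromomap.proportion_ratio(17, 45, 38, 853)
        assert pr.ratio == pytest.approx(8.48, abs=0.005)
        assert pr.fisher_p < 1e-4

    def test_x_versus_autosome_printed_counts(self):
        pr = chromomap.proportion_ratio(80, 840, 38, 853)
        assert pr.ratio == pytest.approx(2.14, abs=0.005)
        assert pr.ci_low < 2.14 < pr.ci_high

    def test_identical_fractions_give_unity(self):
        pr = chromomap.proportion_ratio(10, 100, 10, 100)
        assert pr.ratio == 1.0

    @settings(max_examples=30, derandomize=True)
    @given(st.integers(2, 10))
    def test_invariant_under_common_scaling(self, s):
        base = chromomap.proportion_ratio(12, 200, 30, 400)
        scaled = chromomap.proportion_ratio(12 * s, 200 * s, 30 * s, 400 * s)
        assert scaled.ratio == pytest.approx(base.ratio)

    def test_odds_ratio_reported_separately(self):
        pr = chromomap.proportion_ratio(20, 40, 10, 40)
        assert pr.ratio == pytest.approx(2.0)
        assert pr.odds_ratio == pytest.approx((20 * 30) / (20 * 10))


class TestAgeSplitAnalysis:
    def test_per_epoch_alpha_d_matches_hand_count(self, framework):
        rows = []
        for i in range(6):
            rows.append((f"M{i}", ["OP7"], "br0", "male_specific", "1"))
        for i in range(2):
            rows.append((f"F{i}", ["OP7"], "br0", "female_specific", "1"))
        rows.append(("M9", ["OP7"], "br5", "male_specific", "2"))
        rows.append(("F9", ["OP7"], "br5", "female_specific", "2"))
        prof = make_profiles(rows)
        rec = records_frame([(r[0], r[4], r[2]) for r in rows])
        counts = chromomap.count_by_chromosome(rec, prof, framework)
        result = chromomap.age_split_analysis(counts, prof, framework)
        assert result["alpha_d_by_epoch"]["Euteleostomi"]["alpha_d"] == \
            pytest.approx(3.0)
        assert result["alpha_d_by_epoch"]["Eutheria"]["alpha_d"] == \
            pytest.approx(1.0)

    def test_young_male_x_enrichment_direction(self):
        # construction oracle: planted young X relative risk far above the
        # ancient one must surface as a larger young male excess rate on X
        config = SimulationConfig(
            seed=5, genes_per_branch={f"br{i}": 2500 for i in range(7)},
            rho_x_male_ancient=1.0, rho_x_male_young=3.0)
        bundle = simulate_tables(config)
        genes = bundle.genes
        prof = make_profiles([
            (g.gene_id, ["OP7"], g.branch, g.sex_class_true, g.chromosome)
            for g in genes[genes.is_disease].itertuples()])
        from genagephen.age_framework import AgeFramework
        fw = AgeFramework()
        counts = chromomap.count_by_chromosome(
            records_frame(list(zip(genes.gene_id, genes.chromosome,
                                   genes.branch))), prof, fw)
        result = chromomap.age_split_analysis(counts, prof, fw)
        young = result["splits"]["young"]["male_specific"]["excess_pct_X"]
        ancient = result["splits"]["ancient"]["male_specific"]["excess_pct_X"]
        assert young > ancient

    def test_balanced_data_gives_alpha_d_near_one(self, framework):
        rng = np.random.default_rng(3)
        rows = []
        for i in range(400):
            cls = "male_specific" if rng.random() < 0.5 else "female_specific"
            branch = rng.choice(framework.labels)
            rows.append((f"G{i}", ["OP7"], branch, cls, "1"))
        prof = make_profiles(rows)
        rec = records_frame([(r[0], "1", r[2]) for r in rows])
        counts = chromomap.count_by_chromosome(rec, prof, framework)
        result = chromomap.age_split_analysis(counts, prof, framework)
        vals = [v["alpha_d"] for v in result["alpha_d_by_epoch"].values()
                if v["alpha_d"] is not None]
        assert all(0.6 < v < 1.67 for v in vals)
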