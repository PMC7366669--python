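"""Co-labelling statistics: correlations, categorisation, chi-square and
conditional proportions against hand-computed oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from microquant import colabel, simulate
from microquant.colabel import FourWayCounts, HighLowThresholds


def pi_frame(a, b, case_id="C1"):
    return pd.DataFrame(
        {"case_id": case_id, "pi_hla_dr": np.asarray(a, float),
         "pi_moi": np.asarray(b, float)}
    )


class TestPearsonPooled:
    def test_identity_gives_r_1(self):
        x = np.arange(10, 60, 5.0)
        report = colabel.pearson_pooled(pi_frame(x, x))
        assert report.r == pytest.approx(1.0)
        assert report.band == "strong"

    def test_reflection_gives_r_minus_1(self):
        x = np.arange(10, 60, 5.0)
        report = colabel.pearson_pooled(pi_frame(x, 255.0 - x))
        assert report.r == pytest.approx(-1.0)

    def test_zero_variance_flagged(self):
        report = colabel.pearson_pooled(pi_frame([5, 5, 5], [1, 2, 3]))
        assert report.undefined and math.isnan(report.r)

    def test_planted_rho_recovered(self):
        """Bivariate-normal sampling oracle: rho=0.5 at n=10,000 lands in
        [0.45, 0.55] at this seed."""
        rng = np.random.default_rng(13)
        cov = [[1.0, 0.5], [0.5, 1.0]]
        x, y = rng.multivariate_normal([100, 100], cov, size=10_000).T
        report = colabel.pearson_pooled(pi_frame(x, y))
        assert 0.45 <= report.r <= 0.55
        assert report.band == "moderate"


class TestBanding:
    @pytest.mark.parametrize(
        "r,band",
        [
            (0.0, "weak"), (0.2, "weak"), (0.3, "weak"),
            (0.31, "moderate"), (0.5, "moderate"), (0.79, "moderate"),
            (0.8, "strong"), (0.85, "strong"), (1.0, "strong"),
            (-0.2, "weak"), (-0.9, "strong"),
            (float("nan"), "undefined"),
        ],
    )
    def test_cutoffs(self, r, band):
        assert colabel.interpret_correlation(r) == band


class TestTopDecile:
    def test_exact_tenth_of_distinct_values(self):
        cells = pi_frame(np.arange(20.0), np.arange(20.0)[::-1])
        subset, report = colabel.top_decile_subset(cells, "hla_dr")
        assert len(subset) == 2
        assert set(subset["pi_hla_dr"]) == {18.0, 19.0}
        assert report.subset == "top10_by_hla_dr"
        assert report.undefined  # two cells cannot support a correlation

    def test_ties_at_cut_all_included(self):
        values = np.concatenate([np.arange(85.0), [200.0] * 15])
        cells = pi_frame(values, values)
        subset, _ = colabel.top_decile_subset(cells, "hla_dr")
        assert len(subset) == 15
        assert (subset["pi_hla_dr"] == 200.0).all()

    def test_matches_sort_and_slice_oracle(self):
        rng = np.random.default_rng(4)
        a, b = rng.integers(0, 256, 137), rng.integers(0, 256, 137)
        cells = pi_frame(a, b)
        subset, _ = colabel.top_decile_subset(cells, "moi")
        k = math.ceil(137 / 10)
        cutoff = np.sort(b)[::-1][k - 1]
        oracle = set(np.flatnonzero(b >= cutoff))
        assert set(subset.index) == oracle
        assert oracle <= set(cells.index)  # subset of its input

    def test_needs_ten_cells(self):
        with pytest.raises(ValueError):
            colabel.top_decile_subset(pi_frame([1] * 9, [1] * 9), "moi")


class TestSaturationSensitivity:
    def test_no_saturated_cells_identical_reports(self):
        rng = np.random.default_rng(1)
        cells = pi_frame(rng.integers(0, 200, 50), rng.integers(0, 200, 50))
        out = colabel.saturation_sensitivity(cells)
        assert out["n_excluded"] == 0
        assert out["all"].r == out["unsaturated"].r
        assert out["delta_r"] == 0.0

    def test_all_saturated_flagged(self):
        cells = pi_frame([255] * 5, [255] * 5)
        out = colabel.saturation_sensitivity(cells)
        assert out["all_saturated"] and out["unsaturated"] is None

    def test_clipped_fixture_matches_recomputation(self):
        """Excluding clipped cells equals a brute-force re-correlation on
        the unclipped subset, and never increases n."""
        rng = np.random.default_rng(2)
        x, y = rng.multivariate_normal(
            [200, 200], [[2500, 1500], [1500, 2500]], size=400
        ).T
        cells = pi_frame(np.clip(x, 0, 255).round(), np.clip(y, 0, 255).round())
        out = colabel.saturation_sensitivity(cells)
        mask = (cells["pi_hla_dr"] < 255) & (cells["pi_moi"] < 255)
        assert out["n_excluded"] == int((~mask).sum()) > 0
        r_oracle, _ = stats.pearsonr(cells.loc[mask, "pi_hla_dr"],
                                     cells.loc[mask, "pi_moi"])
        assert out["unsaturated"].r == pytest.approx(r_oracle)
        assert out["delta_r"] == pytest.approx(out["all"].r - r_oracle)
        assert out["unsaturated"].n <= out["all"].n


class TestCategorise:
    def test_all_below_background_all_lowlow(self):
        cells = pi_frame([10, 12, 14, 9], [11, 8, 13, 10])
        cells["iba1_positive"] = True
        cat = colabel.categorize_highlow(
            cells, {"hla_dr": 20.0, "moi": 20.0},
            HighLowThresholds(t_high={"hla_dr": 40.0, "moi": 40.0}),
        )
        counts = colabel.fourway_counts(cat)
        assert counts.n_ll == 4 and counts.total == 4

    def test_zero_threshold_all_highhigh(self):
        cells = pi_frame([30, 40, 50], [35, 45, 55])
        cells["iba1_positive"] = True
        cat = colabel.categorize_highlow(
            cells, {"hla_dr": 20.0, "moi": 20.0},
            HighLowThresholds(t_high={"hla_dr": 0.0, "moi": 0.0}),
        )
        assert colabel.fourway_counts(cat).n_hh == 3

    def test_noise_free_levels_match_planted_states(self, sparse_measured):
        """On a noise-free render the four-way categories equal the
        planted latent states for every Iba1-positive cell."""
        cat = colabel.categorize_highlow(
            sparse_measured, {"hla_dr": 20.0, "moi": 20.0},
            HighLowThresholds(t_high={"hla_dr": 40.0, "moi": 40.0}),
        )
        assert (cat["hla_dr_level"] == cat["hla_state"]).all()
        assert (cat["moi_level"] == cat["moi_state"]).all()

    def test_counts_conserved_pooled_and_per_case(self, sparse_measured):
        cat = colabel.categorize_highlow(
            sparse_measured, {"hla_dr": 20.0, "moi": 20.0}
        )
        n_iba1 = int(sparse_measured["iba1_positive"].sum())
        assert colabel.fourway_counts(cat).total == n_iba1
        per_case = colabel.fourway_by_case(cat)
        assert sum(c.total for c in per_case.values()) == n_iba1

    def test_high_threshold_below_positivity_rejected(self):
        with pytest.raises(ValueError, match="below positivity"):
            HighLowThresholds(t_high={"hla_dr": 10.0, "moi": 40.0},
                              positivity={"hla_dr": 20.0, "moi": 20.0})

    def test_missing_threshold_rejected(self):
        cells = pi_frame([1, 2, 3], [1, 2, 3])
        cells["iba1_positive"] = True
        with pytest.raises(KeyError):
            colabel.categorize_highlow(
                cells, {"hla_dr": 20.0, "moi": 20.0},
                HighLowThresholds(t_high={"hla_dr": 40.0}),
            )


class TestChiSquare:
    def test_perfect_independence(self):
        out = colabel.chi_square_independence(FourWayCounts(10, 10, 10, 10))
        assert out["chi2"] == 0.0 and out["p"] == 1.0 and out["df"] == 1

    def test_hand_formula_balanced_association(self):
        """(30,10,10,30): all expected counts are 20, so chi2 =
        4 * (10^2/20) = 20; p equals the chi2(1) upper tail."""
        out = colabel.chi_square_independence(FourWayCounts(30, 10, 10, 30))
        assert out["chi2"] == pytest.approx(20.0)
        assert out["p"] == pytest.approx(stats.chi2.sf(20.0, df=1))

    def test_yates_correction_flag(self):
        plain = colabel.chi_square_independence(FourWayCounts(30, 10, 10, 30))
        yates = colabel.chi_square_independence(
            FourWayCounts(30, 10, 10, 30), yates=True
        )
        assert yates["chi2"] < plain["chi2"]

    def test_small_expected_count_warns(self):
        with pytest.warns(UserWarning, match="exact"):
            colabel.chi_square_independence(FourWayCounts(2, 3, 3, 40))

    def test_zero_expected_count_rejected(self):
        with pytest.raises(ValueError, match="expected"):
            colabel.chi_square_independence(FourWayCounts(0, 0, 10, 10))


def cohort_from_counts(counts_per_case: dict) -> pd.DataFrame:
    """Expand per-case four-way counts into a categorised cell table."""
    rows = []
    for case_id, (hh, hl, lh, ll) in counts_per_case.items():
        for n, ha, ma in ((hh, "high", "high"), (hl, "high", "low"),
                          (lh, "low", "high"), (ll, "low", "low")):
            rows += [{"case_id": case_id, "hla_dr_level": ha,
                      "moi_level": ma}] * n
    return pd.DataFrame(rows)


class TestConditionalProportions:
    def test_equal_percentages_give_t0_p1(self):
        cells = cohort_from_counts(
            {"A": (10, 10, 10, 10), "B": (20, 20, 20, 20),
             "C": (5, 5, 5, 5)}
        )
        out = colabel.conditional_proportion_test(cells)
        assert out["t"] == 0.0 and out["p"] == 1.0

    def test_matches_pooled_variance_formula(self):
        """Closed-form oracle for the two-sample pooled-variance t."""
        counts = {"A": (30, 10, 12, 28), "B": (22, 18, 9, 31),
                  "C": (35, 5, 15, 25), "D": (28, 12, 10, 30)}
        out = colabel.conditional_proportion_test(cohort_from_counts(counts))
        a = np.array([100 * hh / (hh + hl) for hh, hl, _, _ in counts.values()])
        b = np.array([100 * lh / (lh + ll) for _, _, lh, ll in counts.values()])
        n1, n2 = len(a), len(b)
        sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2)
        t_hand = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / n1 + 1 / n2))
        p_hand = 2 * stats.t.sf(abs(t_hand), df=n1 + n2 - 2)
        assert out["t"] == pytest.approx(t_hand)
        assert out["p"] == pytest.approx(p_hand)
        assert out["df"] == n1 + n2 - 2

    def test_empty_group_case_excluded(self, caplog):
        cells = cohort_from_counts(
            {"A": (10, 10, 10, 10), "B": (15, 5, 10, 10),
             "C": (0, 0, 10, 10)}
        )
        with caplog.at_level("WARNING", logger="microquant.colabel"):
            out = colabel.conditional_proportion_test(cells)
        assert out["n_cases"] == 2
        assert "C" in caplog.text

    def test_planted_dependence_orders_groups_in_every_case(self):
        """log OR = 2: the MOI-high percentage inside the HLA-DR-high
        group exceeds the HLA-DR-low group in every simulated case."""
        rng = np.random.default_rng(17)
        probs = simulate.joint_highlow_probs(0.5, 0.4, 2.0)
        counts = {
            f"C{i}": tuple(rng.multinomial(400, probs)) for i in range(6)
        }
        out = colabel.conditional_proportion_test(cohort_from_counts(counts))
        per_case = out["per_case"]
        assert (
            per_case["pct_outcome_high_in_group_high"]
            > per_case["pct_outcome_high_in_group_low"]
        ).all()
        assert out["p"] < 0.05

    def test_both_grouping_directions(self):
        counts = {"A": (30, 10, 12, 28), "B": (22, 18, 9, 31)}
        cells = cohort_from_counts(counts)
        by_hla = colabel.conditional_proportion_test(cells, group_by="hla_dr",
                                                     outcome="moi")
        by_moi = colabel.conditional_proportion_test(cells, group_by="moi",
                                                     outcome="hla_dr")
        hh, hl, lh, ll = counts["A"]
        assert by_hla["per_case"].iloc[0]["pct_outcome_high_in_group_high"] == (
            pytest.approx(100 * hh / (hh + hl))
        )
        assert by_moi["per_case"].iloc[0]["pct_outcome_high_in_group_high"] == (
            pytest.approx(100 * hh / (hh + lh))
        )
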