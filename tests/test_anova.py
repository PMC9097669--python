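"""Balanced factorial ANOVA, LSD separation, correlations, normality."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fertrial import (
    DomainError,
    IntegrityError,
    descriptive_stats,
    fit_factorial_anova,
    interaction_separation,
    letter_groups,
    lsd_value,
    pearson_matrix,
    shapiro_wilk_check,
)
from fertrial import simulate as sim
from fertrial.anova import cell_means, significance_stars


def brute_force_ss(frame, trait):
    """Independent textbook oracle: sums of squares from marginal-mean
    deviations computed with plain loops."""
    y = {(r.soil, r.treatment, r.block): getattr(r, trait)
         for r in frame.itertuples()}
    soils = sorted({s for s, _, _ in y})
    trts = sorted({t for _, t, _ in y})
    blocks = sorted({b for _, _, b in y})
    grand = sum(y.values()) / len(y)

    def mean(keys):
        vals = [y[k] for k in keys]
        return sum(vals) / len(vals)

    ss = {}
    ss["replication"] = sum(
        len(soils) * len(trts)
        * (mean([(s, t, b) for s in soils for t in trts]) - grand) ** 2
        for b in blocks
    )
    ss["soil"] = sum(
        len(trts) * len(blocks)
        * (mean([(s, t, b) for t in trts for b in blocks]) - grand) ** 2
        for s in soils
    )
    ss["fertilizer"] = sum(
        len(soils) * len(blocks)
        * (mean([(s, t, b) for s in soils for b in blocks]) - grand) ** 2
        for t in trts
    )
    ss["soil:fertilizer"] = sum(
        len(blocks) * (
            mean([(s, t, b) for b in blocks])
            - mean([(s, t2, b) for t2 in trts for b in blocks])
            - mean([(s2, t, b) for s2 in soils for b in blocks])
            + grand
        ) ** 2
        for s in soils for t in trts
    )
    ss_total = sum((v - grand) ** 2 for v in y.values())
    ss["residual"] = ss_total - sum(ss.values())
    ss["total"] = ss_total
    return ss


class TestFactorialAnova:
    def test_df_structure_matches_pooled_design(self, balanced_frame):
        result = fit_factorial_anova(balanced_frame, "GY")
        assert result.table["df"].tolist() == [2, 1, 7, 7, 30]
        assert result.table["df"].sum() == len(balanced_frame) - 1

    def test_ss_match_brute_force_oracle(self, balanced_frame):
        result = fit_factorial_anova(balanced_frame, "GY")
        oracle = brute_force_ss(balanced_frame, "GY")
        for source in ("replication", "soil", "fertilizer",
                       "soil:fertilizer", "residual"):
            assert result.table.loc[source, "sum_sq"] == pytest.approx(
                oracle[source], rel=1e-8, abs=1e-10
            )

    def test_ss_match_statsmodels(self, balanced_frame):
        smf = pytest.importorskip("statsmodels.formula.api")
        from statsmodels.stats.anova import anova_lm

        fit = smf.ols("GY ~ C(block) + C(soil) * C(treatment)",
                      balanced_frame).fit()
        expected = anova_lm(fit, typ=1)
        result = fit_factorial_anova(balanced_frame, "GY")
        assert result.table["sum_sq"].to_numpy() == pytest.approx(
            expected["sum_sq"].to_numpy(), rel=1e-9
        )
        assert result.table["p"].to_numpy()[:-1] == pytest.approx(
            expected["PR(>F)"].to_numpy()[:-1], rel=1e-9
        )

    def test_ss_decomposition_sums_to_total(self, balanced_frame):
        result = fit_factorial_anova(balanced_frame, "GY")
        y = balanced_frame["GY"].to_numpy()
        ss_total = ((y - y.mean()) ** 2).sum()
        assert result.table["sum_sq"].sum() == pytest.approx(
            ss_total, rel=1e-10
        )

    def test_constant_trait_reports_missing_f(self):
        design = sim.balanced_design()
        frame = sim.generate_trial(
            design, sim.EffectSpec("GY", 5.0), seed=0
        )
        result = fit_factorial_anova(frame, "GY")
        assert (result.table["sum_sq"] == 0).all()
        assert result.table["F"].isna().all()

    def test_nested_blocks_change_df(self, balanced_frame):
        result = fit_factorial_anova(balanced_frame, "GY",
                                     block_structure="nested")
        assert result.table["df"].tolist() == [4, 1, 7, 7, 28]

    def test_unbalanced_rejected(self, balanced_frame):
        with pytest.raises(IntegrityError, match="balanced"):
            fit_factorial_anova(balanced_frame.iloc[:-1], "GY")

    def test_multi_season_rejected(self):
        design = sim.balanced_design(seasons=(2017, 2018))
        frame = sim.generate_trial(
            design, sim.default_grain_yield_effects(), seed=0
        )
        with pytest.raises(IntegrityError, match="pool"):
            fit_factorial_anova(frame, "GY")

    def test_cv_r2_on_hand_worked_fixture(self, small_frame):
        """CV and R2 recomputed by hand from the oracle decomposition on a
        12-plot layout."""
        result = fit_factorial_anova(small_frame, "GY")
        oracle = brute_force_ss(small_frame, "GY")
        df_res = 12 - 1 - 1 - 1 - 2 - 2
        mse = oracle["residual"] / df_res
        grand = small_frame["GY"].mean()
        assert result.table["df"].tolist() == [1, 1, 2, 2, 5]
        assert result.cv_percent == pytest.approx(
            100 * math.sqrt(mse) / grand, rel=1e-9
        )
        assert result.r2_percent == pytest.approx(
            100 * (1 - oracle["residual"] / oracle["total"]), rel=1e-9
        )


class TestDescriptiveStats:
    def test_matches_brute_force_on_synthetic_values(self, balanced_frame):
        table = descriptive_stats(balanced_frame, ["GY"])
        for _, row in table.iterrows():
            values = sorted(
                balanced_frame.loc[balanced_frame["soil"] == row["soil"], "GY"]
            )
            n = len(values)
            assert row["min"] == values[0] and row["max"] == values[-1]
            median = (values[n // 2] if n % 2
                      else 0.5 * (values[n // 2 - 1] + values[n // 2]))
            assert row["median"] == pytest.approx(median)
            assert row["mean"] == pytest.approx(sum(values) / n)
            sd = math.sqrt(sum((v - sum(values) / n) ** 2 for v in values)
                           / (n - 1))
            assert row["sd"] == pytest.approx(sd)

    def test_group_mean_equals_mean_of_cell_means(self):
        """On a balanced layout the per-soil mean equals the mean of its
        treatment means — the identity behind quoting 2.63 t/ha as both."""
        from fertrial.reference import GRAIN_YIELD_MEANS

        vertisol = [v for (s, _), v in GRAIN_YIELD_MEANS.items()
                    if s == "Vertisol"]
        assert np.mean(vertisol) == pytest.approx(2.63, abs=0.005)

    def test_constant_trait_degenerate_spread(self):
        frame = pd.DataFrame({
            "soil": ["V"] * 4, "treatment": list("abcd"),
            "block": [1] * 4, "season": ["pooled"] * 4, "GY": [2.0] * 4,
        })
        row = descriptive_stats(frame, ["GY"]).iloc[0]
        assert row["sd"] == 0.0
        assert row["min"] == row["median"] == row["mean"] == row["max"] == 2.0


class TestLsd:
    def test_zero_mse_gives_zero_lsd(self):
        assert lsd_value(0.0, 30, 3) == 0.0

    def test_reference_magnitude(self):
        """t(0.975, 30) * sqrt(2*0.24/3) = 0.8169; the published biological-
        yield LSD of 0.82 sits inside the interval implied by its rounded
        mean square."""
        assert lsd_value(0.24, 30, 3) == pytest.approx(0.8169, abs=5e-4)
        low = lsd_value(0.235, 30, 3)
        high = lsd_value(0.245, 30, 3)
        assert low <= 0.82 <= high

    def test_quadrupling_n_halves_lsd(self):
        assert lsd_value(0.5, 30, 12) == pytest.approx(
            lsd_value(0.5, 30, 3) / 2
        )

    def test_invalid_alpha_rejected(self):
        with pytest.raises(DomainError):
            lsd_value(0.5, 30, 3, alpha=1.5)


class TestLetterGroups:
    def test_clear_separation(self):
        letters = letter_groups({"x": 10.0, "y": 9.9, "z": 5.0}, 0.5)
        assert letters == {"x": "a", "y": "a", "z": "b"}

    def test_all_within_lsd_single_letter(self):
        letters = letter_groups({"x": 1.0, "y": 1.1, "z": 0.9}, 0.5)
        assert set(letters.values()) == {"a"}

    def test_reference_grain_yield_grouping(self):
        """With LSD 0.2 the top treatment stands alone and the two runner-up
        treatments (3.27 and 3.23) share a letter."""
        means = {"T8": 4.33, "T7": 3.27, "T6": 3.23, "T5": 2.63,
                 "T2": 2.13, "T4": 2.07, "T3": 1.77, "T1": 1.58}
        letters = letter_groups(means, 0.2)
        assert letters["T8"] == "a"
        assert letters["T7"] == letters["T6"]
        assert letters["T8"] not in letters["T7"]

    def test_overlap_produces_multi_letter_labels(self):
        letters = letter_groups({"x": 10.0, "y": 9.7, "z": 9.3}, 0.45)
        assert letters == {"x": "a", "y": "ab", "z": "b"}

    @settings(max_examples=100, derandomize=True)
    @given(
        means=st.lists(st.floats(0, 100), min_size=2, max_size=10),
        lsd=st.floats(0, 50),
    )
    def test_share_letter_iff_within_lsd(self, means, lsd):
        labels = [f"m{i}" for i in range(len(means))]
        letters = letter_groups(dict(zip(labels, means)), lsd)
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                shares = bool(set(letters[a]) & set(letters[b]))
                within = abs(means[i] - means[j]) <= lsd
                assert shares == within

    def test_interaction_separation_uses_pooled_error(self, balanced_frame):
        sep = interaction_separation(balanced_frame, "GY")
        assert len(sep.means) == 16
        assert sep.lsd > 0
        assert all(sep.letters.values())


class TestPearson:
    def test_diagonal_is_one(self, balanced_frame):
        frame = balanced_frame.copy()
        frame["BY"] = frame["GY"] * 2 + 1
        r, p = pearson_matrix(frame, ["GY", "BY"])
        assert r.loc["GY", "GY"] == 1.0
        assert r.loc["GY", "BY"] == pytest.approx(1.0)
        assert np.allclose(r.to_numpy(), r.to_numpy().T)

    def test_recovers_known_correlation(self):
        rng = np.random.default_rng(11)
        cov = [[1.0, 0.7], [0.7, 1.0]]
        x = rng.multivariate_normal([0, 0], cov, size=500)
        frame = pd.DataFrame({"soil": "V", "treatment": "T1",
                              "block": 1, "season": "pooled",
                              "GY": x[:, 0], "BY": 10 + x[:, 1]})
        r, _ = pearson_matrix(frame, ["GY", "BY"])
        assert r.loc["GY", "BY"] == pytest.approx(0.7, abs=0.08)

    def test_zero_variance_trait_is_missing_not_zero(self):
        frame = pd.DataFrame({"GY": [1.0, 2.0, 3.0], "BY": [5.0, 5.0, 5.0]})
        r, p = pearson_matrix(frame, ["GY", "BY"])
        assert math.isnan(r.loc["GY", "BY"])


class TestShapiroWilk:
    def test_normal_samples_mostly_pass(self):
        rng = np.random.default_rng(3)
        passes = sum(
            shapiro_wilk_check(rng.normal(size=200)).normal
            for _ in range(100)
        )
        assert passes >= 90

    def test_exponential_sample_fails(self):
        rng = np.random.default_rng(4)
        result = shapiro_wilk_check(rng.exponential(size=100))
        assert not result.normal

    def test_constant_input_rejected(self):
        with pytest.raises(DomainError):
            shapiro_wilk_check([1.0] * 10)

    def test_n_out_of_range_rejected(self):
        with pytest.raises(DomainError):
            shapiro_wilk_check([1.0, 2.0])


def test_significance_stars_thresholds():
    assert [significance_stars(p) for p in (0.0005, 0.005, 0.03, 0.2)] == [
        "***", "**", "*", "ns"
    ]


def test_cell_means_se_over_blocks(balanced_frame):
    cells = cell_means(balanced_frame, "GY")
    assert len(cells) == 16
    assert (cells["n"] == 3).all()
    one = balanced_frame.query("soil == 'Vertisol' and treatment == 'T1'")["GY"]
    row = cells.query("soil == 'Vertisol' and treatment == 'T1'").iloc[0]
    assert row["se"] == pytest.approx(one.std(ddof=1) / math.sqrt(3))
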