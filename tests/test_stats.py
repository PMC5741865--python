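"""Statistical battery against hand-worked and library oracles."""

import numpy as np
import pandas as pd
import pytest

from apakit.simulate import generate_cohort_measures
from apakit.stats import (
    DegenerateInputError,
    DesignError,
    evaluate_pattern,
    levene,
    mixed_anova,
    one_sample_t,
    paired_t,
    pearson_r,
    run_battery,
    shapiro_wilk,
    tukey_hsd,
    two_sample_t,
    variance_ratio_f,
)


def mixed_table(data):
    """data: {(group, unit, level): value} -> long table."""
    rows = [
        {"unit": f"{g}:{u}", "group": g, "level": lv, "y": v}
        for (g, u, lv), v in data.items()
    ]
    return pd.DataFrame(rows)


# integer fixture whose sums of squares were worked out by hand (exact
# fractions): F_between = 4.5, F_within = 1.5, F_interaction = 37.5,
# each on (1, 4) df
HAND_DATA = {
    ("A", 0, "c1"): 3.0, ("A", 0, "c2"): 5.0,
    ("A", 1, "c1"): 4.0, ("A", 1, "c2"): 7.0,
    ("A", 2, "c1"): 5.0, ("A", 2, "c2"): 6.0,
    ("B", 0, "c1"): 8.0, ("B", 0, "c2"): 4.0,
    ("B", 1, "c1"): 9.0, ("B", 1, "c2"): 6.0,
    ("B", 2, "c1"): 7.0, ("B", 2, "c2"): 5.0,
}


class TestOneSampleT:
    def test_symmetric_sample_gives_t_zero(self):
        res = one_sample_t([-1.0, 0.0, 1.0])
        assert res.statistic == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_hand_arithmetic(self):
        # {1..5}: mean 3, sd sqrt(2.5) -> t = 3 / (sqrt(2.5)/sqrt(5))
        res = one_sample_t([1.0, 2.0, 3.0, 4.0, 5.0])
        assert res.statistic == pytest.approx(3.0 / np.sqrt(0.5), abs=1e-10)
        assert res.df == (4.0,)

    def test_constant_sample_degenerate(self):
        with pytest.raises(DegenerateInputError):
            one_sample_t([2.0, 2.0, 2.0])


class TestPairedT:
    def test_hand_arithmetic(self):
        # differences {1,2,3}: mean 2, sd 1 -> t = 2 / (1/sqrt(3))
        res = paired_t([2.0, 4.0, 6.0], [1.0, 2.0, 3.0])
        assert res.statistic == pytest.approx(2.0 * np.sqrt(3.0), abs=1e-10)
        assert res.df == (2.0,)

    def test_antisymmetry(self):
        x, y = [1.0, 5.0, 2.0, 8.0], [0.5, 7.0, 1.0, 4.0]
        assert paired_t(x, y).statistic == pytest.approx(-paired_t(y, x).statistic)

    def test_identical_inputs_degenerate(self):
        with pytest.raises(DegenerateInputError):
            paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])


class TestPearson:
    def test_perfect_linear_relations(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert pearson_r(x, 2 * x + 1).statistic == pytest.approx(1.0)
        assert pearson_r(x, -x).statistic == pytest.approx(-1.0)

    def test_hand_arithmetic(self):
        # cov = 10, var_x = 10, var_y = 14.8 -> r = 10 / sqrt(148)
        res = pearson_r([1, 2, 3, 4, 5], [2, 1, 4, 3, 6])
        assert res.statistic == pytest.approx(10.0 / np.sqrt(148.0), abs=1e-12)


class TestTwoSampleT:
    def test_identical_groups_t_zero(self):
        res = two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == pytest.approx(0.0)

    def test_pooled_path_matches_textbook_formula(self):
        x, y = [1.0, 2.0, 3.0, 4.0, 5.0], [3.0, 4.0, 5.0, 6.0, 7.0]
        res = two_sample_t(x, y)
        # equal variances 2.5 -> pooled s^2 = 2.5, t = -2 / sqrt(2.5 * 2/5)
        assert res.correction == "none"
        assert res.statistic == pytest.approx(-2.0, abs=1e-10)
        assert res.df == (8.0,)

    def test_welch_gate_engages_under_variance_ratio(self):
        rng = np.random.default_rng(5)
        welch_taken = 0
        for _ in range(100):
            x = rng.normal(0, 1, 14)
            y = rng.normal(0, 3, 14)
            if two_sample_t(x, y).correction == "welch":
                welch_taken += 1
        assert welch_taken >= 80

    def test_variance_ratio_f_two_sided(self):
        rng = np.random.default_rng(9)
        x, y = rng.normal(0, 1, 14), rng.normal(0, 1, 14)
        res = variance_ratio_f(x, y)
        assert res.statistic >= 1.0
        assert 0.0 <= res.p <= 1.0


class TestGates:
    def test_shapiro_location_scale_invariant(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        a = shapiro_wilk(x).statistic
        b = shapiro_wilk(5.0 + 3.0 * x).statistic
        assert a == pytest.approx(b, abs=1e-12)

    def test_shapiro_rejects_exponential(self):
        rng = np.random.default_rng(1)
        assert shapiro_wilk(rng.exponential(size=100)).p < 0.001

    def test_levene_identical_groups_zero(self):
        g = [1.0, 2.0, 3.0, 4.0]
        assert levene([g, g, g]).statistic == pytest.approx(0.0)

    def test_levene_detects_variance_ratio_nine(self):
        rng = np.random.default_rng(2)
        rejected = sum(
            levene([rng.normal(0, 1, 20), rng.normal(0, 3, 20)]).p < 0.05
            for _ in range(50)
        )
        assert rejected >= 40


class TestMixedAnova:
    def run_hand(self):
        return mixed_anova(mixed_table(HAND_DATA), dv="y", subject="unit",
                           within="level", between="group")

    def test_matches_hand_worked_sums_of_squares_exactly(self):
        res = self.run_hand()
        assert res.between.statistic == pytest.approx(4.5, abs=1e-12)
        assert res.within.statistic == pytest.approx(1.5, abs=1e-12)
        assert res.interaction.statistic == pytest.approx(37.5, abs=1e-12)
        assert res.between.df == (1.0, 4.0)
        assert res.interaction.extra["ss"] == pytest.approx(18.75, abs=1e-12)

    def test_location_shift_leaves_f_unchanged(self):
        shifted = {k: v + 17.3 for k, v in HAND_DATA.items()}
        a, b = self.run_hand(), mixed_anova(
            mixed_table(shifted), dv="y", subject="unit", within="level",
            between="group",
        )
        for attr in ("between", "within", "interaction"):
            assert getattr(a, attr).statistic == pytest.approx(
                getattr(b, attr).statistic, abs=1e-9
            )

    def test_gg_with_epsilon_one_equals_uncorrected(self):
        # two within levels: epsilon is identically 1, so forcing the
        # correction must reproduce the uncorrected p-values
        free = self.run_hand()
        forced = mixed_anova(mixed_table(HAND_DATA), dv="y", subject="unit",
                             within="level", between="group", apply_gg="always")
        assert forced.epsilon == pytest.approx(1.0)
        assert forced.within.p == pytest.approx(free.within.extra["p_uncorrected"])
        assert forced.interaction.p == pytest.approx(
            free.interaction.extra["p_uncorrected"]
        )

    def test_unbalanced_design_rejected(self):
        data = dict(HAND_DATA)
        del data[("B", 2, "c2")]
        with pytest.raises(DesignError):
            mixed_anova(mixed_table(data), dv="y", subject="unit",
                        within="level", between="group")

    def test_agrees_with_pingouin_on_random_data(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(31)
        rows = []
        for gi, g in enumerate(("x", "y", "z")):
            for u in range(8):
                base = rng.normal(0, 1)
                for lv in ("a", "b", "c"):
                    rows.append({"unit": f"{g}{u}", "group": g, "level": lv,
                                 "y": base + rng.normal(0, 1) + (gi == 1) * 0.5})
        table = pd.DataFrame(rows)
        mine = mixed_anova(table, dv="y", subject="unit", within="level",
                           between="group")
        theirs = pg.mixed_anova(data=table, dv="y", within="level",
                                subject="unit", between="group")
        assert mine.between.statistic == pytest.approx(
            float(theirs.loc[theirs.Source == "group", "F"].iloc[0]), rel=1e-6
        )
        assert mine.within.statistic == pytest.approx(
            float(theirs.loc[theirs.Source == "level", "F"].iloc[0]), rel=1e-6
        )
        assert mine.interaction.statistic == pytest.approx(
            float(theirs.loc[theirs.Source == "Interaction", "F"].iloc[0]), rel=1e-6
        )
        # sphericity machinery against pingouin's; the battery pools the
        # covariance within groups, so hand pingouin group-centered data
        # (W and epsilon are invariant to the df scale of the covariance)
        centered = table.copy()
        centered["y"] -= centered.groupby(["group", "level"])["y"].transform("mean")
        spher = pg.sphericity(data=centered, dv="y", within="level", subject="unit")
        assert mine.mauchly.statistic == pytest.approx(spher.W, rel=1e-9)
        eps_pg = float(pg.epsilon(centered.pivot(index="unit", columns="level",
                                                 values="y"), correction="gg"))
        assert mine.epsilon == pytest.approx(eps_pg, rel=1e-9)


class TestTukey:
    def test_equal_means_give_p_one(self):
        res = tukey_hsd([2.0, 2.0, 2.0], [10, 10, 10], 1.0, 27.0)
        assert all(t.statistic == 0.0 and t.p == pytest.approx(1.0) for t in res)

    def test_hand_worked_q(self):
        # means 0/0/2, n = 10, MS_error = 1: q = 2 / sqrt(0.1) = 6.3246
        res = tukey_hsd([0.0, 0.0, 2.0], [10, 10, 10], 1.0, 27.0,
                        labels=["a", "b", "c"])
        worst = max(res, key=lambda t: t.statistic)
        assert worst.statistic == pytest.approx(2.0 / np.sqrt(0.1), abs=1e-10)
        assert worst.p < 0.01

    def test_symmetric_under_relabeling(self):
        a = tukey_hsd([1.0, 3.0], [5, 5], 2.0, 8.0, labels=["p", "q"])[0]
        b = tukey_hsd([3.0, 1.0], [5, 5], 2.0, 8.0, labels=["q", "p"])[0]
        assert a.statistic == pytest.approx(b.statistic)
        assert a.p == pytest.approx(b.p)


class TestBatteryAndPattern:
    def test_battery_recovers_configured_pattern(self):
        onsets, erp = generate_cohort_measures(n_per_group=14, seed=12345)
        report = run_battery(onsets, erp)
        checks = evaluate_pattern(report)
        assert checks["pattern_reproduced"], checks

    def test_pattern_checks_fail_on_null_cohort(self):
        # a cohort with no effects should not reproduce the young pattern
        rng = np.random.default_rng(3)
        rows = []
        erp_rows = []
        for group in ("young", "older"):
            for s in range(14):
                subj = f"{group}{s}"
                for m in ("ES", "BF", "GcM"):
                    for c in ("p15", "p45", "self"):
                        rows.append({"subject": subj, "group": group,
                                     "condition": c, "muscle": m,
                                     "mean_relative_onset_ms": rng.normal(0, 10)})
                for c in ("p15", "p45"):
                    erp_rows.append({"subject": subj, "group": group,
                                     "condition": c,
                                     "p300_latency_ms": rng.normal(350, 20),
                                     "p300_amplitude_uv": rng.normal(10, 2)})
        report = run_battery(pd.DataFrame(rows), pd.DataFrame(erp_rows))
        checks = evaluate_pattern(report)
        assert not (
            checks["young_gcm_self_earlier_than_p45"]
            and checks["young_gcm_p45_earlier_than_p15"]
        )
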