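"""Tumor-volume bookkeeping and the two-way growth ANOVA."""

import pandas as pd
import pytest

import crosskill as ck
from crosskill.invivo import shared_days
from oracles import balanced_anova_ss_oracle


class TestTumorVolume:
    @pytest.mark.parametrize("l,w", [(10.0, 5.0), (5.0, 10.0)])
    def test_ellipsoid_formula_and_caliper_swap(self, l, w):
        assert ck.tumor_volume(l, w) == 125.0

    def test_sphere_like_identity(self):
        assert ck.tumor_volume(4.0, 4.0) == pytest.approx(4.0**3 / 2)

    def test_monotone_in_both_dimensions(self):
        assert ck.tumor_volume(11.0, 5.0) > ck.tumor_volume(10.0, 5.0)
        assert ck.tumor_volume(10.0, 6.0) > ck.tumor_volume(10.0, 5.0)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            ck.tumor_volume(0.0, 5.0)


def _toy_caliper():
    """3 mice: m1 grows past 1500 at day 10; m2 normal; m3 never reaches 100."""
    rows = []
    # volumes for (L, W): tumor_volume(L, W) = L*W^2/2
    for day, lw in [(0, (8.0, 5.0)), (5, (12.0, 8.0)), (10, (20.0, 13.0)),
                    (15, (22.0, 14.0))]:  # m1: 100, 384, 1690 (cross), 2156
        rows.append(("m1", "control", day, *lw))
    for day, lw in [(0, (8.0, 5.0)), (5, (10.0, 6.0)), (10, (12.0, 7.0))]:
        rows.append(("m2", "control", day, *lw))  # m2: 100, 180, 294
    for day, lw in [(0, (4.0, 3.0)), (5, (4.5, 3.0))]:
        rows.append(("m3", "treated", day, *lw))  # m3: 18, 20 -- never randomized
    return pd.DataFrame(rows, columns=["mouse_id", "group", "day",
                                       "length_mm", "width_mm"])


class TestStudyRules:
    def test_toy_table_bookkeeping_matches_hand_count(self):
        study = ck.apply_study_rules(_toy_caliper())
        # m1 keeps days 0,5,10 (crossing record retained), loses day 15
        # m2 keeps all 3 records; m3 excluded entirely
        assert len(study.measurements) == 6
        assert set(study.measurements["mouse_id"]) == {"m1", "m2"}
        reasons = study.exclusions.set_index("mouse_id")["reason"]
        assert reasons["m3"] == "never_randomized"
        assert reasons["m1"] == "endpoint_volume"
        assert len(study.exclusions) == 2

    def test_all_below_randomization_gives_empty_study(self):
        df = _toy_caliper()
        df[["length_mm", "width_mm"]] = df[["length_mm", "width_mm"]] / 4.0
        study = ck.apply_study_rules(df)
        assert study.measurements.empty
        assert len(study.exclusions) == 3

    def test_endpoint_day_rule(self):
        df = pd.DataFrame([("m", "g", d, 10.0, 8.0) for d in (0, 10, 20)],
                          columns=["mouse_id", "group", "day",
                                   "length_mm", "width_mm"])
        study = ck.apply_study_rules(df, endpoint_day=18)
        assert study.measurements["day"].tolist() == [0, 10]
        assert study.exclusions.iloc[0]["reason"] == "endpoint_day"

    def test_rules_are_idempotent(self):
        once = ck.apply_study_rules(_toy_caliper())
        twice = ck.apply_study_rules(once.measurements)
        pd.testing.assert_frame_equal(once.measurements, twice.measurements)

    def test_no_crossing_synthetic_study_fully_retained(self):
        cal = ck.generate_tumor_study([("a", 3, 0.05), ("b", 3, 0.01)],
                                      v0=150.0, noise_sd=0.0, seed=4)
        study = ck.apply_study_rules(cal)
        assert len(study.measurements) == len(cal)
        assert study.exclusions.empty


class TestTwoWayAnova:
    @staticmethod
    def _study(seed=0, rate_b=0.08, noise=10.0):
        cal = ck.generate_tumor_study([("control", 5, 0.08), ("treated", 5, rate_b)],
                                      v0=150.0, noise_sd=noise, seed=seed)
        return ck.apply_study_rules(cal)

    def test_ss_decomposition_matches_oracle(self):
        study = self._study(seed=1, rate_b=0.03)
        tab = ck.two_way_anova(study)
        df = study.measurements
        ss = balanced_anova_ss_oracle(df["volume_mm3"], df["group"], df["day"])
        for effect, want in zip(["group", "day", "group:day", "residual"], ss):
            assert tab.loc[effect, "sum_sq"] == pytest.approx(want, rel=1e-9)
        total = tab["sum_sq"].sum()
        assert total == pytest.approx(ss[4], rel=1e-9)
        assert tab["df"].sum() == len(df) - 1

    def test_matches_statsmodels_f_and_p(self):
        import statsmodels.api as sm
        import statsmodels.formula.api as smf
        study = self._study(seed=2, rate_b=0.05)
        tab = ck.two_way_anova(study)
        model = smf.ols("volume_mm3 ~ C(group) * C(day)",
                        data=study.measurements).fit()
        ref = sm.stats.anova_lm(model, typ=2)
        assert tab.loc["group", "F"] == pytest.approx(ref["F"].iloc[0], rel=1e-8)
        assert tab.loc["group", "p"] == pytest.approx(ref["PR(>F)"].iloc[0], rel=1e-6)

    def test_planted_group_effect_detected(self):
        study = self._study(seed=3, rate_b=0.01, noise=5.0)
        tab = ck.two_way_anova(study)
        assert tab.loc["group", "p"] < 0.05

    def test_identical_groups_zero_noise_zero_group_ss(self):
        cal = ck.generate_tumor_study([("a", 3, 0.05), ("b", 3, 0.05)],
                                      v0=150.0, noise_sd=0.0, seed=5)
        tab = ck.two_way_anova(ck.apply_study_rules(cal))
        assert tab.loc["group", "sum_sq"] == pytest.approx(0.0, abs=1e-9)

    def test_empty_cell_error_names_cell(self):
        df = pd.DataFrame({"group": ["a", "a", "b"], "day": [0, 2, 0],
                           "volume_mm3": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="group='b'"):
            ck.two_way_anova(df)

    def test_unbalanced_falls_back_to_type_ii(self):
        study = self._study(seed=6, rate_b=0.02)
        df = study.measurements.iloc[:-1]  # drop one observation
        tab = ck.two_way_anova(df)
        assert "Type II" in tab.attrs["ss_type"]
        assert tab.loc["group", "p"] <= 1.0

    def test_shared_days_aligns_staggered_mice(self):
        cal = ck.generate_tumor_study([("a", 4, 0.12), ("b", 4, 0.05)],
                                      v0=100.0, noise_sd=12.0, seed=7)
        study = ck.apply_study_rules(cal)
        aligned = shared_days(study)
        counts = aligned.groupby(["group", "day"]).size()
        assert counts.nunique() == 1  # balanced after alignment
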