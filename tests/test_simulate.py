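"""Generator contracts: planted truth, determinism, layout arithmetic."""

import numpy as np
import pandas as pd
import pytest

import crosskill as ck

TWO_LINES = [("D418", "dog"), ("17-3X", "human")]


class TestCompoundLibrary:
    def test_driver_planting_counts_and_truth(self):
        ann, truth = ck.generate_compound_library(
            200, driver_spec=[("proteasome", 11, 9), ("CRM1", 4, 3)],
            seed=1, n_compounds=2100)
        assert len(ann) == 2100
        assert ann["compound_id"].is_unique
        assert (ann["targets"].map(len) >= 1).all()
        target_of = ann.set_index("compound_id")["targets"].map(lambda s: next(iter(s)))
        assert target_of.nunique() == 200
        assert (target_of == "proteasome").sum() == 11
        assert (target_of == "CRM1").sum() == 4
        # sensitive drugs kill >50 in every line, everything else stays <50
        tk = truth.true_killing(TWO_LINES)
        sens = list(truth.sensitive_compounds)
        assert len([c for c in sens if target_of[c] == "proteasome"]) == 9
        assert len([c for c in sens if target_of[c] == "CRM1"]) == 3
        assert (tk[sens] > 50).all().all()
        others = [c for c in tk.columns if c not in truth.sensitive_compounds]
        assert (tk[others] < 50).all().all()

    def test_empty_driver_spec_plants_nothing_sensitive(self):
        _, truth = ck.generate_compound_library(10, driver_spec=[], seed=0,
                                                n_compounds=50)
        tk = truth.true_killing(TWO_LINES)
        assert not (tk > 50).all(axis=0).any()

    def test_same_seed_reproduces_tables(self):
        a1, t1 = ck.generate_compound_library(20, driver_spec=[("x", 3, 2)],
                                              seed=7, n_compounds=100)
        a2, t2 = ck.generate_compound_library(20, driver_spec=[("x", 3, 2)],
                                              seed=7, n_compounds=100)
        pd.testing.assert_frame_equal(a1, a2)
        pd.testing.assert_series_equal(t1.compound_effects, t2.compound_effects)

    def test_duplicate_driver_target_rejected(self):
        with pytest.raises(ValueError, match="duplicate target"):
            ck.generate_compound_library(10, driver_spec=[("x", 3, 2), ("x", 4, 1)])

    def test_oversubscribed_sensitive_rejected(self):
        with pytest.raises(ValueError, match="n_sensitive"):
            ck.generate_compound_library(10, driver_spec=[("x", 3, 5)])


class TestScreen:
    def test_zero_noise_well_reads_fraction_of_control(self):
        eff = pd.Series([80.0], index=["C0"])
        truth = ck.ScreenTruth(eff, noise_sd=0.0, species_sd=0.0, line_sd=0.0, seed=0)
        wells = ck.generate_screen(truth, [("L1", "human")], n_replicates=3,
                                   control_wells_per_plate=4, plate_size=96, seed=1)
        ctrl = wells[wells.role == "vehicle_control"]["luminescence_rlu"].mean()
        treated = wells[wells.role == "treated"]["luminescence_rlu"]
        assert np.allclose(treated, 0.2 * ctrl)

    def test_replicate_counts_and_pagination(self):
        ann, truth = ck.generate_compound_library(40, seed=2, n_compounds=119)
        lines = [(f"L{i}", "human" if i < 5 else "dog") for i in range(9)]
        wells = ck.generate_screen(truth, lines, n_replicates=3, seed=3)
        treated = wells[wells.role == "treated"]
        assert len(treated) == 9 * 119 * 3
        per_pair = treated.groupby(["cell_line", "compound_id"]).size()
        assert (per_pair == 3).all()
        # 2100 compounds in triplicate on 384-well plates with 32 controls
        _, truth2 = ck.generate_compound_library(200, seed=2, n_compounds=2100)
        w2 = ck.generate_screen(truth2, [("L1", "dog")], n_replicates=3, seed=3)
        n_plates = w2["plate_id"].nunique()
        assert n_plates == int(np.ceil(2100 * 3 / (384 - 32)))
        assert n_plates >= 18
        per_plate_controls = (w2[w2.role == "vehicle_control"]
                              .groupby("plate_id").size())
        assert (per_plate_controls >= 32).all()

    def test_same_seed_identical_wells(self):
        eff = pd.Series(np.linspace(0, 60, 10), index=[f"C{i}" for i in range(10)])
        truth = ck.ScreenTruth(eff, seed=5)
        w1 = ck.generate_screen(truth, TWO_LINES, seed=9)
        w2 = ck.generate_screen(truth, TWO_LINES, seed=9)
        pd.testing.assert_frame_equal(w1, w2)


class TestDoseResponse:
    def test_midpoint_and_low_dose_limit(self):
        d = ck.generate_dose_response(100, 0, 1.25, 1.0, [1.25])
        assert d["viability_pct"].iloc[0] == pytest.approx(50.0)
        d = ck.generate_dose_response(100, 0, 1.25, 2.0, [1e-9])
        assert d["viability_pct"].iloc[0] == pytest.approx(100.0, abs=1e-6)

    def test_nonpositive_concentration_rejected(self):
        with pytest.raises(ValueError):
            ck.generate_dose_response(100, 0, 1.0, 1.0, [1.0, 0.0])
        with pytest.raises(ValueError):
            ck.generate_dose_response(100, 0, -1.0, 1.0, [1.0])


class TestCombinationGrid:
    def test_bliss_additive_and_planted_arithmetic(self):
        g = ck.generate_combination_grid([0.5], [0.5], np.array([[0.1]]))
        assert g.loc[1.0, 1.0] == pytest.approx(0.85)
        g0 = ck.generate_combination_grid([0.3, 0.6], [0.2, 0.4])
        expected = 0.3 + 0.4 - 0.3 * 0.4
        assert g0.loc[1.0, 2.0] == pytest.approx(expected)

    def test_out_of_range_excess_clipped_with_warning(self):
        with pytest.warns(UserWarning, match="clipped"):
            g = ck.generate_combination_grid([0.9], [0.9], np.array([[0.5]]))
        assert g.loc[1.0, 1.0] == 1.0

    def test_same_seed_identical_grid(self):
        g1 = ck.generate_combination_grid([0.2, 0.4], [0.3], noise_sd=0.05, seed=4)
        g2 = ck.generate_combination_grid([0.2, 0.4], [0.3], noise_sd=0.05, seed=4)
        pd.testing.assert_frame_equal(g1, g2)


class TestTumorStudy:
    def test_flat_growth_zero_noise_keeps_v0(self):
        df = ck.generate_tumor_study([("g", 3, 0.0)], v0=123.0, noise_sd=0.0, seed=0)
        vol = df["length_mm"] * df["width_mm"] ** 2 / 2
        assert np.allclose(vol, 123.0)
        assert (df["width_mm"] <= df["length_mm"] + 1e-12).all()

    def test_group_sizes_match_request(self):
        df = ck.generate_tumor_study([("control", 5, 0.1), ("treated", 5, 0.02)],
                                     seed=1)
        assert df.groupby("group")["mouse_id"].nunique().eq(5).all()

    def test_zero_mice_rejected(self):
        with pytest.raises(ValueError):
            ck.generate_tumor_study([("g", 0, 0.1)])


class TestSurvivalCohort:
    def test_censoring_off_means_all_events(self):
        df = ck.generate_survival_cohort(30, 5.0, 0.1, 0.3, censor_rate=0.0, seed=2)
        assert (df["event"] == 1).all()

    def test_same_seed_identical_cohort(self):
        a = ck.generate_survival_cohort(20, 5.0, 0.1, 0.3, censor_rate=0.2, seed=3)
        b = ck.generate_survival_cohort(20, 5.0, 0.1, 0.3, censor_rate=0.2, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_tiny_cohort_rejected(self):
        with pytest.raises(ValueError):
            ck.generate_survival_cohort(3, 5.0, 0.1, 0.3)


def test_shared_effect_sd_plants_requested_r2():
    """Variance-decomposition identity: the planted shared sd reproduces R²."""
    sd = ck.shared_effect_sd(0.54, species_sd=11.0, noise_sd=8.0, n_replicates=3)
    v = 11.0**2 + 8.0**2 / 3
    r = sd**2 / (sd**2 + v)
    assert r**2 == pytest.approx(0.54, abs=1e-12)
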