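"""Model-performance statistics, bands/coverage, sensitivity analysis."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings as hyp_settings
from hypothesis import strategies as st

from pbpkddi.evaluation import (
    ObservedDataset,
    SensitivityResult,
    coverage,
    evaluate_datasets,
    evaluate_predictions,
    local_sensitivity,
    mape,
    mpe,
    mrd,
    perturb_compound,
    prediction_error,
    prediction_interval,
    twofold_fraction,
)

positive_pairs = st.lists(
    st.tuples(st.floats(1e-3, 1e3), st.floats(1e-3, 1e3)),
    min_size=1, max_size=30,
)


class TestPredictionError:
    def test_perfect_prediction_zeroes_all_statistics(self):
        pe = prediction_error([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert np.all(pe == 0.0)
        assert mpe(pe) == 0.0 and mape(pe) == 0.0

    def test_symmetric_errors_cancel_in_mpe_not_mape(self):
        pe = prediction_error([1.5, 0.5], [1.0, 1.0])
        assert mpe(pe) == pytest.approx(0.0)
        assert mape(pe) == pytest.approx(50.0)

    def test_systematic_twofold_overprediction(self):
        pe = prediction_error([2.0, 4.0, 8.0], [1.0, 2.0, 4.0])
        assert mpe(pe) == pytest.approx(100.0)
        assert mape(pe) == pytest.approx(100.0)

    def test_empty_and_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            prediction_error([], [])
        with pytest.raises(ValueError):
            prediction_error([1.0], [0.0])

    @given(pairs=positive_pairs)
    @hyp_settings(max_examples=50, deadline=None)
    def test_mape_dominates_absolute_mpe(self, pairs):
        pred, obs = zip(*pairs)
        pe = prediction_error(pred, obs)
        assert mape(pe) >= abs(mpe(pe)) - 1e-9


class TestMRD:
    def test_perfect_prediction_gives_one(self):
        assert mrd([1.0, 5.0], [1.0, 5.0]) == pytest.approx(1.0)

    def test_single_twofold_pair_gives_exactly_two(self):
        assert mrd([2.0], [1.0]) == pytest.approx(2.0, rel=1e-12)

    def test_symmetric_twofold_pairs_give_two(self):
        # hand evaluation of the root-mean-square form:
        # x = sqrt(((log10 2)^2 + (log10 1/2)^2)/2) = log10 2 -> MRD = 2
        assert mrd([2.0, 1.0], [1.0, 2.0]) == pytest.approx(2.0, rel=1e-12)

    def test_matches_brute_force_oracle_on_random_data(self):
        rng = np.random.default_rng(123)
        for _ in range(20):
            n = rng.integers(1, 40)
            pred = rng.lognormal(0, 1, n)
            obs = rng.lognormal(0, 1, n)
            acc = 0.0
            for p_i, o_i in zip(pred, obs):  # plain-loop re-computation
                acc += (np.log10(p_i) - np.log10(o_i)) ** 2
            expected = 10.0 ** np.sqrt(acc / n)
            assert mrd(pred, obs) == pytest.approx(expected, rel=1e-12)

    @given(pairs=positive_pairs)
    @hyp_settings(max_examples=50, deadline=None)
    def test_mrd_at_least_one_and_order_invariant(self, pairs):
        pred, obs = map(np.array, zip(*pairs))
        val = mrd(pred, obs)
        assert val >= 1.0
        perm = np.random.default_rng(0).permutation(len(pred))
        assert mrd(pred[perm], obs[perm]) == pytest.approx(val, rel=1e-12)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            mrd([0.0], [1.0])


class TestTwofold:
    def test_perfect_prediction_fully_within(self):
        assert twofold_fraction([1.0, 2.0], [1.0, 2.0]) == 1.0

    def test_direct_count(self):
        assert twofold_fraction([0.4, 1.0, 2.5, 1.9]) == 0.5

    def test_boundary_ratios_inclusive(self):
        assert twofold_fraction([2.0, 0.5]) == 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            twofold_fraction([])


class TestEvaluationReport:
    def test_report_consistency_and_lloq_exclusion(self):
        pred = np.array([1.0, 2.0, 3.0, 4.0])
        obs = np.array([1.1, 1.9, 0.05, 4.4])
        rep = evaluate_predictions(pred, obs, lloq=0.1)
        assert rep.n == 3 and rep.n_excluded_lloq == 1
        assert rep.mape >= abs(rep.mpe)
        assert rep.mrd >= 1.0
        assert 0.0 <= rep.fraction_within_twofold <= 1.0

    def test_pooled_and_per_dataset_reports(self):
        pairs = [
            ("a", [1.0, 2.0], [1.0, 2.0]),
            ("b", [4.0], [2.0]),
        ]
        pooled, table = evaluate_datasets(pairs)
        assert pooled.n == 3
        assert set(table["dataset_id"]) == {"a", "b"}
        assert table.loc[table.dataset_id == "b", "mrd"].item() == \
            pytest.approx(2.0)


class TestPredictionInterval:
    def _band(self, n=40):
        t = np.linspace(0, 10, 21)
        rng = np.random.default_rng(4)
        profiles = np.exp(rng.normal(0, 0.2, (n, 1))) * np.exp(-0.1 * t)
        return t, profiles, prediction_interval(t, profiles)

    def test_median_trajectory_fully_covered(self):
        t, profiles, band = self._band()
        med = np.median(profiles, axis=0)
        assert coverage(t, med, band) == 1.0

    def test_observations_above_band_have_zero_coverage(self):
        t, profiles, band = self._band()
        above = band["upper"].to_numpy() * 10.0
        assert coverage(t, above, band) == 0.0

    def test_too_few_subjects_rejected(self):
        t = np.linspace(0, 10, 5)
        with pytest.raises(ValueError):
            prediction_interval(t, np.ones((5, 5)))

    def test_observation_outside_horizon_rejected(self):
        t, _, band = self._band()
        with pytest.raises(ValueError):
            coverage([11.0], [1.0], band)


class TestObservedDataset:
    def test_paired_arrays_enforced(self):
        with pytest.raises(ValueError):
            ObservedDataset("d", "s", "x", [0.0, 1.0], [1.0])

    def test_csv_roundtrip_columns(self):
        ds = ObservedDataset("d", "s", "x", [0.0, 1.0], [1.0, 0.0],
                             lloq=0.1)
        frame = ds.to_frame()
        assert list(frame["below_lloq"]) == [False, True]


class TestLocalSensitivity:
    def test_one_compartment_clearance_sensitivity_is_minus_one(self):
        """AUC = Dose/CL, so S(AUC) for clearance is exactly -1; the metric
        function here is the closed form itself."""

        class M:
            def __init__(self, cl):
                self.auc_last = 100.0 / cl
                self.cmax = 10.0

        s = local_sensitivity(lambda name, f: M(2.0 * f), "clearance.CL",
                              variation_range=10.0, steps=9)
        assert s.relative_sensitivity_auc == pytest.approx(-1.0, rel=0.15)
        assert s.relative_sensitivity_cmax == 0.0
        assert s.steps == 9

    def test_unused_pathway_has_zero_sensitivity(
        self, reference_individual, ruxolitinib, fast_settings
    ):
        """Ruxolitinib has gfr_fraction = 0; perturbing it multiplicatively
        cannot reach plasma."""
        from pbpkddi.engine import DosingRegimen, PBPKModel

        def metric_fn(name, factor):
            cp = perturb_compound(ruxolitinib, name, factor)
            reg = DosingRegimen.single("ruxolitinib", 10.0,
                                       formulation="tablet")
            res = PBPKModel(reference_individual, cp, reg,
                            settings=fast_settings).simulate(12.0,
                                                             grid_h=0.25)
            return res.nca("ruxolitinib", (0.0, 12.0))

        s = local_sensitivity(metric_fn, "gfr_fraction", steps=3)
        assert s.relative_sensitivity_auc == pytest.approx(0.0, abs=1e-6)

    def test_failed_perturbations_recorded_not_silently_dropped(self):
        def metric_fn(name, factor):
            if factor > 3.0:
                raise RuntimeError("solver failure")

            class M:
                auc_last = 1.0 / factor
                cmax = 1.0

            return M()

        s = local_sensitivity(metric_fn, "p", steps=9)
        assert (s.table["error"] != "").sum() > 0
        assert np.isfinite(s.relative_sensitivity_auc)

    def test_lipophilicity_is_dominant_negative_driver_for_posaconazole(
        self, reference_individual, posaconazole, fast_settings
    ):
        """Lipophilicity has a large negative relative sensitivity on
        AUC_last of a single 100 mg tablet dose and outranks the
        elimination-pathway parameters tested alongside it."""
        from pbpkddi.engine import DosingRegimen, PBPKModel

        def metric_fn(name, factor):
            cp = perturb_compound(posaconazole, name, factor)
            reg = DosingRegimen.single("posaconazole", 100.0,
                                       formulation="dr_tablet")
            res = PBPKModel(reference_individual, cp, reg,
                            settings=fast_settings).simulate(48.0,
                                                             grid_h=0.25)
            return res.nca("posaconazole", (0.0, 48.0))

        results = {
            name: local_sensitivity(metric_fn, name, variation_range=10.0,
                                    steps=9)
            for name in ("logp", "gfr_fraction", "clearance.UGT1A4")
        }
        s_logp = results["logp"].relative_sensitivity_auc
        assert s_logp < -0.3
        assert abs(s_logp) > abs(results["gfr_fraction"].relative_sensitivity_auc)
        assert abs(s_logp) > abs(results["clearance.UGT1A4"].relative_sensitivity_auc)


def test_gof_scatter_frame_flags_twofold_points():
    from pbpkddi.evaluation import gof_scatter_frame

    frame = gof_scatter_frame([("a", [1.0, 5.0], [1.0, 2.0])])
    assert list(frame["within_twofold"]) == [True, False]
    assert frame["ratio"].tolist() == [1.0, 2.5]
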