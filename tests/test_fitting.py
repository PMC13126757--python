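"""Aggregation and least-squares estimation of (beta1, beta3, gamma1, gamma2)."""

import numpy as np
import pandas as pd
import pytest

from idminc import (
    IDMIncidenceEstimator,
    IncidenceParams,
    MRRParams,
    fit,
    model_group_prevalence,
    objective,
    representative_ages,
)
from idminc.fitting import _objective_factory, pool_years, validate_groups
from idminc.synthetic import DEFAULT_TRUE_INC, DEFAULT_TRUE_MRR

GROUPS = pd.DataFrame(
    [(0, 24), (25, 34), (35, 44), (45, 54), (55, 64), (65, 74), (75, 84), (85, 109)],
    columns=["age_lo", "age_hi"],
)


class TestRepresentativeAges:
    def test_midpoints_and_open_top_group(self):
        ages = representative_ages(GROUPS)
        np.testing.assert_allclose(ages, [12.5, 30.0, 40.0, 50.0, 60.0, 70.0, 80.0, 91.0])

    def test_top_age_override(self):
        ages = representative_ages(GROUPS, top_age=95.0)
        assert ages[-1] == 95.0

    def test_overlapping_groups_rejected(self):
        bad = pd.DataFrame([(0, 30), (25, 40)], columns=["age_lo", "age_hi"])
        with pytest.raises(ValueError, match="overlap"):
            representative_ages(bad)


class TestModelGroupPrevalence:
    def test_flat_zero_curve_under_both_aggregations(self, hazards):
        """The degenerate constant curve aggregates to itself either way."""
        inc = IncidenceParams(0.0, 55.0, 25.0)
        mp = MRRParams(0.0, 0.0)
        for mode in ("midpoint", "weighted"):
            pred = model_group_prevalence(inc, mp, hazards["male"], GROUPS, aggregate=mode)
            np.testing.assert_array_equal(pred, np.zeros(len(GROUPS)))

    def test_predictions_increase_across_groups(self, hazards, true_params):
        tp = true_params["male"]
        pred = model_group_prevalence(tp["inc"], tp["mrr"], hazards["male"], GROUPS)
        assert np.all(np.diff(pred) > 0)

    def test_unknown_mode_rejected(self, hazards, true_params):
        tp = true_params["male"]
        with pytest.raises(ValueError):
            model_group_prevalence(tp["inc"], tp["mrr"], hazards["male"], GROUPS, aggregate="mean")


class TestObjective:
    def test_zero_at_generating_parameters(self, synth_truth, hazards):
        truth, _ = synth_truth
        tm = truth[truth["sex"] == "male"]
        theta_star = (0.0763, 25.33680, 0.408, -0.0171)
        assert objective(theta_star, 87.5, tm, hazards["male"]) <= 1e-12

    def test_perturbation_increases_objective(self, synth_truth, hazards):
        truth, _ = synth_truth
        tm = truth[truth["sex"] == "male"]
        base = objective((0.0763, 25.33680, 0.408, -0.0171), 87.5, tm, hazards["male"])
        bumped = objective((0.0763 * 1.1, 25.33680, 0.408, -0.0171), 87.5, tm, hazards["male"])
        assert bumped > base

    def test_positive_for_zero_observations_with_positive_beta1(self, synth_truth, hazards):
        truth, _ = synth_truth
        zero = truth[truth["sex"] == "male"].copy()
        zero["prev"] = 0.0
        assert objective((0.0763, 25.33680, 0.408, -0.0171), 87.5, zero, hazards["male"]) > 0

    def test_out_of_bounds_returns_finite_penalty(self, synth_truth, hazards):
        truth, _ = synth_truth
        tm = truth[truth["sex"] == "male"]
        val = objective((1.5, 25.0, 0.4, 0.0), 87.5, tm, hazards["male"])
        assert np.isfinite(val) and val >= 1e6

    @pytest.mark.parametrize("mode", ["trajectory", "derivative"])
    @pytest.mark.parametrize("aggregate", ["midpoint", "weighted"])
    def test_fast_path_matches_reference(self, synth_noisy, hazards, mode, aggregate):
        """The optimizer's precomputed objective equals the public one."""
        observed, _ = synth_noisy
        om = validate_groups(observed[observed["sex"] == "male"])
        fast = _objective_factory(om, hazards["male"], 87.5, mode, aggregate, False, 91.0, 0.05)
        for theta in [
            (0.0763, 25.337, 0.408, -0.0171),
            (0.05, 20.0, 0.1, 0.1),
            (0.09, 30.0, -0.2, 0.4),
        ]:
            ref = objective(np.asarray(theta), 87.5, om, hazards["male"], mode=mode, aggregate=aggregate)
            assert fast(np.asarray(theta)) == pytest.approx(ref, rel=1e-12, abs=1e-18)


class TestFit:
    def test_noiseless_recovery(self, noiseless_fits):
        """Self-consistency: fitting exact model output returns the truth."""
        expected = {
            "male": (0.0763, 25.33680, 0.408, -0.0171),
            "female": (0.0635, 25.18237, 0.321, -0.0376),
        }
        for sex, res in noiseless_fits.items():
            b1, b3, g1, g2 = res.theta
            e1, e3, eg1, eg2 = expected[sex]
            assert res.converged
            assert b1 == pytest.approx(e1, rel=1e-3)
            assert b3 == pytest.approx(e3, rel=1e-3)
            assert g1 == pytest.approx(eg1, abs=5e-3)
            assert g2 == pytest.approx(eg2, abs=5e-3)

    def test_noisy_recovery_at_claims_scale(self, noisy_fits):
        """Binomial noise at multi-million denominators barely moves the fit."""
        assert noisy_fits["male"].params.beta1 == pytest.approx(0.0763, abs=5e-4)
        assert noisy_fits["female"].params.beta1 == pytest.approx(0.0635, abs=5e-4)

    def test_optimum_beats_truth_under_noise(self, synth_noisy, hazards, noisy_fits):
        observed, _ = synth_noisy
        om = observed[observed["sex"] == "male"]
        at_truth = objective((0.0763, 25.33680, 0.408, -0.0171), 87.5, om, hazards["male"])
        assert noisy_fits["male"].objective <= at_truth

    def test_sex_relabeling_equivariance(self, synth_noisy, hazards):
        """The pipelines are fully independent: labels carry no information."""
        observed, _ = synth_noisy
        om = observed[observed["sex"] == "male"]
        relabeled = om.copy()
        relabeled["sex"] = "female"
        a = fit(om, hazards["male"], seed=0)
        b = fit(relabeled, hazards["male"], seed=0)
        assert a.theta == b.theta

    def test_derivative_mode_agrees_up_to_discretization(self, synth_truth, hazards, noiseless_fits):
        """Inverting finite differences of 8 group prevalences is biased by the
        coarse spacing, but lands near the trajectory fit on noiseless data."""
        truth, _ = synth_truth
        tm = truth[truth["sex"] == "male"]
        res = fit(tm, hazards["male"], seed=0, mode="derivative")
        assert res.converged
        ref = noiseless_fits["male"]
        assert res.params.beta1 == pytest.approx(ref.params.beta1, rel=0.10)
        assert res.params.beta3 == pytest.approx(ref.params.beta3, rel=0.10)

    def test_aggregation_options_differ_structurally_but_moderately(
        self, synth_truth, hazards, noiseless_fits
    ):
        truth, _ = synth_truth
        tm = truth[truth["sex"] == "male"]
        res = fit(tm, hazards["male"], seed=0, aggregate="weighted")
        assert res.converged
        ref = noiseless_fits["male"]
        assert res.params.beta1 == pytest.approx(ref.params.beta1, rel=0.10)
        assert res.params.beta3 == pytest.approx(ref.params.beta3, rel=0.10)

    def test_degenerate_zero_prevalence_flagged(self, synth_truth, hazards):
        truth, _ = synth_truth
        zero = truth[truth["sex"] == "male"].copy()
        zero["prev"] = 0.0
        res = fit(zero, hazards["male"], seed=0)
        assert (not res.converged) or res.boundary

    def test_too_few_groups_rejected(self, synth_truth, hazards):
        truth, _ = synth_truth
        few = truth[(truth["sex"] == "male") & (truth["age_lo"] <= 34)]
        with pytest.raises(ValueError, match="informative"):
            fit(few, hazards["male"])

    def test_beta2_sensitivity_refits_converge(self, synth_noisy, hazards, noisy_fits):
        """Mechanism behind the 85/90 sensitivity analyses: refits run and
        return finite parameters."""
        observed, _ = synth_noisy
        om = observed[observed["sex"] == "male"]
        for b2 in (85.0, 90.0):
            res = fit(om, hazards["male"], fixed_beta2=b2, seed=0)
            assert res.converged
            assert np.all(np.isfinite(res.theta))


class TestEstimatorInterface:
    def test_sklearn_contract(self, synth_noisy, hazards):
        observed, _ = synth_noisy
        om = observed[observed["sex"] == "male"]
        est = IDMIncidenceEstimator(hazard=hazards["male"], random_state=0, n_restarts=0,
                                    start=(0.076, 25.3, 0.4, 0.0))
        params = est.get_params()
        assert params["fixed_beta2"] == 87.5
        est.set_params(fixed_beta2=87.5)
        est.fit(om)
        assert est.converged_
        assert est.beta1_ == pytest.approx(0.0763, abs=1e-3)
        pred = est.predict([87.5, 60.0])
        assert pred[0] == pytest.approx(est.beta1_, rel=1e-12)
        assert 0.0 < est.predict_prevalence([60.0])[0] < 1.0
        assert est.predict_mrr([30.0])[0] == pytest.approx(np.exp(est.gamma1_), rel=1e-12)

    def test_unfitted_predict_raises(self, hazards):
        est = IDMIncidenceEstimator(hazard=hazards["male"])
        with pytest.raises(AttributeError):
            est.predict([50.0])

    def test_mixed_sexes_rejected(self, synth_noisy, hazards):
        observed, _ = synth_noisy
        est = IDMIncidenceEstimator(hazard=hazards["male"])
        with pytest.raises(ValueError, match="one sex"):
            est.fit(observed)

    def test_fit_result_json_roundtrip(self, noisy_fits, tmp_path):
        path = tmp_path / "fit.json"
        noisy_fits["male"].to_json(path)
        import json

        back = json.loads(path.read_text())
        assert back["beta1"] == noisy_fits["male"].params.beta1
        assert back["converged"] is True
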