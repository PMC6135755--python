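"""Unit and property tests for the signal-detection observer models."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

from pupilbelief import sdt
from tests.conftest import MU_EASY, MU_HARD, SIGMA


def normal_cdf_oracle(z: float) -> float:
    """Standard-normal CDF by numerical integration, independent of erf."""
    val, _ = quad(lambda x: np.exp(-x * x / 2.0) / np.sqrt(2.0 * np.pi), -12.0, z)
    return val


PHI_1 = normal_cdf_oracle(1.0)  # = 0.841344746...


class TestProbCorrect:
    @pytest.mark.parametrize(
        "x, sigma, expected, tol",
        [
            (0.0, 0.133, 0.5, 0.0),
            (0.133, 0.133, PHI_1, 1e-10),
            (10.0, 0.133, 1.0, 1e-12),
        ],
    )
    def test_values(self, x, sigma, expected, tol):
        assert sdt.prob_correct(x, sigma) == pytest.approx(expected, abs=max(tol, 1e-15))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            sdt.prob_correct(0.1, -1.0)
        with pytest.raises(ValueError):
            sdt.prob_correct(0.1, 0.0)
        with pytest.raises(ValueError):
            sdt.prob_correct(-0.1, 0.133)

    @given(st.floats(0.0, 5.0), st.floats(0.01, 1.0))
    @settings(derandomize=True, max_examples=50)
    def test_range_and_monotonicity(self, x, sigma):
        p = sdt.prob_correct(x, sigma)
        assert 0.5 <= p <= 1.0
        if x / sigma < 7:  # below the double-precision saturation of the CDF
            assert p < 1.0
            assert sdt.prob_correct(x + 0.01, sigma) > p


class TestComplements:
    def test_uncertainty_examples(self):
        assert sdt.uncertainty(0.5) == 0.5
        assert sdt.uncertainty(1.0) == 0.0
        assert sdt.uncertainty(PHI_1) == pytest.approx(1 - PHI_1)

    def test_prediction_error_examples(self):
        assert sdt.prediction_error(1, 0.5) == 0.5
        assert sdt.prediction_error(0, 0.8) == pytest.approx(-0.8)
        assert sdt.prediction_error(1, PHI_1) == pytest.approx(1 - PHI_1)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            sdt.uncertainty(1.5)
        with pytest.raises(ValueError):
            sdt.prediction_error(2, 0.5)


class TestSimulateTrials:
    def test_accuracy_matches_closed_form(self):
        # accuracy at grid point mu equals Phi(|mu|/sigma) within binomial error
        params = sdt.SDTParams(sigma=0.133, mu_grid=(0.5,), n_per_mu=10_000, seed=5)
        trials = sdt.simulate_trials(params)
        expected = normal_cdf_oracle(0.5 / 0.133)
        assert trials["correct"].mean() == pytest.approx(expected, abs=0.005)

    def test_stimulus_confidence_constant_within_level(self):
        params = sdt.SDTParams(sigma=0.133, mu_grid=(0.07,), n_per_mu=500, seed=2)
        trials = sdt.simulate_trials(params)
        assert trials["confidence_stimulus"].nunique() == 1
        assert trials["confidence_stimulus"].iloc[0] == pytest.approx(
            sdt.prob_correct(0.07, 0.133)
        )

    def test_same_seed_reproduces(self):
        params = sdt.SDTParams(mu_grid=(0.1, -0.1), n_per_mu=200, seed=9)
        a = sdt.simulate_trials(params)
        b = sdt.simulate_trials(params)
        pd.testing.assert_frame_equal(a, b)

    def test_belief_confidence_complement_identity(self, design_trials):
        # confidence + uncertainty = 1 at machine precision, every trial
        total = design_trials["confidence_belief"] + design_trials["uncertainty"]
        assert np.allclose(total, 1.0, atol=1e-15)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            sdt.SDTParams(mu_grid=())


class TestSummarizeConditions:
    def test_stimulus_uncertainty_interaction_exactly_zero(self, design_trials):
        s = sdt.summarize_conditions(
            design_trials, "stimulus", "uncertainty", {MU_EASY}, {MU_HARD}
        )
        # analytically zero; cell means of a constant incur only rounding
        assert abs(s.interaction) < 1e-12

    def test_belief_sign_pattern(self, design_trials):
        unc = sdt.summarize_conditions(
            design_trials, "belief", "uncertainty", {MU_EASY}, {MU_HARD}
        )
        cpe = sdt.summarize_conditions(
            design_trials, "belief", "complement_prediction_error", {MU_EASY}, {MU_HARD}
        )
        assert unc.interaction > 0.05
        assert cpe.interaction < -0.05

    def test_matches_brute_force_groupby(self, design_trials):
        s = sdt.summarize_conditions(
            design_trials, "belief", "uncertainty", {MU_EASY}, {MU_HARD}
        )
        df = design_trials.assign(
            unc=1 - design_trials["confidence_belief"],
            difficulty=np.where(
                np.isclose(design_trials["mu"].abs(), MU_EASY), "Easy", "Hard"
            ),
        )
        for cell, mean in s.cell_means.items():
            diff, acc = cell.split("-")
            sel = df[(df["difficulty"] == diff) & (df["correct"] == (acc == "Correct"))]
            assert mean == sel["unc"].mean()
            assert s.cell_ns[cell] == len(sel)

    def test_empty_cell_error_names_cell(self):
        params = sdt.SDTParams(sigma=0.01, mu_grid=(0.4, 0.1), n_per_mu=50, seed=0)
        trials = sdt.simulate_trials(params)  # ~no errors at tiny noise
        with pytest.raises(ValueError, match="Easy-Error"):
            sdt.summarize_conditions(trials, "belief", "uncertainty", {0.4}, {0.1})

    def test_unassigned_level_rejected(self, design_trials):
        with pytest.raises(ValueError, match="not assigned"):
            sdt.summarize_conditions(design_trials, "belief", "uncertainty", {MU_EASY}, {0.3})


class TestInternalNoiseFit:
    def test_slope_sigma_identity(self):
        fit = sdt.PsychometricFit(beta=7.5, bias=0.0)
        assert fit.sigma_hat == 1.0 / 7.5

    def test_parameter_recovery(self):
        rng = np.random.default_rng(77)
        levels = np.array([0.01, 0.05, 0.1, 0.2, 0.35, 0.5])
        mu = np.repeat(np.concatenate([levels, -levels]), 10_000)
        dv = rng.normal(mu, 0.133)
        choice = np.where(dv >= 0, 1, -1)
        fit = sdt.fit_internal_noise(mu, choice)
        assert fit.sigma_hat == pytest.approx(0.133, rel=0.1)

    def test_separable_data_raises(self):
        mu = np.repeat([-0.3, -0.1, 0.1, 0.3], 50)
        choice = np.where(mu > 0, 1, -1).astype(int)  # noiseless, perfectly separable
        with pytest.raises(sdt.FitError):
            sdt.fit_internal_noise(mu, choice)

    def test_identical_choices_raise(self):
        mu = np.repeat([-0.2, -0.1, 0.1, 0.2], 10)
        with pytest.raises(sdt.FitError):
            sdt.fit_internal_noise(mu, np.ones_like(mu))


class TestPredictFromEvidence:
    def test_stimulus_model_at_zero_evidence(self):
        out = sdt.predict_from_evidence(
            np.zeros(3), np.array([1, 0, 1]), sigma=0.133, model="stimulus"
        )
        assert np.allclose(out["uncertainty"], 0.5)

    def test_belief_error_uncertainty_increases_with_evidence(self):
        ev = np.array([0.02, 0.07, 0.14, 0.3])
        out = sdt.predict_from_evidence(ev, np.zeros(4, dtype=int), sigma=0.133)
        assert np.all(np.diff(out["uncertainty"]) > 0)

    def test_belief_correct_uncertainty_decreases_with_evidence(self):
        ev = np.array([0.02, 0.07, 0.14, 0.3])
        out = sdt.predict_from_evidence(ev, np.ones(4, dtype=int), sigma=0.133)
        assert np.all(np.diff(out["uncertainty"]) < 0)

    @pytest.mark.parametrize("correct", [0, 1])
    def test_matches_truncated_normal_simulation(self, correct):
        # simulation oracle for the analytic conditional confidence
        mu, sigma = 0.0697, 0.133
        rng = np.random.default_rng(11)
        dv = rng.normal(mu, sigma, 1_000_000)
        conf = sdt.prob_correct(np.abs(dv), sigma)
        mask = (dv > 0) if correct else (dv <= 0)
        oracle = conf[mask].mean()
        out = sdt.predict_from_evidence(np.array([mu]), np.array([correct]), sigma=sigma)
        assert 1 - out["uncertainty"].iloc[0] == pytest.approx(oracle, abs=2e-3)

    def test_out_of_range_evidence_clipped_with_warning(self):
        with pytest.warns(RuntimeWarning, match="clipping"):
            out = sdt.predict_from_evidence(
                np.array([0.9]), np.array([1]), sigma=0.133, model="stimulus"
            )
        assert out["evidence_mu"].iloc[0] == 0.5


class TestEvidenceCalibration:
    def test_round_trip_on_linear_relation(self):
        rng = np.random.default_rng(3)
        mu = rng.choice([0.0697, 0.1378], 200) * rng.choice([-1, 1], 200)
        me = 40.0 * mu  # motion energy in arbitrary units
        slope, intercept = sdt.calibrate_evidence(me, mu)
        back = sdt.apply_calibration(me, slope, intercept)
        assert np.allclose(back, mu, atol=1e-10)
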