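"""Truncated fitting, extrapolation scoring and extreme-case envelopes."""

import numpy as np
import pytest

from kuznefit.data import PatientRecord, clean, normalize
from kuznefit.fitting import FitConfig, FitResult, fit_patient, goodness
from kuznefit.forecast import (
    PredictConfig,
    extrapolate,
    extreme_envelope,
    fit_truncated,
    mape,
    prediction_table,
)
from kuznefit.model import ScaleConstants
from kuznefit.synthetic import SyntheticSpec, sample_patient

SCALES = ScaleConstants()
FIT_CFG = FitConfig(n_starts=2, max_evals=2500, max_time=30.0, seed=3,
                    target_objective=1e-9)


def make_patient(seed=31, n_visits=(9, 9), noise=0.0):
    spec = SyntheticSpec(n_patients=1, ld_noise_sd=noise, seed=seed, n_visits=n_visits)
    gt = sample_patient(spec, np.random.default_rng(seed))
    rec = normalize(clean(PatientRecord(
        patient_id="F1", time_days=gt.time_days, ld_mm=gt.ld_noisy)), SCALES)
    return rec, gt


class TestMape:
    def test_exact_predictions(self):
        assert mape([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_hand_computed_value(self):
        # (|0.1/1| + |0.2/2|) / 2
        assert mape([1.0, 2.0], [1.1, 1.8]) == pytest.approx(0.1)

    @pytest.mark.parametrize("c", [0.5, 3.0, 100.0])
    def test_scale_invariance(self, c):
        obs, pred = np.array([1.0, 2.0, 4.0]), np.array([1.2, 1.9, 4.4])
        assert mape(c * obs, c * pred) == pytest.approx(mape(obs, pred))

    def test_zero_observation_rejected(self):
        with pytest.raises(ValueError):
            mape([0.0, 1.0], [1.0, 1.0])


class TestFitTruncated:
    def test_zero_holdout_matches_full_fit(self):
        rec, _ = make_patient()
        cfg = PredictConfig(zeta=0)
        ext = fit_truncated(rec, cfg, FIT_CFG, SCALES)
        full = fit_patient(rec, FIT_CFG, SCALES)
        assert ext.fit.objective == full.objective
        assert np.array_equal(ext.fit.theta(), full.theta())

    def test_too_short_record_rejected(self):
        rec, _ = make_patient(n_visits=(4, 4))
        with pytest.raises(ValueError, match="three"):
            fit_truncated(rec, PredictConfig(zeta=2), FIT_CFG, SCALES)

    def test_seven_visits_with_three_held_out(self):
        rec, _ = make_patient(seed=33, n_visits=(7, 7))
        ext = fit_truncated(rec, PredictConfig(zeta=3), FIT_CFG, SCALES)
        assert len(ext.fit.predicted) == 4


class TestExtrapolate:
    def test_truth_parameters_give_tiny_mape(self):
        """Extrapolating the generating parameters reproduces the held-out
        noise-free measurements."""
        rec, gt = make_patient()
        n_fit = len(rec) - 2
        from kuznefit.model import integrate_y
        pred = integrate_y(gt.params.as_array(), gt.x1, rec.y[0],
                           rec.tau[:n_fit], SCALES, FIT_CFG.solver)[:, 1]
        fit = FitResult(patient_id=rec.patient_id, params=gt.params, x1=gt.x1,
                        objective=float(np.sum((pred - rec.y[:n_fit]) ** 2)),
                        predicted=pred, metrics=goodness(rec.y[:n_fit], pred),
                        n_evals=0, starts_used=0, seed=0)
        from kuznefit.forecast import ExtrapolationResult
        ext = extrapolate(ExtrapolationResult(patient_id=rec.patient_id,
                                              zeta=2, fit=fit), rec, SCALES)
        assert ext.mape <= 1e-3
        assert ext.metrics_all.r2 >= 0.999

    def test_recovers_heldout_points_after_fitting(self):
        rec, _ = make_patient(seed=35)
        cfg = PredictConfig(zeta=2)
        ext = extrapolate(fit_truncated(rec, cfg, FIT_CFG, SCALES), rec, SCALES)
        assert ext.predicted_full is not None and len(ext.predicted_full) == len(rec)
        assert ext.mape <= 0.05


class TestExtremeEnvelope:
    @pytest.fixture(scope="class")
    def env_setup(self):
        rec, _ = make_patient(seed=37)
        cfg = PredictConfig(zeta=2, theta=0.10, max_evals=1500, seed=5)
        ext = extrapolate(fit_truncated(rec, cfg, FIT_CFG, SCALES), rec, SCALES)
        env = extreme_envelope(rec, ext, cfg, FIT_CFG, SCALES)
        return rec, cfg, ext, env

    def test_terminal_ordering(self, env_setup):
        _, _, ext, env = env_setup
        y_ext = ext.predicted_full[-1]
        assert env.lower.predicted_full[-1] <= y_ext + 1e-5
        assert y_ext <= env.upper.predicted_full[-1] + 1e-5

    def test_branches_respect_fitted_window(self, env_setup):
        rec, cfg, ext, env = env_setup
        n_fit = len(rec) - cfg.zeta
        y_ref = ext.fit.predicted
        for branch in (env.upper, env.lower):
            dev = np.abs(branch.predicted_full[:n_fit] - y_ref)
            assert np.all(dev <= cfg.theta * y_ref + cfg.constraint_tol)

    def test_spread_widens_with_theta(self):
        rec, _ = make_patient(seed=39)
        fit_part = fit_truncated(rec, PredictConfig(zeta=2), FIT_CFG, SCALES)
        ext = extrapolate(fit_part, rec, SCALES)
        prev_env, prev_spread = None, -np.inf
        for theta in (0.05, 0.10, 0.20):
            cfg = PredictConfig(zeta=2, theta=theta, max_evals=1000, seed=5)
            env = extreme_envelope(rec, ext, cfg, FIT_CFG, SCALES,
                                   seed_envelope=prev_env)
            assert env.terminal_spread() >= prev_spread - 1e-9
            prev_env, prev_spread = env, env.terminal_spread()

    def test_requires_completed_extrapolation(self):
        rec, _ = make_patient(seed=37)
        ext = fit_truncated(rec, PredictConfig(zeta=2), FIT_CFG, SCALES)
        with pytest.raises(ValueError, match="extrapolate"):
            extreme_envelope(rec, ext, PredictConfig(zeta=2), FIT_CFG, SCALES)


def test_prediction_table_shape():
    rec, _ = make_patient(seed=35)
    cfg = PredictConfig(zeta=2, max_evals=800, seed=5)
    ext = extrapolate(fit_truncated(rec, cfg, FIT_CFG, SCALES), rec, SCALES)
    env = extreme_envelope(rec, ext, cfg, FIT_CFG, SCALES)
    table = prediction_table([ext], [env])
    assert len(table) == 1
    assert {"patient_id", "zeta", "mape", "r2", "terminal_y",
            "terminal_y_upper", "terminal_y_lower"} <= set(table.columns)
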