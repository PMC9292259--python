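"""Maximum-likelihood fitting of the eight movement parameters.

Both MLE solvers are validated three ways: parameter recovery from large
samples, optimality against brute-force grid searches, and agreement with
scipy's independent fitters.
"""

import numpy as np
import pytest
from scipy import stats

from audiomaze.fitting import (
    DegenerateDataError,
    GammaParams,
    fit_gamma,
    fit_model_params,
    fit_vonmises,
    log_likelihood,
)
from audiomaze.models import StepLabelSeq
from audiomaze.preprocess import MotionVectors
from audiomaze.util import wrap_angle


def _motions_from(d, theta):
    d = np.asarray(d, float)
    theta = np.asarray(theta, float)
    heading = np.cumsum(theta)
    v = d[:, None] * np.stack([np.cos(heading), np.sin(heading)], axis=1)
    return MotionVectors(v_measured=v, d=d, heading=heading, theta=theta)


class TestGammaMLE:
    def test_parameter_recovery(self):
        rng = np.random.default_rng(0)
        x = rng.gamma(2.0, 0.03, size=10_000)
        p = fit_gamma(x)
        assert p.shape == pytest.approx(2.0, rel=0.05)
        assert p.scale == pytest.approx(0.03, rel=0.05)

    def test_beats_grid_search(self):
        rng = np.random.default_rng(1)
        x = rng.gamma(1.7, 0.05, size=50)
        p = fit_gamma(x)
        ll_fit = stats.gamma.logpdf(x, p.shape, scale=p.scale).sum()
        shapes = np.linspace(0.2, 8.0, 200)
        scales = np.linspace(1e-3, 0.3, 200)
        lls = stats.gamma.logpdf(
            x[None, None, :], shapes[:, None, None],
            scale=scales[None, :, None],
        ).sum(axis=2)
        assert ll_fit >= lls.max() - 1e-9

    def test_agrees_with_scipy_fit(self):
        rng = np.random.default_rng(2)
        x = rng.gamma(3.0, 0.02, size=2000)
        p = fit_gamma(x)
        a_sp, _, scale_sp = stats.gamma.fit(x, floc=0)
        assert p.shape == pytest.approx(a_sp, rel=1e-4)
        assert p.scale == pytest.approx(scale_sp, rel=1e-4)

    def test_mean_accessor(self):
        assert GammaParams(shape=2.0, scale=3.0).mean == 6.0

    def test_error_cases(self):
        with pytest.raises(ValueError, match="positive"):
            fit_gamma([0.1, -0.2, 0.3])
        with pytest.raises(ValueError, match="3 samples"):
            fit_gamma([0.1, 0.2])
        with pytest.raises(DegenerateDataError):
            fit_gamma([0.2, 0.2, 0.2, 0.2])

    def test_bias_shrinks_with_sample_size(self):
        """Average |shape error| at n = 1e4 is below that at n = 1e2."""
        rng = np.random.default_rng(3)
        err_small, err_large = [], []
        for _ in range(100):
            err_small.append(abs(fit_gamma(rng.gamma(2.0, 0.03, 100)).shape - 2.0))
            err_large.append(abs(fit_gamma(rng.gamma(2.0, 0.03, 10_000)).shape - 2.0))
        assert np.mean(err_large) < np.mean(err_small)


class TestVonMisesMLE:
    def test_parameter_recovery(self):
        rng = np.random.default_rng(4)
        th = rng.vonmises(0.5, 4.0, size=10_000)
        p = fit_vonmises(th)
        assert p.location == pytest.approx(0.5, abs=0.05)
        assert p.kappa == pytest.approx(4.0, rel=0.10)

    def test_beats_grid_search(self):
        rng = np.random.default_rng(5)
        th = rng.vonmises(1.0, 2.0, size=50)
        p = fit_vonmises(th)
        ll_fit = stats.vonmises.logpdf(th, p.kappa, loc=p.location).sum()
        locs = np.linspace(-np.pi, np.pi, 200)
        kappas = np.linspace(0.05, 20.0, 200)
        lls = stats.vonmises.logpdf(
            th[None, None, :], kappas[None, :, None], loc=locs[:, None, None]
        ).sum(axis=2)
        assert ll_fit >= lls.max() - 1e-9

    def test_agrees_with_scipy_fit(self):
        rng = np.random.default_rng(6)
        th = rng.vonmises(-0.8, 3.0, size=2000)
        p = fit_vonmises(th)
        kappa_sp, loc_sp, _ = stats.vonmises.fit(th, fscale=1)
        assert p.location == pytest.approx(loc_sp, abs=1e-3)
        assert p.kappa == pytest.approx(kappa_sp, rel=1e-3)

    def test_identical_angles_flagged_concentrated(self):
        p = fit_vonmises([0.7, 0.7, 0.7, 0.7])
        assert p.flag == "concentrated"
        assert p.location == pytest.approx(0.7)
        assert p.dispersion == 0.0
        assert np.isinf(p.kappa)

    def test_uniform_sample_flagged(self):
        # four angles with an exactly vanishing resultant
        p = fit_vonmises([0.0, np.pi / 2, np.pi, -np.pi / 2])
        assert p.flag == "uniform"
        assert np.isinf(p.dispersion)

    def test_rotation_equivariance(self):
        rng = np.random.default_rng(7)
        th = rng.vonmises(0.3, 2.5, size=500)
        base = fit_vonmises(th)
        for shift in (0.5, -2.0, 3.0):
            p = fit_vonmises(wrap_angle(th + shift))
            assert wrap_angle(p.location - base.location - shift) == pytest.approx(
                0.0, abs=1e-10
            )
            assert p.kappa == pytest.approx(base.kappa, rel=1e-10)


class TestFitModelParams:
    def test_all_one_class_flags_other_missing(self):
        rng = np.random.default_rng(8)
        mv = _motions_from(rng.gamma(2, 0.03, 50), rng.vonmises(0, 4, 50))
        labels = StepLabelSeq(labels=np.zeros(50, bool), model_kind="FB")
        params = fit_model_params(mv, labels)
        assert params.missing_classes == ["wall"]
        assert params.gamma_nowall is not None

    def test_recovery_with_oracle_labels(self):
        """Regime-switched draws with known labels: all eight parameters
        recovered within 10% at 500 steps per class."""
        rng = np.random.default_rng(9)
        n = 500
        d = np.concatenate([rng.gamma(2.0, 0.033, n), rng.gamma(1.5, 0.015, n)])
        th = np.concatenate([rng.vonmises(0.2, 4.0, n), rng.vonmises(0.8, 1.5, n)])
        labels = np.concatenate([np.zeros(n, bool), np.ones(n, bool)])
        perm = rng.permutation(2 * n)
        mv = _motions_from(d[perm], th[perm])
        params = fit_model_params(mv, StepLabelSeq(labels=labels[perm], model_kind="FB"))
        assert params.gamma_nowall.shape == pytest.approx(2.0, rel=0.10)
        assert params.gamma_nowall.scale == pytest.approx(0.033, rel=0.10)
        assert params.gamma_wall.shape == pytest.approx(1.5, rel=0.10)
        assert params.gamma_wall.scale == pytest.approx(0.015, rel=0.10)
        assert params.vm_nowall.location == pytest.approx(0.2, abs=0.05)
        assert params.vm_nowall.kappa == pytest.approx(4.0, rel=0.10)
        assert params.vm_wall.location == pytest.approx(0.8, abs=0.10)
        assert params.vm_wall.kappa == pytest.approx(1.5, rel=0.10)

    def test_wall_steps_are_shorter_in_cohort_fits(self, sample_series):
        """Map-using synthetic walks: fitted mean no-wall step exceeds the
        fitted mean wall step."""
        from audiomaze.models import run_model

        run = run_model(sample_series, "MBr", seed=0)
        params = fit_model_params(run.motions, run.labels)
        assert params.gamma_nowall.mean > params.gamma_wall.mean


class TestLogLikelihood:
    def _fitted(self, rng, n=400):
        d = np.concatenate([rng.gamma(2.0, 0.033, n), rng.gamma(1.5, 0.015, n)])
        th = np.concatenate([rng.vonmises(0.0, 4.0, n), rng.vonmises(0.8, 1.5, n)])
        labels = np.concatenate([np.zeros(n, bool), np.ones(n, bool)])
        mv = _motions_from(d, th)
        seq = StepLabelSeq(labels=labels, model_kind="FB")
        return mv, seq, fit_model_params(mv, seq)

    def test_per_step_density_closed_form(self):
        mv = _motions_from([0.05], [0.3])
        labels = StepLabelSeq(labels=np.zeros(1, bool), model_kind="FB")
        # evaluate a hand-specified parameter set against scipy directly
        from audiomaze.fitting import ModelParamSet, VonMisesParams

        params = ModelParamSet(
            gamma_nowall=GammaParams(2.0, 0.03),
            gamma_wall=None,
            vm_nowall=VonMisesParams(location=0.1, dispersion=0.25),
            vm_wall=None,
        )
        fr = log_likelihood(params, mv, labels)
        want_step = stats.gamma.logpdf(0.05, 2.0, scale=0.03)
        want_turn = stats.vonmises.logpdf(0.3, 4.0, loc=0.1)
        assert fr.loglik_step == pytest.approx(want_step, abs=1e-12)
        assert fr.loglik_turn == pytest.approx(want_turn, abs=1e-12)

    def test_duplication_doubles_total_not_normalized(self):
        rng = np.random.default_rng(11)
        mv, seq, params = self._fitted(rng)
        single = log_likelihood(params, mv, seq)
        mv2 = _motions_from(np.tile(mv.d, 2), np.tile(mv.theta, 2))
        seq2 = StepLabelSeq(labels=np.tile(seq.labels, 2), model_kind="FB")
        double = log_likelihood(params, mv2, seq2)
        assert double.loglik_step == pytest.approx(2 * single.loglik_step, rel=1e-12)
        assert double.normalized_step == pytest.approx(single.normalized_step, rel=1e-12)

    def test_mle_beats_random_perturbations(self):
        rng = np.random.default_rng(12)
        mv, seq, params = self._fitted(rng)
        best = log_likelihood(params, mv, seq)
        from dataclasses import replace

        for _ in range(1000):
            f = rng.uniform(0.85, 1.15, size=4)
            jitter = replace(
                params,
                gamma_nowall=GammaParams(
                    params.gamma_nowall.shape * f[0], params.gamma_nowall.scale * f[1]
                ),
                gamma_wall=GammaParams(
                    params.gamma_wall.shape * f[2], params.gamma_wall.scale * f[3]
                ),
            )
            assert log_likelihood(jitter, mv, seq).loglik_step <= best.loglik_step + 1e-9

    def test_normalized_loglik_invariant_to_length(self):
        """For i.i.d. draws from the fitted model the per-step score does
        not depend on trial length (within Monte Carlo error)."""
        rng = np.random.default_rng(13)
        scores = {n: [] for n in (200, 800)}
        for n in scores:
            for _ in range(50):
                d = rng.gamma(2.0, 0.033, n)
                th = rng.vonmises(0.0, 4.0, n)
                mv = _motions_from(d, th)
                seq = StepLabelSeq(labels=np.zeros(n, bool), model_kind="FB")
                params = fit_model_params(mv, seq)
                scores[n].append(log_likelihood(params, mv, seq).normalized_step)
        m200, m800 = np.mean(scores[200]), np.mean(scores[800])
        pooled_se = np.sqrt(np.var(scores[200]) / 50 + np.var(scores[800]) / 50)
        assert abs(m200 - m800) < 4 * pooled_se + 0.02

    def test_missing_class_parameters_rejected(self):
        rng = np.random.default_rng(14)
        mv, seq, params = self._fitted(rng)
        from dataclasses import replace

        broken = replace(params, gamma_wall=None)
        with pytest.raises(ValueError, match="missing"):
            log_likelihood(broken, mv, seq)
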