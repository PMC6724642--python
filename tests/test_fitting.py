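"""Training: loss, BPTT gradients, Levenberg-Marquardt staging, saliency tuning."""

from dataclasses import replace

import numpy as np
import pytest

import timingnet as tn
from timingnet.fitting import (
    FitConfig,
    PeakTimingModel,
    bptt_gradient,
    fit_stage,
    loss,
    residual_jacobian,
    tune_saliency,
)
from timingnet.network import FLASH_WEIGHTS, TONE_WEIGHTS


@pytest.fixture(scope="module")
def random_point():
    rng = np.random.default_rng(3)
    return tn.NetworkWeights(*rng.uniform(-0.5, 0.5, 12), 0.1, 0.9)


class TestLoss:
    def test_zero_at_own_output(self, ref_weights, tone_traj):
        assert loss(ref_weights, tn.tone_protocol(), tone_traj.x_out) == 0.0

    def test_zero_for_silent_model_and_target(self, ref_weights):
        silent = tn.StimulusProtocol()
        assert loss(ref_weights, silent, np.zeros(100)) == 0.0

    def test_constant_offset_gives_offset_squared(self, ref_weights, tone_traj):
        shifted = tone_traj.x_out + 0.3
        assert loss(ref_weights, tn.tone_protocol(), shifted) == pytest.approx(0.09)

    def test_length_mismatch_rejected(self, ref_weights):
        with pytest.raises(ValueError, match="length"):
            loss(ref_weights, tn.tone_protocol(), np.zeros(99))


class TestBpttGradient:
    def test_zero_at_loss_minimum(self, ref_weights, tone_traj):
        g = bptt_gradient(ref_weights, tn.tone_protocol(), tone_traj.x_out)
        assert all(abs(v) < 1e-8 for v in g.values())

    def test_matches_central_finite_differences(self, random_point, moderate_tone_target):
        prot = tn.tone_protocol()
        g = bptt_gradient(random_point, prot, moderate_tone_target)
        for name in tn.NetworkWeights.names:
            v = getattr(random_point, name)
            h = 1e-6 * max(1.0, abs(v))
            lp = loss(replace(random_point, **{name: v + h}), prot, moderate_tone_target)
            lm = loss(replace(random_point, **{name: v - h}), prot, moderate_tone_target)
            fd = (lp - lm) / (2 * h)
            assert g[name] == pytest.approx(fd, rel=1e-5, abs=1e-10), name

    def test_masked_weights_get_zero(self, random_point, moderate_tone_target):
        g = bptt_gradient(
            random_point, tn.tone_protocol(), moderate_tone_target,
            trainable=TONE_WEIGHTS,
        )
        assert g["w13"] == 0.0 and g["w14"] == 0.0
        assert g["w7"] == 0.0 and any(g[n] != 0.0 for n in TONE_WEIGHTS)

    def test_saliency_unsupported(self, random_point, moderate_tone_target, ref_saliency):
        with pytest.raises(NotImplementedError):
            bptt_gradient(
                random_point, tn.compound_protocol(), moderate_tone_target,
                saliency=ref_saliency,
            )

    def test_jacobian_consistent_with_reverse_mode(
        self, random_point, moderate_tone_target
    ):
        """Forward-sensitivity Jacobian and reverse-mode BPTT agree:
        grad = (2/N) J^T r."""
        prot = tn.tone_protocol()
        x, J = residual_jacobian(random_point, prot, TONE_WEIGHTS)
        r = x - moderate_tone_target
        g_fwd = 2.0 / len(x) * (J.T @ r)
        g_rev = bptt_gradient(random_point, prot, moderate_tone_target,
                              trainable=TONE_WEIGHTS)
        np.testing.assert_allclose(
            g_fwd, [g_rev[n] for n in TONE_WEIGHTS], rtol=1e-10, atol=1e-14
        )

    def test_finite_diff_jacobian_matches_analytic(self, random_point):
        from timingnet.fitting import _fd_jacobian

        prot = tn.tone_protocol()
        x_a, J_a = residual_jacobian(random_point, prot, TONE_WEIGHTS)
        x_f, J_f = _fd_jacobian(random_point, prot, TONE_WEIGHTS)
        np.testing.assert_allclose(J_a, J_f, rtol=1e-4, atol=1e-7)


class TestFitStage:
    def test_self_consistent_recovery(self, moderate_tone_target):
        """A model-generated target is recovered to near-zero MSE."""
        res = fit_stage(moderate_tone_target, "tone",
                        config=FitConfig(stage="tone", seed=0))
        assert res.mse < 1e-6

    def test_loss_trace_non_increasing(self, moderate_tone_target):
        res = fit_stage(moderate_tone_target, "tone",
                        config=FitConfig(stage="tone", seed=2, max_iterations=50))
        assert np.all(np.diff(res.loss_trace) <= 0)
        assert res.loss_trace[-1] <= res.loss_trace[0]

    def test_non_convergence_flagged_not_raised(self, moderate_tone_target):
        res = fit_stage(moderate_tone_target, "tone",
                        config=FitConfig(stage="tone", seed=1, max_iterations=2))
        assert res.converged is False

    def test_flash_stage_freezes_tone_weights_bit_identically(self, ref_weights):
        target = tn.simulate_network(tn.flash_protocol(), ref_weights).x_out
        res = fit_stage(target, "flash", start=ref_weights,
                        config=FitConfig(stage="flash", seed=0))
        for name in TONE_WEIGHTS + ("w13", "w14"):
            assert getattr(res.weights, name) == getattr(ref_weights, name)
        assert res.mse < 1e-6

    def test_fit_synthetic_tone_curve_peak_within_one_second(self):
        """Fitting a tone-like behavioral curve puts the model's peak within
        1 s of the curve's 5-s peak."""
        curve = tn.make_curve(tn.CurveSpec(peak_time=5, width50=9, asymmetry=2.0,
                                           baseline=0.05, amplitude=1.0))
        target = curve.rate / curve.rate.max()
        model = PeakTimingModel(target, stage="tone")
        res = model.fit_multistart(seeds=range(3))
        peak = int(np.argmax(res.fittedvalues)) + 1
        target_peak = int(np.argmax(target)) + 1
        assert abs(peak - target_peak) <= 1

    def test_fit_synthetic_flash_curve_peak_within_two_seconds(self):
        curve = tn.make_curve(tn.CurveSpec(peak_time=30, width50=40, asymmetry=1.5,
                                           baseline=0.05, amplitude=1.0))
        target = curve.rate / curve.rate.max()
        res = PeakTimingModel(target, stage="flash").fit_multistart(seeds=range(3))
        peak = int(np.argmax(res.fittedvalues)) + 1
        target_peak = int(np.argmax(target)) + 1
        assert abs(peak - target_peak) <= 2

    def test_solution_is_stationary_for_scipy_least_squares(
        self, moderate_tone_target
    ):
        """Independent optimizer cross-check: scipy's trust-region least
        squares cannot improve on the LM solution from that solution."""
        from scipy.optimize import least_squares as scipy_ls

        prot = tn.tone_protocol()
        res = fit_stage(moderate_tone_target, "tone",
                        config=FitConfig(stage="tone", seed=0))

        def residuals(theta):
            w = res.weights.updated(TONE_WEIGHTS, theta)
            return tn.simulate_network(prot, w).x_out - moderate_tone_target

        def jac(theta):
            w = res.weights.updated(TONE_WEIGHTS, theta)
            return residual_jacobian(w, prot, TONE_WEIGHTS)[1]

        out = scipy_ls(residuals, res.weights.asarray(TONE_WEIGHTS), jac=jac)
        assert 2 * out.cost / 100 <= res.mse + 1e-9

    def test_results_object_surface(self, moderate_tone_target):
        model = PeakTimingModel(moderate_tone_target, stage="tone")
        res = model.fit(FitConfig(stage="tone", seed=0))
        assert res.fittedvalues.shape == (100,)
        assert res.resid.shape == (100,)
        assert "Peak timing network fit" in res.summary()
        assert res.predict().shape == (100,)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            FitConfig(max_iterations=0)
        with pytest.raises(ValueError):
            FitConfig(damping_init=0.0)


class TestTuneSaliency:
    def test_recovers_generating_constants(self, ref):
        w, sal = ref
        target = tn.simulate_network(tn.compound_protocol(), w, sal).x_out
        grid = {
            "t_sat": [1.0, 1.6, 2.2],
            "f_sat": [0.5, 0.85, 1.2],
            "cutoff_a": [-0.8632, -0.5],
            "cutoff_v": [-0.4, -0.2],
        }
        res = tune_saliency(w, target, grid)
        assert res.params.t_sat == 1.6 and res.params.f_sat == 0.85
        assert res.params.cutoff_a == -0.8632 and res.params.cutoff_v == -0.2
        assert res.mse == 0.0

    def test_single_point_grid(self, ref_weights, compound_traj):
        res = tune_saliency(ref_weights, compound_traj.x_out, {"t_sat": [1.1]})
        assert res.params.t_sat == 1.1 and res.n_evaluated == 1

    def test_empty_grid_rejected(self, ref_weights, compound_traj):
        with pytest.raises(ValueError):
            tune_saliency(ref_weights, compound_traj.x_out, {})
        with pytest.raises(ValueError):
            tune_saliency(ref_weights, compound_traj.x_out, {"t_sat": []})

    def test_saliency_improves_intermediate_peak_target(self, ref_weights):
        """On a compound target peaking between the two trained times, tuned
        saliency beats the plain linear (superposed) model."""
        curve = tn.make_curve(tn.CurveSpec(peak_time=16.2, width50=35.9,
                                           asymmetry=1.5, baseline=0.05,
                                           amplitude=1.0))
        y = curve.rate / curve.rate.max()
        prot = tn.compound_protocol()
        mse_linear = loss(ref_weights, prot, y)
        grid = {"t_sat": [1.0, 1.6, 2.2], "f_sat": [0.5, 0.85, 1.2]}
        res = tune_saliency(ref_weights, y, grid)
        assert res.mse <= mse_linear
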