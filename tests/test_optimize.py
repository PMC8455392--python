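"""Inverse identification: objective definition, fit quality metric,
self-consistency and identifiability structure."""

import numpy as np
import pytest

from poroindent.analysis import IndentationExperiment, StepAnnotation
from poroindent.exceptions import PoroindentError
from poroindent.material import FRPEParameters
from poroindent.optimize import (
    OptimizationConfig,
    _FitContext,
    fit_frpe,
    generate_starts,
    goodness_of_fit,
)


class TestGoodnessOfFit:
    def test_identical_series(self):
        y = np.array([1.0, 2.0, 3.0])
        assert goodness_of_fit(y, y) == pytest.approx(1.0)

    def test_constant_mean_prediction_scores_zero(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        assert goodness_of_fit(np.full(4, y.mean()), y) == pytest.approx(0.0)

    def test_four_point_hand_computation(self):
        meas = np.array([1.0, 2.0, 3.0, 4.0])
        sim = np.array([1.1, 1.9, 3.2, 3.9])
        # SS_res = 0.01+0.01+0.04+0.01 = 0.07; SS_tot = 5.0
        assert goodness_of_fit(sim, meas) == pytest.approx(1.0 - 0.07 / 5.0)

    def test_zero_variance_measured_rejected(self):
        with pytest.raises(PoroindentError):
            goodness_of_fit(np.array([1.0, 2.0]), np.array([3.0, 3.0]))


class TestObjective:
    def test_hand_computed_normalized_mse(self, relax_experiment):
        """With the forward model stubbed, the objective must equal the
        weighted MSE over steps 2-3 divided by the squared force range."""
        ctx = _FitContext(relax_experiment, OptimizationConfig())
        shift = 0.01
        ctx.simulated_force = lambda p: ctx.f_fit + shift
        expected = shift**2 / ctx.f_range**2  # uniform weights sum to 1
        assert ctx.objective(None) == pytest.approx(expected, rel=1e-12)

    def test_self_fit_is_zero(self, relax_experiment, ref_params):
        ctx = _FitContext(relax_experiment, OptimizationConfig())
        assert ctx.objective(ref_params) < 1e-12

    def test_identifiability_direction(self, relax_experiment, ref_params):
        ctx = _FitContext(relax_experiment, OptimizationConfig())
        worse = ctx.objective(ref_params.replace(Enf=2 * ref_params.Enf))
        assert worse > ctx.objective(ref_params) + 1e-4

    def test_forward_failure_returns_finite_penalty(self, relax_experiment):
        ctx = _FitContext(relax_experiment, OptimizationConfig())

        def boom(p):
            from poroindent.exceptions import ConvergenceError

            raise ConvergenceError("nope")

        ctx.simulated_force = boom
        val = ctx.objective(None)
        assert np.isfinite(val) and val >= 1e5

    def test_equilibrium_only_window_leaves_k0_unidentified(
        self, relax_experiment, ref_params
    ):
        """Keeping only the end-of-hold samples, the objective is flat in k0
        but still curved in Enf -- the transient window is what identifies
        the permeability."""
        ctx = _FitContext(relax_experiment, OptimizationConfig())
        keep = np.zeros(ctx.t_fit.size, dtype=bool)
        for i in (1, 2):
            s = relax_experiment.steps[i]
            keep |= np.abs(ctx.t_fit - s.t_hold_end) < 1e-6
        ctx.t_fit, ctx.f_fit = ctx.t_fit[keep], ctx.f_fit[keep]
        ctx.f_range = float(ctx.f_fit.max() - ctx.f_fit.min())
        ctx.weights = np.full(ctx.t_fit.size, 1.0 / ctx.t_fit.size)
        d_k0 = ctx.objective(ref_params.replace(k0=5 * ref_params.k0))
        d_enf = ctx.objective(ref_params.replace(Enf=1.3 * ref_params.Enf))
        assert d_k0 < 1e-4
        assert d_enf > 100 * max(d_k0, 1e-12)


class TestFitFrpe:
    def test_flat_force_record_flagged_not_raised(self, geometry):
        t = np.linspace(0, 4000, 100)
        steps = [
            StepAnnotation(f"step{i+1}", 1000.0 * i, 1000.0 * i + 1,
                           1000.0 * (i + 1), 0.05 * i, 0.05 * (i + 1))
            for i in range(4)
        ]
        exp = IndentationExperiment(geometry=geometry, time=t,
                                    displacement=np.zeros_like(t),
                                    force=np.ones_like(t), steps=steps)
        res = fit_frpe(exp, OptimizationConfig())
        assert not res.converged
        assert "degenerate" in res.message

    def test_start_generation_is_seeded_and_bounded(self):
        cfg = OptimizationConfig(n_starts=8, seed=3, perturbation=0.5)
        guess = FRPEParameters(Ef0=1.0, EfEps=10.0, Enf=0.5, k0=5.0, M=5.0)
        a = generate_starts(guess, cfg)
        b = generate_starts(guess, cfg)
        assert all(pa == pb for pa, pb in zip(a, b))
        for p in a:
            for name, (lo, hi) in cfg.bounds.items():
                assert lo <= getattr(p, name) <= hi
            assert 0.5 * guess.Ef0 <= p.Ef0 <= 1.5 * guess.Ef0

    def test_noiseless_recovery_from_perturbed_start(self, relax_experiment, ref_params):
        """Parameter recovery on forward-generated data: the optimum is the
        generating parameter set."""
        start = FRPEParameters(
            Ef0=1.5 * ref_params.Ef0, EfEps=0.5 * ref_params.EfEps,
            Enf=1.5 * ref_params.Enf, k0=0.5 * ref_params.k0, M=1.5 * ref_params.M,
        )
        res = fit_frpe(relax_experiment, OptimizationConfig(max_nfev=80), starts=[start])
        assert res.converged
        assert res.objective < 1e-6
        assert res.r_squared > 0.999
        rel = np.abs(res.params.as_array() / ref_params.as_array() - 1.0)
        assert np.all(rel[[0, 1, 2, 3]] < 0.05)
        assert abs(res.params.M - ref_params.M) < 0.5
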