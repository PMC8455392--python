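"""Property extraction: equilibrium/instantaneous moduli and the Fourier
analysis of sinusoidal blocks."""

import numpy as np
import pytest

from poroindent.analysis import (
    AnalysisOptions,
    DynamicBlock,
    IndentationExperiment,
    StepAnnotation,
    analyze_experiment,
    dynamic_properties,
    equilibrium_modulus,
    instantaneous_moduli,
)
from poroindent.exceptions import SignalQualityError
from poroindent.hayes import flat_punch_force
from poroindent.mesh import SampleGeometry
from poroindent.protocol import PROTOCOL_FREQUENCIES


def synthetic_relaxation(geometry, E_eq, E_inst_per_step, start_strain=0.0,
                         nu_eq=0.42, nu_inst=0.5):
    """Four-step record whose end-of-hold forces follow the flat-punch
    relation for modulus E_eq and whose ramp peaks encode the requested
    per-step instantaneous moduli."""
    h = geometry.thickness
    steps, t, w, f = [], [0.0], [start_strain * h], [0.0]
    f_eq_prev = flat_punch_force(E_eq, nu_eq, geometry.indenter_radius, h,
                                 start_strain * h)
    f[0] = f_eq_prev
    t0 = 0.0
    for i in range(4):
        s0 = start_strain + 0.05 * i
        s1 = s0 + 0.05
        f_eq = flat_punch_force(E_eq, nu_eq, geometry.indenter_radius, h, s1 * h)
        df_peak = (
            E_inst_per_step[i] * 0.05 * geometry.contact_area
            * 2 * h * _kappa(geometry, nu_inst) / (np.pi * geometry.indenter_radius
                                                   * (1 - nu_inst**2))
        )
        ramp_t, hold_t = 1.0, 900.0
        tt = np.concatenate([np.linspace(t0, t0 + ramp_t, 5)[1:],
                             t0 + ramp_t + np.linspace(0, hold_t, 200)[1:]])
        peak = f_eq_prev + df_peak
        fr = np.concatenate([
            np.linspace(f[-1], peak, 5)[1:],
            f_eq + (peak - f_eq) * np.exp(-np.linspace(0, hold_t, 200)[1:] / 30.0),
        ])
        wr = np.concatenate([np.linspace(s0 * h, s1 * h, 5)[1:],
                             np.full(199, s1 * h)])
        t.extend(tt); f.extend(fr); w.extend(wr)
        steps.append(StepAnnotation(f"step{i+1}", t0, t0 + ramp_t,
                                    t0 + ramp_t + hold_t, s0, s1))
        t0 += ramp_t + hold_t
        f_eq_prev = f_eq
    return IndentationExperiment(geometry=geometry, time=np.array(t),
                                 displacement=np.array(w), force=np.array(f),
                                 steps=steps)


def _kappa(geometry, nu):
    from poroindent.hayes import hayes_kappa

    return hayes_kappa(geometry.aspect, nu)


class TestEquilibriumModulus:
    def test_recovers_generating_modulus(self, geometry):
        exp = synthetic_relaxation(geometry, E_eq=0.8, E_inst_per_step=[2, 2, 2, 2])
        out = equilibrium_modulus(exp)
        assert out.E_eq == pytest.approx(0.8, rel=0.01)

    def test_collinear_points_fit_exactly(self, geometry):
        exp = synthetic_relaxation(geometry, E_eq=0.8, E_inst_per_step=[2, 2, 2, 2])
        out = equilibrium_modulus(exp)
        assert out.diagnostics["r2"] == pytest.approx(1.0, abs=1e-6)
        assert np.allclose(out.diagnostics["residuals"], 0.0, atol=1e-9)

    def test_plateau_criterion_flags_unequilibrated_steps(self, geometry):
        exp = synthetic_relaxation(geometry, E_eq=0.8, E_inst_per_step=[2, 2, 2, 2])
        out = equilibrium_modulus(exp)
        assert all(out.diagnostics["equilibrated"])
        # a drastically slower relaxation must trip the flag
        slow = synthetic_relaxation(geometry, 0.8, [2, 2, 2, 2])
        slow.force = slow.force + 0.05 * np.sin(slow.time / 2000.0)
        out2 = equilibrium_modulus(slow)
        assert not all(out2.diagnostics["equilibrated"])


class TestInstantaneousModuli:
    def test_strain_independent_moduli(self, geometry):
        exp = synthetic_relaxation(geometry, 0.8, [3.0, 3.0, 3.0, 3.0])
        E0, Ee, diag = instantaneous_moduli(exp)
        assert E0 == pytest.approx(3.0, rel=0.02)
        assert Ee == pytest.approx(0.0, abs=0.05)

    def test_linear_strain_dependence_recovered_exactly(self, geometry):
        # per-step modulus m_i = 2 + 10 * eps_onset
        onsets = [0.0, 0.05, 0.10, 0.15]
        exp = synthetic_relaxation(geometry, 0.8, [2.0 + 10.0 * e for e in onsets])
        E0, Ee, diag = instantaneous_moduli(exp)
        assert E0 == pytest.approx(2.0, rel=0.02)
        assert Ee == pytest.approx(10.0, rel=0.02)
        assert diag["r2"] == pytest.approx(1.0, abs=1e-6)

    def test_missing_peak_detected(self, geometry):
        exp = synthetic_relaxation(geometry, 0.8, [2, 2, 2, 2])
        exp.force = np.zeros_like(exp.force)  # flat record: no ramp peaks
        with pytest.raises(SignalQualityError):
            instantaneous_moduli(exp)


def _sine_block(geometry, freq, cycles, lag_deg, ratio, n_per_cycle=60,
                offset_w=0.4, offset_f=0.5, amp_w=0.04):
    t = np.linspace(0.0, cycles / freq, int(cycles * n_per_cycle) + 1)
    w = offset_w + amp_w * np.sin(2 * np.pi * freq * t)
    f = offset_f + ratio * amp_w * np.sin(2 * np.pi * freq * t + np.radians(lag_deg))
    return DynamicBlock(frequency=freq, time=t, displacement=w, force=f)


class TestDynamicProperties:
    @pytest.mark.parametrize("freq", PROTOCOL_FREQUENCIES)
    @pytest.mark.parametrize("lag", [0.0, 5.0, 10.0, 45.0])
    def test_phase_and_amplitude_exact_on_clean_sinusoids(self, geometry, freq, lag):
        blk = _sine_block(geometry, freq, cycles=5, lag_deg=lag, ratio=2.0)
        exp = IndentationExperiment(geometry=geometry, time=np.array([0.0, 1.0]),
                                    displacement=np.zeros(2), force=np.zeros(2),
                                    steps=[], dynamic=[blk])
        dyn = dynamic_properties(exp, freq)
        assert dyn.theta_dynamic[0] == pytest.approx(lag, abs=0.1)
        fac = (1 - 0.5**2) / (2 * geometry.indenter_radius * _kappa(geometry, 0.5))
        assert dyn.E_dynamic[0] == pytest.approx(2.0 * fac, rel=1e-3)

    def test_requires_four_cycles(self, geometry):
        blk = _sine_block(geometry, 1.0, cycles=2, lag_deg=0.0, ratio=1.0)
        exp = IndentationExperiment(geometry=geometry, time=np.array([0.0, 1.0]),
                                    displacement=np.zeros(2), force=np.zeros(2),
                                    steps=[], dynamic=[blk])
        with pytest.raises(SignalQualityError):
            dynamic_properties(exp, 1.0)

    def test_noise_floor_guard(self, geometry):
        rng = np.random.default_rng(0)
        blk = _sine_block(geometry, 1.0, cycles=5, lag_deg=0.0, ratio=1e-9)
        blk.force = 0.5 + 0.01 * rng.standard_normal(blk.force.size)
        exp = IndentationExperiment(geometry=geometry, time=np.array([0.0, 1.0]),
                                    displacement=np.zeros(2), force=np.zeros(2),
                                    steps=[], dynamic=[blk])
        with pytest.raises(SignalQualityError):
            dynamic_properties(exp, 1.0)

    def test_negative_lag_flagged_not_wrapped(self, geometry):
        blk = _sine_block(geometry, 0.5, cycles=5, lag_deg=-8.0, ratio=1.5)
        exp = IndentationExperiment(geometry=geometry, time=np.array([0.0, 1.0]),
                                    displacement=np.zeros(2), force=np.zeros(2),
                                    steps=[], dynamic=[blk])
        dyn = dynamic_properties(exp, 0.5)
        assert dyn.artifacts[0]
        assert dyn.theta_dynamic[0] == pytest.approx(-8.0, abs=0.1)


class TestPipelineOnForwardSimulation:
    def test_deterministic_extraction(self, full_experiment):
        a = analyze_experiment(full_experiment)
        b = analyze_experiment(full_experiment)
        assert a == b

    def test_strain_stiffening_surfaces_in_instantaneous_slope(self, full_experiment):
        # the generating model has EfEps > 0, so the per-step instantaneous
        # moduli must increase with strain
        E0, Ee, diag = instantaneous_moduli(full_experiment)
        assert Ee > 0

    def test_phase_lag_decreases_from_lowest_to_highest_frequency(self, full_experiment):
        dyn = dynamic_properties(full_experiment)
        order = np.argsort(dyn.frequencies)
        th = dyn.theta_dynamic[order]
        assert th[-1] < th[0]

    def test_dynamic_modulus_exceeds_equilibrium_modulus(self, full_experiment):
        props = analyze_experiment(full_experiment)
        assert props["E_dyn_1Hz"] > props["E_eq"]
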