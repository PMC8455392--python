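"""Extraction of elastic and dynamic viscoelastic properties from
indentation records.

Elastic properties come from the multi-step stress-relaxation phase:

* ``E_eq`` -- slope of a least-squares line through the Hayes-corrected
  equilibrium stress-strain points of the four steps;
* ``E_inst0`` / ``E_instEps`` -- intercept and slope of a least-squares line
  through the per-step instantaneous moduli (Hayes-corrected peak stress
  increment over strain increment) against the pre-step strain.

Dynamic properties come from the sinusoidal sweeps, per frequency:

* ``E_dynamic`` -- Hayes-corrected stress amplitude over strain amplitude;
* ``theta_dynamic`` -- phase of force minus phase of displacement (deg),
  both read from the discrete Fourier component at the drive frequency.

The Hayes correction converts the measured punch stiffness on a bonded
layer of finite thickness to a modulus:  E = P (1 - nu^2) / (2 a w kappa).
By convention the short-time (instantaneous, dynamic) response is treated
as incompressible (nu = 0.5) and the equilibrium response drained
(nu = 0.42); both are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import SignalQualityError
from .hayes import hayes_kappa
from .mesh import SampleGeometry

__all__ = [
    "AnalysisOptions",
    "IndentationExperiment",
    "ElasticProperties",
    "DynamicProperties",
    "equilibrium_modulus",
    "instantaneous_moduli",
    "dynamic_properties",
    "analyze_experiment",
]


@dataclass(frozen=True)
class AnalysisOptions:
    """Assumed Poisson ratios for the Hayes correction and the plateau
    criterion used to declare a hold equilibrated."""

    nu_equilibrium: float = 0.42
    nu_instantaneous: float = 0.5
    nu_dynamic: float = 0.5
    #: window (s) and relative force-rate threshold (per minute, as a
    #: fraction of the step force change) of the plateau criterion
    plateau_window_s: float = 60.0
    plateau_rate_per_min: float = 0.005


@dataclass
class StepAnnotation:
    """One stress-relaxation step: ramp start/end and hold end times (s) and
    the indentation strain before/after the ramp (fractions of thickness)."""

    label: str
    t_ramp_start: float
    t_ramp_end: float
    t_hold_end: float
    strain_start: float
    strain_end: float


@dataclass
class DynamicBlock:
    """One sinusoidal block tagged with its drive frequency."""

    frequency: float
    time: np.ndarray
    displacement: np.ndarray
    force: np.ndarray


@dataclass
class IndentationExperiment:
    """Time-stamped force/displacement record of one indentation test.

    relaxation series: time (s), displacement (indentation depth, mm),
    force (N); ``steps`` annotates the four stress-relaxation steps;
    ``dynamic`` holds the per-frequency sinusoidal blocks.
    """

    geometry: SampleGeometry
    time: np.ndarray
    displacement: np.ndarray
    force: np.ndarray
    steps: list
    dynamic: list = field(default_factory=list)
    sample_id: str = ""

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.displacement = np.asarray(self.displacement, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if np.any(np.diff(self.time) < 0):
            raise ValueError("relaxation record must be time-sorted")

    def step_window(self, i):
        s = self.steps[i]
        m = (self.time >= s.t_ramp_start - 1e-9) & (self.time <= s.t_hold_end + 1e-9)
        return self.time[m], self.force[m]


@dataclass
class ElasticProperties:
    """Moduli from the stress-relaxation phase (MPa; E_instEps is MPa per
    unit strain) with least-squares diagnostics."""

    E_eq: float
    E_inst0: float
    E_instEps: float
    diagnostics: dict = field(default_factory=dict)


@dataclass
class DynamicProperties:
    """Per-frequency dynamic modulus (MPa) and phase difference (deg)."""

    frequencies: np.ndarray
    E_dynamic: np.ndarray
    theta_dynamic: np.ndarray
    artifacts: np.ndarray  # True where the raw phase difference was negative


def _linfit(x, y):
    """Least-squares line y = a + b x; returns (a, b, r2, residuals)."""
    X = np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    yhat = X @ coef
    res = y - yhat
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - np.sum(res**2) / ss_tot if ss_tot > 0 else 1.0
    return coef[0], coef[1], r2, res


def _stress_to_modulus_factor(geometry: SampleGeometry, nu: float) -> float:
    """Factor converting mean contact stress/strain slope to a modulus:
    E = (sigma/eps) * pi a (1 - nu^2) / (2 h kappa)."""
    a, h = geometry.indenter_radius, geometry.thickness
    return np.pi * a * (1.0 - nu**2) / (2.0 * h * hayes_kappa(a / h, nu))


def equilibrium_modulus(exp: IndentationExperiment, options: AnalysisOptions = None):
    """Equilibrium modulus E_eq from the end-of-hold stress-strain points.

    Each step contributes (strain at hold end, Hayes-corrected equilibrium
    stress); E_eq is the slope of the least-squares line through the points
    (an intercept absorbs the pre-stress offset).  A step whose final
    force-rate exceeds the plateau criterion is flagged in
    ``diagnostics['equilibrated']`` but still used.
    """
    options = options or AnalysisOptions()
    g = exp.geometry
    area = g.contact_area
    fac = _stress_to_modulus_factor(g, options.nu_equilibrium)

    strains, stresses, equilibrated = [], [], []
    for i, s in enumerate(exp.steps):
        t, f = exp.step_window(i)
        stresses.append(f[-1] / area)
        strains.append(s.strain_end)
        m = t >= s.t_hold_end - options.plateau_window_s
        if m.sum() >= 2:
            rate = abs(f[m][-1] - f[m][0]) / max(t[m][-1] - t[m][0], 1e-9) * 60.0
            df_step = abs(f.max() - f[-1])
            equilibrated.append(rate <= options.plateau_rate_per_min * max(df_step, 1e-12))
        else:
            equilibrated.append(False)

    x = np.array(strains)
    y = np.array(stresses) * fac
    a0, slope, r2, res = _linfit(x, y)
    return ElasticProperties(
        E_eq=float(slope),
        E_inst0=np.nan,
        E_instEps=np.nan,
        diagnostics=dict(kind="equilibrium", intercept=float(a0), r2=float(r2),
                         residuals=res, equilibrated=equilibrated),
    )


def instantaneous_moduli(exp: IndentationExperiment, options: AnalysisOptions = None):
    """Instantaneous moduli: per-step Hayes-corrected peak stress increment
    over strain increment, then a least-squares line against pre-step strain
    giving the initial modulus (intercept) and its strain dependence (slope).
    """
    options = options or AnalysisOptions()
    g = exp.geometry
    area = g.contact_area
    fac = _stress_to_modulus_factor(g, options.nu_instantaneous)

    E_i, eps_i = [], []
    f_prev_end = None
    for i, s in enumerate(exp.steps):
        t, f = exp.step_window(i)
        if f.size == 0 or not np.isfinite(f).all():
            raise SignalQualityError(f"step {s.label}: no usable samples")
        peak = f.max()
        if f_prev_end is None:
            # force at step onset (pre-stress equilibrium)
            before = exp.force[exp.time <= s.t_ramp_start + 1e-9]
            f0 = before[-1] if before.size else f[0]
        else:
            f0 = f_prev_end
        dstrain = s.strain_end - s.strain_start
        if peak <= f0 or dstrain <= 0:
            raise SignalQualityError(f"step {s.label}: missing ramp peak")
        E_i.append((peak - f0) / area / dstrain * fac)
        eps_i.append(s.strain_start)
        f_prev_end = f[-1]

    x = np.array(eps_i)
    y = np.array(E_i)
    intercept, slope, r2, res = _linfit(x, y)
    return (
        float(intercept),
        float(slope),
        dict(kind="instantaneous", per_step=y, strains=x, r2=float(r2), residuals=res),
    )


def _fourier_component(t, y, frequency):
    """Amplitude and phase (rad) of the drive-frequency component by
    least-squares projection on [1, cos, sin] -- the discrete Fourier
    component for integer numbers of uniformly sampled cycles."""
    w = 2.0 * np.pi * frequency
    X = np.column_stack([np.ones_like(t), np.cos(w * t), np.sin(w * t)])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    _, B, C = coef
    amp = float(np.hypot(B, C))
    resid = y - X @ coef
    return amp, float(np.arctan2(B, C)), float(np.std(resid)), float(coef[0])


def dynamic_properties(exp: IndentationExperiment, frequency=None,
                       options: AnalysisOptions = None) -> DynamicProperties:
    """Dynamic modulus and phase difference at one frequency (or all tagged
    block frequencies when ``frequency`` is None).

    Requires at least 4 full cycles in the block; the first cycle is dropped
    as a start-up transient when more than 4 are present.  Raises
    SignalQualityError when the drive component does not rise above the
    residual noise floor.
    """
    options = options or AnalysisOptions()
    g = exp.geometry
    blocks = exp.dynamic
    if frequency is not None:
        blocks = [b for b in blocks if abs(b.frequency - frequency) <= 1e-9 + 1e-6 * frequency]
        if not blocks:
            raise SignalQualityError(f"no dynamic block at {frequency} Hz")

    fac = (1.0 - options.nu_dynamic**2) / (
        2.0 * g.indenter_radius * hayes_kappa(g.aspect, options.nu_dynamic)
    )
    freqs, E_dyn, theta, artifacts = [], [], [], []
    for b in blocks:
        t = b.time - b.time[0]
        n_cycles = (t[-1] - t[0]) * b.frequency
        if n_cycles < 4 - 1e-6:
            raise SignalQualityError(
                f"{b.frequency} Hz block holds {n_cycles:.2f} cycles; need >= 4"
            )
        # analyse an integer number of cycles, dropping the first
        start = 1.0 / b.frequency if n_cycles >= 5 else 0.0
        n_use = int(np.floor((t[-1] - start) * b.frequency))
        m = (t >= start - 1e-12) & (t <= start + n_use / b.frequency + 1e-12)
        tt, wdat, fdat = t[m], b.displacement[m], b.force[m]
        w_amp, w_ph, w_res, _ = _fourier_component(tt, wdat, b.frequency)
        f_amp, f_ph, f_res, _ = _fourier_component(tt, fdat, b.frequency)
        if w_amp <= 0 or f_amp < 5.0 * f_res / np.sqrt(max(fdat.size, 1)):
            raise SignalQualityError(f"{b.frequency} Hz: drive component below noise floor")
        th = np.degrees(f_ph - w_ph)
        th = (th + 180.0) % 360.0 - 180.0
        artifacts.append(th < -1e-6)
        theta.append(th)
        # E = F_amp (1 - nu^2) / (2 a w_amp kappa)
        E_dyn.append(f_amp / w_amp * fac)
        freqs.append(b.frequency)

    return DynamicProperties(
        frequencies=np.array(freqs),
        E_dynamic=np.array(E_dyn),
        theta_dynamic=np.array(theta),
        artifacts=np.array(artifacts),
    )


def analyze_experiment(exp: IndentationExperiment, options: AnalysisOptions = None) -> dict:
    """Full per-specimen property extraction as a flat dict (one CSV row)."""
    options = options or AnalysisOptions()
    eq = equilibrium_modulus(exp, options)
    E0, Ee, inst_diag = instantaneous_moduli(exp, options)
    out = dict(
        sample_id=exp.sample_id,
        E_eq=eq.E_eq,
        E_inst0=E0,
        E_instEps=Ee,
        r2_eq=eq.diagnostics["r2"],
        r2_inst=inst_diag["r2"],
    )
    if exp.dynamic:
        dyn = dynamic_properties(exp, options=options)
        for f, E, th in zip(dyn.frequencies, dyn.E_dynamic, dyn.theta_dynamic):
            out[f"E_dyn_{f:g}Hz"] = E
            out[f"theta_{f:g}Hz"] = th
    return out
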