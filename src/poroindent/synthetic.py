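"""Synthetic specimens, indentation experiments and cohorts.

Because raw human indentation records are not publicly deposited, every
stage of the pipeline is exercised on synthetic data: FRPE parameters are
drawn from group-wise log-normal distributions whose defaults emulate the
qualitative osteoarthritis contrast reported for human femoral condyle
cartilage (severe OA: nearly vanished initial fibril modulus, reduced
non-fibrillar modulus and permeability exponent, elevated permeability;
moderate OA barely distinguishable from normal), experiments are forward
simulations of the reference protocol with measurement noise, and cohorts
mirror the 17 normal / 15 moderate / 3 severe grouping of 35 osteochondral
samples with a within-knee random effect on the log-parameters.

The group defaults are conventions chosen for plausibility -- the source
figures print no numbers -- and are fully configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .analysis import DynamicBlock, IndentationExperiment, StepAnnotation
from .material import ConstitutiveConstants, FRPEParameters
from .mesh import Mesh, SampleGeometry, build_mesh
from .protocol import HOLD_DURATION_S, PROTOCOL_FREQUENCIES, STEP_STRAIN
from .solver import SimulationResult, SolverSettings, simulate_paper_protocol

__all__ = [
    "GroupParameterModel",
    "NoiseModel",
    "CohortSpec",
    "SyntheticSample",
    "SyntheticCohort",
    "default_group_model",
    "draw_parameters",
    "generate_experiment",
    "generate_cohort",
    "experiment_from_simulation",
]

GROUPS = ("normal", "moderate", "severe")

#: group-wise log-normal medians for (Ef0, EfEps, Enf, k0, M); units MPa,
#: MPa, MPa, 1e-15 m^4/(N s), --.
_DEFAULT_MEDIANS = {
    "normal": dict(Ef0=1.2, EfEps=12.0, Enf=0.45, k0=7.0, M=9.0),
    "moderate": dict(Ef0=1.0, EfEps=11.0, Enf=0.42, k0=8.0, M=8.0),
    "severe": dict(Ef0=1e-5, EfEps=2.0, Enf=0.15, k0=25.0, M=2.0),
}
_DEFAULT_SCALES = {
    "normal": dict(Ef0=0.45, EfEps=0.40, Enf=0.35, k0=0.50, M=0.35),
    "moderate": dict(Ef0=0.50, EfEps=0.40, Enf=0.35, k0=0.50, M=0.35),
    "severe": dict(Ef0=0.80, EfEps=0.60, Enf=0.40, k0=0.40, M=0.40),
}


@dataclass(frozen=True)
class GroupParameterModel:
    """Log-normal FRPE parameter distributions per OA group.

    medians / log_scales : {group: {parameter: value}}
    knee_correlation     : correlation of log-parameters between samples of
                           the same knee, implemented as a shared knee-level
                           random effect (variance fraction of the log-scale).
    """

    medians: dict = field(default_factory=lambda: dict(_DEFAULT_MEDIANS))
    log_scales: dict = field(default_factory=lambda: dict(_DEFAULT_SCALES))
    knee_correlation: float = 0.6

    def __post_init__(self):
        if not 0.0 <= self.knee_correlation < 1.0:
            raise ValueError("knee_correlation must lie in [0, 1)")
        for g in self.medians:
            if any(s < 0 for s in self.log_scales[g].values()):
                raise ValueError("log scales must be non-negative")


def default_group_model(**kw) -> GroupParameterModel:
    return GroupParameterModel(**kw)


@dataclass(frozen=True)
class NoiseModel:
    """Measurement noise and sampling of the synthetic records.

    force_noise         : multiplicative Gaussian noise on force (fraction)
    displacement_jitter : additive Gaussian noise on displacement (mm)
    relaxation_rate     : sampling rate of the relaxation record (Hz)
    samples_per_cycle   : sampling of the dynamic blocks (per cycle, >= 50
                          gives a comfortable Nyquist margin at 1 Hz)
    """

    force_noise: float = 0.01
    displacement_jitter: float = 0.0
    relaxation_rate: float = 10.0
    samples_per_cycle: int = 50

    def __post_init__(self):
        if self.force_noise < 0 or self.displacement_jitter < 0:
            raise ValueError("noise magnitudes must be non-negative")


def draw_parameters(group: str, model: GroupParameterModel, rng: np.random.Generator,
                    knee_effect: dict = None) -> FRPEParameters:
    """Draw one FRPE parameter set from the group's log-normal distributions.

    ``knee_effect`` optionally supplies standard-normal knee-level deviates
    per parameter; with knee correlation rho the log-parameter is
    mu + sigma (sqrt(rho) z_knee + sqrt(1-rho) z_sample).
    """
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}")
    med = model.medians[group]
    sc = model.log_scales[group]
    rho = model.knee_correlation
    out = {}
    for name in FRPEParameters.names():
        z = rng.standard_normal()
        if knee_effect is not None:
            z = np.sqrt(rho) * knee_effect[name] + np.sqrt(1.0 - rho) * z
        out[name] = med[name] * np.exp(sc[name] * z)
    return FRPEParameters(**out)


def _resample(sim: SimulationResult, noise: NoiseModel, rng, start_strain, thickness):
    """Resample a paper-protocol simulation onto measurement grids, apply
    noise, and annotate steps and dynamic blocks."""
    steps = []
    t_relax_end = 0.0
    ramps = [s for s in sim.segments if s["kind"] == "ramp"]
    holds = [s for s in sim.segments if s["kind"] == "hold"]
    for i, (r, hseg) in enumerate(zip(ramps, holds), start=1):
        steps.append(
            StepAnnotation(
                label=f"step{i}",
                t_ramp_start=r["t_start"],
                t_ramp_end=r["t_end"],
                t_hold_end=hseg["t_end"],
                strain_start=start_strain + (i - 1) * STEP_STRAIN,
                strain_end=start_strain + i * STEP_STRAIN,
            )
        )
        t_relax_end = hseg["t_end"]

    n = int(np.floor(t_relax_end * noise.relaxation_rate)) + 1
    t_meas = np.arange(n) / noise.relaxation_rate
    # make sure the exact step landmarks are part of the record
    landmarks = np.concatenate([[s.t_ramp_start, s.t_ramp_end, s.t_hold_end] for s in steps])
    t_meas = np.unique(np.concatenate([t_meas, landmarks]))
    w = np.interp(t_meas, sim.time, sim.displacement)
    f = np.interp(t_meas, sim.time, sim.force)
    if noise.force_noise > 0:
        f = f * (1.0 + noise.force_noise * rng.standard_normal(f.size))
    if noise.displacement_jitter > 0:
        w = w + noise.displacement_jitter * rng.standard_normal(w.size)

    blocks = []
    for seg in sim.segments:
        if seg["kind"] != "sinusoid":
            continue
        freq = seg["frequency"]
        n_cyc = int(round((seg["t_end"] - seg["t_start"]) * freq))
        nt = noise.samples_per_cycle * n_cyc
        tb = np.linspace(seg["t_start"], seg["t_end"], nt + 1)
        wb = np.interp(tb, sim.time, sim.displacement)
        fb = np.interp(tb, sim.time, sim.force)
        if noise.force_noise > 0:
            fb = fb * (1.0 + noise.force_noise * rng.standard_normal(fb.size))
        if noise.displacement_jitter > 0:
            wb = wb + noise.displacement_jitter * rng.standard_normal(wb.size)
        blocks.append(DynamicBlock(frequency=freq, time=tb, displacement=wb, force=fb))

    return t_meas, w, f, steps, blocks


def experiment_from_simulation(sim: SimulationResult, geometry: SampleGeometry,
                               noise: NoiseModel = None, rng=None,
                               sample_id: str = "") -> IndentationExperiment:
    """Turn a paper-protocol SimulationResult into a measurement-like record."""
    noise = noise or NoiseModel(force_noise=0.0)
    rng = rng or np.random.default_rng(0)
    start_strain = sim.start_depth / geometry.thickness
    t, w, f, steps, blocks = _resample(sim, noise, rng, start_strain, geometry.thickness)
    return IndentationExperiment(
        geometry=geometry, time=t, displacement=w, force=f,
        steps=steps, dynamic=blocks, sample_id=sample_id,
    )


def generate_experiment(
    params: FRPEParameters,
    geometry: SampleGeometry = None,
    noise: NoiseModel = None,
    rng=None,
    constants: ConstitutiveConstants = None,
    settings: SolverSettings = None,
    mesh: Mesh = None,
    include_dynamic: bool = True,
    cycles: int = 5,
    n_steps: int = 4,
    sample_id: str = "",
) -> IndentationExperiment:
    """Forward-simulate the full reference protocol for one specimen and
    return the noisy, resampled indentation record."""
    geometry = geometry or SampleGeometry()
    noise = noise or NoiseModel()
    rng = rng if rng is not None else np.random.default_rng(0)
    constants = constants or ConstitutiveConstants()
    settings = settings or SolverSettings()
    if mesh is None:
        mesh = build_mesh(geometry)
    sim = simulate_paper_protocol(
        mesh, params, constants, settings,
        cycles=cycles, include_dynamic=include_dynamic, n_steps=n_steps,
    )
    return experiment_from_simulation(sim, geometry, noise, rng, sample_id)


@dataclass(frozen=True)
class CohortSpec:
    """Synthetic cohort layout: group sizes default to the 35-sample
    17/15/3 grouping; ~63% of samples arrive in two-sample knees
    (medial + lateral compartments of one knee)."""

    n_normal: int = 17
    n_moderate: int = 15
    n_severe: int = 3
    paired_fraction: float = 0.63
    model: GroupParameterModel = field(default_factory=GroupParameterModel)
    noise: NoiseModel = field(default_factory=NoiseModel)
    geometry: SampleGeometry = field(default_factory=SampleGeometry)
    with_experiments: bool = False

    @property
    def n_total(self):
        return self.n_normal + self.n_moderate + self.n_severe


@dataclass
class SyntheticSample:
    sample_id: str
    knee_id: str
    compartment: str
    group: str
    oarsi_grade: int
    true_params: FRPEParameters
    experiment: IndentationExperiment = None


@dataclass
class SyntheticCohort:
    spec: CohortSpec
    samples: list

    def __len__(self):
        return len(self.samples)

    def group_sizes(self) -> dict:
        out = {g: 0 for g in GROUPS}
        for s in self.samples:
            out[s.group] += 1
        return out

    def to_frame(self):
        import pandas as pd

        rows = []
        for s in self.samples:
            row = dict(
                sample_id=s.sample_id, knee_id=s.knee_id, compartment=s.compartment,
                group=s.group, oarsi_grade=s.oarsi_grade,
            )
            row.update({k: v for k, v in zip(FRPEParameters.names(), s.true_params.as_array())})
            rows.append(row)
        return pd.DataFrame(rows)


#: OARSI grades available per group; the weights mirror the reported skew
#: (normal mostly grade 1, moderate mostly grade 2).
_GRADES = {
    "normal": ([0, 1], [0.3, 0.7]),
    "moderate": ([2, 3], [0.8, 0.2]),
    "severe": ([4], [1.0]),
}


def generate_cohort(spec: CohortSpec = None, rng=None,
                    settings: SolverSettings = None) -> SyntheticCohort:
    """Generate a synthetic cohort with knee-clustered ground truth.

    Samples are assigned to knees (one or two samples each, the two-sample
    knees holding a medial and a lateral specimen); each knee carries a
    shared standard-normal effect per parameter, mixed into the sample draw
    with weight sqrt(knee_correlation).  With ``spec.with_experiments`` the
    forward model is run per sample (expensive); otherwise only ground-truth
    parameters are generated.
    """
    spec = spec or CohortSpec()
    rng = rng if rng is not None else np.random.default_rng(0)

    labels = (["normal"] * spec.n_normal + ["moderate"] * spec.n_moderate
              + ["severe"] * spec.n_severe)
    order = rng.permutation(len(labels))
    n_pairs = int(round(spec.paired_fraction * len(labels) / 2))
    n_pairs = min(n_pairs, len(labels) // 2)

    knee_of = {}
    comp_of = {}
    for k in range(n_pairs):
        i, j = order[2 * k], order[2 * k + 1]
        knee_of[i] = f"knee{k:03d}"
        knee_of[j] = f"knee{k:03d}"
        comp_of[i], comp_of[j] = "medial", "lateral"
    for m, i in enumerate(order[2 * n_pairs:]):
        knee_of[i] = f"knee{n_pairs + m:03d}"
        comp_of[i] = "medial" if rng.random() < 0.5 else "lateral"

    knee_effects = {}
    mesh = build_mesh(spec.geometry) if spec.with_experiments else None
    samples = []
    for i, group in enumerate(labels):
        kid = knee_of[i]
        if kid not in knee_effects:
            knee_effects[kid] = {
                name: rng.standard_normal() for name in FRPEParameters.names()
            }
        params = draw_parameters(group, spec.model, rng, knee_effect=knee_effects[kid])
        grades, wts = _GRADES[group]
        grade = int(rng.choice(grades, p=wts))
        sid = f"S{i:03d}"
        exp = None
        if spec.with_experiments:
            exp = generate_experiment(
                params, spec.geometry, spec.noise, rng,
                settings=settings, mesh=mesh, sample_id=sid,
            )
        samples.append(
            SyntheticSample(
                sample_id=sid, knee_id=kid, compartment=comp_of[i], group=group,
                oarsi_grade=grade, true_params=params, experiment=exp,
            )
        )
    return SyntheticCohort(spec=spec, samples=samples)
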