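"""Plain-text I/O: experiment records as CSV + YAML metadata, parameter
sets as YAML, fit results as JSON, cohorts as directories of the above."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .analysis import DynamicBlock, IndentationExperiment, StepAnnotation
from .material import ConstitutiveConstants, FRPEParameters
from .mesh import SampleGeometry

__all__ = [
    "save_experiment", "load_experiment",
    "save_parameters", "load_parameters",
    "save_fit_result",
    "save_cohort", "load_cohort_frame",
]

_PARAM_UNITS = {
    "Ef0": "MPa", "EfEps": "MPa", "Enf": "MPa",
    "k0": "1e-15 m^4/(N s)", "M": "-",
}


def save_parameters(params: FRPEParameters, path,
                    constants: ConstitutiveConstants = None):
    doc = {
        "frpe_parameters": {k: float(v) for k, v in
                            zip(FRPEParameters.names(), params.as_array())},
        "units": _PARAM_UNITS,
    }
    if constants is not None:
        doc["constants"] = {"nu_nf": constants.nu_nf, "e0": constants.e0}
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_parameters(path):
    doc = yaml.safe_load(Path(path).read_text())
    params = FRPEParameters(**doc["frpe_parameters"])
    constants = ConstitutiveConstants(**doc.get("constants", {}))
    return params, constants


def save_experiment(exp: IndentationExperiment, csv_path, meta_path=None):
    """Relaxation and dynamic series in one CSV (time_s, displacement_mm,
    force_N, phase) plus a YAML metadata file (geometry, step annotations,
    frequency tags)."""
    csv_path = Path(csv_path)
    meta_path = Path(meta_path) if meta_path else csv_path.with_suffix(".yml")
    frames = [pd.DataFrame(dict(time_s=exp.time, displacement_mm=exp.displacement,
                                force_N=exp.force, phase="relaxation"))]
    for b in exp.dynamic:
        frames.append(pd.DataFrame(dict(time_s=b.time, displacement_mm=b.displacement,
                                        force_N=b.force, phase=f"dyn_{b.frequency:g}Hz")))
    pd.concat(frames, ignore_index=True).to_csv(csv_path, index=False)

    meta = dict(
        sample_id=exp.sample_id,
        geometry=dict(thickness=exp.geometry.thickness, radius=exp.geometry.radius,
                      indenter_radius=exp.geometry.indenter_radius),
        steps=[vars(s) for s in exp.steps],
        frequencies=[b.frequency for b in exp.dynamic],
    )
    meta_path.write_text(yaml.safe_dump(meta, sort_keys=False))


def load_experiment(csv_path, meta_path=None) -> IndentationExperiment:
    csv_path = Path(csv_path)
    meta_path = Path(meta_path) if meta_path else csv_path.with_suffix(".yml")
    df = pd.read_csv(csv_path)
    meta = yaml.safe_load(meta_path.read_text())
    geom = SampleGeometry(**meta["geometry"])
    steps = [StepAnnotation(**s) for s in meta["steps"]]
    rel = df[df.phase == "relaxation"]
    blocks = []
    for f in meta.get("frequencies", []):
        b = df[df.phase == f"dyn_{f:g}Hz"]
        blocks.append(DynamicBlock(frequency=f, time=b.time_s.to_numpy(),
                                   displacement=b.displacement_mm.to_numpy(),
                                   force=b.force_N.to_numpy()))
    return IndentationExperiment(
        geometry=geom, time=rel.time_s.to_numpy(),
        displacement=rel.displacement_mm.to_numpy(), force=rel.force_N.to_numpy(),
        steps=steps, dynamic=blocks, sample_id=meta.get("sample_id", ""),
    )


def save_fit_result(fit, path, config=None, seed=None):
    doc = dict(
        parameters={k: float(v) for k, v in
                    zip(FRPEParameters.names(), fit.params.as_array())},
        units=_PARAM_UNITS,
        r_squared=None if not np.isfinite(fit.r_squared) else float(fit.r_squared),
        objective=None if not np.isfinite(fit.objective) else float(fit.objective),
        converged=bool(fit.converged),
        n_evaluations=int(fit.n_evaluations),
        message=fit.message,
    )
    if seed is not None:
        doc["seed"] = int(seed)
    if config is not None:
        doc["config"] = dict(
            n_starts=config.n_starts, perturbation=config.perturbation,
            polish_top=config.polish_top, weighting=config.weighting,
            mesh_resolution=config.mesh_resolution, solver_preset=config.solver_preset,
            bounds={k: list(map(float, v)) for k, v in config.bounds.items()},
        )
    Path(path).write_text(json.dumps(doc, indent=2))


def save_cohort(cohort, out_dir, write_experiments=True):
    """Write a synthetic cohort: per-sample experiment CSV/YAML (when
    present) and a ground-truth manifest JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = []
    for s in cohort.samples:
        rec = dict(sample_id=s.sample_id, knee_id=s.knee_id, compartment=s.compartment,
                   group=s.group, oarsi_grade=int(s.oarsi_grade),
                   true_params={k: float(v) for k, v in
                                zip(FRPEParameters.names(), s.true_params.as_array())})
        if s.experiment is not None and write_experiments:
            save_experiment(s.experiment, out / f"{s.sample_id}.csv")
            rec["experiment_csv"] = f"{s.sample_id}.csv"
        manifest.append(rec)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


def load_cohort_frame(out_dir) -> pd.DataFrame:
    """Ground-truth manifest of a saved cohort as a flat DataFrame."""
    manifest = json.loads((Path(out_dir) / "manifest.json").read_text())
    rows = []
    for rec in manifest:
        row = {k: rec[k] for k in ("sample_id", "knee_id", "compartment", "group", "oarsi_grade")}
        row.update(rec["true_params"])
        rows.append(row)
    return pd.DataFrame(rows)
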