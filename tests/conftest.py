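"""Shared fixtures: one forward simulation of the full reference protocol
and one relaxation-only experiment are generated once per session and shared
across test modules (each costs seconds at the coarse solver preset)."""

import numpy as np
import pytest
from hypothesis import settings as _hyp_settings

_hyp_settings.register_profile("deterministic", derandomize=True, deadline=None)
_hyp_settings.load_profile("deterministic")

from poroindent.material import ConstitutiveConstants, FRPEParameters
from poroindent.mesh import SampleGeometry, build_mesh
from poroindent.solver import SolverSettings, simulate_paper_protocol
from poroindent.synthetic import NoiseModel, experiment_from_simulation, generate_experiment

#: reference FRPE parameter set for healthy femoral condyle cartilage
REF_PARAMS = FRPEParameters(Ef0=1.2, EfEps=12.0, Enf=0.45, k0=7.0, M=9.0)


@pytest.fixture(scope="session")
def geometry():
    return SampleGeometry()


@pytest.fixture(scope="session")
def constants():
    return ConstitutiveConstants()


@pytest.fixture(scope="session")
def ref_params():
    return REF_PARAMS


@pytest.fixture(scope="session")
def coarse_settings():
    return SolverSettings.preset("coarse")


@pytest.fixture(scope="session")
def coarse_mesh(geometry):
    return build_mesh(geometry)


@pytest.fixture(scope="session")
def paper_sim(coarse_mesh, ref_params, constants, coarse_settings):
    """Full reference-protocol simulation (4 relaxation steps + 8 sinusoid
    blocks) at the coarse preset."""
    return simulate_paper_protocol(coarse_mesh, ref_params, constants, coarse_settings)


@pytest.fixture(scope="session")
def full_experiment(paper_sim, geometry):
    """Noiseless measurement-like record resampled from paper_sim."""
    return experiment_from_simulation(
        paper_sim, geometry, NoiseModel(force_noise=0.0), np.random.default_rng(0),
        sample_id="ref",
    )


@pytest.fixture(scope="session")
def relax_experiment(ref_params, geometry, coarse_settings, coarse_mesh):
    """Noiseless relaxation-only record used by the optimizer tests."""
    return generate_experiment(
        ref_params, geometry, NoiseModel(force_noise=0.0), np.random.default_rng(1),
        settings=coarse_settings, mesh=coarse_mesh, include_dynamic=False,
        sample_id="relax",
    )
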