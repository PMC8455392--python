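"""Inverse identification of FRPE parameters from stress-relaxation records.

The five parameters (Ef0, EfEps, Enf, k0, M) are found by minimizing the
normalized mean squared difference between simulated and measured reaction
force over the 2nd and 3rd stress-relaxation steps (ramps and holds).
Restricting the window to the middle steps leaves steps 1 and 4 as built-in
holdout; the transient part of the window is what renders k0 and M
identifiable (equilibrium data alone pin down only the moduli).

k0 is optimized in log10-space (it spans orders of magnitude across OA
states); the other parameters in linear space.  The bounded trust-region
least-squares solver is started from one or several perturbed initial
guesses; with multiple starts, each start is screened with a single forward
solve and the best few are polished.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .exceptions import ConvergenceError, DegenerateDeformationError, PoroindentError
from .material import ConstitutiveConstants, FRPEParameters
from .mesh import SampleGeometry, build_mesh
from .protocol import LoadingProtocol, Segment
from .solver import SolverSettings, simulate, solve_drained, _Assembler
from .analysis import IndentationExperiment

logger = logging.getLogger(__name__)

__all__ = ["OptimizationConfig", "FitResult", "objective", "fit_frpe", "goodness_of_fit"]

#: default parameter bounds: envelope of values reported for human knee and
#: hip cartilage across OA states
DEFAULT_BOUNDS = {
    "Ef0": (1e-6, 50.0),
    "EfEps": (0.0, 500.0),
    "Enf": (0.01, 5.0),
    "k0": (1e-2, 1e3),
    "M": (0.0, 25.0),
}

_PENALTY = 1e6


@dataclass(frozen=True)
class OptimizationConfig:
    """Controls for :func:`fit_frpe`.

    bounds        : {name: (lo, hi)}; k0 bounds in 1e-15 m^4/(N s)
    n_starts      : multistart count (1 = single start)
    perturbation  : multiplicative spread of the random starts around the
                    initial guess (0.5 = factors in [0.5, 1.5])
    polish_top    : number of screened starts polished with least-squares
    weighting     : 'uniform' or 'peak' (ramp samples weighted 3x)
    seed          : seed for start generation
    mesh_resolution, solver_preset : forward-model cost controls
    ftol, xtol    : least-squares convergence tolerances
    """

    bounds: dict = field(default_factory=lambda: dict(DEFAULT_BOUNDS))
    n_starts: int = 1
    perturbation: float = 0.5
    polish_top: int = 2
    weighting: str = "uniform"
    seed: int = 0
    mesh_resolution: float = 1.0
    solver_preset: str = "coarse"
    ftol: float = 1e-10
    xtol: float = 1e-8
    max_nfev: int = 120
    initial_guess: FRPEParameters = None

    def __post_init__(self):
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        for name, (lo, hi) in self.bounds.items():
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError(f"invalid bounds for {name}")
        if self.weighting not in ("uniform", "peak"):
            raise ValueError("weighting must be 'uniform' or 'peak'")


@dataclass
class FitResult:
    """Outcome of an inverse identification."""

    params: FRPEParameters
    r_squared: float
    objective: float
    n_evaluations: int
    converged: bool
    starts: list = field(default_factory=list)  # per-start dicts
    message: str = ""


def goodness_of_fit(simulated, measured) -> float:
    """Coefficient of determination R^2 = 1 - SS_res / SS_tot."""
    simulated = np.asarray(simulated, dtype=float)
    measured = np.asarray(measured, dtype=float)
    if simulated.shape != measured.shape:
        raise ValueError("series must be aligned and of equal length")
    ss_tot = np.sum((measured - measured.mean()) ** 2)
    if ss_tot == 0:
        raise PoroindentError("R^2 undefined for a zero-variance measured series")
    return float(1.0 - np.sum((simulated - measured) ** 2) / ss_tot)


class _FitContext:
    """Shared forward-model state for repeated objective evaluations on one
    experiment: mesh, fitting window, protocol template, warm starts."""

    def __init__(self, experiment: IndentationExperiment, config: OptimizationConfig,
                 constants: ConstitutiveConstants = None,
                 fit_steps=(1, 2), include_all_steps_to=None):
        if len(experiment.steps) < max(fit_steps) + 1:
            raise PoroindentError("experiment lacks the stress-relaxation steps to fit")
        self.exp = experiment
        self.config = config
        self.constants = constants or ConstitutiveConstants()
        self.geometry = experiment.geometry
        self.mesh = build_mesh(self.geometry, resolution=config.mesh_resolution)
        self.settings = SolverSettings.preset(config.solver_preset)
        self.fit_steps = tuple(fit_steps)

        # simulate from protocol start through the last fitted step
        last = max(fit_steps)
        segs = []
        h = self.geometry.thickness
        for s in experiment.steps[: last + 1]:
            segs.append(Segment("ramp", s.t_ramp_end - s.t_ramp_start, target=s.strain_end,
                                label=s.label))
            segs.append(Segment("hold", s.t_hold_end - s.t_ramp_end, label=s.label))
        self.protocol = LoadingProtocol(segs, start_strain=experiment.steps[0].strain_start)

        t0 = experiment.steps[fit_steps[0]].t_ramp_start
        t1 = experiment.steps[fit_steps[-1]].t_hold_end
        m = (experiment.time >= t0 - 1e-9) & (experiment.time <= t1 + 1e-9)
        self.t_fit = experiment.time[m]
        self.f_fit = experiment.force[m]
        self.f_range = float(self.f_fit.max() - self.f_fit.min())
        self.weights = np.ones_like(self.t_fit)
        if config.weighting == "peak":
            for i in fit_steps:
                s = experiment.steps[i]
                ramp = (self.t_fit >= s.t_ramp_start - 1e-9) & (self.t_fit <= s.t_ramp_end + 1e-9)
                self.weights[ramp] = 3.0
        self.weights /= self.weights.sum()
        self.n_evaluations = 0

    def simulated_force(self, params: FRPEParameters):
        res = simulate(self.mesh, params, self.constants, self.protocol, self.settings)
        return np.interp(self.t_fit, res.time, res.force)

    def residuals(self, params: FRPEParameters):
        """Weighted residual vector; sum of squares = normalized objective."""
        self.n_evaluations += 1
        try:
            f_sim = self.simulated_force(params)
        except (ConvergenceError, DegenerateDeformationError) as err:
            logger.warning("forward model failed at %s: %s", params, err)
            return np.full(self.t_fit.size, np.sqrt(_PENALTY / self.t_fit.size))
        return np.sqrt(self.weights) * (f_sim - self.f_fit) / self.f_range

    def objective(self, params: FRPEParameters) -> float:
        r = self.residuals(params)
        return float(np.sum(r * r))


def objective(params: FRPEParameters, experiment: IndentationExperiment,
              config: OptimizationConfig = None,
              constants: ConstitutiveConstants = None) -> float:
    """Normalized discrepancy between simulation and measurement over the
    2nd and 3rd stress-relaxation steps: weighted mean squared force error
    divided by the squared measured force range of the window.  Forward
    failures return a large finite penalty."""
    config = config or OptimizationConfig()
    return _FitContext(experiment, config, constants).objective(params)


def _to_vector(p: FRPEParameters) -> np.ndarray:
    return np.array([p.Ef0, p.EfEps, p.Enf, np.log10(p.k0), p.M])


def _from_vector(x) -> FRPEParameters:
    return FRPEParameters(Ef0=x[0], EfEps=x[1], Enf=x[2], k0=10.0 ** x[3], M=x[4])


def _vector_bounds(bounds):
    names = ("Ef0", "EfEps", "Enf", "k0", "M")
    lo = [bounds[n][0] for n in names]
    hi = [bounds[n][1] for n in names]
    lo[3], hi[3] = np.log10(lo[3]), np.log10(hi[3])
    return np.array(lo), np.array(hi)


def _default_guess(bounds) -> FRPEParameters:
    # geometric midpoint for positive quantities, arithmetic for the rest
    def gmid(lo, hi):
        return float(np.sqrt(max(lo, 1e-6) * hi))

    return FRPEParameters(
        Ef0=gmid(*bounds["Ef0"]), EfEps=gmid(1.0, bounds["EfEps"][1]),
        Enf=gmid(*bounds["Enf"]), k0=gmid(*bounds["k0"]),
        M=0.5 * (bounds["M"][0] + bounds["M"][1]),
    )


def generate_starts(guess: FRPEParameters, config: OptimizationConfig) -> list:
    """Randomized multistart points: each parameter scaled by a factor drawn
    uniformly from [1 - p, 1 + p] (clipped into bounds)."""
    rng = np.random.default_rng(config.seed)
    lo, hi = _vector_bounds(config.bounds)
    starts = []
    base = _to_vector(guess)
    for _ in range(config.n_starts):
        fac = rng.uniform(1.0 - config.perturbation, 1.0 + config.perturbation, 5)
        x = base.copy()
        x[[0, 1, 2, 4]] = base[[0, 1, 2, 4]] * fac[[0, 1, 2, 4]]
        x[3] = base[3] + np.log10(fac[3])  # multiplicative on k0
        starts.append(_from_vector(np.clip(x, lo, hi)))
    return starts


def fit_frpe(experiment: IndentationExperiment, config: OptimizationConfig = None,
             constants: ConstitutiveConstants = None, starts=None) -> FitResult:
    """Fit the five FRPE parameters to the 2nd and 3rd relaxation steps.

    ``starts`` may supply explicit FRPEParameters start points; otherwise
    ``config.n_starts`` randomized starts around the initial guess are
    screened with one forward solve each and the best ``config.polish_top``
    are polished by bounded least squares.  Never raises on optimization
    failure; inspect ``converged``.
    """
    config = config or OptimizationConfig()
    try:
        ctx = _FitContext(experiment, config, constants)
    except PoroindentError as err:
        return FitResult(
            params=config.initial_guess or _default_guess(config.bounds),
            r_squared=np.nan, objective=np.inf, n_evaluations=0,
            converged=False, message=str(err),
        )

    if ctx.f_range <= 0 or not np.isfinite(ctx.f_range):
        return FitResult(
            params=config.initial_guess or _default_guess(config.bounds),
            r_squared=np.nan, objective=np.inf, n_evaluations=0,
            converged=False, message="degenerate (flat) force record",
        )

    guess = config.initial_guess or _default_guess(config.bounds)
    if starts is None:
        starts = [guess] if config.n_starts == 1 else generate_starts(guess, config)

    # screen
    screened = []
    for p in starts:
        screened.append((ctx.objective(p), p))
    screened.sort(key=lambda t: t[0])

    lo, hi = _vector_bounds(config.bounds)
    start_records = [dict(params=p, screen_objective=o) for o, p in screened]

    best = None
    n_polish = min(max(1, config.polish_top), len(screened))
    for rank in range(n_polish):
        o0, p0 = screened[rank]
        x0 = np.clip(_to_vector(p0), lo, hi)
        try:
            sol = least_squares(
                lambda x: ctx.residuals(_from_vector(x)),
                x0, bounds=(lo, hi), method="trf",
                x_scale=np.maximum(np.abs(x0), [0.1, 1.0, 0.05, 0.1, 0.5]),
                diff_step=1e-3, ftol=config.ftol, xtol=config.xtol, gtol=1e-12,
                max_nfev=config.max_nfev,
            )
            obj = float(np.sum(sol.fun**2))
            rec = dict(params=_from_vector(sol.x), objective=obj,
                       success=bool(sol.success), nfev=int(sol.nfev))
        except Exception as err:  # keep the optimizer alive
            logger.warning("polish from start %d failed: %s", rank, err)
            rec = dict(params=p0, objective=o0, success=False, nfev=0)
        start_records[rank].update(rec)
        if best is None or rec["objective"] < best["objective"]:
            best = rec

    if best is None or not np.isfinite(best["objective"]) or best["objective"] >= _PENALTY / 2:
        return FitResult(
            params=guess, r_squared=np.nan, objective=np.inf,
            n_evaluations=ctx.n_evaluations, converged=False,
            starts=start_records, message="no start converged",
        )

    f_sim = ctx.simulated_force(best["params"])
    r2 = goodness_of_fit(f_sim, ctx.f_fit)
    return FitResult(
        params=best["params"], r_squared=r2, objective=best["objective"],
        n_evaluations=ctx.n_evaluations, converged=bool(best.get("success", False)),
        starts=start_records, message="ok",
    )
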