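"""Constrained fidelity optimization and the trade-off analyses.

The design problem: at fixed enzyme specificity ``sigma``, minimize the
normalized KL fidelity F between a target glycan distribution and the
distribution displayed by the cisternal machinery, over the transport
rates ``mu`` (box ``mu_bounds``), per-enzyme catalytic capacities ``R``
(box ``R_bounds``) and enzyme shapes ``L`` (in ``[1, Ns]``).  The
landscape is rugged (permutation and continuous degeneracies), so every
optimization is a seeded multi-start of a gradient-based SQP local
solver (scipy SLSQP) on box-normalized coordinates: ``mu`` and ``R`` are
log-scaled (their boxes span decades), ``L`` is linear.

On top of the single fit sit the study's scans: ``scan_sigma`` traces
the optimized fidelity ``Dbar(sigma)`` over a specificity grid,
``tradeoff_surface`` maps ``min_sigma Dbar`` over (NE, NC),
``maximize_diversity`` swaps the objective for the sigmoid species
count, and ``check_ab_equivalence`` verifies numerically that
optimizing the linear effective-rate parametrization and the full
Michaelis-Menten parametrization reach the same optimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from . import objectives
from .model import (
    GlycanProfile,
    GolgiSystem,
    MMParameterSet,
    ParameterSet,
    steady_state_linear,
    steady_state_mm,
)

__all__ = [
    "ParamTransform",
    "linear_transform",
    "mm_transform",
    "StartRecord",
    "OptimizationResult",
    "SigmaScan",
    "ABEquivalence",
    "optimize_fidelity",
    "scan_sigma",
    "tradeoff_surface",
    "maximize_diversity",
    "check_ab_equivalence",
]

#: a start counts as "near best" if final_F <= best_F + max(0.01, 0.05*best_F)
NEAR_BEST_ABS = 0.01
NEAR_BEST_REL = 0.05

_FAIL_VALUE = 1e6  # objective value recorded for numerically failed evaluations


@dataclass(frozen=True)
class _Block:
    name: str  # coordinate group: "mu", "R", "L", "M", "V" or "sigma"
    size: int
    lo: float
    hi: float
    log: bool


class ParamTransform:
    """Map between box-normalized coordinates x in [0,1]^dim and parameters.

    Log-scaled blocks interpolate geometrically between their bounds,
    linear blocks arithmetically.
    """

    def __init__(self, system: GolgiSystem, blocks: list[_Block], kind: str,
                 sigma: float | None = None):
        self.system = system
        self.blocks = blocks
        self.kind = kind  # "linear" or "mm"
        self.sigma = sigma
        self.dim = sum(b.size for b in blocks)

    @property
    def labels(self) -> list[str]:
        """Per-coordinate block label, in block order."""
        out: list[str] = []
        for b in self.blocks:
            out.extend([b.name] * b.size)
        return out

    def _split(self, x: np.ndarray) -> dict[str, np.ndarray]:
        x = np.asarray(x, dtype=float)
        if x.shape != (self.dim,):
            raise ValueError(f"expected coordinate vector of length {self.dim}")
        vals, i = {}, 0
        for b in self.blocks:
            xi = np.clip(x[i : i + b.size], 0.0, 1.0)
            if b.log:
                v = np.exp(np.log(b.lo) + xi * (np.log(b.hi) - np.log(b.lo)))
            else:
                v = b.lo + xi * (b.hi - b.lo)
            vals[b.name] = v
            i += b.size
        return vals

    def _join(self, vals: dict[str, np.ndarray]) -> np.ndarray:
        parts = []
        for b in self.blocks:
            v = np.asarray(vals[b.name], dtype=float).ravel()
            if b.log:
                xi = (np.log(v) - np.log(b.lo)) / (np.log(b.hi) - np.log(b.lo))
            else:
                xi = (v - b.lo) / (b.hi - b.lo)
            parts.append(np.clip(xi, 0.0, 1.0))
        return np.concatenate(parts)

    def to_params(self, x: np.ndarray):
        v = self._split(x)
        sys = self.system
        shape = (sys.NE, sys.NC)
        if self.kind == "linear":
            sigma = v["sigma"][0] if "sigma" in v else self.sigma
            return ParameterSet(
                mu=v["mu"], R=v["R"].reshape(shape), L=v["L"].reshape(shape),
                sigma=float(sigma),
            )
        return MMParameterSet(
            mu=v["mu"], M=v["M"].reshape(shape), V=v["V"].reshape(shape),
            L=v["L"].reshape(shape), sigma=float(self.sigma),
        )

    def to_x(self, params) -> np.ndarray:
        sys = self.system
        vals = {"mu": params.mu, "L": params.L}
        if isinstance(params, ParameterSet):
            vals["R"] = params.R
        else:
            vals["M"], vals["V"] = params.M, params.V
        if any(b.name == "sigma" for b in self.blocks):
            vals["sigma"] = np.array([params.sigma])
        return self._join(vals)


def linear_transform(
    system: GolgiSystem,
    sigma: float | None = None,
    include_sigma: bool = False,
    sigma_bounds: tuple[float, float] = (0.0, 10.0),
) -> ParamTransform:
    """Coordinates (mu, R, L[, sigma]) of the linear effective-rate model."""
    n = system.NE * system.NC
    blocks = [
        _Block("mu", system.NC, *system.mu_bounds, log=True),
        _Block("R", n, *system.R_bounds, log=True),
        _Block("L", n, 1.0, float(system.Ns), log=False),
    ]
    if include_sigma:
        blocks.append(_Block("sigma", 1, *sigma_bounds, log=False))
    return ParamTransform(system, blocks, "linear", sigma=sigma)


def mm_transform(
    system: GolgiSystem,
    sigma: float,
    M_bounds: tuple[float, float] = (1.0, 1e6),
    V_bounds: tuple[float, float] = (1e-2, 2e7),
) -> ParamTransform:
    """Coordinates (mu, M, V, L) of the full Michaelis-Menten model."""
    n = system.NE * system.NC
    blocks = [
        _Block("mu", system.NC, *system.mu_bounds, log=True),
        _Block("M", n, *M_bounds, log=True),
        _Block("V", n, *V_bounds, log=True),
        _Block("L", n, 1.0, float(system.Ns), log=False),
    ]
    return ParamTransform(system, blocks, "mm", sigma=sigma)


@dataclass(frozen=True)
class StartRecord:
    seed: int
    final_F: float
    converged: bool
    iterations: int


@dataclass
class OptimizationResult:
    """Best solution and per-start diagnostics of a multi-start run."""

    best_params: ParameterSet | MMParameterSet
    best_F: float
    starts: int
    per_start: list[StartRecord]
    fraction_near_best: float
    best_x: np.ndarray
    xs: np.ndarray  # (starts, dim) final normalized coordinates
    transform: ParamTransform = field(repr=False)


def _near_best_tol(best_F: float) -> float:
    return max(NEAR_BEST_ABS, NEAR_BEST_REL * best_F)


def _multistart(
    objective,
    transform: ParamTransform,
    n_starts: int,
    seed: int,
    maxiter: int,
    ftol: float,
    eps: float,
) -> OptimizationResult:
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    dim = transform.dim
    start_seeds = np.random.default_rng(seed).integers(0, 2**31 - 1, size=n_starts)
    records: list[StartRecord] = []
    xs = np.empty((n_starts, dim))
    finals = np.empty(n_starts)
    any_converged = False
    for i, s in enumerate(start_seeds):
        x0 = np.random.default_rng(int(s)).uniform(size=dim)
        res = minimize(
            objective,
            x0,
            method="SLSQP",
            bounds=[(0.0, 1.0)] * dim,
            options={"maxiter": maxiter, "ftol": ftol, "eps": eps},
        )
        xs[i] = np.clip(res.x, 0.0, 1.0)
        finals[i] = objective(xs[i])
        records.append(
            StartRecord(seed=int(s), final_F=float(finals[i]),
                        converged=bool(res.success), iterations=int(res.nit))
        )
        any_converged = any_converged or res.success
    if not any_converged and np.all(finals >= _FAIL_VALUE):
        raise RuntimeError(
            "no start converged; final objective values: " + str(finals.tolist())
        )
    ibest = int(np.argmin(finals))
    best_F = float(finals[ibest])
    frac = float(np.mean(finals <= best_F + _near_best_tol(best_F)))
    return OptimizationResult(
        best_params=transform.to_params(xs[ibest]),
        best_F=best_F,
        starts=n_starts,
        per_start=records,
        fraction_near_best=frac,
        best_x=xs[ibest].copy(),
        xs=xs,
        transform=transform,
    )


def fidelity_objective(system: GolgiSystem, target: GlycanProfile,
                       transform: ParamTransform):
    """Objective x -> F(target || displayed(x)); failed evaluations are
    mapped to a large finite penalty so line searches can back off."""
    tgt = target if target.normalized else target.normalize()
    solver = steady_state_linear if transform.kind == "linear" else steady_state_mm

    def objective(x: np.ndarray) -> float:
        try:
            params = transform.to_params(x)
            disp = solver(system, params).displayed
            return objectives.fidelity(tgt, disp).F
        except (RuntimeError, np.linalg.LinAlgError, FloatingPointError):
            return _FAIL_VALUE

    return objective


def optimize_fidelity(
    system: GolgiSystem,
    target: GlycanProfile,
    sigma: float,
    n_starts: int = 32,
    seed: int = 0,
    maxiter: int = 200,
    ftol: float = 1e-9,
    eps: float = 1e-6,
) -> OptimizationResult:
    """Multi-start SLSQP minimization of F over (mu, R, L) at fixed sigma.

    Deterministic given ``seed``; returns the best parameter set together
    with per-start diagnostics and the fraction of starts landing near
    the best optimum (a degeneracy indicator).
    """
    tgt = target if target.normalized else target.normalize()
    if objectives.entropy(tgt) <= 0:
        raise ValueError("target has zero entropy; fidelity F = D/H is undefined")
    transform = linear_transform(system, sigma=sigma)
    obj = fidelity_objective(system, tgt, transform)
    return _multistart(obj, transform, n_starts, seed, maxiter, ftol, eps)


@dataclass
class SigmaScan:
    """Optimized fidelity Dbar over a specificity grid."""

    sigma_grid: np.ndarray
    Dbar: np.ndarray
    sigma_min: float
    results: list[OptimizationResult | None]
    errors: list[str | None]


def scan_sigma(
    system: GolgiSystem,
    target: GlycanProfile,
    sigma_grid,
    n_starts: int = 32,
    seed: int = 0,
    **kw,
) -> SigmaScan:
    """Optimize fidelity at every sigma on the grid.

    Per-point failures are recorded (Dbar = nan), not fatal.  Argmin
    ties break toward the smallest sigma.
    """
    grid = np.asarray(sigma_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("sigma grid must be nonempty")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("sigma grid must be strictly increasing")
    child_seeds = np.random.default_rng(seed).integers(0, 2**31 - 1, size=grid.size)
    Dbar = np.full(grid.size, np.nan)
    results: list[OptimizationResult | None] = []
    errors: list[str | None] = []
    for i, sg in enumerate(grid):
        try:
            res = optimize_fidelity(system, target, float(sg),
                                    n_starts=n_starts, seed=int(child_seeds[i]), **kw)
            Dbar[i] = res.best_F
            results.append(res)
            errors.append(None)
        except RuntimeError as exc:  # recorded, not fatal
            results.append(None)
            errors.append(str(exc))
    if np.all(np.isnan(Dbar)):
        raise RuntimeError("optimization failed at every sigma grid point")
    # nanargmin returns the first (smallest-sigma) minimizer on ties
    sigma_min = float(grid[np.nanargmin(Dbar)])
    return SigmaScan(sigma_grid=grid, Dbar=Dbar, sigma_min=sigma_min,
                     results=results, errors=errors)


def tradeoff_surface(
    system: GolgiSystem,
    target: GlycanProfile,
    NE_range,
    NC_range,
    sigma_grid,
    n_starts: int = 32,
    seed: int = 0,
    **kw,
) -> pd.DataFrame:
    """Optimum fidelity ``min_sigma Dbar`` and ``sigma_min`` over (NE, NC).

    ``system`` supplies Ns, q and the parameter boxes; NE and NC are
    overridden cell by cell.  Per-cell failures leave NaN rows.
    """
    NE_range, NC_range = list(NE_range), list(NC_range)
    if not NE_range or not NC_range:
        raise ValueError("NE and NC ranges must be nonempty")
    cells = [(ne, nc) for ne in NE_range for nc in NC_range]
    cell_seeds = np.random.default_rng(seed).integers(0, 2**31 - 1, size=len(cells))
    rows = []
    for (ne, nc), cs in zip(cells, cell_seeds):
        sys_cell = GolgiSystem(NC=nc, NE=ne, Ns=system.Ns, q=system.q,
                               mu_bounds=system.mu_bounds, R_bounds=system.R_bounds)
        try:
            scan = scan_sigma(sys_cell, target, sigma_grid,
                              n_starts=n_starts, seed=int(cs), **kw)
            rows.append({"NE": ne, "NC": nc,
                         "Dbar_min": float(np.nanmin(scan.Dbar)),
                         "sigma_min": scan.sigma_min})
        except RuntimeError:
            rows.append({"NE": ne, "NC": nc, "Dbar_min": np.nan, "sigma_min": np.nan})
    return pd.DataFrame(rows)


def maximize_diversity(
    system: GolgiSystem,
    sigma: float,
    n_starts: int = 32,
    seed: int = 0,
    c_th: float | None = None,
    maxiter: int = 200,
    ftol: float = 1e-9,
    eps: float = 1e-6,
) -> OptimizationResult:
    """Maximize the sigmoid species-diversity of the displayed
    distribution over (mu, R, L) at fixed sigma.

    The returned ``best_F`` is the minimized objective, i.e. minus the
    achieved diversity.
    """
    transform = linear_transform(system, sigma=sigma)
    th = 1.0 / system.Ns if c_th is None else c_th

    def objective(x: np.ndarray) -> float:
        try:
            disp = steady_state_linear(system, transform.to_params(x)).displayed
            return -objectives.diversity(disp, c_th=th, Ns=system.Ns).value
        except (RuntimeError, np.linalg.LinAlgError, FloatingPointError):
            return _FAIL_VALUE

    return _multistart(objective, transform, n_starts, seed, maxiter, ftol, eps)


@dataclass(frozen=True)
class ABEquivalence:
    """Optimized fidelities of the two parametrizations of the same
    synthesis machinery: F_B (linear effective rates) and F_A (full MM)."""

    F_B: float
    F_A: float
    result_B: OptimizationResult
    result_A: OptimizationResult


def check_ab_equivalence(
    system: GolgiSystem,
    target: GlycanProfile,
    sigma: float,
    n_starts: int = 16,
    seed: int = 0,
    M_bounds: tuple[float, float] = (1.0, 1e6),
    V_bounds: tuple[float, float] = (1e-2, 2e7),
    maxiter: int = 200,
    ftol: float = 1e-10,
    eps: float = 1e-6,
) -> ABEquivalence:
    """Numerically compare the linear-rate optimum with the MM optimum.

    Intended for small instances (Ns <= 10, NE, NC <= 2) where repeated
    MM fixed-point solves stay cheap.
    """
    res_b = optimize_fidelity(system, target, sigma, n_starts=n_starts,
                              seed=seed, maxiter=maxiter, ftol=ftol, eps=eps)
    transform_a = mm_transform(system, sigma, M_bounds=M_bounds, V_bounds=V_bounds)
    obj_a = fidelity_objective(system, target, transform_a)
    res_a = _multistart(obj_a, transform_a, n_starts, seed + 1, maxiter, ftol, eps)
    return ABEquivalence(F_B=res_b.best_F, F_A=res_a.best_F,
                         result_B=res_b, result_A=res_a)
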