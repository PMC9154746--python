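"""Geometry of the fidelity landscape: Hessian, stiff/sloppy directions,
and degeneracy probing.

At an optimum, the Hessian of F over the full coordinate vector
(mu, R, L, sigma) — dimension ``NC + 2*NE*NC + 1`` — separates stiff
directions (the cell must control these tightly; empirically sigma and
mu) from sloppy ones (most R directions).  Coordinates are
box-normalized to [0, 1] before differencing so curvatures are
comparable across blocks whose physical boxes span different decades.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .model import GlycanProfile, GolgiSystem, ParameterSet, steady_state_linear
from .objectives import fidelity
from .optimize import OptimizationResult, _near_best_tol, linear_transform

__all__ = ["HessianAnalysis", "DegeneracyReport", "hessian_at", "probe_degeneracy"]

_STIFFNESS_FLOOR = 1e-12
BLOCK_ORDER = ("mu", "R", "L", "sigma")


@dataclass
class HessianAnalysis:
    """Eigen-structure of the fidelity Hessian at an optimum."""

    dim: int
    hessian: np.ndarray
    eigenvalues: np.ndarray  # nonincreasing
    eigenvectors: np.ndarray  # orthonormal columns, matching order
    labels: list[str]  # per-coordinate block label
    groups: list[str]  # per-eigenvector dominant block
    group_stiffness: dict[str, float]
    total_stiffness: float


@dataclass
class DegeneracyReport:
    """Discrete (cluster) and continuous (flat-direction) degeneracies."""

    n_clusters: int
    fraction_near_best: float
    n_flat_directions: int


def _central_hessian(f, x0: np.ndarray, step: float) -> np.ndarray:
    """Central finite-difference Hessian on [0,1]^dim coordinates.

    The stencil center is shifted inward wherever x0 is within one step
    of the box boundary (equivalent to one-sided differencing there).
    """
    dim = x0.size
    xc = np.clip(x0, step, 1.0 - step)
    H = np.empty((dim, dim))
    f0 = f(xc)
    # diagonal terms
    for i in range(dim):
        ei = np.zeros(dim)
        ei[i] = step
        H[i, i] = (f(xc + ei) - 2.0 * f0 + f(xc - ei)) / step**2
    # off-diagonal terms
    for i in range(dim):
        ei = np.zeros(dim)
        ei[i] = step
        for j in range(i + 1, dim):
            ej = np.zeros(dim)
            ej[j] = step
            val = (f(xc + ei + ej) - f(xc + ei - ej)
                   - f(xc - ei + ej) + f(xc - ei - ej)) / (4.0 * step**2)
            H[i, j] = H[j, i] = val
    return 0.5 * (H + H.T)


def hessian_at(
    system: GolgiSystem | None,
    target: GlycanProfile | None,
    params_opt: ParameterSet | None,
    step: float = 1e-3,
    sigma_bounds: tuple[float, float] = (0.0, 10.0),
    objective=None,
    labels: list[str] | None = None,
) -> HessianAnalysis:
    """Finite-difference Hessian of F at an optimum, eigen-decomposed and
    grouped by dominant coordinate block.

    By default the objective is the fidelity of the displayed
    distribution over the box-normalized (mu, R, L, sigma) coordinates;
    ``objective`` (a callable on normalized coordinates, with matching
    ``labels``) may replace it, e.g. with an analytically known quadratic
    for validation.
    """
    if objective is None:
        transform = linear_transform(system, include_sigma=True,
                                     sigma_bounds=sigma_bounds)
        tgt = target if target.normalized else target.normalize()

        def objective(x):
            disp = steady_state_linear(system, transform.to_params(x)).displayed
            return fidelity(tgt, disp).F

        x0 = transform.to_x(params_opt)
        labels = transform.labels
    else:
        if labels is None or params_opt is None:
            raise ValueError("custom objectives need explicit labels and a "
                             "normalized coordinate vector in params_opt")
        x0 = np.asarray(params_opt, dtype=float)

    H = _central_hessian(objective, x0, step)
    evals, evecs = np.linalg.eigh(H)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]

    label_arr = np.asarray(labels)
    groups = []
    for v in evecs.T:
        imax_by_block = {b: np.max(np.abs(v)[label_arr == b], initial=0.0)
                         for b in BLOCK_ORDER if np.any(label_arr == b)}
        # dominant block; ties break in BLOCK_ORDER
        groups.append(max(imax_by_block, key=lambda b: (imax_by_block[b],)))

    clipped = np.maximum(evals, 0.0)
    group_stiffness = {}
    for b in BLOCK_ORDER:
        mask = np.asarray(groups) == b
        if np.any(mask):
            group_stiffness[b] = float(
                np.log(max(clipped[mask].mean(), _STIFFNESS_FLOOR))
            )
    total = float(np.log(max(clipped.sum() / evals.size, _STIFFNESS_FLOOR)))
    return HessianAnalysis(
        dim=evals.size, hessian=H, eigenvalues=evals, eigenvectors=evecs,
        labels=list(labels), groups=groups, group_stiffness=group_stiffness,
        total_stiffness=total,
    )


def probe_degeneracy(
    opt_result: OptimizationResult,
    cluster_radius: float = 0.05,
    flat_threshold: float | None = None,
    eigenvalues: np.ndarray | None = None,
) -> DegeneracyReport:
    """Count discrete and continuous degeneracies of an optimum.

    Near-optimal final parameter vectors (box-normalized coordinates)
    are clustered by single linkage at ``cluster_radius``; distinct
    clusters with the same fidelity are discrete degeneracies.  If the
    Hessian eigenvalues are supplied, those below ``flat_threshold``
    (default 1e-6 of the largest) count as continuous flat directions.
    """
    finals = np.array([r.final_F for r in opt_result.per_start])
    near = finals <= opt_result.best_F + _near_best_tol(opt_result.best_F)
    if not np.any(near):
        raise ValueError("no start converged near the best optimum")
    xs = opt_result.xs[near]
    if xs.shape[0] == 1:
        n_clusters = 1
    else:
        Z = linkage(pdist(xs), method="single")
        n_clusters = int(fcluster(Z, t=cluster_radius, criterion="distance").max())
    n_flat = 0
    if eigenvalues is not None:
        ev = np.asarray(eigenvalues, dtype=float)
        thr = (1e-6 * float(np.max(np.abs(ev))) if flat_threshold is None
               else flat_threshold)
        n_flat = int(np.sum(np.abs(ev) < thr))
    return DegeneracyReport(
        n_clusters=n_clusters,
        fraction_near_best=float(np.mean(near)),
        n_flat_directions=n_flat,
    )
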