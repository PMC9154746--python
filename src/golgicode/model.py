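"""Cisternal reaction-transport model of Golgi glycan synthesis.

The Golgi is modelled as an array of ``NC`` cisternae. Unglycosylated
carrier protein is injected into cisterna 1 at rate ``q``; inside each
cisterna a line graph of glycosylation reactions ``k -> k+1``
(``k = 1..Ns-1``) advances the glycan index, and material is forwarded to
the next cisterna (or, from the last one, to the plasma membrane) at rate
``mu``.  Each of the ``NE`` enzyme species has an ideal substrate shape
``l`` and binds substrate ``k`` with probability ``exp(-sigma*|k - l|)``;
``sigma`` is the shared enzyme specificity (0 = fully promiscuous).

Two kinetic closures are provided:

* a linear effective-rate form, where the reaction flux is
  ``R_eff(j, k) * c_k^(j)`` with ``R_eff`` the binding-weighted sum of
  per-enzyme catalytic capacities (solved exactly by forward
  substitution), and
* the full Michaelis-Menten form with enzyme saturation, solved per
  cisterna by damped fixed-point iteration (with a stiff-ODE fallback).

Both return per-cisterna concentrations and the normalized distribution
displayed at the plasma membrane, ``cbar_k = mu^(NC) c_k^(NC) / q``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import solve_banded

__all__ = [
    "GolgiSystem",
    "ParameterSet",
    "MMParameterSet",
    "GlycanProfile",
    "SteadyState",
    "binding_probability",
    "binding_matrix",
    "effective_rates",
    "steady_state_linear",
    "steady_state_mm",
    "swap_cisternae",
]

#: probabilities are floored here to avoid exact underflow to 0
_P_FLOOR_LOG = -690.0  # exp(-690) ~ 1e-300

DEFAULT_MU_BOUNDS = (0.01, 1.0)
DEFAULT_R_BOUNDS = (0.018, 20.0)


@dataclass(frozen=True)
class GolgiSystem:
    """Static problem dimensions and parameter boxes.

    Parameters
    ----------
    NC : number of cisternae.
    NE : number of enzyme species per cisterna.
    Ns : number of glycan species (chain length of the reaction line graph).
    q : injection rate of unglycosylated protein into cisterna 1 (min^-1
        times a concentration scale; pure scale, default 1).
    mu_bounds, R_bounds : box bounds (min^-1) for the transport rates and
        the per-enzyme catalytic capacities.
    """

    NC: int
    NE: int
    Ns: int
    q: float = 1.0
    mu_bounds: tuple[float, float] = DEFAULT_MU_BOUNDS
    R_bounds: tuple[float, float] = DEFAULT_R_BOUNDS

    def __post_init__(self) -> None:
        if self.NC < 1 or self.NE < 1:
            raise ValueError("NC and NE must be >= 1")
        if self.Ns < 2:
            raise ValueError("Ns must be >= 2")
        if self.q <= 0:
            raise ValueError("q must be positive")
        for lo, hi in (self.mu_bounds, self.R_bounds):
            if not (0 < lo < hi):
                raise ValueError("bounds must satisfy 0 < lo < hi")

    @property
    def n_coords(self) -> int:
        """Dimension of the full coordinate vector (mu, R, L, sigma)."""
        return self.NC + 2 * self.NE * self.NC + 1


@dataclass
class ParameterSet:
    """Optimization variables of the linear effective-rate model.

    mu : (NC,) inter-cisternal transfer rates; mu[-1] is exit to the PM.
    R : (NE, NC) k-independent catalytic capacities, min^-1.
    L : (NE, NC) ideal enzyme shapes, continuous reals in [1, Ns].
    sigma : shared specificity, >= 0.
    activity : optional (NE, NC) 0/1 mask restricting enzyme activity to
        particular cisternae (all-ones by default).
    """

    mu: np.ndarray
    R: np.ndarray
    L: np.ndarray
    sigma: float
    activity: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.R = np.atleast_2d(np.asarray(self.R, dtype=float))
        self.L = np.atleast_2d(np.asarray(self.L, dtype=float))
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")
        if self.R.shape != self.L.shape:
            raise ValueError("R and L must have identical (NE, NC) shapes")
        if self.mu.shape != (self.R.shape[1],):
            raise ValueError("mu length must equal the number of cisternae")
        if np.any(self.mu <= 0):
            raise ValueError("all transfer rates mu must be positive")
        if self.activity is not None:
            self.activity = np.atleast_2d(np.asarray(self.activity, dtype=float))
            if self.activity.shape != self.R.shape:
                raise ValueError("activity mask must have shape (NE, NC)")

    @property
    def NC(self) -> int:
        return self.mu.shape[0]

    @property
    def NE(self) -> int:
        return self.R.shape[0]

    def copy(self) -> "ParameterSet":
        return ParameterSet(
            mu=self.mu.copy(),
            R=self.R.copy(),
            L=self.L.copy(),
            sigma=self.sigma,
            activity=None if self.activity is None else self.activity.copy(),
        )


@dataclass
class MMParameterSet:
    """Variables of the full Michaelis-Menten model.

    M : (NE, NC) saturation constants (k-independent).
    V : (NE, NC) maximal velocities, min^-1 times concentration.
    """

    mu: np.ndarray
    M: np.ndarray
    V: np.ndarray
    L: np.ndarray
    sigma: float
    activity: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.M = np.atleast_2d(np.asarray(self.M, dtype=float))
        self.V = np.atleast_2d(np.asarray(self.V, dtype=float))
        self.L = np.atleast_2d(np.asarray(self.L, dtype=float))
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")
        if np.any(self.M <= 0) or np.any(self.V <= 0):
            raise ValueError("M and V must be positive")
        if np.any(self.mu <= 0):
            raise ValueError("all transfer rates mu must be positive")
        if self.activity is not None:
            self.activity = np.atleast_2d(np.asarray(self.activity, dtype=float))

    @property
    def NC(self) -> int:
        return self.mu.shape[0]

    @property
    def NE(self) -> int:
        return self.M.shape[0]


@dataclass
class GlycanProfile:
    """Nonnegative abundances over glycan indices ``k = 1..Ns``."""

    abundance: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.abundance = np.asarray(self.abundance, dtype=float)
        if self.abundance.ndim != 1:
            raise ValueError("abundance must be a 1-d vector")
        if np.any(self.abundance < 0):
            raise ValueError("abundances must be nonnegative")
        if self.normalized and abs(self.abundance.sum() - 1.0) > 1e-10:
            raise ValueError("profile flagged normalized does not sum to 1")

    @property
    def Ns(self) -> int:
        return self.abundance.shape[0]

    def normalize(self) -> "GlycanProfile":
        total = self.abundance.sum()
        if total <= 0:
            raise ValueError("cannot normalize an all-zero profile")
        return GlycanProfile(self.abundance / total, normalized=True)


@dataclass
class SteadyState:
    """Per-cisterna concentrations plus the displayed distribution."""

    conc: np.ndarray  # (NC, Ns)
    displayed: GlycanProfile


def binding_probability(k, l, sigma: float):
    """Enzyme-substrate binding probability ``exp(-sigma * |k - l|)``.

    ``k`` is the substrate index (shape ``l_k = k``), ``l`` the enzyme's
    ideal shape, ``sigma`` the specificity.  Evaluated as the exponential
    of a clipped log so it never underflows to exact zero.
    """
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    logp = -sigma * np.abs(np.asarray(k, dtype=float) - np.asarray(l, dtype=float))
    return np.exp(np.maximum(logp, _P_FLOOR_LOG))


def binding_matrix(Ns: int, L: np.ndarray, sigma: float) -> np.ndarray:
    """Binding probabilities P[alpha, j, k] for all enzymes and substrates."""
    k = np.arange(1, Ns + 1, dtype=float)
    L = np.atleast_2d(np.asarray(L, dtype=float))
    return binding_probability(k[None, None, :], L[:, :, None], sigma)


def effective_rates(system: GolgiSystem, params: ParameterSet) -> np.ndarray:
    """Effective reaction rates ``R_eff(j, k)``, shape (NC, Ns).

    ``R_eff(j, k) = sum_alpha activity * R_alpha^(j) * P^(j)(k, alpha)``
    for ``k < Ns``; the last species is absorbing within a cisterna,
    ``R_eff(j, Ns) = 0``.
    """
    if params.NC != system.NC or params.NE != system.NE:
        raise ValueError("parameter dimensions do not match the system")
    P = binding_matrix(system.Ns, params.L, params.sigma)  # (NE, NC, Ns)
    R = params.R
    if params.activity is not None:
        R = R * params.activity
    Reff = np.einsum("ac,ack->ck", R, P)
    Reff[:, -1] = 0.0
    return Reff


def _forward_solve(Reff_j: np.ndarray, mu_j: float, influx: np.ndarray) -> np.ndarray:
    """Solve one cisterna's bidiagonal balance for its concentrations.

    (R_eff(k) + mu) c_k - R_eff(k-1) c_{k-1} = influx_k, k = 1..Ns.
    """
    Ns = Reff_j.shape[0]
    ab = np.zeros((2, Ns))
    ab[0] = Reff_j + mu_j
    ab[1, : Ns - 1] = -Reff_j[: Ns - 1]
    return solve_banded((1, 0), ab, influx)


def steady_state_linear(system: GolgiSystem, params: ParameterSet) -> SteadyState:
    """Exact steady state of the linear effective-rate model.

    Balance in cisterna j (with reaction flux ``phi = R_eff * c``)::

        influx_k + phi(j, k-1) - phi(j, k) - mu^(j) c_k^(j) = 0

    where influx is ``q`` into species 1 of cisterna 1, and the previous
    cisterna's transport flux thereafter.  Solved by forward substitution
    cisterna by cisterna; the displayed distribution is the normalized
    exit flux ``mu^(NC) c^(NC) / q``.
    """
    Reff = effective_rates(system, params)
    Ns = system.Ns
    conc = np.empty((system.NC, Ns))
    influx = np.zeros(Ns)
    influx[0] = system.q
    for j in range(system.NC):
        conc[j] = _forward_solve(Reff[j], params.mu[j], influx)
        influx = params.mu[j] * conc[j]
    displayed = GlycanProfile(np.maximum(influx, 0.0) / system.q, normalized=False)
    # exact arithmetic guarantees sum == 1; renormalize away rounding
    return SteadyState(conc=conc, displayed=displayed.normalize())


def _mm_effective_rates(
    P_j: np.ndarray, M_j: np.ndarray, V_j: np.ndarray, c: np.ndarray
) -> np.ndarray:
    """Concentration-dependent linearized MM rates for one cisterna.

    With saturation factor ``S_a = 1 + sum_k P(k,a) c_k / M_a`` the MM flux
    out of species k is ``[sum_a V_a P(k,a) / (M_a S_a)] c_k``.
    """
    S = 1.0 + P_j @ c / M_j  # (NE,)
    rates = np.einsum("a,ak->k", V_j / (M_j * S), P_j)
    rates[-1] = 0.0
    return rates


def steady_state_mm(
    system: GolgiSystem,
    params: MMParameterSet,
    damping: float = 0.5,
    max_iter: int = 100_000,
    tol: float = 1e-10,
    ode_fallback: bool = True,
) -> SteadyState:
    """Steady state of the full Michaelis-Menten kinetics.

    Solved cisterna by cisterna: the MM flux is linear in ``c`` once the
    per-enzyme saturation factors are fixed, so each sweep solves the
    bidiagonal system at the current saturation and damps the update.
    Falls back to stiff ODE time integration if the fixed point does not
    reach the residual tolerance.
    """
    if params.NC != system.NC:
        raise ValueError("parameter dimensions do not match the system")
    P = binding_matrix(system.Ns, params.L, params.sigma)  # (NE, NC, Ns)
    V = params.V if params.activity is None else params.V * params.activity
    Ns = system.Ns
    conc = np.empty((system.NC, Ns))
    influx = np.zeros(Ns)
    influx[0] = system.q

    for j in range(system.NC):
        P_j, M_j, V_j = P[:, j, :], params.M[:, j], V[:, j]
        mu_j = params.mu[j]
        c = _forward_solve(_mm_effective_rates(P_j, M_j, V_j, np.zeros(Ns)), mu_j, influx)
        converged = False
        for _ in range(max_iter):
            rates = _mm_effective_rates(P_j, M_j, V_j, c)
            c_new = _forward_solve(rates, mu_j, influx)
            c = (1.0 - damping) * c + damping * c_new
            # balance residual at the current iterate
            rates = _mm_effective_rates(P_j, M_j, V_j, c)
            phi = rates * c
            resid = influx + np.concatenate(([0.0], phi[:-1])) - phi - mu_j * c
            if np.max(np.abs(resid)) < tol * system.q:
                converged = True
                break
        if not converged:
            if not ode_fallback:
                raise RuntimeError(
                    f"MM fixed point did not converge in cisterna {j + 1}; "
                    f"final residual {np.max(np.abs(resid)):.3e}"
                )
            c = _mm_ode_steady_state(P_j, M_j, V_j, mu_j, influx, c, tol * system.q)
        conc[j] = c
        influx = mu_j * c

    displayed = GlycanProfile(np.maximum(influx, 0.0) / system.q, normalized=False)
    return SteadyState(conc=conc, displayed=displayed.normalize())


def _mm_ode_steady_state(P_j, M_j, V_j, mu_j, influx, c0, abs_tol) -> np.ndarray:
    """Stiff time integration of one cisterna's MM kinetics to t -> inf."""

    def rhs(_t, c):
        rates = _mm_effective_rates(P_j, M_j, V_j, c)
        phi = rates * c
        return influx + np.concatenate(([0.0], phi[:-1])) - phi - mu_j * c

    c = np.maximum(c0, 0.0)
    t_end = 100.0 / mu_j
    for _ in range(20):
        sol = solve_ivp(rhs, (0.0, t_end), c, method="LSODA", rtol=1e-12, atol=1e-14)
        c = sol.y[:, -1]
        if np.max(np.abs(rhs(0.0, c))) < abs_tol:
            return c
    raise RuntimeError(
        "MM steady state not reached by ODE fallback; "
        f"final residual {np.max(np.abs(rhs(0.0, c))):.3e}"
    )


def swap_cisternae(params: ParameterSet, j1: int, j2: int) -> ParameterSet:
    """Exchange the enzyme complements (R, L, activity columns) of two
    cisternae; transport rates are untouched.  Indices are 1-based."""
    NC = params.NC
    if not (1 <= j1 <= NC and 1 <= j2 <= NC):
        raise ValueError(f"cisterna indices must lie in 1..{NC}")
    out = params.copy()
    a, b = j1 - 1, j2 - 1
    for mat in (out.R, out.L) + (() if out.activity is None else (out.activity,)):
        mat[:, [a, b]] = mat[:, [b, a]]
    return out
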