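"""Synthetic inputs: Gaussian-mixture targets, delta targets, MSMS-like
noisy raw profiles, and parameter-recovery fixtures.

These generators stand in for deposited mass-spectrometry glycan
profiles: a discrete target distribution on glycan indices ``1..Ns`` is
an m-component Gaussian mixture evaluated on the index grid and
renormalized.  Few-component mixtures have wide peaks (low complexity),
many-component mixtures narrow peaks (high complexity) — the two
benchmark regimes of the analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .model import GlycanProfile, GolgiSystem, ParameterSet, steady_state_linear

__all__ = [
    "TargetSpec",
    "MsmsNoiseSpec",
    "make_gmm_target",
    "make_delta_target",
    "make_msms_like",
    "make_recovery_fixture",
    "random_mixture_spec",
    "separated_mixture_spec",
]


@dataclass(frozen=True)
class TargetSpec:
    """An m-component Gaussian mixture on the index grid ``1..Ns``.

    components : list of (weight, mean, sd); weights must sum to 1.
    """

    Ns: int
    components: tuple[tuple[float, float, float], ...]
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.components) == 0:
            raise ValueError("at least one mixture component is required")
        w = np.array([c[0] for c in self.components])
        if abs(w.sum() - 1.0) > 1e-8:
            raise ValueError("component weights must sum to 1")
        for _, mean, sd in self.components:
            if not (1 <= mean <= self.Ns):
                raise ValueError("component means must lie in [1, Ns]")
            if sd <= 0:
                raise ValueError("component sds must be positive")


@dataclass(frozen=True)
class MsmsNoiseSpec:
    """Counting-noise model for MSMS-like raw profiles.

    total_counts : Poisson intensity scale (total expected ion count).
    baseline : fraction of intensity in a uniform chemical-noise floor.
    """

    total_counts: int
    baseline: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.total_counts < 0:
            raise ValueError("total_counts must be nonnegative")
        if not (0 <= self.baseline < 1):
            raise ValueError("baseline must lie in [0, 1)")


def make_gmm_target(spec: TargetSpec) -> GlycanProfile:
    """Mixture density sampled at ``k = 1..Ns`` and renormalized."""
    k = np.arange(1, spec.Ns + 1, dtype=float)
    dens = np.zeros_like(k)
    for w, mean, sd in spec.components:
        dens += w * norm.pdf(k, loc=mean, scale=sd)
    return GlycanProfile(dens).normalize()


def make_delta_target(Ns: int, M: int) -> GlycanProfile:
    """Point mass at glycan index ``M`` (1-based)."""
    if not (1 <= M <= Ns):
        raise ValueError("M must lie in 1..Ns")
    v = np.zeros(Ns)
    v[M - 1] = 1.0
    return GlycanProfile(v, normalized=True)


def make_msms_like(target: GlycanProfile, noise: MsmsNoiseSpec) -> GlycanProfile:
    """Raw (unnormalized) Poisson counts over a target plus uniform
    chemical-noise baseline."""
    p = target.abundance / target.abundance.sum()
    Ns = target.Ns
    intensity = noise.total_counts * ((1.0 - noise.baseline) * p + noise.baseline / Ns)
    rng = np.random.default_rng(noise.seed)
    counts = rng.poisson(intensity).astype(float)
    return GlycanProfile(counts, normalized=False)


def make_recovery_fixture(
    system: GolgiSystem, sigma: float, seed: int
) -> tuple[ParameterSet, GlycanProfile]:
    """Draw in-bounds parameters and return them with their displayed
    distribution as target (ground truth attains F = 0 by construction)."""
    rng = np.random.default_rng(seed)
    mu_lo, mu_hi = system.mu_bounds
    R_lo, R_hi = system.R_bounds
    params = ParameterSet(
        mu=np.exp(rng.uniform(np.log(mu_lo), np.log(mu_hi), size=system.NC)),
        R=np.exp(rng.uniform(np.log(R_lo), np.log(R_hi), size=(system.NE, system.NC))),
        L=rng.uniform(1.0, system.Ns, size=(system.NE, system.NC)),
        sigma=sigma,
    )
    target = steady_state_linear(system, params).displayed
    return params, target


def random_mixture_spec(
    m: int,
    Ns: int = 200,
    seed: int = 0,
    weight_conc: float = 1.0,
    sd_range: tuple[float, float] = (2.0, 6.0),
) -> TargetSpec:
    """Random m-component mixture emulating coarse-grained MSMS targets.

    Component means are quantile-spaced over ``1..Ns`` with jitter and
    weights are Dirichlet(weight_conc).  The sd range is stated for a
    component spacing of 10 indices (the 20-component regime at Ns=200)
    and is scaled proportionally with the actual spacing, so
    few-component mixtures get wide peaks and many-component mixtures
    narrow ones.  Pass a tighter ``sd_range`` (e.g. ``(1.5, 3)``) when
    well-separated components are required, e.g. for complexity
    round-trip studies.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    rng = np.random.default_rng(seed)
    spacing = Ns / m
    means = (np.arange(m) + 0.5) * spacing + rng.uniform(-0.15, 0.15, size=m) * spacing
    means = np.clip(means, 1.0, float(Ns))
    scale = spacing / 10.0
    sds = np.maximum(rng.uniform(sd_range[0], sd_range[1], size=m) * scale, 1.0)
    weights = rng.dirichlet(np.full(m, weight_conc))
    comps = tuple(
        (float(w), float(mu), float(sd)) for w, mu, sd in zip(weights, means, sds)
    )
    return TargetSpec(Ns=Ns, components=comps, seed=seed)


def separated_mixture_spec(
    m: int,
    Ns: int = 200,
    seed: int = 0,
    weight_conc: float = 5.0,
    sd_range: tuple[float, float] = (1.5, 2.5),
) -> TargetSpec:
    """Well-separated m-component mixture for round-trip complexity studies.

    Narrow components (sd independent of m) on quantile-spaced means with
    small jitter; component separation is >= 4 sd up to m = Ns/10 and
    peaks stay clear of the grid boundary, so the discretized profile is
    an essentially exact m-component mixture.  Weights use a concentrated
    Dirichlet so every component carries comparable, visible mass.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if m * 4 * sd_range[1] > Ns:
        raise ValueError("components cannot be well separated at this (m, Ns)")
    rng = np.random.default_rng(seed)
    spacing = Ns / m
    jitter = min(0.1 * spacing, sd_range[0])
    means = (np.arange(m) + 0.5) * spacing + rng.uniform(-jitter, jitter, size=m)
    means = np.clip(means, 1.0 + 2 * sd_range[1], Ns - 2 * sd_range[1])
    sds = rng.uniform(sd_range[0], sd_range[1], size=m)
    weights = rng.dirichlet(np.full(m, weight_conc))
    comps = tuple(
        (float(w), float(mu), float(sd)) for w, mu, sd in zip(weights, means, sds)
    )
    return TargetSpec(Ns=Ns, components=comps, seed=seed)
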