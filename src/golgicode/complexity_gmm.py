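"""Complexity of a glycan profile via Gaussian-mixture approximation.

A discrete glycan profile (abundances on indices ``1..Ns``) is
approximated by an m-component Gaussian mixture evaluated on the index
grid and renormalized.  The KL divergence D(profile || mixture) drops as
m grows and saturates once the mixture captures every visible mode; the
saturation point m* is the profile's complexity.  The fit is a weighted
EM on the support points (weights = abundances) rather than on resampled
pseudo-counts, so it is deterministic given a seed and directly
minimizes the KL actually reported.

Raw mass-spectrometry profiles carry a uniform chemical-noise floor that
no finite Gaussian mixture can absorb; the mixture therefore optionally
includes one uniform background component (weight fitted by the same
EM), so the component count m measures the peaked signal structure, not
the noise floor.  On noise-free profiles the fitted background weight
collapses toward zero and the fit reduces to a pure mixture.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .model import GlycanProfile
from .objectives import kl_divergence

__all__ = ["GMMApprox", "ComplexityCall", "fit_gmm", "kl_curve", "call_complexity",
           "complexity"]

#: component sds are floored here (index units) to prevent collapse onto
#: a single grid point
SD_FLOOR = 0.5

_EM_TOL = 1e-10
_EM_MAX_ITER = 500
_BG_INIT = 0.01


@dataclass
class GMMApprox:
    """An m-component mixture (plus optional uniform background), its
    discretization on the index grid, and its KL distance."""

    m: int
    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    discretized: GlycanProfile
    kl: float
    background: float = 0.0  # weight of the uniform background component


@dataclass
class ComplexityCall:
    """Saturation call on a KL-vs-m curve (curve[i] is the KL at m=i+1)."""

    m_star: int
    curve: np.ndarray
    tol: float
    window: int
    saturated: bool


def _discretize(weights, means, sds, bg: float, Ns: int) -> GlycanProfile:
    k = np.arange(1, Ns + 1, dtype=float)
    dens = (weights[:, None] * norm.pdf(k[None, :], means[:, None],
                                        sds[:, None])).sum(0)
    dens = dens + bg / Ns
    dens = np.maximum(dens, 1e-300)
    return GlycanProfile(dens / dens.sum(), normalized=True)


def _em(k, p, weights, means, sds, bg):
    """Weighted EM on support points k with masses p, maximizing
    ``sum_k p_k ln p_gmm(k)``; ``bg`` is the uniform-background weight
    (None disables the background component)."""
    weights, means, sds = weights.copy(), means.copy(), sds.copy()
    Ns = k.size
    prev_ll = -np.inf
    for _ in range(_EM_MAX_ITER):
        # E-step in log space; optional uniform row for the background
        logp = (np.log(weights[:, None] + 1e-300)
                + norm.logpdf(k[None, :], means[:, None], sds[:, None]))
        if bg is not None:
            bg_row = np.full((1, Ns), np.log(max(bg, 1e-300)) - np.log(Ns))
            logp = np.vstack([logp, bg_row])
        lse = np.logaddexp.reduce(logp, axis=0)
        resp = np.exp(logp - lse[None, :])
        ll = float(np.sum(p * lse))
        # M-step weighted by profile mass
        wk = resp * p[None, :]
        wsum = np.maximum(wk.sum(axis=1), 1e-300)
        total = wsum.sum()
        if bg is not None:
            bg = float(wsum[-1] / total)
            wk, wsum = wk[:-1], wsum[:-1]
        weights = wsum / total
        means = (wk @ k) / wsum
        var = (wk @ (k**2)) / wsum - means**2
        sds = np.sqrt(np.maximum(var, SD_FLOOR**2))
        if ll - prev_ll < _EM_TOL * max(1.0, abs(ll)):
            break
        prev_ll = ll
    return weights, means, sds, bg


def _build(profile: GlycanProfile, weights, means, sds, bg) -> GMMApprox:
    bg_val = 0.0 if bg is None else float(bg)
    disc = _discretize(weights, means, sds, bg_val, profile.Ns)
    return GMMApprox(m=len(weights), weights=weights, means=means, sds=sds,
                     discretized=disc, kl=kl_divergence(profile, disc),
                     background=bg_val)


def fit_gmm(profile: GlycanProfile, m: int, restarts: int = 10, seed: int = 0,
            background: bool = True) -> GMMApprox:
    """Best-of-restarts weighted EM fit of an m-component mixture.

    Initialization: quantile-spaced means over the support (jittered per
    restart), equal weights, sd = support range / (2m).  With
    ``background`` a uniform noise-floor component is fitted alongside
    the Gaussians (its weight does not count toward m).
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    prof = profile if profile.normalized else profile.normalize()
    support = np.flatnonzero(prof.abundance > 0)
    if m > support.size:
        raise ValueError(
            f"m={m} exceeds the {support.size} support points with positive mass"
        )
    k = np.arange(1, prof.Ns + 1, dtype=float)
    p = prof.abundance
    lo, hi = k[support[0]], k[support[-1]]
    span = max(hi - lo, 1.0)
    cdf = np.cumsum(p)
    quantile_means = np.interp((np.arange(m) + 0.5) / m, cdf, k)
    rng = np.random.default_rng(seed)
    best: GMMApprox | None = None
    for r in range(restarts):
        means = quantile_means.copy()
        if r > 0:
            means = means + rng.normal(scale=span / (4.0 * m), size=m)
        means = np.clip(means, lo, hi)
        sds = np.full(m, max(span / (2.0 * m), SD_FLOOR))
        bg0 = _BG_INIT if background else None
        weights = np.full(m, (1.0 - (bg0 or 0.0)) / m)
        fitted = _build(prof, *_em(k, p, weights, means, sds, bg0))
        if best is None or fitted.kl < best.kl:
            best = fitted
    return best


def _bg0(prev: GMMApprox, background: bool):
    return prev.background if background else None


def _split_candidate(prev: GMMApprox):
    """Warm start with m+1 components: split the heaviest component."""
    i = int(np.argmax(prev.weights))
    weights = np.concatenate([prev.weights, [prev.weights[i] / 2.0]])
    weights[i] /= 2.0
    offset = max(prev.sds[i], SD_FLOOR)
    means = np.concatenate([prev.means, [prev.means[i] + offset]])
    means[i] -= offset
    sds = np.concatenate([prev.sds, [prev.sds[i]]])
    return weights, means, sds


def _insert_candidate(prev: GMMApprox, p: np.ndarray, k: np.ndarray):
    """Warm start with m+1 components: insert a narrow component at the
    index where the current fit most underfits the profile (largest
    pointwise KL excess), the typical signature of a missed peak."""
    q = prev.discretized.abundance
    with np.errstate(divide="ignore", invalid="ignore"):
        excess = np.where(p > 0, p * (np.log(np.maximum(p, 1e-300))
                                      - np.log(np.maximum(q, 1e-300))), 0.0)
    i = int(np.argmax(excess))
    w_new = max(float(p[i]), 0.01)
    gauss_total = prev.weights.sum()
    weights = np.concatenate([prev.weights * (1.0 - w_new),
                              [w_new * gauss_total]])
    means = np.concatenate([prev.means, [k[i]]])
    sds = np.concatenate([prev.sds, [2.0 * SD_FLOOR]])
    return weights, means, sds


def _pad_candidate(prev: GMMApprox, Ns: int):
    """Previous solution plus a vanishing extra component: its KL equals
    the previous KL up to rounding, guaranteeing a nonincreasing curve."""
    weights = np.concatenate([prev.weights * (1.0 - 1e-12), [1e-12]])
    means = np.concatenate([prev.means, [min(prev.means[-1] + 1.0, float(Ns))]])
    sds = np.concatenate([prev.sds, [max(prev.sds[-1], SD_FLOOR)]])
    return weights, means, sds


def kl_curve(profile: GlycanProfile, m_max: int, restarts: int = 10,
             seed: int = 0, background: bool = True) -> np.ndarray:
    """KL divergence of the best m-component fit for m = 1..m_max.

    Each m considers fresh restarts plus warm starts grown from the
    (m-1)-component solution, including an un-refined padded copy of it,
    so the curve is nonincreasing to within 1e-6.
    """
    if m_max < 1:
        raise ValueError("m_max must be >= 1")
    prof = profile if profile.normalized else profile.normalize()
    k = np.arange(1, prof.Ns + 1, dtype=float)
    p = prof.abundance
    rng = np.random.default_rng(seed)
    n_support = int(np.sum(prof.abundance > 0))
    curve = np.empty(m_max)
    prev: GMMApprox | None = None
    for m in range(1, m_max + 1):
        cands = []
        if m <= n_support:
            cands.append(fit_gmm(prof, m, restarts=restarts,
                                 seed=int(rng.integers(2**31)),
                                 background=background))
        if prev is not None:
            bg0 = _bg0(prev, background)
            for w0, mu0, sd0 in (_split_candidate(prev),
                                 _insert_candidate(prev, p, k)):
                cands.append(_build(prof, *_em(k, p, w0, mu0, sd0, bg0)))
            w0, mu0, sd0 = _pad_candidate(prev, prof.Ns)
            cands.append(_build(prof, w0, mu0, sd0, bg0))
        best = min(cands, key=lambda g: g.kl)
        curve[m - 1] = best.kl
        prev = best
    return curve


def call_complexity(curve: np.ndarray, tol: float = 0.01,
                    window: int = 2) -> ComplexityCall:
    """Call the saturation point of a KL-vs-m curve.

    m* is the smallest m whose KL drops by less than ``tol * curve[m=1]``
    over the next ``window`` components.  If no m satisfies this before
    the curve runs out, m_max is returned with ``saturated=False``.
    """
    curve = np.asarray(curve, dtype=float)
    m_max = curve.size
    if m_max < 1:
        raise ValueError("curve must be nonempty")
    thresh = tol * max(curve[0], 1e-12)
    for m in range(1, m_max - window + 1):
        drops = curve[m - 1] - curve[m - 1 + np.arange(1, window + 1)]
        if np.all(drops < thresh):
            return ComplexityCall(m_star=m, curve=curve, tol=tol,
                                  window=window, saturated=True)
    return ComplexityCall(m_star=m_max, curve=curve, tol=tol,
                          window=window, saturated=False)


def complexity(profile: GlycanProfile, m_max: int = 25, restarts: int = 10,
               seed: int = 0, tol: float = 0.01, window: int = 2,
               background: bool = True) -> ComplexityCall:
    """Convenience wrapper: KL curve then saturation call."""
    return call_complexity(
        kl_curve(profile, m_max, restarts=restarts, seed=seed,
                 background=background),
        tol=tol, window=window)
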