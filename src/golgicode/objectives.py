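"""Scalar objectives: entropy, KL divergence, normalized-KL fidelity,
and the sigmoid glycan-diversity score.

Fidelity of a synthesis machinery is the Kullback-Leibler divergence from
the target glycan distribution ``c*`` to the displayed distribution
``cbar``, normalized by the target's entropy so that targets of different
complexity are comparable::

    F(c* || cbar) = D(c* || cbar) / H(c*)

Low F is high fidelity.  Diversity counts the glycan species displayed
above an abundance threshold ``c_th`` (default ``1/Ns``), smoothed by a
sigmoid of sharpness ``Ns`` so the count is differentiable.
All logarithms are natural.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import GlycanProfile

__all__ = [
    "FidelityValue",
    "DiversityValue",
    "entropy",
    "kl_divergence",
    "fidelity",
    "diversity",
]

#: displayed probabilities are floored here before KL; with finite sigma
#: every species has positive probability in exact arithmetic, the floor
#: only guards underflow.
KL_FLOOR = 1e-12

_NORM_TOL = 1e-8


def _as_prob(p) -> np.ndarray:
    arr = p.abundance if isinstance(p, GlycanProfile) else np.asarray(p, dtype=float)
    if np.any(arr < 0):
        raise ValueError("probabilities must be nonnegative")
    if abs(arr.sum() - 1.0) > _NORM_TOL:
        raise ValueError("profile is not normalized; call .normalize() first")
    return arr


@dataclass(frozen=True)
class FidelityValue:
    """KL divergence, target entropy, and their ratio F (all in nats)."""

    kl: float
    entropy: float
    F: float


@dataclass(frozen=True)
class DiversityValue:
    """Sigmoid-smoothed species count above threshold."""

    value: float
    threshold: float
    tau_inverse: float


def entropy(p) -> float:
    """Shannon entropy ``sum_k p_k ln(1/p_k)`` with 0 ln(1/0) := 0."""
    arr = _as_prob(p)
    pos = arr[arr > 0]
    return float(-np.sum(pos * np.log(pos)))


def kl_divergence(p, q, floor: float = KL_FLOOR) -> float:
    """``D(p || q) = sum_{k: p_k>0} p_k ln(p_k / q_k)``, nats.

    ``q`` is floored at ``floor`` and renormalized, so indices where the
    model assigns (numerically) zero probability yield a large finite
    penalty rather than an infinity.
    """
    parr = _as_prob(p)
    qarr = q.abundance if isinstance(q, GlycanProfile) else np.asarray(q, dtype=float)
    if np.any(qarr < 0):
        raise ValueError("probabilities must be nonnegative")
    if parr.shape != qarr.shape:
        raise ValueError("p and q must share the index grid 1..Ns")
    qarr = np.maximum(qarr, floor)
    qarr = qarr / qarr.sum()
    mask = parr > 0
    return float(np.sum(parr[mask] * (np.log(parr[mask]) - np.log(qarr[mask]))))


def fidelity(target, displayed, floor: float = KL_FLOOR) -> FidelityValue:
    """Normalized KL fidelity ``F = D(target || displayed) / H(target)``.

    Raises for a zero-entropy (delta) target, for which the ratio is
    undefined; use :func:`kl_divergence` directly in that case.
    """
    H = entropy(target)
    if H <= 0:
        raise ValueError(
            "target has zero entropy (delta distribution); F = D/H is "
            "undefined — use the unnormalized kl_divergence instead"
        )
    D = kl_divergence(target, displayed, floor=floor)
    return FidelityValue(kl=D, entropy=H, F=D / H)


def diversity(c, c_th: float | None = None, Ns: int | None = None) -> DiversityValue:
    """Sigmoid-smoothed count of species above threshold abundance.

    ``sum_i (1 + exp(-Ns * (c_i - c_th)))^-1`` with sharpness ``1/tau = Ns``
    and default threshold ``c_th = 1/Ns``.  Lies in [0, Ns] and is strictly
    increasing in every ``c_i``.
    """
    arr = _as_prob(c)
    if Ns is None:
        Ns = arr.shape[0]
    if c_th is None:
        c_th = 1.0 / Ns
    if c_th <= 0:
        raise ValueError("threshold c_th must be positive")
    x = np.clip(-float(Ns) * (arr - c_th), -700.0, 700.0)
    value = float(np.sum(1.0 / (1.0 + np.exp(x))))
    return DiversityValue(value=value, threshold=c_th, tau_inverse=float(Ns))
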