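"""Magallón–Sanderson crown-age diversification-rate estimators.

Net diversification rate r = λ − μ (speciation minus extinction) is
estimated from standing species richness n and crown age Δt (MY). With no
extinction the crown estimator is

    r = (ln n − ln 2) / Δt

and with a relative extinction ratio ε = μ/λ in [0, 1):

    r = (1/Δt) · ( ln[ n(1−ε²)/2 + 2ε + (1−ε)/2 · √(n(nε² − 8ε + 2nε + n)) ] − ln 2 )

which reduces algebraically to the extinction-free form at ε = 0. All
logarithms are natural; e.g. for 12 extant species over 4.73 MY,
r = ln(12/2)/4.73 ≈ 0.38 per MY. Values are kept at full precision
internally and rounded only for presentation.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Optional

from .timetrees import TimeTree, crown_age

__all__ = [
    "CladeSummary",
    "RateMethod",
    "RateResult",
    "DiversificationError",
    "extinction_ratio",
    "rate_crown",
    "rate_crown_extinction",
    "rate_from_clade",
]


class DiversificationError(ValueError):
    """Parameters outside the estimator's domain."""


class RateMethod(str, enum.Enum):
    CROWN_NO_EXTINCTION = "crown_no_extinction"
    CROWN_WITH_EXTINCTION = "crown_with_extinction"


@dataclass(frozen=True)
class RateResult:
    """A net diversification rate estimate (per MY) and the estimator used."""

    r: float
    method: RateMethod

    def rounded(self, ndigits: int = 2) -> float:
        """Presentation rounding (the printed convention is 2 d.p.)."""
        return round(self.r, ndigits)


@dataclass(frozen=True)
class CladeSummary:
    """Inputs for the crown estimators: richness, crown age, extinction.

    ``n`` is the total known extant species of the clade (which may exceed
    the tip count of an undersampled tree), ``delta_t`` the crown age in
    MY, ``epsilon`` the extinction ratio μ/λ. ``mu``/``lam`` may be given
    instead of ``epsilon``.
    """

    n: int
    delta_t: float
    epsilon: float = 0.0
    mu: Optional[float] = None
    lam: Optional[float] = None

    def __post_init__(self) -> None:
        if self.n < 2:
            raise DiversificationError("clade must have at least 2 extant species")
        if self.delta_t <= 0:
            raise DiversificationError("crown age must be positive")
        eps = self.epsilon
        if self.mu is not None and self.lam is not None:
            eps = extinction_ratio(self.mu, self.lam)
            object.__setattr__(self, "epsilon", eps)
        if not 0 <= eps < 1:
            raise DiversificationError(
                f"extinction ratio must lie in [0, 1), got {eps}"
            )

    def rate(self) -> RateResult:
        if self.epsilon == 0:
            return rate_crown(self.n, self.delta_t)
        return rate_crown_extinction(self.n, self.delta_t, self.epsilon)


def extinction_ratio(mu: float, lam: float) -> float:
    """Extinction ratio ε = μ/λ; valid only when 0 ≤ μ < λ.

    The bound μ < λ keeps ε in [0, 1), the domain on which the
    extinction-corrected crown estimator is defined (at ε = 1 the log
    argument degenerates).
    """
    if lam <= 0:
        raise DiversificationError(f"speciation rate must be positive, got {lam}")
    if mu < 0:
        raise DiversificationError(f"extinction rate must be nonnegative, got {mu}")
    if mu >= lam:
        raise DiversificationError(
            f"extinction rate {mu} must be below speciation rate {lam}: the "
            "crown estimator with extinction requires ε = μ/λ in [0, 1)"
        )
    return mu / lam


def rate_crown(n: int, delta_t: float) -> RateResult:
    """Crown-age net diversification rate ignoring extinction.

    r = (ln n − ln 2)/Δt, natural logarithm.
    """
    if n < 2:
        raise DiversificationError(f"need at least 2 extant species, got {n}")
    if delta_t <= 0:
        raise DiversificationError(f"crown age must be positive, got {delta_t}")
    r = (math.log(n) - math.log(2)) / delta_t
    return RateResult(r=r, method=RateMethod.CROWN_NO_EXTINCTION)


def rate_crown_extinction(n: int, delta_t: float, epsilon: float) -> RateResult:
    """Crown-age net diversification rate with extinction ratio ε.

    Evaluates the extinction-corrected crown formula (natural log); at
    ε = 0 it equals :func:`rate_crown` to machine precision.
    """
    if n < 2:
        raise DiversificationError(f"need at least 2 extant species, got {n}")
    if delta_t <= 0:
        raise DiversificationError(f"crown age must be positive, got {delta_t}")
    if not 0 <= epsilon < 1:
        raise DiversificationError(
            f"extinction ratio must lie in [0, 1), got {epsilon}"
        )
    radicand = n * (n * epsilon**2 - 8 * epsilon + 2 * n * epsilon + n)
    # On the valid domain (n ≥ 2, 0 ≤ ε < 1) the radicand is positive.
    assert radicand > 0, "internal error: negative radicand in crown estimator"
    inner = (
        n * (1 - epsilon**2) / 2
        + 2 * epsilon
        + (1 - epsilon) / 2 * math.sqrt(radicand)
    )
    r = (math.log(inner) - math.log(2)) / delta_t
    return RateResult(r=r, method=RateMethod.CROWN_WITH_EXTINCTION)


def rate_from_clade(
    tree: TimeTree,
    n_total: Optional[int] = None,
    epsilon: float = 0.0,
) -> RateResult:
    """Diversification rate of a clade given as an ultrametric tree.

    Δt is the tree's crown age; n defaults to the tip count but may be
    overridden with ``n_total`` when the tree undersamples the clade's
    known richness (n_total must then be at least the tip count).
    """
    n_tips = tree.n_tips
    if n_total is None:
        n = n_tips
    else:
        if n_total < n_tips:
            raise DiversificationError(
                f"n_total={n_total} is below the tree's tip count {n_tips}"
            )
        n = n_total
    delta_t = crown_age(tree)
    if epsilon == 0:
        return rate_crown(n, delta_t)
    return rate_crown_extinction(n, delta_t, epsilon)
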