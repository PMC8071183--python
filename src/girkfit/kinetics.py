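"""From time constants to rate constants and kinetic affinities.

The dissociation rate constant is read directly from the washout decay,
k_off = 1/tau_deact.  The association rate constant is the slope of the
observed activation rate against agonist concentration,

    k_obs = [A] * k_on + k_off,

fitted over the low-concentration range where the relation is linear
(at higher concentrations k_obs saturates because G-protein turnover and
solution exchange, not binding, become rate-limiting).  The two rates
combine into the kinetic dissociation constant K_d = k_off / k_on and
pK_d = -log10(K_d), directly comparable to pEC50 when there is no
receptor reserve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .models import KobsLinear


@dataclass(frozen=True)
class KobsPoint:
    """Observed activation rate at one agonist concentration."""

    concentration: float   # molar
    k_obs: float           # s^-1

    def __post_init__(self) -> None:
        if not self.concentration > 0:
            raise ValueError("concentration must be positive")
        if not self.k_obs > 0:
            raise ValueError("k_obs must be positive")


@dataclass(frozen=True)
class LinearRangeFit:
    """OLS line over the linear prefix of the k_obs-concentration relation."""

    slope: float            # M^-1 s^-1, the k_on estimate
    slope_sem: float
    intercept: float        # s^-1, diagnostic only (never used as k_off)
    intercept_sem: float
    included_concentrations: tuple[float, ...]
    excluded_concentrations: tuple[float, ...]
    r_squared: float

    def __post_init__(self) -> None:
        if len(self.included_concentrations) < 3:
            raise ValueError("a linear-range fit needs >= 3 included points")


@dataclass(frozen=True)
class KineticEstimate:
    """Complete kinetic characterization of one ligand x receptor pair."""

    ligand: str
    receptor: str
    k_on: float
    k_on_sem: float
    k_off: float
    k_off_sem: float
    kd: float = field(init=False)
    pkd: float = field(init=False)
    pkd_sem: float = field(init=False)

    def __post_init__(self) -> None:
        kd, pkd = kinetic_kd(self.k_off, self.k_on)
        object.__setattr__(self, "kd", kd)
        object.__setattr__(self, "pkd", pkd)
        object.__setattr__(self, "pkd_sem",
                           pkd_sem(self.k_off, self.k_off_sem,
                                   self.k_on, self.k_on_sem))


def koff_from_tau(tau_deact: float) -> float:
    """Dissociation rate constant as the reciprocal deactivation time constant."""
    if not tau_deact > 0:
        raise ValueError(f"tau_deact must be positive, got {tau_deact}")
    return 1.0 / tau_deact


def select_linear_range(points: list[KobsPoint], alpha: float = 0.05,
                        max_relative_deviation: float = 0.15) -> LinearRangeFit:
    """Fit the largest low-concentration prefix over which k_obs is linear.

    Linearity of a prefix (>= 3 points) requires that a quadratic term
    does not significantly improve the fit (partial F-test at ``alpha``)
    and that the top included point deviates from the line by less than
    ``max_relative_deviation``.  Raises when no prefix qualifies.
    """
    c = np.array([p.concentration for p in points])
    k = np.array([p.k_obs for p in points])
    model = KobsLinear(alpha=alpha,
                       max_relative_deviation=max_relative_deviation).fit(c, k)
    return LinearRangeFit(
        slope=model.slope_, slope_sem=model.slope_sem_,
        intercept=model.intercept_, intercept_sem=model.intercept_sem_,
        included_concentrations=tuple(model.included_),
        excluded_concentrations=tuple(model.excluded_),
        r_squared=model.r_squared_)


def estimate_kon(points: list[KobsPoint], **kwargs) -> LinearRangeFit:
    """Estimate k_on as the linear-range slope of k_obs vs concentration.

    The intercept is retained as a diagnostic to compare with the washout
    k_off, but k_off itself is always taken from washout decays.
    """
    return select_linear_range(points, **kwargs)


def kinetic_kd(k_off: float, k_on: float) -> tuple[float, float]:
    """Kinetic dissociation constant ``K_d = k_off / k_on`` and its pK_d."""
    if not (k_off > 0 and k_on > 0):
        raise ValueError("k_off and k_on must be positive")
    kd = k_off / k_on
    return kd, -math.log10(kd)


def pkd_sem(k_off: float, k_off_sem: float, k_on: float, k_on_sem: float) -> float:
    """Uncertainty of the kinetic pK_d.

    Propagates the relative standard errors of the two rate constants,
    ``sqrt((se_off/k_off)**2 + (se_on/k_on)**2)`` -- the relative SE of
    K_d -- and reports it directly as the pK_d SEM.
    """
    if not (k_off > 0 and k_on > 0):
        raise ValueError("k_off and k_on must be positive")
    if k_off_sem < 0 or k_on_sem < 0:
        raise ValueError("standard errors must be >= 0")
    return math.sqrt((k_off_sem / k_off) ** 2 + (k_on_sem / k_on) ** 2)


#: Ordinal categories by |log10 fold change|: below 0.15 no change, then
#: weak (< 0.7), strong (0.7-2) and very strong (> 2 decades).
_THRESHOLDS = (0.15, 0.7, 2.0)


def classify_shift(wt_value: float, mut_value: float, kind: str) -> str:
    """Classify a WT -> mutant change as an ordinal arrow category.

    ``kind`` is one of ``{"potency", "efficacy", "rate"}``.  Potency is
    passed as EC50 (any unit); its ratio is inverted so an up-arrow means
    the mutant is *more* potent.  Efficacy and rate changes use the plain
    mutant/WT ratio.
    """
    if not (wt_value > 0 and mut_value > 0):
        raise ValueError("values must be positive")
    if kind == "potency":
        fold = wt_value / mut_value
    elif kind in ("efficacy", "rate"):
        fold = mut_value / wt_value
    else:
        raise ValueError(f"unknown kind {kind!r}")
    magnitude = abs(math.log10(fold))
    if magnitude < _THRESHOLDS[0]:
        return "−"
    arrow = "↑" if fold > 1 else "↓"
    if magnitude < _THRESHOLDS[1]:
        return arrow
    if magnitude <= _THRESHOLDS[2]:
        return arrow * 2
    return arrow * 3
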