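"""Concentration-response normalization, logistic fitting and potency math.

Responses are normalized to the amplitude evoked by a maximally effective
concentration of the full agonist (dopamine) in the same cell, so the
fitted Top is a relative efficacy and Top = 1 identifies the full
agonist.  The curve model is the fixed-slope logistic

    Y = Top / (1 + 10**(logEC50 - X)),     X = log10([agonist] / M),

with bottom fixed at 0 and Hill slope fixed at 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .models import ConcentrationResponse


@dataclass(frozen=True)
class CRPoint:
    """One normalized concentration-response observation."""

    log10_concentration: float   # log10(molar)
    normalized_response: float   # dimensionless
    oocyte_id: int | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.normalized_response):
            raise ValueError("normalized_response must be finite")
        if not math.isfinite(self.log10_concentration):
            raise ValueError("log10_concentration must be finite")


@dataclass(frozen=True)
class SigmoidFit:
    """Fitted logistic concentration-response parameters."""

    pec50: float
    top: float
    pec50_sem: float
    top_sem: float
    n_points: int
    converged: bool
    reasons: tuple[str, ...] = ()

    @property
    def ec50(self) -> float:
        """EC50 in molar."""
        return ec50_from_pec50(self.pec50)


def normalize_to_reference(amplitudes, reference_amplitude: float) -> np.ndarray:
    """Divide response amplitudes by the reference-agonist amplitude."""
    if not reference_amplitude > 0:
        raise ValueError(
            f"reference amplitude must be positive, got {reference_amplitude}")
    return np.asarray(amplitudes, dtype=float) / float(reference_amplitude)


def fit_concentration_response(points: list[CRPoint]) -> SigmoidFit:
    """Fit the fixed-slope logistic to pooled concentration-response points.

    Points from different oocytes are fitted jointly; at least 3 distinct
    concentrations are required.  A flat response set is returned with
    ``converged=False`` (non-identifiable) rather than raising.
    """
    x = np.array([p.log10_concentration for p in points])
    y = np.array([p.normalized_response for p in points])
    model = ConcentrationResponse().fit(x, y)
    return SigmoidFit(pec50=model.pec50_, top=model.top_,
                      pec50_sem=model.pec50_sem_, top_sem=model.top_sem_,
                      n_points=model.n_points_, converged=model.converged_,
                      reasons=tuple(model.reasons_))


def ec50_from_pec50(pec50: float) -> float:
    """EC50 in molar from pEC50 = -log10(EC50)."""
    if not math.isfinite(pec50):
        raise ValueError("pec50 must be finite")
    return 10.0 ** (-pec50)


def potency_fold_change(pec50_a: float, pec50_b: float) -> float:
    """Fold difference in potency, ``10**(pEC50_a - pEC50_b)``.

    Greater than 1 when condition *a* is the more potent.
    """
    if not (math.isfinite(pec50_a) and math.isfinite(pec50_b)):
        raise ValueError("pEC50 inputs must be finite")
    return 10.0 ** (pec50_a - pec50_b)


def efficacy_fold_change(top_a: float, top_b: float) -> float:
    """Ratio of relative efficacies ``top_a / top_b``."""
    if not top_b > 0:
        raise ValueError(f"denominator efficacy must be positive, got {top_b}")
    return top_a / top_b
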