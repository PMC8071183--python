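"""Parameter containers for the receptor -> G protein -> GIRK cascade.

The simulated preparation is a *Xenopus* oocyte expressing a Gi/o-coupled
receptor (dopamine D2), the GIRK1/4 channel, and RGS4, voltage-clamped at
-80 mV in a 25 mM K+ bath.  Agonist binding is a two-state bimolecular
reaction; occupied receptors drive a single active-G-protein pool whose
decay is the RGS-accelerated GTP-hydrolysis rate; the channel opens
instantaneously as a Hill function of the active-G fraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace


@dataclass(frozen=True)
class LigandKinetics:
    """Binding kinetics and intrinsic efficacy of one agonist.

    Parameters
    ----------
    name : str
        Ligand label, e.g. ``"dopamine"``.
    k_on : float
        Association rate constant, M^-1 s^-1.
    k_off : float
        Dissociation rate constant, s^-1.  Residence time is ``1/k_off``.
    efficacy : float
        Intrinsic ability of the occupied receptor to activate G protein,
        dimensionless in [0, 1].  1 for a full agonist.
    """

    name: str
    k_on: float
    k_off: float
    efficacy: float = 1.0

    def __post_init__(self) -> None:
        if not (self.k_on > 0 and math.isfinite(self.k_on)):
            raise ValueError(f"k_on must be positive and finite, got {self.k_on}")
        if not (self.k_off > 0 and math.isfinite(self.k_off)):
            raise ValueError(f"k_off must be positive and finite, got {self.k_off}")
        if not 0.0 <= self.efficacy <= 1.0:
            raise ValueError(f"efficacy must lie in [0, 1], got {self.efficacy}")

    @property
    def true_kd(self) -> float:
        """Equilibrium dissociation constant k_off/k_on, molar."""
        return self.k_off / self.k_on

    @property
    def true_pkd(self) -> float:
        """-log10 of the equilibrium dissociation constant."""
        return -math.log10(self.true_kd)


@dataclass(frozen=True)
class CascadeParams:
    """Cascade and recording parameters of the simulated oocyte.

    Defaults describe a preparation where the GIRK readout tracks receptor
    occupancy closely: G-protein amplification is kept low
    (``g_act_rate * efficacy <= 0.1 * g_deact_rate``) and the channel gate
    operates in its linear range (active-G fraction well below
    ``girk_half``).  Under these conditions the washout current decay
    carries the agonist dissociation rate with a few-percent bias at most,
    and the concentration-response relationship is reserve-free
    (EC50 ~ Kd).  See docs/methods.md for the derivation.

    Attributes
    ----------
    g_act_rate : float
        G-protein activation rate per fully occupied receptor, s^-1.
    g_deact_rate : float
        GTP-hydrolysis (deactivation) rate of active G protein, s^-1;
        RGS4 co-expression puts this near the upper physiological range.
    girk_half : float
        Active-G fraction giving half-maximal channel opening, in (0, 1).
    girk_hill : float
        Hill coefficient of channel gating, >= 1.
    i_max : float
        Inward current magnitude if the whole GIRK pool opened,
        microamperes.  With the default low-amplification cascade the
        channel gate tops out near 3%% of the pool for a saturating full
        agonist, so the default yields a maximal dopamine-evoked current
        of ~1.6 uA, matching the scale of real recordings.
    i_basal : float
        Agonist-independent inward current magnitude, microamperes.
    exchange_tau : float
        Solution-exchange time constant around the oocyte, seconds.  The
        default 0.45 s corresponds to an exchange rate of ~2.2 s^-1, the
        slowest rate consistent with the measured bound of > 2 s^-1.
    noise_sd : float
        SD of additive white Gaussian recording noise, microamperes.
    rundown_rate : float
        Optional exponential decay rate of the evoked-current amplitude,
        s^-1 (0 disables rundown).
    sample_rate : float
        Acquisition rate, Hz.
    """

    g_act_rate: float = 1.5
    g_deact_rate: float = 50.0
    girk_half: float = 0.9
    girk_hill: float = 1.0
    i_max: float = 50.0
    i_basal: float = 0.2
    exchange_tau: float = 0.45
    noise_sd: float = 0.005
    rundown_rate: float = 0.0
    sample_rate: float = 156.0

    def __post_init__(self) -> None:
        for field in ("g_act_rate", "g_deact_rate", "i_max", "exchange_tau",
                      "sample_rate"):
            value = getattr(self, field)
            if not value > 0:
                raise ValueError(f"{field} must be strictly positive, got {value}")
        if not 0.0 < self.girk_half < 1.0:
            raise ValueError(f"girk_half must lie in (0, 1), got {self.girk_half}")
        if self.girk_hill < 1.0:
            raise ValueError(f"girk_hill must be >= 1, got {self.girk_hill}")
        if self.i_basal < 0:
            raise ValueError(f"i_basal must be >= 0, got {self.i_basal}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.rundown_rate < 0:
            raise ValueError(f"rundown_rate must be >= 0, got {self.rundown_rate}")

    def replace(self, **changes) -> "CascadeParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **changes)


def fast_reporter_params(**overrides) -> CascadeParams:
    """Cascade parameters of the fast-reporter validation regime.

    Identical to the defaults except that solution exchange is made much
    faster than any simulated residence time (``exchange_tau = 0.05 s``,
    at least 100x shorter than 1/k_off for every bundled ligand), so that
    trace kinetics are limited by binding rather than by perfusion.  Used
    for parameter-recovery validation; the default ``exchange_tau = 0.45``
    emulates the real perfusion system instead.
    """
    kwargs = {"exchange_tau": 0.05, "noise_sd": 0.005}
    kwargs.update(overrides)
    return CascadeParams(**kwargs)
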