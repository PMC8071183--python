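"""Forward model of the receptor -> G protein -> GIRK current cascade.

State variables are the fractional agonist occupancy ``RL``, the
competitive-antagonist occupancy ``RA`` (zero when no antagonist is
applied) and the active-G-protein fraction ``Ga``:

    dRL/dt = k_on * c_a(t) * (1 - RL - RA) - k_off * RL
    dRA/dt = b_on * c_b(t) * (1 - RL - RA) - b_off * RA
    dGa/dt = g_act * efficacy * RL * (1 - Ga) - g_deact * Ga

where ``c_a`` and ``c_b`` are the agonist and antagonist concentrations
at the oocyte surface after finite solution exchange.  The recorded
current magnitude is an instantaneous Hill function of ``Ga``:

    |I|(t) = i_basal + i_max * Ga^h / (Ga^h + girk_half^h)

optionally scaled by exponential rundown of the evoked component, then
sign-flipped to the inward-negative convention of a cell clamped at
-80 mV, with additive Gaussian recording noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .params import CascadeParams, LigandKinetics
from .protocol import PerfusionProtocol


class IntegrationError(RuntimeError):
    """Raised when the cascade ODE produces a non-finite state."""


@dataclass(frozen=True)
class SimulatedTrace:
    """A uniformly sampled voltage-clamp current trace plus its provenance.

    ``current`` is in microamperes, inward-negative.  ``time`` starts at 0
    with spacing ``1 / params.sample_rate``.
    """

    time: np.ndarray
    current: np.ndarray
    seed: int | None
    protocol: PerfusionProtocol
    params: CascadeParams
    ligand: LigandKinetics | None = None
    antagonist: LigandKinetics | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "time", np.asarray(self.time, dtype=float))
        object.__setattr__(self, "current", np.asarray(self.current, dtype=float))
        if len(self.time) != len(self.current):
            raise ValueError("time and current must have equal length")

    @property
    def sample_rate(self) -> float:
        return self.params.sample_rate

    @property
    def evoked(self) -> np.ndarray:
        """Evoked magnitude assuming the basal level has been subtracted."""
        return -self.current

    def with_current(self, current: np.ndarray) -> "SimulatedTrace":
        return SimulatedTrace(time=self.time, current=np.asarray(current, float),
                              seed=self.seed, protocol=self.protocol,
                              params=self.params, ligand=self.ligand,
                              antagonist=self.antagonist)

    def index_at(self, t: float) -> int:
        return int(np.searchsorted(self.time, t - 1e-12))


def _segment_profile(protocol, channel, exchange_tau):
    """Per-segment (start, target, c_at_start) for the exchange-filtered
    concentration, so the exact value is available inside the ODE RHS."""
    steps = protocol._channel(channel)
    bps = sorted({0.0, protocol.total_duration}
                 | {s.t_start for s in steps} | {s.t_end for s in steps})
    mids = np.asarray([0.5 * (a + b) for a, b in zip(bps, bps[1:])])
    targets = protocol.nominal_concentration(mids, channel)
    segs = []
    c = 0.0   # chamber starts in agonist-free buffer
    for (a, b), target in zip(zip(bps, bps[1:]), targets):
        segs.append((a, b, float(target), c))
        c = target + (c - target) * float(np.exp(-(b - a) / exchange_tau))
    return segs


def _integrate_states(ligand: LigandKinetics, params: CascadeParams,
                      protocol: PerfusionProtocol, t_grid: np.ndarray,
                      antagonist: LigandKinetics | None = None) -> np.ndarray:
    """Integrate (RL, RA, Ga) on ``t_grid``; returns array of shape (3, n)."""
    tau = params.exchange_tau
    seg_a = _segment_profile(protocol, "agonist", tau)
    seg_b = _segment_profile(protocol, "antagonist", tau)
    # Merge breakpoints of both channels so each integration piece is smooth.
    cuts = sorted({a for a, *_ in seg_a} | {a for a, *_ in seg_b}
                  | {protocol.total_duration})

    def segment_at(segs, t):
        for a, b, target, c0 in segs:
            if a <= t <= b:
                return a, target, c0
        a, b, target, c0 = segs[-1]
        return a, target, c0

    kon, koff = ligand.k_on, ligand.k_off
    if antagonist is not None:
        bon, boff = antagonist.k_on, antagonist.k_off
    else:
        bon = boff = 0.0
    g_act = params.g_act_rate * ligand.efficacy
    g_deact = params.g_deact_rate
    exp = np.exp

    out = np.empty((3, len(t_grid)))
    y = np.zeros(3)
    filled = 0
    if len(t_grid) and t_grid[0] == 0.0:
        out[:, 0] = y
        filled = 1
    for a, b in zip(cuts, cuts[1:]):
        mid = 0.5 * (a + b)
        sa, target_a, c0_a = segment_at(seg_a, mid)
        sb, target_b, c0_b = segment_at(seg_b, mid)

        def rhs(t, y, sa=sa, target_a=target_a, c0_a=c0_a,
                sb=sb, target_b=target_b, c0_b=c0_b):
            rl, ra, ga = y
            ca = target_a + (c0_a - target_a) * exp(-(t - sa) / tau)
            cb = target_b + (c0_b - target_b) * exp(-(t - sb) / tau)
            free = 1.0 - rl - ra
            return (kon * ca * free - koff * rl,
                    bon * cb * free - boff * ra,
                    g_act * rl * (1.0 - ga) - g_deact * ga)

        stop = int(np.searchsorted(t_grid, b, side="right"))
        t_eval = t_grid[filled:stop]
        if len(t_eval) and t_eval[-1] >= b:
            t_span_eval = t_eval
        else:
            t_span_eval = np.append(t_eval, b)
        sol = solve_ivp(rhs, (a, b), y, method="LSODA", rtol=1e-8, atol=1e-12,
                        t_eval=t_span_eval)
        if not sol.success or not np.all(np.isfinite(sol.y)):
            raise IntegrationError(
                "cascade integration failed between "
                f"t={a:.3f}s and t={b:.3f}s (ligand={ligand.name}, "
                f"k_on={kon:.3g}, k_off={koff:.3g}, exchange_tau={tau:.3g}); "
                f"solver message: {sol.message}")
        if len(t_eval):
            out[:, filled:stop] = sol.y[:, :len(t_eval)]
            filled = stop
        y = sol.y[:, -1]
    return out


def time_grid(params: CascadeParams, total_duration: float) -> np.ndarray:
    """Uniform acquisition grid covering ``[0, total_duration]``."""
    dt = 1.0 / params.sample_rate
    n = int(np.floor(total_duration / dt)) + 1
    return np.arange(n) * dt


def simulate_trace(ligand: LigandKinetics, params: CascadeParams,
                   protocol: PerfusionProtocol, seed: int | None = 0,
                   antagonist: LigandKinetics | None = None) -> SimulatedTrace:
    """Simulate one voltage-clamp current trace.

    Deterministic for a fixed seed; ``seed=None`` or ``noise_sd=0``
    disables recording noise.
    """
    t = time_grid(params, protocol.total_duration)
    states = _integrate_states(ligand, params, protocol, t, antagonist)
    ga = np.clip(states[2], 0.0, 1.0)
    h = params.girk_hill
    gate = ga ** h / (ga ** h + params.girk_half ** h)
    evoked = params.i_max * gate
    if params.rundown_rate > 0:
        evoked = evoked * np.exp(-params.rundown_rate * t)
    current = -(params.i_basal + evoked)
    if params.noise_sd > 0 and seed is not None:
        rng = np.random.default_rng(seed)
        current = current + rng.normal(0.0, params.noise_sd, size=len(t))
    return SimulatedTrace(time=t, current=current, seed=seed, protocol=protocol,
                          params=params, ligand=ligand, antagonist=antagonist)


def simulate_occupancy(ligand: LigandKinetics, protocol: PerfusionProtocol,
                       exchange_tau: float, t_grid,
                       antagonist: LigandKinetics | None = None) -> np.ndarray:
    """Fractional receptor occupancy RL(t) with the cascade bypassed.

    Reports the binding state directly (no G protein, channel, or noise),
    which is the oracle used to verify that the relaxation rate at
    constant concentration equals ``k_on * c + k_off``.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    params = CascadeParams(exchange_tau=exchange_tau, noise_sd=0.0)
    states = _integrate_states(ligand, params, protocol, t_grid, antagonist)
    return states[0]


# ---------------------------------------------------------------------------
# Closed-form steady states (used by tests and by the amplitude analysis)

def occupancy_ss(concentration: float, ligand: LigandKinetics) -> float:
    """Equilibrium occupancy ``c / (c + Kd)`` at constant concentration."""
    return concentration / (concentration + ligand.true_kd)


def active_g_ss(occupancy: float, ligand: LigandKinetics,
                params: CascadeParams) -> float:
    """Equilibrium active-G fraction at constant occupancy."""
    a = params.g_act_rate * ligand.efficacy * occupancy
    return a / (a + params.g_deact_rate)


def evoked_ss(concentration: float, ligand: LigandKinetics,
              params: CascadeParams) -> float:
    """Noise-free steady-state evoked current magnitude, microamperes."""
    ga = active_g_ss(occupancy_ss(concentration, ligand), ligand, params)
    h = params.girk_hill
    gate = ga ** h / (ga ** h + params.girk_half ** h)
    return params.i_max * gate
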