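"""Perfusion protocols and finite solution-exchange kinetics.

A protocol is an ordered sequence of timed bath applications (ligand,
concentration); a separate channel carries a competitive antagonist.
Because the oocyte sits in a perfusion chamber, the concentration it
actually sees relaxes exponentially toward each commanded step with the
solution-exchange time constant, which sets the temporal resolution
floor of the assay.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

BUFFER = "buffer"


class ProtocolError(ValueError):
    """Raised for ill-formed perfusion protocols."""


@dataclass(frozen=True)
class ProtocolStep:
    """One timed application: ``ligand`` at ``concentration`` on [t_start, t_end)."""

    t_start: float
    t_end: float
    ligand: str
    concentration: float

    def __post_init__(self) -> None:
        if not self.t_end > self.t_start:
            raise ProtocolError(
                f"step end {self.t_end} must exceed start {self.t_start}")
        if self.concentration < 0:
            raise ProtocolError(
                f"concentration must be >= 0, got {self.concentration}")

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


def _validate_channel(steps: tuple[ProtocolStep, ...], label: str) -> None:
    for a, b in zip(steps, steps[1:]):
        if b.t_start < a.t_start:
            raise ProtocolError(f"{label} steps must be sorted by start time")
        if b.t_start < a.t_end:
            raise ProtocolError(
                f"{label} steps overlap: [{a.t_start}, {a.t_end}) and "
                f"[{b.t_start}, {b.t_end})")


@dataclass(frozen=True)
class PerfusionProtocol:
    """Timed solution applications for one recording.

    ``steps`` carries the agonist channel, ``antagonist_steps`` a
    competitive blocker.  Steps within a channel must be sorted and
    non-overlapping; periods not covered by any step are agonist-free
    buffer.
    """

    steps: tuple[ProtocolStep, ...]
    total_duration: float
    antagonist_steps: tuple[ProtocolStep, ...] = field(default=())

    def __post_init__(self) -> None:
        object.__setattr__(self, "steps", tuple(self.steps))
        object.__setattr__(self, "antagonist_steps", tuple(self.antagonist_steps))
        _validate_channel(self.steps, "agonist")
        _validate_channel(self.antagonist_steps, "antagonist")
        latest = max((s.t_end for s in self.steps + self.antagonist_steps),
                     default=0.0)
        if self.total_duration < latest:
            raise ProtocolError(
                f"total_duration {self.total_duration} shorter than last "
                f"step end {latest}")

    def _channel(self, channel: str) -> tuple[ProtocolStep, ...]:
        if channel == "agonist":
            return self.steps
        if channel == "antagonist":
            return self.antagonist_steps
        raise ValueError(f"unknown channel {channel!r}")

    def nominal_concentration(self, t, channel: str = "agonist") -> np.ndarray:
        """Commanded concentration at times ``t`` (steps left-closed)."""
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        for step in self._channel(channel):
            out[(t >= step.t_start) & (t < step.t_end)] = step.concentration
        return out

    def buffer_windows(self, channel: str = "agonist") -> list[tuple[float, float]]:
        """Maximal intervals with no application on ``channel``."""
        windows, cursor = [], 0.0
        for step in self._channel(channel):
            if step.t_start > cursor:
                windows.append((cursor, step.t_start))
            cursor = max(cursor, step.t_end)
        if self.total_duration > cursor:
            windows.append((cursor, self.total_duration))
        return windows


def effective_concentration(protocol: PerfusionProtocol, exchange_tau: float,
                            t_grid, channel: str = "agonist") -> np.ndarray:
    """Concentration at the oocyte surface under finite solution exchange.

    Solves ``dc/dt = (c_applied(t) - c) / exchange_tau`` exactly, piecewise
    per protocol segment (the commanded concentration is piecewise
    constant, so within each segment the solution is a single exponential
    approach to the segment's nominal value).  The chamber starts
    equilibrated in agonist-free buffer, ``c(0) = 0``.

    Parameters
    ----------
    exchange_tau : float
        Solution-exchange time constant, s; must be > 0.
    t_grid : array-like
        Sorted evaluation times within ``[0, total_duration]``.
    """
    if not exchange_tau > 0:
        raise ValueError(f"exchange_tau must be > 0, got {exchange_tau}")
    t_grid = np.asarray(t_grid, dtype=float)
    steps = protocol._channel(channel)

    breakpoints = sorted({0.0, protocol.total_duration}
                         | {s.t_start for s in steps}
                         | {s.t_end for s in steps})
    breakpoints = [b for b in breakpoints if 0.0 <= b <= protocol.total_duration]

    out = np.empty_like(t_grid)
    midpoints = np.asarray(
        [0.5 * (a + b) for a, b in zip(breakpoints, breakpoints[1:])])
    targets = protocol.nominal_concentration(midpoints, channel)

    c_start = 0.0   # chamber equilibrated in agonist-free buffer at t = 0
    # Grid points exactly on a boundary belong to the *starting* segment,
    # where the continuous solution equals the previous segment's endpoint.
    seg_index = np.clip(np.searchsorted(breakpoints, t_grid, side="right") - 1,
                        0, len(midpoints) - 1)
    for i, (a, b) in enumerate(zip(breakpoints, breakpoints[1:])):
        mask = seg_index == i
        if mask.any():
            dt = t_grid[mask] - a
            out[mask] = targets[i] + (c_start - targets[i]) * np.exp(-dt / exchange_tau)
        c_start = targets[i] + (c_start - targets[i]) * np.exp(-(b - a) / exchange_tau)
    return out


def make_protocol(kind: str, ligand_name: str, concentrations, **options
                  ) -> PerfusionProtocol:
    """Build one of the four standard experimental protocol shapes.

    Parameters
    ----------
    kind : {"staircase", "washout", "activation", "antagonist_chase"}
        * ``staircase`` -- concentration-response design: a buffer
          stabilization period (default 60 s) followed by back-to-back
          60-s applications of increasing concentrations.
        * ``washout`` -- dissociation design: a single short application
          (default 13 s) of one concentration, then buffer for a long
          tail (default 120 s) during which the response decays.
        * ``activation`` -- association design: one sustained application
          (default 60 s) of one concentration.
        * ``antagonist_chase`` -- the agonist response is terminated by
          co-applying a competitive antagonist in the continued presence
          of agonist; the agonist step spans the antagonist step.
    ligand_name : str
        Agonist label recorded on the steps.
    concentrations : sequence of float
        Molar concentrations; one per staircase step, exactly one for
        the other designs.

    Options
    -------
    pre_s : float
        Buffer stabilization before the first application (default 60 for
        staircase, 10 otherwise).
    step_s, app_s, tail_s : float
        Application and trailing-buffer durations (see above defaults).
    chase_delay_s, antagonist_name, antagonist_concentration :
        antagonist_chase only; the blocker is applied from
        ``pre_s + chase_delay_s`` (default delay 30 s) to the end.
    """
    concentrations = [float(c) for c in concentrations]
    if not concentrations:
        raise ProtocolError("at least one concentration is required")

    if kind == "staircase":
        if any(b <= a for a, b in zip(concentrations, concentrations[1:])):
            raise ProtocolError("staircase concentrations must be increasing")
        pre = float(options.pop("pre_s", 60.0))
        step_s = float(options.pop("step_s", 60.0))
        tail = float(options.pop("tail_s", 0.0))
        steps = tuple(
            ProtocolStep(pre + i * step_s, pre + (i + 1) * step_s, ligand_name, c)
            for i, c in enumerate(concentrations))
        total = pre + step_s * len(concentrations) + tail
        antagonist_steps = ()
    elif kind == "washout":
        (conc,) = concentrations
        pre = float(options.pop("pre_s", 10.0))
        app_s = float(options.pop("app_s", 13.0))
        tail = float(options.pop("tail_s", 120.0))
        steps = (ProtocolStep(pre, pre + app_s, ligand_name, conc),)
        total = pre + app_s + tail
        antagonist_steps = ()
    elif kind == "activation":
        (conc,) = concentrations
        pre = float(options.pop("pre_s", 10.0))
        app_s = float(options.pop("app_s", 60.0))
        tail = float(options.pop("tail_s", 10.0))
        steps = (ProtocolStep(pre, pre + app_s, ligand_name, conc),)
        total = pre + app_s + tail
        antagonist_steps = ()
    elif kind == "antagonist_chase":
        (conc,) = concentrations
        pre = float(options.pop("pre_s", 10.0))
        app_s = float(options.pop("app_s", 120.0))
        delay = float(options.pop("chase_delay_s", 30.0))
        ant_name = options.pop("antagonist_name", "antagonist")
        ant_conc = float(options.pop("antagonist_concentration", 1e-6))
        if not 0.0 < delay < app_s:
            raise ProtocolError("chase_delay_s must fall inside the agonist step")
        total = pre + app_s
        steps = (ProtocolStep(pre, total, ligand_name, conc),)
        antagonist_steps = (ProtocolStep(pre + delay, total, ant_name, ant_conc),)
    else:
        raise ProtocolError(f"unknown protocol kind {kind!r}")

    if options:
        raise TypeError(f"unknown options for {kind}: {sorted(options)}")
    return PerfusionProtocol(steps=steps, total_duration=total,
                             antagonist_steps=antagonist_steps)
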