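"""Amplitude and time-constant extraction from current traces.

All operations work on the evoked current magnitude: traces are
baseline-subtracted so the agonist-independent holding current is removed
and the response is referenced to zero, then activation and deactivation
segments are fitted with single exponentials.  The deactivation time
constant estimates the agonist residence time (k_off = 1/tau_deact) and
the activation rate k_obs = 1/tau_act feeds the k_on regression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d

from .models import MonoExponential
from .protocol import ProtocolStep
from .simulate import SimulatedTrace


@dataclass(frozen=True)
class ExpFitResult:
    """A monoexponential fit ``y = offset + amplitude * exp(-(t-t0)/tau)``."""

    tau: float                 # seconds
    amplitude: float           # microamperes (evoked-magnitude scale)
    offset: float              # microamperes
    rmse: float                # microamperes
    window: tuple[float, float]
    converged: bool
    tau_stderr: float = float("nan")
    reasons: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.tau > 0:
            raise ValueError(f"tau must be positive, got {self.tau}")
        if not self.window[1] > self.window[0]:
            raise ValueError(f"empty fit window {self.window}")
        if self.rmse < 0:
            raise ValueError("rmse must be >= 0")

    @property
    def rate(self) -> float:
        """Relaxation rate 1/tau, s^-1."""
        return 1.0 / self.tau


@dataclass(frozen=True)
class QCResult:
    """Outcome of trace quality control; ``passed`` iff ``reasons`` empty."""

    passed: bool
    reasons: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.passed != (len(self.reasons) == 0):
            raise ValueError("passed must be equivalent to an empty reason list")


def _result_from_model(model: MonoExponential) -> ExpFitResult:
    return ExpFitResult(tau=model.tau_, amplitude=model.amplitude_,
                        offset=model.offset_, rmse=model.rmse_,
                        window=model.window_, converged=model.converged_,
                        tau_stderr=model.tau_stderr_,
                        reasons=tuple(model.reasons_))


def subtract_basal(trace: SimulatedTrace,
                   baseline_window: tuple[float, float]) -> SimulatedTrace:
    """Remove the agonist-independent current.

    Subtracts the mean current over ``baseline_window`` (which must lie
    inside the trace and in a buffer-only period of the protocol) so the
    evoked response is referenced to zero.
    """
    t0, t1 = baseline_window
    if not (t1 > t0):
        raise ValueError(f"empty baseline window {baseline_window}")
    if t0 < trace.time[0] or t1 > trace.time[-1]:
        raise ValueError(f"baseline window {baseline_window} outside trace "
                         f"[{trace.time[0]}, {trace.time[-1]}]")
    for step in trace.protocol.steps + trace.protocol.antagonist_steps:
        if step.concentration > 0 and t0 < step.t_end and step.t_start < t1:
            raise ValueError(
                f"baseline window {baseline_window} overlaps the "
                f"{step.ligand} application [{step.t_start}, {step.t_end})")
    mask = (trace.time >= t0) & (trace.time <= t1)
    return trace.with_current(trace.current - trace.current[mask].mean())


def response_amplitude(trace: SimulatedTrace, step: ProtocolStep,
                       eval_s: float = 1.0) -> float:
    """Steady-state evoked magnitude of one application step.

    Returns the mean evoked magnitude (positive microamperes) over the
    final ``eval_s`` seconds of the step, by which time a steady-state
    response is assumed; the trace must be baseline-subtracted.
    """
    if step.duration < eval_s:
        raise ValueError(
            f"step of {step.duration:.3g}s is shorter than the "
            f"{eval_s:.3g}-s evaluation window")
    mask = (trace.time >= step.t_end - eval_s) & (trace.time <= step.t_end)
    return float(trace.evoked[mask].mean())


def fit_deactivation(trace: SimulatedTrace, washout_start: float,
                     window_s: float, fix_offset: bool = False) -> ExpFitResult:
    """Fit the post-washout decay with a single exponential.

    The fit covers ``[washout_start, washout_start + window_s]`` on the
    evoked magnitude of a baseline-subtracted trace; ``1/tau`` estimates
    the dissociation rate constant.  The offset is free by default
    (``fix_offset=True`` anchors the decay at zero).
    """
    t1 = washout_start + window_s
    if washout_start < trace.time[0] or t1 > trace.time[-1] + 1e-9:
        raise ValueError(
            f"fit window [{washout_start}, {t1}] outside trace span "
            f"[{trace.time[0]}, {trace.time[-1]}]")
    mask = (trace.time >= washout_start) & (trace.time <= t1)
    model = MonoExponential(t0=washout_start, fix_offset=fix_offset)
    model.fit(trace.time[mask], trace.evoked[mask])
    return _result_from_model(model)


def fit_activation(trace: SimulatedTrace, app_start: float,
                   rise_fraction: float = 0.8,
                   plateau_fraction: float = 0.1,
                   fix_offset: bool = False) -> ExpFitResult:
    """Fit the current rise after agonist application.

    The fit window runs from ``app_start`` to the first time the evoked
    magnitude covers ``rise_fraction`` of the increase from its starting
    level to the plateau, where the plateau is the mean over the final
    ``plateau_fraction`` of the application step.  The starting level is
    the mean over the second preceding ``app_start`` and the crossing is
    located on a 0.5-s smoothed copy of the trace, so window selection is
    robust to recording noise; the exponential itself is fitted to the
    raw samples.  The observed activation rate is ``k_obs = 1/tau`` of
    the fitted exponential.
    """
    if not 0.0 < rise_fraction < 1.0:
        raise ValueError("rise_fraction must lie in (0, 1)")
    step = _step_at(trace, app_start)
    t, y = trace.time, trace.evoked

    tail_start = step.t_end - plateau_fraction * step.duration
    tail = y[(t >= tail_start) & (t <= step.t_end)]
    plateau = float(tail.mean())
    i0 = trace.index_at(app_start)
    pre = y[(t >= app_start - 1.0) & (t <= app_start)]
    start_level = float(pre.mean()) if len(pre) else float(y[i0])
    increase = plateau - start_level
    if increase <= 0:
        raise ValueError("no current increase during the application step; "
                         "apply the agonist for longer or at a higher "
                         "concentration")
    # The response must actually have plateaued: the final-window mean may
    # not still be climbing relative to the preceding window by more than
    # 5% of the increase (or noise, whichever is larger).
    prev = y[(t >= tail_start - plateau_fraction * step.duration)
             & (t < tail_start)]
    noise_floor = 5.0 * np.sqrt(2.0) * float(tail.std()) / np.sqrt(len(tail))
    if plateau - float(prev.mean()) > max(0.05 * increase, noise_floor):
        raise ValueError(
            "response is still rising at the end of the application step; "
            "use a longer application")
    threshold = start_level + rise_fraction * increase
    width = max(1, int(round(0.5 * trace.sample_rate)))
    smooth = uniform_filter1d(y, size=width, mode="nearest")
    in_step = np.flatnonzero((t >= app_start) & (t <= step.t_end)
                             & (smooth >= threshold))
    if len(in_step) == 0:
        raise ValueError(
            f"response did not cover {rise_fraction:.0%} of its increase "
            "within the application step; use a longer application")
    end = max(t[in_step[0]], t[min(i0 + 8, len(t) - 1)])
    mask = (t >= app_start) & (t <= end)
    model = MonoExponential(t0=app_start, fix_offset=fix_offset)
    model.fit(t[mask], y[mask])
    return _result_from_model(model)


def _step_at(trace: SimulatedTrace, app_start: float) -> ProtocolStep:
    for step in trace.protocol.steps:
        if step.t_start - 1e-9 <= app_start < step.t_end:
            return step
    raise ValueError(f"no agonist application step begins at t={app_start}s")


def peak_normalize_and_average(traces: list[SimulatedTrace],
                               align_time: float = 0.0) -> SimulatedTrace:
    """Scale each trace to unit peak evoked magnitude and average pointwise.

    Traces must be baseline-subtracted and share a common sample grid; the
    returned time axis is rebased so that ``align_time`` maps to zero.
    """
    if not traces:
        raise ValueError("need at least one trace")
    n = min(len(tr.time) for tr in traces)
    dt0 = np.diff(traces[0].time[:2])[0]
    for tr in traces:
        if abs(np.diff(tr.time[:2])[0] - dt0) > 1e-12:
            raise ValueError("traces have mismatched sample grids")
    scaled = []
    for tr in traces:
        peak = np.max(tr.evoked[:n])
        if peak <= 0:
            raise ValueError("cannot peak-normalize a trace with no evoked "
                             "response")
        scaled.append(tr.evoked[:n] / peak)
    mean_evoked = np.mean(scaled, axis=0)
    first = traces[0]
    return SimulatedTrace(time=first.time[:n] - align_time,
                          current=-mean_evoked, seed=first.seed,
                          protocol=first.protocol, params=first.params,
                          ligand=first.ligand, antagonist=first.antagonist)


def qc_trace(trace: SimulatedTrace, basal_limit: float = 0.5) -> QCResult:
    """Screen a trace the way oocytes are screened before analysis.

    Fails traces whose basal (pre-application) current magnitude exceeds
    ``basal_limit`` microamperes or that contain non-finite samples.
    Never raises.
    """
    reasons: list[str] = []
    if not np.all(np.isfinite(trace.current)):
        reasons.append("trace contains non-finite samples")
    else:
        windows = trace.protocol.buffer_windows()
        if windows and windows[0][0] == 0.0 and windows[0][1] > 0:
            t0, t1 = windows[0]
        else:
            t0, t1 = trace.time[0], min(trace.time[0] + 1.0, trace.time[-1])
        mask = (trace.time >= t0) & (trace.time <= t1)
        basal = abs(float(trace.current[mask].mean()))
        if basal > basal_limit:
            reasons.append(f"basal current exceeds limit "
                           f"({basal:.3g} > {basal_limit:.3g} uA)")
    return QCResult(passed=not reasons, reasons=tuple(reasons))
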