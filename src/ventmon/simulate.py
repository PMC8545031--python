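"""Synthetic pressure-cycled ventilator waveforms with ground truth.

A pressure-cycled pneumatic ventilator switches from inspiration to
exhalation when airway pressure reaches the PIP dial setting, and back
when it falls to PEEP (mechanically fixed at PIP divided by the nominal
ratio of the device, typically around 2.4).  The resulting waveform is a
concave exponential rise from PEEP to PIP followed by an exponential
decay back to PEEP, repeating once per breath.

The generator here reproduces that shape without modeling lung
mechanics: each breath cycle is an exponential approach toward a virtual
target above PIP, rescaled so the trace touches PIP exactly at the end
of inspiration, then an exponential decay rescaled to touch PEEP exactly
at the end of the cycle.  Cycle boundaries are laid out on the sample
grid so the mean period is exactly ``60/rr_set`` seconds.  Scheduled
events superimpose the failure modes a monitor must detect: circuit
disconnects (full or partial), obstruction, dial changes, spontaneous
patient breaths, and small noncycling oscillations.

Every trace is annotated with its per-breath ground truth, so parameter
recovery and alarm timing can be tested without recorded data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

import numpy as np
import pandas as pd

from .envelope import DEFAULT_R_NOM

__all__ = [
    "EventKind",
    "SimEvent",
    "WaveformSpec",
    "AnnotatedTrace",
    "generate",
    "decimate",
    "square_cycling",
]


class EventKind(str, Enum):
    DISCONNECT_ATMOSPHERE = "disconnect_atmosphere"
    DISCONNECT_PARTIAL = "disconnect_partial"
    OBSTRUCTION_HIGH = "obstruction_high"
    DIAL_CHANGE = "dial_change"
    SPONTANEOUS_BREATH = "spontaneous_breath"
    SMALL_OSCILLATION = "small_oscillation"


@dataclass(frozen=True)
class SimEvent:
    """A scheduled departure from normal cycling.

    ``params`` are kind-specific:

    disconnect_atmosphere
        ``residual`` (cm H2O, default 0): pressure after the circuit
        opens to atmosphere.
    disconnect_partial
        ``hold`` (default PEEP): constant pressure after a partial
        disconnect — cycling stops but some pressure remains.
    obstruction_high
        ``hold`` (default PIP), ``dip_pressure`` (default 0.5),
        ``dip_duration`` (s, default 0.3): a momentary drop followed by
        a steady high pressure.
    dial_change
        ``new_pip`` (required), ``ramp_s`` (default one cycle period;
        0 for an instantaneous step): the PIP dial is turned, PEEP
        following mechanically at PIP divided by the nominal ratio.
    spontaneous_breath
        ``dip_to`` (default 0.5), ``duration`` (s, default 0.6): the
        patient pulls pressure below PEEP toward atmosphere, then
        cycling resumes.
    small_oscillation
        ``level`` (default midway PIP/PEEP), ``amplitude`` (default 1),
        ``freq_hz`` (default the set breath rate): cycling is replaced
        by a low-amplitude sinusoid — attack events keep occurring but
        no real breaths do.
    """

    kind: EventKind
    start: float  # seconds
    params: dict = field(default_factory=dict)


@dataclass(frozen=True)
class WaveformSpec:
    """Ground-truth parameters of a synthetic ventilator trace.

    ``peep_set`` defaults to ``pip_set / r_nom`` (the pneumatic design
    fixes the PIP-to-PEEP ratio).  ``tau_insp``/``tau_exp`` are shape
    time-constants of the exponential rise and decay; by default they
    are derived from the phase durations (a quarter of the inspiratory
    time, a third of the expiratory time), giving the familiar rounded
    peak and near-complete decay.
    """

    pip_set: float = 24.0  # cm H2O
    rr_set: float = 20.0  # breaths/min
    peep_set: Optional[float] = None  # cm H2O; default pip_set / r_nom
    r_nom: float = DEFAULT_R_NOM
    inspiratory_fraction: float = 1.0 / 3.0
    tau_insp: Optional[float] = None  # s
    tau_exp: Optional[float] = None  # s
    fs: float = 100.0  # samples/s
    duration: float = 60.0  # s
    noise_sd: float = 0.0  # cm H2O
    seed: int = 0
    events: tuple[SimEvent, ...] = ()

    def __post_init__(self) -> None:
        if self.pip_set <= 0:
            raise ValueError(f"pip_set must be positive, got {self.pip_set}")
        if self.peep_set is not None and not (0 < self.peep_set < self.pip_set):
            raise ValueError(
                f"peep_set must satisfy 0 < peep_set < pip_set, got {self.peep_set}"
            )
        if self.rr_set <= 0:
            raise ValueError(f"rr_set must be positive, got {self.rr_set}")
        if not (0.0 < self.inspiratory_fraction < 1.0):
            raise ValueError(
                f"inspiratory_fraction must be in (0, 1), got {self.inspiratory_fraction}"
            )
        for name in ("tau_insp", "tau_exp"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if self.duration <= 0:
            raise ValueError(f"duration must be positive, got {self.duration}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        for ev in self.events:
            if not (0.0 <= ev.start <= self.duration):
                raise ValueError(
                    f"event {ev.kind.value} start {ev.start}s outside [0, {self.duration}]s"
                )

    @property
    def peep(self) -> float:
        return self.peep_set if self.peep_set is not None else self.pip_set / self.r_nom

    @property
    def period_s(self) -> float:
        return 60.0 / self.rr_set


@dataclass
class AnnotatedTrace:
    """A generated pressure trace with its ground truth.

    truth:
        One row per generated breath cycle: start/peak times (s), the
        true PIP/PEEP of that cycle, its period (s), and whether the
        cycle was left untouched by any scheduled event (``clean``).
    event_windows:
        ``(event kind, start_s, end_s)`` intervals during which the base
        dynamics were overridden.
    """

    pressure: np.ndarray
    fs: float
    spec: WaveformSpec
    truth: pd.DataFrame
    event_windows: list[tuple[EventKind, float, float]] = field(default_factory=list)

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.pressure.size) / self.fs

    @property
    def duration(self) -> float:
        return self.pressure.size / self.fs


def _phase_shape_rise(n: int, tau_samples: float) -> np.ndarray:
    """Exponential approach 0 -> 1 over n samples, hitting 1 exactly."""
    k = np.arange(1, n + 1)
    g = -np.expm1(-k / tau_samples)  # 1 - exp(-k/tau)
    return g / g[-1]


def _phase_shape_fall(n: int, tau_samples: float) -> np.ndarray:
    """Exponential decay 1 -> 0 over n samples, hitting 0 exactly at k=n."""
    k = np.arange(1, n + 1)
    g = np.exp(-k / tau_samples) - math.exp(-n / tau_samples)
    return g / (1.0 - math.exp(-n / tau_samples))


def generate(spec: WaveformSpec) -> AnnotatedTrace:
    """Generate an annotated synthetic trace (deterministic given seed)."""
    fs = spec.fs
    n_total = int(round(spec.duration * fs))
    peep0, pip0 = spec.peep, spec.pip_set
    period = spec.period_s * fs  # samples, possibly fractional

    dial = next(
        (ev for ev in spec.events if ev.kind is EventKind.DIAL_CHANGE), None
    )
    if dial is not None and "new_pip" not in dial.params:
        raise ValueError("dial_change event requires a 'new_pip' parameter")

    def dial_pip(t_s: float) -> float:
        """PIP setting at time t, ramped through any dial_change event."""
        if dial is None or t_s <= dial.start:
            return pip0
        new_pip = float(dial.params["new_pip"])
        ramp = float(dial.params.get("ramp_s", spec.period_s))
        if ramp <= 0 or t_s >= dial.start + ramp:
            return new_pip
        frac = (t_s - dial.start) / ramp
        return pip0 + frac * (new_pip - pip0)

    pressure = np.empty(n_total)
    truth_rows: list[dict] = []
    cycle = 0
    pos = 0
    while pos < n_total:
        c_start = int(round(cycle * period))
        c_end = int(round((cycle + 1) * period))
        n_cycle = c_end - c_start
        n_insp = max(1, int(round(spec.inspiratory_fraction * n_cycle)))
        n_exp = max(1, n_cycle - n_insp)
        pip_c = dial_pip(c_start / fs)
        peep_c = pip_c / (pip0 / peep0)  # PEEP follows the dial mechanically
        tau_i = spec.tau_insp if spec.tau_insp is not None else (n_insp / fs) / 4.0
        tau_e = spec.tau_exp if spec.tau_exp is not None else (n_exp / fs) / 3.0
        rise = peep_c + (pip_c - peep_c) * _phase_shape_rise(n_insp, tau_i * fs)
        fall = peep_c + (pip_c - peep_c) * _phase_shape_fall(n_exp, tau_e * fs)
        seg = np.concatenate([rise, fall])[: n_total - c_start]
        pressure[c_start : c_start + seg.size] = seg
        truth_rows.append(
            {
                "cycle": cycle,
                "start_s": c_start / fs,
                "peak_s": (c_start + n_insp - 1) / fs,  # sample that touches PIP
                "pip": pip_c,
                "peep": peep_c,
                "period_s": n_cycle / fs,
                "clean": True,
            }
        )
        pos = c_start + n_cycle
        cycle += 1
    # First sample starts at baseline PEEP (beginning of the first rise).
    pressure[0] = peep0

    truth = pd.DataFrame(truth_rows)
    event_windows: list[tuple[EventKind, float, float]] = []

    for ev in sorted(spec.events, key=lambda e: e.start):
        i0 = int(round(ev.start * fs))
        i0 = min(max(i0, 0), n_total)
        p = ev.params
        if ev.kind is EventKind.DISCONNECT_ATMOSPHERE:
            pressure[i0:] = float(p.get("residual", 0.0))
            end = spec.duration
        elif ev.kind is EventKind.DISCONNECT_PARTIAL:
            pressure[i0:] = float(p.get("hold", peep0))
            end = spec.duration
        elif ev.kind is EventKind.OBSTRUCTION_HIGH:
            dip_n = int(round(float(p.get("dip_duration", 0.3)) * fs))
            pressure[i0 : i0 + dip_n] = float(p.get("dip_pressure", 0.5))
            pressure[i0 + dip_n :] = float(p.get("hold", pip0))
            end = spec.duration
        elif ev.kind is EventKind.SPONTANEOUS_BREATH:
            dur = float(p.get("duration", 0.6))
            dip_to = float(p.get("dip_to", 0.5))
            n_ev = min(int(round(dur * fs)), n_total - i0)
            k = np.arange(n_ev)
            shape = np.sin(np.pi * k / max(n_ev - 1, 1)) ** 2
            base = pressure[i0 : i0 + n_ev]
            pressure[i0 : i0 + n_ev] = np.maximum(base - (base - dip_to) * shape, 0.0)
            end = ev.start + dur
        elif ev.kind is EventKind.SMALL_OSCILLATION:
            level = float(p.get("level", 0.5 * (pip0 + peep0)))
            amp = float(p.get("amplitude", 1.0))
            freq = float(p.get("freq_hz", spec.rr_set / 60.0))
            k = np.arange(n_total - i0)
            pressure[i0:] = level + amp * np.sin(2.0 * np.pi * freq * k / fs)
            end = spec.duration
        elif ev.kind is EventKind.DIAL_CHANGE:
            # Already folded into the cycle synthesis above.
            end = ev.start + float(p.get("ramp_s", spec.period_s))
        else:  # pragma: no cover - exhaustive enum
            raise ValueError(f"unknown event kind {ev.kind!r}")
        event_windows.append((ev.kind, ev.start, min(end, spec.duration)))
        if not truth.empty:
            overlapped = (truth["start_s"] + truth["period_s"] > ev.start) & (
                truth["start_s"] < event_windows[-1][2]
            )
            truth.loc[overlapped, "clean"] = False

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        pressure = pressure + rng.normal(0.0, spec.noise_sd, size=n_total)

    return AnnotatedTrace(
        pressure=pressure, fs=fs, spec=spec, truth=truth, event_windows=event_windows
    )


def decimate(trace: AnnotatedTrace, factor: int) -> AnnotatedTrace:
    """Keep every ``factor``-th sample, dividing the sample rate.

    Used to study how estimation accuracy degrades at lower sample
    rates.  Ground-truth annotations are expressed in seconds, so they
    carry over unchanged.
    """
    if factor < 1 or int(factor) != factor:
        raise ValueError(f"factor must be a positive integer, got {factor}")
    factor = int(factor)
    if factor == 1:
        return trace
    return AnnotatedTrace(
        pressure=trace.pressure[::factor].copy(),
        fs=trace.fs / factor,
        spec=trace.spec,
        truth=trace.truth.copy(),
        event_windows=list(trace.event_windows),
    )


def square_cycling(
    pip: float,
    peep: float,
    samples_per_phase: int,
    n_cycles: int,
    fs: float = 100.0,
    start_phase_high: bool = True,
) -> np.ndarray:
    """Idealized square-wave cycling between PIP and PEEP plateaus.

    The plateau dwell lets each envelope converge to the plateau value
    to machine precision, which makes this the reference input for the
    analytic release-calibration checks (an instantaneous drop from an
    envelope *exactly* at PIP).
    """
    if samples_per_phase < 1 or n_cycles < 1:
        raise ValueError("samples_per_phase and n_cycles must be >= 1")
    high = np.full(samples_per_phase, float(pip))
    low = np.full(samples_per_phase, float(peep))
    cycle = np.concatenate([high, low] if start_phase_high else [low, high])
    return np.tile(cycle, n_cycles)
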