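"""Single-pass breath monitoring: state machine and PIP/PEEP/RR estimation.

Breath cycles are inferred from *attack events* on the two envelope
trackers: a run of high-tracker attacks marks inspiration, a run of
low-tracker attacks marks exhalation.  The monitor toggles a binary
inhaling/exhaling state on the first attack of the opposite tracker and,
once per breath cycle, updates exponentially smoothed estimates of

* PIP  — the most recent high-tracker attack value at the inhale→exhale
  transition,
* PEEP — the most recent low-tracker attack value at the exhale→inhale
  transition,
* the breath period (samples between successive high peaks), from which
  the respiratory rate RR = 60*fs/period is derived.

Everything is computed in a single forward pass with O(1) state, so the
same code path serves both batch analysis of recorded traces and
sample-at-a-time streaming.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .envelope import (
    Direction,
    EnvelopeState,
    SignalQualityError,
    TrackerCoefficients,
    update_envelope,
)

__all__ = [
    "BreathState",
    "Transition",
    "MonitorConfig",
    "BreathMetrics",
    "MonitorState",
    "init_monitor",
    "step",
    "exponential_smooth",
    "respiratory_rate",
    "run_monitor",
    "MonitorResult",
]

#: Smoothing weight for the per-breath metric updates.
DEFAULT_ALPHA_SMOOTH = 0.5


class BreathState(str, Enum):
    INHALING = "inhaling"
    EXHALING = "exhaling"


class Transition(str, Enum):
    TO_INHALE = "to_inhale"
    TO_EXHALE = "to_exhale"


@dataclass(frozen=True)
class MonitorConfig:
    """Sample rate, tracker coefficients and display conventions.

    ``display_resolution_pressure`` / ``display_resolution_rr`` quantize
    the *displayed* metrics only; alarm comparisons always use the
    unrounded smoothed values.
    """

    fs: float
    coefficients: TrackerCoefficients
    alpha_smooth: float = DEFAULT_ALPHA_SMOOTH
    display_resolution_pressure: float = 1.0
    display_resolution_rr: float = 1.0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if not (0.0 <= self.alpha_smooth < 1.0):
            raise ValueError(f"alpha_smooth must be in [0, 1), got {self.alpha_smooth}")

    @classmethod
    def default(cls, fs: float = 100.0, alpha_attack: Optional[float] = None) -> "MonitorConfig":
        """Config with both tracker coefficients calibrated at ``fs``.

        The attack weight defaults to the value realizing the standard
        ~100 ms attack memory at ``fs`` (0.9 at 100 samples/s); the
        release weight comes from the ratio/timeout alarm alignment.
        """
        return cls(fs=fs, coefficients=TrackerCoefficients.calibrated(fs, alpha_attack=alpha_attack))


@dataclass
class BreathMetrics:
    """Smoothed per-breath estimates.

    ``valid`` stays False until one full breath cycle (peak to peak) has
    been observed: the interval between startup and the first peak is
    not a breath period, so both it and the estimates that depend on it
    are withheld rather than displayed half-initialized.
    """

    pip: float = math.nan
    peep: float = math.nan
    smoothed_period: float = math.nan  # samples between high peaks
    breath_count: int = 0
    valid: bool = False

    def rr(self, fs: float) -> float:
        """Respiratory rate in breaths/min (NaN until valid)."""
        if not self.valid:
            return math.nan
        return respiratory_rate(self.smoothed_period, fs)


@dataclass
class MonitorState:
    """Complete monitor state advanced by :func:`step`.

    ``samples_since_prev_peak`` counts from the *previous* breath-cycle
    maximum (it is rebased, not zeroed, at each completed cycle), so the
    difference against the high tracker's ``samples_since_attack`` is the
    peak-to-peak breath interval.  Invariant: it never falls below the
    high tracker's counter.
    """

    high: EnvelopeState
    low: EnvelopeState
    breath_state: BreathState
    samples_since_prev_peak: int = 0
    metrics: BreathMetrics = field(default_factory=BreathMetrics)
    sample_index: int = 0
    # True once the first inhale->exhale transition has rebased the peak
    # counter onto an actual high peak; intervals before that are not
    # breath periods.
    _period_anchored: bool = field(default=False, repr=False)


def exponential_smooth(prev: float, new: float, alpha_smooth: float) -> float:
    """One-pole smoothing: ``alpha*prev + (1-alpha)*new``.

    The contribution of an update fades as ``alpha_smooth**k`` after
    ``k`` further updates; alpha 0 means no memory.
    """
    if not (0.0 <= alpha_smooth < 1.0):
        raise ValueError(f"alpha_smooth must be in [0, 1), got {alpha_smooth}")
    return alpha_smooth * prev + (1.0 - alpha_smooth) * new


def respiratory_rate(smoothed_period: float, fs: float) -> float:
    """Breaths per minute from a breath period in samples."""
    if not smoothed_period > 0:
        raise ValueError(f"smoothed_period must be positive, got {smoothed_period}")
    return 60.0 * fs / smoothed_period


def init_monitor(config: MonitorConfig, first_pressure: float) -> MonitorState:
    """Fresh monitor state seeded from the first pressure sample.

    Both envelopes start at the first sample and the breath state starts
    as EXHALING so that the first rising edge of the signal registers as
    an inhalation transition.
    """
    high = EnvelopeState.initialized(Direction.HIGH, first_pressure)
    low = EnvelopeState.initialized(Direction.LOW, first_pressure)
    return MonitorState(high=high, low=low, breath_state=BreathState.EXHALING)


def step(
    state: MonitorState, p: float, config: MonitorConfig
) -> tuple[MonitorState, Optional[Transition]]:
    """Advance the monitor by one sample (state is mutated in place).

    The high tracker is updated before the low tracker.  A sample that
    attacks *both* trackers (possible only in the degenerate case where
    it ties two equal envelopes, e.g. a constant signal) is neither a
    breath maximum nor a minimum and produces no transition — so a
    constant input never toggles the breath state.

    First-cycle seeding: the first measurement of PIP, PEEP, or the
    breath period initializes the corresponding smoothed value directly
    instead of smoothing against an undefined prior, and the very first
    peak interval (startup to first peak) is discarded because it is not
    a breath period.
    """
    a_s = config.alpha_smooth
    m = state.metrics
    state.sample_index += 1
    state.samples_since_prev_peak += 1
    transition: Optional[Transition] = None

    _, high_attacked = update_envelope(state.high, p, config.coefficients)
    _, low_attacked = update_envelope(state.low, p, config.coefficients)

    if high_attacked and not low_attacked and state.breath_state is BreathState.EXHALING:
        state.breath_state = BreathState.INHALING
        transition = Transition.TO_INHALE
        v_low = state.low.last_attack_value
        m.peep = v_low if math.isnan(m.peep) else exponential_smooth(m.peep, v_low, a_s)

    if low_attacked and not high_attacked and state.breath_state is BreathState.INHALING:
        state.breath_state = BreathState.EXHALING
        transition = Transition.TO_EXHALE
        v_high = state.high.last_attack_value
        m.pip = v_high if math.isnan(m.pip) else exponential_smooth(m.pip, v_high, a_s)
        interval = state.samples_since_prev_peak - state.high.samples_since_attack
        if state._period_anchored:
            m.smoothed_period = (
                float(interval)
                if math.isnan(m.smoothed_period)
                else exponential_smooth(m.smoothed_period, float(interval), a_s)
            )
        # Rebase the peak counter onto this cycle's maximum.
        state.samples_since_prev_peak = state.high.samples_since_attack
        state._period_anchored = True
        m.breath_count += 1
        if not m.valid and not math.isnan(m.peep) and not math.isnan(m.smoothed_period):
            m.valid = True

    return state, transition


@dataclass
class MonitorResult:
    """Batch output of :func:`run_monitor`.

    trace:
        Per-sample record (pressure, both envelopes, attack flags,
        counters, breath state) for plotting and testing.
    breaths:
        One row per completed breath cycle with smoothed metrics; the
        ``pip_display``/``peep_display``/``rr_display`` columns are
        quantized to the configured display resolution.
    transitions:
        ``(sample_index, Transition)`` pairs (sample_index is 1-based:
        the n-th processed sample after the seeding sample).
    """

    trace: pd.DataFrame
    breaths: pd.DataFrame
    transitions: list[tuple[int, Transition]]
    final_state: MonitorState


def _quantize(x: float, resolution: float) -> float:
    if math.isnan(x):
        return x
    return round(x / resolution) * resolution


def run_monitor(pressure_series: Sequence[float], config: MonitorConfig) -> MonitorResult:
    """Run the streaming monitor over a full recorded trace.

    The first sample seeds the envelopes; every subsequent sample is one
    :func:`step`.  Output is a deterministic function of the input.
    """
    pressures = np.asarray(pressure_series, dtype=float)
    if pressures.size == 0:
        raise ValueError("pressure series is empty")
    if not np.all(np.isfinite(pressures)):
        bad = int(np.flatnonzero(~np.isfinite(pressures))[0])
        raise SignalQualityError(f"non-finite pressure at sample {bad}")

    state = init_monitor(config, float(pressures[0]))
    n = pressures.size
    v_high = np.empty(n)
    v_low = np.empty(n)
    peak_high = np.empty(n)
    peak_low = np.empty(n)
    t_high = np.zeros(n, dtype=int)
    t_low = np.zeros(n, dtype=int)
    t_peak = np.zeros(n, dtype=int)
    inhaling = np.zeros(n, dtype=bool)
    high_attack = np.zeros(n, dtype=bool)
    low_attack = np.zeros(n, dtype=bool)

    v_high[0] = v_low[0] = pressures[0]
    peak_high[0] = peak_low[0] = pressures[0]

    transitions: list[tuple[int, Transition]] = []
    breath_rows: list[dict] = []
    for t in range(1, n):
        _, tr = step(state, float(pressures[t]), config)
        v_high[t] = state.high.value
        v_low[t] = state.low.value
        peak_high[t] = state.high.last_attack_value
        peak_low[t] = state.low.last_attack_value
        t_high[t] = state.high.samples_since_attack
        t_low[t] = state.low.samples_since_attack
        t_peak[t] = state.samples_since_prev_peak
        inhaling[t] = state.breath_state is BreathState.INHALING
        high_attack[t] = state.high.samples_since_attack == 0
        low_attack[t] = state.low.samples_since_attack == 0
        if tr is not None:
            transitions.append((t, tr))
        if tr is Transition.TO_EXHALE:
            m = state.metrics
            rr = m.rr(config.fs)
            breath_rows.append(
                {
                    "breath": m.breath_count,
                    "sample": t,
                    "time_s": t / config.fs,
                    "pip": m.pip,
                    "peep": m.peep,
                    "period_samples": m.smoothed_period,
                    "rr": rr,
                    "valid": m.valid,
                    "pip_display": _quantize(m.pip, config.display_resolution_pressure),
                    "peep_display": _quantize(m.peep, config.display_resolution_pressure),
                    "rr_display": _quantize(rr, config.display_resolution_rr),
                }
            )

    trace = pd.DataFrame(
        {
            "pressure": pressures,
            "v_high": v_high,
            "v_low": v_low,
            "peak_high": peak_high,
            "peak_low": peak_low,
            "t_high": t_high,
            "t_low": t_low,
            "t_peak": t_peak,
            "inhaling": inhaling,
            "high_attack": high_attack,
            "low_attack": low_attack,
        }
    )
    breaths = pd.DataFrame(
        breath_rows,
        columns=[
            "breath",
            "sample",
            "time_s",
            "pip",
            "peep",
            "period_samples",
            "rr",
            "valid",
            "pip_display",
            "peep_display",
            "rr_display",
        ],
    )
    return MonitorResult(trace=trace, breaths=breaths, transitions=transitions, final_state=state)
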