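"""Alarm engine: threshold checks, noncycling detection, event bookkeeping.

Five alarm kinds are monitored:

==============  =====================================================
high_pressure   instantaneous pressure above ``p_max``
low_pressure    instantaneous pressure below ``p_min``
high_rr         smoothed respiratory rate above ``rr_max``
low_rr          smoothed respiratory rate below ``rr_min``
noncycling      the ventilator has stopped switching between
                inhalation and exhalation
==============  =====================================================

The noncycling alarm is a disjunction of four sub-conditions: too many
samples since the last high-tracker attack, too many since the last
low-tracker attack, the high-to-low envelope ratio below ``r_min``, or
the envelope difference below ``d_min``.  Any one suffices — they cover
different failure shapes (flat-line at PEEP, flat-line at PIP, and
small-amplitude oscillation that still produces attack events but no
real breaths).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from enum import Enum
from typing import Iterable, Optional, Sequence

from .envelope import DEFAULT_R_MIN, DEFAULT_R_NOM, DEFAULT_T_MAX_S
from .monitor import BreathMetrics, MonitorConfig, MonitorResult, MonitorState, run_monitor

__all__ = [
    "AlarmKind",
    "NoncyclingCondition",
    "AlarmThresholds",
    "ThresholdError",
    "AlarmEvent",
    "check_instant_alarms",
    "check_noncycling",
    "alarm_timeline",
    "run_alarmed_monitor",
    "AlarmedMonitorResult",
    "RATIO_GUARD_FLOOR",
]

#: Below this low-envelope value (cm H2O) the ratio sub-condition is
#: skipped: near atmospheric pressure the ratio is meaningless and the
#: low-pressure alarm already covers that regime (e.g. a patient-initiated
#: breath pulling the airway toward atmosphere).
RATIO_GUARD_FLOOR = 0.5


class AlarmKind(str, Enum):
    HIGH_PRESSURE = "high_pressure"
    LOW_PRESSURE = "low_pressure"
    HIGH_RR = "high_rr"
    LOW_RR = "low_rr"
    NONCYCLING = "noncycling"


class NoncyclingCondition(str, Enum):
    TIME_HIGH = "time_high"
    TIME_LOW = "time_low"
    RATIO = "ratio"
    DIFFERENCE = "difference"


class ThresholdError(ValueError):
    """An alarm threshold is outside its permitted tunable range."""


# field -> (lower, upper, unit): permitted user-configurable ranges.
_THRESHOLD_RANGES = {
    "p_max": (30.0, 90.0, "cm H2O"),
    "p_min": (1.0, 20.0, "cm H2O"),
    "rr_max": (15.0, 60.0, "breaths/min"),
    "rr_min": (5.0, 15.0, "breaths/min"),
    "t_max": (5.0, 30.0, "s"),
}


@dataclass(frozen=True)
class AlarmThresholds:
    """User-configurable alarm thresholds.

    Defaults sit mid-range for the pressure and rate limits; ``t_max``
    is the conventional 15 s noncycling timeout, ``r_min``/``r_nom``
    match the ratio-alarm calibration (see
    :func:`ventmon.envelope.release_coefficient`), and ``d_min`` is a
    fixed 3 cm H2O minimum envelope separation.
    """

    p_max: float = 40.0  # cm H2O
    p_min: float = 5.0  # cm H2O
    rr_max: float = 40.0  # breaths/min
    rr_min: float = 8.0  # breaths/min
    t_max: float = DEFAULT_T_MAX_S  # seconds
    r_min: float = DEFAULT_R_MIN
    d_min: float = 3.0  # cm H2O
    r_nom: float = DEFAULT_R_NOM

    def __post_init__(self) -> None:
        for name, (lo, hi, unit) in _THRESHOLD_RANGES.items():
            v = getattr(self, name)
            if not (lo <= v <= hi):
                raise ThresholdError(
                    f"{name}={v} outside permitted range {lo}-{hi} {unit}"
                )
        if not (1.0 < self.r_min < self.r_nom):
            raise ThresholdError(
                f"require 1 < r_min < r_nom, got r_min={self.r_min}, r_nom={self.r_nom}"
            )
        if not self.d_min > 0:
            raise ThresholdError(f"d_min must be positive, got {self.d_min}")

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass
class AlarmEvent:
    """One maximal run of consecutive activity of a single alarm kind.

    ``clear_index`` is the first sample on which the alarm is no longer
    active (None if still active at end of trace).  ``sub_condition``
    records which noncycling sub-condition triggered the onset; it is
    present only for noncycling events.
    """

    kind: AlarmKind
    onset_index: int
    clear_index: Optional[int] = None
    sub_condition: Optional[NoncyclingCondition] = None


def _instant_kinds(
    p: float, rr: float, rr_valid: bool, thresholds: AlarmThresholds
) -> set[AlarmKind]:
    active: set[AlarmKind] = set()
    if p > thresholds.p_max:
        active.add(AlarmKind.HIGH_PRESSURE)
    if p < thresholds.p_min:
        active.add(AlarmKind.LOW_PRESSURE)
    if rr_valid:
        if rr > thresholds.rr_max:
            active.add(AlarmKind.HIGH_RR)
        if rr < thresholds.rr_min:
            active.add(AlarmKind.LOW_RR)
    return active


def _noncycling_conditions(
    v_high: float,
    v_low: float,
    samples_since_high_attack: int,
    samples_since_low_attack: int,
    breath_count: int,
    sample_index: int,
    thresholds: AlarmThresholds,
    fs: float,
) -> set[NoncyclingCondition]:
    t_max_samples = thresholds.t_max * fs
    conds: set[NoncyclingCondition] = set()
    if samples_since_high_attack > t_max_samples:
        conds.add(NoncyclingCondition.TIME_HIGH)
    if samples_since_low_attack > t_max_samples:
        conds.add(NoncyclingCondition.TIME_LOW)
    # Warm-up: ratio/difference are suppressed until the first completed
    # breath cycle or t_max seconds, whichever comes first — at startup
    # both envelopes are equal and would trip them instantly.  The time
    # conditions need no suppression: their counters start at zero.
    warmed_up = breath_count >= 1 or sample_index >= t_max_samples
    if warmed_up:
        if v_low >= RATIO_GUARD_FLOOR and v_high / v_low < thresholds.r_min:
            conds.add(NoncyclingCondition.RATIO)
        if v_high - v_low < thresholds.d_min:
            conds.add(NoncyclingCondition.DIFFERENCE)
    return conds


def check_instant_alarms(
    p: float, metrics: BreathMetrics, thresholds: AlarmThresholds, fs: float
) -> set[AlarmKind]:
    """Pressure and respiratory-rate alarms for the current sample.

    Pressure alarms act on the raw sample.  RR alarms compare the
    unrounded smoothed rate and are inactive until the metrics are valid
    (one full breath cycle observed).
    """
    return _instant_kinds(p, metrics.rr(fs), metrics.valid, thresholds)


def check_noncycling(
    state: MonitorState, thresholds: AlarmThresholds, fs: float
) -> tuple[bool, set[NoncyclingCondition]]:
    """Evaluate the four noncycling sub-conditions (OR semantics)."""
    conds = _noncycling_conditions(
        state.high.value,
        state.low.value,
        state.high.samples_since_attack,
        state.low.samples_since_attack,
        state.metrics.breath_count,
        state.sample_index,
        thresholds,
        fs,
    )
    return bool(conds), conds


_SUB_PRIORITY = [
    NoncyclingCondition.TIME_HIGH,
    NoncyclingCondition.TIME_LOW,
    NoncyclingCondition.RATIO,
    NoncyclingCondition.DIFFERENCE,
]
_KIND_ORDER = {k: i for i, k in enumerate(AlarmKind)}


def alarm_timeline(
    per_sample_active: Sequence[Iterable[AlarmKind]],
    per_sample_subconditions: Optional[Sequence[Iterable[NoncyclingCondition]]] = None,
) -> list[AlarmEvent]:
    """Collapse per-sample active-alarm sets into onset/clear events.

    Alarms auto-clear when their condition clears; each maximal run of
    consecutive activity of one kind becomes one event.  Events are
    ordered by onset (ties broken by kind declaration order).
    """
    open_events: dict[AlarmKind, AlarmEvent] = {}
    events: list[AlarmEvent] = []
    for t, active in enumerate(per_sample_active):
        active = set(active)
        for kind in list(open_events):
            if kind not in active:
                open_events.pop(kind).clear_index = t
        for kind in active:
            if kind not in open_events:
                sub = None
                if kind is AlarmKind.NONCYCLING and per_sample_subconditions is not None:
                    onset_subs = set(per_sample_subconditions[t])
                    sub = next((s for s in _SUB_PRIORITY if s in onset_subs), None)
                ev = AlarmEvent(kind=kind, onset_index=t, sub_condition=sub)
                open_events[kind] = ev
                events.append(ev)
    events.sort(key=lambda e: (e.onset_index, _KIND_ORDER[e.kind]))
    return events


@dataclass
class AlarmedMonitorResult:
    """Monitor output plus per-sample alarm activity and events."""

    monitor: MonitorResult
    active_kinds: list[set[AlarmKind]]
    sub_conditions: list[set[NoncyclingCondition]]
    events: list[AlarmEvent]


def run_alarmed_monitor(
    pressure_series: Sequence[float],
    config: MonitorConfig,
    thresholds: Optional[AlarmThresholds] = None,
) -> AlarmedMonitorResult:
    """Run the breath monitor and evaluate every alarm on every sample.

    This is the batch equivalent of the embedded main loop: envelope
    update, breath-cycle tracking, then the alarm checks, once per
    sample.  The alarm pass replays the recorded per-sample trace, so
    the output is a pure function of (trace, thresholds, config).
    """
    thresholds = thresholds if thresholds is not None else AlarmThresholds()
    result = run_monitor(pressure_series, config)
    trace = result.trace
    fs = config.fs

    n = len(trace)
    pressures = trace["pressure"].to_numpy()
    v_high = trace["v_high"].to_numpy()
    v_low = trace["v_low"].to_numpy()
    t_high = trace["t_high"].to_numpy()
    t_low = trace["t_low"].to_numpy()

    # Per-sample smoothed-rate context reconstructed from the breath table.
    breaths = result.breaths
    rr_cur, valid_cur, count_cur = math.nan, False, 0
    rows = iter(breaths[["sample", "rr", "valid"]].itertuples(index=False))
    next_row = next(rows, None)

    active_kinds: list[set[AlarmKind]] = []
    sub_conditions: list[set[NoncyclingCondition]] = []
    for t in range(n):
        while next_row is not None and next_row.sample == t:
            rr_cur, valid_cur = next_row.rr, bool(next_row.valid)
            count_cur += 1
            next_row = next(rows, None)
        active = _instant_kinds(pressures[t], rr_cur, valid_cur, thresholds)
        conds = _noncycling_conditions(
            v_high[t], v_low[t], int(t_high[t]), int(t_low[t]),
            count_cur, t, thresholds, fs,
        )
        if conds:
            active.add(AlarmKind.NONCYCLING)
        active_kinds.append(active)
        sub_conditions.append(conds)

    events = alarm_timeline(active_kinds, sub_conditions)
    return AlarmedMonitorResult(
        monitor=result,
        active_kinds=active_kinds,
        sub_conditions=sub_conditions,
        events=events,
    )
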