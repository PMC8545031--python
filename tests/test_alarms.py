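"""Alarm engine tests: thresholds, noncycling detection, event timelines."""

import numpy as np
import pytest

from ventmon import (
    AlarmKind,
    AlarmThresholds,
    BreathMetrics,
    EventKind,
    MonitorConfig,
    NoncyclingCondition,
    SimEvent,
    ThresholdError,
    WaveformSpec,
    alarm_timeline,
    check_instant_alarms,
    check_noncycling,
    generate,
    init_monitor,
    run_alarmed_monitor,
    square_cycling,
    step,
)

FS = 100.0


def kinds_at(result, t):
    return {k.value for k in result.active_kinds[t]}


def first_firing(result):
    """First sample index at which each noncycling sub-condition holds."""
    firsts = {}
    for t, conds in enumerate(result.sub_conditions):
        for c in conds:
            firsts.setdefault(c, t)
    return firsts


class TestThresholdValidation:
    def test_defaults_valid(self):
        AlarmThresholds()

    @pytest.mark.parametrize(
        "field,value",
        [("p_max", 95.0), ("p_max", 25.0), ("p_min", 0.5), ("p_min", 25.0),
         ("rr_max", 61.0), ("rr_min", 4.0), ("t_max", 31.0), ("t_max", 4.0)],
    )
    def test_out_of_range_named_in_error(self, field, value):
        with pytest.raises(ThresholdError, match=field):
            AlarmThresholds(**{field: value})

    def test_ratio_ordering_enforced(self):
        with pytest.raises(ThresholdError, match="r_min"):
            AlarmThresholds(r_min=2.5, r_nom=2.4)

    def test_serializable(self):
        d = AlarmThresholds().to_dict()
        assert AlarmThresholds(**d) == AlarmThresholds()


class TestInstantAlarms:
    def _metrics(self, rr=20.0, valid=True, fs=FS):
        m = BreathMetrics(pip=24.0, peep=10.0, smoothed_period=60.0 * fs / rr, valid=valid)
        m.breath_count = 5
        return m

    def test_pressure_above_table_upper_limit(self):
        th = AlarmThresholds(p_max=90.0)
        assert check_instant_alarms(95.0, self._metrics(), th, FS) == {AlarmKind.HIGH_PRESSURE}

    def test_pressure_below_table_lower_limit(self):
        th = AlarmThresholds(p_min=1.0)
        assert check_instant_alarms(0.5, self._metrics(), th, FS) == {AlarmKind.LOW_PRESSURE}

    def test_quiet_when_in_band(self):
        th = AlarmThresholds()
        assert check_instant_alarms(20.0, self._metrics(rr=20.0), th, FS) == set()

    def test_rr_alarms_gated_on_validity(self):
        th = AlarmThresholds()
        fast = self._metrics(rr=55.0)
        assert check_instant_alarms(20.0, fast, th, FS) == {AlarmKind.HIGH_RR}
        fast_invalid = self._metrics(rr=55.0, valid=False)
        assert check_instant_alarms(20.0, fast_invalid, th, FS) == set()
        slow = self._metrics(rr=5.0)
        assert check_instant_alarms(20.0, slow, th, FS) == {AlarmKind.LOW_RR}


class TestNoncycling:
    def _warmed_state(self, v_high, v_low, t_high=0, t_low=0):
        config = MonitorConfig.default(fs=FS)
        state = init_monitor(config, v_low)
        state.high.value = v_high
        state.low.value = v_low
        state.high.samples_since_attack = t_high
        state.low.samples_since_attack = t_low
        state.metrics.breath_count = 3  # past warm-up
        state.sample_index = 5000
        return state

    def test_time_high_fires_past_timeout(self):
        th = AlarmThresholds()
        state = self._warmed_state(24.0, 10.0, t_high=int(th.t_max * FS) + 1)
        active, conds = check_noncycling(state, th, FS)
        assert active and conds == {NoncyclingCondition.TIME_HIGH}

    def test_time_low_fires_past_timeout(self):
        th = AlarmThresholds()
        state = self._warmed_state(24.0, 10.0, t_low=int(th.t_max * FS) + 1)
        _, conds = check_noncycling(state, th, FS)
        assert conds == {NoncyclingCondition.TIME_LOW}

    def test_ratio_condition_threshold(self):
        th = AlarmThresholds()
        _, conds = check_noncycling(self._warmed_state(14.9, 10.0), th, FS)
        assert NoncyclingCondition.RATIO in conds
        _, conds = check_noncycling(self._warmed_state(15.1, 10.0), th, FS)
        assert NoncyclingCondition.RATIO not in conds

    def test_difference_condition_threshold(self):
        th = AlarmThresholds()
        _, conds = check_noncycling(self._warmed_state(12.9, 10.0), th, FS)
        assert NoncyclingCondition.DIFFERENCE in conds

    def test_ratio_guard_near_atmospheric(self):
        """Near-zero low envelope disables the ratio check (the
        low-pressure alarm owns that regime)."""
        th = AlarmThresholds()
        _, conds = check_noncycling(self._warmed_state(0.4, 0.3), th, FS)
        assert NoncyclingCondition.RATIO not in conds
        assert NoncyclingCondition.DIFFERENCE in conds

    def test_warm_up_suppresses_level_conditions(self):
        config = MonitorConfig.default(fs=FS)
        state = init_monitor(config, 10.0)
        step(state, 10.0, config)
        active, conds = check_noncycling(state, AlarmThresholds(), FS)
        assert not active and conds == set()


class TestAlarmTimeline:
    def test_empty(self):
        assert alarm_timeline([set()] * 100) == []

    def test_single_run_onset_and_clear(self):
        seq = [set()] * 100 + [{AlarmKind.HIGH_PRESSURE}] * 100 + [set()] * 10
        events = alarm_timeline(seq)
        assert len(events) == 1
        assert events[0].onset_index == 100 and events[0].clear_index == 200

    def test_two_disjoint_runs_of_same_kind(self):
        seq = ([set()] * 10 + [{AlarmKind.LOW_RR}] * 5 + [set()] * 10
               + [{AlarmKind.LOW_RR}] * 5 + [set()] * 2)
        events = alarm_timeline(seq)
        assert [(e.onset_index, e.clear_index) for e in events] == [(10, 15), (25, 30)]

    def test_still_active_event_has_no_clear(self):
        events = alarm_timeline([set(), {AlarmKind.NONCYCLING}])
        assert events[0].clear_index is None

    def test_noncycling_event_records_sub_condition(self):
        seq = [set(), {AlarmKind.NONCYCLING}, {AlarmKind.NONCYCLING}]
        subs = [set(), {NoncyclingCondition.RATIO}, {NoncyclingCondition.RATIO}]
        events = alarm_timeline(seq, subs)
        assert events[0].sub_condition is NoncyclingCondition.RATIO


class TestScenarios:
    def test_step_drop_ratio_and_timeout_coincide(self):
        """On cycling that ends with the envelope converged exactly at
        PIP, then an instantaneous drop to constant PEEP, the calibrated
        release weight makes the ratio and timeout sub-conditions fire
        within one sample of each other, at ~t_max elapsed."""
        sig = np.concatenate([
            [10.0],
            square_cycling(24.0, 10.0, 150, 9, fs=FS),
            np.full(150, 24.0),
            np.full(2000, 10.0),
        ])
        res = run_alarmed_monitor(sig, MonitorConfig.default(fs=FS))
        trace = res.monitor.trace
        last_attack = int(np.flatnonzero(trace["high_attack"].to_numpy())[-1])
        firsts = first_firing(res)
        t_ratio = firsts[NoncyclingCondition.RATIO] - last_attack
        t_time = firsts[NoncyclingCondition.TIME_HIGH] - last_attack
        assert abs(t_ratio - t_time) <= 1
        assert t_time == int(15.0 * FS) + 1
        assert t_ratio == pytest.approx(15.0 * FS, abs=1)

    def test_disconnect_fires_low_pressure_then_noncycling(self):
        """Circuit disconnect to atmosphere: low-pressure alarm within one
        sample of the drop, noncycling t_max after the last attack."""
        drop_s = 31.0
        spec = WaveformSpec(
            pip_set=24.0, peep_set=10.0, rr_set=20.0, fs=FS, duration=60.0,
            events=(SimEvent(EventKind.DISCONNECT_ATMOSPHERE, drop_s),),
        )
        res = run_alarmed_monitor(generate(spec).pressure, MonitorConfig.default(fs=FS))
        by_kind = {e.kind: e for e in res.events}
        drop_idx = int(drop_s * FS)
        assert abs(by_kind[AlarmKind.LOW_PRESSURE].onset_index - drop_idx) <= 1
        last_attack = int(
            np.flatnonzero(res.monitor.trace["high_attack"].to_numpy()[:drop_idx])[-1]
        )
        onset = by_kind[AlarmKind.NONCYCLING].onset_index
        assert onset - last_attack == pytest.approx(15.0 * FS, abs=2)
        assert by_kind[AlarmKind.NONCYCLING].sub_condition is NoncyclingCondition.TIME_HIGH

    def test_small_oscillation_triggers_level_conditions(self):
        """Low-amplitude noncycling oscillation keeps producing attack
        events, so only the ratio/difference conditions can catch it."""
        spec = WaveformSpec(
            pip_set=24.0, peep_set=10.0, rr_set=20.0, fs=FS, duration=90.0,
            events=(SimEvent(EventKind.SMALL_OSCILLATION, 30.0, {"amplitude": 1.0}),),
        )
        res = run_alarmed_monitor(generate(spec).pressure, MonitorConfig.default(fs=FS))
        nc = [e for e in res.events if e.kind is AlarmKind.NONCYCLING]
        assert nc, "oscillation should eventually trigger noncycling"
        assert nc[0].sub_condition in (NoncyclingCondition.RATIO, NoncyclingCondition.DIFFERENCE)

    def test_no_false_alarms_during_normal_cycling(self):
        """Across the PIP dial range with the nominal PEEP ratio, clean
        cycling never alarms with default thresholds."""
        for pip in (20.0, 30.0, 40.0):
            spec = WaveformSpec(pip_set=pip, rr_set=20.0, fs=FS, duration=60.0)
            res = run_alarmed_monitor(generate(spec).pressure, MonitorConfig.default(fs=FS))
            assert res.events == [], f"false alarm at PIP={pip}: {res.events}"

    def test_timeout_monotonicity(self):
        """A larger t_max never makes the time-based alarm fire earlier."""
        sig = np.concatenate([
            [10.0], square_cycling(24.0, 10.0, 150, 5, fs=FS),
            np.full(150, 24.0), np.full(3000, 10.0),
        ])
        onsets = []
        for t_max in (5.0, 10.0, 15.0, 25.0):
            res = run_alarmed_monitor(
                sig, MonitorConfig.default(fs=FS), AlarmThresholds(t_max=t_max)
            )
            firsts = first_firing(res)
            onsets.append(firsts.get(NoncyclingCondition.TIME_HIGH, np.inf))
        assert onsets == sorted(onsets)

    def test_ratio_threshold_monotonicity(self):
        """A larger r_min never makes the ratio alarm fire later."""
        sig = np.concatenate([
            [10.0], square_cycling(24.0, 10.0, 150, 5, fs=FS),
            np.full(150, 24.0), np.full(3000, 10.0),
        ])
        config = MonitorConfig.default(fs=FS)
        onsets = []
        for r_min in (1.2, 1.5, 1.8, 2.1):
            res = run_alarmed_monitor(sig, config, AlarmThresholds(r_min=r_min))
            firsts = first_firing(res)
            onsets.append(firsts.get(NoncyclingCondition.RATIO, np.inf))
        assert onsets == sorted(onsets, reverse=True)
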