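"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from ventmon import AlarmThresholds, MonitorConfig

# A 40-sample toy trace: linear rise 10 -> 24 over 20 samples, then a
# linear fall 24 -> 10.  Small enough to reason about by hand.
TOY_RISE_FALL = [
    10.0, 10.7368, 11.4737, 12.2105, 12.9474, 13.6842, 14.4211, 15.1579,
    15.8947, 16.6316, 17.3684, 18.1053, 18.8421, 19.5789, 20.3158, 21.0526,
    21.7895, 22.5263, 23.2632, 24.0,
    23.2632, 22.5263, 21.7895, 21.0526, 20.3158, 19.5789, 18.8421, 18.1053,
    17.3684, 16.6316, 15.8947, 15.1579, 14.4211, 13.6842, 12.9474, 12.2105,
    11.4737, 10.7368, 10.0, 10.0,
]


@pytest.fixture
def config100() -> MonitorConfig:
    """Default monitor configuration at 100 samples/s."""
    return MonitorConfig.default(fs=100.0)


@pytest.fixture
def thresholds() -> AlarmThresholds:
    return AlarmThresholds()


@pytest.fixture
def toy_trace() -> np.ndarray:
    return np.array(TOY_RISE_FALL)


def oracle_envelopes(pressures, alpha_attack, alpha_release):
    """Straight-line re-implementation of the two tracker recurrences.

    Written independently of the package's update code: plain loops over
    explicit branch comparisons, used as the reference for attack-flag
    and transition behavior.
    """
    p = np.asarray(pressures, dtype=float)
    n = p.size
    v_high = np.empty(n)
    v_low = np.empty(n)
    high_attack = np.zeros(n, dtype=bool)
    low_attack = np.zeros(n, dtype=bool)
    v_high[0] = v_low[0] = p[0]
    for t in range(1, n):
        if p[t] >= v_high[t - 1]:
            v_high[t] = alpha_attack * v_high[t - 1] + (1 - alpha_attack) * p[t]
            high_attack[t] = True
        else:
            v_high[t] = alpha_release * v_high[t - 1] + (1 - alpha_release) * p[t]
        if p[t] <= v_low[t - 1]:
            v_low[t] = alpha_attack * v_low[t - 1] + (1 - alpha_attack) * p[t]
            low_attack[t] = True
        else:
            v_low[t] = alpha_release * v_low[t - 1] + (1 - alpha_release) * p[t]
    return v_high, v_low, high_attack, low_attack


def oracle_transitions(pressures, alpha_attack, alpha_release):
    """Breath transitions found by scanning the oracle attack flags.

    A transition to inhalation is the first exclusive high-attack sample
    while exhaling, and vice versa; samples that attack both trackers
    are neither peaks nor troughs.
    """
    _, _, ha, la = oracle_envelopes(pressures, alpha_attack, alpha_release)
    state = "exhaling"
    out = []
    for t in range(1, len(pressures)):
        if ha[t] and not la[t] and state == "exhaling":
            state = "inhaling"
            out.append((t, "to_inhale"))
        elif la[t] and not ha[t] and state == "inhaling":
            state = "exhaling"
            out.append((t, "to_exhale"))
    return out


def count_cycles_midline(pressures) -> int:
    """Brute-force breath count: falling crossings of the signal midline.

    Completely independent of the envelope machinery — valid only for
    clean periodic inputs, where each breath crosses the midline once in
    each direction.
    """
    p = np.asarray(pressures, dtype=float)
    mid = 0.5 * (p.min() + p.max())
    above = p > mid
    return int(np.count_nonzero(above[:-1] & ~above[1:]))
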