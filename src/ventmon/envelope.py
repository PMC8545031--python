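"""Nonlinear recursive envelope trackers for airway-pressure signals.

A pressure-cycled ventilator produces a waveform that swings between PIP
(peak inspiratory pressure) and PEEP (positive end-expiratory pressure)
once per breath.  Rather than searching a window of stored samples for
maxima and minima, the monitor follows the top and bottom of the signal
with a pair of one-pole recursive averagers of the form

    v[t] = alpha * v[t-1] + (1 - alpha) * p[t]

that switch their feedback coefficient depending on the direction of the
incoming sample.  The *high* tracker uses a small "attack" coefficient
when the signal rises (so it snaps up to new peaks) and a coefficient
close to 1 when the signal falls (so it sags slowly between peaks); the
*low* tracker mirrors this.  Each tracker stores a single envelope value,
which is what makes the scheme suitable for very small microcontrollers
— the same trick used by dynamic-range compressors in hearing aids.

This module is pure computation: the breath-cycle state machine that
consumes attack events lives in :mod:`ventmon.monitor`, and the alarm
logic in :mod:`ventmon.alarms`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Optional

__all__ = [
    "Direction",
    "TrackerCoefficients",
    "EnvelopeState",
    "SignalQualityError",
    "update_envelope",
    "release_coefficient",
    "attack_coefficient",
    "attack_time_constant",
    "closed_form_release",
    "DEFAULT_ALPHA_ATTACK",
    "DEFAULT_R_MIN",
    "DEFAULT_R_NOM",
    "DEFAULT_T_MAX_S",
]

#: Attack coefficient giving a ~100 ms memory at 100 samples/s.
DEFAULT_ALPHA_ATTACK = 0.9
#: The attack memory that coefficient realizes at 100 samples/s:
#: -1/(100*ln 0.9) seconds.  The memory in *seconds* is the design
#: quantity, so at other sample rates the coefficient is rescaled to
#: keep it (see :func:`attack_coefficient`).
DEFAULT_ATTACK_TAU_S = 0.09491221581029904
#: Envelope-ratio alarm threshold (see :mod:`ventmon.alarms`).
DEFAULT_R_MIN = 1.5
#: Nominal PIP-to-PEEP ratio of the target ventilator's pneumatics.
DEFAULT_R_NOM = 2.4
#: Default noncycling alarm timeout, seconds.
DEFAULT_T_MAX_S = 15.0


class SignalQualityError(ValueError):
    """Raised when a pressure sample is NaN or infinite."""


class Direction(str, Enum):
    """Which edge of the signal a tracker follows."""

    HIGH = "high"
    LOW = "low"


@dataclass(frozen=True)
class TrackerCoefficients:
    """Attack/release feedback weights shared by both trackers.

    ``alpha_attack`` must not exceed ``alpha_release``: the attack branch
    is the fast one, so it forgets history more quickly.
    """

    alpha_attack: float = DEFAULT_ALPHA_ATTACK
    alpha_release: float = 0.0  # placeholder; see __post_init__

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha_attack <= self.alpha_release <= 1.0):
            raise ValueError(
                "require 0 <= alpha_attack <= alpha_release <= 1, got "
                f"alpha_attack={self.alpha_attack}, alpha_release={self.alpha_release}"
            )

    @classmethod
    def calibrated(
        cls,
        fs: float,
        alpha_attack: Optional[float] = None,
        r_min: float = DEFAULT_R_MIN,
        r_nom: float = DEFAULT_R_NOM,
        t_max_s: float = DEFAULT_T_MAX_S,
    ) -> "TrackerCoefficients":
        """Coefficients calibrated for the sample rate ``fs``.

        Both weights are derived from time-domain design quantities so
        that tracker behavior is invariant to the sample rate: the
        attack weight from the ~100 ms attack memory (0.9 at 100
        samples/s), and the release weight from the ratio/timeout alarm
        alignment with ``t_max_s`` converted to samples at ``fs``.
        Pass ``alpha_attack`` explicitly to override the derived value.
        """
        if alpha_attack is None:
            alpha_attack = attack_coefficient(fs)
        alpha_r = release_coefficient(r_min, r_nom, t_max_s * fs)
        return cls(alpha_attack=alpha_attack, alpha_release=alpha_r)


@dataclass
class EnvelopeState:
    """Mutable state of one envelope tracker.

    Attributes
    ----------
    direction:
        Whether this tracker follows the top (``HIGH``) or bottom
        (``LOW``) of the signal.
    value:
        Current envelope value, cm H2O.
    last_attack_value:
        The raw pressure sample that most recently triggered the attack
        branch (the running breath-cycle peak for HIGH, trough for LOW).
    samples_since_attack:
        Count of samples since the attack branch last fired; zero exactly
        when the most recent update attacked.
    """

    direction: Direction
    value: float
    last_attack_value: float
    samples_since_attack: int = 0

    @classmethod
    def initialized(cls, direction: Direction, first_pressure: float) -> "EnvelopeState":
        """Seed a tracker from the first observed sample.

        Starting both envelopes at the first sample avoids a spurious
        burst of attack events while the tracker catches up to the
        signal level at power-on.
        """
        if not math.isfinite(first_pressure):
            raise SignalQualityError(f"non-finite initial pressure: {first_pressure!r}")
        return cls(direction=direction, value=first_pressure, last_attack_value=first_pressure)


def update_envelope(
    state: EnvelopeState, p: float, coeffs: TrackerCoefficients
) -> tuple[EnvelopeState, bool]:
    """Advance one tracker by one pressure sample (in place).

    The attack branch fires when the sample moves in the tracked
    direction *or ties* the envelope exactly — a constant signal pins
    both trackers in attack mode, which is what keeps the low tracker's
    counter at zero during a flat-line failure while the high tracker's
    counter runs up to the alarm timeout.

    Returns the (mutated) state and whether the attack branch fired.
    """
    if not math.isfinite(p):
        raise SignalQualityError(f"non-finite pressure sample: {p!r}")
    if state.direction is Direction.HIGH:
        attacked = p >= state.value
    else:
        attacked = p <= state.value
    if attacked:
        a = coeffs.alpha_attack
        state.value = a * state.value + (1.0 - a) * p
        state.last_attack_value = p
        state.samples_since_attack = 0
    else:
        a = coeffs.alpha_release
        state.value = a * state.value + (1.0 - a) * p
        state.samples_since_attack += 1
    return state, attacked


def release_coefficient(r_min: float, r_nom: float, t_max: float) -> float:
    """Release weight that aligns the ratio alarm with the timeout alarm.

    If the pressure drops instantaneously from PIP to PEEP and holds,
    the high envelope decays geometrically toward PEEP (see
    :func:`closed_form_release`) while the low envelope stays put, so the
    high-to-low ratio falls from the pneumatic nominal ``r_nom`` toward 1.
    Choosing

        alpha_release = ((r_min - 1) / (r_nom - 1)) ** (1 / t_max)

    makes the ratio cross the alarm threshold ``r_min`` exactly when the
    time-since-last-peak counter reaches ``t_max`` (in samples), so the
    two noncycling sub-conditions trigger together by design.

    Parameters
    ----------
    r_min:
        Ratio alarm threshold, strictly between 1 and ``r_nom``.
    r_nom:
        Nominal PIP-to-PEEP ratio of the ventilator.
    t_max:
        Alarm timeout in *samples* (may be fractional).
    """
    if t_max < 1:
        raise ValueError(f"t_max must be >= 1 sample, got {t_max}")
    if not (1.0 < r_min < r_nom):
        raise ValueError(
            f"require 1 < r_min < r_nom, got r_min={r_min}, r_nom={r_nom}"
        )
    return ((r_min - 1.0) / (r_nom - 1.0)) ** (1.0 / t_max)


def attack_coefficient(fs: float, tau_s: float = DEFAULT_ATTACK_TAU_S) -> float:
    """Attack weight realizing a given 1/e memory (seconds) at ``fs``.

    Inverse of :func:`attack_time_constant`; with the default memory
    this returns exactly 0.9 at 100 samples/s.
    """
    if fs <= 0:
        raise ValueError(f"fs must be positive, got {fs}")
    if tau_s <= 0:
        raise ValueError(f"tau_s must be positive, got {tau_s}")
    return math.exp(-1.0 / (fs * tau_s))


def attack_time_constant(alpha: float, fs: float) -> float:
    """1/e memory of a one-pole recursive average, in seconds.

    The contribution of a past sample decays as ``alpha**k`` after ``k``
    steps, so the memory is ``-1 / (fs * ln(alpha))``.  With the default
    attack weight 0.9 at 100 samples/s this is roughly 100 ms.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if fs <= 0:
        raise ValueError(f"fs must be positive, got {fs}")
    return -1.0 / (fs * math.log(alpha))


def closed_form_release(
    t_elapsed: float, start: float, floor: float, alpha_release: float
) -> float:
    """Envelope value after ``t_elapsed`` release steps at constant input.

    Under a constant input ``floor``, the recursion contracts the gap
    geometrically:

        v[t] = floor + alpha_release**t * (start - floor)

    This closed form is the analytic oracle for :func:`update_envelope`
    in release mode and the basis of the :func:`release_coefficient`
    calibration.
    """
    if t_elapsed < 0:
        raise ValueError(f"t_elapsed must be >= 0, got {t_elapsed}")
    return floor + alpha_release**t_elapsed * (start - floor)
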