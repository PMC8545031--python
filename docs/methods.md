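# Methods

This note documents the models, parameter choices, numerical behavior
and known limitations of `ventmon`.  It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Envelope tracking

The core of the monitor is a pair of one-pole recursive averagers with
direction-dependent feedback (attack/release), the same primitive used
by dynamic-range compressors in audio processing.  Each tracker stores
one envelope value, the raw sample that last triggered its attack
branch, and a samples-since-attack counter — three scalars per tracker,
versus the ~200 stored samples a two-second rolling min/max window
would need at 100 samples/s.

Under a constant input `c` the release recursion contracts the gap
geometrically, `v[t] − c = α_R^t (v[0] − c)`; this closed form is used
as the analytic oracle for the recursive implementation (agreement to
1e−9 relative over thousands of steps is asserted in the tests — the
recursion and the power form accumulate rounding differently, so exact
bit equality is not expected).

**Tie rule.** A sample equal to the envelope takes the attack branch in
both trackers (`≥` for high, `≤` for low).  Consequently a perfectly
constant signal holds the *low* tracker in attack mode forever (its
counter pinned at zero) while the high tracker's counter runs up — this
asymmetry is what routes a flat-line failure to the
time-since-last-high-peak alarm.

**Initialization.** Both envelopes start at the first observed sample.
Any other choice produces a burst of spurious attack events while the
trackers catch up to the signal level at power-on.

## Coefficients

| parameter | default | meaning |
|---|---|---|
| attack memory | 95 ms | 1/e decay of past samples in attack mode |
| α_A | exp(−1/(f_s·0.0949)) → 0.9 at 100 samples/s | attack weight |
| α_R | ((r_min−1)/(r_nom−1))^(1/(T_max·f_s)) → 0.9993138 at defaults | release weight |
| α_S | 0.5 | per-breath metric smoothing |

Both tracker weights are derived from *time-domain* design quantities
and therefore rescale with the sample rate: the attack weight keeps its
~100 ms memory (exactly 0.9 at 100 samples/s), and the release weight
keeps the alarm-calibration identity below with T_max expressed in
samples at the configured rate.  Keeping the dimensionless weights
fixed across rates instead would change the tracker's physical behavior
with f_s; in particular, at 10 samples/s a 0.9 attack weight implies a
~1 s attack memory, which is slow enough that the first post-peak decay
sample can still lie above the envelope, register as an attack, and
overwrite the recorded breath-cycle maximum.  An explicit
`alpha_attack` override is available for studying that regime.

**Release calibration.** If pressure drops instantaneously from PIP to
PEEP and stays there, the high envelope decays per the closed form
while the low envelope holds at PEEP, so the envelope ratio reaches
r_min exactly when the time-since-last-peak counter reaches T_max —
the ratio and timeout noncycling sub-conditions are designed to fire
together.  `release_coefficient` inverts that relation; the round trip
is exact to 1e−12 relative and the coincidence is verified to ±1 sample
in simulation.

## Breath-cycle state machine

A binary inhaling/exhaling state toggles on the first *exclusive*
attack event of the opposite tracker.  At the exhale→inhale transition
PEEP is updated from the low tracker's last attack value; at the
inhale→exhale transition PIP is updated from the high tracker's last
attack value, the peak-to-peak interval (samples-since-previous-peak
minus samples-since-current-peak) updates the smoothed period, and the
peak counter is rebased onto the current peak.  Metrics therefore
update exactly once per breath cycle regardless of sample rate.

Degenerate case: a sample that attacks *both* trackers is possible only
when it ties two equal envelopes (e.g. a constant signal from startup).
Such a sample is neither a breath maximum nor a minimum, so it produces
no transition; a constant input never toggles the breath state.  On any
non-degenerate signal this rule coincides with evaluating the high
branch before the low branch as the single-pass loop is written.

First-cycle seeding: the first measured PIP, PEEP and period initialize
the smoothed values directly (smoothing against an undefined prior
would bias startup, and the reciprocal-rate form of the update is
undefined at rate zero).  The very first peak interval — startup to
first peak — is not a breath period and is discarded; metrics are
flagged invalid until one full peak-to-peak cycle has been observed,
and rate alarms are gated on that flag.

Displayed metrics are quantized to 1 cm H2O and 1 breath/min; alarm
comparisons always use the unrounded values.

## Alarm engine

The four noncycling sub-conditions combine by OR — each catches a
different failure shape (flat at PEEP, flat at PIP, small residual
oscillation).  Two guards handle regimes where sub-conditions are
meaningless:

* **Warm-up** — ratio and difference are suppressed until the first
  completed breath cycle or T_max seconds, whichever comes first; at
  startup the envelopes are initialized equal and would trip both
  immediately.  The time conditions need no suppression (their counters
  start at zero).
* **Ratio floor** — the ratio check is skipped while the low envelope
  is below 0.5 cm H2O: near atmospheric pressure the ratio is
  numerically meaningless, and the low-pressure alarm owns that regime
  (a spontaneously breathing patient can pull the airway to ~0).

Thresholds are validated against their permitted tunable ranges
(p_max 30–90, p_min 1–20 cm H2O; RR limits 15–60 and 5–15 breaths/min;
T_max 5–30 s) with the violated range named in the error.  Defaults sit
mid-range: p_max 40, p_min 5 cm H2O, RR limits 40/8, T_max 15 s,
r_min 1.5, d_min 3 cm H2O, r_nom 2.4.  Alarms auto-clear when their
condition clears; the event timeline records one onset/clear pair per
maximal run of activity, with the triggering sub-condition (priority
order time_high, time_low, ratio, difference at the onset sample) noted
for noncycling events.

## Waveform simulator

The generator reproduces the *shape* of a pressure-cycled waveform
without a lung model: each cycle is an exponential approach toward a
virtual target above PIP, rescaled to touch PIP exactly at end of
inspiration, then an exponential decay rescaled to touch PEEP exactly
at end of cycle.  Cycle boundaries are laid on the sample grid so the
mean period is exactly 60/rr seconds.  Defaults: PEEP = PIP/2.4 (the
pneumatic ratio), inspiratory fraction 1/3, shape time-constants a
quarter of the inspiratory and a third of the expiratory phase — chosen
once to give the familiar rounded rise and near-complete decay; the
real artificial-lung compliance and resistance behind such recordings
are not publicly characterized, so these are conventions, exposed as
`tau_insp`/`tau_exp`.  Noise is additive white Gaussian with a seeded
generator.  Scheduled events reproduce the failure scenarios: full or
partial disconnect, obstruction (momentary dip then steady high),
PIP-dial changes ramped over one cycle by default (PEEP following
mechanically; set `ramp_s: 0` for a step), spontaneous patient breaths
(a raised-cosine dip below PEEP), and small-amplitude noncycling
oscillation.  `square_cycling` provides an idealized plateau waveform
on which the envelopes converge to PIP/PEEP to machine precision —
the reference input for the exact alarm-calibration checks.

What the simulator does **not** emulate, and hence what passing tests
do not show about real data: lung mechanics (compliance/resistance
transients, cardiogenic oscillations), sensor artifacts (quantization,
drift, band-limited noise), breath-to-breath period variability, and
partial rebreathing waveform distortions.  Its perfectly regular clock
makes period-quantization effects at low sample rates *more* coherent
(a 17/18-sample sawtooth at 10 samples/s for a 35 breaths/min waveform)
than a physiological recording would show.

## Sample-rate experiment

The monitor runs on the same fast-breathing waveform (35 breaths/min —
faster than typical adult rates, making peaks maximally hard to sample;
24/10 cm H2O, noise sd 0.3, 120 s, five seeds) at 100 samples/s and at
decimated rates 50/20/10/5; per-breath PIP and RR estimates are
compared by RMS difference against the full-rate run, pairing breaths
by nearest detection time.  Time pairing matters: when the low-rate run
occasionally misses one low-tracker attack (a noise dip having pulled
the low envelope under the next trough's sparse samples) and merges two
breaths, the resulting rate excursion is charged locally instead of
misaligning every subsequent breath.  Problem sizes (120 s traces, five
seeds) keep the whole experiment under a second while giving ~70
breaths per run.

## Estimation accuracy under noise

Because PIP and PEEP are taken from the raw samples that trigger attack
events, under additive noise they are extreme-order statistics of the
near-peak samples: the PIP estimate is biased slightly above the true
peak and the PEEP estimate slightly below the true trough (≈0.2–0.3
cm H2O at noise sd 0.3 and 100 samples/s).  This bias is inherent to
the attack-value rule, sits well inside the 1 cm H2O display
resolution, but can exceed a 2%-of-PEEP band when PEEP is small
(≈8.3 cm H2O at the lowest PIP dial setting).  Averaging the envelope
rather than the attack sample would reduce it at the cost of a lag —
the attack-value rule is kept as specified.

## Numerical and degenerate-input behavior

Non-finite pressure samples raise a signal-quality error naming the
offending sample.  Empty traces, nonpositive rates/periods and
out-of-range calibration counts are rejected with named errors.  A
single-sample trace seeds the envelopes and reports no metrics.  All
batch outputs are pure functions of (trace, config, thresholds); the
simulator is deterministic given its seed, and trace CSVs round-trip
values to better than 1e−9.
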