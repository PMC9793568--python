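# Methods

## The drift test

**Data model.** A mapping session yields a projected-field observation: a
centroid on a fixed 2-D hand template (threshold-level stimulation, which
evokes a pen-tip-sized percept) or a drawn extent polygon (maximum-level
stimulation). Coordinates are millimetres, origin at the template's
lower-left corner, x rightward, y upward. The time-ordered threshold-level
centroids of one electrode contact form a trajectory; consecutive
observations give displacement steps (d_j, θ_j) with d_j the Euclidean
distance in mm and θ_j = atan2(Δy, Δx) wrapped to [0, 2π).

**Statistic.** The distance-weighted vector strength
vs = |Σ_j d_j e^{iθ_j}| / Σ_j d_j lies in [0, 1]: 1 iff all nonzero steps
share a direction, near 0 under isotropic jitter. Weighting by distance means
large steps dominate — a single big directed jump among small jitter is
evidence of migration, which is the scientifically intended sensitivity.
Zero-length steps contribute to neither numerator nor denominator; if *all*
steps are zero-length the statistic is undefined and an error is raised
rather than reporting 0.

**Null and p-value.** The null hypothesis is "no systematic direction": the
observed distances are kept fixed and each direction is redrawn i.i.d.
Uniform(0, 2π), n_mc = 10,000 times by default. Conditioning on the observed
step sizes isolates directional structure, the quantity of interest. The
reported p-value is the conventional upper tail with add-one correction,
p = (1 + #{vs_null ≥ vs_obs}) / (n_mc + 1), so p ∈ (0, 1] and ties count
conservatively toward rejection. The complementary lower-tail proportion is
exposed as `prop_null_below` because verbal descriptions of "the proportion
larger than chance" are easy to read as either tail. The seed is a required,
logged parameter; identical seeds give identical results.

**Invariances.** vs is invariant to rescaling all d_j by a common factor and
to rotating all θ_j by a common angle, so neither the unknown digitization
scale of the hand template nor its orientation affects inference. Both
invariances, the [0, 1] bounds, and agreement with an independent
complex-resultant implementation to 1e-12 are property-tested.

**Degenerate cases and numerics.** One step gives vs = 1 and p = 1 always —
the test has no power at n = 1. Analytically-unit vector strengths can land
at 1 ± a few ulp in floating point; values within 1e-12 of 1 are snapped to
exactly 1 so the degenerate guarantee holds identically. Computed vs values
are clamped to [0, 1].

## Synthetic world

The generators state one fixed world; their defaults are not tuned.

* **Trajectories.** Random walk from a start point: step lengths are
  half-normal with scale 0.5 mm (sessions move the field "typically a
  millimetre or less"; the true measurement-noise law is unreported, so the
  scale is a simulation parameter, not an estimate). Step directions are von
  Mises with concentration κ about the instantaneous bearing toward a target
  (the sensor-congruent location). κ = 0 reduces *exactly* to Uniform(0, 2π)
  — the no-migration null — and growing κ gives increasingly directed drift;
  this is the simplest one-parameter alternative family nesting the null.
  Sessions are 30 days apart (mapping visits were weeks to months apart);
  12 observations per trajectory is the default cohort shape.
* **Force traces.** Poisson contact onsets (default 2/min), exponential
  contact durations (mean 3 s), trapezoidal force profiles with plateau
  uniform on [0.3, 1] × readout_max, non-overlapping by construction,
  sampled at 10 ms. This emulates a day of grasping (>100 contacts), not any
  particular sensor's noise spectrum.
* **Usage logs.** Per-day wear hours, actuation minutes and stimulation
  minutes are gamma-distributed with the configured means and a common
  coefficient of variation (default 0.3, a plausible day-to-day spread for
  habitual wear; cv = 0 degenerates to constants). Wear is clipped to
  [0, 24] h and the two duration columns are clipped to the day's wear time.
* **Subject.** A deterministic observer: feels a pulse iff its charge ≥ a
  fixed threshold. A step-function psychometric curve validates search
  procedures; it does not model lapses or a graded slope.

What a green test therefore establishes: the test is calibrated and powerful
*within this stated world*. It does not establish anything about real
digitization error, sensor calibration, or behavioural response noise.

## Feedback encoder

While the thumb sensors are in contact, the averaged readout r maps linearly
to pulse frequency f = 5 + 25·(r / readout_max) Hz, so the lightest detected
contact already stimulates at 5 Hz and full scale gives 30 Hz; out of
contact the channel is silent. Sensor units are a device calibration, so the
encoder is specified on normalized readouts. Encoding proceeds in 100-ms
epochs anchored at each contact onset, each carrying the frequency of the
epoch-mean readout (zero-order hold). Continuous stimulation within one
contact event is capped at 5 s — epochs past the cap are emitted at 0 Hz
until release — and the cap re-arms on the next contact event (whether
micro-releases within one grasp should re-arm it is unknowable from the
published description; per-event reset is our documented choice). Contact
detection is readout > deadband, deadband defaulting to 0.

Pulses are cathodic-first, current-controlled, charge-balanced biphasic
waveforms with a 50 µs interphase delay and 10:1 asymmetry: the anodic phase
is 10× wider at 1/10 the amplitude, so phase charges are equal exactly by
construction. Charge per phase is amplitude (µA) × width (µs) / 1000, in nC.
Perceptual thresholds use the ascending method of limits (probe start,
start+step, ... until first detection; overshoot < one step), the feedback
contact is the one with the lowest threshold charge (lexicographic tie-break
on contact id), and the maximum-intensity mapping stimulus is a preset at
120% of threshold amplitude, 30 Hz.

## Usage analytics

Mean daily wear (h) and stimulation (min) average over *all* logged days,
including zero-wear days; whether published means excluded such days is
unreported, and the per-day frame is retained so either convention is
computable. Cumulative curves are running totals over study days. The
epoch-frequency distribution pools ON epochs across trains, bins over
[5, 30] Hz, and reports the exact order-statistic median.

## Calibration harness and test scaling

`calibrate_test` estimates the rejection rate at level α over simulated
trajectories, spawning per-simulation seeds deterministically from one root
seed (NumPy `SeedSequence`). The acceptance suite runs the null calibration
at the prescribed scaled-down n_mc = 2,000 over 1,000 trajectories of 12
points (rejection within [0.03, 0.07] at α = 0.05; p-values uniform by
Kolmogorov–Smirnov at the 1% critical value plus the add-one grid spacing),
and the power sweep over κ ∈ {0, 1, 2, 4, 8} at n_sims = 250, n_mc = 500 —
scaled to keep the suite in seconds; rates at these settings are ≈0.03,
0.32, 0.82, 1.0, 1.0, so the monotonicity check has wide margins.

## Known limitations

* The hand template's absolute scale is not recoverable from published
  figures; all mm values are template-relative (the test itself is
  scale-invariant).
* Polygons are simple rings without holes; geometry (area, Jaccard overlap)
  is delegated to shapely.
* No closed-form Rayleigh/V-test inference path: the Monte Carlo null is the
  primary (and only) inference route, with closed-form expectations used
  solely as test oracles.
* The usage-log parser reads this package's CSV schema, not any embedded
  controller's binary format.
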