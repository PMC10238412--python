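# Methods

This note documents the models, conventions, parameters and numerical
choices behind `whalekin`, and what the synthetic-deployment tests do and
do not establish about real tag data.

## Conventions

Time is seconds since tag-on; the tag-on wall clock, its UTC offset and the
deployment position live in `Deployment`. Depth is meters, positive down,
zero at the sea surface after calibration. The body frame is NED-style
(x forward, y right, z down); pitch is positive nose-up, roll positive
right-side-down, heading clockwise from magnetic north. A motionless level
accelerometer reads the specific force (0, 0, −1) g. The body-to-world
rotation is `Rz(heading)·Ry(pitch)·Rx(roll)`; the simulator and the
analyzer share these definitions through one set of helpers, while the
closed-form unit tests (e.g. pitch 30° ⇒ accelerometer (0.5, 0, −0.866) g)
pin the convention independently of the code that uses it.

## Sensor canonicalization

Channels are ingested at native rate and decimated to a single analysis
rate (default 10 Hz; tags whose channels run at 5 Hz are analyzed at 5 Hz
rather than upsampled). Decimation uses a polyphase FIR anti-alias filter;
the channel mean is removed before filtering and restored afterwards so a
constant channel survives decimation exactly. The native-rate accelerometer
is retained alongside the decimated copy because the tag-jiggle speed proxy
lives above the analysis-band Nyquist.

Depth zeroing finds runs (≥ 10 s) of samples within 1.5 m of the record
minimum and maps their median to 0 m. The rule is translation-covariant,
hence idempotent, and removes any constant pressure offset exactly; what it
cannot know is the true depth of the tag while the animal rests at the
surface, so absolute depths retain a bias of order the surface riding depth
(decimeters). A full temperature-dependent pressure model is out of scope.

## Orientation and speed

The gravity estimate is a zero-phase (forward-backward) 3rd-order
Butterworth low-pass at 0.3 Hz — below stroking frequencies (~0.5 Hz) and
chosen zero-phase so filtering never shifts event times; the residual is
the dynamic acceleration. Pitch = asin(f_x/‖f‖), roll = atan2(−f_y, −f_z);
frames whose static-norm falls outside [0.5, 1.5] g are masked. Heading
de-rotates the magnetometer by roll then pitch and takes
atan2(−m_y, m_x) + declination (declination defaults to 0: relative
headings suffice for circling detection). Samples whose horizontal field
fraction is negligible (near-vertical field) are masked.

OCDR divides the smoothed (1 s) depth rate by |sin(pitch)| and is masked
where |pitch| < 30°; the mask bounds the 1/sin error amplification. Tag
jiggle is the sliding-window (1 s) RMS of the 10–45 Hz band-passed
accelerometer magnitude at native rate; speed is calibrated by ordinary
least squares of OCDR on ln(jiggle RMS) over co-valid samples (≥ 50
required) and the fit is applied everywhere, clipped at zero. When the
band does not fit under the native Nyquist (5 Hz tags) the pipeline falls
back to gap-interpolated OCDR; sharp speed events such as lunges are then
poorly resolved, which mirrors the real limitation of low-rate tags.

MSA = |‖accel‖ − 1 g|·g is, by the reverse triangle inequality, a
per-sample lower bound on the true propulsive acceleration magnitude —
exactly so on noise-free signals, which is how the bound is tested; sensor
noise perturbs ‖accel‖ in both directions. A magnetometer-based separation
of rotational from propulsive acceleration is a possible extension, not
implemented; the norm-based estimator is deliberately conservative.

## Dives, phases, buoyancy, breaths, diel

Dives are maximal intervals above a 2 m surface threshold whose maximum
depth reaches 10 m. The 2 m threshold is robust to surface-wave noise at
10 Hz; both numbers are parameters. Phase boundaries come from the bottom
band [max_depth·(1 − tol), max_depth]: descent ends at first entry, ascent
starts at last exit; tol defaults to 15 % of max depth ("levels to a
relatively narrow depth range"), and a V-shaped dive degenerates to a
zero-length bottom phase. On sharply-cornered simulated dives a 2 % band
recovers the true leveling points to a few seconds; gradual real dives
favor the wider default.

Fluking is declared where the windowed (4 s) power of the 0.3–1 Hz
band-passed dynamic acceleration exceeds 5 % of the dive's maximum window
power; the descent glide onset is the depth of the last fluking sample
before the first sustained (≥ 10 s) glide of the descent, with the mirror
rule on ascent. The neutral-buoyancy proxy is the median over dives of the
per-dive mean of the two cessation depths (≥ 3 complete dives required);
dives without detectable fluking are excluded and logged.

Breaths: without an audio proxy, shallow (< 0.5 m) depth minima with ≥ 2 s
spacing and ≥ 0.15 m prominence; with an exhalation-envelope channel, one
breath per envelope pulse at the shallowest depth within ±1 s, accepted
when that depth is < 0.5 m. The envelope-gated rule handles flat surface
traces (which have no strict minima) and makes precision robust to surface
chop.

Diel labels use geometric solar elevation from the standard NOAA
fractional-year / equation-of-time / declination equations (well under 1°
error, ample for a −6° civil-twilight threshold); elevation exactly at the
threshold counts as day so labeling is deterministic. Hourly rate tables
use complete local clock hours only, discard the partial first/last hours,
and assign the hour containing the evening crossing to night and the
morning crossing to day. An explicit twilight table overrides the
computation.

## Circling and lunges

Heading is unwrapped with shortest-arc increments over runs of valid pitch
(|pitch| < 85°, avoiding gimbal lock). The cumulative rotation is
decomposed into *swings* between confirmed extrema, where an extremum is
confirmed once the series retraces more than the reversal tolerance
(default 30°) beyond it; a swing starts at the last attainment of its start
extremum and ends at the first attainment of its end extremum, so
no-rotation stretches never pad an event. Swings of ≥ 180° lasting ≥ 3 s
(the shortest plausible circle) are circling events. Because the swing
definition alone would let turns minutes apart accumulate across
constant-heading stretches, sustained standstills (rotation rate < 2°/s
for ≥ 10 s, measured over a ±1 s span so magnetometer noise cancels before
rectification) split the series; the rule is parameterized and can be
disabled, which the brute-force oracle comparison does to test the core
swing machinery in isolation.

Lunges are local speed maxima above a deployment-adaptive threshold (90th
percentile of in-dive speed, or an absolute override), standing ≥ 1 m/s
above the pre-peak baseline, whose post-peak deceleration reaches
0.2 m/s² and whose speed falls below the baseline within 15 s. Each circle
links to the first subsequent unlinked lunge within 30 s of its end; a
lunge peaking inside the circle's last 15 s also counts, because sensor
noise randomizes where along the post-circle constant-heading stretch the
rotation extremum lands. The unlinked fraction is the failed-attempt
fraction.

## Energetics

Mass defaults to the allometric value 1000·0.012965·L^2.74 kg (≈ 5.67 t at
L = 9.2 m); a working override (e.g. a rounded 6 t) can be supplied and
both values are carried. Power is M·MSA·v; work is the integral of the
linear interpolant of power, with exact fractional endpoints, so work is
additive over any partition to rounding error and exact for piecewise-
linear power. Masked samples are linearly interpolated; an interval with
more than 20 % masked time is refused. Activity intervals partition each
foraging dive: descent and ascent from the phase boundaries, lunges claim
±15 s windows around their peaks (taking precedence over circles on
overlap), circles their detected intervals, and the remainder of the
bottom phase is "bottom". Lunges show the highest median work per second
and the highest peak power of any activity; total joules per instance can
be larger for the much longer fluking ascent, which is why cost
comparisons across activities are reported as rates and peaks.

## The synthetic deployment generator

The generator renders a behavioral schedule — daytime foraging dives at a
configured hourly rate to 150–210 m, 1–6 lunges per dive (median 1),
circling before ~60 % of lunges with occasional lone (failed) circles,
post-dive surfacings with 7–13 breaths, night dominated by surface rest
with occasional 50–100 m non-foraging dives — into piecewise-linear speed,
pitch, roll and heading profiles on a 10 Hz truth grid. Depth is the
trapezoidal integral of −v·sin(pitch), which is exact when pitch is
constant and speed linear within a segment, so glide onsets and dive
bottoms land exactly at their configured depths. True per-phase work is
the exact integral of the product of the linear interpolants of the
specific-acceleration magnitude and speed, times mass.

Key defaults and their basis: lunge peak speed 5.6 m/s over a 2 m/s cruise
(observed rorqual lunge speeds), ~30° lunge roll with pitch-up-then-down,
descent/ascent pitch ±50°, glide onsets at 26 m (symmetric) or 24/38 m
(asymmetric scenario averaging 31 m), stroke frequency 0.5 Hz with
0.5 m/s² cruise and 1.5 m/s² lunge stroke amplitude (the 1:3 ratio keeps
cruise fluking above the 5 % adaptive glide threshold), circling rotations
of 200–400° over 10–60 s with 5° heading jitter and alternating direction
within a dive, and the 2018-style sensor regime (pressure 10 Hz,
accelerometer 800 Hz, magnetometer 40 Hz). Tag jiggle is band-limited
noise in 0.25–0.45 of the native rate with RMS k·exp(c·v) (k = 0.006 g,
c = 0.45 /m·s⁻¹), plus a slow lognormal wander of the envelope (sd 0.15,
20 s correlation) because the vibration/speed coupling of a real tag
drifts with placement and flow angle — that wander is what keeps the
jiggle–OCDR calibration at field-realistic R² ≈ 0.65–0.75 instead of ~1.
Sensor noise: 0.003 g accelerometer, 0.3 µT magnetometer, 0.05 m depth.

Propulsion is surge-aligned (body x) by default. A heave mode places the
whole propulsive signal on the gravity-aligned body z axis; it exists
because MSA equals the true propulsive magnitude only under that
alignment, which is what the work-recovery validation needs. The realistic
surge mode leaves MSA a strict lower bound, as it is in the field.

What the generator does *not* emulate: hydrodynamics and drag (speed is
prescribed, not dynamically consistent), prey fields, tag slip and
orientation drift, temperature-dependent pressure drift, fractal surface
behavior, or acoustic waveforms (a pulse-per-breath envelope channel
stands in for the hydrophone). Passing tests therefore demonstrate that
the pipeline correctly inverts a forward model with the right qualitative
structure and realistic noise levels — not that its default thresholds are
optimal for any particular real deployment, which is why every threshold
is a parameter.

## Problem sizes

The test-suite and the reproduction script run a compact configuration
(`demo_config`): ~3 daylight hours at 8 dives/hour (≈ 23 dives, ≈ 44
lunges, ≈ 180 breaths) with a 100 Hz accelerometer and 20 Hz magnetometer,
plus a 1 h noise-free deployment for bound checks and 1000 random static
attitudes for the orientation round trip. These sizes give every detector
dozens of events while a full run stays under a minute on one core; the
generator's own defaults remain the full 24 h / 800 Hz regime.

## Known limitations

* MSA-based power is a lower bound and, off the gravity axis, a loose one;
  absolute energetics should be read as relative comparisons between
  activities and individuals, as the mass is itself an allometric guess.
* The jiggle calibration is deployment-specific and needs steep-transit
  OCDR coverage spanning a range of speeds; it cannot rescue 5 Hz tags.
* Tag-slip correction is the caller's responsibility (per-segment frame
  rotations applied upstream); the pipeline assumes a fixed tag frame.
* Heading is magnetic; supply the local declination for true-north work.
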