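# Methods

`mindmotion` analyses two data streams from an eight-week, eight-participant
VR-delivered group mindfulness program: head-orientation recordings from the
participants' headsets, and three questionnaires (SWLS, MAAS, MMSE)
administered before, at midterm, and after the program. The participants
form two groups of four — outpatients recovering from brain injury/tumour
("patients") and hospital employees with self-reported stress — and each
weekly session moves through segments set either in a rendered virtual
environment (fireplace room, mountain view) or a 360-degree nature video
(Dooney Rock, River Bonnet).

## Head-motion model and processing chain

**Orientation representation.** The headset reports orientation as
timestamped unit quaternions at a nominal 50 Hz, which avoids gimbal-lock
singularities at acquisition time. Components are stored scalar-last
(`qx,qy,qz,qw`), the convention of the Unity/GearVR stack the recordings
originate from. `q` and `−q` encode the same rotation; the sign is pinned to
`qw ≥ 0` so outputs are unique.

**Euler conversion (intrinsic Y–Z–X).** Analysis works on yaw (about the
vertical Y axis), pitch (about Z) and roll (about X), factored in that
intrinsic order — the natural frame for a seated wearer. Writing
R = Ry(ψ)·Rz(θ)·Rx(φ), the extraction is

    θ = asin(R₂₁),   ψ = atan2(−R₃₁, R₁₁),   φ = atan2(−R₂₃, R₂₂)

with two-argument arctangents throughout, so yaw and roll cover the full
(−180°, 180°] range and pitch [−90°, 90°]. Within 0.1° of |pitch| = 90° the
yaw/roll pair degenerates (gimbal lock); the convention here sets roll := 0
and absorbs the residual rotation into yaw, computed from the first matrix
row, which stays well-conditioned. This is a deterministic
reparametrization: the rotation itself is preserved (tests verify the
reconstructed matrix). The conversion is hand-written; `scipy`'s `Rotation`
and a brute-force grid factorization serve as independent oracles in the
test suite only.

**Resampling.** Sensor timestamps jitter (the generator's default emulates
2 ms of it), so after per-sample conversion each channel is unwrapped
(no consecutive jump may exceed 180°) and linearly interpolated onto a
uniform grid at the nominal rate. Spectral analysis assumes this uniform
grid. Unwrapping means genuine tracking glitches survive as steps of at
most 180° for the conditioning stage — an orientation stream cannot encode
a larger step, which also bounds what any repair stage can be asked to
find.

**Filtering.** A zero-phase Butterworth low-pass (applied forward and
backward, `sosfiltfilt`) removes sensor noise above the sub-hertz band
where head motion lives. Defaults: cutoff 2 Hz, order 4. The cutoff is
deliberately a configuration parameter: it must sit well above the
0.34–0.44 Hz analysis bands and below the Nyquist frequency (25 Hz at
50 Hz sampling); a requested cutoff at or above Nyquist is refused as a
no-op filter. The first and last `max(order, 10)` filtered samples are
excluded from downstream metrics (edge transients).

**Discontinuity repair.** Tracking re-references and residual wrap
artifacts appear as steps in the angle traces. They are detected on the
*unfiltered* trace (a zero-phase filter smears a step and hides it):
level-1 Haar detail coefficients are computed with the undecimated
(stationary) wavelet transform — the decimated transform sees only
even-aligned steps — and local maxima of the median-centred |detail|
exceeding `threshold_mult × MAD` (default ×8) are flagged. Centring on the
median matters: a constant-slope trace has a large constant detail, and
only deviations from it mark steps. The trace is edge-extrapolated before
the transform so the SWT's periodic wrap-around cannot flag the boundary.
Each flagged step is measured across a ±2-sample straddle with the local
slope subtracted (resampling of jittered timestamps can smear a step over
two samples, so a one-sample difference underestimates it), subtracted
from all later samples, and a short window around the step is linearly
re-interpolated; overlapping windows merge. Repair followed by detection
yields an empty report on the fixture suite, and the detector produces
zero false positives over 1000 seeded smooth traces at the default
threshold.

**Spectra and band power.** Spectra are plain periodograms of the
mean-removed yaw channel: no taper, one-sided, normalized so the power
summed over all bins equals the signal variance (Parseval), making band
power directly interpretable in deg². Windowless spectra keep that
identity exact; the comparisons below are coarse band-power contrasts for
which leakage control matters less than interpretability, and Welch
averaging can be enabled by recomputing on subsegments if needed. Band
power over (f_lo, f_hi] is a half-open sum of bins. Sessions with similar
content are compared by the power above a cut-off frequency — 0.34 Hz for
employees and 0.44 Hz for patients, analyst-supplied constants carried in
configuration, not hard-coded. Channels of unequal length are truncated to
the shorter before comparison so the two periodograms share a grid. The
verdict is *reduced* / *increased* when the later session's high-band power
leaves a ±20% band (`negligible_frac`, configurable) around the earlier
one's, else *negligible*.

**Motion-curve area.** The per-segment "how far did the head wander"
scalar is the convex-hull area of the (yaw, roll) point cloud of the
conditioned trace: deterministic, parameter-free, translation-invariant,
exactly quadratic under scaling, and monotone under added excursions.
Degenerate (constant or collinear) clouds have zero area. A 95%
covariance-ellipse area is available behind `area_metric:
covariance_ellipse` as a robustness check; it assumes an elliptical cloud
and is less faithful for sweep-like trajectories. Changes between matched
segments are reported as signed percentages, negative meaning the later
segment was calmer (100 → 77 is −23%).

## Psychometric scoring

SWLS: five items, 1–7; score is the sum (5–35) with the standard named
bands (31–35 extremely satisfied, 26–30 satisfied, 21–25 slightly
satisfied, 20 neutral, 15–19 slightly dissatisfied, 10–14 dissatisfied,
5–9 extremely dissatisfied). MAAS: fifteen items, 1–6, anchors already
oriented (no reverse-scored items); score is the item mean reported to one
decimal. MMSE is accepted as a 0–30 total and banded normal (25–30), mild
(21–24), moderate (10–20), severe (<10).

Group cells aggregate with the **sample** standard deviation (n−1 divisor)
and **half-away-from-zero** rounding at one decimal. Both conventions are
forced by the published per-participant table: 27.25 must round to 27.3
(banker's rounding gives 27.2), and only the n−1 divisor reproduces the
printed SDs (3.9, 1.8, 0.8, 1.0, 0.7). Where the published table prints an
integer (the employees' midterm SWLS mean of 25), integer rounding of the
same mean is used. Two printed SDs are *not* reproducible from the
individual values under any convention (employees' SWLS-before 2.8 vs the
recomputed 2.9; patients' MAAS-after 0.6 vs 1.1); the recomputed values
are reported and the discrepancy is treated as an inconsistency in the
source table.

## Synthetic data: what it emulates and what it does not

The study's raw recordings were never deposited, so head-motion analyses
run on generated data (`mindmotion.synthetic`), a pure function of
(spec, seed). Per channel, motion is a sum of:

- a Gaussian random-walk drift (default step SD 0.01° per sample — slow
  gaze wander that keeps 30 s traces within a fraction of a degree);
- sinusoidal gaze components. Study-fixture defaults put employees' yaw
  sweeps at 28° amplitude near 0.09 Hz (the "up to ±40°" regime once drift
  and restlessness add in) and patients at half that, with small pitch and
  roll components (the "±10°" regime);
- a 0.6 Hz "restlessness" component, above both analysis cut-offs, whose
  amplitude schedule encodes the study's described pattern: employees calm
  down across sessions in the 360-degree videos (6° × 0.85^(session−1)),
  patients in the rendered environments and sitting practices
  (5° × 0.8^(session−1)), everything else stays level;
- saccade-like steps (true motion) and tracking re-reference artifacts
  (sensor glitches the pipeline must repair), plus 2 ms timestamp jitter.

Three matched segments additionally scale their gaze amplitude to produce
designed motion-area changes of about −23% (employees' sitting, session
5→6), +17% (patients' sitting, 5→6) and −72% (employees' poem reading,
5→7); because restlessness is deliberately left unscaled in the first two
(their spectra should read *negligible*), the realized percentages land
within a few points of the designs rather than exactly on them.

Questionnaire fixtures are item vectors generated to score exactly to the
published per-participant values (SWLS sums exactly; MAAS means within
1/30, so they round to the target at one decimal).

Fixture segments default to 30 s at 50 Hz — a scaled-down stand-in for the
multi-minute program segments that keeps a full 264-recording study cheap
to generate and analyse while leaving ≥18 periodogram bins below 0.6 Hz.
What passing tests on this data shows: the chain recovers injected
frequencies, amplitudes, areas and artifacts, and classifies the designed
contrasts correctly. What it does not show: behaviour under real sensor
noise spectra, biomechanical coupling between axes, magnetometer drift, or
participant idiosyncrasies — none of which are modelled.

One caveat the fixture exposes honestly: with rectangular-window
periodograms, a large sub-cutoff sweep leaks some power above the cut-off,
so comparison cells whose high-band contrast was *not* designed (e.g. the
patients' 360-video body scan) can scatter across verdicts at these short
durations. The designed cells are robust to it.

## Numerical choices and degenerate inputs

- Quaternion norms must be within 1e-3 of 1 for conversion (normalize
  first); normalization rejects the all-zero quaternion by sample index.
- Duplicate timestamps and recordings shorter than two sample periods are
  hard errors; missing segment *files* are warnings that exclude the
  affected comparisons and mark the report partial (small feasibility
  studies have dropouts).
- Zero-variance channels yield all-zero spectra, not errors; a zero
  high-band baseline with positive later power reports an infinite ratio
  sentinel (`null` in JSON) and the verdict *increased*.
- A zero baseline area makes percent change undefined → error.
- Reports carry a config hash, seed and package version, never a wall
  clock, so identical inputs give byte-identical outputs.

## Known limitations

- The convex hull measures the envelope of excursion, not time spent at
  the extremes; a single large sweep dominates it.
- The ±8 MAD detector is tuned for step artifacts ≳ tens of degrees on
  calm traces; artifacts comparable to the motion's own sample-to-sample
  variation are not detectable in principle at this threshold.
- Group-level inference (only 4 per group) is descriptive: means and SDs,
  no hypothesis tests, matching the feasibility framing.
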