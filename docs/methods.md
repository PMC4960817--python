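# Methods

This note documents the models, defaults and numerical choices behind
`gazeperim`, and what the synthetic test bed does and does not establish
about real recordings.

## Device geometry

The perimeter is modelled as two perpendicular arms of stimulus locations
at integer multiples of a 1° angular pitch, with the fixation marker at 0°
and no stimulus there: 95 locations per side on the horizontal arm
(±1°…±95°, 190 total) and 135 on the vertical arm. The vertical split is
75 inferior / 60 superior: the arm count alone does not fix the split, and
this choice matches the asymmetry of the normal monocular field (~75°
inferior, ~60° superior reach) while summing exactly to 135.

The angular grid is the authoritative coordinate system. The physical
figures (870 mm span, 525 mm depth, 10 mm linear LED pitch) are carried as
metadata only: 190 LEDs at 10 mm pitch imply ~1.9 m of strip, which no
single arc within an 870 × 525 mm footprint reproduces at uniform angular
spacing, so deriving angles from millimetres is not well-posed. Azimuth is
positive toward the patient's right and elevation positive up, for both
stimulus and gaze angles.

## Scheduling

Inter-stimulus gaps are drawn uniformly from 0.5–5 s — the interval is
specified only as random within that range, and uniform is the maximum-
entropy choice. Stimulus order is a uniform random permutation; in
accurate mode locations with unfinished staircases re-enter a random pool
each draw (never the same location twice in a row unless it is the only
one left), so spatial position stays unpredictable throughout.

Catch trials default to 10 % of events — a conventional perimetric rate;
the false-positive bookkeeping requires some nonzero rate but no
particular value. Stimulus duration defaults to 200 ms and is
configurable, since localization accuracy depends on it (below). Fast mode
subsamples the grid every 10° (31 locations) at full brightness with the
hardware's intensity jitter, one presentation each; at the default
interval range this finishes in ~1.5 min of scheduled time. Accurate mode
runs all 325 locations; its simulated duration (~2¼ h of exam-clock time
at the default 0.5–5 s gaps) is reported, not constrained — a wall-clock
exam-time target would be a property of the hardware and of a tighter
interval configuration, not of the algorithm.

All stochastic draws flow through one numpy generator seeded by the
protocol, so identical protocols yield byte-identical schedules, traces
and reports.

In accurate mode the staircase may request attenuations that take the
commanded intensity below the colour's nominal minimum (e.g. red below
550 mcd); thresholding is impossible without this, and the stimulus
hardware's dimmable range is treated as reaching down from the colour
maximum.

## Sensitivity scale and staircase

Sensitivity is stimulus attenuation in dB below the colour's maximum
intensity, `a = 10·log10(I_max/I)`, on a 0–25 dB scale. The colour maximum
is the only printed anchor for the scale's zero, so 0 dB = brightest
available stimulus, and a 25 dB threshold means the location still
perceives a stimulus ~316× dimmer.

Thresholds are estimated with a two-reversal 4–2 dB staircase, the
standard adaptive rule in static perimetry: start at 0 dB; seen → +4 dB
(dimmer), missed → −4 dB; the step halves to 2 dB at the first reversal;
the run ends at the second reversal, reporting the midpoint of the last
seen/missed pair, clipped to [0, 25]. Two forced terminations avoid wasted
presentations: a seen presentation already at the 25 dB ceiling ends the
run at 25 (nothing dimmer exists to probe), and a second miss at 0 dB ends
it at 0 (an absolute defect, retested once before being accepted).

The presentation cap is 10. Bracketing a threshold near the top of the
scale needs up to seven 4-dB ascents (0, 4, …, 24) plus two 2-dB probes,
i.e. nine presentations; a cap of 10 guarantees termination without
truncating legitimate runs, and a noiseless responder with any true
threshold on a 1-dB grid in [2, 23] is recovered within the 2 dB final
step (verified exhaustively in the tests).

Blink-contaminated presentations are re-presented once rather than scored
— a blink is an invalid observation, not a miss.

## Response classification

Saccades are maximal runs of samples with angular speed ≥ 30°/s (central
differences over valid samples), merged across gaps < 20 ms, kept at
amplitude ≥ 2° — conventional velocity-threshold detection values, all
configurable. A stimulus is "seen" when a saccade starts within
[0.15, 1.5] s of onset, its displacement component along the stimulated
axis (signed toward the stimulus) is at least half its amplitude, and it
lands within 5° of the stimulus angle on that axis. The window excludes
anticipatory movements below 150 ms and allows slow paediatric responses;
the 5° landing tolerance balances the 1° grid against physiologic
saccadic under/overshoot. Events whose response window is more than 30 %
invalid samples are blink-contaminated and flagged for re-presentation.

False positives are catch trials answered with a qualifying movement plus
stray saccades outside every response window. A stray saccade only counts
if it *starts* within 5° of fixation: a habitual excursion is one
movement, and without this rule its return sweep — equally large, starting
eccentric — would be counted a second time.

False negatives are full-brightness (0 dB) stimuli with no response,
excluding blink-flagged events. In fast mode the hardware jitters
intensity inside the colour range, so everything within the range's own
span of 0 dB counts as full brightness there.

The localization–duration relation is summarized by an ordinary
least-squares fit of group-mean landing error against stimulus duration;
with the simulator's defaults (below) two groups at 100 and 300 ms give a
slope of −5°/s.

## Image chain

Registration is exhaustive integer-pixel normalized cross-correlation over
the ±`max_shift` grid, scored on the overlapping region, ties broken
toward the smaller shift. Sub-pixel registration is unnecessary at the
chain's ≤ 0.5° accuracy target and integer search is exactly verifiable
against brute force. A best shift on the search boundary flags the frame
invalid (head moved too far); invalid frames become blink samples, not
errors.

The illumination surface is the per-pixel median of reference frames taken
at several gaze angles, minus its global median. The median across frames
rejects the moving pupil, leaving background structure (sclera, skin,
shading), so subtracting it flattens static nuisance without eroding the
pupil wherever it currently is. With a single reference frame the pupil
leaks into the surface; the calibration helper documents the need for ≥ 3
frames at distinct gaze angles.

Median filtering uses a 3×3 mask by default (no mask size is dictated by
the problem; 3×3 removes impulse noise at minimal blur) with
edge-replicated borders. Pupil segmentation assumes a dark pupil: pixels
below 0.5× the frame mean, largest connected component, darkness-weighted
centroid; component areas outside [10⁻⁴, 0.25] of the frame are rejected
as blinks/eyelid closure. Gaze calibration is a least-squares affine map
from pupil-centre pixel offsets to degrees (≥ 3 non-collinear points), its
RMS residual reported.

## Simulated patient

Perception is a cumulative-normal frequency-of-seeing curve over the
ground-truth map: `P(seen) = (1 − lapse)·Φ((t − a)/slope)`, defaults
slope 1 dB, lapse 1 % — a standard psychometric model with a spread
comparable to the staircase's final step. Catch trials are never "seen"
through perception; simulated false positives arise only from habitual
saccades.

Oculomotor behaviour around the decisions: latency N(250, 50²) ms;
landing scatter with SD `2.5° − 5(°/s)·duration`, floored at 0.1°, which
encodes the linear improvement of localization with stimulus duration
(100 ms → 2°, 300 ms → 1°) — a patient configured with zero base scatter
is genuinely noiseless; return to fixation 0.3–0.6 s after landing;
fixation drift as a mean-reverting (OU) walk with 0.3° stationary SD and
2 s correlation time (slow enough never to trip the velocity threshold);
blinks as Poisson invalid-sample gaps (0.1/s × 150 ms); habitual saccades
as a Poisson process toward uniform random angles within ±30°. Saccades
are instantaneous steps at trace resolution: velocity profiles do not
affect any verdict at 60 Hz (the default rate, typical of consumer
trackers) and are out of scope.

The frame renderer draws a bright sclera, an anti-aliased dark pupil disk
displacing linearly with gaze (1 px/° default — the ground truth the gaze
calibration must recover), an optional illumination ramp, per-frame pixel
noise, and a *fixed* pseudo-random skin/sclera texture. The texture is
essential, not decorative: with a featureless background the only image
structure is the pupil, and registration would cancel eye rotation as if
it were head motion; the static texture gives the registration the
head-fixed structure real frames have.

## Map comparison

Defect edges are crossings of the 12.5 dB midpoint in each arm's threshold
profile, located by linear interpolation between adjacent locations. The
profile is smoothed with a 3-point running median first: a two-reversal
staircase occasionally leaves one wild threshold (a lapse early in the
ascent brackets a spuriously low value at roughly the lapse rate per
location), and a single-location spike is not a clinical defect edge; a
width-3 median removes it while passing genuine step edges through
unchanged. Edges are paired by rank when the two maps have equal counts,
otherwise each edge of the smaller set scores against its nearest
counterpart. MAE is computed over locations determined in both maps.

## Reporting

The simplified (pass/fail) view thresholds the full map at the same
12.5 dB midpoint; the histogram uses 26 one-dB bins (thresholds rounded to
the nearest dB). Reports persist as versioned JSON (sorted keys, byte-
stable for identical inputs) plus a PNG panel; timestamps are exam-clock
seconds when simulating and whatever the trace carries when replaying.

## What the synthetic tests do and do not show

Passing tests establish that the pipeline is internally consistent: the
staircase recovers the thresholds the simulated patient actually has, the
verdict logic recovers the saccades the trace generator actually placed,
and the image chain inverts its own renderer to ≤ 0.06° worst case. They
do not establish performance on real recordings: the simulator's saccades
are ideal steps without dynamics or curvature, its psychometric function
is stationary (no fatigue, no learning), drift never destroys fixation,
the renderer has no eyelashes, glints, off-axis pupil ellipticity or
camera distortion, and head motion enters only as integer-pixel
translation. Results against this test bed bound the algorithmic error of
the method, not its clinical accuracy.

## Problem sizes

Defaults used by the test suite and the acceptance script: full 325-
location accurate exams for recovery and scale checks; 10,000 draws for
scheduling-bound checks; a 1000 s silent trace at 60 Hz for the Poisson
false-positive check; 50 random 16×16 frames for the median-filter oracle;
the full ±5 px shift grid (121 shifts) for registration; a 9×9 grid of
gaze angles over ±60° for the chain round trip. These sizes make every
stochastic check statistically meaningful while keeping the whole suite
fast on one CPU.
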