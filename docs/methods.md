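# Methods

This note documents the models implemented in `soundseek`, the defaults and
why they were chosen, what the synthetic-data generators do and do not
emulate, and the numerical choices that a maintainer would otherwise have to
reverse-engineer.

## Arena geometry

The arena is a regular octagon partitioned into eight peripheral chambers
and one central chamber. The physical build is described by two numbers —
15 cm walls and a 40 cm longest (vertex-to-vertex) diagonal — that are
mutually inconsistent for a perfectly regular octagon by about 0.8 cm (a
40 cm diagonal implies 15.31 cm walls). We scale the polygon to the diagonal,
which fixes the outer extent that all coordinates must respect, and keep the
nominal 15 cm side as metadata. Chambers are indexed 0..7 counterclockwise;
chamber *k*, wall *k* and port *k* (the wall midpoint) go together, and all
modules share this convention.

The central polygon is a concentric octagon whose side length equals the
chamber entry width (default 5 cm), so each chamber is the convex
quadrilateral between its wall and its entry line. The precise position of
the entry line along the entryway is not pinned down by the build
description; placing it where the entry is 5 cm wide puts it 12.4 cm from
the wall, consistent with the stated 12 cm within build tolerance, and it is
configurable through `entry_width`.

Point classification is total and deterministic: every point maps to exactly
one of chamber 0..7, `CENTER`, or `OUTSIDE`. Boundary points belong to a
chamber, never to the center, so entries fire on the earliest possible
frame; on the (measure-zero) shared edge between two chambers the lower
index wins. Pixel-space pose data is mapped to cm by a per-session affine
calibration (`px_per_cm`, `origin_px`), identity by default for synthetic
data generated in cm.

## Stimulus

Burst trains are gamma renewal processes parameterized by moment matching
(shape μ²/σ², scale σ²/μ with μ = 1000/rate ms), which makes rate and
irregularity independently controllable: σ → 0 recovers a periodic train at
exactly 1/rate, and varying σ at fixed rate leaves the mean interval
unchanged. Intervals are onset-to-onset, so the rate is exactly the
reciprocal mean interval. Intervals shorter than the 10 ms burst duration
are redrawn, because a physical speaker cannot overlap bursts; this only
matters at extreme irregularity (at 10 Hz / σ = 100 ms roughly 14% of raw
draws fall below 10 ms) and slightly truncates the lower interval tail
there.

Variable-parameter draws are log-uniform over their ranges (the ranges span
up to two decades and are conventionally analyzed on log axes);
linear-uniform sampling is available by flag. The error sound is a tritone:
the 8 kHz base plus the base times √2, 250 ms by default (the duration is a
free choice; nothing downstream depends on it).

## Trial state machine and agents

Time is abstract: one agent action (enter a chamber from the center, leave
a chamber, poke) takes one tick, by default 1 s. Behavioral metrics never
depend on absolute time except the 1 s inter-trial bookkeeping. Trials that
exceed 200 actions without a goal poke are flagged incomplete and excluded
from scoring; with the shipped agents this cannot happen unless the checking
agent is configured with a zero poke probability in the goal chamber.
`prev_goal` resets at the start of each session.

Agents are per-trial mixtures of four strategy components (random, cycle,
direct, check), the simplest generative story consistent with a repertoire
of distinguishable strategies; one component is drawn per trial. Agents
start each trial inside the previously rewarded chamber — where the animal
physically is after consuming reward — and leave it before anything else
(optionally first re-entering and poking it with `p_return_prev`). The
random component chooses uniformly among the 7 chambers other than the one
just exited, which makes the cycling null exactly 2/7 and, by
exchangeability of the 7 non-start chambers, keeps the goal's first-visit
rank uniform — so the component sits exactly at chance (4 ports poked, 1/7
correct). The cycle component is traplining: ring order, cw or ccw, poking
every port, which also scores exactly chance but with p_cycling = 1.

Strategy components receive the goal identity at `begin_trial` and are bound
by convention to their cue model: `direct` uses it with probability
`p_direct` per approach (binaural localization from the center), `check`
only through the in-chamber audibility flag (monaural sampling), `random`
and `cycle` never. A design in which the environment injects these cues
into the observation channel would require the environment to know agent
parameters, inverting the abstraction; the convention is enforced by the
component implementations and their tests.

Preset parameters are study conditions, fixed once from the task's reported
operating points, not fitted quantities: the expert preset uses
p_direct = 0.55 because the direct policy's ports-poked distribution is
truncated-geometric with mean (1 − (1 − p)⁷)/p ≈ 1.8, the observed expert
plateau; the bilateral preset is the pure cycle-with-poke policy, which sits
at the chance level of 4 by construction; the unilateral presets trade poke
probability for checking so that recovery shows up as a rising
entries-without-poke rate. The real strategy mixtures of behaving mice were
never quantified, so these presets are illustrative generators, not
parameter estimates.

## Scoring and learning curves

`score_trial` walks the poke sequence once, dropping previous-goal pokes and
repeats; ports-poked is the goal's 1-based position in what remains. On the
first trial of a session there is no previous goal, so all 8 ports count and
the range is 1..8 for that single trial; such trials are excluded from
chance-sensitive tests but included in summaries (one trial per session is
negligible). Learning curves are smoothed with a Gaussian kernel (SD 50
trials) renormalized at the edges — smoothing the data and dividing by the
smoothed all-ones vector — so constants pass through and there is no padding
bias. The criterion for good performance (first session strictly better
than 2.5 ports poked) is assessed on raw per-session means; smoothed curves
are presentation-only.

## Entry detection and path metrics

Entries are maximal chamber-occupancy runs of the snout label, at least
`debounce_frames` (default 2, i.e. 67 ms at 30 fps) long; center or outside
frames separate runs. Two numerical guards suppress boundary chatter:
chamber runs shorter than the debounce are ignored, and sub-debounce
center/outside blips flanked by the *same* chamber are merged into it —
positional jitter near an entry line otherwise splits one visit into two.
Missing snout samples are linearly interpolated across gaps of up to 5
frames; longer gaps split runs. Pokes are aligned to frames by
nearest-frame mapping on the shared session clock.

"Entry with poke" is implemented as a poke into that chamber's port during
the occupancy interval (the natural reading of an entry that culminates in
a poke); entries are otherwise checks, and the two categories partition
every entry. Cycling counts any chamber→chamber transition between
ring-adjacent chambers — passing through the center is topologically forced
in this arena, so no extra condition is needed.

Center segments require at least 3 frames. Straightness is endpoint
distance over path length; a degenerate zero-length path is defined as
straightness 1 (a stationary point is trivially straight). Speeds are
snout frame-to-frame displacements times fps. The stillness threshold
defaults to 0.5 cm/s; because tracking jitter inflates apparent speed (at
jitter SD j cm per coordinate the noise floor is ≈ 1.25·j·fps cm/s), the
analysis driver reports stillness over a threshold sweep rather than a
single number.

## Startle

Whole-body movement at frame *t* is the Euclidean displacement of each part
from frame *t−1*, averaged over parts tracked on both frames; all-missing
frames propagate NaN. The onset frame is the first frame at or after the
stimulus onset, and the magnitude is the mean movement over the 5 frames
from the onset frame (167 ms at 30 fps), with missing samples excluded and
counted. Magnitudes are reported in px/frame with fps in the metadata (the
y-axis unit is a convention; fps converts it). A 15-frame pre-onset
baseline is reported for context but never subtracted — the magnitude is
raw. Trials at 80 and 90 dB SPL are pooled.

## ABR

Cross-talk removal fits one causal FIR filter (default 32 taps) from the
speaker channel to the neural channel by least squares across all epochs
jointly and subtracts its prediction. Identifiability is physical: the
filter can only absorb neural content within the click's lag span
(~2.25 ms), while ABR waves arrive later, so leak and response separate.
A silent speaker channel yields a zero filter with a warning. The high-pass
is a zero-phase (forward–backward) 4th-order Butterworth at 100 Hz.
"Voltage excursion" is read as peak-to-peak per epoch (max-abs is available
by flag), and the rejected set is the union of the top-5% lists by
excursion and by SD — the literal "or" — so the kept fraction lies in
[90%, 95%]; percentile ties break by epoch order (stable), and rejection is
a one-shot operation, not idempotent. Percentiles are computed per
(side, level) recording cell. Averages of left-side responses are
inverted so Wave 1 is positive. Wave amplitude, where needed for
validation, is the least-squares (matched-filter) scale of the known
template in the average.

## Synthetic data: what it does and does not emulate

`synth_trajectory` renders a chamber-entry sequence into a continuous snout
path: constant-speed piecewise-linear motion through waypoints (chamber
anchor, port approach when the visit pokes, center), with dwells at each
waypoint and i.i.d. Gaussian positional jitter on every part-frame. Body
parts ride the snout as a rigid cloud with fixed offsets, sufficient because
all downstream metrics use the snout or the mean per-part displacement.
Waypoints are joined linearly rather than by splines: splines can overshoot
chamber boundaries and break the generator's own invariant that no frame
classifies outside the arena. Chamber-to-center segments stay inside the
chamber's wedge (the wedge is convex and contains the centroid path), so
rendered tracks realize exactly the requested entry sequence; round trips
through `detect_entries` are exact at jitter ≤ 0.2 cm.

`synth_startle_track` superposes a coherent 5-frame whole-body impulse of
`startle_gain` px/frame (random direction per onset) on a common Gaussian
random-walk baseline, so with zero baseline the measured magnitude equals
the gain exactly and the metric's linearity can be asserted to machine
precision.

`synth_abr` builds neural epochs as 10^(−attenuation/20) × template
(sign-flipped for left-side stimulation) + delayed, scaled speaker click +
white noise, with an optional fraction of epochs carrying a 1 kHz burst
artifact (10× the clean peak-to-peak by default) that survives the
high-pass, so injected artifacts are provably the top-excursion set. The
template is a stylized five-wave ABR with peaks at 3.0–6.2 ms and unit
amplitude; defaults are 750 epochs at 16 kHz with noise SD 0.1.

These generators reproduce the *statistical structure the analyses assume*
— not real kinematics or physiology. Passing tests show the pipeline
recovers known ground truth under that structure; they do not show
robustness to systematic tracking errors, non-stationary noise, electrode
drift, or genuinely novel mouse strategies. The agent presets encode the
qualitative phenotype ordering (expert ≈ 1.8 ports poked, bilateral at
chance with cycling and no checks, unilateral recovering through checks);
animal-derived quantities such as learning times or the absolute stillness
percentages depend on the real animals and are not reproduced.

## Problem sizes and reproducibility

All randomness flows from a single seed through named substreams
(`stimulus`, `goals`, `agent`, `pose`, `abr`, `startle`), so components are
independently reproducible, and every generator stamps its parameters into
output metadata. The shipped analysis drivers use desk-scale sizes — 6
synthetic mice × 30 sessions × 60 trials for behavior, 20 rendered trials
per condition for trajectories, 12 stimuli per startle session, 750 epochs
per ABR recording — chosen to give Monte-Carlo error well inside each
test's tolerance; the chance-level checks in the test suite use 10⁵ trials
plus exact enumeration over all 7 × 7! goal/ordering combinations.
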