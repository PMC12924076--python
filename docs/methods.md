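# Methods

## Scope and model of the data

`paratrack` analyses long (24–48 h) dark-field recordings of a shallow
observation chamber containing dozens of freely swimming ciliates, captured
at a fixed frame interval (nominally 1 s). The chamber is 14 × 10 mm and
about 1 mm deep; because imaging is a 2-D projection and the analysed
tracks are 2-D, both the simulation and the analysis ignore the depth axis
entirely. Tracking is *bulk*: individual identity is not preserved across
the recording (fragmentation is expected and embraced), so all statistics
are defined on trajectories, not on cells.

## Synthetic swimmers

The simulator is the package's ground-truth generator; its purpose is to
emulate the qualitative behavioural repertoire of a *P. bursaria*-like
ciliate under a 12:12 light-dark (LD) cycle well enough that every pipeline
stage can be validated against known truth.

**State machine.** Each swimmer occupies one of three states — SWIM
(straight swimming with rotational diffusion of the heading), SPIRAL
(swimming with an added constant heading curvature) and IMMOBILE (resting)
— governed by a continuous-time Markov chain sampled at the simulation
step. Default rates (per second): SWIM→SPIRAL 0.01, SWIM→IMMOBILE 0.005,
SPIRAL→SWIM 0.03, SPIRAL→IMMOBILE 0.005, IMMOBILE→SWIM 0.01, giving dwell
times of tens of seconds to minutes and a stationary IMMOBILE fraction of
about one third. Initial states are drawn from the chain's stationary
distribution unless forced.

**Kinematics.** Euler steps at the frame interval `dt` (default 1 s; the
long coarse studies use 10 s). While moving, a swimmer advances
`speed × dt` along its heading; the heading gains `N(0, 2 D_r dt)` noise in
SWIM (`D_r` = 0.05 rad²/s) plus `κ dt` in SPIRAL (`κ` = 1 rad/s). Base
speed is 300 µm/s — a field-plausible magnitude for a large ciliate, chosen
once; no measured speeds back it.

**Walls.** A step that would leave the chamber is clamped to the boundary
and triggers an avoidance reaction: the heading reverses and the swimmer
backs up for a fixed 2 s, then reorients by `π + N(0, 2.0 rad)` relative to
the backup heading (broad, near-uniform). At coarse `dt` the backup
resolves within a single step; that is an accepted discretisation artifact.

**Light modulation.** The LD schedule enters multiplicatively: speed is
`base_speed × g_v(ZT)` and the IMMOBILE→SWIM (initiation) rate is scaled by
`g_i(ZT)`, where ZT is zeitgeber time (hours since lights-on). No
functional form for these responses is established, so both defaults are
smoothed square waves *locked to the LD transitions*: the behavioural
response recurs after lights-on and after lights-off, so the programmed
profiles have a 12-h period in a 24-h cycle. Defaults: `g_v` high 1.4 / low
1.0, 6 h duty, 1 h raised-sine edge smoothing; `g_i` high 2.0 / low 1.0,
3 h duty. These defaults define the study conditions used throughout the
tests and the reproduction script.

**Rendering.** Frames are `background + Σ A exp(−r²/2σ²) + N(0, σ_n)`,
clipped to [0, 255] and quantised to 8 bit (amplitude 120, spot σ 2 px,
noise σ 3, 70 µm/px on a 200 × 150 px image ≈ the 14 × 10 mm chamber).
The optional static clutter image emulates debris and chamber edges.
Spots leaving the image are silently clipped. PNG is the fixture format
(lossless round-trip); a JPEG option (quality 75) exists for robustness
work.

**What the simulation does not capture.** Real recordings have
depth-dependent defocus, cell-size and brightness variability, algal
autofluorescence, cell division, photoaccumulation toward lit regions, and
behavioural idiosyncrasies beyond a three-state chain. Passing tests
therefore demonstrate that the *pipeline machinery* (detection, linking,
binning, significance calibration) is correct under controlled conditions,
not that any biological magnitude is reproduced.

## Detection

Backgrounds are pixel-wise means over consecutive, non-overlapping blocks
of 100 frames (the final block may be shorter); frame *i* uses block
`i // 100`. Blockwise (rather than rolling) means keep streaming memory at
one running sum and reproduce the essential property that anything
stationary for a block — including an immobile cell — vanishes from the
residual `max(frame − background, 0)`. The residual is smoothed with a
Gaussian (σ 1 px); local maxima at least `separation` (default: the feature
diameter, 9 px) apart and above an absolute height (`threshold`, 10
intensity units — this pre-cut exists purely to avoid refining hundreds of
clipped-noise maxima per frame) are refined by iterated intensity-weighted
centroids over a disk of radius `diameter/2` (≤ 10 iterations or < 0.005 px
shift). Mass is the residual integrated over that disk; detections below
`minmass` (500) are dropped. Coordinates are pixels, origin top-left,
x right, y down, frames 0-based; conversion to µm happens only in the
metrics layer, and when frames are downscaled by a factor *f* the
calibration becomes `um_per_px / f` in exactly one place.

The default `diameter/minmass/threshold` values are tuned to the renderer's
default spot model, not to any published parameters.

## Linking

Candidate links between the active particles and the new frame's
detections are restricted to displacement ≤ `search_range × gap` (gap = 1
for consecutive frames, growing linearly for memory gaps). The candidate
graph splits into connected subnets; each subnet is solved exactly as a
minimum-cost assignment (`scipy.optimize.linear_sum_assignment` on an
augmented matrix) with squared-displacement costs and an unmatched penalty
of `search_range²` per unmatched particle or detection. Subnets larger
than `max_subnet_size` (30) raise an error advising a smaller search
range. Unmatched particles freeze at their last position for up to
`memory_frames` (default 3) frames, then terminate; with memory 0 a single
missed detection fragments the trajectory, which reproduces by
construction the fragmentation regime of long bulk recordings. New
trajectories receive ids in creation order (frame, then y, then x of the
founding detection), making output deterministic. No velocity
extrapolation or appearance model is used — frozen-position memory is the
simplest defensible choice at these densities.

## Behavioural metrics

Trajectories with total path length (sum of consecutive-point Euclidean
steps, × µm/px) below 10 mm are discarded; the threshold is inclusive
(exactly 10 mm is kept). Per trajectory: distance (µm), duration
(`(end_frame − start_frame) × frame interval`, s) and mean speed
(distance/duration, µm/s). Memory-gap segments contribute their
straight-line chord and the full gap time, keeping the three quantities
mutually consistent.

Hour bins are half-open `[k, k+1)` hours aligned to the recording start;
ZT labels are attached for reporting via the schedule's
`zt_at_record_start`. Initiation counts use the trajectory start time.
Active-per-frame is the hourly mean over *all* frames of the number of
trajectories with a detection in that frame. Distance and duration series
attribute each trajectory's whole value to its initiation bin; the speed
series instead splits each segment proportionally in time at bin
boundaries and reports, per bin, the *unweighted* mean over trajectories of
within-bin path length over within-bin time. Both views exist because a
per-trajectory box-plot view and a "when did the movement happen" view
answer different questions; the periodicity analysis uses the within-bin
speed series. Empty bins carry NaN, never zero.

## Periodicity

The classical Lomb–Scargle periodogram (with the Scargle τ rotation, no
floating mean) is computed on the mean-centred series at trial periods
from 2 h to the record length in 0.25-h steps, a grid covering the 12- and
24-h bands of interest. Power is normalised by the total sum of squares,
i.e. reported as the fraction of variance explained by the best sinusoid
at that period (equal, by orthogonality of the τ-rotated design, to a
per-frequency least-squares fit — the test suite verifies this to 1e−8 and
also checks agreement with `scipy.signal.lombscargle(normalize=True)`).
Empty bins are simply dropped; the estimator handles uneven sampling
natively. A basis vector that vanishes identically at a trial frequency
(possible at the Nyquist period of evenly sampled data) is excluded from
the explained sum rather than amplified as 0/0, and a numerically constant
series is defined to have zero power.

**Permutation significance.** The null model is exchangeability: series
values are shuffled uniformly over their fixed time points (the sampling
pattern is preserved, serial structure destroyed), the periodogram is
recomputed for each of `n` shuffles (default 1000), and the per-period
threshold is the `⌈(n+1)q⌉`-th order statistic of the shuffled powers
(q = 0.99). The order-statistic form is used instead of an interpolating
quantile estimator because it is the exactly calibrated permutation
quantile — the pointwise exceedance probability is
`(n + 1 − ⌈(n+1)q⌉)/(n+1) ≤ 1 − q` — whereas interpolating estimators sit
low enough to roughly double the nominal rate at moderate `n`. Thresholds
are per-period (matching a per-frequency significance *line*); a
family-wise alternative based on the permutation distribution of the
grid-maximum power is provided (`max_statistic_threshold`) but not used by
default. Significant peaks are strict local maxima above the line
(plateaus count once, at the left edge; grid endpoints are never peaks),
sorted by descending power.

## Canned studies and problem sizes

Two end-to-end studies (`paratrack.experiments`) are the package's own
reproduction harness, sized so each runs in minutes on one CPU:

* **White-noise calibration** — 200 independent Gaussian series of 48
  hourly samples, 200 permutations each; the pooled fraction of (series,
  period) points above the 99% line is reported as a percentage (expected
  ≈ 1, Monte-Carlo scatter a few tenths of a point).
* **LD recovery** — 15 swimmers, 48 h, simulated and rendered at a 10-s
  step on 200 × 150 px frames (a time-dilated, coarse stand-in for a 1-s /
  12-megapixel recording: displacement per frame and pixel calibration
  scale together, so detection and linking operate in the same regime).
  Full pipeline with search range 80 px, memory 1, 10-mm filter; the
  hourly within-bin mean-speed series is tested with 1000 permutations.
  The top significant peak falls at the programmed 12-h modulation period
  to within one 0.25-h grid step. The measured speeds sit below the
  programmed µm/s values because a 10-s chord under rotational diffusion is
  shorter than the path arc; this affects the scale, not the phase or
  period, of the hourly series.

## Numerical and design notes

* All stochastic stages take explicit seeds; the pipeline splits one
  top-level seed into per-stage children via `numpy` `SeedSequence`. Same
  seed ⇒ bit-identical simulation output and byte-identical CSVs.
* The simulator draws its per-step random numbers for *all* swimmers in a
  fixed order whether or not each draw is consumed, so determinism is
  robust to state-dependent branching.
* Assignment ties between exactly equal-cost matchings resolve to whatever
  the Hungarian solver returns, which is deterministic for identical
  inputs.
* Config files are YAML; unknown keys are rejected with a closest-match
  suggestion, violations are reported with full key paths, omitted
  sections take the documented defaults, and a validated config
  round-trips losslessly.
* Known limitations: no 3-D effects, no appearance-based track stitching,
  no phototaxis or light-gradient behaviour in the simulator, no
  free-running (constant-condition) period estimation, and detection
  defaults are tied to the synthetic spot model rather than measured
  optics.
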