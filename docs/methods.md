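# Methods

This note documents the models, parameter choices and numerical
decisions behind `cionetho`, in the order the pipeline runs.

## Ingestion and calibration

Tracker exports give pixel centroid positions per frame and track. Two
dialects are parsed: a generic CSV (`frame,track_id,x_px,y_px`) and a
ToxTrac-style whitespace table (`frame arena track x y`). Malformed rows
are skipped and counted rather than aborting a file.

Calibration is affine: `x_mm = (x_px − cx)·s`, `y_mm = −(y_px − cy)·s`
with `s = radius_mm / radius_px` taken from the arena circle. The y axis
is flipped from image convention (down) to mathematical convention (up).
Frames missing between a track's first and last observation become
masked gaps; positions are **never interpolated** — every windowed
computation downstream treats gap-touching windows as invalid, so
missing data surfaces as missing output, not as fabricated values.

Trace exclusion follows two rules: traces whose maximal displacement
from the start stays under one body length (default 1.0 mm,
configurable; the body length is not a sharply defined constant) are
excluded as immobile (indistinguishable from dead), and traces observed
for fewer than 2,000 frames are excluded as unrepresentative. Immobility
is checked first; the precedence is arbitrary but fixed, and both
reasons are logged when both apply.

## Kinematics

Two speed notions coexist deliberately:

* **Filtered speed** (used for AC, median/max speed): per-frame velocity
  components are passed through a 4th-order Butterworth low-pass at
  1 Hz, applied forward–backward (`sosfiltfilt`, zero phase), and the
  speed is the magnitude of the filtered velocity. Filtering components
  rather than the rectified magnitude is essential: a perpendicular
  head-undulation tone (default 5 Hz, 50 µm) folds into a large DC
  offset of the raw speed magnitude (mean ≈ 1,000 µm/s over a 300 µm/s
  drift), which no post-hoc low-pass can remove; component filtering
  recovers the drift to well within 5%. About one filter period
  (`fps/cutoff` frames) at each segment edge is flagged invalid as
  warm-up.
* **Lag kinematics** (used for the mode features): displacement vectors
  between coordinates 5 frames apart give ρ (µm/s), heading θ, turn
  Δθ = wrap(θ_{t+5} − θ_t) ∈ (−π, π], and Δρ. The 5-frame lag serves
  the same anti-undulation purpose for angular quantities. Turns are
  computed on unfiltered positions.

The activity coefficient is the fraction of valid frames with filtered
speed ≥ 200 µm/s — a threshold that counts tail-flick/twitch centroid
motion as activity, not only translocating swimming. Reversal points at
low speed can carry a ~π/2 heading imprecision from centroid jitter;
this is documented, not corrected.

Acclimatization: the cohort-mean filtered speed is regressed against
time in sliding windows (default 5 min window, 10 s step); the
stabilisation time is the first window start whose |OLS slope| falls
below 0.05 µm/s² and stays below for all later windows.

## Path complexity

In each 3 s window (odd length 2h+1 frames, stride 1) the trajectory is
fit by constant-velocity motion (x and y linear in time). The 2×2
residual covariance Σ (dof-corrected by w/(w−2)) gives the local
complexity H = ½·log₂((2πe)²·det Σ) bits — the differential entropy of
the Gaussian residual model. Numerical choices:

* eigenvalues of Σ are floored at 1 µm² so degenerate (perfectly
  predictable) windows report the finite floor
  H₀ = ½·log₂((2πe)²·1 µm⁴) ≈ 4.094 bits; flooring eigenvalues rather
  than axis variances keeps H exactly invariant under rotation;
* windows overlapping gaps or underrunning the trace are invalid;
* sliding sums are computed by convolution; cancellation error is
  ~10⁻⁹ of the floor at worst for a 10 mm arena.

Absolute H values depend on these conventions; the meaningful contracts
are the floor, the closed form for isotropic Gaussian residuals
(H = ½·log₂((2πe)²σ⁴)), and monotonicity in noise magnitude.

## Thigmotaxis

The circular arena is split at r = R/√2 into an inner disc and outer
annulus of exactly equal area (R = 5 mm → inner 3.536 mm, outer width
1.464 mm; the commonly printed 3.55/1.45 mm pair is this split rounded).
TTO is the fraction of valid frames with r beyond the inner radius
(boundary counts as inner by default, configurable); TDO assigns each
step between consecutive valid frames to the zone of its midpoint and is
0 (with a warning) for zero total path length. Median distance from the
centre is the robustness companion metric. Raw (unfiltered) positions
are used throughout.

## Behavioural-mode ontology

Features per frame are the means of (ρ, Δρ, Δθ) over a [−25, +25]-frame
window, so each observation carries past and future movement. Windows
that underrun the trace or touch gaps are invalid and are **never
clustered** — the degenerate edge-artifact cluster that otherwise
appears (insufficient points in the window) is prevented structurally,
and such frames appear as `missing` in ethograms.

A seeded subsample (default 50,000 rows) of the pooled valid rows is
clustered with Ward linkage. Up to 20,000 rows this is exact
(`scipy.cluster.hierarchy`); above, an exact pairwise matrix would need
~10 GB, so Ward is constrained to a 40-nearest-neighbour connectivity
graph (scikit-learn); 40 neighbours reproduces the exact tree's cuts on
this data (identical results at 80). The total point-to-centre distance
is recorded for each candidate k (2–20) and the count is chosen by the
elbow; cluster centres are per-cluster means, clusters are relabelled in
order of increasing centre speed (ties by |mean turn|), and a k-NN
classifier (k = 5, Euclidean) fitted on the clustered subsample labels
every frame of every trace.

**Features are not z-scored by default.** The windowed signed-turn
feature has mean ≈ 0 for every regime (turning is symmetric); it carries
dispersion but no location signal. Standardising inflates that
noise-only axis to unit scale and collapses the speed separation that
distinguishes the modes — empirically, clusters then form slices along
the turn axis with near-identical speeds and the ontology is lost. In
the raw units (µm/s dominating radians) the metric is speed-dominated,
which matches the fact that the recovered modes order cleanly by speed.
`standardize=True` remains available.

**Elbow selection.** Writing mc_k = wcd(k) − wcd(k+1) for the drop each
additional cluster buys, the knee is the interior k that best splits
the log-drop sequence into a "still notable" head and a "no longer
notable" tail, scored with the pooled two-sample t statistic on
{log mc_j} — a changepoint detector that directly formalises "further
increasing the cluster count no longer reduces the total distance
notably". The log makes the score scale-free, so neither one dominant
top-level split nor a slowly decaying tail can drag the knee away; the
variance normalisation rewards a clean separation of regimes.
Pointwise alternatives were evaluated and rejected on the curve shapes
this pipeline actually produces: differential curvature is suppressed
at sharp corners by the steep incoming slope (it cannot detect an
L-shaped curve's corner); circumcircle (Menger) curvature is dominated
by small non-monotone wiggles in the flat tail of a greedily cut merge
tree; unnormalised drop-ratio scores are either distracted by the
dominant top-level split or creep toward large k on decaying tails.
The changepoint score selects the true count on every curve family
across seeds and world sizes. Ties break toward smaller k; an
equal-drop (straight-line) curve returns the smallest interior k with
a warning.

An 11-cluster model receives the canonical mode names, ordered by speed:
Inactive 1/2, Small twitches, Large twitches, Collision/Deceleration,
Mode change 1/2, Slow/Medium active swimming, Fast swimming 1/2. Any
other count gets `mode_01 … mode_k`.

## Group statistics

Behavioural summary metrics are non-normal across animals, so the
battery is nonparametric: Shapiro–Wilk per group (documenting
non-normality), Levene for variance equality, Kruskal–Wallis omnibus,
pairwise two-sided Mann–Whitney U. **No multiple-testing correction is
applied**; every result object carries
`multiple_testing_correction="none"`. Mode-distribution contrasts use
Pearson χ² on the 2×k frame-count table (zero-expected modes dropped
with a warning); the per-mode contribution Σ(O−E)²/E over the mode's two
cells identifies the largest contributor. Frame counts are the χ² unit;
treating animals as the unit would need a per-animal bootstrap, offered
as future robustness work. Speed–turn clouds are compared through
sorted Mahalanobis-distance curves (group mean/covariance, diagonal
regularised by 10⁻⁹·trace when near-singular) on seeded subsamples of
up to 100,000 observations, the same subsample size used for polar
scatter plots.

## Synthetic data

The generator emulates 5-min, 30 fps recordings (and the 15-min, 10 fps
acclimatization protocol) of larvae in a 10 mm × 3 mm arena
(volume ≈ 236 mm³) as a regime-switching random walk:

* **Regimes**: the default library holds the 11 modes above. Nominal
  per-step speeds run 15 µm/s (Inactive 1) to 1,885 µm/s (Fast
  swimming 2); inactive regimes sit below the 200 µm/s activity
  threshold and swimming regimes reach the observed ~1,900 µm/s burst
  range. Twitch regimes redraw their heading uniformly every frame and
  are leashed to an anchor (0.5 mm), producing vigorous centroid jitter
  without net displacement; their observed lag-5 speed is consequently
  ~0.4× nominal.
* **Switching**: geometric dwell times via p_stay = 1 − 1/(fps·d̄),
  with off-diagonal mass biased toward speed-adjacent regimes
  (exp(−|i−j|/2)) — locomotor intensity changes gradually. No
  quantitative dwell or transition statistics exist for larvae at this
  granularity; the defaults are plausible (quiescent bouts tens of
  seconds, swim episodes ~5 s) and, critically, every dwell time
  exceeds ~3× the 1.7 s feature window: a mode whose episodes are
  shorter than the window can never produce a pure observation and is
  unrecoverable *by construction*, so recoverability pins a lower bound
  on realistic dwells.
* **Calibration for separability**: the ontology is *meant* to be
  recoverable, so regime speeds are spaced such that (a) adjacent
  observed lag-speed centres differ by ≥ ~3× their windowed-feature
  spread and (b) adjacent-pair Ward merge costs (harmonic pair mass ×
  squared gap) are roughly balanced — the condition under which the
  within-cluster-distance curve has its unique knee at the true count.
  This calibration was designed against these structural rules and then
  verified across independent seeds at full scale (150 animals).
* **Within a regime**: step lengths are gamma-distributed around
  mean_speed/fps with the regime's CV; heading increments are normal
  with σ = 1/√κ (wrapped-normal-like).
* **Wall**: outside positions are projected to the boundary; with
  probability `wall_bias` the heading aligns to the wall tangent
  (preserving travel direction — wall following, the thigmotaxis knob),
  otherwise it reflects specularly.
* **Head undulation**: a perpendicular sinusoid (default 5 Hz, 50 µm —
  above the 1 Hz filter, below a body length) is superimposed during
  active swimming regimes only; tail beating, hence head undulation,
  does not occur in quiescence.
* **Dropout**: missing frames arrive in bursts (geometric runs, mean
  0.5 s) at the configured overall rate (default 2%), matching the
  banded structure of real tracker gaps; i.i.d. frame dropout would
  invalidate most 51-frame windows at the same rate and is unrealistic.
* **Seeding**: one master seed; animal i uses seed + i. Cohort
  overrides can shift any scalar parameter, scale all speeds, or
  re-weight occupancy of named regimes (e.g. a stimulant-like group
  up-weighting fast modes and raising wall_bias).

What the generator does **not** emulate: hydrodynamics, tail posture,
multi-animal interactions, photic responses, and any empirically fitted
dwell/transition structure. A green recovery test therefore establishes
that the analysis recovers the ontology of a world with the stated
statistical structure — not that real larvae have exactly 11 modes.

## Defaults that matter

| Parameter | Default | Unit | Why |
|---|---|---|---|
| filter cutoff | 1 | Hz | removes >1 Hz head undulation from speeds |
| velocity lag | 5 | frames | anti-undulation for angular measures |
| activity threshold | 200 | µm/s | separates twitch/swim from drift |
| complexity window | 3 | s | local predictability horizon |
| variance floor | 1 | µm² | finite floor entropy 4.094 bits |
| feature window | ±25 | frames | past+future context (1.7 s at 30 fps) |
| ward subsample | 50,000 | rows | tractable hierarchical clustering |
| k range | 2–20 | — | candidate mode counts |
| k-NN | 5 | — | classification of all frames |
| min trace | 2,000 | frames | exclusion of unrepresentative traces |
| body length | 1.0 | mm | immobility criterion |
| zone split | R/√2 | mm | exact equal areas |

## Known limitations

* Centroid-only input: no posture, no tail-beat frequency.
* The elbow is a heuristic on a greedy tree; on data without any block
  structure it degrades to "smallest interior k" with a warning.
* χ² on frame counts treats frames as independent, which overstates
  effective sample size for strongly autocorrelated ethograms.
* Mode names beyond the ordering convention (e.g. "Collision") encode
  biological interpretation the clustering itself cannot verify.
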