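# Methods

This note documents the models implemented in `gazefuzz`, the parameter
defaults and why they were chosen, what the synthetic benchmarks emulate,
and the numerical and design decisions that were genuinely open.

## 1. Pupil and glint segmentation

The detector assumes pre-cropped, 8-bit grayscale NIR eye frames (at least
64×64 px; whole-face eye localization is out of scope). Coordinates are
0-based pixels, x right, y down; centers may be fractional.

**Rough localization.** Dark pixels are masked by Otsu's inter-class-variance
threshold (overridable by a fixed intensity; the Otsu level itself is counted
as dark, since Otsu places the threshold on the lower class edge of a bimodal
histogram). The mask is cleaned by a morphological opening (disk radius 2 px)
and a 3×3 median filter, keeping the largest connected component. A circular
Hough transform over the configured radius range (pupil 10–40 px, glint
2–10 px by default) votes from the mask's 8-connected boundary pixels.
Accumulator votes are raw counts, not perimeter-normalized, so a
well-supported large circle beats a small one; a peak below the vote floor
(8 votes) means no circle. The glint pass runs inside an eye ROI around the
rough pupil (half-size 3× the rough radius) and thresholds at
max(0.9 × ROI maximum, 180): corneal glints are near-saturated specular
reflections, and the absolute floor prevents the relative rule from
latching onto the iris in glint-free frames.

**Level-set refinement.** Both rough circles seed a region-based
(piecewise-constant Mumford–Shah / Chan–Vese) refinement restricted to an
*adaptive mask* — a disk centered on the rough circle with radius 1.5×
(pupil) or 2.0× (glint) the rough radius, so the evolution domain tracks
the structure's current size and position. Intensities are normalized to
[0, 1]. The energy is

    E(R) = μ·per(R) + λ_in Σ_{R} (u − c_in)² + λ_out Σ_{D∖R} (u − c_out)²

with per(·) the 4-neighbor discrete perimeter, c_in/c_out the region means,
and defaults μ = 0.25, λ_in = λ_out = 1 (the symmetric textbook weighting;
μ was set so that boundary smoothing matters at the ~0.5 intensity contrast
of pupil/iris without freezing whole-region moves). Minimization is by
alternating coordinate descent: given the means, the data-optimal
relabeling (and a median-smoothed variant of it, which stands in for the
curvature term) are proposed, and a proposal is accepted only if it lowers
E — the energy is therefore non-increasing by construction, which the test
suite asserts per iteration. Convergence is declared when fewer than 0.1%
of the domain pixels change label (at most 200 iterations). A region that
empties or floods its mask raises a collapse error. This component was
written in-package because the mask-restricted variant and the
energy-monotonicity contract are the point; the surrounding standard steps
(Otsu, Hough, morphology, labeling) use scikit-image and scipy.

Pupil size is the pixel count of the refined pupil region with glint
pixels excluded, and the geometric centers are mask centroids. A frame is
`valid` only if both pupil and glint are found — gaze mapping needs both —
but a found pupil is still reported on glint-free frames.

## 2. Feature extraction

**Feature 1, pupil accommodation.** The pupil-size series is smoothed by a
3-tap uniform moving average (end windows truncated and renormalized), and
a 10-frame window (≈333 ms at 30 fps) starting at the fixation anchor is
min-max normalized to [0, 1]; a constant window maps to all zeros (no
accommodation evidence; avoids dividing by zero without dropping the
window). The feature is the minimum SSD against a bank of three length-10
constriction templates — descend linearly from 1 to 0 with the minimum at
sample 3, 5 or 7 (1-based), then recover linearly to 0.6. The shapes encode
"constrict fast/medium/slow, partially recover"; they ship as a CSV so
calibrated templates can be substituted. Ties go to the lowest template id.

**Fixation anchoring.** The anchor S is the first frame of the longest run
of per-frame gaze change Δz below a stillness threshold (default
5 monitor-px/frame, configurable), requiring at least one full window;
ties prefer the earliest run. S is shared by the Feature-1 window and the
Feature-2 dwell window. If no run qualifies, the event carries no features
and scores 0 ("no selection evidence") — this policy, not a raised error,
is what the session scorer uses, so saccadic episodes are cheap negatives.

**Feature 2, short-dwell gaze change.** The glint-compensated pupil
position (pupil − glint, cancelling common head translation) maps to
monitor pixels through the 4-corner bilinear model; the two 4×4 linear
systems are solved exactly, and a near-singular design (collinear eye
points) raises a degenerate-calibration error. When both eyes are valid
their monitor-space gaze points are averaged. Feature 2 sums the Euclidean
Δz over W = 10 frames from S (W matching the Feature-1 window, as no
separate dwell length is defined).

**Feature 3, gaze-target texture.** The Gabor bank uses K = 4 orientations
(θ = nπ/4) and P + 1 = 4 scales, 16 kernels total. Defaults σx = σy = 2 px,
W = 0.25 cycles/px, a = √2, kernel support 4σ (odd size) — a standard
bank spanning four near-octave scales. Following the scaling definition
implemented here, the scale index rescales the *amplitude* (a^−m) of the
rotated mother wavelet; coordinates are rotated but not dilated. Each
kernel is DC-removed so constant regions score exactly 0, making the
"texture-less → low F3" contract exact. The feature is the mean absolute
convolution response (reflect padding) over all kernels and pixels of a
101×101 px gaze-centered ROI (clipped at borders; comparable to the ±1°
≈ 82 px gaze accuracy scale). Color screenshots are averaged to luminance.

## 3. Fuzzy fusion

Raw features are min-max scaled to [0, 1] using training ranges (values
outside the range clip) and Features 1 and 2 are inverted (1 − f) so all
three increase with selection evidence. Each feature has Low and High
linear membership functions: μL is 1 up to a_L, falls linearly to 0 at b_L;
μH is 0 up to a_H, rises linearly to 1 at b_H. Continuity pins the slopes
and intercepts to the endpoints.

**Maximum-entropy fitting.** Given class histograms m_H (selection) and
m_L (non-selection) of a normalized feature, binned at 0.01 and normalized
to sum 1, the class masses p_L = Σ m_L·μL and p_H = Σ m_H·μH define the
entropy −p_L log p_L − p_H log p_H, which is maximized by exhaustive grid
search over (a, b) pairs at step 0.01 — deterministic, with lexicographic
tie-breaking. The search is constrained to overlapping ramps (a_H < b_L):
the L/H value classes are not separable and the membership functions must
share support; without the constraint the unconstrained optimum (mean
class membership ≈ 1/e per term) produces non-covering ramps with dead
zones in which every MIN-rule firing is zero. Because the two entropy
terms depend on disjoint parameters, the constrained joint optimum is
assembled from per-b_L and per-a_H maxima in O(grid²) rather than
O(grid⁴).

On sharply separated training distributions (such as the synthetic
sessions below) even the constrained optimum sits at the support edges,
which makes degrees knife-edged. The session pipeline therefore defaults
to fixed broad symmetric ramps (a = 0.25, b = 0.75 for both L and H on
every feature) and exposes entropy fitting as an option
(`params="fit"`, or membership parameters in the YAML config) for broad,
overlapping real-world distributions.

**Inference and defuzzification.** The eight L/H antecedent combinations
map to output labels through a fixed rule table (LLL→L, LLH→L, LHL→M,
LHH→H, HLL→L, HLH→M, HHL→H, HHH→H). Each combination's inference value is
the MIN (default) or MAX of its three member degrees. IVs aggregate per
output label by maximum (standard Mamdani max-aggregation). The output
sets on [0, 1] are piecewise linear: L falls 1→0 over [0, 0.5], M is the
triangle with apex (0.5, 1), H rises 0→1 over [0.5, 1]. The union of the
height-clipped sets is piecewise linear, so all five defuzzifiers are
computed *exactly* on its breakpoint decomposition (all component kinks
plus pairwise line intersections): FOM/LOM are the first/last abscissae
attaining the union's maximum, MOM their midpoint, COG the centroid of the
union region with overlaps counted once (Simpson-exact segment moments),
and BOA the half-area abscissa, solved per segment with the
cancellation-free quadratic root t = 2·need/(u₁ + √(u₁² + 2·s·need)).
If every IV is zero the score is 0 with a warning. The decision is strict:
selected iff score > threshold, so a score equal to the threshold is not a
selection.

A caution about shape: the rule base is deliberately non-monotone in
features 1 and 3 (LHH→H lets stillness + texture select without pupil
evidence, HHL→H without texture), so raising a single feature through its
L/H crossover can transiently lower the COG score by up to ≈0.05. The
score is monotone in feature 2. The property tests encode exactly this.

## 4. Synthetic data: what it emulates, and what it does not

`gen_eye_frame` renders a mid-gray iris (120), a dark pupil disk (25,
optionally clipped by a flat chord to exercise the non-elliptical case), a
near-saturated glint (250, radius 4) and additive Gaussian sensor noise
clipped to [0, 255]. All randomness flows through integer-seeded
`numpy.random.default_rng`, so a fixed seed reproduces every artifact
bit-for-bit.

`gen_session` generates *signal-level* sessions: per-frame pupil sizes and
monitor gaze plus a monitor image, organized into alternating balanced
events of 4 lead-in + 10 window + 2 tail frames. Selection (TP) events:
the lead-in saccade (steps 15–40 px/frame) completes onto a textured patch
on its last frame — a real saccade ends where the intent fixation begins,
which aligns the stillness run with the constriction onset; the gaze then
jitters ~1 px/frame (well under the 5 px/frame stillness gate) and the
pupil (base 1500 px area, sensor noise σ = 3) follows a jittered template
constriction with a 20% dip. Non-selection (TN) events alternate between
(a) a wandering gaze that never fixates and (b) a *casual* fixation on a
blank screen region with 2.5 px/frame ocular drift — stiller than a
saccade but less stable than an intent gaze — and a slowly *dilating*
pupil (1–2.5 px/frame): the relaxation drift of an unengaged eye, chosen
deliberately because min-max normalization amplifies a flat-or-descending
noisy window into shapes that can spuriously match a constriction
template.

What passing on these sessions shows: the full chain — fixation gating,
template matching, dwell summation, texture scoring, fuzzy fusion,
thresholding — separates construction-faithful positives from negatives
with EER 0 and degrades under injected noise. What it does not show:
performance on real eyes. Real pupillometry has hippus, blinks and
eyelid occlusion; real negatives include engaged-but-unintentional
fixations whose pupil dynamics overlap the accommodation signature; and
real monitor saliency is not bandpass noise patches. Quantitative EERs on
these sessions are properties of the generator's separation, not of human
data.

The noise-robustness experiment perturbs the *detected* pupil sizes and
gaze coordinates (not the rendered images) with zero-mean Gaussian noise
of σ ∈ {0, 5, 10, 20} and re-runs feature extraction and fuzzy scoring
with the clean session's training ranges held fixed. Because gaze noise of
σ = 5 px/frame already pushes frame-to-frame Δz past the 5 px/frame
stillness gate, fixation detection fails for essentially all events and
the EER saturates at chance (50%) from σ = 5 on — the degradation is
gate-dominated and steplike rather than gradual, which still exhibits the
qualitative noise-hurts-accuracy behavior the experiment is meant to probe.

## 5. Problem sizes and determinism

Default verification sizes: 100 noisy frames (σ = 10) for center-recovery
statistics, 1000 random IV sets for the defuzzifier/oracle comparison at
1e-4, 40-event sessions for the end-to-end EER, and 10 replicates per
noise level; a 1000-event batch checks the class-conditional feature
orderings. These sizes give stable statistics while keeping the whole
suite and the acceptance script in the minutes range on one core. Every
stochastic component takes an explicit seed; reruns are byte-identical
(asserted for the CLI pipeline outputs).

## 6. Known limitations

- Eye-region localization from full-face video, blink/eyelid handling and
  3-D gaze (Z-distance compensation) are out of scope.
- The Chan–Vese curvature handling is a median-smoothing proposal rather
  than an explicit curvature flow; it preserves energy monotonicity but
  approximates the length term's geometry.
- The bilinear 4-point calibration is exactly determined; it does not
  regularize or use more than four points.
- Entropy-fitted membership functions degenerate on well-separated
  training classes (see §3); fixed ramps are the robust default there.
- The score saturates: COG of a single active label is insensitive to its
  height, so very weak firings can still place the score near a label's
  centroid. Thresholds should be set on validation scores, not assumed.
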