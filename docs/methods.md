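# Methods

This note records the models, parameter choices and numerical conventions
behind the package, what the synthetic generator does and does not emulate,
and the known limitations.

## Landmark scheme and coordinate conventions

Twelve coordinates are tracked per frame of a lateral-view swallow study.
Their functional groups: head/neck extension (1–5, the skeletal/vertebral
frame), pharyngeal shortening (6), laryngeal elevation (7, 8), hyoid
movement (9), tongue-base retraction (10), pharyngeal constriction (11, 12).
Landmarks 11 and 12 locate the superior and middle pharyngeal constrictors
via hard landmarks — the line of the mandible base, and the line of the
greater horn of the hyoid, each followed posteriorly to the pharyngeal
wall; when patient rotation doubles the mandibular shadow, the superior
shadow is used. These placement rules are stored on the registry as
annotation guidance (for human or synthetic raters), not executable logic.
The anatomical names of landmarks 1–10 come from prior work on the
ten-coordinate scheme and are stored as overridable placeholders.

Internally x increases anteriorly and y superiorly (the phase definitions
reference anterior–superior hyoid motion); tracker files declaring
image-space axes (`y_axis: down`) are flipped on read. Frames are indexed
from 0 and phase intervals are half-open `[onset, offset)`: oral transport
ends on the frame preceding pharyngeal onset, and the frame marking closure
of the upper esophageal sphincter is excluded from the pharyngeal phase.
Half-open intervals remove the off-by-one ambiguity that an inclusive
convention invites.

## File formats

The tracker dialect is a tab-delimited text file, one row per frame
(`frame, x1, y1, …, x12, y12`), with `#`-prefixed header comments carrying
video/rater/trial ids, frame rate, bolus label, axis convention and phase
intervals. Floats are serialized with the shortest round-trip
representation so `read(write(s))` is bit-exact; six-decimal fixed-point
formatting was rejected because it cannot honor the 1e-9 round-trip
contract on arbitrary coordinates. Compilation produces a long-format table
(one landmark per row, key `video × rater × trial × frame × landmark`,
canonically sorted so compilation is order-insensitive) with the per-frame
phase label carried along — reliability analysis consumes the coordinate
columns, the discriminant workflow the phase column. Shapes also round-trip
through the standard TPS format (`LM=`/`ID=` records) for interop with
geometric-morphometrics tools.

## Procrustes superimposition

Full Procrustes: translation removed by centering, scale by division with
centroid size (fluoroscopic magnification differs between studies, so scale
is nuisance), rotation by the closed-form 2-D solution
`θ* = atan2(Σ tᵢ×rᵢ, Σ tᵢ·rᵢ)`, which is always a proper rotation —
lateral-view anatomy must never be mirrored. Generalized Procrustes
analysis initializes the consensus at the first (normalized) shape and
iterates rotate-all/re-average/renormalize until the consensus moves less
than 1e-10 (root-sum-of-squares; far below any annotation noise), capped at
100 iterations; non-convergence is flagged on the result rather than
raised. The converged solution retains a global-rotation gauge freedom; it
is fixed by rotating the consensus's principal axis to +y (the roughly
vertical vertebral column), with a deterministic sign rule, making outputs
reproducible across input orderings.

Tangent-space projection (orthogonal projection onto the plane tangent to
the unit sphere at the consensus) is available as a flag, default off. At
swallowing-scale shape variation the numerical difference is negligible;
the flag exists to make the modeling choice explicit. One consequence worth
knowing: without projection, the unit-size constraint is a sphere, so the
radial direction retains second-order variance — shape PCA then shows a
small 21st eigenvalue (~10⁻² of the first at realistic noise) rather than
an exact zero; with projection the spectrum has exactly ≤ 20 = 2k − 4
nonzero eigenvalues. Centering and rotation are linear constraints and
vanish exactly either way.

## Discriminant function analysis

Each frame's configuration is one observation (the phase classifier is
assigned per coordinate set); frames within a video are not independent,
and this is deliberately not modeled — the analysis matches standard
practice, and the permutation test is calibrated for the exchangeability it
actually tests (see Limitations). The pooled within-group covariance is
singular in the 24-dim flattened space, so the Fisher direction
`w ∝ S_W⁻¹(μ₂ − μ₁)` is computed inside the PCA subspace retaining at most
`min(n₁+n₂−2, 20)` components with eigenvalue above 1e-12 of the largest,
then back-projected and normalized. The axis is oriented so the second
group (alphabetically — 'pharyngeal' vs 'oral_transport') has positive mean
score.

The permutation test shuffles labels and re-fits the discriminant per
shuffle (guarding against selection bias); the statistic is the absolute
difference of group mean scores and `p = (b+1)/(n_perm+1)` with
`n_perm = 999` by default. With a fixed seed the p-value is bit-stable.

Two distinct vectors live on the result, on purpose. The **axis** is the
whitened coefficient vector: it defines scores and the test, but it is not
a shape deformation — dividing by within-group covariance rotates it away
from the group difference whenever within-group variance lies along the
motion trajectory, which is exactly the situation here (frames within the
pharyngeal phase vary along the swallow motion). The **displacement
vectors** — what the arrow plots draw — are the between-group mean
difference of aligned coordinates per landmark, the shape change the
analysis separates. Conflating the two is a classic misreading of
discriminant coefficients in morphometrics.

Anchoring: displacement fields are re-expressed relative to the head/neck
(vertebral) landmark group by subtracting that group's mean displacement —
the shape-space analogue of reading motion against the vertebral column.
The operation is idempotent and sends uniform fields to zero.

## Reliability (ICC)

Annotation agreement uses ICC(2,1): two-way random effects (targets and
raters both random), absolute agreement (a rater's systematic offset counts
against agreement), single measure (each annotation stands alone). Targets
are pooled video-frames per coordinate axis, on raw pixel coordinates —
reliability of annotation precedes, and is independent of, superimposition.
Mean squares come from the two-way ANOVA decomposition with the residual
sum of squares computed definitionally from residuals (not by subtraction),
so an exact duplicate-trial matrix yields ICC exactly 1.0. Confidence
intervals are the F-based Shrout–Fleiss/McGraw–Wong interval with
Satterthwaite degrees of freedom, α = 0.05. All-equal matrices are reported
as estimate 1 with a degeneracy flag rather than dividing 0/0.

A calibration caveat: with k = 2 raters the interval's empirical coverage
is near-nominal (93–96% in our checks at n = 100) when the rater-bias
variance share is small — the trained-rater regime this package's noise
model emulates (~1 px systematic bias vs ~2 px jitter, variance ratio 1:4).
When the rater component is a large share of disagreement the F-interval
genuinely undercovers at k = 2 (we measured ~88% at a 0.3 share, ~73% at
0.5); interpret CIs cautiously in few-rater, high-bias designs.

## Synthetic kinematics generator

The generator defines the study-scale conditions: 20 videos, 2 raters, 2
trials, 30 frames/s, 10 oral + 21 pharyngeal frames per swallow (~0.3 s and
0.7 s — a realistic pharyngeal-phase duration; the odd pharyngeal count
puts the pulse peak exactly on a frame). Motion deforms an invented but
anatomically plausible lateral-view template (pixel units, vertebral column
1–5 roughly vertical and posterior) by per-group peak displacements:
hyoid (+10, +12), larynx (+3, +14), pharyngeal shortening (0, +15), tongue
base (−12, +2), constrictors 11/12 (+8, +2) — i.e. anterosuperior hyoid
excursion, laryngeal elevation, pharyngeal shortening, tongue-base
retraction, and constrictor collapse toward the tongue base — with the
head/neck group stationary. The temporal profile ramps smoothly to a 0.15
fraction during oral transport, then follows a raised-cosine pulse peaking
mid-pharyngeal-phase (profile is pluggable). Per-video amplitude scale is
uniform in 1 ± 0.15.

Nuisance (one similarity transform per video, shared by raters since they
annotate the same recording): rotation uniform ±10°, scale 0.9–1.1,
translation ±20 px — head/neck flexion-extension, patient motion and
magnification variance. Rater noise: isotropic Gaussian, default sd 2 px,
optional per-rater bias, drawn independently per rater × trial. Motion,
nuisance and noise use separate deterministic seed streams, so zeroing the
nuisance or changing the noise leaves ground-truth trajectories bit-identical.

What the generator does **not** emulate: bolus-dependent kinematics, frame
interlacing and motion blur, tracking drift or autocorrelated rater error,
missing/occluded landmarks, and anatomical covariance between subjects
beyond a scalar amplitude. Passing tests therefore demonstrate correctness
of the statistical machinery under a known generative model, not clinical
validity on real fluoroscopy. In particular, published ICC point values
from real raters are not reproducible from simulation and are not targeted;
reliability checks are property-based (identity duplicates, oracle
equivalence, CI coverage, monotonicity in noise).

## Numerical choices and degenerate inputs

- Degenerate (all-coincident) shapes raise rather than propagate NaNs;
  tolerance 1e-12 on centroid size.
- GPA convergence 1e-10 / 100 iterations; pairwise alignment is closed-form.
- DFA with identical groups (zero mean difference) returns a zero axis,
  zero separation and p = 1 instead of failing on a 0/0 normalization.
- PCA keeps every component spanning the sample, so reconstruction is exact
  to numerical precision; rank decisions happen only inside the DFA
  regularization (1e-12 relative eigenvalue floor).
- Permutation comparisons use a 1e-12 slack (`stat ≥ obs − 1e-12`) so exact
  ties count as exceedances, keeping p conservative.
- SVG output pins the renderer hashsalt and omits date metadata so repeated
  renders are byte-identical.

## Problem sizes used in the validation suite

Unit and acceptance tests run on deliberately small instances chosen to
exercise the asymptotics they probe: reliability oracles on matrices up to
200 × 3; CI coverage at n = 100 with 500 replicates per ρ; GPA invariance
on 50 transformed copies; discriminant recovery and nuisance robustness on
the default 20-video cohort at frame level (620 observations, 999
permutations); null calibration over 200 replicates of 30-shape samples
with 199 permutations each. These sizes are the package's own validation
design and keep the full suite in the tens of seconds.

## Known limitations

- Frame-level observations are serially dependent within a video; the DFA
  p-value tests exchangeability of frames, not videos. A video-level or
  mixed-model analysis is future work.
- Full-Procrustes shape space is curved; all statistics are computed on the
  superimposed coordinates (optionally tangent-projected). At the shape
  variation scales of swallowing this is inconsequential, but the flag
  exists for a reason.
- The discriminant regularization (PCA truncation) is one standard choice;
  other software may shrink or truncate differently, so coefficient-level
  agreement with other implementations is not guaranteed — group-difference
  displacement fields and permutation p-values are the comparable outputs.
- ICC confidence intervals: see the k = 2 coverage caveat above.
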