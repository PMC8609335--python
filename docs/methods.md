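# Methods

This note records the modeling choices behind `hyperdecode`: what each stage
assumes, which knobs matter, what the synthetic generator does and does not
emulate, and where the design was genuinely open.

## Surface model and geodesics

Cortical geometry is a pair of subdivided icospheres ("hemispheres") with a
medial-wall cap facing the midline.  The geodesic metric is the shortest
path along mesh edges with Euclidean edge weights — the standard graph
approximation, not exact polyhedral geodesics — and medial-wall vertices
are removed from the graph entirely, so neighborhoods neither include nor
route through the wall.  Searchlights are geodesic disks; every analysis
radius (3 mm ROI-center refinement, 10 mm decoding searchlights, 15 mm ROI
disks, 20 mm alignment searchlights) is in mesh millimeters.

Mesh scale is the one place desk-scale geometry bites.  The tiny test mesh
(42 vertices/hemisphere, ~3 mm spacing) is fine for structural checks and
null calibration, but a 20 mm alignment searchlight covers essentially the
whole hemisphere there.  The 14-subject demo world therefore uses
642-vertex hemispheres at ~5 mm spacing (sphere radius ≈ 36 mm): alignment
searchlights then cover a sensible fraction of a hemisphere, and — because
searchlight alignment spreads information up to roughly twice its radius
(the composed subject→reference operator chains two radius-20 mm maps) —
there remains cortex provably outside the reach of any planted signal.  We
measured the spread directly: with signal confined to a 9 mm disk,
decoding accuracy at 30–40 mm from the region center is far above chance
and decays to chance by ~50 mm; "null territory" in the demo analyses is
defined as vertices more than 55 mm from every signal-region center.

ROI construction follows the two-stage rule: each seed is refined to the
maximum-statistic vertex within 3 mm (vertices must exceed 1.96, falling
back to 1.65), ROIs are 15 mm disks around refined centers, and overlaps
resolve to the geodesically nearer center.  Equidistant ties go to the ROI
listed first, with a warning — the choice is arbitrary and logged rather
than silent.

## Trial sequences

A T1I1 sequence over *n* labels is an Eulerian circuit of the complete
directed graph with self-loops: length n² + 1, first = last, every ordered
pair exactly once.  The generator additionally constrains every aligned
*n*-trial block to be a permutation of the labels, with the *n* self-pairs
landing exactly on block boundaries.  This stronger, serially balanced form
is what makes the run partition clean — 63-trial runs contain each image
exactly 3× and exactly 3 null trials — and it is not implied by the bare
Eulerian property (AABBA is a valid 2-label T1I1 sequence whose first block
lacks a label).  The search is a randomized depth-first backtracking walk
(numba-compiled; a 21-label sequence takes tens of milliseconds).
Block-balanced sequences do not exist for every alphabet — exhaustive
search shows none for n = 3 — so the generator falls back to a plain
Eulerian circuit with a warning for small alphabets.  Inverting a sequence
preserves both properties up to a one-element shift, which
`invert_concatenation` absorbs by dropping the leading duplicate.

Efficiency scoring builds one parametric carry-over regressor per
relationship matrix (identity, head view, mirror symmetry), with the value
at trial *t* equal to the relation between trials *t−1* and *t*,
mean-centered across trials, HRF-convolved over the full response support,
and scores a sequence by 1/trace of the estimator covariance restricted to
those regressors.  The centering makes a constant relation an exactly null
regressor (flagged as rank-deficient), and full-support convolution makes
the score exactly invariant under sequence reversal for symmetric
relations.  The formula is our reading of standard design-detection
efficiency and is exposed as a pluggable scorer.

**Counterbalancing matters for inference.** All subjects see the same two
selected sequences (one per familiarity condition), so the GLM noise
correlations among condition estimates — driven by HRF-range trial
adjacencies that first-order balance cannot remove — are *shared across
subjects* and tied to identity labels.  Left uncorrected, this lets a
between-subject classifier decode pure noise about 1.4 percentage points
above chance and inflates the permutation false-positive rate to ~0.15.
Presenting the inverted sequences to every other participant (as the
`counterbalance_inversion` option, on by default) decorrelates the two
participant groups' design structure and restores calibration (measured
type-I rate 0.037 on a signal-free world).

## Synthetic worlds

A world consists of (a) shared movie latents: unit-variance white series
per cortex vertex; (b) shared condition patterns for 2 familiarities × 4
identities × 5 views, decomposed as a view-invariant identity component +
a view component + a familiarity component, all Gaussian in a template
basis; (c) per-subject mixing transforms.  Identity components are scaled
by `snr_core` in core-region vertices (both conditions) and by
`snr_extended` in extended-region vertices (personally familiar condition
only); view/familiarity components get half the regional scale; null
vertices carry no signal at all.  Defaults: `snr_core = 2.0`,
`snr_extended = 1.5`, `movie_snr = 2.0` against unit sensor noise — chosen
as a regime where local alignment is learnable from a few hundred movie
time points, in the spirit of the strong movie-alignment signals reported
in the functional-alignment literature; they are knobs, not claims about
real effect sizes.

Mixings are block-orthogonal: the cortex is tiled into contiguous geodesic
patches (~8 mm radius, ≥4 vertices — smaller blocks are dissolved so no
vertex stays anatomically aligned by accident) and each patch receives an
independent random orthogonal matrix per subject.  Local rotation is
exactly the transformation class searchlight hyperalignment models, so
recovery is possible in principle; nothing aligns across subjects
anatomically.

Task runs are HRF-convolved condition responses (subject-mixed patterns),
plus per-node random polynomial drift, plus 6 motion-like random-walk and
6 physiological-like oscillatory confound series that also leak into the
data, plus unit Gaussian sensor noise (optional AR(1), default off).
Button presses follow the 1-back identity task deterministically.  What
the generator does **not** emulate: spatial noise correlations, realistic
BOLD nonlinearity and variability of the HRF across cortex, head motion
displacement (only motion-like regressors), physiological aliasing, or
anatomical variability in region layout.  Passing tests therefore show the
pipeline recovers exactly the structure the model class assumes — not that
real data satisfy those assumptions.

## GLM

Nuisance removal is a single least-squares projection onto the span of the
confound columns plus a discrete-cosine basis (all components at or below
0.0066 Hz) plus constant and linear terms, applied per run; outputs are
exactly orthogonal to the removed subspace.  The design has one regressor
per image per run (boxcar of 1.6 s — three 500 ms presentations with two
50 ms gaps — convolved with the canonical double-gamma; peak 6 s,
undershoot 16 s at ratio 1/6), one regressor pooling the repeated lead
trials, one for "same" button presses, and per-run Legendre polynomials up
to order 3.  Estimation is ordinary least squares; t = β/SE with
dof = timepoints − regressors; no prewhitening (the t-values feed a
classifier, not parametric group statistics; white synthetic noise also
makes it exact here).  t-values are computed per run-specific regressor
and averaged across runs at the decoding stage.

## Hyperalignment

Per searchlight, subjects are aligned by orthogonal Procrustes (SVD
solution, reflections allowed, no scaling) to an evolving template: seeded
from the reference subject, updated as a running mean over subjects on the
first pass, then every subject re-aligned to the group mean on each
subsequent pass (3 passes by default; the count is a config knob, chosen
to follow the iterative scheme of the searchlight-alignment literature).
Per-searchlight rotations are summed into one sparse whole-cortex map per
subject without renormalization ("mean" aggregation is available).
Projection into the reference subject's space composes the subject's
forward map with the transpose of the reference's map as a single sparse
operator and is applied to z-scored movie data and to t-value patterns
alike.  The reference subject defaults to subject 0.  For speed on dense
meshes, alignment searchlights may be centered on a sparse covering subset
of vertices (`hyper_center_spacing`); every cortex vertex remains inside
multiple searchlights.

## Decoding

Folds pair one left-out subject with one left-out view, exhaustively
(subject-major order).  Run-averaged patterns give 20 samples (4 identities
× 5 views) per subject per familiarity; training uses
(n_subjects − 1) × 4 × (n_views − 1) samples, testing the held-out
subject's 4 samples at the held-out view.  The classifier is a one-vs-one
linear SVM with vote counting (libsvm via scikit-learn); prediction ties
resolve through the aggregated decision values, then the lowest class
index.  Regularization scales with the data: C = 1 / (mean squared
training-sample norm), implemented equivalently by normalizing the Gram
matrix to unit mean diagonal and fitting at C = 1 (the decision rule is
identical; the normalized problem converges faster).  No per-searchlight
feature normalization is applied by default (a flag exists).

## Inference

Permutations shuffle identity labels within every (participant, view) cell
— each cell holds one sample per identity, so balance is automatic — and
rerun the full decoding.  Null distributions bootstrap n_folds fold-level
accuracies with replacement from the pool of all permutations' folds
(stratified-by-permutation sampling is a config alternative) and average;
the empirical p is (exceedances + 1)/(draws + 1) with ties counted as
exceedances.  BH-FDR comes from statsmodels.  Difference maps floor each
condition's across-fold mean at 25% before subtracting — below-chance
accuracies are noise and would inflate differences — and the same
floor-and-subtract is applied inside every bootstrap draw, with two-sided
absolute-value exceedance counting; the two conditions' permutation
streams are independent.

## Problem sizes and numerical choices

The shipped analyses use two standard worlds: *tiny* (4 subjects,
42-vertex hemispheres, 2 runs per condition, 150 movie TRs) for structural
and null checks, and *demo* (14 subjects, 642-vertex hemispheres, 10 runs
per condition, 300 movie TRs) for full-pipeline recovery.  The end-to-end
test suite runs demo-world ROI inference at 50 permutations × 1,000
bootstraps and type-I calibration at 10 permutations × 1,000 bootstraps
over ~300 null locations on a signal-free world; the library defaults
remain the full 100 permutations and 10,000 bootstraps.  Seeds fan out
from a single global seed through `SeedSequence(seed, spawn_key=(stage,))`;
every emission, permutation and bootstrap is reproducible bit-for-bit from
the recorded seeds.  Degenerate inputs are handled explicitly: all-zero
Procrustes inputs return the identity with a warning; empty ROIs, missing
conditions, rank-deficient designs and over-complete confound bases raise
typed errors.

## Known limitations

* Graph geodesics overestimate true surface distance on coarse meshes;
  all radii are interpreted in the graph metric.
* Sum-aggregated alignment maps are not orthogonal where searchlights
  overlap, so the reference-space round trip is only approximate on
  overlapping tilings (exact on disjoint ones, which is what the
  idempotence test uses).
* Information spreading by searchlight alignment (~2× the alignment
  radius) is intrinsic to the method; on desk-scale meshes it constrains
  where null territory can live, and the package measures rather than
  hides it.
* The efficiency scorer and the iteration schedule are documented readings
  of under-specified conventions, exposed as configuration, not asserted as
  reproductions of any particular toolbox.
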