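# Methods

This note documents the models and procedures `sfmvpa` implements, the
choices made where the design was genuinely open, and what the synthetic
validation does and does not establish.

## Double-radius dividing

The sweep visits vertices in ascending index order.  An unpainted vertex
`v` becomes a seed; unpainted vertices at Euclidean distance < r (strictly)
are painted green and grouped into `v`'s label, unpainted vertices at
[r, R) are painted yellow.  Painted vertices never seed, so any two seeds
are ≥ R apart; with the default R = 2r the inner (green) balls are
provably disjoint.  After the sweep, every vertex that is not green —
yellow vertices, plus any vertex farther than R from every seed on sparse
meshes — joins the label whose *green-member centroid* is nearest, ties
broken toward the lowest label id.

Open choices, resolved as follows:

* **Paint permanence.**  A painted vertex's state never changes during the
  sweep; yellow vertices are assigned only in the final pass.  This
  matches the two-phase structure of the procedure (iteration, then
  assignment of the ungrouped remainder) and makes the sweep
  deterministic.
* **"Center" during yellow assignment** means the centroid of the green
  members at the end of the sweep, not the seed vertex.  Both readings are
  exposed via `label_centers(..., membership=...)`; final centers are
  always recomputed over all members.
* **Strict inequalities** everywhere (< r, < R, < adjacency threshold,
  < searchlight radius), following the "less than" formulation of each
  rule.
* All distances in the package are 3-D Euclidean on the supplied
  coordinates; no geodesic distances are computed.  Statistics such as the
  label count or mean nearest-label distance therefore depend on which
  geometry (white/pial/inflated) a template file carries, and
  `surface_report` should be quoted together with the geometry used.

The optimised implementation (k-d tree ball queries) is required by the
test suite to agree *exactly* with a literal O(n²) transcription of the
rules on meshes up to several hundred vertices.

## Searchlight decoding

* Features are the single frame's label values (no temporal window); the
  21 frame offsets 0…20 s from onset are analysed independently.
* The classifier is a linear SVM with fixed C = 1 in a one-vs-one
  multiclass reduction with majority-vote (Hamming) decoding — the common
  default realisation of an error-correcting output-code model.  No
  hyperparameter search is performed anywhere.
* Cross-validation is leave-one-run-out over the 3 runs.  Features are
  z-scored per feature using training-fold statistics only; test data
  never influence normalisation or training (verified by an affine
  invariance test).  A fold whose training set lacks a class is skipped
  with a warning; if all folds are skipped, the call errors.
* Task-vs-control balancing retains all control instances and
  floor(n_control/4) randomly chosen instances per load.  The subset is
  drawn **once per subject** and reused across all labels and frames, so
  the accuracy map is comparable over the surface; the seed is part of the
  configuration.  (Redrawing per frame is possible by calling
  `balance_instances` per frame, but is not the default.)
* **Null behaviour.**  Leave-one-run-out CV on label-permuted or pure-noise
  data is *conservatively* biased a little below chance: with class counts
  fixed within a dataset, the training majority class is the test
  minority.  Over 200 permuted datasets the two-class mean is ≈ 0.46
  rather than 0.50.  The calibration tests therefore assert the absence of
  *optimistic* bias (mean ≤ chance + 3 SE) plus a small-bias bound, which
  is the direction that matters for the one-sided group test: the test is,
  if anything, slightly conservative.

## Group inference

* Second level: one-sample t across subjects per (label, frame), one-sided
  against chance (0.5 task-vs-control, 0.25 load).  Degenerate zero-variance
  samples use conservative conventions: all subjects exactly at chance →
  t = 0, p = 0.5; zero variance above chance → p = 0, flagged degenerate;
  an all-zero slope sample → p = 1.
* The FDR family is one frame's labels (maps are reported per frame); the
  Benjamini–Hochberg step-up is implemented directly and cross-checked
  against statsmodels.  Applying the correction across the whole
  21-frame family is possible by passing the flattened p array.
* Clusters are connected components of the significant labels on the
  adjacency graph (labels adjacent iff closest vertex–vertex distance
  < 1.1 mm at full resolution; the threshold scales with the mesh).  The
  minimum size is strict: clusters survive only with **more than** 10
  labels.  Cluster area is the sum of member label areas, each label's
  area being one third of its vertices' incident-triangle areas.
* The load regressions (amplitude, connectivity) are random-effects: an
  OLS slope per subject, then a two-sided one-sample t of the slopes
  against zero.  A pooled fixed-effects regression would weight subjects
  by their within-subject precision; the per-subject form matches the
  second-level logic of the rest of the pipeline and is the default.

## Response model

* The HRF is the canonical double gamma: gamma-pdf lobes with response
  peak 6 s, undershoot peak 16 s, unit dispersions, peak:undershoot ratio
  6, sampled at the frame period and peak-normalised; h(0) = 0.
* GLM regressors are 21-s condition boxcars convolved with the HRF,
  truncated to the run; runs are concatenated with run-wise intercepts.
  The GLM runs in label space (one code path with the rest of the
  pipeline); running it per vertex before downsampling is a linear
  operation away and changes betas only through the within-label average.
* Adjacent-condition contrasts (c+1 vs c for c = 0…3, i.e. including
  control vs load 1) are paired t-tests of the per-subject beta
  differences, thresholded element-wise at p < 0.01 with cluster-wise
  p < 0.05 calibrated by sign-flip permutation of the subject difference
  maps (500 flips by default): the observed clusters must exceed the
  95th percentile of the null maximum cluster size.
* Response curves average frames [onset−1, onset+20] over a condition's
  trials, subtract the control average, and zero the pre-onset sample;
  the 21 post-onset samples are returned.  "Average amplitude" is the
  arithmetic mean of those 21 samples (the peak is available by taking
  `curve.max()` instead).

## Synthetic data

The generator emulates the paradigm the analyses assume: 3 runs of 1-s
frames; 100 trials, 20 per condition 0–4 (0 = control), randomly permuted
and split 33/33/34 across runs; onsets every 32 s (≈ stimulus + 20-s delay
+ probe/answer), leaving one pre-onset baseline frame; baseline 100 a.u.;
AR(1) noise (φ = 0.3, innovation sd 1.0) plus white noise (sd 0.5).
Effects, each injected only when its region is configured:

* **Pattern** — per condition, a fixed random spatial vector
  (sd 2.5 a.u.) over the region, gated by the HRF-convolved indicator of
  frames 2–10 and repeated identically across that condition's trials.
  The default strength is validation-grade: clearly decodable wherever a
  searchlight sees any region label, which is what makes exact
  region-recovery claims testable.
* **Amplitude** — an HRF-convolved 21-s boxcar scaled by slope × load
  (default 0.5 a.u./load).  The envelope is mean-normalised over the
  analysis window so the injected slope is in the same units the
  amplitude analysis measures.
* **Coupling** — a shared latent innovation (sd 1.0) added during each
  non-control trial window with weight 1 on the seed region and
  c0 + c1 × load (defaults 0.3 + 0.15 × load) on the target region, so the
  seed–target correlation rises monotonically with load while the seed's
  own variance stays load-independent.

Everything is deterministic under a fixed seed.  What the simulation does
**not** model: vascular/physiological noise structure, spatial noise
correlations beyond the label average, motion, HRF variability across the
cortex, and behavioural responses.  Passing recovery tests therefore
demonstrates the *correctness of the pipeline's computations and the
calibration of its inference*, not performance on real data.

Two cross-talk caveats are intrinsic, not bugs: a load-proportional
amplitude is itself decodable (a mean shift is linearly separable) and
makes task-vs-control separable in its region, so "invisibility to the
decoder" is only tested for the coupling effect; and condition-specific
patterns make *load* decodable by design.  The dissociation tests assert
the pairs that are physically guaranteed: patterns are invisible to the
amplitude and connectivity load regressions (the per-condition vectors
are zero-mean and load-unrelated), and coupling is invisible to decoding
and amplitude analysis (the latent is trial-varying, zero-mean noise from
their viewpoint).

## Validation studies and problem sizes

`sfmvpa.validation` runs the end-to-end studies on a 2562-vertex icosphere
(radius 50 mm, vertex spacing ≈ 3.6 mm) divided at r = 7.5 mm into 102
labels (≈ 16 mm center spacing) with 20-mm searchlights (3–5 labels) —
the same relative geometry as a full-resolution analysis at a size where
each study takes seconds.  Null calibration uses 100 replicates of
20-subject chance-level maps; pattern recovery uses 16 subjects (the
p < 10⁻⁴ per-label threshold demands a real group), amplitude and
coupling recovery 10 subjects each.

Ground truth for searchlight maps is the *searchlight-reachable set*: the
labels whose searchlight contains at least one region member.  A label's
statistic describes its neighbourhood, so a correct pipeline recovers
exactly that set, and region-boundary Jaccard overlaps are computed
against it; per-label analyses (amplitude, connectivity) are compared
against the raw region.

## Known limitations

* No geodesic distances: searchlights near deep sulci on a folded (white/
  pial) geometry can span gyral banks, exactly as in any Euclidean
  searchlight.  On inflated or spherical geometry the issue is minimal.
* No prewhitening or nuisance regression in the GLM; the AR(1) noise in
  the simulations is handled only through the group-level randomisation.
* The recursive cluster criterion and FDR interact: FDR is applied before
  clustering, so cluster membership depends on the whole frame's p
  distribution.
* Undefined (zero-variance) trial correlations are dropped from load
  averages rather than imputed; a load with no usable trial errors out.
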