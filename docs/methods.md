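# Methods

## Data model

A drawing session lives on a `BodyTemplate`: four independent raster canvases
(front, back, left, right), each with a binary body-outline mask and an
integer label map assigning outline pixels to the 19 body regions of the
widespread pain index. Views are independent coordinate frames (row-major,
origin top-left); no registration between views or between sex variants is
attempted. A `SymptomLayer` is one drawn sensation: per-view binary masks, a
descriptor from a fixed 17-item pain/paresthesia vocabulary, one continuous
VAS intensity in [0, 10], and a free depth tag. Labels outside the vocabulary
(clinicians' findings such as "allodynia") are stored but excluded from all
pain analyses. A `PainDrawing` is the ordered layer stack of one subject-role;
all analyses operate on its *pain map*, the per-pixel maximum intensity over
pain layers (so overlapping symptoms never add, and layer order is
irrelevant).

On disk, masks and maps are 8-bit grayscale PNGs with intensity encoded
linearly (gray g ↔ VAS g/255·10, so intensity is quantized to 8 bits by one
write/read cycle and stable afterwards), plus JSON manifests; cohorts add a
ratings CSV. NIfTI export stacks subjects along the third axis, one volume
per view.

## Feature definitions and numerical choices

- **Extent** is normalized per view by that view's outline pixel count, and
  for the whole drawing by the summed outline pixels of all views; the
  severity-restricted variant uses “intensity ≥ threshold” with a default
  threshold of 6 VAS (ties count as severe).
- **Clusters** are connected components of the binarized pain map, counted
  per view and summed. Default connectivity is 8 (stylus strokes produce
  diagonal pixel chains); 4-connectivity is available. Components are
  computed on the merged all-symptom map so that overlapping symptoms form
  one cluster; per-layer counts can be obtained by extracting features from
  single-layer drawings.
- **WPI** counts regions with at least one drawn pixel in any view. The
  synthetic template labels every outline pixel in every view; user-supplied
  templates may leave pixels unassigned, in which case a drawn pixel can
  contribute to extent but to no region.
- **Mean intensity** averages the one-per-symptom VAS ratings, not pixels.
- **Validation** of out-of-outline pixels is strict by default (error naming
  the offending views) with an explicit clip mode that zeroes and counts
  them, for sessions produced outside the capture app.

## Agreement statistics

The **Jaccard index** is computed on binarized masks per view and averaged
over views excluding those empty in *both* drawings (a both-empty view
carries no overlap information); if every view is both-empty the subject's
value is missing. Intensity never enters beyond binarization.

**ICC(3,1)** (Shrout–Fleiss: two-way mixed, single rater, consistency) is
computed from the two-way ANOVA mean squares, with exact F-based two-sided
95% confidence intervals. Degenerate tables (no variance anywhere) return an
estimate of 0 with a missing CI and a warning — no subject variance means no
measurable consistency; tables with zero residual variance return exactly 1.
A small relative tolerance (1e-12 of the total sum of squares) guards both
branches against floating-point round-off.

Whole-drawing ICCs use per-subject totals (whole-drawing extent percent;
summed cluster count). Per-view ICCs include all subjects — a 0–0 pair is
informative for extent agreement — but a view's ICC is dropped entirely when
fewer than 3 subjects have a nonempty pair there, since it would then rest on
structurally empty pairs. Whether the both-empty exclusion should also prune
the per-view ICC subject lists is genuinely open; this implementation's
choice (exclusion for Jaccard averaging only) is deliberate and documented
here.

## Cohort statistics

Average maps are pixel-wise means of the pain maps with a support raster
(fraction of subjects drawing each pixel); thresholding retains pixels drawn
by at least ceil(f·n) subjects — with f = 0.10 and n = 47 that is exactly 5.
Rating tests are one-sided one-sample t-tests against 0 (the hypothesis being
that seeing the drawing *helped*); feature comparisons are two-sided paired
t-tests; both raise on zero variance rather than returning an unstable
statistic. The exploratory rating–feature tables use Pearson correlations by
default (Spearman as an option), two-sided p-values, and deliberately no
multiple-testing correction — they are exploratory screens, and the outputs
are labelled as raw p-values. Constant columns yield missing cells with a
warning.

## Synthetic cohort generator

The generator exists to validate the pipeline, not to model anatomy. Its
defaults are the study conditions used throughout the tests:

- **Template**: geometric humanoid silhouettes (ellipse head, rectangular
  trunk/limbs) at 256×128 pixels per view by default (minimum 40×40); the
  19-region partition uses horizontal bands (10 on the front, 9 on the back,
  all 19 on each profile) so every region is nonempty and region masking is
  exercised on every view.
- **Patients** draw max(1, Poisson(3.63)) clusters — irregular ellipses with
  a satellite lobe, radius 4–9% of view height, placed uniformly on the
  outline — each as its own layer with a frequency-weighted descriptor and a
  VAS intensity ~ N(7.19, 2.17) clipped to [0.5, 10]. A rendered cluster is
  restricted to one connected component so counts stay calibrated at canvas
  gaps.
- **Doctors** reproduce each patient cluster imperfectly: they miss it with
  probability 0.2; otherwise they either redraw it near its true position
  (probability `doctor_agreement` = 0.75, centre jittered by 0.7 radii,
  radius dilated ×1.25) or relocate it entirely. Adjacent same-view clusters
  merge into one area-preserving cluster with a per-doctor merging
  propensity (Beta-distributed around 0.7), doctors occasionally add
  spurious small clusters of their own (Poisson, mean 0.8), and a mild
  per-pair lognormal jitter scales the dilation. The merging/spurious terms
  put noise into cluster *counts* while largely conserving drawn *area*;
  that asymmetry is what makes extent agree better than cluster counts
  between the raters — the qualitative contrast the pipeline is designed to
  detect — and it makes doctors draw fewer, larger clusters on average.
- **Ratings** come from a linear-Gaussian model on the patient's realized
  extent and WPI: rating = clip(round(μ + σ·(w_e·z_e + w_w·z_w + w_n·η))),
  with z-scores formed from frozen population constants (estimated once from
  a large simulated sample; `estimate_feature_stats` recomputes them for
  non-default configurations) and w_n chosen for unit latent variance. With
  unit variance the generating latent–extent correlation is
  w_e + w_w·corr(extent, WPI), independent of the standardization constants;
  defaults (w_e = w_w = 0.243, extent–WPI correlation ≈ 0.85) put it at
  ≈ 0.45, with mean 4.8 and SD 2.6 for understanding and 2.7/1.2 for the
  decision rating. Rounding to 11 integer levels and clipping at 0/10
  attenuate the realized correlation by roughly 1–2%.
- **Reproducibility**: one master seed; per-subject streams are derived by
  subject index (`SeedSequence(seed, spawn_key=(i,))`), so subject i is
  unchanged when the cohort size changes.

What the generator does **not** emulate: real anatomy or dermatomes,
free-form stroke shapes, clinically structured syndromes (radiating patterns,
laterality), correlated missingness of ratings, or multiple doctors per
patient. Passing tests therefore demonstrate that the *measurement pipeline*
is correct and that its statistics behave as designed under controlled
conditions — not that any clinical effect size is reproduced.

## Validation strategy and problem sizes

The validation suite checks, at sizes chosen to keep the full run in the
order of a minute or two each: exact agreement of cluster counting, Jaccard
and ICC(3,1) with independent oracles (stack-based flood fill, coordinate-set
counting, first-principles sums of squares) on ≥100 random small instances;
closed-form limits (shift-invariance of consistency ICC, Jaccard
identity/disjoint, p = 0.5 at t = 0); 95% CI coverage of the ICC over 500
bivariate-normal cohorts of n = 47 at ρ = 0.5; recovery of a generating
rating–extent correlation of 0.45 within ±0.05 over 200 replicate cohorts of
n = 47 (on a 96×64 template, where simulation is cheap); reproduction of the
extent-vs-cluster ICC ordering and the patient>doctor cluster-count direction
in ≥90% of 100 replicate cohorts; the exact ceil-based support-threshold
arithmetic; and an end-to-end smoke run at n = 47 on 128×256-pixel views.

## Known limitations

- The Jaccard/ICC machinery assumes exactly two raters per subject; k > 2
  tables are accepted by `icc31` but unused elsewhere.
- Region labels are integer rasters; overlapping or probabilistic region
  atlases are not supported.
- The per-view ICC subject-inclusion rule (see above) is one defensible
  choice among several; per-view estimates should be read with that in mind.
- Intensity quantization to 8 bits bounds round-trip VAS error at ~0.02.
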