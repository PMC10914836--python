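# Methods

## Problem and model

`slidemil` grades whole-slide images (WSI) of colorectal samples into three
ordered classes — non-neoplastic (NNeo), low-grade dysplasia (LG) and
high-grade dysplasia (HG) — from a slide-level label only, under the ordinal
multiple-instance assumption: a slide S_s is a bag of tiles T_{s,n},
n = 1..n_s, and its label is the most severe tile label,

    C_s = max_n C_{s,n}.

A tile classifier Φ estimates per-tile class probabilities ŷ_{s,n} on the
3-simplex.  Mixed supervision proceeds in two phases:

1. **Supervised pre-training** on the small annotated subset (~9 % of
   slides carry tile-level label masks), minimising cross-entropy on tiles
   with known classes.
2. **Weakly-supervised MIL training** on slide labels.  Each epoch has two
   stages: (a) *severity analysis* — Φ scores every tile of every bag and
   tiles are ranked by the expected severity
   E(Ĉ_{s,n}) = Σ_{i=1..K} i·ŷ_{s,n}(i) ∈ [1, K]; (b) *training* — the
   `n_select = 5` most severe tiles per bag are trained for one epoch with
   the slide label as each tile's target.

After the first epoch's inference, each bag is cut once to its top-`M`
tiles by expected severity (`M = 200` at full scale; bags with n_s ≤ M pass
through unsampled), and the cut is never refreshed.  Validation bags are
sampled too by default (config switch for train-only).  Prediction never
samples.

Slide-level prediction exposes two aggregation rules. The default
`top_tile` rule follows the evaluation protocol: the diagnostic tile is the
argmax of expected severity and the slide class is that tile's argmax
class, with confidence = ŷ(predicted class) at that tile.  The `hard_max`
rule is the literal ordinal-MIL definition Ĉ_s = max_n Ĉ_{s,n}.  The two
can disagree when the top-expected-severity tile's argmax class is lower
than another tile's argmax; the divergence is documented by a dedicated
test, and `top_tile` is the default because validation/evaluation is
defined through the single most severe tile.  An optional aggregation head
concatenates the scorer's hidden features of the 7 most severe tiles (in
severity order, padding by repeating the most severe tile for smaller bags)
and feeds them to a one-hidden-layer MLP trained on frozen features.

## Tessellation

Tissue is segmented on a 32×-downsampled thumbnail (area averaging) by
Otsu's threshold on the HSV saturation channel: H&E background is
near-white and saturation-poor, tissue is colourful, so tissue = high
saturation.  Otsu runs on a 256-bin histogram of S ∈ [0, 1]; ties in the
between-class variance objective break toward the lower threshold; a
zero-variance channel yields an all-background mask with a degenerate
flag.  Tiles are non-overlapping grid squares (512 px at full scale, 32 px
at desk scale), 0-based with half-open extents, retained only when the
mask cells covering them are tissue at fraction ≥ the threshold (default
1.0 — fully-tissue tiles only).  The tissue fraction is computed on the
downsampled mask cells, which is exact because the tile size is enforced
to be a multiple of the downsample factor.  Partial edge tiles are
discarded.

## Tile classifier

The backbone is a deliberately small, fully deterministic NumPy model:
each tile is reduced to an 8×8 RGB block-mean summary (192 features in
[0, 1]) followed by a one-hidden-layer MLP (32 hidden units, ReLU,
softmax) trained with Adam on the cross-entropy.  Defaults: learning rate
5e-3, weight decay 3e-4, batch 32, 40 supervised epochs — sized for the
synthetic appearance classes and a single-CPU budget; all are exposed in
the config for larger settings.  There is no class re-weighting and no
augmentation.  Determinism: initialisation, shuffling and every optimiser
step derive from one integer seed; predictions are pure functions of
(parameters, tile), so batch composition cannot change outputs and
save/load round-trips reproduce predictions exactly.  The hidden
activations double as the aggregation head's per-tile features.

## Synthetic cohorts

The generator emulates the *structure* of a graded WSI cohort, not its
histology.  Each slide is a grid (default 8×8) of cells; a
`background_fraction` (0.25) of cells render as near-white,
saturation-poor noise (HSV V > 0.9, S < 0.05) so the Otsu mask recovers
them; the rest are tissue tiles drawn from class-conditional recipes.  A
tissue tile of class k has mean colour

    base − (k − 1) · separability · step

with base ≈ eosin pink (205, 150, 185), step (28, 22, 6) and i.i.d.
Gaussian pixel noise (σ = 14): severity moves tiles darker and more purple
along one monotone axis, giving the ordinal structure the expected-severity
score assumes.  `separability = 0` makes classes indistinguishable;
at 1 a per-tile mean-intensity threshold is near-perfect.

Per-slide planting: NNeo slides are all-NNeo tissue; LG/HG slides carry
`lesion_fraction` (default 0.3) of tissue tiles in their own class
(at least one) and never a higher class, with non-lesion tissue on HG
slides mixing NNeo and LG — so the max rule holds by construction.
Cohort defaults are the study conditions used by the tests and the
acceptance script: 150 slides, class mix (0.166, 0.513, 0.321) matching a
large colorectal cohort's slide proportions, separability 0.8, 9 % of
slides annotated.  Splits are stratified and disjoint at 0.6/0.2/0.2;
a full-scale 0.82/0.10/0.09 split would leave ~13 test slides at desk
scale, too few to resolve a sensitivity of 0.95, hence the flatter split.
Annotated slides are drawn from the training split (annotated samples are
training material by design), stratified over the classes present so the
supervised stage sees every grade.  Randomness is reproducible per slide —
each slide's stream is seeded by (cohort seed, slide index) — so
regeneration is byte-identical regardless of order.

What the generator does *not* emulate: realistic histology texture, stain
variation, scanner artefacts, duplicated fragments, pyramidal formats, or
ambiguous borderline lesions.  Passing the end-to-end checks therefore
shows the pipeline's machinery (masking, tiling, ranking, sampling, MIL
updates, aggregation, statistics) is correct and stable, not that the tiny
backbone would grade real H&E slides.

## Evaluation statistics

* **Accuracy, binary accuracy (NNeo vs all), sensitivity** (positives =
  LG ∪ HG; reported with n = number of positives), **QWK** with weights
  (i−j)²/(K−1)², per-class recalls and the 3×3 confusion matrix.
* **Binomial CI**: SE = sqrt(m(1−m)/n), half-width z·SE, z = Φ⁻¹((1+c)/2)
  ≈ 1.96 at c = 0.95.  Strictly valid for Bernoulli means (accuracy);
  also printed for QWK/sensitivity with a flag.
* **McNemar**: cells a/b/c/d = both wrong / only second wrong / only first
  wrong / both right; X² = (|b−c|−1)²/(b+c), right-tail χ²(1) p-value,
  significant iff X² > 3.841; b + c = 0 is defined as X² = 0, p = 1.
* **PR curve**: positive score = 1 − ŷ(NNeo) at the diagnostic tile (the
  score definition is a package decision); F1 at the discrete classifier's
  operating point when given, else the best curve threshold.
* **Confidence densities**: Gaussian KDE (Scott's rule) of predicted-class
  confidence for correct vs incorrect predictions on a [0, 1] grid, with
  group means; a zero-variance group degrades to a normalised spike and
  groups under 2 samples are skipped with a flag.
* **Label correction**: disagreements export as a review TSV; a corrected
  table (slide_id, corrected_label) feeds back into `evaluate`, so a
  second labelling round rectifies every metric.

## Reject option

Confidence is the predicted-class probability at the diagnostic tile.  For
a requested rejection rate r, the threshold is t = sorted_conf[floor(r·n)]
(the empirical r-quantile, lower interpolation of the inverted CDF) and
samples with confidence strictly below t are rejected: r = 0 rejects
nothing, the rejected fraction never exceeds r + 1/n, and for distinct
confidences it stays within 1/n of r; ties at the threshold are retained.
`accuracy_rejection_curve` reports retained-sample accuracy per rate,
flagging rates that retain nothing.

## Numerical and design notes

* Severity ties break by ascending tile index everywhere (ranking, top-k,
  diagnostic tile), making every ordering deterministic.
* Nested property: the top-M sets for growing M are nested, so relevance
  loss is non-increasing in M by construction.
* `relevance_loss` counts a tile relevant if it shares the slide label or
  sits in the current top-5 of the full-bag ranking (the tiles that would
  enter training); zero relevant tiles is defined as 0 % with a warning.
* Best MIL checkpoint maximises validation accuracy with QWK as
  tie-break; QWK on single-class splits is NaN and ranks lowest.
* Desk-scale problem sizes (150 slides, 8×8 grids, 32 px tiles, 10 MIL
  epochs) were chosen so the whole pipeline runs in seconds on one CPU;
  full-scale values (512 px tiles, M = 200, 50 epochs) remain available
  through the config.

## Known limitations

* The appearance model is one monotone colour axis; a backbone this small
  cannot represent texture-defined classes.
* The normal-approximation CI is poor near m ∈ {0, 1} at small n (it
  collapses to zero width); exact/bootstrap intervals are out of scope.
* The aggregation head's permutation invariance relies on distinct
  severity scores; exact ties would make the canonical order depend on
  tile indices.
* The percentile reject threshold under-rejects in the presence of heavy
  confidence ties (documented tie semantics).
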