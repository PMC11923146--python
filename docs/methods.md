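# Methods

This note documents the models, procedures and numerical choices behind the
package, in the order data flows through the pipeline.

## Problem setting

Ocular surface squamous neoplasia (OSSN) is diagnosed on in vivo confocal
microscopy (IVCM) through a small set of visual signs — the "starry-sky"
pattern of hyperreflective nuclei, hyperkeratosis, mitotic figures, and
enlarged irregular epithelial cells — visible against the normal polygonal
epithelial cell mosaic. The pipeline reproduces a multi-level analysis
protocol around those signs: sign rectangles are tiled into squares to
enlarge a small annotated dataset, classifiers are trained under splits that
prevent patient-identity leakage, rare signs are handled few-shot, per-cell
binary decisions are aggregated by majority vote to image and patient
decisions, and attribution methods probe what the classifiers use. The
clinical image collection the protocol was designed around is private, so a
synthetic cohort generator provides data with the same statistical
structure; all quantitative results in this repository are therefore
statements about the protocol under synthetic conditions, not about
clinical performance.

## Synthetic cohort generator

Each snapshot is a 384 × 484 8-bit grayscale frame: a 384 × 384 content
area above a 100-row meta-information footer. The footer is a fixed
pseudo-text bar pattern shared by every image (generated from a constant
seed), so it carries no class or identity signal; it exists so that footer
removal is a meaningful, testable step.

The content area is a Voronoi-like polygonal mosaic. Cell centers sit on a
jittered square grid; per-pixel intensity follows the gap between the
distances to the nearest and second-nearest center, giving bright ridges
(cell borders, base level 165) around dark interiors (base level 55, with a
per-cell tone jitter of σ = 7). The frame is blurred (σ = 1 px) and
corrupted with Gaussian noise (σ = 6). The ground-truth cell map marks each
interior (ridge response < 0.35) with an integer label, so truth masks are
pairwise disjoint by construction.

Cohort structure follows the study conditions the generator emulates:

| Parameter | Default | Rationale |
|---|---|---|
| images per patient | mean 27.7, NB-dispersed | reported cohort average |
| class mix | OSSN 0.269, normal 0.562, melanoma 0.097, pterygium 0.041, keratitis 0.031 | the 2,774-image composition |
| mitosis annotations | exactly 3 cohort-wide | the sign's reported rarity |
| cells per image | mean 170 | ~35 px cells, typical of epithelial mosaics at this magnification |
| OSSN-cell fraction in OSSN images | 0.8 | lesional images are dominated by atypical cells but not unanimous |
| stray OSSN-like cells in other images | 0.1 | occasional suspicious cells outside lesions |

Counts are drawn from a rounded negative binomial with a configurable
dispersion (coefficient of extra variation; 0 gives the rounded mean
exactly). With `stratify_classes=True` patient classes follow the mix by
largest-remainder quota instead of sampling, which controlled designs use
to pin exact group sizes.

Sign regions are axis-aligned rectangles planted in OSSN images (Poisson
counts per sign per image; mitosis drawn as exactly `mitosis_total` slots
across OSSN images): starry-sky darkens the field and scatters small bright
Gaussian nuclei; hyperkeratosis overlays a large bright amorphous blob;
mitosis fills its (tight) box with two large paired nuclei on a quiet dark
background, the way a dividing cell fills a tight annotation; irregular
cells re-render the local mosaic with ~2.5× cell diameter, higher border
contrast and extra interior variance. Non-OSSN pathology images carry
fibrous/granular distractor rectangles (`non_ossn`) so the merged binary
task has a negative class. Melanoma, pterygium and keratitis backgrounds
get mild class-specific overlays (bright clusters, directional streaks,
infiltrate blobs); they only need to be mutually distinguishable, which is
all the downstream tasks require.

The per-patient texture fingerprint is a 4-vector (cell-diameter scale,
border-brightness scale, global intensity offset, anisotropy parameter)
with cohort base (1, 1, 0, 0) and per-component deviations of
(0.22, 0.30, 25 intensity units, 0.8) × `fingerprint_strength` × N(0, 1).
At strength 0 all patients are texturally identical; at the strengths used
in the experiments the deviations are large enough to be learnable but far
smaller than the class-defining textures. Anisotropy acts as a rotation–
stretch (factor 1 + 0.3·tanh(a)) of the coordinate frame used for the
Voronoi distances.

What the generator does **not** emulate: optical sectioning artifacts,
motion blur and illumination falloff, overlap between consecutive frames of
one eye, depth-dependent appearance, and the full morphological variety of
real lesions. Passing tests therefore demonstrate that the protocol —
tiling, leakage control, aggregation, few-shot and fingerprint procedures —
behaves as designed, not that the classifiers would reach comparable
accuracy on clinical images.

## Preprocessing

`crop_footer` slices the top 384 × 384 region (never resampling) and
refuses already-cropped or mis-sized inputs, so the crop cannot be applied
twice silently. Quality screening names its criteria but the underlying
scores are package choices: blur = variance of the discrete Laplacian
response, contrast = p99 − p1 robust intensity range. Default thresholds
(blur 20, contrast 40) were calibrated once on the synthetic cohort, where
clean frames score ≈ 850 / 119 and heavily smoothed frames ≈ 0.1 / 52; they
are configuration, not clinical claims. Annotations are exchanged as
CVAT-for-images 1.1 XML; `write_cvat ∘ read_cvat` is the identity on
(image id, sign class, x, y, w, h).

## Square tiling

A rectangle of sides (w, h) is cut into ⌈max(w, h) / min(w, h)⌉ square
tiles of side min(w, h). The bracket is read as a ceiling: a non-square
rectangle then always yields at least 2 tiles, and the final tile must be
anchored flush with the far edge, overlapping its predecessor when the
aspect ratio is fractional — a floor reading could satisfy neither
property (e.g. 150 × 100). Interior tiles advance at stride = side and are
not redistributed; only the last tile's placement is special. Tiles carry
their parent annotation id as `group_id`; because sibling tiles share
pixels, a split that separates them would leak validation content into
training.

Training augmentation applies, in fixed order for reproducibility:
rotation uniform in ±10° with reflection padding, a ±10% scale jitter with
probability 0.5, and a horizontal flip with probability 0.5. The rotation
bound and the two probabilities are the stated recipe; the jitter range is
a package default (declared in `AugmentConfig`).

## Leakage-controlled splitting

Splitting happens at the patient level: patients are shuffled by seed and
assigned to validation until the validation item count reaches the
requested fraction, so the achieved fraction is within one patient's worth
of items of the request. The annotation-group constraint is inherited
(groups never span patients) and then verified; `audit_leakage`
independently recomputes both disjointness invariants and lists offending
ids. The default validation fraction is 0.3 — the per-task proportions of
the original study are unstated, so this is configuration.

## Classifiers

All tasks share a small convolutional backbone implemented directly on
numpy: 3 × 3 same-padded convolutions + ReLU + 2 × 2 max-pooling blocks
(default widths 8, 16, 32), global average pooling, and a linear softmax
head — about 6 × 10³–10⁴ parameters depending on widths, trained with Adam
on weighted cross-entropy. The multi-million-parameter transfer-learning
backbones of the original study are deliberately out of scope; the
protocol, not the backbone capacity, is what this package reproduces, and
the backbone is pluggable through the width schedule. Backpropagation is
verified against finite differences (max relative error ~1e-9). Class
imbalance is countered with inverse-frequency class weights, normalized to
mean 1. Runs are bit-reproducible given the config seed. Image-level tasks
downsample the content area to 48 × 48; tile and cell tasks use 32 × 32.

The few-shot path embeds tiles with the trained CNN's penultimate
(global-average-pool) features and applies the prototypical rule: a query
takes the class of the nearest class-mean embedding under Euclidean
distance. Leave-one-out evaluation classifies each tile with all remaining
tiles as support, using running class sums so the n prototypes are updated
in O(1) per held-out item. The embedder is trained with the rare class
held out entirely: a genuinely rare sign cannot contribute meaningful
training data, which is the situation the protocol addresses.

The fingerprint experiment trains the patient-identity task (class label =
patient id) for 100 epochs. A patient-grouped split is impossible by
construction — the patient is the label — so each patient's images are
split 70/30 with no pixel shared across the boundary (synthetic frames
never overlap). The criterion follows the study's rule: the images hold
patient-specific information when the average of macro accuracy, macro
precision, macro recall and macro F1 on validation exceeds 50%. With nine
balanced patients chance is ≈ 11%, so the criterion sits well above chance.

## Cell segmentation

Cells are recovered classically: Gaussian smoothing (σ = 1.4), Otsu
thresholding of the dark interiors, binary opening, connected components,
and a distance-transform watershed to split components larger than
`max_area` (fused interiors with a broken border ridge). Area gates default
to [30, 5000] px. The segmenter sits behind a name registry so a learned
instance segmenter can replace it without touching callers. Instances are
labeled by the majority ground-truth cell under their mask; instances
covering only background are flagged unmatched for review rather than
labeled. On default synthetic mosaics the segmenter reaches ≥ 0.9 recall
and precision against truth masks (matching at Jaccard ≥ 0.5); these are
internal acceptance numbers for the synthetic texture, not claims about
any particular clinical segmenter.

## Aggregation and metrics

With o/n the OSSN-labeled and total classified cells of an image, the image
is OSSN iff o/n ≥ 0.5; with p/m the OSSN-labeled and total images of a
patient, the patient is OSSN iff p/m ≥ 0.5. Ties at exactly one half
resolve to OSSN at both levels — forced by the "at least" readings of both
rules. An image with zero classified cells has no defined label: it is
excluded from patient tallies with a logged warning rather than silently
counted for either side. All segmented cells count toward n (no
classifier-confidence floor).

Under independent per-cell error ε < 0.5 and unanimous image truth, the
image-level error is bounded by the binomial majority tail
P[Bin(n, ε) ≥ n/2]; with n = 30 cells and ε = 0.12 that tail is ~10⁻⁷,
which is the mechanism behind the near-perfect image- and patient-level F1
in the aggregation study (20 patients × 27 images × 30 cells; per-cell
error rates 0.15/0.12/0.10 emulating the three reported cell classifiers).

Macro metrics are unweighted class means of precision, recall and F1 from
the confusion matrix; zero-denominator cells contribute 0. "Macro
accuracy" is not standard, so the package reports the mean of per-class
recall (balanced accuracy) under that name and carries plain accuracy
alongside.

## Explainability

Shapley attributions use square patch players (default 8 × 8 grid) rather
than single pixels: exact pixel-level Shapley is intractable, per-pixel
values are diffuse, and patch players keep the efficiency property
checkable. The estimator samples permutations of the players, reveals
patches over a mean-intensity baseline, and credits each patch its marginal
score change; each permutation telescopes, so the efficiency identity
(contributions sum to score(image) − score(baseline)) holds to floating
point at any sample count, and sampling error affects only the per-patch
symmetrisation. Grad-CAM weighs the final convolutional response by the
gradient of the target logit — spatially constant under a global-average-
pool head, so the weights are just the head row — rectifies, upsamples and
normalizes to [0, 1]. Permutation importance shuffles each pixel group in
place and reports the mean score drop; groups must partition the grid.

Signed maps are binarized at 0 (positive contribution → 1, flattened
row-major); the original study does not state its binarization rule, so
this simplest rule consistent with binary-data metrics is a declared
choice. The Yule distance 2·c_TF·c_FT / (c_TT·c_FF + c_TF·c_FT) (range
[0, 2], with 0/0 defined as 0) and the Russell-Rao distance 1 − c_TT/n are
implemented from their agreement-count closed forms and cross-checked
against scipy; 2-D embeddings use umap-learn with its built-in
yule/russellrao/hamming/jaccard metrics (identical closed forms) and a
fixed `random_state`. Yule degenerates on near-constant vectors (the
c_TT·c_FF term vanishes), which matters when choosing binarization
thresholds: attribution maps that are almost entirely one sign embed
poorly under Yule.

## Problem sizes and tolerances

Studies are sized to run on one CPU core: the aggregation study uses
20 × 27 × 30 cells (seconds); the few-shot study ~440 tiles and three
30-epoch embedder seeds (~1 min); the fingerprint study three cohorts of
135 images at 100 epochs (~2.5 min); the end-to-end sign study ~490 tiles
at 30 epochs (~25 s). Stochastic experiments report modal values over
noise/seed replicates (aggregation, few-shot) or the minimum over seeds
(fingerprint), so single-seed flukes neither pass nor fail them.

## Known limitations

* The synthetic textures are statistical stand-ins; no claim transfers to
  clinical IVCM without retraining and revalidation.
* The small CNN saturates on the synthetic tasks but is far below the
  capacity of the original study's backbones; absolute accuracies are not
  comparable to the clinical tables.
* The watershed segmenter assumes bright-border/dark-interior mosaics; it
  will not segment nuclei-dominant or inverted-contrast layers.
* Yule-metric embeddings require reasonably balanced binary vectors (see
  above).
* Quality-screen thresholds are calibrated to the synthetic cohort and must
  be re-calibrated for any real acquisition pipeline.
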