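# Methods

This note records the models, conventions and numerical choices behind
cometkit, in enough detail to reproduce every number the toolkit prints.

## Image conventions

All analysis assumes bright comets on a dark background. Silver-stained
brightfield images (dark comets) are inverted at load time,
`v -> max_representable - v`, so a single code path serves both stains.
RGB inputs are collapsed to Rec. 601 luminance (0.299 R + 0.587 G +
0.114 B, rounded). Coordinates are 0-based `(row, col)`; masks are
boundary-inclusive. 16-bit images are quantised to 256 grey levels for
thresholding only; all feature extraction uses the raw values.

Label masks are written as 16-bit grayscale PNG — lossless, diffable, and
able to hold up to 65535 objects per image. Projects are a single sorted
JSON document plus sidecar mask PNGs, so `save -> load -> save` is
byte-identical.

## Threshold modalities

All three modalities operate on a grey-level histogram of counts; a pixel
is foreground when its grey value is strictly greater than the threshold.

* **Otsu**: exhaustive scan of every candidate threshold `t`
  (background = levels ≤ `t`), maximising the between-class variance
  `w0·w1·(μ0−μ1)²`. When several candidates tie (e.g. two isolated
  spikes produce a plateau of equal variance), the plateau midpoint is
  returned, so the threshold lands midway between well-separated modes
  rather than at the first tied level. This tie rule is deliberate and is
  exercised by the brute-force oracle tests.
* **Triangle** (Zack): a line is drawn from the histogram peak to the
  farthest nonempty bin on the longer-tail side; the threshold is the bin
  maximising perpendicular distance between `(level, count)` and that
  line. Ties on peak height resolve to the lowest level (the background
  side); equal-length sides resolve to the bright side; distance ties
  resolve to the bin nearest the peak.
* **Average**: the arithmetic mean of the two.

The default modality for ROI segmentation is **triangle**: a local ROI
histogram is a huge background spike with a sparse bright tail, exactly
the skewed regime the triangle construction was designed for (Otsu's
two-Gaussian assumption places the cut too high there, amputating faint
tails). The automatic detector defaults to **average** on the global
histogram, which is less sensitive to the comet density of the frame.

## Semi-automatic segmentation

Given an ROI (circle, polygon or box):

1. comet/background threshold from the ROI-local histogram, multiplied by
   `comet_scale` and clipped to the valid grey range;
2. foreground restricted to the connected component (8-connectivity) with
   the brightest peak; ties go to the larger component, then the smaller
   label;
3. optional dilation of the comet mask by a disc of `dilation_radius`
   (applied before the head/tail split, which keeps head ⊆ comet trivially
   true);
4. head/tail split (below); `tail = comet \ head` always, so head and tail
   partition the comet exactly.

Threshold scaling is multiplicative because it is the simplest monotone
control: raising `comet_scale` can only shrink the comet mask, raising
`dilation_radius` can only grow it — both monotonicities are tested.

### Head definition

The only commitment the assay makes is that the head is the compact,
most intense region. cometkit anchors the head at the comet's intensity
peak and combines two ingredients:

* the **inscribed disc**: all comet pixels within the peak's
  distance-to-background (euclidean distance transform, +1.5 px
  discretisation tolerance);
* the **super-threshold component**: the connected component of comet
  pixels above the head threshold (comet-pixel histogram, same modality,
  scaled by `head_scale`) that contains the peak, kept only within 1.6×
  the inscribed radius.

The inscribed disc makes a radially symmetric comet entirely head — an
undamaged (class-1) cell has *no* tail, not a thin annulus of dim Gaussian
skirt, which is what a bare threshold split would produce. The 1.6×
eccentricity cap lets a bright head extend beyond the disc but prevents
the head from swallowing a tail whose near end outshines a faint nucleus
(heavily damaged comets). The head threshold histogram uses comet pixels
only (not the whole ROI), so the background level does not bias the split.
With no orientation assumption, tail direction is emergent from the masks.

Known limitation: for class-4/5 comets whose nucleus is dimmer than the
tail start, the peak sits in the tail and the measured tail PercentDNA is
biased low by roughly 10–25 points; mid-damage comets measure within about
±10 points of truth and undamaged comets exactly 0 (all verified on
synthetic frames).

## Features

Per region (comet, head, tail): area (pixel count), mean/SD/sum of raw
intensities (population SD), and max length — the longest chord through
the intensity-weighted centroid, sampled at 1° steps, where a chord is the
projection extent (+1 px) of the pixels within half a pixel of the line.

Sphericity is `sqrt(4π·Area)/Perimeter`, clamped to [0, 1] (equals 1 for a
circle). The perimeter estimator is Moore-neighbour boundary following
with diagonal steps counted as √2; holes are ignored and a single-pixel
region gets the unit-square perimeter 4. This estimator is deterministic
and reproduces sphericity ≈ 0.95 for a rasterised disc of radius 20.

PercentDNA is `100·region_sum/comet_sum`. The tail value is reported as
`100 − head_percent_dna`, which is exact whenever head and tail partition
the comet (guaranteed by construction); computing both ratios
independently can disagree with 100 by one ulp. A comet with no tail
reports all tail features as 0 (never missing) and head PercentDNA 100,
keeping class-1 comets representable in a rectangular table.

The Olive moment multiplies the tail intensity fraction by the euclidean
distance between the head and tail centroids; centroids are
intensity-weighted by default (DNA-mass reading), with geometric centroids
available via `weighted_centroids=False`. The extent moment multiplies the
same fraction by the tail max length, so
`extent = tail_max_length · tail_percent_dna/100` holds identically.

## Synthetic data generator

The generator emulates the two dataset regimes the toolkit targets:
fluorescent frames of 1200×1600 px with 20–100 comets, and silver-stained
frames of 1280×1024 px with 2–20 comets (inverted on disk, bright after
ingestion). Per comet:

* **head**: Gaussian-profile disc, σ = head_radius/2, truncated at the
  disc edge; head_radius ~ U[8, 16] px, peak amplitude ~ U[140, 220] grey
  levels (scaled for bit depth);
* **tail**: one-sided lobe along the shared electrophoresis direction
  (uniform per image, optional per-comet jitter), exponential axial decay
  with length constant tail_length/2, Gaussian cross-section σ =
  head_radius/2, half-width head_radius; tail_length =
  head_radius·(2+10·f)·U[0.85, 1.15] for tail fraction f;
* **damage classes**: tail fraction f drawn per class from the bins
  [0, 0.05), [0.05, 0.25), [0.25, 0.5), [0.5, 0.8), [0.8, 1] — class 1
  draws exactly f = 0 (no tail at all), class 5 is capped at f = 0.97 so a
  nucleus remains visible; the class label is a deterministic function of
  f via these bins;
* **calibration**: head and tail amplitudes are solved jointly so the
  integrated tail intensity over the tail mask divided by the comet total
  equals f exactly. When the implied tail amplitude would exceed the
  dynamic range, the tail is capped and the head dimmed instead — heavily
  damaged cells genuinely have faint nuclei;
* **masks**: the head mask is the geometric disc; the tail mask is trimmed
  to the *visible* support (pixels carrying ≥ 2 grey levels of signal,
  with the calibration re-run on the trimmed mask, so f stays exact).
  Purely geometric lobe masks would include pixels indistinguishable from
  background, which no annotator would outline and no intensity-based
  method could recover;
* **scene**: comets placed by rejection sampling with disjoint bounding
  boxes, none touching the border; additive constant background (default
  12) plus Gaussian noise (default SD 4), rounded and clipped to the bit
  depth. Everything is reproducible bit-for-bit from the seed.

What the generator does **not** model: overlapping or touching comets,
uneven illumination, Poisson (signal-dependent) noise, out-of-focus blur,
staining artefacts. Passing tests therefore demonstrate correctness of
the algorithms under clean, known-truth conditions — not performance on
real slides, where comet density and background structure are harsher.
The default per-image count ranges reflect the target regimes; at the very
top of the fluorescent range (approaching 100 comets per frame) the
no-overlap constraint may be unsatisfiable and the generator raises a
placement error rather than silently overlapping comets.

## Classification

The four families use conventional defaults — CART with Gini impurity,
k-NN with k = 5 (euclidean on z-scored features), Gaussian naive Bayes,
RBF SVM with one-vs-one multiclass — all overridable via `hyperparams`.
Features are z-scored with training-set statistics stored inside the
model; class labels are opaque positive integers, so any number of
(sub)classes works. Feature selection is an explicit include-list
(`feature_names`), never automatic. Training is deterministic given the
seed. Regression-style damage scoring is out of scope.

## Multi-object Jaccard evaluation

For each ground-truth object, the candidate is the predicted object
covering the largest share of its pixels (ties to the lower predicted ID).
Coverage below 50% scores 0; otherwise the pair's Jaccard index
`|A∩B|/|A∪B|` is computed with exact integer counts. The mean over
ground-truth objects is the reported score. Choices left open by the
procedure are configurable: the coverage denominator is the GT object's
area by default (`overlap_denominator="union"` available), and matching is
per-GT greedy — one predicted object may serve several GT objects — with
an optional Hungarian one-to-one mode. Two empty masks have pairwise JI 0
by convention; an empty ground truth is an error (the mean is undefined).

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` run entirely on generated
data: 2 full-size noiseless frames of 20–30 comets for the segmentation
quality bar (semi-automatic ROIs derived from the truth masks, as a user
would draw them), 1000 isolated comets (200 per class) for 5-fold
cross-validated class recovery, 50 randomised two-component histograms
for the threshold oracles, and small constructed scenes for the Jaccard
gate and round-trip checks. These sizes make the full suite run in well
under a minute while keeping every estimate stable across seeds.
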