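# cometkit

Scriptable quantification of **comet assays** (single-cell gel
electrophoresis). After electrophoresis, each cell's DNA forms a "comet": a
bright, near-spherical **head** of intact nuclear DNA and a one-sided
**tail** of fragmented DNA that migrates farther the more damaged it is.
Scoring an experiment means segmenting every comet in a micrograph,
splitting it into head and tail, measuring intensity/shape features, and
assigning each comet a damage class.

cometkit does all of this as a library plus a small CLI, for both
fluorescent micrographs (bright comets, dark background) and silver-stained
brightfield micrographs (dark comets, bright background — inverted on load
so one code path serves both). It ships a synthetic comet-image generator
with exact ground truth, so the whole pipeline is testable without any
external data.

## What it computes

**Segmentation.** Inside a user- or detector-supplied ROI, the
comet/background threshold is taken from the ROI's grey-level histogram by
one of three modalities — Otsu's between-class-variance criterion, Zack's
triangle method, or their arithmetic mean — with multiplicative threshold
scaling and optional mask dilation as manual controls. The head/tail split
thresholds the comet's own pixel histogram and anchors the head at the
comet's intensity peak; no left-to-right orientation is assumed anywhere.
A freehand-contour path and a pluggable automatic detector (global
threshold + connected components by default) are also provided.

**Features.** The 21 standard per-comet measurements: area, max length
(longest chord through the centroid), mean/SD/sum intensity for comet, head
and tail; sphericity `sqrt(4*pi*Area)/Perimeter` for comet and head;
`PercentDNA = 100 * region_sum / comet_sum` for head and tail; and the two
tail moments

```
Extent moment = TailMaxLength * TailSum / CometSum
Olive  moment = |HeadCentroid - TailCentroid| * TailSum / CometSum
```

User-defined features can be registered at run time and appear as extra CSV
columns.

**Classification.** Damage classes (conventionally 1 = undamaged … 5 = all
DNA in the tail; any positive integers accepted) predicted by a decision
tree, k-NN, Gaussian naive Bayes or an RBF SVM on z-scored features.

**Evaluation.** Instance masks are scored against ground truth with a
multi-object Jaccard index: each ground-truth object is paired with the
predicted object of maximum overlap, scores 0 if covered below 50%, else
`|A∩B|/|A∪B|`; the mean over ground-truth objects is reported.

## Worked example

```python
import numpy as np
import cometkit as ck

# one noisy fluorescent frame with known ground truth
truth = ck.generate_dataset(n_images=1, comets_per_image=(15, 25), seed=7)[0]

rois = ck.detect_comets(truth.image)              # automatic proposals
seg  = ck.segment_roi(truth.image, rois[0], ck.ThresholdSettings())
rec  = ck.comet_features(truth.image, seg, image_name="demo.tif")
for k in ("comet_area", "comet_sphericity", "head_percent_dna",
          "tail_percent_dna", "tail_extent_moment", "tail_olive_moment"):
    print(f"{k:22s} {rec.values[k]:.4g}")

pred = np.zeros(truth.image.pixels.shape, np.int32)
for cid, roi in enumerate(rois, 1):
    s = ck.segment_roi(truth.image, roi, comet_id=cid)
    pred[s.comet_mask & (pred == 0)] = cid
print(f"mean JI vs truth: {ck.multi_object_ji(truth.comet_mask, pred).mean_ji:.4f}")
```

prints

```
comet_area             3413
comet_sphericity       0.4979
head_percent_dna       30.28
tail_percent_dna       69.72
tail_extent_moment     109.1
tail_olive_moment      32.85
mean JI vs truth: 0.5951
```

The first comet covers 3413 px with 69.7% of its integrated intensity in
the tail (a heavily damaged, class-4 comet: extent moment 109 px,
Olive moment 32.9); its low sphericity (0.50) reflects the elongated tail.
The fully automatic end-to-end score of 0.60 on a noisy frame is in the
range published comet tools reach on real micrographs; ROIs drawn around
each comet (the semi-automatic mode) raise it to ≥ 0.95 on noiseless
frames.

The same workflow from a shell:

```
cometkit simulate --n-images 2 --comets 10:20 --seed 7 --out data/
cometkit segment  --image data/synthetic_000.tif --out masks/
cometkit measure  --image data/synthetic_000.tif \
    --comet-mask masks/synthetic_000_comet_mask.png \
    --head-mask  masks/synthetic_000_head_mask.png  --out features.csv
cometkit evaluate --gt data/synthetic_000_comet_mask.png \
    --pred masks/synthetic_000_comet_mask.png --out report.csv
```

## Layout

| module | contents |
| --- | --- |
| `cometkit.io_formats` | images, 16-bit label-mask PNGs, measurement CSVs, project files |
| `cometkit.synthetic` | comet renderer and dataset generator with exact ground truth |
| `cometkit.segmentation` | threshold modalities, ROI/contour segmentation, detector |
| `cometkit.features` | the 21 measurements + user-feature registry |
| `cometkit.classify` | the four classifier families, class statistics |
| `cometkit.evaluation` | pairwise and multi-object Jaccard scoring |
| `cometkit.pipeline` / `cometkit.cli` | batch runs, config, subcommands |

See `docs/methods.md` for the models, conventions and numerical choices.
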