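"""Comet and head/tail segmentation.

Three histogram-threshold modalities drive the semi-automatic path, exactly
as a scorer would use them: draw an ROI around one comet, threshold the
ROI-local grey-level histogram to separate comet from background, then
threshold the comet's own pixels to separate the bright head from the tail.
A manual path rasterises a freehand contour, and an automatic front-end
proposes circle ROIs from a global threshold so unattended batch runs are
possible.

Conventions: 0-based (row, col) coordinates; a pixel is foreground when its
(256-level) grey value is strictly greater than the threshold; 16-bit
images are quantised to 256 levels for thresholding only (feature
extraction elsewhere uses the raw values).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage.draw import polygon as draw_polygon
from skimage.morphology import disk

from .errors import (DegenerateHistogramError, EmptySegmentationError,
                     GeometryError)
from .io_formats import IntensityImage

__all__ = [
    "Roi",
    "ThresholdSettings",
    "DetectorSettings",
    "CometSegmentation",
    "otsu_threshold",
    "triangle_threshold",
    "combined_threshold",
    "threshold_function",
    "segment_roi",
    "rasterize_contour",
    "detect_comets",
]


# ---------------------------------------------------------------------------
# Threshold modalities (operate on grey-level histograms of counts)
# ---------------------------------------------------------------------------

def otsu_threshold(histogram: Sequence[int]) -> float:
    """Otsu's threshold on a grey-level histogram.

    Scans every candidate threshold ``t`` (background = levels <= t) and
    returns the one maximising the between-class variance
    ``w0 * w1 * (mu0 - mu1)**2``. When a plateau of candidates ties at the
    maximum the plateau midpoint is returned, so a histogram with two
    isolated spikes thresholds midway between them.
    """
    h = np.asarray(histogram, dtype=np.float64)
    if h.ndim != 1 or h.size < 2:
        raise DegenerateHistogramError("histogram must be 1-D with >= 2 bins")
    if np.count_nonzero(h) < 2:
        raise DegenerateHistogramError("histogram needs >= 2 nonempty bins")
    levels = np.arange(h.size, dtype=np.float64)
    w0 = np.cumsum(h)[:-1]
    w1 = h.sum() - w0
    m0 = np.cumsum(h * levels)[:-1]
    m1 = (h * levels).sum() - m0
    valid = (w0 > 0) & (w1 > 0)
    var_b = np.zeros(h.size - 1)
    var_b[valid] = (w0 * w1)[valid] * (m0[valid] / w0[valid]
                                       - m1[valid] / w1[valid]) ** 2
    best = var_b.max()
    ties = np.flatnonzero(var_b >= best * (1 - 1e-12))
    return float(np.floor(ties.mean()))


def triangle_threshold(histogram: Sequence[int]) -> float:
    """Zack's triangle threshold on a grey-level histogram.

    A line is drawn from the histogram peak to the farthest nonempty bin on
    the longer-tail side; the threshold is the bin between them whose point
    ``(level, count)`` lies at maximum perpendicular distance from that
    line. Ties on peak height are broken toward the lower (background) side;
    ties on the side lengths go to the bright side; ties on distance go to
    the bin nearest the peak.
    """
    h = np.asarray(histogram, dtype=np.float64)
    if h.ndim != 1 or h.size < 2:
        raise DegenerateHistogramError("histogram must be 1-D with >= 2 bins")
    nonempty = np.flatnonzero(h)
    if nonempty.size < 2:
        raise DegenerateHistogramError("histogram needs >= 2 nonempty bins")
    peak = int(np.argmax(h))  # argmax returns the first (lowest) on ties
    lo, hi = int(nonempty[0]), int(nonempty[-1])
    if hi - peak >= peak - lo:
        end = hi
    else:
        end = lo
    if end == peak:
        raise DegenerateHistogramError("histogram peak coincides with its tail end")
    # perpendicular distance of each (t, h[t]) from the peak->end line
    span = np.arange(min(peak, end), max(peak, end) + 1)
    dx, dy = end - peak, h[end] - h[peak]
    norm = np.hypot(dx, dy)
    dist = np.abs(dy * (span - peak) - dx * (h[span] - h[peak])) / norm
    inner = (span != peak) & (span != end)
    if not inner.any():
        return float(min(peak, end))
    dist[~inner] = -1.0
    best = dist.max()
    ties = span[dist >= best * (1 - 1e-12)]
    t = ties[np.argmin(np.abs(ties - peak))]
    return float(t)


def combined_threshold(histogram: Sequence[int]) -> float:
    """Arithmetic mean of the Otsu and triangle thresholds."""
    return 0.5 * (otsu_threshold(histogram) + triangle_threshold(histogram))


_MODALITIES: dict[str, Callable[[Sequence[int]], float]] = {
    "otsu": otsu_threshold,
    "triangle": triangle_threshold,
    "average": combined_threshold,
}


def threshold_function(modality: str) -> Callable[[Sequence[int]], float]:
    try:
        return _MODALITIES[modality]
    except KeyError:
        raise ValueError(f"unknown threshold modality {modality!r}; "
                         f"choose from {sorted(_MODALITIES)}") from None


# ---------------------------------------------------------------------------
# ROIs and settings
# ---------------------------------------------------------------------------

@dataclass
class Roi:
    """A user- or detector-supplied region of interest around one comet.

    ``kind`` is one of ``circle`` (center + radius), ``polygon`` (vertex
    list) or ``box`` (two corners); all coordinates are 0-based (row, col).
    """

    kind: str
    center: tuple[float, float] | None = None
    radius: float | None = None
    vertices: np.ndarray | None = None
    corners: tuple[tuple[float, float], tuple[float, float]] | None = None

    def to_mask(self, shape: tuple[int, int]) -> np.ndarray:
        if self.kind == "circle":
            rr = np.arange(shape[0])[:, None] - self.center[0]
            cc = np.arange(shape[1])[None, :] - self.center[1]
            mask = rr ** 2 + cc ** 2 <= self.radius ** 2
        elif self.kind == "polygon":
            v = np.asarray(self.vertices, dtype=float)
            if v.ndim != 2 or v.shape[0] < 3:
                raise GeometryError("polygon ROI needs >= 3 vertices")
            rr, cc = draw_polygon(v[:, 0], v[:, 1], shape=shape)
            mask = np.zeros(shape, dtype=bool)
            mask[rr, cc] = True
        elif self.kind == "box":
            (r0, c0), (r1, c1) = self.corners
            r0, r1 = sorted((int(np.floor(r0)), int(np.ceil(r1))))
            c0, c1 = sorted((int(np.floor(c0)), int(np.ceil(c1))))
            mask = np.zeros(shape, dtype=bool)
            mask[max(r0, 0):r1 + 1, max(c0, 0):c1 + 1] = True
        else:
            raise GeometryError(f"unknown ROI kind {self.kind!r}")
        if not mask.any():
            raise GeometryError(f"ROI lies entirely outside the {shape} image")
        return mask


@dataclass
class ThresholdSettings:
    """Semi-automatic segmentation controls.

    ``comet_scale`` and ``head_scale`` multiply the comet/background and
    head/tail thresholds (clipped to the valid grey range); ``dilation_radius``
    grows the comet mask with a disc element before the head/tail split.
    The triangle modality is the default: ROI histograms are dominated by a
    background spike with a sparse bright tail, the regime the triangle
    method was designed for.
    """

    modality: str = "triangle"
    comet_scale: float = 1.0
    head_scale: float = 1.0
    dilation_radius: int = 0

    def __post_init__(self) -> None:
        if self.comet_scale <= 0 or self.head_scale <= 0:
            raise ValueError("threshold scales must be > 0")
        if self.dilation_radius < 0:
            raise ValueError("dilation_radius must be >= 0")
        threshold_function(self.modality)


@dataclass
class CometSegmentation:
    """Binary comet/head/tail masks for one comet, in image coordinates."""

    comet_mask: np.ndarray
    head_mask: np.ndarray
    tail_mask: np.ndarray
    roi: Roi | None = None
    settings: ThresholdSettings | None = None
    comet_id: int = 0

    def validate(self) -> None:
        """Check the head/tail partition identities."""
        if (self.head_mask & ~self.comet_mask).any():
            raise ValueError("head_mask is not a subset of comet_mask")
        if (self.head_mask & self.tail_mask).any():
            raise ValueError("head and tail masks overlap")
        if ((self.head_mask | self.tail_mask) != self.comet_mask).any():
            raise ValueError("head and tail do not partition the comet")


# ---------------------------------------------------------------------------
# Segmentation operations
# ---------------------------------------------------------------------------

def _quantized(image: IntensityImage) -> np.ndarray:
    """Grey values on 256 levels (thresholding scale)."""
    if image.bit_depth == 8:
        return image.pixels
    return (image.pixels >> 8).astype(np.uint8)


def _select_component(fg: np.ndarray, raw: np.ndarray) -> np.ndarray:
    """Keep the connected component with the brightest peak.

    Ties go to the larger component, then to the smaller label.
    """
    lbl, n = ndi.label(fg, structure=np.ones((3, 3), dtype=int))
    if n == 1:
        return lbl == 1
    peaks = ndi.labeled_comprehension(raw, lbl, np.arange(1, n + 1),
                                      np.max, float, -np.inf)
    areas = np.bincount(lbl.ravel())[1:]
    order = np.lexsort((np.arange(n), -areas, -peaks))
    return lbl == order[0] + 1


def _split_head(image: IntensityImage, comet_mask: np.ndarray,
                settings: ThresholdSettings) -> np.ndarray:
    """Separate the head from the tail inside a comet mask.

    The head threshold comes from the comet-pixel histogram (same modality,
    scaled by ``head_scale``). The head combines two ingredients around the
    comet's intensity peak:

    * the disc inscribed in the comet at the peak — so a radially symmetric
      comet (no tail) is entirely head, and the nearly circular nucleus is
      always covered;
    * the super-threshold connected component containing the peak, kept only
      within 1.6x the inscribed radius — the head may extend beyond the
      inscribed disc where it stays bright, but cannot swallow a tail whose
      near end outshines a faint nucleus (heavily damaged comets).
    """
    # crop to the comet's bounding box (pad 1 so the EDT sees background)
    obj = ndi.find_objects(comet_mask.astype(np.int8))[0]
    sl = tuple(slice(max(s.start - 1, 0), min(s.stop + 1, dim))
               for s, dim in zip(obj, comet_mask.shape))
    comet = comet_mask[sl]
    q = _quantized(image)[sl]
    raw = image.pixels[sl]
    comet_vals = q[comet]
    qmax = int(comet_vals.max())
    head_out = np.zeros_like(comet_mask)
    try:
        thr = threshold_function(settings.modality)(
            np.bincount(comet_vals, minlength=256)) * settings.head_scale
    except DegenerateHistogramError:
        head_out[sl] = comet  # uniform comet: all head, no tail
        return head_out
    thr = min(float(np.clip(thr, 0, 255)), qmax - 1)  # peak stays foreground

    super_mask = (q > thr) & comet
    flat_peak = np.flatnonzero(comet.ravel())[np.argmax(raw[comet])]
    peak = np.unravel_index(flat_peak, raw.shape)
    lbl, _ = ndi.label(super_mask, structure=np.ones((3, 3), dtype=int))
    head = lbl == lbl[peak]

    # inscribed disc around the peak, eccentricity-capped threshold component
    inscribed = ndi.distance_transform_edt(comet)[peak] + 1.5
    rr = np.arange(raw.shape[0])[:, None] - peak[0]
    cc = np.arange(raw.shape[1])[None, :] - peak[1]
    r2 = rr ** 2 + cc ** 2
    head = comet & ((r2 <= inscribed ** 2)
                    | (head & (r2 <= (1.6 * inscribed) ** 2)))
    # keep the piece containing the peak (the cap can strand far fragments)
    lbl2, n2 = ndi.label(head, structure=np.ones((3, 3), dtype=int))
    if n2 > 1:
        head = lbl2 == lbl2[peak]
    head_out[sl] = head
    return head_out


def segment_roi(image: IntensityImage, roi: Roi,
                settings: ThresholdSettings | None = None,
                comet_id: int = 0) -> CometSegmentation:
    """Segment one comet inside an ROI with the semi-automatic procedure.

    The comet/background threshold is computed on the ROI-local histogram
    and scaled by ``comet_scale``; the foreground is restricted to the
    connected component with the brightest peak; the comet mask is dilated
    by ``dilation_radius`` before the head/tail split.
    """
    settings = settings or ThresholdSettings()
    roi_mask = roi.to_mask(image.pixels.shape)
    q = _quantized(image)
    hist = np.bincount(q[roi_mask], minlength=256)
    thr = threshold_function(settings.modality)(hist) * settings.comet_scale
    thr = float(np.clip(thr, 0, 255))
    fg = (q > thr) & roi_mask
    if not fg.any():
        raise EmptySegmentationError(
            f"no pixels above threshold {thr:.1f} inside the ROI")
    comet = _select_component(fg, image.pixels)
    if settings.dilation_radius > 0:
        comet = ndi.binary_dilation(comet, structure=disk(settings.dilation_radius))
    head = _split_head(image, comet, settings)
    return CometSegmentation(comet_mask=comet, head_mask=head,
                             tail_mask=comet & ~head, roi=roi,
                             settings=settings, comet_id=comet_id)


def rasterize_contour(vertices: np.ndarray, image: IntensityImage,
                      settings: ThresholdSettings | None = None,
                      comet_id: int = 0) -> CometSegmentation:
    """Segment a comet from a freehand contour drawn by the user.

    The comet mask is the filled (boundary-inclusive) polygon interior; the
    head/tail split then follows the same intensity logic as the
    semi-automatic path. A polygon containing no foreground (no pixel above
    the image's global threshold) is rejected.
    """
    settings = settings or ThresholdSettings()
    v = np.asarray(vertices, dtype=float)
    if v.ndim != 2 or v.shape[0] < 3 or v.shape[1] != 2:
        raise GeometryError("contour must be an (n >= 3, 2) vertex array")
    from shapely.geometry import Polygon
    if not Polygon(v).is_simple:
        raise GeometryError("contour polygon is self-intersecting")
    rr, cc = draw_polygon(v[:, 0], v[:, 1], shape=image.pixels.shape)
    comet = np.zeros(image.pixels.shape, dtype=bool)
    comet[rr, cc] = True
    if not comet.any():
        raise GeometryError("contour lies entirely outside the image")

    q = _quantized(image)
    try:
        global_thr = combined_threshold(np.bincount(q.ravel(), minlength=256))
    except DegenerateHistogramError as exc:
        raise EmptySegmentationError(
            "image has no contrast; contour contains no foreground") from exc
    if not (q[comet] > global_thr).any():
        raise EmptySegmentationError(
            "contour contains no pixel above the global foreground threshold")
    head = _split_head(image, comet, settings)
    return CometSegmentation(comet_mask=comet, head_mask=head,
                             tail_mask=comet & ~head, roi=Roi("polygon", vertices=v),
                             settings=settings, comet_id=comet_id)


# ---------------------------------------------------------------------------
# Automatic detection front-end
# ---------------------------------------------------------------------------

@dataclass
class DetectorSettings:
    """Controls for the classical shape-based comet detector.

    ``detector`` makes the front-end pluggable: any callable
    ``(image, settings) -> list[Roi]`` (e.g. a learned model's wrapper) can
    replace the default global-threshold + connected-components proposal.
    """

    modality: str = "average"
    min_area: int = 150
    max_area: int | None = None
    exclude_border: bool = True
    margin: float = 5.0
    detector: Callable[..., list] | None = None


def detect_comets(image: IntensityImage,
                  settings: DetectorSettings | None = None) -> list[Roi]:
    """Propose one circle ROI per comet-like object in the image.

    Default detector: global threshold (``average`` modality) -> connected
    components -> filter by area range and border contact -> circle ROI per
    surviving component, padded by ``margin``. May return an empty list.
    """
    settings = settings or DetectorSettings()
    if settings.detector is not None:
        return settings.detector(image, settings)
    q = _quantized(image)
    try:
        thr = threshold_function(settings.modality)(
            np.bincount(q.ravel(), minlength=256))
    except DegenerateHistogramError:
        return []
    fg = q > thr
    lbl, n = ndi.label(fg, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return []
    rois: list[Roi] = []
    h, w = q.shape
    border_ids = np.unique(np.concatenate([
        lbl[0], lbl[-1], lbl[:, 0], lbl[:, -1]]))
    areas = np.bincount(lbl.ravel())
    for obj_id, sl in enumerate(ndi.find_objects(lbl), start=1):
        if sl is None:
            continue
        area = areas[obj_id]
        if area < settings.min_area:
            continue
        if settings.max_area is not None and area > settings.max_area:
            continue
        if settings.exclude_border and obj_id in border_ids:
            continue
        rr, cc = np.nonzero(lbl[sl] == obj_id)
        rr = rr + sl[0].start
        cc = cc + sl[1].start
        center = (rr.mean(), cc.mean())
        radius = float(np.hypot(rr - center[0], cc - center[1]).max()
                       + settings.margin)
        rois.append(Roi("circle", center=center, radius=radius))
    return rois
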