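"""Intensity and morphological features of segmented comets.

For every comet the toolkit reports 21 features, computed separately on the
whole comet, its head and its tail where each applies:

==============  =========================  ==================================
region          features                   notes
==============  =========================  ==================================
whole comet     area, max length, mean/    max length = longest chord through
                std/sum intensity,         the centroid; sphericity in [0, 1]
                sphericity
head            the same six plus          PercentDNA = 100 * head sum /
                PercentDNA                 comet sum
tail            area, max length, mean/    Extent moment = tail max length *
                std/sum intensity,         tail DNA fraction; Olive moment =
                PercentDNA, extent         head-tail centroid distance *
                moment, Olive moment       tail DNA fraction
==============  =========================  ==================================

A comet with no tail keeps all tail features at 0 (never missing), with
head PercentDNA = 100, so class-1 (undamaged) comets stay representable in
a rectangular table. Centroids entering the Olive moment are
intensity-weighted by default (DNA-mass interpretation); geometric
centroids are available via ``weighted_centroids=False``.

User-defined features can be registered at run time and appear as extra
columns in every subsequent export.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .errors import SchemaError
from .segmentation import CometSegmentation

__all__ = [
    "FeatureRecord",
    "FEATURE_NAMES",
    "METADATA_COLUMNS",
    "measurement_columns",
    "region_basic_features",
    "max_chord_length",
    "chain_perimeter",
    "sphericity",
    "comet_features",
    "register_feature",
    "unregister_feature",
    "registered_features",
]

METADATA_COLUMNS = ["comet_id", "image", "class"]

#: The 21 per-comet feature columns, in the fixed export order
#: (whole comet, then head, then tail).
FEATURE_NAMES = [
    "comet_area", "comet_max_length", "comet_mean_intensity",
    "comet_std_intensity", "comet_sum_intensity", "comet_sphericity",
    "head_area", "head_max_length", "head_mean_intensity",
    "head_std_intensity", "head_sum_intensity", "head_sphericity",
    "head_percent_dna",
    "tail_area", "tail_max_length", "tail_mean_intensity",
    "tail_std_intensity", "tail_sum_intensity", "tail_percent_dna",
    "tail_extent_moment", "tail_olive_moment",
]

_EXTRA_FEATURES: dict[str, Callable] = {}


def register_feature(name: str, function: Callable) -> None:
    """Register a user-defined feature ``function(pixels, masks) -> float``.

    ``masks`` is a dict with ``comet``, ``head`` and ``tail`` boolean
    arrays. The feature appears as an extra column in subsequent
    extractions; a non-finite return value is recorded as missing with a
    warning.
    """
    if name in _EXTRA_FEATURES or name in FEATURE_NAMES:
        raise SchemaError(f"feature {name!r} is already registered")
    _EXTRA_FEATURES[name] = function


def unregister_feature(name: str) -> None:
    _EXTRA_FEATURES.pop(name, None)


def registered_features() -> list[str]:
    return list(_EXTRA_FEATURES)


def measurement_columns() -> list[str]:
    """Full export column order: metadata, the 21 features, extras."""
    return METADATA_COLUMNS + FEATURE_NAMES + registered_features()


@dataclass
class FeatureRecord:
    """The named feature values for one comet."""

    comet_id: int
    image: str = ""
    class_label: int | None = None
    values: dict[str, float] = field(default_factory=dict)
    extras: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        row = {"comet_id": self.comet_id, "image": self.image,
               "class": self.class_label}
        row.update({k: self.values[k] for k in FEATURE_NAMES})
        row.update(self.extras)
        return row


# ---------------------------------------------------------------------------
# Geometry primitives
# ---------------------------------------------------------------------------

def _centroid(pixels: np.ndarray, mask: np.ndarray,
              weighted: bool) -> tuple[float, float]:
    rr, cc = np.nonzero(mask)
    if weighted:
        w = pixels[rr, cc].astype(np.float64)
        if w.sum() > 0:
            return float((rr * w).sum() / w.sum()), float((cc * w).sum() / w.sum())
    return float(rr.mean()), float(cc.mean())


def max_chord_length(mask: np.ndarray,
                     centroid: tuple[float, float] | None = None,
                     angle_step_deg: float = 1.0) -> float:
    """Longest chord through the centroid, sampled at 1-degree steps.

    For each direction, the chord is the extent (max - min projection + 1)
    of the mask pixels lying within half a pixel of the line through the
    centroid. This realises "maximum diameter passing through the centroid"
    on a discrete mask without assuming any comet orientation.
    """
    rr, cc = np.nonzero(mask)
    if rr.size == 0:
        return 0.0
    if rr.size == 1:
        return 1.0
    if centroid is None:
        centroid = (rr.mean(), cc.mean())
    rel = np.stack([rr - centroid[0], cc - centroid[1]], axis=1)
    angles = np.deg2rad(np.arange(0.0, 180.0, angle_step_deg))
    dirs = np.stack([np.cos(angles), np.sin(angles)], axis=1)      # (A, 2)
    proj = rel @ dirs.T                                            # (N, A)
    perp = rel @ np.stack([-dirs[:, 1], dirs[:, 0]], axis=1).T
    on_line = np.abs(perp) <= 0.5
    lo = np.where(on_line, proj, np.inf).min(axis=0)
    hi = np.where(on_line, proj, -np.inf).max(axis=0)
    chords = hi - lo + 1.0
    chords[~np.isfinite(chords)] = 0.0
    return float(chords.max())


# Moore-neighbour clockwise offsets, starting east.
_MOORE = [(0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1), (-1, 0), (-1, 1)]
_STEP_LEN = {off: math.hypot(*off) for off in _MOORE}


def chain_perimeter(mask: np.ndarray) -> float:
    """Outer-boundary perimeter by Moore-neighbour boundary following.

    The boundary chain is traced clockwise from the topmost-leftmost pixel
    and its polygon length summed, with diagonal steps counted as sqrt(2).
    Holes are ignored (comet masks are hole-free by construction). A
    single-pixel region is assigned the unit-square perimeter 4.
    """
    mask = np.asarray(mask, dtype=bool)
    rr, cc = np.nonzero(mask)
    if rr.size == 0:
        raise ValueError("cannot compute the perimeter of an empty mask")
    if rr.size == 1:
        return 4.0
    padded = np.pad(mask, 1)
    start = (rr[0] + 1, cc[np.flatnonzero(rr == rr[0])[0]] + 1)
    # enter from the west, scan clockwise
    chain_len = 0.0
    current = start
    prev_dir = 4  # index of (0, -1): the backtrack points west of start
    first_move = None
    max_steps = 4 * padded.size
    for _ in range(max_steps):
        found = False
        for k in range(1, 9):
            d = (prev_dir + k) % 8
            off = _MOORE[d]
            nxt = (current[0] + off[0], current[1] + off[1])
            if padded[nxt]:
                chain_len += _STEP_LEN[off]
                if first_move is None:
                    first_move = d
                elif current == start and d == first_move:
                    # closed the loop and repeating: subtract the re-entry
                    return chain_len - _STEP_LEN[off]
                current = nxt
                prev_dir = (d + 5) % 8  # backtrack: neighbour before the move
                found = True
                break
        if not found:  # isolated pixel after pruning (cannot happen here)
            return 4.0
        if current == start and first_move is not None and _ > 0:
            return chain_len
    return chain_len


def sphericity(area: float, perimeter: float) -> float:
    """Perimeter of the equal-area circle over the object's perimeter.

    ``sqrt(4 * pi * area) / perimeter``, clamped to [0, 1] against
    rasterisation overshoot; equals 1 for a circle.
    """
    if perimeter <= 0:
        raise ValueError("sphericity requires a positive perimeter")
    return float(np.clip(math.sqrt(4.0 * math.pi * area) / perimeter, 0.0, 1.0))


# ---------------------------------------------------------------------------
# Feature extraction
# ---------------------------------------------------------------------------

def region_basic_features(pixels: np.ndarray, mask: np.ndarray,
                          weighted_centroid: bool = True):
    """(area, max_length, mean, std, sum) of one region.

    Intensity statistics use the raw grey values under the mask (std is the
    population SD); max length is the longest chord through the
    (intensity-weighted) centroid.
    """
    pixels = np.asarray(pixels)
    mask = np.asarray(mask, dtype=bool)
    if pixels.shape != mask.shape:
        raise ValueError(f"image {pixels.shape} and mask {mask.shape} shapes differ")
    vals = pixels[mask].astype(np.float64)
    if vals.size == 0:
        return 0.0, 0.0, 0.0, 0.0, 0.0
    centroid = _centroid(pixels, mask, weighted_centroid)
    return (float(vals.size),
            max_chord_length(mask, centroid),
            float(vals.mean()),
            float(vals.std()),
            float(vals.sum()))


def comet_features(image, seg: CometSegmentation,
                   image_name: str = "", class_label: int | None = None,
                   weighted_centroids: bool = True) -> FeatureRecord:
    """Compute the 21 features (plus registered extras) for one comet.

    ``image`` may be an :class:`~cometkit.io_formats.IntensityImage` or a
    bare 2-D array. Head and tail PercentDNA close to 100 exactly: the tail
    value is reported as the complement of the head value, which is valid
    whenever head and tail partition the comet (enforced by construction).
    """
    pixels = getattr(image, "pixels", np.asarray(image))
    comet_m, head_m, tail_m = seg.comet_mask, seg.head_mask, seg.tail_mask
    if not comet_m.any():
        raise ValueError("comet mask is empty")

    c_area, c_len, c_mean, c_std, c_sum = region_basic_features(
        pixels, comet_m, weighted_centroids)
    h_area, h_len, h_mean, h_std, h_sum = region_basic_features(
        pixels, head_m, weighted_centroids)
    t_area, t_len, t_mean, t_std, t_sum = region_basic_features(
        pixels, tail_m, weighted_centroids)
    if c_sum <= 0:
        raise ValueError(
            f"comet {seg.comet_id} has zero integrated intensity; "
            "PercentDNA is undefined")

    head_pd = 100.0 * h_sum / c_sum
    if t_area == 0:
        head_pd, tail_pd = 100.0, 0.0
        extent = olive = 0.0
    else:
        tail_pd = 100.0 - head_pd  # exact closure under the mask partition
        tail_ratio = t_sum / c_sum
        extent = t_len * tail_ratio
        hc = _centroid(pixels, head_m, weighted_centroids)
        tc = _centroid(pixels, tail_m, weighted_centroids)
        olive = math.hypot(hc[0] - tc[0], hc[1] - tc[1]) * tail_ratio

    values = {
        "comet_area": c_area, "comet_max_length": c_len,
        "comet_mean_intensity": c_mean, "comet_std_intensity": c_std,
        "comet_sum_intensity": c_sum,
        "comet_sphericity": sphericity(c_area, chain_perimeter(comet_m)),
        "head_area": h_area, "head_max_length": h_len,
        "head_mean_intensity": h_mean, "head_std_intensity": h_std,
        "head_sum_intensity": h_sum,
        "head_sphericity": sphericity(h_area, chain_perimeter(head_m))
        if h_area > 0 else 0.0,
        "head_percent_dna": head_pd,
        "tail_area": t_area, "tail_max_length": t_len,
        "tail_mean_intensity": t_mean, "tail_std_intensity": t_std,
        "tail_sum_intensity": t_sum, "tail_percent_dna": tail_pd,
        "tail_extent_moment": extent, "tail_olive_moment": olive,
    }

    extras = {}
    masks = {"comet": comet_m, "head": head_m, "tail": tail_m}
    for name, fn in _EXTRA_FEATURES.items():
        try:
            v = float(fn(pixels, masks))
        except Exception as exc:  # noqa: BLE001 - user code; record and go on
            warnings.warn(f"registered feature {name!r} failed: {exc}",
                          stacklevel=2)
            v = float("nan")
        if not math.isfinite(v):
            warnings.warn(f"registered feature {name!r} returned a "
                          "non-finite value; recorded as missing", stacklevel=2)
            v = float("nan")
        extras[name] = v

    return FeatureRecord(comet_id=seg.comet_id, image=image_name,
                         class_label=class_label, values=values,
                         extras=extras)
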