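"""Synthetic comet-assay micrographs with exact ground truth.

The generator emulates what a scorer sees after single-cell gel
electrophoresis: each cell appears as a bright near-spherical *head*
(undamaged, compact DNA) plus a one-sided *tail* of migrated DNA fragments
whose extent and integrated-intensity fraction grow with DNA damage. Every
image comes with instance label masks (comet and head), per-comet parameters
and damage-class labels, so segmentation, feature extraction, classification
and evaluation can all be tested against known truth.

Photometric model (per comet, before background and noise):

* head: isotropic Gaussian-profile disc, ``B * exp(-r^2 / (2 sigma_h^2))``
  truncated at ``r = head_radius`` with ``sigma_h = head_radius / 2``;
* tail: one-sided lobe along the electrophoresis direction with exponential
  axial decay (length constant ``tail_length / 2``) and Gaussian
  cross-section (``sigma_c = head_radius / 2``, half-width ``head_radius``).

The head and tail amplitudes are calibrated jointly and exactly so that the
integrated tail intensity divided by the total comet intensity equals the
requested ``tail_fraction``; when the tail amplitude would exceed the
dynamic range the head is dimmed instead, mirroring the faint nuclei of
heavily damaged cells.

Ground-truth masks mimic expert annotation: the head mask is the geometric
disc, while the tail mask is trimmed to the *visible* support — pixels whose
rendered signal reaches at least ``visibility_floor`` grey levels (default
2) — because an annotator cannot outline signal indistinguishable from
background. The calibration is re-run on the trimmed mask, so the tail
fraction stays exact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import PlacementError
from .io_formats import IntensityImage, LabelMask

__all__ = [
    "CometParams",
    "SyntheticTruth",
    "DEFAULT_CLASS_BINS",
    "class_for_tail_fraction",
    "render_comet",
    "generate_dataset",
    "labelled_feature_table",
]

#: Damage-class bin edges on tail_fraction for the conventional 5-class
#: scoring scheme: class 1 = no or barely detectable tail, class 5 = almost
#: all DNA in the tail (no visible nucleus).
DEFAULT_CLASS_BINS = (0.0, 0.05, 0.25, 0.5, 0.8, 1.0)

#: Default image shapes (rows, cols) per stain, matching typical camera
#: frames for each preparation.
DEFAULT_IMAGE_SHAPES = {"fluorescent": (1200, 1600), "silver": (1280, 1024)}

#: Default per-image comet count ranges per stain.
DEFAULT_COMET_RANGES = {"fluorescent": (20, 100), "silver": (2, 20)}

DEFAULT_NOISE = {"gaussian_sd": 4.0, "background_level": 12.0}


def class_for_tail_fraction(tail_fraction: float,
                            bins: tuple[float, ...] = DEFAULT_CLASS_BINS) -> int:
    """Map a tail DNA fraction to its damage class (1-based, monotone)."""
    if not 0.0 <= tail_fraction <= 1.0:
        raise ValueError("tail_fraction must lie in [0, 1]")
    # right-open bins except the last, which includes 1.0
    idx = int(np.searchsorted(bins, tail_fraction, side="right"))
    return min(idx, len(bins) - 1)


@dataclass
class CometParams:
    """Ground-truth parameters for one synthetic comet."""

    center: tuple[float, float]  # (row, col) of the head centre
    head_radius: float
    head_peak: float
    tail_length: float
    tail_fraction: float
    orientation: float  # radians; direction the tail points
    class_label: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.tail_fraction <= 1.0:
            raise ValueError("tail_fraction must lie in [0, 1]")
        if (self.tail_length == 0) != (self.tail_fraction == 0):
            raise ValueError("tail_length == 0 exactly when tail_fraction == 0")
        if self.class_label == 0:
            self.class_label = class_for_tail_fraction(self.tail_fraction)


@dataclass
class SyntheticTruth:
    """One generated image bundled with its exact ground truth."""

    image: IntensityImage
    comet_mask: LabelMask
    head_mask: LabelMask
    params: list[CometParams]
    seed: int
    noiseless: np.ndarray = field(repr=False, default=None)

    def raw_pixels(self) -> np.ndarray:
        """Pixels as they would appear on disk (silver frames re-inverted)."""
        px = self.image.pixels
        if self.image.stain_mode == "silver":
            return (self.image.max_representable - px).astype(px.dtype)
        return px


def _support_extent(params: CometParams) -> tuple[float, float, float]:
    """(back, forward, lateral) reach of the comet from the head centre."""
    r = params.head_radius
    back = r
    forward = r + params.tail_length if params.tail_fraction > 0 else r
    lateral = r
    return back, forward, lateral


def _profiles(params: CometParams, shape: tuple[int, int],
              center: tuple[float, float]):
    """Unit-amplitude head/tail profiles and masks on a patch."""
    rows = np.arange(shape[0])[:, None] - center[0]
    cols = np.arange(shape[1])[None, :] - center[1]
    r2 = rows ** 2 + cols ** 2
    hr = params.head_radius
    sigma_h = hr / 2.0
    head_mask = r2 <= hr ** 2
    head_profile = np.where(head_mask, np.exp(-r2 / (2 * sigma_h ** 2)), 0.0)

    if params.tail_fraction > 0:
        d = np.array([np.cos(params.orientation), np.sin(params.orientation)])
        axial = rows * d[0] + cols * d[1]
        perp = -rows * d[1] + cols * d[0]
        sigma_c = hr / 2.0
        lam = params.tail_length / 2.0
        in_lobe = ((axial >= 0) & (axial <= hr + params.tail_length)
                   & (np.abs(perp) <= hr))
        tail_mask = in_lobe & ~head_mask
        decay = np.exp(-np.maximum(axial - hr, 0.0) / lam)
        tail_profile = np.where(tail_mask,
                                decay * np.exp(-perp ** 2 / (2 * sigma_c ** 2)),
                                0.0)
    else:
        tail_mask = np.zeros(shape, dtype=bool)
        tail_profile = np.zeros(shape)
    return head_profile, head_mask, tail_profile, tail_mask


def _amplitudes(params: CometParams, sum_head: float, sum_tail: float,
                amplitude_cap: float | None) -> tuple[float, float]:
    """Joint head/tail amplitudes realising the requested tail fraction."""
    tf = params.tail_fraction
    if tf == 0 or sum_tail == 0:
        return params.head_peak, 0.0
    if tf == 1:
        a = amplitude_cap if amplitude_cap is not None else params.head_peak
        return 0.0, a
    a = tf / (1 - tf) * params.head_peak * sum_head / sum_tail
    b = params.head_peak
    if amplitude_cap is not None and a > amplitude_cap:
        a = amplitude_cap
        b = a * sum_tail * (1 - tf) / (tf * sum_head)
    return b, a


def render_comet(params: CometParams,
                 patch_shape: tuple[int, int] | None = None,
                 center: tuple[float, float] | None = None,
                 amplitude_cap: float | None = None,
                 visibility_floor: float = 2.0):
    """Render one comet on a patch; noiseless, background-free.

    Returns ``(patch, comet_mask, head_mask)``. The tail mask (comet minus
    head) is trimmed to pixels carrying at least ``visibility_floor`` grey
    levels of signal, and the integrated intensity over it divided by the
    total equals ``params.tail_fraction`` exactly (up to float rounding).
    If the patch truncates the comet, a warning reports the achieved
    fraction instead.
    """
    back, forward, lateral = _support_extent(params)
    reach = int(np.ceil(max(back, forward, lateral))) + 2
    if patch_shape is None:
        patch_shape = (2 * reach + 1, 2 * reach + 1)
        center = (reach, reach)
    if center is None:
        center = ((patch_shape[0] - 1) / 2.0, (patch_shape[1] - 1) / 2.0)

    head_p, head_m, tail_p, tail_m = _profiles(params, patch_shape, center)
    b, a = _amplitudes(params, head_p.sum(), tail_p[tail_m].sum(),
                       amplitude_cap)

    # Trim the tail mask to its visible support and recalibrate. Raising
    # the amplitude can only shrink the sub-floor set, so this converges.
    if a > 0:
        for _ in range(8):
            visible = tail_m & (a * tail_p >= visibility_floor)
            if not visible.any():
                break
            if visible.sum() == tail_m.sum():
                break
            tail_m = visible
            b, a = _amplitudes(params, head_p.sum(), tail_p[tail_m].sum(),
                               amplitude_cap)
        tail_p = np.where(tail_m, tail_p, 0.0)

    patch = b * head_p + a * tail_p
    comet_m = head_m | tail_m

    # Truncation check: the comet support reaching the patch border means
    # part of it fell outside.
    border = np.zeros_like(comet_m)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    if (comet_m & border).any():
        sum_tail = a * tail_p.sum()
        total = b * head_p.sum() + sum_tail
        achieved = sum_tail / total if total > 0 else 0.0
        warnings.warn(
            f"comet truncated by patch; achieved tail_fraction {achieved:.4f} "
            f"(requested {params.tail_fraction:.4f})", stacklevel=2)
    return patch, comet_m, head_m


def _sample_params(rng: np.random.Generator, class_label: int,
                   orientation: float, bit_depth: int) -> CometParams:
    """Draw one comet's morphology for a given damage class."""
    bins = DEFAULT_CLASS_BINS
    head_radius = rng.uniform(8.0, 16.0)
    scale = (1 << bit_depth) / 256.0
    head_peak = rng.uniform(140.0, 220.0) * scale
    if class_label == 1:
        tf = 0.0
        tail_length = 0.0
    else:
        lo, hi = bins[class_label - 1], bins[class_label]
        hi = min(hi, 0.97)  # keep a visible head even in class 5
        tf = rng.uniform(lo, hi)
        tail_length = head_radius * (2.0 + 10.0 * tf) * rng.uniform(0.85, 1.15)
    return CometParams(center=(0.0, 0.0), head_radius=head_radius,
                       head_peak=head_peak, tail_length=tail_length,
                       tail_fraction=tf, orientation=orientation,
                       class_label=class_label)


def generate_dataset(n_images: int = 1,
                     comets_per_image: tuple[int, int] | None = None,
                     class_mix: tuple[float, ...] = (0.2, 0.2, 0.2, 0.2, 0.2),
                     stain_mode: str = "fluorescent",
                     noise: dict | None = None,
                     image_shape: tuple[int, int] | None = None,
                     orientation_jitter: float = 0.0,
                     seed: int = 0,
                     bit_depth: int = 8) -> list[SyntheticTruth]:
    """Generate seeded synthetic comet images with exact ground truth.

    Comets are placed by rejection sampling so that their bounding boxes do
    not overlap and no comet touches the image border. All comets in one
    image share the electrophoresis direction (plus optional per-comet
    ``orientation_jitter``, radians SD). ``class_mix`` gives the sampling
    proportions of damage classes 1..5. Reproducible bit-for-bit from
    ``seed``.
    """
    if stain_mode not in DEFAULT_IMAGE_SHAPES:
        raise ValueError(f"unknown stain_mode {stain_mode!r}")
    if image_shape is None:
        image_shape = DEFAULT_IMAGE_SHAPES[stain_mode]
    if comets_per_image is None:
        comets_per_image = DEFAULT_COMET_RANGES[stain_mode]
    noise = {**DEFAULT_NOISE, **(noise or {})}
    mix = np.asarray(class_mix, dtype=float)
    if mix.sum() <= 0 or (mix < 0).any():
        raise ValueError("class_mix must be non-negative with positive sum")
    mix = mix / mix.sum()

    rng = np.random.default_rng(seed)
    max_rep = (1 << bit_depth) - 1
    cap = max(1.0, max_rep - noise["background_level"] - 2.0)
    out: list[SyntheticTruth] = []
    for _ in range(n_images):
        lo, hi = comets_per_image
        n_comets = int(rng.integers(lo, hi + 1))
        direction = rng.uniform(0, 2 * np.pi)
        canvas = np.zeros(image_shape, dtype=np.float64)
        comet_lbl = np.zeros(image_shape, dtype=np.int32)
        head_lbl = np.zeros(image_shape, dtype=np.int32)
        placed_boxes: list[tuple[int, int, int, int]] = []
        params_list: list[CometParams] = []
        margin = 4
        for comet_id in range(1, n_comets + 1):
            cls = int(rng.choice(len(mix), p=mix)) + 1
            placed = False
            for _attempt in range(200):
                theta = direction + (orientation_jitter * rng.standard_normal()
                                     if orientation_jitter else 0.0)
                p = _sample_params(rng, cls, theta, bit_depth)
                back, forward, lateral = _support_extent(p)
                # axis-aligned half-extents of the rotated support
                c, s = np.cos(theta), np.sin(theta)
                half_r = max(abs(back * c), abs(forward * c)) + abs(lateral * s) + 2
                half_c = max(abs(back * s), abs(forward * s)) + abs(lateral * c) + 2
                if (margin + half_r >= image_shape[0] - margin - half_r
                        or margin + half_c >= image_shape[1] - margin - half_c):
                    continue  # too large for the frame: redraw morphology
                r0 = rng.uniform(margin + half_r, image_shape[0] - margin - half_r)
                c0 = rng.uniform(margin + half_c, image_shape[1] - margin - half_c)
                box = (int(r0 - half_r), int(r0 + half_r + 1),
                       int(c0 - half_c), int(c0 + half_c + 1))
                if all(box[1] <= b[0] or box[0] >= b[1]
                       or box[3] <= b[2] or box[2] >= b[3]
                       for b in placed_boxes):
                    placed = True
                    break
            if not placed:
                raise PlacementError(
                    f"could not place comet {comet_id} of {n_comets} in "
                    f"{image_shape} after 200 attempts")
            placed_boxes.append(box)
            p.center = (r0, c0)
            shape = (box[1] - box[0], box[3] - box[2])
            local = (r0 - box[0], c0 - box[2])
            patch, cm, hm = render_comet(
                p, shape, local, amplitude_cap=cap,
                visibility_floor=2.0 * (1 << bit_depth) / 256.0)
            sl = (slice(box[0], box[1]), slice(box[2], box[3]))
            canvas[sl] += patch
            comet_lbl[sl][cm] = comet_id
            head_lbl[sl][hm] = comet_id
            params_list.append(p)

        noisy = canvas + noise["background_level"]
        if noise["gaussian_sd"] > 0:
            noisy = noisy + rng.normal(0.0, noise["gaussian_sd"], image_shape)
        dtype = np.uint16 if bit_depth == 16 else np.uint8
        pixels = np.clip(np.rint(noisy), 0, max_rep).astype(dtype)
        image = IntensityImage(pixels, stain_mode=stain_mode, bit_depth=bit_depth)
        out.append(SyntheticTruth(image=image,
                                  comet_mask=LabelMask(comet_lbl),
                                  head_mask=LabelMask(head_lbl),
                                  params=params_list,
                                  seed=seed,
                                  noiseless=canvas))
    return out


def labelled_feature_table(n_per_class: int = 200, seed: int = 0,
                           background_level: float = 12.0,
                           gaussian_sd: float = 4.0,
                           bit_depth: int = 8):
    """A labelled feature table from isolated comets with true masks.

    Renders ``n_per_class`` comets for each of the five damage classes on
    individual noisy patches and measures the 21 features under the exact
    ground-truth masks — the classifier-training scenario where an expert
    has outlined and scored every comet by hand. Returns a
    :class:`pandas.DataFrame` with a ``class`` column.
    """
    import pandas as pd

    from .features import comet_features
    from .segmentation import CometSegmentation

    rng = np.random.default_rng(seed)
    max_rep = (1 << bit_depth) - 1
    cap = max(1.0, max_rep - background_level - 2.0)
    rows = []
    for cls in range(1, 6):
        for i in range(n_per_class):
            p = _sample_params(rng, cls, rng.uniform(0, 2 * np.pi), bit_depth)
            patch, comet_m, head_m = render_comet(
                p, amplitude_cap=cap,
                visibility_floor=2.0 * (1 << bit_depth) / 256.0)
            noisy = patch + background_level
            if gaussian_sd > 0:
                noisy = noisy + rng.normal(0.0, gaussian_sd, patch.shape)
            pixels = np.clip(np.rint(noisy), 0, max_rep)
            seg = CometSegmentation(comet_mask=comet_m, head_mask=head_m,
                                    tail_mask=comet_m & ~head_m,
                                    comet_id=len(rows) + 1)
            rec = comet_features(pixels, seg, class_label=cls)
            rows.append(rec.to_dict())
    return pd.DataFrame(rows)
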