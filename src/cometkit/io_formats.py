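"""Reading and writing the pipeline's on-disk artifacts.

Handles the four kinds of files a comet-assay analysis touches:

* micrographs (TIFF/PNG/BMP/JPEG, grayscale or RGB, 8- or 16-bit),
* intensity-coded instance label masks (16-bit grayscale PNG),
* measurement tables (CSV, one row per comet),
* editable project files (a JSON document with sidecar mask PNGs).

Silver-stained micrographs show dark comets on a bright background; they are
inverted on load (``v -> max_representable - v``) so that every downstream
stage can assume bright comets on a dark background regardless of stain.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .errors import CapacityError, FormatError, ProjectVersionError

__all__ = [
    "IntensityImage",
    "LabelMask",
    "Project",
    "read_image",
    "write_label_mask",
    "read_label_mask",
    "export_measurements",
    "import_measurements",
    "save_project",
    "load_project",
]

_SUPPORTED_SUFFIXES = {".tif", ".tiff", ".png", ".bmp", ".jpg", ".jpeg"}

#: Rec. 601 luminance weights used to collapse RGB micrographs to gray.
_REC601 = np.array([0.299, 0.587, 0.114])

PROJECT_FORMAT_VERSION = "1"


@dataclass
class IntensityImage:
    """A 2-D grayscale micrograph with stain-mode metadata.

    After ingestion comets are always brighter than background: silver-stained
    inputs are inverted at load time.
    """

    pixels: np.ndarray
    stain_mode: str = "fluorescent"
    bit_depth: int = 8
    source_path: str | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("IntensityImage requires a 2-D pixel array")
        if self.stain_mode not in ("fluorescent", "silver"):
            raise ValueError(f"unknown stain_mode {self.stain_mode!r}")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def max_representable(self) -> int:
        return (1 << self.bit_depth) - 1


@dataclass
class LabelMask:
    """Intensity-coded instance mask: 0 = background, k >= 1 = object k."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("LabelMask requires a 2-D label array")
        if self.labels.min(initial=0) < 0:
            raise ValueError("labels must be non-negative")

    @property
    def ids(self) -> np.ndarray:
        """Sorted array of the positive object IDs present."""
        ids = np.unique(self.labels)
        return ids[ids > 0]

    def object_mask(self, object_id: int) -> np.ndarray:
        return self.labels == object_id


def read_image(path: str | Path, stain_mode: str = "fluorescent") -> IntensityImage:
    """Read a micrograph and normalise it to the bright-comet convention.

    RGB inputs are collapsed to Rec. 601 luminance; silver-stained images are
    inverted so comets are brighter than background. A constant image is
    accepted with a degenerate-input warning.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"image file does not exist: {path}")
    if path.suffix.lower() not in _SUPPORTED_SUFFIXES:
        raise FormatError(f"unsupported image format {path.suffix!r}: {path}")
    try:
        raw = iio.imread(path)
    except Exception as exc:  # noqa: BLE001 - reraised with the offending path
        raise FormatError(f"could not read image {path}: {exc}") from exc

    if raw.ndim == 3:
        raw = raw[..., :3]  # drop alpha if present
        gray = np.rint(raw.astype(np.float64) @ _REC601)
    elif raw.ndim == 2:
        gray = raw.astype(np.float64)
    else:
        raise FormatError(f"image {path} has unsupported dimensionality {raw.ndim}")

    bit_depth = 16 if raw.dtype.itemsize > 1 else 8
    max_rep = (1 << bit_depth) - 1
    if stain_mode == "silver":
        gray = max_rep - gray
    pixels = np.clip(gray, 0, max_rep).astype(np.uint16 if bit_depth == 16 else np.uint8)
    if pixels.min() == pixels.max():
        warnings.warn(f"image {path} is constant-valued", stacklevel=2)
    return IntensityImage(pixels, stain_mode=stain_mode, bit_depth=bit_depth,
                          source_path=str(path))


def write_label_mask(mask: LabelMask, path: str | Path) -> None:
    """Write an instance mask as a lossless 16-bit grayscale PNG."""
    path = Path(path)
    if path.suffix.lower() != ".png":
        raise FormatError(f"label masks are written as PNG, got {path.suffix!r}")
    labels = np.asarray(mask.labels)
    if labels.max(initial=0) > 0xFFFF:
        raise CapacityError("label IDs exceed the 16-bit PNG capacity (65535)")
    iio.imwrite(path, labels.astype(np.uint16))


def read_label_mask(path: str | Path) -> LabelMask:
    """Read an instance mask written by :func:`write_label_mask`."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"label mask does not exist: {path}")
    try:
        labels = iio.imread(path)
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"could not read label mask {path}: {exc}") from exc
    if labels.ndim != 2:
        raise FormatError(f"label mask {path} is not single-channel")
    return LabelMask(labels.astype(np.int64))


def export_measurements(records: Iterable[Mapping[str, object]] | pd.DataFrame,
                        path: str | Path,
                        float_format: str = "%.6g") -> pd.DataFrame:
    """Write one CSV row per comet with the fixed measurement column order.

    ``records`` may be a DataFrame or an iterable of per-comet mappings as
    produced by :func:`cometkit.features.comet_features`. Floats are written
    with 6 significant digits. An empty record list produces a header-only
    file and a warning. Returns the frame as written.
    """
    from .features import measurement_columns  # local import: avoid cycle

    if isinstance(records, pd.DataFrame):
        frame = records.copy()
    else:
        frame = pd.DataFrame(list(records))
    columns = measurement_columns()
    if frame.empty:
        warnings.warn("exporting an empty measurement table (header only)",
                      stacklevel=2)
        frame = pd.DataFrame(columns=columns)
    else:
        missing = [c for c in columns if c not in frame.columns]
        if missing:
            raise ValueError(f"records are missing measurement columns: {missing}")
        extras = [c for c in frame.columns if c not in columns]
        frame = frame[columns + extras]
    frame.to_csv(path, index=False, float_format=float_format)
    return frame


def import_measurements(path: str | Path) -> pd.DataFrame:
    """Read a measurement CSV back (e.g. as classifier training input)."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"measurement table does not exist: {path}")
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# Project files
# ---------------------------------------------------------------------------

@dataclass
class Project:
    """An editable analysis session: images, ROIs, settings, masks, labels.

    Saved as a single JSON document plus sidecar mask PNGs so the project can
    be shared and re-opened for further annotation or re-measurement.
    """

    images: list[dict] = field(default_factory=list)
    comets: list[dict] = field(default_factory=list)
    settings: dict = field(default_factory=dict)
    masks: dict[str, LabelMask] = field(default_factory=dict)
    feature_cache: list[dict] = field(default_factory=list)
    format_version: str = PROJECT_FORMAT_VERSION


def save_project(project: Project, directory: str | Path) -> Path:
    """Save a project as ``project.json`` plus sidecar mask PNGs.

    Saving is idempotent: save -> load -> save produces byte-identical files.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    mask_files = {}
    for name in sorted(project.masks):
        fname = f"mask_{name}.png"
        write_label_mask(project.masks[name], directory / fname)
        mask_files[name] = fname
    doc = {
        "format_version": project.format_version,
        "images": project.images,
        "comets": project.comets,
        "settings": project.settings,
        "masks": mask_files,
        "feature_cache": project.feature_cache,
    }
    out = directory / "project.json"
    out.write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n", encoding="utf-8")
    return out


def load_project(directory: str | Path) -> Project:
    """Load a project saved by :func:`save_project`."""
    directory = Path(directory)
    doc_path = directory / "project.json"
    if not doc_path.exists():
        raise FormatError(f"no project.json under {directory}")
    try:
        doc = json.loads(doc_path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise FormatError(f"could not parse project file {doc_path}: {exc}") from exc
    version = doc.get("format_version")
    if version != PROJECT_FORMAT_VERSION:
        raise ProjectVersionError(
            f"project {doc_path} has format_version {version!r}; "
            f"this toolkit reads version {PROJECT_FORMAT_VERSION!r}")
    masks = {name: read_label_mask(directory / fname)
             for name, fname in doc.get("masks", {}).items()}
    return Project(images=doc.get("images", []),
                   comets=doc.get("comets", []),
                   settings=doc.get("settings", {}),
                   masks=masks,
                   feature_cache=doc.get("feature_cache", []),
                   format_version=version)
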