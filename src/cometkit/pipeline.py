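"""End-to-end batch pipeline: detect -> segment -> measure -> classify.

`run_pipeline` ties the library modules into the unattended workflow a lab
would script: for every input micrograph it proposes ROIs (or takes them
from a file), segments each comet, extracts the 21 features, optionally
applies a trained classifier, and writes label masks, a combined CSV, a log
and a machine-readable manifest. Runs are reproducible bit-for-bit from the
config and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .classify import load_model, predict
from .errors import CometKitError
from .features import comet_features
from .io_formats import LabelMask, export_measurements, read_image, write_label_mask
from .segmentation import (DetectorSettings, Roi, ThresholdSettings,
                           detect_comets, segment_roi)

__all__ = ["RunConfig", "run_pipeline", "load_config"]

log = logging.getLogger("cometkit")


@dataclass
class RunConfig:
    """Fully serialisable description of one pipeline run."""

    stain_mode: str = "fluorescent"
    mode: str = "auto"  # "auto" (detector) or "roi" (user-supplied circles)
    segmentation: dict = field(default_factory=dict)   # ThresholdSettings kwargs
    detector: dict = field(default_factory=dict)       # DetectorSettings kwargs
    model_path: str | None = None                      # optional classifier
    feature_names: list[str] | None = None             # classifier include-list
    rois: dict[str, list] = field(default_factory=dict)  # image name -> ROI rows
    seed: int = 0
    output_dir: str = "cometkit_out"

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:12]


def load_config(path: str | Path) -> RunConfig:
    """Load a run config from a JSON or TOML document."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix == ".toml":
        import tomllib
        doc = tomllib.loads(text)
    else:
        doc = json.loads(text)
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(doc) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**doc)


def _roi_from_row(row: dict) -> Roi:
    kind = row["kind"]
    if kind == "circle":
        return Roi("circle", center=(float(row["center_row"]),
                                     float(row["center_col"])),
                   radius=float(row["radius"]))
    if kind == "box":
        return Roi("box", corners=((float(row["row0"]), float(row["col0"])),
                                   (float(row["row1"]), float(row["col1"]))))
    if kind == "polygon":
        verts = np.asarray(json.loads(row["vertices"]), dtype=float)
        return Roi("polygon", vertices=verts)
    raise ValueError(f"unknown ROI kind {kind!r}")


def run_pipeline(config: RunConfig, images: list[str | Path]) -> Path:
    """Run the full analysis over ``images``; returns the output directory.

    Per-image failures are logged and skipped (exit status semantics are the
    CLI's concern); raises only if the output directory cannot be prepared.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    log.info("cometkit %s | seed=%d | config=%s", __version__, config.seed,
             config.config_hash())
    log.info("config document:\n%s", config.to_json())

    settings = ThresholdSettings(**config.segmentation)
    det_settings = DetectorSettings(**config.detector)
    model = load_model(config.model_path) if config.model_path else None

    records: list[dict] = []
    outputs: list[str] = []
    n_failed = 0
    for img_path in images:
        img_path = Path(img_path)
        try:
            image = read_image(img_path, stain_mode=config.stain_mode)
            if config.mode == "roi":
                rows = config.rois.get(img_path.name, [])
                rois = [_roi_from_row(r) for r in rows]
            else:
                rois = detect_comets(image, det_settings)
            comet_lbl = np.zeros(image.pixels.shape, dtype=np.int32)
            head_lbl = np.zeros(image.pixels.shape, dtype=np.int32)
            for comet_id, roi in enumerate(rois, start=1):
                try:
                    seg = segment_roi(image, roi, settings, comet_id=comet_id)
                except CometKitError as exc:
                    log.warning("%s comet %d skipped: %s", img_path.name,
                                comet_id, exc)
                    continue
                new = seg.comet_mask & (comet_lbl == 0)
                comet_lbl[new] = comet_id
                head_lbl[seg.head_mask & new] = comet_id
                rec = comet_features(image, seg, image_name=img_path.name)
                records.append(rec.to_dict())
            stem = img_path.stem
            for name, lbl in (("comet", comet_lbl), ("head", head_lbl)):
                mask_file = out / f"{stem}_{name}_mask.png"
                write_label_mask(LabelMask(lbl), mask_file)
                outputs.append(mask_file.name)
            log.info("%s: %d ROIs, %d comets measured", img_path.name,
                     len(rois), int(comet_lbl.max()))
        except Exception as exc:  # noqa: BLE001 - per-image isolation
            n_failed += 1
            log.error("image %s failed: %s", img_path, exc)

    if model is not None and records:
        import pandas as pd
        table = pd.DataFrame(records)
        table["class"] = predict(model, table)
        records = table.to_dict("records")

    csv_path = out / "measurements.csv"
    export_measurements(records, csv_path)
    outputs.append(csv_path.name)

    manifest = {
        "tool": f"cometkit {__version__}",
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "n_images": len(images),
        "n_failed_images": n_failed,
        "n_comets": len(records),
        "outputs": sorted(set(outputs)) + ["run.log", "manifest.json"],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True) + "\n")
    log.removeHandler(handler)
    handler.close()
    return out
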