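"""End-to-end run: segment -> cluster -> calibrate -> measure -> report.

Produces, per input image, an annotated overlay (numbered wheal contours
plus a legend of areas in cm^2) and a machine-readable record that
round-trips losslessly through JSON/CSV.  Records embed the resolved
configuration and a config hash so runs are reproducible and auditable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image, ImageDraw
from skimage.segmentation import find_boundaries

from whealmeter.geometry import (
    Calibration,
    CalibrationError,
    WhealMeasurement,
    calibrate,
    cluster_pixels,
    measure_cluster,
)
from whealmeter.nn.train import predict_mask

logger = logging.getLogger(__name__)

_CSV_COLUMNS = ["id", "pixel_count", "area_cm2", "LD_cm", "PD_cm", "MA1_cm2", "MA2_cm2"]


class ReportFormatError(ValueError):
    """A machine-readable record violates the expected schema."""


@dataclass(frozen=True)
class RunConfig:
    """Resolved parameters of one pipeline run."""

    min_size: int = 10
    angle_step_deg: float = 1.0
    pad_px: int = 5
    seed: int = 0

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class AnnotatedReport:
    """Overlay image plus the machine-readable measurement record."""

    source: str
    config: RunConfig
    calibration: Calibration | None
    measurements: list[WhealMeasurement] = field(default_factory=list)
    overlay: np.ndarray | None = None
    error: str | None = None

    def record(self) -> dict:
        """JSON-ready record (no timestamps: byte-identical across runs)."""
        return {
            "source": self.source,
            "config": asdict(self.config),
            "config_hash": self.config.config_hash(),
            "calibration": None
            if self.calibration is None
            else {
                "rt_pixel_count": self.calibration.rt_pixel_count,
                "rt_area_cm2": self.calibration.rt_area_cm2,
                "cm2_per_pixel": self.calibration.cm2_per_pixel,
            },
            "error": self.error,
            "wheals": [
                {
                    "id": m.cluster_id,
                    "pixel_count": m.pixel_count,
                    "area_cm2": m.area_cm2,
                    "LD_cm": m.ld_cm,
                    "PD_cm": m.pd_cm,
                    "MA1_cm2": m.ma1_cm2,
                    "MA2_cm2": m.ma2_cm2,
                }
                for m in self.measurements
            ],
        }


def measure_mask(
    mask: np.ndarray, config: RunConfig, source: str = "", image: np.ndarray | None = None
) -> AnnotatedReport:
    """Measure every wheal in a class-index mask (the post-segmentation stages)."""
    try:
        cal = calibrate(mask)
    except CalibrationError as exc:
        logger.error("skipping %s: %s", source or "<array>", exc)
        return AnnotatedReport(source=source, config=config, calibration=None, error=str(exc))
    clusters = cluster_pixels(mask, min_size=config.min_size)
    measurements = [
        measure_cluster(c, cal, angle_step_deg=config.angle_step_deg) for c in clusters
    ]
    overlay = None
    if image is not None:
        overlay = render_overlay(image, [c.to_mask() for c in clusters], measurements)
    return AnnotatedReport(
        source=source,
        config=config,
        calibration=cal,
        measurements=measurements,
        overlay=overlay,
    )


def run_pipeline(
    images: list,
    config: RunConfig,
    model=None,
    masks: list[np.ndarray] | None = None,
) -> list[AnnotatedReport]:
    """Run the full pipeline over images.

    Segmentation comes from ``model`` (the trained network) or, for oracle
    runs, from pre-computed ``masks`` aligned with ``images``.  Images that
    fail calibration are skipped with a logged error; the run continues.
    """
    if masks is None and model is None:
        raise ValueError("provide a model or oracle masks")
    reports = []
    for i, item in enumerate(images):
        name, img = item if isinstance(item, tuple) else (f"image_{i}", item)
        mask = masks[i] if masks is not None else predict_mask(model, img)
        reports.append(measure_mask(mask, config, source=name, image=img))
    return reports


# ---------------------------------------------------------------------------
# overlay rendering
# ---------------------------------------------------------------------------


def render_overlay(
    image: np.ndarray,
    cluster_masks: list[np.ndarray],
    measurements: list[WhealMeasurement],
) -> np.ndarray:
    """Input image with numbered wheal contours and an upper-left area legend."""
    img = Image.fromarray(np.asarray(image, dtype=np.uint8)).convert("RGB")
    draw = ImageDraw.Draw(img)
    for m, cmask in zip(measurements, cluster_masks):
        boundary = find_boundaries(cmask, mode="inner")
        rr, cc = np.nonzero(boundary)
        for r, c in zip(rr, cc):
            draw.point((int(c), int(r)), fill=(0, 0, 255))
        rows, cols = np.nonzero(cmask)
        draw.text(
            (float(cols.mean()) + 3, float(rows.mean()) + 3),
            str(m.cluster_id),
            fill=(0, 0, 255),
        )
    legend = [f"{m.cluster_id}: {m.area_cm2:.2f} cm2" for m in measurements]
    draw.multiline_text((4, 4), "\n".join(legend) or "no wheals", fill=(0, 0, 255))
    return np.asarray(img)


# ---------------------------------------------------------------------------
# record I/O
# ---------------------------------------------------------------------------


def write_report(report: AnnotatedReport, json_path, csv_path=None, overlay_path=None) -> None:
    """Write the machine record (JSON), per-wheal table (CSV) and overlay (PNG)."""
    record = report.record()
    Path(json_path).write_text(json.dumps(record, indent=2) + "\n")
    if csv_path is not None:
        rows = [
            [w["id"], w["pixel_count"], w["area_cm2"], w["LD_cm"], w["PD_cm"], w["MA1_cm2"], w["MA2_cm2"]]
            for w in record["wheals"]
        ]
        pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(
            csv_path, index=False, float_format="%.17g"
        )
    if overlay_path is not None and report.overlay is not None:
        Image.fromarray(report.overlay).save(overlay_path)


def read_report(json_path) -> dict:
    """Read and validate a machine record written by :func:`write_report`."""
    record = json.loads(Path(json_path).read_text())
    for key in ("source", "config", "config_hash", "calibration", "wheals"):
        if key not in record:
            raise ReportFormatError(f"missing field: {key}")
    for i, w in enumerate(record["wheals"]):
        for key in ("id", "pixel_count", "area_cm2", "LD_cm", "PD_cm", "MA1_cm2", "MA2_cm2"):
            if key not in w:
                raise ReportFormatError(f"missing field: wheals[{i}].{key}")
    return record
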