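"""Wheal geometry: pixel clustering, tag calibration, areas and diameters.

The area estimator is the pixel-proportion rule: a wheal's area equals its
pixel count times the cm^2-per-pixel scale obtained from the 3 x 3 cm
reference tag.  Diameters are chords through the cluster centroid: the
largest chord (LD) and the chord perpendicular to it (PD), from which the
circle (MA1) and ellipse (MA2) clinical approximations are computed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from whealmeter.palette import CLASS_RT, CLASS_WHEAL

logger = logging.getLogger(__name__)

_EIGHT_CONN = np.ones((3, 3), dtype=int)


class CalibrationError(ValueError):
    """The mask contains no reference-tag pixels."""


@dataclass(frozen=True)
class WhealCluster:
    """One 8-connected wheal region."""

    id: int
    pixels: np.ndarray  # (n, 2) int array of (row, col)
    centroid: tuple[float, float]  # (row, col)
    mask_shape: tuple[int, int]

    @property
    def pixel_count(self) -> int:
        return int(self.pixels.shape[0])

    def to_mask(self) -> np.ndarray:
        m = np.zeros(self.mask_shape, dtype=bool)
        m[self.pixels[:, 0], self.pixels[:, 1]] = True
        return m


@dataclass(frozen=True)
class Calibration:
    """Pixel-to-area scale derived from the reference tag."""

    rt_pixel_count: int
    rt_area_cm2: float = 9.0

    def __post_init__(self) -> None:
        if self.rt_pixel_count <= 0:
            raise CalibrationError("rt_pixel_count must be positive")

    @property
    def cm2_per_pixel(self) -> float:
        return self.rt_area_cm2 / self.rt_pixel_count

    @property
    def cm_per_pixel(self) -> float:
        return math.sqrt(self.cm2_per_pixel)

    @classmethod
    def from_pixels_per_cm(cls, pixels_per_cm: float) -> "Calibration":
        """Exact calibration for a known rendering scale (testing/synthetic use)."""
        return cls(rt_pixel_count=round(9.0 * pixels_per_cm**2))


@dataclass(frozen=True)
class WhealMeasurement:
    """All per-wheal size estimates."""

    cluster_id: int
    pixel_count: int
    area_cm2: float  # pixel-proportion area
    ld_cm: float
    pd_cm: float
    ma1_cm2: float
    ma2_cm2: float


def cluster_pixels(
    mask: np.ndarray, target_class: int = CLASS_WHEAL, min_size: int = 10
) -> list[WhealCluster]:
    """8-connected component labeling of ``target_class`` pixels.

    Components smaller than ``min_size`` are discarded; survivors are sorted
    by centroid (row-major) and numbered from 1.
    """
    mask = np.asarray(mask)
    binary = mask == target_class
    labels, n = ndimage.label(binary, structure=_EIGHT_CONN)
    clusters = []
    for lab in range(1, n + 1):
        pix = np.argwhere(labels == lab)
        if pix.shape[0] < min_size:
            continue
        centroid = (float(pix[:, 0].mean()), float(pix[:, 1].mean()))
        clusters.append((centroid, pix))
    clusters.sort(key=lambda t: t[0])
    return [
        WhealCluster(id=i + 1, pixels=pix, centroid=c, mask_shape=mask.shape)
        for i, (c, pix) in enumerate(clusters)
    ]


def calibrate(mask: np.ndarray) -> Calibration:
    """Derive the cm^2-per-pixel scale from the largest reference-tag component."""
    binary = np.asarray(mask) == CLASS_RT
    labels, n = ndimage.label(binary, structure=_EIGHT_CONN)
    if n == 0:
        raise CalibrationError("mask contains no reference-tag pixels")
    counts = np.bincount(labels.ravel())[1:]
    return Calibration(rt_pixel_count=int(counts.max()))


def cluster_area_cm2(cluster: WhealCluster, cal: Calibration) -> float:
    """Pixel-proportion area: pixel count times the calibrated scale."""
    return cluster.pixel_count * cal.cm2_per_pixel


def computational_diameters(
    cluster: WhealCluster,
    cal: Calibration,
    angle_step_deg: float = 1.0,
) -> tuple[float, float]:
    """Largest chord through the centroid (LD) and its perpendicular (PD), in cm.

    For each angle in ``[0, 180)`` the chord is measured on the line through
    the centroid: the extent between the extreme region pixels lying within
    0.5 px of the line, extended by +-0.5 px (the sub-pixel boundary of
    center-sampled rasterization).  LD is the maximal chord (ties: smallest
    angle); PD is the chord at the LD angle + 90 degrees.  When the centroid
    falls outside the region (strongly non-convex shapes) the chord is still
    the extreme-intersection extent; a warning is logged.
    """
    if cluster.pixel_count == 0:
        raise ValueError("cluster is empty")
    if angle_step_deg > 1.0:
        raise ValueError("angle_step_deg must be <= 1 degree")
    r0, c0 = cluster.centroid
    region = cluster.to_mask()
    rr, cc = int(round(r0)), int(round(c0))
    if not (0 <= rr < region.shape[0] and 0 <= cc < region.shape[1] and region[rr, cc]):
        logger.warning(
            "cluster %d centroid lies outside the region; chord = extreme in-region extent",
            cluster.id,
        )

    # chord extremes lie within ~2 px of the region boundary, so a boundary
    # ring suffices and keeps the angular sweep cheap on large regions
    ring = region & ~ndimage.binary_erosion(region, structure=np.ones((3, 3)), iterations=2)
    ring_pixels = np.argwhere(ring) if ring.any() else cluster.pixels
    rel = ring_pixels.astype(float) - np.array([r0, c0])
    angles = np.deg2rad(np.arange(0.0, 180.0, angle_step_deg))
    chords = chord_lengths_px(rel, angles)
    i_ld = int(np.argmax(chords))  # argmax returns the first max -> smallest angle
    theta_pd = (angles[i_ld] + np.pi / 2.0) % np.pi
    pd_chord = float(chord_lengths_px(rel, np.array([theta_pd]))[0])
    ld_px = float(chords[i_ld])
    # an off-grid PD angle could marginally exceed the grid max; keep LD >= PD
    pd_px = min(pd_chord, ld_px)
    return ld_px * cal.cm_per_pixel, pd_px * cal.cm_per_pixel


def chord_lengths_px(
    pixels_rel: np.ndarray, angles_rad: np.ndarray, chunk: int = 45
) -> np.ndarray:
    """Chord length (px) at each angle for a line through the origin.

    ``pixels_rel`` are region pixel centers relative to the centroid.  For a
    direction ``u``, pixels whose perpendicular distance to the line is at
    most 0.5 px form the line's pixel support; the chord spans their extreme
    projections onto ``u`` plus the two half-pixel boundary offsets.
    Angles are processed in chunks to bound memory on large regions.
    """
    lengths = np.empty(angles_rad.shape[0])
    for start in range(0, angles_rad.shape[0], chunk):
        ang = angles_rad[start : start + chunk]
        u = np.stack([np.sin(ang), np.cos(ang)])  # (2, A) as (d_row, d_col)
        v = np.stack([np.cos(ang), -np.sin(ang)])
        proj = pixels_rel @ u  # (n, A)
        in_strip = np.abs(pixels_rel @ v) <= 0.5
        pmax = np.where(in_strip, proj, -np.inf).max(axis=0)
        pmin = np.where(in_strip, proj, np.inf).min(axis=0)
        seg = pmax - pmin + 1.0
        seg[~np.isfinite(seg)] = 0.0  # no pixel support on this line
        lengths[start : start + chunk] = seg
    return lengths


def ma1_area(ld_cm: float, pd_cm: float) -> float:
    """Area of a circle whose diameter is the mean of LD and PD."""
    _check_diameters(ld_cm, pd_cm)
    return math.pi * ((ld_cm + pd_cm) / 2.0 / 2.0) ** 2


def ma2_area(ld_cm: float, pd_cm: float) -> float:
    """Area of an ellipse with major axis LD and minor axis PD."""
    _check_diameters(ld_cm, pd_cm)
    return math.pi * (ld_cm / 2.0) * (pd_cm / 2.0)


def _check_diameters(ld_cm: float, pd_cm: float) -> None:
    if not (ld_cm > 0 and pd_cm > 0):
        raise ValueError(f"diameters must be positive, got LD={ld_cm}, PD={pd_cm}")
    if ld_cm < pd_cm:
        raise ValueError(f"LD must be >= PD, got LD={ld_cm}, PD={pd_cm}")


def measure_cluster(
    cluster: WhealCluster, cal: Calibration, angle_step_deg: float = 1.0
) -> WhealMeasurement:
    """Compute the full set of size estimates for one cluster."""
    ld, pd = computational_diameters(cluster, cal, angle_step_deg)
    return WhealMeasurement(
        cluster_id=cluster.id,
        pixel_count=cluster.pixel_count,
        area_cm2=cluster_area_cm2(cluster, cal),
        ld_cm=ld,
        pd_cm=pd,
        ma1_cm2=ma1_area(ld, pd),
        ma2_cm2=ma2_area(ld, pd),
    )
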