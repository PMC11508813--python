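"""Synthetic labeled scenes and shape sets with known analytic geometry.

Everything downstream (segmentation, calibration, measurement, agreement
statistics) is exercised against data from this module: skin-toned scenes
containing a chroma-key reference tag plus elliptical or pseudopod-shaped
"wheals", and standalone regular/irregular shape sets where the analytic
area and diameters are known exactly.

Conventions
-----------
* Pixel centers sit at integer ``(row, col)`` coordinates, 0-based.
* Physical coordinates: ``x_cm = col / pixels_per_cm``, ``y_cm = row / pixels_per_cm``.
* Rasterization rule: a pixel belongs to a shape iff its **center** lies
  inside the analytic boundary.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from whealmeter.palette import CLASS_BACKGROUND, CLASS_RT, CLASS_WHEAL

logger = logging.getLogger(__name__)

#: chroma-key green used for the tag in rendered RGB scenes (mask color is black)
TAG_SCENE_RGB = (0, 255, 0)
DEFAULT_SKIN_RGB = (224, 172, 148)
#: additive RGB shift applied to wheal pixels in the rendered scene
WHEAL_TINT = (18, -26, -22)

RT_AREA_CM2 = 9.0  # 3 cm x 3 cm reference tag


class PlacementError(ValueError):
    """A shape or the reference tag does not fit, or two regions overlap."""


@dataclass(frozen=True)
class ShapeSpec:
    """Analytic description of one wheal-like shape.

    ``lobes`` is a tuple of ``(angle_deg, radial_amplitude_cm, angular_width_deg)``
    Gaussian bumps added to the elliptical radial profile; it is empty for
    regular kinds.  ``analytic_area_cm2`` is ``pi * a * b`` for circles and
    ellipses and ``None`` for pseudopods.
    """

    kind: str  # circle | ellipse | pseudopod
    center_cm: tuple[float, float]  # (x, y)
    semi_major_cm: float
    semi_minor_cm: float
    rotation_deg: float = 0.0
    lobes: tuple[tuple[float, float, float], ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in ("circle", "ellipse", "pseudopod"):
            raise ValueError(f"unknown shape kind {self.kind!r}")
        if not (self.semi_major_cm >= self.semi_minor_cm > 0):
            raise ValueError(
                f"need semi_major_cm >= semi_minor_cm > 0, "
                f"got {self.semi_major_cm}, {self.semi_minor_cm}"
            )
        if self.kind == "circle" and self.semi_major_cm != self.semi_minor_cm:
            raise ValueError("circle requires equal semi-axes")
        if self.kind != "pseudopod" and self.lobes:
            raise ValueError("lobes are only valid for pseudopods")

    @property
    def analytic_area_cm2(self) -> float | None:
        if self.kind == "pseudopod":
            return None
        return math.pi * self.semi_major_cm * self.semi_minor_cm

    @property
    def max_radius_cm(self) -> float:
        """Maximal radial extent from the center (tight for pseudopods)."""
        if not self.lobes:
            return self.semi_major_cm
        theta = np.linspace(0.0, 2.0 * math.pi, 1441)
        return float(self.radial_profile(theta).max()) * 1.001

    def radial_profile(self, theta_rad: np.ndarray) -> np.ndarray:
        """Boundary radius at polar angle ``theta`` (canvas frame, radians)."""
        phi = theta_rad - math.radians(self.rotation_deg)
        a, b = self.semi_major_cm, self.semi_minor_cm
        r = a * b / np.sqrt((b * np.cos(phi)) ** 2 + (a * np.sin(phi)) ** 2)
        for ang_deg, amp_cm, width_deg in self.lobes:
            delta = np.angle(np.exp(1j * (theta_rad - math.radians(ang_deg))))
            sigma = math.radians(width_deg)
            r = r + amp_cm * np.exp(-0.5 * (delta / sigma) ** 2)
        return r

    def contains(self, x_cm: np.ndarray, y_cm: np.ndarray) -> np.ndarray:
        """Pixel-center membership test at physical coordinates (cm)."""
        dx = np.asarray(x_cm, dtype=float) - self.center_cm[0]
        dy = np.asarray(y_cm, dtype=float) - self.center_cm[1]
        if self.kind == "pseudopod":
            rho = np.hypot(dx, dy)
            theta = np.arctan2(dy, dx)
            return rho <= self.radial_profile(theta)
        rot = math.radians(self.rotation_deg)
        u = dx * math.cos(rot) + dy * math.sin(rot)
        v = -dx * math.sin(rot) + dy * math.cos(rot)
        return (u / self.semi_major_cm) ** 2 + (v / self.semi_minor_cm) ** 2 <= 1.0

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "center_cm": list(self.center_cm),
            "semi_major_cm": self.semi_major_cm,
            "semi_minor_cm": self.semi_minor_cm,
            "rotation_deg": self.rotation_deg,
            "lobes": [list(l) for l in self.lobes],
            "analytic_area_cm2": self.analytic_area_cm2,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ShapeSpec":
        return cls(
            kind=d["kind"],
            center_cm=tuple(d["center_cm"]),
            semi_major_cm=d["semi_major_cm"],
            semi_minor_cm=d["semi_minor_cm"],
            rotation_deg=d.get("rotation_deg", 0.0),
            lobes=tuple(tuple(l) for l in d.get("lobes", [])),
        )


@dataclass(frozen=True)
class RenderedShape:
    """A shape spec plus its rasterized ground-truth pixel set."""

    spec: ShapeSpec
    pixel_mask: np.ndarray  # (H, W) bool

    @property
    def pixel_count(self) -> int:
        return int(self.pixel_mask.sum())


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic SPT-like scene."""

    pixels_per_cm: float
    wheal_specs: tuple[ShapeSpec, ...] = ()
    canvas_px: tuple[int, int] = (640, 480)  # (width, height)
    rt_side_cm: float = 3.0
    rt_position_px: tuple[float, float] = (4.0, 4.0)  # (x, y) of top-left corner
    skin_tone_rgb: tuple[int, int, int] = DEFAULT_SKIN_RGB
    noise_sigma: float = 6.0
    seed: int = 0


def rasterize_shape(
    spec: ShapeSpec, pixels_per_cm: float, canvas_px: tuple[int, int]
) -> np.ndarray:
    """Rasterize one shape onto a ``(height, width)`` boolean grid.

    Only the analytic bounding box is evaluated, so large canvases stay cheap.
    """
    width, height = canvas_px
    cx, cy = spec.center_cm
    r = spec.max_radius_cm
    c0 = max(0, int(math.floor((cx - r) * pixels_per_cm)) - 1)
    c1 = min(width, int(math.ceil((cx + r) * pixels_per_cm)) + 2)
    r0 = max(0, int(math.floor((cy - r) * pixels_per_cm)) - 1)
    r1 = min(height, int(math.ceil((cy + r) * pixels_per_cm)) + 2)
    out = np.zeros((height, width), dtype=bool)
    if c0 >= c1 or r0 >= r1:
        return out
    cols = np.arange(c0, c1, dtype=float)
    rows = np.arange(r0, r1, dtype=float)
    xs = cols[None, :] / pixels_per_cm
    ys = rows[:, None] / pixels_per_cm
    out[r0:r1, c0:c1] = spec.contains(xs, ys)
    return out


def rasterize_tag(
    rt_position_px: tuple[float, float],
    rt_side_cm: float,
    pixels_per_cm: float,
    canvas_px: tuple[int, int],
) -> np.ndarray:
    """Rasterize the square reference tag (pixel-center rule)."""
    width, height = canvas_px
    x0, y0 = rt_position_px
    side = rt_side_cm * pixels_per_cm
    cols = np.arange(width, dtype=float)
    rows = np.arange(height, dtype=float)
    in_x = (cols >= x0) & (cols < x0 + side)
    in_y = (rows >= y0) & (rows < y0 + side)
    return in_y[:, None] & in_x[None, :]


def _check_fits(mask: np.ndarray, name: str) -> None:
    if not mask.any():
        raise PlacementError(f"{name} rasterizes to zero pixels")
    if mask[0].any() or mask[-1].any() or mask[:, 0].any() or mask[:, -1].any():
        raise PlacementError(f"{name} touches the canvas border")


def render_scene(spec: SceneSpec):
    """Render a scene to ``(rgb_image, label_mask, shapes)``.

    ``rgb_image`` is ``(H, W, 3)`` uint8, ``label_mask`` is ``(H, W)`` uint8
    class indices, ``shapes`` a list of :class:`RenderedShape` giving each
    wheal's ground-truth pixel set.  Deterministic given the spec (including
    its ``seed``).
    """
    width, height = spec.canvas_px
    tag = rasterize_tag(spec.rt_position_px, spec.rt_side_cm, spec.pixels_per_cm, spec.canvas_px)
    _check_fits(tag, "reference tag")

    occupied = tag.copy()
    shapes: list[RenderedShape] = []
    for i, shape in enumerate(spec.wheal_specs):
        m = rasterize_shape(shape, spec.pixels_per_cm, spec.canvas_px)
        _check_fits(m, f"wheal {i}")
        if (m & occupied).any():
            raise PlacementError(f"wheal {i} overlaps the tag or another wheal")
        occupied |= m
        shapes.append(RenderedShape(spec=shape, pixel_mask=m))

    mask = np.full((height, width), CLASS_BACKGROUND, dtype=np.uint8)
    for rs in shapes:
        mask[rs.pixel_mask] = CLASS_WHEAL
    mask[tag] = CLASS_RT

    rng = np.random.default_rng(spec.seed)
    img = np.empty((height, width, 3), dtype=float)
    img[:] = spec.skin_tone_rgb
    wheal_px = mask == CLASS_WHEAL
    img[wheal_px] += WHEAL_TINT
    img[tag] = TAG_SCENE_RGB
    if spec.noise_sigma > 0:
        img += rng.normal(0.0, spec.noise_sigma, size=img.shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8), mask, shapes


# ---------------------------------------------------------------------------
# random generators
# ---------------------------------------------------------------------------


def _random_regular_spec(
    rng: np.random.Generator, axis_range_cm: tuple[float, float]
) -> ShapeSpec:
    lo, hi = axis_range_cm
    if rng.random() < 0.5:
        r = float(rng.uniform(lo, hi))
        return ShapeSpec("circle", (0.0, 0.0), r, r)
    a, b = np.sort(rng.uniform(lo, hi, size=2))[::-1]
    if a == b:  # measure-zero, but keep the circle invariant honest
        a = float(a) * 1.000001
    return ShapeSpec("ellipse", (0.0, 0.0), float(a), float(b), float(rng.uniform(0.0, 180.0)))


def _random_pseudopod_spec(
    rng: np.random.Generator, axis_range_cm: tuple[float, float]
) -> ShapeSpec:
    lo, hi = axis_range_cm
    a, b = np.sort(rng.uniform(lo, hi, size=2))[::-1]
    n_lobes = int(rng.integers(3, 9))
    lobes = tuple(
        (
            float(rng.uniform(0.0, 360.0)),
            float(rng.uniform(0.25, 0.6) * b),
            float(rng.uniform(8.0, 20.0)),
        )
        for _ in range(n_lobes)
    )
    return ShapeSpec(
        "pseudopod", (0.0, 0.0), float(a), float(b), float(rng.uniform(0.0, 180.0)), lobes
    )


def _is_connected(mask: np.ndarray) -> bool:
    _, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    return n == 1


def _place_shapes(
    rng: np.random.Generator,
    specs: list[ShapeSpec],
    pixels_per_cm: float,
    canvas_px: tuple[int, int],
    tag: np.ndarray,
    max_tries: int = 2000,
) -> list[RenderedShape]:
    """Place shapes at random non-overlapping positions (>= 1 px separation)."""
    width, height = canvas_px
    occupied = ndimage.binary_dilation(tag, structure=np.ones((3, 3), dtype=bool))
    placed: list[RenderedShape] = []
    for i, spec in enumerate(specs):
        margin_cm = spec.max_radius_cm + 2.0 / pixels_per_cm
        x_lo, x_hi = margin_cm, width / pixels_per_cm - margin_cm
        y_lo, y_hi = margin_cm, height / pixels_per_cm - margin_cm
        if x_lo >= x_hi or y_lo >= y_hi:
            raise PlacementError(f"shape {i} cannot fit on the canvas at this scale")
        for _ in range(max_tries):
            candidate = replace(
                spec,
                center_cm=(float(rng.uniform(x_lo, x_hi)), float(rng.uniform(y_lo, y_hi))),
            )
            m = rasterize_shape(candidate, pixels_per_cm, canvas_px)
            if not m.any():
                continue
            grown = ndimage.binary_dilation(m, structure=np.ones((3, 3), dtype=bool))
            if not (grown & occupied).any():
                occupied |= grown
                placed.append(RenderedShape(spec=candidate, pixel_mask=m))
                break
        else:
            raise PlacementError(f"could not place shape {i} after {max_tries} tries")
    return placed


def make_shape_group(
    group: str,
    n_files: int,
    shapes_per_file: int,
    axis_range_cm: tuple[float, float],
    pixels_per_cm: float,
    seed: int,
    canvas_px: tuple[int, int] = (640, 480),
    rt_position_px: tuple[float, float] = (4.0, 4.0),
) -> list[tuple[np.ndarray, list[RenderedShape]]]:
    """Generate the regular/irregular shape study files.

    Each file is a label mask containing ``shapes_per_file`` shapes plus one
    3 x 3 cm reference square.  ``group`` is ``"regular"`` (circles/ellipses
    with known analytic areas) or ``"irregular"`` (connected pseudopods).
    Returns ``[(label_mask, [RenderedShape, ...]), ...]``.
    """
    if group not in ("regular", "irregular"):
        raise ValueError(f"group must be 'regular' or 'irregular', got {group!r}")
    if shapes_per_file < 1:
        raise ValueError("shapes_per_file must be >= 1")
    lo, hi = axis_range_cm
    if not (0 < lo <= hi):
        raise ValueError(f"axis_range_cm must be positive, got {axis_range_cm}")

    rng = np.random.default_rng(seed)
    tag = rasterize_tag(rt_position_px, 3.0, pixels_per_cm, canvas_px)
    _check_fits(tag, "reference tag")

    out: list[tuple[np.ndarray, list[RenderedShape]]] = []
    for _ in range(max(0, n_files)):
        specs: list[ShapeSpec] = []
        while len(specs) < shapes_per_file:
            if group == "regular":
                specs.append(_random_regular_spec(rng, axis_range_cm))
                continue
            cand = _random_pseudopod_spec(rng, axis_range_cm)
            # connectivity must hold wherever the shape lands; test centered
            probe_canvas = (
                int(math.ceil(2 * cand.max_radius_cm * pixels_per_cm)) + 8,
            ) * 2
            probe = replace(cand, center_cm=(probe_canvas[0] / (2 * pixels_per_cm),) * 2)
            if _is_connected(rasterize_shape(probe, pixels_per_cm, probe_canvas)):
                specs.append(cand)
            else:
                logger.info("pseudopod draw produced a disconnected region; redrawing")
        placed = _place_shapes(rng, specs, pixels_per_cm, canvas_px, tag)
        mask = np.full((canvas_px[1], canvas_px[0]), CLASS_BACKGROUND, dtype=np.uint8)
        for rs in placed:
            mask[rs.pixel_mask] = CLASS_WHEAL
        mask[tag] = CLASS_RT
        out.append((mask, placed))
    return out


def random_scene_spec(
    seed: int,
    canvas_px: tuple[int, int] = (640, 480),
    pixels_per_cm: float | None = None,
    n_wheals: tuple[int, int] = (1, 5),
    axis_range_cm: tuple[float, float] = (0.3, 0.9),
    irregular_fraction: float = 0.3,
    noise_sigma: float = 6.0,
) -> SceneSpec:
    """Draw a random but valid :class:`SceneSpec` (placement pre-resolved)."""
    rng = np.random.default_rng(seed)
    width, height = canvas_px
    if pixels_per_cm is None:
        # tag occupies ~1/5 of the smaller canvas dimension
        pixels_per_cm = min(width, height) / 5.0 / 3.0
    tag = rasterize_tag((4.0, 4.0), 3.0, pixels_per_cm, canvas_px)
    n = int(rng.integers(n_wheals[0], n_wheals[1] + 1))
    specs = [
        _random_pseudopod_spec(rng, axis_range_cm)
        if rng.random() < irregular_fraction
        else _random_regular_spec(rng, axis_range_cm)
        for _ in range(n)
    ]
    placed = _place_shapes(rng, specs, pixels_per_cm, canvas_px, tag)
    skin = tuple(
        int(np.clip(base + rng.integers(-18, 19), 0, 255)) for base in DEFAULT_SKIN_RGB
    )
    return SceneSpec(
        pixels_per_cm=pixels_per_cm,
        wheal_specs=tuple(rs.spec for rs in placed),
        canvas_px=canvas_px,
        skin_tone_rgb=skin,  # type: ignore[arg-type]
        noise_sigma=noise_sigma,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------


def augment_mirror(image: np.ndarray, mask: np.ndarray) -> list[tuple[np.ndarray, np.ndarray]]:
    """Chained mirroring augmentation: original + H, H.V, H.V.H intermediates.

    Applies horizontal mirroring, then vertical mirroring, then horizontal
    mirroring again, keeping each intermediate, so one pair becomes four.
    Image and mask are transformed identically.
    """
    image = np.asarray(image)
    mask = np.asarray(mask)
    if image.shape[:2] != mask.shape[:2]:
        raise ValueError(
            f"image {image.shape[:2]} and mask {mask.shape[:2]} dimensions differ"
        )
    pairs = [(image.copy(), mask.copy())]
    img, msk = image, mask
    for axis in (1, 0, 1):  # horizontal, vertical, horizontal
        img = np.flip(img, axis=axis)
        msk = np.flip(msk, axis=axis)
        pairs.append((img.copy(), msk.copy()))
    return pairs
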