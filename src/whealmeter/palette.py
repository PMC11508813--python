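"""Label-mask class indices and the fixed RGB color code used on disk.

Masks are stored as RGB PNGs with exactly three colors: red background,
magenta wheal, black reference tag.  In memory a mask is a ``(H, W)``
``uint8`` array of class indices.  Background is class 0 so that argmax
tie-breaking in the segmentation head defaults to background.
"""

from __future__ import annotations

import numpy as np

CLASS_BACKGROUND = 0
CLASS_WHEAL = 1
CLASS_RT = 2

#: class index -> RGB color in file form
PALETTE: dict[int, tuple[int, int, int]] = {
    CLASS_BACKGROUND: (255, 0, 0),
    CLASS_WHEAL: (255, 0, 255),
    CLASS_RT: (0, 0, 0),
}

N_CLASSES = len(PALETTE)

CLASS_NAMES = {CLASS_BACKGROUND: "background", CLASS_WHEAL: "wheal", CLASS_RT: "rt"}


class PaletteError(ValueError):
    """An RGB mask image contains a pixel outside the three-color palette."""


def encode_label_mask(mask: np.ndarray) -> np.ndarray:
    """Encode a ``(H, W)`` class-index mask as an ``(H, W, 3)`` uint8 RGB image."""
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError(f"mask must be 2-D, got shape {mask.shape}")
    if mask.size and (mask.min() < 0 or mask.max() >= N_CLASSES):
        bad = int(mask.flat[np.argmax((mask < 0) | (mask >= N_CLASSES))])
        raise ValueError(f"mask contains class index {bad} outside 0..{N_CLASSES - 1}")
    lut = np.zeros((N_CLASSES, 3), dtype=np.uint8)
    for cls, rgb in PALETTE.items():
        lut[cls] = rgb
    return lut[mask.astype(np.intp)]


def decode_label_mask(rgb: np.ndarray) -> np.ndarray:
    """Decode an RGB mask image back to class indices.

    Every pixel must match one of the palette colors exactly; the first
    offending pixel (row-major) is reported otherwise.
    """
    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError(f"expected (H, W, 3) RGB array, got shape {rgb.shape}")
    out = np.full(rgb.shape[:2], -1, dtype=np.int16)
    for cls, color in PALETTE.items():
        out[np.all(rgb == np.asarray(color, dtype=rgb.dtype), axis=-1)] = cls
    bad = np.argwhere(out < 0)
    if bad.size:
        r, c = (int(v) for v in bad[0])
        raise PaletteError(
            f"pixel at (row={r}, col={c}) has off-palette color {tuple(int(v) for v in rgb[r, c])}"
        )
    return out.astype(np.uint8)
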