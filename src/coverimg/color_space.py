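"""Color representations and the two similarity measures used for pixel matching.

Two measures are defined.  The RGB measure is the squared Euclidean distance
over the red/green/blue components.  The YCbCr measure converts both colors to
full-range BT.601 YCbCr and sums the squared chroma differences plus the
squared luma difference divided by 9, deemphasizing brightness relative to hue.
A pixel is "near" a reference color iff the measure is *strictly* less than the
squared tolerance.

The conversion matrix is the full-range ITU-R BT.601 (JPEG) convention with
components clamped to [0, 255].  Gray inputs (r == g == b) map to cb == cr ==
128.  Components are kept as floats (no integer rounding) so that tolerance
boundaries are not quantized.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np

#: Valid metric selector strings, as used in selection files and CLI flags.
METRICS = ("rgb", "ycbcr")

#: Any squared-RGB distance is below this: 3 * 255**2 = 195075 < 442**2.
MAX_RGB_DISTANCE = 442


class Color(NamedTuple):
    """One 8-bit-per-channel RGB pixel value."""

    r: int
    g: int
    b: int

    def validate(self) -> "Color":
        for name, v in zip("rgb", self):
            iv = int(v)
            if iv != v or not 0 <= iv <= 255:
                raise ValueError(f"channel {name}={v!r} outside 0..255")
        return Color(int(self.r), int(self.g), int(self.b))


class YCbCrColor(NamedTuple):
    """A color in YCbCr space; components are reals in [0, 255]."""

    y: float
    cb: float
    cr: float


def rgb_distance_sq(a: Color, b: Color) -> int:
    """Squared Euclidean RGB distance between two colors."""
    return (a[0] - b[0]) ** 2 + (a[1] - b[1]) ** 2 + (a[2] - b[2]) ** 2


def rgb_to_ycbcr(a: Color) -> YCbCrColor:
    """Convert an RGB color to full-range BT.601 YCbCr, clamped to [0, 255]."""
    r, g, b = a[0], a[1], a[2]
    y = 0.299 * r + 0.587 * g + 0.114 * b
    cb = 128.0 - 0.168736 * r - 0.331264 * g + 0.5 * b
    cr = 128.0 + 0.5 * r - 0.418688 * g - 0.081312 * b
    return YCbCrColor(
        min(max(y, 0.0), 255.0),
        min(max(cb, 0.0), 255.0),
        min(max(cr, 0.0), 255.0),
    )


def ycbcr_distance_measure(a: YCbCrColor, b: YCbCrColor) -> float:
    """Chroma-weighted squared measure: dCb^2 + dCr^2 + dY^2 / 9."""
    return (a[1] - b[1]) ** 2 + (a[2] - b[2]) ** 2 + (a[0] - b[0]) ** 2 / 9


def is_near(a: Color, b: Color, tol: float, metric: str) -> bool:
    """True iff the chosen metric's measure is strictly below ``tol**2``.

    Note that the RGB metric typically requires higher tolerances than YCbCr
    for the same visual grouping, since brightness differences contribute
    fully to the RGB measure.
    """
    if tol < 0:
        raise ValueError("tolerance must be non-negative")
    if metric == "rgb":
        return rgb_distance_sq(a, b) < tol * tol
    if metric == "ycbcr":
        return ycbcr_distance_measure(rgb_to_ycbcr(a), rgb_to_ycbcr(b)) < tol * tol
    raise ValueError(f"unknown metric {metric!r}; expected one of {METRICS}")


def planes_to_ycbcr(pixels: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized BT.601 conversion of an (H, W, 3) uint8 array.

    Uses the exact same float64 expression ordering as :func:`rgb_to_ycbcr`
    so vectorized classification is bit-identical to the scalar path.
    """
    r = pixels[..., 0].astype(np.float64)
    g = pixels[..., 1].astype(np.float64)
    b = pixels[..., 2].astype(np.float64)
    y = 0.299 * r + 0.587 * g + 0.114 * b
    cb = 128.0 - 0.168736 * r - 0.331264 * g + 0.5 * b
    cr = 128.0 + 0.5 * r - 0.418688 * g - 0.081312 * b
    np.clip(y, 0.0, 255.0, out=y)
    np.clip(cb, 0.0, 255.0, out=cb)
    np.clip(cr, 0.0, 255.0, out=cr)
    return y, cb, cr
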