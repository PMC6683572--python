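"""Reading and writing 24-bit rasters with physical-resolution metadata.

24-bit BMP is the canonical format: its pixels-per-meter fields carry the DPI
that converts pixel counts into cm².  PNG/TIFF/JPEG are accepted for reading
(their DPI metadata is honored when present); BMP and PNG can be written.

Coordinates are 0-based with a top-left origin, x rightward, y downward.
Rectangles are half-open: ``[x0, x1) x [y0, y1)``.
"""

from __future__ import annotations

import struct
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import NamedTuple

import numpy as np
from PIL import Image

from .color_space import Color
from .errors import (
    AnisotropicResolutionError,
    RegionBoundsError,
    UnsupportedImageError,
)

#: Meters per inch; BMP stores pixels-per-meter, dpi = ppm * 0.0254.
_M_PER_INCH = 0.0254

#: Relative tolerance for horizontal-vs-vertical embedded resolution.
_ANISO_REL_TOL = 0.005


@dataclass(frozen=True)
class Raster:
    """A width x height grid of RGB colors with optional DPI metadata."""

    pixels: np.ndarray  # (height, width, 3) uint8
    dpi: float | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError(f"pixels must be (H>=1, W>=1, 3), got {px.shape}")
        if px.dtype != np.uint8:
            px = px.astype(np.uint8)
        object.__setattr__(self, "pixels", px)
        if self.dpi is not None and not self.dpi > 0:
            raise ValueError(f"dpi must be positive, got {self.dpi}")

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def height(self) -> int:
        return self.pixels.shape[0]


class RegionSpec(NamedTuple):
    """Half-open pixel rectangle [x0, x1) x [y0, y1), 0-based, top-left origin."""

    x0: int
    y0: int
    x1: int
    y1: int

    def validate(self, width: int, height: int) -> "RegionSpec":
        if not (0 <= self.x0 < self.x1 <= width and 0 <= self.y0 < self.y1 <= height):
            raise RegionBoundsError(
                f"region {tuple(self)} outside image {width}x{height} "
                "(need 0 <= x0 < x1 <= width, 0 <= y0 < y1 <= height)"
            )
        return self

    @classmethod
    def parse(cls, text: str) -> "RegionSpec":
        """Parse the CLI form ``"x0,y0,x1,y1"``."""
        parts = text.split(",")
        if len(parts) != 4:
            raise ValueError(f"expected 'x0,y0,x1,y1', got {text!r}")
        return cls(*(int(p) for p in parts))


def _read_bmp_metadata(path: Path) -> tuple[int, int, int]:
    """Return (bit_count, ppm_x, ppm_y) from a BMP header."""
    with open(path, "rb") as fh:
        head = fh.read(54)
    if len(head) < 54 or head[:2] != b"BM":
        raise UnsupportedImageError(f"{path}: not a BMP file")
    dib_size = struct.unpack_from("<I", head, 14)[0]
    if dib_size < 40:
        raise UnsupportedImageError(
            f"{path}: unsupported BMP header (size {dib_size})"
        )
    bit_count = struct.unpack_from("<H", head, 28)[0]
    ppm_x = struct.unpack_from("<i", head, 38)[0]
    ppm_y = struct.unpack_from("<i", head, 42)[0]
    return bit_count, ppm_x, ppm_y


def _resolve_dpi(
    h_dpi: float, v_dpi: float, path, dpi_override: float | None
) -> float | None:
    """Pick the authoritative DPI from per-axis values (0 means absent)."""
    if h_dpi > 0 and v_dpi > 0:
        rel = abs(h_dpi - v_dpi) / max(h_dpi, v_dpi)
        if rel > _ANISO_REL_TOL and dpi_override is None:
            raise AnisotropicResolutionError(
                f"{path}: horizontal {h_dpi:g} vs vertical {v_dpi:g} DPI differ "
                f"by {rel:.2%} (> {_ANISO_REL_TOL:.1%}); pass an explicit "
                "dpi_override (--dpi) to proceed"
            )
        return h_dpi  # horizontal axis is authoritative
    if h_dpi > 0:
        return h_dpi
    if v_dpi > 0:
        return v_dpi
    return None


def read_raster(path, dpi_override: float | None = None) -> Raster:
    """Read an image as a Raster; ``dpi_override``, when given, always wins.

    BMP inputs must be 24-bit; palettized or other depths raise an error with
    a conversion hint.  Alpha channels in other formats are flattened over
    white with a warning.  Absent resolution metadata and no override leave
    ``dpi`` unset (percentage output never needs DPI; only cm² does).
    """
    path = Path(path)
    if dpi_override is not None and not dpi_override > 0:
        raise ValueError(f"dpi_override must be positive, got {dpi_override}")

    is_bmp = path.suffix.lower() in (".bmp", ".dib")
    embedded: float | None = None
    if is_bmp:
        bit_count, ppm_x, ppm_y = _read_bmp_metadata(path)
        if bit_count != 24:
            raise UnsupportedImageError(
                f"{path}: {bit_count}-bit BMP unsupported; convert to 24-bit "
                "RGB (e.g. `coverimg` reads PNG too, or re-save as 24-bit BMP)"
            )
        embedded = _resolve_dpi(
            ppm_x * _M_PER_INCH, ppm_y * _M_PER_INCH, path, dpi_override
        )

    try:
        with Image.open(path) as im:
            im.load()
            if not is_bmp:
                info_dpi = im.info.get("dpi")
                if info_dpi:
                    embedded = _resolve_dpi(
                        float(info_dpi[0]), float(info_dpi[1]), path, dpi_override
                    )
                if im.mode in ("RGBA", "LA", "PA") or "transparency" in im.info:
                    warnings.warn(
                        f"{path}: alpha channel flattened over white",
                        stacklevel=2,
                    )
                    rgba = im.convert("RGBA")
                    flat = Image.new("RGBA", rgba.size, (255, 255, 255, 255))
                    flat.alpha_composite(rgba)
                    im = flat
            rgb = im.convert("RGB")
            pixels = np.asarray(rgb, dtype=np.uint8).copy()
    except UnsupportedImageError:
        raise
    except Exception as exc:  # Pillow raises a zoo of decode errors
        raise UnsupportedImageError(f"{path}: cannot decode image: {exc}") from exc

    dpi = dpi_override if dpi_override is not None else embedded
    return Raster(pixels=pixels, dpi=dpi)


def write_raster(img: Raster, path) -> None:
    """Write a Raster losslessly as 24-bit BMP or PNG.

    BMP resolution fields are written as ``round(dpi / 0.0254)`` pixels per
    meter, or 0 when DPI is unset, so the round-trip error is bounded by the
    integer ppm quantization (|delta dpi| <= 0.0127).
    """
    path = Path(path)
    suffix = path.suffix.lower()
    pil = Image.fromarray(img.pixels, mode="RGB")
    if suffix in (".bmp", ".dib"):
        pil.save(path, format="BMP")
        ppm = round(img.dpi / _M_PER_INCH) if img.dpi is not None else 0
        with open(path, "r+b") as fh:
            fh.seek(38)
            fh.write(struct.pack("<ii", ppm, ppm))
    elif suffix == ".png":
        if img.dpi is not None:
            pil.save(path, format="PNG", dpi=(img.dpi, img.dpi))
        else:
            pil.save(path, format="PNG")
    else:
        raise UnsupportedImageError(
            f"{path}: write supports .bmp and .png, not {suffix!r}"
        )


def blank_region(img: Raster, region: RegionSpec, fill: Color) -> Raster:
    """Overwrite every pixel inside ``region`` with ``fill``.

    CLI analogue of the GUI 'Blank' brush for erasing artifacts (labels,
    margins, out-of-plot background) before classification.
    """
    region = RegionSpec(*region).validate(img.width, img.height)
    fill = Color(*fill).validate()
    out = img.pixels.copy()
    out[region.y0 : region.y1, region.x0 : region.x1] = fill
    return replace(img, pixels=out)


def blank_mask(img: Raster, mask: np.ndarray | Raster, fill: Color) -> Raster:
    """Overwrite pixels where ``mask`` is nonzero (any channel) with ``fill``."""
    fill = Color(*fill).validate()
    m = mask.pixels if isinstance(mask, Raster) else np.asarray(mask)
    if m.ndim == 3:
        m = m.any(axis=2)
    if m.shape != (img.height, img.width):
        raise RegionBoundsError(
            f"mask shape {m.shape} does not match image "
            f"{img.height}x{img.width}"
        )
    out = img.pixels.copy()
    out[m != 0] = fill
    return replace(img, pixels=out)


def crop(img: Raster, region: RegionSpec) -> Raster:
    """Return the sub-raster covered by ``region``; DPI carries over unchanged."""
    region = RegionSpec(*region).validate(img.width, img.height)
    out = img.pixels[region.y0 : region.y1, region.x0 : region.x1].copy()
    return replace(img, pixels=out)
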