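"""Headline quantities: coverage percent, physical area, and selection ratios.

With N total pixels, C foreground, I ignored and B = N - C - I background:

* coverage percent = C * 100 / (N - I), identically C * 100 / (C + B);
* foreground area in cm² = C / (DPI / 2.54)²;
* a two-selection ratio divides the subset coverage percent by the total
  coverage percent (e.g. yellow-brown / whole plant, or green / total callus);
* the senescence delta is the increase of that ratio between two dates.

Degenerate inputs (every pixel ignored; zero total coverage) yield flagged
undefined results rather than exceptions, so one pathological image cannot
abort a long batch.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .classify import LabelCounts, classify_image
from .errors import AreaUnavailableError, SelectionMismatchError
from .raster_io import Raster
from .selection import Selection

STATUS_OK = "ok"
STATUS_ALL_IGNORED = "all-ignored"
STATUS_NO_DPI = "no-dpi"
STATUS_ZERO_TOTAL = "zero-total"


@dataclass(frozen=True)
class CoverageResult:
    """One image's counts, coverage percent, optional area and provenance."""

    image_id: str
    counts: LabelCounts
    coverage_pct: float | None
    area_cm2: float | None
    dpi: float | None
    selection_name: str
    selection_hash: str
    tolerance: float
    metric: str
    status: str


@dataclass(frozen=True)
class RatioResult:
    """Subset-over-total coverage ratio for one image."""

    image_id: str
    counts: LabelCounts
    subset_pct: float | None
    total_pct: float | None
    ratio: float | None
    status: str


def coverage_percent(counts: LabelCounts) -> float | None:
    """C * 100 / (N - I); ``None`` (flagged, never silent zero) when N == I.

    Both printed forms of the formula are asserted identical on every call:
    N - I == C + B exactly, so the divisions agree bit-for-bit.
    """
    if counts.n == counts.i:
        return None
    pct = counts.c * 100.0 / (counts.n - counts.i)
    alt = counts.c * 100.0 / (counts.c + counts.b)
    assert pct == alt, "coverage formula identity violated"
    return pct


def area_cm2(c: int, dpi: float | None) -> float:
    """Foreground area C / (DPI / 2.54)² in cm²."""
    if dpi is None or dpi <= 0:
        raise AreaUnavailableError(
            "area in cm² needs a positive DPI; the image has none embedded — "
            "pass --dpi (percent coverage is available without it)"
        )
    return c / (dpi / 2.54) ** 2


def analyze_image(
    img: Raster,
    sel: Selection,
    image_id: str = "",
    conflict: str = "nearest",
) -> CoverageResult:
    """Classify one image and evaluate the coverage formulas on the counts."""
    _, counts = classify_image(img, sel, conflict=conflict)
    pct = coverage_percent(counts)
    area: float | None
    if img.dpi is not None:
        area = area_cm2(counts.c, img.dpi)
        status = STATUS_OK if pct is not None else STATUS_ALL_IGNORED
    else:
        area = None
        status = STATUS_NO_DPI if pct is not None else STATUS_ALL_IGNORED
    return CoverageResult(
        image_id=image_id,
        counts=counts,
        coverage_pct=pct,
        area_cm2=area,
        dpi=img.dpi,
        selection_name=sel.name,
        selection_hash=sel.hash(),
        tolerance=sel.tolerance,
        metric=sel.metric,
        status=status,
    )


def selection_ratio(
    img: Raster,
    total_sel: Selection,
    subset_sel: Selection,
    image_id: str = "",
    conflict: str = "nearest",
) -> RatioResult:
    """Classify twice and divide subset coverage by total coverage.

    The two selections must share metric and tolerance (uniformity rule); the
    subset is a fresh sampling, not required to be a structural subset of the
    total selection's channels.
    """
    if total_sel.metric != subset_sel.metric:
        raise SelectionMismatchError(
            f"metric mismatch: total={total_sel.metric!r} "
            f"subset={subset_sel.metric!r}"
        )
    if total_sel.tolerance != subset_sel.tolerance:
        raise SelectionMismatchError(
            f"tolerance mismatch: total={total_sel.tolerance} "
            f"subset={subset_sel.tolerance}"
        )
    _, total_counts = classify_image(img, total_sel, conflict=conflict)
    _, subset_counts = classify_image(img, subset_sel, conflict=conflict)
    total_pct = coverage_percent(total_counts)
    subset_pct = coverage_percent(subset_counts)
    if total_pct is None or subset_pct is None:
        return RatioResult(image_id, total_counts, subset_pct, total_pct,
                           None, STATUS_ALL_IGNORED)
    if total_pct == 0:
        return RatioResult(image_id, total_counts, subset_pct, total_pct,
                           None, STATUS_ZERO_TOTAL)
    ratio = subset_pct / total_pct
    if ratio > 1:
        warnings.warn(
            f"{image_id or 'image'}: subset coverage exceeds total coverage "
            f"(ratio {ratio:.4f}); the subset selection matches pixels the "
            "total selection does not",
            stacklevel=2,
        )
    return RatioResult(image_id, total_counts, subset_pct, total_pct,
                       ratio, STATUS_OK)


def senescence_delta(early: RatioResult, late: RatioResult) -> float | None:
    """Increase of the subset/total ratio between two imaging dates.

    Returns ``late.ratio - early.ratio``; a negative delta is unusual for
    senescence and is flagged with a warning.  Undefined input ratios
    propagate as ``None``.
    """
    if early.ratio is None or late.ratio is None:
        warnings.warn(
            "senescence delta undefined: "
            f"early status={early.status!r}, late status={late.status!r}",
            stacklevel=2,
        )
        return None
    delta = late.ratio - early.ratio
    if delta < 0:
        warnings.warn(
            f"negative senescence delta {delta:.4f} "
            f"({early.image_id} -> {late.image_id})",
            stacklevel=2,
        )
    return delta
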