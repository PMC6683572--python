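"""Include/ignore color-channel selections and their JSON persistence.

A :class:`Selection` bundles up to ``max_channels`` include (foreground)
colors, up to ``max_channels`` ignore colors, a metric and a tolerance.  It is
the unit of uniform application: one selection, one tolerance and one metric
are applied identically to every image of a dataset.

Persistence format (schema version 1) is a small UTF-8 JSON document::

    {"schema_version": 1, "name": "...", "metric": "rgb", "tolerance": 35.0,
     "include": [[r, g, b], ...], "ignore": [[r, g, b], ...]}
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal

from .color_space import METRICS, Color
from .errors import (
    ChannelLimitError,
    RegionBoundsError,
    SelectionFormatError,
    SelectionVersionError,
)

#: Published channel limit; overridable per Selection via ``max_channels``.
MAX_CHANNELS = 10

SCHEMA_VERSION = 1

Role = Literal["include", "ignore"]


@dataclass(frozen=True)
class Selection:
    """A named set of include/ignore channels plus metric and tolerance."""

    name: str
    include: tuple[Color, ...]
    ignore: tuple[Color, ...] = ()
    metric: str = "rgb"
    tolerance: float = 35.0
    max_channels: int = MAX_CHANNELS

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "include", tuple(Color(*c).validate() for c in self.include)
        )
        object.__setattr__(
            self, "ignore", tuple(Color(*c).validate() for c in self.ignore)
        )
        if not 1 <= len(self.include) <= self.max_channels:
            raise SelectionFormatError(
                f"include channel count {len(self.include)} outside "
                f"1..{self.max_channels}"
            )
        if len(self.ignore) > self.max_channels:
            raise SelectionFormatError(
                f"ignore channel count {len(self.ignore)} exceeds "
                f"{self.max_channels}"
            )
        if self.metric not in METRICS:
            raise SelectionFormatError(
                f"unknown metric {self.metric!r}; expected one of {METRICS}"
            )
        if self.tolerance < 0:
            raise SelectionFormatError("tolerance must be >= 0")

    def hash(self) -> str:
        """Stable content hash identifying the selection in batch outputs."""
        doc = _to_doc(self)
        blob = json.dumps(doc, sort_keys=True, separators=(",", ":"))
        return hashlib.sha256(blob.encode("utf-8")).hexdigest()[:12]

    def with_overrides(
        self, tolerance: float | None = None, metric: str | None = None
    ) -> "Selection":
        """Return a copy with CLI-style tolerance/metric overrides applied."""
        sel = self
        if tolerance is not None:
            sel = replace(sel, tolerance=float(tolerance))
        if metric is not None:
            sel = replace(sel, metric=metric)
        return sel


def add_channel(
    sel: Selection | None,
    color: Color,
    role: Role,
    *,
    name: str = "",
    max_channels: int | None = None,
) -> Selection:
    """Append ``color`` to the stated role of ``sel``; other channels unchanged.

    Passing ``sel=None`` starts a fresh selection (the color must then be an
    include channel).  Duplicate colors within one role are accepted with a
    warning: classification is a union over channels, so they cannot change
    results.
    """
    color = Color(*color).validate()
    limit = max_channels if max_channels is not None else (
        sel.max_channels if sel is not None else MAX_CHANNELS
    )
    if role not in ("include", "ignore"):
        raise ValueError(f"role must be 'include' or 'ignore', got {role!r}")
    if sel is None:
        if role != "include":
            raise SelectionFormatError(
                "a selection needs at least one include channel before "
                "ignore channels can be added"
            )
        return Selection(name=name, include=(color,), max_channels=limit)
    existing = getattr(sel, role)
    if len(existing) >= limit:
        raise ChannelLimitError(
            f"{role} list already holds {limit} channels"
        )
    if color in existing:
        warnings.warn(
            f"duplicate {role} channel {tuple(color)} (harmless no-op)",
            stacklevel=2,
        )
    return replace(sel, **{role: existing + (color,), "max_channels": limit})


def sample_pixel(img, x: int, y: int) -> Color:
    """Read back the exact stored color at pixel column ``x``, row ``y``.

    CLI analogue of clicking a shade in the displayed image.
    """
    if not (0 <= x < img.width and 0 <= y < img.height):
        raise RegionBoundsError(
            f"pixel ({x}, {y}) outside image {img.width}x{img.height}"
        )
    px = img.pixels[y, x]
    return Color(int(px[0]), int(px[1]), int(px[2]))


def _to_doc(sel: Selection) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "name": sel.name,
        "metric": sel.metric,
        "tolerance": sel.tolerance,
        "include": [list(c) for c in sel.include],
        "ignore": [list(c) for c in sel.ignore],
    }


def save_selection(sel: Selection, path) -> None:
    """Write a selection as UTF-8 JSON (schema version 1)."""
    Path(path).write_text(
        json.dumps(_to_doc(sel), indent=2) + "\n", encoding="utf-8"
    )


def load_selection(path, *, max_channels: int | None = None) -> Selection:
    """Load a selection file; ``load(save(sel))`` reproduces ``sel`` exactly."""
    text = Path(path).read_text(encoding="utf-8")
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise SelectionFormatError(
            f"{path}: not valid JSON (line {exc.lineno}, col {exc.colno}): "
            f"{exc.msg}"
        ) from exc
    if not isinstance(doc, dict):
        raise SelectionFormatError(f"{path}: expected a JSON object")
    version = doc.get("schema_version")
    if version != SCHEMA_VERSION:
        raise SelectionVersionError(
            f"{path}: unknown schema_version {version!r} "
            f"(this build reads version {SCHEMA_VERSION})"
        )
    for fld in ("name", "metric", "tolerance", "include"):
        if fld not in doc:
            raise SelectionFormatError(f"{path}: missing field {fld!r}")
    try:
        include = tuple(Color(*c) for c in doc["include"])
        ignore = tuple(Color(*c) for c in doc.get("ignore", []))
    except (TypeError, ValueError) as exc:
        raise SelectionFormatError(
            f"{path}: malformed channel entry: {exc}"
        ) from exc
    try:
        return Selection(
            name=str(doc["name"]),
            include=include,
            ignore=ignore,
            metric=doc["metric"],
            tolerance=float(doc["tolerance"]),
            max_channels=max_channels if max_channels is not None else MAX_CHANNELS,
        )
    except SelectionFormatError as exc:
        raise SelectionFormatError(f"{path}: {exc}") from exc
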