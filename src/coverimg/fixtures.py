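"""Synthetic raster generators with exact ground-truth labels.

Every generator returns a ``(Raster, FixtureTruth)`` pair: the truth records
the exact per-class pixel counts at construction time, the recommended
selection (include/ignore colors, metric, calibrated tolerance) and, where a
DPI is set, the implied physical areas.  Class palettes are spaced far apart
in RGB (>= ~120 for the main classes) so that typical tolerances sit safely
between the noise and confusion regimes, while the canopy fixture carries a
deliberate near-miss "speckle" soil tone that only enters the foreground at
clearly-too-high tolerances — reproducing the familiar under/over-segmentation
behavior of tolerance sweeps.

Determinism contract: identical parameters + seed produce byte-identical
images.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import product

import numpy as np

from .color_space import Color, rgb_distance_sq
from .raster_io import Raster
from .selection import Selection

# ---------------------------------------------------------------------------
# Palettes (module constants so tests and the CLI can reference them)

WHITE = Color(255, 255, 255)
PINK = Color(240, 130, 170)          # non-plant blanking color
BLACK_BG = Color(20, 20, 25)         # root-scan background
CAL_INK = Color(60, 60, 72)          # calibration-pattern ink
GREEN = Color(52, 130, 60)           # healthy canopy / leaf
YELLOW_BROWN = Color(180, 150, 45)   # senescent tissue
SOIL = Color(170, 110, 75)           # bare soil
SOIL_SPECKLE = Color(80, 118, 70)    # greenish soil tone, near-miss to GREEN
NET_WHITE = Color(250, 250, 250)     # netting / white plot label
NET_ORANGE = Color(235, 145, 40)     # orange netting
LABEL_BLACK = Color(15, 15, 15)      # plot-number paint

_BACKGROUNDS = {"white": WHITE, "pink": PINK, "black": BLACK_BG}


@dataclass(frozen=True)
class FixtureTruth:
    """Exact per-class pixel counts plus the fixture's recommended selection."""

    kind: str
    width: int
    height: int
    dpi: float | None
    counts: dict[str, int]
    include_colors: tuple[Color, ...]
    ignore_colors: tuple[Color, ...]
    tolerance: float
    metric: str = "rgb"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        total = sum(self.counts.values())
        if total != self.width * self.height:
            raise ValueError(
                f"truth counts sum {total} != {self.width * self.height} pixels"
            )

    def selection(self, name: str | None = None) -> Selection:
        """The selection the fixture was calibrated for."""
        return Selection(
            name=name or f"{self.kind}-truth",
            include=self.include_colors,
            ignore=self.ignore_colors,
            metric=self.metric,
            tolerance=self.tolerance,
        )

    def subset_selection(self, name: str | None = None) -> Selection:
        """Subset selection (e.g. senescent shades only) for ratio fixtures."""
        subset = self.meta.get("subset_include")
        if not subset:
            raise ValueError(f"{self.kind} fixture defines no subset selection")
        return Selection(
            name=name or f"{self.kind}-subset",
            include=tuple(Color(*c) for c in subset),
            ignore=self.ignore_colors,
            metric=self.metric,
            tolerance=self.tolerance,
        )

    def to_doc(self) -> dict:
        return {
            "kind": self.kind,
            "width": self.width,
            "height": self.height,
            "dpi": self.dpi,
            "counts": dict(self.counts),
            "include_colors": [list(c) for c in self.include_colors],
            "ignore_colors": [list(c) for c in self.ignore_colors],
            "tolerance": self.tolerance,
            "metric": self.metric,
            "meta": {
                k: ([list(c) for c in v] if k == "subset_include" else v)
                for k, v in self.meta.items()
            },
        }


# ---------------------------------------------------------------------------
# Internals


def _px_per_cm(dpi: float) -> float:
    return dpi / 2.54


def _grow_blob(
    rng: np.random.Generator, allowed: np.ndarray, target: int
) -> np.ndarray:
    """Randomly grown connected region(s) of exactly ``target`` pixels.

    Growth restarts in a fresh allowed component if the current one fills up,
    so fragmented masks (e.g. soil between netting stripes) still reach the
    target.  Counts are exact by construction — no morphology involved.
    """
    h, w = allowed.shape
    capacity = int(allowed.sum())
    if target > capacity:
        raise ValueError(f"target {target} exceeds allowed area {capacity}")
    region = np.zeros((h, w), dtype=bool)
    count = 0
    while count < target:
        free = np.flatnonzero(allowed & ~region)
        start = int(free[rng.integers(len(free))])
        frontier = [(start // w, start % w)]
        while count < target and frontier:
            j = int(rng.integers(len(frontier)))
            frontier[j], frontier[-1] = frontier[-1], frontier[j]
            y, x = frontier.pop()
            if region[y, x] or not allowed[y, x]:
                continue
            region[y, x] = True
            count += 1
            if y > 0:
                frontier.append((y - 1, x))
            if y < h - 1:
                frontier.append((y + 1, x))
            if x > 0:
                frontier.append((y, x - 1))
            if x < w - 1:
                frontier.append((y, x + 1))
    return region


def _brightness_jitter(
    rng: np.random.Generator, base: Color, count: int, amp: int, chan_amp: int = 1
) -> np.ndarray:
    """Noisy samples of ``base``: shared brightness shift +- small chroma shift.

    A shared per-pixel shift d on all three channels moves the color along the
    gray axis — heavily penalized by the RGB measure (3 d²) but nearly free
    under YCbCr (d² / 9) since the BT.601 chroma coefficients sum to zero.
    """
    d = rng.integers(-amp, amp + 1, size=(count, 1))
    e = rng.integers(-chan_amp, chan_amp + 1, size=(count, 3))
    vals = np.asarray(base, dtype=np.int64) + d + e
    return np.clip(vals, 0, 255).astype(np.uint8)


def _min_jitter_dist(base: Color, ref: Color, amp: int, chan_amp: int = 1) -> float:
    """Exact minimum RGB distance from a jittered ``base`` pixel to ``ref``."""
    v = np.asarray(base, dtype=np.int64) - np.asarray(ref, dtype=np.int64)
    best = math.inf
    for d in range(-amp, amp + 1):
        for e in product(range(-chan_amp, chan_amp + 1), repeat=3):
            w = v + d + np.asarray(e)
            best = min(best, float(np.dot(w, w)))
    return math.sqrt(best)


def _max_jitter_dist(amp: int, chan_amp: int = 1) -> float:
    return math.sqrt(3) * (amp + chan_amp)


def _assert_truth_faithful(
    tolerance: float, fg_max_dist: float, other_min_dist: float
) -> None:
    # Guard rail evaluated at generation time: at the calibrated tolerance
    # every noisy foreground pixel stays inside its own channel's ball and
    # every other class stays outside all include channels.
    if not fg_max_dist < tolerance:
        raise AssertionError(
            f"noise reach {fg_max_dist:.1f} >= tolerance {tolerance}; "
            "ground truth would be ill-defined"
        )
    if not tolerance < other_min_dist:
        raise AssertionError(
            f"tolerance {tolerance} >= nearest confusable class at "
            f"{other_min_dist:.1f}; ground truth would be ill-defined"
        )


# ---------------------------------------------------------------------------
# Generators


def make_calibration_grid(
    dpi: float = 254.0,
    count: int = 2,
    side_cm: float = 0.5,
    seed: int = 0,
) -> tuple[Raster, FixtureTruth]:
    """A white sheet carrying a ``count x count`` array of dark squares.

    Square side in pixels is ``round(side_cm * dpi / 2.54)``; the truth
    records the exact dark-pixel count and the intended physical area.  At
    254 DPI a 0.5 cm square is exactly 50 px, so a 2x2 array covers 1 cm²
    with no quantization error at all.
    """
    del seed  # deterministic pattern; accepted for interface uniformity
    if count < 1:
        raise ValueError("count must be >= 1")
    side_px = round(side_cm * _px_per_cm(dpi))
    if side_px < 1:
        raise ValueError(
            f"{side_cm} cm squares are sub-pixel at {dpi} DPI"
        )
    gap_px = max(side_px // 2, 1)
    margin = side_px
    extent = 2 * margin + count * side_px + (count - 1) * gap_px
    pixels = np.full((extent, extent, 3), WHITE, dtype=np.uint8)
    for row in range(count):
        for col in range(count):
            y0 = margin + row * (side_px + gap_px)
            x0 = margin + col * (side_px + gap_px)
            pixels[y0 : y0 + side_px, x0 : x0 + side_px] = CAL_INK
    dark = count * count * side_px * side_px
    tolerance = 35.0
    _assert_truth_faithful(
        tolerance,
        fg_max_dist=0.0,
        other_min_dist=math.sqrt(rgb_distance_sq(CAL_INK, WHITE)),
    )
    truth = FixtureTruth(
        kind="calibration_grid",
        width=extent,
        height=extent,
        dpi=dpi,
        counts={"foreground": dark, "background": extent * extent - dark},
        include_colors=(CAL_INK,),
        ignore_colors=(WHITE,),
        tolerance=tolerance,
        meta={
            "side_px": side_px,
            "intended_area_cm2": count * count * side_cm * side_cm,
            "area_cm2_from_counts": dark / _px_per_cm(dpi) ** 2,
        },
    )
    return Raster(pixels=pixels, dpi=dpi), truth


def make_complex_calibration(
    dpi: float = 254.0,
    target_cm2: float = 4.0,
    seed: int = 0,
) -> tuple[Raster, FixtureTruth]:
    """A randomly grown non-convex object of a known area on a white sheet.

    The dark-pixel count is exactly ``round(target_cm2 * (dpi/2.54)**2)``;
    the silhouette varies with the seed, the count never does.
    """
    n_px = round(target_cm2 * _px_per_cm(dpi) ** 2)
    if n_px < 1:
        raise ValueError(
            f"target {target_cm2} cm² is below one pixel at {dpi} DPI"
        )
    extent = max(int(math.ceil(math.sqrt(n_px / 0.35))), 8)
    rng = np.random.default_rng(seed)
    allowed = np.ones((extent, extent), dtype=bool)
    region = _grow_blob(rng, allowed, n_px)
    pixels = np.full((extent, extent, 3), WHITE, dtype=np.uint8)
    pixels[region] = CAL_INK
    tolerance = 35.0
    _assert_truth_faithful(
        tolerance,
        fg_max_dist=0.0,
        other_min_dist=math.sqrt(rgb_distance_sq(CAL_INK, WHITE)),
    )
    truth = FixtureTruth(
        kind="complex_calibration",
        width=extent,
        height=extent,
        dpi=dpi,
        counts={"foreground": n_px, "background": extent * extent - n_px},
        include_colors=(CAL_INK,),
        ignore_colors=(WHITE,),
        tolerance=tolerance,
        meta={
            "target_cm2": target_cm2,
            "area_cm2_from_counts": n_px / _px_per_cm(dpi) ** 2,
        },
    )
    return Raster(pixels=pixels, dpi=dpi), truth


def make_two_phase_plant(
    green_fraction: float = 0.5,
    pixel_budget: int = 10000,
    noise: int = 6,
    seed: int = 0,
    background: str = "pink",
    size: tuple[int, int] | None = None,
    dpi: float | None = None,
) -> tuple[Raster, FixtureTruth]:
    """A plant-shaped blob split into green and yellow-brown phases.

    ``round(green_fraction * pixel_budget)`` pixels are green, the remainder
    yellow-brown (any rounding remainder lands in the yellow-brown phase and
    is visible in the truth counts).  The background color is sampled as the
    ignore channel, so total coverage is measured against plant pixels only
    and the subset/total ratio recovers ``1 - green_fraction``.
    """
    if not 0 <= green_fraction <= 1:
        raise ValueError("green_fraction must be in [0, 1]")
    if pixel_budget < 1:
        raise ValueError("pixel_budget must be >= 1")
    bg = _BACKGROUNDS[background]
    if size is None:
        extent = max(int(math.ceil(math.sqrt(pixel_budget / 0.35))), 8)
        size = (extent, extent)
    w, h = size
    if pixel_budget > w * h:
        raise ValueError(f"pixel_budget {pixel_budget} exceeds {w}x{h} canvas")
    rng = np.random.default_rng(seed)
    region = _grow_blob(rng, np.ones((h, w), dtype=bool), pixel_budget)
    n_green = round(green_fraction * pixel_budget)
    ys, xs = np.nonzero(region)
    order = rng.permutation(len(ys))
    green_idx = order[:n_green]
    yellow_idx = order[n_green:]

    pixels = np.full((h, w, 3), bg, dtype=np.uint8)
    for base, idx in ((GREEN, green_idx), (YELLOW_BROWN, yellow_idx)):
        if len(idx):
            jitter = rng.integers(-noise, noise + 1, size=(len(idx), 3))
            vals = np.asarray(base, dtype=np.int64) + jitter
            pixels[ys[idx], xs[idx]] = np.clip(vals, 0, 255).astype(np.uint8)

    tolerance = 30.0
    noise_reach = math.sqrt(3) * noise
    other_min = min(
        math.sqrt(rgb_distance_sq(GREEN, YELLOW_BROWN)) - noise_reach,
        math.sqrt(rgb_distance_sq(bg, GREEN)),
        math.sqrt(rgb_distance_sq(bg, YELLOW_BROWN)),
    )
    # Phases must not bleed into each other or the background at tolerance.
    _assert_truth_faithful(tolerance, fg_max_dist=noise_reach,
                           other_min_dist=other_min)
    n_yellow = pixel_budget - n_green
    truth = FixtureTruth(
        kind="two_phase_plant",
        width=w,
        height=h,
        dpi=dpi,
        counts={
            "green": n_green,
            "yellow_brown": n_yellow,
            "ignored": w * h - pixel_budget,
        },
        include_colors=(GREEN, YELLOW_BROWN),
        ignore_colors=(bg,),
        tolerance=tolerance,
        meta={
            "subset_include": [list(YELLOW_BROWN)],
            "green_fraction": green_fraction,
            "ratio_yellow_to_total": n_yellow / pixel_budget,
        },
    )
    return Raster(pixels=pixels, dpi=dpi), truth


def make_canopy_plot(
    cover_fraction: float = 0.3,
    artifacts: tuple[str, ...] = ("netting", "label"),
    noise: int = 10,
    seed: int = 0,
    size: tuple[int, int] = (400, 300),
    speckle_fraction: float = 0.15,
) -> tuple[Raster, FixtureTruth]:
    """Green canopy over soil, with optional netting stripes and plot labels.

    Canopy occupies exactly ``round(cover_fraction * non_artifact_pixels)``
    pixels.  Soil carries a minority greenish "speckle" tone whose distance to
    the canopy channel sits just above the calibrated tolerance: invisible at
    the calibrated setting, progressively swallowed as tolerance grows —
    which is what makes over-segmentation observable in tolerance sweeps.
    Canopy noise is mostly a shared brightness shift, so low tolerances
    under-segment far more under RGB than under YCbCr.
    """
    if not 0 <= cover_fraction <= 1:
        raise ValueError("cover_fraction must be in [0, 1]")
    unknown = set(artifacts) - {"netting", "label"}
    if unknown:
        raise ValueError(f"unknown artifacts {sorted(unknown)}")
    w, h = size
    rng = np.random.default_rng(seed)
    pixels = np.empty((h, w, 3), dtype=np.uint8)

    artifact = np.zeros((h, w), dtype=np.uint8)  # 0 none, 1 white, 2 orange, 3 black
    if "netting" in artifacts:
        stripe = max(w // 70, 3)
        for x0, code in ((w // 6, 1), ((2 * w) // 3, 2)):
            artifact[:, x0 : x0 + stripe] = code
        for y0, code in ((h // 3, 1), ((4 * h) // 5, 2)):
            artifact[y0 : y0 + stripe, :] = code
    if "label" in artifacts:
        lw, lh = max(w // 12, 8), max(h // 18, 6)
        artifact[4 : 4 + lh, 4 : 4 + lw] = 3
        artifact[4 : 4 + lh, 4 + lw : 4 + 2 * lw] = 1

    non_artifact = artifact == 0
    n_free = int(non_artifact.sum())
    canopy_target = round(cover_fraction * n_free)
    canopy = (
        _grow_blob(rng, non_artifact, canopy_target)
        if canopy_target
        else np.zeros((h, w), dtype=bool)
    )
    soil = non_artifact & ~canopy
    soil_flat = np.flatnonzero(soil)
    n_speckle = round(speckle_fraction * len(soil_flat))
    speckle_flat = rng.choice(soil_flat, size=n_speckle, replace=False)
    speckle = np.zeros(h * w, dtype=bool)
    speckle[speckle_flat] = True
    speckle = speckle.reshape(h, w)
    plain_soil = soil & ~speckle

    pixels[artifact == 1] = NET_WHITE
    pixels[artifact == 2] = NET_ORANGE
    pixels[artifact == 3] = LABEL_BLACK
    for base, mask_cls, amp, chan_amp in (
        (GREEN, canopy, noise, 1),
        (SOIL_SPECKLE, speckle, noise, 1),
        (SOIL, plain_soil, 3, 0),
    ):
        cnt = int(mask_cls.sum())
        if cnt:
            pixels[mask_cls] = _brightness_jitter(rng, base, cnt, amp, chan_amp)

    tolerance = 25.0
    fg_reach = _max_jitter_dist(noise, 1)
    speckle_min = _min_jitter_dist(SOIL_SPECKLE, GREEN, noise, 1)
    soil_min = math.sqrt(rgb_distance_sq(SOIL, GREEN)) - _max_jitter_dist(3, 0)
    _assert_truth_faithful(
        tolerance, fg_max_dist=fg_reach, other_min_dist=min(speckle_min, soil_min)
    )

    counts = {
        "canopy": int(canopy.sum()),
        "soil": int(plain_soil.sum()),
        "soil_speckle": int(speckle.sum()),
        "net_white": int((artifact == 1).sum()),
        "net_orange": int((artifact == 2).sum()),
        "label_black": int((artifact == 3).sum()),
    }
    n_ignored = counts["net_white"] + counts["net_orange"] + counts["label_black"]
    n = w * h
    truth = FixtureTruth(
        kind="canopy_plot",
        width=w,
        height=h,
        dpi=None,
        counts=counts,
        include_colors=(GREEN,),
        ignore_colors=(NET_WHITE, NET_ORANGE, LABEL_BLACK),
        tolerance=tolerance,
        meta={
            "cover_fraction": cover_fraction,
            "truth_coverage_pct": (
                counts["canopy"] * 100.0 / (n - n_ignored) if n > n_ignored else None
            ),
            "noise": noise,
        },
    )
    return Raster(pixels=pixels), truth
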