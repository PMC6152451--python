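"""Choropleth map agreement auditing.

Two published choropleth maps of the same regions (e.g. observed vs
model-predicted county mortality) are compared by recovering each region's
ordinal color-scale interval from its pixels, differencing the intervals,
and classifying the per-region discrepancy:

* green  — 0–2 scale intervals apart,
* yellow — 3–5 intervals,
* red    — 6 or more intervals.

On an equal-width m-color scale each interval spans ``100/m`` percentile
ranks, so under uniformly distributed rounding error a difference of
``delta`` intervals corresponds to an expected absolute percentile-rank
difference of ``delta * 100/m`` percentage points (for m=14 one interval is
a "quattuordecile", about 7.14 points).  The summary's mean discrepancy
among delta >= 3 regions uses the conservative lower-bound convention:
"three (six) or more" is scored as exactly three (six).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from PIL import Image

from .core_io import ValidationError, get_logger

log = get_logger("countylex.map_discrepancy")

__all__ = [
    "ColorScale",
    "RegionColorMap",
    "RegionDelta",
    "DiscrepancyReport",
    "CLASS_BOUNDS",
    "DEFAULT_SCALE_14",
    "color_to_interval",
    "extract_region_colors",
    "classify",
    "expected_mean_difference",
    "compare_maps",
    "summarize",
    "render_region_map",
    "render_difference_map",
    "make_tile_masks",
]

RGB = tuple[int, int, int]

#: Discrepancy classes as (low, high) interval-difference bounds; high=None
#: means unbounded above.
CLASS_BOUNDS: dict[str, tuple[int, int | None]] = {
    "green": (0, 2),
    "yellow": (3, 5),
    "red": (6, None),
}

#: Default snapping tolerance (Euclidean RGB units) for colors that are not
#: an exact scale match (anti-aliasing, JPEG noise).
DEFAULT_TOLERANCE = 30.0

_DIFF_COLORS: dict[str, RGB] = {
    "green": (0, 170, 0),
    "yellow": (255, 200, 0),
    "red": (220, 30, 30),
    "nodata": (255, 255, 255),
}


@dataclass(frozen=True)
class ColorScale:
    """Ordered color legend: position i (1-based) encodes ordinal interval i."""

    colors: tuple[RGB, ...]
    background: frozenset[RGB] = frozenset({(255, 255, 255)})

    def __post_init__(self) -> None:
        if len(self.colors) < 2:
            raise ValidationError("color scale needs at least 2 colors")
        if len(set(self.colors)) != len(self.colors):
            raise ValidationError("color scale colors must be distinct")
        object.__setattr__(self, "colors", tuple(tuple(int(v) for v in c) for c in self.colors))
        object.__setattr__(self, "background", frozenset(tuple(int(v) for v in c) for c in self.background))

    @property
    def m(self) -> int:
        return len(self.colors)


def _ramp_scale(m: int = 14) -> ColorScale:
    """Blue-to-red ramp with well-separated colors, used for synthetic maps."""
    t = np.linspace(0.0, 1.0, m)
    colors = tuple(
        (int(round(255 * x)), int(round(80 * (1 - abs(2 * x - 1)))), int(round(255 * (1 - x))))
        for x in t
    )
    return ColorScale(colors=colors)


#: 14-color scale mirroring the quattuordecile legend of the audited maps.
DEFAULT_SCALE_14 = _ramp_scale(14)


@dataclass
class RegionColorMap:
    """Region id -> RGB assignment, optionally with its source raster/masks."""

    colors: dict[str, RGB]
    raster: np.ndarray | None = None
    masks: np.ndarray | None = None

    def regions(self) -> list[str]:
        return sorted(self.colors)


@dataclass(frozen=True)
class RegionDelta:
    """One region's recovered intervals and their classified difference."""

    region: str
    interval_a: int | None
    interval_b: int | None
    delta: int | None
    cls: str


@dataclass
class DiscrepancyReport:
    """Per-region deltas plus a class-count summary over colored regions."""

    regions: list[RegionDelta]
    n_colored: int = 0
    class_counts: dict[str, int] = field(default_factory=dict)
    class_percentages: dict[str, float] = field(default_factory=dict)
    pct_delta_ge_3: float | None = None
    mean_expected_pp: float | None = None
    scale_size: int = 14


# --------------------------------------------------------------------------
# color resolution
# --------------------------------------------------------------------------


def _nearest(color: RGB, candidates: Sequence[RGB]) -> tuple[int, float]:
    arr = np.asarray(candidates, dtype=float)
    d = np.sqrt(((arr - np.asarray(color, dtype=float)) ** 2).sum(axis=1))
    i = int(np.argmin(d))
    return i, float(d[i])


def color_to_interval(
    color: RGB, scale: ColorScale, tolerance: float = DEFAULT_TOLERANCE
) -> int | None:
    """Map a color to its 1-based scale interval, or None for background.

    Exact matches resolve directly; otherwise the nearest scale-or-background
    color within ``tolerance`` RGB units wins.  A color farther than the
    tolerance from everything is an error naming the color and the nearest
    candidates.
    """
    color = tuple(int(v) for v in color)
    if color in scale.background:
        return None
    if color in scale.colors:
        return scale.colors.index(color) + 1
    candidates = list(scale.colors) + sorted(scale.background)
    i, dist = _nearest(color, candidates)
    if dist > tolerance:
        raise ValidationError(
            f"color {color} is {dist:.1f} RGB units from the nearest scale "
            f"color {candidates[i]} (tolerance {tolerance})"
        )
    return None if i >= scale.m else i + 1


def extract_region_colors(
    raster: np.ndarray | Image.Image | str | Path,
    masks: np.ndarray,
    scale: ColorScale,
    tolerance: float = DEFAULT_TOLERANCE,
) -> RegionColorMap:
    """Recover each region's color as the modal snapped pixel color.

    ``masks`` is an integer label array (0 = unlabeled) aligned with the
    raster; every pixel is first snapped to its nearest scale-or-background
    color.  Regions whose pixels are all background are marked no-data; a tie
    in the modal color goes to the lower interval (logged).
    """
    if isinstance(raster, (str, Path)):
        raster = Image.open(raster)
    if isinstance(raster, Image.Image):
        raster = np.asarray(raster.convert("RGB"))
    if raster.shape[:2] != masks.shape:
        raise ValidationError(
            f"raster {raster.shape[:2]} and masks {masks.shape} differ in size"
        )
    palette = np.asarray(list(scale.colors) + sorted(scale.background), dtype=float)
    pixels = raster.reshape(-1, 3).astype(float)
    # snap every pixel to the nearest palette entry
    d2 = ((pixels[:, None, :] - palette[None, :, :]) ** 2).sum(axis=2)
    snapped = np.argmin(d2, axis=1).reshape(masks.shape)

    colors: dict[str, RGB] = {}
    background_start = scale.m
    for label in np.unique(masks):
        if label == 0:
            continue
        region = f"r{int(label):04d}"
        vals = snapped[masks == label]
        counts = Counter(vals.tolist())
        best = max(counts.values())
        tied = sorted(k for k, v in counts.items() if v == best)
        if len(tied) > 1:
            log.info("region %s: modal color tie, taking lower interval", region)
        choice = tied[0]
        if choice >= background_start:
            colors[region] = tuple(int(v) for v in palette[choice])
        else:
            colors[region] = scale.colors[choice]
    return RegionColorMap(colors=colors, raster=raster, masks=masks)


# --------------------------------------------------------------------------
# discrepancy classification and summary
# --------------------------------------------------------------------------


def classify(delta: int) -> str:
    """Class of an interval difference: green 0–2, yellow 3–5, red >= 6."""
    if delta < 0 or int(delta) != delta:
        raise ValidationError(f"delta must be a nonnegative integer, got {delta}")
    if delta <= 2:
        return "green"
    if delta <= 5:
        return "yellow"
    return "red"


def expected_mean_difference(delta: int, m: int) -> float:
    """Expected |percentile-rank difference| for a delta-interval gap.

    On an equal-width m-interval scale with uniformly distributed rounding
    error, two regions delta intervals apart differ by ``delta * 100/m``
    percentage points in expectation.
    """
    if m < 2:
        raise ValidationError("scale must have at least 2 intervals")
    if not 0 <= delta <= m - 1:
        raise ValidationError(f"delta must be in [0, {m - 1}], got {delta}")
    return delta * 100.0 / m


def compare_maps(
    map_a: RegionColorMap,
    map_b: RegionColorMap,
    scale: ColorScale,
    tolerance: float = DEFAULT_TOLERANCE,
    paper_rounding: bool = True,
) -> DiscrepancyReport:
    """Per-region interval differences between two maps, classified and summarized."""
    common = sorted(set(map_a.colors) & set(map_b.colors))
    dropped = (set(map_a.colors) | set(map_b.colors)) - set(common)
    if dropped:
        log.info("compare_maps: %d region(s) present in only one map", len(dropped))
    deltas: list[RegionDelta] = []
    for rid in common:
        ia = color_to_interval(map_a.colors[rid], scale, tolerance)
        ib = color_to_interval(map_b.colors[rid], scale, tolerance)
        if ia is None or ib is None:
            deltas.append(RegionDelta(rid, ia, ib, None, "nodata"))
        else:
            d = abs(ia - ib)
            deltas.append(RegionDelta(rid, ia, ib, d, classify(d)))
    report = DiscrepancyReport(regions=deltas, scale_size=scale.m)
    summarize(report, paper_rounding=paper_rounding)
    return report


def summarize(
    report: DiscrepancyReport, paper_rounding: bool = True
) -> DiscrepancyReport:
    """Fill class counts/percentages and the conservative mean discrepancy.

    The mean expected percentage-point discrepancy among delta >= 3 regions
    treats every yellow region as exactly 3 intervals apart and every red
    region as exactly 6 (a deliberate lower bound).  With ``paper_rounding``
    the class values are rounded to 1 decimal first and the red value is
    twice the rounded yellow value (so 21.4 and 42.8 on a 14-color scale);
    otherwise exact widths are used.
    """
    m = report.scale_size
    colored = [r for r in report.regions if r.cls != "nodata"]
    if not colored:
        raise ValidationError("no colored regions to summarize")
    counts = {cls: 0 for cls in CLASS_BOUNDS}
    for r in colored:
        counts[r.cls] += 1
    n = len(colored)
    report.n_colored = n
    report.class_counts = counts
    report.class_percentages = {c: 100.0 * k / n for c, k in counts.items()}
    n_ge3 = counts["yellow"] + counts["red"]
    report.pct_delta_ge_3 = 100.0 * n_ge3 / n
    if n_ge3 == 0:
        report.mean_expected_pp = None
        log.info("summarize: no regions at delta >= 3; mean discrepancy undefined")
    else:
        if paper_rounding:
            v3 = round(expected_mean_difference(3, m), 1)
            v6 = round(2 * v3, 1)
        else:
            v3 = expected_mean_difference(3, m)
            v6 = expected_mean_difference(6, m)
        report.mean_expected_pp = (
            counts["yellow"] * v3 + counts["red"] * v6
        ) / n_ge3
    log.info(
        "summarize: mode=%s, n=%d, counts=%s",
        "paper-rounded" if paper_rounding else "exact-widths",
        n,
        counts,
    )
    return report


# --------------------------------------------------------------------------
# rasterization
# --------------------------------------------------------------------------


def make_tile_masks(n_regions: int, tile: int = 8, ncols: int | None = None) -> np.ndarray:
    """Label raster of rectangular tiles: region i -> label i+1, row-major."""
    if ncols is None:
        ncols = int(np.ceil(np.sqrt(n_regions)))
    nrows = int(np.ceil(n_regions / ncols))
    masks = np.zeros((nrows * tile, ncols * tile), dtype=np.int32)
    for i in range(n_regions):
        r, c = divmod(i, ncols)
        masks[r * tile : (r + 1) * tile, c * tile : (c + 1) * tile] = i + 1
    return masks


def render_region_map(
    colormap: RegionColorMap, masks: np.ndarray, background: RGB = (255, 255, 255)
) -> np.ndarray:
    """Paint a region->color assignment onto a label raster (H x W x 3 uint8)."""
    out = np.empty((*masks.shape, 3), dtype=np.uint8)
    out[:] = background
    for label in np.unique(masks):
        if label == 0:
            continue
        rid = f"r{int(label):04d}"
        if rid in colormap.colors:
            out[masks == label] = colormap.colors[rid]
    return out


def render_difference_map(report: DiscrepancyReport, masks: np.ndarray) -> np.ndarray:
    """Three-class (green/yellow/red, white no-data) raster of a report."""
    cls_by_region = {r.region: r.cls for r in report.regions}
    cmap = RegionColorMap(
        colors={rid: _DIFF_COLORS[cls] for rid, cls in cls_by_region.items()}
    )
    return render_region_map(cmap, masks, background=_DIFF_COLORS["nodata"])


def save_png(raster: np.ndarray, path: str | Path) -> None:
    Image.fromarray(raster.astype(np.uint8), mode="RGB").save(path)
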