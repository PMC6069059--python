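"""Socially weighted kernel density estimation.

Where do the people an intervention cares about actually go? Every place p
in the location space becomes a point event whose mass

    M_p = Σ_i HS_i · V_ip

is the expected daily visitation weighted by each visitor's health measure
HS_i (social isolation as-is, or an inverted well-being score). A quartic
kernel of bandwidth τ,

    k(d) = 3/(πτ²) · (1 − d²/τ²)²   for d < τ,   0 otherwise,

spreads each mass over its neighbourhood, and the density surface on a
regular grid is

    λ̂(s) = Σ_p k(d_sp) · M_p ,

so dark areas are where high-HS (e.g. highly isolated) participants are
likely to visit and cluster — candidate sites for outreach. The kernel
integrates to 1 over its support disk, so the surface integral equals the
total mass away from grid edges (no boundary correction is applied).

Bandwidth defaults to the common geographic-software rule

    τ = 0.9 · min(SD, √(1/ln 2) · D_m) · n^(−1/5)

with SD the (mass-weighted) standard distance of the events about their
weighted mean centre and D_m the weighted median distance to that centre;
an explicit τ can always be passed and is recorded in output metadata.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import ndimage
from shapely.geometry import box, mapping
from shapely.ops import unary_union

from .activity import HOME_CATEGORY, LocationVector
from .errors import ValidationError
from .geo import Point
from .survey import Gazetteer

__all__ = [
    "PointEvent",
    "GridSpec",
    "KDEGrid",
    "HotSpot",
    "quartic_kernel",
    "point_masses",
    "default_bandwidth",
    "make_grid",
    "estimate_density",
    "hotspots",
    "write_esri_ascii",
    "grid_frame",
    "hotspots_geojson",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PointEvent:
    """A place together with its health-weighted visitation mass."""

    place_id: str
    location: Point
    mass: float

    def __post_init__(self) -> None:
        if self.mass < 0:
            raise ValidationError(f"event {self.place_id!r}: negative mass {self.mass}")
        if not all(math.isfinite(c) for c in self.location):
            raise ValidationError(f"event {self.place_id!r}: non-finite location")


def quartic_kernel(d, tau: float):
    """Quartic (biweight) kernel density weight at distance ``d`` for
    bandwidth ``tau``; exactly 0 for d ≥ τ. Accepts scalars or arrays."""
    if tau <= 0:
        raise ValidationError(f"bandwidth tau must be > 0, got {tau}")
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValidationError("distance must be >= 0")
    u = d / tau
    out = np.where(u < 1.0, 3.0 / (math.pi * tau**2) * (1.0 - u**2) ** 2, 0.0)
    return float(out) if out.ndim == 0 else out


def point_masses(
    vectors: Mapping[str, LocationVector],
    hs: Mapping[str, float],
    gazetteer: Gazetteer,
    exclude_home: bool = True,
) -> list[PointEvent]:
    """One event per place with positive mass M_p = Σ_i HS_i·V_ip.

    ``gazetteer`` must be the extended location space the vectors were
    built against (it resolves place ids to coordinates). Participants
    without an HS value are excluded with a warning; home-category places
    are dropped when ``exclude_home`` (density of *non-home* visits)."""
    masses: dict[str, float] = {}
    for pid, vec in vectors.items():
        if not vec.probs:
            continue
        if pid not in hs:
            logger.warning("participant %s: no health measure; excluded from density", pid)
            continue
        h = hs[pid]
        for place_id, v in vec.probs.items():
            masses[place_id] = masses.get(place_id, 0.0) + h * v
    events = []
    for place_id in sorted(masses):
        if masses[place_id] <= 0.0:
            continue
        place = gazetteer[place_id]
        if exclude_home and place.category == HOME_CATEGORY:
            continue
        events.append(PointEvent(place_id, place.location, masses[place_id]))
    return events


def default_bandwidth(events: Sequence[PointEvent]) -> float:
    """Mass-weighted default bandwidth (see module docstring). Requires at
    least two distinct event locations; zero-mass events are ignored."""
    pts = np.array([e.location for e in events if e.mass > 0], dtype=float)
    w = np.array([e.mass for e in events if e.mass > 0], dtype=float)
    if len(pts) == 0 or np.unique(pts, axis=0).shape[0] < 2:
        raise ValidationError(
            "default_bandwidth needs >= 2 distinct event locations; "
            "pass an explicit tau"
        )
    center = (pts * w[:, None]).sum(axis=0) / w.sum()
    dist = np.hypot(pts[:, 0] - center[0], pts[:, 1] - center[1])
    sd = math.sqrt(float((w * dist**2).sum() / w.sum()))
    order = np.argsort(dist)
    cum = np.cumsum(w[order])
    dm = float(dist[order][np.searchsorted(cum, 0.5 * w.sum())])
    n = len(pts)
    tau = 0.9 * min(sd, math.sqrt(1.0 / math.log(2.0)) * dm) * n ** (-0.2)
    if tau <= 0:
        raise ValidationError("degenerate event geometry; pass an explicit tau")
    return tau


@dataclass(frozen=True)
class GridSpec:
    """Regular planar grid: lower-left corner, square cells, counts."""

    origin: Point  # (x, y) of the lower-left corner
    cell_size: float
    ncols: int
    nrows: int

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValidationError(f"cell_size must be > 0, got {self.cell_size}")
        if self.ncols < 1 or self.nrows < 1:
            raise ValidationError("grid must have at least one cell")

    def x_centers(self) -> np.ndarray:
        return self.origin[0] + (np.arange(self.ncols) + 0.5) * self.cell_size

    def y_centers(self) -> np.ndarray:
        return self.origin[1] + (np.arange(self.nrows) + 0.5) * self.cell_size


@dataclass(frozen=True)
class KDEGrid:
    """Density surface: ``values[row, col]`` with row 0 at the *bottom*
    (south); writers flip to the raster top-down convention."""

    spec: GridSpec
    bandwidth: float
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.values.shape != (self.spec.nrows, self.spec.ncols):
            raise ValidationError("values shape does not match grid spec")

    def cell_of(self, point: Point) -> tuple[int, int]:
        col = int((point[0] - self.spec.origin[0]) // self.spec.cell_size)
        row = int((point[1] - self.spec.origin[1]) // self.spec.cell_size)
        return row, col

    def total_mass(self) -> float:
        """Cell-sum × cell-area ≈ Σ M_p when events sit ≥ τ inside the
        boundary (kernel unit integral)."""
        return float(self.values.sum()) * self.spec.cell_size**2


def make_grid(
    events: Sequence[PointEvent],
    tau: float,
    cell_size: float | None = None,
    max_cells_per_axis: int = 500,
) -> GridSpec:
    """Grid covering the event bounding box padded by τ.

    Default cell size is τ/20, coarsened if needed so neither axis exceeds
    ``max_cells_per_axis``; the origin is snapped down to a cell_size
    multiple so rasters are reproducible across runs."""
    if not events:
        raise ValidationError("cannot build a grid with no events")
    if tau <= 0:
        raise ValidationError("tau must be > 0")
    xs = np.array([e.location[0] for e in events])
    ys = np.array([e.location[1] for e in events])
    xmin, xmax = xs.min() - tau, xs.max() + tau
    ymin, ymax = ys.min() - tau, ys.max() + tau
    if cell_size is None:
        cell_size = tau / 20.0
        span = max(xmax - xmin, ymax - ymin)
        if span / cell_size > max_cells_per_axis:
            cell_size = span / max_cells_per_axis
    origin = (
        math.floor(xmin / cell_size) * cell_size,
        math.floor(ymin / cell_size) * cell_size,
    )
    ncols = int(math.ceil((xmax - origin[0]) / cell_size))
    nrows = int(math.ceil((ymax - origin[1]) / cell_size))
    return GridSpec(origin=origin, cell_size=cell_size, ncols=ncols, nrows=nrows)


def estimate_density(
    events: Sequence[PointEvent], grid_spec: GridSpec, tau: float
) -> KDEGrid:
    """λ̂(s) = Σ_p k(d_sp)·M_p at every cell centre.

    The grid must cover the event bounding box padded by τ on every side.
    Cells farther than τ from all events are exactly 0 (compact support)."""
    if tau <= 0:
        raise ValidationError("tau must be > 0")
    xs = grid_spec.x_centers()
    ys = grid_spec.y_centers()
    if events:
        ex = np.array([e.location[0] for e in events])
        ey = np.array([e.location[1] for e in events])
        x0, y0 = grid_spec.origin
        x1 = x0 + grid_spec.ncols * grid_spec.cell_size
        y1 = y0 + grid_spec.nrows * grid_spec.cell_size
        if ex.min() - tau < x0 or ex.max() + tau > x1 or ey.min() - tau < y0 or ey.max() + tau > y1:
            raise ValidationError(
                "grid does not cover the event bounding box padded by tau"
            )
    values = np.zeros((grid_spec.nrows, grid_spec.ncols), dtype=float)
    norm = 3.0 / (math.pi * tau**2)
    for ev in events:
        if ev.mass == 0.0:
            continue
        # only cells within tau of the event can receive weight
        c0 = np.searchsorted(xs, ev.location[0] - tau)
        c1 = np.searchsorted(xs, ev.location[0] + tau, side="right")
        r0 = np.searchsorted(ys, ev.location[1] - tau)
        r1 = np.searchsorted(ys, ev.location[1] + tau, side="right")
        if c0 >= c1 or r0 >= r1:
            continue
        dx = xs[c0:c1] - ev.location[0]
        dy = ys[r0:r1] - ev.location[1]
        d2 = dy[:, None] ** 2 + dx[None, :] ** 2
        u2 = d2 / tau**2
        contrib = np.where(u2 < 1.0, norm * (1.0 - u2) ** 2, 0.0)
        values[r0:r1, c0:c1] += ev.mass * contrib
    return KDEGrid(spec=grid_spec, bandwidth=tau, values=values)


# ---------------------------------------------------------------------------
# hotspots


@dataclass(frozen=True)
class HotSpot:
    """Connected high-density region, ranked by its peak density."""

    rank: int
    peak_value: float
    peak_cell: tuple[int, int]  # (row, col)
    cells: tuple[tuple[int, int], ...]
    threshold: float

    def contains_cell(self, cell: tuple[int, int]) -> bool:
        return tuple(cell) in set(self.cells)


def hotspots(grid: KDEGrid, quantile: float = 0.9) -> list[HotSpot]:
    """Connected components (8-neighbour) of cells whose density is at or
    above the given quantile of the *positive* cells, ranked by peak
    density descending. All-zero grid → empty list."""
    if not (0.0 < quantile < 1.0):
        raise ValidationError(f"quantile must be in (0, 1), got {quantile}")
    positive = grid.values[grid.values > 0]
    if positive.size == 0:
        return []
    threshold = float(np.quantile(positive, quantile))
    mask = grid.values >= threshold
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    spots = []
    for lab in range(1, n + 1):
        cells = np.argwhere(labels == lab)
        vals = grid.values[labels == lab]
        peak_idx = int(np.argmax(vals))
        spots.append(
            (
                float(vals[peak_idx]),
                tuple(int(c) for c in cells[peak_idx]),
                tuple(tuple(int(c) for c in rc) for rc in cells),
            )
        )
    spots.sort(key=lambda t: (-t[0], t[1]))
    return [
        HotSpot(rank=r + 1, peak_value=pv, peak_cell=pc, cells=cells, threshold=threshold)
        for r, (pv, pc, cells) in enumerate(spots)
    ]


# ---------------------------------------------------------------------------
# output formats


def write_esri_ascii(grid: KDEGrid, path: str | Path, nodata: float = -9999.0) -> None:
    """ESRI ASCII raster (.asc): 6-line header then rows north→south."""
    spec = grid.spec
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"ncols {spec.ncols}\n")
        fh.write(f"nrows {spec.nrows}\n")
        fh.write(f"xllcorner {spec.origin[0]:.6f}\n")
        fh.write(f"yllcorner {spec.origin[1]:.6f}\n")
        fh.write(f"cellsize {spec.cell_size:.6f}\n")
        fh.write(f"NODATA_value {nodata:g}\n")
        for row in grid.values[::-1]:  # top-down
            fh.write(" ".join(f"{v:.10g}" for v in row))
            fh.write("\n")


def grid_frame(grid: KDEGrid):
    """Cell centres and densities as a DataFrame (x, y, density)."""
    import pandas as pd

    xs = grid.spec.x_centers()
    ys = grid.spec.y_centers()
    xx, yy = np.meshgrid(xs, ys)
    return pd.DataFrame(
        {"x": xx.ravel(), "y": yy.ravel(), "density": grid.values.ravel()}
    )


def _spot_polygon(grid: KDEGrid, spot: HotSpot):
    spec = grid.spec
    boxes = [
        box(
            spec.origin[0] + c * spec.cell_size,
            spec.origin[1] + r * spec.cell_size,
            spec.origin[0] + (c + 1) * spec.cell_size,
            spec.origin[1] + (r + 1) * spec.cell_size,
        )
        for r, c in spot.cells
    ]
    return unary_union(boxes)


def hotspots_geojson(
    grid: KDEGrid, spots: Sequence[HotSpot], path: str | Path | None = None
) -> dict:
    """Hotspot regions as a GeoJSON FeatureCollection of polygons with
    rank and peak density properties; optionally written to ``path``."""
    features = []
    for spot in spots:
        geom = _spot_polygon(grid, spot)
        features.append(
            {
                "type": "Feature",
                "geometry": mapping(geom),
                "properties": {
                    "rank": spot.rank,
                    "peak_density": spot.peak_value,
                    "threshold": spot.threshold,
                    "n_cells": len(spot.cells),
                },
            }
        )
    fc = {"type": "FeatureCollection", "features": features}
    if path is not None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(fc, fh, indent=1, sort_keys=True)
            fh.write("\n")
    return fc
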