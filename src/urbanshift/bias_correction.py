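"""Sampling-bias correction: spatial thinning and restricted backgrounds.

Community-science archives oversample accessible places. Two corrections are
applied before fitting: (i) spatial thinning, keeping at most one record per
coarse grid cell (25 km by default, five times the climate resolution), and
(ii) restricting the background (pseudo-absence) sample to a buffered convex
hull of the thinned presences intersected with land, so the background
describes the climate actually available to the species rather than the
whole continent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely import contains_xy as _shp_contains
from shapely.geometry import MultiPoint, Point, box

from .grids import ClimateStack


@dataclass
class BackgroundSet:
    """Background (pseudo-absence) points plus the restriction geometry."""

    points: pd.DataFrame  # columns x, y
    restriction_polygon: object  # shapely geometry

    @property
    def n(self) -> int:
        return len(self.points)


def thin(
    records: pd.DataFrame,
    stack: ClimateStack,
    cell_size_km: float = 25.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Keep at most one record per coarse cell, chosen uniformly at random.

    Thinning cells are half-open squares anchored at the climate-lattice
    origin. The survivor within each occupied cell is drawn with the given
    seed (not "first record"), so results do not depend on upstream row
    order beyond the seeded draw.
    """
    if records.empty:
        return records.copy()
    rng = np.random.default_rng(seed)
    x = records["x"].to_numpy(dtype=float)
    y = records["y"].to_numpy(dtype=float)
    col = np.floor((x - stack.origin[0]) / cell_size_km).astype(int)
    row = np.floor((y - stack.origin[1]) / cell_size_km).astype(int)
    df = records.reset_index(drop=True)
    keep = []
    groups = df.groupby([row, col], sort=True).indices
    for key in sorted(groups):
        idx = np.sort(groups[key])
        keep.append(idx[rng.integers(0, len(idx))])
    return df.loc[sorted(keep)].reset_index(drop=True)


def make_background(
    presences: pd.DataFrame,
    stack: ClimateStack,
    n_bg: int = 10_000,
    buffer_km: float = 100.0,
    seed: int = 0,
    species_id: str | None = None,
) -> BackgroundSet:
    """Sample background points uniformly over land inside the restriction.

    The restriction polygon is the convex hull of the presences buffered by
    ``buffer_km`` (a bounding box fallback when fewer than 3 distinct
    non-collinear presences exist), intersected with land cells. Points are
    placed at the centers of eligible cells, drawn uniformly with
    replacement, so presences may coincide with background (this is a
    presence-background design, not presence-absence).
    """
    rng = np.random.default_rng(seed)
    pts = presences[["x", "y"]].to_numpy(dtype=float)
    hull = MultiPoint([Point(p) for p in pts]).convex_hull
    if hull.area == 0:  # <3 points or collinear -> bounding-box fallback
        x0, y0 = pts.min(axis=0)
        x1, y1 = pts.max(axis=0)
        hull = box(x0, y0, x1, y1)
    poly = hull.buffer(buffer_km)

    xg, yg = stack.cell_centers()
    eligible = stack.land_mask & _shp_contains(poly, xg, yg)
    rows, cols = np.where(eligible)
    if rows.size == 0:
        who = f" for species {species_id}" if species_id else ""
        raise ValueError(f"background restriction contains zero land cells{who}")
    pick = rng.integers(0, rows.size, size=n_bg)
    bx = stack.origin[0] + (cols[pick] + 0.5) * stack.cell_size
    by = stack.origin[1] + (rows[pick] + 0.5) * stack.cell_size
    return BackgroundSet(points=pd.DataFrame({"x": bx, "y": by}), restriction_polygon=poly)
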