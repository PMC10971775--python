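"""Planar climate grids and the lattice arithmetic shared by every stage.

All coordinates are planar kilometres on a regular lattice. Cell membership
is half-open: a point (x, y) belongs to column ``floor((x - x0)/cell)`` and
row ``floor((y - y0)/cell)``, so lattice edges are owned by the cell above
them in index order and no point is counted twice. Row 0 is the southern
edge (y = y0); arrays are indexed ``[row, col]``.

Rasters are stored on disk as ESRI ASCII grids (plain text), one file per
scenario/variable pair, with ocean cells written as the NODATA value.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

SCENARIOS = ("historic", "SSP1-26", "SSP3-70", "SSP5-85")
FUTURE_SCENARIOS = SCENARIOS[1:]

_NODATA = -9999.0


@dataclass
class ClimateStack:
    """A set of named climate variables on one shared rectangular lattice.

    Parameters
    ----------
    scenario : str
        One of ``historic``, ``SSP1-26``, ``SSP3-70``, ``SSP5-85``.
    variables : dict of str -> 2-D float array
        Variable grids, all with identical shape, indexed ``[row, col]``
        with row 0 at the southern (low-y) edge.
    cell_size : float
        Edge length of one cell, km.
    origin : (float, float)
        Planar coordinates of the lattice's lower-left corner.
    land_mask : 2-D bool array
        True where the cell is land; ocean cells carry no valid climate.
    """

    scenario: str
    variables: dict[str, np.ndarray]
    cell_size: float
    origin: tuple[float, float]
    land_mask: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario label {self.scenario!r}")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if not self.variables:
            raise ValueError("a ClimateStack needs at least one variable")
        shapes = {v.shape for v in self.variables.values()}
        if len(shapes) != 1:
            raise ValueError(f"variable grids disagree in shape: {shapes}")
        self.land_mask = np.asarray(self.land_mask, dtype=bool)
        if self.land_mask.shape != next(iter(shapes)):
            raise ValueError("land_mask shape does not match variable grids")
        self.variables = {k: np.asarray(v, dtype=float) for k, v in self.variables.items()}

    # -- lattice geometry ---------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.land_mask.shape

    @property
    def var_names(self) -> list[str]:
        return list(self.variables)

    def same_lattice(self, other: "ClimateStack") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.cell_size, other.cell_size)
            and np.allclose(self.origin, other.origin)
        )

    def cell_of(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Half-open (row, col) of each point; may fall outside the lattice."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.origin[0]) / self.cell_size).astype(int)
        row = np.floor((y - self.origin[1]) / self.cell_size).astype(int)
        return row, col

    def in_bounds(self, x, y) -> np.ndarray:
        row, col = self.cell_of(x, y)
        nr, nc = self.shape
        return (row >= 0) & (row < nr) & (col >= 0) & (col < nc)

    def on_land(self, x, y) -> np.ndarray:
        """True where the containing cell exists and is land."""
        row, col = self.cell_of(x, y)
        nr, nc = self.shape
        ok = (row >= 0) & (row < nr) & (col >= 0) & (col < nc)
        out = np.zeros(np.shape(ok), dtype=bool)
        out[ok] = self.land_mask[row[ok], col[ok]]
        return out

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) center coordinate grids, shape = lattice shape."""
        nr, nc = self.shape
        xs = self.origin[0] + (np.arange(nc) + 0.5) * self.cell_size
        ys = self.origin[1] + (np.arange(nr) + 0.5) * self.cell_size
        return np.meshgrid(xs, ys)

    # -- value access -------------------------------------------------------

    def extract(self, x, y, variables: Sequence[str] | None = None) -> pd.DataFrame:
        """Nearest-cell (containing-cell) climate lookup at planar points.

        Points must lie inside the lattice; masked (ocean) cells yield NaN,
        never zero. Returns one row per point, one column per variable.
        """
        x = np.atleast_1d(np.asarray(x, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=float))
        if not np.all(self.in_bounds(x, y)):
            bad = np.flatnonzero(~self.in_bounds(x, y))[:3]
            raise ValueError(f"points off the lattice at indices {bad.tolist()}")
        row, col = self.cell_of(x, y)
        names = list(variables) if variables is not None else self.var_names
        land = self.land_mask[row, col]
        data = {}
        for name in names:
            if name not in self.variables:
                raise KeyError(f"variable {name!r} not in stack")
            vals = self.variables[name][row, col].astype(float)
            vals[~land] = np.nan
            data[name] = vals
        return pd.DataFrame(data)

    def land_table(self) -> pd.DataFrame:
        """All land-cell values, one row per cell, plus x/y center columns."""
        xg, yg = self.cell_centers()
        m = self.land_mask
        data = {"x": xg[m], "y": yg[m]}
        for name, grid in self.variables.items():
            data[name] = grid[m]
        return pd.DataFrame(data)


# -- disk format ------------------------------------------------------------

def write_ascii_grid(path: str | Path, grid: np.ndarray, mask: np.ndarray,
                     cell_size: float, origin: tuple[float, float]) -> None:
    """Write one variable as an ESRI ASCII grid; ocean becomes NODATA."""
    nr, nc = grid.shape
    out = np.where(mask, grid, _NODATA)
    header = (
        f"ncols {nc}\nnrows {nr}\nxllcorner {origin[0]}\nyllcorner {origin[1]}\n"
        f"cellsize {cell_size}\nNODATA_value {_NODATA}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        # ASCII grids are stored north-to-south; our row 0 is the south edge.
        np.savetxt(fh, out[::-1], fmt="%.6g")


def read_ascii_grid(path: str | Path):
    with open(path) as fh:
        header = {}
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        data = np.loadtxt(fh)
    data = data[::-1]
    nodata = header.get("nodata_value", _NODATA)
    mask = data != nodata
    return data, mask, header["cellsize"], (header["xllcorner"], header["yllcorner"])


def write_stack(stack: ClimateStack, out_dir: str | Path) -> list[Path]:
    """Write every variable as ``<scenario>__<variable>.asc`` under out_dir."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, grid in stack.variables.items():
        p = out_dir / f"{stack.scenario}__{name}.asc"
        write_ascii_grid(p, grid, stack.land_mask, stack.cell_size, stack.origin)
        paths.append(p)
    return paths


def read_stacks(in_dir: str | Path) -> dict[str, ClimateStack]:
    """Read every ``<scenario>__<variable>.asc`` in a directory into stacks."""
    in_dir = Path(in_dir)
    found: dict[str, dict[str, np.ndarray]] = {}
    masks: dict[str, np.ndarray] = {}
    meta = None
    for p in sorted(in_dir.glob("*__*.asc")):
        m = re.match(r"(.+)__(.+)\.asc$", p.name)
        scenario, var = m.group(1), m.group(2)
        grid, mask, cell, origin = read_ascii_grid(p)
        found.setdefault(scenario, {})[var] = grid
        masks[scenario] = mask
        meta = (cell, origin)
    if not found:
        raise FileNotFoundError(f"no ASCII grids under {in_dir}")
    cell, origin = meta
    return {
        sc: ClimateStack(scenario=sc, variables=vars_, cell_size=cell,
                         origin=origin, land_mask=masks[sc])
        for sc, vars_ in found.items()
    }
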