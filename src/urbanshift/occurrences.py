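"""Record cleaning and the city/species inclusion filters.

Cleaning drops, in order of precedence: records off the lattice, records on
ocean cells, records outside the recency window (when a window is given),
and exact duplicates by (species_id, x, y, date) keeping the first seen.
Each rejected record is tallied once, under the first rule it fails, so the
tally plus the retained count always reconciles with the input count.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grids import ClimateStack


@dataclass
class CityQuadrat:
    """A square sampling quadrat centred on a city (default 20x20 km)."""

    city_name: str
    centroid: tuple[float, float]
    half_width: float = 10.0
    population: int = 0
    historic_MAT: float = float("nan")
    historic_MAP: float = float("nan")

    def __post_init__(self) -> None:
        if self.half_width <= 0:
            raise ValueError("half_width must be positive")

    def contains(self, x, y) -> np.ndarray:
        """Half-open membership: [cx-hw, cx+hw) x [cy-hw, cy+hw)."""
        cx, cy = self.centroid
        hw = self.half_width
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (x >= cx - hw) & (x < cx + hw) & (y >= cy - hw) & (y < cy + hw)


@dataclass
class SpeciesRecordSet:
    """Cleaned records of one species."""

    species_id: str
    records: pd.DataFrame

    @property
    def n_records(self) -> int:
        return len(self.records)


def clean_records(
    records: pd.DataFrame,
    stack: ClimateStack,
    window: tuple[dt.date, dt.date] | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Drop out-of-bounds, ocean, stale and duplicate records.

    Returns the retained records (original order, first duplicate kept) and a
    tally ``{bounds, ocean, out_of_window, duplicate}``.
    """
    tally = {"bounds": 0, "ocean": 0, "out_of_window": 0, "duplicate": 0}
    if records.empty:
        return records.copy(), tally
    if window is not None and window[0] > window[1]:
        raise ValueError("date window is reversed")

    df = records.reset_index(drop=True)
    alive = np.ones(len(df), dtype=bool)

    inb = stack.in_bounds(df["x"].to_numpy(), df["y"].to_numpy())
    tally["bounds"] = int((~inb).sum())
    alive &= inb

    land = stack.on_land(df["x"].to_numpy(), df["y"].to_numpy())
    ocean_bad = alive & ~land
    tally["ocean"] = int(ocean_bad.sum())
    alive &= land

    if window is not None:
        dates = df["date"]
        in_win = np.array([(window[0] <= d <= window[1]) for d in dates])
        stale = alive & ~in_win
        tally["out_of_window"] = int(stale.sum())
        alive &= in_win

    dup = df.duplicated(subset=["species_id", "x", "y", "date"], keep="first").to_numpy()
    dup_bad = alive & dup
    tally["duplicate"] = int(dup_bad.sum())
    alive &= ~dup

    return df.loc[alive].reset_index(drop=True), tally


def city_species_lists(
    records: pd.DataFrame,
    quadrats: list[CityQuadrat],
    min_n: int = 10,
) -> pd.DataFrame:
    """Species retained per city: >= ``min_n`` cleaned records in the quadrat.

    Returns a tidy frame (city, species_id, n_in_quadrat) holding only the
    listings that pass; the union of ``species_id`` over rows is the pool of
    species eligible for modelling.
    """
    rows = []
    if records.empty:
        return pd.DataFrame(columns=["city", "species_id", "n_in_quadrat"])
    x = records["x"].to_numpy()
    y = records["y"].to_numpy()
    for q in quadrats:
        inside = q.contains(x, y)
        if not inside.any():
            continue
        counts = records.loc[inside, "species_id"].value_counts()
        for sp, n in counts.items():
            if n >= min_n:
                rows.append({"city": q.city_name, "species_id": sp, "n_in_quadrat": int(n)})
    out = pd.DataFrame(rows, columns=["city", "species_id", "n_in_quadrat"])
    return out.sort_values(["city", "species_id"], ignore_index=True)


def modelable(record_set: SpeciesRecordSet, min_n: int = 10) -> bool:
    """True when a species keeps enough cleaned records to fit a model."""
    return record_set.n_records >= min_n


def read_city_table(path) -> list[CityQuadrat]:
    """City table CSV: city,x,y,population[,half_width]."""
    df = pd.read_csv(path)
    return [
        CityQuadrat(
            city_name=str(r["city"]),
            centroid=(float(r["x"]), float(r["y"])),
            half_width=float(r.get("half_width", 10.0) or 10.0),
            population=int(r["population"]),
        )
        for r in df.to_dict("records")
    ]


def write_city_table(quadrats: list[CityQuadrat], path) -> None:
    pd.DataFrame(
        {
            "city": [q.city_name for q in quadrats],
            "x": [q.centroid[0] for q in quadrats],
            "y": [q.centroid[1] for q in quadrats],
            "population": [q.population for q in quadrats],
            "half_width": [q.half_width for q in quadrats],
        }
    ).to_csv(path, index=False)
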