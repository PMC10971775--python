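"""City-level presence projection and species-turnover accounting.

Each city quadrat receives a stratified 10x10 grid of 100 prediction
points. A species is called present in a city under a scenario when its
mean logistic suitability over the grid's land points is strictly above its
fitted threshold. Comparing each future scenario against the historic
baseline yields, per city, the numbers of gained, lost and unaffected
species, and per species the numbers of new, extirpated and unchanged
cities — the turnover accounting behind the projected urban-wildlife shift.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grids import FUTURE_SCENARIOS, ClimateStack
from .maxent import MaxEntResults
from .occurrences import CityQuadrat


@dataclass
class CityGrid:
    """100 stratified prediction points on a 10x10 partition of the quadrat."""

    city_name: str
    points: pd.DataFrame  # columns x, y


def build_city_grid(quadrat: CityQuadrat, n_side: int = 10) -> CityGrid:
    """Deterministic subcell centers: one point per (2hw/n_side)-km subcell."""
    cx, cy = quadrat.centroid
    hw = quadrat.half_width
    step = 2.0 * hw / n_side
    offs = -hw + (np.arange(n_side) + 0.5) * step
    xx, yy = np.meshgrid(cx + offs, cy + offs)
    return CityGrid(
        city_name=quadrat.city_name,
        points=pd.DataFrame({"x": xx.ravel(), "y": yy.ravel()}),
    )


def city_presence(
    results: MaxEntResults,
    stack: ClimateStack,
    grid: CityGrid,
    max_masked_frac: float = 0.5,
) -> tuple[float, bool]:
    """(mean suitability, present) for one species x city x scenario.

    Mean logistic suitability over the grid's non-masked points, present iff
    strictly above the species threshold. When more than half the grid
    points are masked (open water), suitability is NaN and the species is
    called absent.
    """
    if results.threshold is None:
        raise ValueError("model has no threshold; run tuning first")
    vals = stack.extract(grid.points["x"].to_numpy(), grid.points["y"].to_numpy(),
                         variables=results.var_names)
    masked_frac = vals.isna().any(axis=1).mean()
    if masked_frac > max_masked_frac:
        return float("nan"), False
    scores = results.predict(vals, scale="logistic")
    mean_s = float(np.nanmean(scores))
    return mean_s, bool(mean_s > results.threshold)


def assemble_matrix(
    models: dict[str, MaxEntResults],
    stacks: dict[str, ClimateStack],
    quadrats: list[CityQuadrat],
) -> pd.DataFrame:
    """Species x city x scenario presence matrix (tidy rows).

    ``models`` must hold only gated-in species; every stack must share the
    historic lattice. Columns: species_id, city, scenario, mean_suitability,
    present.
    """
    if "historic" not in stacks:
        raise KeyError("missing historic scenario stack")
    for sc in FUTURE_SCENARIOS:
        if sc not in stacks:
            raise KeyError(f"missing scenario stack {sc}")
        if not stacks[sc].same_lattice(stacks["historic"]):
            raise ValueError(f"stack {sc} not on the historic lattice")
    grids = [build_city_grid(q) for q in quadrats]
    rows = []
    for sp in sorted(models):
        res = models[sp]
        for grid in grids:
            for sc in ("historic",) + tuple(FUTURE_SCENARIOS):
                mean_s, present = city_presence(res, stacks[sc], grid)
                rows.append(
                    {"species_id": sp, "city": grid.city_name, "scenario": sc,
                     "mean_suitability": mean_s, "present": present}
                )
    return pd.DataFrame(rows)


@dataclass
class TurnoverSummary:
    """Gains/losses per city, city counts per species, taxon roll-up."""

    city_table: pd.DataFrame
    species_table: pd.DataFrame
    taxon_table: pd.DataFrame | None = None

    def check_conservation(self) -> None:
        """Assert the accounting identities; raises AssertionError on breach."""
        ct = self.city_table
        assert (ct["net"] == ct["gained"] - ct["lost"]).all()
        assert (ct["net"] == ct["future_richness"] - ct["historic_richness"]).all()
        for sc, sub in ct.groupby("scenario"):
            sp = self.species_table[self.species_table["scenario"] == sc]
            assert sub["gained"].sum() == sp["n_new_cities"].sum()
            assert sub["lost"].sum() == sp["n_extirpated_cities"].sum()


def compute_turnover(
    matrix: pd.DataFrame,
    taxon_labels: dict[str, str] | None = None,
) -> TurnoverSummary:
    """Classify every species x city cell against the historic baseline.

    Per future scenario: gained = absent -> present, lost = present ->
    absent, unaffected-present / unaffected-absent otherwise. A species is
    fully extirpated under a scenario when it held at least one city
    historically and none in that future. The taxon roll-up is the
    arithmetic mean of member species' net city change.
    """
    if matrix.empty:
        raise ValueError("presence matrix is empty (no gated-in species)")
    wide = matrix.pivot_table(
        index=["species_id", "city"], columns="scenario", values="present", aggfunc="first"
    ).astype(bool)
    species_pool = sorted(matrix["species_id"].unique())
    cities = sorted(matrix["city"].unique())

    city_rows, species_rows, taxon_rows = [], [], []
    for sc in FUTURE_SCENARIOS:
        hist = wide["historic"]
        fut = wide[sc]
        gained = (~hist) & fut
        lost = hist & (~fut)
        per_city = pd.DataFrame(
            {"gained": gained.groupby(level="city").sum(),
             "lost": lost.groupby(level="city").sum(),
             "unaffected_present": (hist & fut).groupby(level="city").sum(),
             "unaffected_absent": ((~hist) & (~fut)).groupby(level="city").sum(),
             "historic_richness": hist.groupby(level="city").sum(),
             "future_richness": fut.groupby(level="city").sum()}
        ).reindex(cities, fill_value=0)
        per_city["net"] = per_city["gained"] - per_city["lost"]
        for city, r in per_city.iterrows():
            city_rows.append({"city": city, "scenario": sc, **r.astype(int).to_dict()})

        per_sp = pd.DataFrame(
            {"n_new_cities": gained.groupby(level="species_id").sum(),
             "n_extirpated_cities": lost.groupby(level="species_id").sum(),
             "n_unchanged_cities": (hist & fut).groupby(level="species_id").sum(),
             "historic_cities": hist.groupby(level="species_id").sum(),
             "future_cities": fut.groupby(level="species_id").sum()}
        ).reindex(species_pool, fill_value=0)
        per_sp["net_cities"] = per_sp["n_new_cities"] - per_sp["n_extirpated_cities"]
        per_sp["fully_extirpated"] = (per_sp["historic_cities"] >= 1) & (per_sp["future_cities"] == 0)
        for sp, r in per_sp.iterrows():
            d = r.to_dict()
            d = {k: (bool(v) if k == "fully_extirpated" else int(v)) for k, v in d.items()}
            species_rows.append({"species_id": sp, "scenario": sc, **d})

        if taxon_labels:
            lab = pd.Series({sp: taxon_labels.get(sp, "unknown") for sp in species_pool})
            net = per_sp["net_cities"]
            for taxon, members in lab.groupby(lab):
                taxon_rows.append(
                    {"taxon_label": taxon, "scenario": sc,
                     "mean_net_cities": float(net.loc[members.index].mean()),
                     "n_species": int(len(members))}
                )

    return TurnoverSummary(
        city_table=pd.DataFrame(city_rows),
        species_table=pd.DataFrame(species_rows),
        taxon_table=pd.DataFrame(taxon_rows) if taxon_labels else None,
    )
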