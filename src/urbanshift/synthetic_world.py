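"""Synthetic climate landscapes, virtual species, and biased occurrence samples.

Every downstream stage of the pipeline — cleaning, thinning, background
generation, niche fitting, projection and turnover accounting — is exercised
against worlds built here, where the truth (each species' niche optimum,
breadth and true suitability surface) is known exactly.

The landscape is a regular planar lattice of km-sized cells. Each climate
variable is a spatially autocorrelated random field (Gaussian-smoothed white
noise); the temperature-like variable additionally carries a monotone
north-south gradient, precipitation is kept positive, and a configurable
number of variable pairs are constructed to be nearly collinear (|r| > 0.9
over land) so that collinearity pruning has real work to do. A contiguous
coastal margin is masked out as ocean. Future scenarios are deterministic
transforms of the historic stack: an additive warming delta, a precipitation
multiplier, and a smaller coupled shift on the remaining variables.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .grids import SCENARIOS, ClimateStack

#: default scenario perturbations: (temperature delta degC, precip multiplier).
#: Ordered so SSP5-85 is the strongest perturbation, as the emission
#: trajectories imply.
DEFAULT_SSP_DELTAS: dict[str, tuple[float, float]] = {
    "SSP1-26": (1.5, 1.03),
    "SSP3-70": (3.5, 1.07),
    "SSP5-85": (5.5, 1.12),
}

#: reference "today" anchoring the 10-year recency window (config, not wall clock)
DEFAULT_REFERENCE_DATE = dt.date(2020, 12, 31)
RECENCY_YEARS = 10

_TAXA = ("bird", "mammal", "insect", "amphibian", "reptile")


@dataclass
class VirtualSpecies:
    """A species with a known Gaussian niche over 1-3 climate variables."""

    species_id: str
    niche_vars: list[str]
    optima: list[float]
    breadths: list[float]
    max_prob: float = 0.9
    taxon_label: str = "bird"

    def __post_init__(self) -> None:
        if not (0 < self.max_prob <= 1):
            raise ValueError("max_prob must be in (0, 1]")
        if any(b <= 0 for b in self.breadths):
            raise ValueError("niche breadths must be positive")
        if not (1 <= len(self.niche_vars) <= 3):
            raise ValueError("a niche uses 1-3 variables")
        if len(self.optima) != len(self.niche_vars) or len(self.breadths) != len(self.niche_vars):
            raise ValueError("optima/breadths must align with niche_vars")


@dataclass
class BiasSurface:
    """Relative sampling-effort weights on the climate lattice (accessibility bias)."""

    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(self.weights < 0) or not np.any(self.weights > 0):
            raise ValueError("bias weights must be nonnegative with at least one positive cell")

    @classmethod
    def uniform(cls, shape: tuple[int, int]) -> "BiasSurface":
        return cls(np.ones(shape))

    @classmethod
    def roads(cls, shape: tuple[int, int], spacing: int = 12,
              strength: float = 5.0, floor: float = 1.0) -> "BiasSurface":
        """Multiplicative 'road' bands every ``spacing`` cells over a uniform floor."""
        w = np.full(shape, floor)
        w[::spacing, :] *= strength
        w[:, ::spacing] *= strength
        return cls(w)

    def with_urban_centers(
        self,
        stack: "ClimateStack",
        centers: Sequence[tuple[float, float]],
        amplitude: float = 15.0,
        sigma_km: float = 12.0,
    ) -> "BiasSurface":
        """Overlay Gaussian sampling-effort hotspots at city centroids.

        Community-science archives are dominated by records from urban
        cores; the hotspot amplitude makes in-quadrat record densities
        realistic relative to the hinterland.
        """
        xg, yg = stack.cell_centers()
        boost = np.zeros(stack.shape)
        for cx, cy in centers:
            d2 = (xg - cx) ** 2 + (yg - cy) ** 2
            boost += amplitude * np.exp(-d2 / (2.0 * sigma_km**2))
        return BiasSurface(self.weights * (1.0 + boost))


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], kernel: float) -> np.ndarray:
    """Standardized spatially autocorrelated field: smoothed white noise."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), kernel, mode="reflect")
    return (f - f.mean()) / f.std()


def _orthogonalize(fields: list[np.ndarray], mask: np.ndarray) -> list[np.ndarray]:
    """Gram-Schmidt over land cells so base fields are exactly uncorrelated."""
    out: list[np.ndarray] = []
    for f in fields:
        g = f.copy()
        v = g[mask] - g[mask].mean()
        for prev in out:
            p = prev[mask] - prev[mask].mean()
            g = g - (v @ p) / (p @ p) * prev
            v = g[mask] - g[mask].mean()
        g = (g - g[mask].mean()) / v.std()
        out.append(g)
    return out


def generate_climate(
    seed: int,
    shape: tuple[int, int] = (80, 80),
    n_vars: int = 6,
    collinear_pairs: int = 1,
    ssp_deltas: Mapping[str, tuple[float, float]] | None = None,
    cell_size: float = 4.6,
    kernel: float = 6.0,
    ocean_margin_frac: float = 0.08,
    collinear_r: float = 0.95,
) -> dict[str, ClimateStack]:
    """Build one historic stack plus three future stacks on a shared lattice.

    Variables are named ``MAT`` (degC, with the latitudinal gradient), ``MAP``
    (mm, positive), then ``bio03``, ``bio04``, ... Collinear partners are the
    trailing variables, each a noisy copy of one of the leading generic
    variables with Pearson |r| ~ ``collinear_r`` over land.

    Returns a dict keyed by scenario label.
    """
    if n_vars < 2:
        raise ValueError("need at least 2 climate variables (MAT and MAP)")
    if shape[0] < 20 or shape[1] < 20:
        raise ValueError("lattice must be at least 20x20")
    if n_vars - collinear_pairs < 2:
        raise ValueError("too many collinear pairs for n_vars")
    ssp_deltas = dict(ssp_deltas) if ssp_deltas is not None else dict(DEFAULT_SSP_DELTAS)

    rng = np.random.default_rng(seed)
    nr, nc = shape
    margin = max(2, int(round(ocean_margin_frac * min(nr, nc))))
    land = np.ones(shape, dtype=bool)
    land[:, :margin] = False  # west coast
    land[:margin, :] = False  # south coast

    n_base = n_vars - collinear_pairs
    raw = [_smooth_field(rng, shape, kernel) for _ in range(n_base)]
    # north-south gradient pattern, orthogonalized against so MAT's gradient
    # does not leak correlation into the other variables
    yy = np.linspace(0.0, 1.0, nr)[:, None] * np.ones((1, nc))
    base = _orthogonalize([yy] + raw, land)
    gradient, base = base[0], base[1:]

    variables: dict[str, np.ndarray] = {}
    # MAT: warm south, cool north, modest local texture
    variables["MAT"] = 22.0 - 18.0 * (gradient - gradient[land].min()) / (
        gradient[land].max() - gradient[land].min()
    ) + 2.0 * base[0]
    # MAP: positive, mm/yr scale
    variables["MAP"] = np.clip(900.0 + 280.0 * base[1], 50.0, None)
    generic_scales = {}
    for i in range(2, n_base):
        name = f"bio{i + 1:02d}"
        scale = 1.0 + 0.5 * (i % 3)
        variables[name] = 10.0 * (i - 1) + scale * base[i]
        generic_scales[name] = scale
    # collinear partners: noisy copies of the leading generic (or MAT/MAP)
    # vars; the noise term is remembered so future scenarios keep the pair
    # coherent (real bioclim variables stay correlated under warming)
    partner_sources = [n for n in variables if n not in ("MAT",)][:collinear_pairs]
    eps = np.sqrt(1.0 / collinear_r**2 - 1.0)
    partner_of: dict[str, tuple[str, np.ndarray]] = {}
    for j, src in enumerate(partner_sources):
        name = f"bio{n_base + j + 1:02d}"
        src_grid = variables[src]
        sd = src_grid[land].std()
        # smooth deviation field: real collinear climate variables differ by
        # spatially structured anomalies, not cell-to-cell white noise
        noise = _orthogonalize([src_grid, _smooth_field(rng, shape, kernel)], land)[1]
        noise_term = eps * sd * noise
        variables[name] = src_grid + noise_term
        partner_of[name] = (src, noise_term)

    stacks: dict[str, ClimateStack] = {}
    stacks["historic"] = ClimateStack(
        scenario="historic", variables={k: v.copy() for k, v in variables.items()},
        cell_size=cell_size, origin=(0.0, 0.0), land_mask=land,
    )
    for sc in SCENARIOS[1:]:
        d_t, p_mult = ssp_deltas[sc]
        fut: dict[str, np.ndarray] = {}
        for name, grid in variables.items():
            if name in partner_of:
                continue  # second pass, after the source is transformed
            if name == "MAT":
                fut[name] = grid + d_t
            elif name == "MAP":
                fut[name] = grid * p_mult
            else:
                # generic variables drift with warming at a fixed coupling so
                # that niches on any axis are exposed to scenario change
                fut[name] = grid + 0.4 * d_t * generic_scales.get(name, 1.0)
        for name, (src, noise_term) in partner_of.items():
            fut[name] = fut[src] + noise_term
        fut = {name: fut[name] for name in variables}  # restore input order
        stacks[sc] = ClimateStack(
            scenario=sc, variables=fut, cell_size=cell_size,
            origin=(0.0, 0.0), land_mask=land,
        )
    return stacks


def generate_species(
    seed: int,
    n_species: int,
    stack: ClimateStack,
    niche_vars: Sequence[str] | None = None,
    n_niche_vars: int = 1,
    breadth_frac: tuple[float, float] = (0.04, 0.10),
    optimum_quantiles: tuple[float, float] = (0.15, 0.85),
    max_prob: float = 0.9,
) -> list[VirtualSpecies]:
    """Draw virtual species with Gaussian niches inside the observed climate.

    Optima are drawn uniformly between the stated quantiles of each niche
    variable over land; breadths uniformly between ``breadth_frac`` times the
    variable's land range. The default breadths keep each niche narrow
    relative to the modelled domain — the continental-scale regime in which
    presence-background models are discriminative and most species clear an
    AUC quality gate. Taxon labels cycle round-robin through a fixed
    vocabulary so taxon-level roll-ups are testable.
    """
    if n_species <= 0:
        raise ValueError("n_species must be positive")
    rng = np.random.default_rng(seed)
    pool = list(niche_vars) if niche_vars is not None else stack.var_names
    out = []
    for i in range(n_species):
        k = min(n_niche_vars, len(pool))
        chosen = sorted(rng.choice(len(pool), size=k, replace=False).tolist())
        names, opts, brs = [], [], []
        for j in chosen:
            name = pool[j]
            vals = stack.variables[name][stack.land_mask]
            lo, hi = np.quantile(vals, optimum_quantiles)
            rng_width = vals.max() - vals.min()
            names.append(name)
            opts.append(float(rng.uniform(lo, hi)))
            brs.append(float(rng.uniform(*breadth_frac) * rng_width))
        out.append(
            VirtualSpecies(
                species_id=f"sp{i + 1:03d}", niche_vars=names, optima=opts,
                breadths=brs, max_prob=max_prob, taxon_label=_TAXA[i % len(_TAXA)],
            )
        )
    return out


def true_suitability(species: VirtualSpecies, stack: ClimateStack) -> np.ndarray:
    """True occurrence probability per cell: a product-Gaussian response.

    ``max_prob * prod_v exp(-(v - opt)^2 / (2 breadth^2))`` on land; NaN on
    ocean cells.
    """
    prob = np.full(stack.shape, float(species.max_prob))
    for name, opt, br in zip(species.niche_vars, species.optima, species.breadths):
        if name not in stack.variables:
            raise KeyError(f"niche variable {name!r} missing from stack")
        v = stack.variables[name]
        prob = prob * np.exp(-((v - opt) ** 2) / (2.0 * br**2))
    prob[~stack.land_mask] = np.nan
    return prob


def _random_dates(rng: np.random.Generator, n: int, start: dt.date, end: dt.date) -> list[dt.date]:
    span = (end - start).days
    return [start + dt.timedelta(days=int(d)) for d in rng.integers(0, span + 1, size=n)]


def sample_occurrences(
    species: VirtualSpecies,
    stack: ClimateStack,
    bias: BiasSurface | None,
    n_target: int,
    seed: int,
    contamination: Mapping[str, float] | None = None,
    reference_date: dt.date = DEFAULT_REFERENCE_DATE,
) -> pd.DataFrame:
    """Sample biased occurrence records, then append known contamination.

    Clean records are drawn cell-wise with probability proportional to
    ``true_suitability * bias``, jittered uniformly within the cell, and dated
    inside the 10-year recency window ending at ``reference_date``. Exact
    duplicates, ocean records and stale (pre-window) records are then appended
    at the stated fractions of ``n_target`` (rounded), emulating the dirt real
    archives carry.

    Returns a DataFrame with columns species_id, x, y, date, source_id.
    """
    contamination = dict(contamination or {})
    for key, frac in contamination.items():
        if not (0 <= frac < 1):
            raise ValueError(f"contamination fraction {key}={frac} outside [0, 1)")
    cols = ["species_id", "x", "y", "date", "source_id"]
    if n_target == 0:
        return pd.DataFrame(columns=cols)
    rng = np.random.default_rng(seed)
    if bias is None:
        bias = BiasSurface.uniform(stack.shape)

    suit = true_suitability(species, stack)
    weight = np.where(stack.land_mask, np.nan_to_num(suit) * bias.weights, 0.0)
    total = weight.sum()
    if total <= 0:
        raise ValueError(f"species {species.species_id} has zero sampling weight everywhere")
    p = (weight / total).ravel()
    cells = rng.choice(p.size, size=n_target, replace=True, p=p)
    row, col = np.unravel_index(cells, stack.shape)
    x = stack.origin[0] + (col + rng.uniform(0, 1, n_target)) * stack.cell_size
    y = stack.origin[1] + (row + rng.uniform(0, 1, n_target)) * stack.cell_size
    window_start = reference_date - dt.timedelta(days=RECENCY_YEARS * 365)
    dates = _random_dates(rng, n_target, window_start, reference_date)
    sources = [f"src-{int(s):02d}" for s in rng.integers(0, 8, n_target)]
    recs = pd.DataFrame(
        {"species_id": species.species_id, "x": x, "y": y, "date": dates, "source_id": sources}
    )

    extras = []
    n_dup = int(round(contamination.get("duplicate_frac", 0.0) * n_target))
    if n_dup:
        idx = rng.integers(0, len(recs), n_dup)
        extras.append(recs.iloc[idx].copy())
    n_ocean = int(round(contamination.get("ocean_frac", 0.0) * n_target))
    if n_ocean:
        orow, ocol = np.where(~stack.land_mask)
        pick = rng.integers(0, orow.size, n_ocean)
        extras.append(
            pd.DataFrame(
                {
                    "species_id": species.species_id,
                    "x": stack.origin[0] + (ocol[pick] + 0.5) * stack.cell_size,
                    "y": stack.origin[1] + (orow[pick] + 0.5) * stack.cell_size,
                    "date": _random_dates(rng, n_ocean, window_start, reference_date),
                    "source_id": "src-99",
                }
            )
        )
    n_old = int(round(contamination.get("out_of_window_frac", 0.0) * n_target))
    if n_old:
        idx = rng.integers(0, len(recs), n_old)
        stale = recs.iloc[idx].copy()
        stale["date"] = _random_dates(
            rng, n_old, window_start - dt.timedelta(days=3650), window_start - dt.timedelta(days=1)
        )
        extras.append(stale)
    if extras:
        recs = pd.concat([recs] + extras, ignore_index=True)
    return recs[cols]


def write_occurrences(records: pd.DataFrame, path: str | Path) -> None:
    records.to_csv(path, index=False)


def read_occurrences(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["date"] = pd.to_datetime(df["date"]).dt.date
    return df
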