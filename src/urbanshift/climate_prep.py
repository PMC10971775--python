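"""Ensemble averaging and collinearity pruning of climate stacks.

Future projections usually arrive as several general-circulation-model
members per scenario; averaging them damps model-specific anomalies and
gives a more conservative projection. Collinear variable pairs are pruned
greedily on |Pearson r| evaluated at background points over land — the
modelling domain — not over the whole lattice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grids import ClimateStack


@dataclass
class VariableSelection:
    """Outcome of collinearity pruning: kept order and an audit of drops."""

    kept: list[str]
    dropped: list[dict] = field(default_factory=list)  # name, reason, partner, r

    def to_frame(self) -> pd.DataFrame:
        rows = [{"variable": k, "status": "kept", "reason": "", "partner": "", "r": np.nan}
                for k in self.kept]
        rows += [{"variable": d["name"], "status": "dropped", "reason": d["reason"],
                  "partner": d["partner"], "r": d["r"]} for d in self.dropped]
        return pd.DataFrame(rows)


def ensemble_mean(members: list[ClimateStack], scenario_label: str) -> ClimateStack:
    """Per-cell, per-variable arithmetic mean over ensemble members."""
    if not members:
        raise ValueError("ensemble needs at least one member")
    first = members[0]
    names = set(first.var_names)
    for m in members[1:]:
        if not first.same_lattice(m):
            raise ValueError("ensemble members disagree in lattice")
        if set(m.var_names) != names:
            raise ValueError("ensemble members disagree in variable names")
    variables = {
        name: np.mean([m.variables[name] for m in members], axis=0)
        for name in first.var_names
    }
    return ClimateStack(
        scenario=scenario_label, variables=variables, cell_size=first.cell_size,
        origin=first.origin, land_mask=first.land_mask.copy(),
    )


def prune_collinear(
    stack: ClimateStack,
    sample_points: np.ndarray | pd.DataFrame,
    r_threshold: float = 0.7,
) -> VariableSelection:
    """Greedy pairwise-|r| pruning at sample points on land.

    Zero-variance variables are dropped first. Then, while any kept pair has
    |Pearson r| above the threshold, the member of the worst pair with the
    larger mean absolute correlation to the other kept variables is dropped;
    ties drop the variable later in input order. Deterministic.
    """
    if len(stack.var_names) < 2:
        raise ValueError("need at least 2 variables to prune")
    if isinstance(sample_points, pd.DataFrame):
        x = sample_points["x"].to_numpy()
        y = sample_points["y"].to_numpy()
    else:
        pts = np.asarray(sample_points, dtype=float)
        x, y = pts[:, 0], pts[:, 1]
    vals = stack.extract(x, y)
    vals = vals.dropna(axis=0)
    if len(vals) < 10:
        raise ValueError("need at least 10 sample points on land")

    names = list(vals.columns)
    dropped: list[dict] = []
    sd = vals.std(ddof=0)
    for name in [n for n in names if sd[n] == 0]:
        dropped.append({"name": name, "reason": "zero variance", "partner": "", "r": np.nan})
        names.remove(name)

    corr = vals[names].corr().abs()
    order = {n: i for i, n in enumerate(stack.var_names)}
    while len(names) > 1:
        sub = corr.loc[names, names].to_numpy(copy=True)
        np.fill_diagonal(sub, 0.0)
        i, j = np.unravel_index(np.argmax(sub), sub.shape)
        worst = sub[i, j]
        if worst <= r_threshold:
            break
        a, b = names[i], names[j]
        mean_abs = sub.mean(axis=0) * len(names) / max(len(names) - 1, 1)
        ma, mb = mean_abs[i], mean_abs[j]
        if np.isclose(ma, mb):
            victim = a if order[a] > order[b] else b
        else:
            victim = a if ma > mb else b
        partner = b if victim == a else a
        dropped.append(
            {"name": victim, "reason": "collinear", "partner": partner, "r": float(worst)}
        )
        names.remove(victim)
    return VariableSelection(kept=names, dropped=dropped)


def extract(stack: ClimateStack, points) -> pd.DataFrame:
    """Containing-cell climate lookup; NaN on masked cells. See ClimateStack.extract."""
    if isinstance(points, pd.DataFrame):
        return stack.extract(points["x"].to_numpy(), points["y"].to_numpy())
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    return stack.extract(pts[:, 0], pts[:, 1])
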