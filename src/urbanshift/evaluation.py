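"""Model evaluation and tuning: spatial-block CV, AUC, continuous Boyce
index, the 48-cell tuning grid, permutation contributions, threshold choice
and the quality gate.

Tuning fits every combination of the eight feature-class sets and six
regularization multipliers under k-fold spatial-block cross-validation
(quadrants at the presence medians), averages the held-out continuous Boyce
index and AUC across folds, and selects the candidate with the highest mean
Boyce index. Species are gated out when they keep fewer than 10 records,
no candidate converges, or the winning model's mean training AUC falls
below 0.70.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .maxent import (
    FEATURE_CLASS_SETS,
    REG_MULTIPLIERS,
    ConvergenceError,
    FeatureSpec,
    MaxEnt,
    MaxEntResults,
    expand_features,
)


class FoldError(ValueError):
    """A spatial-block fold ended up with zero presences."""


@dataclass
class FoldAssignment:
    """Fold ids (1..k) for presences and background points."""

    presence_folds: np.ndarray
    background_folds: np.ndarray
    k: int = 4
    method: str = "spatial_block"


def assign_blocks(
    presences: pd.DataFrame,
    background: pd.DataFrame,
    k: int = 4,
) -> FoldAssignment:
    """Quadrant folds split at the presence median x and median y.

    Quadrants are numbered SW=1, SE=2, NW=3, NE=4; points exactly on a
    split line go to the lower-index (south/west) side. Background points
    are cut by the same lines and may be unbalanced. Raises FoldError if
    any presence fold is empty (callers fall back to seeded random folds).
    """
    if k != 4:
        raise ValueError("spatial-block assignment is defined for k=4 quadrants")
    px = presences["x"].to_numpy(dtype=float)
    py = presences["y"].to_numpy(dtype=float)
    if len(px) < k:
        raise FoldError(f"only {len(px)} presences for {k} folds")
    mx, my = np.median(px), np.median(py)

    def fold_of(x, y):
        east = x > mx
        north = y > my
        return 1 + east.astype(int) + 2 * north.astype(int)

    pf = fold_of(px, py)
    bf = fold_of(background["x"].to_numpy(dtype=float), background["y"].to_numpy(dtype=float))
    if len(np.unique(pf)) < k:
        raise FoldError("at least one presence quadrant is empty")
    return FoldAssignment(presence_folds=pf, background_folds=bf, k=k)


def random_folds(n_presence: int, n_background: int, k: int, seed: int) -> FoldAssignment:
    """Seeded random k-fold fallback when quadrant folds degenerate."""
    rng = np.random.default_rng(seed)
    pf = 1 + (rng.permutation(n_presence) % k)
    bf = 1 + (rng.permutation(n_background) % k)
    return FoldAssignment(presence_folds=pf, background_folds=bf, k=k, method="random")


def auc(presence_scores, background_scores) -> float:
    """Rank-sum AUC: P(random presence outranks random background), ties 1/2."""
    p = np.asarray(presence_scores, dtype=float)
    b = np.asarray(background_scores, dtype=float)
    if p.size == 0 or b.size == 0:
        raise ValueError("AUC needs non-empty score sets")
    ranks = stats.rankdata(np.concatenate([p, b]))
    u = ranks[: p.size].sum() - p.size * (p.size + 1) / 2.0
    return float(u / (p.size * b.size))


def boyce(
    presence_scores,
    background_scores,
    n_windows: int = 101,
    window_width: float = 0.1,
) -> float:
    """Continuous Boyce index on [0, 1]-scale suitability scores.

    Overlapping windows of the given width have centers evenly spaced over
    [0, 1]. Per window, P = fraction of presence scores inside and E =
    fraction of background scores inside; empty-E windows are skipped and
    the index is the Spearman rank correlation between P/E and the window
    center. Returns NaN when fewer than 3 windows are retained (the model
    then fails the gate); a flat P/E profile scores 0 (indistinguishable
    from random).
    """
    p = np.asarray(presence_scores, dtype=float)
    b = np.asarray(background_scores, dtype=float)
    centers = np.linspace(0.0, 1.0, n_windows)
    half = window_width / 2.0
    ratios, kept_centers = [], []
    for c in centers:
        lo, hi = c - half, c + half
        e = np.mean((b >= lo) & (b <= hi))
        if e == 0:
            continue
        pr = np.mean((p >= lo) & (p <= hi))
        ratios.append(pr / e)
        kept_centers.append(c)
    if len(ratios) < 3:
        return float("nan")
    ratios = np.asarray(ratios)
    if np.all(ratios == ratios[0]):
        return 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho = stats.spearmanr(kept_centers, ratios).statistic
    return 0.0 if np.isnan(rho) else float(rho)


def select_threshold(presence_scores, background_scores, rule: str = "max_sens_spec") -> float:
    """Suitability cutoff balancing sensitivity and specificity.

    Candidates are the observed scores; a point is called present when its
    score >= threshold. ``max_sens_spec`` (default) maximizes sensitivity +
    specificity with background standing in for absences; ``equal_sens_spec``
    minimizes |sensitivity - specificity|. Ties take the smallest threshold.
    """
    p = np.asarray(presence_scores, dtype=float)
    b = np.asarray(background_scores, dtype=float)
    if p.size == 0 or b.size == 0:
        raise ValueError("threshold selection needs non-empty score sets")
    cands = np.unique(np.concatenate([p, b]))
    sens = np.array([(p >= t).mean() for t in cands])
    spec = np.array([(b < t).mean() for t in cands])
    if rule == "max_sens_spec":
        crit = sens + spec
        best = np.flatnonzero(crit == crit.max())[0]
    elif rule == "equal_sens_spec":
        crit = np.abs(sens - spec)
        best = np.flatnonzero(crit == crit.min())[0]
    else:
        raise ValueError(f"unknown threshold rule {rule!r}")
    return float(cands[best])


def percent_contribution(
    results: MaxEntResults,
    presence: pd.DataFrame,
    background: pd.DataFrame,
    seed: int = 0,
    n_perm: int = 10,
) -> dict[str, float]:
    """Permutation importance per climate variable, normalized to 100.

    Each variable's column is shuffled (jointly over presence+background)
    n_perm times; the mean drop in training AUC, floored at zero, is the
    variable's raw importance. All-zero drops yield uniform shares.
    """
    rng = np.random.default_rng(seed)
    base_p = results.predict(presence, scale="raw")
    base_b = results.predict(background, scale="raw")
    base_auc = auc(base_p, base_b)
    drops = {}
    n_p = len(presence)
    combined = pd.concat([presence, background], ignore_index=True)
    for var in results.var_names:
        d = []
        for _ in range(n_perm):
            shuffled = combined.copy()
            shuffled[var] = rng.permutation(shuffled[var].to_numpy())
            sc = results.predict(shuffled, scale="raw")
            d.append(base_auc - auc(sc[:n_p], sc[n_p:]))
        drops[var] = max(0.0, float(np.mean(d)))
    total = sum(drops.values())
    if total == 0:
        share = 100.0 / len(drops)
        return {v: share for v in drops}
    return {v: 100.0 * d / total for v, d in drops.items()}


@dataclass
class TuningResult:
    """All 48 candidates' CV metrics plus the refit winner."""

    candidates: pd.DataFrame
    winner_spec: FeatureSpec | None
    winner: MaxEntResults | None
    folds: FoldAssignment | None = None

    @property
    def has_best_model(self) -> bool:
        return self.winner is not None


def _logistic_scores(res, X: np.ndarray) -> np.ndarray:
    """Logistic suitability straight from an expanded feature matrix."""
    raw = np.exp(X @ res.params - res.offset)
    s = np.exp(res.entropy) * raw * res.tau
    return s / (1.0 - res.tau + s)


def default_grid(n_hinge_knots: int = 20) -> list[FeatureSpec]:
    """The full tuning grid: 8 feature-class sets x 6 multipliers = 48 cells."""
    return [
        FeatureSpec(classes=c, reg_multiplier=r, n_hinge_knots=n_hinge_knots)
        for c in FEATURE_CLASS_SETS
        for r in REG_MULTIPLIERS
    ]


def tune(
    presence: pd.DataFrame,
    background: pd.DataFrame,
    presence_xy: pd.DataFrame | None = None,
    background_xy: pd.DataFrame | None = None,
    grid: list[FeatureSpec] | None = None,
    k: int = 4,
    seed: int = 0,
    maxiter: int = 10_000,
    tol: float = 1e-6,
    boyce_windows: int = 101,
    boyce_width: float = 0.1,
    threshold_rule: str = "max_sens_spec",
) -> TuningResult:
    """Cross-validate the tuning grid, pick the best Boyce index, refit.

    ``presence``/``background`` carry climate values; ``presence_xy`` /
    ``background_xy`` carry coordinates for the spatial blocks (random folds
    are used, with a warning, when quadrant folds degenerate or coordinates
    are not supplied). Ties on mean BCI break by higher mean test AUC, then
    lower reg multiplier, then fewer feature classes.

    The winner is refit on all folds; its threshold and metrics (mean train/
    test AUC, mean BCI, AUC_diff) are attached to the returned results.
    """
    grid = grid if grid is not None else default_grid()
    if presence_xy is not None and background_xy is not None:
        try:
            folds = assign_blocks(presence_xy, background_xy, k=k)
        except FoldError as err:
            warnings.warn(f"spatial blocks degenerate ({err}); falling back to random folds")
            folds = random_folds(len(presence), len(background), k, seed)
    else:
        folds = random_folds(len(presence), len(background), k, seed)

    ranges = {
        n: (float(background[n].min()), float(background[n].max()))
        for n in presence.columns
    }
    var_names = list(presence.columns)
    # expand each feature-class set once; multipliers and folds reuse it
    expansions: dict[tuple, tuple] = {}
    for spec in grid:
        key = (spec.classes, spec.n_hinge_knots)
        if key not in expansions:
            Xp, fnames, fclasses = expand_features(presence, spec, ranges)
            Xb, _, _ = expand_features(background, spec, ranges)
            expansions[key] = (Xp, Xb, fnames, fclasses)

    # evaluate folds per feature-class group, walking the regularization
    # path from strongest to weakest penalty with warm starts
    per_spec = {spec: {"bci": [], "test": [], "train": [], "failed": False}
                for spec in grid}
    for key, (Xp, Xb, fnames, fclasses) in expansions.items():
        group = sorted(
            (s for s in grid if (s.classes, s.n_hinge_knots) == key),
            key=lambda s: -s.reg_multiplier,
        )
        for f in range(1, folds.k + 1):
            tr_pm = folds.presence_folds != f
            tr_bm = folds.background_folds != f
            if (~tr_pm).sum() == 0 or (~tr_bm).sum() == 0 or tr_pm.sum() < 2 or tr_bm.sum() < 50:
                for s in group:
                    per_spec[s]["failed"] = True
                continue
            warm = None
            for spec in group:
                if per_spec[spec]["failed"]:
                    continue
                try:
                    res = MaxEnt.from_features(
                        Xp[tr_pm], Xb[tr_bm], spec, fnames, fclasses,
                        var_names, ranges, min_presence=2,
                    ).fit(maxiter=maxiter, tol=tol, start_params=warm)
                except (ConvergenceError, ValueError):
                    per_spec[spec]["failed"] = True
                    warm = None
                    continue
                warm = res.params
                d = per_spec[spec]
                d["train"].append(auc(_logistic_scores(res, Xp[tr_pm]),
                                      _logistic_scores(res, Xb[tr_bm])))
                te_p = _logistic_scores(res, Xp[~tr_pm])
                te_b = _logistic_scores(res, Xb[~tr_bm])
                d["test"].append(auc(te_p, te_b))
                d["bci"].append(boyce(te_p, te_b, n_windows=boyce_windows,
                                      window_width=boyce_width))

    rows = []
    for spec in grid:
        d = per_spec[spec]
        ok = (not d["failed"]) and len(d["bci"]) == folds.k and not np.any(np.isnan(d["bci"]))
        if not ok:
            rows.append(
                {"classes": spec.classes, "reg_multiplier": spec.reg_multiplier,
                 "mean_BCI": np.nan, "mean_test_AUC": np.nan,
                 "mean_train_AUC": np.nan, "AUC_diff": np.nan, "ok": False}
            )
            continue
        rows.append(
            {
                "classes": spec.classes,
                "reg_multiplier": spec.reg_multiplier,
                "mean_BCI": float(np.mean(d["bci"])),
                "mean_test_AUC": float(np.mean(d["test"])),
                "mean_train_AUC": float(np.mean(d["train"])),
                "AUC_diff": float(np.mean(d["train"]) - np.mean(d["test"])),
                "ok": True,
            }
        )
    cand = pd.DataFrame(rows)
    ok = cand[cand["ok"]]
    if ok.empty:
        return TuningResult(candidates=cand, winner_spec=None, winner=None, folds=folds)

    ranked = ok.assign(n_classes=ok["classes"].str.len()).sort_values(
        by=["mean_BCI", "mean_test_AUC", "reg_multiplier", "n_classes"],
        ascending=[False, False, True, True],
        kind="mergesort",
    )
    top = ranked.iloc[0]
    winner_spec = grid[0].__class__(
        classes=top["classes"], reg_multiplier=float(top["reg_multiplier"]),
        n_hinge_knots=grid[0].n_hinge_knots,
    )
    Xp, Xb, fnames, fclasses = expansions[(winner_spec.classes, winner_spec.n_hinge_knots)]
    final = MaxEnt.from_features(
        Xp, Xb, winner_spec, fnames, fclasses, var_names, ranges
    ).fit(maxiter=maxiter, tol=tol)
    sp = _logistic_scores(final, Xp)
    sb = _logistic_scores(final, Xb)
    final.threshold = select_threshold(sp, sb, rule=threshold_rule)
    final.metrics.update(
        mean_BCI=float(top["mean_BCI"]),
        mean_test_AUC=float(top["mean_test_AUC"]),
        mean_train_AUC=float(top["mean_train_AUC"]),
        AUC_diff=float(top["AUC_diff"]),
        fold_method=folds.method,
    )
    final.metrics["percent_contribution"] = percent_contribution(
        final, presence, background, seed=seed
    )
    return TuningResult(candidates=cand.drop(columns="ok"), winner_spec=winner_spec,
                        winner=final, folds=folds)


def quality_gate(
    tuning: TuningResult | None,
    n_records: int,
    min_n: int = 10,
    auc_gate: float = 0.70,
) -> tuple[bool, str]:
    """(keep, reason). Drop when records < min_n, no best model, or mean
    training AUC strictly below the gate (0.70 exactly passes)."""
    if n_records < min_n:
        return False, f"insufficient records (n={n_records} < {min_n})"
    if tuning is None or not tuning.has_best_model:
        return False, "no best model"
    train_auc = tuning.winner.metrics.get("mean_train_AUC", float("nan"))
    if np.isnan(train_auc) or train_auc < auc_gate:
        return False, f"AUC below gate ({train_auc:.3f} < {auc_gate})"
    return True, "keep"
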