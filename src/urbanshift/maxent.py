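"""L1-regularized maximum-entropy niche model (presence-background).

The model estimates the distribution over the landscape that maximizes
entropy subject to regularized constraints that fitted feature expectations
match presence-sample means. Equivalently, with linear predictor
``eta(x) = sum_f beta_f f(x)`` over expanded features, it minimizes the
penalized conditional negative log-likelihood

    J(beta) = log sum_bg exp(eta(x_j)) - mean_pres eta(x_i)
              + sum_f lambda_f |beta_f|

which is convex; the KKT condition at lambda=0 is exact moment matching
between the fitted background distribution and the presence sample.

Feature classes follow the MaxEnt convention: linear (L), quadratic (Q),
pairwise product (P), hinge (H, forward and reverse ramps at evenly spaced
knots) and threshold (T, step indicators at the same knots), all on
variables rescaled to [0, 1] over their training range and clamped to that
range at prediction time. Per-feature penalties use the published MaxEnt
default schedule: ``lambda_f = reg_multiplier * beta_class(n_presence) *
sd_f / sqrt(n_presence)``, with ``beta_class`` interpolated from the default
tables per feature class.

Usage follows the Model/Results convention::

    model = MaxEnt(presence_values, background_values, spec)
    res = model.fit()
    res.predict(new_values, scale="logistic")
    print(res.summary())
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


def _logsumexp(v: np.ndarray) -> float:
    """Stable log-sum-exp without scipy's per-call dispatch overhead."""
    m = v.max()
    return float(m + np.log(np.exp(v - m).sum()))

FEATURE_CLASS_SETS = ("L", "Q", "P", "LQ", "HQ", "QPH", "QPHT", "LQHP")
REG_MULTIPLIERS = (0.5, 1.0, 1.5, 2.0, 2.5, 3.0)

#: published default beta interpolation tables (presence count -> beta),
#: one per feature class; hinge is flat, the rest shrink with sample size.
_BETA_TABLES = {
    "L": ([0, 10, 30, 100], [1.0, 1.0, 0.2, 0.05]),
    "Q": ([0, 10, 17, 30, 100], [1.3, 0.8, 0.5, 0.25, 0.05]),
    "P": ([0, 10, 17, 30, 100], [2.6, 1.6, 0.9, 0.55, 0.05]),
    "H": ([0, 1], [0.5, 0.5]),
    "T": ([0, 100], [2.0, 1.0]),
}


def _cd_kernel_py(H, diag, b, lam, w, Hw, inner_tol, max_sweeps):
    """Cyclic coordinate descent on an L1-penalized quadratic model."""
    n = w.shape[0]
    for _ in range(max_sweeps):
        max_move = 0.0
        for j in range(n):
            r = b[j] - Hw[j] + H[j, j] * w[j]
            if r > lam[j]:
                new = (r - lam[j]) / diag[j]
            elif r < -lam[j]:
                new = (r + lam[j]) / diag[j]
            else:
                new = 0.0
            move = new - w[j]
            if move != 0.0:
                for i in range(n):
                    Hw[i] += H[i, j] * move
                w[j] = new
                if abs(move) > max_move:
                    max_move = abs(move)
        if max_move < inner_tol:
            break
    return w


try:  # JIT when available; the pure-Python kernel is the reference behavior
    from numba import njit as _njit

    _cd_kernel = _njit(cache=True)(_cd_kernel_py)
except ImportError:  # pragma: no cover
    _cd_kernel = _cd_kernel_py


class ConvergenceError(RuntimeError):
    """Raised when the proximal-gradient solver fails to converge."""

    def __init__(self, spec: "FeatureSpec"):
        super().__init__(f"maxent fit did not converge for spec {spec}")
        self.spec = spec


@dataclass(frozen=True)
class FeatureSpec:
    """A tuning cell: which feature classes to expand and how hard to penalize.

    ``classes`` is one of the eight class sets of the tuning grid;
    ``reg_multiplier`` one of the six grid values (0.0 is also accepted, for
    the unpenalized model used in diagnostics).
    """

    classes: str = "LQ"
    reg_multiplier: float = 1.0
    n_hinge_knots: int = 20

    def __post_init__(self) -> None:
        if self.classes not in FEATURE_CLASS_SETS:
            raise ValueError(f"classes must be one of {FEATURE_CLASS_SETS}")
        if self.reg_multiplier != 0.0 and self.reg_multiplier not in REG_MULTIPLIERS:
            raise ValueError(f"reg_multiplier must be 0.0 or one of {REG_MULTIPLIERS}")
        if self.n_hinge_knots < 1:
            raise ValueError("n_hinge_knots must be >= 1")

    @property
    def letters(self) -> str:
        return self.classes


def _knots(n: int) -> np.ndarray:
    """n knots evenly spaced strictly inside (0, 1)."""
    return np.arange(1, n + 1) / (n + 1)


def expand_features(
    values: pd.DataFrame | np.ndarray,
    spec: FeatureSpec,
    ranges: dict[str, tuple[float, float]],
    var_names: list[str] | None = None,
) -> tuple[np.ndarray, list[str], list[str]]:
    """Expand raw climate values into the spec's feature matrix.

    Values are clamped to the training ranges and rescaled to u = (v - lo) /
    (hi - lo). Emits, in deterministic order (class letters L,Q,P,H,T; within
    a class, variables in kept order; within hinge/threshold, knot order with
    forward hinges before reverse): the union of the spec's classes.

    Returns (matrix, feature names, feature class letter per column).
    """
    if isinstance(values, pd.DataFrame):
        var_names = list(ranges)
        vals = values[var_names].to_numpy(dtype=float)
    else:
        if var_names is None:
            var_names = list(ranges)
        vals = np.asarray(values, dtype=float)
        if vals.ndim == 1:
            vals = vals[:, None]
    u = np.empty_like(vals)
    for j, name in enumerate(var_names):
        lo, hi = ranges[name]
        if hi > lo:
            u[:, j] = np.clip((vals[:, j] - lo) / (hi - lo), 0.0, 1.0)
        else:  # degenerate range: constant column, flagged by the caller
            u[:, j] = 0.0

    cols: list[np.ndarray] = []
    names: list[str] = []
    classes: list[str] = []
    letters = spec.letters
    if "L" in letters:
        for j, name in enumerate(var_names):
            cols.append(u[:, j]); names.append(f"L({name})"); classes.append("L")
    if "Q" in letters:
        for j, name in enumerate(var_names):
            cols.append(u[:, j] ** 2); names.append(f"Q({name})"); classes.append("Q")
    if "P" in letters:
        for i in range(len(var_names)):
            for j in range(i + 1, len(var_names)):
                cols.append(u[:, i] * u[:, j])
                names.append(f"P({var_names[i]},{var_names[j]})")
                classes.append("P")
    if "H" in letters:
        ks = _knots(spec.n_hinge_knots)
        for j, name in enumerate(var_names):
            for k in ks:
                cols.append(np.maximum(0.0, (u[:, j] - k) / (1.0 - k)))
                names.append(f"H+({name},{k:.3f})"); classes.append("H")
            for k in ks:
                cols.append(np.maximum(0.0, (k - u[:, j]) / k))
                names.append(f"H-({name},{k:.3f})"); classes.append("H")
    if "T" in letters:
        ks = _knots(spec.n_hinge_knots)
        for j, name in enumerate(var_names):
            for k in ks:
                cols.append((u[:, j] > k).astype(float))
                names.append(f"T({name},{k:.3f})"); classes.append("T")
    X = np.column_stack(cols) if cols else np.empty((len(u), 0))
    return X, names, classes


def _beta_schedule(classes: list[str], n_presence: int) -> np.ndarray:
    out = np.empty(len(classes))
    for i, c in enumerate(classes):
        xs, ys = _BETA_TABLES[c]
        out[i] = np.interp(n_presence, xs, ys)
    return out


class MaxEnt:
    """Presence-background maximum-entropy model over expanded climate features.

    Parameters
    ----------
    presence, background : DataFrame
        Raw climate values (one column per variable) at presence and
        background points. Background defines both the candidate landscape
        and the normalizer of the fitted distribution.
    spec : FeatureSpec
        Feature classes and regularization multiplier.
    variable_ranges : dict, optional
        Per-variable (min, max) used for scaling/clamping; defaults to the
        background range (the training domain).
    """

    def __init__(
        self,
        presence: pd.DataFrame,
        background: pd.DataFrame,
        spec: FeatureSpec | None = None,
        variable_ranges: dict[str, tuple[float, float]] | None = None,
        min_presence: int = 5,
        min_background: int = 50,
    ):
        self.spec = spec or FeatureSpec()
        if len(presence) < min_presence:
            raise ValueError(f"need >= {min_presence} presence rows, got {len(presence)}")
        if len(background) < min_background:
            raise ValueError(f"need >= {min_background} background rows, got {len(background)}")
        self.var_names = list(presence.columns)
        if list(background.columns) != self.var_names:
            background = background[self.var_names]
        if variable_ranges is None:
            variable_ranges = {
                n: (float(background[n].min()), float(background[n].max()))
                for n in self.var_names
            }
        self.variable_ranges = variable_ranges
        X_pres, names, classes = expand_features(presence, self.spec, variable_ranges)
        X_bg, _, _ = expand_features(background, self.spec, variable_ranges)
        self._setup(X_pres, X_bg, names, classes)

    @classmethod
    def from_features(
        cls,
        X_pres: np.ndarray,
        X_bg: np.ndarray,
        spec: FeatureSpec,
        feature_names: list[str],
        feature_classes: list[str],
        var_names: list[str],
        variable_ranges: dict[str, tuple[float, float]],
        min_presence: int = 5,
        min_background: int = 50,
    ) -> "MaxEnt":
        """Build a model from already-expanded feature matrices.

        Lets callers (the tuner) expand each feature-class set once and
        reuse the matrices across regularization multipliers and CV folds.
        """
        if len(X_pres) < min_presence:
            raise ValueError(f"need >= {min_presence} presence rows, got {len(X_pres)}")
        if len(X_bg) < min_background:
            raise ValueError(f"need >= {min_background} background rows, got {len(X_bg)}")
        obj = cls.__new__(cls)
        obj.spec = spec
        obj.var_names = list(var_names)
        obj.variable_ranges = variable_ranges
        obj._setup(np.asarray(X_pres, float), np.asarray(X_bg, float),
                   list(feature_names), list(feature_classes))
        return obj

    def _setup(self, X_pres, X_bg, names, classes) -> None:
        self.degenerate_vars = [
            n for n, (lo, hi) in self.variable_ranges.items() if hi <= lo
        ]
        self.X_pres = X_pres
        self.X_bg = X_bg
        self.feature_names = names
        self.feature_classes = classes
        self.n_presence = len(X_pres)
        self.n_background = len(X_bg)

        sd = self.X_bg.std(axis=0, ddof=0)
        beta = _beta_schedule(self.feature_classes, self.n_presence)
        self.penalty = (
            self.spec.reg_multiplier * beta * sd / np.sqrt(self.n_presence)
        )

        # The solver works in background-standardized feature space: it
        # equalizes curvature across features (hinge/threshold columns at
        # extreme knots otherwise condition the problem badly) and turns the
        # per-feature penalty into the exactly equivalent
        # reg * beta_class / sqrt(n) on the standardized coefficients.
        # Features constant over the background carry no information about
        # the fitted distribution and make the unpenalized likelihood
        # unbounded; they are excluded (coefficient pinned at zero).
        self._sd = sd
        self._active = sd > 0
        self._sd_safe = np.where(self._active, sd, 1.0)
        mu = self.X_bg.mean(axis=0)
        self._Z_bg = np.where(self._active, (self.X_bg - mu) / self._sd_safe, 0.0)
        self._Z_pres = np.where(self._active, (self.X_pres - mu) / self._sd_safe, 0.0)
        self._zpen = np.where(
            self._active,
            self.spec.reg_multiplier * beta / np.sqrt(self.n_presence),
            0.0,
        )

    # objective pieces (standardized space) --------------------------------

    def _objective(self, zcoef: np.ndarray) -> float:
        eta_bg = self._Z_bg @ zcoef
        eta_p = self._Z_pres @ zcoef
        return float(
            _logsumexp(eta_bg) - np.log(self.n_background)
            - eta_p.mean()
            + np.abs(zcoef) @ self._zpen
        )

    def _smooth_grad(self, zcoef: np.ndarray) -> tuple[float, np.ndarray]:
        eta_bg = self._Z_bg @ zcoef
        lse = _logsumexp(eta_bg)
        q = np.exp(eta_bg - lse)
        smooth = float(lse - np.log(self.n_background) - (self._Z_pres @ zcoef).mean())
        grad = q @ self._Z_bg - self._Z_pres.mean(axis=0)
        return smooth, grad

    def fit(
        self,
        maxiter: int = 10_000,
        tol: float = 1e-6,
        start_params: np.ndarray | None = None,
    ) -> "MaxEntResults":
        """Solve by proximal Newton: IRLS outer steps, each minimizing the
        L1-penalized local quadratic model by cyclic coordinate descent,
        with backtracking on the true penalized objective and adaptive
        (Levenberg-style) damping when the local model is near-singular.

        Converged when the max absolute change of the (standardized)
        coefficients between outer steps falls below ``tol``; raises
        ConvergenceError after ``maxiter`` outer iterations.
        ``start_params`` (raw-feature scale, e.g. a previous fit on the same
        matrices) warm-starts the solver.
        """
        Z = self._Z_bg
        n_feat = Z.shape[1]
        if start_params is not None:
            coef = np.asarray(start_params, dtype=float) * self._sd_safe
            coef[~self._active] = 0.0
        else:
            coef = np.zeros(n_feat)
        lam = self._zpen
        pres_mean = self._Z_pres.mean(axis=0)
        ridge = 1e-6
        it = 0

        def full_grad(c):
            eta = Z @ c
            q = np.exp(eta - _logsumexp(eta))
            return q @ Z - pres_mean

        # working-set strategy: optimize only over features that are nonzero
        # or violate the KKT conditions; grow the set until no violators
        # remain, then the full-problem optimum is certified
        active = (np.abs(full_grad(coef)) > lam) | (lam <= 0) | (coef != 0)
        active &= self._active
        for _ in range(50):
            idx = np.flatnonzero(active)
            if idx.size:
                Za = np.ascontiguousarray(Z[:, idx])
                Pa_mean = pres_mean[idx]
                lam_a = lam[idx]
                ca = coef[idx]
                obj = self._objective(coef)
                damp = 0.0
                while it < maxiter:
                    it += 1
                    eta = Za @ ca
                    lse = _logsumexp(eta)
                    q = np.exp(eta - lse)
                    m1 = q @ Za
                    grad = m1 - Pa_mean
                    H = (Za * q[:, None]).T @ Za - np.outer(m1, m1)
                    if damp > 0.0:
                        H[np.diag_indices_from(H)] += damp
                    diag = np.clip(np.diag(H).copy(), ridge, None)
                    # inner CD: min_w (grad - H ca).w + 1/2 w'Hw + sum lam|w|
                    b = H @ ca - grad
                    w = ca.copy()
                    Hw = H @ w
                    w = _cd_kernel(H, diag, b, lam_a, w, Hw, 0.1 * tol, 1000)
                    direction = w - ca
                    step = 1.0
                    for _ in range(30):  # backtrack on the true objective
                        cand = ca + step * direction
                        coef[idx] = cand
                        cand_obj = self._objective(coef)
                        if cand_obj <= obj + 1e-12:
                            break
                        step *= 0.5
                    else:
                        raise ConvergenceError(self.spec)
                    # damping feedback: grow when the full Newton step was
                    # rejected, relax when it was accepted
                    damp = max(damp * 4.0, 1e-3) if step < 1.0 else damp * 0.25
                    delta = np.max(np.abs(step * direction))
                    ca = cand
                    obj = cand_obj
                    if delta < tol:
                        break
                    if np.abs(ca).max() > 1e6:
                        # presence means outside the background feature hull:
                        # the likelihood is unbounded, stop early
                        raise ConvergenceError(self.spec)
                else:
                    raise ConvergenceError(self.spec)
                coef[idx] = ca
            violators = (~active) & self._active & (np.abs(full_grad(coef)) > lam + 1e-9)
            if not violators.any():
                break
            active |= violators
        else:
            raise ConvergenceError(self.spec)
        return self._make_results(coef / self._sd_safe, n_iter=max(it, 1))

    def _make_results(self, coef: np.ndarray, n_iter: int) -> "MaxEntResults":
        eta_bg = self.X_bg @ coef
        offset = float(_logsumexp(eta_bg))
        p = np.exp(eta_bg - offset)
        with np.errstate(divide="ignore", invalid="ignore"):
            ent = float(-np.sum(np.where(p > 0, p * np.log(p), 0.0)))
        return MaxEntResults(
            model=self,
            spec=self.spec,
            var_names=self.var_names,
            variable_ranges=self.variable_ranges,
            params=coef,
            feature_names=self.feature_names,
            offset=offset,
            entropy=ent,
            n_iter=n_iter,
        )


@dataclass
class MaxEntResults:
    """A fitted maximum-entropy niche model.

    Carries everything needed to project suitability without refitting:
    feature spec, training ranges, sparse coefficients, the log-partition
    offset, and the entropy H of the fitted background distribution that
    parameterizes the logistic output.
    """

    spec: FeatureSpec
    var_names: list[str]
    variable_ranges: dict[str, tuple[float, float]]
    params: np.ndarray
    feature_names: list[str]
    offset: float
    entropy: float
    n_iter: int = 0
    model: "MaxEnt | None" = None
    threshold: float | None = None
    metrics: dict = field(default_factory=dict)
    tau: float = 0.5  # assumed prevalence of the logistic transform

    # -- prediction --------------------------------------------------------

    def linear_predictor(self, values: pd.DataFrame) -> np.ndarray:
        missing = [v for v in self.var_names if v not in values.columns]
        if missing:
            raise KeyError(f"missing variable columns {missing}")
        X, _, _ = expand_features(values[self.var_names], self.spec, self.variable_ranges)
        return X @ self.params

    def predict(self, values: pd.DataFrame, scale: str = "logistic") -> np.ndarray:
        """Suitability per row; ``raw`` (sums to 1 over training background)
        or ``logistic`` (in [0, 1], 0.5 at an uninformative predictor).

        Rows with any NaN climate value yield NaN.
        """
        eta = self.linear_predictor(values.fillna(0.0))
        bad = values[self.var_names].isna().any(axis=1).to_numpy()
        raw = np.exp(eta - self.offset)
        if scale == "raw":
            out = raw
        elif scale == "logistic":
            s = np.exp(self.entropy) * raw * self.tau
            out = s / (1.0 - self.tau + s)
        else:
            raise ValueError("scale must be 'raw' or 'logistic'")
        out = np.asarray(out, dtype=float)
        out[bad] = np.nan
        return out

    @property
    def n_nonzero(self) -> int:
        return int(np.sum(self.params != 0))

    def percent_contribution(self) -> dict[str, float]:
        return dict(self.metrics.get("percent_contribution", {}))

    def summary(self) -> str:
        lines = [
            "Maximum-entropy niche model",
            "===========================",
            f"feature classes:     {self.spec.classes}",
            f"reg multiplier:      {self.spec.reg_multiplier}",
            f"variables:           {', '.join(self.var_names)}",
            f"nonzero features:    {self.n_nonzero} / {len(self.params)}",
            f"entropy H:           {self.entropy:.4f}",
            f"threshold:           {self.threshold if self.threshold is not None else 'unset'}",
        ]
        for k in ("mean_train_AUC", "mean_test_AUC", "mean_BCI", "AUC_diff"):
            if k in self.metrics:
                lines.append(f"{k + ':':<21}{self.metrics[k]:.4f}")
        pc = self.percent_contribution()
        if pc:
            lines.append("percent contribution:")
            for v, c in sorted(pc.items(), key=lambda kv: -kv[1]):
                lines.append(f"  {v:<12}{c:6.1f}%")
        active = [
            (n, c) for n, c in zip(self.feature_names, self.params) if c != 0
        ]
        lines.append(f"active features ({len(active)}):")
        for n, c in sorted(active, key=lambda nc: -abs(nc[1]))[:15]:
            lines.append(f"  {n:<22}{c:+.4f}")
        return "\n".join(lines)

    def plot_response(self, variable: str, ax=None, n: int = 200):
        """Marginal response curve: vary one variable, others at mid-range."""
        import matplotlib.pyplot as plt

        grid = {}
        for v in self.var_names:
            lo, hi = self.variable_ranges[v]
            grid[v] = np.full(n, (lo + hi) / 2.0)
        lo, hi = self.variable_ranges[variable]
        grid[variable] = np.linspace(lo, hi, n)
        df = pd.DataFrame(grid)
        y = self.predict(df, scale="logistic")
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(grid[variable], y)
        ax.set_xlabel(variable)
        ax.set_ylabel("suitability (logistic)")
        return ax

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        nz = np.flatnonzero(self.params)
        return {
            "spec": {
                "classes": self.spec.classes,
                "reg_multiplier": self.spec.reg_multiplier,
                "n_hinge_knots": self.spec.n_hinge_knots,
            },
            "var_names": self.var_names,
            "variable_ranges": {k: list(v) for k, v in self.variable_ranges.items()},
            "n_features": len(self.params),
            "coefficients": {int(i): float(self.params[i]) for i in nz},
            "feature_names": self.feature_names,
            "offset": self.offset,
            "entropy": self.entropy,
            "tau": self.tau,
            "threshold": self.threshold,
            "metrics": _jsonable(self.metrics),
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))

    @classmethod
    def from_dict(cls, d: dict) -> "MaxEntResults":
        spec = FeatureSpec(**d["spec"])
        params = np.zeros(d["n_features"])
        for i, c in d["coefficients"].items():
            params[int(i)] = c
        return cls(
            spec=spec,
            var_names=list(d["var_names"]),
            variable_ranges={k: tuple(v) for k, v in d["variable_ranges"].items()},
            params=params,
            feature_names=list(d["feature_names"]),
            offset=d["offset"],
            entropy=d["entropy"],
            tau=d.get("tau", 0.5),
            threshold=d.get("threshold"),
            metrics=d.get("metrics", {}),
        )

    @classmethod
    def load(cls, path: str | Path) -> "MaxEntResults":
        return cls.from_dict(json.loads(Path(path).read_text()))


def fit_lq_optimum(
    presence: pd.DataFrame,
    background: pd.DataFrame,
    variable: str,
    reg_multiplier: float = 0.0,
) -> float:
    """Estimate a species' niche optimum on one variable from an LQ fit.

    Fits a single-variable linear+quadratic model; for a concave response
    (negative quadratic coefficient) the optimum is the stationary point
    ``-c_L / (2 c_Q)`` mapped back to raw units and clipped to the training
    range; a non-concave fit returns the range endpoint with the higher
    suitability (a boundary niche).
    """
    spec = FeatureSpec(classes="LQ", reg_multiplier=reg_multiplier)
    res = MaxEnt(presence[[variable]], background[[variable]], spec).fit()
    c_l = res.params[res.feature_names.index(f"L({variable})")]
    c_q = res.params[res.feature_names.index(f"Q({variable})")]
    lo, hi = res.variable_ranges[variable]
    if c_q < 0:
        u_opt = float(np.clip(-c_l / (2.0 * c_q), 0.0, 1.0))
    else:
        u_opt = 1.0 if c_l + c_q > 0 else 0.0
    return lo + u_opt * (hi - lo)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj
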