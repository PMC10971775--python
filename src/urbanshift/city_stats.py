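"""Statistical summaries of the turnover projections.

Per-city gained/lost species counts are overdispersed, so effects of
scenario, historic climate (MAT, MAP) and historic richness are tested with
log-link negative-binomial GLMs (dispersion estimated by maximum
likelihood) and term-wise likelihood-ratio chi-square tests against nested
models. The relationship between city population and projected change is
summarized by a Pearson correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats


@dataclass
class GLMTermTest:
    term: str
    chi2: float
    df: int
    df_resid: int
    p: float


@dataclass
class NBGLMResult:
    """Coefficients and likelihood-ratio term tests of one count model."""

    response: str
    formula: str
    coefficients: pd.Series
    stderrs: pd.Series
    term_tests: list[GLMTermTest]
    family: str  # 'negative_binomial' or the quasi-poisson fallback
    llf: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"term": t.term, "chi2": t.chi2, "df": t.df,
              "df_resid": t.df_resid, "p": t.p} for t in self.term_tests]
        )

    def report(self) -> str:
        lines = [f"NB GLM: {self.formula}  [{self.family}]"]
        for t in self.term_tests:
            lines.append(
                f"  {t.term:<22} chi2_{t.df},{t.df_resid} = {t.chi2:.2f}, p = {t.p:.4g}"
            )
        return "\n".join(lines)


_TERM_FORMULAS = {
    "SSP": "C(scenario)",
    "MAT": "historic_MAT",
    "MAP": "historic_MAP",
    "historic_richness": "historic_richness",
    "SSP_x_richness": "C(scenario):historic_richness",
}


def _fit_nb(formula: str, data: pd.DataFrame):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.negativebinomial(formula, data=data)
        res = model.fit(disp=0, maxiter=200, method="bfgs")
        if not res.mle_retvals.get("converged", True):
            res = model.fit(disp=0, maxiter=500, method="nm",
                            start_params=res.params)
    return res


def nb_glm_test(
    table: pd.DataFrame,
    response: str,
    predictors: list[str] = ("SSP",),
) -> NBGLMResult:
    """Negative-binomial GLM of a count response with LR chi-square tests.

    ``table`` needs one row per city x SSP with columns for the response and
    whichever of scenario, historic_MAT, historic_MAP, historic_richness,
    population the predictors reference. Each term's chi-square comes from a
    likelihood-ratio comparison against the model with that term removed
    (dispersion re-estimated in both fits). Falls back to a quasi-Poisson
    fit, with a warning, if the NB likelihood fails to converge.
    """
    if len(table) < 10:
        raise ValueError("need at least 10 rows")
    resp = table[response]
    if (resp < 0).any() or not np.allclose(resp, resp.round()):
        raise ValueError("response must be nonnegative integer counts")
    preds = list(predictors)
    unknown = set(preds) - set(_TERM_FORMULAS)
    if unknown:
        raise ValueError(f"unknown predictors {sorted(unknown)}")
    rhs = " + ".join(_TERM_FORMULAS[p] for p in preds) or "1"
    formula = f"{response} ~ {rhs}"

    try:
        full = _fit_nb(formula, table)
        family = "negative_binomial"
        fit = _fit_nb
    except Exception:
        warnings.warn("NB fit failed to converge; falling back to quasi-Poisson")
        family = "quasi_poisson"

        def fit(f, d):
            return smf.glm(f, data=d, family=sm.families.Poisson()).fit(scale="X2")

        full = fit(formula, table)

    tests = []
    for p in preds:
        reduced_terms = [_TERM_FORMULAS[q] for q in preds if q != p]
        red_formula = f"{response} ~ {' + '.join(reduced_terms) or '1'}"
        red = fit(red_formula, table)
        lr = 2.0 * (full.llf - red.llf)
        df = int(full.df_model - red.df_model)
        if family == "quasi_poisson":  # scaled LR for the fallback
            lr = lr / float(full.scale)
        df_resid = int(full.df_resid)
        pval = float(stats.chi2.sf(max(lr, 0.0), df)) if df > 0 else float("nan")
        tests.append(GLMTermTest(term=p, chi2=float(max(lr, 0.0)), df=df,
                                 df_resid=df_resid, p=pval))
    return NBGLMResult(
        response=response, formula=formula, coefficients=full.params,
        stderrs=full.bse, term_tests=tests, family=family, llf=float(full.llf),
    )


def population_correlation(table: pd.DataFrame, response: str) -> dict[str, float]:
    """Pearson correlation of per-city response (mean over SSPs) vs population.

    Returns {r, p, n}; zero-variance inputs yield NaN r with a flag.
    """
    per_city = table.groupby("city").agg(
        resp=(response, "mean"), population=("population", "first")
    )
    if len(per_city) < 3:
        raise ValueError("need at least 3 cities")
    x = per_city["population"].to_numpy(dtype=float)
    y = per_city["resp"].to_numpy(dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        return {"r": float("nan"), "p": float("nan"), "n": len(per_city),
                "degenerate": True}
    r, p = stats.pearsonr(x, y)
    return {"r": float(r), "p": float(p), "n": int(len(per_city))}


def stats_report(
    city_table: pd.DataFrame,
    city_covariates: pd.DataFrame,
) -> tuple[pd.DataFrame, str]:
    """The statistical summary layer over the turnover city table.

    ``city_covariates``: one row per city with historic_MAT, historic_MAP,
    population, historic_richness. Fits NB GLMs of gains and losses on SSP,
    richness, MAT and MAP, plus the population correlations; returns a tidy
    frame of term tests and a human-readable text block.
    """
    merged = city_table.merge(city_covariates, on="city", how="left",
                              suffixes=("", "_cov"))
    out_rows, text = [], []
    for response in ("gained", "lost"):
        for preds in (["SSP"], ["historic_richness", "SSP", "SSP_x_richness"],
                      ["MAT", "MAP"]):
            try:
                res = nb_glm_test(merged, response, preds)
            except Exception as err:  # degenerate demo tables are legal
                text.append(f"[{response} ~ {'+'.join(preds)}] failed: {err}")
                continue
            text.append(res.report())
            for t in res.term_tests:
                out_rows.append({"response": response, "model": "+".join(preds),
                                 "term": t.term, "chi2": t.chi2, "df": t.df,
                                 "df_resid": t.df_resid, "p": t.p,
                                 "family": res.family})
        corr = population_correlation(merged, response)
        text.append(
            f"Pearson {response} vs population: r = {corr['r']:.2f}, "
            f"p = {corr['p']:.2g} (n = {corr['n']})"
        )
        out_rows.append({"response": response, "model": "population_corr",
                         "term": "population", "chi2": np.nan, "df": np.nan,
                         "df_resid": corr["n"] - 2, "p": corr["p"],
                         "family": "pearson", "r": corr["r"]})
    return pd.DataFrame(out_rows), "\n".join(text)
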