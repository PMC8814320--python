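"""Mutually adjusted multilevel models of income constructs and
cardiovascular outcomes.

One model per outcome includes all four income exposures simultaneously —
absolute equivalized income (per HKD 1,000), Yitzhaki deprivation (per HKD
1,000), neighborhood median-income quartile and neighborhood Gini quartile
(indicator contrasts against the 1st quartile) — plus age, sex and
birthplace. Continuous outcomes use a linear mixed model with random
intercepts for household nested in neighborhood, reported with intraclass
correlations. Binary outcomes default to a single-level logistic model with
household-cluster-robust standard errors (flagged in the output); a
variational-Bayes mixed logistic model is available as
``binary_method="mixed_vb"`` when latent-scale ICCs are wanted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = ["AssocResult", "icc", "bonferroni_flag", "fit_income_models",
            "results_to_frame"]

EXPOSURE_TERMS = [
    ("absolute_income_1000", "Absolute household income (per HKD 1,000)"),
    ("yitzhaki_1000", "Relative household income deprivation (per HKD 1,000)"),
    ("nbhd_median_q2", "Absolute neighborhood median income: 2nd quartile"),
    ("nbhd_median_q3", "Absolute neighborhood median income: 3rd quartile"),
    ("nbhd_median_q4", "Absolute neighborhood median income: 4th quartile"),
    ("nbhd_gini_q2", "Neighborhood income inequality: 2nd quartile"),
    ("nbhd_gini_q3", "Neighborhood income inequality: 3rd quartile"),
    ("nbhd_gini_q4", "Neighborhood income inequality: 4th quartile"),
]

BINARY_OUTCOMES = {"cvd", "diabetes"}


@dataclass
class AssocResult:
    outcome: str
    exposure: str
    estimate: float          # beta (outcome units) or OR
    ci_low: float
    ci_high: float
    p: float
    n: int
    icc_household: float
    icc_neighborhood: float
    is_odds_ratio: bool
    significant: bool | None = None
    bonferroni_threshold: float | None = None
    fit_method: str = "mixed"


def icc(variance_components: dict) -> dict:
    """Intraclass correlations for household-in-neighborhood nesting.

    ``variance_components`` maps ``neighborhood``/``household``/``residual``
    to variances. ICC(neighborhood) = s2_nbhd / total; ICC(household) =
    (s2_nbhd + s2_hh) / total — the correlation of two members of the same
    household, who also share a neighborhood. For latent-scale logistic
    models pass ``residual = pi**2 / 3``.
    """
    s2_nb = variance_components.get("neighborhood", 0.0)
    s2_hh = variance_components.get("household", 0.0)
    s2_e = variance_components["residual"]
    if s2_nb < 0 or s2_hh < 0 or s2_e <= 0:
        raise ValueError("variances must be non-negative, residual positive")
    total = s2_nb + s2_hh + s2_e
    return {"neighborhood": s2_nb / total, "household": (s2_nb + s2_hh) / total}


def bonferroni_flag(p: float, n_tests: int, alpha: float = 0.05) -> tuple[bool, float]:
    """Bonferroni significance flag and the corrected threshold alpha/n."""
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    threshold = alpha / n_tests
    return bool(p < threshold), threshold


def _design_frame(cohort: pd.DataFrame, constructs: pd.DataFrame) -> pd.DataFrame:
    df = cohort.merge(constructs, on="individual_id", how="inner").copy()
    df["absolute_income_1000"] = df["absolute_income"] / 1000.0
    df["yitzhaki_1000"] = df["yitzhaki"] / 1000.0
    for q in (2, 3, 4):
        df[f"nbhd_median_q{q}"] = (df["nbhd_median_quartile"] == q).astype(float)
        df[f"nbhd_gini_q{q}"] = (df["nbhd_gini_quartile"] == q).astype(float)
    df["male"] = (df["sex"] == "male").astype(float)
    df["born_local"] = (df["birthplace"] == "local").astype(float)
    return df


_FIXED = [t for t, _ in EXPOSURE_TERMS] + ["age", "male", "born_local"]


def _check_design(df: pd.DataFrame) -> None:
    for col in _FIXED:
        if df[col].nunique() <= 1:
            raise ValueError(f"singular design: column {col!r} is constant")


def fit_income_models(
    cohort: pd.DataFrame,
    constructs: pd.DataFrame,
    outcomes=("bmi", "bodyfat", "sbp", "dbp", "cvd", "diabetes"),
    binary_method: str = "cluster_robust",
    n_tests: int | None = None,
    alpha: float = 0.05,
) -> list[AssocResult]:
    """Fit one mutually adjusted model per outcome; returns one
    :class:`AssocResult` per exposure term per outcome.

    ``n_tests`` for the Bonferroni flag defaults to (number of exposure
    terms) x (number of outcomes) — 48 for the full grid of 8 terms by 6
    outcomes. Missing outcome or covariate values are dropped per model
    (complete-case), so ``n`` can differ across outcomes.
    """
    df_all = _design_frame(cohort, constructs)
    results: list[AssocResult] = []
    if n_tests is None:
        n_tests = len(EXPOSURE_TERMS) * len(outcomes)

    for outcome in outcomes:
        if outcome not in df_all.columns:
            raise ValueError(f"outcome column {outcome!r} absent from cohort")
        cols = _FIXED + [outcome, "household_id", "neighborhood_id"]
        df = df_all.dropna(subset=cols)
        _check_design(df)
        n = len(df)
        formula = f"{outcome} ~ " + " + ".join(_FIXED)

        if outcome in BINARY_OUTCOMES:
            rows = _fit_binary(df, formula, outcome, binary_method, n)
        else:
            rows = _fit_linear_mixed(df, formula, outcome, n)
        for r in rows:
            r.significant, r.bonferroni_threshold = bonferroni_flag(r.p, n_tests, alpha)
        results.extend(rows)
    return results


def _fit_linear_mixed(df, formula, outcome, n) -> list[AssocResult]:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(
            formula, df, groups=df["neighborhood_id"], re_formula="1",
            vc_formula={"household": "0 + C(household_id)"},
        )
        # lbfgs is unreliable for this nested variance-component profile
        # (converges to spurious optima, esp. on the zero boundary); powell
        # is slower but lands on the right components
        fit = model.fit(reml=True, method="powell")
    s2_nb = float(np.asarray(fit.cov_re)[0, 0])
    s2_hh = float(fit.vcomp[0]) if len(fit.vcomp) else 0.0
    iccs = icc({"neighborhood": s2_nb, "household": s2_hh, "residual": float(fit.scale)})
    out = []
    ci = fit.conf_int()
    for term, label in EXPOSURE_TERMS:
        out.append(AssocResult(
            outcome=outcome, exposure=label,
            estimate=float(fit.params[term]),
            ci_low=float(ci.loc[term, 0]), ci_high=float(ci.loc[term, 1]),
            p=float(fit.pvalues[term]), n=n,
            icc_household=iccs["household"], icc_neighborhood=iccs["neighborhood"],
            is_odds_ratio=False, fit_method="linear_mixed",
        ))
    return out


def _fit_binary(df, formula, outcome, method, n) -> list[AssocResult]:
    if method == "mixed_vb":
        try:
            return _fit_binary_mixed_vb(df, formula, outcome, n)
        except Exception as exc:  # fall back, flagged
            warnings.warn(f"mixed_vb logistic fit failed ({exc}); "
                          "falling back to cluster-robust logistic")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.logit(formula, df)
        fit = model.fit(disp=0, cov_type="cluster",
                        cov_kwds={"groups": df["household_id"]})
    ci = fit.conf_int()
    out = []
    for term, label in EXPOSURE_TERMS:
        out.append(AssocResult(
            outcome=outcome, exposure=label,
            estimate=float(np.exp(fit.params[term])),
            ci_low=float(np.exp(ci.loc[term, 0])),
            ci_high=float(np.exp(ci.loc[term, 1])),
            p=float(fit.pvalues[term]), n=n,
            icc_household=np.nan, icc_neighborhood=np.nan,
            is_odds_ratio=True, fit_method="logistic_cluster_robust",
        ))
    return out


def _fit_binary_mixed_vb(df, formula, outcome, n) -> list[AssocResult]:
    """Variational-Bayes mixed logistic with household and neighborhood
    random intercepts; latent-scale ICCs use residual pi^2/3."""
    from statsmodels.genmod.bayes_mixed_glm import BinomialBayesMixedGLM

    vc_formulas = {"household": "0 + C(household_id)",
                   "neighborhood": "0 + C(neighborhood_id)"}
    model = BinomialBayesMixedGLM.from_formula(formula, vc_formulas, df)
    fit = model.fit_vb()
    names = list(model.exog_names)
    means = fit.fe_mean
    sds = fit.fe_sd
    vc_sd = dict(zip(model.vcp_names, np.exp(fit.vcp_mean)))
    iccs = icc({"neighborhood": vc_sd.get("neighborhood", 0.0) ** 2,
                "household": vc_sd.get("household", 0.0) ** 2,
                "residual": np.pi ** 2 / 3.0})
    from scipy import stats as sps
    out = []
    for term, label in EXPOSURE_TERMS:
        k = names.index(term)
        z = means[k] / sds[k]
        out.append(AssocResult(
            outcome=outcome, exposure=label,
            estimate=float(np.exp(means[k])),
            ci_low=float(np.exp(means[k] - 1.959964 * sds[k])),
            ci_high=float(np.exp(means[k] + 1.959964 * sds[k])),
            p=float(2 * sps.norm.sf(abs(z))), n=n,
            icc_household=iccs["household"], icc_neighborhood=iccs["neighborhood"],
            is_odds_ratio=True, fit_method="logistic_mixed_vb",
        ))
    return out


def results_to_frame(results: list[AssocResult]) -> pd.DataFrame:
    """Exposure-by-outcome grid of estimates and CIs (long format)."""
    return pd.DataFrame([{
        "outcome": r.outcome, "exposure": r.exposure,
        "estimate": r.estimate, "ci_low": r.ci_low, "ci_high": r.ci_high,
        "p": r.p, "n": r.n, "odds_ratio": r.is_odds_ratio,
        "icc_household": r.icc_household, "icc_neighborhood": r.icc_neighborhood,
        "bonferroni_significant": r.significant,
        "bonferroni_threshold": r.bonferroni_threshold,
        "fit_method": r.fit_method,
    } for r in results])
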