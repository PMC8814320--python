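"""Counterfactual mediation of income deprivation effects through cortisol.

The exposure is relative household income deprivation (scaled per HKD
1,000), the mediator is natural-log serum cortisol, and the outcome is a
cardiovascular trait (linear family) or disease indicator (logistic family).
The mediator model is linear; the outcome model includes the exposure, the
mediator, their product (exposure-mediator interaction) and covariates.
Natural direct/indirect effects, total effect and proportion mediated follow
the regression-based closed forms; for binary outcomes, the rare-outcome
odds-ratio approximation is used and a warning is attached above 10%
prevalence. Confidence intervals come from an individual-resampling
percentile bootstrap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = ["MediationModels", "MediationResult", "fit_mediation_models",
           "natural_effects", "mediation_bootstrap"]

DEFAULT_COVARIATES = ("age", "male", "born_local")


@dataclass
class MediationModels:
    """Fitted mediator and outcome models.

    Mediator:  M = beta0 + beta1*A + beta2' C + eps,  eps ~ N(0, sigma2)
    Outcome:   g(E[Y]) = theta0 + theta1*A + theta2*M + theta3*A*M + theta4' C
    with g identity (linear family) or logit (logistic family).
    """

    beta0: float
    beta1: float
    beta2: np.ndarray
    sigma2: float
    theta0: float
    theta1: float
    theta2: float
    theta3: float
    theta4: np.ndarray
    family: str                      # "linear" | "logistic"
    covariate_names: tuple
    covariate_means: np.ndarray
    exposure_mean: float
    p_interaction: float
    n: int
    outcome_prevalence: float | None = None
    warnings: list = field(default_factory=list)


@dataclass
class MediationResult:
    nde: float
    nie: float
    te: float
    proportion_mediated: float | None
    p_interaction: float
    family: str
    n: int
    ci: dict = field(default_factory=dict)   # name -> (lo, hi)
    warnings: list = field(default_factory=list)


def _prepare(cohort: pd.DataFrame, exposure: str, mediator: str, outcome: str,
             covariates=DEFAULT_COVARIATES) -> pd.DataFrame:
    df = cohort.copy()
    if "male" in covariates and "male" not in df.columns:
        df["male"] = (df["sex"] == "male").astype(float)
    if "born_local" in covariates and "born_local" not in df.columns:
        df["born_local"] = (df["birthplace"] == "local").astype(float)
    cols = [exposure, mediator, outcome, *covariates]
    return df.dropna(subset=cols)[cols].astype(float)


def fit_mediation_models(
    cohort: pd.DataFrame,
    exposure: str = "yitzhaki_1000",
    mediator: str = "log_cortisol",
    outcome: str = "sbp",
    covariates=DEFAULT_COVARIATES,
    family: str | None = None,
) -> MediationModels:
    """Fit the linear mediator model and the (linear or logistic) outcome
    model with exposure-mediator interaction on complete cases.

    ``family`` is inferred from the outcome values when not given: a {0,1}
    outcome is treated as logistic. The p-for-interaction is the Wald test
    of the product term.
    """
    df = _prepare(cohort, exposure, mediator, outcome, covariates)
    n = len(df)
    if n == 0:
        raise ValueError("no complete cases")
    m = df[mediator].to_numpy()
    if np.var(m) == 0:
        raise ValueError("zero-variance mediator")
    a = df[exposure].to_numpy()
    y = df[outcome].to_numpy()
    C = df[list(covariates)].to_numpy()

    if family is None:
        family = "logistic" if set(np.unique(y)) <= {0.0, 1.0} else "linear"

    # mediator model (always linear)
    Xm = np.column_stack([np.ones(n), a, C])
    med_fit = sm.OLS(m, Xm).fit()
    k = Xm.shape[1]
    sigma2 = float(med_fit.ssr / (n - k))

    # outcome model with interaction
    Xy = np.column_stack([np.ones(n), a, m, a * m, C])
    warns: list[str] = []
    if family == "logistic":
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                out_fit = sm.Logit(y, Xy).fit(disp=0, maxiter=200)
        except Exception as exc:
            raise ValueError(f"logistic outcome model failed (separation?): {exc}")
        prev = float(y.mean())
        if prev > 0.10:
            warns.append(f"outcome prevalence {prev:.2f} > 0.10: rare-outcome "
                         "odds-ratio approximation may be inaccurate")
    else:
        out_fit = sm.OLS(y, Xy).fit()
        prev = None

    return MediationModels(
        beta0=float(med_fit.params[0]), beta1=float(med_fit.params[1]),
        beta2=np.asarray(med_fit.params[2:], dtype=float), sigma2=sigma2,
        theta0=float(out_fit.params[0]), theta1=float(out_fit.params[1]),
        theta2=float(out_fit.params[2]), theta3=float(out_fit.params[3]),
        theta4=np.asarray(out_fit.params[4:], dtype=float),
        family=family, covariate_names=tuple(covariates),
        covariate_means=C.mean(axis=0), exposure_mean=float(a.mean()),
        p_interaction=float(out_fit.pvalues[3]), n=n,
        outcome_prevalence=prev, warnings=warns,
    )


def natural_effects(
    models: MediationModels,
    a: float | None = None,
    a_star: float | None = None,
    c: np.ndarray | None = None,
) -> MediationResult:
    """Natural direct/indirect effects for the contrast a vs a_star at
    covariate values ``c`` (default: sample means; sex and birthplace enter
    at their observed proportions).

    Defaults: ``a_star`` is the sample-mean exposure and ``a`` is one unit
    above it (one unit = HKD 1,000 of deprivation with the default scaling).
    Linear family returns effects in outcome units with TE = NDE + NIE
    exactly; logistic family returns log odds ratios under the rare-outcome
    approximation, with the proportion mediated computed on the OR scale.
    """
    if a_star is None:
        a_star = models.exposure_mean
    if a is None:
        a = a_star + 1.0
    if a == a_star:
        raise ValueError("a and a_star must differ")
    c = models.covariate_means if c is None else np.asarray(c, dtype=float)
    b0, b1, b2 = models.beta0, models.beta1, models.beta2
    t1, t2, t3 = models.theta1, models.theta2, models.theta3
    s2 = models.sigma2
    bc = float(b2 @ c)
    da = a - a_star

    if models.family == "linear":
        nde = (t1 + t3 * (b0 + b1 * a_star + bc)) * da
        nie = (t2 + t3 * a) * b1 * da
        te = nde + nie
        pm = None if te == 0 else nie / te
    else:
        log_or_nde = (t1 + t3 * (b0 + b1 * a_star + bc + t2 * s2)) * da \
            + 0.5 * t3 ** 2 * s2 * (a ** 2 - a_star ** 2)
        log_or_nie = (t2 + t3 * a) * b1 * da
        nde, nie = log_or_nde, log_or_nie
        te = nde + nie
        or_nde, or_nie = np.exp(nde), np.exp(nie)
        denom = or_nde * or_nie - 1.0
        pm = None if denom == 0 else float(or_nde * (or_nie - 1.0) / denom)

    return MediationResult(
        nde=float(nde), nie=float(nie), te=float(te), proportion_mediated=pm,
        p_interaction=models.p_interaction, family=models.family, n=models.n,
        warnings=list(models.warnings),
    )


def mediation_bootstrap(
    cohort: pd.DataFrame,
    n_boot: int = 1000,
    seed: int = 0,
    a: float | None = None,
    a_star: float | None = None,
    max_failure_fraction: float = 0.05,
    **fit_kwargs,
) -> MediationResult:
    """Percentile bootstrap CIs for NDE/NIE/TE/PM by individual-level
    resampling, refitting both models in every replicate.

    Deterministic for a fixed ``seed``. Aborts if more than
    ``max_failure_fraction`` of replicates fail to fit.
    """
    if n_boot < 200:
        raise ValueError("n_boot must be >= 200 for stable percentile CIs")
    models = fit_mediation_models(cohort, **fit_kwargs)
    point = natural_effects(models, a=a, a_star=a_star)
    # contrast fixed at the full-sample default so replicates are comparable
    a_star_fix = models.exposure_mean if a_star is None else a_star
    a_fix = (a_star_fix + 1.0) if a is None else a

    rng = np.random.default_rng(seed)
    n = len(cohort)
    draws = {"nde": [], "nie": [], "te": [], "pm": []}
    failures = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        try:
            rep = natural_effects(
                fit_mediation_models(cohort.iloc[idx], **fit_kwargs),
                a=a_fix, a_star=a_star_fix)
        except (ValueError, np.linalg.LinAlgError):
            failures += 1
            continue
        draws["nde"].append(rep.nde)
        draws["nie"].append(rep.nie)
        draws["te"].append(rep.te)
        if rep.proportion_mediated is not None:
            draws["pm"].append(rep.proportion_mediated)
    if failures > max_failure_fraction * n_boot:
        raise RuntimeError(f"{failures}/{n_boot} bootstrap replicates failed")

    for name, vals in draws.items():
        if vals:
            lo, hi = np.percentile(vals, [2.5, 97.5])
            point.ci[name] = (float(lo), float(hi))
    return point
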