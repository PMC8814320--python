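"""One-sample Mendelian randomization of cortisol on cardiovascular traits.

The genetic instrument is an internally weighted polygenic score (PGS) for
log cortisol: per-SNP marginal slopes are estimated by generalized least
squares under a kinship covariance (variance components by Haseman-Elston
regression), each SNP is re-aligned to its cortisol-increasing allele, and
the score is the weighted allele-dosage sum. Causal effects are estimated by
two-stage least squares for continuous outcomes and by a multiplicative
structural mean model solved by GMM (just-identified moments, percentile
bootstrap CIs) for binary outcomes, with first-stage partial F / partial R-
squared diagnostics and a Hausman comparison against the observational
(linear or Poisson) estimate adjusted for age and sex.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats
from scipy.linalg import solve_triangular

from .geno import GenotypeMatrix

__all__ = ["SnpWeight", "MRResult", "haseman_elston", "gls_snp_weights",
           "build_pgs", "tsls", "mgmm", "hausman", "observational_reference"]


@dataclass
class SnpWeight:
    snp_id: str
    increasing_allele: str       # cortisol-increasing allele
    weight: float                # log(ug/dL) per allele, >= 0 after alignment
    se: float
    n: int
    flipped: bool                # True if counted allele differs from the
                                 # matrix's effect allele


@dataclass
class MRResult:
    method: str                  # "2SLS" | "MGMM"
    estimate: float              # mean difference or risk ratio
    ci_low: float
    ci_high: float
    first_stage_F: float
    first_stage_partial_r2: float
    hausman_p: float | None
    hausman_stat: float | None
    n: int
    warnings: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# kinship-GLS instrument weights
# ---------------------------------------------------------------------------

def haseman_elston(y_adj: np.ndarray, K: np.ndarray) -> tuple[float, float]:
    """Haseman-Elston variance components for Omega = s2_g K + s2_e I.

    Regresses off-diagonal cross-products of the (covariate-adjusted,
    centered) trait on the corresponding kinship entries; the residual
    variance is the remainder of the total. Negative estimates are clipped
    to zero with a warning.
    """
    y = y_adj - y_adj.mean()
    n = len(y)
    iu = np.triu_indices(n, k=1)
    k_off = K[iu]
    cp = np.outer(y, y)[iu]
    denom = float(k_off @ k_off)
    s2_g = float(k_off @ cp) / denom if denom > 0 else 0.0
    s2_total = float(y @ y) / n
    s2_e = s2_total - s2_g
    if s2_g < 0 or s2_e <= 0:
        warnings.warn("negative variance component clipped to zero")
        s2_g = max(s2_g, 0.0)
        s2_e = max(s2_e, 1e-8 * max(s2_total, 1e-12))
    return s2_g, s2_e


def gls_snp_weights(
    log_cortisol: np.ndarray,
    G: GenotypeMatrix,
    K: np.ndarray,
    covariates: np.ndarray | None = None,
    ridge: float = 1e-6,
) -> list[SnpWeight]:
    """Per-SNP marginal GLS slopes for log cortisol under kinship covariance.

    The trait covariance Omega = s2_g K + s2_e I is estimated once by
    Haseman-Elston regression on the covariate-adjusted trait; each SNP's
    slope comes from GLS of the trait on [intercept, dosage, covariates].
    SNPs are then re-aligned so the counted (cortisol-increasing) allele has
    a non-negative weight. Missing dosages are excluded per SNP.
    """
    y = np.asarray(log_cortisol, dtype=float)
    n = len(y)
    if K.shape != (n, n):
        raise ValueError("kinship matrix shape mismatch")
    C = np.ones((n, 1)) if covariates is None else np.column_stack(
        [np.ones(n), covariates])

    # adjust trait for covariates (OLS) before variance-component estimation
    resid = y - C @ np.linalg.lstsq(C, y, rcond=None)[0]
    s2_g, s2_e = haseman_elston(resid, K)

    Omega = s2_g * K + s2_e * np.eye(n)
    Omega[np.diag_indices_from(Omega)] += ridge
    try:
        L = np.linalg.cholesky(Omega)
    except np.linalg.LinAlgError:
        raise np.linalg.LinAlgError("kinship covariance is singular")

    # whiten the shared blocks once; per-SNP work is one triangular solve
    Cw_full = solve_triangular(L, C, lower=True)
    yw_full = solve_triangular(L, y, lower=True)

    weights: list[SnpWeight] = []
    for j in range(G.n_snps):
        g = G.dosages[:, j]
        obs = ~np.isnan(g)
        if obs.all():
            gw = solve_triangular(L, g, lower=True)
            Xw = np.column_stack([Cw_full, gw])
            yw2 = yw_full
        else:
            Om = Omega[np.ix_(obs, obs)]
            Lw = np.linalg.cholesky(Om)
            Xw = solve_triangular(Lw, np.column_stack([C[obs], g[obs]]), lower=True)
            yw2 = solve_triangular(Lw, y[obs], lower=True)
        XtX = Xw.T @ Xw
        beta = np.linalg.solve(XtX, Xw.T @ yw2)
        dof = len(yw2) - Xw.shape[1]
        sigma2 = float((yw2 - Xw @ beta) @ (yw2 - Xw @ beta)) / max(dof, 1)
        se = float(np.sqrt(sigma2 * np.linalg.inv(XtX)[-1, -1]))
        slope = float(beta[-1])
        flipped = slope < 0
        weights.append(SnpWeight(
            snp_id=G.snp_ids[j],
            increasing_allele=(G.other_alleles[j] if flipped else G.effect_alleles[j]),
            weight=abs(slope), se=se, n=int(obs.sum()), flipped=flipped,
        ))
    return weights


def build_pgs(G: GenotypeMatrix, weights: list[SnpWeight]) -> np.ndarray:
    """Polygenic score: weighted sum of aligned allele dosages.

    A flipped SNP contributes ``2 - dosage`` (the other-allele count).
    Missing dosages are imputed to twice the counted-allele frequency.
    """
    idx = {sid: j for j, sid in enumerate(G.snp_ids)}
    score = np.zeros(G.n_samples)
    freq = G.allele_freq()
    for w in weights:
        if w.snp_id not in idx:
            raise KeyError(f"SNP {w.snp_id} absent from genotype matrix")
        j = idx[w.snp_id]
        d = G.dosages[:, j]
        if w.flipped:
            d = 2.0 - d
            p = 1.0 - freq[j]
        else:
            p = freq[j]
        d = np.where(np.isnan(d), 2.0 * p, d)
        score += w.weight * d
    return score


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

def _first_stage(x, z, C):
    """Stage-1 diagnostics: partial F (squared t of the instrument) and
    partial R^2 for a single instrument."""
    n = len(x)
    X1 = np.column_stack([np.ones(n), z, C]) if C is not None else \
        np.column_stack([np.ones(n), z])
    fit = sm.OLS(x, X1).fit()
    t = fit.tvalues[1]
    F = float(t * t)
    dof = n - X1.shape[1]
    partial_r2 = F / (F + dof)
    return fit, F, partial_r2


def tsls(
    outcome: np.ndarray,
    exposure: np.ndarray,
    instrument: np.ndarray,
    covariates: np.ndarray | None = None,
    obs_result: tuple | None = None,
) -> MRResult:
    """Two-stage least squares with a single instrument.

    Stage 1 regresses the exposure on the instrument and covariates; stage 2
    regresses the outcome on the fitted exposure and covariates, with
    2SLS-consistent standard errors (residuals from the *observed*
    exposure). With no covariates this equals the Wald ratio
    cov(Z, Y)/cov(Z, X). If ``obs_result`` = (estimate, variance) from the
    observational model is given, the Hausman statistic is attached.
    """
    y = np.asarray(outcome, float)
    x = np.asarray(exposure, float)
    z = np.asarray(instrument, float)
    n = len(y)
    C = None if covariates is None else np.atleast_2d(np.asarray(covariates, float))
    if C is not None and C.shape[0] != n:
        C = C.T

    s1, F, pr2 = _first_stage(x, z, C)
    warns = []
    if F < 10:
        warns.append(f"weak instrument: first-stage partial F = {F:.2f}")
    x_hat = s1.fittedvalues

    X2 = np.column_stack([np.ones(n), x_hat]) if C is None else \
        np.column_stack([np.ones(n), x_hat, C])
    X2a = np.column_stack([np.ones(n), x]) if C is None else \
        np.column_stack([np.ones(n), x, C])
    XtXi = np.linalg.inv(X2.T @ X2)
    beta = XtXi @ (X2.T @ y)
    resid = y - X2a @ beta          # structural residuals use observed x
    sigma2 = float(resid @ resid) / (n - X2.shape[1])
    V = sigma2 * XtXi
    est = float(beta[1])
    se = float(np.sqrt(V[1, 1]))

    h_stat = h_p = None
    if obs_result is not None:
        h_stat, h_p, flag = hausman(est, se ** 2, obs_result[0], obs_result[1])
        if flag:
            warns.append("Hausman variance difference non-positive; statistic set to 0")
    return MRResult("2SLS", est, est - 1.959964 * se, est + 1.959964 * se,
                    F, pr2, h_p, h_stat, n, warns)


def _mgmm_moments(params, y, x, Zmat):
    """Sample moments E[(Y exp(-b0 - bx X - g'C) - 1) * z] for z in Zmat."""
    lin = params[0] + x * params[1]
    if Zmat.shape[1] > 2:
        lin = lin + Zmat[:, 2:] @ params[2:]
    # clip the exponent: keeps the moment surface finite while the solver
    # explores extreme parameter values
    r = y * np.exp(-np.clip(lin, -500.0, 500.0)) - 1.0
    return Zmat.T @ r / len(y)


def mgmm(
    outcome: np.ndarray,
    exposure: np.ndarray,
    instrument: np.ndarray,
    covariates: np.ndarray | None = None,
    n_boot: int = 1000,
    seed: int = 0,
    obs_result: tuple | None = None,
    _point_only: bool = False,
) -> MRResult:
    """Multiplicative structural mean model by just-identified GMM.

    Solves E[(Y exp(-b0 - bx X - g'C) - 1) (1, Z, C')'] = 0 and reports
    exp(bx) as a risk ratio. CIs are percentile bootstrap over individuals
    (heteroskedasticity-robust by construction). Deterministic under a
    fixed seed.
    """
    y = np.asarray(outcome, float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("MGMM outcome must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("degenerate outcome: all 0 or all 1")
    if not _point_only and (n_boot is None or n_boot < 200):
        raise ValueError("n_boot must be >= 200")
    x = np.asarray(exposure, float)
    z = np.asarray(instrument, float)
    if np.std(z) == 0:
        raise ValueError("constant instrument: moment conditions collinear")
    n = len(y)
    C = None if covariates is None else np.atleast_2d(np.asarray(covariates, float))
    if C is not None and C.shape[0] != n:
        C = C.T

    Zmat = np.column_stack([np.ones(n), z]) if C is None else \
        np.column_stack([np.ones(n), z, C])

    # standardize the exposure and covariates for the solver (the moment
    # surface is badly scaled otherwise); slopes are mapped back afterwards
    x_mu, x_sd = x.mean(), x.std()
    if x_sd == 0:
        raise ValueError("constant exposure")
    xs = (x - x_mu) / x_sd
    if C is not None:
        c_mu, c_sd = C.mean(axis=0), C.std(axis=0)
        c_sd[c_sd == 0] = 1.0
        Cs = (C - c_mu) / c_sd
        Zs = np.column_stack([np.ones(n), z, Cs])
    else:
        Zs = Zmat

    solver_rng = np.random.default_rng(seed)

    def solve(yb, xb, Zb, strict=True):
        # start from a Poisson log-linear fit (instrument replaced by exposure)
        Xp = np.column_stack([np.ones(len(yb), ), xb]) if Zb.shape[1] == 2 else \
            np.column_stack([np.ones(len(yb)), xb, Zb[:, 2:]])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            start = sm.GLM(yb, Xp, family=sm.families.Poisson()).fit().params
        starts = [start, np.zeros_like(start)]
        if strict:
            starts += [start + 0.3 * solver_rng.standard_normal(start.size)
                       for _ in range(3)]
        last_msg = ""
        for s0 in starts:
            sol = optimize.root(_mgmm_moments, s0, args=(yb, xb, Zb),
                                method="hybr")
            if sol.success:
                return sol.x, True
            last_msg = sol.message
        # no exact root found: report the GMM-objective minimizer instead
        # (what a quadratic-form GMM routine returns). With a weak
        # instrument and few cases the resampled — or even the observed —
        # moment system can genuinely lack a root.
        ls = optimize.least_squares(_mgmm_moments, start, args=(yb, xb, Zb),
                                    method="lm")
        if np.max(np.abs(ls.fun)) < 1e-8:
            return ls.x, True
        if strict and not np.all(np.isfinite(ls.x)):
            raise RuntimeError(f"MGMM moment solver failed: {last_msg}")
        return ls.x, False

    params, exact = solve(y, xs, Zs)
    beta_x = float(params[1]) / x_sd
    rr = float(np.exp(beta_x))

    _, F, pr2 = _first_stage(x, z, C)
    warns = []
    if F < 10:
        warns.append(f"weak instrument: first-stage partial F = {F:.2f}")
    if not exact:
        warns.append("moment conditions have no exact root; GMM-objective "
                     "minimizer reported")

    if _point_only:
        return MRResult("MGMM", rr, np.nan, np.nan, F, pr2, None, None, n, warns)

    rng = np.random.default_rng(seed)
    boots = []
    failures = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        yb = y[idx]
        if yb.min() == yb.max():
            failures += 1
            continue
        try:
            rep_params, _ = solve(yb, xs[idx], Zs[idx], strict=False)
            boots.append(rep_params[1] / x_sd)
        except (RuntimeError, np.linalg.LinAlgError):
            failures += 1
    if failures > 0.05 * n_boot:
        raise RuntimeError(f"{failures}/{n_boot} MGMM bootstrap replicates failed")
    lo, hi = np.exp(np.percentile(boots, [2.5, 97.5]))

    # bootstrap variance of log-RR feeds the Hausman comparison
    h_stat = h_p = None
    if obs_result is not None:
        var_b = float(np.var(boots, ddof=1))
        h_stat, h_p, flag = hausman(beta_x, var_b, obs_result[0], obs_result[1])
        if flag:
            warns.append("Hausman variance difference non-positive; statistic set to 0")
    return MRResult("MGMM", rr, float(lo), float(hi), F, pr2, h_p, h_stat, n, warns)


def hausman(iv_estimate: float, iv_variance: float,
            obs_estimate: float, obs_variance: float) -> tuple[float, float, bool]:
    """Hausman endogeneity test.

    H = (b_IV - b_obs)^2 / (V_IV - V_obs), chi-square with 1 df. The
    efficient estimator's variance must be smaller; if V_IV <= V_obs the
    statistic is reported as 0 with p = 1 and the degeneracy flag set.
    Returns (statistic, p, degenerate).
    """
    if iv_variance <= 0 or obs_variance <= 0:
        raise ValueError("variances must be positive")
    dv = iv_variance - obs_variance
    if dv <= 0:
        return 0.0, 1.0, True
    h = (iv_estimate - obs_estimate) ** 2 / dv
    return float(h), float(stats.chi2.sf(h, df=1)), False


def observational_reference(
    outcome: np.ndarray,
    exposure: np.ndarray,
    covariates: np.ndarray | None = None,
    family: str | None = None,
) -> dict:
    """Observational comparator: linear regression for continuous outcomes,
    Poisson regression with robust (HC0) errors reporting an incidence rate
    ratio for binary outcomes; adjusted for the supplied covariates.

    Returns a dict with ``estimate`` (slope or IRR), ``log_estimate`` (for
    Poisson), ``ci``, ``variance`` (of the slope / log-IRR) and ``n``.
    """
    y = np.asarray(outcome, float)
    x = np.asarray(exposure, float)
    n = len(y)
    C = None if covariates is None else np.atleast_2d(np.asarray(covariates, float))
    if C is not None and C.shape[0] != n:
        C = C.T
    X = np.column_stack([np.ones(n), x]) if C is None else \
        np.column_stack([np.ones(n), x, C])
    if family is None:
        family = "poisson" if set(np.unique(y)) <= {0.0, 1.0} else "linear"
    if family == "poisson":
        if y.min() == y.max():
            raise ValueError("degenerate outcome")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.GLM(y, X, family=sm.families.Poisson()).fit(cov_type="HC0")
        b = float(fit.params[1])
        se = float(fit.bse[1])
        return {"estimate": float(np.exp(b)), "log_estimate": b,
                "ci": (float(np.exp(b - 1.959964 * se)), float(np.exp(b + 1.959964 * se))),
                "variance": se ** 2, "n": n, "family": "poisson"}
    fit = sm.OLS(y, X).fit()
    b = float(fit.params[1])
    se = float(fit.bse[1])
    return {"estimate": b, "log_estimate": None,
            "ci": (b - 1.959964 * se, b + 1.959964 * se),
            "variance": se ** 2, "n": n, "family": "linear"}
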