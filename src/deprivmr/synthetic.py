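"""Synthetic family cohort generator with recorded ground truth.

Emulates the statistical structure the downstream analyses assume: households
nested in neighborhoods, one right-skewed (lognormal) income draw per
household reported in 29 bands, two-generation pedigrees (founder couples
plus optional full siblings), founder genotypes in Hardy-Weinberg
equilibrium, serum cortisol partly driven by a polygenic component and by
relative income deprivation, and continuous/binary cardiovascular outcomes
with configurable deprivation and cortisol effects.

Every generated dataset is accompanied by a :class:`SimTruth` record holding
the exact parameters used, so each estimator downstream can be checked
against known truth. All randomness flows from one seeded
``numpy.random.Generator``; a config's ``seed`` fully determines the output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .income import (
    DEFAULT_BAND_EDGES,
    band_income,
    equivalize,
    yitzhaki_index,
)
from .geno import GenotypeMatrix

__all__ = ["SimConfig", "SimTruth", "generate_cohort", "band_income",
           "write_cohort_csv", "read_cohort_csv",
           "write_pedigree_tsv", "read_pedigree_tsv"]

CONTINUOUS_OUTCOMES = ("bmi", "bodyfat", "sbp", "dbp")
BINARY_OUTCOMES = ("cvd", "diabetes")


@dataclass
class SimConfig:
    """All knobs of the generator. Defaults mirror the cohort the analyses
    target: mean age ~44, log-cortisol ~2.0 (SD 0.4) log ug/dL, SBP ~125
    mmHg, CVD prevalence ~4.6%, diabetes ~6.5%, right-skewed equivalized
    income around HKD 15,000/month."""

    n_neighborhoods: int = 40
    households_per_neighborhood: int = 25
    mean_household_size: float = 3.0
    income_lognormal_mu_range: tuple = (9.6, 10.4)   # log HKD/month
    income_lognormal_sigma_range: tuple = (0.5, 0.8)
    n_snps: int = 30
    maf_range: tuple = (0.30, 0.50)
    snp_beta_scale: float = 0.02      # log ug/dL per effect allele
    deprivation_to_sbp: float = 0.5   # mmHg per HKD 1,000 of deprivation
    deprivation_to_cortisol: float = 0.01  # log ug/dL per HKD 1,000
    cortisol_to_sbp: float = 2.0      # mmHg per log ug/dL
    outcome_noise_sd: dict = field(default_factory=lambda: {
        "bmi": 3.8, "bodyfat": 6.0, "sbp": 14.0, "dbp": 9.0,
        "log_cortisol": 0.38,
    })
    binary_baseline_prevalence: dict = field(default_factory=lambda: {
        "cvd": 0.046, "diabetes": 0.065,
    })
    # log-odds per unit of each driver, per binary outcome
    binary_effects: dict = field(default_factory=lambda: {
        "cvd": {"deprivation_per_1000": 0.0, "log_cortisol": 0.0},
        "diabetes": {"deprivation_per_1000": 0.0, "log_cortisol": 0.0},
    })
    sibling_fraction: float = 0.5
    # shared cluster residuals, as fractions of each outcome's noise SD
    # (0.35 and 0.15 give household/neighborhood ICCs of roughly 0.13/0.02)
    hh_intercept_sd: float = 0.35
    nbhd_intercept_sd: float = 0.15
    seed: int = 0
    band_edges: tuple = DEFAULT_BAND_EDGES

    def validate(self) -> None:
        if self.n_neighborhoods < 1 or self.households_per_neighborhood < 1:
            raise ValueError("counts must be positive")
        if self.mean_household_size <= 0:
            raise ValueError("mean household size must be positive")
        for lo, hi in (self.income_lognormal_mu_range,
                       self.income_lognormal_sigma_range, self.maf_range):
            if lo > hi:
                raise ValueError("range must be ordered low <= high")
        if self.income_lognormal_sigma_range[0] <= 0:
            raise ValueError("income sigma must be positive")
        if self.n_snps < 0:
            raise ValueError("n_snps must be non-negative")
        if not (0 < self.maf_range[0] and self.maf_range[1] <= 0.5):
            raise ValueError("MAF range must lie in (0, 0.5]")
        if not (0 <= self.sibling_fraction <= 1):
            raise ValueError("sibling_fraction must be in [0, 1]")
        for k, v in self.binary_baseline_prevalence.items():
            if not (0 < v < 1):
                raise ValueError(f"prevalence for {k} must be in (0, 1)")
        for k, v in self.outcome_noise_sd.items():
            if v <= 0:
                raise ValueError(f"noise SD for {k} must be positive")


@dataclass
class SimTruth:
    """Ground truth of one generated cohort — everything needed to compute
    the expected value of every downstream estimator."""

    snp_ids: list
    snp_betas: np.ndarray        # per effect allele, log ug/dL
    snp_eaf: np.ndarray          # effect-allele frequencies used
    mediator_model: dict         # beta0, beta1 (per HKD 1,000), sigma2
    outcome_model: dict          # theta0..theta3 for SBP
    causal_effects: dict         # true cortisol effect per outcome
    deprivation_effects: dict    # true deprivation effect per outcome
    binary_intercepts: dict      # solved logit intercepts
    neighborhood_income_params: pd.DataFrame  # mu, sigma per neighborhood
    config: SimConfig

    def to_dict(self) -> dict:
        d = asdict(self)
        d["snp_betas"] = list(map(float, self.snp_betas))
        d["snp_eaf"] = list(map(float, self.snp_eaf))
        d["neighborhood_income_params"] = self.neighborhood_income_params.to_dict("list")
        return d


def _solve_logit_intercept(eta: np.ndarray, target: float) -> float:
    """Intercept alpha with mean(sigmoid(alpha + eta)) == target."""
    from scipy.optimize import brentq

    def f(a):
        return np.mean(1.0 / (1.0 + np.exp(-(a + eta)))) - target

    return float(brentq(f, -30.0, 30.0))


def generate_cohort(config: SimConfig):
    """Generate one cohort.

    Returns ``(cohort, genotypes, pedigree, truth)``: a per-individual
    DataFrame, a :class:`~deprivmr.geno.GenotypeMatrix`, a pedigree
    DataFrame (id, father, mother, family; "0" for founders) and the
    :class:`SimTruth` record.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    # --- households nested in neighborhoods -------------------------------
    nb_mu = rng.uniform(*config.income_lognormal_mu_range, config.n_neighborhoods)
    nb_sigma = rng.uniform(*config.income_lognormal_sigma_range, config.n_neighborhoods)

    rows = []          # per individual
    ped_rows = []
    geno_rows = []     # dosage per individual
    p_snp = rng.uniform(*config.maf_range, config.n_snps)
    snp_ids = [f"rs{1000 + j}" for j in range(config.n_snps)]
    betas = rng.choice([-1.0, 1.0], config.n_snps) * config.snp_beta_scale

    def founder_geno():
        return rng.binomial(2, p_snp).astype(float)

    def child_geno(gf, gm):
        return (rng.random(config.n_snps) < gf / 2.0).astype(float) + \
               (rng.random(config.n_snps) < gm / 2.0).astype(float)

    iid = 0
    for nb in range(config.n_neighborhoods):
        nbhd_id = f"N{nb:04d}"
        for h in range(config.households_per_neighborhood):
            hh_id = f"{nbhd_id}_H{h:04d}"
            size = 1 + rng.poisson(max(config.mean_household_size - 1.0, 0.0))
            income = float(rng.lognormal(nb_mu[nb], nb_sigma[nb]))
            with_sibs = size >= 3 and rng.random() < config.sibling_fraction

            members = []
            if size == 1:
                members.append(("founder", None, None))
            else:
                members.append(("founder_m", None, None))
                members.append(("founder_f", None, None))
                for _ in range(size - 2):
                    members.append(("child", 0, 1) if with_sibs else ("founder", None, None))

            genos = {}
            for k, (role, fa, mo) in enumerate(members):
                pid = f"I{iid + k:06d}"
                if role == "child":
                    g = child_geno(genos[fa], genos[mo])
                    father, mother = f"I{iid + fa:06d}", f"I{iid + mo:06d}"
                    age = float(np.clip(rng.normal(30.0, 8.0), 18.0, 60.0))
                    sex = "male" if rng.random() < 0.5 else "female"
                else:
                    g = founder_geno()
                    father = mother = "0"
                    age = float(np.clip(rng.normal(51.0, 13.0), 25.0, 88.0))
                    if role == "founder_m":
                        sex = "male"
                    elif role == "founder_f":
                        sex = "female"
                    else:
                        sex = "male" if rng.random() < 0.47 else "female"
                genos[k] = g
                geno_rows.append(g)
                ped_rows.append((pid, father, mother, hh_id))
                rows.append({
                    "individual_id": pid, "household_id": hh_id,
                    "neighborhood_id": nbhd_id, "age": round(age, 1), "sex": sex,
                    "birthplace": "local" if rng.random() < 0.54 else "elsewhere",
                    "household_size": size, "household_income": round(income, 2),
                })
            iid += len(members)

    cohort = pd.DataFrame(rows)
    cohort["income_band"] = band_income(cohort["household_income"].to_numpy(),
                                        config.band_edges)
    dosages = np.vstack(geno_rows) if geno_rows else np.empty((len(cohort), 0))
    genotypes = GenotypeMatrix(
        sample_ids=list(cohort["individual_id"]),
        snp_ids=snp_ids,
        effect_alleles=["A"] * config.n_snps,
        other_alleles=["G"] * config.n_snps,
        dosages=dosages,
    )
    pedigree = pd.DataFrame(ped_rows, columns=["id", "father", "mother", "family"])

    # --- exposures feeding the outcome models -----------------------------
    equiv = equivalize(cohort["household_income"].to_numpy(),
                       cohort["household_size"].to_numpy())
    hh_equiv = pd.Series(equiv, index=cohort.index).groupby(
        cohort["household_id"]).first()
    hh_depriv = pd.Series(yitzhaki_index(hh_equiv.to_numpy()), index=hh_equiv.index)
    depriv = hh_depriv.reindex(cohort["household_id"]).to_numpy()  # HKD/month
    d1000 = depriv / 1000.0

    # --- cortisol: polygenic + deprivation + noise ------------------------
    g_centered = dosages - 2.0 * p_snp
    genetic = g_centered @ betas if config.n_snps else np.zeros(len(cohort))
    beta0 = 2.0
    sigma_c = config.outcome_noise_sd["log_cortisol"]
    log_cortisol = (beta0 + genetic + config.deprivation_to_cortisol * d1000
                    + rng.normal(0.0, sigma_c, len(cohort)))
    cohort["cortisol"] = np.round(np.exp(log_cortisol), 3)

    # --- shared cluster residuals (drive non-zero ICCs) -------------------
    hh_codes, hh_uniq = pd.factorize(cohort["household_id"])
    nb_codes, nb_uniq = pd.factorize(cohort["neighborhood_id"])

    age_c = cohort["age"].to_numpy() - 44.0
    male = (cohort["sex"] == "male").astype(float).to_numpy()
    lc_c = log_cortisol - beta0

    def cont(base, age_b, sex_b, dep_b, cort_b, noise_key):
        sd = config.outcome_noise_sd[noise_key]
        u_hh = rng.normal(0.0, config.hh_intercept_sd * sd, len(hh_uniq))[hh_codes]
        u_nb = rng.normal(0.0, config.nbhd_intercept_sd * sd, len(nb_uniq))[nb_codes]
        return (base + age_b * age_c + sex_b * male + dep_b * d1000
                + cort_b * lc_c + u_hh + u_nb
                + rng.normal(0.0, sd, len(cohort)))

    cohort["bmi"] = np.round(cont(23.2, 0.02, 0.3, 0.0, 0.0, "bmi"), 2)
    cohort["bodyfat"] = np.round(cont(27.0, 0.05, -6.0, 0.0, 0.0, "bodyfat"), 2)
    cohort["sbp"] = np.round(cont(125.0, 0.55, 3.0, config.deprivation_to_sbp,
                                  config.cortisol_to_sbp, "sbp"), 1)
    cohort["dbp"] = np.round(cont(78.0, 0.15, 2.0, 0.0, 0.0, "dbp"), 1)

    # --- binary outcomes: logistic with solved intercepts -----------------
    binary_intercepts = {}
    for out in BINARY_OUTCOMES:
        eff = config.binary_effects.get(out, {})
        eta = (0.06 * age_c
               + eff.get("deprivation_per_1000", 0.0) * d1000
               + eff.get("log_cortisol", 0.0) * lc_c)
        alpha = _solve_logit_intercept(eta, config.binary_baseline_prevalence[out])
        binary_intercepts[out] = alpha
        p = 1.0 / (1.0 + np.exp(-(alpha + eta)))
        cohort[out] = (rng.random(len(cohort)) < p).astype(int)

    truth = SimTruth(
        snp_ids=snp_ids,
        snp_betas=betas,
        snp_eaf=p_snp,
        mediator_model={"beta0": beta0,
                        "beta1_per_1000": config.deprivation_to_cortisol,
                        "sigma2": sigma_c ** 2},
        outcome_model={"theta1_per_1000": config.deprivation_to_sbp,
                       "theta2": config.cortisol_to_sbp, "theta3": 0.0},
        causal_effects={"sbp": config.cortisol_to_sbp, "dbp": 0.0,
                        "bmi": 0.0, "bodyfat": 0.0,
                        "cvd": config.binary_effects.get("cvd", {}).get("log_cortisol", 0.0),
                        "diabetes": config.binary_effects.get("diabetes", {}).get("log_cortisol", 0.0)},
        deprivation_effects={"sbp": config.deprivation_to_sbp,
                             "log_cortisol": config.deprivation_to_cortisol},
        binary_intercepts=binary_intercepts,
        neighborhood_income_params=pd.DataFrame(
            {"neighborhood_id": [f"N{k:04d}" for k in range(config.n_neighborhoods)],
             "mu": nb_mu, "sigma": nb_sigma}),
        config=config,
    )
    return cohort, genotypes, pedigree, truth


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_cohort_csv(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False)


def read_cohort_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_pedigree_tsv(pedigree: pd.DataFrame, path) -> None:
    pedigree.to_csv(path, sep="\t", index=False)


def read_pedigree_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str)
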