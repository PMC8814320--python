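"""One-sample Mendelian randomization of cortisol on cardiovascular traits.

Builds the internally weighted polygenic score (kinship-GLS per-SNP weights,
aligned to the cortisol-increasing allele), then estimates the causal effect
of log-cortisol on systolic blood pressure by 2SLS and on CVD by the
multiplicative GMM, each against its observational comparator with a
Hausman test.
"""

import warnings

warnings.filterwarnings("ignore")

import numpy as np

from deprivmr import SimConfig, generate_cohort
from deprivmr.geno import kinship_from_pedigree, pca
from deprivmr.mr import (build_pgs, gls_snp_weights, mgmm,
                         observational_reference, tsls)

cfg = SimConfig(n_neighborhoods=25, households_per_neighborhood=20,
                mean_household_size=3, seed=31)
cohort, G, ped, truth = generate_cohort(cfg)
K, _ = kinship_from_pedigree(ped)
log_cortisol = np.log(cohort["cortisol"].to_numpy())
age = cohort["age"].to_numpy()
male = (cohort["sex"] == "male").to_numpy(float)

pcs = pca(G, n_components=10)
weights = gls_snp_weights(log_cortisol, G, K,
                          np.column_stack([age, male, pcs]))
pgs = build_pgs(G, weights)
covs = np.column_stack([age, male])

print(f"n = {len(cohort)}; PGS from {len(weights)} SNPs, all weights >= 0: "
      f"{all(w.weight >= 0 for w in weights)}")

sbp = cohort["sbp"].to_numpy()
obs = observational_reference(sbp, log_cortisol, covs)
res = tsls(sbp, log_cortisol, pgs, covs,
           obs_result=(obs["estimate"], obs["variance"]))
print(f"SBP  observational {obs['estimate']:+.2f} mmHg per log-unit cortisol; "
      f"2SLS {res.estimate:+.2f} (95% CI {res.ci_low:+.2f} to {res.ci_high:+.2f}); "
      f"truth {truth.causal_effects['sbp']:+.2f}")
print(f"     first-stage partial F {res.first_stage_F:.1f}, "
      f"partial R2 {res.first_stage_partial_r2:.3f}, "
      f"Hausman p {res.hausman_p:.2f}")

cvd = cohort["cvd"].to_numpy(float)
obs_b = observational_reference(cvd, log_cortisol, covs)
res_b = mgmm(cvd, log_cortisol, pgs, covs, n_boot=500, seed=2,
             obs_result=(obs_b["log_estimate"], obs_b["variance"]))
print(f"CVD  Poisson IRR {obs_b['estimate']:.2f}; MGMM risk ratio "
      f"{res_b.estimate:.2f} (95% CI {res_b.ci_low:.2f} to {res_b.ci_high:.2f}); "
      f"truth RR 1.00")

# The observational SBP estimate is confounded by deprivation (which raises
# both cortisol and SBP in the generator); the genetic instrument removes
# that pathway at the price of a much wider interval — at this sample size
# and instrument strength the 2SLS CI is several-fold wider than the
# observational one, and both cover the simulated truth here.
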