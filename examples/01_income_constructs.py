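"""Compute the four income exposure constructs on a small synthetic cohort.

Generates a cohort of households nested in neighborhoods, then derives each
individual's absolute equivalized income, Yitzhaki relative deprivation,
neighborhood median-income quartile and neighborhood Gini quartile.
"""

import numpy as np

from deprivmr import SimConfig, generate_cohort
from deprivmr.income import compute_constructs

cohort, _, _, _ = generate_cohort(
    SimConfig(n_neighborhoods=20, households_per_neighborhood=25, seed=1))
constructs = compute_constructs(cohort)

print(f"cohort: {len(cohort)} individuals, "
      f"{cohort['household_id'].nunique()} households, "
      f"{cohort['neighborhood_id'].nunique()} neighborhoods")
print(f"mean equivalized income : HKD {constructs['absolute_income'].mean():,.0f}/month")
print(f"mean Yitzhaki deprivation: HKD {constructs['yitzhaki'].mean():,.0f}/month "
      f"(SD {constructs['yitzhaki'].std():,.0f})")
print(f"neighborhood Gini range : "
      f"{constructs['nbhd_gini'].min():.2f}-{constructs['nbhd_gini'].max():.2f}")

# The Yitzhaki index is the average income shortfall relative to all richer
# households: the mean value says how much less income a typical household
# has than the households above it, averaged over the whole reference group.
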