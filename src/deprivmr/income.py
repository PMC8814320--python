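"""Income exposure constructs.

Four exposures are derived from reported household income:

* **absolute equivalized income** — household income divided by the square
  root of household size, so that larger households are not mechanically
  coded as richer per head;
* **relative deprivation** (Yitzhaki index ``D_i``) — the average shortfall
  of a household's equivalized income relative to every richer household in
  a reference group, averaged over the *whole* group;
* **neighborhood median-income quartile** — quartile of the neighborhood
  median equivalized income, cut over the neighborhood-level distribution;
* **neighborhood inequality quartile** — quartile of the neighborhood Gini
  coefficient.

All incomes are in HKD/month unless stated otherwise.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_BAND_EDGES",
    "HKD_PER_USD",
    "hkd_to_usd",
    "equivalize",
    "band_income",
    "midpoint_income",
    "yitzhaki_index",
    "yitzhaki_brute_force",
    "gini",
    "gini_lorenz",
    "assign_neighborhood_quartiles",
    "compute_constructs",
]

# 29 monthly-income bands. The survey instrument documents only the first
# band (HKD 1-499) and the open top band (>= 150,000); intermediate edges are
# a package default: 500-wide bands up to 4,000, then progressively wider
# bands tracking the right-skew of household incomes.
DEFAULT_BAND_EDGES: tuple[float, ...] = (
    1, 500, 1000, 1500, 2000, 2500, 3000, 3500, 4000,
    5000, 6000, 7000, 8000, 10000, 12000, 14000, 16000, 18000,
    20000, 25000, 30000, 35000, 40000, 50000, 60000, 80000,
    100000, 125000, 150000,
)
# len == 29: edge[k-1] is the lower edge of band k; band k (k<29) covers
# [edge[k-1], edge[k]); band 29 is open-ended above 150,000.


# Hong Kong dollar is pegged to the US dollar
HKD_PER_USD = 7.8


def hkd_to_usd(amount_hkd: float) -> float:
    """Convert HKD to USD at the 7.8 peg (used when reporting association
    increments, e.g. HKD 1,000 ~ USD 128)."""
    return amount_hkd / HKD_PER_USD


def _check_edges(band_edges: Sequence[float]) -> np.ndarray:
    edges = np.asarray(band_edges, dtype=float)
    if edges.ndim != 1 or edges.size != 29:
        raise ValueError(f"expected 29 band edges, got {edges.size}")
    if not np.all(np.diff(edges) > 0):
        raise ValueError("band edges must be strictly increasing")
    return edges


def equivalize(household_income, household_size):
    """Equivalized income: household income / sqrt(household size).

    Parameters may be scalars or arrays. Raises if any size < 1 or income < 0.
    """
    income = np.asarray(household_income, dtype=float)
    size = np.asarray(household_size, dtype=float)
    if np.any(size < 1):
        raise ValueError("household size must be >= 1")
    if np.any(income < 0):
        raise ValueError("household income must be >= 0")
    out = income / np.sqrt(size)
    return float(out) if out.ndim == 0 else out


def band_income(exact_income, band_edges: Sequence[float] = DEFAULT_BAND_EDGES):
    """Map an exact income to its band index 1..29.

    Band ``k`` (k < 29) covers ``[edge[k-1], edge[k])``; band 29 is the open
    top band. Incomes below the first edge fall into band 1.
    """
    edges = _check_edges(band_edges)
    income = np.asarray(exact_income, dtype=float)
    if np.any(income < 0):
        raise ValueError("income must be non-negative")
    # searchsorted against upper edges: band k has upper edge edges[k]
    band = np.searchsorted(edges[1:], income, side="right") + 1
    band = np.clip(band, 1, 29)
    return int(band) if band.ndim == 0 else band.astype(int)


def midpoint_income(band, band_edges: Sequence[float] = DEFAULT_BAND_EDGES):
    """Representative income for a band: arithmetic midpoint of a closed
    band, lower edge for the open top band.

    Bands are integer HKD ranges (band k < 29 covers ``edge[k-1]`` to
    ``edge[k] - 1`` inclusive), so the closed-band midpoint is
    ``(lower + upper) / 2`` with ``upper = edge[k] - 1``.
    """
    edges = _check_edges(band_edges)
    b = np.asarray(band, dtype=int)
    if np.any((b < 1) | (b > 29)):
        raise ValueError("band index must be in 1..29")
    mids = np.empty(29)
    mids[:-1] = (edges[:-1] + edges[1:] - 1) / 2.0
    mids[-1] = edges[-1]  # open top band: lower edge
    out = mids[b - 1]
    return float(out) if out.ndim == 0 else out


def yitzhaki_brute_force(incomes: Sequence[float]) -> np.ndarray:
    """O(n^2) reference implementation of the Yitzhaki index.

    D_i = (1/N) * sum_{j: y_j > y_i} (y_j - y_i), N the reference-group size.
    """
    y = np.asarray(incomes, dtype=float)
    n = y.size
    if n == 0:
        raise ValueError("reference group is empty")
    out = np.zeros(n)
    for i in range(n):
        for j in range(n):
            if y[j] > y[i]:
                out[i] += y[j] - y[i]
    return out / n


def yitzhaki_index(incomes: Sequence[float], reference=None) -> np.ndarray:
    """Vectorized Yitzhaki relative deprivation index.

    ``D_i`` is the mean, over the full reference group of size ``N``, of the
    income excess of every household richer than household ``i``. The value
    is 0 for the richest household and invariant to adding a constant to all
    incomes; scaling all incomes by ``k`` scales ``D`` by ``k``.

    Parameters
    ----------
    incomes : array of household incomes (one value per household).
    reference : optional boolean mask or index array selecting the reference
        (comparison) group; deprivation is still returned for every input
        household, each compared against the reference group. Default: all.
    """
    y = np.asarray(incomes, dtype=float)
    if y.size == 0:
        raise ValueError("incomes is empty")
    if not np.all(np.isfinite(y)) or np.any(y < 0):
        raise ValueError("incomes must be finite and non-negative")
    if reference is None:
        ref = y
    else:
        ref = y[np.asarray(reference)]
        if ref.size == 0:
            raise ValueError("reference group is empty")
    n_ref = ref.size
    ref_sorted = np.sort(ref)
    # suffix sums: total income of reference households strictly above a value
    csum = np.concatenate(([0.0], np.cumsum(ref_sorted)))
    total = csum[-1]
    # for each y_i: k = count of ref <= y_i (strictly-greater cutoff)
    k = np.searchsorted(ref_sorted, y, side="right")
    sum_above = total - csum[k]
    count_above = n_ref - k
    return (sum_above - count_above * y) / n_ref


def gini(incomes: Sequence[float]) -> float:
    """Gini coefficient, population mean-difference form.

    G = sum_i sum_j |y_i - y_j| / (2 n^2 ybar), in [0, 1]. Computed via the
    sorted-rank identity, O(n log n).
    """
    y = np.asarray(incomes, dtype=float)
    n = y.size
    if n < 2:
        raise ValueError("need at least 2 incomes")
    mean = y.mean()
    if mean <= 0:
        raise ValueError("Gini undefined for non-positive mean income")
    ys = np.sort(y)
    i = np.arange(1, n + 1)
    # sum_i sum_j |y_i - y_j| = 2 * sum_i (2i - n - 1) * y_(i)
    mad_sum = 2.0 * np.sum((2 * i - n - 1) * ys)
    return float(mad_sum / (2.0 * n * n * mean))


def gini_lorenz(incomes: Sequence[float]) -> float:
    """Independent Gini oracle: 1 - 2 * area under the Lorenz curve
    (trapezoid rule on the empirical curve)."""
    y = np.sort(np.asarray(incomes, dtype=float))
    n = y.size
    if n < 2 or y.mean() <= 0:
        raise ValueError("invalid input for Lorenz Gini")
    cum = np.concatenate(([0.0], np.cumsum(y))) / y.sum()
    p = np.arange(n + 1) / n
    area = np.trapezoid(cum, p)
    return float(1.0 - 2.0 * area)


def assign_neighborhood_quartiles(values: Mapping) -> dict:
    """Assign quartiles 1..4 to neighborhoods by their summary value.

    Cut points are the empirical 25/50/75 percentiles of the
    *neighborhood-level* distribution (not person-weighted); a neighborhood
    on a cut point is assigned to the lower quartile.
    """
    keys = list(values.keys())
    v = np.asarray([values[k] for k in keys], dtype=float)
    if v.size < 4:
        raise ValueError("need at least 4 neighborhoods for quartiles")
    cuts = np.quantile(v, [0.25, 0.50, 0.75])
    quart = 1 + (v[:, None] > cuts[None, :]).sum(axis=1)
    return dict(zip(keys, quart.astype(int)))


def compute_constructs(
    cohort: pd.DataFrame,
    band_edges: Sequence[float] = DEFAULT_BAND_EDGES,
    reference: str = "all",
) -> pd.DataFrame:
    """Compute all four income constructs for a cohort table.

    The cohort must carry ``individual_id``, ``household_id``,
    ``neighborhood_id``, ``household_size`` and either ``household_income``
    (exact HKD/month) or ``income_band`` (1..29, converted via band
    midpoints). Income is a household attribute: it is equivalized once per
    household and the Yitzhaki index is computed over households (each
    household enters the reference group once), then broadcast to members.

    Returns a per-individual frame with columns ``individual_id``,
    ``absolute_income``, ``yitzhaki``, ``nbhd_median_quartile``,
    ``nbhd_gini``, ``nbhd_gini_quartile``.
    """
    required = {"individual_id", "household_id", "neighborhood_id", "household_size"}
    missing = required - set(cohort.columns)
    if missing:
        raise ValueError(f"cohort is missing columns: {sorted(missing)}")
    if reference != "all":
        raise ValueError("only the full-sample reference group is supported here; "
                         "call yitzhaki_index directly for subgroup references")

    df = cohort.copy()
    if "household_income" in df.columns and df["household_income"].notna().any():
        income = df["household_income"].astype(float)
    elif "income_band" in df.columns:
        income = pd.Series(
            midpoint_income(df["income_band"].to_numpy(), band_edges), index=df.index
        )
    else:
        raise ValueError("cohort needs household_income or income_band")

    df["_equiv"] = equivalize(income.to_numpy(), df["household_size"].to_numpy())

    # household-level deprivation over the full sample of households
    hh = df.drop_duplicates("household_id")[["household_id", "neighborhood_id", "_equiv"]]
    hh = hh.set_index("household_id")
    hh["yitzhaki"] = yitzhaki_index(hh["_equiv"].to_numpy())

    # neighborhood-level summaries over households
    nbhd_median = hh.groupby("neighborhood_id")["_equiv"].median()
    nbhd_gini = hh.groupby("neighborhood_id")["_equiv"].apply(
        lambda g: gini(g.to_numpy()) if len(g) >= 2 else 0.0
    )
    med_q = assign_neighborhood_quartiles(nbhd_median.to_dict())
    gini_q = assign_neighborhood_quartiles(nbhd_gini.to_dict())

    out = pd.DataFrame({
        "individual_id": df["individual_id"].to_numpy(),
        "absolute_income": df["_equiv"].to_numpy(),
        "yitzhaki": hh["yitzhaki"].reindex(df["household_id"]).to_numpy(),
        "nbhd_median_quartile": df["neighborhood_id"].map(med_q).to_numpy(),
        "nbhd_gini": df["neighborhood_id"].map(nbhd_gini).to_numpy(),
        "nbhd_gini_quartile": df["neighborhood_id"].map(gini_q).to_numpy(),
    })
    return out
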