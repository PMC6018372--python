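"""Paired statistics for strain before vs after treatment.

Specimen-level comparisons use the exact Wilcoxon signed-rank test: with
only six eyes, the smallest attainable two-sided p (all differences one
sign) is 2/2^6 = 0.03125, which a normal approximation cannot reproduce,
so the null distribution is enumerated exactly. Regional comparisons use
generalized estimating equations (GEE) with an exchangeable
(compound-symmetry) working correlation — the eight regional measures of
one eye are treated as repeat measurements of that eye, eyes as
independent clusters — with robust (sandwich) standard errors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import rankdata

__all__ = [
    "TestResult",
    "GeeResult",
    "wilcoxon_signed_rank_exact",
    "fit_gee_exchangeable",
    "build_paired_table",
    "strain_change_models",
]

STRAIN_MEASURES = ("E_XX", "E_YY", "E_max", "Gamma_max")


@dataclass
class TestResult:
    statistic: float
    p_value: float
    n: int
    method: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


def wilcoxon_signed_rank_exact(differences) -> TestResult:
    """Exact two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped; tied magnitudes receive mid-ranks. The
    two-sided p-value is twice the smaller tail of the exact null
    distribution of W+ (the positive-rank sum) over all 2^n equally
    likely sign assignments, capped at 1.
    """
    d = np.asarray(differences, dtype=np.float64)
    d = d[d != 0]
    n = d.size
    if n == 0:
        warnings.warn("all paired differences are zero; p = 1", stacklevel=2)
        return TestResult(statistic=0.0, p_value=1.0, n=0, method="wilcoxon-exact")
    if n > 20:
        raise ValueError("exact enumeration supported for n <= 20")

    ranks = rankdata(np.abs(d))  # mid-ranks for ties
    w_plus = float(ranks[d > 0].sum())

    # exact null distribution of W+ over doubled (integer) ranks via the
    # standard generating-polynomial recursion — identical to enumerating
    # all 2^n sign vectors
    r2 = np.round(2.0 * ranks).astype(int)
    total = int(r2.sum())
    counts = np.zeros(total + 1, dtype=np.float64)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    counts /= 2.0**n

    w2 = int(round(2.0 * w_plus))
    p_low = float(counts[: w2 + 1].sum())
    p_high = float(counts[w2:].sum())
    p = min(1.0, 2.0 * min(p_low, p_high))
    return TestResult(statistic=w_plus, p_value=p, n=n, method="wilcoxon-exact")


@dataclass
class GeeResult:
    params: dict[str, float]
    robust_se: dict[str, float]
    p_values: dict[str, float]
    working_correlation: float
    n_clusters: int
    n_obs: int
    converged: bool = True
    model: object = field(default=None, repr=False)


def fit_gee_exchangeable(
    data: pd.DataFrame,
    formula: str,
    groups: str,
    independence: bool = False,
) -> GeeResult:
    """Fit a Gaussian GEE linear model with exchangeable working correlation.

    Parameters
    ----------
    data
        One row per observation (e.g. per region per eye).
    formula
        Patsy formula for the mean model, e.g. ``"change ~ location"``.
    groups
        Column naming the cluster (the eye).
    independence
        Force the working correlation to zero; with one observation per
        cluster, or generally under independence, the coefficient
        estimates coincide with ordinary least squares.
    """
    n_clusters = data[groups].nunique()
    if n_clusters < 2:
        raise ValueError("GEE requires at least 2 clusters")
    cov = sm.cov_struct.Independence() if independence else sm.cov_struct.Exchangeable()
    model = sm.GEE.from_formula(formula, groups=groups, data=data, cov_struct=cov)
    res = model.fit(maxiter=200)
    rho = 0.0 if independence else float(np.atleast_1d(cov.dep_params)[0])
    m = data.groupby(groups).size().max()
    if m > 1 and not independence and not (-1.0 / (m - 1) < rho < 1.0):
        raise RuntimeError(f"exchangeable correlation {rho:.3f} outside its valid range")
    return GeeResult(
        params=dict(res.params),
        robust_se=dict(res.bse),
        p_values=dict(res.pvalues),
        working_correlation=rho,
        n_clusters=int(n_clusters),
        n_obs=int(len(data)),
        converged=bool(getattr(res, "converged", True)),
        model=res,
    )


def build_paired_table(
    before: pd.DataFrame,
    after: pd.DataFrame,
    metadata: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Join per-region strain magnitudes across treatment states.

    ``before`` and ``after`` carry columns ``specimen, region, measure,
    pressure_pair, value``. Regions valid in only one state are dropped
    (and reported via a warning); a specimen present in only one state is
    an error. ``metadata`` may add per-specimen covariates (``age_group``,
    ``laterality``). The result has one row per specimen x region x
    measure x pressure pair with ``value_before``, ``value_after``,
    ``change`` (after minus before), ``location`` and ``quadrant`` parsed
    from the region label, sorted canonically.
    """
    keys = ["specimen", "region", "measure", "pressure_pair"]
    for df, name in ((before, "before"), (after, "after")):
        missing = set(keys + ["value"]) - set(df.columns)
        if missing:
            raise ValueError(f"{name} table lacks columns {sorted(missing)}")
    only_b = set(before["specimen"]) - set(after["specimen"])
    only_a = set(after["specimen"]) - set(before["specimen"])
    if only_b or only_a:
        raise ValueError(f"specimens present in one state only: {sorted(only_b | only_a)}")

    merged = before.merge(after, on=keys, how="outer", suffixes=("_before", "_after"), indicator=True)
    dropped = merged[merged["_merge"] != "both"]
    if len(dropped):
        lost = sorted(set(zip(dropped["specimen"], dropped["region"])))
        warnings.warn(f"dropping regions valid in one state only: {lost}", stacklevel=2)
    merged = merged[merged["_merge"] == "both"].drop(columns="_merge")
    merged["change"] = merged["value_after"] - merged["value_before"]
    parts = merged["region"].str.split("_", n=1, expand=True)
    merged["location"] = parts[0]
    merged["quadrant"] = parts[1]
    if metadata is not None:
        merged = merged.merge(metadata, on="specimen", how="left")
    return merged.sort_values(keys).reset_index(drop=True)


def strain_change_models(
    table: pd.DataFrame,
    measure: str,
    pressure_pair: str,
) -> dict[str, GeeResult]:
    """The four GEE models for one strain measure and pressure pair.

    1. intercept-only on the paired change (did strain change?);
    2. change ~ baseline strain magnitude;
    3. change ~ central/peripheral location;
    4. change ~ age group.
    Clusters are eyes; exchangeable working correlation throughout.
    """
    sub = table[(table["measure"] == measure) & (table["pressure_pair"] == pressure_pair)]
    if sub.empty:
        raise ValueError(f"no rows for {measure} at {pressure_pair}")
    out = {
        "change": fit_gee_exchangeable(sub, "change ~ 1", groups="specimen"),
        "vs_baseline": fit_gee_exchangeable(sub, "change ~ value_before", groups="specimen"),
        "vs_location": fit_gee_exchangeable(sub, "change ~ location", groups="specimen"),
    }
    if "age_group" in sub.columns and sub["age_group"].nunique() > 1:
        out["vs_age"] = fit_gee_exchangeable(sub, "change ~ age_group", groups="specimen")
    return out
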