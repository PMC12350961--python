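"""Empirical fidelity-longevity correlation analyses.

Joins the per-strain lifespan and translation-error-rate tables, runs
the short-lived-strain removal scan with bootstrap standard errors and
Bonferroni adjustment, supports allele-conditioned (stratified) scans,
and provides the small descriptive statistics used alongside: signed
percent change, a Kolmogorov-Smirnov normality check, and the one-way
strain-effect ANOVA.
"""

from __future__ import annotations

import math
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import orgel_model
from .orgel_model import DEFAULT_FRACTIONS, RemovalScanRow
from .qtl_mapping import GenotypeMatrix

__all__ = [
    "joint_table",
    "empirical_removal_scan",
    "stratified_scan",
    "percent_change",
    "ks_normality",
    "anova_strain_effect",
]


def joint_table(
    cls_table: pd.DataFrame, ter_table: pd.DataFrame, on: str = "strain"
) -> pd.DataFrame:
    """Inner join of the lifespan and error-rate tables on strain id.

    Expects a ``cls_mean`` (or ``cls``) column in the first table and an
    ``error_rate`` column in the second; raises on empty intersection.
    """
    left = cls_table.rename(columns={"cls_mean": "cls"})
    joined = left.merge(ter_table, on=on, suffixes=("_cls", "_ter"))
    joined = joined.dropna(subset=["cls", "error_rate"])
    if joined.empty:
        raise ValueError("no strains present in both trait tables")
    return joined.reset_index(drop=True)


def empirical_removal_scan(
    joint: pd.DataFrame,
    fractions: Sequence[float] = DEFAULT_FRACTIONS,
    n_boot: int = 100,
    seed: int | None = None,
) -> list[RemovalScanRow]:
    """Removal scan of the error-rate-vs-lifespan Spearman correlation.

    Removal is keyed to ascending mean CLS (shortest-lived strains are
    dropped first), with ties broken by strain id for determinism.
    Delegates to the simulation module's scan so empirical and simulated
    cohorts go through identical statistics.
    """
    ordered = joint.sort_values(["cls", "strain"], kind="stable").reset_index(drop=True)
    return orgel_model.removal_scan(
        ordered["error_rate"].to_numpy(),
        ordered["cls"].to_numpy(),
        fractions,
        n_boot=n_boot,
        seed=seed,
    )


def stratified_scan(
    joint: pd.DataFrame,
    geno: GenotypeMatrix,
    conditions: Sequence[tuple[str, float]],
    fractions: Sequence[float] = DEFAULT_FRACTIONS,
    n_boot: int = 100,
    seed: int | None = None,
) -> list[RemovalScanRow]:
    """Removal scan restricted to strains satisfying allele conditions.

    ``conditions`` is a list of (marker id, required call) with calls
    coded 0 = BY, 1 = RM; strains missing any conditioned marker are
    excluded.  Raises when fewer than 3 strains satisfy all conditions.
    """
    keep = pd.Series(True, index=geno.calls.index)
    for marker, allele in conditions:
        keep &= geno.calls[marker] == allele
    strains = keep.index[keep]
    subset = joint[joint["strain"].isin(strains)]
    if len(subset) < 3:
        raise ValueError("fewer than 3 strains satisfy the allele conditions")
    return empirical_removal_scan(subset, fractions, n_boot=n_boot, seed=seed)


def percent_change(reference: float, new: float) -> float:
    """Signed percent change, 100*(reference - new)/reference.

    Reductions relative to the reference are positive (a lower error
    rate in the derived strain is reported as a positive percent
    reduction); increases are negative.
    """
    if reference == 0:
        raise ValueError("reference value must be nonzero")
    return 100.0 * (reference - new) / reference


def ks_normality(values) -> tuple[float, float]:
    """One-sample Kolmogorov-Smirnov test against a fitted normal.

    The normal's mean and SD are estimated from the data, which makes
    the classical KS P value anti-conservative; a warning says so.  Use
    :func:`lilliefors_normality` for the corrected version.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 5:
        raise ValueError("need n >= 5")
    sd = values.std(ddof=1)
    if sd == 0:
        raise ValueError("zero-variance sample")
    warnings.warn(
        "KS test with parameters estimated from the data yields an "
        "anti-conservative P value; consider lilliefors_normality",
        UserWarning,
        stacklevel=2,
    )
    res = stats.kstest(values, "norm", args=(values.mean(), sd))
    return float(res.statistic), float(res.pvalue)


def lilliefors_normality(values) -> tuple[float, float]:
    """Lilliefors-corrected normality test (estimated-parameter KS)."""
    from statsmodels.stats.diagnostic import lilliefors

    values = np.asarray(values, dtype=float)
    if len(values) < 5:
        raise ValueError("need n >= 5")
    if values.std(ddof=1) == 0:
        raise ValueError("zero-variance sample")
    stat, p = lilliefors(values, dist="norm")
    return float(stat), float(p)


def anova_strain_effect(replicates: pd.DataFrame) -> tuple[float, float, dict]:
    """One-way ANOVA of strain identity on a replicated trait.

    ``replicates`` has columns strain, value.  Returns (F, P, detail)
    where detail holds the sums of squares and variance fractions; F is
    +inf (P = 0) when the within-strain mean square is zero while the
    between-strain one is not, and NaN when all values are identical.
    """
    groups = [
        grp["value"].dropna().to_numpy(dtype=float)
        for _, grp in replicates.groupby("strain", sort=True)
    ]
    groups = [g for g in groups if len(g) >= 2]
    if len(groups) < 2:
        raise ValueError("need >= 2 strains with >= 2 replicates")
    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_between = len(groups) - 1
    df_within = len(all_vals) - len(groups)
    msb = ss_between / df_between
    msw = ss_within / df_within
    detail = {
        "ss_between": ss_between,
        "ss_within": ss_within,
        "df_between": df_between,
        "df_within": df_within,
        "frac_between": ss_between / (ss_between + ss_within)
        if (ss_between + ss_within) > 0
        else math.nan,
    }
    if msw == 0:
        if msb == 0:
            return math.nan, math.nan, detail
        return math.inf, 0.0, detail
    F = msb / msw
    p = float(stats.f.sf(F, df_between, df_within))
    return float(F), p, detail
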