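"""Broad- and narrow-sense heritability with jackknife standard errors.

Broad-sense heritability H^2 = sigma2_G / (sigma2_G + sigma2_E) is
estimated from replicate-level trait values by one-way random-effects
variance components (method of moments on the between/within mean
squares, with k replicates drawn per strain to unify sample size).
Narrow-sense heritability h^2 = sigma2_A / (sigma2_A + sigma2_EV) comes
from a kinship-REML additive model: y = mu + g + e with
cov(g) = sigma2_A * K, where K = Z Z'/m is built from column-
standardized marker genotypes, and the variance ratio is profiled by
restricted maximum likelihood over the spectral decomposition of K
(equivalent in expectation to ridge-regression BLUP on markers).
Standard errors for both use the delete-one-strain jackknife.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .qtl_mapping import GenotypeMatrix

__all__ = [
    "HeritabilityEstimate",
    "broad_sense_h2",
    "narrow_sense_h2",
    "jackknife_se",
]


@dataclass(frozen=True)
class HeritabilityEstimate:
    """A heritability point estimate with components and jackknife SE."""

    estimate: float
    se: float
    components: tuple[float, float]  # (genetic variance, residual variance)
    n_strains: int
    clamped: bool = False
    flags: tuple[str, ...] = ()


def jackknife_se(values: Sequence, statistic: Callable) -> float:
    """Delete-one jackknife SE of ``statistic`` over strain-level units.

    ``statistic`` receives the list of retained units.  SE =
    sqrt(((n-1)/n) * sum_i (theta_(-i) - theta_bar)^2).  Leave-one-out
    sets on which the statistic is undefined (raises or returns NaN) are
    skipped.
    """
    values = list(values)
    n = len(values)
    if n < 3:
        raise ValueError("jackknife needs >= 3 strains")
    thetas = []
    for i in range(n):
        subset = values[:i] + values[i + 1 :]
        try:
            t = statistic(subset)
        except Exception:
            continue
        if t is not None and not math.isnan(t):
            thetas.append(t)
    if len(thetas) < 2:
        return math.nan
    thetas_arr = np.asarray(thetas)
    m = len(thetas_arr)
    return float(math.sqrt((m - 1) / m * np.sum((thetas_arr - thetas_arr.mean()) ** 2)))


def _anova_components(groups: list[np.ndarray], k: int) -> tuple[float, float]:
    """One-way random-effects variance components for balanced groups of
    size k: (sigma2_G, sigma2_E), with negative sigma2_G clamped to 0."""
    s = len(groups)
    grand = np.mean([g.mean() for g in groups])
    msb = k * sum((g.mean() - grand) ** 2 for g in groups) / (s - 1)
    msw = sum(((g - g.mean()) ** 2).sum() for g in groups) / (s * (k - 1))
    sigma_g = (msb - msw) / k
    return max(sigma_g, 0.0), msw


def _h2_from_groups(groups: list[np.ndarray], k: int) -> float:
    sg, se_ = _anova_components(groups, k)
    tot = sg + se_
    if tot == 0:
        return math.nan
    return min(max(sg / tot, 0.0), 1.0)


def broad_sense_h2(
    replicates: pd.DataFrame,
    k: int = 2,
    seed: int | None = None,
    method: str = "moments",
) -> HeritabilityEstimate:
    """Broad-sense heritability from replicate-level trait values.

    ``replicates`` has columns strain, value (one row per biological
    replicate).  ``k`` replicates are drawn per strain without
    replacement (seeded) to unify sample size; strains with fewer than k
    replicates are excluded with a flag.  ``method="moments"`` uses
    one-way ANOVA variance components; ``method="reml"`` fits the same
    random-intercept model by REML through statsmodels MixedLM as a
    cross-check.
    """
    if method not in ("moments", "reml"):
        raise ValueError(f"unknown method {method!r}")
    rng = np.random.default_rng(seed)
    flags: list[str] = []
    groups: list[np.ndarray] = []
    strains: list = []
    for strain, grp in replicates.groupby("strain", sort=True):
        vals = grp["value"].dropna().to_numpy(dtype=float)
        if len(vals) < k:
            flags.append(f"{strain}:fewer-than-{k}-replicates")
            continue
        pick = rng.choice(len(vals), size=k, replace=False) if len(vals) > k else np.arange(k)
        groups.append(vals[pick])
        strains.append(strain)
    if len(groups) < 3:
        raise ValueError("need >= 3 strains with enough replicates")

    if method == "reml":
        sg, se_var = _reml_components(groups)
    else:
        sg, se_var = _anova_components(groups, k)
    tot = sg + se_var
    est_raw = sg / tot if tot > 0 else math.nan
    clamped = not (0.0 <= est_raw <= 1.0)
    estimate = min(max(est_raw, 0.0), 1.0)

    if method == "reml":
        stat = lambda subset: _reml_h2(subset)
    else:
        stat = lambda subset: _h2_from_groups(subset, k)
    se = jackknife_se(groups, stat)
    return HeritabilityEstimate(
        estimate=estimate,
        se=se,
        components=(sg, se_var),
        n_strains=len(groups),
        clamped=clamped,
        flags=tuple(flags),
    )


def _reml_components(groups: list[np.ndarray]) -> tuple[float, float]:
    import statsmodels.formula.api as smf

    df = pd.DataFrame(
        {
            "value": np.concatenate(groups),
            "strain": np.repeat(np.arange(len(groups)), [len(g) for g in groups]),
        }
    )
    model = smf.mixedlm("value ~ 1", df, groups=df["strain"])
    fit = model.fit(reml=True)
    sg = float(fit.cov_re.iloc[0, 0])
    return sg, float(fit.scale)


def _reml_h2(groups: list[np.ndarray]) -> float:
    sg, se_ = _reml_components(groups)
    tot = sg + se_
    return min(max(sg / tot, 0.0), 1.0) if tot > 0 else math.nan


def kinship(geno: GenotypeMatrix | pd.DataFrame) -> pd.DataFrame:
    """Marker-based kinship K = Z Z'/m from column-standardized genotypes.

    Missing calls are imputed to the marker mean; monomorphic markers are
    dropped.
    """
    calls = geno.calls if isinstance(geno, GenotypeMatrix) else geno
    G = calls.to_numpy(dtype=float)
    mean = np.nanmean(G, axis=0)
    G = np.where(np.isnan(G), mean, G)
    sd = G.std(axis=0, ddof=0)
    poly = sd > 0
    if poly.sum() < 1:
        raise ValueError("no polymorphic markers")
    Z = (G[:, poly] - mean[poly]) / sd[poly]
    K = Z @ Z.T / poly.sum()
    return pd.DataFrame(K, index=calls.index, columns=calls.index)


def _reml_ratio(
    K: np.ndarray, y: np.ndarray, log_delta_bounds: tuple[float, float] = (-12.0, 12.0)
) -> tuple[float, float, float, bool]:
    """Profile REML over delta = sigma2_EV/sigma2_A on the spectrum of K.

    Returns (h2, sigma2_A, sigma2_EV, at_bound).  The criterion minimized
    is (n-1)ln(RSS) + sum ln(s+delta) + ln(sum w x~^2) with w = 1/(s+delta)
    and x~, y~ the eigenrotated intercept and phenotype.
    """
    n = len(y)
    s, U = np.linalg.eigh(K)
    s = np.clip(s, 0.0, None)
    yt = U.T @ y
    xt = U.T @ np.ones(n)

    def neg_restricted_ll(log_delta: float) -> float:
        delta = math.exp(log_delta)
        w = 1.0 / (s + delta)
        sxx = np.sum(w * xt * xt)
        beta = np.sum(w * xt * yt) / sxx
        resid = yt - xt * beta
        rss = np.sum(w * resid * resid)
        if rss <= 0:
            return math.inf
        return (n - 1) * math.log(rss) + np.sum(np.log(s + delta)) + math.log(sxx)

    lo, hi = log_delta_bounds
    grid = np.linspace(lo, hi, 100)
    vals = np.array([neg_restricted_ll(g) for g in grid])
    best = int(np.argmin(vals))
    a = grid[max(best - 1, 0)]
    b = grid[min(best + 1, len(grid) - 1)]
    res = minimize_scalar(neg_restricted_ll, bounds=(a, b), method="bounded")
    log_delta = float(res.x) if res.fun <= vals[best] else float(grid[best])
    at_bound = best in (0, len(grid) - 1)
    delta = math.exp(log_delta)
    w = 1.0 / (s + delta)
    sxx = np.sum(w * xt * xt)
    beta = np.sum(w * xt * yt) / sxx
    rss = float(np.sum(w * (yt - xt * beta) ** 2))
    sigma_a = rss / (n - 1)
    sigma_ev = delta * sigma_a
    h2 = 1.0 / (1.0 + delta)
    return h2, sigma_a, sigma_ev, at_bound


def narrow_sense_h2(
    geno: GenotypeMatrix,
    phenotype: pd.Series,
    jackknife: bool = True,
) -> HeritabilityEstimate:
    """Narrow-sense heritability by kinship REML.

    Strains present in both the genotype matrix and the (non-missing)
    phenotype are used.  ``jackknife=False`` skips the delete-one-strain
    SE, which requires one REML fit per strain.
    """
    pheno = phenotype.dropna()
    common = geno.calls.index.intersection(pheno.index)
    if len(common) < 20:
        raise ValueError("need >= 20 strains with genotype and phenotype")
    calls = geno.calls.loc[common]
    n_poly = int((calls.std(axis=0, ddof=0) > 0).sum())
    if n_poly < 10:
        raise ValueError("need >= 10 polymorphic markers")
    K_full = kinship(calls).to_numpy()
    y = pheno.loc[common].to_numpy(dtype=float)

    h2, sa, sev, at_bound = _reml_ratio(K_full, y)
    flags = ("ratio-at-optimizer-bound",) if at_bound else ()

    se = math.nan
    if jackknife:
        idx = np.arange(len(y))

        def stat(subset: Sequence[int]) -> float:
            keep = np.asarray(subset)
            K_sub = kinship(calls.iloc[keep])
            h, *_ = _reml_ratio(K_sub.to_numpy(), y[keep])
            return h

        se = jackknife_se(list(idx), stat)
    return HeritabilityEstimate(
        estimate=h2,
        se=se,
        components=(sa, sev),
        n_strains=len(common),
        clamped=False,
        flags=flags,
    )
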