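"""Marker-trait linkage mapping for haploid segregant panels.

Genotypes are biallelic (0 = BY allele, 1 = RM allele, NaN = missing).
The linkage statistic per marker is the LOD score

    LOD = -n * ln(1 - r^2) / (2 ln 10)

with ``r`` the Pearson correlation between the 0/1 genotype coding and
the trait over the n strains non-missing at that marker.  Genome-wide
significance thresholds come from permuting the phenotype-to-strain
assignment (mean + 3 SD of the per-permutation maximum LOD by default),
QTL locations are summarized by a 95% Bayesian credible interval built
from posterior weights proportional to 10^LOD, and pleiotropy is probed
by interval overlap and a combined (summed) LOD across two traits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "LODProfile",
    "QTLInterval",
    "lod_scan",
    "permutation_threshold",
    "call_peaks",
    "credible_interval",
    "interval_overlap",
    "combined_lod",
    "allele_means",
]

LN10_2 = 2.0 * math.log(10.0)


@dataclass(frozen=True)
class GenotypeMatrix:
    """Strains x markers call matrix with a marker map.

    ``calls`` is a DataFrame indexed by strain id with marker-id columns
    and values in {0.0, 1.0, NaN}; ``markers`` maps marker id to
    chromosome and 1-based bp position (ascending within chromosome).
    """

    calls: pd.DataFrame
    markers: pd.DataFrame  # index: marker id; columns: chrom, pos

    def __post_init__(self) -> None:
        if list(self.calls.columns) != list(self.markers.index):
            raise ValueError("marker map must match call-matrix columns in order")
        for _, grp in self.markers.groupby("chrom", sort=False):
            if np.any(np.diff(grp["pos"].to_numpy()) < 0):
                raise ValueError("marker positions must ascend within a chromosome")
        bad = ~(self.calls.isin([0.0, 1.0]) | self.calls.isna())
        if bad.to_numpy().any():
            raise ValueError("genotype calls must be 0, 1 or missing")

    @classmethod
    def from_frame(cls, calls: pd.DataFrame) -> "GenotypeMatrix":
        """Build from a call matrix whose columns are named 'chrom:pos'."""
        chroms, pos = zip(*(c.rsplit(":", 1) for c in calls.columns))
        markers = pd.DataFrame(
            {"chrom": chroms, "pos": [int(p) for p in pos]},
            index=pd.Index(calls.columns, name="marker"),
        )
        return cls(calls=calls.astype(float), markers=markers)


@dataclass(frozen=True)
class LODProfile:
    """Per-marker LOD scores for one trait."""

    table: pd.DataFrame  # columns: chrom, pos, lod, n_used, r; index: marker id
    trait: str = ""


@dataclass(frozen=True)
class QTLInterval:
    """Closed 1-based physical interval around a QTL peak."""

    chrom: str
    start: int
    end: int
    peak_marker: str
    coverage: float

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("interval start must be <= end")


def _align(geno: GenotypeMatrix, phenotype: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    pheno = phenotype.dropna()
    common = geno.calls.index.intersection(pheno.index)
    if len(common) < 3:
        raise ValueError("need >= 3 strains with both genotype and phenotype")
    G = geno.calls.loc[common].to_numpy(dtype=float)
    y = pheno.loc[common].to_numpy(dtype=float)
    return G, y


def _pearson_by_marker(G: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column-wise Pearson r between markers G (n x p, NaN allowed) and
    phenotype columns Y (n x k), with pairwise deletion of missing calls.

    Returns (r, n_used) with shapes (p, k) and (p,).
    """
    W = ~np.isnan(G)
    Gz = np.nan_to_num(G)
    n = W.sum(axis=0).astype(float)  # (p,)
    sg = Gz.sum(axis=0)
    sg2 = (Gz**2).sum(axis=0)
    sy = W.T @ Y  # (p, k)
    sy2 = W.T @ (Y**2)
    sgy = Gz.T @ Y
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = n[:, None] * sgy - sg[:, None] * sy
        var_g = n * sg2 - sg**2
        var_y = n[:, None] * sy2 - sy**2
        r = cov / np.sqrt(var_g[:, None] * var_y)
    r[var_g <= 0, :] = np.nan  # monomorphic markers
    return r, n.astype(int)


def lod_scan(geno: GenotypeMatrix, phenotype: pd.Series, trait: str = "") -> LODProfile:
    """Per-marker LOD profile for one trait.

    Strains missing the phenotype are dropped; genotype missingness is
    handled by pairwise deletion with n set per marker.  Monomorphic
    markers (or a zero-variance phenotype) yield NaN LOD; |r| = 1 yields
    +inf.
    """
    G, y = _align(geno, phenotype)
    r, n = _pearson_by_marker(G, y[:, None])
    r = r[:, 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        lod = -n * np.log1p(-(r**2)) / LN10_2
    lod[np.isclose(np.abs(r), 1.0)] = np.inf
    table = pd.DataFrame(
        {
            "chrom": geno.markers["chrom"].to_numpy(),
            "pos": geno.markers["pos"].to_numpy(),
            "lod": lod,
            "n_used": n,
            "r": r,
        },
        index=geno.markers.index,
    )
    return LODProfile(table=table, trait=trait)


def permutation_threshold(
    geno: GenotypeMatrix,
    phenotype: pd.Series,
    n_perm: int = 1000,
    mode: str = "genomewide_max",
    seed: int | None = None,
):
    """Permutation significance threshold(s): mean + 3 SD of permuted LODs.

    Phenotype-to-strain assignments are permuted ``n_perm`` times.  In
    ``genomewide_max`` mode (family-wise control, the default) the
    threshold is mean + 3*SD of the per-permutation maximum LOD; in
    ``per_marker`` mode a per-marker Series of mean + 3*SD is returned.
    When n! <= n_perm all n! assignments are enumerated exactly instead
    of sampled.
    """
    if mode not in ("genomewide_max", "per_marker"):
        raise ValueError(f"unknown mode {mode!r}")
    G, y = _align(geno, phenotype)
    n = len(y)
    if math.factorial(n) <= n_perm:
        perms = np.array(list(permutations(range(n))), dtype=int)
    else:
        rng = np.random.default_rng(seed)
        perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    Y = y[perms.T]  # (n, n_perm)
    r, n_used = _pearson_by_marker(G, Y)
    with np.errstate(divide="ignore", invalid="ignore"):
        lod = -n_used[:, None] * np.log1p(-(r**2)) / LN10_2
    if mode == "per_marker":
        mean = np.nanmean(lod, axis=1)
        sd = np.nanstd(lod, axis=1, ddof=1)
        return pd.Series(mean + 3 * sd, index=geno.markers.index)
    max_lod = np.nanmax(lod, axis=0)
    return float(np.mean(max_lod) + 3 * np.std(max_lod, ddof=1))


def call_peaks(profile: LODProfile, threshold: float) -> pd.DataFrame:
    """Per-chromosome peak markers reaching the threshold.

    For each chromosome with any marker LOD >= threshold, the maximal-LOD
    marker is reported (ties broken toward the lowest position).
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    t = profile.table
    peaks = []
    for chrom, grp in t.groupby("chrom", sort=False):
        grp = grp[grp["lod"] >= threshold]
        if grp.empty:
            continue
        best = grp.sort_values(["lod", "pos"], ascending=[False, True]).iloc[0]
        peaks.append(
            {
                "marker": best.name,
                "chrom": chrom,
                "pos": int(best["pos"]),
                "lod": float(best["lod"]),
            }
        )
    return pd.DataFrame(peaks, columns=["marker", "chrom", "pos", "lod"])


def credible_interval(
    profile: LODProfile, chrom: str, coverage: float = 0.95
) -> QTLInterval:
    """Bayesian credible interval for the QTL on one chromosome.

    Posterior marker weights are proportional to 10^LOD, normalized over
    the chromosome.  Markers are accumulated in decreasing weight order
    until the target coverage is reached; the interval spans the
    accumulated markers, expanded by one flanking marker on each side
    when available (emulating the ranked-weight credible-interval
    construction of standard QTL software).
    """
    t = profile.table[profile.table["chrom"] == chrom]
    t = t[np.isfinite(t["lod"]) | np.isinf(t["lod"])]
    t = t.dropna(subset=["lod"])
    if t.empty:
        raise ValueError(f"no finite-LOD markers on chromosome {chrom!r}")
    lod = t["lod"].to_numpy(dtype=float)
    if np.isinf(lod).any():
        weights = np.where(np.isinf(lod), 1.0, 0.0)
    else:
        weights = 10.0 ** (lod - lod.max())
    weights = weights / weights.sum()
    order = np.lexsort((t["pos"].to_numpy(), -weights))  # weight desc, pos asc
    cum = 0.0
    chosen: list[int] = []
    for i in order:
        chosen.append(i)
        cum += weights[i]
        if cum >= coverage - 1e-12:
            break
    pos = t["pos"].to_numpy()
    pos_sorted_idx = np.argsort(pos, kind="stable")
    lo = min(chosen, key=lambda i: pos[i])
    hi = max(chosen, key=lambda i: pos[i])
    # expand by one flanking marker on each side when available
    rank = {i: k for k, i in enumerate(pos_sorted_idx)}
    lo_rank = max(rank[lo] - 1, 0)
    hi_rank = min(rank[hi] + 1, len(pos) - 1)
    start = int(pos[pos_sorted_idx[lo_rank]])
    end = int(pos[pos_sorted_idx[hi_rank]])
    peak = t.index[int(np.lexsort((pos, -lod))[0])]
    return QTLInterval(chrom=chrom, start=start, end=end, peak_marker=peak, coverage=coverage)


def interval_overlap(a: QTLInterval, b: QTLInterval) -> QTLInterval | None:
    """Overlap of two credible intervals, or None when disjoint or on
    different chromosomes."""
    if a.chrom != b.chrom:
        return None
    start = max(a.start, b.start)
    end = min(a.end, b.end)
    if start > end:
        return None
    return QTLInterval(
        chrom=a.chrom,
        start=start,
        end=end,
        peak_marker=a.peak_marker,
        coverage=min(a.coverage, b.coverage),
    )


def combined_lod(
    profile_a: LODProfile, profile_b: LODProfile, region: QTLInterval
) -> pd.Series:
    """Marker maximizing LOD_a + LOD_b within a region (ties: lowest pos).

    Returns a Series with marker, chrom, pos, lod_a, lod_b and the
    combined score.  The combination is a plain sum of the two traits'
    LOD scores.
    """
    ta, tb = profile_a.table, profile_b.table
    shared = ta.index.intersection(tb.index)
    ta = ta.loc[shared]
    in_region = (
        (ta["chrom"] == region.chrom)
        & (ta["pos"] >= region.start)
        & (ta["pos"] <= region.end)
    )
    markers = shared[in_region.to_numpy()]
    if len(markers) == 0:
        raise ValueError("no shared markers within the region")
    total = ta.loc[markers, "lod"] + tb.loc[markers, "lod"]
    sub = pd.DataFrame(
        {"combined_lod": total, "pos": ta.loc[markers, "pos"]}
    ).sort_values(["combined_lod", "pos"], ascending=[False, True])
    best = sub.index[0]
    return pd.Series(
        {
            "marker": best,
            "chrom": region.chrom,
            "pos": int(ta.loc[best, "pos"]),
            "lod_a": float(ta.loc[best, "lod"]),
            "lod_b": float(tb.loc[best, "lod"]),
            "combined_lod": float(sub.iloc[0]["combined_lod"]),
        }
    )


def allele_means(genotype_col: pd.Series, phenotype: pd.Series) -> pd.DataFrame:
    """Per-allele phenotype mean, SE and n at one marker.

    Strains with a missing genotype or phenotype are excluded from both
    groups; a monomorphic marker is an error.
    """
    df = pd.DataFrame({"g": genotype_col, "y": phenotype}).dropna()
    groups = df.groupby("g")["y"]
    if groups.ngroups < 2:
        raise ValueError("marker is monomorphic among phenotyped strains")
    out = groups.agg(
        mean="mean",
        se=lambda v: float(np.std(v, ddof=1) / math.sqrt(len(v))) if len(v) > 1 else math.nan,
        n="count",
    )
    out.index = out.index.map({0.0: "BY", 1.0: "RM"})
    out.index.name = "allele"
    return out
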