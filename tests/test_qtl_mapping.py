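"""QTL mapping: LOD scans, permutation thresholds, credible intervals."""

import math
from itertools import permutations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fidlong import synthetic_data as sd
from fidlong.qtl_mapping import (
    GenotypeMatrix,
    LODProfile,
    QTLInterval,
    allele_means,
    call_peaks,
    combined_lod,
    credible_interval,
    interval_overlap,
    lod_scan,
    permutation_threshold,
)

LN10_2 = 2 * math.log(10)


def _geno(calls: np.ndarray, chroms=None) -> GenotypeMatrix:
    n, p = calls.shape
    chroms = chroms or ["chr1"] * p
    cols = [f"{c}:{1000 * (i + 1)}" for i, c in enumerate(chroms)]
    frame = pd.DataFrame(calls, columns=cols, index=[f"s{i}" for i in range(n)])
    return GenotypeMatrix.from_frame(frame)


def _profile(lods, chroms=None, positions=None) -> LODProfile:
    p = len(lods)
    chroms = chroms or ["chr1"] * p
    positions = positions or [1000 * (i + 1) for i in range(p)]
    table = pd.DataFrame(
        {"chrom": chroms, "pos": positions, "lod": lods, "n_used": 10, "r": 0.0},
        index=[f"m{i}" for i in range(p)],
    )
    return LODProfile(table=table)


class TestLodScan:
    def test_formula_matches_pearson_reference(self):
        rng = np.random.default_rng(0)
        g = rng.integers(0, 2, size=(60, 5)).astype(float)
        y = g[:, 0] + rng.normal(size=60)
        gm = _geno(g)
        prof = lod_scan(gm, pd.Series(y, index=gm.calls.index))
        for j, marker in enumerate(gm.calls.columns):
            r_ref = stats.pearsonr(g[:, j], y).statistic
            expected = -60 * math.log10(1 - r_ref**2) / 2
            assert prof.table.loc[marker, "lod"] == pytest.approx(expected, abs=1e-10)

    def test_known_r_half_value(self):
        # construct a 118-strain dataset with Pearson r exactly 0.5
        n = 118
        g = np.repeat([0.0, 1.0], n // 2)
        rng = np.random.default_rng(8)
        z0 = rng.normal(size=n)
        X = np.column_stack([np.ones(n), g])
        z = z0 - X @ np.linalg.lstsq(X, z0, rcond=None)[0]  # orthogonal to g
        z *= math.sqrt(3 * g.var() / z.var())
        y = g + z  # var(z) = 3 var(g), cov(g,z) = 0 -> r = 0.5 exactly
        gm = _geno(g[:, None])
        prof = lod_scan(gm, pd.Series(y, index=gm.calls.index))
        assert prof.table["lod"].iloc[0] == pytest.approx(
            -118 * math.log(1 - 0.25) / LN10_2
        )
        assert prof.table["lod"].iloc[0] == pytest.approx(7.371, abs=5e-4)

    def test_ln_and_log10_forms_identical(self):
        rng = np.random.default_rng(1)
        for r in rng.uniform(-0.999, 0.999, size=100):
            n = 100
            a = -n * math.log(1 - r**2) / LN10_2
            b = -n * math.log10(1 - r**2) / 2
            assert a == pytest.approx(b, abs=1e-12)

    def test_perfect_correlation_infinite_lod(self):
        g = np.repeat([0.0, 1.0], 5)
        gm = _geno(g[:, None])
        prof = lod_scan(gm, pd.Series(g, index=gm.calls.index))
        assert np.isinf(prof.table["lod"].iloc[0])

    def test_monomorphic_marker_undefined(self):
        g = np.column_stack([np.zeros(10), np.repeat([0.0, 1.0], 5)])
        gm = _geno(g)
        rng = np.random.default_rng(2)
        prof = lod_scan(gm, pd.Series(rng.normal(size=10), index=gm.calls.index))
        assert math.isnan(prof.table["lod"].iloc[0])
        assert np.isfinite(prof.table["lod"].iloc[1])

    def test_missing_calls_pairwise_deletion(self):
        g = np.repeat([0.0, 1.0], 10)[:, None].copy()
        g[0, 0] = np.nan
        gm = _geno(g)
        y = np.arange(20.0)
        prof = lod_scan(gm, pd.Series(y, index=gm.calls.index))
        assert prof.table["n_used"].iloc[0] == 19
        r_ref = stats.pearsonr(g[1:, 0], y[1:]).statistic
        assert prof.table["lod"].iloc[0] == pytest.approx(
            -19 * math.log(1 - r_ref**2) / LN10_2
        )

    def test_invariant_to_strain_order_shuffling(self):
        rng = np.random.default_rng(3)
        g = rng.integers(0, 2, size=(40, 8)).astype(float)
        y = g[:, 2] + rng.normal(size=40)
        gm = _geno(g)
        pheno = pd.Series(y, index=gm.calls.index)
        prof = lod_scan(gm, pheno)
        perm = rng.permutation(40)
        gm2 = GenotypeMatrix(gm.calls.iloc[perm], gm.markers)
        prof2 = lod_scan(gm2, pheno.iloc[perm])
        np.testing.assert_allclose(
            prof.table["lod"], prof2.table["lod"], rtol=1e-10
        )


class TestPermutationThreshold:
    def test_seeded_reproducible(self):
        rng = np.random.default_rng(4)
        g = rng.integers(0, 2, size=(30, 10)).astype(float)
        gm = _geno(g)
        y = pd.Series(rng.normal(size=30), index=gm.calls.index)
        a = permutation_threshold(gm, y, n_perm=200, seed=7)
        b = permutation_threshold(gm, y, n_perm=200, seed=7)
        assert a == b

    def test_exhaustive_enumeration_matches_brute_force(self):
        g = np.array([0.0, 0.0, 1.0, 1.0])
        gm = _geno(g[:, None])
        y = np.array([1.0, 2.0, 3.0, 4.0])
        thr = permutation_threshold(
            gm, pd.Series(y, index=gm.calls.index), n_perm=1000, seed=0
        )
        lods = []
        for perm in permutations(range(4)):
            r = stats.pearsonr(g, y[list(perm)]).statistic
            lods.append(-4 * math.log(1 - r**2) / LN10_2)
        expected = np.mean(lods) + 3 * np.std(lods, ddof=1)
        assert thr == pytest.approx(expected, rel=1e-12)

    def test_threshold_exceeds_null_scan_maximum(self):
        # with the trait independent of every marker, the genome-wide
        # mean + 3 SD threshold should sit above the observed null max
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            g = rng.integers(0, 2, size=(80, 120)).astype(float)
            gm = _geno(g, chroms=[f"chr{1 + i // 30}" for i in range(120)])
            y = pd.Series(rng.normal(size=80), index=gm.calls.index)
            thr = permutation_threshold(gm, y, n_perm=500, seed=seed)
            obs = lod_scan(gm, y).table["lod"].max()
            hits += thr > obs
        assert hits >= 19

    def test_per_marker_mode_returns_series(self):
        rng = np.random.default_rng(5)
        g = rng.integers(0, 2, size=(25, 6)).astype(float)
        gm = _geno(g)
        y = pd.Series(rng.normal(size=25), index=gm.calls.index)
        thr = permutation_threshold(gm, y, n_perm=100, mode="per_marker", seed=1)
        assert isinstance(thr, pd.Series)
        assert len(thr) == 6
        assert (thr > 0).all()


class TestPeaksAndIntervals:
    def test_no_marker_reaches_threshold(self):
        assert call_peaks(_profile([1.0, 2.0, 1.5]), 5.0).empty

    def test_single_peak_called(self):
        peaks = call_peaks(_profile([1.0, 6.0, 2.0]), 5.0)
        assert list(peaks["marker"]) == ["m1"]

    def test_tied_maxima_lowest_position_wins(self):
        peaks = call_peaks(_profile([1.0, 4.0, 4.0]), 3.0)
        assert peaks["pos"].iloc[0] == 2000

    def test_single_marker_chromosome_interval(self):
        prof = _profile([3.0], positions=[5000])
        ci = credible_interval(prof, "chr1")
        assert (ci.start, ci.end) == (5000, 5000)

    def test_flat_profile_spans_chromosome(self):
        prof = _profile([2.0] * 10)
        ci = credible_interval(prof, "chr1")
        assert (ci.start, ci.end) == (1000, 10000)

    def test_triangular_profile_matches_enumeration_oracle(self):
        lods = [0, 1, 2, 3, 4, 5, 4, 3, 2, 1, 0]
        prof = _profile(lods)
        ci = credible_interval(prof, "chr1", coverage=0.95)
        # independent brute-force accumulation
        pos = [1000 * (i + 1) for i in range(11)]
        w = [10.0**l for l in lods]
        total = sum(w)
        order = sorted(range(11), key=lambda i: (-w[i], pos[i]))
        acc, cum = [], 0.0
        for i in order:
            acc.append(i)
            cum += w[i] / total
            if cum >= 0.95:
                break
        lo, hi = min(acc), max(acc)
        lo = max(lo - 1, 0)
        hi = min(hi + 1, 10)
        assert (ci.start, ci.end) == (pos[lo], pos[hi])

    def test_interval_contains_chromosome_peak(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            lods = rng.uniform(0, 6, size=15)
            prof = _profile(list(lods))
            ci = credible_interval(prof, "chr1")
            peak_pos = prof.table.loc[prof.table["lod"].idxmax(), "pos"]
            assert ci.start <= peak_pos <= ci.end

    def test_all_undefined_chromosome_rejected(self):
        prof = _profile([math.nan, math.nan])
        with pytest.raises(ValueError):
            credible_interval(prof, "chr1")


class TestOverlapAndCombined:
    def _iv(self, chrom, start, end):
        return QTLInterval(chrom=chrom, start=start, end=end, peak_marker="m", coverage=0.95)

    def test_identical_intervals(self):
        a = self._iv("chr1", 100, 500)
        ov = interval_overlap(a, a)
        assert (ov.start, ov.end) == (100, 500)

    def test_partial_overlap(self):
        ov = interval_overlap(self._iv("chr1", 100, 500), self._iv("chr1", 300, 900))
        assert (ov.start, ov.end) == (300, 500)

    def test_disjoint_and_cross_chromosome_empty(self):
        assert interval_overlap(self._iv("chr1", 100, 200), self._iv("chr1", 300, 400)) is None
        assert interval_overlap(self._iv("chr1", 100, 200), self._iv("chr2", 100, 200)) is None

    def test_combined_lod_argmax_and_ties(self):
        a = _profile([3.0, 5.0, 4.0])
        b = _profile([0.0, 0.0, 0.0])
        region = self._iv("chr1", 1000, 3000)
        best = combined_lod(a, b, region)
        assert best["marker"] == "m1"
        assert best["combined_lod"] == pytest.approx(5.0)
        # single-marker region
        best2 = combined_lod(a, b, self._iv("chr1", 3000, 3000))
        assert best2["marker"] == "m2"

    def test_empty_region_rejected(self):
        a = _profile([1.0])
        with pytest.raises(ValueError):
            combined_lod(a, a, self._iv("chr2", 0, 10))


class TestAlleleMeans:
    def test_hand_computed_groups(self):
        g = pd.Series([0, 0, 0, 1, 1, 1], index=list("abcdef"), dtype=float)
        y = pd.Series([1, 2, 3, 4, 5, 6], index=list("abcdef"), dtype=float)
        out = allele_means(g, y)
        assert out.loc["BY", "mean"] == pytest.approx(2.0)
        assert out.loc["RM", "mean"] == pytest.approx(5.0)
        assert out.loc["BY", "se"] == pytest.approx(np.std([1, 2, 3], ddof=1) / math.sqrt(3))

    def test_zero_within_group_variance(self):
        g = pd.Series([0, 0, 1, 1], dtype=float)
        y = pd.Series([2.0, 2.0, 5.0, 5.0])
        out = allele_means(g, y)
        assert (out["se"] == 0).all()

    def test_missing_genotypes_excluded(self):
        g = pd.Series([0, 0, 1, 1, np.nan], dtype=float)
        y = pd.Series([1.0, 2.0, 3.0, 4.0, 100.0])
        out = allele_means(g, y)
        assert out["n"].sum() == 4

    def test_monomorphic_rejected(self):
        with pytest.raises(ValueError):
            allele_means(pd.Series([1.0, 1.0, 1.0]), pd.Series([1.0, 2.0, 3.0]))


class TestParameterRecovery:
    def test_planted_qtl_recovered_genomewide(self):
        # one additive QTL explaining 20% of trait variance on the
        # default 120-strain x 480-marker panel
        cfg = sd.SynthConfig()
        peak_hits = ci_hits = 0
        n_seeds = 100
        for seed in range(n_seeds):
            geno = sd.gen_genotypes(cfg, seed=500 + seed)
            marker = sd.resolve_marker(geno, cfg, "auto")
            chrom = marker.split(":")[0]
            rng = np.random.default_rng(900 + seed)
            g = geno.calls[marker].to_numpy()
            y = g + rng.normal(0, 1.0, size=len(g))  # QTL share = 0.25/1.25
            pheno = pd.Series(y, index=geno.calls.index)
            prof = lod_scan(geno, pheno)
            top = prof.table["lod"].idxmax()
            peak_hits += prof.table.loc[top, "chrom"] == chrom
            ci = credible_interval(prof, chrom)
            pos = geno.markers.loc[marker, "pos"]
            ci_hits += ci.start <= pos <= ci.end
        assert peak_hits >= 95
        assert ci_hits >= 85
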