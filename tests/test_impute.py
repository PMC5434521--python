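"""Haploid Li-Stephens imputation, accuracy statistics, longest-IBS runs."""

import itertools

import numpy as np
import pytest

from scaffoldphase import (
    MISSING,
    DosageMatrix,
    GenotypeMatrix,
    HaplotypeSet,
    MarkerPanel,
    accuracy_stats,
    crossval_impute,
    impute,
    longest_ibs,
)
from scaffoldphase.impute import _haploid_posteriors


def make_panel(pos, scaffold_idx=None):
    pos = np.asarray(pos)
    sc = np.zeros(len(pos), bool)
    if scaffold_idx is not None:
        sc[scaffold_idx] = True
    return MarkerPanel(
        chrom=np.array(["1"] * len(pos), dtype=object),
        pos=pos,
        ref=np.array(["A"] * len(pos), dtype=object),
        alt=np.array(["T"] * len(pos), dtype=object),
        is_scaffold=sc,
    )


class TestHaploidPosteriors:
    def test_matches_exhaustive_path_enumeration(self):
        ref = np.array([[0, 1, 0, 1], [1, 1, 0, 0]], dtype=np.int8)
        hap = np.array([0, 1, 0, 0], dtype=np.int8)
        gpos = np.array([0.0, 1.0, 2.5, 7.0])
        ne, e = 100.0, 0.01
        K, m = ref.shape
        d = np.diff(gpos) / 100.0
        sw = 1 - np.exp(-4 * ne * d / K)
        total = 0.0
        marg = np.zeros((m, K))
        for path in itertools.product(range(K), repeat=m):
            p = 1.0 / K
            for t in range(m):
                if t > 0:
                    p *= (1 - sw[t - 1] + sw[t - 1] / K) if path[t] == path[t - 1] else sw[t - 1] / K
                p *= (1 - e) if ref[path[t], t] == hap[t] else e
            total += p
            for t in range(m):
                marg[t, path[t]] += p
        marg /= total
        got = _haploid_posteriors(hap, ref, gpos, ne, e)
        assert np.allclose(got, marg, atol=1e-10)


class TestImpute:
    def _setup(self):
        # 2 reference individuals (4 haplotypes), 8 dense markers, scaffold on
        # the even markers; every haplotype has a unique typed-site pattern so
        # a perfect copy is identifiable from the scaffold alone
        h = np.array(
            [
                [0, 0, 0, 0, 0, 0, 0, 0],
                [1, 1, 1, 1, 1, 1, 1, 1],
                [0, 1, 1, 0, 0, 1, 1, 0],
                [1, 0, 0, 1, 1, 0, 0, 1],
            ],
            dtype=np.int8,
        )
        ref_alleles = np.stack(
            [np.stack([h[0], h[1]], axis=1), np.stack([h[2], h[3]], axis=1)]
        ).astype(np.int8)
        panel = make_panel((np.arange(8) + 1) * 1_000_000, scaffold_idx=[0, 2, 4, 6])
        return panel, HaplotypeSet(ref_alleles), h

    def test_perfect_copy_limit(self):
        panel, ref, h = self._setup()
        sc = panel.scaffold_indices
        target_full = np.stack([h[0], h[2]], axis=1)[None, :, :].astype(np.int8)
        target = HaplotypeSet(target_full[:, sc, :].copy())
        # small Ne keeps the copying path sticky so the identical reference
        # haplotype is followed across untyped sites
        dos = impute(target, ref, panel, ne=0.01, emission_mismatch=1e-9)
        want = (h[0] + h[2]).astype(float)
        assert np.allclose(dos.genotype[0], want, atol=1e-3)

    def test_monomorphic_marker_constant_dosage(self):
        panel, ref, h = self._setup()
        ref.alleles[:, 3, :] = 1
        sc = panel.scaffold_indices
        target = HaplotypeSet(ref.alleles[:2, sc, :].copy())
        dos = impute(target, ref, panel)
        assert np.allclose(dos.genotype[:, 3], 2.0, atol=1e-2)

    def test_unphased_target_rejected(self):
        panel, ref, h = self._setup()
        sc = panel.scaffold_indices
        bad = ref.alleles[:1, sc, :].copy()
        bad[0, 1, 1] = MISSING
        with pytest.raises(ValueError, match="phased"):
            impute(HaplotypeSet(bad), ref, panel)

    def test_dosage_bounds_and_hap_sum(self):
        panel, ref, h = self._setup()
        sc = panel.scaffold_indices
        target = HaplotypeSet(ref.alleles[:, sc, :].copy())
        dos = impute(target, ref, panel)
        assert np.all(dos.haplotype >= 0) and np.all(dos.haplotype <= 1)
        assert np.allclose(dos.genotype, dos.haplotype.sum(axis=2))


class TestCrossval:
    def test_full_coverage_pools(self):
        rng = np.random.default_rng(1)
        alleles = rng.integers(0, 2, size=(12, 10, 2)).astype(np.int8)
        panel = make_panel((np.arange(10) + 1) * 500_000, scaffold_idx=list(range(0, 10, 2)))
        haps = HaplotypeSet(alleles)
        target = HaplotypeSet(alleles[:, panel.scaffold_indices, :].copy())
        dos = crossval_impute(target, haps, panel, k_pools=4, pool_size=3, seed=9)
        assert not np.isnan(dos.genotype).any()  # every individual imputed exactly once

    def test_single_all_pool_rejected(self):
        alleles = np.zeros((4, 4, 2), dtype=np.int8)
        panel = make_panel([1, 2, 3, 4], scaffold_idx=[0, 2])
        haps = HaplotypeSet(alleles)
        target = HaplotypeSet(alleles[:, panel.scaffold_indices, :].copy())
        with pytest.raises(ValueError, match="reference"):
            crossval_impute(target, haps, panel, k_pools=1, pool_size=4, seed=0)

    def test_pool_assignment_deterministic(self):
        rng = np.random.default_rng(1)
        alleles = rng.integers(0, 2, size=(12, 10, 2)).astype(np.int8)
        panel = make_panel((np.arange(10) + 1) * 500_000, scaffold_idx=list(range(0, 10, 2)))
        haps = HaplotypeSet(alleles)
        target = HaplotypeSet(alleles[:, panel.scaffold_indices, :].copy())
        a = crossval_impute(target, haps, panel, k_pools=3, pool_size=4, seed=5)
        b = crossval_impute(target, haps, panel, k_pools=3, pool_size=4, seed=5)
        assert np.array_equal(a.genotype, b.genotype, equal_nan=True)


class TestAccuracyStats:
    def test_exact_dosages_r2_one_error_zero(self, rng):
        panel = make_panel((np.arange(6) + 1) * 1_000_000)
        obs = GenotypeMatrix(rng.integers(0, 3, size=(10, 6)).astype(np.int8))
        dos = DosageMatrix.__new__(DosageMatrix)
        dos.genotype = obs.values.astype(float)
        dos.haplotype = None
        stats = accuracy_stats(dos, obs, panel)
        poly = stats["snp"]["r2"].dropna()
        assert np.allclose(poly, 1.0)
        assert stats["mean_error_rate"] == 0.0

    def test_constant_offset_keeps_r2(self, rng):
        panel = make_panel((np.arange(6) + 1) * 1_000_000)
        obs = GenotypeMatrix(rng.integers(0, 3, size=(10, 6)).astype(np.int8))
        dos = DosageMatrix.__new__(DosageMatrix)
        dos.genotype = obs.values.astype(float) + 0.1
        dos.haplotype = None
        stats = accuracy_stats(dos, obs, panel)
        poly = stats["snp"]["r2"].dropna()
        assert np.allclose(poly, 1.0)
        assert stats["mean_error_rate"] == pytest.approx(0.1 / 2)

    def test_r2_matches_two_pass_formula(self, rng):
        panel = make_panel((np.arange(5) + 1) * 1_000_000)
        obs = GenotypeMatrix(rng.integers(0, 3, size=(20, 5)).astype(np.int8))
        dos = DosageMatrix.__new__(DosageMatrix)
        dos.genotype = rng.random((20, 5)) * 2
        dos.haplotype = None
        stats = accuracy_stats(dos, obs, panel)
        for j in range(5):
            x, y = dos.genotype[:, j], obs.values[:, j].astype(float)
            if np.var(y) == 0:
                assert np.isnan(stats["snp"]["r2"][j])
                continue
            sxy = np.mean(x * y) - x.mean() * y.mean()
            want = sxy**2 / (np.var(x) * np.var(y))
            assert stats["snp"]["r2"][j] == pytest.approx(want)


class TestLongestIbs:
    def test_target_equals_reference_spans_chromosome(self):
        panel = make_panel([1_000_000, 2_000_000, 5_000_000, 9_000_000])
        ref = HaplotypeSet(np.zeros((1, 4, 2), dtype=np.int8))
        target = HaplotypeSet(np.zeros((1, 4, 2), dtype=np.int8))
        tab = longest_ibs(target, ref, panel, scaffold_idx=np.arange(4))
        assert tab["longest_ibs_mb"].max() == pytest.approx(8.0)

    def test_alternating_mismatch_spans_one_interval(self):
        pos = (np.arange(5) + 1) * 1_000_000  # uniform 1 Mb spacing
        panel = make_panel(pos)
        ref = HaplotypeSet(np.zeros((1, 5, 2), dtype=np.int8))
        t = np.zeros((1, 5, 2), dtype=np.int8)
        t[0, 0::2, :] = 1  # differs at every even marker
        tab = longest_ibs(HaplotypeSet(t), ref, panel, scaffold_idx=np.arange(5))
        assert tab["longest_ibs_mb"].max() == pytest.approx(1.0)

    def test_matches_brute_force_scan(self, rng):
        pos = np.sort(rng.choice(50_000_000, size=12, replace=False)) + 1
        panel = make_panel(pos)
        ref = HaplotypeSet(rng.integers(0, 2, size=(3, 12, 2)).astype(np.int8))
        target = HaplotypeSet(rng.integers(0, 2, size=(2, 12, 2)).astype(np.int8))
        tab = longest_ibs(target, ref, panel, scaffold_idx=np.arange(12))
        mids = np.empty(13)
        mids[0], mids[-1] = pos[0], pos[-1]
        mids[1:-1] = (pos[1:] + pos[:-1]) / 2
        flat_ref = np.concatenate([ref.alleles[:, :, 0], ref.alleles[:, :, 1]])
        for _, row in tab.iterrows():
            t = target.alleles[int(row.individual), :, int(row.hap)]
            best = 0.0
            for r in flat_ref:
                run_best, start = 0.0, None
                for k in range(13):
                    if k < 12 and t[k] == r[k]:
                        if start is None:
                            start = k
                    elif start is not None:
                        run_best = max(run_best, mids[k] - mids[start])
                        start = None
                best = max(best, run_best)
            assert row.longest_ibs_mb == pytest.approx(best / 1e6)
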