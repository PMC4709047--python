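"""Two-locus EM against exhaustive grid-search, D' arithmetic, span counting."""

import numpy as np
import pytest

from founderscan.datatypes import MISSING, GenotypeDataset, SampleRecord, VariantRecord
from founderscan.ld import (
    PairLD,
    _batch_dprime,
    _em_tables,
    d_prime,
    em_haplotype_freqs,
    span_count,
)


def grid_max_loglik(tab, levels=5):
    """Oracle: maximise the observed-data log-likelihood over the haplotype
    frequency 3-simplex by nested grid refinement."""
    tab = np.asarray(tab, dtype=float)

    def loglik(p):
        p1, p2, p3, p4 = p
        cell = np.array(
            [
                [p4**2, 2 * p3 * p4, p3**2],
                [2 * p2 * p4, 2 * (p1 * p4 + p2 * p3), 2 * p1 * p3],
                [p2**2, 2 * p1 * p2, p1**2],
            ]
        )
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = tab * np.log(cell)
        return float(np.where(tab == 0, 0.0, terms).sum())

    center = np.full(4, 0.25)
    width = 0.5
    step = 0.05
    best, best_ll = center, loglik(center)
    for _ in range(levels):
        axes = [np.arange(max(c - width, 0.0), min(c + width, 1.0) + step / 2, step)
                for c in best[:3]]
        for x in axes[0]:
            for y in axes[1]:
                for z in axes[2]:
                    w = 1.0 - x - y - z
                    if w < -1e-12:
                        continue
                    p = np.clip([x, y, z, max(w, 0.0)], 0.0, 1.0)
                    s = p.sum()
                    if s == 0:
                        continue
                    ll = loglik(p / s)
                    if ll > best_ll:
                        best_ll, best = ll, p / s
        width = 2 * step
        step /= 5.0
    return best_ll, best


def _random_table(rng, n=120):
    """Random two-locus genotype table, both loci polymorphic."""
    while True:
        p = rng.dirichlet([1.5, 1.5, 1.5, 1.5])
        haps = rng.choice(4, size=(n, 2), p=p)
        ab = np.array([[1, 1], [1, 0], [0, 1], [0, 0]])
        g = ab[haps].sum(axis=1)  # (n, 2) dosages
        tab = np.zeros((3, 3))
        np.add.at(tab, (g[:, 0], g[:, 1]), 1)
        ca, cb = g[:, 0].sum(), g[:, 1].sum()
        if 0 < ca < 2 * n and 0 < cb < 2 * n:
            return tab, g


class TestEmHaplotypeFreqs:
    def test_no_double_heterozygotes_equals_direct_counting(self):
        # phase unambiguous: haplotype counts are read off the genotypes
        g1 = np.array([2, 2, 0, 0, 1, 1, 2, 0])
        g2 = np.array([2, 2, 0, 0, 0, 2, 1, 1])
        assert not np.any((g1 == 1) & (g2 == 1))
        pair = em_haplotype_freqs(g1, g2)
        # haplotypes read off directly: s1,s2 -> AB,AB; s3,s4 -> ab,ab;
        # s5 -> Ab+ab; s6 -> AB+aB; s7 -> AB+Ab; s8 -> aB+ab
        expect = np.array([6, 2, 2, 6], dtype=float) / 16.0
        got = np.array([pair.p_AB, pair.p_Ab, pair.p_aB, pair.p_ab])
        assert np.allclose(got, expect, atol=1e-9)

    def test_loglik_matches_grid_search(self, rng):
        for _ in range(8):
            tab, g = _random_table(rng, n=100)
            pair = em_haplotype_freqs(g[:, 0], g[:, 1], tol=1e-14, max_iter=5000)
            oracle_ll, _ = grid_max_loglik(tab)
            assert pair.loglik >= oracle_ll - 1e-6
            assert pair.loglik <= oracle_ll + 1e-4  # grid should come close

    def test_recovers_pool_frequencies_from_phased_pairs(self, rng):
        p_true = np.array([0.45, 0.15, 0.10, 0.30])
        n = 4000
        haps = rng.choice(4, size=(n, 2), p=p_true)
        ab = np.array([[1, 1], [1, 0], [0, 1], [0, 0]])
        g = ab[haps].sum(axis=1)
        pair = em_haplotype_freqs(g[:, 0], g[:, 1])
        se = np.sqrt(p_true * (1 - p_true) / (2 * n))
        got = np.array([pair.p_AB, pair.p_Ab, pair.p_aB, pair.p_ab])
        assert np.all(np.abs(got - p_true) < 3 * se)

    def test_frequencies_form_simplex(self, rng):
        tab, g = _random_table(rng)
        pair = em_haplotype_freqs(g[:, 0], g[:, 1])
        total = pair.p_AB + pair.p_Ab + pair.p_aB + pair.p_ab
        assert total == pytest.approx(1.0, abs=1e-9)
        assert abs(pair.d_prime) <= 1 + 1e-9
        assert -1e-9 <= pair.r2 <= 1 + 1e-9

    def test_missing_excluded_pairwise(self):
        g1 = np.array([2, 2, 0, 0, MISSING, 1])
        g2 = np.array([2, 2, 0, 0, 1, MISSING])
        pair = em_haplotype_freqs(g1, g2)
        assert pair.n_used == 4

    def test_monomorphic_rejected(self):
        with pytest.raises(ValueError, match="monomorphic"):
            em_haplotype_freqs(np.array([1, 1, 0, 2]), np.array([0, 0, 0, 0]))

    def test_scalar_and_batch_paths_agree(self, rng):
        g_index = rng.binomial(2, 0.3, size=150)
        g_region = rng.binomial(2, rng.uniform(0.1, 0.4, size=12), size=(150, 12))
        dp_batch, mono = _batch_dprime(g_index.astype(np.int8), g_region.astype(np.int8))
        for j in range(12):
            if mono[j]:
                continue
            pair = em_haplotype_freqs(g_index, g_region[:, j])
            assert dp_batch[j] == pytest.approx(abs(pair.d_prime), abs=1e-6)


class TestDPrime:
    def test_equilibrium_is_zero(self):
        pair = PairLD(0.12, 0.28, 0.18, 0.42, 0.0, 0.0, 0.0, 100, 1, 0.0)  # p_AB = pA*pB
        assert d_prime(pair) == 0.0

    def test_missing_haplotype_class_is_complete_ld(self):
        pair = PairLD(0.3, 0.0, 0.2, 0.5, 0.0, 0.0, 0.0, 100, 1, 0.0)
        assert abs(d_prime(pair)) == pytest.approx(1.0)

    def test_hand_formula(self):
        p = np.array([0.4, 0.2, 0.1, 0.3])
        pair = PairLD(*p, 0.0, 0.0, 0.0, 100, 1, 0.0)
        pa, pb = 0.6, 0.5
        d = 0.4 - pa * pb
        dmax = min(pa * (1 - pb), (1 - pa) * pb) if d > 0 else min(pa * pb, (1 - pa) * (1 - pb))
        assert d_prime(pair) == pytest.approx(d / dmax)

    def test_label_swap_invariance(self, rng):
        tab, g = _random_table(rng)
        dp1 = em_haplotype_freqs(g[:, 0], g[:, 1]).d_prime
        dp2 = em_haplotype_freqs(2 - g[:, 0], g[:, 1]).d_prime
        assert abs(dp1) == pytest.approx(abs(dp2), abs=1e-6)
        assert dp1 == pytest.approx(-dp2, abs=1e-6)


def _span_fixture():
    """5 SNPs x 8 samples with hand-enumerable LD to the index (SNP v3).

    Alleles chosen so that, against the index column, v1 and v2 have a missing
    haplotype class (|D'| = 1) while v4 and v5 do not.
    """
    samples = [SampleRecord(f"s{i}", "IV", 60.0, "male") for i in range(8)]
    variants = [
        VariantRecord(f"v{j + 1}", "1", 1000 * (j + 1), "G", "A", is_index=(j == 2))
        for j in range(5)
    ]
    idx = [0, 1, 2, 0, 1, 0, 2, 1]
    v1 = [0, 1, 2, 0, 1, 0, 2, 1]  # identical to index -> D' = 1
    v2 = [0, 0, 2, 0, 0, 0, 2, 0]  # minor allele only with index hom -> D' = 1
    v4 = [0, 0, 2, 2, 0, 0, 0, 2]  # all four classes seen unambiguously -> D' < 1
    v5 = [2, 1, 0, 2, 1, 2, 0, 1]  # mirror of the index: complete negative LD
    dos = np.array([v1, v2, idx, v4, v5], dtype=np.int8).T
    return GenotypeDataset(dos, samples, variants)


class TestSpanCount:
    def test_hand_enumerated_fixture(self):
        ds = _span_fixture()
        res = span_count(ds, "v3", ("1", 1, 6000), np.ones(8, dtype=bool))
        assert "v3" not in res.d_prime_by_snp  # index excluded from its own count
        assert res.d_prime_by_snp["v1"] == pytest.approx(1.0, abs=1e-6)
        assert res.d_prime_by_snp["v2"] == pytest.approx(1.0, abs=1e-6)
        assert res.d_prime_by_snp["v4"] < 1 - 1e-6
        assert res.count == sum(
            1 for v, dp in res.d_prime_by_snp.items() if dp >= 1 - 1e-6
        )

    def test_region_with_only_index(self, small_dataset, small_truth):
        ds = small_dataset
        j = ds.variant_index(small_truth.index_variant_id)
        pos = ds.variants[j].pos
        res = span_count(ds, small_truth.index_variant_id, ("1", pos, pos),
                         ds.stage_mask(["IV"]))
        assert res.count == 0 and res.snp_ids == []

    def test_monotone_in_tolerance(self, small_dataset, small_truth):
        ds = small_dataset
        region = ("1", 1, 10_000_000)
        mask = ds.stage_mask(["IV"])
        counts = [
            span_count(ds, small_truth.index_variant_id, region, mask, tolerance=t).count
            for t in (1e-9, 1e-6, 1e-3, 0.1)
        ]
        assert counts == sorted(counts)

    def test_shared_snp_restriction(self, small_dataset, small_truth):
        ds = small_dataset
        region = ("1", 1, 10_000_000)
        shared = ds.variant_ids[:10]
        res = span_count(ds, small_truth.index_variant_id, region,
                         ds.stage_mask(["IV"]), shared_snps=shared)
        assert set(res.snp_ids) <= set(shared)

    def test_index_monomorphic_rejected(self, small_dataset, small_truth):
        ds = small_dataset
        j = ds.variant_index(small_truth.index_variant_id)
        ds2 = small_dataset.subset()
        ds2.dosages[:, j] = 0
        with pytest.raises(ValueError, match="monomorphic"):
            span_count(ds2, small_truth.index_variant_id, ("1", 1, 10_000_000),
                       ds2.stage_mask(["IV"]))
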