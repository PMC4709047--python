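"""QC filters, the exact Hardy-Weinberg test against enumeration, and cmdscale."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from founderscan.datatypes import MISSING, GenotypeDataset, SampleRecord, VariantRecord
from founderscan.qc import (
    filter_samples,
    filter_variants,
    hwe_exact_p,
    ibs_distance_matrix,
    mds_components,
)


def hwe_brute_force(n_AA, n_Aa, n_aa):
    """Independent oracle: exact conditional test by Fraction enumeration.

    Enumerates every heterozygote count compatible with the allele counts,
    computes each configuration's probability with exact rational arithmetic,
    and sums those not exceeding the observed configuration's probability.
    """
    n = n_AA + n_Aa + n_aa
    n_a = n_Aa + 2 * n_aa
    rare = min(n_a, 2 * n - n_a)

    def weight(h):
        hom_rare = (rare - h) // 2
        hom_common = n - h - hom_rare
        return Fraction(
            2**h * math.factorial(n),
            math.factorial(h) * math.factorial(hom_rare) * math.factorial(hom_common),
        )

    hets = range(rare % 2, rare + 1, 2)
    weights = {h: weight(h) for h in hets}
    total = sum(weights.values())
    p_obs = weights[n_Aa]
    return float(sum(w for w in weights.values() if w <= p_obs) / total)


class TestHweExact:
    def test_monomorphic_is_one(self):
        assert hwe_exact_p(25, 0, 0) == 1.0
        assert hwe_exact_p(0, 0, 25) == 1.0

    def test_single_het_is_one(self):
        assert hwe_exact_p(0, 1, 0) == 1.0

    def test_matches_enumeration_on_balanced_table(self):
        assert hwe_exact_p(10, 10, 10) == pytest.approx(hwe_brute_force(10, 10, 10), rel=1e-9)

    @given(
        st.tuples(
            st.integers(min_value=0, max_value=25),
            st.integers(min_value=0, max_value=25),
            st.integers(min_value=0, max_value=25),
        ).filter(lambda t: sum(t) > 0)
    )
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_matches_enumeration_property(self, counts):
        assert hwe_exact_p(*counts) == pytest.approx(hwe_brute_force(*counts), rel=1e-9)

    def test_rejects_empty_table(self):
        with pytest.raises(ValueError):
            hwe_exact_p(0, 0, 0)


def _qc_dataset():
    """15 samples (12 stage I/II as the HWE reference group), 4 variants:
    v_good passes everything; v_raremaf has MAF 1/30; v_miss has 4/15 missing;
    v_hwe is heterozygous in every sample (exact HWE p ~ 0.002 at n = 12)."""
    samples = [
        SampleRecord(f"s{i}", stage, 60.0, "male")
        for i, stage in enumerate(["IV"] * 3 + ["I"] * 12)
    ]
    variants = [
        VariantRecord("v_good", "1", 100, "G", "A"),
        VariantRecord("v_raremaf", "1", 200, "G", "A"),
        VariantRecord("v_miss", "1", 300, "G", "A"),
        VariantRecord("v_hwe", "1", 400, "G", "A"),
    ]
    v_good = [1, 0, 2, 0, 1, 0, 1, 1, 0, 0, 1, 0, 1, 0, 1]
    v_rare = [0] * 15
    v_rare[5] = 1
    v_miss = [MISSING, 0, MISSING, 1, 0, MISSING, 1, 0, MISSING, 1, 0, 1, 0, 1, 0]
    v_hwe = [1] * 15
    dos = np.array([v_good, v_rare, v_miss, v_hwe], dtype=np.int8).T
    return GenotypeDataset(dos, samples, variants)


class TestVariantFilter:
    def test_clean_fixture_untouched(self, small_dataset):
        filtered, report = filter_variants(small_dataset, maf_min=0.0, miss_max=1.0, hwe_alpha=0.0)
        assert filtered.n_variants == small_dataset.n_variants
        assert report.removed_variants == []

    def test_each_rule_triggers_once(self):
        ds = _qc_dataset()
        filtered, report = filter_variants(ds, maf_min=0.1, miss_max=0.2, hwe_alpha=0.01)
        reasons = dict(report.removed_variants)
        assert reasons == {"v_raremaf": "maf", "v_miss": "missingness", "v_hwe": "hwe"}
        assert filtered.variant_ids == ["v_good"]
        # removed + retained partition the input
        assert set(reasons) | set(filtered.variant_ids) == set(ds.variant_ids)

    def test_paper_style_thresholds(self):
        # MAF < 0.01 and missingness > 2% are the conventional cutoffs
        samples = [SampleRecord(f"s{i}", "I", 60.0, "male") for i in range(100)]
        variants = [VariantRecord("v_rare", "1", 100, "G", "A"),
                    VariantRecord("v_gap", "1", 200, "G", "A")]
        dos = np.zeros((100, 2), dtype=np.int8)
        dos[0, 0] = 1  # MAF 0.005
        dos[:50, 1] = 1
        dos[:3, 1] = MISSING  # 3% missing
        ds = GenotypeDataset(dos, samples, variants)
        _, report = filter_variants(ds, maf_min=0.01, miss_max=0.02, hwe_alpha=0.0)
        assert ("v_rare", "maf") in report.removed_variants
        assert ("v_gap", "missingness") in report.removed_variants

    def test_empty_dataset_rejected(self):
        ds = _qc_dataset().subset(variant_idx=[])
        with pytest.raises(ValueError):
            filter_variants(ds)


class TestSampleFilter:
    def test_complete_data_kept(self, small_dataset):
        filtered, report = filter_samples(small_dataset, call_rate_min=0.0)
        assert filtered.n_samples == small_dataset.n_samples
        assert report.removed_samples == []

    def test_low_call_rate_removed(self):
        ds = _qc_dataset()
        # sample s0 has 1 of 4 missing -> call rate 0.75
        filtered, report = filter_samples(ds, call_rate_min=0.8)
        removed = [sid for sid, _ in report.removed_samples]
        assert "s0" in removed
        assert all(r == "call_rate" for _, r in report.removed_samples)
        assert filtered.n_samples + len(removed) == ds.n_samples

    def test_98_percent_convention(self):
        samples = [SampleRecord(f"s{i}", "I", 60.0, "male") for i in range(2)]
        variants = [VariantRecord(f"v{j}", "1", 100 + j, "G", "A") for j in range(100)]
        dos = np.zeros((2, 100), dtype=np.int8)
        dos[1, :3] = MISSING  # 97% call rate
        ds = GenotypeDataset(dos, samples, variants)
        _, report = filter_samples(ds, call_rate_min=0.98)
        assert report.removed_samples == [("s1", "call_rate")]


class TestMds:
    def test_identical_samples_zero_distance(self):
        samples = [SampleRecord(f"s{i}", "I", 60.0, "male") for i in range(3)]
        variants = [VariantRecord(f"v{j}", "1", 100 + j, "G", "A") for j in range(5)]
        dos = np.array([[1, 0, 2, 1, 0]] * 2 + [[0, 2, 0, 1, 2]], dtype=np.int8)
        d = ibs_distance_matrix(GenotypeDataset(dos, samples, variants))
        assert d[0, 1] == 0.0
        assert d[0, 2] > 0

    def test_hand_computed_cmdscale(self):
        # 3 samples, 2 SNPs: distances computed by hand, coordinates checked
        # against a direct eigendecomposition of the centred matrix
        samples = [SampleRecord(f"s{i}", "I", 60.0, "male") for i in range(3)]
        variants = [VariantRecord(f"v{j}", "1", 100 + j, "G", "A") for j in range(2)]
        dos = np.array([[0, 0], [2, 0], [2, 2]], dtype=np.int8)
        ds = GenotypeDataset(dos, samples, variants)
        d = ibs_distance_matrix(ds)
        expect_d = np.array([[0, 0.5, 1.0], [0.5, 0, 0.5], [1.0, 0.5, 0]])
        assert np.allclose(d, expect_d)
        res = mds_components(ds, k=1)
        j = np.eye(3) - np.ones((3, 3)) / 3
        b = -0.5 * j @ (expect_d**2) @ j
        lam, vec = np.linalg.eigh(b)
        coord = vec[:, -1] * np.sqrt(lam[-1])
        if coord[np.argmax(np.abs(coord))] < 0:
            coord = -coord
        assert np.allclose(res.components[:, 0], coord - coord.mean(), atol=1e-10)
        assert res.eigenvalues[0] == pytest.approx(lam[-1])

    def test_two_populations_separate_on_first_axis(self, rng):
        # two haplotype pools with very different allele frequencies
        n_per, m = 25, 60
        pa = rng.uniform(0.05, 0.2, size=m)
        pb = rng.uniform(0.6, 0.9, size=m)
        ga = rng.binomial(2, pa, size=(n_per, m))
        gb = rng.binomial(2, pb, size=(n_per, m))
        dos = np.vstack([ga, gb]).astype(np.int8)
        samples = [SampleRecord(f"s{i}", "I", 60.0, "male") for i in range(2 * n_per)]
        variants = [VariantRecord(f"v{j}", "1", 100 + j, "G", "A") for j in range(m)]
        res = mds_components(GenotypeDataset(dos, samples, variants), k=2)
        axis = res.components[:, 0]
        mu_a, mu_b = axis[:n_per].mean(), axis[n_per:].mean()
        spread = max(axis[:n_per].std(), axis[n_per:].std())
        assert abs(mu_a - mu_b) > 4 * spread  # clean separation
        assert abs(axis.mean()) < 1e-10  # centred
        assert res.eigenvalues[0] >= res.eigenvalues[1]

    def test_too_few_samples_rejected(self):
        ds = _qc_dataset().subset(sample_idx=[0])
        with pytest.raises(ValueError):
            mds_components(ds, k=1)
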