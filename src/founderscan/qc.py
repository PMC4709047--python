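"""Marker/sample quality control and population-stratification axes.

Implements the conventional GWAS filters used throughout the pipeline:
per-variant minor-allele frequency, missingness and an exact
Hardy-Weinberg-equilibrium test, a per-sample call-rate filter, and classical
multidimensional scaling (cmdscale) of the allele-sharing distance matrix for
stratification components.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .datatypes import MISSING, GenotypeDataset, genotype_counts


# ------------------------------------------------------------------- HWE exact
def hwe_exact_p(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact conditional Hardy-Weinberg test p-value.

    Conditions on the observed allele counts and sums the probabilities of all
    heterozygote counts whose conditional probability does not exceed that of
    the observed configuration (two-sided sum-of-smaller-probabilities
    definition, no mid-p correction).
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("all genotype counts are zero")
    n_a = n_Aa + 2 * n_aa  # minor-allele count; symmetry makes the choice immaterial
    n_A = 2 * n - n_a
    rare = min(n_a, n_A)

    # log P(het = h | allele counts) up to a constant:
    #   P(h) ∝ n! / (nAA! nAa! naa!) * 2^h   with nAa = h
    hets = np.arange(rare % 2, rare + 1, 2)
    logp = np.empty(hets.size)
    for k, h in enumerate(hets):
        hom_rare = (rare - h) // 2
        hom_common = n - h - hom_rare
        logp[k] = (
            h * math.log(2.0)
            - math.lgamma(h + 1)
            - math.lgamma(hom_rare + 1)
            - math.lgamma(hom_common + 1)
        )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    p_obs = probs[np.searchsorted(hets, n_Aa)]
    p = probs[probs <= p_obs * (1 + 1e-12)].sum()
    return float(min(p, 1.0))


# --------------------------------------------------------------------- reports
@dataclass
class QCReport:
    """Record of one QC pass: per-unit statistics and removals with reasons."""

    variant_maf: dict[str, float] = field(default_factory=dict)
    variant_missing: dict[str, float] = field(default_factory=dict)
    variant_hwe_p: dict[str, float] = field(default_factory=dict)
    sample_call_rate: dict[str, float] = field(default_factory=dict)
    removed_variants: list[tuple[str, str]] = field(default_factory=list)  # (id, reason)
    removed_samples: list[tuple[str, str]] = field(default_factory=list)
    # reserved for checks out of this artifact's scope (no X / IBD machinery)
    sex_mismatch: list[str] = field(default_factory=list)
    relatedness_flags: list[tuple[str, str]] = field(default_factory=list)


def filter_variants(
    dataset: GenotypeDataset,
    maf_min: float = 0.01,
    miss_max: float = 0.02,
    hwe_alpha: float = 1e-6,
    hwe_stages: tuple[str, ...] = ("I", "II"),
) -> tuple[GenotypeDataset, QCReport]:
    """Drop variants failing MAF / missingness / HWE thresholds.

    Rules are checked in a fixed order (MAF, then missingness, then HWE) and
    each removal records only its first triggering rule.  HWE is assessed in
    the non-metastatic reference group (``hwe_stages``); if no sample belongs
    to it, all samples are used.
    """
    for name, val in (("maf_min", maf_min), ("miss_max", miss_max), ("hwe_alpha", hwe_alpha)):
        if not 0 <= val <= 1:
            raise ValueError(f"{name} must be in [0, 1]")
    if dataset.n_variants == 0 or dataset.n_samples == 0:
        raise ValueError("empty dataset")

    report = QCReport()
    hwe_mask = dataset.stage_mask(hwe_stages)
    if not hwe_mask.any():
        hwe_mask = np.ones(dataset.n_samples, dtype=bool)

    keep = []
    for j, v in enumerate(dataset.variants):
        col = dataset.dosages[:, j]
        obs = col != MISSING
        miss_rate = 1.0 - obs.mean()
        maf = float(col[obs].sum()) / (2 * obs.sum()) if obs.any() else 0.0
        maf = min(maf, 1.0 - maf)
        report.variant_missing[v.variant_id] = float(miss_rate)
        report.variant_maf[v.variant_id] = maf
        n_AA, n_Aa, n_aa = genotype_counts(col[hwe_mask])
        hwe_p = hwe_exact_p(n_AA, n_Aa, n_aa) if (n_AA + n_Aa + n_aa) > 0 else 1.0
        report.variant_hwe_p[v.variant_id] = hwe_p
        if maf < maf_min:
            report.removed_variants.append((v.variant_id, "maf"))
        elif miss_rate > miss_max:
            report.removed_variants.append((v.variant_id, "missingness"))
        elif hwe_p < hwe_alpha:
            report.removed_variants.append((v.variant_id, "hwe"))
        else:
            keep.append(j)
    return dataset.subset(variant_idx=keep), report


def filter_samples(
    dataset: GenotypeDataset, call_rate_min: float = 0.98
) -> tuple[GenotypeDataset, QCReport]:
    """Drop samples whose genotype call rate falls below ``call_rate_min``."""
    if not 0 <= call_rate_min <= 1:
        raise ValueError("call_rate_min must be in [0, 1]")
    if dataset.n_variants == 0 or dataset.n_samples == 0:
        raise ValueError("empty dataset")
    report = QCReport()
    call_rate = (dataset.dosages != MISSING).mean(axis=1)
    keep = []
    for i, s in enumerate(dataset.samples):
        report.sample_call_rate[s.sample_id] = float(call_rate[i])
        if call_rate[i] < call_rate_min:
            report.removed_samples.append((s.sample_id, "call_rate"))
        else:
            keep.append(i)
    if not keep:
        raise ValueError("all samples removed by call-rate filter")
    return dataset.subset(sample_idx=keep), report


# ------------------------------------------------------------------------- MDS
@dataclass
class StratificationResult:
    components: np.ndarray  # samples x k, zero mean per axis
    eigenvalues: np.ndarray  # length k, decreasing
    k: int


def ibs_distance_matrix(dataset: GenotypeDataset) -> np.ndarray:
    """Pairwise allele-sharing distance: 1 - (shared alleles / 2) averaged
    over loci non-missing in both samples."""
    if dataset.n_samples < 2:
        raise ValueError("need at least 2 samples for a distance matrix")
    g = dataset.dosages.astype(float)
    g[dataset.dosages == MISSING] = np.nan
    n = g.shape[0]
    dist = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(g[i] - g)  # broadcasting over samples
        dist[i] = np.nanmean(diff, axis=1) / 2.0
    np.fill_diagonal(dist, 0.0)
    return dist


def mds_components(dataset: GenotypeDataset, k: int = 2) -> StratificationResult:
    """Classical metric scaling (cmdscale) of the allele-sharing distance.

    Eigen-decomposes the doubly-centred squared-distance matrix and returns
    the first ``k`` coordinate axes scaled by sqrt(eigenvalue), ordered by
    decreasing eigenvalue.  Each axis's sign is fixed so its largest-magnitude
    loading is positive.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if dataset.n_samples < k + 1:
        raise ValueError("need at least k+1 samples")
    d = ibs_distance_matrix(dataset)
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    eigval, eigvec = np.linalg.eigh(b)
    order = np.argsort(eigval)[::-1][:k]
    lam = np.clip(eigval[order], 0.0, None)
    coords = eigvec[:, order] * np.sqrt(lam)[None, :]
    for a in range(k):
        top = np.argmax(np.abs(coords[:, a]))
        if coords[top, a] < 0:
            coords[:, a] = -coords[:, a]
    coords -= coords.mean(axis=0, keepdims=True)
    return StratificationResult(components=coords, eigenvalues=lam, k=k)


__all__ = [
    "QCReport",
    "StratificationResult",
    "filter_samples",
    "filter_variants",
    "hwe_exact_p",
    "ibs_distance_matrix",
    "mds_components",
]
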