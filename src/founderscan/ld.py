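"""Pairwise linkage disequilibrium from unphased genotypes.

Two-locus haplotype frequencies are estimated by EM over the
double-heterozygote phase ambiguity, and D, D' and r^2 are derived from the
fitted frequencies.  The haplotype-span statistic counts, within one sample
group, the region SNPs in complete LD (|D'| = 1 within tolerance) with an
index SNP — the signature of a recent founder allele on a long conserved
haplotype.

The module keeps two EM code paths: :func:`em_haplotype_freqs`, a fully
instrumented single-pair estimator (iteration count, log-likelihood trace,
monotonicity check), and a vectorised internal batch used by
:func:`span_count` and the permutation test, where the same EM runs on many
index/SNP 3x3 genotype tables at once.  The two are tested for agreement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .datatypes import MISSING, GenotypeDataset

logger = logging.getLogger(__name__)

D_PRIME_TOL = 1e-6  # |D'| >= 1 - tol counts as complete LD
EM_TOL = 1e-12
EM_MAX_ITER = 1000


@dataclass
class PairLD:
    """Two-locus haplotype frequencies and derived LD measures.

    Haplotype classes are AB, Ab, aB, ab where A/a are the A1/A2 alleles at
    locus 1 and B/b at locus 2; D = p_AB − p_A·p_B.
    """

    p_AB: float
    p_Ab: float
    p_aB: float
    p_ab: float
    D: float
    d_prime: float
    r2: float
    n_used: int
    em_iterations: int
    loglik: float


def _crosstab(g1: np.ndarray, g2: np.ndarray) -> np.ndarray:
    """3x3 genotype cross-table over pairwise-complete samples."""
    ok = (g1 != MISSING) & (g2 != MISSING)
    tab = np.zeros((3, 3), dtype=np.int64)
    np.add.at(tab, (g1[ok], g2[ok]), 1)
    return tab


def _loglik_tables(tab: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Observed-data log-likelihood for (...,3,3) tables at (...,4) frequencies."""
    p1, p2, p3, p4 = p[..., 0], p[..., 1], p[..., 2], p[..., 3]
    # genotype-class probabilities; dosage g1 counts A, g2 counts B
    cell = np.empty(tab.shape[:-2] + (3, 3))
    cell[..., 2, 2] = p1**2
    cell[..., 2, 1] = 2 * p1 * p2
    cell[..., 2, 0] = p2**2
    cell[..., 1, 2] = 2 * p1 * p3
    cell[..., 1, 1] = 2 * (p1 * p4 + p2 * p3)
    cell[..., 1, 0] = 2 * p2 * p4
    cell[..., 0, 2] = p3**2
    cell[..., 0, 1] = 2 * p3 * p4
    cell[..., 0, 0] = p4**2
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = tab * np.log(cell)
    terms = np.where(tab == 0, 0.0, terms)
    return terms.sum(axis=(-2, -1))


def _em_tables(
    tables: np.ndarray, tol: float = EM_TOL, max_iter: int = EM_MAX_ITER
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Batch EM on (m,3,3) genotype cross-tables.

    Returns (freqs (m,4) in order AB, Ab, aB, ab; loglik (m,); iterations (m,)).
    Initialised at linkage equilibrium; iterates until the log-likelihood gain
    of every active table drops below ``tol``.
    """
    tab = np.asarray(tables, dtype=float)
    if tab.ndim == 2:
        tab = tab[None]
    m = tab.shape[0]
    n = tab.sum(axis=(1, 2))
    if np.any(n == 0):
        raise ValueError("empty genotype table")
    # allele counts: dosage value times cell count
    dos = np.arange(3, dtype=float)
    cA = (tab.sum(axis=2) * dos).sum(axis=1)
    cB = (tab.sum(axis=1) * dos).sum(axis=1)
    pA, pB = cA / (2 * n), cB / (2 * n)
    if np.any((cA == 0) | (cA == 2 * n) | (cB == 0) | (cB == 2 * n)):
        raise ValueError("LD undefined: a locus is monomorphic in the analysis set")

    # known haplotype counts from unambiguous cells
    base = np.empty((m, 4))
    base[:, 0] = 2 * tab[:, 2, 2] + tab[:, 2, 1] + tab[:, 1, 2]  # AB
    base[:, 1] = 2 * tab[:, 2, 0] + tab[:, 2, 1] + tab[:, 1, 0]  # Ab
    base[:, 2] = 2 * tab[:, 0, 2] + tab[:, 0, 1] + tab[:, 1, 2]  # aB
    base[:, 3] = 2 * tab[:, 0, 0] + tab[:, 0, 1] + tab[:, 1, 0]  # ab
    dh = tab[:, 1, 1]  # double heterozygotes: AB/ab vs Ab/aB

    p = np.column_stack([pA * pB, pA * (1 - pB), (1 - pA) * pB, (1 - pA) * (1 - pB)])
    p = np.clip(p, 1e-12, None)
    p /= p.sum(axis=1, keepdims=True)
    ll = _loglik_tables(tab, p)
    iters = np.zeros(m, dtype=int)
    active = np.ones(m, dtype=bool)
    for _ in range(max_iter):
        if not active.any():
            break
        pa = p[active]
        cis = pa[:, 0] * pa[:, 3]
        trans = pa[:, 1] * pa[:, 2]
        denom = cis + trans
        w = np.where(denom > 0, cis / np.where(denom > 0, denom, 1.0), 0.5)
        counts = base[active].copy()
        counts[:, 0] += w * dh[active]
        counts[:, 3] += w * dh[active]
        counts[:, 1] += (1 - w) * dh[active]
        counts[:, 2] += (1 - w) * dh[active]
        p_new = counts / (2 * n[active])[:, None]
        ll_new = _loglik_tables(tab[active], p_new)
        gain = ll_new - ll[active]
        p[active] = p_new
        iters[active] += 1
        idx = np.flatnonzero(active)
        ll[idx] = ll_new
        active[idx[gain < tol]] = False
    return p, ll, iters


def _ld_from_freqs(p: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(D, D', r2) arrays from (m,4) haplotype frequencies."""
    pA = p[:, 0] + p[:, 1]
    pB = p[:, 0] + p[:, 2]
    D = p[:, 0] - pA * pB
    with np.errstate(divide="ignore", invalid="ignore"):
        dmax_pos = np.minimum(pA * (1 - pB), (1 - pA) * pB)
        dmax_neg = np.minimum(pA * pB, (1 - pA) * (1 - pB))
        dmax = np.where(D >= 0, dmax_pos, dmax_neg)
        d_prime = np.where(D == 0, 0.0, D / dmax)
        r2 = D**2 / (pA * (1 - pA) * pB * (1 - pB))
    return D, d_prime, r2


def em_haplotype_freqs(
    dosages_locus1: np.ndarray,
    dosages_locus2: np.ndarray,
    tol: float = EM_TOL,
    max_iter: int = EM_MAX_ITER,
) -> PairLD:
    """EM haplotype-frequency estimate for one pair of loci.

    Samples missing at either locus are excluded pairwise.  The EM ascends the
    observed-data likelihood monotonically (asserted each iteration) from a
    linkage-equilibrium start.
    """
    g1 = np.asarray(dosages_locus1)
    g2 = np.asarray(dosages_locus2)
    tab = _crosstab(g1, g2).astype(float)
    n_used = int(tab.sum())
    n = tab.sum()
    if n == 0:
        raise ValueError("no pairwise-complete samples")
    dos = np.arange(3, dtype=float)
    cA = (tab.sum(axis=1) * dos).sum()
    cB = (tab.sum(axis=0) * dos).sum()
    if cA in (0, 2 * n) or cB in (0, 2 * n):
        raise ValueError("LD undefined: a locus is monomorphic in the analysis set")
    pA, pB = cA / (2 * n), cB / (2 * n)

    base = np.array(
        [
            2 * tab[2, 2] + tab[2, 1] + tab[1, 2],  # AB
            2 * tab[2, 0] + tab[2, 1] + tab[1, 0],  # Ab
            2 * tab[0, 2] + tab[0, 1] + tab[1, 2],  # aB
            2 * tab[0, 0] + tab[0, 1] + tab[1, 0],  # ab
        ]
    )
    dh = tab[1, 1]
    p = np.array([pA * pB, pA * (1 - pB), (1 - pA) * pB, (1 - pA) * (1 - pB)])
    p = np.clip(p, 1e-12, None)
    p /= p.sum()
    ll = float(_loglik_tables(tab[None], p[None])[0])
    iters = 0
    for _ in range(max_iter):
        cis, trans = p[0] * p[3], p[1] * p[2]
        w = cis / (cis + trans) if (cis + trans) > 0 else 0.5
        counts = base + dh * np.array([w, 1 - w, 1 - w, w])
        p_new = counts / (2 * n)
        ll_new = float(_loglik_tables(tab[None], p_new[None])[0])
        if ll_new < ll - 1e-9:
            raise AssertionError("EM log-likelihood decreased")
        gain = ll_new - ll
        p, ll = p_new, ll_new
        iters += 1
        if gain < tol:
            break
    D, dp, r2 = _ld_from_freqs(p[None])
    return PairLD(
        p_AB=float(p[0]), p_Ab=float(p[1]), p_aB=float(p[2]), p_ab=float(p[3]),
        D=float(D[0]), d_prime=float(dp[0]), r2=float(r2[0]),
        n_used=n_used, em_iterations=iters, loglik=ll,
    )


def d_prime(pair: PairLD) -> float:
    """Signed D' = D / Dmax from fitted haplotype frequencies."""
    p = np.array([[pair.p_AB, pair.p_Ab, pair.p_aB, pair.p_ab]])
    pA = p[0, 0] + p[0, 1]
    pB = p[0, 0] + p[0, 2]
    if min(pA, 1 - pA, pB, 1 - pB) <= 0:
        raise ValueError("D' undefined: a locus is monomorphic")
    _, dp, _ = _ld_from_freqs(p)
    return float(dp[0])


@dataclass
class SpanCount:
    group: str
    region: tuple[str, int, int]  # chrom, start, end (1-based inclusive)
    snp_ids: list[str]
    count: int
    d_prime_by_snp: dict[str, float] = field(default_factory=dict)
    skipped: list[str] = field(default_factory=list)


def region_columns(
    dataset: GenotypeDataset,
    region: tuple[str, int, int],
    shared_snps: Optional[Sequence[str]] = None,
) -> list[int]:
    chrom, start, end = region
    shared = set(shared_snps) if shared_snps is not None else None
    cols = [
        j
        for j, v in enumerate(dataset.variants)
        if v.chrom == chrom and start <= v.pos <= end and (shared is None or v.variant_id in shared)
    ]
    return cols


def dprime_from_tables(tables: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """|D'| via EM for a batch of (k,3,3) genotype cross-tables.

    Returns (|D'| with NaN where LD is undefined, monomorphic mask).
    """
    tab = np.asarray(tables, dtype=float)
    k = tab.shape[0]
    n = tab.sum(axis=(1, 2))
    dos = np.arange(3, dtype=float)
    cA = (tab.sum(axis=2) * dos).sum(axis=1)
    cB = (tab.sum(axis=1) * dos).sum(axis=1)
    mono = (n == 0) | (cA == 0) | (cA == 2 * n) | (cB == 0) | (cB == 2 * n)
    out = np.full(k, np.nan)
    ok = ~mono
    if ok.any():
        p, _, _ = _em_tables(tab[ok])
        _, dp, _ = _ld_from_freqs(p)
        out[ok] = np.abs(dp)
    return out, mono


def genotype_code_matrix(g_index: np.ndarray, g_region: np.ndarray) -> np.ndarray:
    """Per-sample, per-SNP code 3*g_index + g_snp in 0..8; 9 = pairwise missing."""
    valid = (g_index[:, None] != MISSING) & (g_region != MISSING)
    return np.where(valid, g_index[:, None] * 3 + g_region, 9)


def _batch_dprime(
    g_index: np.ndarray, g_region: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """|D'| of the index against each column of ``g_region`` in one EM batch.

    Missing dosages are handled pairwise-complete per column.
    """
    m = g_region.shape[1]
    code = genotype_code_matrix(g_index, g_region)
    offset = code + 10 * np.arange(m)[None, :]
    tab = np.bincount(offset.ravel(), minlength=10 * m).reshape(m, 10)[:, :9]
    return dprime_from_tables(tab.reshape(m, 3, 3))


def span_count(
    dataset: GenotypeDataset,
    index_id: str,
    region: tuple[str, int, int],
    group_mask: np.ndarray,
    shared_snps: Optional[Sequence[str]] = None,
    tolerance: float = D_PRIME_TOL,
) -> SpanCount:
    """Count region SNPs with |D'| = 1 (within tolerance) to the index SNP.

    LD is computed within ``group_mask`` samples only; the index SNP is
    excluded from its own count; SNPs monomorphic in the group are skipped
    and logged.
    """
    if not np.asarray(group_mask).any():
        raise ValueError("empty sample group")
    idx_col = dataset.variant_index(index_id)
    v_index = dataset.variants[idx_col]
    chrom, start, end = region
    if not (v_index.chrom == chrom and start <= v_index.pos <= end):
        raise ValueError("index SNP lies outside the requested region")
    cols = [j for j in region_columns(dataset, region, shared_snps) if j != idx_col]

    g_index = dataset.dosages[group_mask, idx_col]
    obs = g_index[g_index != MISSING]
    if obs.size == 0 or obs.sum() in (0, 2 * obs.size):
        raise ValueError("index SNP monomorphic in group")
    dp, mono = _batch_dprime(g_index, dataset.dosages[np.ix_(np.flatnonzero(group_mask), cols)])

    ids = [dataset.variants[j].variant_id for j in cols]
    skipped = [vid for vid, is_mono in zip(ids, mono) if is_mono]
    if skipped:
        logger.debug("span_count: skipped %d monomorphic SNP(s)", len(skipped))
    finite = ~np.isnan(dp)
    hits = int((dp[finite] >= 1.0 - tolerance).sum())
    return SpanCount(
        group="",
        region=region,
        snp_ids=ids,
        count=hits,
        d_prime_by_snp={vid: float(x) for vid, x in zip(ids, dp)},
        skipped=skipped,
    )


__all__ = [
    "D_PRIME_TOL",
    "PairLD",
    "SpanCount",
    "d_prime",
    "em_haplotype_freqs",
    "region_columns",
    "span_count",
]
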