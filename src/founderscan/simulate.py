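"""Synthetic case-case genotype cohorts with a planted founder risk haplotype.

The generator emulates a retrospective metastatic vs. non-metastatic colon
cancer contrast: fixed numbers of stage IV and stage I/II cases (plus optional
cancer-free controls used only as an allele-frequency reference), a biallelic
index SNP whose minor allele (A1) rides on a founder haplotype, and a
surrounding LD region in which stage IV carriers share a *longer* conserved
flanking haplotype than stage I/II carriers.

Model
-----
Each sample draws two haplotypes over the LD region independently.  With
probability ``f_g`` (group-specific) a haplotype belongs to the founder
lineage: it carries A1 at the index SNP and the fixed founder allele pattern
over a conserved tract of flanking SNPs; outside its conserved tract, and on
all non-founder haplotypes, alleles are independent Bernoulli draws at
per-SNP background frequencies (linkage equilibrium).  The founder frequency
is ``f0 = index_maf`` in stage I/II and ``f4`` in stage IV, chosen so the
allelic odds ratio between the groups equals ``allelic_or``:

    f4 / (1 - f4) = allelic_or * f0 / (1 - f0)

The founder-age signature is encoded by tract length: every founder
haplotype conserves a central core (the fraction ``1 - span_erosion`` of the
span nearest the index), stage IV founder haplotypes always conserve the
full ``founder_span``, and stage I/II (and control) founder copies are
intact over the full span only with probability
``nonmetastatic_intact_prob`` — the rest are "older" copies whose distal
flanks were shuffled by historical recombination.  A single recombinant copy
in a sample group breaks complete LD (|D'| = 1) between an outer-span SNP
and the index there, so the D'-span is systematically longer in stage IV.
With ``founder_span = 0`` the two groups are exchangeable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .datatypes import MISSING, GenotypeDataset, SampleRecord, VariantRecord

SNP_SPACING_BP = 5000  # uniform grid on one synthetic chromosome
MEAN_AGE, SD_AGE = 71.2, 10.3  # years
P_MALE = 0.52


@dataclass
class CohortSpec:
    """Parameters of one simulated cohort.

    Defaults follow the discovery-cohort design: 89 stage IV vs 234 stage I/II
    cases, index-SNP minor-allele frequency 0.14 in stage I/II and an allelic
    odds ratio of 2.63 for stage IV.
    """

    n_stage4: int = 89
    n_stage12: int = 234
    n_controls: int = 0
    n_snps: int = 60
    region_snps: int = 41
    index_maf: float = 0.14
    allelic_or: float = 2.63
    founder_span: int = 20
    background_maf_range: tuple[float, float] = (0.05, 0.45)
    missing_rate: float = 0.005
    seed: int = 0
    cohort_id: str = "cohort1"
    # Fraction of the founder span conserved only on intact (young) founder
    # copies; the remaining core nearest the index is conserved on every
    # founder haplotype.  0 makes both groups carry the full-length haplotype.
    span_erosion: float = 2.0 / 3.0
    # Probability that a stage I/II or control founder copy is intact over
    # the full span (stage IV copies always are); recombinant copies carry
    # background alleles on the eroded flanks.
    nonmetastatic_intact_prob: float = 0.5
    # Seed for the variant panel (background MAFs and founder allele pattern).
    # Cohorts sharing a panel_seed share the same genetic architecture and
    # differ only in their sample draws; None derives the panel from ``seed``.
    panel_seed: int | None = None

    def __post_init__(self) -> None:
        if min(self.n_stage4, self.n_stage12) <= 0 or self.n_controls < 0:
            raise ValueError("sample counts must be positive (controls may be 0)")
        if not 0 < self.index_maf <= 0.5:
            raise ValueError("index_maf must be in (0, 0.5]")
        if self.allelic_or <= 0:
            raise ValueError("allelic_or must be positive")
        if not 0 <= self.founder_span <= self.region_snps - 1 or self.region_snps > self.n_snps:
            raise ValueError("need founder_span <= region_snps - 1 and region_snps <= n_snps")
        lo, hi = self.background_maf_range
        if not 0 < lo <= hi <= 0.5:
            raise ValueError("background_maf_range must satisfy 0 < lo <= hi <= 0.5")
        if not 0 <= self.missing_rate <= 0.1:
            raise ValueError("missing_rate must be in [0, 0.1]")
        if not 0 <= self.span_erosion <= 1:
            raise ValueError("span_erosion must be in [0, 1]")
        if not 0 <= self.nonmetastatic_intact_prob <= 1:
            raise ValueError("nonmetastatic_intact_prob must be in [0, 1]")
        f4 = founder_freq_stage4(self.index_maf, self.allelic_or)
        if f4 >= 1:
            raise ValueError("allelic_or incompatible with index_maf (case frequency >= 1)")


def founder_freq_stage4(index_maf: float, allelic_or: float) -> float:
    """Stage IV A1 frequency implied by the stage I/II frequency and the odds ratio."""
    odds = allelic_or * index_maf / (1.0 - index_maf)
    return odds / (1.0 + odds)


def _span_layout(spec: CohortSpec) -> tuple[int, np.ndarray, np.ndarray]:
    """(index column, full founder-span columns, always-conserved core columns).

    Region SNPs occupy columns ``0..region_snps-1``; the index sits mid-region.
    The span is split as evenly as possible around the index, and the core
    keeps the SNPs nearest the index.
    """
    idx = spec.region_snps // 2
    left = spec.founder_span // 2
    right = spec.founder_span - left
    if idx - left < 0 or idx + right >= spec.region_snps:
        # re-balance at region edges
        left = min(left, idx)
        right = spec.founder_span - left
        if idx + right >= spec.region_snps:
            right = spec.region_snps - 1 - idx
            left = spec.founder_span - right
    span = np.array(
        sorted(range(idx - left, idx + right + 1), key=lambda j: (abs(j - idx), j)),
        dtype=int,
    )
    span = span[span != idx][: spec.founder_span]
    n_keep = int(round(spec.founder_span * (1.0 - spec.span_erosion)))
    return idx, np.sort(span), np.sort(span[:n_keep])


@dataclass
class TruthRecord:
    """Planted parameters of a simulated cohort, for recovery tests."""

    index_variant_id: str
    allelic_or: float
    founder_span: int
    f_stage12: float
    f_stage4: float
    f_controls: float
    span_variant_ids: list[str] = field(default_factory=list)
    conserved_stage12_ids: list[str] = field(default_factory=list)
    expected_span_difference: int = 0


def truth_table(spec: CohortSpec) -> TruthRecord:
    """Planted ground truth implied by a cohort spec (no simulation needed)."""
    idx, span_full, span_core = _span_layout(spec)
    ids = [_variant_id(j) for j in range(spec.n_snps)]
    return TruthRecord(
        index_variant_id=ids[idx],
        allelic_or=spec.allelic_or,
        founder_span=spec.founder_span,
        f_stage12=spec.index_maf,
        f_stage4=founder_freq_stage4(spec.index_maf, spec.allelic_or),
        f_controls=spec.index_maf,
        span_variant_ids=[ids[j] for j in span_full],
        conserved_stage12_ids=[ids[j] for j in span_core],
        expected_span_difference=len(span_full) - len(span_core),
    )


def _variant_id(j: int) -> str:
    return f"snp{j + 1:05d}"


def _draw_haplotypes(
    n_hap: int,
    founder_freq: float,
    founder_pattern: np.ndarray,
    core_cols: np.ndarray,
    full_cols: np.ndarray,
    intact_prob: float,
    index_col: int,
    maf: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw ``n_hap`` phased region haplotypes (0/1 A1 indicators).

    ``founder_pattern`` gives the founder allele at every region SNP; founder
    haplotypes copy it over the core span (always) and the full span (with
    probability ``intact_prob``); everything else is a background draw.
    """
    m = maf.size
    hap = (rng.random((n_hap, m)) < maf[None, :]).astype(np.int8)
    is_founder = rng.random(n_hap) < founder_freq
    intact = rng.random(n_hap) < intact_prob
    for mask, cols in ((is_founder & intact, full_cols), (is_founder & ~intact, core_cols)):
        if mask.any() and cols.size:
            hap[np.ix_(mask, cols)] = founder_pattern[cols][None, :]
    hap[is_founder, index_col] = 1
    hap[~is_founder, index_col] = 0  # A1 at the index segregates only on the founder lineage
    return hap


def simulate_cohort(spec: CohortSpec) -> GenotypeDataset:
    """Simulate one cohort; fully reproducible from ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    panel_rng = rng if spec.panel_seed is None else np.random.default_rng(spec.panel_seed)
    idx_col, span_full, span_core = _span_layout(spec)

    lo, hi = spec.background_maf_range
    maf = panel_rng.uniform(lo, hi, size=spec.n_snps)
    region = slice(0, spec.region_snps)
    # the founder haplotype is itself a draw from the background pool, so its
    # flanking alleles follow the per-SNP frequencies (mostly major alleles)
    founder_pattern = (panel_rng.random(spec.region_snps) < maf[region]).astype(np.int8)

    f0 = spec.index_maf
    f4 = founder_freq_stage4(spec.index_maf, spec.allelic_or)

    groups = [
        ("IV", spec.n_stage4, f4, 1.0),
        ("I/II", spec.n_stage12, f0, spec.nonmetastatic_intact_prob),
        ("control", spec.n_controls, f0, spec.nonmetastatic_intact_prob),
    ]
    hap_blocks = []
    stages: list[str] = []
    for label, n, freq, intact_prob in groups:
        if n == 0:
            continue
        h = (rng.random((2 * n, spec.n_snps)) < maf[None, :]).astype(np.int8)
        h[:, region] = _draw_haplotypes(
            2 * n, freq, founder_pattern, span_core, span_full, intact_prob,
            idx_col, maf[region], rng,
        )
        hap_blocks.append(h.reshape(n, 2, spec.n_snps))
        if label == "I/II":
            stages.extend(rng.choice(["I", "II"], size=n).tolist())
        else:
            stages.extend([label] * n)

    haplotypes = np.concatenate(hap_blocks, axis=0)
    dosages = haplotypes.sum(axis=1).astype(np.int8)
    n_total = dosages.shape[0]

    if spec.missing_rate > 0:
        mask = rng.random(dosages.shape) < spec.missing_rate
        dosages[mask] = MISSING

    ages = np.clip(rng.normal(MEAN_AGE, SD_AGE, size=n_total), 20.0, None)
    sexes = np.where(rng.random(n_total) < P_MALE, "male", "female")

    samples = [
        SampleRecord(
            sample_id=f"{spec.cohort_id}_s{i + 1:04d}",
            stage=stages[i],
            age=round(float(ages[i]), 1),
            sex=str(sexes[i]),
            cohort_id=spec.cohort_id,
        )
        for i in range(n_total)
    ]
    variants = [
        VariantRecord(
            variant_id=_variant_id(j),
            chrom="1",
            pos=SNP_SPACING_BP * (j + 1),
            a1="G",
            a2="A",
            is_index=(j == idx_col),
        )
        for j in range(spec.n_snps)
    ]
    return GenotypeDataset(dosages=dosages, samples=samples, variants=variants, haplotypes=haplotypes)


def simulate_index_snp(
    n_stage4: int,
    n_stage12: int,
    index_maf: float,
    allelic_or: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Fast path: dosages at the index SNP only, plus the 0/1 phenotype.

    Used by calibration studies that need many replicates of the association
    step without the LD region.
    """
    f4 = founder_freq_stage4(index_maf, allelic_or)
    if f4 >= 1:
        raise ValueError("allelic_or incompatible with index_maf")
    d4 = rng.binomial(2, f4, size=n_stage4)
    d12 = rng.binomial(2, index_maf, size=n_stage12)
    dosage = np.concatenate([d4, d12])
    pheno = np.concatenate([np.ones(n_stage4, dtype=int), np.zeros(n_stage12, dtype=int)])
    return dosage, pheno


__all__ = [
    "CohortSpec",
    "TruthRecord",
    "founder_freq_stage4",
    "simulate_cohort",
    "simulate_index_snp",
    "truth_table",
]
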