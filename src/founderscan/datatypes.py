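"""Core containers shared across the pipeline.

Genotypes are stored as a dense ``int8`` matrix of minor-allele (A1) dosages,
samples in rows and variants in columns, with ``-1`` marking a missing call.
Sample and variant metadata travel alongside as lists of records so that
filtering operations can subset all three consistently.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

MISSING = -1

VALID_STAGES = ("I", "II", "IV", "control")
VALID_SEXES = ("male", "female")


@dataclass
class SampleRecord:
    sample_id: str
    stage: str  # one of I, II, IV, control
    age: float
    sex: str  # male / female
    cohort_id: str = "cohort1"

    def __post_init__(self) -> None:
        if self.stage not in VALID_STAGES:
            raise ValueError(f"invalid stage {self.stage!r} for sample {self.sample_id}")
        if self.sex not in VALID_SEXES:
            raise ValueError(f"invalid sex {self.sex!r} for sample {self.sample_id}")
        if self.age <= 0:
            raise ValueError(f"age must be positive for sample {self.sample_id}")


@dataclass
class VariantRecord:
    variant_id: str
    chrom: str
    pos: int  # 1-based
    a1: str  # effect (minor) allele
    a2: str  # other allele
    is_index: bool = False

    def __post_init__(self) -> None:
        if self.pos <= 0:
            raise ValueError(f"position must be positive for {self.variant_id}")
        if self.a1 == self.a2:
            raise ValueError(f"alleles must differ for {self.variant_id}")


@dataclass
class GenotypeDataset:
    """Sample x variant dosage matrix plus metadata.

    ``dosages[i, j]`` counts copies of A1 for sample ``i`` at variant ``j``;
    ``-1`` means missing.  ``haplotypes``, when present (simulator output), is
    an ``(n_samples, 2, n_variants)`` 0/1 array of phased A1 indicators and is
    dropped by any I/O round trip.
    """

    dosages: np.ndarray
    samples: list[SampleRecord]
    variants: list[VariantRecord]
    haplotypes: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.ndim != 2:
            raise ValueError("dosage matrix must be 2-D (samples x variants)")
        n, m = self.dosages.shape
        if n != len(self.samples) or m != len(self.variants):
            raise ValueError(
                f"dosage matrix {n}x{m} does not match {len(self.samples)} samples / "
                f"{len(self.variants)} variants"
            )
        bad = ~np.isin(self.dosages, (MISSING, 0, 1, 2))
        if bad.any():
            raise ValueError("dosages must be in {0,1,2} or -1 (missing)")

    # ---- convenience accessors -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def variant_ids(self) -> list[str]:
        return [v.variant_id for v in self.variants]

    def variant_index(self, variant_id: str) -> int:
        for j, v in enumerate(self.variants):
            if v.variant_id == variant_id:
                return j
        raise KeyError(f"variant {variant_id!r} not in dataset")

    def stage_mask(self, stages: Sequence[str]) -> np.ndarray:
        stages = set(stages)
        return np.array([s.stage in stages for s in self.samples], dtype=bool)

    def subset(self, sample_idx=None, variant_idx=None) -> "GenotypeDataset":
        sample_idx = (
            np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        )
        variant_idx = (
            np.arange(self.n_variants) if variant_idx is None else np.asarray(variant_idx)
        )
        if sample_idx.dtype == bool:
            sample_idx = np.flatnonzero(sample_idx)
        if variant_idx.dtype == bool:
            variant_idx = np.flatnonzero(variant_idx)
        sample_idx = sample_idx.astype(np.intp)
        variant_idx = variant_idx.astype(np.intp)
        hap = None
        if self.haplotypes is not None:
            hap = self.haplotypes[sample_idx][:, :, variant_idx]
        return GenotypeDataset(
            dosages=self.dosages[np.ix_(sample_idx, variant_idx)],
            samples=[self.samples[i] for i in sample_idx],
            variants=[self.variants[j] for j in variant_idx],
            haplotypes=hap,
        )

    def a1_frequency(self, variant_idx: int, sample_mask: Optional[np.ndarray] = None) -> float:
        """Observed A1 allele frequency at one variant, ignoring missing calls."""
        col = self.dosages[:, variant_idx]
        if sample_mask is not None:
            col = col[sample_mask]
        col = col[col != MISSING]
        if col.size == 0:
            raise ValueError("no non-missing genotypes at variant")
        return float(col.sum()) / (2 * col.size)


def genotype_counts(col: np.ndarray) -> tuple[int, int, int]:
    """(n_AA, n_Aa, n_aa) where 'a' is the A1 allele, from a dosage column."""
    col = col[col != MISSING]
    return int((col == 0).sum()), int((col == 1).sum()), int((col == 2).sum())


__all__ = [
    "MISSING",
    "SampleRecord",
    "VariantRecord",
    "GenotypeDataset",
    "genotype_counts",
    "replace",
    "field",
]
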