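"""Readers and writers for the formats the pipeline touches.

VCF (4.2, GT-only), PLINK-style text .ped/.map, tab-delimited covariate and
result tables, and a YAML run configuration.  All readers normalise genotypes
to minor-allele (A1) dosage: after loading, A1 at every site is the less
common allele across all loaded samples, and any site whose ALT/original A1
turned out to be the major allele is flipped (dosage -> 2 - dosage) with the
flip recorded, so either convention can be audited.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd
import yaml
from cyvcf2 import VCF

from .datatypes import MISSING, GenotypeDataset, SampleRecord, VariantRecord, VALID_STAGES

logger = logging.getLogger(__name__)

COVARIATE_COLUMNS = ["sample_id", "stage", "age", "sex", "cohort_id"]
RESULT_COLUMNS = ["SNP", "Chr", "BP", "A1", "MAF", "OR", "95% CI", "P-value"]


# --------------------------------------------------------------------------- VCF
def write_vcf(dataset: GenotypeDataset, path) -> None:
    """Write unphased GT-only VCF 4.2; REF = A2, ALT = A1, missing = ./."""
    path = Path(path)
    contigs = sorted({v.chrom for v in dataset.variants})
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=founderscan\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(dataset.sample_ids)
            + "\n"
        )
        for j, v in enumerate(dataset.variants):
            col = dataset.dosages[:, j]
            gts = "\t".join(gt_map[int(d)] for d in col)
            fh.write(f"{v.chrom}\t{v.pos}\t{v.variant_id}\t{v.a2}\t{v.a1}\t.\tPASS\t.\tGT\t{gts}\n")


def _flip_to_minor(dosages: np.ndarray, variants: list[VariantRecord]) -> list[str]:
    """Re-designate A1 to the minor allele in place; return flipped variant ids."""
    flipped = []
    for j, v in enumerate(variants):
        col = dosages[:, j]
        obs = col[col != MISSING]
        if obs.size == 0:
            continue
        if obs.sum() > obs.size:  # A1 frequency > 0.5
            col[col != MISSING] = 2 - col[col != MISSING]
            variants[j] = VariantRecord(
                variant_id=v.variant_id,
                chrom=v.chrom,
                pos=v.pos,
                a1=v.a2,
                a2=v.a1,
                is_index=v.is_index,
            )
            flipped.append(v.variant_id)
    if flipped:
        logger.info("re-designated A1 to the minor allele at %d site(s)", len(flipped))
    return flipped


@dataclass
class LoadReport:
    n_loaded: int = 0
    n_skipped_multiallelic: int = 0
    n_skipped_nonsnp: int = 0
    flipped_variant_ids: list[str] = field(default_factory=list)


def read_vcf(path, report: Optional[LoadReport] = None) -> GenotypeDataset:
    """Load biallelic SNPs from a VCF with GT; multi-allelic sites are skipped.

    Dosages count the minor allele across all loaded samples (sites flipped as
    needed, recorded in ``report.flipped_variant_ids``).
    """
    path = str(path)
    rpt = report if report is not None else LoadReport()
    vcf = VCF(path, gts012=True)
    sample_ids = list(vcf.samples)
    rows: list[np.ndarray] = []
    variants: list[VariantRecord] = []
    for rec in vcf:
        if len(rec.ALT) != 1:
            rpt.n_skipped_multiallelic += 1
            continue
        ref, alt = rec.REF, rec.ALT[0]
        if len(ref) != 1 or len(alt) != 1:
            rpt.n_skipped_nonsnp += 1
            continue
        # with gts012=True: 0/1/2 = ALT dosage, 3 = missing
        gt = np.asarray(rec.gt_types, dtype=np.int8)
        gt[gt == 3] = MISSING
        rows.append(gt)
        vid = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}"
        variants.append(
            VariantRecord(variant_id=vid, chrom=str(rec.CHROM), pos=int(rec.POS), a1=alt, a2=ref)
        )
    vcf.close()
    if rpt.n_skipped_multiallelic:
        logger.warning("skipped %d multi-allelic site(s) in %s", rpt.n_skipped_multiallelic, path)
    if not rows:
        raise ValueError(f"no biallelic SNPs loaded from {path}")
    dosages = np.stack(rows, axis=1)
    rpt.flipped_variant_ids = _flip_to_minor(dosages, variants)
    rpt.n_loaded = len(variants)
    samples = [
        SampleRecord(sample_id=s, stage="control", age=50.0, sex="female") for s in sample_ids
    ]
    return GenotypeDataset(dosages=dosages, samples=samples, variants=variants)


# ------------------------------------------------------------------- PLINK text
def write_plink_text(dataset: GenotypeDataset, ped_path, map_path) -> None:
    """PLINK-style text .ped/.map; missing genotype written as '0 0'."""
    with Path(map_path).open("w") as fh:
        for v in dataset.variants:
            fh.write(f"{v.chrom}\t{v.variant_id}\t0\t{v.pos}\n")
    with Path(ped_path).open("w") as fh:
        for i, s in enumerate(dataset.samples):
            sex_code = "1" if s.sex == "male" else "2"
            pheno = {"IV": "2", "I": "1", "II": "1"}.get(s.stage, "0")
            fields = [s.cohort_id, s.sample_id, "0", "0", sex_code, pheno]
            for j, v in enumerate(dataset.variants):
                d = int(dataset.dosages[i, j])
                pair = {0: (v.a2, v.a2), 1: (v.a1, v.a2), 2: (v.a1, v.a1), MISSING: ("0", "0")}[d]
                fields.extend(pair)
            fh.write("\t".join(fields) + "\n")


def read_plink_text(ped_path, map_path) -> GenotypeDataset:
    """Read paired .ped/.map text files; '0 0' genotypes become missing."""
    variants: list[VariantRecord] = []
    with Path(map_path).open() as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, vid, _cm, pos = line.split()[:4]
            variants.append(
                VariantRecord(variant_id=vid, chrom=chrom, pos=int(pos), a1="?", a2="!")
            )
    m = len(variants)
    samples: list[SampleRecord] = []
    allele_rows: list[list[tuple[str, str]]] = []
    with Path(ped_path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            toks = line.split()
            if len(toks) != 6 + 2 * m:
                raise ValueError(
                    f"{ped_path} line {lineno}: expected {6 + 2 * m} fields "
                    f"({m} variants in map), got {len(toks)}"
                )
            fid, iid, _pat, _mat, sex_code, _pheno = toks[:6]
            samples.append(
                SampleRecord(
                    sample_id=iid,
                    stage="control",
                    age=50.0,
                    sex="male" if sex_code == "1" else "female",
                    cohort_id=fid,
                )
            )
            allele_rows.append(
                [(toks[6 + 2 * j], toks[7 + 2 * j]) for j in range(m)]
            )
    if not samples:
        raise ValueError(f"no samples in {ped_path}")

    dosages = np.full((len(samples), m), MISSING, dtype=np.int8)
    for j in range(m):
        counts: dict[str, int] = {}
        for row in allele_rows:
            for a in row[j]:
                if a != "0":
                    counts[a] = counts.get(a, 0) + 1
        if not counts:
            continue
        alleles = sorted(counts, key=lambda a: (counts[a], a))
        a1 = alleles[0]  # rarest observed allele
        a2 = alleles[-1] if len(alleles) > 1 else ("A" if a1 != "A" else "T")
        if len(counts) > 2:
            raise ValueError(f"variant {variants[j].variant_id}: more than two alleles in .ped")
        v = variants[j]
        variants[j] = VariantRecord(
            variant_id=v.variant_id, chrom=v.chrom, pos=v.pos, a1=a1, a2=a2
        )
        for i, row in enumerate(allele_rows):
            x, y = row[j]
            if x == "0" or y == "0":
                continue
            dosages[i, j] = (x == a1) + (y == a1)
    _flip_to_minor(dosages, variants)
    return GenotypeDataset(dosages=dosages, samples=samples, variants=variants)


# ------------------------------------------------------------------- covariates
def write_covariates(dataset: GenotypeDataset, path) -> None:
    df = pd.DataFrame(
        [[s.sample_id, s.stage, s.age, s.sex, s.cohort_id] for s in dataset.samples],
        columns=COVARIATE_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_covariates(path) -> list[SampleRecord]:
    """Read the tab-delimited covariate table (header required)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    missing = [c for c in COVARIATE_COLUMNS[:4] if c not in df.columns]
    if missing:
        raise ValueError(f"covariate file {path} missing required column(s): {missing}")
    if "cohort_id" not in df.columns:
        df["cohort_id"] = "cohort1"
    records = []
    for i, row in df.iterrows():
        if row["stage"] not in VALID_STAGES:
            raise ValueError(
                f"covariate file {path} row {i + 2}: invalid stage {row['stage']!r}"
            )
        records.append(
            SampleRecord(
                sample_id=str(row["sample_id"]),
                stage=str(row["stage"]),
                age=float(row["age"]),
                sex=str(row["sex"]),
                cohort_id=str(row["cohort_id"]),
            )
        )
    return records


def attach_covariates(dataset: GenotypeDataset, records: Iterable[SampleRecord]) -> list[str]:
    """Join covariate records to genotype samples by id; return unmatched ids."""
    by_id = {r.sample_id: r for r in records}
    unmatched = [sid for sid in by_id if sid not in set(dataset.sample_ids)]
    for i, s in enumerate(dataset.samples):
        if s.sample_id in by_id:
            dataset.samples[i] = by_id[s.sample_id]
    missing_cov = [s for s in dataset.sample_ids if s not in by_id]
    if missing_cov:
        logger.warning("%d genotyped sample(s) lack covariates", len(missing_cov))
    if unmatched:
        logger.warning("dropped %d covariate row(s) with no genotyped sample", len(unmatched))
    return unmatched


# ---------------------------------------------------------------- result tables
def write_results_table(results, path) -> None:
    """Tab-delimited association table (one row per SNP), stable column order.

    ``results`` is an iterable of AssociationResult carrying .variant (a
    VariantRecord), .maf, .or_, .ci_lo, .ci_hi, .p.
    """
    rows = []
    for r in results:
        v = r.variant
        rows.append(
            [
                v.variant_id,
                v.chrom,
                v.pos,
                v.a1,
                f"{r.maf:.4g}" if r.maf is not None else "NA",
                f"{r.or_:.4g}" if r.converged else "NA",
                f"({r.ci_lo:.4g}, {r.ci_hi:.4g})" if r.converged else "NA",
                f"{r.p:.4g}" if r.converged else "NA",
            ]
        )
    pd.DataFrame(rows, columns=RESULT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_results_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ----------------------------------------------------------------------- config
@dataclass
class RunConfig:
    """Pipeline run configuration (YAML-serialisable)."""

    genotype_path: str = ""
    covariate_path: str = ""
    metastatic_stages: tuple[str, ...] = ("IV",)
    nonmetastatic_stages: tuple[str, ...] = ("I", "II")
    maf_min: float = 0.01
    miss_max: float = 0.02
    call_rate_min: float = 0.98
    hwe_alpha: float = 1e-6
    covariates: tuple[str, ...] = ("age", "sex", "PC1", "PC2")
    tier1_size: int = 9
    tier1_alpha: float = 0.04
    tier2_size: int = 8
    tier2_alpha: float = 0.01
    power_floor: float = 0.80
    region: Optional[tuple[str, int, int]] = None
    n_perm: int = 10_000
    seed: int = 0
    out_dir: str = "results"

    def __post_init__(self) -> None:
        for name in ("maf_min", "miss_max", "call_rate_min", "hwe_alpha"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be a fraction in [0, 1]")
        if self.n_perm < 100:
            raise ValueError("n_perm must be >= 100")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with Path(path).open() as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("metastatic_stages", "nonmetastatic_stages", "covariates"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if raw.get("region") is not None:
            raw["region"] = tuple(raw["region"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        data = {
            k: (list(v) if isinstance(v, tuple) else v) for k, v in self.__dict__.items()
        }
        with Path(path).open("w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


__all__ = [
    "LoadReport",
    "RunConfig",
    "attach_covariates",
    "read_covariates",
    "read_plink_text",
    "read_results_table",
    "read_vcf",
    "write_covariates",
    "write_plink_text",
    "write_results_table",
    "write_vcf",
]
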