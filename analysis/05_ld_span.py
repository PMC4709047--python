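#!/usr/bin/env python
"""Per-group D' profiles around the index SNP and the haplotype-span counts.

The index SNP is chosen from the discovery scan: among the significant
region SNPs (an LD block typically carries several correlated top hits), the
founder-haplotype representative is the one with the longest |D'| = 1 span
in the stage IV group.  Because that choice looks at discovery span lengths,
the discovery-cohort permutation test downstream is descriptive; the
validation cohort supplies the selection-free test.  For each cohort and stage group the driver then
estimates two-locus haplotype frequencies by EM between that index and every
other region SNP, writes the D' profile (the data behind a founder-haplotype
LD plot) and the span counts under results/ld/, and records the chosen index
for the permutation-test driver.
"""

import argparse
from pathlib import Path

import pandas as pd

from founderscan.io import attach_covariates, read_covariates, read_vcf
from founderscan.ld import region_columns, span_count
from founderscan.qc import filter_samples, filter_variants

REGION = ("1", 1, 5000 * 41)


def _choose_index(assoc: pd.DataFrame, ds) -> str:
    """Founder-haplotype representative: longest stage IV span among the
    near-tied most significant region SNPs."""
    region_ids = {ds.variants[j].variant_id for j in region_columns(ds, REGION)}
    assoc = assoc[assoc["SNP"].isin(region_ids)].dropna(subset=["P-value"])
    p_best = assoc["P-value"].min()
    cut = max(0.005, 10 * p_best)
    candidates = assoc[assoc["P-value"] <= cut].nsmallest(8, "P-value")
    mask = ds.stage_mask(["IV"])
    best_id, best_key = None, None
    for _, row in candidates.iterrows():
        vid = str(row["SNP"])
        try:
            span = span_count(ds, vid, REGION, mask).count
        except ValueError:
            continue
        key = (-span, row["P-value"])
        if best_key is None or key < best_key:
            best_id, best_key = vid, key
    if best_id is None:
        raise SystemExit("no usable index SNP in the candidate region")
    return best_id


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohorts", nargs="+", default=["discovery", "validation1"])
    ap.add_argument("--out-root", type=Path, default=Path("results"))
    args = ap.parse_args()

    out = args.out_root / "ld"
    out.mkdir(parents=True, exist_ok=True)
    assoc_path = args.out_root / "assoc" / "discovery.assoc.tsv"
    if not assoc_path.exists():
        raise SystemExit(f"{assoc_path} not found - run analysis/03_assoc_scan.py first")
    index_id = None
    for cohort in args.cohorts:
        data = args.out_root / "data"
        ds = read_vcf(data / f"{cohort}.vcf")
        attach_covariates(ds, read_covariates(data / f"{cohort}.covar.tsv"))
        ds, _ = filter_samples(ds)
        ds, _ = filter_variants(ds)
        if index_id is None:  # choose once, on the discovery cohort
            index_id = _choose_index(pd.read_csv(assoc_path, sep="\t"), ds)
            (out / "index_snp.txt").write_text(index_id + "\n")
        rows = []
        counts = {}
        for label, stages in (("IV", ["IV"]), ("I/II", ["I", "II"])):
            sc = span_count(ds, index_id, REGION, ds.stage_mask(stages))
            counts[label] = sc.count
            for vid, dp in sc.d_prime_by_snp.items():
                rows.append({"group": label, "snp": vid, "abs_d_prime": dp})
        pd.DataFrame(rows).to_csv(out / f"{cohort}.d_prime.tsv", sep="\t", index=False)
        print(
            f"{cohort}: |D'|=1 span around {index_id}: "
            f"{counts['IV']} SNPs in stage IV vs {counts['I/II']} in stage I/II"
        )


if __name__ == "__main__":
    main()
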