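#!/usr/bin/env python
"""Quality control of the simulated discovery cohort.

Applies the standard marker filters (MAF >= 0.01, missingness <= 2%, exact
HWE in the stage I/II reference group) and the 98% sample call-rate filter,
then derives two cmdscale stratification axes from allele-sharing distances
over the SNPs outside the candidate LD region.  Writes the filtered variant
list, a QC summary and the component table under results/qc/.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from founderscan.io import attach_covariates, read_covariates, read_vcf
from founderscan.qc import filter_samples, filter_variants, mds_components

REGION_END_BP = 5000 * 41  # candidate LD region of the simulated panel


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", default="discovery")
    ap.add_argument("--out-root", type=Path, default=Path("results"))
    args = ap.parse_args()

    data = args.out_root / "data"
    vcf = data / f"{args.cohort}.vcf"
    if not vcf.exists():
        raise SystemExit(f"{vcf} not found - run analysis/01_simulate.py first")
    ds = read_vcf(vcf)
    attach_covariates(ds, read_covariates(data / f"{args.cohort}.covar.tsv"))

    ds, sample_report = filter_samples(ds, call_rate_min=0.98)
    ds, variant_report = filter_variants(ds, maf_min=0.01, miss_max=0.02, hwe_alpha=1e-6)
    background = [j for j, v in enumerate(ds.variants) if v.pos > REGION_END_BP]
    comp = mds_components(ds.subset(variant_idx=background), k=2)

    out = args.out_root / "qc"
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {
            "variant_id": list(variant_report.variant_maf),
            "maf": list(variant_report.variant_maf.values()),
            "missing_rate": list(variant_report.variant_missing.values()),
            "hwe_p": list(variant_report.variant_hwe_p.values()),
        }
    ).to_csv(out / f"{args.cohort}.variant_qc.tsv", sep="\t", index=False)
    pd.DataFrame(
        {"sample_id": ds.sample_ids, "PC1": comp.components[:, 0], "PC2": comp.components[:, 1]}
    ).to_csv(out / f"{args.cohort}.components.tsv", sep="\t", index=False)
    summary = {
        "cohort": args.cohort,
        "samples_kept": ds.n_samples,
        "samples_removed": len(sample_report.removed_samples),
        "variants_kept": ds.n_variants,
        "variants_removed": [
            {"variant_id": vid, "reason": why} for vid, why in variant_report.removed_variants
        ],
        "mds_eigenvalues": comp.eigenvalues.tolist(),
    }
    (out / f"{args.cohort}.qc_summary.json").write_text(json.dumps(summary, indent=2))
    print(
        f"{args.cohort}: kept {ds.n_samples} samples "
        f"({len(sample_report.removed_samples)} failed call rate) and "
        f"{ds.n_variants} variants "
        f"({len(variant_report.removed_variants)} removed); "
        f"2 stratification axes from {len(background)} off-region SNPs"
    )


if __name__ == "__main__":
    main()
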