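#!/usr/bin/env python
"""Covariate-adjusted log-additive association scan, stage IV vs stage I/II.

Fits one trend-model logistic regression per QC-passing SNP, adjusted for
age, sex and the two stratification axes, and writes the association table
(OR, 95% CI, Wald p per SNP), per-group genotype summaries for the top SNP,
and Q-Q plot data under results/assoc/.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from founderscan.association import build_design, genome_scan, qq_data
from founderscan.io import attach_covariates, read_covariates, read_vcf, write_results_table
from founderscan.qc import filter_samples, filter_variants


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", default="discovery")
    ap.add_argument("--out-root", type=Path, default=Path("results"))
    args = ap.parse_args()

    data = args.out_root / "data"
    ds = read_vcf(data / f"{args.cohort}.vcf")
    attach_covariates(ds, read_covariates(data / f"{args.cohort}.covar.tsv"))
    ds, _ = filter_samples(ds)
    ds, _ = filter_variants(ds)

    comp_path = args.out_root / "qc" / f"{args.cohort}.components.tsv"
    if not comp_path.exists():
        raise SystemExit(f"{comp_path} not found - run analysis/02_qc.py first")
    comp = pd.read_csv(comp_path, sep="\t").set_index("sample_id")
    comp = comp.loc[ds.sample_ids, ["PC1", "PC2"]].to_numpy()
    covars = build_design(ds, ["age", "sex", "PC1", "PC2"], components=comp)

    results, summaries = genome_scan(ds, covariates=covars)
    out = args.out_root / "assoc"
    out.mkdir(parents=True, exist_ok=True)
    ordered = sorted(results, key=lambda r: (np.isnan(r.p), r.p))
    write_results_table(ordered, out / f"{args.cohort}.assoc.tsv")

    ps = [r.p for r in results if r.converged]
    pd.DataFrame(qq_data(ps), columns=["expected_neglog10_p", "observed_neglog10_p"]).to_csv(
        out / f"{args.cohort}.qq.tsv", sep="\t", index=False
    )
    top = ordered[0]
    rows = [
        {"group": g.group, "n_AA": g.n_AA, "n_Aa": g.n_Aa, "n_aa": g.n_aa, "maf": g.maf}
        for g in summaries[top.variant_id].values()
    ]
    pd.DataFrame(rows).to_csv(out / f"{args.cohort}.top_snp_genotypes.tsv", sep="\t", index=False)
    print(
        f"{args.cohort}: scanned {len(results)} SNPs; top hit {top.variant_id} "
        f"OR {top.or_:.2f} ({top.ci_lo:.2f}, {top.ci_hi:.2f}), p {top.p:.2e}"
    )


if __name__ == "__main__":
    main()
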