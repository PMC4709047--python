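#!/usr/bin/env python
"""Permutation test: is the D' = 1 span longer in stage IV than stage I/II?

Re-partitions the case labels into pseudo-groups of the original sizes,
estimates the per-group-size count variances V1 and V2 from the permutation
distribution, and reports the combined SD = sqrt(V1 + V2), the normal
one-sided p for the observed difference, and the empirical permutation tail
p.  Writes one summary row per cohort under results/spantest/.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from founderscan.io import attach_covariates, read_covariates, read_vcf
from founderscan.qc import filter_samples, filter_variants
from founderscan.spantest import permutation_span_test, span_report

REGION = ("1", 1, 5000 * 41)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohorts", nargs="+", default=["discovery", "validation1"])
    ap.add_argument("--n-perm", type=int, default=10_000)
    ap.add_argument("--seed", type=int, default=2016)
    ap.add_argument("--out-root", type=Path, default=Path("results"))
    args = ap.parse_args()

    index_path = args.out_root / "ld" / "index_snp.txt"
    if not index_path.exists():
        raise SystemExit(f"{index_path} not found - run analysis/05_ld_span.py first")
    index_id = index_path.read_text().strip()

    out = args.out_root / "spantest"
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for k, cohort in enumerate(args.cohorts):
        data = args.out_root / "data"
        ds = read_vcf(data / f"{cohort}.vcf")
        attach_covariates(ds, read_covariates(data / f"{cohort}.covar.tsv"))
        ds, _ = filter_samples(ds)
        ds, _ = filter_variants(ds)
        cases = ds.stage_mask(["IV", "I", "II"])
        ds = ds.subset(sample_idx=cases)
        labels = np.array([s.stage == "IV" for s in ds.samples])
        res = permutation_span_test(
            ds, index_id, REGION, labels, n_perm=args.n_perm, seed=args.seed + k
        )
        row = span_report(res)
        row.insert(0, "cohort", cohort)
        rows.append(row)
        print(
            f"{cohort}: span {res.count_iv} (stage IV) vs {res.count_i_ii} (stage I/II), "
            f"difference {res.diff} +/- {res.sd_diff:.2f}, "
            f"one-sided normal p {res.p_one_sided:.2e}, empirical p {res.p_empirical:.2e}"
        )
    pd.concat(rows, ignore_index=True).to_csv(out / "span_test.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
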