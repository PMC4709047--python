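#!/usr/bin/env python
"""Meta-analysis of the index-SNP odds ratio across the three cohorts.

Pools (i) the three published per-study estimates and (ii) the index-SNP
estimates measured in the three simulated cohorts, under inverse-variance
fixed effects and DerSimonian-Laird random effects, with Cochran's Q and the
METAL-style sample-size-weighted z alongside.  Writes forest-plot data and a
summary JSON under results/meta/.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from founderscan.association import genome_scan
from founderscan.io import attach_covariates, read_covariates, read_vcf
from founderscan.meta import (
    StudyEstimate,
    forest_data,
    meta_analysis,
    sample_size_weighted_z,
)
from founderscan.qc import filter_samples, filter_variants

PUBLISHED = [
    StudyEstimate("discovery", 2.83, 1.81, 4.44, n=323, p=2.73e-6),
    StudyEstimate("validation1", 1.89, 1.27, 2.80, n=462, p=8.05e-4),
    StudyEstimate("validation2", 1.31, 0.81, 2.12, n=343, p=0.235),
]


def _summary(estimates) -> dict:
    m = meta_analysis(estimates)
    out = {
        "fixed": {"or": m.fixed.pooled_or, "ci": [m.fixed.ci_lo, m.fixed.ci_hi],
                  "p": m.fixed.p},
        "random": {"or": m.random.pooled_or, "ci": [m.random.ci_lo, m.random.ci_hi],
                   "p": m.random.p},
        "q": m.q, "df": m.df, "q_p": m.q_p, "tau2": m.tau2,
        "forest": forest_data(estimates, m),
    }
    if all(e.p is not None for e in estimates):
        z, p = sample_size_weighted_z(
            [e.p for e in estimates], [e.direction for e in estimates],
            [e.n for e in estimates],
        )
        out["sample_size_weighted"] = {"z": z, "p": p}
    return out


def _simulated_estimates(out_root: Path) -> list[StudyEstimate]:
    index_id = str(
        pd.read_csv(out_root / "assoc" / "discovery.assoc.tsv", sep="\t").loc[0, "SNP"]
    )
    estimates = []
    for cohort in ("discovery", "validation1", "validation2"):
        ds = read_vcf(out_root / "data" / f"{cohort}.vcf")
        attach_covariates(ds, read_covariates(out_root / "data" / f"{cohort}.covar.tsv"))
        ds, _ = filter_samples(ds)
        ds, _ = filter_variants(ds)
        results, _ = genome_scan(ds)
        r = next(x for x in results if x.variant_id == index_id)
        if r.converged:
            estimates.append(
                StudyEstimate(cohort, r.or_, r.ci_lo, r.ci_hi, n=r.n_used, p=r.p)
            )
    return estimates


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out-root", type=Path, default=Path("results"))
    args = ap.parse_args()

    out = args.out_root / "meta"
    out.mkdir(parents=True, exist_ok=True)
    payload = {"published_inputs": _summary(PUBLISHED)}
    try:
        sim = _simulated_estimates(args.out_root)
        if len(sim) >= 2:
            payload["simulated_cohorts"] = _summary(sim)
    except FileNotFoundError:
        print("simulated cohorts not found - run scripts 01-03 first; "
              "pooling published inputs only")
    (out / "meta.json").write_text(json.dumps(payload, indent=2))

    pub = payload["published_inputs"]
    print(
        "published inputs: fixed OR {:.2f} ({:.2f}, {:.2f}), random OR {:.2f} "
        "({:.2f}, {:.2f}), Q {:.2f} (df {}, p {:.3f})".format(
            pub["fixed"]["or"], *pub["fixed"]["ci"], pub["random"]["or"],
            *pub["random"]["ci"], pub["q"], pub["df"], pub["q_p"],
        )
    )
    if "simulated_cohorts" in payload:
        sim = payload["simulated_cohorts"]
        print(
            "simulated cohorts: fixed OR {:.2f} ({:.2f}, {:.2f}), "
            "random OR {:.2f} ({:.2f}, {:.2f})".format(
                sim["fixed"]["or"], *sim["fixed"]["ci"],
                sim["random"]["or"], *sim["random"]["ci"],
            )
        )


if __name__ == "__main__":
    main()
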