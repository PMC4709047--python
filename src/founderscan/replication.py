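"""Power-guided selection of SNPs for the validation (replication) stage.

Discovery effect sizes are inflated by the winner's curse, so replication
power is computed from a shrunken odds ratio: the lower bound of a 50%
confidence interval (the estimate minus 0.6745 log-scale standard errors).
SNPs with adequate shrunken-OR power are placed in two Bonferroni-budgeted
tiers — up to 9 SNPs sharing a 0.04 budget and up to 8 more sharing 0.01, for
an overall type-I error of 0.05 — and SNPs in complete LD (D' = 1) with a
tier-1 member ride along as unadjusted companions.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy import stats

Z95 = 1.96
Z50 = 0.6745  # 75th-percentile standard-normal quantile: lower bound of a 50% CI


@dataclass
class PowerInput:
    or_hat: float
    ci_lo: float
    ci_hi: float
    maf: float  # reference-group minor-allele frequency
    n_cases: int
    n_controls: int
    alpha: float

    def __post_init__(self) -> None:
        if not 0 < self.ci_lo <= self.or_hat <= self.ci_hi:
            raise ValueError("need 0 < ci_lo <= or_hat <= ci_hi")
        if not 0 < self.maf <= 0.5:
            raise ValueError("maf must be in (0, 0.5]")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if min(self.n_cases, self.n_controls) <= 0:
            raise ValueError("group sizes must be positive")


def shrunken_or(or_hat: float, ci_lo: float, ci_hi: float) -> float:
    """Winner's-curse-shrunken OR: lower bound of the 50% CI.

    The log-scale SE is reconstructed from the 95% CI, and the estimate is
    shrunk by 0.6745 SEs (the 50%-CI half-width in SE units).
    """
    if ci_lo > ci_hi:
        raise ValueError("ci_lo must not exceed ci_hi")
    if ci_lo <= 0 or or_hat <= 0:
        raise ValueError("odds ratios must be positive")
    se = (math.log(ci_hi) - math.log(ci_lo)) / (2 * Z95)
    return math.exp(math.log(or_hat) - Z50 * se)


def expected_allele_freq_cases(maf: float, or_: float) -> float:
    """Case-group allele frequency implied by the reference MAF and allelic OR."""
    odds = or_ * maf / (1 - maf)
    return odds / (1 + odds)


@dataclass
class PowerResult:
    power: float
    shrunken_or: float
    unreliable: bool = False  # an expected allele-table cell fell below 1


def _allelic_test_power_exact(
    p_case: float, p_ref: float, n_cases: int, n_controls: int, alpha: float
) -> float:
    """Exact power of the two-sided allelic (Woolf) z-test.

    The two allele counts are independent binomials, so the rejection
    probability is a finite double sum over their joint pmf; empty cells get
    the conventional 0.5 substitution inside the test statistic.
    """
    na, nc = 2 * n_cases, 2 * n_controls
    a = np.arange(na + 1, dtype=float)
    c = np.arange(nc + 1, dtype=float)
    b = na - a
    d = nc - c
    a_, b_ = np.where(a == 0, 0.5, a), np.where(b == 0, 0.5, b)
    c_, d_ = np.where(c == 0, 0.5, c), np.where(d == 0, 0.5, d)
    ln_or = (np.log(a_) - np.log(b_))[:, None] + (np.log(d_) - np.log(c_))[None, :]
    var = (1 / a_ + 1 / b_)[:, None] + (1 / c_ + 1 / d_)[None, :]
    z = np.abs(ln_or) / np.sqrt(var)
    reject = z > stats.norm.isf(alpha / 2)
    pmf = np.outer(
        stats.binom.pmf(a, na, p_case), stats.binom.pmf(c, nc, p_ref)
    )
    return float(pmf[reject].sum())


def replication_power(inp: PowerInput, method: str = "exact") -> PowerResult:
    """Power of the two-sided allelic (2x2 allele-table) test at ``alpha``.

    The discovery OR is first shrunk to its 50% lower confidence limit, and
    the expected allele frequencies of the two groups follow from the
    reference MAF and the shrunken OR.  ``method="exact"`` (default) sums the
    rejection region of the Woolf z-test over the joint binomial allele-count
    distribution; ``method="normal"`` uses the classical approximation
    power = Phi(|lnOR*|/SE* − z_crit) + Phi(−|lnOR*|/SE* − z_crit) with
    SE*^2 the sum of reciprocal expected cell counts, which overstates power
    by a few percent for strong effects at low MAF.
    """
    or_star = shrunken_or(inp.or_hat, inp.ci_lo, inp.ci_hi)
    p_ref = inp.maf
    p_case = expected_allele_freq_cases(p_ref, or_star)
    cells = np.array(
        [
            2 * inp.n_cases * p_case,
            2 * inp.n_cases * (1 - p_case),
            2 * inp.n_controls * p_ref,
            2 * inp.n_controls * (1 - p_ref),
        ]
    )
    unreliable = bool((cells < 1).any())
    if method == "exact":
        power = _allelic_test_power_exact(
            p_case, p_ref, inp.n_cases, inp.n_controls, inp.alpha
        )
    elif method == "normal":
        se_star = float(np.sqrt((1.0 / cells).sum()))
        ln_or_star = abs(math.log(or_star))
        z_crit = stats.norm.isf(inp.alpha / 2)
        power = float(
            stats.norm.cdf(ln_or_star / se_star - z_crit)
            + stats.norm.cdf(-ln_or_star / se_star - z_crit)
        )
    else:
        raise ValueError(f"unknown power method {method!r}")
    return PowerResult(power=power, shrunken_or=or_star, unreliable=unreliable)


@dataclass
class ReplicationPlan:
    tier1: list[str]
    tier2: list[str]
    a1: float  # per-test alpha, tier 1
    a2: float  # per-test alpha, tier 2
    companions: list[tuple[str, str]] = field(default_factory=list)  # (companion, partner)
    overall_alpha: float = 0.05
    power_by_snp: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        spent = len(self.tier1) * self.a1 + len(self.tier2) * self.a2
        if spent > self.overall_alpha + 1e-12:
            raise ValueError("tier budgets exceed the overall alpha")
        if set(self.tier1) & set(self.tier2):
            raise ValueError("tiers must be disjoint")

    @property
    def all_snps(self) -> list[str]:
        return self.tier1 + self.tier2 + [c for c, _ in self.companions]

    def tier_alpha(self, snp_id: str) -> float:
        if snp_id in self.tier1:
            return self.a1
        if snp_id in self.tier2:
            return self.a2
        for comp, partner in self.companions:
            if comp == snp_id:
                return self.tier_alpha(partner)  # for reporting only
        raise KeyError(snp_id)

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "tier1": self.tier1,
                    "tier2": self.tier2,
                    "a1": self.a1,
                    "a2": self.a2,
                    "companions": self.companions,
                    "overall_alpha": self.overall_alpha,
                    "power_by_snp": self.power_by_snp,
                },
                indent=2,
            )
        )


def build_plan(
    scan_results: Sequence,
    n_cases: int,
    n_controls: int,
    ld_pairs: Optional[Sequence[tuple[str, str, float]]] = None,
    tier1_size: int = 9,
    tier1_budget: float = 0.04,
    tier2_size: int = 8,
    tier2_budget: float = 0.01,
    power_floor: float = 0.80,
    d_prime_tol: float = 1e-6,
) -> ReplicationPlan:
    """Pick the replication SNP set from discovery scan results.

    ``scan_results`` are AssociationResult-like rows (variant_id, or_, ci_lo,
    ci_hi, p, maf) sorted or sortable by p.  The most significant SNPs whose
    shrunken-OR replication power reaches ``power_floor`` fill tier 1 (per-test
    alpha = tier1_budget / |tier1|), the next fill tier 2, and companions at
    D' = 1 with any tier-1 member are appended with no statistical adjustment.
    Ties in p are broken by higher power, then variant id.
    """
    rows = [r for r in scan_results if getattr(r, "converged", True) and np.isfinite(r.p)]
    if not rows:
        raise ValueError("empty scan results")

    a1_alpha = tier1_budget / tier1_size
    scored = []
    for r in rows:
        maf = r.maf if r.maf and r.maf > 0 else None
        if maf is None:
            continue
        pw = replication_power(
            PowerInput(
                or_hat=max(r.or_, 1.0 / r.or_),
                ci_lo=min(max(r.ci_lo, 1e-9), r.or_) if r.or_ >= 1 else min(1 / r.ci_hi, 1 / r.or_),
                ci_hi=max(r.ci_hi, r.or_) if r.or_ >= 1 else max(1 / r.ci_lo, 1 / r.or_),
                maf=min(maf, 0.5),
                n_cases=n_cases,
                n_controls=n_controls,
                alpha=a1_alpha,
            )
        )
        scored.append((r, pw))
    scored.sort(key=lambda rp: (rp[0].p, -rp[1].power, rp[0].variant_id))

    qualifying = [(r, pw) for r, pw in scored if pw.power >= power_floor]
    tier1 = [r.variant_id for r, _ in qualifying[:tier1_size]]
    tier2 = [r.variant_id for r, _ in qualifying[tier1_size : tier1_size + tier2_size]]
    companions: list[tuple[str, str]] = []
    if ld_pairs:
        chosen = set(tier1) | set(tier2)
        for snp_a, snp_b, dp in ld_pairs:
            if abs(abs(dp) - 1.0) > d_prime_tol:
                continue
            if snp_b in tier1 and snp_a not in chosen:
                companions.append((snp_a, snp_b))
                chosen.add(snp_a)
            elif snp_a in tier1 and snp_b not in chosen:
                companions.append((snp_b, snp_a))
                chosen.add(snp_b)
    return ReplicationPlan(
        tier1=tier1,
        tier2=tier2,
        a1=tier1_budget / len(tier1) if tier1 else 0.0,
        a2=tier2_budget / len(tier2) if tier2 else 0.0,
        companions=companions,
        overall_alpha=tier1_budget + tier2_budget,
        power_by_snp={r.variant_id: pw.power for r, pw in scored},
    )


@dataclass
class ReplicationVerdict:
    variant_id: str
    tier_alpha: float
    validation_p: Optional[float]
    direction_match: Optional[bool]
    replicated: bool
    note: str = ""


def evaluate_replication(
    plan: ReplicationPlan,
    validation_results: dict[str, tuple[float, float]],
    discovery_directions: dict[str, float],
) -> list[ReplicationVerdict]:
    """Per-SNP verdicts against the pre-specified tier thresholds.

    ``validation_results`` maps variant id to (two-sided p, lnOR direction
    sign); a missing entry records a genotyping failure.  A SNP replicates
    iff its validation p is strictly below its tier alpha AND the effect
    direction matches discovery.  Companions inherit their partner's alpha
    for reporting only.
    """
    verdicts = []
    for snp in plan.all_snps:
        alpha = plan.tier_alpha(snp)
        if snp not in validation_results:
            verdicts.append(
                ReplicationVerdict(snp, alpha, None, None, False, "genotyping failure (NA)")
            )
            continue
        p, direction = validation_results[snp]
        same = np.sign(direction) == np.sign(discovery_directions[snp])
        verdicts.append(
            ReplicationVerdict(
                variant_id=snp,
                tier_alpha=alpha,
                validation_p=p,
                direction_match=bool(same),
                replicated=bool(p < alpha and same),
                note="" if snp not in [c for c, _ in plan.companions] else "companion",
            )
        )
    return verdicts


__all__ = [
    "PowerInput",
    "PowerResult",
    "ReplicationPlan",
    "ReplicationVerdict",
    "build_plan",
    "evaluate_replication",
    "expected_allele_freq_cases",
    "replication_power",
    "shrunken_or",
]
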