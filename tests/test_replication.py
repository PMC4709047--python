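"""Winner's-curse shrinkage, replication power vs Monte-Carlo, plan budgeting."""

import math
from dataclasses import dataclass

import numpy as np
import pytest
from scipy import stats

from founderscan.replication import (
    PowerInput,
    ReplicationPlan,
    build_plan,
    evaluate_replication,
    expected_allele_freq_cases,
    replication_power,
    shrunken_or,
)


class TestShrunkenOr:
    def test_degenerate_ci_returns_estimate(self):
        assert shrunken_or(2.0, 2.0, 2.0) == pytest.approx(2.0)

    def test_discovery_top_snp_arithmetic(self):
        # OR 2.83, CI (1.81, 4.44): SE = ln(4.44/1.81)/3.92 = 0.2289,
        # shrunken OR = exp(ln 2.83 - 0.6745 * 0.2289) = 2.42
        se = (math.log(4.44) - math.log(1.81)) / 3.92
        assert se == pytest.approx(0.2289, abs=2e-4)
        assert shrunken_or(2.83, 1.81, 4.44) == pytest.approx(2.425, abs=0.005)

    def test_shrinks_downward(self):
        assert shrunken_or(1.0, 0.5, 2.0) < 1.0

    def test_never_exceeds_estimate(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            or_hat = rng.uniform(1.0, 5.0)
            se = rng.uniform(0.0, 1.0)
            lo, hi = or_hat * math.exp(-1.96 * se), or_hat * math.exp(1.96 * se)
            assert shrunken_or(or_hat, lo, hi) <= or_hat + 1e-12

    def test_invalid_ci_rejected(self):
        with pytest.raises(ValueError):
            shrunken_or(2.0, 3.0, 1.5)


def power_monte_carlo(or_, maf, n_cases, n_controls, alpha, n_sim, rng):
    """Oracle: rejection rate of the two-sided allelic z-test over simulated
    2x2 allele tables (0.5 added to empty cells)."""
    p_case = expected_allele_freq_cases(maf, or_)
    a = rng.binomial(2 * n_cases, p_case, size=n_sim).astype(float)
    c = rng.binomial(2 * n_controls, maf, size=n_sim).astype(float)
    b = 2 * n_cases - a
    d = 2 * n_controls - c
    for arr in (a, b, c, d):
        arr[arr == 0] = 0.5
    ln_or = np.log(a * d / (b * c))
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z_crit = stats.norm.isf(alpha / 2)
    return float((np.abs(ln_or / se) > z_crit).mean())


class TestReplicationPower:
    def _input(self, or_, maf, n_cases=89, n_controls=373, alpha=0.0044):
        # degenerate CI: no shrinkage, so power is evaluated at or_ itself
        return PowerInput(or_hat=or_, ci_lo=or_, ci_hi=or_, maf=maf,
                          n_cases=n_cases, n_controls=n_controls, alpha=alpha)

    def test_null_or_power_equals_alpha(self):
        # the normal approximation returns exactly the level at OR = 1
        res = replication_power(self._input(1.0, 0.2, alpha=0.05), method="normal")
        assert res.power == pytest.approx(0.05, abs=1e-6)
        # the exact enumeration returns the test's true (discrete) size
        size = replication_power(self._input(1.0, 0.2, alpha=0.05)).power
        assert size == pytest.approx(0.05, abs=0.01)

    def test_monotone_in_n_and_effect(self):
        grid_or = [1.3, 1.8, 2.5]
        for maf in (0.1, 0.3):
            powers = [replication_power(self._input(o, maf)).power for o in grid_or]
            assert powers == sorted(powers)
        for o in grid_or:
            p_small = replication_power(self._input(o, 0.2, n_cases=50)).power
            p_large = replication_power(self._input(o, 0.2, n_cases=200)).power
            assert p_small <= p_large

    @pytest.mark.parametrize("or_,maf,n_cases,n_controls",
                             [(2.0, 0.2, 89, 373), (1.5, 0.3, 200, 200),
                              (2.5, 0.1, 89, 373)])
    def test_matches_monte_carlo(self, or_, maf, n_cases, n_controls, rng):
        alpha = 0.0044
        analytic = replication_power(
            self._input(or_, maf, n_cases, n_controls, alpha)).power
        mc = power_monte_carlo(or_, maf, n_cases, n_controls, alpha, 20_000, rng)
        assert analytic == pytest.approx(mc, abs=0.02)

    def test_small_cell_flagged(self):
        res = replication_power(self._input(1.2, 0.01, n_cases=10, n_controls=10))
        assert res.unreliable

    def test_shrinkage_applied_inside(self):
        wide = PowerInput(or_hat=2.0, ci_lo=1.1, ci_hi=3.6, maf=0.2,
                          n_cases=89, n_controls=373, alpha=0.0044)
        narrow = self._input(2.0, 0.2)
        assert replication_power(wide).power < replication_power(narrow).power


@dataclass
class Row:
    variant_id: str
    or_: float
    ci_lo: float
    ci_hi: float
    p: float
    maf: float
    converged: bool = True


def _scan_rows(n, start_p=1e-6):
    rows = []
    for i in range(n):
        p = start_p * (i + 1)
        rows.append(Row(f"rs{i:03d}", 2.5, 1.7, 3.7, p, 0.2))
    return rows


class TestBuildPlan:
    def test_published_budget_shape(self):
        # 9 + 8 qualifying SNPs plus 3 companions -> 20 SNPs, alphas 0.04/9, 0.01/8
        rows = _scan_rows(17)
        ld_pairs = [(f"c{i}", f"rs00{i}", 1.0) for i in range(3)]
        plan = build_plan(rows, n_cases=89, n_controls=373, ld_pairs=ld_pairs)
        assert len(plan.tier1) == 9 and len(plan.tier2) == 8
        assert len(plan.companions) == 3
        assert len(plan.all_snps) == 20
        assert plan.a1 == pytest.approx(0.04 / 9)
        assert plan.a2 == pytest.approx(0.01 / 8)
        assert 9 * plan.a1 + 8 * plan.a2 == pytest.approx(0.05)

    def test_underfull_tiers(self):
        plan = build_plan(_scan_rows(5), n_cases=89, n_controls=373)
        assert len(plan.tier1) == 5 and plan.tier2 == []
        assert plan.a1 == pytest.approx(0.04 / 5)
        assert plan.overall_alpha == pytest.approx(0.05)

    def test_companions_require_complete_ld_with_tier1(self):
        rows = _scan_rows(12)
        ld_pairs = [("cA", "rs000", 0.97), ("cB", "rs001", 1.0),
                    ("cC", "rs011", 1.0)]  # rs011 lands in tier 2
        plan = build_plan(rows, n_cases=89, n_controls=373, ld_pairs=ld_pairs)
        assert plan.companions == [("cB", "rs001")]

    def test_power_floor_excludes_weak_snps(self):
        rows = _scan_rows(12)
        rows[0] = Row("rs_weak", 1.05, 0.7, 1.6, 1e-7, 0.2)  # tiny shrunken effect
        plan = build_plan(rows, n_cases=89, n_controls=373)
        assert "rs_weak" not in plan.tier1 + plan.tier2

    def test_alpha_accounting_invariant(self):
        for n in (3, 9, 12, 17):
            plan = build_plan(_scan_rows(n), n_cases=89, n_controls=373)
            spent = len(plan.tier1) * plan.a1 + len(plan.tier2) * plan.a2
            assert spent <= 0.05 + 1e-12

    def test_empty_scan_rejected(self):
        with pytest.raises(ValueError):
            build_plan([], n_cases=89, n_controls=373)


class TestEvaluateReplication:
    def _plan(self):
        return ReplicationPlan(tier1=["rs_top", "rs_flip"], tier2=["rs_weak"],
                               a1=0.0044, a2=0.00125,
                               companions=[("rs_comp", "rs_top")])

    def test_published_verdicts(self):
        # validation p = 8.05e-4 with matching direction replicates at 0.0044;
        # a direction-reversed SNP at p = 0.215 does not
        plan = self._plan()
        verdicts = evaluate_replication(
            plan,
            validation_results={
                "rs_top": (8.05e-4, +1), "rs_flip": (0.215, -1),
                "rs_weak": (0.5, +1), "rs_comp": (9.12e-4, +1),
            },
            discovery_directions={"rs_top": +1, "rs_flip": +1,
                                  "rs_weak": +1, "rs_comp": +1},
        )
        by_id = {v.variant_id: v for v in verdicts}
        assert by_id["rs_top"].replicated
        assert not by_id["rs_flip"].replicated  # direction gate
        assert not by_id["rs_weak"].replicated
        assert by_id["rs_comp"].replicated and by_id["rs_comp"].tier_alpha == 0.0044

    def test_boundary_p_not_replicated(self):
        plan = self._plan()
        verdicts = evaluate_replication(
            plan, {"rs_top": (0.0044, +1), "rs_flip": (1.0, +1), "rs_weak": (1.0, +1),
                   "rs_comp": (1.0, +1)},
            {"rs_top": +1, "rs_flip": +1, "rs_weak": +1, "rs_comp": +1})
        assert not {v.variant_id: v for v in verdicts}["rs_top"].replicated

    def test_genotyping_failure_recorded(self):
        plan = self._plan()
        verdicts = evaluate_replication(
            plan, {"rs_flip": (1.0, +1), "rs_weak": (1.0, +1), "rs_comp": (1.0, +1)},
            {"rs_top": +1, "rs_flip": +1, "rs_weak": +1, "rs_comp": +1})
        v = {x.variant_id: x for x in verdicts}["rs_top"]
        assert not v.replicated and "failure" in v.note
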