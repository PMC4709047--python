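"""Pooling per-study odds ratios: fixed effects, DerSimonian-Laird random
effects, Cochran's Q homogeneity test, and METAL-style sample-size-weighted z.

Published studies usually report only OR and 95% CI, so the log-scale
standard error is reconstructed as (ln ci_hi − ln ci_lo) / (2 * 1.96).
Inverse-variance pooling and the sample-size-weighted z combination are both
provided; where a report conflates them, the discrepancy can be inspected
directly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

Z95 = 1.96


def se_from_ci(or_: float, ci_lo: float, ci_hi: float) -> float:
    """Log-scale SE reconstructed from a 95% CI."""
    if ci_lo >= ci_hi:
        if ci_lo == ci_hi == or_:
            return 0.0
        raise ValueError("ci_lo must be below ci_hi")
    if not 0 < ci_lo <= or_ <= ci_hi:
        raise ValueError("need 0 < ci_lo <= or_ <= ci_hi")
    return (math.log(ci_hi) - math.log(ci_lo)) / (2 * Z95)


@dataclass
class StudyEstimate:
    study_id: str
    or_: float
    ci_lo: float
    ci_hi: float
    n: int = 0
    p: Optional[float] = None

    @property
    def ln_or(self) -> float:
        return math.log(self.or_)

    @property
    def se(self) -> float:
        return se_from_ci(self.or_, self.ci_lo, self.ci_hi)

    @property
    def direction(self) -> float:
        return math.copysign(1.0, self.ln_or) if self.ln_or != 0 else 0.0


@dataclass
class ModelResult:
    pooled_ln_or: float
    pooled_se: float
    pooled_or: float
    ci_lo: float
    ci_hi: float
    z: float
    p: float
    weights: dict[str, float] = field(default_factory=dict)  # normalised


@dataclass
class MetaResult:
    fixed: ModelResult
    random: ModelResult
    q: float
    df: int
    q_p: float
    tau2: float


def _pool(estimates: Sequence[StudyEstimate], variances: np.ndarray) -> ModelResult:
    ln_or = np.array([e.ln_or for e in estimates])
    w = 1.0 / variances
    pooled = float((w * ln_or).sum() / w.sum())
    se = float(1.0 / math.sqrt(w.sum()))
    z = pooled / se if se > 0 else math.inf
    wn = w / w.sum()
    return ModelResult(
        pooled_ln_or=pooled,
        pooled_se=se,
        pooled_or=math.exp(pooled),
        ci_lo=math.exp(pooled - Z95 * se),
        ci_hi=math.exp(pooled + Z95 * se),
        z=float(z),
        p=float(2 * stats.norm.sf(abs(z))),
        weights={e.study_id: float(x) for e, x in zip(estimates, wn)},
    )


def fixed_effects(estimates: Sequence[StudyEstimate]) -> ModelResult:
    """Inverse-variance fixed-effects pooling of log odds ratios."""
    if not estimates:
        raise ValueError("no estimates to pool")
    se = np.array([e.se for e in estimates])
    if len(estimates) == 1:
        e = estimates[0]
        z = e.ln_or / e.se if e.se > 0 else math.inf
        return ModelResult(
            pooled_ln_or=e.ln_or, pooled_se=e.se, pooled_or=e.or_,
            ci_lo=math.exp(e.ln_or - Z95 * e.se), ci_hi=math.exp(e.ln_or + Z95 * e.se),
            z=float(z), p=float(2 * stats.norm.sf(abs(z))), weights={e.study_id: 1.0},
        )
    if np.any(se == 0):
        raise ValueError("a study has zero SE: infinite weight with >1 study")
    return _pool(estimates, se**2)


def cochran_q(estimates: Sequence[StudyEstimate]) -> tuple[float, int, float]:
    """Cochran's Q homogeneity statistic, its df, and the chi-square upper-tail p."""
    if len(estimates) < 2:
        raise ValueError("Cochran's Q needs at least 2 studies")
    se = np.array([e.se for e in estimates])
    if np.any(se == 0):
        raise ValueError("a study has zero SE")
    ln_or = np.array([e.ln_or for e in estimates])
    w = 1.0 / se**2
    pooled = (w * ln_or).sum() / w.sum()
    q = float((w * (ln_or - pooled) ** 2).sum())
    df = len(estimates) - 1
    return q, df, float(stats.chi2.sf(q, df))


def dersimonian_laird(estimates: Sequence[StudyEstimate]) -> tuple[ModelResult, float]:
    """DerSimonian-Laird random-effects pooling; returns (result, tau^2).

    tau^2 = max(0, (Q − df) / (Σw − Σw²/Σw)) with fixed-effects weights w;
    when Q ≤ df the result coincides with the fixed-effects model.
    """
    q, df, _ = cochran_q(estimates)
    se = np.array([e.se for e in estimates])
    w = 1.0 / se**2
    denom = w.sum() - (w**2).sum() / w.sum()
    tau2 = max(0.0, (q - df) / denom) if denom > 0 else 0.0
    return _pool(estimates, se**2 + tau2), tau2


def meta_analysis(estimates: Sequence[StudyEstimate]) -> MetaResult:
    """Fixed and random effects plus heterogeneity in one call."""
    fixed = fixed_effects(estimates)
    q, df, q_p = cochran_q(estimates)
    random_, tau2 = dersimonian_laird(estimates)
    return MetaResult(fixed=fixed, random=random_, q=q, df=df, q_p=q_p, tau2=tau2)


def sample_size_weighted_z(
    per_study_p: Sequence[float],
    directions: Sequence[float],
    sample_sizes: Sequence[float],
) -> tuple[float, float]:
    """METAL-style combination: z_i = signed quantile of p_i/2, weights sqrt(n_i).

    Z = Σ sqrt(n_i) z_i / sqrt(Σ n_i); returns (Z, two-sided p).
    """
    p = np.asarray(per_study_p, dtype=float)
    sgn = np.sign(np.asarray(directions, dtype=float))
    n = np.asarray(sample_sizes, dtype=float)
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    if np.any(n <= 0):
        raise ValueError("sample sizes must be positive")
    z_i = sgn * stats.norm.isf(p / 2)
    w = np.sqrt(n)
    z = float((w * z_i).sum() / math.sqrt((w**2).sum()))
    return z, float(2 * stats.norm.sf(abs(z)))


def forest_data(estimates: Sequence[StudyEstimate], result: MetaResult) -> list[dict]:
    """Forest-plot rows: each study's OR/CI plus the two pooled rows."""
    rows = [
        {
            "label": e.study_id,
            "or": e.or_,
            "ci_lo": e.ci_lo,
            "ci_hi": e.ci_hi,
            "weight_fixed": result.fixed.weights.get(e.study_id),
            "weight_random": result.random.weights.get(e.study_id),
        }
        for e in estimates
    ]
    for label, model in (("pooled (fixed)", result.fixed), ("pooled (random)", result.random)):
        rows.append(
            {
                "label": label,
                "or": model.pooled_or,
                "ci_lo": model.ci_lo,
                "ci_hi": model.ci_hi,
                "weight_fixed": None,
                "weight_random": None,
            }
        )
    return rows


__all__ = [
    "MetaResult",
    "ModelResult",
    "StudyEstimate",
    "cochran_q",
    "dersimonian_laird",
    "fixed_effects",
    "forest_data",
    "meta_analysis",
    "sample_size_weighted_z",
    "se_from_ci",
]
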