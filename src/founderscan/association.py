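"""Log-additive (allele-dosage trend) logistic association, stage IV vs stage I/II.

The contrast is case-case: metastatic (stage IV) cancers are coded 1 and
non-metastatic (stage I/II) cancers 0; cancer-free controls never enter a fit
and appear only in descriptive allele-frequency summaries.  Each SNP is
tested with a covariate-adjusted logistic regression on 0/1/2 minor-allele
dosage; inference is Wald (z = beta/se, two-sided), the PLINK convention the
replication thresholds were designed around.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .datatypes import MISSING, GenotypeDataset, VariantRecord, genotype_counts

logger = logging.getLogger(__name__)

Z95 = 1.96  # CI multiplier, matching two-decimal published intervals


@dataclass
class AssociationResult:
    variant_id: str
    beta: float
    se: float
    or_: float
    ci_lo: float
    ci_hi: float
    p: float
    n_used: int
    converged: bool
    note: str = ""
    variant: Optional[VariantRecord] = None
    maf: Optional[float] = None  # reference-group (stage I/II) MAF


@dataclass
class GroupGenotypeSummary:
    group: str
    n_AA: int
    n_Aa: int
    n_aa: int

    @property
    def maf(self) -> float:
        return maf_from_counts(self.n_AA, self.n_Aa, self.n_aa)


def maf_from_counts(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Minor-allele frequency from genotype counts: (het + 2*hom) / (2*total)."""
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    total = n_AA + n_Aa + n_aa
    if total == 0:
        raise ValueError("total genotype count is zero")
    return (n_Aa + 2 * n_aa) / (2 * total)


def fit_logistic_trend(
    dosages: np.ndarray,
    phenotype: np.ndarray,
    covariates: Optional[np.ndarray] = None,
    variant_id: str = "",
) -> AssociationResult:
    """ML logistic fit of phenotype on intercept + dosage (+ covariates).

    Samples with missing dosage (−1) or any non-finite covariate are dropped
    listwise.  Fitting is Newton/IRLS (relative log-likelihood tolerance
    1e-10, at most 100 iterations); non-convergence or separation is reported
    with ``converged=False`` rather than a silent estimate.
    """
    dosages = np.asarray(dosages, dtype=float)
    phenotype = np.asarray(phenotype, dtype=float)
    keep = dosages != MISSING
    if covariates is not None:
        covariates = np.asarray(covariates, dtype=float)
        if covariates.ndim == 1:
            covariates = covariates[:, None]
        keep &= np.isfinite(covariates).all(axis=1)
    d = dosages[keep]
    y = phenotype[keep]
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("phenotype must be binary 0/1")
    if len(np.unique(y)) < 2:
        raise ValueError("phenotype has a single class in the analysis set")
    if np.ptp(d) == 0:
        raise ValueError(f"variant {variant_id or '?'} monomorphic in analysis set")

    x = d[:, None] if covariates is None else np.column_stack([d, covariates[keep]])
    x = sm.add_constant(x, prepend=True, has_constant="add")

    def _failed(note: str) -> AssociationResult:
        return AssociationResult(
            variant_id=variant_id, beta=np.nan, se=np.nan, or_=np.nan,
            ci_lo=np.nan, ci_hi=np.nan, p=np.nan, n_used=int(keep.sum()),
            converged=False, note=note,
        )

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, x).fit(method="newton", maxiter=100, tol=1e-10, disp=0)
        except Exception as exc:  # separation raises PerfectSeparationError
            return _failed(f"fit failed: {type(exc).__name__}")
    beta = float(fit.params[1])
    se = float(fit.bse[1])
    if not fit.mle_retvals.get("converged", False):
        return _failed("no convergence in 100 iterations")
    if not np.isfinite(se) or se <= 0 or abs(beta) > 15:
        return _failed("quasi-separation: unstable estimate")
    z = beta / se
    return AssociationResult(
        variant_id=variant_id,
        beta=beta,
        se=se,
        or_=float(np.exp(beta)),
        ci_lo=float(np.exp(beta - Z95 * se)),
        ci_hi=float(np.exp(beta + Z95 * se)),
        p=float(2 * stats.norm.sf(abs(z))),
        n_used=int(keep.sum()),
        converged=True,
    )


def build_design(
    dataset: GenotypeDataset,
    covariate_names: Sequence[str],
    components: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Covariate design matrix from sample metadata plus optional MDS axes.

    Recognised names: ``age``, ``sex`` (male = 1), and ``PC1..PCk`` drawn from
    ``components`` columns.
    """
    cols = []
    for name in covariate_names:
        if name == "age":
            cols.append([s.age for s in dataset.samples])
        elif name == "sex":
            cols.append([1.0 if s.sex == "male" else 0.0 for s in dataset.samples])
        elif name.upper().startswith("PC"):
            if components is None:
                raise ValueError(f"covariate {name} requested but no components supplied")
            idx = int(name[2:]) - 1
            cols.append(components[:, idx])
        else:
            raise ValueError(f"unknown covariate {name!r}")
    return np.column_stack(cols) if cols else np.empty((dataset.n_samples, 0))


def genome_scan(
    dataset: GenotypeDataset,
    covariates: Optional[np.ndarray] = None,
    case_stages: Sequence[str] = ("IV",),
    ref_stages: Sequence[str] = ("I", "II"),
    summary_groups: bool = True,
) -> tuple[list[AssociationResult], dict[str, dict[str, GroupGenotypeSummary]]]:
    """One trend fit per variant; per-variant failures are flagged, not fatal.

    Returns the results (scan order) and, per variant, genotype-count
    summaries for the case, reference, combined and (if present) control
    groups.  Controls contribute to summaries only.
    """
    case_mask = dataset.stage_mask(case_stages)
    ref_mask = dataset.stage_mask(ref_stages)
    ctrl_mask = dataset.stage_mask(["control"])
    if not case_mask.any() or not ref_mask.any():
        raise ValueError("both case and reference groups must be non-empty")
    fit_mask = case_mask | ref_mask
    pheno = case_mask[fit_mask].astype(float)
    cov = covariates[fit_mask] if covariates is not None else None

    results: list[AssociationResult] = []
    summaries: dict[str, dict[str, GroupGenotypeSummary]] = {}
    for j, v in enumerate(dataset.variants):
        col = dataset.dosages[:, j]
        try:
            res = fit_logistic_trend(col[fit_mask], pheno, cov, variant_id=v.variant_id)
        except ValueError as exc:
            res = AssociationResult(
                variant_id=v.variant_id, beta=np.nan, se=np.nan, or_=np.nan,
                ci_lo=np.nan, ci_hi=np.nan, p=np.nan, n_used=0,
                converged=False, note=str(exc),
            )
        res.variant = v
        ref_counts = genotype_counts(col[ref_mask])
        if sum(ref_counts) > 0:
            res.maf = maf_from_counts(*ref_counts)
        results.append(res)
        if summary_groups:
            groups = {
                "case": GroupGenotypeSummary("case", *genotype_counts(col[case_mask])),
                "reference": GroupGenotypeSummary("reference", *ref_counts),
                "combined": GroupGenotypeSummary("combined", *genotype_counts(col[fit_mask])),
            }
            if ctrl_mask.any():
                groups["control"] = GroupGenotypeSummary(
                    "control", *genotype_counts(col[ctrl_mask])
                )
            summaries[v.variant_id] = groups
    return results, summaries


def qq_data(p_values: Sequence[float]) -> np.ndarray:
    """(expected, observed) −log10 p pairs for a Q-Q plot, ascending order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    p_sorted = np.sort(p)
    n = p.size
    expected = np.arange(1, n + 1) / (n + 1)
    return np.column_stack([-np.log10(expected), -np.log10(p_sorted)])


__all__ = [
    "AssociationResult",
    "GroupGenotypeSummary",
    "build_design",
    "fit_logistic_trend",
    "genome_scan",
    "maf_from_counts",
    "qq_data",
]
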