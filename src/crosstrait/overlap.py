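"""Sample-overlap correction for cross-study z-score lookups.

When two case-control GWAS share subjects, their z-scores at null SNPs
are correlated: querying study 2 at study 1's hits then yields spurious
replication.  This module models the pair (z1, z2) at a null SNP as a
bivariate normal with marginal variances sigma1^2, sigma2^2 (the mean
chi-square inflation of each study) and covariance c induced by the
shared subjects.  Study 2's z is then replaced by the standardized
residual of its conditional distribution given z1,

    z_corr = (z2 - (c / sigma1^2) z1) / sqrt(sigma2^2 - c^2 / sigma1^2),

which is standard normal under the null, so ordinary two-sided
p-values apply after correction.

The overlap covariance can be obtained three ways, which should agree:
theoretically from the sample counts (:func:`theoretical_overlap_cov`),
empirically as the mean z1*z2 product over null SNPs, or as the
intercept of the cross-trait LD-score regression of z1*z2 products on
LD scores (:func:`empirical_overlap_cov`), which is robust to true
genetic correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .sumstats import p_from_z


@dataclass(frozen=True)
class OverlapSpec:
    """Per-study case/control counts and the counts of shared subjects."""

    n1_case: int
    n1_control: int
    n2_case: int
    n2_control: int
    ns_case: int
    ns_control: int

    def __post_init__(self) -> None:
        for name in ("n1_case", "n1_control", "n2_case", "n2_control"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 <= self.ns_case <= min(self.n1_case, self.n2_case):
            raise ValueError("shared cases exceed a study's case count")
        if not 0 <= self.ns_control <= min(self.n1_control, self.n2_control):
            raise ValueError("shared controls exceed a study's control count")

    @property
    def n1_total(self) -> int:
        return self.n1_case + self.n1_control

    @property
    def n2_total(self) -> int:
        return self.n2_case + self.n2_control

    def swapped(self) -> "OverlapSpec":
        return OverlapSpec(
            self.n2_case, self.n2_control, self.n1_case, self.n1_control,
            self.ns_case, self.ns_control,
        )


@dataclass(frozen=True)
class BivariateNullModel:
    """The null bivariate normal for (z1, z2): variances, covariance, correlation."""

    var1: float
    var2: float
    cov: float
    corr: float

    def __post_init__(self) -> None:
        if self.var1 <= 0 or self.var2 <= 0:
            raise ValueError("variances must be positive")
        if abs(self.corr) > 1:
            raise ValueError(f"implied correlation {self.corr:.4f} outside [-1, 1]")
        if self.conditional_var <= 0:
            raise ValueError("conditional variance must be positive")

    @property
    def conditional_var(self) -> float:
        """Var(z2 | z1) = sigma2^2 - c^2 / sigma1^2."""
        return self.var2 - self.cov**2 / self.var1

    def swapped(self) -> "BivariateNullModel":
        return BivariateNullModel(self.var2, self.var1, self.cov, self.corr)


def estimate_inflation(z_values) -> float:
    """Variance of a study's z-scores, estimated as the mean of z^2.

    The caller chooses the SNP set; restrict to well-imputed common
    SNPs (a HapMap3-like set) so the estimate reflects genome-wide
    inflation rather than imputation noise.
    """
    z = np.asarray(z_values, dtype=float)
    if z.size == 0:
        raise ValueError("cannot estimate inflation from an empty z-score set")
    if z.size < 100:
        warnings.warn(
            f"inflation estimated from only {z.size} z-scores; expect noise",
            stacklevel=2,
        )
    return float(np.mean(z**2))


def theoretical_overlap_cov(spec: OverlapSpec) -> float:
    """Overlap-induced z-score covariance from sample counts alone.

    For two case-control studies with N_s shared cases and controls,
    assuming no genetic correlation, the covariance between the
    studies' z-scores at a null SNP is

        c = [ ns_case * sqrt((n1_ctl * n2_ctl) / (n1_case * n2_case))
            + ns_ctl  * sqrt((n1_case * n2_case) / (n1_ctl * n2_ctl)) ]
            / sqrt(N1 * N2).

    Shared cases and shared controls both push the covariance up;
    subjects who are a case in one study and a control in the other
    are not modelled (they would enter negatively).
    """
    if min(spec.n1_case, spec.n1_control, spec.n2_case, spec.n2_control) == 0:
        raise ValueError("overlap covariance undefined when a case/control count is zero")
    ratio = (spec.n1_control * spec.n2_control) / (spec.n1_case * spec.n2_case)
    num = spec.ns_case * np.sqrt(ratio) + spec.ns_control / np.sqrt(ratio)
    return float(num / np.sqrt(spec.n1_total * spec.n2_total))


def build_null(var1: float, var2: float, cov: float) -> BivariateNullModel:
    """Assemble the bivariate null from marginal variances and covariance."""
    if var1 <= 0 or var2 <= 0:
        raise ValueError("variances must be positive")
    corr = cov / np.sqrt(var1 * var2)
    return BivariateNullModel(var1=float(var1), var2=float(var2), cov=float(cov), corr=float(corr))


def empirical_overlap_cov(z_pairs, ld_scores=None) -> float:
    """Estimate the overlap covariance from paired z-scores.

    Without LD scores this is the mean product z1*z2 across SNPs.  With
    per-SNP LD scores it is the intercept of the ordinary least squares
    regression of z1*z2 on LD score — the cross-trait LD-score
    regression intercept, which separates sample-overlap covariance
    (constant in LD) from genetic correlation (growing with LD score).
    """
    pairs = np.asarray(z_pairs, dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2:
        raise ValueError("z_pairs must be an (n, 2) array of paired z-scores")
    n = pairs.shape[0]
    if n < 100:
        warnings.warn(f"covariance estimated from only {n} pairs; expect noise", stacklevel=2)
    prod = pairs[:, 0] * pairs[:, 1]
    if ld_scores is None:
        return float(prod.mean())
    ld = np.asarray(ld_scores, dtype=float)
    if ld.shape[0] != n:
        raise ValueError("ld_scores length must match number of z pairs")
    design = np.column_stack([np.ones(n), ld])
    coef, *_ = np.linalg.lstsq(design, prod, rcond=None)
    return float(coef[0])


def conditional_transform(
    z1,
    z2,
    model: BivariateNullModel,
    variance_mode: Literal["marginal", "unit"] = "marginal",
) -> tuple[np.ndarray, np.ndarray]:
    """Correct study-2 z-scores for sample overlap with study 1.

    Returns ``(z_corrected, p_corrected)`` where z_corrected is the
    standardized residual of z2 given z1 under ``model`` and
    p_corrected its two-sided normal p-value.  Accepts scalars or
    arrays.

    ``variance_mode='marginal'`` standardizes by the full conditional
    variance sigma2^2 - c^2/sigma1^2, which includes study 2's
    polygenic inflation and is therefore conservative for truly
    associated SNPs.  ``'unit'`` substitutes 1 for sigma2^2 as a
    sensitivity analysis.
    """
    z1 = np.asarray(z1, dtype=float)
    z2 = np.asarray(z2, dtype=float)
    mu = (model.cov / model.var1) * z1
    var2 = 1.0 if variance_mode == "unit" else model.var2
    tau2 = var2 - model.cov**2 / model.var1
    if tau2 <= 0:
        raise ValueError(f"conditional variance {tau2:.4g} is not positive")
    z_corr = (z2 - mu) / np.sqrt(tau2)
    p_corr = p_from_z(z_corr)
    if z_corr.ndim == 0:
        return float(z_corr), float(p_corr)
    return z_corr, p_corr


def model_from_spec(
    spec: OverlapSpec, var1: float, var2: float, cov: float | None = None
) -> BivariateNullModel:
    """Build the null model, deriving the covariance from counts unless given."""
    c = theoretical_overlap_cov(spec) if cov is None else cov
    return build_null(var1, var2, c)
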