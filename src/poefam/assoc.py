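"""Allelic association tests on a log-transformed quantitative trait.

Three per-SNP test modes share one ordinary-least-squares machinery:

* ``standard`` — regress ln(BMI) on the 0-2 minor-allele dosage,
* ``paternal`` — on the 0/1 paternally inherited allele,
* ``maternal`` — on the 0/1 maternally inherited allele,

each adjusted for age, sex and type-2-diabetes status, complete-case per
SNP. Paternal and maternal effect sizes are then compared with a two-sample
z/t statistic on the two independent estimates,
``t = (b_pat - b_mat) / sqrt(se_pat^2 + se_mat^2)``, referred by default to
the standard normal (at family-cohort sample sizes the difference from a t
reference is negligible; a degrees-of-freedom override is available).

Note on scale: some tools accept only diploid predictors and encode a
parental allele by doubling it (0/2). Doubling halves the slope and its
standard error and leaves t and p unchanged; results here are on the
natural per-allele 0/1 scale, and the reporting layer can emit the
doubled-scale slope alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .io import PhenotypeTable

Z_975 = 1.959964  # two-sided 95% normal quantile

MODES = ("standard", "paternal", "maternal")


class AssociationError(ValueError):
    """Raised when a regression cannot be fit (monomorphic, too few rows)."""


@dataclass
class AssocResult:
    snp_id: str
    mode: str
    effect_allele: str
    beta: float
    se: float
    ci95: tuple[float, float]
    p: float
    n: int

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class BetaComparison:
    snp_id: str
    delta: float  # beta_paternal - beta_maternal
    t: float
    p: float


def ln_transform(ph: PhenotypeTable) -> pd.Series:
    """Natural log of BMI for every valid row (BMI > 0 is enforced at I/O)."""
    bmi = ph.data["bmi"]
    if (bmi <= 0).any():
        bad = bmi.index[bmi <= 0].tolist()
        raise ValueError(f"non-positive BMI for individuals {bad}")
    return np.log(bmi)


def fit_allelic_regression(
    y: pd.Series,
    predictor: pd.Series,
    covariates: pd.DataFrame,
    mode: str,
    snp_id: str = "",
    effect_allele: str = "",
) -> AssocResult:
    """OLS of the transformed trait on an allele predictor plus covariates.

    Rows with a missing trait value, predictor or covariate are dropped
    (complete-case, so ``n`` varies by SNP). The predictor is the dosage
    (0-2) in ``standard`` mode or the transmitted allele (0/1) in the
    parental modes.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}")
    df = pd.concat(
        [y.rename("__y"), predictor.rename("__x"), covariates], axis=1, join="inner"
    ).dropna()
    n = len(df)
    k_params = 2 + covariates.shape[1]
    if n <= k_params:
        raise AssociationError(
            f"{snp_id} [{mode}]: {n} complete cases for {k_params} parameters"
        )
    if df["__x"].nunique() < 2:
        raise AssociationError(f"{snp_id} [{mode}]: predictor is monomorphic/unusable")

    X = sm.add_constant(df.drop(columns="__y"))
    fit = sm.OLS(df["__y"], X).fit()
    beta = float(fit.params["__x"])
    se = float(fit.bse["__x"])
    p = float(fit.pvalues["__x"])
    return AssocResult(
        snp_id=snp_id,
        mode=mode,
        effect_allele=effect_allele,
        beta=beta,
        se=se,
        ci95=(beta - Z_975 * se, beta + Z_975 * se),
        p=p,
        n=n,
    )


def compare_betas(
    a: AssocResult, b: AssocResult, df_override: int | None = None
) -> BetaComparison:
    """Test equality of the paternal and maternal per-allele effects.

    ``a`` must be the paternal-mode and ``b`` the maternal-mode result for
    the same SNP with the same effect allele. The statistic is referred to
    the standard normal unless ``df_override`` selects a t reference.
    """
    if a.snp_id != b.snp_id:
        raise ValueError(f"snp mismatch: {a.snp_id!r} vs {b.snp_id!r}")
    if a.effect_allele != b.effect_allele:
        raise ValueError(
            f"{a.snp_id}: effect-allele orientation mismatch "
            f"({a.effect_allele!r} vs {b.effect_allele!r}); re-orient first"
        )
    return _compare(a.snp_id, a.beta, a.se, b.beta, b.se, df_override)


def _compare(
    snp_id: str,
    beta_pat: float,
    se_pat: float,
    beta_mat: float,
    se_mat: float,
    df_override: int | None = None,
) -> BetaComparison:
    if se_pat <= 0 or se_mat <= 0:
        raise ValueError(f"{snp_id}: standard errors must be positive")
    delta = beta_pat - beta_mat
    t = delta / np.hypot(se_pat, se_mat)
    if df_override is not None:
        p = 2 * stats.t.sf(abs(t), df=df_override)
    else:
        p = 2 * stats.norm.sf(abs(t))
    return BetaComparison(snp_id=snp_id, delta=float(delta), t=float(t), p=float(min(1.0, p)))


def compare_reported_estimates(
    snp_id: str,
    beta_pat: float,
    ci_pat: tuple[float, float],
    beta_mat: float,
    ci_mat: tuple[float, float],
    df_override: int | None = None,
) -> BetaComparison:
    """Paternal-vs-maternal comparison reconstructed from reported summaries.

    Takes published effect sizes and 95% confidence intervals at face value
    (each on its own reported effect allele), recovers the standard errors
    from the interval widths, and applies the same statistic as
    :func:`compare_betas`. Interval bounds printed in reversed order are
    normalised to (low, high).
    """
    return _compare(
        snp_id,
        beta_pat,
        se_from_ci(ci_pat, beta_pat),
        beta_mat,
        se_from_ci(ci_mat, beta_mat),
        df_override,
    )


def se_from_ci(ci95: tuple[float, float], beta: float) -> float:
    """Standard error implied by a 95% confidence interval.

    Bounds may arrive in either order; after normalisation the interval must
    be non-degenerate and bracket ``beta`` (small tolerance for rounding of
    printed values).
    """
    lo, hi = sorted(ci95)
    if hi <= lo:
        raise ValueError(f"degenerate confidence interval {ci95}")
    tol = (hi - lo) * 0.26  # printed intervals are rounded; allow slack
    if not (lo - tol <= beta <= hi + tol):
        raise ValueError(f"interval {ci95} does not bracket beta={beta}")
    return (hi - lo) / (2 * Z_975)


def bonferroni_threshold(alpha: float, m_snps: int, k_tests: int) -> float:
    """Family-wise significance threshold alpha / (m_snps * k_tests)."""
    if alpha <= 0 or m_snps <= 0 or k_tests <= 0:
        raise ValueError("alpha, m_snps and k_tests must be positive")
    return alpha / (m_snps * k_tests)
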