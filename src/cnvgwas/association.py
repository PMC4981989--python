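"""Trait association with copy-number dose.

Two-stage analysis: lung-function traits (FEV1, FVC, FEV1/FVC) are first
adjusted for age, age^2, sex, height, height^2 and the leading ancestry
principal components; the residuals are then regressed on the per-sample
copy-number dose.  Cohorts of unrelated individuals use ordinary least
squares; family-structured cohorts use generalized estimating equations
(exchangeable working correlation, robust sandwich standard errors).

``DoseAssociation`` / ``DoseAssociationResults`` follow the statsmodels
Model/Results convention and wrap statsmodels OLS / GEE.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "AssociationResult",
    "DoseAssociation",
    "DoseAssociationResults",
    "adjust_phenotype",
    "inverse_normal_transform",
    "linear_dose_association",
    "gee_dose_association",
]

MIN_N = 30
ADJUSTMENT_COVARIATES = ("age", "sex", "height", "PC1", "PC2", "PC3", "PC4")


def build_adjustment_design(covariates: pd.DataFrame) -> pd.DataFrame:
    """Design matrix intercept + age + age^2 + sex + height + height^2 + PCs.

    Uses whichever of the standard covariate columns are present; quadratic
    terms for age and height are added automatically.  Constant columns
    (e.g. sex in a single-sex subset) are dropped with a warning.
    """
    X = pd.DataFrame(index=covariates.index)
    X["const"] = 1.0
    for col in ADJUSTMENT_COVARIATES:
        if col not in covariates.columns:
            continue
        v = pd.to_numeric(covariates[col], errors="coerce")
        X[col] = v
        if col in ("age", "height"):
            X[col + "2"] = v**2
    # drop degenerate columns so the fit stays full rank
    for col in list(X.columns):
        if col != "const" and X[col].nunique(dropna=True) <= 1:
            warnings.warn(f"dropping constant covariate column {col!r}")
            X = X.drop(columns=col)
    return X


def adjust_phenotype(trait: pd.Series, covariates: pd.DataFrame) -> pd.Series:
    """Residuals of trait on the standard adjustment covariates (complete cases)."""
    X = build_adjustment_design(covariates)
    df = X.join(pd.to_numeric(trait, errors="coerce").rename("_trait"), how="inner")
    df = df.dropna()
    fit = sm.OLS(df["_trait"], df.drop(columns="_trait")).fit()
    return fit.resid


def inverse_normal_transform(values, offset: float = 3.0 / 8.0) -> pd.Series:
    """Rank-based inverse-normal transform, Blom offset by default.

    A value with (average, tie-sharing) rank r among n maps to
    Phi^-1((r - offset) / (n - 2*offset + 1)); for the Blom offset 3/8 that is
    Phi^-1((r - 3/8) / (n + 1/4)).
    """
    s = pd.Series(values, dtype=float)
    x = s.dropna()
    if x.size < 2:
        raise ValueError("need >= 2 values to rank-transform")
    if x.nunique() < 2:
        raise ValueError("all values equal: no order information to transform")
    ranks = stats.rankdata(x, method="average")
    z = stats.norm.ppf((ranks - offset) / (x.size - 2 * offset + 1))
    out = pd.Series(np.nan, index=s.index)
    out[x.index] = z
    return out


@dataclass
class AssociationResult:
    """One CNVR x trait x cohort association record."""

    region_id: str
    trait: str
    cohort: str
    beta: Optional[float]
    se: Optional[float]
    pvalue: Optional[float]
    n: int
    direction: str  # '+', '-' or '.' when no result
    method: str = "ols"

    @property
    def has_result(self) -> bool:
        return self.direction != "."


class DoseAssociation:
    """Linear model of an adjusted trait on copy-number dose.

    Parameters
    ----------
    endog : adjusted trait values (residuals), aligned with ``dose``
    dose : continuous copy-number dose per sample
    groups : optional family ids; when given, fit() uses GEE with an
        exchangeable working correlation and robust standard errors.
    """

    def __init__(self, endog, dose, groups=None) -> None:
        y = np.asarray(endog, dtype=float)
        d = np.asarray(dose, dtype=float)
        if y.shape != d.shape:
            raise ValueError("endog and dose must be the same length")
        mask = np.isfinite(y) & np.isfinite(d)
        if groups is not None:
            groups = np.asarray(groups)
            groups = groups[mask]
        self.endog = y[mask]
        self.dose = d[mask]
        self.groups = groups

    @property
    def nobs(self) -> int:
        return self.endog.size

    def fit(self, cov_struct: str = "exchangeable") -> "DoseAssociationResults":
        n = self.nobs
        if n < MIN_N:
            raise ValueError(f"need >= {MIN_N} samples, got {n}")
        if np.ptp(self.dose) == 0.0 or np.var(self.dose) == 0.0:
            return DoseAssociationResults(None, None, None, n, method="none")
        X = sm.add_constant(self.dose)
        if self.groups is None:
            res = sm.OLS(self.endog, X).fit()
            return DoseAssociationResults(
                float(res.params[1]), float(res.bse[1]), float(res.pvalues[1]),
                n, method="ols", sm_results=res,
            )
        cs = {
            "exchangeable": sm.cov_struct.Exchangeable,
            "independence": sm.cov_struct.Independence,
        }[cov_struct]()
        res = sm.GEE(self.endog, X, groups=self.groups, cov_struct=cs).fit()
        return DoseAssociationResults(
            float(res.params[1]), float(res.bse[1]), float(res.pvalues[1]),
            n, method="gee", sm_results=res,
        )


class DoseAssociationResults:
    """Slope estimate for dose with its uncertainty and two-sided P."""

    def __init__(self, beta, se, pvalue, n, method, sm_results=None):
        self.beta = beta
        self.se = se
        self.pvalue = pvalue
        self.n = n
        self.method = method
        self.sm_results = sm_results

    @property
    def direction(self) -> str:
        if self.beta is None:
            return "."
        return "+" if self.beta >= 0 else "-"

    def to_record(self, region_id: str, trait: str, cohort: str) -> AssociationResult:
        return AssociationResult(
            region_id, trait, cohort, self.beta, self.se, self.pvalue,
            self.n, self.direction, self.method,
        )

    def summary(self) -> str:
        if self.beta is None:
            return f"DoseAssociation: no result (n={self.n}, zero dose variance)"
        return (
            f"DoseAssociation ({self.method.upper()}): n={self.n}, "
            f"beta={self.beta:.6g}, SE={self.se:.6g}, P={self.pvalue:.4g}, "
            f"direction={self.direction}"
        )


def linear_dose_association(
    adjusted_trait, dose, region_id="?", trait="?", cohort="?"
) -> AssociationResult:
    """OLS slope of adjusted trait on dose (unrelated individuals)."""
    res = DoseAssociation(adjusted_trait, dose).fit()
    return res.to_record(region_id, trait, cohort)


def gee_dose_association(
    adjusted_trait, dose, family_ids, region_id="?", trait="?", cohort="?",
    cov_struct: str = "exchangeable",
) -> AssociationResult:
    """GEE slope with robust SE for cohorts with family structure."""
    res = DoseAssociation(adjusted_trait, dose, groups=family_ids).fit(cov_struct=cov_struct)
    return res.to_record(region_id, trait, cohort)
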