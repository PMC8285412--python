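"""Explained variance and genetic risk scores over signal-index variants.

The variance in the (log) phenotype explained by one variant is
R^2 = b^2 * Var(G) / Var(Y) with Var(G) = 2*MAF*(1-MAF) under Hardy-Weinberg;
conditional effects are used at multi-signal loci and per-variant
contributions are summed.  Genetic risk scores orient every variant to its
outcome-decreasing allele: the unweighted score counts decreasing alleles,
the weighted score multiplies the decreasing-allele dosage by |beta|.  GRS
effects are reported per standard deviation of the score and translated into
the expected outcome difference between the 95th and 5th score percentiles
(3.29 SDs apart under normality).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as _st

__all__ = [
    "VarExpConfig",
    "GRSProfile",
    "explained_variance",
    "build_grs",
    "grs_regression",
    "percentile_difference",
]

#: Phi^-1(0.95) - Phi^-1(0.05): SD spread between the 95th and 5th percentiles
NORMAL_90_SPREAD = float(_st.norm.ppf(0.95) - _st.norm.ppf(0.05))


@dataclass(frozen=True)
class VarExpConfig:
    """Reference phenotype variance of the age-/sex-adjusted log outcome.

    0.016 corresponds to a population-based reference cohort, 0.078 to a
    hospital-based one.
    """

    var_y: float = 0.016

    def __post_init__(self) -> None:
        if self.var_y <= 0:
            raise ValueError("var_y must be > 0")


@dataclass
class GRSProfile:
    scores: np.ndarray
    mode: str
    variants_used: list[str]
    variants_dropped: list[str] = field(default_factory=list)


def explained_variance(betas, eafs, var_y: float = 0.016) -> tuple[np.ndarray, float]:
    """Per-variant and total phenotype variance explained.

    ``betas`` are per-allele effects on the log outcome (conditional at
    multi-signal loci); ``eafs`` effect-allele frequencies.  R^2 per variant
    is b^2 * 2*MAF*(1-MAF) / var_y (orientation invariant); total is the sum.
    """
    if var_y <= 0:
        raise ValueError("var_y must be > 0")
    b = np.asarray(betas, float)
    eaf = np.asarray(eafs, float)
    maf = np.minimum(eaf, 1.0 - eaf)
    r2 = b**2 * 2.0 * maf * (1.0 - maf) / var_y
    return r2, float(r2.sum())


def build_grs(dosages: pd.DataFrame, betas: dict[str, float],
              mode: str = "unweighted") -> GRSProfile:
    """Genetic risk score per individual over signal-index variants.

    ``dosages`` is individuals x variants (columns are cpaids, values in
    [0, 2] counting the *effect* allele of each variant's beta).  Every
    variant is oriented to its outcome-decreasing allele: if beta > 0 the
    decreasing allele is the other allele and the dosage is reflected to
    2 - dosage.  Variants missing from the dosage matrix are dropped with a
    warning and recorded.
    """
    if mode not in ("unweighted", "weighted"):
        raise ValueError(f"mode must be unweighted or weighted, got {mode!r}")
    used, dropped, cols = [], [], []
    for cpaid, b in betas.items():
        if cpaid not in dosages.columns:
            dropped.append(cpaid)
            continue
        d = dosages[cpaid].to_numpy(float)
        dec = d if b < 0 else 2.0 - d  # decreasing-allele dosage
        w = abs(b) if mode == "weighted" else 1.0
        cols.append(w * dec)
        used.append(cpaid)
    if dropped:
        warnings.warn(f"{len(dropped)} variant(s) missing dosages, excluded: "
                      f"{dropped[:3]}", stacklevel=2)
    if not cols:
        raise ValueError("no variants with dosages available")
    scores = np.sum(cols, axis=0)
    return GRSProfile(scores=scores, mode=mode, variants_used=used,
                      variants_dropped=dropped)


def grs_regression(scores: np.ndarray, outcome: np.ndarray,
                   covariates: np.ndarray | None = None) -> dict:
    """OLS of the raw-scale outcome on the standardized GRS plus covariates.

    Returns the effect per SD of the GRS (outcome units), its SE and
    two-sided p, and the incremental R^2 of the GRS term over the
    covariate-only model.
    """
    scores = np.asarray(scores, float)
    outcome = np.asarray(outcome, float)
    z = (scores - scores.mean()) / scores.std(ddof=0)
    if covariates is None:
        C = np.ones((len(outcome), 1))
    else:
        C = np.column_stack([np.ones(len(outcome)), np.asarray(covariates, float)])
    if np.linalg.matrix_rank(C) < C.shape[1]:
        raise ValueError("rank-deficient covariate design")
    X = np.column_stack([C, z])
    fit = sm.OLS(outcome, X).fit()
    base = sm.OLS(outcome, C).fit()
    return {
        "effect_per_sd": float(fit.params[-1]),
        "se": float(fit.bse[-1]),
        "p": float(fit.pvalues[-1]),
        "r2_incremental": float(fit.rsquared - base.rsquared),
    }


def percentile_difference(effect_per_sd: float, method: str = "normal_approx",
                          scores: np.ndarray | None = None,
                          predict=None) -> float:
    """Expected outcome difference between the 95th and 5th GRS percentiles.

    ``normal_approx`` multiplies the per-SD effect by the 3.2897-SD spread of
    the standard normal; ``empirical`` evaluates an outcome-model prediction
    at the two empirical score percentiles (``predict`` maps standardized
    scores to predicted outcomes; linear in the effect by default).
    """
    if method == "normal_approx":
        return float(NORMAL_90_SPREAD * effect_per_sd)
    if method == "empirical":
        if scores is None:
            raise ValueError("empirical method requires scores")
        scores = np.asarray(scores, float)
        z = (scores - scores.mean()) / scores.std(ddof=0)
        lo, hi = np.percentile(z, [5, 95])
        if predict is None:
            predict = lambda q: effect_per_sd * q
        return float(predict(hi) - predict(lo))
    raise ValueError(f"unknown method {method!r}")
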