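"""Approximate-Bayes-factor colocalization of a GWAS signal with an eQTL signal.

The enumeration follows the standard five-hypothesis scheme: H0 neither trait
associated in the region, H1/H2 only trait 1/2, H3 both but through distinct
causal variants, H4 both through one shared causal variant.  Per-variant
Wakefield log-ABFs are computed for each trait with its own prior effect
variance, combined with per-variant priors (p1, p2, p12) and normalized —
everything in log space.

The trait-2 (expression) prior SD is derived from an effect-size range via
the normal quantile: sd = bound / z_{(1+coverage)/2}, e.g. a 95% range of
+/-1.07 gives sd 0.55.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _st
from scipy.special import logsumexp

from .finemap import DEFAULT_W, Signal, wakefield_log_abf
from .sumstats import SumStats

__all__ = [
    "ColocPriors",
    "ColocResult",
    "derive_prior_sd",
    "coloc_abf",
    "coloc_per_signal",
    "POSITIVE_PP_H4",
]

#: posterior probability of H4 at or above which a colocalization is "positive"
POSITIVE_PP_H4 = 0.80


def derive_prior_sd(range_bound: float, coverage: float = 0.95) -> float:
    """Prior effect SD from a symmetric effect-size range covering ``coverage``."""
    if range_bound <= 0:
        raise ValueError("range bound must be > 0")
    if not 0 < coverage < 1:
        raise ValueError("coverage must be in (0,1)")
    return float(range_bound / _st.norm.ppf((1 + coverage) / 2))


@dataclass(frozen=True)
class ColocPriors:
    """Per-variant hypothesis priors and per-trait effect-prior variances."""

    p1: float = 1e-4
    p2: float = 1e-4
    p12: float = 1e-5
    W1: float = DEFAULT_W
    W2: float = derive_prior_sd(1.07) ** 2  # tubule-interstitial expression

    def __post_init__(self) -> None:
        if not (0 < self.p12 <= min(self.p1, self.p2) < 1):
            raise ValueError("require 0 < p12 <= min(p1, p2) < 1")
        if self.W1 <= 0 or self.W2 <= 0:
            raise ValueError("prior variances must be > 0")


GLOMERULAR_W2 = derive_prior_sd(1.04) ** 2


@dataclass
class ColocResult:
    pp: np.ndarray  # PP_H0..PP_H4
    n_variants: int
    locus_id: str = ""
    signal_id: str = ""
    gene: str = ""
    tissue: str = ""

    def __post_init__(self) -> None:
        self.pp = np.asarray(self.pp, float)
        if self.pp.shape != (5,) or not np.isclose(self.pp.sum(), 1.0, atol=1e-9):
            raise ValueError("pp must be five probabilities summing to 1")

    @property
    def pp_h4(self) -> float:
        return float(self.pp[4])

    @property
    def positive(self) -> bool:
        return self.pp_h4 >= POSITIVE_PP_H4


def coloc_abf(stats1: SumStats, stats2: SumStats,
              priors: ColocPriors = ColocPriors(), **labels) -> ColocResult:
    """Colocalize two traits over the intersection of their variants.

    Variants are matched by cpaid; effect orientation is irrelevant because
    the Wakefield ABF depends on beta only through z^2.
    """
    d1 = stats1.df.set_index("cpaid")
    d2 = stats2.df.set_index("cpaid")
    shared = d1.index.intersection(d2.index)
    # drop eQTL rows with missing SE rather than imputing
    shared = shared[~(d2.loc[shared, "se"].isna() | d1.loc[shared, "se"].isna())]
    if len(shared) == 0:
        raise ValueError(
            f"no shared variants (trait1 has {len(d1)}, trait2 has {len(d2)})"
        )
    l1 = wakefield_log_abf(d1.loc[shared, "beta"].to_numpy(),
                           d1.loc[shared, "se"].to_numpy(), priors.W1)
    l2 = wakefield_log_abf(d2.loc[shared, "beta"].to_numpy(),
                           d2.loc[shared, "se"].to_numpy(), priors.W2)
    l1 = np.atleast_1d(l1)
    l2 = np.atleast_1d(l2)

    s1 = logsumexp(l1)
    s2 = logsumexp(l2)
    s12 = logsumexp(l1 + l2)
    lh = np.empty(5)
    lh[0] = 0.0
    lh[1] = np.log(priors.p1) + s1
    lh[2] = np.log(priors.p2) + s2
    # sum over ordered pairs i != j of exp(l1_i + l2_j), stably in log space
    if len(shared) == 1:
        lh[3] = -np.inf
    else:
        diff = s12 - s1 - s2
        lh[3] = (np.log(priors.p1) + np.log(priors.p2) + s1 + s2
                 + np.log1p(-np.exp(min(diff, -1e-12))))
    lh[4] = np.log(priors.p12) + s12
    pp = np.exp(lh - logsumexp(lh))
    pp /= pp.sum()
    return ColocResult(pp=pp, n_variants=len(shared), **labels)


def coloc_per_signal(signal: Signal, eqtl_tables: pd.DataFrame,
                     priors_by_tissue: dict[str, ColocPriors] | None = None,
                     tissues: list[str] | None = None) -> tuple[list[ColocResult], list[str]]:
    """Colocalize one GWAS signal against each (gene, tissue) eQTL table.

    ``eqtl_tables`` is a long-format frame with columns gene, tissue, cpaid,
    ea, oa, beta, se, p, n.  Genes without overlapping variants are skipped
    with a logged reason.  Returns (results, skip log).
    """
    default = ColocPriors()
    priors_by_tissue = priors_by_tissue or {}
    results, skipped = [], []
    groups = eqtl_tables.groupby(["gene", "tissue"], sort=True)
    for (gene, tissue), table in groups:
        if tissues is not None and tissue not in tissues:
            continue
        pri = priors_by_tissue.get(tissue, default)
        estats_df = table.rename(columns=str.lower)
        try:
            estats = SumStats(estats_df.assign(
                chrom=[c.split(":")[0] for c in estats_df["cpaid"]],
                pos=[int(c.split(":")[1]) for c in estats_df["cpaid"]],
            ), trait="expression")
            res = coloc_abf(signal.conditional_stats, estats, pri,
                            locus_id=signal.locus_id, signal_id=signal.signal_id,
                            gene=str(gene), tissue=str(tissue))
        except ValueError as exc:
            skipped.append(f"{gene}/{tissue}: {exc}")
            continue
        results.append(res)
    return results, skipped
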