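"""Variant QC, genomic control and fixed-effect inverse-variance meta-analysis.

QC mirrors the conventions of large kidney-function meta-analyses: imputation
info >= 0.6 and MAF >= 0.1% before meta-analysis, minor allele count >= 400
on the combined sample afterwards (all exclusions strict "<").  Genomic
control estimates the inflation factor lambda as the median association
chi-square over its null median and, when lambda > 1, inflates standard
errors by sqrt(lambda); deflation is never applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _st

from .sumstats import HarmonizationError, SumStats, wald_p

__all__ = [
    "QCThresholds",
    "GCResult",
    "apply_qc_filters",
    "genomic_control_lambda",
    "gc_correct",
    "ivw_meta",
    "second_meta_support",
]

# median of the chi-square(1) distribution
CHI2_MEDIAN_1DF = float(_st.chi2.ppf(0.5, df=1))


@dataclass(frozen=True)
class QCThresholds:
    """Exclusion thresholds (records strictly below a threshold are dropped)."""

    min_info: float = 0.6
    min_maf: float = 0.001
    min_mac_post_meta: float = 400.0

    def __post_init__(self) -> None:
        if min(self.min_info, self.min_maf, self.min_mac_post_meta) < 0:
            raise ValueError("thresholds must be >= 0")
        if self.min_maf >= 0.5:
            raise ValueError("min_maf must be < 0.5")


@dataclass(frozen=True)
class GCResult:
    lambda_gc: float
    corrected: bool

    def __post_init__(self) -> None:
        if self.lambda_gc <= 0:
            raise ValueError("lambda_gc must be > 0")


def apply_qc_filters(stats: SumStats, thresholds: QCThresholds = QCThresholds(),
                     stage: str = "pre_meta") -> tuple[SumStats, pd.DataFrame]:
    """Apply stage-appropriate variant filters.

    ``pre_meta`` applies the imputation-info and MAF filters; ``post_meta``
    applies the minor-allele-count filter with MAC = 2*n*min(eaf, 1-eaf).
    Returns the surviving records and an exclusion log (cpaid, filter, value).
    Missing info passes only for records flagged genotyped (conservative QC):
    the table carries an optional boolean ``genotyped`` column.
    """
    if stage not in ("pre_meta", "post_meta"):
        raise ValueError(f"stage must be pre_meta or post_meta, got {stage!r}")
    df = stats.df
    exclusions: list[dict] = []
    if stage == "pre_meta":
        info = df["info"].to_numpy(float)
        genotyped = (
            df["genotyped"].to_numpy(bool)
            if "genotyped" in df.columns
            else np.zeros(len(df), bool)
        )
        info_eff = np.where(np.isnan(info) & genotyped, 1.0, info)
        # missing info on an imputed record fails the filter
        info_fail = np.isnan(info_eff) | (info_eff < thresholds.min_info)
        maf = np.minimum(df["eaf"], 1.0 - df["eaf"]).to_numpy(float)
        maf_fail = maf < thresholds.min_maf
        for i in np.flatnonzero(info_fail):
            exclusions.append({"cpaid": df["cpaid"].iat[i], "filter": "info",
                               "value": float(info[i])})
        for i in np.flatnonzero(~info_fail & maf_fail):
            exclusions.append({"cpaid": df["cpaid"].iat[i], "filter": "maf",
                               "value": float(maf[i])})
        keep = ~(info_fail | maf_fail)
    else:
        mac = 2.0 * df["n"].to_numpy(float) * np.minimum(df["eaf"], 1 - df["eaf"]).to_numpy(float)
        keep = mac >= thresholds.min_mac_post_meta
        for i in np.flatnonzero(~keep):
            exclusions.append({"cpaid": df["cpaid"].iat[i], "filter": "mac",
                               "value": float(mac[i])})
    log = pd.DataFrame(exclusions, columns=["cpaid", "filter", "value"])
    kept = SumStats(df[keep].copy(), trait=stats.trait, provenance=stats.provenance)
    return kept, log


def genomic_control_lambda(stats: SumStats) -> float:
    """Genomic-control inflation factor: median (beta/se)^2 over the chi2(1) median."""
    z2 = (stats.df["beta"] / stats.df["se"]).to_numpy(float) ** 2
    z2 = z2[np.isfinite(z2)]
    if z2.size == 0:
        raise ValueError("no finite association statistics")
    return float(np.median(z2) / CHI2_MEDIAN_1DF)


def gc_correct(stats: SumStats, lambda_gc: float) -> SumStats:
    """Inflate SEs by sqrt(lambda) and recompute Wald p; identity when lambda <= 1.

    No deflation is applied for lambda < 1, matching the convention of the
    standard meta-analysis tools.
    """
    if lambda_gc <= 0:
        raise ValueError("lambda_gc must be > 0")
    if lambda_gc <= 1.0:
        return stats
    df = stats.df.copy()
    df["se"] = df["se"] * np.sqrt(lambda_gc)
    z = np.abs(df["beta"] / df["se"])
    df["p"] = np.clip(2.0 * _st.norm.sf(z), np.nextafter(0, 1), 1.0)
    return SumStats(df, trait=stats.trait, provenance=stats.provenance)


def ivw_meta(studies: list[SumStats], trait: str = "") -> SumStats:
    """Fixed-effect inverse-variance-weighted meta-analysis across studies.

    Records are aligned per cpaid to the first study's effect allele; a study
    whose allele pair disagrees raises.  Per variant: beta = sum(w b)/sum(w)
    with w = 1/se^2, se = sum(w)^(-1/2), two-sided Wald p, n summed and eaf
    the sample-size-weighted mean.  Variants present in a single study pass
    through unchanged.
    """
    if not studies:
        raise ValueError("at least one study required")
    frames = []
    for k, s in enumerate(studies):
        d = s.df[["cpaid", "chrom", "pos", "ea", "oa", "eaf", "beta", "se", "n"]].copy()
        d["study"] = k
        frames.append(d)
    allrec = pd.concat(frames, ignore_index=True)
    ref = allrec.drop_duplicates("cpaid").set_index("cpaid")[["ea", "oa"]]
    ref_ea = allrec["cpaid"].map(ref["ea"])
    ref_oa = allrec["cpaid"].map(ref["oa"])
    flipped = allrec["ea"] == ref_oa
    aligned = allrec["ea"] == ref_ea
    bad = ~(flipped | aligned) | (flipped & (allrec["oa"] != ref_ea)) \
        | (aligned & (allrec["oa"] != ref_oa))
    if bad.any():
        raise HarmonizationError(
            "unharmonizable alleles at "
            f"{allrec.loc[bad, 'cpaid'].unique()[:3].tolist()}"
        )
    allrec.loc[flipped, "beta"] = -allrec.loc[flipped, "beta"]
    allrec.loc[flipped, "eaf"] = 1.0 - allrec.loc[flipped, "eaf"]
    allrec["ea"], allrec["oa"] = ref_ea, ref_oa

    w = 1.0 / allrec["se"] ** 2
    allrec["_w"] = w
    allrec["_wb"] = w * allrec["beta"]
    allrec["_neaf"] = allrec["n"] * allrec["eaf"]
    g = allrec.groupby("cpaid", sort=False)
    agg = g.agg(
        chrom=("chrom", "first"), pos=("pos", "first"),
        ea=("ea", "first"), oa=("oa", "first"),
        sw=("_w", "sum"), swb=("_wb", "sum"),
        n=("n", "sum"), sneaf=("_neaf", "sum"),
    ).reset_index()
    agg["beta"] = agg["swb"] / agg["sw"]
    agg["se"] = agg["sw"] ** -0.5
    agg["eaf"] = agg["sneaf"] / agg["n"]
    z = np.abs(agg["beta"] / agg["se"])
    agg["p"] = np.clip(2.0 * _st.norm.sf(z), np.nextafter(0, 1), 1.0)
    out = agg[["cpaid", "chrom", "pos", "ea", "oa", "eaf", "beta", "se", "p", "n"]]
    return SumStats(out.copy(), trait=trait or (studies[0].trait),
                    provenance="ivw_meta")


def second_meta_support(beta_primary: float, beta_rep: float, p_rep: float,
                        alpha: float = 0.05) -> bool:
    """Directional support rule for an independent replication meta-analysis.

    True iff the replication effect has the same sign as the primary effect
    and the one-sided p in the primary direction is below ``alpha``
    (equivalently: two-sided p < 2*alpha with concordant sign).
    """
    if beta_primary == 0:
        raise ValueError("primary effect is zero: direction undefined")
    if np.sign(beta_rep) != np.sign(beta_primary):
        return False
    return 0.5 * p_rep < alpha
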