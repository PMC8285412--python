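"""Conditional signal detection and Wakefield credible-set fine-mapping.

Two pieces of machinery live here:

* an approximate conditional analysis in the GCTA-COJO tradition — marginal
  per-allele effects plus an external LD reference stand in for individual-
  level genotypes, so that the conditional (joint-model) effect of a variant
  given a conditioning set can be computed from summary statistics alone;
* Wakefield approximate Bayes factors with a fixed prior effect variance W,
  normalized to posterior probabilities of association (PPA) over a signal's
  variants and collected into 99% credible sets.

Effects are moved to the standardized-genotype scale b* = b*sqrt(2f(1-f))
using reference allele frequencies, conditioned through the reference
correlation matrix, and mapped back to the per-allele scale.  When the LD
reference is the analysis sample itself the conditional estimates agree with
exact multiple regression up to sampling noise in the summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _st
from scipy.special import logsumexp

from .loci import GWS_THRESHOLD, Locus
from .sumstats import SumStats

__all__ = [
    "LDReference",
    "Signal",
    "CredibleConfig",
    "CredibleSet",
    "conditional_sumstats",
    "stepwise_signals",
    "wakefield_log_abf",
    "posterior_probabilities",
    "credible_set",
]

#: prior variance of the trait effect; SD 0.005 on the log-phenotype scale
DEFAULT_W = 0.005 ** 2
#: squared multiple correlation above which a variant is flagged collinear
COLLINEARITY_CAP = 0.9


class LDSingularError(np.linalg.LinAlgError):
    """The conditioning set's correlation matrix is numerically singular."""


@dataclass
class LDReference:
    """Variant panel with allele frequencies and pairwise genotype correlation.

    ``freq`` is aligned to each variant's alleleA (the cpaid's first allele);
    ``R`` must be symmetric with unit diagonal and eigenvalues >= -1e-6.
    """

    cpaids: list[str]
    freq: np.ndarray
    R: np.ndarray
    n_ref: int
    dosage_var: np.ndarray | None = None
    _index: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.freq = np.asarray(self.freq, float)
        self.R = np.asarray(self.R, float)
        if self.dosage_var is not None:
            self.dosage_var = np.asarray(self.dosage_var, float)
        m = len(self.cpaids)
        if self.R.shape != (m, m) or self.freq.shape != (m,):
            raise ValueError("inconsistent panel dimensions")
        if not np.allclose(self.R, self.R.T, atol=1e-8):
            raise ValueError("R must be symmetric")
        if not np.allclose(np.diag(self.R), 1.0, atol=1e-6):
            raise ValueError("R must have unit diagonal")
        if np.any((self.freq <= 0) | (self.freq >= 1)):
            raise ValueError("allele frequencies must lie in (0,1)")
        ev_min = float(np.linalg.eigvalsh(self.R).min())
        if ev_min < -1e-6:
            raise ValueError(f"R is not PSD within tolerance (min eigenvalue {ev_min:.2e})")
        self._index = {c: i for i, c in enumerate(self.cpaids)}

    def __contains__(self, cpaid: str) -> bool:
        return cpaid in self._index

    def indices(self, cpaids: list[str]) -> np.ndarray:
        try:
            return np.array([self._index[c] for c in cpaids], int)
        except KeyError as exc:
            raise KeyError(f"variant {exc.args[0]} absent from LD reference") from None

    @classmethod
    def from_dosages(cls, cpaids: list[str], dosages: np.ndarray,
                     counted_alleles: list[str] | None = None) -> "LDReference":
        """Build a reference from a dosage matrix (individuals x variants).

        ``counted_alleles`` names the allele each dosage column counts
        (default: every column counts its variant's alleleA).  Columns
        counting alleleB are reflected so that stored frequencies,
        variances and correlations are alleleA-oriented.
        """
        dosages = np.asarray(dosages, float)
        sd = dosages.std(axis=0)
        if np.any(sd == 0):
            raise ValueError("monomorphic variant in reference panel")
        freq = dosages.mean(axis=0) / 2.0
        with np.errstate(invalid="ignore"):
            R = np.corrcoef(dosages, rowvar=False)
        if counted_alleles is not None:
            alleleA = [c.rsplit(":", 1)[1].split("_")[0] for c in cpaids]
            sign = np.where(np.asarray(counted_alleles) == np.asarray(alleleA),
                            1.0, -1.0)
            freq = np.where(sign > 0, freq, 1.0 - freq)
            R = R * np.outer(sign, sign)
        return cls(list(cpaids), freq, R, n_ref=dosages.shape[0],
                   dosage_var=sd**2)


@dataclass
class Signal:
    """One independent association signal inside a locus."""

    signal_id: str
    locus_id: str
    index_cpaid: str
    conditioning_set: list[str]
    conditional_stats: SumStats
    order: int
    index_p_cond: float

    @property
    def is_primary(self) -> bool:
        return self.order == 1


@dataclass(frozen=True)
class CredibleConfig:
    W: float = DEFAULT_W
    mass: float = 0.99

    def __post_init__(self) -> None:
        if self.W <= 0:
            raise ValueError("prior variance W must be > 0")
        if not 0 < self.mass < 1:
            raise ValueError("mass must be in (0,1)")


@dataclass
class CredibleSet:
    """PPA-ranked variants whose cumulative posterior mass reaches the target."""

    signal_id: str
    members: pd.DataFrame  # cpaid, ppa, cum_ppa (PPA descending)
    mass: float = 0.99

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def small(self) -> bool:
        return self.size <= 5

    @property
    def single(self) -> bool:
        return self.size == 1

    def __contains__(self, cpaid: str) -> bool:
        return cpaid in set(self.members["cpaid"])


def _std_scale(freq: np.ndarray) -> np.ndarray:
    """Genotype SD under Hardy-Weinberg: sqrt(2 f (1-f))."""
    return np.sqrt(2.0 * freq * (1.0 - freq))


def _aligned_effects(stats: SumStats, ld: LDReference) -> tuple[np.ndarray, ...]:
    """Per-allele effects oriented to the reference alleleA, with panel freqs.

    Returns (order of stats rows restricted to panel variants): cpaids, panel
    indices, beta (alleleA-oriented), se, n, panel freq.
    """
    df = stats.df[stats.df["cpaid"].isin(set(ld.cpaids))].reset_index(drop=True)
    idx = ld.indices(df["cpaid"].tolist())
    alleleA = df["cpaid"].str.rsplit(":", n=1).str[1].str.split("_").str[0]
    sign = np.where(df["ea"].to_numpy() == alleleA.to_numpy(), 1.0, -1.0)
    beta = df["beta"].to_numpy(float) * sign
    se = df["se"].to_numpy(float)
    n = df["n"].to_numpy(float)
    f = ld.freq[idx]
    eaf_A = np.where(sign > 0, df["eaf"].to_numpy(float), 1 - df["eaf"].to_numpy(float))
    if np.any(np.abs(f - eaf_A) > 0.1):
        worst = df["cpaid"].iloc[int(np.argmax(np.abs(f - eaf_A)))]
        warnings.warn(
            f"reference and GWAS allele frequencies differ by >0.1 (e.g. {worst})",
            stacklevel=3,
        )
    return df["cpaid"].to_numpy(), idx, beta, se, n, f, sign, df


def conditional_sumstats(stats: SumStats, ld: LDReference,
                         conditioning_set: list[str],
                         collinearity_cap: float = COLLINEARITY_CAP) -> SumStats:
    """Summary statistics for each variant conditioned on a set of variants.

    For variant i with conditioning set S: effects are standardized with
    reference frequencies, the joint model over S u {i} is solved through the
    reference correlation matrix, and the coefficient of i with its standard
    error (using a residual-variance estimate from the joint fit) is mapped
    back to the per-allele scale.  Variants whose squared multiple correlation
    with S exceeds ``collinearity_cap`` are returned with beta 0, se NaN and a
    ``collinear`` flag instead of an estimate.  An empty conditioning set
    returns the marginal statistics unchanged.
    """
    if not conditioning_set:
        return stats
    cpaids, idx, beta, se, n, f, sign, df = _aligned_effects(stats, ld)
    pos_of = {c: k for k, c in enumerate(cpaids)}
    missing = [c for c in conditioning_set if c not in pos_of]
    if missing:
        raise KeyError(f"conditioning variants absent from locus stats: {missing[:3]}")
    s_rows = np.array([pos_of[c] for c in conditioning_set], int)

    # empirical reference dosage SD when available, else Hardy-Weinberg
    if ld.dosage_var is not None:
        scale = np.sqrt(ld.dosage_var[idx])
    else:
        scale = _std_scale(f)
    b_std = beta * scale
    se_std = se * scale
    # per-variant phenotypic variance proxy; median over the locus for robustness
    var_y = float(np.median(n * se_std**2))

    iS = idx[s_rows]
    R_S = ld.R[np.ix_(iS, iS)]
    # guard against numerically singular conditioning sets
    cond = np.linalg.cond(R_S)
    if not np.isfinite(cond) or cond > 1e8:
        raise LDSingularError(
            f"conditioning-set LD matrix is numerically singular (cond={cond:.2e})"
        )
    R_S_inv = np.linalg.inv(R_S)
    b_S = b_std[s_rows]
    r_all = ld.R[np.ix_(idx, iS)]          # correlations of every variant with S
    proj = r_all @ R_S_inv                  # (m, |S|)
    h = np.einsum("ij,ij->i", proj, r_all)  # squared multiple correlation with S
    beta_given_S = b_std - proj @ b_S       # numerator of the conditional effect

    in_S = np.zeros(len(cpaids), bool)
    in_S[s_rows] = True
    collinear = (h > collinearity_cap) & ~in_S

    out = df.copy()
    out["collinear"] = collinear
    denom = 1.0 - h
    with np.errstate(divide="ignore", invalid="ignore"):
        b_joint = beta_given_S / denom      # joint-model coefficient of i
        # residual variance after fitting S u {i}: var_y minus explained
        explained_S = float(b_S @ R_S_inv @ b_S)
        expl_i = beta_given_S**2 / denom
        sigma2 = np.maximum(var_y - explained_S - expl_i, 0.05 * var_y)
        se_joint = np.sqrt(sigma2 / (n * denom))
    b_out = b_joint / scale * sign
    se_out = se_joint / scale
    keep = ~in_S & ~collinear
    out.loc[keep, "beta"] = b_out[keep]
    out.loc[keep, "se"] = se_out[keep]
    zabs = np.abs(b_joint / se_joint)
    out.loc[keep, "p"] = np.clip(2.0 * _st.norm.sf(zabs[keep]), np.nextafter(0, 1), 1.0)
    out.loc[collinear, "beta"] = 0.0
    out.loc[collinear, "p"] = 1.0
    out = out[~out["cpaid"].isin(set(conditioning_set))].reset_index(drop=True)
    return SumStats(out, trait=stats.trait, provenance="conditional")


def stepwise_signals(locus: Locus, stats: SumStats, ld: LDReference,
                     p_cond_threshold: float = GWS_THRESHOLD) -> list[Signal]:
    """Stepwise selection of independent signals at one locus.

    The locus lead is signal 1.  Conditioning on the current index variants,
    the smallest conditional-p variant is promoted whenever its conditional p
    is genome-wide significant, and the loop repeats.  Finally each signal's
    conditional statistics are recomputed conditioning on all *other* index
    variants, so that single-signal loci keep their marginal statistics.
    """
    locus_stats = stats.subset(
        stats.df.loc[(stats.df["chrom"] == locus.chrom)
                     & stats.df["pos"].between(locus.start, locus.end), "cpaid"]
    )
    if locus.lead_cpaid not in ld:
        raise KeyError(f"locus lead {locus.lead_cpaid} absent from LD reference")
    index_variants = [locus.lead_cpaid]
    while True:
        cond = conditional_sumstats(locus_stats, ld, index_variants)
        usable = cond.df[~cond.df.get("collinear", False).astype(bool)]
        if usable.empty:
            break
        best = usable.loc[usable["p"].idxmin()]
        if best["p"] < p_cond_threshold:
            index_variants.append(str(best["cpaid"]))
        else:
            break
    signals: list[Signal] = []
    for j, cp in enumerate(index_variants, start=1):
        others = [c for c in index_variants if c != cp]
        cstats = conditional_sumstats(locus_stats, ld, others) if others else locus_stats
        prow = cstats.df.loc[cstats.df["cpaid"] == cp, "p"]
        signals.append(Signal(
            signal_id=f"{locus.locus_id}.{j}", locus_id=locus.locus_id,
            index_cpaid=cp, conditioning_set=others, conditional_stats=cstats,
            order=j, index_p_cond=float(prow.iloc[0]) if len(prow) else np.nan,
        ))
    return signals


def wakefield_log_abf(beta, se, W: float = DEFAULT_W):
    """Wakefield log approximate Bayes factor in favour of association.

    log ABF = 0.5*log(se^2/(se^2+W)) + (z^2/2) * W/(se^2+W)  with z = beta/se.
    Monotone increasing in |z| at fixed se and W; tends to 0 as W -> 0.
    """
    beta = np.asarray(beta, float)
    se = np.asarray(se, float)
    if np.any(se <= 0):
        raise ValueError("se must be > 0")
    if W <= 0:
        raise ValueError("W must be > 0")
    v = se**2
    shrink = W / (v + W)
    z2 = (beta / se) ** 2
    out = 0.5 * np.log(v / (v + W)) + 0.5 * z2 * shrink
    return float(out) if out.ndim == 0 else out


def posterior_probabilities(log_abfs) -> np.ndarray:
    """Normalize log-ABFs to PPAs under a flat prior, in log space."""
    la = np.asarray(log_abfs, float)
    if la.size == 0:
        raise ValueError("no variants")
    return np.exp(la - logsumexp(la))


def credible_set(cpaids, ppa, mass: float = 0.99, signal_id: str = "",
                 p_cond=None, pos=None) -> CredibleSet:
    """Smallest PPA-ranked variant set with cumulative mass >= ``mass``.

    Ties in PPA at the boundary are broken by smaller conditional p, then by
    position (both optional); the cumulative threshold is inclusive.
    """
    ppa = np.asarray(ppa, float)
    if not np.isclose(ppa.sum(), 1.0, atol=1e-9):
        raise ValueError(f"PPAs must sum to 1, got {ppa.sum()!r}")
    m = len(ppa)
    p_cond = np.asarray(p_cond, float) if p_cond is not None else np.zeros(m)
    pos = np.asarray(pos) if pos is not None else np.arange(m)
    order = np.lexsort((pos, p_cond, -ppa))
    cum = np.cumsum(ppa[order])
    # shortest prefix reaching the mass (inclusive threshold)
    k = int(np.searchsorted(cum, mass - 1e-12)) + 1
    k = min(k, m)
    sel = order[:k]
    members = pd.DataFrame({
        "cpaid": np.asarray(cpaids)[sel],
        "ppa": ppa[sel],
        "cum_ppa": cum[:k],
    })
    return CredibleSet(signal_id=signal_id, members=members, mass=mass)


def credible_set_for_signal(signal: Signal,
                            config: CredibleConfig = CredibleConfig()) -> CredibleSet:
    """Wakefield fine-mapping of one signal from its conditional statistics."""
    df = signal.conditional_stats.df
    usable = df[~df.get("collinear", pd.Series(False, index=df.index)).astype(bool)]
    la = wakefield_log_abf(usable["beta"].to_numpy(), usable["se"].to_numpy(), config.W)
    ppa = posterior_probabilities(la)
    return credible_set(
        usable["cpaid"].to_numpy(), ppa, mass=config.mass,
        signal_id=signal.signal_id,
        p_cond=usable["p"].to_numpy(), pos=usable["pos"].to_numpy(),
    )
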