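"""Synthetic inputs with the statistical structure the pipeline assumes.

Everything the analysis consumes can be generated here under an explicit
seed: block-structured LD reference panels (Gaussian-copula genotypes),
multi-biomarker cohorts in which "kidney" causal effects propagate to
creatinine-based eGFR, cystatin-based eGFR (attenuated, same direction) and
blood urea nitrogen (opposite direction) while creatinine-specific effects
touch eGFRcrea only, per-study GWAS summary statistics with optional
genomic-control inflation, kidney-tissue-panel-scale eQTL datasets (n = 187),
gene-annotation / variant-relevance / phenotype-flag tables.

A lighter summary-statistic-level simulator (``simulate_summary_stats``)
draws marginal z-scores directly from the multivariate normal implied by the
LD matrix and the planted standardized effects — the standard generative
model for summary statistics — and is used where thousands of replicate
loci are needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _st

from .finemap import LDReference
from .gps import GeneAnnotation
from .sumstats import SumStats, make_cpaid

__all__ = [
    "SimConfig",
    "CausalVariant",
    "simulate_reference_panel",
    "prepare_phenotype",
    "simulate_multitrait_cohort",
    "run_study_gwas",
    "simulate_eqtl_dataset",
    "simulate_gene_annotation",
    "simulate_summary_stats",
    "default_scenario",
]

EQTL_SAMPLE_SIZE = 187  # scale of the kidney-tissue expression panels emulated


@dataclass(frozen=True)
class CausalVariant:
    """A planted causal variant: index into the panel plus its two effects.

    ``beta_kidney`` is shared kidney biology (propagates to all biomarkers),
    ``beta_crea`` is creatinine metabolism (touches eGFRcrea only); both on
    the per-allele log-phenotype scale.
    """

    index: int
    beta_kidney: float = 0.0
    beta_crea: float = 0.0


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the structure of the emulated meta-analysis at desk
    scale: two studies of 10,000 individuals, block LD with neighbour
    correlation 0.9, MAF in [0.05, 0.5] at causal-bearing blocks, phenotype
    noise variance 0.016 (the variance of age-/sex-adjusted log eGFR in a
    population-based reference), cystatin attenuation 0.8 and BUN reflection
    0.5, and mild genomic-control inflation (1.1) on the first study.
    """

    seed: int = 0
    n_per_study: tuple[int, ...] = (10_000, 10_000)
    block_sizes: tuple[int, ...] = (50, 50, 50)
    block_starts_bp: tuple[int, ...] = (10_000_000, 20_000_000, 30_000_000)
    spacing_bp: int = 5_000
    chrom: str = "1"
    neighbour_rho: float | tuple[float, ...] = 0.9  # scalar or per block
    maf_range: tuple[float, float] = (0.05, 0.5)
    causal: tuple[CausalVariant, ...] = ()
    cys_attenuation: float = 0.8   # a in cys = a * kidney genetic value
    bun_reflection: float = 0.5    # c in bun = -c * kidney genetic value
    noise_var: float = 0.016
    gc_lambda_study0: float = 1.1
    low_info_fraction: float = 0.0

    @property
    def n_variants(self) -> int:
        return int(sum(self.block_sizes))

    def __post_init__(self) -> None:
        if self.noise_var <= 0:
            raise ValueError("noise variance must be > 0")
        if len(self.block_starts_bp) != len(self.block_sizes):
            raise ValueError("one start position per block required")
        if isinstance(self.neighbour_rho, tuple) and \
                len(self.neighbour_rho) != len(self.block_sizes):
            raise ValueError("one neighbour_rho per block required")

    def rho_for_block(self, b: int) -> float:
        r = self.neighbour_rho
        return float(r[b]) if isinstance(r, tuple) else float(r)


def _block_corr(m: int, rho: float) -> np.ndarray:
    idx = np.arange(m)
    return rho ** np.abs(idx[:, None] - idx[None, :])


# Gauss-Legendre nodes/weights on [0, 1] for the tetrachoric integral
_GL_U, _GL_W = np.polynomial.legendre.leggauss(24)
_GL_U = (_GL_U + 1.0) / 2.0
_GL_W = _GL_W / 2.0


def _tetrachoric_cov(rho: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Cov(1{X>a}, 1{Y>b}) for standard bivariate normals at latent corr rho.

    Drezner form: (1/2pi) * int_0^rho exp(-(a^2 - 2tab + b^2)/(2(1-t^2)))
    / sqrt(1-t^2) dt, evaluated by fixed quadrature (vectorized over pairs).
    """
    t = rho[..., None] * _GL_U
    one_m = 1.0 - t**2
    integrand = np.exp(-(a[..., None]**2 - 2 * t * (a * b)[..., None]
                         + b[..., None]**2) / (2 * one_m)) / np.sqrt(one_m)
    return rho / (2 * np.pi) * (integrand * _GL_W).sum(axis=-1)


def _latent_corr(target_r: np.ndarray, f1: np.ndarray, f2: np.ndarray) -> np.ndarray:
    """Latent normal correlation giving dosage correlation ``target_r``.

    Haplotype indicators at frequencies f1, f2 need covariance
    target_r * sqrt(f1 q1 f2 q2); the monotone tetrachoric relation is
    inverted by a clipped Newton iteration.
    """
    a = _st.norm.ppf(1.0 - f1)
    b = _st.norm.ppf(1.0 - f2)
    want = target_r * np.sqrt(f1 * (1 - f1) * f2 * (1 - f2))
    # monotone in rho: vectorized bisection; saturates at the attainable
    # maximum when the target correlation is infeasible for these frequencies
    lo = np.full_like(want, -0.9999)
    hi = np.full_like(want, 0.9999)
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        too_low = _tetrachoric_cov(mid, a, b) < want
        lo = np.where(too_low, mid, lo)
        hi = np.where(too_low, hi, mid)
    return 0.5 * (lo + hi)


def _calibrated_block_corr(freqs: np.ndarray, rho: float) -> np.ndarray:
    """Latent correlation matrix whose thresholded dosages hit the target
    neighbour correlation.

    Each adjacent pair's latent correlation is calibrated exactly; longer-
    range latent correlations are products along the chain (a Gaussian
    Markov structure), which keeps the matrix positive definite by
    construction and yields approximately geometric dosage-correlation
    decay.
    """
    m = len(freqs)
    if rho == 0.0 or m == 1:
        return np.eye(m)
    adj = _latent_corr(np.full(m - 1, rho), freqs[:-1], freqs[1:])
    # cumulative log-products give latent corr between any pair via the chain
    logs = np.concatenate([[0.0], np.cumsum(np.log(np.clip(adj, 1e-6, 1.0)))])
    lat = np.exp(-np.abs(logs[:, None] - logs[None, :]))
    np.fill_diagonal(lat, 1.0)
    return lat


def panel_layout(config: SimConfig) -> tuple[list[str], np.ndarray, np.ndarray]:
    """cpaids, positions and target allele frequencies for the panel.

    Frequencies are drawn around a per-block base with a small jitter:
    tightly linked variants share haplotypes and hence frequencies, and a
    high correlation target is only attainable between variants of similar
    frequency.
    """
    rng = np.random.default_rng(config.seed)
    cpaids, positions, freqs = [], [], []
    lo, hi = config.maf_range
    for start, size in zip(config.block_starts_bp, config.block_sizes):
        base = rng.uniform(lo, hi)
        for j in range(size):
            pos = start + j * config.spacing_bp
            positions.append(pos)
            cpaids.append(make_cpaid(config.chrom, pos, "A", "G"))
            freqs.append(np.clip(base + rng.uniform(-0.03, 0.03),
                                 max(lo, 0.01), max(hi, 0.02)))
    return cpaids, np.array(positions), np.array(freqs)


def simulate_genotypes(config: SimConfig, n: int,
                       rng: np.random.Generator) -> np.ndarray:
    """Gaussian-copula genotype dosages (n x variants) in Hardy-Weinberg.

    Two latent haplotypes per individual are drawn per LD block from a
    multivariate normal and thresholded at the allele-frequency quantile; the
    dosage is their sum, so within-block haplotype correlations carry over to
    dosages while blocks stay independent.  The latent correlations are
    calibrated (inverse tetrachoric) so that the *dosage* correlations match
    the neighbour-decay target rather than being attenuated by thresholding.
    """
    _, _, freqs = panel_layout(config)
    cols = []
    offset = 0
    for b, size in enumerate(config.block_sizes):
        C = _calibrated_block_corr(freqs[offset:offset + size],
                                   config.rho_for_block(b))
        L = np.linalg.cholesky(C)
        f = freqs[offset:offset + size]
        thresh = _st.norm.ppf(1.0 - f)
        h1 = (rng.standard_normal((n, size)) @ L.T > thresh).astype(np.int8)
        h2 = (rng.standard_normal((n, size)) @ L.T > thresh).astype(np.int8)
        cols.append((h1 + h2).astype(np.float64))
        offset += size
    return np.hstack(cols)


def simulate_reference_panel(config: SimConfig, n_ref: int = 5_000
                             ) -> tuple[np.ndarray, LDReference]:
    """Reference genotype dosages and the LDReference computed from them."""
    rng = np.random.default_rng((config.seed, 1))
    X = simulate_genotypes(config, n_ref, rng)
    cpaids, _, _ = panel_layout(config)
    mono = X.std(axis=0) == 0
    if mono.any():
        raise ValueError(f"monomorphic reference variant(s) at indices "
                         f"{np.flatnonzero(mono)[:3].tolist()}; increase n_ref or MAF")
    # dosages count the alternate (G) allele of every A/G panel variant
    counted = [c.rsplit(":", 1)[1].split("_")[1] for c in cpaids]
    return X, LDReference.from_dosages(cpaids, X, counted_alleles=counted)


def prepare_phenotype(raw: np.ndarray, kind: str) -> np.ndarray:
    """Transform raw phenotype units to the analysis (natural-log) scale.

    ``egfr``: winsorize at [15, 200] ml/min/1.73m^2 then log.
    ``bun_from_urea``: urea mg/dL * 2.8 -> BUN, then log.
    """
    raw = np.asarray(raw, float)
    if kind == "egfr":
        return np.log(np.clip(raw, 15.0, 200.0))
    if kind == "bun_from_urea":
        if np.any(raw <= 0):
            raise ValueError("urea values must be positive")
        return np.log(raw * 2.8)
    raise ValueError(f"unknown phenotype kind {kind!r}")


def simulate_multitrait_cohort(genotypes: np.ndarray, config: SimConfig,
                               rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Log-scale eGFRcrea / eGFRcys / BUN phenotypes for one cohort.

    Genetic values: g_kidney from the kidney effects, g_crea from the
    creatinine-specific effects.  crea = g_kidney + g_crea + noise;
    cys = a * g_kidney + noise; bun = -c * g_kidney + noise.
    """
    n = genotypes.shape[0]
    g_kid = np.zeros(n)
    g_crea = np.zeros(n)
    for cv in config.causal:
        x = genotypes[:, cv.index]
        g_kid += cv.beta_kidney * x
        g_crea += cv.beta_crea * x
    sd = np.sqrt(config.noise_var)
    return {
        "crea": g_kid + g_crea + rng.normal(0, sd, n),
        "cys": config.cys_attenuation * g_kid + rng.normal(0, sd, n),
        "bun": -config.bun_reflection * g_kid + rng.normal(0, sd, n),
        "genetic_crea": g_kid + g_crea,
        "genetic_kidney": g_kid,
    }


def run_study_gwas(genotypes: np.ndarray, phenotype: np.ndarray,
                   cpaids: list[str], positions: np.ndarray, chrom: str,
                   covariates: np.ndarray | None = None,
                   trait: str = "", info: np.ndarray | None = None,
                   gc_lambda: float = 1.0) -> SumStats:
    """Per-variant additive OLS scan producing a summary-statistics table.

    Phenotype and genotypes are residualized on the covariates (plus an
    intercept) and the per-variant slope, SE and two-sided Wald p are
    computed in closed form.  ``gc_lambda`` > 1 emulates uncorrected
    population-stratification inflation by shrinking reported SEs by
    sqrt(lambda).  Zero-variance genotype columns are dropped with a warning
    entry in the table's provenance.
    """
    y = np.asarray(phenotype, float)
    X = np.asarray(genotypes, float)
    n = len(y)
    if covariates is None:
        C = np.ones((n, 1))
    else:
        C = np.column_stack([np.ones(n), np.asarray(covariates, float)])
    Q, _ = np.linalg.qr(C)
    y_r = y - Q @ (Q.T @ y)
    X_r = X - Q @ (Q.T @ X)
    xx = np.einsum("ij,ij->j", X_r, X_r)
    # columns residualized to (numerical) zero variance are dropped
    keep = xx > 1e-9 * n
    xy = y_r @ X_r
    dof = n - C.shape[1] - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = xy / xx
        rss = (y_r @ y_r) - beta * xy
        se = np.sqrt(np.maximum(rss, 0) / dof / xx)
    if gc_lambda > 1.0:
        se = se / np.sqrt(gc_lambda)
    with np.errstate(invalid="ignore"):
        p = np.clip(2.0 * _st.norm.sf(np.abs(beta / se)), np.nextafter(0, 1), 1.0)
    eaf = X.mean(axis=0) / 2.0
    df = pd.DataFrame({
        "cpaid": cpaids, "chrom": str(chrom), "pos": positions,
        "ea": "G", "oa": "A",  # dosages count the alternate (G) allele
        "eaf": eaf, "beta": beta, "se": se, "p": p, "n": float(n),
        "info": 1.0 if info is None else info,
    })
    dropped = int((~keep).sum())
    df = df[keep].copy()
    prov = f"simulated gwas ({dropped} monomorphic dropped)" if dropped else "simulated gwas"
    return SumStats(df, trait=trait, provenance=prov)


def simulate_eqtl_dataset(config: SimConfig, gene_effects: dict[str, dict],
                          n: int = EQTL_SAMPLE_SIZE,
                          seed_salt: int = 7) -> pd.DataFrame:
    """Long-format eQTL association tables per (gene, tissue).

    ``gene_effects`` maps gene id -> {"tissue": str, "causal_index": int,
    "delta": float, "variant_indices": list[int]} where ``variant_indices``
    restricts the table to the gene's cis window (defaults to all panel
    variants).  Expression = dosage * delta + standard-normal noise.
    """
    rng = np.random.default_rng((config.seed, seed_salt))
    cpaids, positions, _ = panel_layout(config)
    frames = []
    for gene, spec in gene_effects.items():
        G = simulate_genotypes(config, n, rng)
        y = rng.standard_normal(n)
        if spec.get("delta", 0.0) != 0.0:
            y = y + spec["delta"] * G[:, spec["causal_index"]]
        idx = spec.get("variant_indices")
        idx = np.arange(config.n_variants) if idx is None else np.asarray(idx, int)
        stats = run_study_gwas(G[:, idx], y, [cpaids[i] for i in idx],
                               positions[idx], config.chrom, trait="expression")
        d = stats.df.copy()
        d["gene"] = gene
        d["tissue"] = spec.get("tissue", "tubulointerstitial")
        frames.append(d[["gene", "tissue", "cpaid", "ea", "oa",
                         "beta", "se", "p", "n", "eaf"]])
    return pd.concat(frames, ignore_index=True)


def simulate_gene_annotation(config: SimConfig,
                             genes: list[dict] | None = None,
                             protein_variants: dict[str, tuple[float, int, str]] | None = None,
                             mouse_genes: list[str] = (),
                             human_genes: list[str] = (),
                             ) -> tuple[list[GeneAnnotation], pd.DataFrame, pd.DataFrame]:
    """Gene intervals, a variant-relevance table and phenotype-flag tables.

    Without an explicit gene list, one gene is tiled over each LD block
    (covering the block's span plus a margin).  ``protein_variants`` maps
    cpaid -> (cadd_phred, cons_score, gene_id) for variants to mark as
    protein-relevant candidates.
    """
    if genes is None:
        genes = []
        for b, (start, size) in enumerate(zip(config.block_starts_bp,
                                              config.block_sizes)):
            span = (size - 1) * config.spacing_bp
            genes.append({
                "gene_id": f"GENE_{chr(65 + b)}", "symbol": f"GENE_{chr(65 + b)}",
                "chrom": config.chrom,
                "start": start - 10_000, "end": start + span + 10_000,
                "n_indep_variants": size,
            })
    annotations = [GeneAnnotation(**g) for g in genes]
    rows = []
    for cpaid, (cadd, cons, gene) in (protein_variants or {}).items():
        rows.append({"cpaid": cpaid, "evidence": "protein", "gene": gene,
                     "tissue": np.nan, "cadd_phred": cadd, "cons_score": cons,
                     "fdr": np.nan})
    relevance = pd.DataFrame(
        rows, columns=["cpaid", "evidence", "gene", "tissue",
                       "cadd_phred", "cons_score", "fdr"])
    flags = pd.DataFrame(
        [{"gene": g, "source": "mouse"} for g in mouse_genes]
        + [{"gene": g, "source": "human"} for g in human_genes],
        columns=["gene", "source"])
    return annotations, relevance, flags


def simulate_summary_stats(R: np.ndarray, freqs: np.ndarray,
                           causal_idx, causal_beta_std, n: int,
                           rng: np.random.Generator,
                           cpaids: list[str] | None = None,
                           positions: np.ndarray | None = None,
                           chrom: str = "1", sigma_y: float = 1.0) -> SumStats:
    """Marginal summary statistics drawn at the summary level.

    Standardized marginal effects follow b*_marg = R @ b*_joint with sampling
    noise: z ~ MVN(sqrt(n) * R @ b_std, R) where b_std is in per-genotype-SD,
    per-phenotype-SD units; per-allele beta and se are recovered with the
    phenotype SD ``sigma_y`` and the Hardy-Weinberg genotype SD
    sqrt(2 f (1-f)).
    """
    m = R.shape[0]
    b = np.zeros(m)
    b[np.asarray(causal_idx, int)] = np.asarray(causal_beta_std, float)
    mean = np.sqrt(n) * (R @ b)
    L = np.linalg.cholesky(R + 1e-10 * np.eye(m))
    z = mean + L @ rng.standard_normal(m)
    scale = np.sqrt(2.0 * freqs * (1.0 - freqs))
    se = sigma_y / (np.sqrt(n) * scale)
    beta = z * se
    p = np.clip(2.0 * _st.norm.sf(np.abs(z)), np.nextafter(0, 1), 1.0)
    if cpaids is None:
        positions = np.arange(m) * 5_000 + 1_000_000
        cpaids = [make_cpaid(chrom, int(pp), "A", "G") for pp in positions]
    df = pd.DataFrame({
        "cpaid": cpaids, "chrom": chrom, "pos": positions,
        "ea": "G", "oa": "A", "eaf": freqs, "beta": beta, "se": se,
        "p": p, "n": float(n), "info": 1.0,
    })
    return SumStats(df, trait="eGFRcrea", provenance="summary-level simulation")


def default_scenario() -> SimConfig:
    """The standard seeded end-to-end scenario.

    Three causal LD blocks of 50 variants: block A carries one kidney causal
    variant, block B two (in low mutual LD, r ~ 0.1), block C one
    creatinine-specific causal variant.  Three additional null blocks of 150
    variants stand in for the rest of the genome so that the genomic-control
    inflation factor is estimated over predominantly null statistics, as in a
    genome-wide scan.  Effect sizes give every signal overwhelming power at
    the combined n = 20,000.
    """
    return SimConfig(
        seed=20_21,
        block_sizes=(50, 50, 50, 450, 450, 450),
        block_starts_bp=(10_000_000, 20_000_000, 30_000_000,
                         50_000_000, 60_000_000, 70_000_000),
        neighbour_rho=(0.9, 0.9, 0.9, 0.2, 0.2, 0.2),
        causal=(
            CausalVariant(index=15, beta_kidney=0.020),            # block A
            CausalVariant(index=60, beta_kidney=0.020),            # block B, signal 1
            CausalVariant(index=85, beta_kidney=0.018),            # block B, signal 2
            CausalVariant(index=125, beta_crea=0.020),             # block C, crea-only
        ),
    )
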