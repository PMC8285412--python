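"""Seeded benchmark routines measuring the pipeline against its oracles.

Each function sets up a synthetic experiment, runs the corresponding module,
and returns the measured quantity: oracle agreement for the conditional
estimator and the meta-analysis, frequentist coverage of the 99% credible
sets, discrimination of the colocalization posteriors, calibration of the
matched-resampling enrichment test, and the partition property of the locus
algorithm.  Problem sizes are desk scale and documented in the methods note.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .coloc import ColocPriors, coloc_abf
from .enrichment import SpecificitySets, matched_resampling_enrichment
from .finemap import (
    LDReference,
    conditional_sumstats,
    credible_set,
    posterior_probabilities,
    wakefield_log_abf,
)
from .loci import define_loci
from .meta import ivw_meta
from .simulate import (
    CausalVariant,
    SimConfig,
    panel_layout,
    run_study_gwas,
    simulate_genotypes,
    simulate_summary_stats,
)
from .sumstats import SumStats

LOG_EGFR_SD = 0.126  # sqrt of the population-reference phenotype variance 0.016


def conditional_oracle_error(seed: int = 0,
                             configs=((50, 1), (100, 2), (200, 3)),
                             n: int = 5_000) -> dict:
    """Worst relative deviation of summary-stat conditional estimates from
    exact joint OLS, using the analysis sample as its own LD reference.

    For each (variant count, causal count) configuration a cohort is
    simulated, the first causal is conditioned on, and every remaining
    variant's conditional beta/SE is compared against the multiple
    regression on individual-level data.  Relative error on beta is taken
    against max(|beta|, SE) so that null effects do not divide by zero.
    """
    rng = np.random.default_rng((seed, 31))
    worst_beta = worst_se = 0.0
    for m, k in configs:
        cfg = SimConfig(seed=seed + m, block_sizes=(m,),
                        block_starts_bp=(10_000_000,))
        G = simulate_genotypes(cfg, n, rng)
        cpaids, pos, _ = panel_layout(cfg)
        causal_idx = rng.choice(m, size=k, replace=False)
        y = rng.normal(0, LOG_EGFR_SD, n)
        for i in causal_idx:
            y = y + rng.uniform(0.015, 0.03) * G[:, i]
        stats = run_study_gwas(G, y, cpaids, pos, "1")
        counted = [c.rsplit(":", 1)[1].split("_")[1] for c in cpaids]
        ld = LDReference.from_dosages(cpaids, G, counted_alleles=counted)
        cond_on = int(causal_idx[0])
        cond = conditional_sumstats(stats, ld, [cpaids[cond_on]])
        x_c = G[:, cond_on]
        for _, row in cond.df.iterrows():
            if row["collinear"]:
                continue
            i = cpaids.index(row["cpaid"])
            fit = sm.OLS(y, sm.add_constant(
                np.column_stack([G[:, i], x_c]))).fit()
            b_ref, se_ref = fit.params[1], fit.bse[1]
            worst_beta = max(worst_beta,
                             abs(row["beta"] - b_ref) / max(abs(b_ref), se_ref))
            worst_se = max(worst_se, abs(row["se"] - se_ref) / se_ref)
    return {"max_rel_err_beta": worst_beta, "max_rel_err_se": worst_se,
            "n": n}


def credible_set_coverage(seed: int = 0, n_sim: int = 500,
                          n_gwas: int = 100_000) -> dict:
    """Fraction of single-causal simulations whose planted variant lands in
    the 99% credible set.

    Loci of 100-500 variants with geometric LD decay; marginal statistics
    drawn from the exact summary-level model; Wakefield fine-mapping with
    W = 0.005^2 on the log-phenotype scale.
    """
    rng = np.random.default_rng((seed, 32))
    chol_cache: dict[int, np.ndarray] = {}
    hits = 0
    for s in range(n_sim):
        m = int(rng.choice([100, 200, 300, 500]))
        if m not in chol_cache:
            R = 0.95 ** np.abs(np.subtract.outer(np.arange(m), np.arange(m)))
            chol_cache[m] = R
        R = chol_cache[m]
        freqs = rng.uniform(0.05, 0.5, m)
        causal = int(rng.integers(m))
        z_target = rng.uniform(6, 12)
        stats = simulate_summary_stats(
            R, freqs, [causal], [z_target / np.sqrt(n_gwas)], n_gwas, rng,
            sigma_y=LOG_EGFR_SD)
        la = wakefield_log_abf(stats.df["beta"].to_numpy(),
                               stats.df["se"].to_numpy(), 0.005**2)
        ppa = posterior_probabilities(la)
        cs = credible_set(stats.df["cpaid"].to_numpy(), ppa,
                          p_cond=stats.df["p"].to_numpy(),
                          pos=stats.df["pos"].to_numpy())
        hits += stats.df["cpaid"].iloc[causal] in cs
    return {"coverage": hits / n_sim, "n": n_sim}


def meta_equivalence_error(seed: int = 0, n_total: int = 8_000,
                           n_studies: int = 2, m: int = 60) -> dict:
    """IVW meta of a study-split cohort versus pooled per-variant OLS.

    The same synthetic cohort is analysed whole and split into equal
    studies; the worst relative difference of the meta-analysed effect from
    the pooled estimate is reported over variants with non-trivial effects.
    """
    rng = np.random.default_rng((seed, 33))
    cfg = SimConfig(seed=seed + 77, block_sizes=(m,),
                    block_starts_bp=(10_000_000,))
    G = simulate_genotypes(cfg, n_total, rng)
    cpaids, pos, _ = panel_layout(cfg)
    y = 0.02 * G[:, 10] + 0.02 * G[:, 40] + rng.normal(0, LOG_EGFR_SD, n_total)
    pooled = run_study_gwas(G, y, cpaids, pos, "1")
    splits = np.array_split(np.arange(n_total), n_studies)
    studies = [run_study_gwas(G[ix], y[ix], cpaids, pos, "1") for ix in splits]
    meta = ivw_meta(studies)
    merged = pooled.df.merge(meta.df, on="cpaid", suffixes=("_pool", "_meta"))
    denom = np.maximum(np.abs(merged["beta_pool"]), merged["se_pool"])
    err_b = (np.abs(merged["beta_meta"] - merged["beta_pool"]) / denom).max()
    err_se = (np.abs(merged["se_meta"] - merged["se_pool"])
              / merged["se_pool"]).max()
    return {"max_rel_err_beta": float(err_b), "max_rel_err_se": float(err_se),
            "n": n_total}


def coloc_discrimination(seed: int = 0, m: int = 60,
                         n_gwas: int = 100_000, n_eqtl: int = 187) -> dict:
    """PP_H4 under a shared causal variant and PP_H3 under distinct ones."""
    rng = np.random.default_rng((seed, 34))
    R = 0.9 ** np.abs(np.subtract.outer(np.arange(m), np.arange(m)))
    freqs = np.full(m, 0.3)
    shared = m // 2
    s1 = simulate_summary_stats(R, freqs, [shared], [9.0 / np.sqrt(n_gwas)],
                                n_gwas, rng, sigma_y=LOG_EGFR_SD)
    s2 = simulate_summary_stats(R, freqs, [shared], [8.0 / np.sqrt(n_eqtl)],
                                n_eqtl, rng)
    pp_h4_shared = coloc_abf(s1, s2).pp_h4
    # distinct causal variants at opposite block ends: r^2 < 0.1
    s3 = simulate_summary_stats(R, freqs, [2], [9.0 / np.sqrt(n_gwas)],
                                n_gwas, rng, sigma_y=LOG_EGFR_SD)
    s4 = simulate_summary_stats(R, freqs, [m - 3], [8.0 / np.sqrt(n_eqtl)],
                                n_eqtl, rng)
    pp_h3_distinct = float(coloc_abf(s3, s4).pp[3])
    # swap symmetry under p1 = p2
    pri = ColocPriors(p1=1e-4, p2=1e-4, W1=0.01, W2=0.01)
    a, b = coloc_abf(s1, s4, pri), coloc_abf(s4, s1, pri)
    swap_err = float(max(abs(a.pp[1] - b.pp[2]), abs(a.pp[2] - b.pp[1]),
                         abs(a.pp[4] - b.pp[4])))
    return {"pp_h4_shared": float(pp_h4_shared),
            "pp_h3_distinct": pp_h3_distinct,
            "swap_symmetry_error": swap_err, "n": m}


def enrichment_calibration(seed: int = 0, n_rep: int = 400, M: int = 2_000,
                           n_genes: int = 2_000, n_cand: int = 100) -> dict:
    """Type-I error of the matched-resampling test under its own null.

    Candidate lists are drawn by the matched null sampler itself, so the
    nominal rejection rate at p < 0.05 should be attained up to the
    discreteness of the add-one estimator.  The universe and candidate-list
    sizes are chosen so the null overlap distribution is fine-grained enough
    (expected overlap ~10) that discreteness does not dominate the rate.
    """
    rng = np.random.default_rng((seed, 35))
    genes = [f"g{i:04d}" for i in range(n_genes)]
    length = dict(zip(genes, np.exp(rng.normal(10, 1, n_genes))))
    nvar = dict(zip(genes, rng.poisson(20, n_genes) + 1.0))
    tissue_set = set(rng.choice(genes, n_genes // 10, replace=False))
    sets = SpecificitySets(sets={"T": tissue_set}, universe=genes)
    rejections = 0
    for _ in range(n_rep):
        cand = list(rng.choice(genes, n_cand, replace=False))
        res = matched_resampling_enrichment(cand, sets, length, nvar,
                                            M=M, seed=rng)
        rejections += res[0].p < 0.05
    return {"rejection_rate": rejections / n_rep, "n": n_rep}


def locus_partition_check(seed: int = 0, n_cases: int = 1_000) -> dict:
    """Randomized locus configurations: disjointness + exact GWS partition."""
    rng = np.random.default_rng((seed, 36))
    failures = 0
    for _ in range(n_cases):
        k = int(rng.integers(1, 30))
        positions = np.sort(rng.choice(np.arange(1, 400) * 100_000, size=k,
                                       replace=False))
        pvals = 10.0 ** rng.uniform(-30, 0, k)
        df = pd.DataFrame({
            "cpaid": [f"1:{p}:A_G" for p in positions], "chrom": "1",
            "pos": positions, "ea": "A", "oa": "G", "eaf": 0.3,
            "beta": 0.01, "se": 0.002, "p": pvals, "n": 1e5, "info": 1.0,
        })
        loci = define_loci(SumStats(df))
        gws = {f"1:{p}:A_G" for p, q in zip(positions, pvals) if q < 5e-8}
        assigned = [c for l in loci for c in l.gws_cpaids]
        ok = sorted(assigned) == sorted(gws)
        for a in loci:
            for b in loci:
                if a is not b and not (a.end < b.start or b.end < a.start):
                    ok = False
        failures += not ok
    return {"failures": failures, "n": n_cases}
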