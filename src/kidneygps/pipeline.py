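"""End-to-end run of the post-GWAS pipeline on the standard synthetic scenario.

This wires the modules together the way the emulated study does: per-study
GWAS -> QC -> genomic control -> inverse-variance meta-analysis -> locus
definition -> stepwise conditional signals -> credible sets -> biomarker
validation -> eQTL colocalization -> gene prioritisation.  It exists for
integration testing and for the worked examples; each stage is equally
usable on its own.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import coloc as _coloc
from . import meta as _meta
from .finemap import CredibleConfig, credible_set_for_signal, stepwise_signals
from .gps import build_gps, eqtl_fdr_annotation, gps_query
from .loci import classify_loci, define_loci
from .simulate import (
    SimConfig,
    default_scenario,
    panel_layout,
    run_study_gwas,
    simulate_eqtl_dataset,
    simulate_gene_annotation,
    simulate_genotypes,
    simulate_multitrait_cohort,
    simulate_reference_panel,
)
from .validation import validate_lead_variant, validation_summary


@dataclass
class PipelineResult:
    config: SimConfig
    meta: object
    loci: list
    signals: list
    credsets: dict
    validation_results: list
    validation_counts: dict
    coloc_results: list
    gps_by_signal: pd.DataFrame
    gps_by_locus: pd.DataFrame
    gps_hits: pd.DataFrame
    cpaids: list
    truth_cpaids: list


def run_pipeline(config: SimConfig | None = None,
                 gene_effects: dict | None = None,
                 known_regions: list | None = None) -> PipelineResult:
    """Run the full pipeline on a synthetic scenario; see module docstring."""
    config = config or default_scenario()
    rng = np.random.default_rng((config.seed, 2))
    cpaids, positions, _ = panel_layout(config)
    truth = [cpaids[cv.index] for cv in config.causal]

    # per-study cohorts and GWAS for the three biomarkers
    per_study: dict[str, list] = {"crea": [], "cys": [], "bun": []}
    for k, n in enumerate(config.n_per_study):
        G = simulate_genotypes(config, n, rng)
        phen = simulate_multitrait_cohort(G, config, rng)
        lam = config.gc_lambda_study0 if k == 0 else 1.0
        for trait in ("crea", "cys", "bun"):
            stats = run_study_gwas(G, phen[trait], cpaids, positions,
                                   config.chrom, trait=trait, gc_lambda=lam)
            stats, _ = _meta.apply_qc_filters(stats, stage="pre_meta")
            if lam > 1.0:
                lam_hat = _meta.genomic_control_lambda(stats)
                stats = _meta.gc_correct(stats, lam_hat)
            per_study[trait].append(stats)

    metas = {t: _meta.ivw_meta(per_study[t], trait=t) for t in per_study}
    meta_crea, _ = _meta.apply_qc_filters(metas["crea"], stage="post_meta")

    # loci and conditional signals against a fresh reference panel
    loci = define_loci(meta_crea)
    loci = classify_loci(loci, known_regions or [])
    _, ld = simulate_reference_panel(config)
    signals = []
    for locus in loci:
        signals.extend(stepwise_signals(locus, meta_crea, ld))
    credsets = {s.signal_id: credible_set_for_signal(s, CredibleConfig())
                for s in signals}

    # biomarker validation of locus leads
    vres = []
    for locus in loci:
        crea = meta_crea.get(locus.lead_cpaid)
        cys = _get_or_none(metas["cys"], locus.lead_cpaid)
        bun = _get_or_none(metas["bun"], locus.lead_cpaid)
        vres.append(validate_lead_variant(crea, cys, bun))
    vcounts = validation_summary(vres)
    validated = {l.locus_id: r.validated for l, r in zip(loci, vres)}

    # eQTL data, FDR annotation and colocalization
    if gene_effects is None:
        gene_effects = {
            "GENE_A": {"tissue": "tubulointerstitial", "delta": 1.0,
                       "causal_index": config.causal[0].index,
                       "variant_indices": list(range(config.block_sizes[0]))},
        }
    eqtl = simulate_eqtl_dataset(config, gene_effects)
    hits = eqtl_fdr_annotation(eqtl.rename(columns={"p": "p"}))
    coloc_results = []
    for sig in signals:
        res, _ = _coloc.coloc_per_signal(sig, eqtl)
        coloc_results.extend(res)

    # gene prioritisation
    genes, relevance, flags = simulate_gene_annotation(
        config,
        protein_variants={truth[2]: (25.0, 8, "GENE_B")},
        mouse_genes=["GENE_A"],
    )
    eq_rows = hits.assign(evidence="eqtl", cadd_phred=np.nan, cons_score=np.nan)
    relevance = pd.concat(
        [relevance, eq_rows[["cpaid", "evidence", "gene", "tissue",
                             "cadd_phred", "cons_score", "fdr"]]],
        ignore_index=True)
    by_signal, by_locus = build_gps(loci, signals, credsets, genes, relevance,
                                    flags, validated)
    gps_hits = gps_query(
        by_signal,
        filters={"validated": True},
        weights={"protein_relevant": 1.0, "kidney_regulatory": 1.0},
        min_score=1.0,
    )
    return PipelineResult(
        config=config, meta=meta_crea, loci=loci, signals=signals,
        credsets=credsets, validation_results=vres, validation_counts=vcounts,
        coloc_results=coloc_results, gps_by_signal=by_signal,
        gps_by_locus=by_locus, gps_hits=gps_hits, cpaids=cpaids,
        truth_cpaids=truth,
    )


def _get_or_none(stats, cpaid):
    try:
        return stats.get(cpaid)
    except KeyError:
        return None
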