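"""Gene PrioritiSation (GPS): candidate genes, variant relevance, scoring.

Every gene overlapping a locus region is a candidate.  Credible-set variants
annotate candidates through two evidence channels: predicted protein impact
(a CADD-like PHRED score >= 15 for a variant inside the gene, bucketed by the
consequence score) and regulatory impact (eQTL/sQTL hits at FDR < 0.05 for a
gene inside the same locus, split into kidney vs other tissue).  Gene-level
phenotype evidence (mouse / human kidney phenotype flags) is consumed as
precompiled tables.  Rows carry binary indicators; the score is a
user-weighted sum of indicators, queried with hard filters and a minimum
score, in gene-by-signal and gene-by-locus views.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .loci import Locus

__all__ = [
    "GeneAnnotation",
    "candidate_genes",
    "classify_cadd_consequence",
    "eqtl_fdr_annotation",
    "build_gps",
    "gps_query",
    "CADD_THRESHOLD",
    "FEATURES",
]

CADD_THRESHOLD = 15.0

FEATURES = (
    "protein_relevant",
    "kidney_regulatory",
    "other_regulatory",
    "mouse_kidney_phenotype",
    "human_kidney_phenotype",
)


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene interval (1-based, closed) with enrichment-matching covariates."""

    gene_id: str
    symbol: str
    chrom: str
    start: int
    end: int
    n_indep_variants: int = 0

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start > end")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def candidate_genes(locus: Locus, genes: list[GeneAnnotation]) -> list[GeneAnnotation]:
    """Genes whose interval shares >= 1 bp with the locus (closed intervals)."""
    return [g for g in genes
            if g.chrom == locus.chrom and g.start <= locus.end and g.end >= locus.start]


def classify_cadd_consequence(cadd_phred: float, cons_score: int,
                              within_gene: str | None) -> str:
    """Bucket a deleterious within-gene variant by its consequence score.

    Consequence scores 8/7 are protein-altering (stop gained/lost,
    non-synonymous), 6/5 splice/synonymous-class, 4-0 "other".  Variants
    below the CADD threshold or outside any gene get "none".
    """
    if not 0 <= int(cons_score) <= 8:
        raise ValueError(f"cons_score must be in 0..8, got {cons_score}")
    if within_gene is None or cadd_phred < CADD_THRESHOLD:
        return "none"
    if cons_score >= 7:
        return "protein_altering"
    if cons_score >= 5:
        return "splice_synonymous"
    return "other"


def eqtl_fdr_annotation(assoc: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Benjamini-Hochberg FDR per tissue over all variant x gene tests.

    ``assoc`` needs columns cpaid, gene, tissue, p.  Returns the rows with
    FDR < alpha, with an added ``fdr`` column (the BH-adjusted p-value after
    the standard cumulative-minimum step).
    """
    out = []
    for tissue, grp in assoc.groupby("tissue", sort=True):
        fdr = multipletests(grp["p"].to_numpy(float), method="fdr_bh")[1]
        g = grp.copy()
        g["fdr"] = fdr
        out.append(g[g["fdr"] < alpha])
    if not out:
        return assoc.iloc[0:0].assign(fdr=np.nan)
    return pd.concat(out, ignore_index=True)


def _variant_gene_evidence(credset_members: pd.DataFrame,
                           relevance: pd.DataFrame,
                           locus_gene_ids: set[str],
                           kidney_tissues: set[str]) -> pd.DataFrame:
    """Per (gene, evidence) rows for one signal's credible variants.

    ``relevance`` columns: cpaid, cadd_phred, cons_score, within_gene (may be
    NA), plus optional eqtl hit columns gene, tissue, fdr stacked long-form in
    a companion frame.  Here ``relevance`` is the combined long-form table
    with an ``evidence`` column in {protein, eqtl, sqtl}.
    """
    cred = set(credset_members["cpaid"])
    ppa_of = dict(zip(credset_members["cpaid"], credset_members["ppa"]))
    rows = []
    for r in relevance.itertuples(index=False):
        if r.cpaid not in cred:
            continue
        if r.evidence == "protein":
            group = classify_cadd_consequence(r.cadd_phred, int(r.cons_score),
                                              r.gene if pd.notna(r.gene) else None)
            if group == "none" or r.gene not in locus_gene_ids:
                continue
            rows.append({"gene": r.gene, "feature": "protein_relevant",
                         "ppa": ppa_of[r.cpaid], "detail": group})
        else:  # eqtl / sqtl hit, already FDR-filtered; cis constraint applies
            if r.gene not in locus_gene_ids:
                continue
            feat = ("kidney_regulatory" if r.tissue in kidney_tissues
                    else "other_regulatory")
            rows.append({"gene": r.gene, "feature": feat,
                         "ppa": ppa_of[r.cpaid], "detail": r.tissue})
    return pd.DataFrame(rows, columns=["gene", "feature", "ppa", "detail"])


def build_gps(loci: list[Locus], signals: list, credsets: dict,
              genes: list[GeneAnnotation], relevance: pd.DataFrame,
              phenotype_flags: pd.DataFrame, validation: dict[str, bool],
              kidney_tissues: set[str] = frozenset({"tubulointerstitial",
                                                    "glomerular", "kidney"})
              ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assemble the gene-by-signal and gene-by-locus GPS views.

    Parameters
    ----------
    credsets : mapping signal_id -> CredibleSet
    relevance : long-form evidence table with columns
        cpaid, evidence ('protein'|'eqtl'|'sqtl'), gene, tissue,
        cadd_phred, cons_score (protein rows), fdr (eqtl/sqtl rows, already
        FDR-significant).
    phenotype_flags : columns gene, source ('mouse'|'human').
    validation : mapping locus_id -> validated flag (eGFRcys/BUN support).

    Every candidate gene is listed for every signal of its locus, with all
    indicators zero when no evidence maps to it.  The locus view aggregates
    indicators by OR over signals and credible-set size by min.
    """
    known_ids = {l.locus_id for l in loci}
    for sig in signals:
        if sig.locus_id not in known_ids:
            raise KeyError(f"signal {sig.signal_id} references unknown locus "
                           f"{sig.locus_id}")
        if sig.signal_id not in credsets:
            raise KeyError(f"no credible set for signal {sig.signal_id}")
    mouse = set(phenotype_flags.loc[phenotype_flags["source"] == "mouse", "gene"])
    human = set(phenotype_flags.loc[phenotype_flags["source"] == "human", "gene"])
    by_locus = {l.locus_id: l for l in loci}
    rows = []
    for sig in signals:
        locus = by_locus[sig.locus_id]
        cands = candidate_genes(locus, genes)
        cset = credsets[sig.signal_id]
        gene_ids = {g.gene_id for g in cands}
        ev = _variant_gene_evidence(cset.members, relevance, gene_ids,
                                    set(kidney_tissues))
        for g in cands:
            sub = ev[ev["gene"] == g.gene_id]
            ind = {f: 0 for f in FEATURES}
            for feat in ("protein_relevant", "kidney_regulatory", "other_regulatory"):
                if (sub["feature"] == feat).any():
                    ind[feat] = 1
            ind["mouse_kidney_phenotype"] = int(g.gene_id in mouse)
            ind["human_kidney_phenotype"] = int(g.gene_id in human)
            best_ppa = float(sub["ppa"].max()) if len(sub) else np.nan
            rows.append({
                "gene_id": g.gene_id, "symbol": g.symbol,
                "locus_id": locus.locus_id, "signal_id": sig.signal_id,
                "validated": bool(validation.get(locus.locus_id, False)),
                "credset_size": cset.size, "best_relevant_ppa": best_ppa,
                **ind,
            })
    by_signal = pd.DataFrame(rows)
    if by_signal.empty:
        return by_signal, by_signal
    agg = {f: "max" for f in FEATURES}
    agg.update({"symbol": "first", "validated": "first", "credset_size": "min",
                "best_relevant_ppa": "max"})
    by_locus_view = (by_signal
                     .groupby(["gene_id", "locus_id"], as_index=False)
                     .agg(agg))
    return by_signal, by_locus_view


def gps_query(rows: pd.DataFrame, filters: dict | None = None,
              weights: dict[str, float] | None = None,
              min_score: float = 0.0,
              min_ppa: float | None = None) -> pd.DataFrame:
    """Filter, score and sort GPS rows.

    ``filters`` may contain ``validated`` (bool) and ``max_credset_size``
    (int).  ``weights`` maps feature names to non-negative weights; the score
    is the weighted sum of the binary indicators.  Rows scoring below
    ``min_score`` are dropped; the result is sorted by (score desc,
    best_relevant_ppa desc).  ``min_ppa`` optionally requires the best
    relevant variant's PPA to reach a floor (e.g. 0.10 for adequate
    fine-mapping resolution).
    """
    filters = filters or {}
    weights = dict(weights or {})
    unknown = set(weights) - set(FEATURES)
    if unknown:
        raise ValueError(f"unknown feature(s) in weights: {sorted(unknown)}")
    if any(w < 0 for w in weights.values()):
        raise ValueError("weights must be non-negative")
    out = rows.copy()
    if "validated" in filters:
        out = out[out["validated"] == bool(filters["validated"])]
    if "max_credset_size" in filters:
        out = out[out["credset_size"] <= int(filters["max_credset_size"])]
    score = np.zeros(len(out))
    for feat, w in weights.items():
        score = score + w * out[feat].to_numpy(float)
    out = out.assign(score=score)
    out = out[out["score"] >= min_score]
    if min_ppa is not None:
        out = out[out["best_relevant_ppa"].fillna(0.0) >= min_ppa]
    return out.sort_values(["score", "best_relevant_ppa"],
                           ascending=[False, False],
                           na_position="last").reset_index(drop=True)
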