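"""Gene prioritisation: candidates, consequence classes, FDR, scoring, views."""

import numpy as np
import pandas as pd
import pytest

from kidneygps.finemap import CredibleSet
from kidneygps.gps import (
    GeneAnnotation,
    build_gps,
    candidate_genes,
    classify_cadd_consequence,
    eqtl_fdr_annotation,
    gps_query,
)
from kidneygps.loci import Locus


def _locus(start=150, end=400, locus_id="n1"):
    return Locus(locus_id=locus_id, chrom="1", start=start, end=end,
                 lead_cpaid="1:200:A_G", lead_pos=200, lead_p=1e-9,
                 gws_cpaids=["1:200:A_G"], gws_positions=[200])


class TestCandidateGenes:
    genes = [GeneAnnotation("g1", "G1", "1", 100, 200),
             GeneAnnotation("g2", "G2", "1", 401, 500),
             GeneAnnotation("g3", "G3", "1", 100, 450)]

    def test_overlap_rules(self):
        out = {g.gene_id for g in candidate_genes(_locus(), self.genes)}
        # g1 overlaps at [150,200]; g2 starts 1 bp after the closed end; g3 spans
        assert out == {"g1", "g3"}

    def test_gene_length_closed_interval(self):
        assert GeneAnnotation("g", "G", "1", 100, 200).length == 101


class TestConsequenceClasses:
    @pytest.mark.parametrize("cadd, cons, gene, expected", [
        (32.0, 7, "CERS2", "protein_altering"),
        (14.9, 8, "GENE", "none"),           # below the deleteriousness cut
        (18.4, 3, "HOXD11", "other"),
        (20.0, 5, "GENE", "splice_synonymous"),
        (20.0, 0, "GENE", "other"),
        (20.0, 8, None, "none"),             # outside any gene
    ])
    def test_classification(self, cadd, cons, gene, expected):
        assert classify_cadd_consequence(cadd, cons, gene) == expected

    def test_out_of_range_cons_score(self):
        with pytest.raises(ValueError):
            classify_cadd_consequence(20.0, 9, "GENE")


class TestFDR:
    def test_single_test(self):
        tab = pd.DataFrame({"cpaid": ["v1"], "gene": ["g"], "tissue": ["t"],
                            "p": [0.01]})
        out = eqtl_fdr_annotation(tab)
        assert out["fdr"].iloc[0] == pytest.approx(0.01)

    def test_identical_pvalues(self):
        tab = pd.DataFrame({"cpaid": [f"v{i}" for i in range(4)],
                            "gene": "g", "tissue": "t", "p": 0.02})
        out = eqtl_fdr_annotation(tab)
        assert out["fdr"].tolist() == pytest.approx([0.02] * 4)

    def test_hand_computed_step_up(self):
        tab = pd.DataFrame({"cpaid": [f"v{i}" for i in range(4)],
                            "gene": "g", "tissue": "t",
                            "p": [0.001, 0.01, 0.03, 0.8]})
        out = eqtl_fdr_annotation(tab, alpha=1.1)
        assert sorted(out["fdr"]) == pytest.approx([0.004, 0.02, 0.04, 0.8])

    def test_tissues_corrected_separately(self):
        tab = pd.DataFrame({
            "cpaid": ["v1", "v2", "v3", "v4"], "gene": "g",
            "tissue": ["a", "a", "b", "b"], "p": [0.01, 0.8, 0.01, 0.8]})
        out = eqtl_fdr_annotation(tab)
        assert out["fdr"].tolist() == pytest.approx([0.02, 0.02])


def _build_fixture():
    locus = _locus()
    genes = [GeneAnnotation("g1", "G1", "1", 100, 250),
             GeneAnnotation("g2", "G2", "1", 260, 380),
             GeneAnnotation("g3", "G3", "1", 390, 400)]

    class Sig:
        signal_id, locus_id = "n1.1", "n1"

    credset = CredibleSet(signal_id="n1.1", members=pd.DataFrame({
        "cpaid": ["1:200:A_G"], "ppa": [0.995], "cum_ppa": [0.995]}))
    relevance = pd.DataFrame([
        {"cpaid": "1:200:A_G", "evidence": "protein", "gene": "g1",
         "tissue": np.nan, "cadd_phred": 25.0, "cons_score": 8, "fdr": np.nan},
        {"cpaid": "1:200:A_G", "evidence": "eqtl", "gene": "g2",
         "tissue": "liver", "cadd_phred": np.nan, "cons_score": np.nan,
         "fdr": 0.01},
    ])
    flags = pd.DataFrame([{"gene": "g3", "source": "mouse"}])
    return build_gps([locus], [Sig()], {"n1.1": credset}, genes, relevance,
                     flags, {"n1": True})


class TestBuildGPS:
    def test_assembly_indicators(self):
        by_signal, _ = _build_fixture()
        g1 = by_signal[by_signal["gene_id"] == "g1"].iloc[0]
        assert g1["protein_relevant"] == 1 and g1["validated"]
        assert g1["credset_size"] == 1
        g2 = by_signal[by_signal["gene_id"] == "g2"].iloc[0]
        assert g2["kidney_regulatory"] == 0 and g2["other_regulatory"] == 1

    def test_gene_without_evidence_still_listed(self):
        by_signal, _ = _build_fixture()
        g3 = by_signal[by_signal["gene_id"] == "g3"].iloc[0]
        assert g3[["protein_relevant", "kidney_regulatory",
                   "other_regulatory"]].sum() == 0
        assert g3["mouse_kidney_phenotype"] == 1

    def test_locus_view_is_or_of_signal_view(self):
        by_signal, by_locus = _build_fixture()
        for _, row in by_locus.iterrows():
            sub = by_signal[(by_signal["gene_id"] == row["gene_id"])
                            & (by_signal["locus_id"] == row["locus_id"])]
            for feat in ("protein_relevant", "kidney_regulatory",
                         "other_regulatory"):
                assert row[feat] == sub[feat].max()
            assert row["credset_size"] == sub["credset_size"].min()

    def test_dangling_signal_rejected(self):
        class Sig:
            signal_id, locus_id = "x.1", "missing"
        with pytest.raises(KeyError, match="missing"):
            build_gps([_locus()], [Sig()], {}, [], pd.DataFrame(),
                      pd.DataFrame(columns=["gene", "source"]), {})


class TestQuery:
    def test_published_style_query_returns_qualifying_genes(self):
        by_signal, _ = _build_fixture()
        out = gps_query(by_signal, filters={"validated": True,
                                            "max_credset_size": 5},
                        weights={"protein_relevant": 1.0,
                                 "kidney_regulatory": 1.0},
                        min_score=1.0)
        assert out["gene_id"].tolist() == ["g1"]

    def test_zero_weights_empty(self):
        by_signal, _ = _build_fixture()
        assert gps_query(by_signal, weights={}, min_score=1.0).empty

    def test_identity_query_returns_all_sorted(self):
        by_signal, _ = _build_fixture()
        out = gps_query(by_signal, min_score=0.0)
        assert len(out) == len(by_signal)

    def test_monotone_in_min_score_and_weights(self):
        by_signal, _ = _build_fixture()
        w = {"protein_relevant": 1.0}
        lo = gps_query(by_signal, weights=w, min_score=0.5)
        hi = gps_query(by_signal, weights=w, min_score=1.5)
        assert set(hi["gene_id"]) <= set(lo["gene_id"])
        more = gps_query(by_signal, weights={**w, "other_regulatory": 1.0},
                         min_score=0.5)
        assert set(lo["gene_id"]) <= set(more["gene_id"])

    def test_unknown_feature_rejected(self):
        by_signal, _ = _build_fixture()
        with pytest.raises(ValueError, match="unknown"):
            gps_query(by_signal, weights={"nonsense": 1.0})

    def test_ppa_floor(self):
        by_signal, _ = _build_fixture()
        out = gps_query(by_signal, weights={"protein_relevant": 1.0},
                        min_score=1.0, min_ppa=0.10)
        assert out["gene_id"].tolist() == ["g1"]
        out = gps_query(by_signal, weights={"protein_relevant": 1.0},
                        min_score=1.0, min_ppa=0.999)
        assert out.empty
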