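"""Synthetic-data generator: LD structure, phenotypes, GWAS scan, eQTLs."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as _st

from kidneygps.meta import genomic_control_lambda
from kidneygps.simulate import (
    CausalVariant,
    SimConfig,
    panel_layout,
    prepare_phenotype,
    run_study_gwas,
    simulate_eqtl_dataset,
    simulate_gene_annotation,
    simulate_genotypes,
    simulate_multitrait_cohort,
    simulate_reference_panel,
)


@pytest.fixture(scope="module")
def small_cfg():
    return SimConfig(seed=1, block_sizes=(10, 10), neighbour_rho=0.8,
                     block_starts_bp=(1_000_000, 5_000_000),
                     causal=(CausalVariant(3, beta_kidney=0.02),
                             CausalVariant(15, beta_crea=0.02)))


class TestGenotypes:
    def test_neighbour_correlation_near_target(self, small_cfg):
        G = simulate_genotypes(small_cfg, 5000, np.random.default_rng(0))
        R = np.corrcoef(G, rowvar=False)
        neigh = [R[i, i + 1] for i in range(9)]
        assert all(0.7 <= r <= 0.9 for r in neigh)

    def test_cross_block_uncorrelated(self, small_cfg):
        G = simulate_genotypes(small_cfg, 5000, np.random.default_rng(0))
        R = np.corrcoef(G, rowvar=False)
        cross = np.abs(R[:10, 10:])
        assert cross.max() < 0.05

    def test_deterministic_under_fixed_seed(self, small_cfg):
        a = simulate_genotypes(small_cfg, 200, np.random.default_rng(7))
        b = simulate_genotypes(small_cfg, 200, np.random.default_rng(7))
        assert np.array_equal(a, b)

    def test_reference_panel_consistency(self, small_cfg):
        X, ld = simulate_reference_panel(small_cfg, n_ref=2000)
        assert ld.R.shape == (20, 20)
        assert np.allclose(np.diag(ld.R), 1.0)
        # frequencies are alleleA-oriented: dosages count G (alleleB)
        assert np.allclose(ld.freq, 1.0 - X.mean(axis=0) / 2.0)


class TestPreparePhenotype:
    def test_winsorize_then_log(self):
        assert prepare_phenotype([250.0], "egfr")[0] == pytest.approx(np.log(200))
        assert prepare_phenotype([10.0], "egfr")[0] == pytest.approx(np.log(15))

    def test_urea_to_bun(self):
        assert prepare_phenotype([10.0], "bun_from_urea")[0] == \
            pytest.approx(np.log(28.0))

    def test_nonpositive_urea_rejected(self):
        with pytest.raises(ValueError):
            prepare_phenotype([0.0], "bun_from_urea")


class TestMultitraitCohort:
    def test_creatinine_specific_effect_isolated(self, small_cfg):
        cfg = SimConfig(seed=1, block_sizes=(10,), block_starts_bp=(1_000_000,),
                        causal=(CausalVariant(3, beta_crea=0.05),))
        G = simulate_genotypes(cfg, 3000, np.random.default_rng(1))
        phen = simulate_multitrait_cohort(G, cfg, np.random.default_rng(2))
        # cys genetic value is identically zero without kidney effects
        assert np.all(phen["genetic_kidney"] == 0)
        assert np.corrcoef(phen["genetic_crea"],
                           phen["cys"])[0, 1] == pytest.approx(0.0, abs=0.05)

    def test_bun_opposes_crea_for_kidney_effects(self, small_cfg):
        cfg = SimConfig(seed=1, block_sizes=(10,), block_starts_bp=(1_000_000,),
                        causal=(CausalVariant(3, beta_kidney=0.05),))
        G = simulate_genotypes(cfg, 3000, np.random.default_rng(1))
        phen = simulate_multitrait_cohort(G, cfg, np.random.default_rng(2))
        x = G[:, 3]
        b_crea = np.polyfit(x, phen["crea"], 1)[0]
        b_bun = np.polyfit(x, phen["bun"], 1)[0]
        assert np.sign(b_bun) == -np.sign(b_crea)

    def test_effect_recovery_within_sampling_error(self):
        # one causal per block so the marginal estimate is unbiased for the
        # planted effect (no LD leakage from a second causal)
        cfg = SimConfig(seed=4, block_sizes=(20, 20),
                        block_starts_bp=(1_000_000, 5_000_000),
                        causal=(CausalVariant(5, beta_kidney=0.02),
                                CausalVariant(35, beta_kidney=0.015)))
        rng = np.random.default_rng(5)
        G = simulate_genotypes(cfg, 20_000, rng)
        phen = simulate_multitrait_cohort(G, cfg, rng)
        cpaids, pos, _ = panel_layout(cfg)
        stats = run_study_gwas(G, phen["crea"], cpaids, pos, "1")
        for cv in cfg.causal:
            row = stats.df[stats.df["cpaid"] == cpaids[cv.index]].iloc[0]
            assert abs(abs(row["beta"]) - cv.beta_kidney) < 3 * row["se"]


class TestGWASScan:
    def test_null_phenotype_is_calibrated(self):
        # independent variants: the KS test and the lambda tolerance assume
        # independent association statistics
        cfg = SimConfig(seed=2, block_sizes=(200,) * 50, neighbour_rho=0.0,
                        block_starts_bp=tuple(10_000_000 * (i + 1)
                                              for i in range(50)))
        rng = np.random.default_rng(3)
        G = simulate_genotypes(cfg, 1000, rng)
        y = rng.standard_normal(1000)
        cpaids, pos, _ = panel_layout(cfg)
        stats = run_study_gwas(G, y, cpaids, pos, "1")
        lam = genomic_control_lambda(stats)
        assert 0.95 <= lam <= 1.05
        ks = _st.kstest(stats.df["p"], "uniform")
        assert ks.pvalue > 0.01

    def test_causal_variant_attains_min_p(self, small_cfg):
        rng = np.random.default_rng(6)
        G = simulate_genotypes(small_cfg, 5000, rng)
        y = 0.5 * G[:, 3] + rng.standard_normal(5000)
        cpaids, pos, _ = panel_layout(small_cfg)
        stats = run_study_gwas(G, y, cpaids, pos, "1")
        assert stats.df.loc[stats.df["p"].idxmin(), "cpaid"] == cpaids[3]

    def test_perfect_covariate_shrinks_betas(self, small_cfg):
        rng = np.random.default_rng(8)
        G = simulate_genotypes(small_cfg, 5000, rng)
        g = 0.1 * G[:, 3]
        y = g + rng.normal(0, 0.1, 5000)
        cpaids, pos, _ = panel_layout(small_cfg)
        raw = run_study_gwas(G, y, cpaids, pos, "1")
        adj = run_study_gwas(G, y, cpaids, pos, "1", covariates=g[:, None])
        # controlling the full genetic value leaves only noise-level slopes
        assert abs(adj.df["beta"]).max() < 0.2 * abs(raw.df["beta"]).max()
        # the causal variant itself is collinear with the covariate: dropped
        assert cpaids[3] not in set(adj.df["cpaid"])

    def test_gc_lambda_emulation_inflates_statistics(self):
        cfg = SimConfig(seed=2, block_sizes=(100,), neighbour_rho=0.0,
                        block_starts_bp=(10_000_000,))
        rng = np.random.default_rng(3)
        G = simulate_genotypes(cfg, 2000, rng)
        y = rng.standard_normal(2000)
        cpaids, pos, _ = panel_layout(cfg)
        clean = run_study_gwas(G, y, cpaids, pos, "1")
        inflated = run_study_gwas(G, y, cpaids, pos, "1", gc_lambda=1.5)
        lam_ratio = genomic_control_lambda(inflated) / genomic_control_lambda(clean)
        assert lam_ratio == pytest.approx(1.5, rel=1e-6)


class TestEqtl:
    cfg = SimConfig(seed=9, block_sizes=(20,), block_starts_bp=(1_000_000,))

    def test_null_gene_uniform_p(self):
        cfg = SimConfig(seed=9, block_sizes=(300,), neighbour_rho=0.0,
                        block_starts_bp=(1_000_000,))
        tab = simulate_eqtl_dataset(cfg, {
            "G0": {"tissue": "tubulointerstitial", "delta": 0.0,
                   "causal_index": 0}}, n=500)
        ks = _st.kstest(tab["p"], "uniform")
        assert ks.pvalue > 0.01

    def test_planted_eqtl_detected(self):
        tab = simulate_eqtl_dataset(self.cfg, {
            "G0": {"tissue": "tubulointerstitial", "delta": 1.0,
                   "causal_index": 10}})
        cpaids, _, _ = panel_layout(self.cfg)
        assert tab.loc[tab["p"].idxmin(), "cpaid"] == cpaids[10]

    def test_deterministic_tables(self):
        spec = {"G0": {"tissue": "glomerular", "delta": 0.5, "causal_index": 3}}
        a = simulate_eqtl_dataset(self.cfg, spec)
        b = simulate_eqtl_dataset(self.cfg, spec)
        pd.testing.assert_frame_equal(a, b)


class TestGeneAnnotation:
    def test_default_tiling_covers_blocks(self):
        cfg = SimConfig(seed=0, block_sizes=(10, 10),
                        block_starts_bp=(1_000_000, 5_000_000))
        genes, relevance, flags = simulate_gene_annotation(cfg)
        assert len(genes) == 2
        assert genes[0].start <= cfg.block_starts_bp[0]
        assert relevance.empty and flags.empty

    def test_protein_variant_table(self):
        cfg = SimConfig(seed=0, block_sizes=(10,), block_starts_bp=(1_000_000,))
        _, relevance, flags = simulate_gene_annotation(
            cfg, protein_variants={"1:1000000:A_G": (25.0, 8, "GENE_A")},
            mouse_genes=["GENE_A"])
        assert relevance.iloc[0]["evidence"] == "protein"
        assert flags.iloc[0]["source"] == "mouse"
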