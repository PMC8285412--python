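"""Conditional analysis, Wakefield Bayes factors, PPAs and credible sets."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats as _st

from kidneygps.finemap import (
    CredibleConfig,
    LDReference,
    conditional_sumstats,
    credible_set,
    credible_set_for_signal,
    posterior_probabilities,
    stepwise_signals,
    wakefield_log_abf,
)
from kidneygps.loci import define_loci
from kidneygps.simulate import (
    CausalVariant,
    SimConfig,
    panel_layout,
    run_study_gwas,
    simulate_genotypes,
    simulate_summary_stats,
)

from conftest import make_stats

W = 0.005 ** 2


def _cohort(seed=3, n=5000, causal=((5, 0.03), (30, 0.025)), m=50):
    cfg = SimConfig(seed=seed, block_sizes=(m,), block_starts_bp=(10_000_000,),
                    causal=tuple(CausalVariant(i, beta_kidney=b) for i, b in causal))
    rng = np.random.default_rng(seed + 100)
    G = simulate_genotypes(cfg, n, rng)
    cpaids, pos, _ = panel_layout(cfg)
    y = rng.normal(0, 0.127, n)
    for i, b in causal:
        y = y + b * G[:, i]
    stats = run_study_gwas(G, y, cpaids, pos, "1")
    counted = [c.rsplit(":", 1)[1].split("_")[1] for c in cpaids]
    ld = LDReference.from_dosages(cpaids, G, counted_alleles=counted)
    return cfg, G, y, stats, ld, cpaids


class TestConditional:
    def test_empty_conditioning_set_is_identity(self):
        _, _, _, stats, ld, _ = _cohort()
        assert conditional_sumstats(stats, ld, []) is stats

    def test_perfect_proxy_flagged_collinear(self):
        cpaids = ["1:100:A_G", "1:200:A_G"]
        R = np.array([[1.0, 1.0], [1.0, 1.0]])
        ld = LDReference(cpaids, np.array([0.7, 0.7]), R, n_ref=1000)
        stats = make_stats([(c, "G", "A", 0.3, 0.02, 0.004, 5.7e-7, 1e4)
                            for c in cpaids])
        out = conditional_sumstats(stats, ld, [cpaids[0]])
        row = out.df.iloc[0]
        assert bool(row["collinear"])
        assert row["beta"] == 0.0

    def test_orthogonal_variant_keeps_marginal_effect(self):
        cpaids = ["1:100:A_G", "1:200:A_G"]
        ld = LDReference(cpaids, np.array([0.7, 0.7]), np.eye(2), n_ref=1000)
        stats = make_stats([(c, "G", "A", 0.3, 0.02, 0.004, 5.7e-7, 1e4)
                            for c in cpaids])
        out = conditional_sumstats(stats, ld, [cpaids[0]])
        assert out.df.iloc[0]["beta"] == pytest.approx(0.02, rel=1e-6)

    def test_matches_exact_joint_ols(self):
        """With the analysis sample as reference, conditional estimates track
        exact multiple regression within 2% on beta and SE."""
        _, G, y, stats, ld, cpaids = _cohort()
        cond = conditional_sumstats(stats, ld, [cpaids[5]])
        x_cond = G[:, 5]
        for _, row in cond.df.iterrows():
            if row["collinear"]:
                continue
            i = cpaids.index(row["cpaid"])
            fit = sm.OLS(y, sm.add_constant(np.column_stack([G[:, i], x_cond]))).fit()
            denom = max(abs(fit.params[1]), fit.bse[1])  # avoid 0/0 at null betas
            assert abs(row["beta"] - fit.params[1]) / denom < 0.02
            assert abs(row["se"] - fit.bse[1]) / fit.bse[1] < 0.02


class TestStepwise:
    def _signals(self, causal, seed=9):
        cfg, G, y, stats, ld, cpaids = _cohort(seed=seed, n=20_000, causal=causal)
        loci = define_loci(stats)
        assert len(loci) == 1
        return stepwise_signals(loci[0], stats, ld), cpaids

    def test_single_causal_yields_one_signal(self):
        signals, _ = self._signals(((25, 0.03),))
        assert len(signals) == 1

    def test_two_weakly_linked_causals_yield_two_signals(self):
        signals, cpaids = self._signals(((5, 0.03), (45, 0.03)))
        assert len(signals) == 2
        found = {s.index_cpaid for s in signals}
        # index variants are the planted ones or near-perfect proxies (r^2 > 0.8)
        for planted in (cpaids[5], cpaids[45]):
            assert any(
                abs(int(planted.split(":")[1]) - int(f.split(":")[1])) <= 10_000
                for f in found
            )

    def test_each_signal_conditions_on_the_others(self):
        signals, _ = self._signals(((5, 0.03), (45, 0.03)))
        for s in signals:
            others = {t.index_cpaid for t in signals} - {s.index_cpaid}
            assert set(s.conditioning_set) == others
            assert s.index_cpaid in set(s.conditional_stats.df["cpaid"])


class TestWakefield:
    def test_null_effect_gives_negative_log_abf(self):
        la = wakefield_log_abf(0.0, 0.004, W)
        assert la == pytest.approx(0.5 * np.log(0.004**2 / (0.004**2 + W)))
        assert la < 0

    def test_vanishing_prior_collapses_to_zero(self):
        assert wakefield_log_abf(0.01, 0.002, 1e-12) == pytest.approx(0.0, abs=1e-4)

    def test_printed_example_value(self):
        assert wakefield_log_abf(0.01, 0.002, W) == pytest.approx(9.785, abs=0.005)

    def test_monotone_in_abs_z(self):
        se = 0.002
        zs = np.array([0.0, 1.0, 2.0, 5.0, 10.0])
        las = wakefield_log_abf(zs * se, se, W)
        assert np.all(np.diff(las) > 0)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            wakefield_log_abf(0.1, 0.0, W)
        with pytest.raises(ValueError):
            wakefield_log_abf(0.1, 0.01, 0.0)


class TestPPA:
    def test_single_variant_gets_full_mass(self):
        assert posterior_probabilities([3.7]) == pytest.approx([1.0])

    def test_identical_pair_splits_evenly(self):
        la = wakefield_log_abf(np.array([0.01, 0.01]), np.array([0.002, 0.002]), W)
        assert posterior_probabilities(la) == pytest.approx([0.5, 0.5])

    def test_logsumexp_matches_naive_exponentiation(self):
        la = np.array([10.0, 9.0, 0.0])
        naive = np.exp(la) / np.exp(la).sum()
        assert posterior_probabilities(la) == pytest.approx(naive, rel=1e-12)

    def test_shift_invariance(self):
        la = np.array([2.0, -1.0, 0.5])
        assert posterior_probabilities(la + 123.4) == pytest.approx(
            posterior_probabilities(la))

    def test_orientation_invariance(self):
        """Flipping effect-allele orientation leaves the PPA ranking unchanged."""
        beta = np.array([0.01, -0.008, 0.002])
        se = np.array([0.002, 0.002, 0.002])
        a = posterior_probabilities(wakefield_log_abf(beta, se, W))
        b = posterior_probabilities(wakefield_log_abf(-beta, se, W))
        assert a == pytest.approx(b)


class TestCredibleSet:
    def test_dominant_variant_single_set(self):
        cs = credible_set(["a", "b"], [0.995, 0.005])
        assert cs.size == 1 and cs.single and cs.small

    def test_uniform_inclusive_threshold(self):
        # 200 variants at 0.005: cumulative hits 0.99 exactly at 198
        cs = credible_set([f"v{i}" for i in range(200)], [0.005] * 200)
        assert cs.size == 198

    def test_arithmetic_example(self):
        cs = credible_set(list("abcde"), [0.5, 0.3, 0.15, 0.04, 0.01])
        assert cs.size == 4

    def test_minimality(self):
        cs = credible_set(list("abcd"), [0.6, 0.3, 0.08, 0.02])
        assert cs.members["cum_ppa"].iloc[-1] >= 0.99
        assert cs.members["cum_ppa"].iloc[-2] < 0.99

    def test_ppa_must_normalize(self):
        with pytest.raises(ValueError):
            credible_set(["a", "b"], [0.5, 0.4])


def test_coverage_of_planted_variant_quick():
    """Planted causal variant sits in the 99% credible set in nearly all
    single-causal simulations (quick version; the full run lives in the
    acceptance suite)."""
    rng = np.random.default_rng(42)
    m = 100
    R = 0.95 ** np.abs(np.subtract.outer(np.arange(m), np.arange(m)))
    freqs = rng.uniform(0.05, 0.5, m)
    hits = 0
    n_sim = 100
    for _ in range(n_sim):
        causal = int(rng.integers(m))
        z_target = rng.uniform(6, 12)
        b_std = z_target / np.sqrt(100_000)
        stats = simulate_summary_stats(R, freqs, [causal], [b_std], 100_000,
                                       rng, sigma_y=0.126)
        la = wakefield_log_abf(stats.df["beta"].to_numpy(),
                               stats.df["se"].to_numpy(), W)
        ppa = posterior_probabilities(la)
        cs = credible_set(stats.df["cpaid"].to_numpy(), ppa,
                          p_cond=stats.df["p"].to_numpy(),
                          pos=stats.df["pos"].to_numpy())
        planted = stats.df["cpaid"].iloc[causal]
        hits += planted in cs
    assert hits / n_sim >= 0.93
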