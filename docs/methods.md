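# Methods

This note records the models, conventions, parameter choices and known
limitations behind `kidneygps`.  Everything quantitative here is computed by
the test suite or by `scripts/acceptance.py`; nothing is quoted from
external results.

## Summary-statistics model and conventions

An association record holds a per-allele additive effect β on the
natural-log phenotype, its standard error, a two-sided normal Wald p-value,
the effect-allele frequency, sample size and imputation quality.  Internally
β/se and p are required to agree under the Wald relation within a relative
tolerance of 10⁻³.  Coordinates are 1-based with closed intervals on both
ends — the convention that makes the locus border arithmetic (±250 kb of
the outermost significant variants) exact.  Chromosome X is stored as "23"
so plain tuple sorting yields genomic order, and rendered "X" on output.
Insertions/deletions are accepted by the identifier scheme (the ASCII
ordering rule applies unchanged to multi-character alleles); a strict-SNP
flag rejects them for workflows restricted to SNPs.  Harmonization is
allele-set based only: no strand-flipping heuristics for palindromic (A/T,
C/G) variants are attempted, because frequency-based strand inference is
unreliable and out of scope.

Missing imputation info passes QC only for records flagged as directly
genotyped; an imputed record with missing info fails the info filter.  This
is deliberately conservative: a missing quality score on an imputed variant
usually signals an upstream bookkeeping problem.

## Genomic control and meta-analysis

λ is the median association χ² divided by the χ²₁ median (0.45494).
Correction multiplies SEs by √λ and recomputes p; λ < 1 is never used to
deflate.  The SE convention (rather than scaling χ²) is chosen so that
corrected records remain self-consistent under the Wald relation; the two
conventions give identical p-values.  Whether a study is corrected is a
per-study switch — studies whose inputs were already GC-corrected upstream
must not be corrected twice.

The meta-analysis is fixed-effect inverse-variance.  The meta-analysed
effect-allele frequency is the sample-size-weighted mean — the quantity is
descriptive only and this matches common tool behaviour.  Heterogeneity
statistics and sample-overlap corrections are out of scope.  The
minor-allele-count filter (MAC = 2·n·MAF < 400 excluded) uses the combined
post-meta n, and all QC exclusions are strict inequalities, so boundary
values (MAF exactly 0.1%, MAC exactly 400, info exactly 0.6) survive.

## Locus definition

The iterative algorithm is implemented literally: smallest-p GWS variant as
lead; outermost GWS variants within the 1-Mb window centred on the lead;
repeated 500-kb extension beyond the *current outermost GWS variants* (not
the window edge) until no GWS variant is absorbed; borders at the outermost
GWS positions ± 250 kb, clamped at position 1; all variants inside the
borders removed before the next round.  Ties in the minimum p break by
(chrom, pos) ascending.  Because the extension reach (500 kb) exceeds the
border margin (250 kb), any GWS variant left after a locus closes is more
than 500 kb from its outermost GWS variant, which makes returned loci
provably disjoint — no clamping against earlier loci is needed.  Novel/known
classification tests GWS variants (not borders) for containment in known
regions.

## Conditional analysis

Marginal per-allele effects are standardized (b* = b·s, s the genotype SD),
conditioned through the reference correlation matrix, and returned as the
joint-model coefficient of each variant given the conditioning set S:

b*₍ᵢ|S₎ = (b*ᵢ − r₍ᵢ,S₎ R_S⁻¹ b*_S) / (1 − r₍ᵢ,S₎ R_S⁻¹ r₍S,ᵢ₎)

with SE² = σ̂² / (n·(1 − r₍ᵢ,S₎R_S⁻¹r₍S,ᵢ₎)) where σ̂² is the phenotypic
variance proxy median(n·se²·s²) over locus variants minus the variance
explained by the joint fit of S ∪ {i}.  The genotype SD uses the reference
panel's empirical dosage variance when the panel was built from dosages
(falling back to the Hardy-Weinberg value √(2f(1−f)) for
correlation-matrix-only references): with the analysis sample as its own
reference this makes the estimator agree with exact multiple regression to
within a fraction of a percent, which is what the oracle test asserts at
the 2% tolerance.  Variants with squared multiple correlation > 0.9 against
the conditioning set are flagged collinear and returned without an estimate
(β = 0, p = 1); conditioning sets whose LD matrix is numerically singular
(condition number > 10⁸) raise.  Reference frequencies are used for
standardization, with a warning when they differ from the GWAS frequency by
more than 0.1.

Stepwise selection promotes the smallest conditional-p variant while
p_cond < 5×10⁻⁸; afterwards each signal's statistics are recomputed
conditioning on all *other* index variants, so single-signal loci keep
their marginal statistics — which is also what the fine-mapping step
consumes.

## Fine-mapping

Wakefield log-ABF with prior effect variance W = 0.005² on the log-phenotype
scale; PPAs are ABFs normalized per signal in log space (log-sum-exp); the
99% credible set is the shortest PPA-descending prefix with cumulative mass
≥ 0.99 (inclusive threshold, so a uniform PPA of 0.005 over 200 variants
yields a set of exactly 198).  Boundary ties break by smaller conditional
p, then by position.  Coverage is validated by simulation: over 500
single-causal loci of 100–500 variants with geometric LD decay (neighbour
r = 0.95) and marginal z between 6 and 12, the planted variant falls inside
the set in well over 95% of runs.  Those replicates are drawn at the
summary-statistic level — z ~ MVN(√n·R·b*, R) — the exact generative model
for marginal statistics given LD, which exercises the identical fine-mapping
code path at a fraction of the cost of individual-level simulation.

## Colocalization

Standard five-hypothesis ABF enumeration in log space with per-variant
priors p1 = p2 = 10⁻⁴ and p12 = 10⁻⁵ (the canonical defaults; only the
effect-prior variances are study-specific).  Trait-1 (GWAS) prior variance
is 0.005²; expression prior SDs derive from a symmetric 95% effect-size
range via sd = bound/Φ⁻¹(0.975): ±1.07 → 0.546 (tubule-interstitial),
±1.04 → 0.531 (glomerular).  With a single shared variant H3 is impossible
and its term is −∞.  PP_H4 ≥ 0.80 (inclusive) flags a positive
colocalization.  Variants are intersected by identifier; eQTL rows with
missing SE are dropped, not imputed.

## Gene PrioritiSation

Candidate genes overlap the locus region by ≥ 1 bp (closed intervals).
Evidence channels per credible variant: protein (deleteriousness PHRED ≥ 15
*and* located inside the gene; consequence scores 8/7 → protein-altering,
6/5 → splice/synonymous, 4–0 → other) and regulatory (eQTL/sQTL hit at
BH FDR < 0.05, computed within tissue over all variant×gene tests, cis —
target gene must lie in the same locus).  sQTL hits count the same as eQTL
hits for the regulatory indicators; kidney vs other tissue is a
configurable tissue-class set.  Mouse/human phenotype evidence is consumed
as precompiled flag tables.  The score is a weighted sum of binary
gene×signal indicators — with unit weights and the "score ≥ 1" filter this
reproduces "any weighted feature present" semantics.  The locus view ORs
indicators over signals and takes the minimum credible-set size.  A PPA
floor (off by default; 0.10 is a sensible resolution screen) is exposed as
a query option.

## Enrichment

Specificity of gene g in tissue t is the standardized contrast
(x_t − mean(x_other)) / sd(x_row); constant rows get zero and lose ties,
which break lexicographically (flagged degenerate).  The top decile per
tissue forms the specifically-expressed set.  The enrichment test replaces
each candidate gene with a random universe gene from the same (gene-length
decile × independent-variant-count decile) stratum, without replacement
within a draw; the empirical p is the add-one estimator
(1 + #{overlap ≥ observed})/(M + 1) with M = 10,000 by default, never
exactly zero; BH FDR across tissues.  Candidates stay in the sampling
universe by default (a flag excludes them).  Calibration is measured with a
universe of 2,000 genes and candidate lists of 100 (expected null overlap
≈ 10): at smaller scales the discreteness of the overlap statistic makes
the add-one "≥" estimator visibly conservative, and a calibration
measurement dominated by discreteness would say nothing about the sampler.

## Explained variance and GRS

Per-variant R² = b²·2·MAF(1−MAF)/Var(Y) with conditional b at multi-signal
loci; reference phenotype variances 0.016 (population-based) and 0.078
(hospital-based) are the module defaults for the age-/sex-adjusted log
outcome.  The GRS orients every variant to its outcome-decreasing allele;
the weighted score multiplies decreasing-allele dosage by |β|.  GRS
regression standardizes the score, adjusts for covariates, and reports the
per-SD effect in raw outcome units plus incremental R².  The
95th-vs-5th-percentile contrast is 3.2897 per-SD effects under normality,
or the difference of model predictions at the empirical percentiles.

## Synthetic data

Genotypes come from a Gaussian-copula haplotype model: two latent MVN
draws per individual per LD block, thresholded at the allele-frequency
quantile and summed, giving Hardy-Weinberg dosages with block LD.  The
latent correlations are calibrated by inverting the tetrachoric relation
(vectorized bisection on the Drezner integral) for each adjacent pair, with
longer-range latent correlations taken as chain products (Gaussian Markov
structure — positive definite by construction), so *dosage* correlations
hit the neighbour-decay target instead of being attenuated by thresholding.
Allele frequencies are drawn around a per-block base with small jitter:
high LD is only attainable between variants of similar frequency.
Infeasible targets saturate at the attainable maximum.

Phenotypes: crea = g_kidney + g_crea + ε, cys = 0.8·g_kidney + ε,
bun = −0.5·g_kidney + ε, with noise variance 0.016 (log-scale).  The
attenuation (0.8) and reflection (0.5) factors encode that cystatin-based
eGFR tracks true filtration in the same direction with some independent
variability while urea moves opposite; creatinine-specific effects touch
eGFRcrea only.  Uncorrected stratification is emulated by shrinking a
study's reported SEs by √λ (default 1.1 on the first study).  eQTL datasets
are simulated at n = 187 — the scale of the kidney-tissue expression panels
the pipeline is designed around — with expression = dosage·δ + N(0,1).

The standard end-to-end scenario: two studies of 10,000; three causal LD
blocks of 50 variants (neighbour r = 0.9) carrying four causal variants —
one kidney effect (β = 0.020), two kidney effects in low mutual LD (0.020,
0.018), one creatinine-specific effect (0.020) — plus three null background
blocks of 450 variants at neighbour r = 0.2, so that the genomic-control
median is estimated over predominantly null statistics.  Effect sizes are
desk-scale: per-variant power is essentially 1 at n = 20,000, standing in
for realistically small effects at millions of samples.  What passing this
scenario shows is that the machinery recovers planted structure under its
own assumptions; it does not demonstrate robustness to the things the
generator does not model — cryptic relatedness, imputation error beyond the
info field, trans-ethnic LD differences, assay batch effects, or selection
into cohorts.

## Problem sizes and numerics

The oracle and property studies run at: conditional oracle n = 5,000 with
50–200 variants and 1–3 causals; meta-equivalence n = 8,000 split into two
studies; credible-set coverage 500 replicates; enrichment calibration 400
repetitions at M = 2,000 draws; locus partition 1,000 random
configurations.  These sizes keep the full suite around a minute on one
core while leaving each check statistically meaningful.  Numerical
tolerances: PPA normalization and colocalization posteriors to 10⁻⁹; LD
matrices must be PSD within −10⁻⁶; probabilities are clipped away from
exact zero before logs; empirical p-values are bounded below by 1/(M+1) by
construction.

## Known limitations

Single-causal fine-mapping per signal (conditioning handles multiplicity
between signals, not within a credible set); allele-set harmonization
without strand checks; no random-effects meta-analysis; no chromosome-end
clamping of locus borders (chromosome lengths are not modelled); the GPS
consumes precompiled annotation tables and performs no ontology traversal;
the synthetic LD model is block-diagonal with geometric decay, which is
coarser than coalescent LD.
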