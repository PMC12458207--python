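# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the known limitations of `invgwa`.

## Panel and trait simulation

The generator emulates an inbred reference panel of near-homozygous lines.
Each line is a pair of identical haplotypes, so dosages sit at {0, 2} except
at residually heterozygous sites (dosage 1, rate `residual_het_rate`,
default 0.002 ≈ the residual heterozygosity of a heavily inbred panel). The
same rate governs whether a line is called HET for an inversion, treating the
inversion as one more residually heterozygous locus; with the rate at zero
the panel is exactly inbred, which several tests exploit.

Background variants draw alternate-allele frequencies from Beta(0.5, 0.5)
truncated to [0.05, 0.95] — a U-shaped folded site-frequency spectrum — and
alleles are sampled independently per line, so background LD is approximately
zero. Inside an inversion span, each line first draws an arrangement
(inverted at frequency `frequency`, default 0.30, the order of a common
cosmopolitan inversion) and then draws alleles from arrangement-specific
frequencies separated by a divergence `d = |p_inv − p_std|` (default 0.80).
This produces the high in-span LD that the analysis responds to without
simulating recombination history: LD with arrangement status rises
monotonically with `d`, reaching r² = 1 at `d = 1`. Default geometry is two
20 Mb arms of 1000 variants each with a 10 Mb span on 2L; 200 lines.

Traits are built per line as

```
y = b_inv · inversion dosage + Σ_j b_j · causal dosage_j + γ · covariate + ε
```

with each genetic component rescaled so its realized sample variance equals
its configured fraction of total variance (`inversion_effect_r2`, default
0.10 — the share of trait variance a strongly associated cosmopolitan
inversion typically explains; `polygenic_h2`); ε is Gaussian with the
complementary variance. Causal variants are drawn outside inversion spans
unless `causal_inside_spans` is set (used for the power contrast, where the
architecture of interest is inversion-linked). A configured tail of traits is
pure noise plus covariate. Phenotype and genotype missingness are completely
at random. The truth table (causal indices, effects, null flags) is returned
alongside the phenotype table.

What the generator does **not** emulate: coalescent relatedness between
lines, recombination maps, background LD between nearby variants, selection,
and any non-random missingness. Tests passing on these panels therefore show
that the estimators respond correctly to inversion-style structure, not that
they are robust to every feature of real panel data.

## Inversion-trait models and the matched null

The inversion model is OLS of a trait on the arrangement indicator over
INV/STD homozygous lines only; HET lines are excluded because an inbred
line's heterozygous call does not identify the genotype of any phenotyped
individual. F and p come from the comparison with the intercept-only model;
designs with fewer than three lines in either group return a degenerate-fit
marker rather than NaNs.

The matched null refits the same model on variants matched to the inversion:
same arm, alternate-allele frequency within ±1% (default) of the
inverted-arrangement allele frequency (HET counted as one inverted allele —
the only inversion frequency on the same scale as variant frequencies),
outside the span and at least 2 Mb from both breakpoints. Requiring the
variants to lie outside the span, not merely away from the breakpoints, keeps
maximally inversion-linked variants out of a null meant to represent unlinked
polymorphism. Matched variants are fitted through their homozygous dosage
classes to mirror the heterozygote exclusion. A trait is
"inversion-associated" when p < 0.05, its R² exceeds the null's 95% quantile,
and inverted homozygotes are ≥5% of the lines used.

## Trait PCA and imputation

Missing trait cells are imputed by regularized iterative PCA: initialize at
trait means; iterate {standardize with current column statistics, rank-`ncp`
SVD with each leading eigenvalue shrunk by the mean trailing eigenvalue
(noise variance), overwrite missing cells only} until the largest relative
change in an imputed cell falls below `tol` (1e-6). `ncp` defaults to 2,
matching the two components analysed downstream. Observed cells are never
modified and the iteration is a fixed point of its own output. PCA is by SVD
of the column-standardized matrix (traits arrive on wildly different scales).
Arrangement groups are compared on component scores with the Welch
(unequal-variance) t-test with Satterthwaite degrees of freedom — the groups
are small, imbalanced, and genuinely heteroskedastic, and fractional df is
the observable signature of this choice.

## Variant selection, genomic PCA and GRMs

Three selection strategies: **Full** (MAF > 0.05, missingness < 0.20), **LD**
(MAF > 0.05, missingness < 0.15, greedy pruning to pairwise r² < 0.2 with a
5 kb spacing floor), **LOCO** (LD applied to the complement of one arm).
Pruning scans position-sorted candidates left to right, checking dosage r²
(pairwise-complete, composite LD — phase-free and well defined with missing
data) against the last 50 kept variants; the window is defined over kept
predecessors because only the spacing floor is externally fixed. The scan is
deterministic and idempotent.

Genomic PCA standardizes each variant to `(x − 2p)/√(2p(1−p))`, zeroes
missing entries after centring, and eigendecomposes the line covariance;
scores are eigenvectors scaled by singular values.

GRMs: VanRaden on the Full selection (missing dosages imputed to `2p`; PSD
by construction) and GCTA on the LD/LOCO selections (pairwise-complete
averaging). The pairwise-complete GCTA estimator is not exactly PSD under
missing data because each pair is normalised by its own variant count; at
realistic missingness (≤2%) the most negative eigenvalue is within 2% of the
largest, and the REML fit clips kernel eigenvalues at zero.

## Mixed model, score test and permutations

REML profiles the variance ratio λ = σ²g/σ²e through one eigendecomposition
of the GRM, evaluating the restricted likelihood on {0} ∪ a 17-point log grid
over [1e-4, 1e4] and refining with bounded Brent search (tolerance 1e-8 in
λ). A kernel numerically proportional to the identity makes the components
non-identifiable; the fit flags this and reports the OLS residual variance as
total variance. Score tests are vectorized in the kernel eigenbasis, with
missing dosages mean-imputed within the analysis set so the projection P is
shared by all variants of a scan; the per-variant effect and standard error
(`β = U/Vs`, `se = 1/√Vs`) are the one-step approximations consumed by
colocalization. Variant filters (MAF > 0.05, missingness < 0.15) are
computed on the analysis line set.

The LOCO scan scores each arm's variants against the sub-GRM built without
that arm; the Factored-out scan residualizes the trait on the panel's
inversion dosages (additive coding including HET lines, constant columns
dropped) and uses the Full GRM. Permutations shuffle the raw trait values
across measured lines — before residualization in the factored strategy —
and refit the null model each time; each permutation's generator derives
from (master seed, permutation index), so any single permutation is
reproducible in isolation.

## Summaries, exceedance, enrichment, colocalization

Variants are binned per arm into inside/outside-inversion (1-based inclusive
spans, overlaps unioned). Hit proportion uses strict p < α; the genomic
inflation factor divides the bin's median score-test χ² by the χ²₁ median
0.4549364231. Exceedance compares an observed statistic with the
permutations' 95th percentile under the linear interpolation-between-ranks
convention (with 100 permutations the percentile sits between the 95th and
96th order statistics). Method and region contrasts use two-sided Fisher
exact tests with Clopper–Pearson intervals on proportions.

Enrichment crosses the top-k smallest-p variants (ties broken by genomic
position) with an externally supplied outlier set over the GWA-filtered
universe; odds ratios are reported as sample, conditional-MLE, and
Haldane–Anscombe (+0.5) values, the last used for ranking against permuted
scans so unbounded tables still order.

Colocalization uses the Wakefield log approximate Bayes factor
`½log(1−r) + ½Z²r`, `r = W²/(W² + se²)`, with prior effect SD `W = 0.15`
(the quantitative-trait convention) and priors p1 = p2 = 1e-4, p12 = 1e-5.
Hypothesis sums are accumulated in log space; windows tile each arm from
position 1 (inclusive start, exclusive end) and windows under `min_variants`
are flagged rather than dropped.

## Calibration checks at reduced scale

The acceptance suite verifies the false-positive behaviour of each
permutation device on pure-noise traits with 25 permutations and ~2000
variants. Two design choices keep the devices in their nominal ~5% regime at
this scale: the calibration hit threshold is 5e-4, so the expected null hit
count per scan is of order one (the same counting regime the 10⁻⁵ threshold
produces on a multi-million-variant genome), and the enrichment tables use
40 outliers × top-40 hits. Both choices were fixed from order-statistics
calculations of the exceedance probability before any calibration run; the
expected rates are 5.7–6.2% against an acceptance band of 3–8%. The
matched-null device is calibrated against its own 100 matched variants and
needs no adjustment. The power-contrast check uses 20 inversion-linked
traits (one causal variant inside the span, R² = 0.1) plus 20 null traits;
a single concentrated causal effect is the smallest architecture that can
clear the 10⁻⁵ hit threshold at n = 200 lines.

## Numerical conventions and degenerate inputs

Coordinates are 1-based inclusive everywhere; a variant is inside a span iff
start ≤ pos ≤ end. Dosage 0/1/2 with MAF = allele count/(2n). All-missing
sites are rejected at ingestion; non-biallelic VCF records are skipped with a
logged count; duplicate variant ids, duplicate (line, trait) rows and
unsorted positions are errors. Score variances ≤ 1e-12 mark a variant
skipped. Monomorphic selections raise rather than divide by zero. p-values
from the score test use `erfc(√(χ²/2))`, the exact χ²₁ tail.

## Limitations

- The score-test β/se pairs are one-step approximations, not per-variant
  Wald refits; colocalization posteriors inherit this approximation.
- Binary traits, haplotype tests, dominance/epistatic kernels, and joint
  modelling of multiple inversions are out of scope.
- The simulator's independence of background variants means LD-pruning is
  exercised mainly by the spacing rule and the inversion block; real panels
  prune far more aggressively.
- Welch t on principal-component scores treats scores as fixed data; no
  account is taken of PCA estimation noise.
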