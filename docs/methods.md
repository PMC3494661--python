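# Methods

## The problem

A GWAS tests each SNP marker for association with a binary trait and reports
the loci with the smallest p-values. The number of markers per gene spans
orders of magnitude, so under the global null the minimum p-value inside a
gene with M markers is stochastically smaller the larger M is:
P(min p ≤ t) = 1 − (1 − t)^M for independent uniform p-values. Selecting
genes by their best SNP therefore favours SNP-dense genes, and any
downstream gene-set analysis inherits the bias when gene sets differ in mean
gene size. This package computes per-gene significance that removes (or at
least quantifies) that bias.

## Per-SNP tests

Case/control association uses the Pearson chi-squared test without
continuity correction on a 2 × K table. The default coding is genotypic
(2 × 3 over dosage classes 0/1/2); empty genotype classes are dropped with
the degrees of freedom reduced, which collapses to the 2 × 2 test
automatically. Carrier (dosage ≥ 1) and allelic codings are available.
Missing dosages are dropped per SNP; monomorphic SNPs get p = 1. The G-test
uses 2 Σ O ln(O/E) with zero-observed cells contributing 0.

QC follows standard practice: samples below the call-rate threshold are
removed first; then SNPs failing minor-allele-frequency, call-rate, or
Hardy–Weinberg thresholds (HWE tested by the 1-df chi-squared test in
controls only, since cases can deviate under association).

### Power conventions

`power_two_group` returns by default the **exact** power of the
two-proportion chi-squared test, obtained by enumerating the two binomial
count distributions and summing the probability of the rejection region. At
genome-wide significance levels the discreteness of the table matters: for
5% vs 6% carriers at α = 10⁻⁶ with 1,000 + 1,000 subjects the exact power is
3.3 × 10⁻⁵ while the noncentral-chi-squared approximation (available as
`method="asymptotic"`) gives 4.6 × 10⁻⁵. The G-test power is estimated by
vectorised Monte Carlo over simulated tables (its exact value at the same
design is 4.66 × 10⁻⁵; the G-test rejects slightly more often than Pearson
on discrete tables).

## Gene-level methods

Let p₍₁₎ ≤ … ≤ p₍ₘ₎ be the sorted SNP p-values of a gene (ties broken by
SNP index for determinism) and r the allelic (dosage) correlation matrix.

* **Fisher**: X = −2 Σ ln pᵢ against χ² with 2m df. Assumes independence;
  under positive LD the variance of X is inflated and the test is
  anticonservative, increasingly so for larger m — this is why Fisher fails
  to correct the size bias (it replaces one size-dependent artefact with
  another).
* **Simes**: min over i of m p₍ᵢ₎/i. Valid under independence and
  positive-regression dependence; under LD it discounts by the full m and
  therefore overcorrects slightly (small positive size-bias slopes).
* **GATES** (extended Simes): min over i of m_e p₍ᵢ₎ / m_e(i), where m_e is
  the effective number of independent tests of the whole gene and m_e(i)
  that of the i most significant SNPs. Effective numbers use the
  eigenvalue budget m_e = m − Σ_{λ>1}(λ − 1) on the p-value correlation
  matrix, clipped to [1, m] (exactly m for the identity matrix, exactly 1
  for the all-ones matrix).
* **VEGAS**: the observed T = Σ χ²ᵢ (per-SNP 1-df statistics) is compared
  with Monte Carlo draws T = Σ zᵢ² where z is multivariate normal with
  correlation r. The empirical p-value uses (k + 1)/(n + 1); nsim escalates
  tenfold (default cap 10⁶) while p < 10/nsim so small p-values stay
  resolved.
* **FOSCO** (first-order-statistic correction):
  p_adj = 1 − (1 − p₍₁₎)^(α·M). At α = 1 this is the exact CDF of the
  minimum of M independent uniforms; α < 1 discounts M for LD-induced
  redundancy. Only the minimum p-value and the count M are used — no LD
  matrix — which is the method's point: it applies to any user-defined gene
  units. An alternative exponent form M^α is available
  (`exponent="power"`); both agree at α = 1, and the two cannot be
  distinguished by the α = 1 limit alone, so the linear form (effective
  test count proportional to M) is the default.

### The p-value correlation transform

GATES needs corr(pᵢ, pⱼ) given the dosage correlation r. We tabulate the
**exact** null correlation of two two-sided χ²₁ p-values whose z-statistics
are bivariate normal with correlation r, by Gauss–Legendre quadrature split
at the |z| kink, and interpolate (the function is even in r, 0 at r = 0 and
1 at |r| = 1; at r = 0.8 it equals 0.504). The common quadratic
approximation r² overstates the correlation at strong LD (0.64 at r = 0.8),
which shrinks m_e too aggressively and leaves a residual negative size-bias
slope; the exact transform halves that residual on the reference cohort.

### Numerical choices

* p-values exactly 0 are clamped to 10⁻³⁰⁰ (with a warning) before logs;
  p₍₁₎ is capped below 1 − 10⁻¹⁶ before the FOSCO power.
* Sample LD matrices (pairwise-complete Pearson on dosages, monomorphic
  SNPs zeroed with a warning) are PSD-repaired by eigenvalue clipping at
  10⁻⁸ plus diagonal renormalisation before eigen-analysis or Cholesky.
* VEGAS child seeds are spawned deterministically from the run seed in
  gene-id order, so whole runs are byte-reproducible.
* Genes with M = 0 are excluded from testing and reported in a skipped-genes
  log. Multi-gene SNPs count in every overlapping gene. Coordinates are
  1-based closed; a BED3+1 reader converts on input.

## Tuning α

Following the permutation logic, case/control labels are permuted (genotypes
fixed) so every SNP is null while LD is preserved; α is chosen on one
reserved permutation by enumerating a grid (default 0.05–2.00, step 0.01)
and minimising |Pearson corr(p_adj, M)|, ties toward the smallest α. The
reserved permutation's seed is disjoint from the evaluation permutations.

**Identifiability caveat.** Under exact independence p_adj = 1 − (1 − U)^α
with U uniform and independent of M for *every* α, so the objective is flat
and the grid argmin is sampling noise. More generally, whenever the
effective test count is proportional to M (e.g. fixed-size LD blocks with
homogeneous within-block correlation), the same cancellation occurs; the
correlation objective only has a gradient where the effective-count ratio
varies with M (in block LD, through genes smaller than one block), and even
there E[p_adj | M] is monotone in M for every α, so the minimiser tends to
the grid boundary. The practical consequence — verified on the reference
cohort — is benign: in these regimes FOSCO's size-bias slope is near zero
for *any* α, so the tuned α should be read as "a value achieving minimal
residual correlation", not as a structural LD parameter. On data whose
LD redundancy varies non-proportionally with M, the objective acquires
curvature and the tuned α becomes meaningful.

## Size-bias diagnostics

`size_bias_regression` fits OLS of ln(gene p) on M and reports the slope,
its two-sided t-test p-value, and the intercept. Natural log is the
default; the base only rescales the slope, never its p-value. A constant
response returns slope 0 with slope_p = NaN. `ks_compare_snp_counts` and
`gene_set_size_anova` wrap the two-sample Kolmogorov–Smirnov test and
one-way ANOVA on per-gene SNP counts (genes in several sets count in each,
as annotation categories overlap; sets with fewer than 2 genes are
dropped).

## The synthetic cohort generator

Genotypes are built from two independent haplotype layers: within each LD
block, latent standard Gaussians share an exchangeable correlation and are
thresholded at the MAF quantile; the dosage is the sum of the two layers, so
every SNP is marginally Binomial(2, MAF) — HWE holds by construction.
MAF is drawn per LD block (uniform on `maf_range`, default 0.05–0.5) and
shared by the block's SNPs: tightly linked variants have similar
frequencies, and a dosage-scale LD target is infeasible across strongly
mismatched frequencies (the phi coefficient of 0/1 alleles at MAF 0.05 vs
0.5 cannot exceed ≈ 0.23).

`ld_rho` may be given on two scales: `latent` (the Gaussian correlation
before thresholding; the realised dosage correlation is attenuated) or
`dosage` (the target allelic correlation r, the scale LD is quoted on; the
generator inverts the threshold-Gaussian phi coefficient per block by
bisection on a quadrature formula). Gene intervals are tiled on one
synthetic chromosome with 10 kb gaps and one SNP per 100 bp; positions are
bookkeeping only — there is no recombination or coalescent model, and
between-block/between-gene LD is exactly zero, which real genomes violate.

Per-gene SNP counts default to log-normal(μ = 2.5, σ = 1.2) rounded and
truncated to [1, 200] (median ≈ 12, a heavy right tail), mimicking the
orders-of-magnitude spread of real per-gene marker counts at a size that
keeps a full permutation study on one CPU in minutes.

Phenotypes are either null with exact case/control counts, or logistic in
the causal dosages with the intercept solved by bisection to match the
target case fraction. A fast generator of per-gene null p-value sets
(independent or equicorrelated) supports method-level calibration tests
without genotypes.

**The reference scenario** (`make_study_spec`): 2,000 genes, SNP counts
1–200 as above, LD blocks of 10 SNPs with within-block allelic r = 0.8,
1,000 cases + 1,000 controls. On ten phenotype permutations of one such
cohort the package reproduces the expected pattern (mean slopes of ln p on
M): uncorrected min-p ≈ −2.6 × 10⁻², Fisher ≈ −7 × 10⁻³ and significantly
negative in ≥ 9/10 permutations, Simes and VEGAS slightly positive, FOSCO
and GATES reduced more than tenfold with unremarkable slope p-values.
GATES retains a small negative residual (≈ 4% of the uncorrected bias) —
the effective-number approximation is not exact at strong LD.

## What passing tests do and do not show

The generator's exchangeable blocks make within-gene LD homogeneous, so the
effective test count is nearly proportional to M; real LD is heterogeneous
across genes and scales, which strengthens α's identifiability but can also
make a single global α less adequate. Calibration results on synthetic data
therefore demonstrate correctness of the machinery and the qualitative
bias/correction pattern, not quantitative transfer of α or slope magnitudes
to any particular dataset.

## Known limitations

* No covariates, no imputation, no logistic per-SNP model; dosage TSV only
  (no VCF) in this version.
* Fisher and Simes are included as comparators; neither is recommended for
  LD data.
* The FOSCO exponent form (α·M vs M^α) is a modelling choice; both are
  implemented and agree at α = 1.
* VEGAS sums over all SNPs of a gene (no top-k truncation variant).
* The α grid objective is weakly identified in homogeneous-LD regimes (see
  above); consider inspecting the full grid curve, which `tune_alpha`
  returns, rather than the argmin alone.
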