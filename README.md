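# genesize

Gene-level statistical significance for GWAS, with correction of the
**gene-size bias**: under the null hypothesis, a gene covered by many SNPs is
far more likely to contain the study's smallest p-values than a gene covered
by one SNP, so picking genes near the most significant markers
systematically favours SNP-dense genes and distorts downstream pathway and
gene-set analyses.

The package is for statistical geneticists who have SNP-level association
p-values (and optionally genotypes) and want per-gene p-values that are
calibrated with respect to the number of markers M assigned to each gene.

## Methods

For a gene with m SNP p-values p₍₁₎ ≤ … ≤ p₍ₘ₎ and (optionally) the m × m
allelic correlation matrix r estimated from dosages:

| method | gene-level p-value |
|---|---|
| Fisher  | upper tail of χ²₂ₘ at X = −2 Σᵢ ln pᵢ (independence assumed) |
| Simes   | minᵢ m · p₍ᵢ₎ / i |
| GATES   | minᵢ m_e · p₍ᵢ₎ / m_e(i), with m_e the effective number of independent tests from the eigenvalues of the p-value correlation matrix |
| VEGAS   | Monte Carlo tail of T = Σᵢ χ²ᵢ under multivariate-normal z with correlation r |
| FOSCO   | 1 − (1 − p₍₁₎)^(α·M), the first-order-statistic correction; α = 1 is exact for independent SNPs, and α is tuned on a phenotype permutation by grid search minimising \|corr(p_adj, M)\| |

Effective test counts use m_e = m − Σ_{λ>1}(λ − 1) over the eigenvalues λ of
the p-value correlation matrix; the p-value correlation is the exact null
correlation of two-sided χ²₁ p-values given the z correlation, tabulated by
quadrature. Diagnostics quantify the bias as the OLS slope of ln(gene p) on
M (negative slope = large genes favoured), plus a two-sample
Kolmogorov–Smirnov comparison of SNP-count distributions and a one-way ANOVA
of SNP counts across gene sets.

A synthetic cohort generator provides case/control dosage data with
Hardy–Weinberg marginals, block LD (latent threshold-Gaussian haplotypes,
with an option to target the allelic correlation scale directly), per-gene
SNP counts spanning orders of magnitude, and null or causal phenotypes.

## Worked example

The classic single-SNP vs large-gene comparison: a causal SNP whose risk
genotype moves from 5% (controls) to 6% (cases) in a 1,000 + 1,000 study,
versus a null gene with 100 SNPs, both judged at the 10⁻⁶ threshold:

```python
>>> from genesize import power_two_group, min_p_exceedance
>>> power_two_group(0.05, 0.06, 1000, 1000, 1e-6)   # exact chi-squared power
3.304137471065317e-05
>>> min_p_exceedance(100, 1e-6)                      # P(any of 100 null SNPs < 1e-6)
9.999505016169608e-05
```

The null 100-SNP gene is **three times more likely** to be reported than the
truly causal single-SNP gene — that is the bias this package corrects.

End-to-end on synthetic data:

```bash
genesize simulate --spec spec.yaml --out-prefix sim/
genesize assoc --cohort sim/dosages.tsv --pheno sim/phenotype.tsv --out pv.tsv
genesize genetest --pvalues snps_with_p.tsv --genes sim/genes.tsv \
    --method fosco --alpha 1.0 --out res.tsv
```

yields one adjusted p-value per gene:

```
gene_id  method  M   p_adj                extras_json
gA       fosco   1   0.8981100333940047   {"alpha": 1.0, "exponent": "linear"}
gB       fosco   6   0.630832180303017    {"alpha": 1.0, "exponent": "linear"}
gC       fosco   12  0.4701202198901172   {"alpha": 1.0, "exponent": "linear"}
```

(for gA, M = 1, the adjusted value equals the SNP's own p-value). Other
subcommands: `tune-alpha` (grid-search α on a phenotype permutation),
`evaluate` (multi-permutation size-bias diagnostics), `diagnose`, `ks`,
`anova`. Every subcommand writes a JSON run manifest (inputs, config, seeds)
next to its output.

## Layout

- `src/genesize/datamodel.py` — tables, TSV/BED I/O, SNP-to-gene assignment
- `src/genesize/assoc.py` — per-SNP χ²/G tests, QC, power calculations
- `src/genesize/genelevel.py` — the five gene-level methods and LD machinery
- `src/genesize/tuning.py` — phenotype permutation and α grid search
- `src/genesize/diagnostics.py` — size-bias regression, KS, ANOVA
- `src/genesize/synthcohort.py` — synthetic cohort generator
- `src/genesize/cli.py` — the `genesize` command
- `docs/methods.md` — modelling assumptions, defaults, and limitations
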