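"""Phenotype permutation and the grid search calibrating FOSCO's alpha.

Under a permuted phenotype every SNP is null, so a well-calibrated
gene-level p-value must be unrelated to the gene's SNP count M.  alpha is
chosen by enumerating a grid and picking the value minimizing the absolute
Pearson correlation between the FOSCO-adjusted p-values and M on one
reserved permutation; the remaining permutations then evaluate all methods
via the size-bias regression.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from genesize.assoc import CohortData, per_snp_scan
from genesize.datamodel import GeneSnpMap
from genesize.diagnostics import size_bias_regression
from genesize.genelevel import fosco_adjust, run_gene_tests


@dataclass
class AlphaSearchResult:
    alpha_star: float
    grid: list[tuple[float, float]] = field(default_factory=list)
    permutation_seed: int | None = None

    def as_dict(self) -> dict:
        return {
            "alpha_star": self.alpha_star,
            "grid": [[a, c] for a, c in self.grid],
            "permutation_seed": self.permutation_seed,
        }


def permute_phenotype(phenotype, seed: int) -> np.ndarray:
    """Uniform random permutation of the 0/1 labels (counts preserved)."""
    y = np.asarray(phenotype)
    rng = np.random.default_rng(seed)
    return y[rng.permutation(y.shape[0])]


def tune_alpha(
    min_p_per_gene,
    M_per_gene,
    grid_lo: float = 0.05,
    grid_hi: float = 2.0,
    grid_step: float = 0.01,
    exponent: str = "linear",
    rank_corr: bool = False,
    permutation_seed: int | None = None,
) -> AlphaSearchResult:
    """Grid search for the alpha minimizing |corr(p_adj, M)|.

    ``min_p_per_gene`` are the per-gene minimum SNP p-values from a single
    permuted (null) dataset; correlation is Pearson on the raw adjusted
    p-values by default (Spearman via ``rank_corr=True``).  Ties break
    toward the smallest alpha.
    """
    p1 = np.asarray(min_p_per_gene, dtype=float)
    m = np.asarray(M_per_gene, dtype=float)
    if p1.shape != m.shape or p1.size < 10:
        raise ValueError("need matching vectors of length >= 10")
    if np.ptp(m) == 0:
        raise ValueError("correlation with M undefined: all genes have equal M")
    if not 0 < grid_lo < grid_hi:
        raise ValueError("require 0 < grid_lo < grid_hi")
    alphas = np.round(np.arange(grid_lo, grid_hi + grid_step / 2, grid_step), 10)
    if rank_corr:
        m_v = pd.Series(m).rank().to_numpy()
    else:
        m_v = m
    grid = []
    for a in alphas:
        padj = fosco_adjust(p1, m, a, exponent=exponent)
        y = pd.Series(padj).rank().to_numpy() if rank_corr else padj
        c = np.corrcoef(y, m_v)[0, 1]
        grid.append((float(a), float(abs(c))))
    best = min(range(len(grid)), key=lambda i: (grid[i][1], grid[i][0]))
    return AlphaSearchResult(
        alpha_star=grid[best][0], grid=grid, permutation_seed=permutation_seed
    )


def evaluate_on_permutations(
    cohort: CohortData,
    gene_map: GeneSnpMap,
    methods: list[str],
    n_perms: int = 10,
    base_seed: int = 0,
    scan_mode: str = "genotypic2x3",
    alpha: float | None = None,
    fosco_exponent_form: str = "linear",
    nsim: int = 1000,
    grid: tuple[float, float, float] = (0.05, 2.0, 0.01),
) -> tuple[pd.DataFrame, AlphaSearchResult | None]:
    """Permutation evaluation of gene-level methods for size bias.

    For each of ``n_perms`` phenotype permutations: rescan the cohort,
    compute every method's gene-level p-values, and regress their log on M.
    When ``fosco`` is requested and ``alpha`` is None, one additional
    held-out permutation (a seed disjoint from the evaluation seeds) is
    used to tune alpha first.  Returns the per-permutation diagnostics
    table and the tuning result (None if not tuned).
    """
    if n_perms < 1:
        raise ValueError("n_perms must be >= 1")
    seed_seq = np.random.SeedSequence(base_seed)
    # one extra child reserved up front for tuning, disjoint from evaluation
    children = seed_seq.spawn(n_perms + 1)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in children]
    tune_seed, eval_seeds = seeds[0], seeds[1:]
    counts = gene_map.counts()
    gene_ids = sorted(gene_map.tested_genes())
    M = counts.loc[gene_ids].to_numpy()

    ld_cache: dict = {}
    tuning_result = None
    if "fosco" in methods and alpha is None:
        y = permute_phenotype(cohort.phenotype, tune_seed)
        pvals = per_snp_scan(
            CohortData(cohort.dosages, y, cohort.subject_ids, cohort.snp_ids),
            mode=scan_mode,
        )
        minp = run_gene_tests(pvals, gene_map, "minp")
        minp = minp.set_index("gene_id").loc[gene_ids]
        tuning_result = tune_alpha(
            minp["p_adj"].to_numpy(), M, *grid,
            exponent=fosco_exponent_form, permutation_seed=tune_seed,
        )
        alpha = tuning_result.alpha_star

    rows = []
    for k, s in enumerate(eval_seeds):
        y = permute_phenotype(cohort.phenotype, s)
        perm_cohort = CohortData(cohort.dosages, y, cohort.subject_ids, cohort.snp_ids)
        pvals = per_snp_scan(perm_cohort, mode=scan_mode)
        for method in methods:
            res = run_gene_tests(
                pvals, gene_map, method,
                cohort=perm_cohort, ld_cache=ld_cache,
                alpha=alpha if alpha is not None else 1.0,
                fosco_exponent_form=fosco_exponent_form,
                nsim=nsim, seed=s,
            )
            reg = size_bias_regression(res["p_adj"].to_numpy(), res["M"].to_numpy())
            rows.append(
                {
                    "perm": k,
                    "seed": s,
                    "method": method,
                    "slope": reg.slope,
                    "slope_p": reg.slope_p,
                    "intercept": reg.intercept,
                    "n_genes": reg.n_genes,
                    "alpha": alpha if method == "fosco" else np.nan,
                }
            )
    return pd.DataFrame(rows), tuning_result
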