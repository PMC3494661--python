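"""Gene-size bias diagnostics.

Three checks quantify whether gene-level significance is biased toward
genes covered by many SNPs:

* :func:`size_bias_regression` — OLS of log gene p-value on the SNP count
  M; a significantly negative slope means large genes get smaller p-values
  under the null (the bias), a slope near zero with a uniform slope_p over
  permutations means the correction worked.
* :func:`ks_compare_snp_counts` — two-sample Kolmogorov–Smirnov comparison
  of SNP-count distributions (e.g. reported trait-related genes vs all
  annotated genes).
* :func:`gene_set_size_anova` — one-way ANOVA of per-gene SNP counts across
  gene sets (e.g. GO categories), testing whether sets differ in mean size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from genesize.genelevel import P_FLOOR


@dataclass
class BiasRegressionResult:
    slope: float
    slope_p: float
    intercept: float
    n_genes: int
    log_base: float = np.e

    def as_dict(self) -> dict:
        return {
            "slope": self.slope,
            "slope_p": self.slope_p,
            "intercept": self.intercept,
            "n_genes": self.n_genes,
            "log_base": self.log_base,
        }


def size_bias_regression(
    gene_pvalues, M, log_base: float = np.e
) -> BiasRegressionResult:
    """OLS of log(gene p-value) on SNP count M with the slope's t-test.

    Natural log by default; changing the base rescales the slope and
    intercept but leaves the slope p-value untouched.  A constant response
    (zero residual variance) yields slope 0 with slope_p = NaN.
    """
    p = np.asarray(gene_pvalues, dtype=float)
    m = np.asarray(M, dtype=float)
    if p.shape != m.shape or p.size < 3:
        raise ValueError("need matching vectors of length >= 3")
    if np.ptp(m) == 0:
        raise ValueError("regression on constant M is undefined")
    if (p <= 0).any():
        warnings.warn("p-values at 0 clamped before taking logs")
        p = np.clip(p, P_FLOOR, None)
    y = np.log(p) / np.log(log_base)
    if np.ptp(y) == 0:
        return BiasRegressionResult(0.0, np.nan, float(y[0]), p.size, log_base)
    fit = stats.linregress(m, y)
    return BiasRegressionResult(
        float(fit.slope), float(fit.pvalue), float(fit.intercept), p.size, log_base
    )


def ks_compare_snp_counts(counts_a, counts_b) -> tuple[float, float]:
    """Two-sample KS statistic and asymptotic p-value on SNP-count vectors."""
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both count vectors must be non-empty")
    res = stats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


def gene_set_size_anova(
    sets: dict[str, np.ndarray], min_genes: int = 2, log_stream=None
) -> tuple[float, float, int, int]:
    """One-way ANOVA of per-gene SNP counts across gene sets.

    Sets with fewer than ``min_genes`` members are dropped (with an
    optional log line); genes belonging to several sets contribute to each,
    matching overlapping annotation categories.  Returns
    ``(F, p, df_between, df_within)``.
    """
    usable = {k: np.asarray(v, dtype=float) for k, v in sets.items()
              if len(v) >= min_genes}
    dropped = sorted(set(sets) - set(usable))
    if dropped and log_stream is not None:
        print(
            f"genesize: {len(dropped)} gene set(s) with < {min_genes} genes "
            f"excluded from ANOVA: {', '.join(dropped[:10])}",
            file=log_stream,
        )
    if len(usable) < 2:
        raise ValueError("ANOVA needs at least 2 gene sets with >= 2 genes each")
    groups = list(usable.values())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f, p = stats.f_oneway(*groups)
    k = len(groups)
    n = sum(len(g) for g in groups)
    if np.isnan(f):  # all groups constant and equal, or zero within-variance
        grand = np.concatenate(groups)
        if np.ptp(grand) == 0:
            f, p = 0.0, 1.0
        else:
            f, p = np.inf, 0.0
    return float(f), float(p), k - 1, n - k


def summarize_counts(counts_a, counts_b) -> dict:
    """Means and log2-binned histograms of two SNP-count vectors.

    Zero counts go into a dedicated ``0`` bin (log2 undefined); positive
    counts are binned by floor(log2(count)).
    """
    out = {}
    for name, v in (("a", counts_a), ("b", counts_b)):
        v = np.asarray(v, dtype=float)
        if v.size == 0:
            raise ValueError("count vectors must be non-empty")
        pos = v[v > 0]
        hist: dict[str, int] = {"0": int((v == 0).sum())}
        if pos.size:
            bins = np.floor(np.log2(pos)).astype(int)
            for b in range(bins.min(), bins.max() + 1):
                hist[f"2^{b}"] = int((bins == b).sum())
        out[f"mean_{name}"] = float(v.mean())
        out[f"hist_{name}"] = hist
    return out


def gene_sets_from_table(genes: pd.DataFrame, counts: pd.Series) -> dict[str, np.ndarray]:
    """Build the set-label -> SNP-count-vector mapping from a gene table's
    comma-separated ``sets`` column and a per-gene count series."""
    sets: dict[str, list] = {}
    for row in genes.itertuples(index=False):
        labels = [s for s in str(row.sets).split(",") if s]
        for lab in labels:
            sets.setdefault(lab, []).append(counts.get(row.gene_id, 0))
    return {k: np.asarray(v) for k, v in sets.items()}
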