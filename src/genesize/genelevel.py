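"""Gene-level significance methods: Fisher, Simes, GATES, VEGAS and FOSCO.

All five combine per-SNP p-values (or chi-squared statistics) assigned to a
gene into a single gene-level p-value.  Fisher and Simes assume independent
SNPs; GATES replaces the raw SNP count with an effective number of
independent tests derived from the eigenvalues of the p-value correlation
matrix; VEGAS simulates the null of the summed chi-squared statistic under
the gene's LD; FOSCO adjusts the minimum p-value by the first-order
statistic of an effective number of uniforms, ``1 - (1 - p_(1))^(alpha M)``,
with the exponent's scale ``alpha`` tuned by phenotype permutation (see
:mod:`genesize.tuning`).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from genesize.assoc import CohortData
from genesize.datamodel import GeneSnpMap

P_FLOOR = 1e-300
P_CEIL = 1.0 - 1e-16


@dataclass
class GeneLevelResult:
    gene_id: str
    method: str
    p_adj: float
    M: int
    extras: dict = field(default_factory=dict)


def _clamp_pvalues(p: np.ndarray, floor: float = P_FLOOR) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value set")
    if np.isnan(p).any():
        raise ValueError("missing p-values must be dropped upstream")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    if (p <= 0).any():
        warnings.warn("p-values at 0 clamped before logs/powers")
        p = np.clip(p, floor, None)
    return p


def fisher_combine(pvalues, gene_id: str = "") -> GeneLevelResult:
    """Fisher's combined probability test: X = -2 sum(ln p_i) ~ chi2(2m)."""
    p = _clamp_pvalues(pvalues)
    m = p.size
    x = -2.0 * np.log(p).sum()
    p_adj = float(stats.chi2.sf(x, 2 * m))
    return GeneLevelResult(gene_id, "fisher", p_adj, m, {"statistic": float(x)})


def simes(pvalues, gene_id: str = "") -> GeneLevelResult:
    """Simes combination: min over i of m * p_(i) / i, capped at 1."""
    p = np.sort(np.asarray(pvalues, dtype=float))
    if p.size == 0:
        raise ValueError("empty p-value set")
    m = p.size
    ranks = np.arange(1, m + 1)
    p_adj = float(min(1.0, (m * p / ranks).min()))
    return GeneLevelResult(gene_id, "simes", p_adj, m, {})


def effective_number(corr: np.ndarray) -> float:
    """Effective number of independent tests from a correlation matrix.

    m_e = m - sum over eigenvalues > 1 of (lambda - 1), clipped to [1, m]
    (the Li–Ji-style eigenvalue budget: a block of perfectly correlated
    tests contributes a single effective test).
    """
    c = np.asarray(corr, dtype=float)
    m = c.shape[0]
    if c.shape != (m, m):
        raise ValueError("correlation matrix must be square")
    if m == 1:
        return 1.0
    lam = np.linalg.eigvalsh(c)
    if lam[0] < -1e-6:
        raise ValueError("correlation matrix is not positive semi-definite")
    me = m - float(lam[lam > 1.0].sum() - (lam > 1.0).sum())
    return float(np.clip(me, 1.0, m))


def _pvalue_corr_table(n_grid: int = 51, n_nodes: int = 80):
    """Tabulate the exact null correlation of two-sided chi-squared(1)
    p-values as a function of the z-statistic correlation.

    With (z_i, z_j) bivariate standard normal with correlation r and
    p = 2 Phi(-|z|) ~ Uniform(0,1), corr(p_i, p_j) = 12 (E[p_i p_j] - 1/4),
    computed by Gauss–Hermite quadrature on z_j = r z_i + sqrt(1-r^2) w.
    The function is even in r, 0 at r = 0 and 1 at |r| = 1.
    """
    # split at the |z| kink: integrate over the positive quadrant only,
    # pairing the (+,+) and (+,-) quadrants of the bivariate density
    nodes, weights = np.polynomial.legendre.leggauss(n_nodes)
    hi = 9.0
    u = 0.5 * hi * (nodes + 1.0)
    w = 0.5 * hi * weights
    h = 2.0 * stats.norm.sf(u)  # p-value as a function of |z|
    uu, vv = np.meshgrid(u, u, indexing="ij")
    ww = np.outer(w * h, w * h)
    rs = np.linspace(0.0, 1.0, n_grid)
    out = np.empty(n_grid)
    for k, r in enumerate(rs):
        if r >= 1.0:
            out[k] = 1.0
            continue
        det = 1.0 - r * r
        norm = 1.0 / (2.0 * np.pi * np.sqrt(det))
        q_same = norm * np.exp(-(uu**2 - 2 * r * uu * vv + vv**2) / (2 * det))
        q_opp = norm * np.exp(-(uu**2 + 2 * r * uu * vv + vv**2) / (2 * det))
        e_pq = 2.0 * (ww * (q_same + q_opp)).sum()
        out[k] = 12.0 * (e_pq - 0.25)
    return rs, out


_PCORR_GRID, _PCORR_VALS = _pvalue_corr_table()


def pvalue_correlation(r: np.ndarray) -> np.ndarray:
    """Null correlation between the p-values of two 1-df chi-squared SNP
    tests given the allelic (dosage) correlation r of the underlying
    z-statistics.

    Evaluated from a quadrature-exact table (even in r; 0 at r = 0, 1 at
    |r| = 1); close to r^2 for weak LD but noticeably larger at strong LD,
    where the quadratic approximation undercorrects.
    """
    r = np.asarray(r, dtype=float)
    return np.interp(np.abs(r), _PCORR_GRID, _PCORR_VALS)


def psd_repair(corr: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    """Clip negative eigenvalues and re-normalize to unit diagonal.

    Sample correlation matrices built pairwise-complete can be indefinite;
    multivariate-normal sampling and the eigenvalue budget require PSD.
    """
    c = np.asarray(corr, dtype=float)
    c = (c + c.T) / 2.0
    lam, vec = np.linalg.eigh(c)
    if lam[0] >= eps:
        return c
    lam = np.clip(lam, eps, None)
    c = (vec * lam) @ vec.T
    d = np.sqrt(np.diag(c))
    c = c / np.outer(d, d)
    np.fill_diagonal(c, 1.0)
    return c


def gates(
    pvalues,
    ld: np.ndarray,
    gene_id: str = "",
    transform=pvalue_correlation,
) -> GeneLevelResult:
    """Extended Simes test with LD-derived effective test counts.

    With p-values sorted ascending, p_adj = min over i of
    ``m_e * p_(i) / m_e(i)`` where m_e is the effective number of tests
    for the whole gene and m_e(i) the effective number among the top-i SNPs.
    Under identity LD this reduces exactly to Simes; under perfect LD it
    returns the minimum p-value unadjusted.
    """
    p = np.asarray(pvalues, dtype=float)
    r = np.asarray(ld, dtype=float)
    m = p.size
    if r.shape != (m, m):
        raise ValueError("LD matrix does not match the p-value set")
    order = np.lexsort((np.arange(m), p))  # stable: ties broken by SNP index
    p_sorted = p[order]
    c = psd_repair(transform(r[np.ix_(order, order)]))
    me_full = effective_number(c)
    me_top = np.empty(m)
    for i in range(1, m + 1):
        me_top[i - 1] = effective_number(c[:i, :i])
    p_adj = float(min(1.0, (me_full * p_sorted / me_top).min()))
    return GeneLevelResult(gene_id, "gates", p_adj, m, {"m_e": me_full})


def vegas(
    chisq_stats,
    ld: np.ndarray,
    nsim: int = 1000,
    seed: int | None = None,
    gene_id: str = "",
    adaptive: bool = True,
    max_nsim: int = 1_000_000,
) -> GeneLevelResult:
    """Monte Carlo p-value for the sum of per-SNP 1-df chi-squared
    statistics under the gene's LD.

    Null sums are generated as T = sum(z^2) with z multivariate normal with
    the (PSD-repaired) LD correlation; the empirical p-value uses the
    (k + 1)/(n + 1) estimator.  When ``adaptive``, nsim escalates tenfold
    (up to ``max_nsim``) while the p-value is too small to be resolved.
    """
    t = np.asarray(chisq_stats, dtype=float)
    m = t.size
    r = np.asarray(ld, dtype=float)
    if r.shape != (m, m):
        raise ValueError("LD matrix does not match the statistic vector")
    if nsim < 1000:
        raise ValueError("nsim must be at least 1000")
    t_obs = float(t.sum())
    chol = np.linalg.cholesky(psd_repair(r) + 1e-10 * np.eye(m))
    rng = np.random.default_rng(seed)
    n_used = 0
    exceed = 0
    cur = nsim
    while True:
        draw = cur - n_used
        z = rng.standard_normal((draw, m)) @ chol.T
        exceed += int(((z**2).sum(axis=1) >= t_obs).sum())
        n_used = cur
        p_adj = (exceed + 1) / (n_used + 1)
        if not adaptive or p_adj >= 10.0 / n_used or n_used >= max_nsim:
            break
        cur = min(n_used * 10, max_nsim)
    if p_adj <= 1.0 / (n_used + 1) + 1e-15:
        warnings.warn(
            f"VEGAS p-value at Monte Carlo resolution limit (nsim={n_used})"
        )
    return GeneLevelResult(
        gene_id, "vegas", float(p_adj), m,
        {"nsim": n_used, "seed": seed, "T_obs": t_obs},
    )


def fosco(
    pvalues,
    alpha: float,
    gene_id: str = "",
    exponent: str = "linear",
) -> GeneLevelResult:
    """First Order Statistic Correction of the gene's minimum p-value.

    p_adj = 1 - (1 - p_(1))^(alpha * M) (``exponent='linear'``, default) or
    1 - (1 - p_(1))^(M^alpha) (``exponent='power'``).  At alpha = 1 both
    equal the exact distribution of the minimum of M independent uniforms;
    alpha < 1 discounts the count for LD-induced dependence.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value set")
    m = p.size
    p1 = float(np.clip(p.min(), 0.0, P_CEIL))
    e = fosco_exponent(m, alpha, exponent)
    p_adj = float(-np.expm1(e * np.log1p(-p1)))
    return GeneLevelResult(
        gene_id, "fosco", p_adj, m, {"alpha": alpha, "exponent": exponent}
    )


def fosco_exponent(M, alpha: float, exponent: str = "linear"):
    M = np.asarray(M, dtype=float)
    if exponent == "linear":
        return alpha * M
    if exponent == "power":
        return M**alpha
    raise ValueError(f"unknown fosco exponent form {exponent!r}")


def fosco_adjust(min_p, M, alpha: float, exponent: str = "linear") -> np.ndarray:
    """Vectorized FOSCO adjustment of per-gene minimum p-values."""
    p1 = np.clip(np.asarray(min_p, dtype=float), 0.0, P_CEIL)
    e = fosco_exponent(M, alpha, exponent)
    return -np.expm1(e * np.log1p(-p1))


def estimate_ld(cohort: CohortData, snp_indices) -> np.ndarray:
    """Pairwise-complete Pearson correlation of dosage vectors.

    Missing dosages (< 0) are excluded pair by pair; monomorphic SNPs get
    zero correlation with everything (with a warning); the result is
    PSD-repaired so it can feed GATES and VEGAS directly.
    """
    idx = np.asarray(snp_indices, dtype=int)
    d = cohort.dosages[:, idx].astype(float)
    d[d < 0] = np.nan
    m = d.shape[1]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        if np.isnan(d).any():
            r = pd.DataFrame(d).corr(min_periods=2).to_numpy()
        else:
            sd = d.std(axis=0)
            if (sd == 0).any():
                r = np.full((m, m), np.nan)
                ok = sd > 0
                if ok.any():
                    r[np.ix_(ok, ok)] = np.corrcoef(d[:, ok], rowvar=False)
            else:
                r = np.atleast_2d(np.corrcoef(d, rowvar=False))
    if np.isnan(r).any():
        warnings.warn("monomorphic or unestimable SNP pairs set to r = 0")
        r = np.nan_to_num(r, nan=0.0)
    np.fill_diagonal(r, 1.0)
    return psd_repair(np.clip(r, -1.0, 1.0))


_METHODS = ("fisher", "simes", "gates", "vegas", "fosco", "minp")
_LD_METHODS = ("gates", "vegas")


def run_gene_tests(
    snp_pvalues,
    gene_map: GeneSnpMap,
    method: str,
    cohort: CohortData | None = None,
    ld_cache: dict | None = None,
    alpha: float = 1.0,
    fosco_exponent_form: str = "linear",
    nsim: int = 1000,
    seed: int | None = None,
    adaptive_nsim: bool = True,
    max_nsim: int = 1_000_000,
) -> pd.DataFrame:
    """Apply one gene-level method to every gene with at least one SNP.

    ``minp`` is the uncorrected minimum p-value pseudo-method used as the
    bias baseline.  GATES and VEGAS need an LD source: either ``cohort``
    (LD estimated from dosages, optionally memoized in ``ld_cache`` keyed by
    gene_id) or precomputed matrices already present in ``ld_cache``.
    Results are ordered by gene_id; VEGAS child seeds are drawn
    deterministically from ``seed`` in that order.
    """
    if method not in _METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {_METHODS}")
    p_all = np.asarray(snp_pvalues, dtype=float)
    gene_ids = sorted(gene_map.tested_genes())
    if method in _LD_METHODS and cohort is None and not ld_cache:
        raise ValueError(f"method {method!r} requires genotypes (cohort) for LD")
    seed_seq = np.random.SeedSequence(seed if seed is not None else 0)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in seed_seq.spawn(len(gene_ids))]

    rows = []
    for gi, gid in enumerate(gene_ids):
        idx = gene_map.mapping[gid]
        p = p_all[idx]
        keep = ~np.isnan(p)
        idx, p = idx[keep], p[keep]
        if p.size == 0:
            continue
        if method in _LD_METHODS:
            ld = None
            if ld_cache is not None:
                ld = ld_cache.get(gid)
            if ld is None:
                ld = estimate_ld(cohort, idx)
                if ld_cache is not None:
                    ld_cache[gid] = ld
        if method == "fisher":
            res = fisher_combine(p, gid)
        elif method == "simes":
            res = simes(p, gid)
        elif method == "gates":
            res = gates(p, ld, gid)
        elif method == "vegas":
            t = stats.chi2.isf(np.clip(p, P_FLOOR, 1.0), 1)
            res = vegas(
                t, ld, nsim=nsim, seed=child_seeds[gi], gene_id=gid,
                adaptive=adaptive_nsim, max_nsim=max_nsim,
            )
        elif method == "fosco":
            res = fosco(p, alpha, gid, exponent=fosco_exponent_form)
        else:  # minp
            res = GeneLevelResult(gid, "minp", float(p.min()), int(p.size), {})
        rows.append(
            (res.gene_id, res.method, res.M, res.p_adj, json.dumps(res.extras))
        )
    return pd.DataFrame(
        rows, columns=["gene_id", "method", "M", "p_adj", "extras_json"]
    )
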