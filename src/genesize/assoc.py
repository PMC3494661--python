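"""Per-SNP case/control association tests, QC, and power calculations.

The association test is the Pearson chi-squared test without Yates
continuity correction, applied to a 2 x K contingency table of case/control
counts over genotype classes.  Three codings are supported:

* ``genotypic2x3`` — the three dosage classes 0/1/2 (empty classes are
  dropped with the degrees of freedom reduced, so a SNP with a missing
  genotype class collapses to a 2 x 2 test);
* ``carrier2x2``  — carriers (dosage >= 1) vs non-carriers;
* ``allelic2x2``  — allele counts (2n alleles per subject).

Power helpers implement the single-SNP worked example: the analytic power
of the two-proportion chi-squared test via the noncentral chi-squared
distribution, a Monte Carlo G-test power estimate, and the probability that
the minimum of M independent uniform p-values falls below a threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class CohortData:
    """Subjects x SNPs dosage matrix with binary phenotype labels.

    ``dosages`` is an integer matrix with values {0, 1, 2} and -1 for
    missing; ``phenotype`` is 0/1 with 1 = case.
    """

    dosages: np.ndarray
    phenotype: np.ndarray
    subject_ids: list[str] | None = None
    snp_ids: list[str] | None = None

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages)
        self.phenotype = np.asarray(self.phenotype).astype(np.int8)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (subjects x SNPs)")
        if self.dosages.shape[0] != self.phenotype.shape[0]:
            raise ValueError("phenotype length must match number of subjects")
        if not (self.phenotype == 1).any() or not (self.phenotype == 0).any():
            raise ValueError("cohort needs at least one case and one control")

    @property
    def n_subjects(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]


@dataclass
class QcThresholds:
    """QC thresholds: exclude samples with call rate below
    ``min_sample_call_rate``, then SNPs with MAF below ``min_maf``, call rate
    below ``min_snp_call_rate``, or control-group HWE p-value below
    ``max_hwe_p_exclusion``."""

    min_maf: float = 0.01
    min_snp_call_rate: float = 0.95
    max_hwe_p_exclusion: float = 1e-7
    min_sample_call_rate: float = 0.97

    def __post_init__(self):
        for name in ("min_maf", "min_snp_call_rate", "max_hwe_p_exclusion",
                     "min_sample_call_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


def _chisq_core(table: np.ndarray, statistic: str) -> tuple[float, float]:
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] != 2:
        raise ValueError("expected a 2 x K table")
    if (obs < 0).any():
        raise ValueError("counts must be non-negative")
    row = obs.sum(axis=1)
    if (row == 0).any():
        raise ValueError("both row sums must be positive")
    col = obs.sum(axis=0)
    keep = col > 0
    df = int(keep.sum()) - 1
    if df <= 0:
        return 0.0, 1.0
    obs = obs[:, keep]
    n = obs.sum()
    exp = np.outer(row, col[keep]) / n
    if statistic == "pearson":
        stat = float(((obs - exp) ** 2 / exp).sum())
    else:  # G-test; zero-observed cells contribute 0 (O ln(O/E) -> 0)
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(obs > 0, obs * np.log(obs / exp), 0.0)
        stat = float(2.0 * terms.sum())
    return stat, float(stats.chi2.sf(stat, df))


def pearson_chisq(table) -> tuple[float, float]:
    """Pearson chi-squared test (no Yates correction) on a 2 x K table.

    Columns with zero total are dropped and df reduced accordingly; a table
    with a single non-empty column yields statistic 0, p = 1.
    """
    return _chisq_core(table, "pearson")


def g_test(table) -> tuple[float, float]:
    """Log-likelihood-ratio (G) test on a 2 x K table, same df convention
    as :func:`pearson_chisq`."""
    return _chisq_core(table, "g")


def _group_genotype_counts(cohort: CohortData) -> tuple[np.ndarray, np.ndarray]:
    """(2 groups x 3 classes x m SNPs) counts, missing dosages excluded."""
    d = cohort.dosages
    case = cohort.phenotype == 1
    counts = np.empty((2, 3, d.shape[1]), dtype=np.int64)
    for k in range(3):
        is_k = d == k
        counts[0, k] = is_k[case].sum(axis=0)
        counts[1, k] = is_k[~case].sum(axis=0)
    return counts[0], counts[1]


def _vectorized_2xk_pvalues(obs: np.ndarray) -> np.ndarray:
    """p-values for stacked 2 x K tables, shape (2, K, m).

    Empty columns are dropped per SNP via df reduction; SNPs where fewer
    than two columns are populated get p = 1 (monomorphic).
    """
    obs = obs.astype(float)
    row = obs.sum(axis=1)  # (2, m)
    col = obs.sum(axis=0)  # (K, m)
    n = row.sum(axis=0)  # (m,)
    with np.errstate(divide="ignore", invalid="ignore"):
        exp = row[:, None, :] * col[None, :, :] / n
        terms = np.where(exp > 0, (obs - exp) ** 2 / exp, 0.0)
    stat = terms.sum(axis=(0, 1))
    df = (col > 0).sum(axis=0) - 1
    pvals = np.ones(obs.shape[2])
    ok = df >= 1
    pvals[ok] = stats.chi2.sf(stat[ok], df[ok])
    return pvals


def per_snp_scan(
    cohort: CohortData, mode: str = "genotypic2x3", log_stream=None
) -> np.ndarray:
    """One association p-value per SNP under the chosen table coding.

    Missing dosages are dropped per SNP; monomorphic SNPs get p = 1 and are
    counted in a log line on ``log_stream`` (default: silent).
    """
    case_counts, ctrl_counts = _group_genotype_counts(cohort)
    if mode == "genotypic2x3":
        obs = np.stack([case_counts, ctrl_counts])  # (2, 3, m)
    elif mode == "carrier2x2":
        obs = np.stack(
            [
                np.stack([case_counts[0], case_counts[1] + case_counts[2]]),
                np.stack([ctrl_counts[0], ctrl_counts[1] + ctrl_counts[2]]),
            ]
        )
    elif mode == "allelic2x2":
        # allele counts: minor-allele copies vs the rest of the 2n alleles
        case_alt = (case_counts[1] + 2 * case_counts[2]).astype(np.int64)
        ctrl_alt = (ctrl_counts[1] + 2 * ctrl_counts[2]).astype(np.int64)
        case_tot = 2 * case_counts.sum(axis=0)
        ctrl_tot = 2 * ctrl_counts.sum(axis=0)
        obs = np.stack(
            [
                np.stack([case_alt, case_tot - case_alt]),
                np.stack([ctrl_alt, ctrl_tot - ctrl_alt]),
            ]
        )
    else:
        raise ValueError(f"unknown scan mode {mode!r}")
    pvals = _vectorized_2xk_pvalues(obs)
    if log_stream is not None:
        total = (case_counts + ctrl_counts)
        mono = ((total > 0).sum(axis=0) <= 1).sum()
        if mono:
            print(f"genesize: {mono} monomorphic SNP(s) set to p = 1", file=log_stream)
    return pvals


def hwe_chisq_p(n0: np.ndarray, n1: np.ndarray, n2: np.ndarray) -> np.ndarray:
    """Vectorized 1-df chi-squared HWE test from genotype counts."""
    n0 = np.asarray(n0, dtype=float)
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    n = n0 + n1 + n2
    with np.errstate(divide="ignore", invalid="ignore"):
        p = (n1 + 2 * n2) / (2 * n)
        e0 = n * (1 - p) ** 2
        e1 = n * 2 * p * (1 - p)
        e2 = n * p**2
        stat = np.zeros_like(n)
        for o, e in ((n0, e0), (n1, e1), (n2, e2)):
            stat += np.where(e > 0, (o - e) ** 2 / e, 0.0)
    out = np.ones_like(stat)
    ok = (n > 0) & (p > 0) & (p < 1)
    out[ok] = stats.chi2.sf(stat[ok], 1)
    return out


def qc_filter(
    cohort: CohortData, thr: QcThresholds
) -> tuple[np.ndarray, np.ndarray]:
    """Boolean keep-masks ``(snp_keep, sample_keep)``.

    Samples with call rate below ``min_sample_call_rate`` are removed first;
    SNP statistics (MAF, call rate, control HWE) are then computed on the
    retained samples.  HWE is tested in controls only.
    """
    d = cohort.dosages
    observed = d >= 0
    sample_rate = observed.mean(axis=1)
    sample_keep = sample_rate >= thr.min_sample_call_rate
    if not sample_keep.any():
        raise ValueError("all samples fail the sample call-rate threshold")

    d2 = d[sample_keep]
    pheno2 = cohort.phenotype[sample_keep]
    obs2 = d2 >= 0
    snp_rate = obs2.mean(axis=0)
    n_obs = obs2.sum(axis=0)
    with np.errstate(invalid="ignore"):
        alt_freq = np.where(n_obs > 0, np.where(d2 >= 0, d2, 0).sum(axis=0) / (2 * n_obs), 0.0)
    maf = np.minimum(alt_freq, 1 - alt_freq)

    ctrl = pheno2 == 0
    dc = d2[ctrl]
    n0 = (dc == 0).sum(axis=0)
    n1 = (dc == 1).sum(axis=0)
    n2 = (dc == 2).sum(axis=0)
    hwe_p = hwe_chisq_p(n0, n1, n2)

    snp_keep = (
        (maf >= thr.min_maf)
        & (snp_rate >= thr.min_snp_call_rate)
        & (hwe_p >= thr.max_hwe_p_exclusion)
    )
    if not snp_keep.any():
        raise ValueError(
            "all SNPs removed by QC; review min_maf / call-rate / HWE thresholds"
        )
    return snp_keep, sample_keep


def power_two_group(
    p1: float,
    p2: float,
    n1: int,
    n2: int,
    sig_level: float,
    method: str = "exact",
) -> float:
    """Power of the 1-df Pearson chi-squared two-proportion test.

    ``method='exact'`` (default) enumerates the two independent binomial
    count distributions and sums the probability of the rejection region
    {X^2 > chi2_1 critical value}; at stringent significance levels the
    discreteness of the table makes this noticeably smaller than the
    asymptotic value.  ``method='asymptotic'`` uses the noncentral
    chi-squared approximation with
    ncp = (p1 - p2)^2 / (pbar (1 - pbar) (1/n1 + 1/n2)).
    """
    if not (0 < p1 < 1 and 0 < p2 < 1):
        raise ValueError("proportions must lie strictly in (0, 1)")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("sample sizes must be positive")
    if not 0 < sig_level < 1:
        raise ValueError("sig_level must lie in (0, 1)")
    crit = stats.chi2.isf(sig_level, 1)
    if method == "asymptotic":
        pbar = (n1 * p1 + n2 * p2) / (n1 + n2)
        ncp = (p1 - p2) ** 2 / (pbar * (1 - pbar) * (1 / n1 + 1 / n2))
        return float(stats.ncx2.sf(crit, 1, ncp))
    if method != "exact":
        raise ValueError(f"unknown power method {method!r}")

    n = n1 + n2
    x2 = np.arange(n2 + 1, dtype=np.float64)
    w2 = stats.binom.pmf(x2, n2, p2)
    power = 0.0
    chunk = max(1, 10_000_000 // (n2 + 1))
    for lo in range(0, n1 + 1, chunk):
        x1 = np.arange(lo, min(lo + chunk, n1 + 1), dtype=np.float64)
        w1 = stats.binom.pmf(x1, n1, p1)
        a = x1[:, None]
        c = x2[None, :]
        col1 = a + c
        col2 = n - col1
        with np.errstate(divide="ignore", invalid="ignore"):
            stat = n * (a * (n2 - c) - (n1 - a) * c) ** 2 / (n1 * n2 * col1 * col2)
        stat = np.nan_to_num(stat)
        power += float((w1[:, None] * w2[None, :] * (stat > crit)).sum())
    return power


def simulate_g_test_power(
    p1: float,
    p2: float,
    n1: int,
    n2: int,
    sig_level: float,
    nsim: int,
    seed: int,
    chunk: int = 2_000_000,
) -> tuple[float, float]:
    """Monte Carlo power of the 2 x 2 G-test, with its binomial SE.

    Simulates ``nsim`` pairs of binomial counts (carriers among cases and
    controls), computes the vectorized G statistic, and returns the fraction
    of simulated tables with p below ``sig_level``.
    """
    if nsim < 1:
        raise ValueError("nsim must be positive")
    rng = np.random.default_rng(seed)
    crit = stats.chi2.isf(sig_level, 1)
    hits = 0
    remaining = nsim
    while remaining > 0:
        b = min(chunk, remaining)
        x1 = rng.binomial(n1, p1, size=b).astype(np.float64)
        x2 = rng.binomial(n2, p2, size=b).astype(np.float64)
        obs = np.empty((4, b))
        obs[0], obs[1] = x1, n1 - x1
        obs[2], obs[3] = x2, n2 - x2
        rowc = np.stack([x1 + x2, (n1 - x1) + (n2 - x2)])  # column totals of 2x2
        n = float(n1 + n2)
        exp = np.empty_like(obs)
        exp[0] = n1 * rowc[0] / n
        exp[1] = n1 * rowc[1] / n
        exp[2] = n2 * rowc[0] / n
        exp[3] = n2 * rowc[1] / n
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(obs > 0, obs * np.log(obs / exp), 0.0)
        g = 2.0 * np.nansum(terms, axis=0)
        # degenerate tables (an empty column) carry no evidence
        g[(rowc[0] == 0) | (rowc[1] == 0)] = 0.0
        hits += int((g > crit).sum())
        remaining -= b
    est = hits / nsim
    se = float(np.sqrt(max(est * (1 - est), 1.0 / nsim) / nsim))
    return est, se


def min_p_exceedance(M: int, threshold: float) -> float:
    """P(min of M independent uniform p-values <= threshold)
    = 1 - (1 - threshold)^M."""
    if M < 1:
        raise ValueError("M must be >= 1")
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must lie in [0, 1]")
    return float(-np.expm1(M * np.log1p(-threshold))) if threshold < 1 else 1.0
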