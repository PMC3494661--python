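import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from genesize.assoc import CohortData
from genesize.genelevel import (
    effective_number,
    estimate_ld,
    fisher_combine,
    fosco,
    fosco_adjust,
    gates,
    psd_repair,
    pvalue_correlation,
    run_gene_tests,
    simes,
    vegas,
)
from genesize.datamodel import GeneSnpMap


class TestFisher:
    def test_single_p_identity(self):
        assert fisher_combine([0.5]).p_adj == pytest.approx(0.5, rel=1e-12)

    def test_two_p_closed_form(self):
        # df 4 tail: (1 + X/2) exp(-X/2), X = -2(ln .01 + ln .04) = 15.6481
        res = fisher_combine([0.01, 0.04])
        x = -2 * (np.log(0.01) + np.log(0.04))
        assert res.p_adj == pytest.approx((1 + x / 2) * np.exp(-x / 2), rel=1e-10)
        assert res.p_adj == pytest.approx(3.53e-3, rel=5e-3)

    def test_null_uniform(self):
        rng = np.random.default_rng(8)
        padj = [fisher_combine(rng.uniform(size=5)).p_adj for _ in range(10_000)]
        assert stats.kstest(padj, "uniform").pvalue > 0.01

    def test_zero_p_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            res = fisher_combine([0.0, 0.5])
        assert 0 <= res.p_adj <= 1


class TestSimes:
    def test_single_p_identity(self):
        assert simes([0.37]).p_adj == 0.37

    def test_enumeration_example(self):
        # min(3*.01/1, 3*.02/2, 3*.9/3) = min(.03, .03, .9)
        assert simes([0.01, 0.02, 0.9]).p_adj == pytest.approx(0.03)

    def test_all_equal_returns_q(self):
        assert simes([0.2, 0.2, 0.2, 0.2]).p_adj == pytest.approx(0.2)

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=20))
    def test_bounds_and_min_dominance(self, ps):
        res = simes(ps)
        assert min(ps) <= res.p_adj <= 1.0


class TestEffectiveNumber:
    def test_identity_gives_m(self):
        assert effective_number(np.eye(7)) == pytest.approx(7.0)

    def test_all_ones_gives_one(self):
        assert effective_number(np.ones((6, 6))) == pytest.approx(1.0)

    def test_matches_independent_eigen_oracle(self):
        rng = np.random.default_rng(10)
        a = rng.standard_normal((5, 8))
        c = np.corrcoef(a)
        # oracle: same formula through the general (non-symmetric) solver
        lam = np.sort(np.real(np.linalg.eigvals(c)))
        oracle = len(c) - sum(x - 1 for x in lam if x > 1)
        assert effective_number(c) == pytest.approx(oracle, abs=1e-10)

    def test_range_clipped(self):
        c = np.eye(3)
        assert 1.0 <= effective_number(c) <= 3.0


class TestGates:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_equals_simes_under_identity_ld(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(size=rng.integers(1, 12))
        res = gates(p, np.eye(len(p)))
        assert res.p_adj == pytest.approx(simes(p).p_adj, rel=1e-12)

    def test_perfect_ld_returns_min_p(self):
        p = [0.3, 0.05, 0.6]
        res = gates(p, np.ones((3, 3)))
        assert res.p_adj == pytest.approx(0.05, rel=1e-6)

    def test_block_ld_matches_brute_force(self):
        p = np.array([0.02, 0.5, 0.04])
        r = np.array([[1.0, 0.8, 0.1], [0.8, 1.0, 0.1], [0.1, 0.1, 1.0]])
        res = gates(p, r)
        # oracle: explicit recomputation of min_i m_e p_(i) / m_e(i)
        order = np.argsort(p)
        c = psd_repair(pvalue_correlation(r[np.ix_(order, order)]))
        ps = p[order]

        def me(mat):
            lam = np.linalg.eigvalsh(mat)
            return np.clip(len(mat) - sum(l - 1 for l in lam if l > 1), 1, len(mat))

        oracle = min(me(c) * ps[i - 1] / me(c[:i, :i]) for i in range(1, 4))
        assert res.p_adj == pytest.approx(min(1.0, oracle), abs=1e-10)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            gates([0.1, 0.2], np.eye(3))


class TestVegas:
    def test_identity_ld_matches_chi2_tail(self):
        rng = np.random.default_rng(4)
        t = stats.chi2.rvs(1, size=6, random_state=rng)
        res = vegas(t, np.eye(6), nsim=100_000, seed=5, adaptive=False)
        closed = stats.chi2.sf(t.sum(), 6)
        se = np.sqrt(closed * (1 - closed) / 100_000)
        assert abs(res.p_adj - closed) < 3 * se + 2 / 100_000

    def test_single_snp_matches_its_p(self):
        t = np.array([stats.chi2.isf(0.07, 1)])
        res = vegas(t, np.eye(1), nsim=200_000, seed=6, adaptive=False)
        assert res.p_adj == pytest.approx(0.07, abs=0.005)

    def test_deterministic_under_seed(self):
        t = np.array([1.0, 2.0, 3.0])
        r = np.eye(3)
        a = vegas(t, r, nsim=2000, seed=11)
        b = vegas(t, r, nsim=2000, seed=11)
        assert a.p_adj == b.p_adj

    def test_adaptive_escalation_resolves_small_p(self):
        t = np.full(4, 30.0)  # very large observed sum
        res = vegas(t, np.eye(4), nsim=1000, seed=0, adaptive=True, max_nsim=100_000)
        assert res.extras["nsim"] == 100_000


class TestFosco:
    def test_worked_example(self):
        res = fosco([0.01] + [0.5] * 9, alpha=1.0)
        assert res.p_adj == pytest.approx(1 - 0.99**10, rel=1e-12)
        assert res.p_adj == pytest.approx(0.0956179, abs=1e-7)

    def test_single_snp_identity(self):
        assert fosco([0.42], alpha=1.0).p_adj == pytest.approx(0.42, rel=1e-12)

    def test_alpha_one_matches_order_statistic_simulation(self):
        m, p1 = 7, 0.05
        rng = np.random.default_rng(13)
        nsim = 1_000_000
        hits = (rng.random((nsim, m)).min(axis=1) <= p1).mean()
        expect = fosco([p1] + [0.9] * (m - 1), alpha=1.0).p_adj
        se = np.sqrt(expect * (1 - expect) / nsim)
        assert abs(expect - hits) < 3 * se

    def test_invalid_alpha(self):
        with pytest.raises(ValueError):
            fosco([0.1], alpha=0.0)

    @settings(max_examples=50, derandomize=True)
    @given(
        p1=st.floats(1e-6, 0.99),
        m=st.integers(1, 300),
        alpha=st.floats(0.05, 2.0),
    )
    def test_monotone_in_p1_m_alpha(self, p1, m, alpha):
        base = fosco_adjust(p1, m, alpha)
        assert 0.0 <= base <= 1.0
        assert fosco_adjust(min(p1 * 1.1, 0.999), m, alpha) >= base
        # strictly increasing in M and alpha until saturated at 1
        if base < 1.0 - 1e-12:
            assert fosco_adjust(p1, m + 1, alpha) > base
            assert fosco_adjust(p1, m, alpha + 0.1) > base

    def test_power_exponent_form(self):
        p1, m, a = 0.03, 16, 0.5
        lin = fosco_adjust(p1, m, a, exponent="linear")
        pw = fosco_adjust(p1, m, a, exponent="power")
        assert lin == pytest.approx(1 - (1 - p1) ** (a * m))
        assert pw == pytest.approx(1 - (1 - p1) ** (m**a))


class TestEstimateLd:
    def test_duplicated_column_perfect_r(self):
        rng = np.random.default_rng(1)
        col = rng.binomial(2, 0.4, size=50).astype(np.int8)
        d = np.column_stack([col, col, rng.binomial(2, 0.4, 50).astype(np.int8)])
        y = np.array([1, 0] * 25, dtype=np.int8)
        r = estimate_ld(CohortData(d, y), [0, 1, 2])
        assert r[0, 1] == pytest.approx(1.0, abs=1e-6)

    def test_independent_snps_near_zero(self):
        rng = np.random.default_rng(2)
        d = rng.binomial(2, 0.3, size=(10_000, 5)).astype(np.int8)
        y = np.array([1, 0] * 5000, dtype=np.int8)
        r = estimate_ld(CohortData(d, y), np.arange(5))
        off = r[~np.eye(5, dtype=bool)]
        assert (np.abs(off) < 0.03).all()

    def test_matches_hand_computation(self):
        d = np.array([[0, 2], [1, 1], [2, 0], [2, 2]], dtype=np.int8)
        y = np.array([1, 1, 0, 0], dtype=np.int8)
        r = estimate_ld(CohortData(d, y), [0, 1])
        a, b = d[:, 0].astype(float), d[:, 1].astype(float)
        hand = np.mean((a - a.mean()) * (b - b.mean())) / (a.std() * b.std())
        assert r[0, 1] == pytest.approx(hand, abs=1e-10)

    def test_monomorphic_zeroed_with_warning(self):
        d = np.column_stack(
            [np.ones(20, dtype=np.int8), np.tile([0, 1, 2, 1], 5).astype(np.int8)]
        )
        y = np.array([1, 0] * 10, dtype=np.int8)
        with pytest.warns(UserWarning, match="monomorphic"):
            r = estimate_ld(CohortData(d, y), [0, 1])
        assert r[0, 1] == pytest.approx(0.0, abs=1e-9)


class TestPsdRepair:
    def test_indefinite_matrix_repaired(self):
        r = np.array([[1.0, 0.9, -0.9], [0.9, 1.0, 0.9], [-0.9, 0.9, 1.0]])
        fixed = psd_repair(r)
        assert np.linalg.eigvalsh(fixed)[0] >= 0
        assert np.allclose(np.diag(fixed), 1.0)

    def test_psd_input_untouched(self):
        r = np.array([[1.0, 0.5], [0.5, 1.0]])
        assert np.allclose(psd_repair(r), r)


class TestRunGeneTests:
    def _map(self):
        return GeneSnpMap(
            {"gA": np.array([0, 1, 2]), "gB": np.array([3]), "gC": np.array([4, 5])}
        )

    def test_simes_composition(self):
        p = np.array([0.5, 0.01, 0.3, 0.2, 0.9, 0.05])
        out = run_gene_tests(p, self._map(), "simes")
        assert len(out) == 3
        assert out.set_index("gene_id").loc["gA", "p_adj"] == pytest.approx(
            simes(p[:3]).p_adj
        )

    def test_fosco_m1_identity(self):
        gmap = GeneSnpMap({f"g{i}": np.array([i]) for i in range(4)})
        p = np.array([0.1, 0.2, 0.3, 0.4])
        out = run_gene_tests(p, gmap, "fosco", alpha=1.0)
        assert np.allclose(np.sort(out["p_adj"]), p)

    def test_missing_pvalues_dropped(self):
        p = np.array([0.5, np.nan, 0.3, 0.2, 0.9, 0.05])
        out = run_gene_tests(p, self._map(), "simes")
        assert out.set_index("gene_id").loc["gA", "M"] == 2

    def test_ld_method_without_cohort_raises(self):
        with pytest.raises(ValueError, match="requires genotypes"):
            run_gene_tests(np.full(6, 0.5), self._map(), "gates")

    def test_all_methods_in_range_on_null_cohort(self, null_cohort_session):
        from genesize.assoc import per_snp_scan

        cohort, _, _, gmap = null_cohort_session
        p = per_snp_scan(cohort)
        cache = {}
        for method in ("fisher", "simes", "gates", "vegas", "fosco", "minp"):
            out = run_gene_tests(
                p, gmap, method, cohort=cohort, ld_cache=cache, seed=2, alpha=0.9
            )
            assert ((out["p_adj"] >= 0) & (out["p_adj"] <= 1)).all()
            assert len(out) == len(gmap.tested_genes())
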