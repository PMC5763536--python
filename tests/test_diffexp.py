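"""Exact NB test, BH FDR, MA/heatmap/ECDF/correlation transforms."""

import math

import numpy as np
import pandas as pd
import pytest

from evsmallrna.diffexp import (
    DEConfig,
    DEResult,
    bh_fdr,
    call_significant,
    cumulative_frequency,
    differential_expression,
    exact_nb_test,
    heatmap_matrix,
    ma_values,
    pearson_correlation,
)
from evsmallrna.mirquant import ExpressionMatrix


def oracle_exact_test(a: int, b: int, phi: float) -> float:
    """Brute-force enumeration with an independent lgamma-based NB pmf."""
    s = a + b
    if s == 0:
        return 1.0
    mu = s / 2

    def pmf(x: int) -> float:
        if phi == 0:
            return math.exp(-mu + x * math.log(mu) - math.lgamma(x + 1))
        r = 1 / phi
        return math.exp(
            math.lgamma(x + r) - math.lgamma(r) - math.lgamma(x + 1)
            + r * math.log(r / (r + mu)) + x * math.log(mu / (r + mu))
        )

    probs = [pmf(x) * pmf(s - x) for x in range(s + 1)]
    total = sum(probs)
    obs = probs[a]
    return sum(p for p in probs if p <= obs * (1 + 1e-12)) / total


class TestExactTest:
    def test_mode_gives_p_one(self):
        for phi in (0.0, 0.1, 0.5):
            assert exact_nb_test(5, 5, 1e6, 1e6, phi) == 1.0

    def test_zero_total_gives_p_one(self):
        assert exact_nb_test(0, 0, 1e6, 1e6, 0.1) == 1.0

    def test_binomial_limit_at_zero_dispersion(self):
        """phi=0 equals the conditional binomial mass-criterion test."""
        from scipy import stats

        s = 20
        pm = stats.binom.pmf(np.arange(s + 1), s, 0.5)
        expected = pm[pm <= pm[0] * (1 + 1e-12)].sum()
        assert exact_nb_test(0, 20, 1e6, 1e6, 0.0) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("phi", [0.0, 0.1, 0.5])
    def test_matches_brute_force_for_all_totals_up_to_50(self, phi):
        for s in range(51):
            for a in range(s + 1):
                p = exact_nb_test(a, s - a, 1e6, 1e6, phi)
                assert p == pytest.approx(oracle_exact_test(a, s - a, phi), abs=1e-10)
                assert 0 < p <= 1

    def test_library_size_scaling(self):
        """Counts are scaled to the geometric-mean library size first."""
        # 10 in a half-size library ~ 20 at geometric mean vs 20*sqrt(1/2)=14
        p_unequal = exact_nb_test(10, 20, 5e5, 1e6, 0.0)
        a = round(10 * math.sqrt(2))  # 14
        b = round(20 / math.sqrt(2))  # 14
        assert p_unequal == pytest.approx(oracle_exact_test(a, b, 0.0), abs=1e-10)

    def test_negative_input_is_fatal(self):
        with pytest.raises(ValueError):
            exact_nb_test(-1, 3, 1e6, 1e6, 0.1)
        with pytest.raises(ValueError):
            exact_nb_test(1, 3, 0, 1e6, 0.1)

    def test_type_one_error_calibrated(self):
        """2000 null NB pairs at phi=0.1: rejection rate near nominal 5%."""
        rng = np.random.default_rng(11)
        phi, mu = 0.1, 100
        r, pp = 1 / phi, (1 / phi) / (1 / phi + mu)
        a = rng.negative_binomial(r, pp, 2000)
        b = rng.negative_binomial(r, pp, 2000)
        ps = np.array(
            [exact_nb_test(int(x), int(y), 1e6, 1e6, phi) for x, y in zip(a, b)]
        )
        frac = (ps < 0.05).mean()
        assert 0.03 <= frac <= 0.07


def oracle_bh(pvals):
    """Independent textbook step-up: q(i) = min_{j>=i} p(j) * n / j."""
    n = len(pvals)
    order = sorted(range(n), key=lambda i: pvals[i])
    q = [None] * n
    best = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        best = min(best, pvals[i] * n / rank)
        q[i] = best
    return q


class TestBH:
    def test_single_p_is_identity(self):
        assert list(bh_fdr([0.5])) == [0.5]

    def test_equal_ps_unchanged(self):
        assert list(bh_fdr([0.5] * 4)) == [0.5] * 4

    def test_hand_worked_example(self):
        assert bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_out_of_range_is_fatal(self):
        with pytest.raises(ValueError):
            bh_fdr([0.0, 0.5])
        with pytest.raises(ValueError):
            bh_fdr([1.5])

    def test_matches_hand_coded_step_up_on_random_vectors(self):
        rng = np.random.default_rng(3)
        for _ in range(1000):
            p = rng.uniform(1e-6, 1.0, size=rng.integers(1, 40))
            assert bh_fdr(p) == pytest.approx(oracle_bh(list(p)), abs=1e-12)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(4)
        p = rng.uniform(1e-6, 1.0, size=200)
        _, q_sm, *_ = multipletests(p, method="fdr_bh")
        assert bh_fdr(p) == pytest.approx(q_sm, abs=1e-12)


class TestMA:
    def test_equal_rpm_gives_m_zero(self):
        m, _ = ma_values(7.3, 7.3)
        assert m == 0.0

    def test_worked_example(self):
        m, _ = ma_values(1.9, 3.9)  # log2(4.0 / 2.0), B over A
        assert m == pytest.approx(1.0)

    def test_double_zero(self):
        m, a = ma_values(0.0, 0.0)
        assert m == 0.0
        assert a == pytest.approx(math.log2(0.1))


class TestHeatmap:
    def _expr(self, rows):
        counts = pd.DataFrame(rows, columns=["A", "B", "C"])
        counts.index = [f"m{i}" for i in range(len(counts))]
        return ExpressionMatrix(counts, {"A": 10**6, "B": 10**6, "C": 10**6})

    def test_low_abundance_rows_dropped(self):
        # counts == RPM at one-million clean reads
        expr = self._expr([[0, 0, 0], [2, 0, 0], [1, 1, 1]])
        hm = heatmap_matrix(expr)
        assert list(hm.index) == ["m1", "m2"]  # all-groups-<1 row removed

    def test_log2_transform_values(self):
        expr = self._expr([[2, 0, 0]])
        hm = heatmap_matrix(expr)
        assert hm.loc["m0", "A"] == pytest.approx(math.log2(2.1))
        assert hm.loc["m0", "B"] == pytest.approx(math.log2(0.1))


class TestEcdf:
    def test_fraction_below_one_rpm(self):
        _, _, frac = cumulative_frequency([0.5, 2.0])
        assert frac == 0.5

    def test_single_jump_on_constant_input(self):
        x, f, _ = cumulative_frequency([3.0, 3.0, 3.0])
        assert np.allclose(x, math.log2(3.1))
        assert f[-1] == 1.0

    def test_matches_sort_rank_oracle(self):
        rng = np.random.default_rng(9)
        vals = rng.lognormal(2, 1.5, size=200)
        x, f, _ = cumulative_frequency(vals)
        srt = np.sort(np.log2(vals + 0.1))
        assert x == pytest.approx(srt)
        assert f == pytest.approx((np.arange(200) + 1) / 200)
        assert (np.diff(f) >= 0).all()

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            cumulative_frequency([])


class TestPearson:
    def test_self_correlation(self):
        assert pearson_correlation([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_anti_correlation(self):
        assert pearson_correlation([1, 2, 3], [-1, -2, -3]) == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        # deviations (-1,0,1) and (-4/3,-1/3,5/3): cov 3, vars 2 and 14/3
        assert pearson_correlation([1, 2, 3], [1, 2, 4]) == pytest.approx(
            math.sqrt(27 / 28)
        )

    def test_zero_variance_is_error(self):
        with pytest.raises(ValueError):
            pearson_correlation([1, 1, 1], [1, 2, 3])


class TestSignificance:
    @pytest.mark.parametrize(
        "p,fdr,m,expected",
        [
            (0.01, 0.01, 1.5, True),
            (0.01, 0.01, 0.9, False),  # |M| below 1
            (0.06, 0.01, 2.0, False),  # p above 0.05
            (0.01, 0.06, 2.0, False),  # FDR above 0.05
            (0.01, 0.01, -1.2, True),  # down-regulated
        ],
    )
    def test_threshold_rule(self, p, fdr, m, expected):
        r = DEResult("f", 1, 1, 1, 1, m, 0, p, fdr)
        flagged, summary = call_significant([r])
        assert flagged[0].significant is expected
        assert summary["up"] + summary["down"] == int(expected)

    def test_fold_change_recovery_with_planted_4x(self):
        """200/2000 deep features at 4-fold: nearly all pass the thresholds."""
        rng = np.random.default_rng(5)
        n, k, base = 2000, 200, 2000
        mu_a = np.full(n, float(base))
        mu_b = mu_a.copy()
        mu_b[:k] *= 4
        lib = 10**7
        counts = pd.DataFrame(
            {"A": rng.poisson(mu_a), "B": rng.poisson(mu_b)},
            index=[f"m{i}" for i in range(n)],
        )
        expr = ExpressionMatrix(counts, {"A": lib, "B": lib})
        results = differential_expression(expr, "A", "B", DEConfig(dispersion=0.1))
        sig = np.array([r.significant for r in results])
        m = np.array([r.m for r in results])
        assert sig[:k].mean() >= 0.90
        assert sig[k:].sum() == 0  # no planted-null feature called
        assert abs(m[:k].mean() - 2.0) <= 0.3
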