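"""RPKM, TMM, the exact Poisson test and per-contrast DE calling."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kinominer.expression_mining import (
    call_de,
    choose_reference_sample,
    expressed_matrix,
    poisson_de_test,
    rpkm,
    tmm_factor,
)
from kinominer.io_formats import CountMatrix


class TestRpkm:
    def test_zero_count(self):
        assert rpkm(0, 1000, 10**7) == 0.0

    def test_direct_formula(self):
        assert rpkm(1000, 2000, 10**7) == pytest.approx(50.0)

    def test_scale_invariance(self):
        assert rpkm(500, 1500, 5 * 10**6) == pytest.approx(
            rpkm(1000, 1500, 10**7))


def tmm_oracle(x, r, n_x, n_r, trim_m=0.30, trim_a=0.05):
    """Independent straight-line recomputation of the TMM definition."""
    x, r = np.asarray(x, float), np.asarray(r, float)
    keep = (x > 0) & (r > 0)
    x, r = x[keep], r[keep]
    m = np.log2((x / n_x) / (r / n_r))
    a = 0.5 * np.log2(x * r / (n_x * n_r))
    w = 1.0 / (1 / x - 1 / n_x + 1 / r - 1 / n_r)
    n = len(m)
    lo_m, hi_m = int(np.ceil(trim_m * n)), n - int(np.ceil(trim_m * n))
    lo_a, hi_a = int(np.ceil(trim_a * n)), n - int(np.ceil(trim_a * n))
    m_sorted = np.argsort(m, kind="stable")
    a_sorted = np.argsort(a, kind="stable")
    keep_m = np.zeros(n, bool)
    keep_m[m_sorted[lo_m:hi_m]] = True
    keep_a = np.zeros(n, bool)
    keep_a[a_sorted[lo_a:hi_a]] = True
    kept = keep_m & keep_a
    if not kept.any():
        return 1.0
    return 2.0 ** (np.sum(w[kept] * m[kept]) / np.sum(w[kept]))


class TestTmm:
    def test_self_factor_is_exactly_one(self, rng):
        x = rng.poisson(50, size=300) + 1
        assert tmm_factor(x, x) == 1.0

    def test_pure_depth_difference_normalizes_out(self, rng):
        r = rng.poisson(80, size=300) + 1
        assert tmm_factor(2 * r, r, n_test=2 * r.sum(), n_ref=r.sum()) \
            == pytest.approx(1.0)

    def test_matches_independent_recomputation(self):
        rng = np.random.default_rng(42)
        r = rng.poisson(100, size=200) + 1
        x = rng.poisson(100, size=200) + 1
        x[rng.choice(200, size=10, replace=False)] *= 6  # 5% perturbed up
        got = tmm_factor(x, r)
        expected = tmm_oracle(x, r, x.sum(), r.sum())
        assert got == pytest.approx(expected, rel=1e-12)

    def test_all_zero_sample_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            tmm_factor(np.zeros(10), np.ones(10))


def ac_oracle(x, y, n1, n2):
    """Exact tail summation of the conditional count distribution."""
    if x == 0 and y == 0:
        return 1.0
    ratio = n2 / n1

    def pmf(v):
        return math.exp(
            v * math.log(ratio)
            + math.lgamma(x + v + 1) - math.lgamma(x + 1) - math.lgamma(v + 1)
            - (x + v + 1) * math.log1p(ratio))

    lower = sum(pmf(v) for v in range(0, y + 1))
    if lower <= 0.5:
        smaller = lower
    else:
        # strict upper tail summed directly (avoids 1 - lower cancellation)
        mean = (x + 1) * ratio
        smaller, v = 0.0, y + 1
        while True:
            term = pmf(v)
            smaller += term
            v += 1
            if v > mean and term < 1e-280:
                break
    return min(1.0, 2.0 * smaller)


class TestPoissonDeTest:
    @pytest.mark.parametrize("x,y,n1,n2", [
        (20, 0, 10**6, 10**6),
        (3, 17, 10**6, 10**6),
        (100, 55, 2 * 10**6, 10**6),
        (0, 9, 10**6, 4 * 10**6),
        (7, 7, 10**6, 3 * 10**6),
    ])
    def test_matches_exact_tail_summation(self, x, y, n1, n2):
        assert poisson_de_test(x, y, n1, n2) == pytest.approx(
            ac_oracle(x, y, n1, n2), rel=1e-9)

    def test_exchangeable_between_libraries(self, rng):
        for _ in range(200):
            x, y = rng.integers(0, 500, size=2)
            n1, n2 = rng.integers(10**5, 10**8, size=2)
            assert abs(poisson_de_test(x, y, n1, n2)
                       - poisson_de_test(y, x, n2, n1)) < 1e-12

    def test_equal_counts_equal_depths_uninformative(self):
        assert poisson_de_test(5, 5, 10**6, 10**6) == 1.0

    def test_double_zero_uninformative(self):
        assert poisson_de_test(0, 0, 10**6, 3 * 10**6) == 1.0

    @given(x=st.integers(0, 2000), y=st.integers(0, 2000),
           n1=st.integers(10**4, 10**9), n2=st.integers(10**4, 10**9))
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_exchangeability_property(self, x, y, n1, n2):
        p_fwd = poisson_de_test(x, y, n1, n2)
        p_rev = poisson_de_test(y, x, n2, n1)
        assert 0.0 <= p_fwd <= 1.0
        assert abs(p_fwd - p_rev) < 1e-12


def _matrix(counts: dict, lengths, libs):
    genes = [f"g{i}" for i in range(len(lengths))]
    return CountMatrix(
        counts=pd.DataFrame(counts, index=genes),
        gene_lengths=pd.Series(lengths, index=genes),
        library_sizes=pd.Series(libs),
    )


class TestExpressedMatrix:
    def test_threshold_boundary(self):
        # RPKM 0.99 is non-expressed, exactly 1.0 is expressed
        lib = 10**6
        length = 1000
        c_low = int(0.99 * lib * length / 1e9)   # RPKM 0.99
        c_at = int(1.00 * lib * length / 1e9)    # RPKM 1.00
        m = _matrix({"s": [c_low, c_at, 0]}, [length] * 3, {"s": lib})
        expr = expressed_matrix(m)
        assert list(expr["s"]) == [False, True, False]


class TestCallDe:
    def test_null_fixture_controls_false_positives(self):
        rng = np.random.default_rng(7)
        lam = 10 ** rng.uniform(0.5, 2.5, size=2000)
        m = _matrix({"t": rng.poisson(lam), "c": rng.poisson(lam)},
                    [1000] * 2000, {"t": 10**7, "c": 10**7})
        results = call_de(m, [("t", "c")], alpha=0.05)
        frac = np.mean([r.adjusted_p <= 0.05 for r in results])
        se = math.sqrt(0.05 * 0.95 / 2000)
        assert frac <= 0.05 + 2 * se

    def test_strong_signal_is_called_up(self, rng):
        lam = np.full(200, 100.0)
        t = rng.poisson(lam)
        t[0] = rng.poisson(800)  # rate ratio 8 at mean count 100
        m = _matrix({"t": t, "c": rng.poisson(lam)},
                    [1000] * 200, {"t": 10**6, "c": 10**6})
        results = call_de(m, [("t", "c")])
        assert results[0].direction == "up"
        assert results[0].fold_change > 2

    def test_zero_zero_gene_is_none(self, rng):
        counts = {"t": [0, 50], "c": [0, 50]}
        m = _matrix(counts, [1000, 1000], {"t": 10**6, "c": 10**6})
        results = call_de(m, [("t", "c")])
        assert results[0].direction == "none"
        assert results[0].p_value == 1.0

    def test_unknown_sample_rejected(self, rng):
        m = _matrix({"t": [1], "c": [1]}, [1000], {"t": 10, "c": 10})
        with pytest.raises(KeyError, match="zz"):
            call_de(m, [("zz", "c")])


class TestReferenceSample:
    def test_picks_typical_depth_profile(self, rng):
        base = rng.poisson(100, size=500)
        m = _matrix(
            {"a": base, "b": base * 2, "c": base},
            [1000] * 500,
            {"a": base.sum(), "b": 2 * base.sum(), "c": base.sum()},
        )
        # all samples identical after depth scaling; any is acceptable
        assert choose_reference_sample(m) in {"a", "b", "c"}
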