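"""Statistical layer: closed-form oracles, enumeration oracles, invariants."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from chinpoint import (
    AnalysisConfig,
    PairedSeries,
    ValidationError,
    bonferroni_threshold,
    descriptive,
    independent_t,
    paired_t,
    pearson_r,
    validity_errors,
    wilcoxon_signed_rank,
)


def _series(a, b):
    a = np.asarray(a, dtype=float)
    return PairedSeries(labels=tuple(f"s{i}" for i in range(a.size)), a=a, b=b)


# ---------------------------------------------------------------------------
# independent brute-force oracles (textbook formulas, no scipy test calls)
# ---------------------------------------------------------------------------

def oracle_paired_t(a, b):
    d = np.asarray(a, float) - np.asarray(b, float)
    n = d.size
    t = d.mean() / (d.std(ddof=1) / math.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), n - 1)
    return t, p


def oracle_welch(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    vx, vy = x.var(ddof=1) / x.size, y.var(ddof=1) / y.size
    t = (x.mean() - y.mean()) / math.sqrt(vx + vy)
    df = (vx + vy) ** 2 / (vx**2 / (x.size - 1) + vy**2 / (y.size - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return t, df, p


def oracle_pearson(a, b):
    a, b = np.asarray(a, float), np.asarray(b, float)
    n = a.size
    ca, cb = a - a.mean(), b - b.mean()
    r = (ca @ cb) / math.sqrt((ca @ ca) * (cb @ cb))
    t = r * math.sqrt((n - 2) / (1 - r * r))
    p = 2.0 * sps.t.sf(abs(t), n - 2)
    return r, p


def oracle_wilcoxon_two_sided(d):
    """Exact two-sided signed-rank p by full 2^n enumeration."""
    d = np.asarray(d, float)
    d = d[d != 0.0]
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = []
    for signs in itertools.product([0, 1], repeat=d.size):
        ws.append(sum(r for s, r in zip(signs, ranks) if s))
    ws = np.asarray(ws)
    p_le = np.mean(ws <= w_obs + 1e-12)
    p_ge = np.mean(ws >= w_obs - 1e-12)
    return min(1.0, 2.0 * min(p_le, p_ge))


class TestDescriptive:
    def test_closed_form_example(self):
        d = descriptive([1.0, 2.0, 3.0])
        assert (d.mean, d.sd) == (2.0, 1.0)
        half = sps.t.ppf(0.975, 2) / math.sqrt(3)
        assert d.ci95_low == pytest.approx(2.0 - half, abs=1e-9)
        assert d.ci95_high == pytest.approx(2.0 + half, abs=1e-9)
        assert d.ci95_low == pytest.approx(-0.4841, abs=5e-4)

    def test_constant_series_degenerate_ci(self):
        d = descriptive([4.0, 4.0, 4.0])
        assert d.sd == 0.0
        assert d.ci95_low == d.ci95_high == 4.0

    def test_single_value_rejected(self):
        with pytest.raises(ValidationError):
            descriptive([1.0])


class TestPairedT:
    def test_closed_form_example(self):
        res = paired_t(_series([2.0, 3.0, 4.0], [1.0, 1.0, 1.0]))
        assert res.t == pytest.approx(2.0 / (1.0 / math.sqrt(3)), abs=1e-12)
        assert res.df == 2

    def test_identical_series_convention(self):
        res = paired_t(_series([1.0, 2.0], [1.0, 2.0]))
        assert (res.t, res.p) == (0.0, 1.0)
        shifted = paired_t(_series([2.0, 3.0], [1.0, 2.0]))
        assert math.isinf(shifted.t) and shifted.p == 0.0

    def test_sign_flip_symmetry(self, rng):
        a = rng.normal(size=12)
        b = rng.normal(size=12)
        r1 = paired_t(_series(a, b))
        r2 = paired_t(_series(b, a))
        assert r1.t == pytest.approx(-r2.t, abs=1e-12)
        assert r1.p == pytest.approx(r2.p, abs=1e-12)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(200):
            n = rng.integers(3, 30)
            a, b = rng.normal(size=n), rng.normal(size=n)
            res = paired_t(_series(a, b))
            t, p = oracle_paired_t(a, b)
            assert res.t == pytest.approx(t, abs=1e-12)
            assert res.p == pytest.approx(p, abs=1e-12)


class TestWilcoxon:
    def test_all_positive_small_sample(self):
        res = wilcoxon_signed_rank(_series([1, 2, 3, 4, 5], [0, 0, 0, 0, 0]))
        assert res.w == 15.0
        assert res.p == pytest.approx(2.0 / 32.0, abs=1e-15)
        assert res.method == "exact"

    def test_antisymmetric_differences_not_significant(self):
        res = wilcoxon_signed_rank(_series([1, -1, 2, -2, 3, -3], [0] * 6))
        assert res.p > 0.9

    def test_exact_p_matches_enumeration_with_ties(self, rng):
        for n in range(5, 13):
            for _ in range(3):
                # half-integer grid forces tied absolute differences
                d = np.round(rng.normal(scale=2.0, size=n) * 2) / 2.0
                d[d == 0.0] = 0.5
                res = wilcoxon_signed_rank(_series(d, np.zeros(n)))
                assert res.p == pytest.approx(oracle_wilcoxon_two_sided(d), abs=1e-12)

    def test_agrees_with_scipy_when_tie_free(self, rng):
        # independent library cross-check on continuous data
        for _ in range(20):
            d = rng.normal(size=15)
            res = wilcoxon_signed_rank(_series(d, np.zeros(15)))
            ref = sps.wilcoxon(d, method="exact", alternative="two-sided")
            assert res.p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_large_sample_uses_normal_approximation(self, rng):
        d = rng.normal(size=60)
        res = wilcoxon_signed_rank(_series(d, np.zeros(60)))
        assert res.method == "normal"
        ref = sps.wilcoxon(d, method="approx", correction=True)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_too_few_nonzero_differences_rejected(self):
        with pytest.raises(ValidationError):
            wilcoxon_signed_rank(_series([1, 0, 0, 0, 0, 2], [0] * 6))


class TestValidityErrors:
    @pytest.mark.parametrize(
        "d, me, mae",
        [
            ([1.0, -1.0], 0.0, 1.0),
            ([2.0, -1.0, -1.0], 0.0, 4.0 / 3.0),
            ([0.0, 0.0], 0.0, 0.0),
        ],
    )
    def test_small_examples(self, d, me, mae):
        d = np.asarray(d)
        v = validity_errors(_series(d, np.zeros_like(d)))
        assert v.me_mean == pytest.approx(me, abs=1e-12)
        assert v.mae_mean == pytest.approx(mae, abs=1e-12)

    def test_mae_dominates_me_on_random_inputs(self, rng):
        for _ in range(300):
            n = rng.integers(2, 40)
            a, b = rng.normal(size=n), rng.normal(size=n)
            v = validity_errors(_series(a, b))
            assert v.mae_mean >= abs(v.me_mean) - 1e-12
            assert v.mae_mean >= 0.0
            assert v.me_min <= v.me_max and v.mae_min <= v.mae_max
            if np.all(a == b):
                assert v.mae_mean == 0.0

    def test_equality_iff_one_signed(self, rng):
        a = np.abs(rng.normal(size=10)) + 0.1
        v = validity_errors(_series(a, np.zeros(10)))
        assert v.mae_mean == pytest.approx(abs(v.me_mean), abs=1e-12)
        mixed = validity_errors(_series(np.array([1.0, -2.0, 3.0]), np.zeros(3)))
        assert mixed.mae_mean > abs(mixed.me_mean)


class TestPearson:
    def test_perfect_linearity(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        r, _ = pearson_r(_series(a, 2 * a + 1))
        assert r == pytest.approx(1.0, abs=1e-12)
        r2, _ = pearson_r(_series(a, -a))
        assert r2 == pytest.approx(-1.0, abs=1e-12)

    def test_constant_series_rejected(self):
        with pytest.raises(ValidationError):
            pearson_r(_series([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]))

    def test_matches_covariance_formula(self, rng):
        for _ in range(200):
            n = rng.integers(4, 40)
            a, b = rng.normal(size=n), rng.normal(size=n)
            r, p = pearson_r(_series(a, b))
            ro, po = oracle_pearson(a, b)
            assert r == pytest.approx(ro, abs=1e-12)
            assert p == pytest.approx(po, abs=1e-12)


class TestWelch:
    def test_identical_groups(self):
        res = independent_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == 0.0 and res.p == pytest.approx(1.0)

    def test_antisymmetry_under_group_swap(self, rng):
        x, y = rng.normal(size=10), rng.normal(1.0, 2.0, size=14)
        r1, r2 = independent_t(x, y), independent_t(y, x)
        assert r1.t == pytest.approx(-r2.t, abs=1e-12)
        assert r1.p == pytest.approx(r2.p, abs=1e-12)

    def test_matches_closed_form(self, rng):
        for _ in range(200):
            x = rng.normal(size=rng.integers(3, 25))
            y = rng.normal(0.5, 1.7, size=rng.integers(3, 25))
            res = independent_t(x, y)
            t, df, p = oracle_welch(x, y)
            assert res.t == pytest.approx(t, abs=1e-12)
            assert res.df == pytest.approx(df, abs=1e-9)
            assert res.p == pytest.approx(p, abs=1e-12)


class TestBonferroni:
    def test_paper_mode_reproduces_published_threshold(self):
        assert bonferroni_threshold(AnalysisConfig()) == 0.01

    def test_exact_mode_divides(self):
        cfg = AnalysisConfig(bonferroni_mode="exact")
        assert bonferroni_threshold(cfg) == pytest.approx(0.0125)
        cfg1 = AnalysisConfig(bonferroni_mode="exact", n_tests=1)
        assert bonferroni_threshold(cfg1) == pytest.approx(0.05)

    def test_paper_mode_falls_back_for_other_settings(self):
        cfg = AnalysisConfig(alpha=0.10, n_tests=5)
        assert bonferroni_threshold(cfg) == pytest.approx(0.02)
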