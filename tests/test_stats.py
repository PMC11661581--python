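import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst
from scipy import stats as sps
from scipy.special import gammaln

from lipidstrat import stats as st


# ---------------------------------------------------------------------------
# independent oracles


def mw_enumeration_oracle(x, y):
    """Two-sided exact p by direct enumeration of rank-sum assignments,
    formulated over the y-sample (independent of the implementation's
    x-side U-statistic path)."""
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    n, n2 = len(pooled), len(y)
    obs = ranks[len(x):].sum()
    mean = n2 * (n + 1) / 2.0
    total = hits = 0
    for idx in itertools.combinations(range(n), n2):
        s = ranks[list(idx)].sum()
        total += 1
        if abs(s - mean) >= abs(obs - mean) - 1e-9:
            hits += 1
    return hits / total


def fisher_2x2_oracle(table):
    """Point-probability two-sided p by looping over the whole support with
    explicit factorial arithmetic."""
    a, b = table[0]
    c, d = table[1]
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def log_p(aa):
        return (
            gammaln(r1 + 1) + gammaln(r2 + 1) + gammaln(c1 + 1)
            + gammaln(n - c1 + 1) - gammaln(n + 1)
            - gammaln(aa + 1) - gammaln(r1 - aa + 1)
            - gammaln(c1 - aa + 1) - gammaln(r2 - c1 + aa + 1)
        )

    lp_obs = log_p(a)
    p = 0.0
    for aa in range(max(0, c1 - r2), min(r1, c1) + 1):
        lp = log_p(aa)
        if lp <= lp_obs + 1e-9:
            p += math.exp(lp)
    return min(p, 1.0)


def kw_rank_formula_oracle(groups):
    pooled = np.concatenate(groups)
    ranks = sps.rankdata(pooled)
    n = len(pooled)
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start:start + len(g)]
        h += r.sum() ** 2 / len(g)
        start += len(g)
    h = 12 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    return h / (1 - ((counts**3 - counts).sum()) / (n**3 - n))


# ---------------------------------------------------------------------------


class TestMannWhitney:
    def test_small_separated(self):
        r = st.mann_whitney([1, 2], [3, 4])
        assert r.statistic == 0.0
        assert r.p_raw == pytest.approx(2 / 6)

    def test_identical_multisets(self):
        r = st.mann_whitney([1, 2, 3], [1, 2, 3])
        assert r.p_raw == pytest.approx(1.0)

    def test_exact_matches_enumeration(self, rng):
        for _ in range(5):
            x = rng.normal(size=8)
            y = rng.normal(size=8)
            r = st.mann_whitney(x, y)
            assert r.p_raw == pytest.approx(mw_enumeration_oracle(x, y), abs=1e-12)

    def test_exact_with_ties(self, rng):
        x = rng.integers(0, 3, 7).astype(float)
        y = rng.integers(0, 3, 6).astype(float)
        r = st.mann_whitney(x, y)
        assert r.p_raw == pytest.approx(mw_enumeration_oracle(x, y), abs=1e-12)

    def test_empty_sample(self):
        with pytest.raises(ValueError):
            st.mann_whitney([], [1.0])

    def test_approx_path_large_n(self, rng):
        r = st.mann_whitney(rng.normal(size=30), rng.normal(size=30) + 2)
        assert r.p_raw < 0.001


class TestKruskalWallis:
    def test_three_separated_pairs(self):
        r = st.kruskal_wallis([[1, 2], [3, 4], [5, 6]])
        assert r.statistic == pytest.approx(32 / 7)

    def test_matches_rank_oracle(self, rng):
        groups = [rng.normal(size=k) for k in (5, 7, 6)]
        r = st.kruskal_wallis(groups)
        assert r.statistic == pytest.approx(kw_rank_formula_oracle(groups))

    def test_degenerate_all_equal(self):
        with pytest.warns(UserWarning):
            r = st.kruskal_wallis([[1, 1], [1, 1]])
        assert r.p_raw == 1.0

    def test_two_group_equals_mw_z_squared(self, rng):
        x = rng.normal(size=12)
        y = rng.normal(size=15) + 0.5
        kw = st.kruskal_wallis([x, y])
        mw = st.mann_whitney(x, y, exact_cutoff=0)  # force normal approx
        mu = 12 * 15 / 2
        var = 12 * 15 / 12 * (12 + 15 + 1)
        z = (mw.statistic - mu) / math.sqrt(var)
        assert kw.statistic == pytest.approx(z * z, rel=1e-10)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            st.kruskal_wallis([[1, 2, 3]])


class TestFisherExact:
    def test_diagonal_1(self):
        assert st.fisher_exact([[1, 0], [0, 1]]).p_raw == pytest.approx(1.0)

    def test_5x5_diagonal(self):
        assert st.fisher_exact([[5, 0], [0, 5]]).p_raw == pytest.approx(2 / 252)

    def test_published_counts(self):
        # high-TG-score carriers: 15/29 in one group vs 5/41 in another
        table = [[15, 14], [5, 36]]
        r = st.fisher_exact(table)
        assert r.p_raw == pytest.approx(fisher_2x2_oracle(table), abs=1e-12)
        assert r.p_raw < 0.05

    def test_random_2x2_against_oracle(self, rng):
        for _ in range(50):
            t = rng.integers(0, 12, size=(2, 2))
            if t.sum() == 0:
                continue
            assert st.fisher_exact(t).p_raw == pytest.approx(
                fisher_2x2_oracle(t), abs=1e-12
            )

    def test_rxc_exact_small(self):
        t = np.array([[3, 1, 2], [2, 3, 1]])
        r = st.fisher_exact(t)
        assert r.method == "FISHER_RxC"
        assert 0 < r.p_raw <= 1
        assert r.mc_standard_error is None

    def test_rxc_monte_carlo_close_to_exact(self, monkeypatch):
        t = np.array([[8, 4, 6], [3, 9, 5], [6, 5, 8]])
        exact = st.fisher_exact(t).p_raw
        monkeypatch.setattr(st, "RXC_ENUM_LIMIT", 10)
        mc = st.fisher_exact(t, seed=5, n_mc=20000)
        assert mc.mc_standard_error is not None
        assert mc.p_raw == pytest.approx(exact, abs=5 * mc.mc_standard_error + 1e-4)

    def test_negative_counts(self):
        with pytest.raises(ValueError):
            st.fisher_exact([[1, -1], [0, 2]])


def holm_oracle(ps):
    """Hand-stepped Holm formula, independent of the implementation."""
    m = len(ps)
    order = sorted(range(m), key=lambda i: ps[i])
    out = [0.0] * m
    prev = 0.0
    for rank, i in enumerate(order):
        val = min(1.0, (m - rank) * ps[i])
        prev = max(prev, val)
        out[i] = prev
    return out


class TestHolm:
    def test_single(self):
        assert st.holm_adjust([0.04]) == [0.04]

    def test_two(self):
        assert st.holm_adjust([0.01, 0.04]) == pytest.approx([0.02, 0.04])

    def test_three_hand_stepped(self):
        assert st.holm_adjust([0.01, 0.04, 0.03]) == pytest.approx(
            [0.03, 0.06, 0.06]
        )

    def test_empty(self):
        assert st.holm_adjust([]) == []

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            st.holm_adjust([0.5, 1.2])

    @settings(max_examples=200, deadline=None)
    @given(hst.lists(hst.floats(min_value=0, max_value=1), min_size=1, max_size=12))
    def test_matches_oracle_and_invariants(self, ps):
        adj = st.holm_adjust(ps)
        assert adj == pytest.approx(holm_oracle(ps))
        assert all(a >= p - 1e-12 for a, p in zip(adj, ps))
        assert all(a <= 1.0 for a in adj)
        # smallest raw p gets the Bonferroni adjustment
        i = int(np.argmin(ps))
        assert adj[i] == pytest.approx(min(1.0, len(ps) * ps[i]))


class TestAdjustedContrasts:
    def test_detects_strong_effect(self, rng):
        n = 200
        outcome = np.concatenate([rng.normal(0, 1, n), rng.normal(2, 1, n)])
        labels = np.repeat(["A", "B"], n)
        cov = pd.DataFrame({"age": rng.normal(50, 5, 2 * n)})
        res = st.adjusted_pairwise_contrasts(outcome, labels, cov)
        assert len(res) == 1
        assert res[0].method == "LOGISTIC_WALD"
        assert res[0].p_adjusted < 0.001

    def test_zero_event_group_falls_back(self, rng):
        outcome = np.concatenate([np.zeros(30), np.full(30, 10.0)])
        outcome[:30] += rng.normal(0, 0.01, 30)  # all below the median
        labels = np.repeat(["A", "B"], 30)
        res = st.adjusted_pairwise_contrasts(outcome, labels)
        assert res[0].fallback_used
        assert res[0].method == "MANN_WHITNEY"

    def test_pair_family_holm_adjusted(self, rng):
        outcome = rng.normal(size=90)
        labels = np.repeat(["A", "B", "C"], 30)
        res = st.adjusted_pairwise_contrasts(outcome, labels)
        assert len(res) == 3
        raw = [r.p_raw for r in res]
        adj = [r.p_adjusted for r in res]
        assert adj == pytest.approx(holm_oracle(raw))

    def test_constant_outcome_rejected(self):
        with pytest.raises(ValueError):
            st.adjusted_pairwise_contrasts(
                np.ones(20), np.repeat(["A", "B"], 10)
            )


class TestSingleFactor:
    def test_single_contrast_adjusted_equals_raw(self, rng):
        outcome = rng.normal(size=60)
        labels = np.repeat(["A", "CTRL"], 30)
        res = st.single_factor_comparison(outcome, labels, "CTRL")
        assert len(res) == 1
        assert res[0].p_adjusted == pytest.approx(res[0].p_raw)

    def test_shift_detected(self, rng):
        outcome = np.concatenate([rng.normal(3, 1, 80), rng.normal(0, 1, 80)])
        labels = np.repeat(["A", "CTRL"], 80)
        res = st.single_factor_comparison(outcome, labels, "CTRL")
        assert res[0].p_adjusted < 0.001

    def test_categorical_uses_fisher(self, rng):
        outcome = np.concatenate([np.ones(20), np.zeros(30)]).astype(int)
        labels = np.array(["A"] * 25 + ["CTRL"] * 25)
        res = st.single_factor_comparison(outcome, labels, "CTRL", categorical=True)
        assert res[0].method == "FISHER_2x2"

    def test_missing_control(self):
        with pytest.raises(ValueError):
            st.single_factor_comparison([1, 2], ["A", "B"], "CTRL")


class TestPower:
    def test_inverse_consistency(self):
        spec = st.PowerSpec(29, 41, sd=2.0)
        d = st.detectable_difference(spec)
        assert st.power_two_sample_t(d, spec) == pytest.approx(0.80, abs=1e-6)

    def test_normal_approx_limit(self):
        spec = st.PowerSpec(1000, 1000, sd=1.0)
        d = st.detectable_difference(spec)
        approx = (sps.norm.ppf(0.975) + sps.norm.ppf(0.80)) * math.sqrt(2 / 1000)
        assert d == pytest.approx(approx, rel=0.01)

    def test_monotone_in_n(self):
        d_small = st.detectable_difference(st.PowerSpec(29, 41, sd=1.0))
        d_large = st.detectable_difference(st.PowerSpec(100, 100, sd=1.0))
        assert d_small > d_large

    def test_scale_equivariance(self):
        d1 = st.detectable_difference(st.PowerSpec(30, 30, sd=1.0))
        d2 = st.detectable_difference(st.PowerSpec(30, 30, sd=2.0))
        assert d2 == pytest.approx(2 * d1, rel=1e-9)

    def test_invalid_spec(self):
        with pytest.raises(ValueError):
            st.PowerSpec(1, 10, sd=1.0)


class TestSummarize:
    def test_one_to_five(self):
        s = st.summarize([1, 2, 3, 4, 5])
        assert (s.median, s.q1, s.q3) == (3, 2, 4)

    def test_single_value(self):
        s = st.summarize([7.0])
        assert s.median == s.q1 == s.q3 == 7.0

    def test_published_percent(self):
        s = st.summarize_categorical(51, 61)
        assert round(s.percent, 1) == 83.6

    def test_empty(self):
        with pytest.raises(ValueError):
            st.summarize([])

    def test_count_bounds(self):
        with pytest.raises(ValueError):
            st.summarize_categorical(5, 4)
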