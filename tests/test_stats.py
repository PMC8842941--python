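"""Rank statistics: worked examples, exact-enumeration oracles, invariances."""

from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from ltsq.errors import ValidationError
from ltsq.stats import kruskal_wallis, mann_whitney_u, pearson_r, spearman_rho


# --- correlations ----------------------------------------------------------


def test_monotone_series_give_unit_rho():
    x = np.array([1.0, 2.0, 5.0, 9.0, 12.0])
    assert spearman_rho(x, x**3)[0] == pytest.approx(1.0)
    assert spearman_rho(x, -x)[0] == pytest.approx(-1.0)


def test_rho_equals_pearson_on_midranks(rng):
    x = rng.integers(0, 5, 30).astype(float)  # heavy ties
    y = rng.integers(0, 5, 30).astype(float)
    rho, _ = spearman_rho(x, y)
    r = np.corrcoef(sps.rankdata(x), sps.rankdata(y))[0, 1]
    assert rho == pytest.approx(r, abs=1e-12)


@settings(deadline=None, derandomize=True, max_examples=30)
@given(st.integers(0, 10**6))
def test_rho_invariant_under_monotone_transforms(seed):
    r = np.random.default_rng(seed)
    x = r.normal(size=12)
    y = r.normal(size=12)
    rho1, _ = spearman_rho(x, y)
    rho2, _ = spearman_rho(np.exp(x), y**3)
    assert rho1 == pytest.approx(rho2, abs=1e-12)


def test_linear_series_give_unit_pearson():
    x = np.arange(10, dtype=float)
    assert pearson_r(x, 2 * x + 1)[0] == pytest.approx(1.0)


def test_orthogonal_series_give_zero_pearson(rng):
    x = rng.normal(size=20)
    y = rng.normal(size=20)
    x = x - x.mean()
    y = y - y.mean()
    y = y - (y @ x) / (x @ x) * x  # Gram-Schmidt against x
    assert pearson_r(x, y)[0] == pytest.approx(0.0, abs=1e-12)


def test_pearson_three_point_hand_computation():
    x = np.array([0.0, 1.0, 2.0])
    y = np.array([1.0, 0.0, 2.0])
    # hand: cov = 0.5*2/3... easier by direct formula
    r_hand = np.sum((x - 1) * (y - 1)) / np.sqrt(np.sum((x - 1) ** 2) * np.sum((y - 1) ** 2))
    assert pearson_r(x, y)[0] == pytest.approx(r_hand, abs=1e-12)


def test_zero_variance_flagged():
    assert np.isnan(pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])[0])


def test_short_series_rejected():
    with pytest.raises(ValidationError):
        spearman_rho([1.0, 2.0], [3.0, 4.0])


# --- Mann-Whitney ----------------------------------------------------------


def test_fully_separated_groups_have_zero_u():
    u, p = mann_whitney_u([1.0, 2.0, 3.0], [10.0, 11.0, 12.0])
    assert u == 0.0
    assert 0 < p <= 0.2


def test_identical_groups_have_p_near_one():
    a = [1.0, 2.0, 3.0, 4.0]
    _, p = mann_whitney_u(a, a)
    assert p > 0.9


def test_u_statistics_sum_to_product():
    rng = np.random.default_rng(0)
    for _ in range(20):
        a = rng.integers(0, 6, 5).astype(float)
        b = rng.integers(0, 6, 7).astype(float)
        ra = sps.rankdata(np.concatenate([a, b]))[: len(a)].sum()
        ua = ra - len(a) * (len(a) + 1) / 2
        ub = len(a) * len(b) - ua
        u, _ = mann_whitney_u(a, b)
        assert u == pytest.approx(min(ua, ub), abs=1e-12)
        assert ua + ub == pytest.approx(len(a) * len(b), abs=1e-12)


def pairwise_u_and_exact_p(a, b):
    """Independent oracle: U by direct pair counting; p by enumerating all
    group assignments of the pooled values."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    n_a, n_b = len(a), len(b)

    def u_min_of(xs, ys):
        u = sum((x > y) + 0.5 * (x == y) for x in xs for y in ys)
        return min(u, len(xs) * len(ys) - u)

    u_obs = u_min_of(a, b)
    pooled = np.concatenate([a, b])
    total, hits = 0, 0
    for pos in combinations(range(n_a + n_b), n_a):
        mask = np.zeros(n_a + n_b, dtype=bool)
        mask[list(pos)] = True
        total += 1
        if u_min_of(pooled[mask], pooled[~mask]) <= u_obs + 1e-9:
            hits += 1
    return u_obs, hits / total


@pytest.mark.parametrize("seed", range(10))
def test_exact_p_matches_full_enumeration_oracle(seed):
    rng = np.random.default_rng(seed)
    a = rng.integers(0, 8, 4).astype(float)
    b = rng.integers(0, 8, 4).astype(float)
    u, p = mann_whitney_u(a, b)
    u_ref, p_ref = pairwise_u_and_exact_p(a, b)
    assert u == pytest.approx(u_ref, abs=1e-12)
    assert p == pytest.approx(p_ref, abs=1e-12)


def test_large_sample_p_close_to_scipy(rng):
    a = rng.normal(0, 1, 30)
    b = rng.normal(0.8, 1, 25)
    _, p = mann_whitney_u(a, b)
    p_ref = sps.mannwhitneyu(a, b, alternative="two-sided").pvalue
    assert p == pytest.approx(p_ref, rel=0.05)


def test_empty_group_rejected():
    with pytest.raises(ValidationError):
        mann_whitney_u([], [1.0])


# --- Kruskal-Wallis --------------------------------------------------------


def test_all_constant_groups_flagged():
    h, p = kruskal_wallis([[2.0, 2.0], [2.0, 2.0], [2.0, 2.0]])
    assert h == 0.0
    assert np.isnan(p)


def test_ordered_groups_match_hand_rank_formula():
    groups = [[1.0, 2.0, 3.0], [4.0, 5.0, 6.0], [7.0, 8.0, 9.0]]
    h, p = kruskal_wallis(groups)
    # ranks 1..9 without ties: H = 12/(9*10) * sum(Rk^2/3) - 3*10
    h_hand = 12 / 90 * ((6**2 + 15**2 + 24**2) / 3) - 30
    assert h == pytest.approx(h_hand, abs=1e-12)
    assert 0 < p < 0.05


def test_matches_scipy_with_ties(rng):
    groups = [rng.integers(0, 5, 12).astype(float) for _ in range(3)]
    h, p = kruskal_wallis(groups)
    ref = sps.kruskal(*groups)
    assert h == pytest.approx(ref.statistic, abs=1e-10)
    assert p == pytest.approx(ref.pvalue, abs=1e-10)


def test_two_group_p_tracks_mann_whitney(rng):
    agree = 0
    pairs = []
    for _ in range(50):
        a = rng.normal(0, 1, 10)
        b = rng.normal(rng.uniform(0, 1.5), 1, 12)
        _, p_u = mann_whitney_u(a, b)
        _, p_h = kruskal_wallis([a, b])
        pairs.append((p_u, p_h))
    # the two p-values must be monotonically related across datasets
    pu = np.array([x for x, _ in pairs])
    ph = np.array([y for _, y in pairs])
    rho, _ = spearman_rho(pu, ph)
    assert rho > 0.99
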