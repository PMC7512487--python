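"""Unit and property tests for the entropy measures on RR segments."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import afentropy as af
from afentropy.core import (
    EntropyParams,
    InvalidInputError,
    RRSegment,
    chebyshev_distance,
    cosen,
    embed,
    entropy_af,
    flexible_r_search,
    fuzzy_similarity,
    fuzzymen,
    mean_similarity,
    ranged_distance,
    sampen,
)

# ---------------------------------------------------------------------------
# Oracles: straight-from-the-definition double loops
# ---------------------------------------------------------------------------


def brute_ranged(u, v, eps=1e-10):
    ad = [abs(a - b) for a, b in zip(u, v)]
    return (max(ad) - min(ad)) / (max(ad) + min(ad) + eps)


def brute_mean_similarity(x, dim, n, r, distance, similarity, include_self, n_templates):
    temps = [x[i : i + dim] for i in range(n_templates)]
    total, count = 0.0, 0
    for i in range(n_templates):
        for j in range(n_templates):
            if not include_self and i == j:
                continue
            d = brute_ranged(temps[i], temps[j]) if distance == "ranged" \
                else max(abs(a - b) for a, b in zip(temps[i], temps[j]))
            s = np.exp(-(d**n) / r) if similarity == "fuzzy" else float(d <= r)
            total += s
            count += 1
    return total / count


def brute_sampen(x, m, r):
    n_t = len(x) - m
    b = a = 0
    for i in range(n_t):
        for j in range(n_t):
            if i == j:
                continue
            if max(abs(x[i + k] - x[j + k]) for k in range(m)) <= r:
                b += 1
            if max(abs(x[i + k] - x[j + k]) for k in range(m + 1)) <= r:
                a += 1
    if b == 0:
        return float("nan")
    if a == 0:
        return float("inf")
    return -np.log(a / b)


def brute_fuzzymen(x, m, n, r):
    """Independent re-implementation: local + global fuzzy conditional terms."""
    x = np.asarray(x, float)
    mu = x.mean()
    n_t = x.size - m

    def term(dim, center):
        temps = []
        for i in range(n_t):
            v = x[i : i + dim]
            temps.append(v - v.mean() if center == "local" else v - mu)
        total = 0.0
        for i in range(n_t):
            for j in range(n_t):
                if i == j:
                    continue
                d = max(abs(a - b) for a, b in zip(temps[i], temps[j]))
                total += np.exp(-(d**n) / r)
        return total / (n_t * (n_t - 1))

    out = 0.0
    for center in ("local", "global"):
        out += -np.log(term(m + 1, center) / term(m, center))
    return out


# ---------------------------------------------------------------------------
# Embedding and distances
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "x,m,expected",
    [
        ((0.8, 0.9, 0.7, 0.8), 2, [(0.8, 0.9), (0.9, 0.7)]),
        ((1.0, 2.0, 3.0), 2, [(1.0, 2.0)]),
    ],
)
def test_embed_forms_n_minus_m_consecutive_vectors(x, m, expected):
    np.testing.assert_allclose(embed(x, m), expected)


def test_embed_count_and_errors():
    assert embed(np.linspace(0.5, 1.0, 30), 1).shape == (29, 1)
    with pytest.raises(InvalidInputError, match="N=3, m=3"):
        embed((1.0, 2.0, 3.0), 3)


def test_ranged_distance_examples():
    assert ranged_distance((0.8, 0.8), (0.8, 0.8)) == 0.0
    # (max-min)/(max+min) = (2-1)/(2+1)
    assert ranged_distance((1, 2), (2, 4)) == pytest.approx(1 / 3, abs=1e-9)
    # single-element vectors: max == min, distance identically 0
    assert ranged_distance((0.6,), (1.4,)) == pytest.approx(0.0, abs=1e-9)
    with pytest.raises(InvalidInputError):
        ranged_distance((1, 2), (1, 2, 3))


@settings(derandomize=True, max_examples=200)
@given(st.integers(0, 2**32 - 1), st.integers(2, 6))
def test_ranged_distance_bounds_and_invariances(seed, m):
    rng = np.random.default_rng(seed)
    u, v = rng.uniform(0.3, 1.5, m), rng.uniform(0.3, 1.5, m)
    d = ranged_distance(u, v)
    assert 0.0 <= d < 1.0
    assert d == pytest.approx(brute_ranged(u, v))
    # gain and offset invariance (up to the epsilon perturbation)
    assert ranged_distance(3.0 * u, 3.0 * v) == pytest.approx(d, abs=1e-8)
    assert ranged_distance(u + 0.7, v + 0.7) == pytest.approx(d, abs=1e-8)


def test_ranged_distance_zero_iff_identical(rng):
    for _ in range(200):
        u = rng.uniform(0.3, 1.5, 3)
        assert ranged_distance(u, u) == 0.0


def test_chebyshev_distance_examples():
    assert chebyshev_distance((0.8, 0.9), (0.7, 1.1)) == pytest.approx(0.2)
    assert chebyshev_distance((0.5, 0.5), (0.5, 0.5)) == 0.0
    assert chebyshev_distance((1.0,), (3.0,)) == 2.0


def test_fuzzy_similarity_examples_and_shape():
    assert fuzzy_similarity(0.0, n=3.0, r=0.1) == 1.0
    assert fuzzy_similarity(0.3, n=1.0, r=0.3) == pytest.approx(np.exp(-1))
    assert fuzzy_similarity(0.5, n=2.0, r=0.2) == pytest.approx(np.exp(-1.25))
    d = np.linspace(0, 1, 50)
    s = fuzzy_similarity(d, n=2.0, r=0.2)
    assert np.all(np.diff(s) < 0)  # strictly decreasing in d
    with pytest.raises(InvalidInputError):
        fuzzy_similarity(0.1, n=2.0, r=0.0)


# ---------------------------------------------------------------------------
# Mean similarity
# ---------------------------------------------------------------------------


def test_mean_similarity_constant_segment_is_one():
    x = np.full(20, 0.8)
    for dim in (1, 2, 3):
        assert mean_similarity(x, dim, 2.0, 0.05) == pytest.approx(1.0)


def test_mean_similarity_two_template_instance():
    # m=2 templates (0.8, 0.9) and (0.9, 1.1): |d| = (0.1, 0.2), ranged
    # distance (0.2-0.1)/(0.2+0.1) = 1/3. Two self-pairs contribute 1 each,
    # two cross-pairs exp(-(1/3)/0.3) at n=1, r=0.3.
    x = np.array([0.8, 0.9, 1.1, 0.7])
    got = mean_similarity(x, 2, n=1.0, r=0.3, n_templates=2)
    expected = (2 * 1.0 + 2 * np.exp(-(1 / 3) / 0.3)) / 4
    assert got == pytest.approx(expected, rel=1e-8)


@pytest.mark.parametrize("distance", ["ranged", "chebyshev"])
@pytest.mark.parametrize("similarity", ["fuzzy", "heaviside"])
@pytest.mark.parametrize("include_self", [True, False])
def test_mean_similarity_matches_brute_force(rng, distance, similarity, include_self):
    for _ in range(10):
        x = rng.uniform(0.4, 1.2, rng.integers(8, 16))
        dim = int(rng.integers(1, 4))
        r = 0.3 if distance == "ranged" else 0.1
        got = mean_similarity(x, dim, 2.0, r, distance, similarity,
                              include_self=include_self)
        want = brute_mean_similarity(x, dim, 2.0, r, distance, similarity,
                                     include_self, x.size - dim)
        assert got == pytest.approx(want, rel=1e-12)


def test_heaviside_matching_monotone_in_dimension(rng):
    # matches can only be lost, never gained, when the template grows
    for _ in range(50):
        x = rng.uniform(0.4, 1.2, 20)
        for m in (1, 2, 3):
            hi = mean_similarity(x, m, 1.0, 0.1, "chebyshev", "heaviside",
                                 n_templates=x.size - m - 1)
            lo = mean_similarity(x, m + 1, 1.0, 0.1, "chebyshev", "heaviside",
                                 n_templates=x.size - m - 1)
            assert hi >= lo


# ---------------------------------------------------------------------------
# Flexible tolerance search
# ---------------------------------------------------------------------------


def brute_r_search(x, params, distance, similarity):
    """Exhaustive scan over the same grid."""
    from afentropy.core import _match_mass_per_template, _avg_matches_at, _r_grid

    x = np.asarray(x, float)
    D, include_self = _match_mass_per_template(x, params, distance, similarity)
    grid = _r_grid(x, params, distance, D)
    hits = [r for r in grid
            if _avg_matches_at(D, include_self, params, similarity, float(r))
            >= params.min_avg_matches]
    return float(hits[0]) if hits else float(grid[-1])


@pytest.mark.parametrize("distance,similarity", [("ranged", "fuzzy"), ("chebyshev", "heaviside")])
def test_flexible_r_equals_exhaustive_scan(rng, distance, similarity):
    params = EntropyParams(m=1)
    for _ in range(20):
        x = rng.uniform(0.4, 1.2, 30)
        got = flexible_r_search(x, params, distance, similarity)
        assert got.r == brute_r_search(x, params, distance, similarity)


def test_flexible_r_constant_segment_terminates_at_r_init():
    x = np.full(30, 0.8)
    res = flexible_r_search(x, EntropyParams(m=1))
    assert res.r == 0.05 and res.quota_met


def test_flexible_r_unmet_quota_returns_cap_with_flag():
    # quota larger than the number of templates can never be met
    params = EntropyParams(m=1, min_avg_matches=1000.0)
    x = np.random.default_rng(5).uniform(0.4, 1.2, 30)
    with pytest.warns(RuntimeWarning, match="quota"):
        res = flexible_r_search(x, params)
    assert not res.quota_met
    assert res.r == pytest.approx(params.r_max)


# ---------------------------------------------------------------------------
# Entropy_AF
# ---------------------------------------------------------------------------


def test_density_identity_probability_plus_log2r(rng):
    # -ln((A/(2r)^(m+1)) / (B/(2r)^m)) == -ln(A/B) + ln(2r)
    for _ in range(200):
        a, b, r = rng.uniform(1e-6, 1), rng.uniform(1e-6, 1), rng.uniform(1e-3, 1)
        m = int(rng.integers(1, 5))
        lhs = -np.log((a / (2 * r) ** (m + 1)) / (b / (2 * r) ** m))
        rhs = -np.log(a / b) + np.log(2 * r)
        assert lhs == pytest.approx(rhs, rel=1e-12)


def test_entropy_af_heart_rate_term_vanishes_at_unit_mean(rng):
    x = rng.uniform(0.5, 1.5, 30)
    x = x / x.mean()  # RRmean = 1 s
    with_hr = entropy_af(x, EntropyParams(m=2, w=1.0))
    without_hr = entropy_af(x, EntropyParams(m=2, w=0.0))
    assert with_hr.value == pytest.approx(without_hr.value, rel=1e-12)
    assert with_hr.value == pytest.approx(
        -np.log(with_hr.a_m1 / with_hr.b_m) + np.log(2 * with_hr.r_used), rel=1e-12
    )


def test_entropy_af_scaling_shifts_by_w_log_c(mixed_segments):
    for w in (0.5, 1.0, 2.0):
        params = EntropyParams(m=2, w=w)
        for x in mixed_segments[::10]:
            v0 = entropy_af(x, params).value
            for c in (0.5, 2.0, 10.0):
                vc = entropy_af(c * x, params).value
                assert vc - v0 == pytest.approx(-w * np.log(c), abs=1e-9)


def test_entropy_af_carries_diagnostics():
    x = np.random.default_rng(1).uniform(0.4, 0.9, 30)
    res = entropy_af(x)
    assert res.measure == "ENTROPY_AF"
    assert 0 < res.b_m <= 1 and 0 <= res.a_m1 <= 1
    assert res.r_used >= 0.05 and res.is_finite


def test_entropy_af_m1_degeneracy_documented():
    # at m=1 every dimension-1 ranged distance is 0, so B == 1 exactly
    x = np.random.default_rng(2).uniform(0.4, 0.9, 30)
    res = entropy_af(x, EntropyParams(m=1))
    assert res.b_m == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# SampEn
# ---------------------------------------------------------------------------


def test_sampen_periodic_segment_matches_brute_force():
    x = np.tile([0.8, 1.0], 15)
    got = sampen(x, m=2, r=0.05)
    assert got.value == pytest.approx(brute_sampen(x, 2, 0.05))


def test_sampen_matches_brute_force_on_random_segments(rng):
    for _ in range(30):
        x = rng.uniform(0.4, 1.2, rng.integers(10, 41))
        m = int(rng.integers(1, 4))
        r = float(rng.uniform(0.05, 0.3))
        got = sampen(x, m=m, r=r).value
        want = brute_sampen(x, m, r)
        if np.isnan(want):
            assert np.isnan(got)
        elif np.isinf(want):
            assert np.isinf(got)
        else:
            assert got == pytest.approx(want, rel=1e-12)


def test_sampen_limits():
    assert sampen(np.full(30, 0.8), m=2, r=0.01).value == 0.0  # constant series
    x = np.random.default_rng(3).uniform(0.4, 1.2, 30)
    assert sampen(x, m=2, r=1e9).value == 0.0  # r -> inf: everything matches


def test_sampen_zero_matches_flagged_not_coerced():
    x = np.array([0.4, 1.9, 0.4, 1.9, 0.5, 1.8, 0.6, 1.7]) * np.arange(1, 9)
    res = sampen(x, m=2, r=1e-6)
    assert not res.is_finite
    assert res.error in ("A_ZERO", "B_ZERO")


# ---------------------------------------------------------------------------
# FuzzyMEn
# ---------------------------------------------------------------------------


def test_fuzzymen_constant_segment_is_zero():
    assert fuzzymen(np.full(30, 0.8), r=0.05).value == pytest.approx(0.0)


def test_fuzzymen_matches_independent_reimplementation(rng):
    for _ in range(5):
        x = rng.uniform(0.4, 1.2, 30)
        got = fuzzymen(x, EntropyParams(m=2, n=2.0), r=0.1).value
        assert got == pytest.approx(brute_fuzzymen(x, 2, 2.0, 0.1), rel=1e-10)


def test_fuzzymen_increases_with_dispersion(rng):
    # iid segments with growing spread should look increasingly irregular
    medians = []
    for sd in (0.01, 0.05, 0.15):
        vals = [
            fuzzymen(np.clip(rng.normal(0.8, sd, 30), 0.25, 2.0), r=0.02).value
            for _ in range(200)
        ]
        medians.append(np.median(vals))
    assert medians[0] < medians[1] < medians[2]


# ---------------------------------------------------------------------------
# COSEn
# ---------------------------------------------------------------------------


def test_cosen_is_the_documented_composition(rng):
    params = EntropyParams(m=1)
    for scale in (1.0, 0.5):
        x = scale * rng.uniform(0.4, 0.9, 30)
        search = flexible_r_search(x, params, "chebyshev", "heaviside")
        want = sampen(x, m=1, r=search.r).value + np.log(2 * search.r) - np.log(x.mean())
        assert cosen(x, params).value == pytest.approx(want, rel=1e-12)


def test_cosen_constant_segment_closed_form():
    x = np.full(30, 0.8)
    res = cosen(x)
    assert res.value == pytest.approx(np.log(2 * 0.05) - np.log(0.8))
    assert res.r_used == pytest.approx(0.05)


# ---------------------------------------------------------------------------
# Cross-measure properties
# ---------------------------------------------------------------------------


def test_fuzzy_match_mass_converges_to_heaviside_count(mixed_segments):
    # as n grows, exp(-d^n/r) -> 1 for d < 1: the fuzzy mass climbs
    # monotonically toward the all-pairs count (threshold 1 for ranged d)
    for x in mixed_segments[::20]:
        T = embed(x, 3)
        from afentropy.core import _pairwise_distances

        D = _pairwise_distances(np.asarray(T), "ranged", 1e-10)
        target = float((D <= 1.0).sum())
        masses = [np.exp(-(D**n) / 0.05).sum() for n in (1, 2, 5, 25, 400)]
        assert all(a < b for a, b in zip(masses, masses[1:]))  # monotone from below
        assert masses[-1] <= target
        # far beyond the tested grid the mass is essentially the count
        assert target - masses[-1] < 0.1 * target


def test_all_measures_separate_af_from_nsr(scores_30):
    vals, labels = scores_30
    is_af = labels == "AF"
    for name, v in vals.items():
        af_mean = np.nanmean(np.where(np.isfinite(v), v, np.nan)[is_af])
        nsr_mean = np.nanmean(np.where(np.isfinite(v), v, np.nan)[~is_af])
        assert af_mean > nsr_mean, name


def test_entropy_af_separates_at_m1_and_m2(dataset_30):
    subset = dataset_30[:100] + dataset_30[-100:]
    labels = np.array([s.label for s in subset])
    for m in (1, 2):
        v = np.array([entropy_af(s, EntropyParams(m=m)).value for s in subset])
        assert v[labels == "AF"].mean() > v[labels == "NONAF"].mean()


def test_segment_and_params_validation():
    with pytest.raises(InvalidInputError):
        RRSegment(np.array([0.8, 0.9, 1.0]))  # too short
    with pytest.raises(InvalidInputError):
        RRSegment(np.array([0.8, -0.1, 0.9, 1.0]))  # non-positive interval
    with pytest.raises(InvalidInputError):
        RRSegment(np.full(10, 0.8), label="XYZ")
    with pytest.raises(InvalidInputError):
        EntropyParams(m=0)
    with pytest.raises(InvalidInputError):
        EntropyParams(r_init=-0.1)
    with pytest.raises(InvalidInputError):
        EntropyParams(w=-1.0)
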