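"""Template correlation, null calibration, classification, consistency counts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate

from loopstate import (
    analytic_null_cdf,
    analytic_null_density,
    analytic_tail_probability,
    classify_profiles,
    crossplatform_correlation,
    directional_consistency,
    ideal_pattern,
    profile_sd,
    simulate_null,
    steady_state_r,
    steady_state_r_brute,
)
from loopstate.steady import SteadyStateClassifier

from oracles import pearson_oracle


def _profiles_frame(rows):
    recs = []
    for j, x in enumerate(rows):
        rec = {"gene_id": f"G{j:03d}", "singular": False}
        for i in range(6):
            rec[f"x{i + 1}"] = x[i]
        recs.append(rec)
    return pd.DataFrame(recs)


# ---------------------------------------------------------------- profile SD

def test_profile_sd_alternating_example():
    # sum of squared deviations 0.375 over 5 -> sqrt(0.075)
    sd = profile_sd([0.5, 0, 0.5, 0, 0.5, 0])
    assert sd == pytest.approx(np.sqrt(0.075), abs=1e-12)
    assert sd > 0.21


def test_profile_sd_constant_and_missing():
    assert profile_sd([1.0] * 6) == 0.0
    assert np.isnan(profile_sd([1.0, np.nan, 0, 0, 0, 0]))


@settings(derandomize=True, max_examples=30, deadline=None)
@given(st.floats(-10, 10), st.integers(0, 2**31 - 1))
def test_profile_sd_homogeneity(c, seed):
    x = np.random.default_rng(seed).normal(size=6)
    assert profile_sd(c * x) == pytest.approx(abs(c) * profile_sd(x), rel=1e-9, abs=1e-12)


# -------------------------------------------------------------- R statistic

def test_r_of_pattern_itself_is_one():
    assert steady_state_r(ideal_pattern(2.0, -1.0)) == pytest.approx(1.0)
    assert steady_state_r_brute(ideal_pattern(2.0, -1.0), 2.0, -1.0) == pytest.approx(1.0)


def test_r_of_antipattern_is_minus_one():
    anti = ideal_pattern(0.0, 1.0)  # (s, r, s, r, s, r) relative to r>s template
    assert steady_state_r(anti) == pytest.approx(-1.0)


def test_closed_form_matches_brute_force_and_oracle():
    rng = np.random.default_rng(4)
    for _ in range(300):
        x = rng.normal(size=6)
        r, s = sorted(rng.uniform(-3, 3, 2))[::-1]
        if r == s:
            continue
        closed = steady_state_r(x, r=r, s=s)
        brute = steady_state_r_brute(x, r=r, s=s)
        ref = pearson_oracle(list(x), list(ideal_pattern(r, s)))
        assert closed == pytest.approx(brute, abs=1e-12)
        assert closed == pytest.approx(ref, abs=1e-12)


@settings(derandomize=True, max_examples=30, deadline=None)
@given(st.integers(0, 2**31 - 1), st.floats(0.1, 5), st.floats(-3, 3))
def test_r_affine_invariance_of_pattern(seed, scale, shift):
    """Replacing (r, s) by (a r + b, a s + b), a > 0, leaves R unchanged."""
    x = np.random.default_rng(seed).normal(size=6)
    base = steady_state_r_brute(x, r=1.0, s=0.0)
    moved = steady_state_r_brute(x, r=scale * 1.0 + shift, s=scale * 0.0 + shift)
    assert moved == pytest.approx(base, rel=1e-9, abs=1e-12)


def test_r_undefined_for_zero_variance():
    assert np.isnan(steady_state_r([1.0] * 6))


# ------------------------------------------------------------ analytic null

def test_analytic_density_n6_values():
    assert analytic_null_density(0.0) == pytest.approx(0.75, abs=1e-12)
    assert analytic_null_density(1.0) == 0.0
    assert analytic_null_density(-1.0) == 0.0
    with pytest.raises(ValueError):
        analytic_null_density(1.5)


def test_analytic_density_integrates_to_one():
    for n in (5, 6, 8):
        total, _ = integrate.quad(lambda r: analytic_null_density(r, n=n), -1, 1)
        assert total == pytest.approx(1.0, abs=1e-9)


def test_analytic_cdf_consistent_with_density():
    for n in (5, 6, 8):
        for r in (-0.9, -0.3, 0.0, 0.5, 0.75):
            num, _ = integrate.quad(lambda t: analytic_null_density(t, n=n), -1, r)
            assert analytic_null_cdf(r, n=n) == pytest.approx(num, abs=1e-9)


def test_exact_tail_probability_at_075():
    # integral of 0.75(1 - r^2) over |r| > 0.75
    assert analytic_tail_probability(0.75) == pytest.approx(0.0859375, abs=1e-12)


# --------------------------------------------------------- simulated null

@pytest.fixture(scope="module")
def null_200k():
    return simulate_null(200_000, seed=12345)


def test_null_symmetric_and_bounded(null_200k):
    assert np.all(np.abs(null_200k.draws) <= 1.0)
    assert abs(null_200k.draws.mean()) < 0.005


def test_null_density_near_analytic(null_200k):
    assert null_200k.density_at(0.0) == pytest.approx(0.75, abs=0.02)
    assert null_200k.tail_probability(0.75) == pytest.approx(0.0859375, abs=0.004)


def test_general_n_family_matches_simulation():
    for n in (5, 8):
        null = simulate_null(100_000, seed=n, n_points=n)
        assert null.ks_distance(n=n) < 0.01


def test_permutation_null_matches_exact_enumeration():
    """Permutation draws follow the exact 720-permutation distribution."""
    from itertools import permutations
    rng = np.random.default_rng(7)
    profile = rng.normal(size=6)
    exact = np.array([steady_state_r(np.array(p)) for p in permutations(profile)])
    null = simulate_null(100_000, seed=99, mode="permutation", profile=profile)
    assert abs(null.draws.mean()) < 0.01              # exchangeability: symmetric
    exact_tail = np.mean(np.abs(exact) > 0.75)
    assert null.tail_probability(0.75) == pytest.approx(exact_tail, abs=0.01)
    assert np.mean(exact > 0.5) == pytest.approx(np.mean(null.draws > 0.5), abs=0.01)


def test_null_model_summary_round_trip(tmp_path, null_200k):
    path = tmp_path / "null.json"
    null_200k.to_json(path)
    import json
    back = json.loads(path.read_text())
    assert back["n_draws"] == 200_000
    assert back["seed"] == 12345


# ----------------------------------------------------------- classification

def test_classify_boundary_strictness():
    base = np.array([1.0, 0, 1, 0, 1, 0])
    sd_boundary = base * (0.21 / profile_sd(base))
    prof = _profiles_frame([sd_boundary, sd_boundary * 1.0001])
    # set the cut to the profile's own SD: exact equality must be rejected
    calls = classify_profiles(prof, sd_min=profile_sd(sd_boundary))
    assert calls.loc[0, "label"] == "none"
    assert calls.loc[0, "reason"] == "sd_filter"
    assert calls.loc[1, "label"] == "up"             # just above: accepted


def test_classify_r_threshold_strict():
    x = np.array([1.0, 0.0, 1.0, 0.0, 2.5, 0.0])
    prof = _profiles_frame([x])
    # set the threshold to the profile's own |R|: strict ">" must reject it
    calls = classify_profiles(prof, r_threshold=abs(steady_state_r(x)))
    assert calls.loc[0, "label"] == "none"


def test_classify_directions_and_exclusions():
    up = [0.5, 0, 0.5, 0, 0.5, 0]
    down = [-0.5, 0, -0.5, 0, -0.5, 0]
    flat = [0.01, -0.01, 0.0, 0.01, -0.01, 0.0]
    prof = _profiles_frame([up, down, flat])
    prof.loc[3] = prof.loc[0]
    prof.loc[3, "gene_id"] = "G_sing"
    prof.loc[3, "singular"] = True
    prof.loc[4] = prof.loc[0]
    prof.loc[4, "gene_id"] = "G_miss"
    prof.loc[4, "x2"] = np.nan
    calls = classify_profiles(prof)
    assert list(calls["label"]) == ["up", "down", "none", "none", "none"]
    assert calls.loc[2, "reason"] == "sd_filter"
    assert calls.loc[3, "reason"] == "singular"
    assert calls.loc[4, "reason"] == "incomplete"


def test_classify_r_invariant_to_positive_rescaling():
    """R is scale-free; only the SD filter reacts to rescaling."""
    x = np.array([0.5, 0, 0.5, 0, 0.5, 0])
    big = _profiles_frame([x * 10])
    small = _profiles_frame([x * 0.1])
    calls_big = classify_profiles(big)
    calls_small = classify_profiles(small)
    assert calls_big.loc[0, "R"] == pytest.approx(steady_state_r(x), abs=1e-12)
    assert calls_big.loc[0, "label"] == "up"
    # rescaled below the SD filter: same R would arise but the gene is filtered
    assert calls_small.loc[0, "label"] == "none"
    assert calls_small.loc[0, "reason"] == "sd_filter"


def test_classifier_power_monotone_in_effect_and_noise():
    rng = np.random.default_rng(42)
    def power(a, sigma, n=150):
        x = np.tile([a, 0.0, a, 0.0, a, 0.0], (n, 1)) + rng.normal(0, sigma, (n, 6))
        calls = classify_profiles(_profiles_frame(x))
        return (calls["label"] == "up").mean()
    assert power(0.2, 0.1) <= power(0.4, 0.1) <= power(0.6, 0.1)
    assert power(0.5, 0.3) <= power(0.5, 0.15) <= power(0.5, 0.05)


def test_steady_up_genes_called_with_high_probability():
    """a = 0.5, sigma = 0.05: essentially every replicate gene is labelled up."""
    rng = np.random.default_rng(11)
    x = np.tile([0.5, 0.0, 0.5, 0.0, 0.5, 0.0], (200, 1)) + rng.normal(0, 0.05, (200, 6))
    calls = classify_profiles(_profiles_frame(x))
    assert (calls["label"] == "up").mean() >= 0.95


def test_flat_gene_false_positive_rate_bounded():
    """Flat genes at sigma = 0.05 rarely clear both filters."""
    rng = np.random.default_rng(12)
    x = rng.normal(0, 0.05, (400, 6))
    calls = classify_profiles(_profiles_frame(x))
    fp = (calls["label"] != "none").mean()
    assert fp <= 0.0859375 + 0.02  # analytic tail plus slack; SD filter only helps


def test_sklearn_classifier_interface():
    clf = SteadyStateClassifier(null_draws=10_000, random_state=0)
    clf.fit()
    assert clf.null_model_.n_draws == 10_000
    labels = clf.predict(_profiles_frame([[0.5, 0, 0.5, 0, 0.5, 0]]))
    assert list(labels) == ["up"]
    assert clf.calls_.loc[0, "passed_sd_filter"].item()


# --------------------------------------------------- directional consistency

def test_directional_consistency_all_positive():
    out = directional_consistency(np.ones((7, 8)), "up")
    assert (out.n_directional, out.n_total) == (56, 56)
    assert out.fraction == pytest.approx(1.0)


def test_directional_consistency_constructed_fractions():
    vals = np.full((7, 8), -1.0)
    flat = vals.ravel()
    flat[:35] = 1.0
    out = directional_consistency(flat.reshape(7, 8), "up")
    assert (out.n_directional, out.n_total) == (35, 56)
    assert out.fraction == pytest.approx(0.625)
    mostly_down = np.full((12, 8), -1.0)
    mostly_down.ravel()[:8] = 1.0
    out2 = directional_consistency(mostly_down, "down")
    assert (out2.n_directional, out2.n_total) == (88, 96)
    assert out2.fraction == pytest.approx(88 / 96)


def test_directional_consistency_sign_flip_and_zeros():
    rng = np.random.default_rng(3)
    vals = rng.normal(size=(5, 6))
    vals[0, 0] = 0.0
    vals[1, 2] = np.nan
    up = directional_consistency(vals, "up")
    down = directional_consistency(-vals, "down")
    assert up.n_directional == down.n_directional
    assert up.n_zero == down.n_zero == 1
    assert up.n_total == 29  # NaN excluded, zero kept in the denominator
    empty = directional_consistency(np.full((2, 3), np.nan), "up")
    assert empty.n_total == 0 and np.isnan(empty.fraction)


# ------------------------------------------------ cross-platform correlation

def test_crossplatform_correlation_basic():
    a = np.array([0.1, 0.5, -0.4, 1.2, -0.8])
    assert crossplatform_correlation(a, a) == pytest.approx(1.0)
    assert crossplatform_correlation(a, -a) == pytest.approx(-1.0)
    rng = np.random.default_rng(5)
    x, y = rng.normal(size=20), rng.normal(size=20)
    assert crossplatform_correlation(x, y) == pytest.approx(
        pearson_oracle(list(x), list(y)), abs=1e-12
    )


def test_crossplatform_correlation_degenerate():
    assert np.isnan(crossplatform_correlation([1, 1, 1], [1, 2, 3]))
    with pytest.raises(ValueError):
        crossplatform_correlation([1.0, 2.0], [1.0, 2.0])
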