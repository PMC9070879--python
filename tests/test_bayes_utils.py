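"""Posterior summaries against closed forms, and convergence diagnostics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from strendo.bayes_utils import (
    DrawVector,
    convergence_report,
    hdi,
    map_estimate,
    prob_direction,
    summarize,
)

RNG = np.random.default_rng(2024)


def test_hdi_uniform_width():
    lo, hi = hdi(RNG.uniform(0, 1, 10_000), 0.9)
    assert (hi - lo) == pytest.approx(0.9, abs=0.02)


def test_hdi_normal_matches_central_interval():
    lo, hi = hdi(RNG.standard_normal(10_000), 0.9)
    assert lo == pytest.approx(-1.645, abs=0.05)
    assert hi == pytest.approx(1.645, abs=0.05)


def test_hdi_degenerate_draws():
    lo, hi = hdi(np.full(500, 5.0))
    assert (lo, hi) == (5.0, 5.0)


def test_map_normal_mode():
    draws = RNG.normal(10.0, 2.0, 50_000)
    assert map_estimate(draws) == pytest.approx(10.0, abs=0.1)


def test_map_lognormal_mode_below_mean():
    draws = np.exp(RNG.standard_normal(50_000))
    m = map_estimate(draws)
    assert m == pytest.approx(np.exp(-1.0), abs=0.05)  # closed-form mode
    assert m < np.mean(draws)  # mean ~ exp(1/2) ~ 1.65


def test_map_constant_draws():
    assert map_estimate(np.full(200, 2.5)) == 2.5


def test_prob_direction_cases():
    assert prob_direction(np.abs(RNG.standard_normal(1000)) + 0.1) == 1.0
    assert prob_direction(RNG.standard_normal(100_000)) == pytest.approx(0.5, abs=0.01)
    v = np.concatenate([np.full(973, -1.0), np.full(27, 1.0)])
    s = summarize(v)
    assert s.prob_direction == pytest.approx(0.973)
    assert s.clear


def test_minimum_draw_count_enforced():
    with pytest.raises(ValueError, match="draws"):
        hdi(np.zeros(50))
    with pytest.raises(ValueError):
        map_estimate(np.zeros(99))
    with pytest.raises(ValueError):
        hdi(np.zeros(500), mass=1.5)


def test_summary_orders_bounds():
    s = summarize(RNG.normal(3.0, 1.0, 5000))
    assert s.hdi_low <= s.map <= s.hdi_high


@settings(max_examples=30, deadline=None)
@given(st.integers(0, 2**31 - 1), st.sampled_from([0.5, 0.8, 0.9, 0.95]))
def test_hdi_no_wider_than_equal_tailed(seed, mass):
    rng = np.random.default_rng(seed)
    draws = np.exp(rng.standard_normal(2000))  # skewed: HDI should beat quantiles
    lo, hi = hdi(draws, mass)
    q_lo, q_hi = np.quantile(draws, [(1 - mass) / 2, (1 + mass) / 2])
    assert (hi - lo) <= (q_hi - q_lo) + 1e-12


@settings(max_examples=20, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_map_invariant_to_draw_order(seed):
    rng = np.random.default_rng(seed)
    draws = rng.normal(5.0, 2.0, 1500)
    shuffled = rng.permutation(draws)
    assert map_estimate(draws) == map_estimate(shuffled)


def test_draw_vector_flattens():
    dv = DrawVector(np.ones((4, 50)), name="x")
    assert len(dv) == 200


def test_convergence_report_iid_chains_pass():
    draws = RNG.standard_normal((4, 1000))
    rep = convergence_report({"x": draws})
    assert rep.loc["x", "rhat"] == pytest.approx(1.0, abs=0.01)
    assert rep.attrs["usable"]


def test_convergence_report_flags_disjoint_chains():
    chains = np.stack([RNG.normal(loc, 0.1, 500) for loc in (0.0, 5.0, 10.0, 15.0)])
    rep = convergence_report({"x": chains})
    assert rep.loc["x", "rhat"] > 1.01
    assert not rep.attrs["usable"]


def test_convergence_report_ar1_ess_much_smaller_than_n():
    rho, n = 0.95, 4000
    chains = np.empty((4, n))
    for c in range(4):
        eps = RNG.standard_normal(n) * np.sqrt(1 - rho**2)
        x = np.empty(n)
        x[0] = RNG.standard_normal()
        for t in range(1, n):
            x[t] = rho * x[t - 1] + eps[t]
        chains[c] = x
    rep = convergence_report({"x": chains})
    # theoretical ESS factor (1-rho)/(1+rho) ~ 1/39
    assert rep.loc["x", "ess_bulk"] < 0.1 * 4 * n


def test_convergence_report_needs_two_chains():
    with pytest.raises(ValueError, match="chains"):
        convergence_report({"x": np.zeros((1, 500))})
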