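"""Individual profile fitting, prediction and repetition-maximum tables."""

import numpy as np
import pytest

from strendo.models import forward
from strendo.profile_builder import (
    fit_individual_profile,
    predict_load,
    predict_rtf,
    rm_table,
)

# group-mean load-RTF points: (relative load, RTF)
GROUP_POINTS = [(100.0, 1.0), (90.0, 4.2), (80.0, 7.8), (70.0, 12.2)]


def test_linear_ols_on_group_mean_points():
    prof = fit_individual_profile(GROUP_POINTS, "lin")
    assert prof.params["a"] == pytest.approx(101.846, abs=0.01)
    assert prof.params["b"] == pytest.approx(-2.674, abs=0.005)


def test_lin_closed_form_equals_iterative_fit():
    from strendo._fitting import _lin_closed_form, _refine

    rtf = np.array([p[1] for p in GROUP_POINTS])
    load = np.array([p[0] for p in GROUP_POINTS])
    closed, _ = _lin_closed_form(rtf, load)
    iterative, _ = _refine("lin", np.array([100.0, -2.0]), rtf, load)
    assert np.allclose(closed, iterative, atol=1e-10)


def test_noiseless_ex2_recovered_exactly():
    a, b = 102.6, -0.031
    rtf = np.array([1.0, 4.0, 8.0, 12.0])
    pts = list(zip(forward("ex2", (a, b), rtf), rtf))
    prof = fit_individual_profile(pts, "ex2")
    assert prof.params["a"] == pytest.approx(a, abs=1e-6)
    assert prof.params["b"] == pytest.approx(b, abs=1e-8)
    assert prof.adj_r_squared == pytest.approx(1.0, abs=1e-12)


def test_adjusted_r2_decreases_with_noise():
    rng = np.random.default_rng(6)
    rtf = np.linspace(1, 14, 8)
    clean = np.asarray(forward("lin", (101.5, -2.73), rtf))
    r2s = []
    for noise in (0.0, 1.0, 3.0):
        pts = list(zip(clean + noise * rng.standard_normal(rtf.size), rtf))
        r2s.append(fit_individual_profile(pts, "lin").adj_r_squared)
    assert r2s[0] == pytest.approx(1.0, abs=1e-12)
    assert r2s[0] > r2s[1] > r2s[2]


def test_underdetermined_fits_rejected():
    with pytest.raises(ValueError):
        fit_individual_profile(GROUP_POINTS[:2], "ex3", allow_unstable=True)
    with pytest.raises(ValueError):
        fit_individual_profile([(90.0, 4.0), (80.0, 4.0)], "lin")  # duplicate RTF


def test_unstable_families_warn():
    with pytest.warns(UserWarning, match="recommended"):
        fit_individual_profile(GROUP_POINTS, "crit")


def test_prediction_values_and_round_trip():
    prof = fit_individual_profile(GROUP_POINTS, "lin")
    prof.params.update({"a": 101.5, "b": -2.73})  # evaluate at reference parameters
    assert predict_load(prof, 1.0) == pytest.approx(98.77, abs=0.01)
    assert predict_rtf(prof, predict_load(prof, 6.5)) == pytest.approx(6.5, abs=1e-9)

    rtf = np.array([1.0, 5.0, 10.0])
    pts = list(zip(forward("ex2", (102.6, -0.031), rtf), rtf))
    prof2 = fit_individual_profile(pts, "ex2")
    assert predict_load(prof2, 10.0) == pytest.approx(102.6 * np.exp(-0.31), abs=1e-6)


def test_prediction_window_enforced():
    prof = fit_individual_profile(GROUP_POINTS, "lin")
    with pytest.raises(ValueError, match="window"):
        predict_load(prof, 45.0)
    with pytest.raises(ValueError, match="window"):
        predict_rtf(prof, 110.0)  # implies RTF < 1


def test_rm_table_values_and_monotonicity():
    prof = fit_individual_profile(GROUP_POINTS, "lin")
    prof.params.update({"a": 101.5, "b": -2.73})
    table = rm_table(prof, one_rm_kg=100.0, max_reps=15)
    assert len(table) == 15
    row12 = table[table.rtf == 12].iloc[0]
    assert row12.relative_load == pytest.approx(68.74, abs=0.01)
    assert row12.absolute_load_kg == pytest.approx(68.5)  # 0.5 kg rounding
    assert (np.diff(table.relative_load) < 0).all()


def test_rm_table_single_row_and_exact_curve():
    a, b = 102.6, -0.031
    rtf = np.array([1.0, 4.0, 8.0, 12.0])
    pts = list(zip(forward("ex2", (a, b), rtf), rtf))
    prof = fit_individual_profile(pts, "ex2")
    one = rm_table(prof, max_reps=1)
    assert len(one) == 1
    table = rm_table(prof, max_reps=12)
    assert np.allclose(table.relative_load, forward("ex2", (a, b), table.rtf), atol=1e-6)
    assert (np.diff(table.relative_load) < 0).all()


def test_rm_table_rejects_non_monotone_profile():
    prof = fit_individual_profile(GROUP_POINTS, "lin")
    prof.params.update({"a": 90.0, "b": 0.5})
    with pytest.raises(ValueError, match="decreasing"):
        rm_table(prof)
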