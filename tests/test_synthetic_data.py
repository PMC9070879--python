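"""Cohort generator: determinism, closed-form checks, study calibration."""

import numpy as np
import pytest

from strendo.synthetic_data import CohortConfig, generate_cohort, invert_profile, study_config

from oracles import moment_consistency

# Reference consistency-statistic intervals for the emulated study conditions
# (per measure: dt, SEM, WSCV %, SEP, ICC), used to check that generated
# cohorts look like the cohort the defaults were calibrated to.
STUDY_INTERVALS = {
    "1RM": {"dt": (1.0, 2.7), "SEM": (1.4, 2.3), "WSCV": (1.4, 2.5), "SEP": (1.6, 3.3), "ICC": (0.985, 1.0)},
    "RTF90": {"dt": (-0.1, 0.6), "SEM": (0.5, 0.9), "WSCV": (12.3, 21.3), "SEP": (0.7, 1.1), "ICC": (0.39, 0.83)},
    "RTF80": {"dt": (0.3, 1.0), "SEM": (0.6, 1.4), "WSCV": (7.2, 12.2), "SEP": (0.7, 1.9), "ICC": (0.64, 0.93)},
    "RTF70": {"dt": (0.2, 1.2), "SEM": (0.8, 1.4), "WSCV": (6.9, 11.8), "SEP": (1.0, 1.9), "ICC": (0.71, 0.93)},
}


def _degenerate_config(**overrides):
    base = dict(
        group_param_sds={"a": 0.0, "b": 0.0},
        group_change_means={"a": 0.0, "b": 0.0},
        group_change_sds={"a": 0.0, "b": 0.0},
        one_rm_noise_sd=0.0,
        time_effect_one_rm=0.0,
        rtf_noise_sd=0.0,
        one_rm_sd=0.0,
    )
    base.update(overrides)
    return study_config("lin", **base)


def test_all_zero_sds_give_deterministic_rtf_pattern():
    ds, _ = generate_cohort(_degenerate_config(seed=4))
    # round((load - 101.5) / -2.73) at 90/80/70 -> 4, 8, 12 for every subject
    for measure, expect in (("RTF90", 4), ("RTF80", 8), ("RTF70", 12)):
        vals = ds.table.loc[ds.table["measure"] == measure, "value"]
        assert (vals == expect).all()


def test_seeded_generation_is_reproducible():
    cfg = study_config("lin", seed=9)
    ds1, t1 = generate_cohort(cfg)
    ds2, t2 = generate_cohort(study_config("lin", seed=9))
    assert ds1.equals(ds2)
    assert t1.params_t1.equals(t2.params_t1)
    assert not ds1.equals(generate_cohort(study_config("lin", seed=10))[0])


def test_retest_difference_sd_matches_closed_form():
    # with fixed curves, sd(T2 - T1) at one load ~ sqrt(2) * rtf noise
    cfg = _degenerate_config(n_subjects=1000, rtf_noise_sd=1.1, seed=12)
    ds, _ = generate_cohort(cfg)
    paired = ds.paired_values("RTF70")
    diff_sd = float((paired["T2"] - paired["T1"]).std(ddof=1))
    assert diff_sd == pytest.approx(np.sqrt(2) * 1.1, rel=0.05)


def test_group_means_converge_to_configured_means():
    cfg = study_config("lin", n_subjects=2000, seed=13)
    _, truth = generate_cohort(cfg)
    for name, target in cfg.group_param_means.items():
        se = cfg.group_param_sds[name] / np.sqrt(2000)
        assert abs(truth.params_t1[name].mean() - target) < 3 * se
    rm_se = cfg.one_rm_sd / np.sqrt(2000)
    assert abs(truth.true_one_rm["T1"].mean() - cfg.one_rm_mean) < 3 * rm_se


def test_study_scale_cohorts_reproduce_consistency_intervals():
    """Moment statistics of replicate cohorts fall in the reference intervals
    for >= 80 % of (statistic, replicate) pairs."""
    hits = total = 0
    for rep in range(50):
        ds, _ = generate_cohort(study_config("lin", seed=3000 + rep))
        for measure, bands in STUDY_INTERVALS.items():
            stats = moment_consistency(ds, measure)
            for key, (lo, hi) in bands.items():
                hits += lo <= stats[key] <= hi
                total += 1
    assert total == 50 * 20
    assert hits / total >= 0.80


def test_invert_profile_round_trip():
    assert invert_profile("lin", (101.5, -2.73), 90.0) == pytest.approx(4.21245, abs=1e-4)
    with pytest.raises(ValueError):
        invert_profile("ex2", (102.6, -0.031), 110.0)  # above the ex2 ceiling


def test_invalid_group_curves_error_out():
    cfg = study_config("lin")
    cfg.group_param_means["b"] = 2.73  # increasing curve: no valid redraws possible
    cfg.group_param_sds["b"] = 0.0
    cfg.max_redraws = 10
    with pytest.raises(RuntimeError, match="redraws"):
        generate_cohort(cfg)


def test_config_file_round_trip(tmp_path):
    cfg = study_config("crit", seed=77, n_subjects=12)
    path = tmp_path / "cohort.json"
    cfg.to_file(path)
    again = CohortConfig.from_file(path)
    assert again == cfg


def test_config_validation():
    with pytest.raises(ValueError):
        CohortConfig(n_subjects=1)
    with pytest.raises(ValueError):
        study_config("lin", one_rm_sd=-1.0)
    with pytest.raises(ValueError):
        CohortConfig(group_param_means={"a": 1.0})  # missing 'b'
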