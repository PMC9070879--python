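"""Synthetic test-retest cohorts with known ground truth.

Generates bench-press-style cohorts with the statistical structure the
downstream analyses assume: subject 1-RMs drawn from a normal
distribution, subject-specific load-RTF curves whose parameters (and
test-retest change effects) are drawn from group-level normals, and
integer repetition counts observed with day-to-day noise.  Defaults
are calibrated to a 24-athlete mixed-sex cohort (see
:func:`study_config` and docs/methods.md for the derivation), so a
generated cohort emulates the study conditions the package analyses.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io_data import PerformanceDataset
from .models import PARAM_NAMES, forward, invert, is_decreasing

__all__ = ["CohortConfig", "SyntheticTruth", "generate_cohort", "invert_profile", "study_config"]

#: relative loads (% 1-RM) at which repetition-maximum tests are simulated
DEFAULT_LOADS = (90.0, 80.0, 70.0)

# Group-level curve parameters per model family: (means, SDs, change-effect
# means, change-effect SDs) on the natural scale.  Values mirror a trained
# cohort whose group curve passes near (RTF 1, 100 %) and whose retest shifts
# are small; see docs/methods.md.
_STUDY_PARAMS = {
    "lin": (
        {"a": 101.5, "b": -2.73},
        {"a": 0.8, "b": 0.6},
        {"a": 0.25, "b": 0.13},
        {"a": 0.6, "b": 0.15},
    ),
    "ex2": (
        {"a": 102.6, "b": -0.031},
        {"a": 0.8, "b": 0.006},
        {"a": 0.3, "b": 0.002},
        {"a": 0.6, "b": 0.002},
    ),
    "ex3": (
        {"a": 76.3, "b": -0.045, "c": 27.3},
        {"a": 8.0, "b": 0.014, "c": 9.0},
        {"a": -12.7, "b": -0.010, "c": 13.7},
        {"a": 6.0, "b": 0.006, "c": 6.0},
    ),
    "crit": (
        {"Lp": 3638.8, "k": -32.0, "CL": -17.4},
        {"Lp": 1300.0, "k": 8.0, "CL": 14.0},
        {"Lp": 613.7, "k": -4.1, "CL": -3.3},
        {"Lp": 400.0, "k": 2.0, "CL": 5.0},
    ),
}

#: day-to-day RTF noise (repetitions) per relative load; larger at lower
#: loads, where absolute variability of repetition counts is higher
DEFAULT_RTF_NOISE = {90.0: 0.65, 80.0: 0.7, 70.0: 1.0}


@dataclass
class CohortConfig:
    """Generator settings; defaults emulate the study cohort (Lin profile)."""

    n_subjects: int = 24
    n_male: int | None = None  # default: 15/24 of the cohort
    one_rm_mean: float = 93.5
    one_rm_sd: float = 28.9
    profile_model: str = "lin"
    group_param_means: dict = field(default_factory=lambda: dict(_STUDY_PARAMS["lin"][0]))
    group_param_sds: dict = field(default_factory=lambda: dict(_STUDY_PARAMS["lin"][1]))
    group_change_means: dict = field(default_factory=lambda: dict(_STUDY_PARAMS["lin"][2]))
    group_change_sds: dict = field(default_factory=lambda: dict(_STUDY_PARAMS["lin"][3]))
    param_corr: list | None = None  # correlation matrix of T1 parameters
    change_corr: list | None = None
    #: correlation between each T1 parameter and its own change effect.
    #: Test-retest data regress to the mean (extreme baselines shrink on
    #: retest), which keeps retest spread at or below baseline spread; a
    #: generator with independent change effects cannot show that.
    cross_corr: float = -0.7
    residual_sd_load: float = 0.0  # % 1-RM jitter on the prescribed load
    rtf_noise_sd: float | dict = field(default_factory=lambda: dict(DEFAULT_RTF_NOISE))
    time_effect_one_rm: float = 1.9  # systematic T1 -> T2 shift of the 1-RM (kg)
    one_rm_noise_sd: float = 1.7  # trial-to-trial 1-RM measurement noise (kg)
    loads: tuple = DEFAULT_LOADS
    round_one_rm_to: float = 2.5  # smallest 1-RM load increment (kg)
    max_redraws: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if self.n_male is None:
            self.n_male = int(round(self.n_subjects * 15 / 24))
        self.profile_model = self.profile_model.lower()
        names = PARAM_NAMES[self.profile_model]
        for d in (self.group_param_means, self.group_param_sds, self.group_change_means, self.group_change_sds):
            if set(d) != set(names):
                raise ValueError(f"parameter dicts must have keys {names}, got {sorted(d)}")
        sds = [self.one_rm_sd, self.one_rm_noise_sd, self.residual_sd_load]
        sds += list(self.group_param_sds.values()) + list(self.group_change_sds.values())
        if any(s < 0 for s in sds):
            raise ValueError("all SDs must be >= 0")

    def noise_at(self, load: float) -> float:
        if isinstance(self.rtf_noise_sd, dict):
            try:
                return float(self.rtf_noise_sd[float(load)])
            except KeyError as exc:
                raise ValueError(f"no rtf_noise_sd entry for load {load}") from exc
        return float(self.rtf_noise_sd)

    # plain-text round trip ----------------------------------------------------
    def to_file(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=float))

    @classmethod
    def from_file(cls, path) -> "CohortConfig":
        raw = json.loads(Path(path).read_text())
        if isinstance(raw.get("rtf_noise_sd"), dict):
            raw["rtf_noise_sd"] = {float(k): float(v) for k, v in raw["rtf_noise_sd"].items()}
        if "loads" in raw:
            raw["loads"] = tuple(float(x) for x in raw["loads"])
        return cls(**raw)


#: calibrated correlation between intercept-like and slope-like T1 parameters
#: (stronger athletes at a given load spectrum show flatter load-RTF slopes)
_STUDY_PARAM_CORR = {"lin": -0.45}


def study_config(profile_model: str = "lin", **overrides) -> CohortConfig:
    """A :class:`CohortConfig` calibrated to the study conditions for one model family."""
    means, sds, dmeans, dsds = (dict(d) for d in _STUDY_PARAMS[profile_model.lower()])
    cfg = dict(
        profile_model=profile_model.lower(),
        group_param_means=means,
        group_param_sds=sds,
        group_change_means=dmeans,
        group_change_sds=dsds,
    )
    rho = _STUDY_PARAM_CORR.get(profile_model.lower())
    if rho is not None:
        cfg["param_corr"] = [[1.0, rho], [rho, 1.0]]
    cfg.update(overrides)
    return CohortConfig(**cfg)


@dataclass
class SyntheticTruth:
    """Latent ground truth behind a generated cohort (for recovery tests)."""

    params_t1: pd.DataFrame  # subject x parameter, T1 curve parameters
    change_effects: pd.DataFrame  # subject x parameter, T2 - T1 change effects
    true_one_rm: pd.DataFrame  # subject x {T1, T2} latent (noise-free) 1-RM in kg
    config: CohortConfig


def invert_profile(model: str, params, relative_load: float) -> float:
    """Latent (real-valued) RTF at which the curve predicts ``relative_load``.

    Thin alias of :func:`strendo.models.invert`, kept here because the
    generator is its main consumer.
    """
    return invert(model, params, relative_load)


def _curve_ok(model, params, loads) -> bool:
    p = [params[k] for k in PARAM_NAMES[model]]
    if not is_decreasing(model, p, rtf_range=(0.5, 30.0)):
        return False
    try:
        lat = [invert(model, p, L) for L in loads]
    except ValueError:
        return False
    return all(0.0 < r < 50.0 for r in lat)


def _cov(sds: np.ndarray, corr) -> np.ndarray:
    r = np.eye(len(sds)) if corr is None else np.asarray(corr, dtype=float)
    return np.outer(sds, sds) * r


def generate_cohort(config: CohortConfig) -> tuple[PerformanceDataset, SyntheticTruth]:
    """Generate one synthetic test-retest cohort.

    Per subject: a latent 1-RM from ``Normal(one_rm_mean, one_rm_sd)``;
    T1 curve parameters from the group-level (multivariate) normal and
    T2 parameters as T1 plus a change effect; per trial and relative
    load the latent RTF solves the subject's curve, is perturbed by
    repetition-scale noise and rounded to an integer with floor 1.
    Observed 1-RMs add trial noise, the systematic T1->T2 shift, and
    rounding to the smallest load increment.  Draws violating curve
    validity (non-decreasing, or loads outside the curve's range) are
    redrawn up to ``config.max_redraws`` times.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    model = cfg.profile_model
    names = PARAM_NAMES[model]
    p = len(names)
    s_t = np.array([cfg.group_param_sds[k] for k in names])
    s_d = np.array([cfg.group_change_sds[k] for k in names])
    joint_mean = np.concatenate(
        [[cfg.group_param_means[k] for k in names], [cfg.group_change_means[k] for k in names]]
    )
    # joint covariance of (T1 parameters, change effects): within-block
    # correlations plus a diagonal cross block tying each parameter to its
    # own change effect (regression to the mean when cross_corr < 0)
    joint_cov = np.zeros((2 * p, 2 * p))
    joint_cov[:p, :p] = _cov(s_t, cfg.param_corr)
    joint_cov[p:, p:] = _cov(s_d, cfg.change_corr)
    cross = np.diag(cfg.cross_corr * s_t * s_d)
    joint_cov[:p, p:] = cross
    joint_cov[p:, :p] = cross
    if np.min(np.linalg.eigvalsh(joint_cov)) < -1e-9:
        raise ValueError("parameter/change correlation settings give a non-PSD joint covariance")

    width = len(str(cfg.n_subjects))
    rows, t1_rows, ch_rows, rm_rows, sids = [], [], [], [], []
    for i in range(cfg.n_subjects):
        sid = f"S{i + 1:0{width}d}"
        sex = "male" if i < cfg.n_male else "female"
        # latent 1-RM, redrawn on (rare) non-positive draws
        for _ in range(cfg.max_redraws):
            rm_true = rng.normal(cfg.one_rm_mean, cfg.one_rm_sd)
            if rm_true > 0:
                break
        else:
            raise RuntimeError("could not draw a positive 1-RM; check one_rm_mean/sd")

        # curve parameters: both trials must describe valid decreasing curves
        for _ in range(cfg.max_redraws):
            vec = rng.multivariate_normal(joint_mean, joint_cov)
            th = dict(zip(names, vec[:p]))
            dh = dict(zip(names, vec[p:]))
            t2 = {k: th[k] + dh[k] for k in names}
            if _curve_ok(model, th, cfg.loads) and _curve_ok(model, t2, cfg.loads):
                break
        else:
            raise RuntimeError(
                f"subject {sid}: no valid load-RTF curve within {cfg.max_redraws} redraws; "
                "group parameter settings likely imply non-decreasing curves"
            )

        rm_t1_lat, rm_t2_lat = rm_true, rm_true + cfg.time_effect_one_rm
        sids.append(sid)
        t1_rows.append(th)
        ch_rows.append(dh)
        rm_rows.append({"T1": rm_t1_lat, "T2": rm_t2_lat})

        for trial, rm_lat, params in (("T1", rm_t1_lat, th), ("T2", rm_t2_lat, t2)):
            rm_obs = rm_lat + rng.normal(0.0, cfg.one_rm_noise_sd)
            if cfg.round_one_rm_to > 0:
                rm_obs = round(rm_obs / cfg.round_one_rm_to) * cfg.round_one_rm_to
            rm_obs = max(rm_obs, cfg.round_one_rm_to or 1.0)
            rows.append(
                dict(subject_id=sid, sex=sex, trial=trial, measure="1RM", value=float(rm_obs), absolute_load_kg=np.nan)
            )
            pvec = [params[k] for k in names]
            for load in cfg.loads:
                nominal = load + (rng.normal(0.0, cfg.residual_sd_load) if cfg.residual_sd_load > 0 else 0.0)
                latent = invert(model, pvec, nominal)
                rtf = int(max(1, round(latent + rng.normal(0.0, cfg.noise_at(load)))))
                abs_load = round(load / 100.0 * rm_obs / 0.5) * 0.5
                rows.append(
                    dict(
                        subject_id=sid,
                        sex=sex,
                        trial=trial,
                        measure=f"RTF{int(load)}",
                        value=float(rtf),
                        absolute_load_kg=abs_load,
                    )
                )

    ds = PerformanceDataset(
        pd.DataFrame(rows),
        metadata={"generator": "strendo.synthetic_data", "profile_model": model, "seed": cfg.seed},
    )
    truth = SyntheticTruth(
        params_t1=pd.DataFrame(t1_rows, index=sids),
        change_effects=pd.DataFrame(ch_rows, index=sids),
        true_one_rm=pd.DataFrame(rm_rows, index=sids),
        config=cfg,
    )
    return ds, truth
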