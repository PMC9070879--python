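"""Individual strength-endurance profiles and repetition-maximum tables.

Fits a single athlete's load-RTF points with one of the four model
families by least squares, reports an adjusted R-squared, and builds a
repetition-maximum table predicting the relative (and, given the 1-RM,
absolute) load for each target repetition count.  The linear and
2-parameter exponential families are the recommended defaults — they
give the most reproducible parameter estimates across test-retest
trials — while the 3-parameter families remain available behind an
explicit flag with a stability warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._fitting import fit_curve
from .models import PARAM_NAMES, forward, invert, is_decreasing

__all__ = ["IndividualProfile", "fit_individual_profile", "predict_load", "predict_rtf", "rm_table"]

#: validity window for predictions (repetitions)
RTF_WINDOW = (1.0, 30.0)
RECOMMENDED_MODELS = ("lin", "ex2")


@dataclass
class IndividualProfile:
    """A fitted per-athlete load-RTF curve with fit diagnostics."""

    model_type: str
    params: dict
    adj_r_squared: float
    residuals: np.ndarray
    n_points: int
    rtf: np.ndarray = field(repr=False, default=None)
    load: np.ndarray = field(repr=False, default=None)

    @property
    def param_vector(self) -> np.ndarray:
        return np.array([self.params[k] for k in PARAM_NAMES[self.model_type]])

    def equation(self) -> str:
        a = self.params
        if self.model_type == "lin":
            return f"load = {a['a']:.2f} + ({a['b']:.3f}) * RTF"
        if self.model_type == "ex2":
            return f"load = {a['a']:.2f} * exp({a['b']:.4f} * RTF)"
        if self.model_type == "ex3":
            return f"load = {a['c']:.2f} + {a['a']:.2f} * exp({a['b']:.4f} * RTF)"
        return f"load = {a['Lp']:.1f} / (RTF - ({a['k']:.2f})) + ({a['CL']:.2f})"


def fit_individual_profile(points, model_type: str = "ex2", allow_unstable: bool = False) -> IndividualProfile:
    """Least-squares fit of one athlete's (relative load, RTF) points.

    ``points`` is a sequence of objects with ``relative_load`` and
    ``rtf`` attributes (e.g. :class:`strendo.io_data.LoadRepPoint`) or
    of (relative_load, rtf) pairs.  Requires at least 2 points for
    lin/ex2 and 3 for ex3/crit, with distinct RTF values; one more
    point than parameters is needed for a defined adjusted R-squared.
    """
    mt = model_type.lower()
    if mt in ("ex3", "crit") and not allow_unstable:
        warnings.warn(
            f"{mt} profiles are poorly reproducible across test-retest trials; "
            "lin or ex2 is recommended (pass allow_unstable=True to silence)"
        )
    try:
        rtf = np.array([p.rtf for p in points], dtype=float)
        load = np.array([p.relative_load for p in points], dtype=float)
    except AttributeError:
        arr = np.asarray(points, dtype=float)
        load, rtf = arr[:, 0], arr[:, 1]
    n, p = rtf.size, len(PARAM_NAMES[mt])
    if n < p:
        raise ValueError(f"{mt}: {n} points cannot determine {p} parameters")
    params, sse = fit_curve(mt, rtf, load)
    resid = load - np.asarray(forward(mt, params, rtf))
    sst = float(np.sum((load - load.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else 1.0
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1) if n > p + 1 else np.nan
    return IndividualProfile(mt, dict(zip(PARAM_NAMES[mt], params)), float(adj), resid, n, rtf, load)


def _check_window(profile: IndividualProfile, rtf) -> None:
    lo, hi = RTF_WINDOW
    if np.any((np.asarray(rtf) < lo) | (np.asarray(rtf) > hi)):
        raise ValueError(f"RTF {rtf} outside the validity window [{lo:.0f}, {hi:.0f}] repetitions")


def predict_load(profile: IndividualProfile, rtf):
    """Relative load (% 1-RM) the profile predicts at ``rtf`` repetitions."""
    _check_window(profile, rtf)
    return forward(profile.model_type, profile.param_vector, rtf)


def predict_rtf(profile: IndividualProfile, relative_load):
    """Real-valued RTF at which the profile predicts ``relative_load``."""
    out = invert(profile.model_type, profile.param_vector, relative_load)
    _check_window(profile, out)
    return out


def rm_table(
    profile: IndividualProfile,
    one_rm_kg: float | None = None,
    max_reps: int = 15,
    rounding_kg: float = 0.5,
) -> pd.DataFrame:
    """Repetition-maximum table for target RTF 1..``max_reps``.

    Columns: ``rtf``, ``relative_load`` (% 1-RM) and, when
    ``one_rm_kg`` is given, ``absolute_load_kg`` rounded to
    ``rounding_kg``.  Requires a strictly decreasing profile over the
    table range.
    """
    if max_reps < 1:
        raise ValueError("max_reps must be >= 1")
    pv = profile.param_vector
    if not is_decreasing(profile.model_type, pv, rtf_range=(1.0, float(max_reps) + 1e-9)):
        raise ValueError("profile is not strictly decreasing over the requested range; no valid table")
    reps = np.arange(1, max_reps + 1)
    rel = np.asarray(forward(profile.model_type, pv, reps), dtype=float)
    out = pd.DataFrame({"rtf": reps, "relative_load": rel})
    if one_rm_kg is not None:
        absolute = rel / 100.0 * one_rm_kg
        if rounding_kg:
            absolute = np.round(absolute / rounding_kg) * rounding_kg
        out["absolute_load_kg"] = absolute
    return out
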