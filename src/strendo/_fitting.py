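"""Least-squares fitting of the four load-RTF curves (internal).

Shared by :mod:`strendo.profile_builder` (individual profiles) and
:mod:`strendo.se_models` (coarse per-subject and pooled fits that seed
priors and initial sampler states).  Nonlinear families use a coarse
grid of sign-consistent starting points followed by local refinement,
because three- and four-point fits are fragile under single-start
optimizers.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import least_squares

from .models import PARAM_NAMES, forward

__all__ = ["fit_curve"]


def _bounds(model, rtf, load):
    """Parameter boxes that exclude the degenerate ridges of the nonlinear
    families (e.g. the critical-load hyperbola flattening into a line as
    Lp -> inf, k -> -inf)."""
    lo_load = float(np.min(load))
    rmin = float(np.min(rtf))
    if model == "ex2":
        return ([1e-6, -5.0], [1e4, 5.0])
    if model == "ex3":
        return ([1e-6, -5.0, -500.0], [1e4, -1e-6, lo_load])
    if model == "crit":
        return ([1e-6, rmin - 100.0, -500.0], [5e4, rmin - 1e-3, lo_load])
    return (-np.inf, np.inf)


def _refine(model, p0, rtf, load):
    def resid(p):
        return forward(model, p, rtf) - load

    lo, hi = _bounds(model, rtf, load)
    p0 = np.clip(p0, np.asarray(lo) + 1e-9, np.asarray(hi) - 1e-9)
    try:
        sol = least_squares(resid, p0, method="trf", bounds=(lo, hi), max_nfev=2000)
    except Exception:
        return None
    if not np.all(np.isfinite(sol.x)):
        return None
    return sol.x, float(np.sum(sol.fun**2))


def _lin_closed_form(rtf, load):
    X = np.column_stack([np.ones_like(rtf), rtf])
    coef, *_ = np.linalg.lstsq(X, load, rcond=None)
    sse = float(np.sum((load - X @ coef) ** 2))
    return np.array([coef[0], coef[1]]), sse


def _ex2_starts(rtf, load):
    # log-linearize: log(load) = log(a) + b * RTF
    coef = np.polyfit(rtf, np.log(np.maximum(load, 1e-9)), 1)
    yield np.array([np.exp(coef[1]), coef[0]])
    yield np.array([np.max(load) * 1.05, -0.03])


def _ex3_starts(rtf, load):
    lo = float(np.min(load))
    for c in np.linspace(0.0, 0.9 * lo, 6):
        shifted = load - c
        coef = np.polyfit(rtf, np.log(np.maximum(shifted, 1e-9)), 1)
        yield np.array([np.exp(coef[1]), coef[0], c])


def _crit_starts(rtf, load):
    rmin = float(np.min(rtf))
    for k in (rmin - 1.0, rmin - 5.0, rmin - 15.0, rmin - 35.0, rmin - 60.0):
        x = 1.0 / (rtf - k)
        coef = np.polyfit(x, load, 1)  # load = Lp * x + CL
        yield np.array([coef[0], k, coef[1]])


def fit_curve(model_type: str, rtf, load) -> tuple[np.ndarray, float]:
    """Least-squares parameter estimates and SSE for one point set.

    Closed form for ``lin``; multi-start local refinement otherwise.
    Raises ``RuntimeError`` when no start converges.
    """
    mt = model_type.lower()
    rtf = np.asarray(rtf, dtype=float)
    load = np.asarray(load, dtype=float)
    p = len(PARAM_NAMES[mt])
    if rtf.size < p:
        raise ValueError(f"{mt}: need >= {p} points, got {rtf.size}")
    if np.unique(rtf).size < 2:
        raise ValueError("need at least two distinct RTF values")
    if mt == "lin":
        return _lin_closed_form(rtf, load)
    starts = {"ex2": _ex2_starts, "ex3": _ex3_starts, "crit": _crit_starts}[mt](rtf, load)
    best = None
    for p0 in starts:
        res = _refine(mt, p0, rtf, load)
        if res is not None and (best is None or res[1] < best[1]):
            best = res
    if best is None:
        raise RuntimeError(
            f"{mt}: nonlinear fit failed to converge from all starting points; "
            "consider the lin or ex2 model for this point set"
        )
    return best
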