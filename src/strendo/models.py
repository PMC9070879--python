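"""Strength-endurance model equations.

Four bivariate models of the relationship between relative load
(percent of the one-repetition maximum, 0-100 scale) and the number of
repetitions performed to momentary failure (RTF):

========  ============================  ==========================
name      load = f(RTF)                 parameters
========  ============================  ==========================
``lin``   ``a + b*RTF``                 a (% 1-RM), b (%/rep)
``ex2``   ``a * exp(b*RTF)``            a (% 1-RM), b (1/rep)
``ex3``   ``c + a * exp(b*RTF)``        a, c (% 1-RM), b (1/rep)
``crit``  ``Lp / (RTF - k) + CL``       Lp (%*rep), k (rep), CL (%)
========  ============================  ==========================

``lin`` and ``ex2`` describe a decreasing curve whenever ``b < 0``;
``ex3`` additionally shifts the exponential by an asymptote ``c``;
``crit`` is the critical-load hyperbola (asymptote ``CL`` as RTF grows,
work-capacity analogue ``Lp``, horizontal offset ``k``).  All four are
strictly decreasing in RTF on their valid domain, which is what the
inverse (``invert``) relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["MODEL_TYPES", "PARAM_NAMES", "SEModelSpec", "forward", "invert", "is_decreasing"]

MODEL_TYPES = ("lin", "ex2", "ex3", "crit")

PARAM_NAMES: dict[str, tuple[str, ...]] = {
    "lin": ("a", "b"),
    "ex2": ("a", "b"),
    "ex3": ("a", "b", "c"),
    "crit": ("Lp", "k", "CL"),
}


def _canon(model_type: str) -> str:
    mt = model_type.lower()
    if mt not in MODEL_TYPES:
        raise ValueError(f"unknown model type {model_type!r}; expected one of {MODEL_TYPES}")
    return mt


@dataclass(frozen=True)
class SEModelSpec:
    """A strength-endurance model family and its parameter layout."""

    model_type: str
    param_names: tuple[str, ...] = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "model_type", _canon(self.model_type))
        object.__setattr__(self, "param_names", PARAM_NAMES[self.model_type])

    @property
    def n_params(self) -> int:
        return len(self.param_names)


def forward(model_type: str, params, rtf):
    """Relative load (% 1-RM) predicted at ``rtf`` repetitions.

    ``params`` is a sequence in the order of ``PARAM_NAMES[model_type]``.
    Accepts scalars or arrays for ``rtf``; ``params`` may carry leading
    broadcast dimensions (last axis = parameter index is NOT assumed —
    pass individual parameter arrays via tuple unpacking instead).
    """
    mt = _canon(model_type)
    rtf = np.asarray(rtf, dtype=float)
    if mt == "lin":
        a, b = params
        out = a + b * rtf
    elif mt == "ex2":
        a, b = params
        out = a * np.exp(b * rtf)
    elif mt == "ex3":
        a, b, c = params
        out = c + a * np.exp(b * rtf)
    else:  # crit
        lp, k, cl = params
        out = lp / (rtf - k) + cl
    return out if out.shape else float(out)


def invert(model_type: str, params, relative_load):
    """RTF (real-valued) at which the curve predicts ``relative_load``.

    Exact algebraic inversion of :func:`forward`; raises ``ValueError``
    when the load lies outside the curve's range (e.g. above ``a`` for
    ``ex2``, or at/below the ``CL`` asymptote for ``crit``).
    """
    mt = _canon(model_type)
    load = np.asarray(relative_load, dtype=float)
    if mt == "lin":
        a, b = params
        if np.any(b == 0):
            raise ValueError("lin model with b = 0 has no inverse")
        out = (load - a) / b
    elif mt == "ex2":
        a, b = params
        if np.any(load <= 0) or np.any((load / a) <= 0):
            raise ValueError("ex2 inverse requires 0 < load and sign(load) == sign(a)")
        if np.any(b < 0) and np.any(load > a):
            raise ValueError("ex2 inverse: load exceeds the curve's ceiling a (RTF would be negative)")
        out = np.log(load / a) / b
    elif mt == "ex3":
        a, b, c = params
        ratio = (load - c) / a
        if np.any(ratio <= 0):
            raise ValueError("ex3 inverse requires (load - c)/a > 0 (load above the asymptote c)")
        out = np.log(ratio) / b
    else:  # crit
        lp, k, cl = params
        if np.any(load - cl == 0):
            raise ValueError("crit inverse undefined at the asymptote load == CL")
        out = lp / (load - cl) + k
    return out if out.shape else float(out)


def is_decreasing(model_type: str, params, rtf_range=(1.0, 30.0), n_grid: int = 64) -> bool:
    """Whether the curve is strictly decreasing across ``rtf_range``.

    Used by the cohort generator to reject parameter draws that do not
    describe a physiologically meaningful strength-endurance profile,
    and by the repetition-maximum table builder.
    """
    mt = _canon(model_type)
    lo, hi = rtf_range
    if mt == "crit":
        lp, k, _ = params
        # hyperbola decreasing on (k, inf) iff Lp > 0; the whole range must sit right of k
        if not (lp > 0 and k < lo):
            return False
    grid = np.linspace(lo, hi, n_grid)
    vals = forward(mt, params, grid)
    return bool(np.all(np.diff(vals) < 0))
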