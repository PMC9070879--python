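"""Pooling of subgroup descriptive statistics.

Combines per-subgroup (n, mean, SD) summaries — e.g. the male and
female sub-cohorts of a mixed-sex study — into the whole-sample mean
and SD using the exact two-pass pooling identity, so that published
subgroup tables can be checked against a published pooled abstract.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SubgroupStats", "pool_subgroups"]


@dataclass(frozen=True)
class SubgroupStats:
    """Descriptive summary (count, mean, standard deviation) of one subgroup."""

    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("subgroup size must be >= 1")
        if self.sd < 0:
            raise ValueError("SD must be >= 0")


def pool_subgroups(groups: list[SubgroupStats]) -> SubgroupStats:
    """Exact pooled (n, mean, SD) of disjoint subgroups.

    The pooled variance combines within-group sums of squares
    ``(n_g - 1) * sd_g**2`` with the between-group dispersion
    ``n_g * (mean_g - pooled_mean)**2``, divided by ``n - 1``.
    """
    if not groups:
        raise ValueError("need at least one subgroup")
    n = sum(g.n for g in groups)
    mean = sum(g.n * g.mean for g in groups) / n
    if n == 1:
        return SubgroupStats(n, mean, 0.0)
    ss = sum((g.n - 1) * g.sd**2 + g.n * (g.mean - mean) ** 2 for g in groups)
    return SubgroupStats(n, mean, float(np.sqrt(ss / (n - 1))))
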