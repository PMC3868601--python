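"""Empirical percentile ranks of a sample via the j/g order-statistic rule.

For the t-th percentile of n ordered values x_1 ≤ … ≤ x_n, write
np = j + g with p = t/100, j = ⌊np⌋ and g the fractional part. Then

    y = (x_j + x_{j+1}) / 2   if g = 0
    y = x_{j+1}               if g > 0

(Hyndman–Fan "type 2", the SAS default percentile definition). When
np < 1 the rule degenerates to j = 0, g > 0 and returns x_1. Ties in
the data are kept as-is in the order statistics — no deduplication.
"""

from __future__ import annotations

from typing import Dict, Iterable, Sequence, Tuple

import numpy as np

from .cohort_io import GroupedCohort

__all__ = ["DEFAULT_LEVELS", "empirical_percentile", "group_percentiles"]

#: Percentile ranks used throughout: 5th, 25th, 50th, 75th, 95th.
DEFAULT_LEVELS: Tuple[float, ...] = (5.0, 25.0, 50.0, 75.0, 95.0)

#: np computed in floating point may miss exact integrality; a fractional
#: part within this tolerance of 0 (or 1) is treated as g = 0.
G_TOL = 1e-9


def empirical_percentile(values: Sequence[float] | np.ndarray, t: float) -> float:
    """The t-th percentile of ``values`` (0 < t < 100).

    The input need not be pre-sorted; a sorted copy is taken. The result
    is either an element of the sample or the midpoint of two adjacent
    order statistics.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    if n == 0:
        raise ValueError("cannot take a percentile of an empty sample")
    if not 0.0 < t < 100.0:
        raise ValueError(f"percentile level t={t!r} must lie strictly in (0, 100)")
    np_ = n * t / 100.0
    j = int(np.floor(np_))
    g = np_ - j
    if g < G_TOL:
        g = 0.0
    elif g > 1.0 - G_TOL:  # float undershoot of an exact integer np
        j += 1
        g = 0.0
    if g == 0.0:
        # t > 0 forces j >= 1; t < 100 forces j <= n - 1, but guard the
        # float edge where j == n.
        if j >= n:
            return float(x[-1])
        return float(0.5 * (x[j - 1] + x[j]))
    return float(x[j])  # x_{j+1} in 1-based indexing


def group_percentiles(
    cohort: GroupedCohort,
    levels: Iterable[float] = DEFAULT_LEVELS,
) -> Dict[Tuple[int, float], float]:
    """Directly calculated percentile ranks, per age band.

    Applies :func:`empirical_percentile` independently within each coded
    age group. Output maps (code, t) → percentile value and is monotone
    nondecreasing in t within each group.
    """
    levels = tuple(levels)
    out: Dict[Tuple[int, float], float] = {}
    for code in cohort.codes:
        sample = cohort.groups[code]
        if sample.size == 0:
            raise ValueError(f"age group {code} of cohort {cohort.label!r} is empty")
        for t in levels:
            out[(code, t)] = empirical_percentile(sample, t)
    return out
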