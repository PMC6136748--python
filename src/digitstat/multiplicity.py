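"""Holm-Bonferroni sequentially rejective multiple-testing correction.

Produces adjusted p-values: sort the raw p ascending, multiply the i-th
smallest by (m - i + 1) where m is the family size, take the running
maximum so adjusted values are monotone in raw rank, cap at 1, and map
back to input order.  Rejecting adjusted p <= alpha is then equivalent
to the classical step-down rule p_(i) <= alpha / (m - i + 1).

The family size m is an explicit parameter (default: the number of
supplied p-values) because a correction is sometimes applied over a
larger declared family than the p-values at hand.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np


@dataclasses.dataclass(frozen=True)
class AdjustedPValues:
    raw: tuple[float, ...]
    adjusted: tuple[float, ...]
    family_size: int


def holm_adjust(
    raw: Sequence[float], family_size: int | None = None
) -> AdjustedPValues:
    """Holm-Bonferroni adjusted p-values in the input order."""
    p = np.asarray(raw, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("need a non-empty 1-d vector of p-values")
    if np.any(p <= 0.0) or np.any(p > 1.0):
        bad = p[(p <= 0.0) | (p > 1.0)]
        raise ValueError(f"p-values must lie in (0, 1], got {bad.tolist()}")
    m = int(family_size) if family_size is not None else p.size
    if m < p.size:
        raise ValueError(
            f"family_size ({m}) cannot be smaller than the number of "
            f"p-values supplied ({p.size})"
        )
    order = np.argsort(p, kind="stable")
    multipliers = m - np.arange(p.size)
    candidates = p[order] * multipliers
    adjusted_sorted = np.minimum(np.maximum.accumulate(candidates), 1.0)
    adjusted = np.empty_like(p)
    adjusted[order] = adjusted_sorted
    return AdjustedPValues(
        raw=tuple(p.tolist()),
        adjusted=tuple(adjusted.tolist()),
        family_size=m,
    )
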