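"""Shared statistical primitives: BH adjustment and Fisher/hypergeometric tests.

These two functions back every multiple-testing correction and every
over-representation / overlap statistic in the package, so their conventions
are fixed here once:

* ``bh_adjust`` is the Benjamini-Hochberg step-up, order-preserving with the
  input and clipped to [0, 1].
* ``fisher_overlap`` builds the 2x2 membership table
  ``[[k, a-k], [b-k, N-a-b+k]]`` for an overlap of size ``k`` between sets of
  sizes ``a`` and ``b`` drawn from a universe of size ``N``.  The odds ratio
  is the plain cross-product ratio (+inf / 0 for zero cells, no Haldane
  correction — the exact p-value drives inference); the two-sided p sums
  hypergeometric point masses no larger than the observed one, the
  conventional exact definition.
"""

from __future__ import annotations

import math
from collections.abc import Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError

__all__ = ["bh_adjust", "fisher_overlap"]


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg q-values, in the same order as the input.

    Parameters
    ----------
    p_values:
        Raw p-values, each in [0, 1].

    Returns
    -------
    numpy.ndarray of q-values, ``q[i] >= p[i]`` element-wise.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def fisher_overlap(
    overlap: int,
    size_a: int,
    size_b: int,
    universe: int,
    sidedness: str = "two_sided",
) -> tuple[float, float]:
    """Exact Fisher test of the overlap between two sets in a finite universe.

    Parameters
    ----------
    overlap, size_a, size_b, universe:
        ``k = |A ∩ B|``, ``a = |A|``, ``b = |B|``, ``N = |universe|``.
    sidedness:
        ``"two_sided"`` or ``"greater"`` (enrichment).

    Returns
    -------
    (odds_ratio, p_value).  The odds ratio is ``(k (N-a-b+k)) / ((a-k)(b-k))``
    with +inf when the denominator alone is zero, 0.0 when the numerator
    alone is zero, and NaN when both are.
    """
    k, a, b, n = int(overlap), int(size_a), int(size_b), int(universe)
    cells = (k, a - k, b - k, n - a - b + k)
    if any(c < 0 for c in cells):
        raise ValidationError(
            f"inconsistent 2x2 table from k={k}, a={a}, b={b}, N={n}: {cells}"
        )
    if sidedness not in ("two_sided", "greater"):
        raise ValidationError(f"unknown sidedness {sidedness!r}")

    num = cells[0] * cells[3]
    den = cells[1] * cells[2]
    if den > 0:
        odds = num / den
    elif num > 0:
        odds = math.inf
    else:
        odds = math.nan

    alternative = "two-sided" if sidedness == "two_sided" else "greater"
    table = np.array(cells, dtype=np.int64).reshape(2, 2)
    _, p = sps.fisher_exact(table, alternative=alternative)
    return odds, float(min(p, 1.0))
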