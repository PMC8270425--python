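"""Exact 2x2 contingency statistics shared across analysis stages.

Fisher's exact test is computed by exact integer enumeration of the
hypergeometric distribution (``math.comb``), so the two-sided
probability-mass rule — sum the probabilities of every table with the
same margins whose point probability does not exceed the observed
table's — involves no floating-point tie ambiguity.  The odds ratio is
the cross-product ratio a*d / (b*c) with explicit conventions for zero
cells rather than NaN propagation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["AssociationResult", "fisher_exact", "odds_ratio"]


@dataclass(frozen=True)
class AssociationResult:
    """Outcome of a Fisher exact association test on a 2x2 table.

    Attributes
    ----------
    odds_ratio : float
        Cross-product ratio ``(a*d)/(b*c)``; ``inf`` when ``b*c == 0``
        and ``a*d > 0``, ``0`` when ``a*d == 0`` and ``b*c > 0``, ``1``
        when both products vanish.
    p_value : float
        Two-sided p-value (probability-mass method), in [0, 1].
    table : tuple
        The ((a, b), (c, d)) input.
    """

    odds_ratio: float
    p_value: float
    table: tuple


def _as_table(table) -> tuple[int, int, int, int]:
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {arr.shape}")
    if not np.all(np.isfinite(arr.astype(float))):
        raise ValueError("table entries must be finite")
    flat = arr.astype(float).ravel()
    if np.any(flat < 0):
        raise ValueError("table entries must be nonnegative")
    if np.any(flat != np.round(flat)):
        raise ValueError("table entries must be integers")
    a, b, c, d = (int(v) for v in np.round(flat))
    return a, b, c, d


def odds_ratio(table) -> float:
    """Cross-product odds ratio of a 2x2 table.

    Conventions for zero cells: ``(a*d, b*c) = (+, 0) -> inf``,
    ``(0, +) -> 0``, ``(0, 0) -> 1``.
    """
    a, b, c, d = _as_table(table)
    ad, bc = a * d, b * c
    if bc == 0:
        return math.inf if ad > 0 else 1.0
    return ad / bc


def fisher_exact(table) -> AssociationResult:
    """Two-sided Fisher exact test on a 2x2 table.

    Conditional on the observed margins, the number of events in the
    first cell follows a hypergeometric distribution; the p-value sums
    the probabilities of all tables at least as extreme (point
    probability <= observed) computed with exact integer weights.

    Raises
    ------
    ValueError
        On negative or non-integer entries, or an all-zero table.
    """
    a, b, c, d = _as_table(table)
    if a + b + c + d == 0:
        raise ValueError("all-zero table has no defined test")

    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    # Exact integer hypergeometric weights C(r1, x) * C(r2, c1 - x).
    weights = [math.comb(r1, x) * math.comb(r2, c1 - x) for x in range(lo, hi + 1)]
    w_obs = weights[a - lo]
    numer = sum(w for w in weights if w <= w_obs)
    p = numer / math.comb(n, c1)
    return AssociationResult(odds_ratio=odds_ratio(((a, b), (c, d))),
                             p_value=min(1.0, p),
                             table=((a, b), (c, d)))
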