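"""Stereological scaling of per-section immunopositive cell counts.

Cells are counted on a systematic 1-in-12 series of sections (40 um
sections spaced 240 um apart, hemibrain), so the whole-structure
estimate is the summed count times the sampling-fraction reciprocal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SectionCounts", "estimate_total_count"]


@dataclass(frozen=True)
class SectionCounts:
    counts: tuple
    multiplier: int = 12

    def __post_init__(self):
        if not self.counts:
            raise ValueError("need at least one section count")
        if any(c < 0 or c != int(c) for c in self.counts):
            raise ValueError("section counts must be nonnegative integers")
        if self.multiplier < 1:
            raise ValueError("multiplier must be >= 1")


def estimate_total_count(counts, multiplier: int = 12,
                         method: str = "sum") -> float:
    """Estimate the whole-structure count from sampled sections.

    ``method="sum"`` (default) multiplies the summed section counts by
    the sampling-fraction reciprocal; ``method="mean"`` scales the
    per-section average instead.
    """
    sc = counts if isinstance(counts, SectionCounts) \
        else SectionCounts(tuple(counts), multiplier)
    arr = np.asarray(sc.counts, dtype=float)
    if method == "sum":
        return float(arr.sum() * sc.multiplier)
    if method == "mean":
        return float(arr.mean() * sc.multiplier)
    raise ValueError(f"unknown method {method!r}; use 'sum' or 'mean'")
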