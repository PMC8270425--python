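"""Cumulative S-phase labeling kinetics.

In a cumulative-labeling experiment a thymidine analogue (EdU/BrdU) is
kept available while samples are fixed at increasing exposure times.
The labeling index LI(t) — the percent of cells that have passed
through S phase — rises linearly and then plateaus once every cycling
cell has been labeled:

    LI(t) = GF * (Ts + t) / Tc     for t <= Tc - Ts
          = GF                     otherwise

where GF is the growth fraction (percent of cells actively cycling),
Tc the cell-cycle length and Ts the S-phase length (hours).  Fitting
one regression line to the rise and a horizontal line to the plateau
gives slope m = GF/Tc and intercept b = Li0 = GF*Ts/Tc, hence

    Tc = GF / m,   Ts = b / m,   t* = (GF - b) / m = Tc - Ts,

with t* the intersection time of the two lines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "TwoSegmentRegression",
    "TwoLineFit",
    "CycleKinetics",
    "NoRiseError",
    "fit_two_segment",
    "derive_kinetics",
    "forward_model",
    "bootstrap_kinetics",
    "timecourse_arrays",
]


class NoRiseError(ValueError):
    """Raised when the best fit has a nonpositive rise slope."""


@dataclass
class TwoLineFit:
    """Independent rise line and horizontal plateau fitted to LI(t).

    ``breakpoint`` is the SSE-optimal split between rise and plateau
    points; ``t_star = (plateau - intercept)/slope`` is the analytic
    intersection of the two lines, which estimates Tc - Ts and need
    not coincide with the split.
    """

    slope: float           # m, percent per hour
    intercept: float       # b = Li0, percent
    plateau: float         # GF, percent
    breakpoint: float      # SSE-optimal split time, hours
    t_star: float          # (GF - b) / m, hours
    sse: float
    r2_rise: float
    n_rise: int
    n_plateau: int


@dataclass
class CycleKinetics:
    """Growth fraction and cycle timing derived from a two-line fit."""

    GF: float    # percent
    Tc: float    # hours
    Ts: float    # hours
    Li0: float   # percent


def timecourse_arrays(timecourse) -> tuple[np.ndarray, np.ndarray]:
    """Extract (time_h, li_percent) points from a timecourse table.

    Accepts a DataFrame with ``time_h`` plus either ``li_percent`` or
    ``labeled``/``total`` columns, or a pair of arrays.
    """
    if isinstance(timecourse, pd.DataFrame):
        t = np.asarray(timecourse["time_h"], dtype=float)
        if "li_percent" in timecourse.columns:
            li = np.asarray(timecourse["li_percent"], dtype=float)
        else:
            li = 100.0 * np.asarray(timecourse["labeled"], dtype=float) \
                / np.asarray(timecourse["total"], dtype=float)
    else:
        t, li = (np.asarray(a, dtype=float).ravel() for a in timecourse)
    if np.any(t < 0):
        raise ValueError("labeling times must be nonnegative")
    if np.any((li < 0) | (li > 100)):
        raise ValueError("labeling index must be within [0, 100]")
    return t, li


class TwoSegmentRegression(BaseEstimator, RegressorMixin):
    """Rise-plus-plateau regression for cumulative labeling curves.

    Candidate breakpoints are the midpoints between consecutive
    distinct sample times.  For each candidate, points at or before it
    are fitted by ordinary least squares (the rise) and points after
    it by their mean (the horizontal plateau); the candidate with the
    smallest pooled sum of squared errors wins, ties going to the
    smallest breakpoint.  Replicates enter as individual points.

    Parameters
    ----------
    min_rise_points, min_plateau_points : int
        Minimum points on each side of an admissible split.  The
        defaults (3 and 2) leave the rise slope one residual degree of
        freedom.

    Attributes (after ``fit``)
    --------------------------
    slope_, intercept_, plateau_, breakpoint_, t_star_, sse_, r2_rise_
        See :class:`TwoLineFit`.
    """

    def __init__(self, min_rise_points: int = 3, min_plateau_points: int = 2):
        self.min_rise_points = min_rise_points
        self.min_plateau_points = min_plateau_points

    def fit(self, X, y):
        t = np.asarray(X, dtype=float).ravel()
        li = np.asarray(y, dtype=float).ravel()
        if t.size != li.size:
            raise ValueError("time and labeling index must have equal length")
        if self.min_rise_points < 2 or self.min_plateau_points < 2:
            raise ValueError("need at least 2 points per segment")
        distinct = np.unique(t)
        if distinct.size < 4:
            raise ValueError(
                f"need >= 4 distinct time values, got {distinct.size}")

        candidates = 0.5 * (distinct[:-1] + distinct[1:])
        best = None
        any_admissible = False
        for bp in candidates:
            rise = t <= bp
            n_rise, n_plat = int(rise.sum()), int((~rise).sum())
            if n_rise < self.min_rise_points or n_plat < self.min_plateau_points:
                continue
            if np.unique(t[rise]).size < 2:
                continue
            any_admissible = True
            coef, rss_rise = _ols_line(t[rise], li[rise])
            if coef[0] <= 0:
                # The model's rise is increasing by construction; a
                # split whose rise line falls is not a candidate fit.
                continue
            plateau = float(li[~rise].mean())
            rss_plat = float(((li[~rise] - plateau) ** 2).sum())
            sse = rss_rise + rss_plat
            if best is None or sse < best[0] - 1e-12:
                tss = float(((li[rise] - li[rise].mean()) ** 2).sum())
                r2 = 1.0 - rss_rise / tss if tss > 0 else 1.0
                best = (sse, bp, coef, plateau, r2, n_rise, n_plat)
        if not any_admissible:
            raise ValueError("no admissible breakpoint for the given minima")
        if best is None:
            raise NoRiseError(
                "no breakpoint yields a rising initial segment; "
                "no kinetics derivable from a non-increasing timecourse")
        sse, bp, (m, b), plateau, r2, n_rise, n_plat = best
        self.slope_ = float(m)
        self.intercept_ = float(b)
        self.plateau_ = float(plateau)
        self.breakpoint_ = float(bp)
        self.t_star_ = (self.plateau_ - self.intercept_) / self.slope_
        self.sse_ = float(sse)
        self.r2_rise_ = float(r2)
        self.n_rise_ = n_rise
        self.n_plateau_ = n_plat
        return self

    def predict(self, X) -> np.ndarray:
        t = np.asarray(X, dtype=float).ravel()
        return np.minimum(self.slope_ * t + self.intercept_, self.plateau_)

    def result_(self) -> TwoLineFit:
        return TwoLineFit(
            slope=self.slope_, intercept=self.intercept_, plateau=self.plateau_,
            breakpoint=self.breakpoint_, t_star=self.t_star_, sse=self.sse_,
            r2_rise=self.r2_rise_, n_rise=self.n_rise_, n_plateau=self.n_plateau_)


def _ols_line(t, y):
    """Least-squares line; returns ((slope, intercept), rss)."""
    A = np.column_stack([t, np.ones_like(t)])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    return (float(coef[0]), float(coef[1])), float(resid @ resid)


def fit_two_segment(timecourse, min_rise_points: int = 3,
                    min_plateau_points: int = 2) -> TwoLineFit:
    """Fit the rise/plateau model to a labeling timecourse table."""
    t, li = timecourse_arrays(timecourse)
    est = TwoSegmentRegression(min_rise_points, min_plateau_points).fit(t, li)
    return est.result_()


def derive_kinetics(fit: TwoLineFit) -> CycleKinetics:
    """Convert a two-line fit into (GF, Tc, Ts, Li0).

    Requires a positive slope and plateau and an intercept within
    ``[0, plateau]`` (an intercept above the plateau is geometrically
    inconsistent with a rise meeting it).
    """
    m, b, gf = fit.slope, fit.intercept, fit.plateau
    if m <= 0:
        raise NoRiseError("nonpositive slope: kinetics undefined")
    if gf <= 0:
        raise ValueError("plateau (growth fraction) must be positive")
    if b < 0:
        raise ValueError("negative intercept: Li0 cannot be negative")
    if b > gf:
        raise ValueError(
            f"intercept {b:.4g} exceeds plateau {gf:.4g}: inconsistent fit")
    return CycleKinetics(GF=gf, Tc=gf / m, Ts=b / m, Li0=b)


def forward_model(k: CycleKinetics, times) -> np.ndarray:
    """Theoretical LI(t): linear rise to the plateau at t = Tc - Ts."""
    t = np.asarray(times, dtype=float)
    if np.any(t < 0):
        raise ValueError("times must be nonnegative")
    if not (k.Tc > 0 and 0 <= k.Ts <= k.Tc and 0 < k.GF <= 100):
        raise ValueError("invalid kinetics parameters")
    return np.minimum(k.GF * (k.Ts + t) / k.Tc, k.GF)


def bootstrap_kinetics(timecourse, n_boot: int = 1000, seed: int = 0,
                       ci: float = 0.95, **fit_kwargs) -> pd.DataFrame:
    """Percentile bootstrap intervals for (GF, Tc, Ts, Li0).

    Points are resampled with replacement within each sample time, so
    the time design of the experiment is preserved.  Resamples where
    the two-line fit degenerates (e.g. nonpositive slope) are dropped.
    """
    t, li = timecourse_arrays(timecourse)
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(n_boot):
        idx = []
        for tv in np.unique(t):
            members = np.flatnonzero(t == tv)
            idx.append(rng.choice(members, size=members.size, replace=True))
        idx = np.concatenate(idx)
        try:
            k = derive_kinetics(fit_two_segment((t[idx], li[idx]), **fit_kwargs))
        except (ValueError, NoRiseError):
            continue
        rows.append((k.GF, k.Tc, k.Ts, k.Li0))
    if not rows:
        raise RuntimeError("all bootstrap resamples failed to fit")
    boot = pd.DataFrame(rows, columns=["GF", "Tc", "Ts", "Li0"])
    alpha = (1 - ci) / 2
    return pd.DataFrame({
        "estimate": boot.median(),
        "ci_low": boot.quantile(alpha),
        "ci_high": boot.quantile(1 - alpha),
        "n_resamples": len(boot),
    })
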