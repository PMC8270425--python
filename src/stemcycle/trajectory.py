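"""Pseudotime expression-trend analysis and stage segmentation.

The procedure mirrors a common single-cell workflow on a precomputed
trajectory: per-gene expression is rescaled to relative units
``log2(CPM+1) / max(log2(CPM+1))``, smoothed against pseudotime with a
local polynomial (loess-type) regression, and an early/late stage
boundary (T1 vs T2) is placed at the rightmost stationary point of a
chosen marker's trend that precedes its final rise — operationally,
the time at which an intermediate-progenitor marker such as Tbr2
starts increasing.  Per-stage positive-cell counts are then compared
with Fisher's exact test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from anndata import AnnData
from sklearn.base import BaseEstimator, RegressorMixin

from .profile import gene_cpm, validate_profile
from .stats import AssociationResult, fisher_exact, odds_ratio  # noqa: F401 (re-export)

__all__ = [
    "LocalPolynomialTrend",
    "TrendFit",
    "StageCut",
    "PositiveCounts",
    "NoCutoffError",
    "relative_expression",
    "fit_trend",
    "stage_cutoff",
    "assign_stages",
    "count_positive_by_stage",
    "fisher_exact",
    "odds_ratio",
]


class NoCutoffError(ValueError):
    """Raised when a trend has no stationary point preceding a rise."""


def relative_expression(profile: AnnData, gene: str) -> np.ndarray:
    """Per-cell relative expression ``log2(CPM+1) / max(log2(CPM+1))``.

    The output lies in [0, 1]; an all-zero gene maps to the all-zero
    vector (0/0 convention).
    """
    log_expr = np.log2(gene_cpm(profile, gene) + 1.0)
    m = log_expr.max() if log_expr.size else 0.0
    if m == 0:
        return np.zeros_like(log_expr)
    return log_expr / m


class LocalPolynomialTrend(BaseEstimator, RegressorMixin):
    """Local polynomial (loess-type) regression of a trend on pseudotime.

    At each evaluation point the nearest ``span`` fraction of cells is
    weighted with the tricube kernel and a weighted polynomial of
    ``degree`` is fitted; the prediction is the local intercept.  The
    smoother is linear in the responses, so pointwise standard errors
    follow from the norm of the equivalent-kernel weights and a
    residual variance estimated with ``n - tr(L)`` degrees of freedom.

    Parameters
    ----------
    span : float, default 0.75
        Fraction of points in each local neighborhood, in (0, 1].
    degree : int, default 2
        Local polynomial degree (2 = local quadratic, the R default).

    Attributes
    ----------
    x_, y_ : ndarray
        Training points, sorted by ``x``.
    sigma2_ : float
        Residual variance estimate.
    hat_trace_ : float
        Trace of the smoother matrix (effective model df).
    """

    def __init__(self, span: float = 0.75, degree: int = 2):
        self.span = span
        self.degree = degree

    def _neighborhood(self, x0: float):
        dist = np.abs(self.x_ - x0)
        n = self.x_.size
        q = int(math.floor(self.span * n + 1e-9))
        q = max(self.degree + 1, min(n, q))
        h = np.partition(dist, q - 1)[q - 1]
        if h <= 0:
            # >= q replicated abscissae at x0: fall back to uniform
            # weights over the tied points.
            w = (dist == 0).astype(float)
        else:
            u = np.clip(dist / h, 0.0, 1.0)
            w = (1.0 - u**3) ** 3
        return w

    def _equivalent_kernel(self, x0: float) -> np.ndarray:
        """Weights l(x0) with prediction = l(x0) @ y."""
        w = self._neighborhood(x0)
        z = self.x_ - x0
        scale = np.max(np.abs(z[w > 0])) or 1.0
        B = np.vander(z / scale, N=self.degree + 1, increasing=True)
        Bw = B * w[:, None]
        M = B.T @ Bw
        # Ridge of last resort for rank-deficient neighborhoods.
        M += np.eye(self.degree + 1) * 1e-12 * max(1.0, np.trace(M))
        sol = np.linalg.solve(M, Bw.T)
        return sol[0]

    def fit(self, X, y):
        x = np.asarray(X, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        if x.size != y.size:
            raise ValueError("X and y must have the same length")
        if x.size < max(10, self.degree + 1):
            raise ValueError(f"need at least 10 points, got {x.size}")
        if not (0 < self.span <= 1):
            raise ValueError(f"span must be in (0, 1], got {self.span}")
        if np.ptp(x) == 0:
            raise ValueError("degenerate pseudotime: all values identical")
        order = np.argsort(x, kind="stable")
        self.x_, self.y_ = x[order], y[order]

        n = x.size
        fitted = np.empty(n)
        hat_diag = np.empty(n)
        for i, xi in enumerate(self.x_):
            l = self._equivalent_kernel(xi)
            fitted[i] = l @ self.y_
            hat_diag[i] = l[i]
        self.fitted_train_ = fitted
        self.hat_trace_ = float(hat_diag.sum())
        rss = float(((self.y_ - fitted) ** 2).sum())
        df = max(n - self.hat_trace_, 1.0)
        self.sigma2_ = rss / df
        return self

    def predict(self, X) -> np.ndarray:
        grid = np.asarray(X, dtype=float).ravel()
        return np.array([self._equivalent_kernel(g) @ self.y_ for g in grid])

    def standard_error(self, X) -> np.ndarray:
        """Pointwise standard error of the fitted trend."""
        grid = np.asarray(X, dtype=float).ravel()
        se = np.empty(grid.size)
        for i, g in enumerate(grid):
            l = self._equivalent_kernel(g)
            se[i] = math.sqrt(self.sigma2_ * float(l @ l))
        return se


@dataclass
class TrendFit:
    """Smoothed relative-expression trend on a pseudotime grid.

    ``ci_low``/``ci_high`` are pointwise 95% normal-approximation
    bounds (fitted ± 1.96·SE).  ``cell_pseudotime``/``cell_ids`` carry
    the cells the trend was fitted on, so a stage cutoff derived from
    this trend can label them.
    """

    gene_id: str
    grid: np.ndarray
    fitted: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    span: float
    cell_ids: Optional[np.ndarray] = field(default=None, repr=False)
    cell_pseudotime: Optional[np.ndarray] = field(default=None, repr=False)


def fit_trend(profile: AnnData, gene: str, span: float = 0.75,
              n_grid: int = 200, degree: int = 2) -> TrendFit:
    """Fit a gene's relative-expression trend along pseudotime.

    Parameters
    ----------
    profile : AnnData
        Cells x genes CPM with ``obs["pseudotime"]``.
    gene : str
        Gene to smooth.
    span : float
        Loess span in (0, 1].
    n_grid : int
        Evenly spaced evaluation points over the observed pseudotime
        range (>= 20).
    """
    if n_grid < 20:
        raise ValueError(f"n_grid must be >= 20, got {n_grid}")
    validate_profile(profile)
    pt = np.asarray(profile.obs["pseudotime"], dtype=float)
    rel = relative_expression(profile, gene)
    model = LocalPolynomialTrend(span=span, degree=degree).fit(pt, rel)
    grid = np.linspace(pt.min(), pt.max(), n_grid)
    fitted = model.predict(grid)
    se = model.standard_error(grid)
    return TrendFit(
        gene_id=gene,
        grid=grid,
        fitted=fitted,
        ci_low=fitted - 1.96 * se,
        ci_high=fitted + 1.96 * se,
        span=span,
        cell_ids=np.asarray(profile.obs_names),
        cell_pseudotime=pt,
    )


@dataclass
class StageCut:
    """A pseudotime cutoff splitting cells into stages T1 and T2."""

    cutoff: float
    stage_of_cell: Optional[pd.Series] = None  # "T1"/"T2" per cell id


def assign_stages(pseudotime, cutoff: float, cell_ids=None) -> pd.Series:
    """Label cells T1 (pseudotime <= cutoff) or T2 (> cutoff)."""
    pt = np.asarray(pseudotime, dtype=float)
    labels = np.where(pt <= cutoff, "T1", "T2")
    index = pd.Index(cell_ids if cell_ids is not None else range(pt.size))
    return pd.Series(labels, index=index, name="stage")


def stage_cutoff(trend: TrendFit, derivative_tol: Optional[float] = None) -> StageCut:
    """Place the T1/T2 boundary at the trend's last stationary point.

    The derivative of the fitted curve is taken by central finite
    differences on the grid.  Grid points where the derivative changes
    sign, or where its magnitude falls below ``derivative_tol``, are
    stationary; the cutoff is the RIGHTMOST stationary point that is
    followed by a positive derivative (i.e. precedes the final rise of
    the marker).  If the curve ends flat, the last sign-change
    location is used instead.

    The default tolerance is ``1e-4 * range(fitted) / grid_step``.

    Raises
    ------
    NoCutoffError
        If the trend is monotone (no qualifying stationary point).
    """
    grid = np.asarray(trend.grid, dtype=float)
    fitted = np.asarray(trend.fitted, dtype=float)
    if grid.size < 20:
        raise ValueError("trend grid too coarse for cutoff detection")
    step = grid[1] - grid[0]
    if derivative_tol is None:
        derivative_tol = 1e-4 * float(np.ptp(fitted)) / step
    d = np.gradient(fitted, grid)

    flat = np.abs(d) <= derivative_tol
    stationary = flat.copy()
    sign_change = np.zeros_like(flat)
    sign_change[:-1] = d[:-1] * d[1:] < 0
    stationary |= sign_change

    idx = np.flatnonzero(stationary)
    cutoff_idx = None
    for i in idx[::-1]:
        after = np.flatnonzero(~flat[i + 1:])
        if after.size and d[i + 1 + after[0]] > 0:
            cutoff_idx = i
            break
    if cutoff_idx is None:
        # Curve ending flat: fall back to the last sign change.
        changes = np.flatnonzero(sign_change)
        ends_flat = flat[-1] if flat.size else False
        if ends_flat and changes.size:
            cutoff_idx = changes[-1]
        else:
            raise NoCutoffError(
                f"trend for {trend.gene_id!r} has no stationary point "
                "followed by a rise; cannot place a stage cutoff")

    cutoff = float(grid[cutoff_idx])
    stages = None
    if trend.cell_pseudotime is not None:
        stages = assign_stages(trend.cell_pseudotime, cutoff, trend.cell_ids)
    return StageCut(cutoff=cutoff, stage_of_cell=stages)


@dataclass
class PositiveCounts:
    """2x2 table of expression-positive cells by stage.

    ``table`` rows are (T1, T2), columns (positive, negative).
    """

    gene_id: str
    table: np.ndarray
    positivity_threshold: float

    def as_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.table, index=["T1", "T2"],
                            columns=["positive", "negative"])


def count_positive_by_stage(profile: AnnData, gene: str, cut: StageCut,
                            positivity_threshold: float = 0.0) -> PositiveCounts:
    """Cross-tabulate expression positivity (CPM > threshold) by stage."""
    cpm = gene_cpm(profile, gene)
    if cut.stage_of_cell is not None:
        stages = cut.stage_of_cell.reindex(profile.obs_names)
        if stages.isna().any():
            missing = stages.index[stages.isna()][0]
            raise ValueError(f"stage cut does not cover cell {missing!r}")
        stages = stages.to_numpy()
    else:
        stages = assign_stages(profile.obs["pseudotime"], cut.cutoff).to_numpy()
    pos = cpm > positivity_threshold
    table = np.array([
        [int(np.sum(pos & (stages == "T1"))), int(np.sum(~pos & (stages == "T1")))],
        [int(np.sum(pos & (stages == "T2"))), int(np.sum(~pos & (stages == "T2")))],
    ])
    return PositiveCounts(gene_id=gene, table=table,
                          positivity_threshold=positivity_threshold)
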