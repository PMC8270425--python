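"""Summed-marker cell-cycle scoring and cycling/positivity association.

Each cell gets a G1/S and a G2/M score: the sum of transformed
expression over a phase's marker genes, divided by the median of that
sum across cells (so a typical cell scores 1).  Cells whose larger
normalized score clears a threshold are called cycling, and cycling
status is cross-tabulated against positivity for a gene of interest
(here typically the MHC-I gene H2-K1), summarized by per-group cycling
percentages and a cross-product odds ratio.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from anndata import AnnData
from sklearn.base import BaseEstimator, TransformerMixin

from .profile import gene_cpm, validate_profile
from .stats import fisher_exact, odds_ratio  # noqa: F401 (re-export)

__all__ = [
    "MarkerSet",
    "CycleScores",
    "CyclingCall",
    "CellCycleScorer",
    "load_default_markers",
    "load_markers",
    "score_cell_cycle",
    "classify_cycling",
    "tabulate_by_positivity",
    "percent_cycling",
    "odds_ratio",
]

logger = logging.getLogger(__name__)

_TRANSFORMS = {
    "log2cpm1": lambda x: np.log2(x + 1.0),
    "cpm": lambda x: x,
}


@dataclass(frozen=True)
class MarkerSet:
    """Phase marker gene lists for G1/S and G2/M scores."""

    g1s_genes: tuple
    g2m_genes: tuple
    provenance: str = ""

    def __post_init__(self):
        for name, genes in (("g1s", self.g1s_genes), ("g2m", self.g2m_genes)):
            if not genes:
                raise ValueError(f"{name} marker list is empty")
            if len(set(genes)) != len(genes):
                raise ValueError(f"duplicate identifiers in {name} marker list")


def _read_marker_file(handle) -> tuple:
    return tuple(line.strip() for line in handle
                 if line.strip() and not line.startswith("#"))


def load_default_markers() -> MarkerSet:
    """Bundled mouse-cased consensus G1/S and G2/M signatures."""
    data = resources.files("stemcycle") / "data"
    with (data / "g1s_markers_mouse.txt").open() as f:
        g1s = _read_marker_file(f)
    with (data / "g2m_markers_mouse.txt").open() as f:
        g2m = _read_marker_file(f)
    return MarkerSet(g1s, g2m, provenance="bundled mouse-cased consensus signature")


def load_markers(path_g1s=None, path_g2m=None, json_path=None) -> MarkerSet:
    """Load marker lists from two plain-text files or one JSON file.

    Plain text: one gene per line, ``#`` comments allowed.  JSON: an
    object with keys ``g1s`` and ``g2m``.
    """
    if json_path is not None:
        payload = json.loads(Path(json_path).read_text())
        return MarkerSet(tuple(payload["g1s"]), tuple(payload["g2m"]),
                         provenance=str(json_path))
    if path_g1s is None or path_g2m is None:
        raise ValueError("provide either json_path or both phase files")
    with open(path_g1s) as f:
        g1s = _read_marker_file(f)
    with open(path_g2m) as f:
        g2m = _read_marker_file(f)
    return MarkerSet(g1s, g2m, provenance=f"{path_g1s} + {path_g2m}")


@dataclass
class CycleScores:
    """Raw and median-normalized per-cell cycle scores."""

    cell_ids: np.ndarray
    raw_g1s: np.ndarray
    raw_g2m: np.ndarray
    norm_g1s: np.ndarray
    norm_g2m: np.ndarray
    markers_used: dict = field(default_factory=dict, repr=False)

    def as_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "raw_g1s": self.raw_g1s, "raw_g2m": self.raw_g2m,
            "norm_g1s": self.norm_g1s, "norm_g2m": self.norm_g2m,
        }, index=pd.Index(self.cell_ids, name="cell_id"))


@dataclass
class CyclingCall:
    """Per-cell cycling flags and the threshold that produced them."""

    cell_ids: np.ndarray
    cycling: np.ndarray
    threshold: float


class CellCycleScorer(BaseEstimator, TransformerMixin):
    """Transformer computing summed-marker cell-cycle scores.

    Parameters
    ----------
    markers : MarkerSet or None
        Phase marker lists; ``None`` loads the bundled mouse set.
    scale : {"log2cpm1", "cpm"}
        Expression transform summed per phase; the default matches
        the log2(CPM+1) scale used by the trajectory stage.
    threshold : float
        Cycling call threshold on the larger normalized score.
    """

    def __init__(self, markers: Optional[MarkerSet] = None,
                 scale: str = "log2cpm1", threshold: float = 2.0):
        self.markers = markers
        self.scale = scale
        self.threshold = threshold

    def _phase_score(self, profile: AnnData, genes: Sequence[str], phase: str):
        present = [g for g in genes if g in profile.var_names]
        missing = sorted(set(genes) - set(present))
        if not present:
            raise ValueError(f"no {phase} marker genes found in the matrix")
        if missing:
            logger.warning("%s: %d/%d marker genes absent from matrix (e.g. %s)",
                           phase, len(missing), len(genes), missing[0])
        f = _TRANSFORMS[self.scale]
        X = np.asarray(profile[:, present].X, dtype=float)
        return f(X).sum(axis=1), present

    def fit(self, X: AnnData, y=None):
        if self.scale not in _TRANSFORMS:
            raise ValueError(f"unknown transform {self.scale!r}")
        validate_profile(X)
        markers = self.markers if self.markers is not None else load_default_markers()
        raw_g1s, used_g1s = self._phase_score(X, markers.g1s_genes, "g1s")
        raw_g2m, used_g2m = self._phase_score(X, markers.g2m_genes, "g2m")
        self.median_g1s_ = float(np.median(raw_g1s))
        self.median_g2m_ = float(np.median(raw_g2m))
        self.markers_used_ = {"g1s": used_g1s, "g2m": used_g2m}
        self._fit_scores_ = self._normalize(X.obs_names.to_numpy(), raw_g1s, raw_g2m)
        return self

    def _normalize(self, cell_ids, raw_g1s, raw_g2m) -> CycleScores:
        norms = []
        for raw, med, phase in ((raw_g1s, self.median_g1s_, "g1s"),
                                (raw_g2m, self.median_g2m_, "g2m")):
            if med > 0:
                norms.append(raw / med)
            else:
                # Sparse-data fallback: median of zeros; scale by the
                # mean of the strictly positive scores if any exist.
                positive = raw[raw > 0]
                if positive.size:
                    logger.warning("%s median score is 0; normalizing by the "
                                   "mean of positive scores", phase)
                    norms.append(raw / positive.mean())
                else:
                    logger.warning("%s scores are all zero; left unnormalized",
                                   phase)
                    norms.append(raw.copy())
        return CycleScores(np.asarray(cell_ids), raw_g1s, raw_g2m,
                           norms[0], norms[1], dict(self.markers_used_))

    def transform(self, X: AnnData) -> pd.DataFrame:
        scores = self.score(X)
        return scores.as_dataframe()

    def score(self, X: AnnData) -> CycleScores:
        """Score a profile with the medians learned in ``fit``."""
        markers = self.markers if self.markers is not None else load_default_markers()
        raw_g1s, _ = self._phase_score(X, markers.g1s_genes, "g1s")
        raw_g2m, _ = self._phase_score(X, markers.g2m_genes, "g2m")
        return self._normalize(X.obs_names.to_numpy(), raw_g1s, raw_g2m)

    def classify(self, scores: CycleScores) -> CyclingCall:
        return classify_cycling(scores, self.threshold)


def score_cell_cycle(profile: AnnData, markers: Optional[MarkerSet] = None,
                     transform: str = "log2cpm1") -> CycleScores:
    """Summed-marker scores normalized by the across-cell median."""
    scorer = CellCycleScorer(markers=markers, scale=transform).fit(profile)
    return scorer._fit_scores_


def classify_cycling(scores: CycleScores, threshold: float = 2.0) -> CyclingCall:
    """Call a cell cycling iff max(norm_g1s, norm_g2m) >= threshold."""
    if not (threshold > 0):
        raise ValueError(f"threshold must be positive, got {threshold}")
    logger.info("cycling classification at threshold %.3g on normalized scores",
                threshold)
    cycling = np.maximum(scores.norm_g1s, scores.norm_g2m) >= threshold
    return CyclingCall(scores.cell_ids, cycling, threshold)


def tabulate_by_positivity(calls: CyclingCall, profile: AnnData, gene: str,
                           positivity_threshold: float = 0.0) -> np.ndarray:
    """2x2 table: rows (gene-positive, gene-negative) x (cycling, noncycling)."""
    flags = pd.Series(calls.cycling, index=pd.Index(calls.cell_ids))
    flags = flags.reindex(profile.obs_names)
    if flags.isna().any():
        missing = flags.index[flags.isna()][0]
        raise ValueError(f"cycling call missing for cell {missing!r}")
    cyc = flags.to_numpy(dtype=bool)
    pos = gene_cpm(profile, gene) > positivity_threshold
    return np.array([
        [int(np.sum(pos & cyc)), int(np.sum(pos & ~cyc))],
        [int(np.sum(~pos & cyc)), int(np.sum(~pos & ~cyc))],
    ])


def percent_cycling(table) -> dict:
    """Per-row cycling percentages, rounded half-away-from-zero to 1 d.p.

    Rows with no cells are reported as ``None`` (undefined), never 0.
    """
    arr = np.asarray(table, dtype=float)
    if arr.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {arr.shape}")
    out = {}
    for name, (cycling, noncycling) in zip(("positive", "negative"), arr):
        total = cycling + noncycling
        if total == 0:
            out[name] = None
        else:
            pct = 100.0 * cycling / total
            out[name] = math.floor(pct * 10 + 0.5) / 10
    return out
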