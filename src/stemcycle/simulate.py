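"""Seeded synthetic data with the structure each analysis stage assumes.

Three generators:

* :func:`simulate_trajectory` — a cells x genes CPM matrix along an
  evenly spaced [0, 1] pseudotime, with per-gene mean trends drawn
  from a small family (logistic sigmoids for monotone shapes, a
  Gaussian bump for unimodal ones), multiplicative log-normal noise
  and Bernoulli dropout.  Emulates decreasing (MHC-I-like), static
  (housekeeping-like) and increasing (proliferation-marker-like)
  profiles along a neurogenic trajectory.
* :func:`simulate_labeling` — a cumulative-labeling timecourse with
  labeled counts drawn binomially around the theoretical
  LI(t) = min(GF*(Ts+t)/Tc, GF) curve.
* :func:`simulate_cycling_population` — two marker-positivity groups
  with different cycling fractions and well-separated cycle-marker
  expression, together with the ground-truth cycling labels.

Every generator is deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from anndata import AnnData

from .cellcycle import MarkerSet, load_default_markers
from .kinetics import CycleKinetics, forward_model
from .profile import make_profile

__all__ = [
    "GeneTrendSpec",
    "KineticsSimSpec",
    "PopulationSimSpec",
    "simulate_trajectory",
    "simulate_labeling",
    "simulate_cycling_population",
    "example_trajectory_specs",
]

_SHAPES = ("decreasing", "constant", "increasing", "unimodal")


@dataclass(frozen=True)
class GeneTrendSpec:
    """Mean-expression trend of one gene along [0, 1] pseudotime.

    ``baseline`` is the mean CPM at pseudotime 0 and ``amplitude`` the
    signed change across the trajectory (monotone shapes) or the bump
    height at ``inflection`` (unimodal).  ``steepness`` sets the
    logistic slope at the midpoint and ``width`` the unimodal Gaussian
    standard deviation, both on the [0, 1] pseudotime scale.
    ``dispersion`` is the sigma of multiplicative log-normal noise.
    ``dropout`` is the zeroing probability for cells where the gene
    sits at its trajectory-maximum mean; cells at lower mean drop out
    more, ``p_drop = dropout ** (mean / max_mean)``, emulating the
    inverse detection/abundance relationship of single-cell data
    (``dropout=0`` disables zeroing entirely, ``dropout=1`` zeroes
    every cell).
    """

    gene_id: str
    shape: str
    baseline: float
    amplitude: float = 0.0
    inflection: float = 0.5
    dropout: float = 0.0
    dispersion: float = 0.0
    steepness: float = 10.0
    width: float = 0.15

    def __post_init__(self):
        if self.shape not in _SHAPES:
            raise ValueError(f"unknown shape {self.shape!r}; choose from {_SHAPES}")
        if not 0 <= self.dropout <= 1:
            raise ValueError(f"dropout must be in [0, 1], got {self.dropout}")
        if self.baseline < 0:
            raise ValueError(f"baseline must be nonnegative, got {self.baseline}")
        if self.dispersion < 0:
            raise ValueError(f"dispersion must be >= 0, got {self.dispersion}")
        if self.shape == "decreasing" and self.amplitude > 0:
            raise ValueError("decreasing shape requires amplitude <= 0")
        if self.shape == "increasing" and self.amplitude < 0:
            raise ValueError("increasing shape requires amplitude >= 0")
        t = np.linspace(0, 1, 201)
        if np.any(self.mean_curve(t) < -1e-9):
            raise ValueError(
                f"trend for {self.gene_id!r} has negative expected CPM")

    def mean_curve(self, t) -> np.ndarray:
        """Noiseless expected CPM at pseudotimes ``t``."""
        t = np.asarray(t, dtype=float)
        if self.shape == "constant":
            return np.full_like(t, self.baseline)
        if self.shape == "unimodal":
            bump = np.exp(-0.5 * ((t - self.inflection) / self.width) ** 2)
            return self.baseline + self.amplitude * bump
        # Logistic sigmoid from baseline at t=0 toward baseline+amplitude,
        # rescaled so the endpoints are attained exactly.
        s = 1.0 / (1.0 + np.exp(-self.steepness * (t - self.inflection)))
        s0 = 1.0 / (1.0 + np.exp(self.steepness * self.inflection))
        s1 = 1.0 / (1.0 + np.exp(-self.steepness * (1.0 - self.inflection)))
        frac = (s - s0) / (s1 - s0)
        return self.baseline + self.amplitude * frac


def simulate_trajectory(specs: Sequence[GeneTrendSpec], n_cells: int,
                        seed: int = 0) -> AnnData:
    """Generate an expression profile along an evenly spaced pseudotime.

    With ``dispersion=0`` and ``dropout=0`` every gene equals its
    spec's expected curve exactly.
    """
    if not specs:
        raise ValueError("spec list must be nonempty")
    if n_cells < 2:
        raise ValueError(f"n_cells must be >= 2, got {n_cells}")
    ids = [s.gene_id for s in specs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate gene ids in specs")
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, 1.0, n_cells)
    X = np.empty((n_cells, len(specs)))
    for j, spec in enumerate(specs):
        mean = spec.mean_curve(t)
        col = mean.copy()
        if spec.dispersion > 0:
            col = col * rng.lognormal(0.0, spec.dispersion, size=n_cells)
        if spec.dropout > 0:
            mmax = mean.max()
            p_drop = spec.dropout ** (mean / mmax) if mmax > 0 \
                else np.full(n_cells, spec.dropout)
            col = col * (rng.random(n_cells) >= p_drop)
        X[:, j] = col
    cells = [f"cell_{i:04d}" for i in range(n_cells)]
    return make_profile(X, cells, ids, t)


def example_trajectory_specs(dropout: float = 0.3,
                             dispersion: float = 0.5) -> list:
    """Default gene trends of a neurogenic-trajectory simulation.

    The cast mirrors the profiles the trajectory stage is meant to
    resolve: an MHC-I-like gene falling as the trajectory progresses
    (``H2-K1``), a static paralog (``H2-D1``) and housekeeping gene
    (``Gapdh``), a proliferation marker rising mid-trajectory
    (``Mki67``), an intermediate-progenitor marker rising late
    (``Tbr2``, whose last stationary point places the stage cutoff),
    and a stem-cell marker falling late (``Gfap``).
    """
    return [
        GeneTrendSpec("H2-K1", "decreasing", baseline=100, amplitude=-95,
                      inflection=0.45, dropout=dropout, dispersion=dispersion),
        GeneTrendSpec("H2-D1", "constant", baseline=40,
                      dropout=dropout, dispersion=dispersion),
        GeneTrendSpec("Gapdh", "constant", baseline=500,
                      dropout=0.0, dispersion=dispersion),
        GeneTrendSpec("Mki67", "increasing", baseline=1, amplitude=80,
                      inflection=0.5, dropout=dropout, dispersion=dispersion),
        GeneTrendSpec("Tbr2", "increasing", baseline=0.0, amplitude=120,
                      inflection=0.7, steepness=15,
                      dropout=dropout, dispersion=dispersion),
        GeneTrendSpec("Gfap", "decreasing", baseline=150, amplitude=-150,
                      inflection=0.6, dropout=dropout, dispersion=dispersion),
    ]


@dataclass(frozen=True)
class KineticsSimSpec:
    """Design of a simulated cumulative-labeling experiment.

    ``cells_per_sample=None`` is the noiseless sentinel: the labeling
    index equals the theoretical curve exactly.  The defaults mirror
    the experimental design the kinetics stage targets — wild-type
    NSPC-like kinetics (GF 16.3%, Tc 26.5 h, Ts 13.0 h), fixation
    every 2 h from 2 h to 24 h, duplicate samples of ~200 cells.
    """

    GF: float = 16.3
    Tc: float = 26.5
    Ts: float = 13.0
    sample_times: tuple = tuple(range(2, 25, 2))
    cells_per_sample: Optional[int] = 200
    replicates: int = 2
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.GF <= 100:
            raise ValueError(f"GF must be in (0, 100], got {self.GF}")
        if self.Tc <= 0:
            raise ValueError(f"Tc must be positive, got {self.Tc}")
        if not 0 <= self.Ts <= self.Tc:
            raise ValueError(f"need 0 <= Ts <= Tc, got Ts={self.Ts}, Tc={self.Tc}")
        if not self.sample_times:
            raise ValueError("sample_times must be nonempty")
        times = tuple(float(t) for t in self.sample_times)
        if any(t < 0 for t in times):
            raise ValueError("sample_times must be nonnegative")
        if list(times) != sorted(times):
            raise ValueError("sample_times must be sorted ascending")
        if self.cells_per_sample is not None and self.cells_per_sample <= 0:
            raise ValueError("cells_per_sample must be positive (or None)")
        if self.replicates <= 0:
            raise ValueError("replicates must be positive")

    def kinetics(self) -> CycleKinetics:
        return CycleKinetics(GF=self.GF, Tc=self.Tc, Ts=self.Ts,
                             Li0=self.GF * self.Ts / self.Tc)


def simulate_labeling(spec: KineticsSimSpec) -> pd.DataFrame:
    """Simulate a cumulative-labeling timecourse.

    Returns one record per (time, replicate) with columns
    ``time_h, labeled, total, replicate, li_percent``.  Labeled counts
    are Binomial(cells_per_sample, LI(t)/100); in noiseless mode the
    expectation is returned exactly.
    """
    rng = np.random.default_rng(spec.seed)
    times = np.asarray(spec.sample_times, dtype=float)
    li_true = forward_model(spec.kinetics(), times)
    rows = []
    for rep in range(1, spec.replicates + 1):
        if spec.cells_per_sample is None:
            labeled = li_true / 100.0
            total = np.ones_like(li_true)
        else:
            total = np.full(times.size, spec.cells_per_sample)
            labeled = rng.binomial(spec.cells_per_sample, li_true / 100.0)
        for t, lab, tot in zip(times, labeled, total):
            rows.append((t, lab, tot, rep, 100.0 * lab / tot))
    return pd.DataFrame(rows, columns=["time_h", "labeled", "total",
                                       "replicate", "li_percent"])


@dataclass(frozen=True)
class PopulationSimSpec:
    """Two marker-positivity groups with different cycling fractions.

    ``n_pos`` cells express the positivity gene (CPM drawn log-normal
    around ``positive_gene_cpm``); ``n_neg`` cells do not.  Each cell
    is cycling with its group's probability; cycling cells express the
    cycle marker genes around ``cycling_marker_cpm`` CPM, noncycling
    cells around ``noncycling_marker_cpm`` — separated enough, after
    median normalization, for a thresholded cycling call.
    """

    n_pos: int
    n_neg: int
    cycling_frac_pos: float
    cycling_frac_neg: float
    positivity_gene: str = "H2-K1"
    positive_gene_cpm: float = 30.0
    cycling_marker_cpm: float = 50.0
    noncycling_marker_cpm: float = 1.0
    dispersion: float = 0.4
    dropout: float = 0.2
    markers: Optional[MarkerSet] = field(default=None, repr=False)
    seed: int = 0

    def __post_init__(self):
        if self.n_pos <= 0 or self.n_neg <= 0:
            raise ValueError("group counts must be positive")
        for p in (self.cycling_frac_pos, self.cycling_frac_neg):
            if not 0 <= p <= 1:
                raise ValueError(f"cycling fraction must be in [0, 1], got {p}")


def simulate_cycling_population(spec: PopulationSimSpec):
    """Generate (profile, true_cycling) for the cell-cycle stage.

    ``true_cycling`` is a boolean array aligned with the profile's
    cells.  Empirical group cycling fractions converge to the spec's
    probabilities as counts grow.
    """
    rng = np.random.default_rng(spec.seed)
    markers = spec.markers if spec.markers is not None else load_default_markers()
    genes = [spec.positivity_gene] + list(markers.g1s_genes) + list(markers.g2m_genes)
    n = spec.n_pos + spec.n_neg
    is_pos = np.zeros(n, dtype=bool)
    is_pos[:spec.n_pos] = True
    p_cycle = np.where(is_pos, spec.cycling_frac_pos, spec.cycling_frac_neg)
    cycling = rng.random(n) < p_cycle

    X = np.zeros((n, len(genes)))
    # Positivity gene: expressed only in the positive group.
    X[is_pos, 0] = spec.positive_gene_cpm * rng.lognormal(0, spec.dispersion,
                                                          is_pos.sum())
    marker_mean = np.where(cycling, spec.cycling_marker_cpm,
                           spec.noncycling_marker_cpm)
    n_markers = len(genes) - 1
    noise = rng.lognormal(0, spec.dispersion, (n, n_markers))
    keep = rng.random((n, n_markers)) >= spec.dropout
    X[:, 1:] = marker_mean[:, None] * noise * keep

    cells = [f"cell_{i:05d}" for i in range(n)]
    profile = make_profile(X, cells, genes, np.linspace(0, 1, n))
    return profile, cycling
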