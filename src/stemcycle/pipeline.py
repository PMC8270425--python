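"""Deterministic orchestration of the analysis stages.

A run is described by a single JSON or YAML configuration document;
``run_pipeline`` executes the requested stages in order (trajectory ->
cellcycle -> kinetics -> quant, as configured) and stamps every output
with the seed and a hash of the resolved configuration, so repeated
runs with the same config produce byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cellcycle, io, kinetics, quant, trajectory

__all__ = ["AnalysisConfig", "PipelineError", "run_pipeline"]

_STAGE_ORDER = ("trajectory", "cellcycle", "kinetics", "quant")

_DEFAULT_PARAMS = {
    "span": 0.75,
    "n_grid": 200,
    "derivative_tol": None,
    "positivity_threshold": 0.0,
    "transform": "log2cpm1",
    "cycling_threshold": 2.0,
    "min_rise_points": 3,
    "min_plateau_points": 2,
    "multiplier": 12,
    "quant_method": "sum",
    "genes": ["H2-K1", "H2-D1", "Mki67", "Gapdh"],
    "cutoff_gene": "Tbr2",
    "positivity_gene": "H2-K1",
    "bootstrap": 0,
}


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class AnalysisConfig:
    stages: tuple
    inputs: dict = field(default_factory=dict)
    params: dict = field(default_factory=dict)
    seed: int = 0
    outdir: str = "stemcycle_out"
    verbose: bool = False

    def __post_init__(self):
        unknown = set(self.stages) - set(_STAGE_ORDER)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        self.stages = tuple(s for s in _STAGE_ORDER if s in self.stages)
        bad = set(self.params) - set(_DEFAULT_PARAMS)
        if bad:
            raise ValueError(f"unknown parameters: {sorted(bad)}")
        self.params = {**_DEFAULT_PARAMS, **self.params}

    @classmethod
    def from_file(cls, path) -> "AnalysisConfig":
        text = Path(path).read_text()
        doc = yaml.safe_load(text) if str(path).endswith((".yaml", ".yml")) \
            else json.loads(text)
        return cls(**doc)

    def resolved(self) -> dict:
        return {"stages": list(self.stages), "inputs": dict(self.inputs),
                "params": dict(self.params), "seed": self.seed,
                "outdir": str(self.outdir)}

    def hash(self) -> str:
        canon = json.dumps(self.resolved(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _require_input(config: AnalysisConfig, stage: str, key: str) -> Path:
    try:
        path = Path(config.inputs[key])
    except KeyError:
        raise PipelineError(f"[{stage}] missing required input {key!r}")
    if not path.exists():
        raise PipelineError(f"[{stage}] input file not found: {path}")
    return path


def _stamp(config: AnalysisConfig) -> dict:
    return {"seed": config.seed, "config_hash": config.hash()}


def _run_trajectory(config: AnalysisConfig, outdir: Path) -> dict:
    p = config.params
    expr = _require_input(config, "trajectory", "expression")
    pt = _require_input(config, "trajectory", "pseudotime")
    profile = io.read_profile(expr, pt)
    comment = f"seed={config.seed} config_hash={config.hash()}"

    cut_trend = trajectory.fit_trend(profile, p["cutoff_gene"], span=p["span"],
                                     n_grid=p["n_grid"])
    cut = trajectory.stage_cutoff(cut_trend, derivative_tol=p["derivative_tol"])

    report = {**_stamp(config), "cutoff_gene": p["cutoff_gene"],
              "cutoff": cut.cutoff, "genes": {}}
    for gene in [p["cutoff_gene"], *p["genes"]]:
        trend = cut_trend if gene == p["cutoff_gene"] else \
            trajectory.fit_trend(profile, gene, span=p["span"], n_grid=p["n_grid"])
        table = pd.DataFrame({"grid": trend.grid, "fit": trend.fitted,
                              "ci_low": trend.ci_low, "ci_high": trend.ci_high})
        out = outdir / f"trend_{gene}.tsv"
        with open(out, "w") as f:
            f.write(f"# {comment}\n")
            table.to_csv(f, sep="\t", index=False)
        if gene == p["cutoff_gene"]:
            continue
        counts = trajectory.count_positive_by_stage(
            profile, gene, cut, p["positivity_threshold"])
        assoc = trajectory.fisher_exact(counts.table)
        report["genes"][gene] = {
            "table": counts.table.tolist(),
            "odds_ratio": assoc.odds_ratio,
            "p_value": assoc.p_value,
        }
    io.write_report(report, outdir / "stage_report.json")
    return report


def _run_cellcycle(config: AnalysisConfig, outdir: Path) -> dict:
    p = config.params
    expr = _require_input(config, "cellcycle", "expression")
    pt = config.inputs.get("pseudotime")
    if pt is not None and not Path(pt).exists():
        raise PipelineError(f"[cellcycle] pseudotime file not found: {pt}")
    profile = io.read_profile(expr, pt)

    markers = None
    if "markers" in config.inputs:
        mpath = Path(config.inputs["markers"])
        if not mpath.exists():
            raise PipelineError(f"[cellcycle] marker file not found: {mpath}")
        markers = cellcycle.load_markers(json_path=mpath)

    scores = cellcycle.score_cell_cycle(profile, markers, p["transform"])
    calls = cellcycle.classify_cycling(scores, p["cycling_threshold"])
    table = cellcycle.tabulate_by_positivity(calls, profile, p["positivity_gene"],
                                             p["positivity_threshold"])
    assoc = cellcycle.fisher_exact(table)
    pct = cellcycle.percent_cycling(table)

    out = scores.as_dataframe()
    out["cycling"] = calls.cycling
    with open(outdir / "cycle_scores.tsv", "w") as f:
        f.write(f"# seed={config.seed} config_hash={config.hash()}\n")
        out.to_csv(f, sep="\t")
    report = {**_stamp(config), "gene": p["positivity_gene"],
              "table": table.tolist(), "percent_cycling": pct,
              "odds_ratio": assoc.odds_ratio, "p_value": assoc.p_value}
    io.write_report(report, outdir / "cycle_association.json")
    return report


def _run_kinetics(config: AnalysisConfig, outdir: Path) -> dict:
    p = config.params
    path = _require_input(config, "kinetics", "timecourse")
    tc = io.read_timecourse(path)
    fit = kinetics.fit_two_segment(tc, p["min_rise_points"], p["min_plateau_points"])
    k = kinetics.derive_kinetics(fit)
    report = {**_stamp(config),
              "slope": fit.slope, "intercept": fit.intercept,
              "plateau": fit.plateau, "breakpoint": fit.breakpoint,
              "t_star": fit.t_star, "sse": fit.sse, "r2_rise": fit.r2_rise,
              "GF": k.GF, "Tc": k.Tc, "Ts": k.Ts, "Li0": k.Li0}
    if p["bootstrap"]:
        boot = kinetics.bootstrap_kinetics(tc, n_boot=int(p["bootstrap"]),
                                           seed=config.seed)
        report["bootstrap"] = boot.to_dict(orient="index")
    io.write_report(report, outdir / "kinetics.json")
    return report


def _run_quant(config: AnalysisConfig, outdir: Path) -> dict:
    p = config.params
    path = _require_input(config, "quant", "section_counts")
    df = pd.read_csv(path, comment="#")
    if "count" not in df.columns:
        raise PipelineError(f"[quant] {path} must have a 'count' column")
    counts = df["count"].tolist()
    total = quant.estimate_total_count(counts, p["multiplier"], p["quant_method"])
    report = {**_stamp(config), "section_counts": counts,
              "multiplier": p["multiplier"], "method": p["quant_method"],
              "estimated_total": total}
    io.write_report(report, outdir / "quant.json")
    return report


_RUNNERS = {"trajectory": _run_trajectory, "cellcycle": _run_cellcycle,
            "kinetics": _run_kinetics, "quant": _run_quant}


def run_pipeline(config: AnalysisConfig) -> dict:
    """Execute the configured stages; returns the per-stage reports.

    A resolved-config snapshot (including the hash and seed) is
    written to the output directory.  Any stage error is re-raised as
    :class:`PipelineError` naming the stage.
    """
    np.random.seed(config.seed % (2**32))  # legacy global state, for safety
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    snapshot = {**config.resolved(), "config_hash": config.hash()}
    io.write_report(snapshot, outdir / "config_resolved.json")
    results = {}
    for stage in config.stages:
        try:
            results[stage] = _RUNNERS[stage](config, outdir)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"[{stage}] {exc}") from exc
    return results
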