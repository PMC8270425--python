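"""Readers and writers for the flat-file dialects of the pipeline.

Expression matrices travel either as a TSV (rows = genes, columns =
cells, first column ``gene_id``, values = CPM) or as a MatrixMarket
triplet (``matrix.mtx`` oriented genes x cells, with ``genes.tsv`` and
``cells.tsv`` sidecars).  Pseudotime is a two-column TSV
``cell_id<TAB>pseudotime`` joined to the matrix by id, never by
position.  Labeling timecourses are CSV with either
``time_h,labeled,total,replicate`` or ``time_h,li_percent,replicate``.

Readers reject malformed input (reporting line numbers) rather than
silently coercing it.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
from anndata import AnnData

from .profile import make_profile

__all__ = [
    "read_expression_tsv", "write_expression_tsv",
    "read_expression_mtx", "write_expression_mtx",
    "read_pseudotime", "write_pseudotime",
    "read_profile", "write_profile",
    "read_timecourse", "write_timecourse",
    "write_report",
]


def _numeric_frame(raw: pd.DataFrame, path, header_lines: int) -> pd.DataFrame:
    """Convert a string frame to floats, reporting bad cells by line."""
    converted = raw.apply(pd.to_numeric, errors="coerce")
    bad = converted.isna() & raw.notna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"{path}: malformed numeric field {raw.iat[i, j]!r} at line "
            f"{i + 1 + header_lines}, column {raw.columns[j]!r}")
    if converted.isna().to_numpy().any():
        i, j = np.argwhere(converted.isna().to_numpy())[0]
        raise ValueError(f"{path}: missing value at line {i + 1 + header_lines}, "
                         f"column {raw.columns[j]!r}")
    # pd.to_numeric's fast parser loses the last ulp; numpy's strtod
    # round-trips, which the write/read fidelity contract requires.
    exact = raw.to_numpy(dtype=str).astype(np.float64)
    return pd.DataFrame(exact, index=raw.index, columns=raw.columns)


def read_expression_tsv(path) -> pd.DataFrame:
    """Genes x cells CPM table from TSV; validates ids and values."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, comment="#")
    df.index.name = "gene_id"
    if df.index.duplicated().any():
        raise ValueError(f"{path}: duplicate gene id "
                         f"{df.index[df.index.duplicated()][0]!r}")
    if df.columns.duplicated().any():
        raise ValueError(f"{path}: duplicate cell id "
                         f"{df.columns[df.columns.duplicated()][0]!r}")
    values = _numeric_frame(df, path, header_lines=1)
    if (values.to_numpy() < 0).any():
        i, j = np.argwhere(values.to_numpy() < 0)[0]
        raise ValueError(f"{path}: negative CPM for gene {values.index[i]!r}, "
                         f"cell {values.columns[j]!r}")
    return values


def write_expression_tsv(profile: AnnData, path, comment: str = "") -> None:
    df = pd.DataFrame(np.asarray(profile.X).T, index=profile.var_names,
                      columns=profile.obs_names)
    df.index.name = "gene_id"
    with open(path, "w") as f:
        if comment:
            f.write(f"# {comment}\n")
        df.to_csv(f, sep="\t", float_format="%.17g")


def read_expression_mtx(directory) -> pd.DataFrame:
    """Genes x cells CPM from matrix.mtx + genes.tsv + cells.tsv."""
    d = Path(directory)
    mat = scipy.io.mmread(d / "matrix.mtx")
    genes = [l.strip() for l in (d / "genes.tsv").read_text().splitlines() if l.strip()]
    cells = [l.strip() for l in (d / "cells.tsv").read_text().splitlines() if l.strip()]
    arr = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat, dtype=float)
    if arr.shape != (len(genes), len(cells)):
        raise ValueError(f"{d}: matrix shape {arr.shape} does not match "
                         f"{len(genes)} genes x {len(cells)} cells")
    df = pd.DataFrame(arr, index=pd.Index(genes, name="gene_id"), columns=cells)
    if df.index.duplicated().any() or df.columns.duplicated().any():
        raise ValueError(f"{d}: duplicate gene or cell ids in sidecar files")
    if (arr < 0).any():
        i, j = np.argwhere(arr < 0)[0]
        raise ValueError(f"{d}: negative CPM for gene {genes[i]!r}, cell {cells[j]!r}")
    return df


def write_expression_mtx(profile: AnnData, directory) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(d / "matrix.mtx"),
                     scipy.sparse.coo_matrix(np.asarray(profile.X).T))
    (d / "genes.tsv").write_text("\n".join(profile.var_names) + "\n")
    (d / "cells.tsv").write_text("\n".join(profile.obs_names) + "\n")


def read_pseudotime(path) -> pd.Series:
    """Per-cell pseudotime from a ``cell_id<TAB>pseudotime`` TSV."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if list(df.columns[:2]) != ["cell_id", "pseudotime"]:
        raise ValueError(f"{path}: expected header 'cell_id\\tpseudotime', "
                         f"got {list(df.columns)!r}")
    if df["cell_id"].duplicated().any():
        dup = df["cell_id"][df["cell_id"].duplicated()].iloc[0]
        raise ValueError(f"{path}: duplicate cell id {dup!r}")
    values = _numeric_frame(df[["pseudotime"]], path, header_lines=1)
    series = pd.Series(values["pseudotime"].to_numpy(), index=df["cell_id"],
                       name="pseudotime")
    if not np.all(np.isfinite(series)):
        bad = series.index[~np.isfinite(series)][0]
        raise ValueError(f"{path}: non-finite pseudotime for cell {bad!r}")
    return series


def write_pseudotime(profile: AnnData, path, comment: str = "") -> None:
    with open(path, "w") as f:
        if comment:
            f.write(f"# {comment}\n")
        f.write("cell_id\tpseudotime\n")
        for cell, pt in zip(profile.obs_names, profile.obs["pseudotime"]):
            f.write(f"{cell}\t{pt!r}\n")


def read_profile(expression_path, pseudotime_path=None, fmt: str = "tsv") -> AnnData:
    """Load an expression profile, joining pseudotime by cell id.

    Without a pseudotime file the profile gets pseudotime 0 for every
    cell (enough for stages that ignore trajectory order, such as
    cell-cycle scoring).
    """
    if fmt == "tsv":
        expr = read_expression_tsv(expression_path)
    elif fmt == "mtx":
        expr = read_expression_mtx(expression_path)
    else:
        raise ValueError(f"unknown expression format {fmt!r}")
    cells = list(expr.columns)
    if pseudotime_path is not None:
        pt = read_pseudotime(pseudotime_path)
        missing = set(cells) - set(pt.index)
        if missing:
            raise ValueError(f"cells missing a pseudotime: {sorted(missing)[:5]!r}")
        pseudotime = pt.reindex(cells).to_numpy()
    else:
        pseudotime = np.zeros(len(cells))
    return make_profile(expr.to_numpy().T, cells, list(expr.index), pseudotime)


def write_profile(profile: AnnData, expression_path, pseudotime_path,
                  comment: str = "") -> None:
    write_expression_tsv(profile, expression_path, comment=comment)
    write_pseudotime(profile, pseudotime_path, comment=comment)


def read_timecourse(path) -> pd.DataFrame:
    """Cumulative-labeling timecourse CSV in either accepted dialect."""
    df = pd.read_csv(path, dtype=str, comment="#")
    cols = list(df.columns)
    if cols[:4] == ["time_h", "labeled", "total", "replicate"]:
        num = _numeric_frame(df[["time_h", "labeled", "total"]], path, 1)
        out = num.assign(replicate=df["replicate"].to_numpy())
        out["li_percent"] = 100.0 * out["labeled"] / out["total"]
    elif cols[:3] == ["time_h", "li_percent", "replicate"]:
        num = _numeric_frame(df[["time_h", "li_percent"]], path, 1)
        out = num.assign(replicate=df["replicate"].to_numpy())
    else:
        raise ValueError(
            f"{path}: expected columns time_h,labeled,total,replicate or "
            f"time_h,li_percent,replicate; got {cols!r}")
    if (out["time_h"] < 0).any():
        line = int(np.argwhere((out["time_h"] < 0).to_numpy())[0][0]) + 2
        raise ValueError(f"{path}: negative time at line {line}")
    if ((out["li_percent"] < 0) | (out["li_percent"] > 100)).any():
        bad = (out["li_percent"] < 0) | (out["li_percent"] > 100)
        line = int(np.argwhere(bad.to_numpy())[0][0]) + 2
        raise ValueError(f"{path}: labeling index outside [0, 100] at line {line}")
    return out


def write_timecourse(df: pd.DataFrame, path, comment: str = "") -> None:
    cols = [c for c in ["time_h", "labeled", "total", "replicate"] if c in df.columns]
    if cols != ["time_h", "labeled", "total", "replicate"]:
        cols = ["time_h", "li_percent", "replicate"]
    with open(path, "w") as f:
        if comment:
            f.write(f"# {comment}\n")
        df[cols].to_csv(f, index=False, float_format="%.17g")


def write_report(results: dict, path) -> None:
    """JSON report writer (handles numpy scalars/arrays)."""
    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.bool_,)):
            return bool(o)
        raise TypeError(f"not JSON-serializable: {type(o)}")
    Path(path).write_text(json.dumps(results, indent=2, default=default,
                                     allow_nan=True) + "\n")
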