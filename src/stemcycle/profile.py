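"""Expression-profile container helpers.

A profile is an :class:`anndata.AnnData` with cells as observations,
genes as variables, counts-per-million (CPM) in ``X``, and a per-cell
pseudotime estimate in ``obs["pseudotime"]``.  Pseudotime is taken as
given (an upstream trajectory assignment), never inferred here.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from anndata import AnnData

__all__ = ["make_profile", "validate_profile", "gene_cpm"]


def make_profile(cpm, cell_ids, gene_ids, pseudotime) -> AnnData:
    """Assemble a validated cells x genes CPM profile.

    Parameters
    ----------
    cpm : array-like, shape (n_cells, n_genes)
        Nonnegative counts-per-million values.
    cell_ids, gene_ids : sequences of str
        Unique identifiers.
    pseudotime : array-like, shape (n_cells,)
        Finite per-cell pseudotime (arbitrary units).
    """
    X = np.asarray(cpm, dtype=float)
    obs = pd.DataFrame({"pseudotime": np.asarray(pseudotime, dtype=float)},
                       index=pd.Index([str(c) for c in cell_ids], name="cell_id"))
    var = pd.DataFrame(index=pd.Index([str(g) for g in gene_ids], name="gene_id"))
    adata = AnnData(X=X, obs=obs, var=var)
    validate_profile(adata)
    return adata


def validate_profile(adata: AnnData) -> None:
    """Enforce profile invariants; raise ValueError naming the offender."""
    if adata.obs_names.duplicated().any():
        dup = adata.obs_names[adata.obs_names.duplicated()][0]
        raise ValueError(f"duplicate cell id: {dup!r}")
    if adata.var_names.duplicated().any():
        dup = adata.var_names[adata.var_names.duplicated()][0]
        raise ValueError(f"duplicate gene id: {dup!r}")
    if "pseudotime" not in adata.obs:
        raise ValueError("profile is missing obs['pseudotime']")
    pt = np.asarray(adata.obs["pseudotime"], dtype=float)
    if not np.all(np.isfinite(pt)):
        bad = adata.obs_names[~np.isfinite(pt)][0]
        raise ValueError(f"non-finite pseudotime for cell {bad!r}")
    X = np.asarray(adata.X, dtype=float)
    if not np.all(np.isfinite(X)):
        i, j = np.argwhere(~np.isfinite(X))[0]
        raise ValueError(
            f"non-finite CPM at cell {adata.obs_names[i]!r}, gene {adata.var_names[j]!r}")
    if np.any(X < 0):
        i, j = np.argwhere(X < 0)[0]
        raise ValueError(
            f"negative CPM at cell {adata.obs_names[i]!r}, gene {adata.var_names[j]!r}")


def gene_cpm(adata: AnnData, gene: str) -> np.ndarray:
    """Per-cell CPM vector for one gene; KeyError on unknown id."""
    if gene not in adata.var_names:
        raise KeyError(f"unknown gene id: {gene!r}")
    col = adata[:, gene].X
    return np.asarray(col, dtype=float).ravel()
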