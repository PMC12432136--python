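"""Regional cell-type abundance maps from marker-gene expression.

Starts from a gene x region expression matrix (upstream donor-level
processing is out of scope).  Genes are normalized across regions with a
scaled robust sigmoid, then each cell type's map is the unweighted mean of
its marker genes' normalized region vectors.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .regions import hemisphere_pairs

log = logging.getLogger(__name__)

__all__ = ["normalize_genes", "aggregate_marker_sets", "collapse_hemispheres"]

#: normal-consistent IQR -> SD conversion used by the robust sigmoid
IQR_TO_SD = 1.35


def normalize_genes(expr: pd.DataFrame, min_values: int = 3) -> pd.DataFrame:
    """Scaled robust sigmoid per gene, then min-max rescale to [0, 1].

    For gene g with median m and interquartile range IQR across regions:
    ``s = 1 / (1 + exp(-(x - m) / (IQR / 1.35)))`` followed by per-gene
    min-max rescaling.  Genes with IQR = 0 (or fewer than ``min_values``
    observed values) are dropped with a warning.
    """
    X = expr.to_numpy(dtype=float)
    n_obs = np.sum(np.isfinite(X), axis=1)
    med = np.nanmedian(X, axis=1, keepdims=True)
    q75, q25 = np.nanpercentile(X, [75, 25], axis=1)
    iqr = (q75 - q25)[:, None]
    keep = (iqr[:, 0] > 0) & (n_obs >= min_values)
    dropped = expr.index[~keep]
    if len(dropped):
        log.warning("dropping %d genes with zero IQR or too few values: %s",
                    len(dropped), list(dropped[:5]))
    X, med, iqr = X[keep], med[keep], iqr[keep]
    with np.errstate(over="ignore"):
        s = 1.0 / (1.0 + np.exp(-(X - med) / (iqr / IQR_TO_SD)))
    lo = np.nanmin(s, axis=1, keepdims=True)
    hi = np.nanmax(s, axis=1, keepdims=True)
    s = (s - lo) / (hi - lo)
    return pd.DataFrame(s, index=expr.index[keep], columns=expr.columns)


def aggregate_marker_sets(expr_norm: pd.DataFrame, marker_sets: dict) -> pd.DataFrame:
    """Cell types x regions: unweighted mean over each set's marker genes.

    Marker genes absent from the (normalized) matrix are reported and
    dropped; an empty intersection raises, naming the cell type.
    """
    rows = {}
    for cell_type, genes in marker_sets.items():
        present = [g for g in genes if g in expr_norm.index]
        missing = sorted(set(genes) - set(present))
        if missing:
            log.warning("cell type %s: %d marker genes absent (%s...)",
                        cell_type, len(missing), missing[:3])
        if not present:
            raise ValueError(f"no marker genes of cell type {cell_type!r} present in matrix")
        rows[cell_type] = expr_norm.loc[present].mean(axis=0)
    maps = pd.DataFrame(rows).T
    maps.index.name = "cell_type"
    return maps


def collapse_hemispheres(expr: pd.DataFrame) -> pd.DataFrame:
    """Average homologous left/right columns into bilateral regions.

    Columns must be resolvable hemisphere names (``lh_*``/``rh_*`` style).
    If only one hemisphere of a pair is present it is used as-is (flagged);
    names with neither hemisphere resolvable are dropped.
    """
    resolvable = []
    for c in expr.columns:
        try:
            hemisphere_pairs([c])
            resolvable.append(c)
        except ValueError:
            log.warning("dropping unpaired column %r", c)
    pairs = hemisphere_pairs(resolvable)
    out = {}
    for base, (left, right) in pairs.items():
        if left is not None and right is not None:
            out[base] = (expr[left] + expr[right]) / 2.0
        else:
            only = left or right
            log.warning("region %r present in one hemisphere only (%r)", base, only)
            out[base] = expr[only]
    return pd.DataFrame(out)
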