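"""Cell-level quality control and normalization.

QC keeps cells passing all of: detected-gene count, UMI count bounds, library
complexity (log10 genes / log10 UMIs), and mitochondrial / ribosomal UMI
fraction caps. Normalization is library-size scaling to a fixed target followed
by log1p — the standard contract when no further parameters are given.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import ConsistencyError, CountMatrix, ExpressionMatrix

DEFAULT_MITO_PREFIXES: Tuple[str, ...] = ("MT-",)
DEFAULT_RIBO_PREFIXES: Tuple[str, ...] = ("RPL", "RPS")


@dataclass
class QCThresholds:
    min_genes: int = 200
    min_umis: int = 500
    max_umis: int = 100_000
    min_complexity: float = 0.8
    max_mito_fraction: float = 0.2
    max_ribo_fraction: float = 0.6

    def validate(self) -> None:
        if not self.min_umis < self.max_umis:
            raise ValueError("min_umis must be < max_umis")
        if not (0.0 < self.min_complexity <= 1.0):
            raise ValueError("min_complexity must lie in (0, 1]")
        for f in (self.max_mito_fraction, self.max_ribo_fraction):
            if not (0.0 <= f <= 1.0):
                raise ValueError("fractions must lie in [0, 1]")


def _prefix_mask(gene_ids, prefixes: Sequence[str]) -> np.ndarray:
    ids = pd.Index(gene_ids).astype(str)
    mask = np.zeros(len(ids), dtype=bool)
    for p in prefixes:
        mask |= np.asarray(ids.str.startswith(p))
    return mask


def qc_metrics(
    counts: CountMatrix,
    mito_prefixes: Sequence[str] = DEFAULT_MITO_PREFIXES,
    ribo_prefixes: Sequence[str] = DEFAULT_RIBO_PREFIXES,
) -> pd.DataFrame:
    """Per-cell QC metrics: genes detected, UMIs, complexity, mito/ribo fraction.

    Complexity is log10(genes detected) / log10(total UMIs); cells with <= 1
    UMI get complexity 0 by rule (log of 1 is 0), so they fail any positive
    complexity threshold without a division error.
    """
    X = counts.values.tocsr()
    umis = np.asarray(X.sum(axis=1)).ravel()
    genes = X.getnnz(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        complexity = np.where(
            umis > 1, np.log10(np.maximum(genes, 1)) / np.log10(np.maximum(umis, 2)), 0.0
        )
    mito = _prefix_mask(counts.gene_ids, mito_prefixes)
    ribo = _prefix_mask(counts.gene_ids, ribo_prefixes)
    denom = np.maximum(umis, 1)
    mito_frac = np.asarray(X[:, mito].sum(axis=1)).ravel() / denom
    ribo_frac = np.asarray(X[:, ribo].sum(axis=1)).ravel() / denom
    return pd.DataFrame(
        {
            "cell_id": counts.cell_ids,
            "n_genes": genes,
            "n_umis": umis.astype(np.int64),
            "complexity": complexity,
            "mito_fraction": mito_frac,
            "ribo_fraction": ribo_frac,
        }
    )


def qc_filter(
    counts: CountMatrix,
    meta: pd.DataFrame,
    thresholds: QCThresholds | None = None,
    mito_prefixes: Sequence[str] = DEFAULT_MITO_PREFIXES,
    ribo_prefixes: Sequence[str] = DEFAULT_RIBO_PREFIXES,
):
    """Filter cells; returns (filtered counts, filtered meta, report DataFrame).

    The report lists, per criterion, how many cells failed it (criteria are not
    mutually exclusive) plus totals. Idempotent: re-filtering the output
    removes nothing.
    """
    thresholds = thresholds or QCThresholds()
    thresholds.validate()
    if not counts.cell_ids.equals(pd.Index(meta["cell_id"])):
        raise ConsistencyError("counts and metadata cell ids differ or are reordered")

    m = qc_metrics(counts, mito_prefixes, ribo_prefixes)
    fails = {
        "min_genes": m["n_genes"] < thresholds.min_genes,
        "min_umis": m["n_umis"] < thresholds.min_umis,
        "max_umis": m["n_umis"] > thresholds.max_umis,
        "min_complexity": m["complexity"] < thresholds.min_complexity,
        "max_mito_fraction": m["mito_fraction"] > thresholds.max_mito_fraction,
        "max_ribo_fraction": m["ribo_fraction"] > thresholds.max_ribo_fraction,
    }
    keep = ~np.logical_or.reduce(list(fails.values()))
    report = pd.DataFrame(
        {
            "criterion": list(fails) + ["total_removed", "total_kept"],
            "n_cells": [int(v.sum()) for v in fails.values()]
            + [int((~keep).sum()), int(keep.sum())],
        }
    )
    filtered = counts.subset_cells(keep)
    meta_f = meta.loc[keep].reset_index(drop=True)
    return filtered, meta_f, report


def normalize_log(counts: CountMatrix, scale: float = 10_000.0) -> ExpressionMatrix:
    """log1p(count / cell_total * scale); preserves the sparsity pattern."""
    X = counts.values.tocsr().astype(np.float64)
    totals = np.asarray(X.sum(axis=1)).ravel()
    if (totals == 0).any():
        raise ValueError(
            "cells with zero total counts present; run qc_filter before normalizing"
        )
    inv = sp.diags(scale / totals)
    Xn = inv @ X
    Xn.data = np.log1p(Xn.data)
    return ExpressionMatrix(values=Xn.tocsr(), cell_ids=counts.cell_ids, gene_ids=counts.gene_ids)
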