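"""Expression-dosage evidence channel.

A simplified copy-number scoring scheme in the spirit of expression-based CNA
callers: normalized expression is averaged into fixed genomic bins, baselined
against a healthy reference, smoothed along each chromosome with a moving
average, restricted to the target-region bins, clustered per sample with
k-means (k=80 by default), and the cluster centroids are split by a 1-D
two-means into a putative deleted group and a neutral group. The lower group's
cells are called deleted only if its mean region score falls below a negative
cutoff. Because k-means concentrates the lowest-scoring cells even in pure
noise, the cutoff must sit between the noise regime of lower-group means
(>= -0.15 on the log1p scale at typical depth) and the hemizygous-dosage
regime (~ -0.40); the default -0.25 splits the two.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.ndimage
import scipy.sparse as sp
from sklearn.cluster import KMeans

from .genome import GenomeAnnotation
from .io import ExpressionMatrix

CALL_DELETED = "deleted"
CALL_NEUTRAL = "neutral"

DEFAULT_BIN_SIZE = 220_000  # bp
DEFAULT_K = 80
DEFAULT_CUTOFF = -0.25  # on the log1p expression scale
DEFAULT_SMOOTH_HALFWIDTH = 2  # bins


@dataclass
class BinMatrix:
    """Per-cell per-bin dosage scores plus the bin table."""

    scores: np.ndarray  # cells x bins
    bins: pd.DataFrame  # chromosome, start_bp, end_bp, bin_id
    bin_size: int
    cell_ids: pd.Index

    def region_bin_mask(self, genome: GenomeAnnotation) -> np.ndarray:
        r = genome.target_region
        b = self.bins
        return (
            (b["chromosome"] == r.chromosome)
            & (b["end_bp"] > r.start_bp)
            & (b["start_bp"] < r.end_bp)
        ).to_numpy()


@dataclass
class ExpressionChannelResult:
    calls: pd.DataFrame  # cell_id, sample_id, cluster_id, mean_region_score, expression_call
    cluster_table: pd.DataFrame  # cluster_id, sample_id, mean_region_score, call
    cutoff: float
    degenerate: bool = False
    warnings: list = field(default_factory=list)


def assign_bins(genome: GenomeAnnotation, bin_size: int = DEFAULT_BIN_SIZE):
    """Map every gene to the half-open ``bin_size`` tile containing its start.

    Returns ``(gene_bin: int array aligned to genome.genes, bins: DataFrame)``.
    Bins tile each chromosome from 0 up to the last gene; only chromosome tiles
    are materialized (bin boundaries are floor(start / bin_size)).
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be > 0")
    genes = genome.genes
    bin_idx_within = (genes["start_bp"] // bin_size).to_numpy()
    bins_rows = []
    gene_bin = np.full(len(genes), -1, dtype=np.int64)
    offset = 0
    for chrom, sub in genes.groupby("chromosome", sort=True):
        n_bins = int(sub["start_bp"].max() // bin_size) + 1
        start = np.arange(n_bins, dtype=np.int64) * bin_size
        bins_rows.append(
            pd.DataFrame(
                {"chromosome": chrom, "start_bp": start, "end_bp": start + bin_size}
            )
        )
        gene_bin[sub.index.to_numpy()] = offset + bin_idx_within[sub.index.to_numpy()]
        offset += n_bins
    bins = pd.concat(bins_rows, ignore_index=True)
    bins["bin_id"] = np.arange(len(bins))
    return gene_bin, bins


def _shrinking_moving_average(x: np.ndarray, halfwidth: int) -> np.ndarray:
    """Centered moving average along the last axis; window shrinks at the ends."""
    if halfwidth == 0:
        return x
    w = 2 * halfwidth + 1
    kernel = np.ones(w)
    num = scipy.ndimage.convolve1d(x, kernel, axis=-1, mode="constant", cval=0.0)
    n = x.shape[-1]
    idx = np.arange(n)
    den = np.minimum(idx + halfwidth, n - 1) - np.maximum(idx - halfwidth, 0) + 1
    return num / den


def bin_scores(
    norm_expr: ExpressionMatrix,
    reference_cells: Sequence[str],
    genome: GenomeAnnotation,
    bin_size: int = DEFAULT_BIN_SIZE,
    smoothing_halfwidth: int = DEFAULT_SMOOTH_HALFWIDTH,
    cells: Optional[Sequence[str]] = None,
) -> BinMatrix:
    """Reference-baselined, imputed and smoothed per-cell bin scores.

    Raw bin value = mean normalized expression of the bin's detected genes in
    that cell minus the reference-cell mean for the same bin; bins with no
    detected genes are imputed from the nearest non-empty bin on the same
    chromosome before a centered moving-average smoothing along each
    chromosome.
    """
    reference_cells = pd.Index(reference_cells)
    if len(reference_cells) == 0:
        raise ValueError("reference cell set is empty")
    gene_bin, bins = assign_bins(genome, bin_size)

    X = norm_expr.values.tocsc()
    detected = np.asarray((X != 0).sum(axis=0)).ravel() > 0
    n_bins = len(bins)
    # gene -> bin averaging operator over detected genes
    cols = np.flatnonzero(detected)
    if cols.size == 0:
        raise ValueError("no detected genes")
    counts_per_bin = np.bincount(gene_bin[cols], minlength=n_bins)
    weights = 1.0 / np.maximum(counts_per_bin[gene_bin[cols]], 1)
    agg = sp.csr_matrix(
        (weights, (cols, gene_bin[cols])), shape=(X.shape[1], n_bins)
    )

    ref_idx = norm_expr.cell_ids.get_indexer(reference_cells)
    if (ref_idx < 0).any():
        raise ValueError("reference cells missing from the expression matrix")
    if cells is None:
        cell_idx = np.arange(norm_expr.values.shape[0])
        cell_ids = norm_expr.cell_ids
    else:
        cell_ids = pd.Index(cells)
        cell_idx = norm_expr.cell_ids.get_indexer(cell_ids)
        if (cell_idx < 0).any():
            raise ValueError("scored cells missing from the expression matrix")

    cellbin = np.asarray((norm_expr.values[cell_idx] @ agg).todense())
    refbin = np.asarray((norm_expr.values[ref_idx] @ agg).todense()).mean(axis=0)
    raw = cellbin - refbin[None, :]

    nonempty = counts_per_bin > 0
    out = np.empty_like(raw)
    for chrom, sub in bins.groupby("chromosome", sort=True):
        cols_b = sub["bin_id"].to_numpy()
        ne = nonempty[cols_b]
        if not ne.any():
            warnings.warn(f"chromosome {chrom} has no detected genes; bins excluded")
            out[:, cols_b] = 0.0
            continue
        block = raw[:, cols_b]
        # impute empty bins from the nearest non-empty neighbor
        if not ne.all():
            pos = np.flatnonzero(ne)
            nearest = pos[
                np.abs(pos[None, :] - np.arange(len(cols_b))[:, None]).argmin(axis=1)
            ]
            block = block[:, nearest]
            block[:, pos] = raw[:, cols_b[pos]]
        out[:, cols_b] = _shrinking_moving_average(block, smoothing_halfwidth)
    return BinMatrix(scores=out, bins=bins, bin_size=bin_size, cell_ids=cell_ids)


def cluster_cells(
    bin_matrix: BinMatrix,
    region_mask: np.ndarray,
    k: int = DEFAULT_K,
    seed: int = 0,
    n_init: int = 10,
):
    """K-means over the region-restricted bin scores.

    Returns ``(labels, centroid_region_means, degenerate)``. ``k`` is clamped
    (with a warning) when it exceeds the number of cells; an all-identical
    input collapses to a single effective cluster and is flagged degenerate.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    data = bin_matrix.scores[:, region_mask]
    n_cells = data.shape[0]
    if n_cells == 0:
        raise ValueError("no cells to cluster")
    if k > n_cells:
        warnings.warn(f"k={k} exceeds n_cells={n_cells}; clamping")
        k = n_cells
    degenerate = bool(np.allclose(data, data[0]))
    if degenerate:
        labels = np.zeros(n_cells, dtype=int)
        centroids = np.array([data.mean()])
        return labels, centroids, True
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(data)
    centroids = km.cluster_centers_.mean(axis=1)  # mean region score per cluster
    return labels, centroids, False


def _two_means_1d(values: np.ndarray):
    """Exact 1-D 2-means: scan the sorted split minimizing within-group SS.

    Returns a boolean mask marking the lower group.
    """
    order = np.argsort(values)
    v = values[order]
    n = len(v)
    csum = np.cumsum(v)
    total = csum[-1]
    best_i, best_ss = 1, np.inf
    for i in range(1, n):
        m1, m2 = csum[i - 1] / i, (total - csum[i - 1]) / (n - i)
        ss = -(i * m1 * m1 + (n - i) * m2 * m2)  # minimizing SS == maximizing this
        if ss < best_ss:
            best_ss, best_i = ss, i
    lower = np.zeros(n, dtype=bool)
    lower[order[:best_i]] = True
    return lower


def call_deletion_clusters(
    labels: np.ndarray,
    centroid_means: np.ndarray,
    cell_ids: pd.Index,
    cutoff: float = DEFAULT_CUTOFF,
    sample_id: str = "",
) -> ExpressionChannelResult:
    """Split centroids into two groups; call the lower group deleted iff its
    mean region score is below ``cutoff`` (ties break toward neutral)."""
    centroid_means = np.asarray(centroid_means, dtype=float)
    if len(centroid_means) == 1:
        deleted_clusters = centroid_means < cutoff
    else:
        lower = _two_means_1d(centroid_means)
        group_mean = centroid_means[lower].mean()
        deleted_clusters = lower if group_mean < cutoff else np.zeros_like(lower)
    cell_call = np.where(deleted_clusters[labels], CALL_DELETED, CALL_NEUTRAL)
    calls = pd.DataFrame(
        {
            "cell_id": cell_ids,
            "sample_id": sample_id,
            "cluster_id": [f"{sample_id}:{l}" for l in labels],
            "mean_region_score": centroid_means[labels],
            "expression_call": cell_call,
        }
    )
    cluster_table = pd.DataFrame(
        {
            "cluster_id": [f"{sample_id}:{i}" for i in range(len(centroid_means))],
            "sample_id": sample_id,
            "mean_region_score": centroid_means,
            "call": np.where(deleted_clusters, CALL_DELETED, CALL_NEUTRAL),
        }
    )
    return ExpressionChannelResult(
        calls=calls, cluster_table=cluster_table, cutoff=cutoff
    )


def expression_channel(
    norm_expr: ExpressionMatrix,
    meta: pd.DataFrame,
    genome: GenomeAnnotation,
    reference_condition: str = "healthy",
    bin_size: int = DEFAULT_BIN_SIZE,
    smoothing_halfwidth: int = DEFAULT_SMOOTH_HALFWIDTH,
    k: int = DEFAULT_K,
    cutoff: float = DEFAULT_CUTOFF,
    seed: int = 0,
    genome_wide: bool = False,
) -> ExpressionChannelResult:
    """Run the full channel per sample against the pooled reference cells."""
    ref_cells = meta.loc[meta["condition"] == reference_condition, "cell_id"]
    if len(ref_cells) == 0:
        raise ValueError(f"no cells with condition {reference_condition!r} for reference")
    samples = meta.loc[meta["condition"] != reference_condition, "sample_id"].unique()
    all_calls, all_clusters, degenerate = [], [], False
    for i, sample in enumerate(sorted(samples)):
        cells = meta.loc[meta["sample_id"] == sample, "cell_id"]
        bm = bin_scores(
            norm_expr, ref_cells, genome, bin_size, smoothing_halfwidth, cells=cells
        )
        mask = (
            np.ones(len(bm.bins), dtype=bool) if genome_wide else bm.region_bin_mask(genome)
        )
        region_scores = bm.scores[:, bm.region_bin_mask(genome)].mean(axis=1)
        labels, centroids, degen = cluster_cells(bm, mask, k=k, seed=seed + i)
        degenerate |= degen
        # cluster mean over the *region* bins regardless of clustering space
        n_clusters = int(labels.max()) + 1
        centroid_region = np.array(
            [region_scores[labels == c].mean() for c in range(n_clusters)]
        )
        res = call_deletion_clusters(
            labels, centroid_region, bm.cell_ids, cutoff=cutoff, sample_id=sample
        )
        all_calls.append(res.calls)
        all_clusters.append(res.cluster_table)
    return ExpressionChannelResult(
        calls=pd.concat(all_calls, ignore_index=True),
        cluster_table=pd.concat(all_clusters, ignore_index=True),
        cutoff=cutoff,
        degenerate=degenerate,
    )
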