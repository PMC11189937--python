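"""Validation of the consensus genotype calls.

Three checks mirror how one validates a mosaic-deletion classification without
orthogonal ground truth on real data:

1. *Marker dosage*: the six detectable commonly-deleted-region genes must show
   lower pseudobulk expression in del5q cells, sample by sample.
2. *Region enrichment*: genes ranked lower in del5q cells should be enriched
   for target-region genes (one-sided hypergeometric over the downregulated
   set from per-gene rank-sum tests).
3. *Shuffle control*: permuting the genotype labels must destroy that
   enrichment — the permuted enrichment p-values behave like a null sample,
   and their median exceeds the true-label p.

Plus the karyotype-style concordance: |estimated - expected| clone fraction
per sample.

The downregulated set defaults to the raw p < alpha rule: under label
exchange that statistic is approximately uniform, which is what makes the
shuffle control interpretable as a calibration check. A BH-adjusted rule
(``adjust="bh"``) is available for conservative reporting but is degenerate
under permutation (the null set is almost always empty, pinning the
enrichment p at 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .config import CDR_MARKER_GENES
from .consensus import GENOTYPE_DEL, GENOTYPE_NON_DEL
from .de import bh_adjust
from .genome import GenomeAnnotation
from .io import ExpressionMatrix
from .ranktest import RankSumTester


def marker_gene_check(
    norm_expr: ExpressionMatrix,
    calls: pd.DataFrame,
    markers: Sequence[str] = CDR_MARKER_GENES,
    sample_col: str = "sample_id",
) -> pd.DataFrame:
    """Per-sample pseudobulk marker means by genotype and their difference.

    Returns one row per (sample, marker) with columns ``mean_del``,
    ``mean_non_del`` and ``difference`` (del minus non-del; negative =
    dosage-consistent). Samples lacking either genotype class are reported
    with ``skipped=True``; absent markers are listed with ``missing=True``.
    """
    gene_idx = norm_expr.gene_ids.get_indexer(pd.Index(markers))
    rows = []
    cell_pos = norm_expr.cell_ids.get_indexer(calls["cell_id"])
    if (cell_pos < 0).any():
        raise ValueError("calls reference cells missing from the expression matrix")
    for sample, sub in calls.groupby(sample_col, sort=True):
        pos = norm_expr.cell_ids.get_indexer(sub["cell_id"])
        del_pos = pos[(sub["genotype"] == GENOTYPE_DEL).to_numpy()]
        non_pos = pos[(sub["genotype"] == GENOTYPE_NON_DEL).to_numpy()]
        skipped = len(del_pos) == 0 or len(non_pos) == 0
        for marker, gi in zip(markers, gene_idx):
            if gi < 0:
                rows.append(
                    dict(sample_id=sample, gene_id=marker, missing=True,
                         skipped=skipped, mean_del=np.nan, mean_non_del=np.nan,
                         difference=np.nan)
                )
                continue
            if skipped:
                rows.append(
                    dict(sample_id=sample, gene_id=marker, missing=False,
                         skipped=True, mean_del=np.nan, mean_non_del=np.nan,
                         difference=np.nan)
                )
                continue
            m_del = norm_expr.values[del_pos, gi].mean()
            m_non = norm_expr.values[non_pos, gi].mean()
            rows.append(
                dict(sample_id=sample, gene_id=marker, missing=False, skipped=False,
                     mean_del=m_del, mean_non_del=m_non, difference=m_del - m_non)
            )
    return pd.DataFrame(rows)


@dataclass
class EnrichmentOutcome:
    gene_table: pd.DataFrame  # gene_id, p, fdr, lower_in_del, downregulated
    enrichment_p: float
    n_downregulated: int
    n_region_in_down: int
    n_tested: int
    n_region_tested: int
    empty_down_set: bool = False
    notes: list = field(default_factory=list)


def _enrichment_from_downset(
    down: np.ndarray, region: np.ndarray
) -> tuple[float, int, int, bool]:
    n_tested = len(down)
    K = int(region.sum())
    n_down = int(down.sum())
    k = int((down & region).sum())
    if n_down == 0:
        return 1.0, 0, 0, True
    p = float(scipy.stats.hypergeom.sf(k - 1, n_tested, K, n_down))
    return p, n_down, k, False


class _RegionTestContext:
    """Shared dense data + rank precomputation for true and shuffled labels."""

    def __init__(
        self,
        norm_expr: ExpressionMatrix,
        calls: pd.DataFrame,
        genome: GenomeAnnotation,
        min_cells: int = 20,
    ):
        classified = calls[calls["genotype"].isin([GENOTYPE_DEL, GENOTYPE_NON_DEL])]
        n_del = int((classified["genotype"] == GENOTYPE_DEL).sum())
        n_non = len(classified) - n_del
        if min(n_del, n_non) < min_cells:
            raise ValueError(
                f"need >= {min_cells} cells per genotype class "
                f"(have {n_del} del5q, {n_non} non_del5q)"
            )
        pos = norm_expr.cell_ids.get_indexer(classified["cell_id"])
        if (pos < 0).any():
            raise ValueError("calls reference cells missing from the expression matrix")
        dense = np.asarray(norm_expr.values[pos].todense())
        tested = dense.max(axis=0) > 0
        region_mask = genome.region_gene_mask()
        if not region_mask.any():
            raise ValueError("no target-region genes annotated; enrichment undefined")
        self.gene_ids = norm_expr.gene_ids[tested]
        self.region = region_mask[tested]
        self.tester = RankSumTester(dense[:, tested])
        self.del_mask = (classified["genotype"] == GENOTYPE_DEL).to_numpy()
        self.n_cells = len(classified)

    def enrichment(self, del_mask: np.ndarray, alpha: float, adjust: str):
        p, diff = self.tester.pvalues(del_mask)
        lower_in_del = diff < 0
        if adjust == "bh":
            crit = bh_adjust(p)
        elif adjust == "raw":
            crit = p
        else:
            raise ValueError("adjust must be 'raw' or 'bh'")
        down = (crit < alpha) & lower_in_del
        ep, n_down, k, empty = _enrichment_from_downset(down, self.region)
        return p, lower_in_del, down, ep, n_down, k, empty


def region_enrichment_test(
    norm_expr: ExpressionMatrix,
    calls: pd.DataFrame,
    genome: GenomeAnnotation,
    alpha: float = 0.05,
    adjust: str = "raw",
    min_cells: int = 20,
) -> EnrichmentOutcome:
    """Rank-sum DE between genotype classes + hypergeometric region enrichment.

    Per gene, a two-sided Mann-Whitney test of normalized expression, del5q vs
    non_del5q; the "downregulated set" is genes lower in del5q passing the
    significance rule (raw or BH-adjusted p < alpha, see module docstring);
    enrichment p is the one-sided hypergeometric over-representation of
    target-region genes in that set relative to all tested genes.
    """
    ctx = _RegionTestContext(norm_expr, calls, genome, min_cells=min_cells)
    p, lower, down, ep, n_down, k, empty = ctx.enrichment(ctx.del_mask, alpha, adjust)
    table = pd.DataFrame(
        {
            "gene_id": ctx.gene_ids,
            "p": p,
            "fdr": bh_adjust(p),
            "lower_in_del": lower,
            "in_region": ctx.region,
            "downregulated": down,
        }
    )
    out = EnrichmentOutcome(
        gene_table=table,
        enrichment_p=ep,
        n_downregulated=n_down,
        n_region_in_down=k,
        n_tested=len(ctx.gene_ids),
        n_region_tested=int(ctx.region.sum()),
        empty_down_set=empty,
    )
    if empty:
        out.notes.append("downregulated set empty; enrichment p = 1 by convention")
    return out


@dataclass
class ShuffleControl:
    p_values: np.ndarray
    median_p: float
    fraction_below_alpha: float
    true_p: float
    n_perms: int
    degenerate: bool = False


def shuffled_control(
    norm_expr: ExpressionMatrix,
    calls: pd.DataFrame,
    genome: GenomeAnnotation,
    n_perms: int = 100,
    seed: int = 0,
    alpha: float = 0.05,
    adjust: str = "raw",
    min_cells: int = 20,
) -> ShuffleControl:
    """Permute genotype labels among classified cells; recompute enrichment p.

    The true-label enrichment should be extreme while the permuted p-values
    behave like a null sample (the "fade-away" control).
    """
    if n_perms < 1:
        raise ValueError("n_perms must be >= 1")
    ctx = _RegionTestContext(norm_expr, calls, genome, min_cells=min_cells)
    true_p = ctx.enrichment(ctx.del_mask, alpha, adjust)[3]
    degenerate = ctx.del_mask.all() or not ctx.del_mask.any()
    rng = np.random.default_rng(seed)
    ps = np.empty(n_perms)
    for i in range(n_perms):
        perm = rng.permutation(ctx.del_mask)
        ps[i] = ctx.enrichment(perm, alpha, adjust)[3]
    return ShuffleControl(
        p_values=ps,
        median_p=float(np.median(ps)),
        fraction_below_alpha=float((ps < alpha).mean()),
        true_p=float(true_p),
        n_perms=n_perms,
        degenerate=degenerate,
    )


def concordance(
    fractions: pd.DataFrame,
    expected: dict,
    column: str = "fraction_classified",
) -> pd.DataFrame:
    """Per-sample |estimated - expected| clone-fraction gaps.

    Samples without an expected value are omitted with a note column.
    """
    rows = []
    for _, row in fractions.iterrows():
        sid = row["sample_id"]
        if sid not in expected:
            rows.append(dict(sample_id=sid, estimated=row[column], expected=np.nan,
                             gap=np.nan, note="no expected value; omitted"))
            continue
        exp = float(expected[sid])
        if not (0.0 <= exp <= 1.0):
            raise ValueError(f"expected fraction for {sid} outside [0, 1]")
        rows.append(dict(sample_id=sid, estimated=row[column], expected=exp,
                         gap=abs(row[column] - exp), note=""))
    return pd.DataFrame(rows)
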