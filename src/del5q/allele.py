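"""Allelic-imbalance evidence channel.

Per heterozygous SNP with coverage, the B-allele frequency BAF = alt/(ref+alt)
deviates from 0.5 under hemizygous loss. The channel computes per-cell
deviation profiles along a chromosome arm, checks their consistency across
several median-filter smoothing scales (an event must survive >= 75% of the
scales by default), and binarizes each arm to amplified / neutral / deleted
using the sign of the cell's arm-level expression shift — BAF alone cannot
distinguish a deletion from an amplification. Cells covering fewer than
``min_snps`` arm SNPs are first-class "uninformative".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.ndimage

from .genome import CENTROMERES, GenomeAnnotation
from .io import ExpressionMatrix

CALL_AMPLIFIED = "amplified"
CALL_NEUTRAL = "neutral"
CALL_DELETED = "deleted"
CALL_UNINFORMATIVE = "uninformative"

DEFAULT_TAU = 0.75
DEFAULT_D_EVENT = 0.2
DEFAULT_MIN_SNPS = 3
DEFAULT_SCALES = (1, 3, 5, 7)


@dataclass
class DeviationProfiles:
    """Per-cell per-SNP BAF deviations on one arm, position-ordered.

    ``dev``/``total`` are cells x SNPs dense arrays; ``dev`` is NaN where a
    SNP has no reads in that cell.
    """

    cell_ids: pd.Index
    snp_ids: pd.Index
    pos_bp: np.ndarray
    dev: np.ndarray
    total: np.ndarray
    min_snps: int

    @property
    def n_informative(self) -> np.ndarray:
        return (self.total > 0).sum(axis=1)

    @property
    def informative(self) -> np.ndarray:
        return self.n_informative >= self.min_snps

    def arm_deviation(self) -> np.ndarray:
        """Coverage-weighted mean deviation per cell (NaN if uninformative)."""
        w = self.total.astype(float)
        num = np.nansum(np.where(w > 0, self.dev, 0.0) * w, axis=1)
        den = w.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            d = num / den
        d[~self.informative] = np.nan
        return d


def arm_snp_mask(genome: GenomeAnnotation, arm: str) -> np.ndarray:
    """Mask over genome.snps for an arm spec like ``"5q"``."""
    chrom, a = arm[:-1], arm[-1]
    if a not in ("p", "q"):
        raise ValueError(f"arm must end in 'p' or 'q': {arm!r}")
    snps = genome.snps
    cen = CENTROMERES[chrom]
    on_chrom = (snps["chromosome"].astype(str) == chrom).to_numpy()
    pos = snps["pos_bp"].to_numpy()
    return on_chrom & ((pos < cen) if a == "p" else (pos >= cen))


def baf_deviation(
    alleles: pd.DataFrame,
    genome: GenomeAnnotation,
    cell_ids: Sequence[str],
    arm: str = "5q",
    min_snps: int = DEFAULT_MIN_SNPS,
) -> DeviationProfiles:
    """Build position-ordered per-cell BAF deviation profiles for one arm.

    Deviation d = |BAF - 0.5| per covered SNP; zero-coverage SNPs are NaN.
    ``cell_ids`` fixes the row universe so cells with no allele reads at all
    still appear (as fully uncovered, hence uninformative).
    """
    cell_ids = pd.Index(cell_ids)
    snps = genome.snps.loc[arm_snp_mask(genome, arm)].sort_values("pos_bp")
    snp_ids = pd.Index(snps["snp_id"])
    n_cells, n_snps = len(cell_ids), len(snp_ids)
    dev = np.full((n_cells, n_snps), np.nan)
    total = np.zeros((n_cells, n_snps), dtype=np.int64)
    if n_snps and len(alleles):
        sub = alleles[alleles["snp_id"].isin(snp_ids)]
        ci = cell_ids.get_indexer(sub["cell_id"])
        si = snp_ids.get_indexer(sub["snp_id"])
        ok = ci >= 0
        ci, si = ci[ok], si[ok]
        tot = (sub["ref_count"] + sub["alt_count"]).to_numpy()[ok]
        alt = sub["alt_count"].to_numpy()[ok]
        covered = tot > 0
        ci, si, tot, alt = ci[covered], si[covered], tot[covered], alt[covered]
        total[ci, si] = tot
        dev[ci, si] = np.abs(alt / tot - 0.5)
    return DeviationProfiles(
        cell_ids=cell_ids,
        snp_ids=snp_ids,
        pos_bp=snps["pos_bp"].to_numpy(),
        dev=dev,
        total=total,
        min_snps=min_snps,
    )


def multiscale_consistency(
    profiles: DeviationProfiles,
    scales: Sequence[int] = DEFAULT_SCALES,
    d_event: float = DEFAULT_D_EVENT,
) -> np.ndarray:
    """Fraction of smoothing scales at which the arm looks event-bearing.

    At each scale the cell's covered-SNP deviation sequence is median-filtered
    with that window (positional order; window shrinks at the arm ends via
    nearest-edge handling) and the arm is flagged iff the mean smoothed
    deviation exceeds ``d_event``. Uninformative cells propagate as NaN.
    """
    scales = list(scales)
    if len(scales) < 2:
        raise ValueError("need >= 2 smoothing scales")
    out = np.full(len(profiles.cell_ids), np.nan)
    informative = profiles.informative
    for i in np.flatnonzero(informative):
        d = profiles.dev[i]
        d = d[~np.isnan(d)]
        flagged = 0
        for s in scales:
            sm = d if s <= 1 else scipy.ndimage.median_filter(d, size=s, mode="nearest")
            if sm.mean() > d_event:
                flagged += 1
        out[i] = flagged / len(scales)
    return out


def arm_expression_shift(
    norm_expr: ExpressionMatrix,
    genome: GenomeAnnotation,
    reference_cells: Sequence[str],
    arm: str = "5q",
) -> pd.Series:
    """Per-cell mean normalized expression over arm genes minus the reference mean."""
    chrom, a = arm[:-1], arm[-1]
    mask = genome.arm_gene_mask(chrom, a)
    if not mask.any():
        raise ValueError(f"no genes annotated on arm {arm}")
    X = norm_expr.values[:, np.flatnonzero(mask)]
    per_cell = np.asarray(X.mean(axis=1)).ravel()
    ref_idx = norm_expr.cell_ids.get_indexer(pd.Index(reference_cells))
    if (ref_idx < 0).any():
        raise ValueError("reference cells missing from the expression matrix")
    shift = per_cell - per_cell[ref_idx].mean()
    return pd.Series(shift, index=norm_expr.cell_ids, name="expression_shift")


@dataclass
class AlleleChannelResult:
    calls: pd.DataFrame  # cell_id, arm, n_informative_snps, deviation, consistency, allele_call
    tau: float
    d_event: float
    min_snps: int


def arm_calls(
    profiles: DeviationProfiles,
    consistency: np.ndarray,
    expression_shift: pd.Series,
    arm: str = "5q",
    tau: float = DEFAULT_TAU,
) -> AlleleChannelResult:
    """Binarize: event iff consistency >= tau; direction from the expression
    shift sign (negative = deleted, positive = amplified, exact tie = neutral)."""
    if not (0.0 < tau <= 1.0):
        raise ValueError("tau must lie in (0, 1]")
    shift = expression_shift.reindex(profiles.cell_ids).to_numpy()
    call = np.full(len(profiles.cell_ids), CALL_NEUTRAL, dtype=object)
    informative = profiles.informative
    event = informative & (np.nan_to_num(consistency, nan=-1.0) >= tau)
    call[event & (shift < 0)] = CALL_DELETED
    call[event & (shift > 0)] = CALL_AMPLIFIED
    call[~informative] = CALL_UNINFORMATIVE
    calls = pd.DataFrame(
        {
            "cell_id": profiles.cell_ids,
            "arm": arm,
            "n_informative_snps": profiles.n_informative,
            "deviation": profiles.arm_deviation(),
            "consistency": consistency,
            "allele_call": call,
        }
    )
    return AlleleChannelResult(
        calls=calls, tau=tau, d_event=np.nan, min_snps=profiles.min_snps
    )


def allele_channel(
    alleles: pd.DataFrame,
    norm_expr: ExpressionMatrix,
    meta: pd.DataFrame,
    genome: GenomeAnnotation,
    arm: str = "5q",
    reference_condition: str = "healthy",
    tau: float = DEFAULT_TAU,
    d_event: float = DEFAULT_D_EVENT,
    min_snps: int = DEFAULT_MIN_SNPS,
    scales: Sequence[int] = DEFAULT_SCALES,
    cells: Optional[Sequence[str]] = None,
) -> AlleleChannelResult:
    """Full channel for the non-reference cells of a cohort."""
    if cells is None:
        cells = meta.loc[meta["condition"] != reference_condition, "cell_id"]
    ref_cells = meta.loc[meta["condition"] == reference_condition, "cell_id"]
    if len(ref_cells) == 0:
        raise ValueError(f"no cells with condition {reference_condition!r} for reference")
    profiles = baf_deviation(alleles, genome, cells, arm=arm, min_snps=min_snps)
    consistency = multiscale_consistency(profiles, scales=scales, d_event=d_event)
    shift = arm_expression_shift(norm_expr, genome, ref_cells, arm=arm)
    res = arm_calls(profiles, consistency, shift, arm=arm, tau=tau)
    res.d_event = d_event
    return res
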