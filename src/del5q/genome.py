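"""Genome annotation for the simulated cohort.

Gene intervals are 0-based half-open throughout the in-memory representation;
SNP positions are likewise 0-based internally and converted to 1-based only at
the file boundary (VCF convention). The target deletion region models the
commonly deleted interval on chromosome 5q (bands q13-q33 clinically; laid out
here as a contiguous span on the q arm).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .config import CDR_MARKER_GENES, InvalidConfigError, SimulationConfig

# GRCh38-scale chromosome sizes / centromere midpoints (bp) for the two
# chromosomes the simulator populates.
CHROM_SIZES = {"1": 248_956_422, "5": 181_538_259}
CENTROMERES = {"1": 123_400_000, "5": 48_800_000}

#: Default left edge of the simulated deletion (proximal 5q).
REGION_START_BP = 71_000_000

_MIN_GENE_SLOT_BP = 1_000


class TargetRegion(NamedTuple):
    chromosome: str
    start_bp: int
    end_bp: int
    label: str


@dataclass
class GenomeAnnotation:
    """Gene table, SNP table and the target deletion region.

    genes: columns (gene_id, chromosome, arm, start_bp, end_bp)
    snps:  columns (snp_id, chromosome, pos_bp, in_region)
    """

    genes: pd.DataFrame
    snps: pd.DataFrame
    target_region: TargetRegion

    def region_gene_mask(self) -> np.ndarray:
        """Boolean mask over ``genes`` rows for genes inside the target region."""
        r = self.target_region
        g = self.genes
        return (
            (g["chromosome"] == r.chromosome)
            & (g["start_bp"] >= r.start_bp)
            & (g["end_bp"] <= r.end_bp)
        ).to_numpy()

    def arm_gene_mask(self, chromosome: str, arm: str) -> np.ndarray:
        g = self.genes
        return ((g["chromosome"] == chromosome) & (g["arm"] == arm)).to_numpy()


def arm_of(chromosome: str, pos_bp) -> np.ndarray:
    """Vectorized p/q arm assignment by centromere midpoint."""
    cen = CENTROMERES[str(chromosome)]
    return np.where(np.asarray(pos_bp) < cen, "p", "q")


def _place_genes(start: int, end: int, n: int, lengths_rng: np.random.Generator):
    """Evenly slot ``n`` non-overlapping genes into [start, end)."""
    if n == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    slot = (end - start) // n
    if slot < _MIN_GENE_SLOT_BP:
        raise InvalidConfigError(
            f"span {end - start} bp too small to host {n} non-overlapping genes"
        )
    starts = start + np.arange(n, dtype=np.int64) * slot
    max_len = min(20_000, slot - 1)
    lengths = lengths_rng.integers(max(500, max_len // 2), max_len + 1, size=n)
    lengths = np.minimum(lengths, slot - 1)
    return starts, starts + lengths


def build_genome(config: SimulationConfig) -> GenomeAnnotation:
    """Lay out genes and heterozygous SNPs around a chr5q target region.

    Exactly ``n_region_genes`` genes fall inside the target region; six of them
    (evenly spread) are named after the detectable CDR markers CD74, RPS14,
    BTF3, COX7C, HINT1 and RPS23. Remaining genes are distributed over chr1 and
    the non-deleted parts of chr5 so that reference bins exist on more than one
    chromosome. Deterministic for a fixed config (including seed).
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 101])

    region_end = REGION_START_BP + config.region_span_bp
    if region_end > CHROM_SIZES["5"]:
        raise InvalidConfigError("region_span_bp extends past the end of chr5")
    region = TargetRegion("5", REGION_START_BP, region_end, "del(5q)")

    rows = []
    # Region genes (chr5 q arm, inside the deletion).
    r_starts, r_ends = _place_genes(region.start_bp, region.end_bp, config.n_region_genes, rng)
    marker_names = list(CDR_MARKER_GENES[: min(len(CDR_MARKER_GENES), config.n_region_genes)])
    marker_idx = np.unique(
        np.round(np.linspace(0, config.n_region_genes - 1, len(marker_names))).astype(int)
    )
    marker_map = dict(zip(marker_idx, marker_names))
    for i in range(config.n_region_genes):
        rows.append((marker_map.get(i, ""), "5", r_starts[i], r_ends[i]))

    # Background genes: chr1, chr5 p arm, and chr5 q-arm flanks of the region.
    n_other = config.n_genes - config.n_region_genes
    n_chr1 = n_other // 2
    n_5p = n_other // 5
    n_5q_flank = n_other - n_chr1 - n_5p
    pre_span = region.start_bp - (CENTROMERES["5"] + 2_000_000)
    post_span = CHROM_SIZES["5"] - 2_000_000 - region.end_bp
    n_pre = int(round(n_5q_flank * pre_span / max(pre_span + post_span, 1)))
    n_post = n_5q_flank - n_pre

    zones = [
        ("1", 1_000_000, CHROM_SIZES["1"] - 2_000_000, n_chr1),
        ("5", 2_000_000, CENTROMERES["5"] - 2_000_000, n_5p),
        ("5", CENTROMERES["5"] + 2_000_000, region.start_bp, n_pre),
        ("5", region.end_bp, CHROM_SIZES["5"] - 2_000_000, n_post),
    ]
    for chrom, lo, hi, n in zones:
        if n <= 0:
            continue
        starts, ends = _place_genes(lo, hi, n, rng)
        rows.extend(("", chrom, s, e) for s, e in zip(starts, ends))

    genes = pd.DataFrame(rows, columns=["gene_id", "chromosome", "start_bp", "end_bp"])
    anon = genes["gene_id"] == ""
    genes.loc[anon, "gene_id"] = [f"G{i:05d}" for i in range(int(anon.sum()))]
    genes["arm"] = [
        arm_of(c, s).item() for c, s in zip(genes["chromosome"], genes["start_bp"])
    ]
    genes = genes[["gene_id", "chromosome", "arm", "start_bp", "end_bp"]]
    if genes["gene_id"].duplicated().any():
        raise InvalidConfigError("duplicate gene identifiers generated")

    # SNPs: in-region plus flanks (half chr5p, rest split around the region on 5q).
    snp_rows = []
    if config.n_snps_region > 0:
        step = config.region_span_bp / config.n_snps_region
        pos = (region.start_bp + (np.arange(config.n_snps_region) + 0.5) * step).astype(np.int64)
        snp_rows.extend(("5", p, True) for p in pos)
    n_p = config.n_snps_flank // 2
    n_qf = config.n_snps_flank - n_p
    flank_zones = [
        ("5", 5_000_000, CENTROMERES["5"] - 2_000_000, n_p),
        ("5", CENTROMERES["5"] + 2_000_000, region.start_bp, n_qf // 2),
        ("5", region.end_bp, CHROM_SIZES["5"] - 2_000_000, n_qf - n_qf // 2),
    ]
    for chrom, lo, hi, n in flank_zones:
        if n <= 0:
            continue
        step = (hi - lo) / n
        pos = (lo + (np.arange(n) + 0.5) * step).astype(np.int64)
        snp_rows.extend((chrom, p, False) for p in pos)
    snps = pd.DataFrame(snp_rows, columns=["chromosome", "pos_bp", "in_region"])
    snps.insert(0, "snp_id", [f"S{i:05d}" for i in range(len(snps))])
    snps["in_region"] = snps["in_region"].astype(bool)

    return GenomeAnnotation(genes=genes, snps=snps, target_region=region)
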