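"""Synthetic del(5q) cohort generator.

Generative model
----------------
UMI counts for cell *c*, gene *g*:

    counts ~ NB(mu = s_c * m_{g,t(c)} * d_{cg},  var = mu + phi * mu^2)

with per-cell library-size factor ``s_c ~ LogNormal(meanlog, sdlog)``,
cell-type program mean ``m_{g,t}``, and dosage ``d_{cg} = dosage_factor`` for
target-region genes in deleted cells (1 otherwise). NB sampling is realized as
a Gamma-Poisson mixture.

Allele counts at heterozygous SNPs: per (cell, SNP) total reads ~
Poisson(snp_coverage_mean); diploid cell/SNP draws alt ~ Binomial(total, 0.5).
For a deleted cell at an in-region SNP one haplotype is retained — which one
is drawn once per SNP per sample (a clonal deletion) — and the lost allele
appears with probability ``error_rate`` per read.

Truth genotypes are recorded per cell, and the number of deleted cells per
sample equals ``round(cells_per_sample * fraction)`` exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .config import (
    HEMATOPOIETIC_CELL_TYPES,
    InvalidConfigError,
    SimulationConfig,
)
from .genome import GenomeAnnotation, build_genome
from .io import CountMatrix, write_dataset  # noqa: F401  (write_dataset re-exported)

TRUTH_DEL = "del"
TRUTH_NON_DEL = "non_del"


@dataclass
class SimulatedDataset:
    counts: CountMatrix
    meta: pd.DataFrame
    alleles: pd.DataFrame
    genome: GenomeAnnotation
    config: SimulationConfig


def _sample_plan(config: SimulationConfig):
    plan = [
        (f"MDS_{i + 1}", "mds", float(f), config.cells_per_sample)
        for i, f in enumerate(config.del_fraction_per_sample)
    ]
    plan += [
        (f"Healthy_{i + 1}", "healthy", 0.0, config.reference_cells_per_sample)
        for i in range(config.n_reference_samples)
    ]
    return plan


def simulate_cohort(
    config: SimulationConfig, genome: GenomeAnnotation
) -> SimulatedDataset:
    """Draw a full multi-sample cohort with ground-truth genotypes."""
    config.validate()
    if len(genome.genes) != config.n_genes:
        raise InvalidConfigError(
            f"genome has {len(genome.genes)} genes but config expects {config.n_genes}"
        )
    rng = np.random.default_rng([config.seed, 202])
    prog = config.celltype_program_params
    n_genes = config.n_genes
    n_types = config.n_cell_types
    type_names = list(HEMATOPOIETIC_CELL_TYPES[:n_types])

    base = rng.gamma(prog.gamma_shape, prog.gamma_scale, size=n_genes)
    base = np.maximum(base, 1e-6)
    is_marker = (genome.genes["gene_id"].isin(
        ("CD74", "RPS14", "BTF3", "COX7C", "HINT1", "RPS23"))).to_numpy()
    base[is_marker] *= prog.cdr_marker_boost

    type_factor = np.ones((n_types, n_genes))
    n_type_markers = int(round(prog.marker_fraction * n_genes))
    for t in range(n_types):
        idx = rng.choice(n_genes, size=n_type_markers, replace=False)
        type_factor[t, idx] *= prog.marker_magnitude

    region_mask = genome.region_gene_mask()
    snps = genome.snps
    n_snps = len(snps)
    region_snp = snps["in_region"].to_numpy()

    phi = config.nb_dispersion
    meanlog, sdlog = config.libsize_lognormal
    bias = (
        np.asarray(config.del_celltype_bias, dtype=float)
        if config.del_celltype_bias is not None
        else None
    )

    blocks, meta_rows, allele_frames = [], [], []
    for sample_id, condition, frac, n_cells in _sample_plan(config):
        ctype_probs = rng.dirichlet(np.full(n_types, 5.0))
        ctype = rng.choice(n_types, size=n_cells, p=ctype_probs)
        libsize = rng.lognormal(meanlog, sdlog, size=n_cells)

        n_del = int(round(n_cells * frac))
        is_del = np.zeros(n_cells, dtype=bool)
        if n_del > 0:
            if bias is not None:
                w = bias[ctype].astype(float)
                w = w / w.sum()
                del_idx = rng.choice(n_cells, size=n_del, replace=False, p=w)
            else:
                del_idx = rng.choice(n_cells, size=n_del, replace=False)
            is_del[del_idx] = True

        mu = libsize[:, None] * (base[None, :] * type_factor[ctype])
        if n_del > 0:
            mu[np.ix_(is_del, region_mask)] *= config.dosage_factor
        lam = rng.gamma(1.0 / phi, phi * mu)
        counts = rng.poisson(lam).astype(np.int64)
        blocks.append(sp.csr_matrix(counts))

        cell_ids = [f"{sample_id}_c{i:05d}" for i in range(n_cells)]
        meta_rows.append(
            pd.DataFrame(
                {
                    "cell_id": cell_ids,
                    "sample_id": sample_id,
                    "condition": condition,
                    "cell_type": [type_names[t] for t in ctype],
                    "truth_genotype": np.where(is_del, TRUTH_DEL, TRUTH_NON_DEL),
                    "libsize_factor": libsize,
                }
            )
        )

        if n_snps:
            totals = rng.poisson(config.snp_coverage_mean, size=(n_cells, n_snps))
            # clonal phase: which haplotype (ref or alt) survives, per SNP per sample
            ref_retained = rng.random(n_snps) < 0.5
            p_alt = np.full((n_cells, n_snps), 0.5)
            if n_del > 0 and region_snp.any():
                p_loss = np.where(ref_retained, config.error_rate, 1.0 - config.error_rate)
                cols = np.flatnonzero(region_snp)
                p_alt[np.ix_(is_del, cols)] = p_loss[cols]
            alt = rng.binomial(totals, p_alt)
            ci, si = np.nonzero(totals)
            allele_frames.append(
                pd.DataFrame(
                    {
                        "cell_id": np.asarray(cell_ids, dtype=object)[ci],
                        "snp_id": snps["snp_id"].to_numpy()[si],
                        "chromosome": snps["chromosome"].to_numpy()[si],
                        "pos_bp": snps["pos_bp"].to_numpy()[si],
                        "ref_count": (totals - alt)[ci, si],
                        "alt_count": alt[ci, si],
                    }
                )
            )

    counts_all = sp.vstack(blocks, format="csr")
    meta = pd.concat(meta_rows, ignore_index=True)
    alleles = (
        pd.concat(allele_frames, ignore_index=True)
        if allele_frames
        else pd.DataFrame(
            columns=["cell_id", "snp_id", "chromosome", "pos_bp", "ref_count", "alt_count"]
        )
    )
    cm = CountMatrix(
        values=counts_all,
        cell_ids=pd.Index(meta["cell_id"]),
        gene_ids=pd.Index(genome.genes["gene_id"]),
    )
    return SimulatedDataset(counts=cm, meta=meta, alleles=alleles, genome=genome, config=config)


def simulate(config: SimulationConfig) -> SimulatedDataset:
    """build_genome + simulate_cohort in one call."""
    return simulate_cohort(config, build_genome(config))
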