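"""End-to-end orchestration: simulate -> QC -> both CNA channels -> consensus
-> validation -> enrichment -> DE, with a provenance manifest.

All stage randomness derives from one global seed via stable per-stage
hashing, so a rerun with the same config reproduces checksum-identical
outputs. Logging goes to the standard logging machinery (stderr by default);
no log file is written into the run directory, keeping its contents fully
covered by the manifest.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from . import allele as allele_mod
from . import expression as expr_mod
from .config import CDR_MARKER_GENES, InvalidConfigError, SimulationConfig
from .consensus import GENOTYPE_DEL, GENOTYPE_NON_DEL, combine, estimate_fraction
from .de import hurdle_lrt, make_pseudobulk, nb_glm_lrt
from .enrichment import abundance_test, celltype_proportions, hypergeom_enrichment
from .io import read_dataset, write_dataset, write_manifest
from .preprocess import QCThresholds, normalize_log, qc_filter
from .simulate import simulate
from .validation import (
    concordance,
    marker_gene_check,
    region_enrichment_test,
    shuffled_control,
)

log = logging.getLogger("del5q")


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    return (int(global_seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


@dataclass
class DESettings:
    fdr_alpha: float = 0.05
    log2fc_cutoff: float = 2.0
    min_cells: int = 20
    min_total: int = 10

    def validate(self) -> None:
        if not (0.0 < self.fdr_alpha < 1.0):
            raise InvalidConfigError("fdr_alpha must lie in (0, 1)")
        if self.log2fc_cutoff < 0 or self.min_cells < 1 or self.min_total < 0:
            raise InvalidConfigError("invalid DE settings")


@dataclass
class PipelineConfig:
    """Every threshold used anywhere in the pipeline lives here (or in the
    nested SimulationConfig / QCThresholds / DESettings)."""

    seed: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    qc: QCThresholds = field(default_factory=QCThresholds)
    bin_size: int = expr_mod.DEFAULT_BIN_SIZE
    k_clusters: int = expr_mod.DEFAULT_K
    deletion_cutoff: float = expr_mod.DEFAULT_CUTOFF
    smoothing_halfwidth: int = expr_mod.DEFAULT_SMOOTH_HALFWIDTH
    consistency_threshold: float = allele_mod.DEFAULT_TAU
    d_event: float = allele_mod.DEFAULT_D_EVENT
    min_snps: int = allele_mod.DEFAULT_MIN_SNPS
    scales: Tuple[int, ...] = allele_mod.DEFAULT_SCALES
    arm: str = "5q"
    reference_condition: str = "healthy"
    markers: Tuple[str, ...] = CDR_MARKER_GENES
    n_perms: int = 100
    enrichment_alpha: float = 0.05
    de: DESettings = field(default_factory=DESettings)

    def validate(self) -> None:
        if not (0.0 < self.consistency_threshold <= 1.0):
            raise InvalidConfigError("consistency_threshold must lie in (0, 1]")
        if not (0.0 < self.enrichment_alpha < 1.0):
            raise InvalidConfigError("enrichment_alpha must lie in (0, 1)")
        if self.bin_size <= 0 or self.k_clusters < 2:
            raise InvalidConfigError("bin_size must be > 0 and k_clusters >= 2")
        if self.n_perms < 1:
            raise InvalidConfigError("n_perms must be >= 1")
        if len(self.scales) < 2:
            raise InvalidConfigError("need >= 2 smoothing scales")
        self.simulation.validate()
        self.qc.validate()
        self.de.validate()

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["simulation"] = self.simulation.to_dict()
        d["scales"] = list(self.scales)
        d["markers"] = list(self.markers)
        return d


def run_all(
    config: PipelineConfig,
    outdir,
    simulate_data: bool = True,
    indir: Optional[str] = None,
) -> Path:
    """Execute every stage in order; returns the run directory.

    Stage failure raises :class:`StageError` naming the stage; outputs written
    before the failure remain in place (marked by the absent manifest).
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        stage = "simulate" if simulate_data else "read"
        if simulate_data:
            sim_cfg = dataclasses.replace(
                config.simulation, seed=stage_seed(config.seed, "simulate")
            )
            dataset = simulate(sim_cfg)
            write_dataset(dataset, outdir / "dataset", overwrite=True)
            counts, meta, alleles, genome = (
                dataset.counts, dataset.meta, dataset.alleles, dataset.genome,
            )
        else:
            if indir is None:
                raise StageError("read: no input directory given")
            counts, meta, alleles, genome = read_dataset(indir)
        log.info("%s: %d cells x %d genes", stage, counts.n_cells, counts.n_genes)

        stage = "qc"
        counts, meta, qc_report = qc_filter(counts, meta, config.qc)
        qc_report.to_csv(outdir / "qc_report.tsv", sep="\t", index=False)
        log.info("qc: kept %d cells", counts.n_cells)

        stage = "normalize"
        norm = normalize_log(counts)

        stage = "cna-expr"
        expr_res = expr_mod.expression_channel(
            norm, meta, genome,
            reference_condition=config.reference_condition,
            bin_size=config.bin_size,
            smoothing_halfwidth=config.smoothing_halfwidth,
            k=config.k_clusters,
            cutoff=config.deletion_cutoff,
            seed=stage_seed(config.seed, "cna-expr"),
        )
        expr_res.calls.to_csv(outdir / "calls_expr.tsv", sep="\t", index=False)

        stage = "cna-allele"
        allele_res = allele_mod.allele_channel(
            alleles, norm, meta, genome,
            arm=config.arm,
            reference_condition=config.reference_condition,
            tau=config.consistency_threshold,
            d_event=config.d_event,
            min_snps=config.min_snps,
            scales=config.scales,
        )
        allele_res.calls.to_csv(
            outdir / "calls_allele.tsv", sep="\t", index=False, float_format="%.6g"
        )

        stage = "genotype"
        genotypes = combine(expr_res.calls, allele_res.calls)
        genotypes = genotypes.merge(
            meta[["cell_id", "sample_id", "condition", "cell_type"]], on="cell_id"
        )
        genotypes.to_csv(outdir / "genotypes.tsv", sep="\t", index=False)
        fractions = estimate_fraction(genotypes)
        fractions.to_csv(
            outdir / "fractions.tsv", sep="\t", index=False, float_format="%.6g"
        )

        n_del = int((genotypes["genotype"] == GENOTYPE_DEL).sum())
        n_non = int((genotypes["genotype"] == GENOTYPE_NON_DEL).sum())
        notes = []

        stage = "validate"
        vdir = outdir / "validation"
        vdir.mkdir(exist_ok=True)
        markers = marker_gene_check(norm, genotypes, markers=config.markers)
        markers.to_csv(vdir / "markers.tsv", sep="\t", index=False, float_format="%.6g")
        min_cells = config.de.min_cells
        if n_del >= min_cells and n_non >= min_cells:
            enr = region_enrichment_test(
                norm, genotypes, genome, alpha=config.enrichment_alpha
            )
            shuffle = shuffled_control(
                norm, genotypes, genome,
                n_perms=config.n_perms,
                seed=stage_seed(config.seed, "shuffle"),
                alpha=config.enrichment_alpha,
            )
            summary = {
                "enrichment_p": enr.enrichment_p,
                "n_downregulated": enr.n_downregulated,
                "n_region_in_down": enr.n_region_in_down,
                "n_tested": enr.n_tested,
                "shuffle_median_p": shuffle.median_p,
                "shuffle_fraction_below_alpha": shuffle.fraction_below_alpha,
                "n_perms": shuffle.n_perms,
            }
            pd.DataFrame({"perm_p": shuffle.p_values}).to_csv(
                vdir / "shuffle.tsv", sep="\t", index=False, float_format="%.6g"
            )
        else:
            summary = {"skipped": f"too few classified cells ({n_del} del5q, {n_non} non_del5q)"}
            notes.append("validation enrichment skipped: " + summary["skipped"])
        if config.simulation is not None and simulate_data:
            truth = dict(
                zip(
                    [f"MDS_{i+1}" for i in range(config.simulation.n_samples)],
                    config.simulation.del_fraction_per_sample,
                )
            )
            gaps = concordance(fractions.rename(columns={"sample_id": "sample_id"}), truth)
            gaps.to_csv(vdir / "concordance.tsv", sep="\t", index=False, float_format="%.6g")
        with open(vdir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=1, sort_keys=True)
            fh.write("\n")

        stage = "enrich"
        hypergeom_enrichment(genotypes).to_csv(
            outdir / "enrichment.tsv", sep="\t", index=False, float_format="%.6g"
        )
        props = celltype_proportions(meta)
        groups = meta.drop_duplicates("sample_id").set_index("sample_id")["condition"]
        if groups.nunique() == 2 and groups.value_counts().min() >= 2:
            abundance_test(props, groups.to_dict()).to_csv(
                outdir / "abundance.tsv", sep="\t", index=False, float_format="%.6g"
            )

        stage = "de"
        dedir = outdir / "de"
        dedir.mkdir(exist_ok=True)
        de_summary = {}
        if n_del >= config.de.min_cells and n_non >= config.de.min_cells:
            classified = genotypes[
                genotypes["genotype"].isin([GENOTYPE_DEL, GENOTYPE_NON_DEL])
            ]
            pb = make_pseudobulk(
                counts, classified, min_cells=config.de.min_cells
            )
            for ct, reps in pb.replicates.groupby("cell_type", sort=True):
                ok = (reps["group"] == GENOTYPE_DEL).sum() >= 2 and (
                    reps["group"] == GENOTYPE_NON_DEL
                ).sum() >= 2
                if ok:
                    sub = dataclasses.replace(
                        pb,
                        counts=pb.counts[reps.index.to_numpy()],
                        replicates=reps.reset_index(drop=True),
                    )
                    table = nb_glm_lrt(
                        sub,
                        contrast=(GENOTYPE_DEL, GENOTYPE_NON_DEL),
                        min_total=config.de.min_total,
                        fdr_alpha=config.de.fdr_alpha,
                        log2fc_cutoff=config.de.log2fc_cutoff,
                    )
                    method = "pseudobulk_nb_lrt"
                else:
                    cells = classified[classified["cell_type"] == ct]
                    if (cells["genotype"] == GENOTYPE_DEL).sum() < config.de.min_cells or (
                        cells["genotype"] == GENOTYPE_NON_DEL
                    ).sum() < config.de.min_cells:
                        de_summary[ct] = {"skipped": "too few cells/replicates"}
                        continue
                    sub_norm = norm.subset_cells(cells["cell_id"].to_numpy())
                    table = hurdle_lrt(
                        sub_norm,
                        cells["genotype"].to_numpy(),
                        contrast=(GENOTYPE_DEL, GENOTYPE_NON_DEL),
                        min_cells=config.de.min_cells,
                        fdr_alpha=config.de.fdr_alpha,
                        log2fc_cutoff=config.de.log2fc_cutoff,
                    )
                    method = "hurdle_lrt"
                safe = str(ct).replace("/", "_")
                table.to_csv(
                    dedir / f"{safe}.tsv", sep="\t", index=False, float_format="%.6g"
                )
                de_summary[ct] = {
                    "method": method,
                    "n_significant": int(table["significant"].sum()),
                }
        else:
            de_summary["skipped"] = (
                f"del-vs-non-del contrast skipped: {n_del} del5q, {n_non} non_del5q cells"
            )
            notes.append(de_summary["skipped"])
        with open(dedir / "summary.json", "w") as fh:
            json.dump(de_summary, fh, indent=1, sort_keys=True)
            fh.write("\n")

        stage = "manifest"
        with open(outdir / "run_config.json", "w") as fh:
            json.dump(config.to_dict(), fh, indent=1, sort_keys=True)
            fh.write("\n")
        if notes:
            with open(outdir / "notes.txt", "w") as fh:
                fh.write("\n".join(notes) + "\n")
        write_manifest(outdir)
    except StageError:
        raise
    except Exception as exc:
        raise StageError(f"stage {stage!r} failed: {exc}") from exc
    return outdir
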