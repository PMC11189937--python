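"""Simulation configuration.

The simulator emulates the statistical structure of a multi-sample CD34+
scRNA-seq cohort carrying a clonal interstitial deletion on chromosome 5q:
negative-binomial UMI counts with ~50% dosage reduction for genes inside the
deleted region in deleted cells, and loss of heterozygosity (BAF shift) at
heterozygous SNPs inside the region. Defaults reflect the cohort design the
downstream genotyper is built for: four patient samples whose mosaic clone
fractions span 0.35-0.90, plus healthy reference samples.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple


class InvalidConfigError(ValueError):
    """Raised when a configuration violates its invariants."""


#: Canonical hematopoietic progenitor labels used for simulated cell types.
HEMATOPOIETIC_CELL_TYPES: Tuple[str, ...] = (
    "HSC", "LMPP", "GMP", "Granulocyte", "Monocyte", "DendriticCell",
    "CLP", "pro-B", "T", "MEP", "MK_Prog", "EarlyErythroid",
    "LateErythroid", "Basophil",
)

#: The six commonly-deleted-region marker genes used by the dosage check.
CDR_MARKER_GENES: Tuple[str, ...] = (
    "CD74", "RPS14", "BTF3", "COX7C", "HINT1", "RPS23",
)


@dataclass
class CellTypeProgram:
    """Parameters of the per-cell-type expression programs.

    Baseline gene means are Gamma(gamma_shape, gamma_scale) draws shared by all
    cell types; each cell type additionally up-regulates a random
    ``marker_fraction`` of genes by ``marker_magnitude``. The six CDR marker
    genes get an elevated baseline (``cdr_marker_boost``) so that, as in real
    data, they are reliably detected despite sparsity.
    """

    gamma_shape: float = 1.0
    gamma_scale: float = 2.0
    marker_fraction: float = 0.08
    marker_magnitude: float = 3.0
    cdr_marker_boost: float = 10.0


@dataclass
class SimulationConfig:
    """Full parameterization of a simulated del(5q) cohort.

    ``del_fraction_per_sample`` gives the per-patient mosaic clone fraction
    (the karyotype range observed clinically is roughly 0.35-0.90).
    ``dosage_factor`` multiplies the NB mean of target-region genes in deleted
    cells (0.5 = hemizygous dosage). ``error_rate`` is the probability that a
    read at an in-region SNP of a deleted cell reports the lost allele.
    """

    seed: int = 0
    n_samples: int = 4
    cells_per_sample: int = 2000
    del_fraction_per_sample: Sequence[float] = (0.35, 0.50, 0.70, 0.90)
    n_reference_samples: int = 2
    reference_cells_per_sample: int = 1500
    n_genes: int = 2000
    n_region_genes: int = 300
    region_span_bp: int = 40_000_000
    dosage_factor: float = 0.5
    n_cell_types: int = 10
    celltype_program_params: CellTypeProgram = field(default_factory=CellTypeProgram)
    nb_dispersion: float = 0.3
    libsize_lognormal: Tuple[float, float] = (0.0, 0.35)
    n_snps_region: int = 150
    n_snps_flank: int = 150
    snp_coverage_mean: float = 6.0
    error_rate: float = 0.02
    #: Optional per-cell-type sampling weights for which cells carry the
    #: deletion (length n_cell_types); None = uniform across cells.
    del_celltype_bias: Optional[Sequence[float]] = None

    def validate(self) -> None:
        cfg = self
        if cfg.n_samples <= 0 or cfg.cells_per_sample <= 0:
            raise InvalidConfigError("n_samples and cells_per_sample must be > 0")
        if len(cfg.del_fraction_per_sample) != cfg.n_samples:
            raise InvalidConfigError(
                "del_fraction_per_sample must have length n_samples "
                f"({len(cfg.del_fraction_per_sample)} != {cfg.n_samples})"
            )
        for f in cfg.del_fraction_per_sample:
            if not (0.0 <= f <= 1.0):
                raise InvalidConfigError(f"del fraction {f} outside [0, 1]")
        if cfg.n_genes <= 0 or cfg.n_region_genes <= 0:
            raise InvalidConfigError("gene counts must be > 0")
        if cfg.n_region_genes > cfg.n_genes:
            raise InvalidConfigError("n_region_genes cannot exceed n_genes")
        if not (0.0 < cfg.dosage_factor <= 1.0):
            raise InvalidConfigError("dosage_factor must lie in (0, 1]")
        if not (0.0 <= cfg.error_rate <= 0.1):
            raise InvalidConfigError("error_rate must lie in [0, 0.1]")
        if cfg.n_cell_types <= 0 or cfg.n_cell_types > len(HEMATOPOIETIC_CELL_TYPES):
            raise InvalidConfigError(
                f"n_cell_types must be in [1, {len(HEMATOPOIETIC_CELL_TYPES)}]"
            )
        if cfg.nb_dispersion <= 0:
            raise InvalidConfigError("nb_dispersion must be > 0")
        if cfg.region_span_bp <= 0:
            raise InvalidConfigError("region_span_bp must be > 0")
        if cfg.n_snps_region < 0 or cfg.n_snps_flank < 0:
            raise InvalidConfigError("SNP counts must be >= 0")
        if cfg.snp_coverage_mean < 0:
            raise InvalidConfigError("snp_coverage_mean must be >= 0")
        if cfg.n_reference_samples < 0 or cfg.reference_cells_per_sample <= 0:
            raise InvalidConfigError("reference sample sizes invalid")
        if cfg.del_celltype_bias is not None:
            if len(cfg.del_celltype_bias) != cfg.n_cell_types:
                raise InvalidConfigError("del_celltype_bias length != n_cell_types")
            if any(w < 0 for w in cfg.del_celltype_bias) or sum(cfg.del_celltype_bias) <= 0:
                raise InvalidConfigError("del_celltype_bias weights must be >= 0, sum > 0")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["del_fraction_per_sample"] = list(d["del_fraction_per_sample"])
        d["libsize_lognormal"] = list(d["libsize_lognormal"])
        if d["del_celltype_bias"] is not None:
            d["del_celltype_bias"] = list(d["del_celltype_bias"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        prog = d.get("celltype_program_params")
        if isinstance(prog, dict):
            d["celltype_program_params"] = CellTypeProgram(**prog)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise InvalidConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        cfg.validate()
        return cfg
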