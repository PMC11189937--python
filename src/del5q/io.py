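"""Readers and writers for the on-disk cohort layout.

A dataset directory contains:

* ``matrix.mtx``    — Matrix Market integer counts, genes x cells
* ``features.tsv``  — gene_id, chromosome, arm, start_bp, end_bp (0-based half-open)
* ``barcodes.tsv``  — cell_id
* ``cell_meta.tsv`` — cell_id, sample_id, condition, cell_type, truth_genotype
* ``alleles.tsv``   — cell_id, snp_id, chromosome, pos (1-based), ref_count, alt_count
* ``snps.tsv``      — snp_id, chromosome, pos (1-based), in_region
* ``region.json``   — target region (chromosome, start_bp, end_bp, label)
* ``config.yaml``   — echo of the simulation config (if simulated)
* ``manifest.json`` — file list with sha256 checksums

All tables carry a header row. SNP positions are shifted to 1-based in files
and back to 0-based in memory.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import yaml

from .config import SimulationConfig
from .genome import GenomeAnnotation, TargetRegion


class ConsistencyError(ValueError):
    """Cross-file identifier mismatch in a dataset directory."""


class FormatError(ValueError):
    """A file failed to parse in its declared format."""


@dataclass
class CountMatrix:
    """Sparse non-negative integer UMI counts, cells x genes."""

    values: sp.csr_matrix
    cell_ids: pd.Index
    gene_ids: pd.Index

    def __post_init__(self):
        self.cell_ids = pd.Index(self.cell_ids)
        self.gene_ids = pd.Index(self.gene_ids)
        if self.values.shape != (len(self.cell_ids), len(self.gene_ids)):
            raise ConsistencyError(
                f"matrix shape {self.values.shape} does not match id lists "
                f"({len(self.cell_ids)} cells, {len(self.gene_ids)} genes)"
            )

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def subset_cells(self, mask_or_ids) -> "CountMatrix":
        idx = _cell_indexer(self.cell_ids, mask_or_ids)
        return type(self)(self.values[idx], self.cell_ids[idx], self.gene_ids)


@dataclass
class ExpressionMatrix(CountMatrix):
    """Real-valued (e.g. log-normalized) expression, cells x genes."""


def _cell_indexer(cell_ids: pd.Index, mask_or_ids) -> np.ndarray:
    arr = np.asarray(mask_or_ids)
    if arr.dtype == bool:
        return np.flatnonzero(arr)
    locs = cell_ids.get_indexer(arr)
    if (locs < 0).any():
        missing = list(np.asarray(arr)[locs < 0][:5])
        raise ConsistencyError(f"unknown cell ids: {missing}")
    return locs


def sha256_of(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(directory: Path, exclude: tuple = ("manifest.json",)) -> dict:
    """Write manifest.json listing every file under ``directory`` with checksums."""
    directory = Path(directory)
    entries = {}
    for p in sorted(directory.rglob("*")):
        if p.is_file():
            rel = p.relative_to(directory).as_posix()
            if rel in exclude:
                continue
            entries[rel] = {"sha256": sha256_of(p), "bytes": p.stat().st_size}
    manifest = {"format_version": 1, "files": entries}
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return manifest


def write_dataset(dataset, directory, overwrite: bool = False) -> dict:
    """Write a SimulatedDataset (or equivalent tuple of tables) to ``directory``.

    Refuses to write into an existing non-empty directory unless ``overwrite``.
    Returns the manifest. Writing the same dataset twice yields byte-identical
    data files.
    """
    directory = Path(directory)
    if directory.exists() and any(directory.iterdir()) and not overwrite:
        raise FileExistsError(
            f"{directory} is not empty; pass overwrite=True to replace it"
        )
    directory.mkdir(parents=True, exist_ok=True)

    counts: CountMatrix = dataset.counts
    genome: GenomeAnnotation = dataset.genome

    scipy.io.mmwrite(
        directory / "matrix.mtx", counts.values.T.tocoo(), field="integer"
    )
    feats = genome.genes.set_index("gene_id").loc[counts.gene_ids].reset_index()
    feats[["gene_id", "chromosome", "arm", "start_bp", "end_bp"]].to_csv(
        directory / "features.tsv", sep="\t", index=False
    )
    pd.DataFrame({"cell_id": counts.cell_ids}).to_csv(
        directory / "barcodes.tsv", sep="\t", index=False
    )
    dataset.meta.to_csv(directory / "cell_meta.tsv", sep="\t", index=False)

    alleles = dataset.alleles.copy()
    alleles["pos"] = alleles.pop("pos_bp") + 1  # 1-based in files
    alleles[["cell_id", "snp_id", "chromosome", "pos", "ref_count", "alt_count"]].to_csv(
        directory / "alleles.tsv", sep="\t", index=False
    )
    snps = genome.snps.copy()
    snps["pos"] = snps.pop("pos_bp") + 1
    snps[["snp_id", "chromosome", "pos", "in_region"]].to_csv(
        directory / "snps.tsv", sep="\t", index=False
    )
    with open(directory / "region.json", "w") as fh:
        json.dump(genome.target_region._asdict(), fh, indent=1)
        fh.write("\n")
    if getattr(dataset, "config", None) is not None:
        with open(directory / "config.yaml", "w") as fh:
            yaml.safe_dump(dataset.config.to_dict(), fh, sort_keys=True)
    return write_manifest(directory)


def read_dataset(directory):
    """Read a dataset directory back into in-memory objects.

    Returns ``(CountMatrix, meta DataFrame, alleles DataFrame, GenomeAnnotation)``.
    Raises :class:`ConsistencyError` naming the offending identifier when the
    tables disagree, and :class:`FormatError` on unparsable files.
    """
    directory = Path(directory)
    if not (directory / "manifest.json").exists():
        raise FormatError(f"{directory} has no manifest.json; not a dataset directory")

    try:
        mat = scipy.io.mmread(directory / "matrix.mtx")
    except Exception as exc:  # scipy raises bare ValueError on bad headers
        raise FormatError(f"malformed Matrix Market file: {exc}") from exc
    feats = pd.read_csv(directory / "features.tsv", sep="\t", dtype={"chromosome": str})
    barcodes = pd.read_csv(directory / "barcodes.tsv", sep="\t")
    meta = pd.read_csv(directory / "cell_meta.tsv", sep="\t", dtype={"cell_id": str})
    alleles = pd.read_csv(directory / "alleles.tsv", sep="\t", dtype={"chromosome": str})
    snps = pd.read_csv(directory / "snps.tsv", sep="\t", dtype={"chromosome": str})
    with open(directory / "region.json") as fh:
        region = TargetRegion(**json.load(fh))

    counts = CountMatrix(
        values=sp.csr_matrix(mat.T, dtype=np.int64),
        cell_ids=pd.Index(barcodes["cell_id"].astype(str)),
        gene_ids=pd.Index(feats["gene_id"].astype(str)),
    )
    missing = counts.cell_ids.difference(pd.Index(meta["cell_id"]))
    if len(missing):
        raise ConsistencyError(
            f"barcodes present in counts but absent from metadata: {list(missing[:5])}"
        )
    unknown_cells = pd.Index(alleles["cell_id"].astype(str)).difference(counts.cell_ids)
    if len(unknown_cells):
        raise ConsistencyError(
            f"allele table references unknown cell ids: {list(unknown_cells[:5])}"
        )
    unknown_snps = pd.Index(alleles["snp_id"].astype(str)).difference(
        pd.Index(snps["snp_id"])
    )
    if len(unknown_snps):
        raise ConsistencyError(
            f"allele table references unknown SNP ids: {list(unknown_snps[:5])}"
        )
    if (alleles[["ref_count", "alt_count"]].to_numpy() < 0).any():
        raise FormatError("negative allele counts")

    alleles = alleles.rename(columns={"pos": "pos_bp"})
    alleles["pos_bp"] = alleles["pos_bp"] - 1  # back to 0-based
    snps = snps.rename(columns={"pos": "pos_bp"})
    snps["pos_bp"] = snps["pos_bp"] - 1
    snps["in_region"] = snps["in_region"].astype(bool)

    genome = GenomeAnnotation(
        genes=feats[["gene_id", "chromosome", "arm", "start_bp", "end_bp"]].copy(),
        snps=snps[["snp_id", "chromosome", "pos_bp", "in_region"]].copy(),
        target_region=region,
    )
    # align metadata row order to the count matrix
    meta = meta.set_index("cell_id").loc[counts.cell_ids].reset_index()
    return counts, meta, alleles, genome


def read_config(directory) -> Optional[SimulationConfig]:
    path = Path(directory) / "config.yaml"
    if not path.exists():
        return None
    with open(path) as fh:
        return SimulationConfig.from_dict(yaml.safe_load(fh))
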