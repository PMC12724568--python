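"""Typed containers and readers/writers for the pipeline's on-disk formats.

Expression data travels as the 10x-style MatrixMarket triplet (matrix.mtx
stored genes x cells, genes.tsv, barcodes.tsv) plus a cell metadata TSV;
ortholog maps as a three-column TSV (species, gene_id, family); results as
TSV tables. Counts are held cells x rows internally (cells are observations).
"""

from __future__ import annotations

import logging
import tomllib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger("best4pipe")

#: metadata columns every dataset carries; missing ones are filled with "NA"
META_COLUMNS = ("cluster", "dataset_id", "species", "genotype", "batch", "region")

NORM_SCALE = 1e4


@dataclass
class ExpressionDataset:
    """Sparse cells x genes counts with optional normalized layer and per-cell
    annotations (cluster, dataset/species of origin, genotype, batch, region).
    """

    counts: sp.csr_matrix
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    cell_meta: pd.DataFrame
    norm: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        n_cells, n_genes = self.counts.shape
        if len(self.gene_ids) != n_genes:
            raise ValueError(
                f"counts has {n_genes} gene columns but {len(self.gene_ids)} gene ids"
            )
        if len(self.cell_ids) != n_cells:
            raise ValueError(
                f"counts has {n_cells} cell rows but {len(self.cell_ids)} cell ids"
            )
        for name, ids in (("gene", self.gene_ids), ("cell", self.cell_ids)):
            if len(set(ids)) != len(ids):
                seen: set[str] = set()
                dup = next(i for i in ids if i in seen or seen.add(i))
                raise ValueError(f"duplicate {name} id: {dup!r}")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("counts matrix contains negative entries")
        if list(self.cell_meta.index) != list(self.cell_ids):
            raise ValueError("cell_meta index does not match cell_ids")
        for col in ("cluster", "dataset_id"):
            if col not in self.cell_meta.columns:
                raise ValueError(f"cell_meta lacks required column {col!r}")
        if self.norm is not None and self.norm.shape != self.counts.shape:
            raise ValueError("norm layer shape differs from counts")

    # -- conveniences -------------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def gene_index(self, gene: str) -> int:
        idx = np.flatnonzero(self.gene_ids == gene)
        if idx.size == 0:
            raise KeyError(f"gene {gene!r} not in dataset")
        return int(idx[0])

    def cells_in_cluster(self, cluster: str) -> np.ndarray:
        """Boolean mask over cells for one cluster label."""
        return (self.cell_meta["cluster"] == cluster).to_numpy()

    def cell_mask(self, cell_ids: Sequence[str]) -> np.ndarray:
        wanted = set(cell_ids)
        return np.array([c in wanted for c in self.cell_ids])

    def subset_cells(self, mask: np.ndarray) -> "ExpressionDataset":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return ExpressionDataset(
            counts=self.counts[idx],
            gene_ids=self.gene_ids,
            cell_ids=self.cell_ids[idx],
            cell_meta=self.cell_meta.iloc[idx],
            norm=None if self.norm is None else self.norm[idx],
        )

    def norm_or_raise(self) -> np.ndarray:
        if self.norm is None:
            raise ValueError("dataset has no normalized layer; run log_normalize first")
        return self.norm

    def copy_with(self, **kw) -> "ExpressionDataset":
        return replace(self, **kw)


@dataclass(frozen=True)
class OrthologTable:
    """Many-to-many map from (species, gene_id) to a reference family symbol.

    Paralogs are first-class: e.g. zebrafish pbx3a and pbx3b both map to the
    human family PBX3, and a single gene may belong to several families.
    """

    table: pd.DataFrame  # columns: species, gene_id, family

    def __post_init__(self) -> None:
        missing = {"species", "gene_id", "family"} - set(self.table.columns)
        if missing:
            raise ValueError(f"ortholog table missing columns: {sorted(missing)}")
        if (self.table["family"].astype(str).str.len() == 0).any():
            raise ValueError("ortholog table has row with empty family")
        dedup = self.table.drop_duplicates(["species", "gene_id", "family"])
        object.__setattr__(self, "table", dedup.reset_index(drop=True))

    def species(self) -> list[str]:
        return sorted(self.table["species"].unique())

    def families_of(self, species: str, gene_id: str) -> list[str]:
        sel = (self.table["species"] == species) & (self.table["gene_id"] == gene_id)
        return sorted(self.table.loc[sel, "family"])

    def gene_to_families(self, species: str) -> dict[str, list[str]]:
        sub = self.table[self.table["species"] == species]
        return {g: sorted(d["family"]) for g, d in sub.groupby("gene_id")}

    def families(self) -> list[str]:
        return sorted(self.table["family"].unique())


@dataclass
class PipelineConfig:
    """Flat key->value bag of every tunable threshold, plus the global seed.

    Defaults are supplied by the stage-level config dataclasses; this object
    only carries overrides read from a TOML file or the CLI.
    """

    values: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        for key, val in self.values.items():
            if isinstance(val, (int, float)) and not isinstance(val, bool):
                if key.endswith(("_quantile", "_fraction")) and not 0 < val < 1:
                    raise ValueError(f"{key} must lie in (0,1), got {val}")
                if key.startswith(("min_", "max_", "k_")) and val <= 0:
                    raise ValueError(f"{key} must be strictly positive, got {val}")

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        seed = int(raw.pop("seed", 0))
        return cls(values=raw, seed=seed)

    def get(self, key: str, default=None):
        return self.values.get(key, default)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _read_id_column(path: str | Path, what: str) -> np.ndarray:
    ids = pd.read_csv(path, sep="\t", header=None, dtype=str)[0].to_numpy(dtype=object)
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate {what} id in {path}")
    return ids


def read_expression(
    matrix_path: str | Path,
    genes_path: str | Path,
    cells_path: str | Path,
    meta_path: str | Path | None = None,
) -> ExpressionDataset:
    """Read a 10x-style MTX triplet (+ optional metadata TSV) into memory.

    The on-disk matrix is genes x cells and is transposed on read. Cells
    present in the matrix but absent from the metadata get "NA" fields and a
    logged warning; a dimension mismatch between matrix and ID files is a
    hard error.
    """
    try:
        mat = scipy.io.mmread(str(matrix_path))
    except Exception as exc:  # malformed header, truncated file, ...
        raise ValueError(f"malformed MatrixMarket file {matrix_path}: {exc}") from exc
    counts = sp.csr_matrix(mat.T)
    gene_ids = _read_id_column(genes_path, "gene")
    cell_ids = _read_id_column(cells_path, "cell")
    if counts.shape[1] != len(gene_ids):
        raise ValueError(
            f"matrix {matrix_path} has {counts.shape[1]} genes but "
            f"{genes_path} lists {len(gene_ids)}"
        )
    if counts.shape[0] != len(cell_ids):
        raise ValueError(
            f"matrix {matrix_path} has {counts.shape[0]} cells but "
            f"{cells_path} lists {len(cell_ids)}"
        )
    if counts.nnz and not np.allclose(counts.data, np.round(counts.data)):
        raise ValueError(f"matrix {matrix_path} has non-integer entries")
    counts = counts.astype(np.int64)
    if counts.nnz == 0:
        logger.warning("matrix %s has no stored entries (all-zero counts)", matrix_path)

    if meta_path is not None:
        meta = pd.read_csv(meta_path, sep="\t", dtype=str)
        if "cell_id" not in meta.columns:
            raise ValueError(f"metadata {meta_path} lacks a cell_id column")
        meta = meta.set_index("cell_id")
    else:
        meta = pd.DataFrame(index=pd.Index([], name="cell_id"))
    meta = meta.reindex(cell_ids)
    n_missing = int(meta["cluster"].isna().sum()) if "cluster" in meta else len(meta)
    for col in META_COLUMNS:
        if col not in meta.columns:
            meta[col] = "NA"
    meta = meta[list(META_COLUMNS)].fillna("NA")
    if n_missing:
        logger.warning(
            "%d cell(s) in %s missing from metadata; fields set to NA",
            n_missing,
            matrix_path,
        )
    meta.index = pd.Index(cell_ids, name="cell_id")
    return ExpressionDataset(counts=counts, gene_ids=gene_ids, cell_ids=cell_ids, cell_meta=meta)


def write_expression(ds: ExpressionDataset, outdir: str | Path) -> None:
    """Write the MTX triplet + metadata TSV that :func:`read_expression` reads."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(outdir / "matrix.mtx"), sp.coo_matrix(ds.counts.T), field="integer")
    pd.Series(ds.gene_ids).to_csv(outdir / "genes.tsv", sep="\t", header=False, index=False)
    pd.Series(ds.cell_ids).to_csv(outdir / "barcodes.tsv", sep="\t", header=False, index=False)
    meta = ds.cell_meta.reset_index()
    meta.to_csv(outdir / "meta.tsv", sep="\t", index=False)


def read_expression_dir(indir: str | Path) -> ExpressionDataset:
    indir = Path(indir)
    return read_expression(
        indir / "matrix.mtx", indir / "genes.tsv", indir / "barcodes.tsv", indir / "meta.tsv"
    )


def read_ortholog_table(path: str | Path) -> OrthologTable:
    """Read the species/gene_id/family TSV, deduplicating exact repeats.

    Logs, per species, how many genes map to two or more families (paralogy
    going the other way round is expected and silent).
    """
    raw = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"species", "gene_id", "family"} - set(raw.columns)
    if missing:
        raise ValueError(f"ortholog table {path} missing columns: {sorted(missing)}")
    if raw["family"].isna().any() or (raw["family"].astype(str).str.len() == 0).any():
        raise ValueError(f"ortholog table {path} has row with empty family")
    table = OrthologTable(raw[["species", "gene_id", "family"]])
    multi = (
        table.table.groupby(["species", "gene_id"])["family"].nunique().pipe(lambda s: s[s >= 2])
    )
    for species, count in multi.groupby(level="species").size().items():
        logger.info("%s: %d gene(s) mapping to >=2 families", species, count)
    return table


# ---------------------------------------------------------------------------
# writer
# ---------------------------------------------------------------------------

def write_table(records: pd.DataFrame | Mapping | Sequence, path: str | Path) -> None:
    """Write any tabular result as UTF-8 TSV with a header.

    Column order follows the frame; floats are rendered with 9 significant
    digits so a read-back reproduces values well within 1e-6 relative.
    """
    df = records if isinstance(records, pd.DataFrame) else pd.DataFrame(records)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.9g", encoding="utf-8")
    logger.info("wrote %d row(s) to %s", len(df), path)
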