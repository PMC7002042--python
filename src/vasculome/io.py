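"""On-disk formats: count TSVs, sample metadata, MatrixMarket triplets, GMT
gene sets, YAML analysis configuration, and the ground-truth JSON sidecar."""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import io as spio
from scipy import sparse

from .containers import ExpressionMatrix
from .errors import ConfigurationError, DomainError, ParseError

__all__ = [
    "GeneSetCollection",
    "AnalysisConfig",
    "read_counts_tsv",
    "write_counts_tsv",
    "read_metadata_tsv",
    "write_metadata_tsv",
    "read_matrix_tsv",
    "write_matrix_tsv",
    "read_mtx",
    "write_mtx",
    "read_gmt",
    "write_gmt",
    "write_truth_json",
    "read_truth_json",
]


class GeneSetCollection:
    """Ordered named gene sets (GMT semantics): name -> (description, members)."""

    def __init__(self) -> None:
        self._sets: dict[str, tuple[str, list[str]]] = {}

    def add(self, name: str, members: list[str], description: str = "") -> None:
        if name in self._sets:
            raise DomainError(f"duplicate gene-set name {name!r}")
        seen: set[str] = set()
        dedup = [g for g in members if not (g in seen or seen.add(g))]
        n_dup = len(members) - len(dedup)
        if n_dup:
            warnings.warn(f"gene set {name!r}: removed {n_dup} duplicate members")
        self._sets[name] = (description, dedup)

    def names(self) -> list[str]:
        return list(self._sets)

    def members(self, name: str) -> list[str]:
        return list(self._sets[name][1])

    def description(self, name: str) -> str:
        return self._sets[name][0]

    def items(self):
        for name, (_, members) in self._sets.items():
            yield name, list(members)

    def __len__(self) -> int:
        return len(self._sets)

    def __contains__(self, name: str) -> bool:
        return name in self._sets

    def __eq__(self, other) -> bool:
        return isinstance(other, GeneSetCollection) and self._sets == other._sets


# ---------------------------------------------------------------------------
# TSV matrices and metadata
# ---------------------------------------------------------------------------


def write_counts_tsv(matrix: ExpressionMatrix, path: str | Path) -> None:
    out = matrix.values.copy()
    if matrix.scale == "counts":
        out = out.astype(np.int64)
    out.index.name = "gene"
    out.to_csv(path, sep="\t", float_format="%.6g", lineterminator="\n")


write_matrix_tsv = write_counts_tsv


def _read_tsv_matrix(path: str | Path, scale: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"file not found: {path}")
    if path.stat().st_size == 0:
        raise ParseError(f"empty file: {path}")
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:  # noqa: BLE001 - wrap any pandas parse failure
        raise ParseError(f"could not parse {path}: {exc}") from exc
    if df.shape[1] == 0:
        raise ParseError(f"{path}: no sample columns found")
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ParseError(f"{path}: duplicated gene row {dup!r}")
    non_numeric = df.columns[df.dtypes == object]
    if len(non_numeric):
        for col in non_numeric:
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            if len(bad):
                line = df.index.get_loc(bad.index[0]) + 2
                raise ParseError(f"{path}: non-numeric cell at line {line}, column {col!r}")
        df = df.apply(pd.to_numeric)
    return df


def read_counts_tsv(path: str | Path, metadata: pd.DataFrame | None = None) -> ExpressionMatrix:
    df = _read_tsv_matrix(path, "counts")
    if metadata is None:
        metadata = pd.DataFrame(index=df.columns)
    return ExpressionMatrix(values=df, samples=metadata.loc[df.columns], scale="counts")


def read_matrix_tsv(path: str | Path, scale: str = "log2", metadata: pd.DataFrame | None = None) -> ExpressionMatrix:
    df = _read_tsv_matrix(path, scale)
    if metadata is None:
        metadata = pd.DataFrame(index=df.columns)
    return ExpressionMatrix(values=df, samples=metadata.loc[df.columns], scale=scale)


def write_metadata_tsv(matrix: ExpressionMatrix, path: str | Path) -> None:
    meta = matrix.samples.copy()
    meta.index.name = "sample_id"
    meta.to_csv(path, sep="\t", lineterminator="\n")


def read_metadata_tsv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"file not found: {path}")
    meta = pd.read_csv(path, sep="\t", index_col=0)
    return meta


# ---------------------------------------------------------------------------
# MatrixMarket single-cell triplets
# ---------------------------------------------------------------------------


def write_mtx(matrix: ExpressionMatrix, out_dir: str | Path) -> None:
    """Write counts as matrix.mtx (genes x cells) + genes.tsv + cells.tsv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sp = sparse.csc_matrix(matrix.values.to_numpy())
    spio.mmwrite(str(out / "matrix.mtx"), sp, field="integer" if matrix.scale == "counts" else "real")
    pd.Series(matrix.gene_ids).to_csv(out / "genes.tsv", sep="\t", index=False, header=["gene"], lineterminator="\n")
    cells = matrix.samples.copy()
    cells.index.name = "cell_id"
    cells.to_csv(out / "cells.tsv", sep="\t", lineterminator="\n")


def read_mtx(dir_or_paths: str | Path | tuple) -> ExpressionMatrix:
    """Read a MatrixMarket triplet directory (matrix.mtx, genes.tsv, cells.tsv).

    MatrixMarket stores 1-based coordinates; they are mapped to 0-based
    internal addressing.  Dimensions must match the annotation files.
    """
    if isinstance(dir_or_paths, (str, Path)):
        d = Path(dir_or_paths)
        mtx_path, genes_path, cells_path = d / "matrix.mtx", d / "genes.tsv", d / "cells.tsv"
    else:
        mtx_path, genes_path, cells_path = (Path(p) for p in dir_or_paths)
    for p in (mtx_path, genes_path, cells_path):
        if not p.exists():
            raise ParseError(f"file not found: {p}")
    try:
        mat = spio.mmread(str(mtx_path)).tocsc()
    except Exception as exc:  # noqa: BLE001
        raise ParseError(f"could not parse {mtx_path}: {exc}") from exc
    genes = pd.read_csv(genes_path, sep="\t")
    gene_ids = genes.iloc[:, 0].astype(str)
    cells = pd.read_csv(cells_path, sep="\t", index_col=0)
    if mat.shape != (len(gene_ids), len(cells)):
        raise ParseError(
            f"dimension mismatch: matrix is {mat.shape}, annotations describe "
            f"({len(gene_ids)}, {len(cells)})"
        )
    values = pd.DataFrame(
        mat.toarray(), index=pd.Index(gene_ids, name="gene"), columns=cells.index
    )
    scale = "counts" if np.allclose(values.to_numpy() % 1, 0) else "log2"
    if scale == "counts":
        values = values.astype(np.int64)
    return ExpressionMatrix(values=values, samples=cells, scale=scale)


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------


def read_gmt(path: str | Path) -> GeneSetCollection:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"file not found: {path}")
    coll = GeneSetCollection()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >= 3 tab-separated fields")
            name, desc, *members = fields
            coll.add(name, [m for m in members if m], description=desc)
    return coll


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in collection.names():
            fields = [name, collection.description(name), *collection.members(name)]
            fh.write("\t".join(fields) + "\n")


def read_gene_list(path: str | Path) -> list[str]:
    """One-gene-per-line list."""
    path = Path(path)
    if not path.exists():
        raise ParseError(f"file not found: {path}")
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_gene_list(genes: list[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(g + "\n")


# ---------------------------------------------------------------------------
# Differential-expression tables
# ---------------------------------------------------------------------------


def write_de_table(table, path: str | Path) -> None:
    """Fixed column order: gene, logFC, t, p, q, mean_expr."""
    from .containers import DifferentialTable

    tab = table.table if isinstance(table, DifferentialTable) else table
    out = tab[["logFC", "t", "p", "q", "mean_expr"]].copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t", float_format="%.6g", lineterminator="\n")


def read_de_table(path: str | Path, contrast: str = "") -> "DifferentialTable":
    from .containers import DifferentialTable

    df = _read_tsv_matrix(path, "log2")
    return DifferentialTable(table=df, contrast=contrast or Path(path).stem)


# ---------------------------------------------------------------------------
# Analysis configuration
# ---------------------------------------------------------------------------


@dataclass
class AnalysisConfig:
    """Pipeline thresholds (the analysis constants of the study design)."""

    fdr_max: float = 0.05
    logfc_min_gsea: float = 1.0
    top_k_markers: int = 10
    top_k_go: int = 20
    top_k_overlap: int = 50
    sc_min_cell_fraction: float = 0.10
    purity_k: int = 500
    pseudocount: float = 0.5
    n_perm: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.fdr_max < 1:
            raise ConfigurationError("fdr_max must lie in (0, 1)")
        if not 0 <= self.sc_min_cell_fraction <= 1:
            raise ConfigurationError("sc_min_cell_fraction must lie in [0, 1]")
        for name in ("top_k_markers", "top_k_go", "top_k_overlap", "purity_k", "n_perm"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(data) - known)
        if unknown:
            raise ConfigurationError(f"unknown configuration keys: {unknown}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# Ground-truth sidecar
# ---------------------------------------------------------------------------


def write_truth_json(truth, path: str | Path) -> None:
    data = {
        "contamination_fraction_f": truth.contamination_fraction_f,
        "kinetic_amplitude_log2": truth.kinetic_amplitude_log2,
        "roles": truth.roles.to_dict(),
        "role_tissue": truth.role_tissue.to_dict(),
        "housekeeping_genes": truth.housekeeping_genes,
        "ec_marker_genes": truth.ec_marker_genes,
        "surface_catalog": truth.surface_catalog,
        "pan_preferred_tissue": truth.pan_preferred_tissue.to_dict(),
        "kinetic_patterns": [
            {"gene": g, "tissue": t, "pattern": p} for (g, t), p in sorted(truth.kinetic_patterns.items())
        ],
    }
    with open(path, "w") as fh:
        json.dump(data, fh, indent=1, sort_keys=True)


def read_truth_json(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
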