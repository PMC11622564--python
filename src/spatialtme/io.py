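"""Readers/writers for the external formats and the canonical in-memory model.

The canonical data model is:

* a *cell table*: a :class:`pandas.DataFrame` with one row per cell and columns
  ``cell_id`` (unique), ``fov_id``, ``sample_id``, ``patient_id``,
  ``compartment`` (``tumor``/``stroma``), ``cohort``, ``x``/``y`` (µm),
  ``area`` (µm², positive) and optionally ``phenotype``;
* a *dataset*: an :class:`anndata.AnnData` whose ``obs`` is the cell table,
  ``X`` holds sparse raw integer counts (cells × genes), and
  ``obsm["spatial"]`` carries the µm coordinates.  The variance-stabilized
  layer added by :func:`spatialtme.qc.normalize` lives in
  ``layers["normalized"]``.

Coordinates are stored in µm throughout.  Instrument pixel coordinates are
converted on read with a configurable pixel size (default 0.18 µm/px, i.e.
150 px = 27 µm).
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .errors import IntegrityError, ParseError, SchemaError

logger = logging.getLogger(__name__)

DEFAULT_PIXEL_SIZE = 0.18  # µm per pixel: 150 px ↔ 27 µm

REQUIRED_CELL_COLUMNS = (
    "cell_id",
    "fov_id",
    "sample_id",
    "patient_id",
    "compartment",
    "cohort",
    "area",
)
COMPARTMENTS = ("tumor", "stroma")
COHORTS = ("io_naive_nonsarc", "io_naive_sarc", "io_exposed")


def read_cell_table(path: str | Path, pixel_size: float = DEFAULT_PIXEL_SIZE) -> pd.DataFrame:
    """Read a per-cell CSV and return the canonical cell table (µm coordinates).

    Coordinates may be given either as ``x_um``/``y_um`` (already in µm, taken
    as-is) or as ``x``/``y`` or ``x_px``/``y_px`` pixel coordinates, which are
    multiplied by ``pixel_size``.
    """
    if pixel_size <= 0:
        raise SchemaError("pixel_size must be > 0")
    try:
        df = pd.read_csv(path, dtype={"cell_id": str, "fov_id": str})
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"empty cell table file: {path}") from exc
    missing = [c for c in REQUIRED_CELL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"cell table missing required column(s): {', '.join(missing)}")
    if "x_um" in df.columns and "y_um" in df.columns:
        df = df.rename(columns={"x_um": "x", "y_um": "y"})
    elif "x_px" in df.columns and "y_px" in df.columns:
        df["x"] = df["x_px"].astype(float) * pixel_size
        df["y"] = df["y_px"].astype(float) * pixel_size
        df = df.drop(columns=["x_px", "y_px"])
    elif "x" in df.columns and "y" in df.columns:
        df["x"] = df["x"].astype(float) * pixel_size
        df["y"] = df["y"].astype(float) * pixel_size
    else:
        raise SchemaError("cell table missing coordinate columns (x/y, x_px/y_px or x_um/y_um)")
    return validate_cell_table(df)


def validate_cell_table(df: pd.DataFrame) -> pd.DataFrame:
    """Check cell-table invariants; returns the (possibly re-typed) table."""
    missing = [c for c in REQUIRED_CELL_COLUMNS + ("x", "y") if c not in df.columns]
    if missing:
        raise SchemaError(f"cell table missing required column(s): {', '.join(missing)}")
    df = df.copy()
    df["cell_id"] = df["cell_id"].astype(str)
    if df["cell_id"].duplicated().any():
        dup = df["cell_id"][df["cell_id"].duplicated()].iloc[0]
        raise IntegrityError(f"duplicate cell_id: {dup!r}")
    for col in ("x", "y"):
        if not np.isfinite(df[col].to_numpy(dtype=float)).all():
            raise IntegrityError(f"non-finite values in column {col!r}")
    if (df["area"].to_numpy(dtype=float) <= 0).any():
        raise IntegrityError("cell areas must be > 0")
    bad = set(df["compartment"]) - set(COMPARTMENTS)
    if bad:
        raise SchemaError(f"unknown compartment value(s): {sorted(bad)}")
    bad = set(df["cohort"]) - set(COHORTS)
    if bad:
        raise SchemaError(f"unknown cohort value(s): {sorted(bad)}")
    ncoh = df.groupby("patient_id", observed=True)["cohort"].nunique()
    if (ncoh > 1).any():
        pid = ncoh[ncoh > 1].index[0]
        raise IntegrityError(f"patient {pid!r} appears in more than one cohort")
    if "phenotype" not in df.columns:
        df["phenotype"] = pd.Series([None] * len(df), dtype=object)
    return df.reset_index(drop=True)


def write_cell_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a cell table as CSV with µm coordinates (columns ``x_um``/``y_um``)."""
    out = df.rename(columns={"x": "x_um", "y": "y_um"})
    out.to_csv(path, index=False)


def read_counts(
    path: str | Path,
    cell_ids: pd.Index | list[str] | None = None,
) -> tuple[sp.csr_matrix, list[str], list[str]]:
    """Read raw counts as a sparse cells × genes integer matrix.

    Two on-disk layouts are supported:

    * MatrixMarket triplet (``*.mtx``, rows = cells) with sibling
      ``features.tsv``/``genes.tsv`` (gene symbols) and ``barcodes.tsv``
      (cell ids) files in the same directory;
    * wide CSV with a leading cell-id column and one column per gene.

    If ``cell_ids`` is given, rows are aligned to that order; a barcode
    missing from ``cell_ids`` — or vice versa — is an integrity error.

    Returns ``(matrix, barcodes, genes)`` with rows in the aligned order.
    """
    path = Path(path)
    if path.suffix == ".mtx":
        mat = scipy.io.mmread(str(path))
        folder = path.parent
        feat = _first_existing(folder, ("features.tsv", "genes.tsv"))
        bc = _first_existing(folder, ("barcodes.tsv",))
        genes = [ln.rstrip("\n").split("\t")[0] for ln in _read_lines(feat) if ln.strip()]
        barcodes = [ln.rstrip("\n").split("\t")[0] for ln in _read_lines(bc) if ln.strip()]
        mat = sp.csr_matrix(mat)
        if mat.shape != (len(barcodes), len(genes)):
            raise IntegrityError(
                f"matrix shape {mat.shape} does not match {len(barcodes)} barcodes × {len(genes)} features"
            )
    else:
        df = pd.read_csv(path, index_col=0)
        genes = [str(g) for g in df.columns]
        barcodes = [str(b) for b in df.index]
        mat = sp.csr_matrix(df.to_numpy())
    data = mat.data
    if data.size and (np.any(data < 0) or np.any(data != np.round(data))):
        raise IntegrityError("raw counts must be nonnegative integers")
    mat = mat.astype(np.int64).tocsr()
    if cell_ids is not None:
        cell_ids = [str(c) for c in cell_ids]
        pos = {b: i for i, b in enumerate(barcodes)}
        unknown = set(barcodes) - set(cell_ids)
        if unknown:
            raise IntegrityError(f"barcode(s) absent from cell table: {sorted(unknown)[:5]}")
        try:
            order = [pos[c] for c in cell_ids]
        except KeyError as exc:
            raise IntegrityError(f"cell {exc.args[0]!r} has no row in the count matrix") from exc
        mat = mat[order]
        barcodes = list(cell_ids)
    return mat, barcodes, genes


def write_counts(matrix: sp.spmatrix, barcodes: list[str], genes: list[str], path: str | Path) -> None:
    """Write counts as MatrixMarket triplet + features.tsv/barcodes.tsv siblings."""
    path = Path(path)
    scipy.io.mmwrite(str(path), sp.coo_matrix(matrix), field="integer")
    (path.parent / "features.tsv").write_text("".join(g + "\n" for g in genes))
    (path.parent / "barcodes.tsv").write_text("".join(b + "\n" for b in barcodes))


def build_dataset(cells: pd.DataFrame, counts: sp.spmatrix, genes: list[str]) -> ad.AnnData:
    """Assemble the canonical AnnData dataset from a cell table and counts."""
    cells = validate_cell_table(cells)
    if counts.shape[0] != len(cells):
        raise IntegrityError(
            f"count matrix has {counts.shape[0]} rows for {len(cells)} cells"
        )
    if counts.shape[1] != len(genes):
        raise IntegrityError("gene list length does not match count matrix columns")
    obs = cells.set_index("cell_id")
    obs.index = obs.index.astype(str)
    adata = ad.AnnData(
        X=sp.csr_matrix(counts, dtype=np.int64),
        obs=obs,
        var=pd.DataFrame(index=pd.Index([g.strip() for g in genes], name="gene")),
    )
    adata.obsm["spatial"] = obs[["x", "y"]].to_numpy(dtype=float)
    return adata


def load_dataset(
    directory: str | Path,
    pixel_size: float = DEFAULT_PIXEL_SIZE,
    cells_file: str = "cells.csv",
    counts_file: str = "counts.mtx",
) -> ad.AnnData:
    """Load a dataset directory (cells.csv + counts.mtx triplet) into AnnData."""
    directory = Path(directory)
    cells = read_cell_table(directory / cells_file, pixel_size=pixel_size)
    counts, _, genes = read_counts(directory / counts_file, cell_ids=cells["cell_id"])
    return build_dataset(cells, counts, genes)


def save_dataset(adata: ad.AnnData, directory: str | Path) -> None:
    """Write an AnnData dataset back to the cells.csv + counts.mtx layout."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    cells = adata.obs.reset_index().rename(columns={adata.obs.index.name or "index": "cell_id"})
    write_cell_table(cells, directory / "cells.csv")
    write_counts(adata.X, list(adata.obs_names), list(adata.var_names), directory / "counts.mtx")


def read_gene_sets(path: str | Path) -> dict[str, list[str]]:
    """Parse a GMT file (``name<TAB>description<TAB>gene...``) into named sets.

    Duplicate genes within a set are dropped (first occurrence kept) with a
    warning; empty sets or malformed lines raise :class:`ParseError` with the
    line number.
    """
    sets: dict[str, list[str]] = {}
    for lineno, line in enumerate(_read_lines(Path(path)), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ParseError(f"{path}:{lineno}: GMT line needs name, description and ≥1 gene")
        name = parts[0].strip()
        genes: list[str] = []
        seen: set[str] = set()
        for g in parts[2:]:
            g = g.strip()
            if not g:
                continue
            if g in seen:
                warnings.warn(f"duplicate gene {g!r} in set {name!r} dropped", stacklevel=2)
                continue
            seen.add(g)
            genes.append(g)
        if not genes:
            raise ParseError(f"{path}:{lineno}: gene set {name!r} is empty")
        sets[name] = genes
    return sets


def read_lr_pairs(path: str | Path) -> pd.DataFrame:
    """Read a ligand–receptor pair TSV with columns ligand, receptor[, source_set].

    Duplicate (ligand, receptor) rows are collapsed to one with a warning.
    """
    df = pd.read_csv(path, sep="\t")
    for col in ("ligand", "receptor"):
        if col not in df.columns:
            raise SchemaError(f"ligand-receptor table missing column {col!r}")
    if "source_set" not in df.columns:
        df["source_set"] = ""
    df["ligand"] = df["ligand"].astype(str).str.strip()
    df["receptor"] = df["receptor"].astype(str).str.strip()
    dups = df.duplicated(subset=["ligand", "receptor"])
    if dups.any():
        warnings.warn(f"{int(dups.sum())} duplicate ligand-receptor row(s) dropped", stacklevel=2)
        df = df[~dups]
    return df[["ligand", "receptor", "source_set"]].reset_index(drop=True)


def read_phenotype_map(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV mapping fine phenotype labels to collapsed ones."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise SchemaError("phenotype map needs two columns (fine, collapsed)")
    fine, collapsed = df.columns[:2]
    return dict(zip(df[fine].astype(str), df[collapsed].astype(str)))


def collapse_phenotypes(cells: pd.DataFrame, mapping: dict[str, str]) -> pd.DataFrame:
    """Remap fine phenotype labels to collapsed ones.

    The map is total over the input: labels absent from ``mapping`` pass
    through unchanged (logged).  Row count and all other columns are
    preserved.
    """
    out = cells.copy()
    labels = out["phenotype"]
    unmapped = sorted(set(labels.dropna()) - set(mapping))
    if unmapped:
        logger.info("phenotype labels passed through unmapped: %s", unmapped)
    out["phenotype"] = labels.map(lambda v: mapping.get(v, v) if pd.notna(v) else v)
    return out


def write_result_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a long-format statistics table as TSV with header."""
    df.to_csv(path, sep="\t", index=False)


def _first_existing(folder: Path, names: tuple[str, ...]) -> Path:
    for name in names:
        p = folder / name
        if p.exists():
            return p
    raise SchemaError(f"none of {names} found next to matrix in {folder}")


def _read_lines(path: Path) -> list[str]:
    with open(path) as fh:
        return fh.readlines()
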