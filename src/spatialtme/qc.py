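"""Cell/FOV quality filters and variance-stabilizing normalization.

Cells with fewer than 20 transcripts, or with an area greater than five times
the geometric mean cell area (a segmentation-error signature), are removed;
fields of view left with fewer than 5 cells are treated as failed assays and
dropped whole.  Counts are then converted to analytic negative-binomial
Pearson residuals — a variance-stabilized expression layer that removes the
technical cell-to-cell depth variation that raw counts carry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import scipy.sparse as sp

from .errors import IntegrityError

NORMALIZED_LAYER = "normalized"


@dataclass
class QCReport:
    """Bookkeeping for one filtering pass; ``n_cells_in - removed = n_cells_out``."""

    n_cells_in: int
    n_cells_out: int
    removed_low_count: int = 0
    removed_large_area: int = 0
    fovs_dropped: list[str] = field(default_factory=list)
    per_fov_retained: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if min(self.n_cells_in, self.n_cells_out, self.removed_low_count, self.removed_large_area) < 0:
            raise IntegrityError("QC report counts must be nonnegative")
        if self.n_cells_out > self.n_cells_in:
            raise IntegrityError("QC report arithmetic is inconsistent")

    @property
    def n_removed(self) -> int:
        return self.n_cells_in - self.n_cells_out


def filter_cells(
    adata: ad.AnnData,
    min_counts: int = 20,
    area_factor: float = 5.0,
) -> tuple[ad.AnnData, QCReport]:
    """Remove low-count cells and abnormally large cells.

    A cell is removed if its total transcript count is strictly below
    ``min_counts`` (so a 19-count cell goes, a 20-count cell stays), or if its
    area exceeds ``area_factor`` times the geometric mean area.  The geometric
    mean is computed over the whole dataset on cells that pass the count
    filter, so one segmentation blob cannot inflate its own cutoff via cells
    that are about to be discarded anyway.
    """
    totals = np.asarray(adata.X.sum(axis=1)).ravel()
    pass_counts = totals >= min_counts
    areas = adata.obs["area"].to_numpy(dtype=float)
    if math.isinf(area_factor):
        pass_area = np.ones(len(adata), dtype=bool)
    else:
        if not pass_counts.any():
            raise IntegrityError("all cells removed by the count filter")
        geomean = float(np.exp(np.mean(np.log(areas[pass_counts]))))
        pass_area = areas <= area_factor * geomean
    keep = pass_counts & pass_area
    if not keep.any():
        raise IntegrityError("quality filters removed every cell")
    report = QCReport(
        n_cells_in=int(len(adata)),
        n_cells_out=int(keep.sum()),
        removed_low_count=int((~pass_counts).sum()),
        removed_large_area=int((pass_counts & ~pass_area).sum()),
        per_fov_retained=adata.obs.loc[keep, "fov_id"].value_counts().to_dict(),
    )
    return adata[keep].copy(), report


def filter_fovs(adata: ad.AnnData, min_cells: int = 5) -> tuple[ad.AnnData, QCReport]:
    """Drop entire fields of view that retain fewer than ``min_cells`` cells."""
    sizes = adata.obs["fov_id"].value_counts()
    bad = sizes[sizes < min_cells].index.tolist()
    keep = ~adata.obs["fov_id"].isin(bad).to_numpy()
    if not keep.any():
        raise IntegrityError("FOV filter removed every cell")
    report = QCReport(
        n_cells_in=int(len(adata)),
        n_cells_out=int(keep.sum()),
        fovs_dropped=sorted(str(f) for f in bad),
        per_fov_retained=adata.obs.loc[keep, "fov_id"].value_counts().to_dict(),
    )
    return adata[keep].copy(), report


def normalize(
    adata: ad.AnnData,
    theta: float = 100.0,
    clip: float | None = None,
    chunk_size: int = 20_000,
) -> ad.AnnData:
    """Add an analytic NB Pearson-residual layer (``layers["normalized"]``).

    For cell *j* with library size ``L_j`` and gene *g* with overall fraction
    ``p_g`` of the grand total, the expected count is ``mu = L_j * p_g`` and
    the residual is ``(x - mu) / sqrt(mu + mu**2 / theta)``, clipped to
    ``±clip`` (default ``sqrt(n_cells)``).  Genes with zero total count get
    residual 0 everywhere.  ``theta=inf`` gives the Poisson special case.
    """
    X = sp.csr_matrix(adata.X)
    n, g = X.shape
    if clip is None:
        clip = math.sqrt(n)
    L = np.asarray(X.sum(axis=1), dtype=float).ravel()
    gene_tot = np.asarray(X.sum(axis=0), dtype=float).ravel()
    grand = gene_tot.sum()
    if grand <= 0:
        raise IntegrityError("count matrix is all zero")
    p = gene_tot / grand
    nonzero = p > 0
    out = np.zeros((n, g), dtype=np.float32)
    for start in range(0, n, chunk_size):
        stop = min(n, start + chunk_size)
        x = np.asarray(X[start:stop].todense(), dtype=float)
        mu = np.outer(L[start:stop], p)
        with np.errstate(divide="ignore", invalid="ignore"):
            if math.isinf(theta):
                denom = np.sqrt(mu)
            else:
                denom = np.sqrt(mu + mu * mu / theta)
            res = (x - mu) / denom
        res[:, ~nonzero] = 0.0
        res[~np.isfinite(res)] = 0.0
        np.clip(res, -clip, clip, out=res)
        out[start:stop] = res.astype(np.float32)
    adata.layers[NORMALIZED_LAYER] = out
    adata.uns["normalization"] = {"method": "nb_pearson", "theta": theta, "clip": float(clip)}
    return adata


def run_qc(
    adata: ad.AnnData,
    min_counts: int = 20,
    area_factor: float = 5.0,
    min_fov_cells: int = 5,
    theta: float = 100.0,
) -> tuple[ad.AnnData, QCReport, QCReport]:
    """Convenience wrapper: cell filter → FOV filter → normalization."""
    adata, cell_report = filter_cells(adata, min_counts=min_counts, area_factor=area_factor)
    adata, fov_report = filter_fovs(adata, min_cells=min_fov_cells)
    adata = normalize(adata, theta=theta)
    return adata, cell_report, fov_report
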