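"""Per-FOV spatial statistics.

* k-nearest-neighbor binary spatial weights (default k = 3);
* Ripley's K pair-count statistic and its empirical-CSR adjustment, the
  "degree of clustering exact" (DOCE): phenotype K minus the all-cells K of
  the same FOV at the same radius (default r = 27 µm, i.e. 150 px);
* per-cell gene-set scores and a permutation test for spatial aggregation of
  high-scoring cells (hotspots);
* bivariate Moran's I for ligand–receptor spatial autocorrelation.

All statistics are computed within a single field of view; cross-FOV
comparisons live in :mod:`spatialtme.differential`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist, squareform

from .errors import ConfigError
from .qc import NORMALIZED_LAYER

logger = logging.getLogger(__name__)

DEFAULT_RADIUS_UM = 27.0  # 150 px at 0.18 µm/px


@dataclass
class SpatialWeights:
    """Binary kNN weights for one FOV: row i's neighbors get weight 1 each."""

    neighbors: np.ndarray  # (n, k) int, no self-neighbors
    k: int
    symmetrized: bool = False
    matrix: sp.csr_matrix = field(init=False, repr=False)

    def __post_init__(self) -> None:
        n, k = self.neighbors.shape
        if k != self.k:
            raise ConfigError("neighbor array width does not match k")
        rows = np.repeat(np.arange(n), k)
        cols = self.neighbors.ravel()
        if np.any(rows == cols):
            raise ConfigError("self-neighbors are not allowed")
        W = sp.csr_matrix((np.ones(n * k), (rows, cols)), shape=(n, n))
        if self.symmetrized:
            W = W.maximum(W.T)
        self.matrix = W

    @property
    def n(self) -> int:
        return self.neighbors.shape[0]

    @property
    def s0(self) -> float:
        """Total weight; k·n for the unsymmetrized graph."""
        return float(self.matrix.sum())


def knn_weights(coords: np.ndarray, k: int = 3, symmetrize: bool = False) -> SpatialWeights:
    """Exact Euclidean k-nearest neighbors with ties broken by ascending index.

    Requires at least k+1 cells.  For small FOVs the full distance matrix is
    used (stable, index-ordered); larger FOVs use a KD-tree with enough
    padding that distance ties are re-ordered by index before truncation.
    """
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    if n <= k:
        raise ConfigError(f"kNN weights need at least {k + 1} cells, got {n}")
    if n <= 2000:
        d = squareform(pdist(coords))
        np.fill_diagonal(d, np.inf)
        # stable sort on distance keeps ascending-index order within ties
        nbrs = np.argsort(d, axis=1, kind="stable")[:, :k]
    else:
        pad = min(n, k + 16)
        tree = cKDTree(coords)
        dist, idx = tree.query(coords, k=pad)
        nbrs = np.empty((n, k), dtype=int)
        for i in range(n):
            di, ii = dist[i], idx[i]
            mask = ii != i
            di, ii = di[mask], ii[mask]
            order = np.lexsort((ii, np.round(di, 9)))
            nbrs[i] = ii[order][:k]
    return SpatialWeights(neighbors=nbrs, k=k, symmetrized=symmetrize)


def ripley_k(
    coords: np.ndarray,
    mask: np.ndarray | None,
    r: float,
    area: float,
) -> float | None:
    """Ripley's K pair-count statistic, no analytic edge correction.

    ``K(r) = area / (m (m-1)) * #{ordered pairs i≠j in subset with d_ij <= r}``.
    Returns None when the subset has fewer than two points (undefined).
    """
    coords = np.asarray(coords, dtype=float)
    pts = coords if mask is None else coords[np.asarray(mask, dtype=bool)]
    m = len(pts)
    if m < 2:
        return None
    if area <= 0 or r < 0:
        raise ConfigError("area must be > 0 and radius >= 0")
    tree = cKDTree(pts)
    n_unordered = tree.count_neighbors(tree, r) - m  # remove self-pairs
    return float(area * n_unordered / (m * (m - 1)))


@dataclass
class DoceResult:
    fov_id: str
    phenotype: str
    r: float
    k_pheno: float | None
    k_all: float | None
    doce: float | None
    n_pheno: int
    reason: str | None = None


def doce(
    coords: np.ndarray,
    labels: np.ndarray,
    phenotype: str,
    r: float = DEFAULT_RADIUS_UM,
    area: float | None = None,
    fov_id: str = "",
) -> DoceResult:
    """Degree of clustering exact: K(phenotype) − K(all cells) at radius r.

    The all-cells K acts as an empirical complete-spatial-randomness reference
    for the FOV, absorbing its geometry (holes, missing tissue) without an
    analytic edge correction.  ``area`` defaults to the coordinate bounding
    box.
    """
    coords = np.asarray(coords, dtype=float)
    labels = np.asarray(labels, dtype=object)
    if area is None:
        span = coords.max(axis=0) - coords.min(axis=0)
        area = float(span[0] * span[1])
    mask = labels == phenotype
    m = int(mask.sum())
    k_all = ripley_k(coords, None, r, area)
    k_ph = ripley_k(coords, mask, r, area)
    if k_ph is None or k_all is None:
        return DoceResult(fov_id, phenotype, r, k_ph, k_all, None, m, reason="fewer than 2 cells in subset")
    return DoceResult(fov_id, phenotype, r, k_ph, k_all, k_ph - k_all, m)


def doce_table(
    adata: ad.AnnData,
    r: float = DEFAULT_RADIUS_UM,
    area: float | None = None,
    phenotypes: list[str] | None = None,
    phenotype_col: str = "phenotype",
) -> pd.DataFrame:
    """DOCE for every (FOV, phenotype) combination; missing cases carry a reason."""
    rows = []
    for fid, obs in adata.obs.groupby("fov_id", observed=True):
        coords = adata[obs.index].obsm["spatial"]
        labels = obs[phenotype_col].to_numpy(dtype=object)
        phs = phenotypes if phenotypes is not None else sorted(pd.unique(labels.astype(str)))
        for ph in phs:
            res = doce(coords, labels, ph, r=r, area=area, fov_id=str(fid))
            rows.append(
                {
                    "fov_id": res.fov_id,
                    "phenotype": ph,
                    "r": r,
                    "k_pheno": res.k_pheno,
                    "k_all": res.k_all,
                    "doce": res.doce,
                    "n_pheno": res.n_pheno,
                    "reason": res.reason,
                }
            )
    return pd.DataFrame(rows)


def score_gene_set(
    norm_expr: np.ndarray,
    genes: list[str],
    set_genes: list[str],
    zscore: bool = True,
) -> np.ndarray | None:
    """Per-cell gene-set score: mean over set genes of per-gene z-scores.

    z-scoring is across the cells passed in (one FOV), making the downstream
    mean + 1 SD threshold scale-free; ``zscore=False`` gives the raw mean of
    the normalized expression instead.  Genes absent from the panel are
    dropped with a log message; fewer than 2 present genes → None (skipped).
    """
    idx = [genes.index(g) for g in set_genes if g in genes]
    missing = [g for g in set_genes if g not in genes]
    if missing:
        logger.info("gene-set genes absent from panel dropped: %s", missing)
    if len(idx) < 2:
        return None
    sub = np.asarray(norm_expr[:, idx], dtype=float)
    if zscore:
        mu = sub.mean(axis=0)
        sd = sub.std(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            sub = np.where(sd > 0, (sub - mu) / sd, 0.0)
    return sub.mean(axis=1)


@dataclass
class EnrichResult:
    fov_id: str
    set_name: str
    n_high: int
    observed_sum_distance: float | None
    p_empirical: float | None
    n_perm: int
    reason: str | None = None


def spatial_enrichment(
    scores: np.ndarray,
    coords: np.ndarray,
    n_perm: int = 1000,
    min_high: int = 5,
    rng: np.random.Generator | None = None,
    fov_id: str = "",
    set_name: str = "",
) -> EnrichResult:
    """Permutation test for spatial aggregation of high-scoring cells.

    Cells scoring above mean + 1 SD are the "high" set H; the observed
    statistic is the summed pairwise Euclidean distance within H (small =
    aggregated).  The null redraws |H| cells uniformly without replacement
    n_perm times; ``p = (1 + #{T_perm <= T_obs}) / (n_perm + 1)``.
    """
    rng = np.random.default_rng() if rng is None else rng
    scores = np.asarray(scores, dtype=float)
    coords = np.asarray(coords, dtype=float)
    sd = scores.std()
    if sd <= 0:
        return EnrichResult(fov_id, set_name, 0, None, None, n_perm, reason="zero score variance")
    high = scores > scores.mean() + sd
    n_high = int(high.sum())
    if n_high < min_high:
        return EnrichResult(fov_id, set_name, n_high, None, None, n_perm, reason="too few high cells")
    t_obs = float(pdist(coords[high]).sum())
    n = len(coords)
    le = 0
    for _ in range(n_perm):
        idx = rng.choice(n, size=n_high, replace=False)
        if pdist(coords[idx]).sum() <= t_obs:
            le += 1
    p = (1 + le) / (n_perm + 1)
    return EnrichResult(fov_id, set_name, n_high, t_obs, p, n_perm)


def enrichment_scan(
    adata: ad.AnnData,
    gene_sets: dict[str, list[str]],
    n_perm: int = 1000,
    min_high: int = 5,
    seed: int = 0,
    zscore: bool = True,
) -> pd.DataFrame:
    """Hotspot permutation test for every (FOV, gene set); long result table."""
    genes = list(adata.var_names)
    rows = []
    for fid, obs in adata.obs.groupby("fov_id", observed=True):
        sub = adata[obs.index]
        coords = sub.obsm["spatial"]
        expr = np.asarray(sub.layers[NORMALIZED_LAYER])
        for set_name, set_genes in gene_sets.items():
            rng = np.random.default_rng(
                np.random.SeedSequence([seed, _stable_hash(str(fid)), _stable_hash(set_name)])
            )
            scores = score_gene_set(expr, genes, set_genes, zscore=zscore)
            if scores is None:
                res = EnrichResult(str(fid), set_name, 0, None, None, n_perm, reason="fewer than 2 set genes in panel")
            else:
                res = spatial_enrichment(
                    scores, coords, n_perm=n_perm, min_high=min_high, rng=rng,
                    fov_id=str(fid), set_name=set_name,
                )
            rows.append(vars(res))
    return pd.DataFrame(rows)


def bivariate_moran(x: np.ndarray, y: np.ndarray, weights: SpatialWeights) -> float | None:
    """Bivariate Moran's I of x against its neighbors' y over binary kNN weights.

    ``I = (n / S0) * sum_i sum_{j in N(i)} (x_i - x̄)(y_j - ȳ)
    / sqrt(sum (x - x̄)² · sum (y - ȳ)²)``; ranges from −1 (inverse spatial
    coupling) to +1 (direct).  Returns None if either variable has zero
    variance on the FOV.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = weights.n
    if len(x) != n or len(y) != n:
        raise ConfigError("x/y length must match the weights")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum() * (yc**2).sum())
    if denom <= 0:
        return None
    num = float(xc @ (weights.matrix @ yc))
    return float(n / weights.s0 * num / denom)


def moran_pair_scan(
    adata: ad.AnnData,
    pairs: pd.DataFrame,
    k: int = 3,
    layer: str = NORMALIZED_LAYER,
) -> pd.DataFrame:
    """Bivariate Moran's I for every (FOV, ligand–receptor pair).

    Pairs with a gene absent from the panel, FOVs too small for the kNN graph,
    and zero-variance genes are recorded as missing with a reason.
    """
    genes = {g: i for i, g in enumerate(adata.var_names)}
    rows = []
    for fid, obs in adata.obs.groupby("fov_id", observed=True):
        sub = adata[obs.index]
        n = len(sub)
        weights = None
        if n > k:
            weights = knn_weights(sub.obsm["spatial"], k=k)
        expr = np.asarray(sub.layers[layer])
        for _, pair in pairs.iterrows():
            lig, rec = pair["ligand"], pair["receptor"]
            row = {"fov_id": str(fid), "ligand": lig, "receptor": rec, "n_cells": n,
                   "I": None, "reason": None}
            if lig not in genes or rec not in genes:
                row["reason"] = "gene absent from panel"
            elif weights is None:
                row["reason"] = f"FOV has <= {k} cells"
            else:
                i_val = bivariate_moran(expr[:, genes[lig]], expr[:, genes[rec]], weights)
                if i_val is None:
                    row["reason"] = "zero variance"
                else:
                    row["I"] = i_val
            rows.append(row)
    df = pd.DataFrame(rows)
    df["I"] = df["I"].astype(float)
    return df


def _stable_hash(text: str) -> int:
    """Deterministic 31-bit hash for seed derivation (process-independent)."""
    h = 2166136261
    for ch in text.encode():
        h = (h ^ ch) * 16777619 % (1 << 32)
    return h % (1 << 31)
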