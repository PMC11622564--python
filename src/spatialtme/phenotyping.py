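"""Reference-based cell phenotyping and cluster refinement.

Phenotypes are assigned from reference expression profiles built by rescaling
each reference cell to the largest library size and averaging per label.  The
assignment itself is a supervised multinomial naive-Bayes classifier on the
profile gene fractions: cell j gets ``argmax_k sum_g x_gj log pi_gk`` (the
library-size term is constant in k), with posterior probabilities from the
normalized likelihoods.  T-cell / mononuclear-phagocyte refinement is
PCA → shared-nearest-neighbor graph → Louvain communities, followed by
one-vs-rest Wilcoxon marker tests (|LFC| > 0.25, P < 0.004).
"""

from __future__ import annotations

import logging
import random
import warnings
from dataclasses import dataclass

import igraph as ig
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.special import logsumexp
from scipy.stats import mannwhitneyu
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .errors import ConfigError, IntegrityError

logger = logging.getLogger(__name__)

UNASSIGNED = "unassigned"


@dataclass
class ReferenceProfiles:
    """Phenotype × gene mean expression profiles plus the scaling target."""

    profiles: pd.DataFrame  # rows: phenotype, cols: gene
    target_library_size: float

    def __post_init__(self) -> None:
        if (self.profiles.to_numpy() < 0).any():
            raise IntegrityError("reference profiles must be nonnegative")
        zero = self.profiles.sum(axis=1) == 0
        if zero.any():
            raise IntegrityError(f"all-zero reference profile(s): {list(self.profiles.index[zero])}")


def build_reference(
    ref_expr: pd.DataFrame,
    ref_labels: pd.Series | np.ndarray,
    target: float | None = None,
) -> ReferenceProfiles:
    """Build phenotype profiles: rescale every cell to the largest library size,
    then average gene expression per label.

    ``ref_expr`` is cells × genes; ``target`` defaults to the largest cell
    total in the reference.
    """
    labels = pd.Series(np.asarray(ref_labels, dtype=object), index=ref_expr.index, name="label")
    if labels.isna().any():
        raise IntegrityError("reference labels contain missing values")
    totals = ref_expr.sum(axis=1).to_numpy(dtype=float)
    if (totals <= 0).any():
        raise IntegrityError("reference cells with zero total counts cannot be rescaled")
    if target is None:
        target = float(totals.max())
    if target <= 0:
        raise ConfigError("target library size must be > 0")
    scaled = ref_expr.to_numpy(dtype=float) * (target / totals)[:, None]
    scaled = pd.DataFrame(scaled, index=ref_expr.index, columns=ref_expr.columns)
    prof = scaled.groupby(labels, observed=True).mean()
    if (prof.sum(axis=1) == 0).any():
        raise IntegrityError("a label produced an all-zero profile")
    counts = labels.value_counts()
    if (counts == 0).any():
        raise IntegrityError("label with zero cells in reference")
    prof = prof.sort_index()
    prof.columns = [str(c).strip() for c in prof.columns]
    return ReferenceProfiles(profiles=prof, target_library_size=target)


def assign_phenotypes(
    counts: sp.spmatrix | np.ndarray,
    genes: list[str],
    reference: ReferenceProfiles,
    pseudo: float = 1e-10,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Multinomial naive-Bayes phenotype assignment on raw counts.

    Gene symbols are intersected case-sensitively (after stripping) between
    panel and reference.  Cells with zero counts on the shared genes are
    labeled ``"unassigned"`` with a uniform posterior.  Ties break to the
    lexicographically first label.  Returns (labels, posterior) with posterior
    rows summing to 1.
    """
    genes = [g.strip() for g in genes]
    shared = [g for g in genes if g in reference.profiles.columns]
    if not shared:
        raise ConfigError("no genes shared between panel and reference profiles")
    X = sp.csr_matrix(counts)[:, [genes.index(g) for g in shared]]
    prof = reference.profiles[shared].sort_index()  # lexicographic label order
    pi = prof.to_numpy(dtype=float) + pseudo
    pi = pi / pi.sum(axis=1, keepdims=True)
    loglik = np.asarray(X @ np.log(pi).T)  # cells × labels
    post = np.exp(loglik - logsumexp(loglik, axis=1, keepdims=True))
    labels = np.asarray(prof.index, dtype=object)[np.argmax(loglik, axis=1)]
    zero = np.asarray(X.sum(axis=1)).ravel() == 0
    if zero.any():
        labels[zero] = UNASSIGNED
        post[zero] = 1.0 / post.shape[1]
    posterior = pd.DataFrame(post, columns=list(prof.index))
    return labels, posterior


@dataclass
class ClusterResult:
    """Louvain subclustering output; cluster ids contiguous from 0 by size."""

    labels: np.ndarray
    pcs: np.ndarray
    n_pcs: int
    k_graph: int
    resolution: float
    seed: int


def subcluster(
    norm_expr: np.ndarray,
    n_pcs: int = 50,
    k_graph: int = 20,
    resolution: float = 1.0,
    seed: int = 0,
    snn_prune: float = 1 / 15,
) -> ClusterResult:
    """PCA → shared-nearest-neighbor graph → Louvain communities.

    ``norm_expr`` is the normalized layer restricted to the subset to refine
    (e.g. all T cells).  If the subset has fewer than ``n_pcs + 1`` cells the
    component count is reduced with a warning.  Deterministic for fixed seed.
    """
    X = np.asarray(norm_expr, dtype=float)
    n = len(X)
    if n < 3:
        raise ConfigError("subclustering needs at least 3 cells")
    if n < n_pcs + 1:
        warnings.warn(f"subset of {n} cells: reducing n_pcs from {n_pcs} to {n - 1}", stacklevel=2)
        n_pcs = n - 1
    n_pcs = min(n_pcs, X.shape[1])
    pcs = PCA(n_components=n_pcs, svd_solver="full", random_state=seed).fit_transform(X)
    k = min(k_graph, n - 1)
    nn = NearestNeighbors(n_neighbors=k).fit(pcs)
    knn = nn.kneighbors_graph(pcs, mode="connectivity")  # includes self? no: excludes
    # SNN edge weight: Jaccard overlap of neighbor lists (Seurat-style), pruned
    shared = (knn @ knn.T).tocoo()
    jac = shared.data / (2 * k - shared.data)
    keep = jac >= snn_prune
    src, dst, wts = shared.row[keep], shared.col[keep], jac[keep]
    mask = src < dst
    edges = list(zip(src[mask].tolist(), dst[mask].tolist()))
    graph = ig.Graph(n=n, edges=edges)
    graph.es["weight"] = wts[mask].tolist()
    ig.set_random_number_generator(random.Random(seed))
    part = graph.community_multilevel(weights="weight", resolution=resolution)
    labels = np.asarray(part.membership)
    # relabel contiguously by decreasing cluster size, ties by old id
    sizes = pd.Series(labels).value_counts()
    remap = {old: new for new, old in enumerate(sizes.sort_values(ascending=False).index)}
    labels = np.asarray([remap[v] for v in labels])
    return ClusterResult(labels=labels, pcs=pcs, n_pcs=n_pcs, k_graph=k, resolution=resolution, seed=seed)


def find_markers(
    norm_expr: np.ndarray,
    genes: list[str],
    cluster_labels: np.ndarray,
    lfc_min: float = 0.25,
    p_max: float = 0.004,
) -> pd.DataFrame:
    """One-vs-rest Wilcoxon marker test per cluster on the normalized layer.

    The log-fold change analogue is ``log((mean(expm1(in)) + 1) /
    (mean(expm1(out)) + 1))`` on the normalized values.  Rows with
    ``|lfc| > lfc_min`` and ``p < p_max`` carry ``is_marker = True``.
    Clusters of a single cell are skipped with a warning.  Invariant to
    cluster relabeling.
    """
    X = np.asarray(norm_expr, dtype=float)
    labels = np.asarray(cluster_labels)
    uniq = sorted(pd.unique(labels).tolist(), key=str)
    if len(uniq) < 2:
        raise ConfigError("marker testing needs at least 2 clusters")
    rows = []
    # guard expm1 against overflow for extreme clipped residuals
    E = np.expm1(np.minimum(X, 80.0))
    for cl in uniq:
        mask = labels == cl
        if mask.sum() < 2:
            warnings.warn(f"cluster {cl!r} has fewer than 2 cells; skipped", stacklevel=2)
            continue
        if (~mask).sum() < 2:
            warnings.warn(f"complement of cluster {cl!r} has fewer than 2 cells; skipped", stacklevel=2)
            continue
        x_in, x_out = X[mask], X[~mask]
        with np.errstate(invalid="ignore"):
            stat, p = mannwhitneyu(x_in, x_out, axis=0, alternative="two-sided")
        lfc = np.log((E[mask].mean(axis=0) + 1.0) / (E[~mask].mean(axis=0) + 1.0))
        df = pd.DataFrame(
            {
                "cluster": cl,
                "gene": genes,
                "lfc": lfc,
                "statistic": stat,
                "p": p,
            }
        )
        rows.append(df)
    out = pd.concat(rows, ignore_index=True)
    out["p"] = out["p"].fillna(1.0)
    out["is_marker"] = (out["lfc"].abs() > lfc_min) & (out["p"] < p_max)
    return out
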