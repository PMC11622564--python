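"""Malignant-cell identification by VEGFA-seeded LASSO logistic regression.

Clear-cell RCC arises from the proximal tubule and overexpresses VEGFA, so
proximal-tubule cells on tumor-compartment FOVs whose FOV-mean VEGFA falls in
the top tercile are seeded as MALIGNANT, and those on stroma FOVs in the
bottom tercile as NORMAL.  Markers separating the seeds feed an L1-penalized
logistic regression (10-fold cross-validation, penalty chosen at the CV
deviance minimum); the surviving genes are refit in an unpenalized GLM whose
fitted probability is P(NORMAL), so a score **below** 0.5 calls the cell
malignant and a score at or above 0.5 calls it nontumor.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import rankdata
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV
from sklearn.model_selection import StratifiedKFold

from .errors import ConfigError, IntegrityError
from .phenotyping import find_markers
from .qc import NORMALIZED_LAYER

logger = logging.getLogger(__name__)

MALIGNANT = "malignant"
NORMAL = "normal"


@dataclass
class MalignancyModel:
    """Fitted malignant-cell caller on the logit scale.

    ``score = P(NORMAL) = expit(intercept + x @ coef)``; a cell is called
    malignant iff its score is strictly below ``threshold``.
    """

    genes: list[str]
    coef: np.ndarray
    intercept: float
    threshold: float = 0.5
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 < self.threshold < 1.0):
            raise ConfigError("threshold must lie in (0, 1)")
        if len(self.genes) != len(self.coef):
            raise ConfigError("one coefficient per gene required")

    def score(self, expr: np.ndarray) -> np.ndarray:
        """P(NORMAL) for rows of ``expr`` aligned to ``self.genes``."""
        return expit(self.intercept + np.asarray(expr, dtype=float) @ self.coef)


def seed_labels(
    adata: ad.AnnData,
    gene: str = "VEGFA",
    cell_type: str = "proximal tubule",
    min_cells_per_class: int = 50,
    layer: str = NORMALIZED_LAYER,
) -> pd.Series:
    """Label seed cells by FOV-level marker-gene terciles.

    Proximal-tubule cells on tumor-compartment FOVs whose FOV-mean marker
    expression is in the top tercile of tumor FOVs become MALIGNANT seeds;
    those on stroma FOVs in the bottom tercile of stroma FOVs become NORMAL
    seeds.  Returns a Series indexed by cell id with values
    ``"malignant"``/``"normal"`` for the seeds only.
    """
    if gene not in adata.var_names:
        raise ConfigError(f"seed gene {gene!r} absent from panel")
    obs = adata.obs
    if obs["phenotype"].isna().all():
        raise IntegrityError("phenotypes must be assigned before seeding labels")
    expr = np.asarray(adata[:, gene].layers[layer]).ravel()
    is_ct = (obs["phenotype"] == cell_type).to_numpy()
    per_fov = (
        pd.DataFrame({"fov_id": obs["fov_id"], "compartment": obs["compartment"], "v": expr})
        .loc[is_ct]
        .groupby(["fov_id", "compartment"], observed=True)["v"]
        .mean()
        .reset_index()
    )
    labels: dict[str, str] = {}
    for compartment, which in (("tumor", MALIGNANT), ("stroma", NORMAL)):
        sub = per_fov[per_fov["compartment"] == compartment]
        if sub.empty:
            continue
        vals = sub["v"].to_numpy()
        if np.ptp(vals) < 1e-12:
            warnings.warn(
                f"FOV-mean {gene} is uniform across {compartment} FOVs; seed separation is weak",
                stacklevel=2,
            )
        lo, hi = np.quantile(vals, [1 / 3, 2 / 3])
        chosen = sub.loc[vals >= hi, "fov_id"] if which == MALIGNANT else sub.loc[vals <= lo, "fov_id"]
        in_fov = obs["fov_id"].isin(set(chosen)).to_numpy()
        for cid in obs.index[is_ct & in_fov & (obs["compartment"] == compartment).to_numpy()]:
            labels[cid] = which
    out = pd.Series(labels, name="seed_label")
    n_mal = int((out == MALIGNANT).sum())
    n_norm = int((out == NORMAL).sum())
    if n_mal < min_cells_per_class or n_norm < min_cells_per_class:
        raise IntegrityError(
            f"too few seed cells: {n_mal} malignant / {n_norm} normal (need {min_cells_per_class} each)"
        )
    return out


def select_candidate_markers(
    adata: ad.AnnData,
    seeds: pd.Series,
    lfc_min: float = 0.25,
    p_max: float = 0.004,
    layer: str = NORMALIZED_LAYER,
) -> list[str]:
    """Differentially expressed genes between the malignant and normal seeds."""
    sub = adata[seeds.index]
    table = find_markers(
        np.asarray(sub.layers[layer]),
        list(adata.var_names),
        seeds.to_numpy(dtype=object),
        lfc_min=lfc_min,
        p_max=p_max,
    )
    markers = sorted(table.loc[table["is_marker"], "gene"].unique().tolist())
    if not markers:
        raise IntegrityError(
            "no candidate markers passed the thresholds; relax lfc_min/p_max or check the seeds"
        )
    return markers


def fit_lasso(
    expr: np.ndarray,
    labels: np.ndarray,
    genes: list[str],
    folds: int = 10,
    seed: int = 0,
    Cs: int | list[float] = 30,
) -> MalignancyModel:
    """L1 logistic path with 10-fold CV; refit an unpenalized GLM on survivors.

    The penalty is chosen at the minimum cross-validated deviance.  The
    positive class is NORMAL so the fitted probability follows the
    "< 0.5 ⇒ malignant" convention.
    """
    X = np.asarray(expr, dtype=float)
    y = (np.asarray(labels, dtype=object) == NORMAL).astype(int)
    classes = np.unique(y)
    if len(classes) < 2:
        raise IntegrityError("both classes required to fit the model")
    n_min = min(np.bincount(y))
    if n_min < folds:
        raise IntegrityError(f"need at least {folds} cells per class for {folds}-fold CV")
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    lasso = LogisticRegressionCV(
        Cs=Cs,
        cv=cv,
        penalty="l1",
        solver="liblinear",
        scoring="neg_log_loss",  # CV deviance minimum
        max_iter=5000,
        random_state=seed,
    ).fit(X, y)
    nz = np.flatnonzero(lasso.coef_.ravel())
    if nz.size == 0:
        raise IntegrityError("the selected penalty zeroed every coefficient (empty model)")
    selected = [genes[i] for i in nz]
    glm = LogisticRegression(C=np.inf, max_iter=5000).fit(X[:, nz], y)
    return MalignancyModel(
        genes=selected,
        coef=glm.coef_.ravel().copy(),
        intercept=float(glm.intercept_[0]),
        metadata={
            "folds": folds,
            "lambda_rule": "min-cv-deviance",
            "seed": seed,
            "C": float(lasso.C_[0]),
            "n_candidates": len(genes),
            "n_train": len(y),
        },
    )


def _expr_for_model(
    model: MalignancyModel,
    source: ad.AnnData | pd.DataFrame,
    layer: str = NORMALIZED_LAYER,
) -> np.ndarray:
    """Expression matrix for the model genes; missing genes imputed as 0."""
    if isinstance(source, ad.AnnData):
        genes = list(source.var_names)
        mat = np.asarray(source.layers[layer])
    else:
        genes = [str(c) for c in source.columns]
        mat = source.to_numpy(dtype=float)
    out = np.zeros((mat.shape[0], len(model.genes)))
    missing = []
    for j, g in enumerate(model.genes):
        if g in genes:
            out[:, j] = mat[:, genes.index(g)]
        else:
            missing.append(g)
    if missing:
        warnings.warn(f"model gene(s) absent from input, imputed as 0: {missing}", stacklevel=2)
    return out


def predict_malignant(
    model: MalignancyModel,
    source: ad.AnnData | pd.DataFrame,
    layer: str = NORMALIZED_LAYER,
    glomerular_override: bool = True,
) -> pd.DataFrame:
    """Score cells and call malignancy at the model threshold.

    ``score = P(NORMAL)``; class is MALIGNANT iff score < threshold (0.49 is
    malignant, 0.50 is normal).  With ``glomerular_override`` (default on),
    cells phenotyped as glomerular endothelium on stroma FOVs keep their
    phenotype even when the model calls them malignant — their call is reset
    to normal and flagged.
    """
    scores = model.score(_expr_for_model(model, source, layer=layer))
    call = np.where(scores < model.threshold, MALIGNANT, NORMAL)
    overridden = np.zeros(len(scores), dtype=bool)
    if glomerular_override and isinstance(source, ad.AnnData):
        obs = source.obs
        if "phenotype" in obs.columns and "compartment" in obs.columns:
            mask = (
                (obs["compartment"].to_numpy() == "stroma")
                & (obs["phenotype"].to_numpy(dtype=object) == "glomerular endothelium")
                & (call == MALIGNANT)
            )
            call[mask] = NORMAL
            overridden = mask
    index = source.obs_names if isinstance(source, ad.AnnData) else source.index
    return pd.DataFrame(
        {"score": scores, "call": call, "glomerular_override": overridden}, index=index
    )


def auc_mann_whitney(scores: np.ndarray, positive: np.ndarray) -> float:
    """Rank-based AUC: P(score_pos > score_neg) with ties counted half."""
    scores = np.asarray(scores, dtype=float)
    positive = np.asarray(positive, dtype=bool)
    n1, n0 = int(positive.sum()), int((~positive).sum())
    if n1 == 0 or n0 == 0:
        raise IntegrityError("AUC needs both classes")
    ranks = rankdata(scores)
    u = ranks[positive].sum() - n1 * (n1 + 1) / 2
    return float(u / (n1 * n0))


def evaluate_external(
    model: MalignancyModel,
    expr: pd.DataFrame,
    malignant_truth: np.ndarray,
) -> dict:
    """External evaluation: AUC plus the confusion at the model threshold.

    Malignant is the positive class and is predicted by a *low* score, so the
    AUC uses ``1 - score``.  Genes missing from the external panel are
    zero-imputed with a warning.
    """
    truth = np.asarray(malignant_truth, dtype=bool)
    scores = model.score(_expr_for_model(model, expr))
    call_malignant = scores < model.threshold
    tp = int((call_malignant & truth).sum())
    tn = int((~call_malignant & ~truth).sum())
    n_pos, n_neg = int(truth.sum()), int((~truth).sum())
    return {
        "auc": auc_mann_whitney(1.0 - scores, truth),
        "n_malignant": n_pos,
        "n_normal": n_neg,
        "malignant_correct": tp,
        "normal_correct": tn,
        "malignant_rate": tp / n_pos if n_pos else float("nan"),
        "normal_rate": tn / n_neg if n_neg else float("nan"),
    }
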