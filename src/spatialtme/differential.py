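"""Group-comparison statistics shared by all pipeline stages.

Covers Benjamini–Hochberg FDR, beta-binomial differential cell-type
abundance, FOV-level pseudobulk Welch t-tests, cell-level linear mixed models
with a random FOV intercept, Wilcoxon rank-sum utilities, and the group
comparisons of the spatial statistics (DOCE linear models, Moran's I t-tests,
hotspot count summaries).  Every test emits rows in a shared long-format
result schema: unit of analysis, contrast, estimate, standard error,
statistic, p, and BH-adjusted FDR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats as st
import statsmodels.api as sm
from scipy.special import expit, logit
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.numdiff import approx_hess1

from .errors import ConfigError, IntegrityError

DEFAULT_FDR_ALPHA = 0.1


def bh_fdr(p_values: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (NaNs pass through)."""
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


@dataclass
class BetaBinomFit:
    """ML fit of a two-group beta-binomial on positive-cell counts.

    ``y_i ~ BetaBinomial(n_i, mu(group_i), rho)`` with
    ``logit(mu) = b0 + b1·group``; the shape parameters relate to (mu, rho)
    by ``a = mu (1-rho)/rho`` and ``b = (1-mu)(1-rho)/rho``.
    """

    mu: dict[str, float]
    rho: float
    b0: float
    b1: float
    se_b1: float
    loglik: float
    wald: float
    p: float
    groups: tuple[str, str]
    converged: bool
    boundary: bool = False
    p_lrt: float | None = None


def betabinom_loglik(params: np.ndarray, y: np.ndarray, n: np.ndarray, g: np.ndarray) -> float:
    """Log-likelihood at (b0, b1, logit rho); rho → 0 falls back to binomial."""
    b0, b1, lr = params
    mu = expit(b0 + b1 * g)
    rho = expit(lr)
    mu = np.clip(mu, 1e-12, 1 - 1e-12)
    if rho < 1e-6:
        # betabinom.logpmf cancels catastrophically for huge (a, b); the
        # binomial limit is exact to beyond float precision here
        return float(st.binom.logpmf(y, n, mu).sum())
    a = mu * (1 - rho) / rho
    b = (1 - mu) * (1 - rho) / rho
    return float(st.betabinom.logpmf(y, n, a, b).sum())


def betabinom_abundance(
    y: np.ndarray,
    n: np.ndarray,
    groups: np.ndarray,
    lrt: bool = False,
) -> BetaBinomFit:
    """Fit the two-group beta-binomial by direct ML with multiple starts.

    Inference on the group effect is a Wald test from the numerical Hessian;
    ``lrt=True`` additionally reports a likelihood-ratio p-value.  A group
    with all-zero counts drives the fit to the boundary, which is flagged.
    """
    y = np.asarray(y, dtype=float)
    n = np.asarray(n, dtype=float)
    groups = np.asarray(groups, dtype=object)
    uniq = sorted(pd.unique(groups).tolist(), key=str)
    if len(uniq) != 2:
        raise ConfigError(f"exactly two groups required, got {uniq}")
    g = (groups == uniq[1]).astype(float)
    for lab in uniq:
        if (groups == lab).sum() < 2:
            raise IntegrityError(f"group {lab!r} has fewer than 2 FOVs")
    if (n < 1).any():
        raise IntegrityError("every FOV must have n_i >= 1 cells")
    pooled = float(np.clip(y.sum() / n.sum(), 1e-6, 1 - 1e-6))
    p1 = float(np.clip(y[g == 1].sum() / n[g == 1].sum(), 1e-6, 1 - 1e-6))
    p0 = float(np.clip(y[g == 0].sum() / n[g == 0].sum(), 1e-6, 1 - 1e-6))
    starts = [
        np.array([logit(p0), logit(p1) - logit(p0), lr0])
        for lr0 in (-5.0, -3.0, -1.5)
    ] + [np.array([logit(pooled), 0.0, -3.0])]
    best = None
    for x0 in starts:
        res = scipy.optimize.minimize(
            lambda p: -betabinom_loglik(p, y, n, g),
            x0,
            method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 4000},
        )
        if best is None or res.fun < best.fun:
            best = res
    b0, b1, lr = best.x
    rho = float(expit(lr))
    boundary = bool((y[g == 0].sum() == 0) or (y[g == 1].sum() == 0) or rho < 1e-6)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if boundary:
            # rho on the 0 boundary: profile it out and use the analytic
            # binomial (logistic) information matrix for the (b0, b1) block
            mu_i = np.clip(expit(b0 + b1 * g), 1e-12, 1 - 1e-12)
            wts = n * mu_i * (1 - mu_i)
            X = np.column_stack([np.ones_like(g), g])
            hess = X.T @ (wts[:, None] * X)
        else:
            hess = approx_hess1(best.x, lambda p: -betabinom_loglik(p, y, n, g))
    try:
        cov = np.linalg.inv(hess)
        se_b1 = float(np.sqrt(max(cov[1, 1], 0.0)))
    except np.linalg.LinAlgError:
        se_b1 = float("nan")
    wald = b1 / se_b1 if se_b1 and np.isfinite(se_b1) and se_b1 > 0 else float("nan")
    p = 2 * st.norm.sf(abs(wald)) if np.isfinite(wald) else float("nan")
    p_lrt = None
    if lrt:
        null = min(
            (
                scipy.optimize.minimize(
                    lambda q: -betabinom_loglik(np.array([q[0], 0.0, q[1]]), y, n, g),
                    np.array([logit(pooled), lr0]),
                    method="Nelder-Mead",
                    options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 4000},
                )
                for lr0 in (-5.0, -1.5)
            ),
            key=lambda r: r.fun,
        )
        stat = 2 * (null.fun - best.fun)
        p_lrt = float(st.chi2.sf(max(stat, 0.0), df=1))
    return BetaBinomFit(
        mu={uniq[0]: float(expit(b0)), uniq[1]: float(expit(b0 + b1))},
        rho=rho,
        b0=float(b0),
        b1=float(b1),
        se_b1=se_b1,
        loglik=float(-best.fun),
        wald=float(wald),
        p=float(p),
        groups=(str(uniq[0]), str(uniq[1])),
        converged=bool(best.success),
        boundary=boundary,
        p_lrt=p_lrt,
    )


def abundance_scan(
    cells: pd.DataFrame,
    contrast: tuple[str, str],
    group_col: str = "cohort",
    compartment: str | None = None,
    alpha: float = DEFAULT_FDR_ALPHA,
) -> pd.DataFrame:
    """Beta-binomial abundance test for every phenotype between two cohorts."""
    df = cells
    if compartment is not None:
        df = df[df["compartment"] == compartment]
    df = df[df[group_col].isin(contrast)]
    fov_groups = df.groupby("fov_id", observed=True)[group_col].first()
    totals = df.groupby("fov_id", observed=True).size()
    rows = []
    for ph in sorted(df["phenotype"].dropna().unique(), key=str):
        pos = df[df["phenotype"] == ph].groupby("fov_id", observed=True).size()
        y = pos.reindex(totals.index, fill_value=0).to_numpy(dtype=float)
        try:
            fit = betabinom_abundance(y, totals.to_numpy(dtype=float), fov_groups.to_numpy(dtype=object))
        except (ConfigError, IntegrityError) as exc:
            rows.append({"unit": ph, "contrast": "|".join(contrast), "estimate": np.nan,
                         "se": np.nan, "statistic": np.nan, "p": np.nan, "reason": str(exc)})
            continue
        rows.append({
            "unit": ph, "contrast": "|".join(contrast), "estimate": fit.b1, "se": fit.se_b1,
            "statistic": fit.wald, "p": fit.p, "rho": fit.rho, "boundary": fit.boundary,
            "reason": None,
        })
    out = pd.DataFrame(rows)
    out["fdr"] = bh_fdr(out["p"])
    out["significant"] = out["fdr"] < alpha
    return out


def pseudobulk_de(
    norm_expr: np.ndarray,
    genes: list[str],
    cells: pd.DataFrame,
    contrast: tuple[str, str],
    group_col: str = "cohort",
    equal_var: bool = False,
    alpha: float = DEFAULT_FDR_ALPHA,
) -> pd.DataFrame:
    """Per-gene two-sample t-test on FOV-mean ("pseudobulk") expression.

    Expression is averaged over all cells of each FOV, then the two cohorts'
    FOV means are compared per gene (Welch by default, pooled via
    ``equal_var=True``), with BH adjustment across genes.
    """
    X = np.asarray(norm_expr, dtype=float)
    fov = cells["fov_id"].to_numpy()
    grp = cells[group_col].to_numpy(dtype=object)
    fov_means, fov_grp = _fov_means(X, fov, grp)
    m1 = fov_means[fov_grp == contrast[0]]
    m2 = fov_means[fov_grp == contrast[1]]
    if len(m1) < 2 or len(m2) < 2:
        raise IntegrityError("each group needs at least 2 FOVs")
    diff = m1.mean(axis=0) - m2.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = st.ttest_ind(m1, m2, axis=0, equal_var=equal_var)
    # degenerate genes: identical means and zero variance → no evidence
    zero = ~np.isfinite(t)
    t = np.where(zero & (diff == 0), 0.0, t)
    p = np.where(zero & (diff == 0), 1.0, p)
    out = pd.DataFrame({
        "unit": genes, "contrast": "|".join(contrast), "estimate": diff,
        "statistic": t, "p": p,
        "n_per_group": f"{len(m1)}|{len(m2)}",
    })
    out["fdr"] = bh_fdr(out["p"])
    out["significant"] = out["fdr"] < alpha
    return out


def _fov_means(X: np.ndarray, fov: np.ndarray, grp: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    fovs = pd.unique(fov)
    means = np.empty((len(fovs), X.shape[1]))
    groups = np.empty(len(fovs), dtype=object)
    for i, f in enumerate(fovs):
        mask = fov == f
        means[i] = X[mask].mean(axis=0)
        g = pd.unique(grp[mask])
        if len(g) != 1:
            raise IntegrityError(f"FOV {f!r} spans multiple groups")
        groups[i] = g[0]
    return means, groups


def mixedmodel_de(
    norm_expr: np.ndarray,
    genes: list[str],
    cells: pd.DataFrame,
    contrast: tuple[str, str],
    group_col: str = "cohort",
    alpha: float = DEFAULT_FDR_ALPHA,
) -> pd.DataFrame:
    """Cell-level differential expression with a random FOV intercept.

    Per gene: ``expression ~ group + (1 | FOV)`` fit by REML; the group effect
    is tested with a Wald t using between-FOV degrees of freedom
    (``n_FOV − 2``), which is exact for balanced designs and guards the test
    against the pseudo-replication that a naive per-cell t-test commits.
    Singular fits (zero FOV variance) are flagged and reduce to OLS.
    """
    X = np.asarray(norm_expr, dtype=float)
    keep = cells[group_col].isin(contrast).to_numpy()
    X = X[keep]
    sub = cells.loc[keep]
    g = (sub[group_col].to_numpy(dtype=object) == contrast[1]).astype(float)
    fov = sub["fov_id"].astype(str).to_numpy()
    n_fov_per = sub.groupby(group_col, observed=True)["fov_id"].nunique()
    if (n_fov_per.reindex(list(contrast)).fillna(0) < 2).any():
        raise IntegrityError("each group needs at least 2 FOVs with cells present")
    n_fov = len(pd.unique(fov))
    df_resid = max(n_fov - 2, 1)
    exog = sm.add_constant(g)
    rows = []
    for j, gene in enumerate(genes):
        yj = X[:, j]
        flag = None
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.MixedLM(yj, exog, groups=fov).fit(reml=True)
            est = float(fit.params[1])
            se = float(fit.bse[1])
            if not np.isfinite(se) or se <= 0:
                raise ValueError("non-finite SE")
            var_fov = float(np.asarray(fit.cov_re).ravel()[0])
            if var_fov <= 1e-10:
                flag = "singular_fov_variance"
        except Exception:
            ols = sm.OLS(yj, exog).fit()
            est, se = float(ols.params[1]), float(ols.bse[1])
            flag = "ols_fallback"
        tstat = est / se if se > 0 else 0.0
        p = 2 * st.t.sf(abs(tstat), df=df_resid)
        rows.append({
            "unit": gene, "contrast": "|".join(contrast), "estimate": est, "se": se,
            "statistic": tstat, "p": p, "df": df_resid, "df_method": "between-fov",
            "flag": flag,
        })
    out = pd.DataFrame(rows)
    out["fdr"] = bh_fdr(out["p"])
    out["significant"] = out["fdr"] < alpha
    return out


def wilcoxon_groups(values: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann–Whitney U (tie-corrected normal approximation).

    Returns (U of the first label's sample, p).  Identical samples give p = 1.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=object)
    uniq = sorted(pd.unique(labels).tolist(), key=str)
    if len(uniq) != 2:
        raise ConfigError(f"exactly two groups required, got {uniq}")
    x = values[labels == uniq[0]]
    y = values[labels == uniq[1]]
    res = st.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic", use_continuity=False)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def compare_doce(
    doce_df: pd.DataFrame,
    fov_groups: pd.Series,
    contrast: tuple[str, str],
    alpha: float = DEFAULT_FDR_ALPHA,
) -> pd.DataFrame:
    """Linear model of DOCE on cohort, one row per phenotype, BH across phenotypes.

    ``fov_groups`` maps fov_id → cohort.  The two-group OLS slope equals the
    difference of cohort means; its t-test p is reported.
    """
    df = doce_df.dropna(subset=["doce"]).copy()
    df["group"] = df["fov_id"].map(fov_groups)
    df = df[df["group"].isin(contrast)]
    rows = []
    for ph in sorted(df["phenotype"].unique(), key=str):
        sub = df[df["phenotype"] == ph]
        g = (sub["group"] == contrast[1]).astype(float).to_numpy()
        yv = sub["doce"].to_numpy(dtype=float)
        if len(np.unique(g)) < 2 or (g == 1).sum() < 2 or (g == 0).sum() < 2:
            rows.append({"unit": ph, "contrast": "|".join(contrast), "estimate": np.nan,
                         "se": np.nan, "statistic": np.nan, "p": np.nan,
                         "reason": "needs >=2 FOVs per group"})
            continue
        fit = sm.OLS(yv, sm.add_constant(g)).fit()
        rows.append({"unit": ph, "contrast": "|".join(contrast),
                     "estimate": float(fit.params[1]), "se": float(fit.bse[1]),
                     "statistic": float(fit.tvalues[1]), "p": float(fit.pvalues[1]),
                     "reason": None})
    out = pd.DataFrame(rows)
    out["fdr"] = bh_fdr(out["p"])
    out["significant"] = out["fdr"] < alpha
    return out


def compare_moran(
    moran_df: pd.DataFrame,
    fov_groups: pd.Series,
    contrast: tuple[str, str],
    equal_var: bool = False,
    alpha: float = DEFAULT_FDR_ALPHA,
) -> pd.DataFrame:
    """Two-sample t-test on per-FOV Moran's I for every pair, BH across pairs."""
    df = moran_df.dropna(subset=["I"]).copy()
    df["group"] = df["fov_id"].map(fov_groups)
    df = df[df["group"].isin(contrast)]
    rows = []
    for (lig, rec), sub in df.groupby(["ligand", "receptor"], observed=True, sort=True):
        x = sub.loc[sub["group"] == contrast[0], "I"].to_numpy(dtype=float)
        y = sub.loc[sub["group"] == contrast[1], "I"].to_numpy(dtype=float)
        row = {"unit": f"{lig}-{rec}", "ligand": lig, "receptor": rec,
               "contrast": "|".join(contrast),
               "mean_0": x.mean() if len(x) else np.nan,
               "mean_1": y.mean() if len(y) else np.nan,
               "n_per_group": f"{len(x)}|{len(y)}"}
        if len(x) < 2 or len(y) < 2:
            row.update(estimate=np.nan, statistic=np.nan, p=np.nan,
                       reason="needs >=2 FOVs per group")
        else:
            t, p = st.ttest_ind(x, y, equal_var=equal_var)
            row.update(estimate=float(y.mean() - x.mean()), statistic=float(t),
                       p=float(p), reason=None)
        rows.append(row)
    out = pd.DataFrame(rows)
    out["fdr"] = bh_fdr(out["p"])
    out["significant"] = out["fdr"] < alpha
    return out


def compare_enrichment(
    enrich_df: pd.DataFrame,
    fov_meta: pd.DataFrame,
    contrast: tuple[str, str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Count samples showing significant hotspot evidence per gene set and cohort.

    ``fov_meta`` maps fov_id → (sample_id, cohort).  A sample counts as
    enriched when its smallest FOV-level empirical p is below ``alpha`` (with
    one FOV per sample-compartment the two coincide).
    """
    df = enrich_df.dropna(subset=["p_empirical"]).merge(
        fov_meta[["fov_id", "sample_id", "cohort"]].drop_duplicates(), on="fov_id"
    )
    df = df[df["cohort"].isin(contrast)]
    rows = []
    for set_name, sub in df.groupby("set_name", observed=True, sort=True):
        per_sample = sub.groupby(["cohort", "sample_id"], observed=True)["p_empirical"].min()
        for cohort in contrast:
            ps = per_sample.loc[cohort] if cohort in per_sample.index.get_level_values(0) else pd.Series(dtype=float)
            rows.append({
                "unit": set_name, "cohort": cohort, "alpha": alpha,
                "n_samples": int(ps.shape[0] if hasattr(ps, "shape") else 1),
                "n_enriched": int((ps < alpha).sum()),
            })
    return pd.DataFrame(rows)
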