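"""LASSO predictor selection followed by cluster-robust OLS inference.

For each airway outcome the chain is: winsorize at the 1st/99th
percentiles, log-transform CV outcomes (right-skewed), Z-standardize;
select predictors from the eight candidates (mouth position, sex,
symptomatic status as 0/1 indicators; age, neck circumference, BMI, height,
weight standardized) with 10-fold cross-validated LASSO whose folds keep
each participant's two rows (closed/open) together; refit the selected
predictors with OLS; report cluster-robust (CR1) standard errors treating
each participant as a cluster, with t inference on G-1 degrees of freedom;
and run collinearity/residual diagnostics (VIF, Shapiro on residuals,
Breusch-Pagan).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.linear_model import Lasso, LassoCV

from ._rng import substream

BINARY_PREDICTORS = ("mouth_position", "sex_male", "symptomatic")
CONTINUOUS_PREDICTORS = ("age", "neck_circumference", "bmi", "height", "weight")
ALL_PREDICTORS = BINARY_PREDICTORS + CONTINUOUS_PREDICTORS

MEAN_OUTCOMES = ("total_length_cm", "epiglottic_length_cm", "mean_csa_cm2",
                 "retropalatal_csa_cm2", "retroglossal_csa_cm2",
                 "total_volume_cm3", "epiglottic_volume_cm3")
CV_OUTCOMES = ("mean_csa_cm2_cv", "retropalatal_csa_cm2_cv",
               "retroglossal_csa_cm2_cv", "total_volume_cm3_cv",
               "epiglottic_volume_cm3_cv")


class RegressionError(ValueError):
    pass


# --------------------------------------------------------------------------
# outcome conditioning
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ConditionedOutcome:
    values: np.ndarray
    winsorized: bool
    log_cv: bool
    standardized: bool
    n_clamped: int
    n_floored: int


def condition_outcome(values: Sequence[float], is_cv: bool) -> ConditionedOutcome:
    """Winsorize at P1/P99, log-transform CVs, Z-standardize.

    Percentiles use linear interpolation between order statistics.  Zero
    CVs (possible on a motionless series) are floored at the smallest
    positive observed value before the log and flagged.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 10:
        raise RegressionError("outcome conditioning needs at least 10 observations")
    if np.ptp(v) == 0:
        raise RegressionError("outcome is constant; nothing to model")
    p1, p99 = np.percentile(v, [1, 99])
    clamped = np.clip(v, p1, p99)
    n_clamped = int((v < p1).sum() + (v > p99).sum())
    n_floored = 0
    if is_cv:
        positive = clamped[clamped > 0]
        if positive.size == 0:
            raise RegressionError("all CV values are zero; log transform undefined")
        floor = positive.min()
        n_floored = int((clamped <= 0).sum())
        clamped = np.log(np.maximum(clamped, floor))
    sd = clamped.std(ddof=1)
    if sd == 0:
        raise RegressionError("outcome is constant after conditioning")
    z = (clamped - clamped.mean()) / sd
    return ConditionedOutcome(z, True, is_cv, True, n_clamped, n_floored)


# --------------------------------------------------------------------------
# LASSO selection
# --------------------------------------------------------------------------

def _cluster_folds(clusters: np.ndarray, n_folds: int,
                   rng: np.random.Generator) -> list[tuple[np.ndarray, np.ndarray]]:
    """Fold index pairs keeping all rows of one cluster in the same fold."""
    uniq = np.unique(clusters)
    perm = rng.permutation(uniq)
    all_idx = np.arange(clusters.size)
    folds = []
    for chunk in np.array_split(perm, n_folds):
        test = all_idx[np.isin(clusters, chunk)]
        train = all_idx[~np.isin(clusters, chunk)]
        folds.append((train, test))
    return folds


@dataclass(frozen=True)
class LassoSelection:
    selected: tuple[str, ...]
    alpha: float
    coefficients: dict[str, float]
    cv_alphas: np.ndarray
    cv_mse: np.ndarray


def lasso_select(X: pd.DataFrame, y: np.ndarray, clusters: Sequence | None = None,
                 n_folds: int = 10, seed: int = 0) -> LassoSelection:
    """LASSO with cross-validated penalty; the minimizer of mean CV MSE.

    Folds are stratified by cluster so a participant's closed and open rows
    never straddle a train/test boundary.
    """
    y = np.asarray(y, dtype=float)
    if X.shape[0] <= n_folds:
        raise RegressionError("need more observations than folds")
    if np.linalg.matrix_rank(np.asarray(X, dtype=float)) == 0:
        raise RegressionError("design matrix has rank zero")
    rng = substream(seed, "lasso_folds")
    clusters = np.asarray(clusters if clusters is not None else np.arange(X.shape[0]))
    cv = _cluster_folds(clusters, n_folds, rng)
    model = LassoCV(cv=cv, alphas=100, max_iter=50_000).fit(np.asarray(X, float), y)
    coefs = dict(zip(X.columns, model.coef_))
    selected = tuple(name for name, c in coefs.items() if c != 0.0)
    return LassoSelection(selected=selected, alpha=float(model.alpha_),
                          coefficients=coefs, cv_alphas=model.alphas_,
                          cv_mse=model.mse_path_.mean(axis=1))


def lasso_coefficients(X: pd.DataFrame, y: np.ndarray, alpha: float) -> dict[str, float]:
    """Coefficients of a single LASSO fit at a fixed penalty (alpha=0 -> OLS)."""
    if alpha == 0.0:
        beta, *_ = np.linalg.lstsq(
            np.column_stack([np.ones(len(y)), np.asarray(X, float)]),
            np.asarray(y, float), rcond=None)
        return dict(zip(X.columns, beta[1:]))
    model = Lasso(alpha=alpha, max_iter=100_000).fit(np.asarray(X, float), y)
    return dict(zip(X.columns, model.coef_))


# --------------------------------------------------------------------------
# OLS refit with cluster-robust errors
# --------------------------------------------------------------------------

@dataclass
class RegressionResult:
    outcome: str
    selected: tuple[str, ...]
    coefficients: dict[str, float]
    cluster_robust_se: dict[str, float]
    p_values: dict[str, float]
    alpha: float
    cv_curve: tuple[np.ndarray, np.ndarray] | None
    vif: dict[str, float] = field(default_factory=dict)
    diagnostics: dict[str, float] = field(default_factory=dict)
    conditioning: ConditionedOutcome | None = None


def ols_cluster_robust(X: pd.DataFrame, y: np.ndarray, clusters: Sequence,
                       outcome: str = "") -> RegressionResult:
    """OLS refit with CR1 sandwich standard errors and t(G-1) inference.

    The small-sample factor is G/(G-1) * (n-1)/(n-k); with singleton
    clusters this reduces exactly to HC1 heteroskedasticity-robust errors.
    """
    clusters = np.asarray(clusters)
    if np.unique(clusters).size < 2:
        raise RegressionError("cluster-robust errors need at least two clusters")
    Xc = sm.add_constant(np.asarray(X, dtype=float), has_constant="add")
    names = ["const"] + list(X.columns)
    if np.linalg.matrix_rank(Xc) < Xc.shape[1]:
        corr = pd.DataFrame(np.asarray(X, float), columns=X.columns).corr().abs()
        np.fill_diagonal(corr.values, 0)
        worst = corr.stack().idxmax() if len(X.columns) > 1 else (X.columns[0],)
        raise RegressionError(f"singular design; near-collinear columns: {worst}")
    res = sm.OLS(np.asarray(y, float), Xc).fit(
        cov_type="cluster", cov_kwds={"groups": clusters}, use_t=True)
    coef = dict(zip(names, res.params))
    se = dict(zip(names, res.bse))
    pvals = dict(zip(names, res.pvalues))
    diag = diagnostics(X, np.asarray(res.resid))
    return RegressionResult(
        outcome=outcome, selected=tuple(X.columns), coefficients=coef,
        cluster_robust_se=se, p_values=pvals, alpha=float("nan"), cv_curve=None,
        vif=diag.pop("vif"), diagnostics=diag)


def diagnostics(X: pd.DataFrame, residuals: np.ndarray) -> dict:
    """VIF per predictor plus residual normality and spread checks."""
    Xa = np.asarray(X, dtype=float)
    vif: dict[str, float] = {}
    for j, name in enumerate(X.columns):
        others = np.delete(Xa, j, axis=1)
        others = np.column_stack([np.ones(Xa.shape[0]), others])
        beta, *_ = np.linalg.lstsq(others, Xa[:, j], rcond=None)
        resid = Xa[:, j] - others @ beta
        ss_tot = ((Xa[:, j] - Xa[:, j].mean()) ** 2).sum()
        r2 = 1.0 - (resid ** 2).sum() / ss_tot if ss_tot > 0 else 0.0
        vif[name] = float("inf") if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    out: dict = {"vif": vif, "vif_flagged": [n for n, v in vif.items() if v >= 10]}
    if residuals.size >= 3 and np.ptp(residuals) > 0:
        out["residual_shapiro_p"] = float(stats.shapiro(residuals).pvalue)
        from statsmodels.stats.diagnostic import het_breuschpagan
        _, bp_p, *_ = het_breuschpagan(residuals,
                                       np.column_stack([np.ones(Xa.shape[0]), Xa]))
        out["breusch_pagan_p"] = float(bp_p)
    return out


# --------------------------------------------------------------------------
# full chain over all outcomes
# --------------------------------------------------------------------------

def build_design(metrics_df: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """Long-format design (two rows per participant) and cluster ids.

    Binary predictors are 0/1 indicators; continuous predictors are
    Z-standardized across all rows.
    """
    df = metrics_df[~metrics_df["osa_excluded"]].copy()
    df = df.sort_values(["participant", "position"]).reset_index(drop=True)
    sizes = df.groupby("participant").size()
    if not (sizes == 2).all():
        raise RegressionError("every participant needs exactly two rows (closed, open)")
    X = pd.DataFrame({
        "mouth_position": (df["position"] == "open").astype(float),
        "sex_male": (df["sex"] == "male").astype(float),
        "symptomatic": df["symptomatic"].astype(float),
    })
    for name in CONTINUOUS_PREDICTORS:
        col = df[name].astype(float)
        X[name] = (col - col.mean()) / col.std(ddof=1)
    return X, df["participant"].to_numpy()


def fit_outcome(metrics_df: pd.DataFrame, outcome: str, seed: int = 0,
                n_folds: int = 10) -> RegressionResult:
    """Run the full conditioning -> LASSO -> cluster-robust OLS chain."""
    X, clusters = build_design(metrics_df)
    df = metrics_df[~metrics_df["osa_excluded"]].sort_values(
        ["participant", "position"]).reset_index(drop=True)
    cond = condition_outcome(df[outcome].to_numpy(), is_cv=outcome.endswith("_cv"))
    sel = lasso_select(X, cond.values, clusters=clusters, n_folds=n_folds, seed=seed)
    if not sel.selected:
        result = RegressionResult(outcome=outcome, selected=(), coefficients={},
                                  cluster_robust_se={}, p_values={},
                                  alpha=sel.alpha,
                                  cv_curve=(sel.cv_alphas, sel.cv_mse))
        result.conditioning = cond
        return result
    result = ols_cluster_robust(X[list(sel.selected)], cond.values, clusters,
                                outcome=outcome)
    result.alpha = sel.alpha
    result.cv_curve = (sel.cv_alphas, sel.cv_mse)
    result.conditioning = cond
    return result


def fit_all_outcomes(metrics_df: pd.DataFrame, seed: int = 0,
                     n_folds: int = 10) -> tuple[pd.DataFrame, dict[str, RegressionResult]]:
    """Fit every mean and CV outcome; return the coefficient heat-map matrix.

    The matrix has one row per outcome and two columns per predictor
    (standardized beta and p); cells of unselected predictors are NaN.
    """
    results: dict[str, RegressionResult] = {}
    rows = []
    for outcome in MEAN_OUTCOMES + CV_OUTCOMES:
        res = fit_outcome(metrics_df, outcome, seed=seed, n_folds=n_folds)
        results[outcome] = res
        row: dict[str, float] = {"outcome": outcome, "lambda": res.alpha}
        for name in ALL_PREDICTORS:
            row[f"beta_{name}"] = res.coefficients.get(name, np.nan)
            row[f"p_{name}"] = res.p_values.get(name, np.nan)
        rows.append(row)
    return pd.DataFrame(rows).set_index("outcome"), results
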