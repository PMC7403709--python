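"""Tile-level classification and the patient-level pathology score.

The modeling chain:

1. z-score standardization, fitted on primary-cohort tiles only;
2. L1-penalized (LASSO) logistic regression over a log-spaced penalty
   grid with 10-fold cross-validation — folds grouped by patient so all
   tiles of a patient stay in one fold — selecting the features with
   nonzero coefficients at the deviance-minimizing penalty;
3. an RBF-kernel SVM tile classifier, hyperparameters grid-searched by
   stratified CV on AUC, with Platt-scaled probability outputs;
4. per-patient aggregation: the arithmetic mean of a patient's tile
   probabilities;
5. a univariable logistic regression of outcome on that mean — its
   fitted probability is the patient's *pathology score*;
6. a multivariable logistic model adjusting the score for age, gender,
   clinical T and N stage, and CEA level.

Tile labels are inherited from the patient outcome: no tile-level
ground truth exists, so the tile classifier is trained against patient
PR status by design (this injects label noise on real data).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from sklearn.calibration import CalibratedClassifierCV
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, StratifiedGroupKFold, StratifiedKFold
from sklearn.svm import SVC

__all__ = [
    "StandardizationParams",
    "LassoResult",
    "TileClassifier",
    "PathologySignature",
    "MultivariableModel",
    "standardize_fit",
    "standardize_apply",
    "lasso_select",
    "train_tile_classifier",
    "aggregate_patient",
    "aggregate_patients",
    "fit_signature",
    "fit_multivariable",
]

#: Default SVM hyperparameter grids (powers of two, exponent step 2).
DEFAULT_C_GRID = tuple(2.0 ** np.arange(-3, 8, 2))
DEFAULT_GAMMA_GRID = tuple(2.0 ** np.arange(-9, 2, 2))

#: Reference categories for dummy coding of the clinical covariates.
COVARIATE_REFERENCES = {"gender": "male", "t_stage": "T3", "n_stage": "N0", "cea": "normal"}


# ---------------------------------------------------------------------------
# standardization
# ---------------------------------------------------------------------------

@dataclass
class StandardizationParams:
    """Per-feature location/scale estimated on the primary cohort."""

    mean: pd.Series
    sd: pd.Series

    @property
    def features(self) -> list[str]:
        return list(self.mean.index)


def standardize_fit(X: pd.DataFrame) -> StandardizationParams:
    """Estimate per-feature mean and SD; zero-variance features are dropped."""
    if len(X) < 2:
        raise ValueError("need at least 2 rows to standardize")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    dead = sd[sd == 0].index
    if len(dead):
        warnings.warn(
            f"dropping {len(dead)} zero-variance feature(s): {list(dead)[:5]}...",
            stacklevel=2,
        )
        mean, sd = mean.drop(dead), sd.drop(dead)
    return StandardizationParams(mean=mean, sd=sd)


def standardize_apply(params: StandardizationParams, X: pd.DataFrame) -> pd.DataFrame:
    """Apply primary-cohort z-scoring to any feature table."""
    cols = params.features
    return (X[cols] - params.mean) / params.sd


# ---------------------------------------------------------------------------
# LASSO feature selection
# ---------------------------------------------------------------------------

@dataclass
class LassoResult:
    alphas: np.ndarray                      # penalty grid (glmnet-style lambda)
    coef_path: np.ndarray                   # (n_alphas, n_features) full-data path
    cv_deviance: np.ndarray                 # mean CV binomial deviance per alpha
    cv_deviance_se: np.ndarray
    alpha_min: float
    alpha_1se: float
    chosen_alpha: float
    rule: str
    feature_names: list[str]
    selected: list[str]


def _binomial_deviance(y: np.ndarray, p: np.ndarray) -> float:
    eps = 1e-12
    p = np.clip(p, eps, 1 - eps)
    return float(-2.0 * np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def _l1_logistic(C: float) -> LogisticRegression:
    # liblinear is by far the fastest exact L1 solver at this problem size;
    # its intercept penalty is neutralized with a large intercept_scaling.
    # The iteration budget is deliberately modest: texture banks contain
    # near-duplicate columns, and exact coordinate descent at the weakly
    # penalized end of the path can cycle between them almost forever.
    return LogisticRegression(
        solver="liblinear", l1_ratio=1.0, C=C, intercept_scaling=100.0,
        max_iter=200, tol=1e-4,
    )


def _l1_path(X: np.ndarray, y: np.ndarray, alphas: np.ndarray) -> np.ndarray:
    """Coefficient path of L1 logistic regression along a descending grid.

    ``alpha`` is the glmnet-style penalty on the (1/n)-scaled
    log-likelihood, so sklearn's C = 1 / (n * alpha).
    """
    n = len(y)
    coefs = np.empty((len(alphas), X.shape[1]))
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", category=ConvergenceWarning)
        for k, alpha in enumerate(alphas):
            model = _l1_logistic(1.0 / (n * alpha))
            model.fit(X, y)
            coefs[k] = model.coef_[0]
    return coefs


def lasso_select(
    X: pd.DataFrame,
    y: "np.ndarray | pd.Series",
    groups: "np.ndarray | pd.Series | None" = None,
    n_folds: int = 10,
    n_alphas: int = 50,
    alpha_min_ratio: float = 1e-2,
    rule: str = "min",
    seed: int = 0,
) -> LassoResult:
    """LASSO logistic feature selection with cross-validated penalty choice.

    Parameters
    ----------
    X : standardized tile-feature table.
    y : binary tile labels (tiles inherit their patient's PR status).
    groups : optional per-tile patient ids; when given, CV folds are
        grouped so no patient straddles folds (prevents leakage).
    rule : "min" picks the deviance-minimizing penalty; "1se" the
        largest penalty within one SE of that minimum.
    """
    y = np.asarray(y).astype(float)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("tile labels contain a single class; cannot select features")
    if rule not in ("min", "1se"):
        raise ValueError("rule must be 'min' or '1se'")
    Xv = np.asarray(X, dtype=np.float64)
    n = len(y)

    # glmnet-style grid from the smallest penalty that kills every feature
    alpha_max = np.abs(Xv.T @ (y - y.mean())).max() / n
    alphas = np.geomspace(alpha_max, alpha_max * alpha_min_ratio, n_alphas)

    if groups is not None:
        splitter = StratifiedGroupKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        folds = list(splitter.split(Xv, y, np.asarray(groups)))
    else:
        splitter = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        folds = list(splitter.split(Xv, y))

    dev = np.empty((len(folds), n_alphas))
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", category=ConvergenceWarning)
        for f, (tr, te) in enumerate(folds):
            for k, alpha in enumerate(alphas):
                model = _l1_logistic(1.0 / (len(tr) * alpha))
                model.fit(Xv[tr], y[tr])
                p = model.predict_proba(Xv[te])[:, 1]
                dev[f, k] = _binomial_deviance(y[te], p)

    cv_mean = dev.mean(axis=0)
    cv_se = dev.std(axis=0, ddof=1) / np.sqrt(len(folds))
    k_min = int(np.argmin(cv_mean))
    alpha_min = float(alphas[k_min])
    within = cv_mean <= cv_mean[k_min] + cv_se[k_min]
    alpha_1se = float(alphas[np.flatnonzero(within)[0]])  # grid is descending
    chosen = alpha_min if rule == "min" else alpha_1se

    coef_path = _l1_path(Xv, y, alphas)
    k_chosen = int(np.argmin(np.abs(alphas - chosen)))
    nz = np.abs(coef_path[k_chosen]) > 1e-8
    names = list(X.columns)
    return LassoResult(
        alphas=alphas,
        coef_path=coef_path,
        cv_deviance=cv_mean,
        cv_deviance_se=cv_se,
        alpha_min=alpha_min,
        alpha_1se=alpha_1se,
        chosen_alpha=float(chosen),
        rule=rule,
        feature_names=names,
        selected=[names[i] for i in np.flatnonzero(nz)],
    )


# ---------------------------------------------------------------------------
# RBF-SVM tile classifier
# ---------------------------------------------------------------------------

@dataclass
class TileClassifier:
    """Fitted RBF-SVM with Platt-scaled probabilities on selected features."""

    model: CalibratedClassifierCV
    features: list[str]
    C: float
    gamma: float
    cv_auc: float

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        """P(PR) per tile, in [0, 1]."""
        return self.model.predict_proba(np.asarray(X[self.features], dtype=float))[:, 1]


def train_tile_classifier(
    X: pd.DataFrame,
    y: "np.ndarray | pd.Series",
    cv_folds: int = 5,
    C_grid=DEFAULT_C_GRID,
    gamma_grid=DEFAULT_GAMMA_GRID,
    seed: int = 0,
) -> TileClassifier:
    """Grid-search (C, gamma) by stratified CV AUC, then refit with Platt scaling.

    The search scores the SVM decision function (AUC is rank-based, so
    Platt calibration is only needed for the final probability model).
    """
    y = np.asarray(y).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("need both classes to train the tile classifier")
    C_grid, gamma_grid = list(C_grid), list(gamma_grid)
    if not C_grid or not gamma_grid:
        raise ValueError("hyperparameter grids must be non-empty")
    Xv = np.asarray(X, dtype=np.float64)
    cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    search = GridSearchCV(
        SVC(kernel="rbf"),
        {"C": C_grid, "gamma": gamma_grid},
        scoring="roc_auc",
        cv=cv,
        n_jobs=1,
    )
    search.fit(Xv, y)
    best = search.best_params_
    # Platt scaling (sigmoid calibration) fitted within CV; ensemble=False
    # keeps a single SVM refit on the full data, with the calibrator
    # mapping its decision values to probabilities monotonically.
    final = CalibratedClassifierCV(
        SVC(kernel="rbf", C=best["C"], gamma=best["gamma"]),
        method="sigmoid",
        cv=StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed),
        ensemble=False,
    )
    final.fit(Xv, y)
    return TileClassifier(
        model=final,
        features=list(X.columns),
        C=float(best["C"]),
        gamma=float(best["gamma"]),
        cv_auc=float(search.best_score_),
    )


# ---------------------------------------------------------------------------
# patient aggregation and pathology score
# ---------------------------------------------------------------------------

def aggregate_patient(tile_probs) -> float:
    """Arithmetic mean of one patient's selected-tile probabilities."""
    probs = np.asarray(tile_probs, dtype=float)
    if probs.size == 0:
        raise ValueError("patient has no selected tiles")
    if probs.min() < 0 or probs.max() > 1:
        raise ValueError("tile probabilities must lie in [0, 1]")
    return float(probs.mean())


def aggregate_patients(tile_table: pd.DataFrame, prob_col: str = "prob") -> pd.Series:
    """Per-patient mean tile probability from a (patient_id, prob) table.

    Patients appearing with zero tiles (all-NaN probabilities) are
    excluded with a warning.
    """
    grouped = tile_table.groupby("patient_id")[prob_col].mean()
    missing = grouped[grouped.isna()].index
    if len(missing):
        warnings.warn(f"excluding {len(missing)} patient(s) with no tiles", stacklevel=2)
        grouped = grouped.drop(missing)
    return grouped.rename("mean_prob")


@dataclass
class PathologySignature:
    """Univariable logistic transform of the patient mean tile probability.

    score(m) = sigmoid(beta0 + beta1 * m); strictly monotone in m when
    beta1 > 0, so patient ranking (and AUC) is preserved.
    """

    beta0: float
    beta1: float
    ridge_fallback: bool = False

    def score(self, m) -> np.ndarray:
        return expit(self.beta0 + self.beta1 * np.asarray(m, dtype=float))


def fit_signature(means, labels) -> PathologySignature:
    """Maximum-likelihood logistic fit of outcome on the patient mean.

    Perfectly separated data (common at small n with a strong
    classifier) make the MLE diverge; in that case the fit falls back to
    a lightly ridge-penalized (1e-4) logistic regression with a warning.
    """
    m = np.asarray(means, dtype=float)
    y = np.asarray(labels).astype(float)
    if len(np.unique(y)) < 2 or min((y == 1).sum(), (y == 0).sum()) < 2:
        raise ValueError("need >=2 patients in each class to fit the signature")
    X = sm.add_constant(m)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        params = np.asarray(res.params)
        if not np.all(np.isfinite(params)) or np.abs(params).max() > 1e4:
            raise RuntimeError("divergent logistic fit")
        return PathologySignature(beta0=float(params[0]), beta1=float(params[1]))
    except Exception:
        warnings.warn(
            "logistic MLE failed (likely perfect separation); "
            "falling back to ridge penalty 1e-4",
            stacklevel=2,
        )
        lr = LogisticRegression(C=1.0 / 1e-4, solver="lbfgs", max_iter=5000)
        lr.fit(m.reshape(-1, 1), y)
        return PathologySignature(
            beta0=float(lr.intercept_[0]), beta1=float(lr.coef_[0, 0]), ridge_fallback=True
        )


# ---------------------------------------------------------------------------
# multivariable adjustment
# ---------------------------------------------------------------------------

@dataclass
class MultivariableModel:
    """Logistic model of outcome on the pathology score + clinical covariates."""

    summary: pd.DataFrame  # coef, se, odds_ratio, ci_low, ci_high, p_value
    converged: bool

    def p_value(self, term: str) -> float:
        return float(self.summary.loc[term, "p_value"])


def _design_matrix(table: pd.DataFrame, score_col: str) -> pd.DataFrame:
    cols: dict[str, np.ndarray] = {}
    if "age" in table:
        cols["age"] = table["age"].astype(float).to_numpy()
    for var, ref in COVARIATE_REFERENCES.items():
        if var not in table:
            continue
        values = table[var].astype(str)
        for level in sorted(values.unique()):
            if level == ref:
                continue
            cols[f"{var}[{level}]"] = (values == level).astype(float).to_numpy()
    cols[score_col] = table[score_col].astype(float).to_numpy()
    return pd.DataFrame(cols, index=table.index)


def fit_multivariable(
    table: pd.DataFrame, score_col: str = "pathology_score", label_col: str = "label",
    positive: str = "PR",
) -> MultivariableModel:
    """Multivariable logistic regression with Wald tests and odds ratios.

    Categorical covariates are dummy-coded against fixed references
    (gender=male, T3, N0, CEA=normal); age and the pathology score enter
    continuously.  Exactly collinear columns raise an error naming them.
    """
    y = (table[label_col].astype(str) == positive).astype(float).to_numpy()
    X = _design_matrix(table, score_col)
    Xv = X.to_numpy()
    # identify exact collinearity (including constant columns) by rank growth
    if np.linalg.matrix_rank(np.column_stack([np.ones(len(X)), Xv])) < X.shape[1] + 1:
        bad = []
        base = np.ones((len(X), 1))
        for name in X.columns:
            cand = np.column_stack([base, X[name].to_numpy()])
            if np.linalg.matrix_rank(cand) == base.shape[1]:
                bad.append(name)
            else:
                base = cand
        raise ValueError(f"collinear design columns: {bad}")
    design = sm.add_constant(X)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, design).fit(disp=0, maxiter=500)
            converged = bool(res.mle_retvals.get("converged", True))
            params, bse, pvals = res.params, res.bse, res.pvalues
        except Exception:
            # quasi-separation: ridge-stabilized fallback, Wald stats approximate
            lr = LogisticRegression(C=1e4, solver="lbfgs", max_iter=5000)
            lr.fit(Xv, y)
            params = pd.Series(
                np.concatenate([[lr.intercept_[0]], lr.coef_[0]]), index=design.columns
            )
            bse = pd.Series(np.full(len(params), np.nan), index=design.columns)
            pvals = bse.copy()
            converged = False
    z = 1.959963984540054
    summary = pd.DataFrame(
        {
            "coef": params,
            "se": bse,
            "odds_ratio": np.exp(params),
            "ci_low": np.exp(params - z * bse),
            "ci_high": np.exp(params + z * bse),
            "p_value": pvals,
        }
    )
    return MultivariableModel(summary=summary, converged=converged)
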