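"""Cohort splitting and performance evaluation of the pathology signature.

Covers the four evaluation axes of a clinical prediction model:
discrimination (ROC/AUC with bootstrap or DeLong confidence intervals,
threshold metrics at the Youden-optimal cutoff), calibration
(equal-frequency calibration curve and the Hosmer-Lemeshow chi-square
test), clinical utility (decision-curve net benefit), and baseline-table
univariable association tests (chi-square / Fisher / Mann-Whitney).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import train_test_split

__all__ = [
    "RocResult",
    "ThresholdMetrics",
    "HLResult",
    "GroupComparison",
    "split_cohort",
    "compute_auc",
    "delong_ci",
    "bootstrap_ci",
    "youden_threshold",
    "threshold_metrics",
    "calibration_curve",
    "hosmer_lemeshow",
    "decision_curve",
    "univariable_tests",
    "summarize_cohort",
]


# ---------------------------------------------------------------------------
# cohort split
# ---------------------------------------------------------------------------

def split_cohort(
    patients: pd.DataFrame,
    ratio: float = 0.8,
    seed: int = 0,
    stratify: bool = True,
    label_col: str = "label",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random primary/validation split of the patient table.

    Primary size is floor(n * ratio) — a 151-patient cohort at 80:20
    yields (120, 31).  Stratification keeps the outcome prevalence
    matched between the two datasets.
    """
    if not (0.0 < ratio < 1.0):
        raise ValueError("ratio must lie strictly in (0, 1)")
    n = len(patients)
    if n < 5:
        raise ValueError("need at least 5 patients to split")
    n_primary = int(n * ratio)
    strat = patients[label_col] if stratify else None
    primary, validation = train_test_split(
        patients, train_size=n_primary, random_state=seed, stratify=strat, shuffle=True
    )
    return primary, validation


# ---------------------------------------------------------------------------
# discrimination
# ---------------------------------------------------------------------------

@dataclass
class RocResult:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    n_pos: int
    n_neg: int
    ci: "tuple[float, float] | None" = None
    ci_method: "str | None" = None


def _check_two_classes(labels: np.ndarray) -> None:
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")


def compute_auc(
    scores,
    labels,
    ci: "str | None" = None,
    B: int = 2000,
    level: float = 0.95,
    seed: int = 0,
) -> RocResult:
    """ROC curve and rank-sum (Mann-Whitney) AUC; ties count 1/2.

    ``ci`` may be "bootstrap" (stratified percentile) or "delong".
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    _check_two_classes(labels)
    fpr, tpr, thr = roc_curve(labels, scores)
    auc = float(roc_auc_score(labels, scores))
    result = RocResult(
        fpr=fpr,
        tpr=tpr,
        thresholds=thr,
        auc=auc,
        n_pos=int((labels == 1).sum()),
        n_neg=int((labels == 0).sum()),
    )
    if ci == "bootstrap":
        result.ci = bootstrap_ci(
            lambda s, l: roc_auc_score(l, s), scores, labels, B=B, level=level, seed=seed
        )
        result.ci_method = "bootstrap"
    elif ci == "delong":
        result.ci = delong_ci(scores, labels, level=level)
        result.ci_method = "delong"
    elif ci is not None:
        raise ValueError("ci must be None, 'bootstrap' or 'delong'")
    return result


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def delong_ci(scores, labels, level: float = 0.95) -> tuple[float, float]:
    """DeLong variance estimate of the AUC with a normal-theory interval."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    _check_two_classes(labels)
    pos, neg = scores[labels == 1], scores[labels == 0]
    m, n = len(pos), len(neg)
    all_ranks = _midrank(np.concatenate([pos, neg]))
    pos_ranks, neg_ranks = _midrank(pos), _midrank(neg)
    auc = (all_ranks[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v01 = (all_ranks[:m] - pos_ranks) / n          # structural components, positives
    v10 = 1.0 - (all_ranks[m:] - neg_ranks) / m    # structural components, negatives
    var = np.var(v01, ddof=1) / m + np.var(v10, ddof=1) / n
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(var)
    return (float(max(0.0, auc - half)), float(min(1.0, auc + half)))


def bootstrap_ci(
    metric_fn,
    scores,
    labels,
    B: int = 2000,
    level: float = 0.95,
    seed: int = 0,
    stratified: bool = True,
) -> tuple[float, float]:
    """Percentile bootstrap CI of ``metric_fn(scores, labels)``.

    Resampling is stratified within class by default so every resample
    contains both classes; with ``stratified=False``, degenerate
    one-class resamples are redrawn (the count is recorded in a
    warning when it happens).
    """
    if B < 100:
        raise ValueError("B must be >= 100")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    rng = np.random.default_rng(seed)
    idx_pos = np.flatnonzero(labels == 1)
    idx_neg = np.flatnonzero(labels == 0)
    values = np.empty(B)
    redrawn = 0
    for b in range(B):
        if stratified:
            take = np.concatenate(
                [
                    rng.choice(idx_pos, size=len(idx_pos), replace=True),
                    rng.choice(idx_neg, size=len(idx_neg), replace=True),
                ]
            )
        else:
            while True:
                take = rng.integers(0, len(labels), size=len(labels))
                if len(np.unique(labels[take])) > 1:
                    break
                redrawn += 1
        values[b] = metric_fn(scores[take], labels[take])
    if redrawn:
        warnings.warn(f"redrew {redrawn} one-class bootstrap resamples", stacklevel=2)
    lo, hi = np.quantile(values, [(1 - level) / 2.0, 0.5 + level / 2.0])
    return (float(lo), float(hi))


@dataclass
class ThresholdMetrics:
    threshold: float
    accuracy: float
    sensitivity: float
    specificity: float
    f1: float
    tp: int
    fp: int
    tn: int
    fn: int
    ci: dict = field(default_factory=dict)


def youden_threshold(scores, labels) -> float:
    """Score cutoff maximizing Youden's J = sensitivity + specificity - 1."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    _check_two_classes(labels)
    fpr, tpr, thr = roc_curve(labels, scores)
    j = tpr - fpr
    return float(thr[np.argmax(j)])


def threshold_metrics(
    scores,
    labels,
    threshold: float = 0.5,
    ci: bool = False,
    B: int = 2000,
    seed: int = 0,
) -> ThresholdMetrics:
    """Confusion-matrix metrics at ``score >= threshold``.

    F1 is 0 when precision + sensitivity is 0 (no true or predicted
    positives).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pred = scores >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    tn = int(np.sum(~pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    acc = (tp + tn) / len(labels)
    prec = tp / (tp + fp) if tp + fp else 0.0
    f1 = 2 * prec * sens / (prec + sens) if prec + sens else 0.0
    out = ThresholdMetrics(
        threshold=float(threshold), accuracy=acc, sensitivity=sens,
        specificity=spec, f1=f1, tp=tp, fp=fp, tn=tn, fn=fn,
    )
    if ci:
        def metric(name):
            def fn_(s, l):
                return getattr(threshold_metrics(s, l, threshold), name)
            return fn_

        for name in ("accuracy", "sensitivity", "specificity", "f1"):
            out.ci[name] = bootstrap_ci(metric(name), scores, labels, B=B, seed=seed)
    return out


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

def _quantile_bins(scores: np.ndarray, g: int) -> np.ndarray:
    """Equal-frequency bin index per observation; tied edges merge bins."""
    edges = np.quantile(scores, np.linspace(0, 1, g + 1))
    edges = np.unique(edges)
    if len(edges) - 1 < g:
        warnings.warn(
            f"score ties collapse {g} bins into {max(1, len(edges) - 1)}", stacklevel=3
        )
    if len(edges) < 2:  # constant score
        return np.zeros(len(scores), dtype=int)
    return np.clip(np.searchsorted(edges, scores, side="right") - 1, 0, len(edges) - 2)


def calibration_curve(scores, labels, g: int = 10) -> pd.DataFrame:
    """Decile (equal-frequency) calibration table.

    Returns one row per bin with size, mean predicted probability and
    observed event fraction.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if len(scores) < g:
        raise ValueError("need at least g observations")
    bins = _quantile_bins(scores, g)
    rows = []
    for b in np.unique(bins):
        sel = bins == b
        rows.append(
            {
                "bin": int(b),
                "n": int(sel.sum()),
                "mean_predicted": float(scores[sel].mean()),
                "observed_fraction": float(labels[sel].mean()),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class HLResult:
    statistic: float
    df: int
    p_value: float
    table: pd.DataFrame  # per-bin n, observed, expected


def hosmer_lemeshow(scores, labels, g: int = 10) -> HLResult:
    """Hosmer-Lemeshow goodness-of-fit chi-square over score deciles.

    H = sum over bins of (O - E)^2 / (E * (1 - E/n_bin)); p-value from a
    chi-square distribution with g - 2 degrees of freedom.  Bins where
    the variance term vanishes (all predicted 0 or 1) are merged into a
    neighbor with a warning.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if len(scores) < 2 * g:
        raise ValueError(f"need at least {2 * g} observations for g={g} bins")
    bins = _quantile_bins(scores, g)
    ids = np.unique(bins)
    n_b = np.array([(bins == b).sum() for b in ids], dtype=float)
    obs = np.array([labels[bins == b].sum() for b in ids], dtype=float)
    exp = np.array([scores[bins == b].sum() for b in ids], dtype=float)
    var = exp * (1.0 - exp / n_b)
    while np.any(var <= 0) and len(n_b) > 1:
        k = int(np.argmax(var <= 0))
        j = k - 1 if k > 0 else k + 1
        warnings.warn("merging a degenerate Hosmer-Lemeshow bin", stacklevel=2)
        n_b[j] += n_b[k]
        obs[j] += obs[k]
        exp[j] += exp[k]
        n_b, obs, exp = np.delete(n_b, k), np.delete(obs, k), np.delete(exp, k)
        var = exp * (1.0 - exp / n_b)
    h = float((((obs - exp) ** 2) / var).sum())
    df = max(1, len(n_b) - 2)
    p = float(stats.chi2.sf(h, df))
    table = pd.DataFrame({"n": n_b.astype(int), "observed": obs, "expected": exp})
    return HLResult(statistic=h, df=df, p_value=p, table=table)


# ---------------------------------------------------------------------------
# decision curve analysis
# ---------------------------------------------------------------------------

def decision_curve(scores, labels, thresholds=None) -> pd.DataFrame:
    """Net benefit of the model vs treat-all vs treat-none.

    NB(t) = TP(t)/N - FP(t)/N * t/(1-t); the treat-all strategy has
    NB = pi - (1-pi) * t/(1-t) where pi is prevalence; treat-none is 0.
    Thresholds at or above 1 are excluded.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    _check_two_classes(labels)
    if thresholds is None:
        thresholds = np.arange(0.01, 1.0, 0.01)
    thresholds = np.asarray(thresholds, dtype=float)
    thresholds = thresholds[(thresholds > 0) & (thresholds < 1)]
    n = len(labels)
    pi = labels.mean()
    rows = []
    for t in thresholds:
        pred = scores >= t
        tp = np.sum(pred & (labels == 1))
        fp = np.sum(pred & (labels == 0))
        odds = t / (1.0 - t)
        rows.append(
            {
                "threshold": float(t),
                "net_benefit_model": float(tp / n - fp / n * odds),
                "net_benefit_all": float(pi - (1 - pi) * odds),
                "net_benefit_none": 0.0,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# baseline-table statistics
# ---------------------------------------------------------------------------

@dataclass
class GroupComparison:
    variable: str
    test: str
    statistic: float
    p_value: float
    df: "int | None" = None


#: Default typing of the cohort-table variables.
DEFAULT_VARIABLE_TYPES = {
    "age": "continuous",
    "gender": "categorical",
    "t_stage": "categorical",
    "n_stage": "categorical",
    "cea": "categorical",
    "mean_prob": "continuous",
    "pathology_score": "continuous",
}


def _categorical_test(
    table: np.ndarray, variable: str, continuity: bool = True
) -> GroupComparison:
    """Pearson chi-square; Yates continuity correction on 2x2 tables by
    default (the convention that reproduces standard baseline tables),
    and Fisher's exact test when a 2x2 table has any expected cell
    below 5."""
    chi2, p, df, expected = stats.chi2_contingency(table, correction=continuity)
    if (expected < 5).any() and table.shape == (2, 2):
        _, p = stats.fisher_exact(table)
        return GroupComparison(variable, "fisher", float("nan"), float(p))
    if (expected < 5).any():
        warnings.warn(
            f"{variable}: expected cell < 5 in a >2x2 table; chi-square approximate",
            stacklevel=3,
        )
    return GroupComparison(variable, "chi-square", float(chi2), float(p), df=int(df))


def univariable_tests(
    cohort: pd.DataFrame,
    label_col: str = "label",
    variable_types: "dict[str, str] | None" = None,
    continuous_test: str = "mann-whitney",
    continuity: bool = True,
) -> list[GroupComparison]:
    """Per-variable association tests against the outcome label.

    Categorical variables get a Pearson chi-square (Yates-corrected on
    2x2 tables unless ``continuity=False``; Fisher exact for sparse 2x2
    tables); continuous variables a
    Mann-Whitney U by default (Welch t-test via
    ``continuous_test="t"``).  Single-category variables are skipped
    with a warning.
    """
    types = dict(DEFAULT_VARIABLE_TYPES)
    if variable_types:
        types.update(variable_types)
    groups = cohort[label_col]
    levels = sorted(groups.astype(str).unique())
    results: list[GroupComparison] = []
    for var, kind in types.items():
        if var not in cohort.columns:
            continue
        if kind == "categorical":
            tab = pd.crosstab(cohort[var], groups)
            if tab.shape[0] < 2 or tab.shape[1] < 2:
                warnings.warn(f"skipping single-category variable {var!r}", stacklevel=2)
                continue
            results.append(_categorical_test(tab.to_numpy(), var, continuity))
        else:
            a = cohort.loc[groups.astype(str) == levels[0], var].astype(float)
            b = cohort.loc[groups.astype(str) == levels[-1], var].astype(float)
            if continuous_test == "mann-whitney":
                stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
                results.append(GroupComparison(var, "mann-whitney", float(stat), float(p)))
            elif continuous_test == "t":
                stat, p = stats.ttest_ind(a, b, equal_var=False)
                results.append(GroupComparison(var, "t", float(stat), float(p)))
            else:
                raise ValueError("continuous_test must be 'mann-whitney' or 't'")
    return results


def summarize_cohort(
    cohort: pd.DataFrame,
    label_col: str = "label",
    variable_types: "dict[str, str] | None" = None,
) -> pd.DataFrame:
    """Baseline characteristics table stratified by outcome.

    Categorical variables are reported as ``count (percent%)`` with
    percentages within each outcome column; continuous ones as
    ``mean +/- SD`` and ``median (IQR)``.
    """
    types = dict(DEFAULT_VARIABLE_TYPES)
    if variable_types:
        types.update(variable_types)
    groups = sorted(cohort[label_col].astype(str).unique())
    rows = []
    for var, kind in types.items():
        if var not in cohort.columns:
            continue
        if kind == "categorical":
            for level in sorted(cohort[var].astype(str).unique()):
                row = {"variable": var, "level": level}
                for grp in groups:
                    sub = cohort[cohort[label_col].astype(str) == grp]
                    n = int((sub[var].astype(str) == level).sum())
                    pct = 100.0 * n / len(sub) if len(sub) else float("nan")
                    row[grp] = f"{n} ({pct:.1f}%)"
                    row[f"{grp}_pct"] = pct
                rows.append(row)
        else:
            row = {"variable": var, "level": "mean±sd"}
            row_med = {"variable": var, "level": "median(IQR)"}
            for grp in groups:
                vals = cohort.loc[cohort[label_col].astype(str) == grp, var].astype(float)
                row[grp] = f"{vals.mean():.1f} ± {vals.std():.1f}"
                q1, q2, q3 = vals.quantile([0.25, 0.5, 0.75])
                row_med[grp] = f"{q2:.3f} ({q1:.3f} to {q3:.3f})"
            rows.extend([row, row_med])
    return pd.DataFrame(rows)
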