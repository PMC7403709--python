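"""Configuration-driven pipeline runner.

Wires the stages end to end — simulate -> (tile) -> features -> split ->
standardize -> LASSO select -> SVM train -> aggregate -> signature ->
evaluate — with one root seed fanned out into per-stage substreams, and
writes diff-able artifacts (CSV tables, JSON models/metrics) plus a
manifest recording the configuration and seed that produced them.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import evaluation, modeling
from .synthetic import SyntheticCohort, SyntheticCohortConfig, generate_cohort
from .texture import GlcmConfig, extract_features, feature_names

__all__ = ["PipelineConfig", "run_pipeline", "PipelineInputError", "StageError"]

log = logging.getLogger("pathosig")


class PipelineInputError(ValueError):
    """Invalid configuration or missing/malformed input artifact."""


class StageError(RuntimeError):
    """A pipeline stage failed; partial artifacts are retained."""


@dataclass
class PipelineConfig:
    """All knobs of a full synthetic-demo run.

    The root ``seed`` fans out into named substreams (cohort generation,
    split, LASSO folds, SVM folds, bootstrap), so per-stage re-runs are
    reproducible without re-running earlier stages.
    """

    seed: int = 0
    cohort: SyntheticCohortConfig = field(default_factory=SyntheticCohortConfig)
    glcm: GlcmConfig = field(default_factory=GlcmConfig)
    split_ratio: float = 0.8
    lasso_folds: int = 10
    lasso_alphas: int = 50
    lasso_rule: str = "min"
    svm_folds: int = 5
    c_grid: tuple = modeling.DEFAULT_C_GRID
    gamma_grid: tuple = modeling.DEFAULT_GAMMA_GRID
    bootstrap_B: int = 2000
    hl_bins: int = 10
    ci_method: str = "bootstrap"

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage 31-bit seed derived from the root seed."""
        digest = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(digest[:4], "big") % (2**31)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise PipelineInputError(f"unknown config keys: {sorted(unknown)}")
        if "cohort" in data and isinstance(data["cohort"], dict):
            try:
                data["cohort"] = SyntheticCohortConfig(**data["cohort"])
            except TypeError as exc:
                raise PipelineInputError(f"bad cohort config: {exc}") from None
        if "glcm" in data and isinstance(data["glcm"], dict):
            g = dict(data["glcm"])
            for key in ("distances", "angles"):
                if key in g:
                    g[key] = tuple(g[key])
            data["glcm"] = GlcmConfig(**g)
        for key in ("c_grid", "gamma_grid"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        path = Path(path)
        if not path.exists():
            raise PipelineInputError(f"config file not found: {path}")
        return cls.from_dict(yaml.safe_load(path.read_text()) or {})

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["c_grid"] = list(self.c_grid)
        d["gamma_grid"] = list(self.gamma_grid)
        d["glcm"]["distances"] = list(self.glcm.distances)
        d["glcm"]["angles"] = list(self.glcm.angles)
        return d


def demo_config(seed: int = 0, strong: bool = True) -> PipelineConfig:
    """A cohort sized for a quick one-command demonstration:
    60 patients with 10-20 tumor tiles each and a strong class effect."""
    return PipelineConfig(
        seed=seed,
        cohort=SyntheticCohortConfig(
            n_patients=60,
            tiles_per_patient_min=10,
            tiles_per_patient_max=20,
            effect_size=1.0 if strong else 0.0,
            seed=seed,
        ),
        bootstrap_B=500,
    )


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def compute_cohort_features(
    cohort: SyntheticCohort, config: GlcmConfig = GlcmConfig()
) -> pd.DataFrame:
    """Texture features of every tile; tiles rendered and discarded in turn."""
    rows = {}
    owners = {}
    for tid, pid, img in cohort.iter_tiles():
        rows[tid] = extract_features(img, config)
        owners[tid] = pid
    feats = pd.DataFrame.from_dict(rows, orient="index")[feature_names(config)]
    feats.insert(0, "patient_id", pd.Series(owners))
    feats.index.name = "tile_id"
    return feats


def features_from_tiles_dir(tiles_dir, config: GlcmConfig = GlcmConfig()) -> pd.DataFrame:
    """Feature table from a directory of {patient}_{...}.png tiles."""
    from PIL import Image

    tiles_dir = Path(tiles_dir)
    paths = sorted(tiles_dir.glob("*.png"))
    if not paths:
        raise PipelineInputError(f"no PNG tiles found in {tiles_dir}")
    rows, owners = {}, {}
    for p in paths:
        tid = p.stem
        rows[tid] = extract_features(np.asarray(Image.open(p).convert("RGB")), config)
        owners[tid] = tid.split("_")[0]
    feats = pd.DataFrame.from_dict(rows, orient="index")[feature_names(config)]
    feats.insert(0, "patient_id", pd.Series(owners))
    feats.index.name = "tile_id"
    return feats


def _evaluate_cohort(
    scores: np.ndarray,
    labels: np.ndarray,
    threshold: float,
    config: PipelineConfig,
    seed: int,
) -> dict:
    roc = evaluation.compute_auc(
        scores, labels, ci=config.ci_method, B=config.bootstrap_B, seed=seed
    )
    tm = evaluation.threshold_metrics(scores, labels, threshold)
    out = {
        "n": int(len(labels)),
        "n_pr": int(labels.sum()),
        "auc": roc.auc,
        "auc_ci": list(roc.ci) if roc.ci else None,
        "threshold": threshold,
        "accuracy": tm.accuracy,
        "sensitivity": tm.sensitivity,
        "specificity": tm.specificity,
        "f1": tm.f1,
    }
    g = config.hl_bins if len(labels) >= 2 * config.hl_bins else max(3, len(labels) // 4)
    if len(labels) >= 2 * g:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            hl = evaluation.hosmer_lemeshow(scores, labels, g=g)
            cal = evaluation.calibration_curve(scores, labels, g=g)
        out["hosmer_lemeshow"] = {
            "statistic": hl.statistic, "df": hl.df, "p_value": hl.p_value, "bins": g,
        }
        out["calibration"] = cal.to_dict(orient="records")
    else:
        out["hosmer_lemeshow"] = None
        out["calibration"] = None
    dc = evaluation.decision_curve(scores, labels)
    out["decision_curve"] = {
        "threshold": dc["threshold"].round(4).tolist(),
        "net_benefit_model": dc["net_benefit_model"].tolist(),
        "net_benefit_all": dc["net_benefit_all"].tolist(),
    }
    return out


def run_pipeline(
    config: PipelineConfig,
    outdir=None,
    features: "pd.DataFrame | None" = None,
    patients: "pd.DataFrame | None" = None,
) -> dict:
    """Execute the full analysis and return the evaluation report.

    When ``features``/``patients`` are given (e.g. loaded from stage
    artifacts) the simulation and feature stages are skipped.  When
    ``outdir`` is set every stage artifact is written there.
    """
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)

    def _save_df(df: pd.DataFrame, name: str, index: bool = True) -> None:
        if outdir is not None:
            df.to_csv(outdir / name, index=index)

    try:
        if features is None or patients is None:
            log.info("stage simulate: generating synthetic cohort")
            cohort = generate_cohort(
                dataclasses.replace(config.cohort, seed=config.stage_seed("simulate"))
            )
            patients = cohort.patient_table()
            log.info("stage features: %d tiles", len(cohort.tile_ids))
            features = compute_cohort_features(cohort, config.glcm)
        patients = patients.set_index("patient_id", drop=False) \
            if "patient_id" in patients else patients
        _save_df(patients, "cohort.csv", index=False)
        _save_df(features, "features.csv")
    except (PipelineInputError, StageError):
        raise
    except Exception as exc:
        raise StageError(f"simulate/features stage failed: {exc}") from exc

    try:
        log.info("stage split: ratio %.2f", config.split_ratio)
        primary_pat, validation_pat = evaluation.split_cohort(
            patients, ratio=config.split_ratio, seed=config.stage_seed("split")
        )
        cohort_of = pd.Series("primary", index=patients.index)
        cohort_of[validation_pat.index] = "validation"
        tile_cohort = features["patient_id"].map(cohort_of)
        tile_label = (
            features["patient_id"].map(patients["label"]) == "PR"
        ).astype(int)

        X = features.drop(columns="patient_id")
        prim_mask = (tile_cohort == "primary").to_numpy()
        log.info("stage standardize: %d primary tiles", int(prim_mask.sum()))
        std = modeling.standardize_fit(X[prim_mask])
        Xz = modeling.standardize_apply(std, X)

        log.info("stage select: LASSO with %d-fold grouped CV", config.lasso_folds)
        lasso = modeling.lasso_select(
            Xz[prim_mask],
            tile_label[prim_mask],
            groups=features["patient_id"][prim_mask],
            n_folds=config.lasso_folds,
            n_alphas=config.lasso_alphas,
            rule=config.lasso_rule,
            seed=config.stage_seed("lasso"),
        )
        if not lasso.selected:
            warnings.warn(
                "LASSO selected zero features; falling back to an "
                "uninformative prevalence model",
                stacklevel=2,
            )
        log.info("selected %d features", len(lasso.selected))
    except (PipelineInputError, StageError):
        raise
    except Exception as exc:
        raise StageError(f"select stage failed: {exc}") from exc

    try:
        if not lasso.selected:
            # no informative texture: every tile gets the primary prevalence,
            # the signature is flat, and discrimination collapses to chance
            prevalence = float(tile_label[prim_mask].mean())
            tile_probs = pd.Series(prevalence, index=features.index, name="prob")
            tile_table = pd.DataFrame(
                {"patient_id": features["patient_id"], "prob": tile_probs,
                 "cohort": tile_cohort, "label": tile_label}
            )
            _save_df(tile_table, "tile_probs.csv")
            pat = patients.copy()
            pat["cohort"] = cohort_of
            pat["mean_prob"] = modeling.aggregate_patients(tile_table)
            pat = pat.dropna(subset=["mean_prob"])
            from scipy.special import logit as _logit

            signature = modeling.PathologySignature(
                beta0=float(_logit(prevalence)), beta1=0.0
            )
            clf = None
            pat["pathology_score"] = signature.score(pat["mean_prob"])
            _save_df(
                pat[["patient_id", "label", "cohort", "mean_prob", "pathology_score"]],
                "patient_scores.csv",
                index=False,
            )
        else:
            log.info("stage train: RBF-SVM grid search")
            clf = modeling.train_tile_classifier(
                Xz.loc[prim_mask, lasso.selected],
                tile_label[prim_mask],
                cv_folds=config.svm_folds,
                C_grid=config.c_grid,
                gamma_grid=config.gamma_grid,
                seed=config.stage_seed("svm"),
            )
            tile_probs = pd.Series(
                clf.predict_proba(Xz[lasso.selected]), index=features.index, name="prob"
            )
            tile_table = pd.DataFrame(
                {"patient_id": features["patient_id"], "prob": tile_probs,
                 "cohort": tile_cohort, "label": tile_label}
            )
            _save_df(tile_table, "tile_probs.csv")

            means = modeling.aggregate_patients(tile_table)
            pat = patients.copy()
            pat["cohort"] = cohort_of
            pat["mean_prob"] = means
            pat = pat.dropna(subset=["mean_prob"])
            sig_mask = pat["cohort"] == "primary"
            signature = modeling.fit_signature(
                pat.loc[sig_mask, "mean_prob"],
                (pat.loc[sig_mask, "label"] == "PR").astype(int),
            )
            pat["pathology_score"] = signature.score(pat["mean_prob"])
            _save_df(
                pat[["patient_id", "label", "cohort", "mean_prob", "pathology_score"]],
                "patient_scores.csv",
                index=False,
            )
    except (PipelineInputError, StageError):
        raise
    except Exception as exc:
        raise StageError(f"train stage failed: {exc}") from exc

    try:
        log.info("stage evaluate")
        report = evaluate_scores(pat, tile_table, config)
        report["selected_features"] = lasso.selected
        report["chosen_alpha"] = lasso.chosen_alpha
        report["svm"] = (
            {"C": clf.C, "gamma": clf.gamma, "cv_auc": clf.cv_auc} if clf else None
        )
        report["signature"] = {
            "beta0": signature.beta0,
            "beta1": signature.beta1,
            "ridge_fallback": signature.ridge_fallback,
        }
        report["seed"] = config.seed
        if outdir is not None:
            (outdir / "model.json").write_text(
                json.dumps(
                    {
                        "standardization": {
                            "mean": std.mean.to_dict(), "sd": std.sd.to_dict()
                        },
                        "selected_features": lasso.selected,
                        "svm": {"C": clf.C, "gamma": clf.gamma} if clf else None,
                        "signature": {"beta0": signature.beta0, "beta1": signature.beta1},
                    },
                    indent=2,
                    sort_keys=True,
                )
            )
            (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
            manifest = {
                "config": config.to_dict(),
                "seed": config.seed,
                "versions": _versions(),
                "config_sha256": hashlib.sha256(
                    json.dumps(config.to_dict(), sort_keys=True).encode()
                ).hexdigest(),
            }
            (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        return report
    except (PipelineInputError, StageError):
        raise
    except Exception as exc:
        raise StageError(f"evaluate stage failed: {exc}") from exc


def evaluate_scores(
    patient_scores: pd.DataFrame,
    tile_table: "pd.DataFrame | None",
    config: PipelineConfig,
) -> dict:
    """Evaluation report from the per-patient score table (and optionally
    the per-tile probability table)."""
    pat = patient_scores
    seed = config.stage_seed("bootstrap")
    y_prim = (pat.loc[pat["cohort"] == "primary", "label"] == "PR").to_numpy(int)
    s_prim = pat.loc[pat["cohort"] == "primary", "pathology_score"].to_numpy(float)
    y_val = (pat.loc[pat["cohort"] == "validation", "label"] == "PR").to_numpy(int)
    s_val = pat.loc[pat["cohort"] == "validation", "pathology_score"].to_numpy(float)
    threshold = evaluation.youden_threshold(s_prim, y_prim)

    report: dict = {"patient_level": {}, "tile_level": {}}
    report["patient_level"]["primary"] = _evaluate_cohort(
        s_prim, y_prim, threshold, config, seed
    )
    if len(np.unique(y_val)) > 1:
        report["patient_level"]["validation"] = _evaluate_cohort(
            s_val, y_val, threshold, config, seed + 1
        )
    else:
        report["patient_level"]["validation"] = None

    if tile_table is not None:
        for name in ("primary", "validation"):
            sub = tile_table[tile_table["cohort"] == name]
            labels = sub["label"].to_numpy(int)
            if len(np.unique(labels)) > 1:
                t_thr = evaluation.youden_threshold(
                    tile_table.loc[tile_table["cohort"] == "primary", "prob"],
                    tile_table.loc[tile_table["cohort"] == "primary", "label"],
                )
                tm = evaluation.threshold_metrics(sub["prob"], labels, t_thr)
                roc = evaluation.compute_auc(
                    sub["prob"], labels, ci=config.ci_method, B=config.bootstrap_B,
                    seed=seed + 2,
                )
                report["tile_level"][name] = {
                    "n": int(len(sub)),
                    "auc": roc.auc,
                    "auc_ci": list(roc.ci) if roc.ci else None,
                    "accuracy": tm.accuracy,
                    "sensitivity": tm.sensitivity,
                    "specificity": tm.specificity,
                    "f1": tm.f1,
                }
            else:
                report["tile_level"][name] = None

    # baseline-table statistics on the primary dataset
    prim = pat[pat["cohort"] == "primary"]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tests = evaluation.univariable_tests(prim)
    report["univariable"] = [dataclasses.asdict(t) for t in tests]
    covars = [c for c in ("age", "gender", "t_stage", "n_stage", "cea") if c in prim]
    if covars and len(prim) >= 20:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                mv = modeling.fit_multivariable(prim)
            report["multivariable"] = {
                term: {
                    "coef": float(row["coef"]),
                    "odds_ratio": float(row["odds_ratio"]),
                    "p_value": float(row["p_value"]),
                }
                for term, row in mv.summary.iterrows()
            }
        except ValueError as exc:
            report["multivariable"] = {"error": str(exc)}
    else:
        report["multivariable"] = None
    return report


def _versions() -> dict:
    import sklearn
    import skimage
    import statsmodels

    return {
        "python": sys.version.split()[0],
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scikit-learn": sklearn.__version__,
        "scikit-image": skimage.__version__,
        "statsmodels": statsmodels.__version__,
    }
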