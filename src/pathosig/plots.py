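"""Figure-style plots of a saved evaluation report: ROC, calibration,
decision curves (one panel per cohort)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np


def plot_roc(scores_by_cohort: dict, labels_by_cohort: dict, path) -> None:
    from .evaluation import compute_auc

    fig, ax = plt.subplots(figsize=(5, 5))
    for name, scores in scores_by_cohort.items():
        roc = compute_auc(scores, labels_by_cohort[name])
        ax.plot(roc.fpr, roc.tpr, label=f"{name} (AUC {roc.auc:.3f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_calibration(report: dict, path) -> None:
    fig, ax = plt.subplots(figsize=(5, 5))
    for name, res in report["patient_level"].items():
        if not res or not res.get("calibration"):
            continue
        cal = res["calibration"]
        ax.plot(
            [b["mean_predicted"] for b in cal],
            [b["observed_fraction"] for b in cal],
            "o-",
            label=name,
        )
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("predicted probability")
    ax.set_ylabel("observed PR fraction")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_decision_curve(report: dict, path) -> None:
    fig, axes = plt.subplots(
        1, len(report["patient_level"]), figsize=(10, 4.5), squeeze=False
    )
    for ax, (name, res) in zip(axes[0], report["patient_level"].items()):
        if not res:
            ax.set_visible(False)
            continue
        dc = res["decision_curve"]
        t = np.asarray(dc["threshold"])
        ax.plot(t, dc["net_benefit_model"], label="signature")
        ax.plot(t, dc["net_benefit_all"], label="treat all")
        ax.axhline(0.0, color="k", lw=0.8, label="treat none")
        ax.set_ylim(-0.1, max(dc["net_benefit_model"]) + 0.1)
        ax.set_xlabel("threshold probability")
        ax.set_ylabel("net benefit")
        ax.set_title(name)
        ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def render_report(report: dict, patient_scores, outdir) -> list[Path]:
    """Render the standard panel set from a report + score table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    scores, labels = {}, {}
    for name in ("primary", "validation"):
        sub = patient_scores[patient_scores["cohort"] == name]
        if sub["label"].nunique() > 1:
            scores[name] = sub["pathology_score"].to_numpy(float)
            labels[name] = (sub["label"] == "PR").to_numpy(int)
    p = outdir / "roc.png"
    plot_roc(scores, labels, p)
    paths.append(p)
    p = outdir / "calibration.png"
    plot_calibration(report, p)
    paths.append(p)
    p = outdir / "decision_curve.png"
    plot_decision_curve(report, p)
    paths.append(p)
    return paths
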