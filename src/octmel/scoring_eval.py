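"""Volume-level melanoma probability scoring, longitudinal curves, metrics,
and the subject-exclusive cross-validation protocol.

A volume's melanoma probability score is the arithmetic mean of its per-slice
network scores — interpretable as the malignant fraction of the scanned area.
Cross-validation is five-fold with subjects (not images) assigned to folds,
stratified by group; within the non-test folds, images are shuffled and split
9:1 into train and validation.  No subject ever spans the train/val vs test
wall.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve


@dataclass
class SplitPlan:
    """Subject -> fold assignment plus per-fold train/val image rows."""

    subject_fold: dict[str, int]
    n_folds: int
    #: fold -> (train row positions, val row positions) into the image index
    fold_rows: dict[int, tuple[np.ndarray, np.ndarray]]
    seed: int

    def test_subjects(self, fold: int) -> list[str]:
        return sorted(s for s, f in self.subject_fold.items() if f == fold)

    def to_dict(self) -> dict:
        return {
            "n_folds": self.n_folds,
            "seed": self.seed,
            "folds": {str(f): self.test_subjects(f) for f in range(self.n_folds)},
        }


def make_split(index: pd.DataFrame, n_folds: int = 5, val_fraction: float = 0.1,
               seed: int = 0) -> SplitPlan:
    """Build the cross-validation plan.

    ``index`` needs columns subject_id, group and one row per image (a design
    table with one row per volume also works; rows are what gets split 9:1).
    Subjects are stratified by group across folds; for each fold, the images
    of all other subjects are shuffled and split ``1 - val_fraction`` :
    ``val_fraction`` into train and validation.
    """
    subjects = index[["subject_id", "group"]].drop_duplicates()
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    subject_fold: dict[str, int] = {}
    for _, grp in subjects.groupby("group"):
        ids = grp["subject_id"].tolist()
        if len(ids) < n_folds:
            raise ValueError(
                f"need >= {n_folds} subjects per group, got {len(ids)}")
        order = rng.permutation(len(ids))
        for pos, i in enumerate(order):
            subject_fold[ids[i]] = pos % n_folds
    fold_rows = {}
    fold_of_row = index["subject_id"].map(subject_fold).to_numpy()
    for fold in range(n_folds):
        rest = np.flatnonzero(fold_of_row != fold)
        rest = rest[rng.permutation(rest.size)]
        n_train = int(round((1.0 - val_fraction) * rest.size))
        fold_rows[fold] = (np.sort(rest[:n_train]), np.sort(rest[n_train:]))
    return SplitPlan(subject_fold=subject_fold, n_folds=n_folds,
                     fold_rows=fold_rows, seed=seed)


@dataclass
class VolumeScore:
    subject_id: str
    week: int
    score: float
    n_slices: int


def volume_score(predictions: pd.DataFrame) -> VolumeScore:
    """Mean slice score for one (subject, week) volume."""
    if len(predictions) == 0:
        raise ValueError("need >= 1 slice prediction")
    subjects = predictions["subject_id"].unique()
    weeks = predictions["week"].unique()
    if len(subjects) != 1 or len(weeks) != 1:
        raise ValueError("predictions mix subjects or weeks")
    return VolumeScore(subject_id=str(subjects[0]), week=int(weeks[0]),
                       score=float(predictions["score"].mean()),
                       n_slices=len(predictions))


def volume_scores(predictions: pd.DataFrame) -> pd.DataFrame:
    """Per-(subject, week) mean slice score table."""
    rows = [volume_score(g) for _, g in predictions.groupby(["subject_id", "week"])]
    out = pd.DataFrame([r.__dict__ for r in rows])
    if "group" in predictions.columns:
        groups = predictions[["subject_id", "group"]].drop_duplicates()
        out = out.merge(groups, on="subject_id")
    return out.sort_values(["subject_id", "week"]).reset_index(drop=True)


def longitudinal_curves(vol_scores: pd.DataFrame) -> pd.DataFrame:
    """Group mean +/- SD of volume scores per week (no smoothing)."""
    if "group" not in vol_scores.columns:
        raise ValueError("volume scores need a 'group' column")
    out = (vol_scores.groupby(["group", "week"])["score"]
           .agg(mean="mean", sd=lambda s: float(np.std(s, ddof=0)), n="count")
           .reset_index())
    return out


def plot_curves(curves: pd.DataFrame, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    for group, g in curves.groupby("group"):
        ax.errorbar(g["week"], g["mean"], yerr=g["sd"], marker="o",
                    capsize=3, label=group)
    ax.set_xlabel("week")
    ax.set_ylabel("melanoma probability score")
    ax.set_ylim(-0.05, 1.05)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


@dataclass
class EvalReport:
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    accuracy: float
    auc: float | None
    roc_fpr: np.ndarray = field(default_factory=lambda: np.zeros(0))
    roc_tpr: np.ndarray = field(default_factory=lambda: np.zeros(0))
    one_class: bool = False

    def to_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "accuracy": self.accuracy, "auc": self.auc,
        }


def evaluate(scores, labels, threshold: float = 0.5) -> EvalReport:
    """Confusion matrix at ``threshold`` plus ROC/AUC.

    The ROC sweeps every observed score threshold; AUC is the trapezoidal
    area, equivalent to the normalized Mann-Whitney U statistic with the
    rank-average treatment of ties.  With only one class present the AUC is
    undefined (None) but the confusion matrix is still returned.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must align")
    pred = (scores > threshold).astype(int)
    tp = int(np.sum((pred == 1) & (labels == 1)))
    fp = int(np.sum((pred == 1) & (labels == 0)))
    tn = int(np.sum((pred == 0) & (labels == 0)))
    fn = int(np.sum((pred == 0) & (labels == 1)))
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    acc = (tp + tn) / labels.size if labels.size else 0.0
    if len(np.unique(labels)) < 2:
        return EvalReport(tp=tp, fp=fp, tn=tn, fn=fn, sensitivity=sens,
                          specificity=spec, accuracy=acc, auc=None,
                          one_class=True)
    fpr, tpr, _ = roc_curve(labels, scores)
    auc = float(np.trapezoid(tpr, fpr))
    return EvalReport(tp=tp, fp=fp, tn=tn, fn=fn, sensitivity=sens,
                      specificity=spec, accuracy=acc, auc=auc,
                      roc_fpr=fpr, roc_tpr=tpr)


def pool_reports(reports: list[EvalReport]) -> dict:
    """Sum of per-fold confusion matrices plus mean-of-folds metrics."""
    tp = sum(r.tp for r in reports)
    fp = sum(r.fp for r in reports)
    tn = sum(r.tn for r in reports)
    fn = sum(r.fn for r in reports)
    total = tp + fp + tn + fn
    aucs = [r.auc for r in reports if r.auc is not None]
    return {
        "pooled": {
            "tp": tp, "fp": fp, "tn": tn, "fn": fn,
            "sensitivity": tp / (tp + fn) if tp + fn else 0.0,
            "specificity": tn / (tn + fp) if tn + fp else 0.0,
            "accuracy": (tp + tn) / total if total else 0.0,
        },
        "per_fold_mean": {
            "sensitivity": float(np.mean([r.sensitivity for r in reports])),
            "specificity": float(np.mean([r.specificity for r in reports])),
            "accuracy": float(np.mean([r.accuracy for r in reports])),
            "auc": float(np.mean(aucs)) if aucs else None,
        },
    }
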