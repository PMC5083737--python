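"""Two-level lesion classification pipeline.

Tissue level: nucleus features are pooled per tissue by the sample average,
a penalized multinomial model is fitted on the pooled vectors, and each
lesion receives three class probabilities (summing to 1), a predicted class
(the maximum probability, ties broken by the fixed order CP < IPMN < PC),
and a certainty score

    C = max_k p_k - min_k p_k  in [0, 1],

0 at the uniform distribution (assignment by chance) and 1 at a degenerate
one (perfect assignment).

Nuclear level: nucleus labels are not observed directly, so each nucleus is
first imputed the label the tissue-level model assigns to its raw feature
vector, and a second penalized fit is run on per-nucleus features.

Generalization is estimated by repeated stratified 3:1 train/test splits
with the tuning parameter re-selected inside each training set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve

from . import multinomial as mn
from .synthetic import TissueSample

CLASS_ORDER = mn.CLASS_ORDER

ID_COLUMNS = ("tissue_id", "nucleus_id", "class")


def feature_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in ID_COLUMNS]


def pool_tissue(sample: TissueSample) -> pd.Series:
    """Component-wise mean of a tissue's nucleus feature vectors."""
    numeric = sample.features[feature_columns(sample.features)]
    if len(numeric) < 1:
        raise ValueError("empty tissue sample")
    return numeric.mean(axis=0)


def pool_cohort(samples: list[TissueSample]) -> pd.DataFrame:
    """Tissue-level table (one pooled row per tissue) from a nucleus cohort."""
    rows = []
    for s in samples:
        row = pool_tissue(s)
        row["tissue_id"] = s.tissue_id
        row["class"] = s.true_class
        rows.append(row)
    table = pd.DataFrame(rows)
    cols = ["tissue_id", "class"] + [c for c in table.columns if c not in ID_COLUMNS]
    return table[cols].reset_index(drop=True)


def classify(probabilities: np.ndarray, class_order: tuple[str, ...] = CLASS_ORDER) -> str:
    """Class of highest probability; exact ties go to the earliest class in
    the fixed order."""
    p = np.asarray(probabilities, dtype=float)
    _check_simplex(p)
    return class_order[int(np.argmax(p))]


def certainty(probabilities: np.ndarray) -> float:
    """Largest minus smallest class probability, in [0, 1]."""
    p = np.asarray(probabilities, dtype=float)
    _check_simplex(p)
    return float(p.max() - p.min())


def _check_simplex(p: np.ndarray) -> None:
    if p.ndim != 1 or len(p) != len(CLASS_ORDER):
        raise ValueError("expected one probability per class")
    if (p < -1e-9).any() or abs(p.sum() - 1.0) > 1e-8:
        raise ValueError("probabilities must be a point on the simplex")


def _calls_frame(
    tissue_ids, truth, probs: np.ndarray, class_order=CLASS_ORDER
) -> pd.DataFrame:
    calls = pd.DataFrame({"tissue_id": tissue_ids, "true_class": truth})
    for k, cls in enumerate(class_order):
        calls[f"p_{cls}"] = probs[:, k]
    calls["predicted_class"] = [classify(p, class_order) for p in probs]
    calls["certainty"] = [certainty(p) for p in probs]
    if calls["true_class"].notna().all():
        calls["correct"] = calls["predicted_class"] == calls["true_class"]
    return calls


@dataclass
class TissueLevelResult:
    model: mn.ModelFit
    calls: pd.DataFrame
    summary: dict = field(default_factory=dict)


def run_tissue_level(
    table: pd.DataFrame,
    penalty: str = "lasso",
    criterion: str = "deviance",
    folds: int = 5,
    seed: int = 0,
) -> TissueLevelResult:
    """Whole-data tissue-level analysis.

    Fits the penalized model (lambda by stratified CV) on all pooled
    tissues, then reports per-lesion probability profiles, predictions,
    certainties, training accuracy, the selected-feature count, and mean
    certainty among correct vs incorrect calls.
    """
    cols = feature_columns(table)
    X = table[cols].to_numpy(dtype=float)
    y = table["class"].to_numpy()
    model = mn.fit_cv(
        X, y, penalty_kind=penalty, criterion=criterion, folds=folds, seed=seed,
        feature_names=cols,
    )
    probs = mn.predict_proba(model, X)
    calls = _calls_frame(table["tissue_id"].to_numpy(), y, probs)
    correct = calls["correct"].to_numpy()
    summary = {
        "training_accuracy": float(correct.mean()),
        "n_selected_features": int(len(model.selected_features)),
        "selected_features": [cols[j] for j in model.selected_features],
        "mean_certainty_correct": float(calls.loc[correct, "certainty"].mean())
        if correct.any()
        else float("nan"),
        "mean_certainty_incorrect": float(calls.loc[~correct, "certainty"].mean())
        if (~correct).any()
        else float("nan"),
        "lambda_selected": model.lambda_selected,
    }
    return TissueLevelResult(model=model, calls=calls, summary=summary)


@dataclass
class NuclearLevelResult:
    model: mn.ModelFit
    imputed_labels: pd.DataFrame
    summary: dict = field(default_factory=dict)


def impute_and_run_nuclear_level(
    samples: list[TissueSample],
    tissue_model: mn.ModelFit,
    penalty: str = "lasso",
    criterion: str = "deviance",
    folds: int = 5,
    seed: int = 0,
) -> NuclearLevelResult:
    """Nuclear-level analysis with labels imputed from the tissue model.

    Each nucleus is labeled by the tissue-level model applied to its raw
    feature vector; a second penalized fit runs on per-nucleus features
    against those imputed labels.  Reports the nuclear model's agreement
    with the imputed labels and its per-tissue majority-vote accuracy
    against tissue truth (when known).
    """
    frames, ids, tissues, truths = [], [], [], []
    for s in samples:
        cols = feature_columns(s.features)
        frames.append(s.features[cols].to_numpy(dtype=float))
        ids.extend(s.features.get("nucleus_id", pd.Series(range(len(s.features)))).tolist())
        tissues.extend([s.tissue_id] * len(s.features))
        truths.extend([s.true_class] * len(s.features))
    X = np.vstack(frames)
    probs = mn.predict_proba(tissue_model, X)
    imputed = np.array([classify(p) for p in probs])
    labels = pd.DataFrame(
        {
            "nucleus_id": ids,
            "tissue_id": tissues,
            "tissue_class": truths,
            "imputed_class": imputed,
        }
    )
    if len(np.unique(imputed)) < 2:
        # Degenerate tissue model (e.g. the null model at lambda_max): no
        # nuclear-level fit is identifiable.
        return NuclearLevelResult(
            model=tissue_model,
            imputed_labels=labels,
            summary={"degenerate_imputation": True},
        )
    model = mn.fit_cv(
        X, imputed, penalty_kind=penalty, criterion=criterion, folds=folds,
        seed=seed, feature_names=cols,
    )
    nuc_pred = np.array(
        [classify(p) for p in mn.predict_proba(model, X)]
    )
    labels["nuclear_predicted_class"] = nuc_pred
    majority_correct = []
    for tid, group in labels.groupby("tissue_id", sort=False):
        vote = group["nuclear_predicted_class"].mode().iloc[0]
        truth = group["tissue_class"].iloc[0]
        if truth is not None:
            majority_correct.append(vote == truth)
    summary = {
        "degenerate_imputation": False,
        "accuracy_vs_imputed": float((nuc_pred == imputed).mean()),
        "tissue_majority_accuracy": float(np.mean(majority_correct))
        if majority_correct
        else float("nan"),
        "n_selected_features": int(len(model.selected_features)),
        "selected_features": [cols[j] for j in model.selected_features],
    }
    return NuclearLevelResult(model=model, imputed_labels=labels, summary=summary)


@dataclass
class SplitEvaluation:
    accuracies: list[float]
    feature_counts: list[int]
    train_fraction: float
    n_splits: int
    seed: int

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.accuracies))

    @property
    def mean_feature_count(self) -> float:
        return float(np.mean(self.feature_counts))


def _stratified_split(
    y: np.ndarray, train_fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    train, test = [], []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        n_train = int(round(train_fraction * len(idx)))
        n_train = min(max(n_train, 1), len(idx) - 1) if len(idx) > 1 else n_train
        train.extend(idx[:n_train])
        test.extend(idx[n_train:])
    return np.array(sorted(train)), np.array(sorted(test))


def evaluate_splits(
    table: pd.DataFrame,
    penalty: str = "lasso",
    criterion: str = "deviance",
    n_splits: int = 20,
    train_fraction: float = 0.75,
    folds: int = 5,
    seed: int = 0,
) -> SplitEvaluation:
    """Repeated stratified 3:1 train/test evaluation at the tissue level.

    Each split refits the model (with internal CV for lambda) on the
    training tissues and scores accuracy on the held-out quarter; reports
    per-split accuracies and selected-feature counts.
    """
    if n_splits < 1:
        raise ValueError("n_splits must be >= 1")
    cols = feature_columns(table)
    X = table[cols].to_numpy(dtype=float)
    y = table["class"].to_numpy()
    counts = pd.Series(y).value_counts()
    if (counts < 2).any() or len(counts) < 2:
        raise ValueError("need >= 2 tissues in each of >= 2 classes")
    rng = np.random.default_rng(seed)
    accuracies, n_features = [], []
    for split in range(n_splits):
        for _ in range(10):
            train, test = _stratified_split(y, train_fraction, rng)
            if len(np.unique(y[train])) == len(counts):
                break
        model = mn.fit_cv(
            X[train], y[train], penalty_kind=penalty, criterion=criterion,
            folds=folds, seed=int(rng.integers(2**31)), feature_names=cols,
        )
        pred = [classify(p) for p in mn.predict_proba(model, X[test])]
        accuracies.append(float(np.mean(np.asarray(pred) == y[test])))
        n_features.append(int(len(model.selected_features)))
    return SplitEvaluation(
        accuracies=accuracies,
        feature_counts=n_features,
        train_fraction=train_fraction,
        n_splits=n_splits,
        seed=seed,
    )


@dataclass
class RocResult:
    curves: dict[str, tuple[np.ndarray, np.ndarray]]
    aucs: dict[str, float]

    @property
    def macro_auc(self) -> float:
        return float(np.mean(list(self.aucs.values())))


def roc_analysis(calls: pd.DataFrame, class_order: tuple[str, ...] = CLASS_ORDER) -> RocResult:
    """Macro one-vs-rest ROC of the per-class probability scores.

    For each class the score is that class's predicted probability and the
    positive label is truth == class; AUC by trapezoidal integration of the
    empirical curve, macro-averaged over the classes present.
    """
    truth = calls["true_class"].to_numpy()
    if len(np.unique(truth)) < 2:
        raise ValueError("ROC analysis needs >= 2 classes in the truth labels")
    curves, aucs = {}, {}
    for cls in class_order:
        positives = truth == cls
        if positives.all() or not positives.any():
            continue
        fpr, tpr, _ = roc_curve(positives, calls[f"p_{cls}"].to_numpy())
        curves[cls] = (fpr, tpr)
        aucs[cls] = float(np.trapezoid(tpr, fpr))
    return RocResult(curves=curves, aucs=aucs)


# ---------------------------------------------------------------------------
# plots (probability profile per lesion, ROC curves)

def plot_probability_profile(calls: pd.DataFrame, path: str) -> None:
    """Stacked per-lesion class-probability bars, grouped by true class."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    classes = [c for c in CLASS_ORDER if (calls["true_class"] == c).any()]
    fig, axes = plt.subplots(len(classes), 1, figsize=(9, 2.6 * len(classes)), squeeze=False)
    shades = {"CP": "0.5", "IPMN": "0.8", "PC": "0.2"}
    for ax, cls in zip(axes[:, 0], classes):
        sub = calls[calls["true_class"] == cls]
        bottom = np.zeros(len(sub))
        for k in CLASS_ORDER:
            p = sub[f"p_{k}"].to_numpy()
            ax.bar(sub["tissue_id"], p, bottom=bottom, color=shades[k], label=k)
            bottom += p
        ax.set_title(f"true class: {cls}")
        ax.set_ylabel("probability")
        ax.tick_params(axis="x", rotation=90, labelsize=6)
    axes[0, 0].legend(loc="upper right", fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_roc(roc: RocResult, path: str) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for cls, (fpr, tpr) in roc.curves.items():
        ax.plot(fpr, tpr, label=f"{cls} (AUC {roc.aucs[cls]:.3f})")
    ax.plot([0, 1], [0, 1], "k:", lw=0.8)
    ax.set_xlabel("false-positive rate")
    ax.set_ylabel("true-positive rate")
    ax.set_title(f"one-vs-rest ROC, macro AUC {roc.macro_auc:.3f}")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
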