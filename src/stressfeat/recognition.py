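"""Landing-pattern classification of bone stress-distribution features.

Each bone's stress feature is scored by how well three canonical classifier
families — k-nearest neighbours, a radial-basis SVM, and a small feed-forward
neural network — can tell two landing conditions apart from it under
stratified 10-fold cross-validation.  Per-fold training includes per-column
standardisation fitted on the training fold only.  Aggregating the per-bone,
per-family accuracies across node-subset cases and condition comparisons
yields the recognition report that mirrors how recognisability concentrates
in high-stress nodes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .errors import ValidationError
from .stress import FeatureMatrix

__all__ = [
    "ClassifierSpec",
    "RecognitionReport",
    "default_classifier_specs",
    "make_classifier",
    "train_eval_cv",
    "per_bone_report",
    "total_accuracy",
]

HIGHLIGHT_MARGIN = 0.10  # "clearly above the others": accuracy >= median + margin


@dataclass(frozen=True)
class ClassifierSpec:
    """One classifier family with its (deliberately small-data) hyperparameters.

    Defaults: KNN with k = 5; SVM with an RBF kernel, unit regularisation and
    inverse-dimension kernel width; ANN with a single hidden layer of 10
    logistic units trained for at most 500 epochs from a seeded
    initialisation.
    """

    family: str
    params: Mapping[str, float | int | str] = dc_field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in ("knn", "svm", "ann"):
            raise ValidationError(f"unsupported classifier family {self.family!r}")
        object.__setattr__(self, "params", dict(self.params))


def default_classifier_specs(seed: int = 0) -> tuple[ClassifierSpec, ...]:
    return (
        ClassifierSpec("knn", {"n_neighbors": 5}, seed=seed),
        ClassifierSpec("svm", {"C": 1.0, "kernel": "rbf", "gamma": "scale"}, seed=seed),
        ClassifierSpec(
            "ann", {"hidden_units": 10, "max_epochs": 500}, seed=seed
        ),
    )


def make_classifier(spec: ClassifierSpec) -> Pipeline:
    """Build the scaler + classifier pipeline for one family.

    The scaler inside the pipeline guarantees per-fold standardisation fitted
    on the training fold only.
    """
    p = dict(spec.params)
    if spec.family == "knn":
        clf = KNeighborsClassifier(n_neighbors=int(p.get("n_neighbors", 5)))
    elif spec.family == "svm":
        clf = SVC(
            C=float(p.get("C", 1.0)),
            kernel=str(p.get("kernel", "rbf")),
            gamma=p.get("gamma", "scale"),
        )
    else:
        clf = MLPClassifier(
            hidden_layer_sizes=(int(p.get("hidden_units", 10)),),
            activation="logistic",
            max_iter=int(p.get("max_epochs", 500)),
            random_state=int(spec.seed),
        )
    return Pipeline([("scale", StandardScaler()), ("clf", clf)])


def train_eval_cv(
    X: np.ndarray | pd.DataFrame,
    y: np.ndarray,
    spec: ClassifierSpec,
    folds: int = 10,
    fold_seed: int | None = None,
) -> float:
    """Mean stratified k-fold cross-validated accuracy of one classifier.

    Folds are stratified and seeded (``fold_seed`` defaults to the classifier
    spec's seed); every class must contribute at least ``folds`` instances.
    """
    Xa = np.asarray(X, dtype=float)
    if Xa.ndim == 1:
        Xa = Xa[:, None]
    ya = np.asarray(y)
    _, counts = np.unique(ya, return_counts=True)
    if counts.min() < folds:
        raise ValidationError(
            f"every class needs at least {folds} instances for {folds}-fold CV"
        )
    seed = spec.seed if fold_seed is None else fold_seed
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=int(seed))
    model = make_classifier(spec)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # MLP convergence chatter on null folds
        scores = cross_val_score(model, Xa, ya, cv=skf, scoring="accuracy")
    return float(scores.mean())


@dataclass(frozen=True)
class RecognitionReport:
    """Cross-validated accuracies per (comparison, case, bone, family)."""

    table: pd.DataFrame  # columns: comparison, case, bone, family, accuracy
    fold_seed: int
    highlight_margin: float = HIGHLIGHT_MARGIN

    def __post_init__(self) -> None:
        required = {"comparison", "case", "bone", "family", "accuracy"}
        if not required.issubset(self.table.columns):
            raise ValidationError(f"report table must contain columns {sorted(required)}")
        acc = self.table["accuracy"]
        if acc.isna().any() or (acc < 0).any() or (acc > 1).any():
            raise ValidationError("accuracies must be complete and lie in [0, 1]")

    def highlights(self) -> pd.DataFrame:
        """Bones whose accuracy clears the within-(comparison, case, family) median
        by the highlight margin — the features that stand out from the rest."""
        median = self.table.groupby(["comparison", "case", "family"])[
            "accuracy"
        ].transform("median")
        mask = self.table["accuracy"] >= median + self.highlight_margin
        return self.table[mask].reset_index(drop=True)


def per_bone_report(
    datasets: Mapping[tuple[str, str], FeatureMatrix],
    specs: Sequence[ClassifierSpec],
    folds: int = 10,
    fold_seed: int = 0,
    highlight_margin: float = HIGHLIGHT_MARGIN,
) -> RecognitionReport:
    """Classify every bone on its own column for every (comparison, case).

    ``datasets`` maps ``(comparison, case)`` to the feature matrix for that
    combination.  The report holds one accuracy per (comparison, case, bone,
    classifier family) with no missing cells.
    """
    if not datasets:
        raise ValidationError("per_bone_report requires at least one dataset")
    rows = []
    for (comparison, case), fm in datasets.items():
        if fm is None:
            raise ValidationError(f"missing data for comparison {comparison!r} case {case!r}")
        for bone in fm.bone_labels:
            col = fm.X[bone].to_numpy(dtype=float)[:, None]
            for spec in specs:
                acc = train_eval_cv(col, fm.y, spec, folds=folds, fold_seed=fold_seed)
                rows.append(
                    {
                        "comparison": comparison,
                        "case": case,
                        "bone": bone,
                        "family": spec.family,
                        "accuracy": acc,
                    }
                )
    return RecognitionReport(pd.DataFrame(rows), fold_seed=fold_seed,
                             highlight_margin=highlight_margin)


def total_accuracy(report: RecognitionReport, level: str = "case") -> pd.Series:
    """Arithmetic-mean aggregate accuracies at the requested level.

    ``level='case'`` averages within each (comparison, case);
    ``level='comparison'`` averages within each comparison.
    """
    if level == "case":
        keys = ["comparison", "case"]
    elif level == "comparison":
        keys = ["comparison"]
    else:
        raise ValidationError(f"unknown aggregation level {level!r}")
    return report.table.groupby(keys)["accuracy"].mean()
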