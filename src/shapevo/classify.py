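"""Downstream classification on the shapelet distance transform.

The discovery stage and the classifier are deliberately decoupled: the
genetic search scores candidate sets with a fixed ridge logistic
regression, and only the final transform gets a properly tuned model —
regularization type (ridge vs lasso) and strength selected by stratified
3-fold cross-validated log loss over a 2 x 7 grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import log_loss
from sklearn.model_selection import StratifiedKFold

from .core import LengthError, ShapeletSet, TimeSeriesDataset, distance_matrix
from .engine import EvolutionConfig, evolve

C_GRID = (0.001, 0.01, 0.1, 1.0, 10.0, 100.0, 1000.0)
PENALTIES = ("l2", "l1")  # ridge, lasso


def _make_lr(penalty: str, C: float) -> LogisticRegression:
    if penalty == "l1":
        return LogisticRegression(
            penalty="l1", C=C, solver="saga", max_iter=5000, random_state=0
        )
    return LogisticRegression(penalty="l2", C=C, max_iter=5000)


@dataclass
class TunedClassifier:
    model: LogisticRegression
    penalty: str
    C: float
    cv_losses: dict = field(default_factory=dict)

    def predict(self, D: np.ndarray) -> np.ndarray:
        return self.model.predict(D)

    def predict_proba(self, D: np.ndarray) -> np.ndarray:
        return self.model.predict_proba(D)


def fit_tuned_lr(D: np.ndarray, y) -> TunedClassifier:
    """Grid-search penalty type and strength by 3-fold CV log loss.

    Evaluates all 14 (penalty, C) pairs; ties prefer stronger regularization
    (smaller C, ridge before lasso). Classes with fewer than 3 members
    reduce the fold count to the smallest class size, with a warning.
    """
    D = np.asarray(D, dtype=float)
    y = np.asarray(y)
    classes, y_enc = np.unique(y, return_inverse=True)
    if classes.size < 2:
        raise ValueError("need at least two classes")
    min_class = int(np.bincount(y_enc).min())
    n_folds = 3
    if min_class < n_folds:
        n_folds = max(2, min_class)
        warnings.warn(
            f"smallest class has {min_class} members; using {n_folds} folds"
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=False)
    cv_losses: dict[tuple[str, float], float] = {}
    for penalty in PENALTIES:
        for C in C_GRID:
            losses = []
            for tr, te in skf.split(D, y_enc):
                model = _make_lr(penalty, C)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    model.fit(D[tr], y_enc[tr])
                proba = model.predict_proba(D[te])
                full = np.zeros((proba.shape[0], classes.size))
                full[:, model.classes_] = proba
                losses.append(log_loss(y_enc[te], full, labels=np.arange(classes.size)))
            cv_losses[(penalty, C)] = float(np.mean(losses))
    # ties -> stronger regularization: smaller C first, ridge before lasso
    ranked = sorted(
        cv_losses,
        key=lambda pc: (cv_losses[pc], pc[1], PENALTIES.index(pc[0])),
    )
    penalty, C = ranked[0]
    model = _make_lr(penalty, C)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(D, y_enc)
    # re-map encoded classes back to original labels for predict()
    model.classes_ = classes[model.classes_]
    return TunedClassifier(model=model, penalty=penalty, C=C, cv_losses=cv_losses)


def evaluate_accuracy(
    classifier: TunedClassifier,
    shapelet_set: ShapeletSet,
    dataset: TimeSeriesDataset,
    y=None,
) -> float:
    """Transform the dataset and return the fraction of correct predictions."""
    y = dataset.labels if y is None else np.asarray(y)
    D = distance_matrix(shapelet_set, dataset)
    return float(np.mean(classifier.predict(D) == y))


def _cv_log_loss(D: np.ndarray, y: np.ndarray, n_folds: int = 3) -> float:
    """3-fold CV log loss of the fixed ridge LR used by the fitness."""
    classes, y_enc = np.unique(y, return_inverse=True)
    n_folds = min(n_folds, int(np.bincount(y_enc).min()))
    n_folds = max(2, n_folds)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=False)
    losses = []
    for tr, te in skf.split(D, y_enc):
        model = LogisticRegression(C=1.0, max_iter=1000)
        model.fit(D[tr], y_enc[tr])
        proba = model.predict_proba(D[te])
        full = np.zeros((proba.shape[0], classes.size))
        full[:, model.classes_] = proba
        losses.append(log_loss(y_enc[te], full, labels=np.arange(classes.size)))
    return float(np.mean(losses))


def tune_max_len(
    dataset: TimeSeriesDataset,
    config: Optional[EvolutionConfig] = None,
    budget_population: int = 25,
    budget_generations: int = 30,
) -> int:
    """Select max_len from {M/4, M/2, 3M/4, M} by cross-validated loss.

    For each grid value a reduced-budget evolution is run and the 3-fold CV
    log loss of the ridge LR on its transform is measured; the argmin wins,
    ties preferring the smaller length. The reduced budget keeps the
    protocol desk-scale; full-budget runs only sharpen the same comparison.
    """
    M = dataset.min_length
    if M < 16:
        raise LengthError(f"max_len tuning needs series of length >= 16, got {M}")
    base = config or EvolutionConfig()
    grid = sorted({int(np.ceil(M * f)) for f in (0.25, 0.5, 0.75, 1.0)})
    best_len, best_loss = None, np.inf
    for i, candidate in enumerate(grid):
        cfg = replace(
            base,
            max_len=candidate,
            population_size=min(base.population_size, budget_population),
            generations=min(base.generations, budget_generations),
            seed=None if base.seed is None else base.seed + i,
        )
        elite, _ = evolve(dataset, cfg)
        D = distance_matrix(elite, dataset)
        loss = _cv_log_loss(D, dataset.labels)
        if loss < best_loss:
            best_loss, best_len = loss, candidate
    return int(best_len)
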