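"""Level-1 risk models: random forest, Gaussian naive Bayes, perceptron.

Three probabilistic classifiers of different families run concurrently on
the selected, normalized variables; each emits a readmission risk in
[0, 1].  The triple (R1, R2, R3) — forest, naive Bayes, multilayer
perceptron, in that order — is the input space of the level-2 fuzzy
aggregator.  The learners are interchangeable calculation engines behind
one probabilistic-classifier contract; the defaults are:

* random forest: 100 trees, Gini criterion, unbounded depth,
  ``min_samples_split=2``;
* Gaussian naive Bayes: variance smoothing 1e-9;
* multilayer perceptron: one hidden layer of 9 neurons, logistic
  activation, Adam, L2 penalty 1e-4, constant learning rate, at most
  1000 epochs.
"""

from __future__ import annotations

import base64
import logging
import pickle
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.naive_bayes import GaussianNB
from sklearn.neural_network import MLPClassifier

log = logging.getLogger(__name__)


class RiskTriple(NamedTuple):
    """Level-1 risks: forest (r1), naive Bayes (r2), perceptron (r3)."""

    r1: float
    r2: float
    r3: float


@dataclass(frozen=True)
class Level1Config:
    forest_n_trees: int = 100
    forest_criterion: str = "gini"
    forest_max_depth: Optional[int] = None
    forest_min_samples_split: int = 2
    nb_var_smoothing: float = 1e-9
    mlp_hidden: tuple[int, ...] = (9,)
    mlp_activation: str = "logistic"
    mlp_solver: str = "adam"
    mlp_l2: float = 1e-4
    mlp_learning_rate: str = "constant"
    mlp_max_epochs: int = 1000
    seed: Optional[int] = 0


@dataclass
class Level1Models:
    """The three fitted classifiers plus the feature order they expect."""

    forest: RandomForestClassifier
    nb: GaussianNB
    mlp: MLPClassifier
    feature_names: tuple[str, ...]
    config: Level1Config
    mlp_converged: bool = True

    def __iter__(self):
        return iter((self.forest, self.nb, self.mlp))


def train_level1(X_train: pd.DataFrame, y_train: Sequence[int],
                 cfg: Optional[Level1Config] = None) -> Level1Models:
    """Fit the three level-1 classifiers on normalized training data."""
    cfg = cfg or Level1Config()
    y = np.asarray(y_train)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    X = X_train.to_numpy(dtype=float)

    forest = RandomForestClassifier(
        n_estimators=cfg.forest_n_trees, criterion=cfg.forest_criterion,
        max_depth=cfg.forest_max_depth,
        min_samples_split=cfg.forest_min_samples_split,
        random_state=cfg.seed, n_jobs=1)
    nb = GaussianNB(var_smoothing=cfg.nb_var_smoothing)
    mlp = MLPClassifier(
        hidden_layer_sizes=cfg.mlp_hidden, activation=cfg.mlp_activation,
        solver=cfg.mlp_solver, alpha=cfg.mlp_l2,
        learning_rate=cfg.mlp_learning_rate, max_iter=cfg.mlp_max_epochs,
        random_state=cfg.seed)

    forest.fit(X, y)
    nb.fit(X, y)
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        mlp.fit(X, y)
    if any(issubclass(w.category, ConvergenceWarning) for w in caught):
        converged = False
        log.warning("perceptron did not converge within %d epochs",
                    cfg.mlp_max_epochs)

    return Level1Models(forest=forest, nb=nb, mlp=mlp,
                        feature_names=tuple(X_train.columns), config=cfg,
                        mlp_converged=converged)


def _positive_column(model, X: np.ndarray) -> np.ndarray:
    proba = model.predict_proba(X)
    return proba[:, list(model.classes_).index(1)]


def predict_risk_matrix(models: Level1Models, X: pd.DataFrame) -> np.ndarray:
    """Positive-class probabilities for every row: an (n, 3) matrix."""
    Xa = X[list(models.feature_names)].to_numpy(dtype=float)
    return np.column_stack([_positive_column(m, Xa) for m in models])


def predict_risks(models: Level1Models, x: pd.Series | pd.DataFrame) -> RiskTriple:
    """Risk triple (R1, R2, R3) for a single patient."""
    if isinstance(x, pd.Series):
        x = x.to_frame().T
    mat = predict_risk_matrix(models, x)
    return RiskTriple(*(float(v) for v in mat[0]))


def models_to_payload(models: Level1Models) -> dict:
    """Serialize the fitted classifiers for embedding in a JSON artifact.

    sklearn estimators have no canonical JSON form, so the fitted objects
    are pickled and base64-encoded; round-trips are bit-identical.
    """
    return {
        "format": "sklearn-pickle-b64",
        "feature_names": list(models.feature_names),
        "mlp_converged": models.mlp_converged,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in vars(models.config).items()},
        "data": base64.b64encode(pickle.dumps(
            (models.forest, models.nb, models.mlp))).decode("ascii"),
    }


def payload_to_models(payload: dict) -> Level1Models:
    if payload.get("format") != "sklearn-pickle-b64":
        raise ValueError("unrecognized level-1 model payload format")
    forest, nb, mlp = pickle.loads(base64.b64decode(payload["data"]))
    cfg_raw = dict(payload["config"])
    cfg_raw["mlp_hidden"] = tuple(cfg_raw["mlp_hidden"])
    return Level1Models(forest=forest, nb=nb, mlp=mlp,
                        feature_names=tuple(payload["feature_names"]),
                        config=Level1Config(**cfg_raw),
                        mlp_converged=bool(payload["mlp_converged"]))
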