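"""Classifiers: the 1/3/5-NN majority-voting ensemble, the MLP sizing rule,
and a uniform configuration layer over established learner backends.

The proposed classifier is a homogeneous ensemble of k-nearest-neighbor
models sharing one training set and metric, with k = 1, 3, 5. Each base model
predicts by plurality among its k nearest training samples (distance ties
broken by training index order, vote ties by the nearest neighbor's class);
the ensemble assigns the most frequent of the three base predictions, ties
going to the smallest-k model's vote.

Everything else (random forests, MLP, SMO-style SVM, bagging, stacking,
voting, gradient boosting, XGBoost) is delegated to scikit-learn / xgboost
with fixed hyperparameter presets; only the configuration layer is part of
this package.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "KnnVoteEnsemble",
    "ClassifierConfig",
    "knn_predict",
    "vote",
    "mlp_hidden_units",
    "fit_backend",
    "predict_backend",
    "BACKEND_PRESETS",
]


def _pairwise_sq_dists(queries: np.ndarray, train: np.ndarray) -> np.ndarray:
    q = np.asarray(queries, dtype=float)
    t = np.asarray(train, dtype=float)
    return ((q[:, None, :] - t[None, :, :]) ** 2).sum(axis=2)


def knn_predict(
    train_X: np.ndarray,
    train_y: Sequence,
    query: np.ndarray,
    k: int,
    metric: str = "euclidean",
) -> object:
    """Plurality label among the k nearest training samples.

    Distance ties are broken by training index order (stable sort); a vote tie
    is broken by the nearest neighbor's class.
    """
    train_X = np.asarray(train_X, dtype=float)
    if train_X.shape[0] == 0:
        raise ValueError("empty training set")
    if k > train_X.shape[0]:
        raise ValueError(f"k={k} exceeds training size {train_X.shape[0]}")
    if metric != "euclidean":
        raise ValueError(f"unsupported metric {metric!r}")
    d = ((train_X - np.asarray(query, dtype=float)) ** 2).sum(axis=1)
    order = np.argsort(d, kind="stable")[:k]
    labels = [train_y[i] for i in order]
    return vote(labels)


def vote(predictions: Sequence) -> object:
    """Most frequent label; ties go to the earliest prediction whose label is tied."""
    if len(predictions) == 0:
        raise ValueError("need at least one prediction")
    counts = Counter(predictions)
    top = max(counts.values())
    tied = {lbl for lbl, c in counts.items() if c == top}
    for p in predictions:
        if p in tied:
            return p
    raise AssertionError("unreachable")


@dataclass
class KnnVoteEnsemble:
    """Three nearest-neighbor models (k = 1, 3, 5 by default) sharing one
    training set, combined by majority vote."""

    ks: tuple[int, ...] = (1, 3, 5)
    metric: str = "euclidean"
    train_X: np.ndarray | None = None
    train_y: np.ndarray | None = None

    def __post_init__(self) -> None:
        if list(self.ks) != sorted(set(self.ks)) or any(k % 2 == 0 for k in self.ks):
            raise ValueError("k values must be odd, distinct and ascending")

    def fit(self, X: np.ndarray, y: Sequence) -> "KnnVoteEnsemble":
        X = np.asarray(X, dtype=float)
        if X.shape[0] == 0:
            raise ValueError("training set is empty")
        self.train_X = X
        self.train_y = np.asarray(y, dtype=object)
        return self

    @property
    def effective_ks(self) -> tuple[int, ...]:
        n = 0 if self.train_X is None else self.train_X.shape[0]
        ks = tuple(k for k in self.ks if k <= n)
        if self.train_X is not None and ks != tuple(self.ks):
            warnings.warn(
                f"training set of {n} samples: k values clamped to {ks}", stacklevel=2
            )
        return ks if ks else (1,)

    def predict(self, queries: np.ndarray) -> np.ndarray:
        if self.train_X is None:
            raise ValueError("ensemble is not fitted")
        queries = np.asarray(queries, dtype=float)
        ks = self.effective_ks
        d = _pairwise_sq_dists(queries, self.train_X)
        order = np.argsort(d, axis=1, kind="stable")
        out = np.empty(queries.shape[0], dtype=object)
        for i in range(queries.shape[0]):
            base = [vote([self.train_y[j] for j in order[i, :k]]) for k in ks]
            out[i] = vote(base)
        return out


def mlp_hidden_units(n_features: int, n_classes: int) -> int:
    """Hidden-layer width rule: the rounded (half-up) average of the input and
    output dimensions, e.g. 300 genes and 7 classes -> 154 neurons."""
    if n_features < 1 or n_classes < 1:
        raise ValueError("n_features and n_classes must be >= 1")
    return (n_features + n_classes + 1) // 2


#: Fixed hyperparameter presets for the evaluated backends.
BACKEND_PRESETS: dict[str, dict] = {
    "knn_vote": {"ks": (1, 3, 5), "metric": "euclidean"},
    "random_forests": {
        "n_estimators": 100,
        "criterion": "gini",
        "min_samples_split": 2,
        "bootstrap": True,
    },
    "bagging": {
        "n_estimators": 10,
        "max_samples": 1.0,
        "max_features": 1.0,
        "bootstrap": True,
        "bootstrap_features": False,
    },
    "gradient_boosting": {
        "loss": "log_loss",
        "learning_rate": 0.1,
        "n_estimators": 100,
        "subsample": 1.0,
        "criterion": "friedman_mse",
        "min_samples_split": 2,
        "min_samples_leaf": 1,
    },
    "xgboost": {
        "booster": "gbtree",
        "learning_rate": 0.3,
        "gamma": 0,
        "max_depth": 6,
        "sampling_method": "uniform",
    },
    "stacking": {},
    "voting_hard": {},
    "voting_soft": {},
    "mlp": {"learning_rate_init": 0.3, "momentum": 0.2},
    "smo_svm": {"C": 1.0, "kernel": "poly"},
    "smo_svm_puk_approx": {"C": 1.0, "kernel": "rbf"},
}


@dataclass(frozen=True)
class ClassifierConfig:
    """Backend tag plus hyperparameter overrides, validated against the preset."""

    backend: str
    params: Mapping[str, object] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.backend not in BACKEND_PRESETS:
            raise ValueError(
                f"unknown backend {self.backend!r}; choose from {sorted(BACKEND_PRESETS)}"
            )
        preset = BACKEND_PRESETS[self.backend]
        if self.backend not in ("stacking", "voting_hard", "voting_soft"):
            unknown = set(self.params) - set(preset)
            if unknown:
                raise ValueError(f"unknown hyperparameters for {self.backend!r}: {sorted(unknown)}")

    def resolved(self) -> dict:
        return {**BACKEND_PRESETS[self.backend], **dict(self.params)}

    def to_dict(self) -> dict:
        return {"backend": self.backend, "params": dict(self.params), "seed": self.seed}

    @classmethod
    def from_dict(cls, d: Mapping) -> "ClassifierConfig":
        return cls(backend=d["backend"], params=dict(d.get("params", {})), seed=int(d.get("seed", 0)))


def _voting_base(seed: int):
    from sklearn.linear_model import LogisticRegression
    from sklearn.svm import SVC
    from sklearn.tree import DecisionTreeClassifier

    return [
        ("svm", SVC(C=1.0, kernel="rbf", degree=3, gamma="auto", tol=0.001,
                    cache_size=200, probability=True, random_state=seed)),
        ("dt", DecisionTreeClassifier(criterion="gini", splitter="best", max_depth=None,
                                      min_samples_split=2, min_samples_leaf=1,
                                      random_state=seed)),
        ("lr", LogisticRegression(solver="newton-cg", max_iter=200)),
    ]


def fit_backend(config: ClassifierConfig, train_X: np.ndarray, train_y: Sequence):
    """Instantiate and fit the configured backend on (train_X, train_y)."""
    p = config.resolved()
    seed = config.seed
    tag = config.backend
    if tag == "knn_vote":
        return KnnVoteEnsemble(ks=tuple(p["ks"]), metric=p["metric"]).fit(train_X, train_y)
    if tag == "random_forests":
        from sklearn.ensemble import RandomForestClassifier

        model = RandomForestClassifier(random_state=seed, **p)
    elif tag == "bagging":
        from sklearn.ensemble import BaggingClassifier

        model = BaggingClassifier(random_state=seed, **p)
    elif tag == "gradient_boosting":
        from sklearn.ensemble import GradientBoostingClassifier

        model = GradientBoostingClassifier(random_state=seed, **p)
    elif tag == "xgboost":
        from sklearn.preprocessing import LabelEncoder
        from xgboost import XGBClassifier

        enc = LabelEncoder().fit(np.asarray(train_y, dtype=object).astype(str))
        model = XGBClassifier(random_state=seed, **p)
        model.fit(np.asarray(train_X, dtype=float), enc.transform(np.asarray(train_y, dtype=object).astype(str)))
        model._geneximb_label_encoder = enc
        return model
    elif tag == "stacking":
        from sklearn.ensemble import StackingClassifier
        from sklearn.linear_model import LogisticRegression

        model = StackingClassifier(
            estimators=_voting_base(seed),
            final_estimator=LogisticRegression(solver="newton-cg", max_iter=200),
        )
    elif tag in ("voting_hard", "voting_soft"):
        from sklearn.ensemble import VotingClassifier

        model = VotingClassifier(
            estimators=_voting_base(seed),
            voting="hard" if tag == "voting_hard" else "soft",
        )
    elif tag == "mlp":
        from sklearn.neural_network import MLPClassifier

        n_features = np.asarray(train_X).shape[1]
        n_classes = len(set(np.asarray(train_y, dtype=object).tolist()))
        model = MLPClassifier(
            hidden_layer_sizes=(mlp_hidden_units(n_features, n_classes),),
            solver="sgd",
            learning_rate_init=p["learning_rate_init"],
            momentum=p["momentum"],
            max_iter=500,
            random_state=seed,
        )
    elif tag in ("smo_svm", "smo_svm_puk_approx"):
        from sklearn.svm import SVC

        # SVC multiclass is inherently one-vs-one; the PUK kernel is
        # approximated by RBF (documented limitation)
        model = SVC(C=p["C"], kernel=p["kernel"], decision_function_shape="ovo",
                    random_state=seed)
    else:  # pragma: no cover
        raise ValueError(tag)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # small folds trip convergence warnings
        model.fit(np.asarray(train_X, dtype=float), np.asarray(train_y, dtype=object).astype(str))
    return model


def predict_backend(model, queries: np.ndarray) -> np.ndarray:
    """Predict labels with a model returned by :func:`fit_backend`."""
    if isinstance(model, KnnVoteEnsemble):
        return model.predict(queries)
    pred = model.predict(np.asarray(queries, dtype=float))
    enc = getattr(model, "_geneximb_label_encoder", None)
    if enc is not None:
        pred = enc.inverse_transform(pred)
    return np.asarray(pred, dtype=object)
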