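"""Sequence encoding and the desk-scale baseline classifiers.

The two trainable model families are scikit-learn style estimators:

* :class:`RandomForestSequenceClassifier` — a random forest over the
  flattened one-hot vector (length 4N);
* :class:`ConvNetSequenceClassifier` — a small 1-D CNN over the (N, 4)
  one-hot matrix, implemented in numpy (see :mod:`negset.conv`).

Both take raw sequence strings as X and the label strings as y, so
they compose directly with the dataset containers and with sklearn
model-selection utilities. Externally computed probabilities (e.g. from
transformer models run elsewhere) enter the audit through
:func:`import_predictions`.
"""

from __future__ import annotations

import hashlib
import itertools
from dataclasses import dataclass, field as dc_field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.utils.validation import check_is_fitted

from .conv import ConvNet
from .core import NON_PROMOTER, PROMOTER, PredictionRecord, SequenceSet
from .evaluation import metrics_from_records
from . import io as nio

_ONE_HOT = {
    "A": (1.0, 0.0, 0.0, 0.0),
    "C": (0.0, 1.0, 0.0, 0.0),
    "G": (0.0, 0.0, 1.0, 0.0),
    "T": (0.0, 0.0, 0.0, 1.0),
}
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_DECODE = np.array(list("ACGT"))


def one_hot(sequence: str) -> np.ndarray:
    """(N, 4) one-hot matrix; A/C/G/T map to unit vectors in that order."""
    try:
        codes = [_CODE[c] for c in sequence]
    except KeyError as exc:
        raise ValueError(f"one_hot: illegal character {exc.args[0]!r}") from None
    mat = np.zeros((len(codes), 4))
    mat[np.arange(len(codes)), codes] = 1.0
    return mat


def flatten(matrix: np.ndarray) -> np.ndarray:
    """Row-major (position-major) flattening to a 4N vector."""
    return np.asarray(matrix).reshape(-1)


def decode_one_hot(matrix: np.ndarray) -> str:
    """Inverse of :func:`one_hot` via per-row argmax."""
    return "".join(_DECODE[np.argmax(matrix, axis=1)])


def encode_batch(sequences: list[str], flat: bool = False) -> np.ndarray:
    """Stack one-hot encodings: (B, N, 4), or (B, 4N) when ``flat``."""
    if not sequences:
        n = 0
        return np.zeros((0, 0) if flat else (0, 0, 4))
    arr = np.frombuffer("".join(sequences).encode(), dtype=np.uint8)
    arr = arr.reshape(len(sequences), -1)
    lut = np.full(256, -1, dtype=np.int64)
    for c, i in _CODE.items():
        lut[ord(c)] = i
    codes = lut[arr]
    if (codes < 0).any():
        bad = chr(int(arr[codes < 0][0]))
        raise ValueError(f"one_hot: illegal character {bad!r}")
    out = np.zeros((*codes.shape, 4))
    np.put_along_axis(out, codes[..., None], 1.0, axis=2)
    return out.reshape(len(sequences), -1) if flat else out


def _to_binary(labels) -> np.ndarray:
    y = np.asarray([1 if lab == PROMOTER else 0 for lab in labels])
    return y


class RandomForestSequenceClassifier(BaseEstimator, ClassifierMixin):
    """Random forest on flattened one-hot DNA (4N features)."""

    def __init__(self, n_estimators: int = 300, max_depth: int | None = None,
                 min_samples_leaf: int = 1, random_state: int = 0):
        self.n_estimators = n_estimators
        self.max_depth = max_depth
        self.min_samples_leaf = min_samples_leaf
        self.random_state = random_state

    def fit(self, X, y):
        seqs = list(X)
        yb = _to_binary(y)
        if len(set(yb)) < 2:
            raise ValueError("training set contains a single class")
        self.window_length_ = len(seqs[0])
        self.model_ = RandomForestClassifier(
            n_estimators=self.n_estimators,
            max_depth=self.max_depth,
            min_samples_leaf=self.min_samples_leaf,
            random_state=self.random_state,
            n_jobs=1,
        )
        self.model_.fit(encode_batch(seqs, flat=True), yb)
        self.classes_ = np.array([NON_PROMOTER, PROMOTER])
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "model_")
        seqs = list(X)
        if not seqs:
            return np.zeros((0, 2))
        proba = self.model_.predict_proba(encode_batch(seqs, flat=True))
        if proba.shape[1] == 1:  # degenerate forest
            proba = np.hstack([1 - proba, proba])
        return proba

    def promoter_proba(self, X) -> np.ndarray:
        """Promoter-class probability per sequence, order preserving."""
        return self.predict_proba(X)[:, 1]

    def predict(self, X):
        return self.classes_[(self.promoter_proba(X) >= 0.5).astype(int)]


class ConvNetSequenceClassifier(BaseEstimator, ClassifierMixin):
    """Small 1-D CNN on (N, 4) one-hot DNA (numpy backend, deterministic)."""

    def __init__(self, kernel1: int = 7, filters1: int = 32, kernel2: int = 5,
                 filters2: int = 64, pool: int = 2, hidden: int = 64,
                 learning_rate: float = 1e-3, epochs: int = 20,
                 batch_size: int = 64, random_state: int = 0):
        self.kernel1 = kernel1
        self.filters1 = filters1
        self.kernel2 = kernel2
        self.filters2 = filters2
        self.pool = pool
        self.hidden = hidden
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.random_state = random_state

    def fit(self, X, y):
        seqs = list(X)
        yb = _to_binary(y).astype(float)
        if len(set(yb)) < 2:
            raise ValueError("training set contains a single class")
        self.window_length_ = len(seqs[0])
        rng = np.random.default_rng(self.random_state)
        self.net_ = ConvNet(
            length=self.window_length_, kernel1=self.kernel1, filters1=self.filters1,
            kernel2=self.kernel2, filters2=self.filters2, pool=self.pool,
            hidden=self.hidden, rng=rng,
        )
        self.loss_history_ = self.net_.fit(
            encode_batch(seqs), yb, epochs=self.epochs, batch_size=self.batch_size,
            learning_rate=self.learning_rate, rng=rng,
        )
        self.classes_ = np.array([NON_PROMOTER, PROMOTER])
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "net_")
        seqs = list(X)
        if not seqs:
            return np.zeros((0, 2))
        p = np.concatenate([
            self.net_.forward(encode_batch(seqs[i:i + 512]))
            for i in range(0, len(seqs), 512)
        ])
        return np.column_stack([1 - p, p])

    def promoter_proba(self, X) -> np.ndarray:
        return self.predict_proba(X)[:, 1]

    def predict(self, X):
        return self.classes_[(self.promoter_proba(X) >= 0.5).astype(int)]

    def embed(self, X) -> np.ndarray:
        """Penultimate-layer embedding per sequence, shape (B, hidden)."""
        check_is_fitted(self, "net_")
        seqs = list(X)
        if not seqs:
            return np.zeros((0, self.hidden))
        return np.vstack([
            self.net_.embed(encode_batch(seqs[i:i + 512]))
            for i in range(0, len(seqs), 512)
        ])


FAMILIES = {"RF": RandomForestSequenceClassifier, "CNN": ConvNetSequenceClassifier}

DEFAULT_GRIDS = {
    "RF": {"n_estimators": [100, 300], "max_depth": [None, 20], "min_samples_leaf": [1, 5]},
    "CNN": {"learning_rate": [1e-3, 1e-4], "filters1": [32, 64]},
}


@dataclass(slots=True)
class TuningPlan:
    model_family: str
    grid: dict[str, list] = dc_field(default_factory=dict)
    k: int = 5
    inner_fraction: float = 0.8
    objective: str = "mcc"
    seed: int = 0
    standard_cv: bool = False

    def __post_init__(self) -> None:
        if self.model_family not in FAMILIES:
            raise ValueError(f"unknown model family {self.model_family!r}")
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if not self.grid:
            self.grid = {k: list(v) for k, v in DEFAULT_GRIDS[self.model_family].items()}


def _objective_score(records: list[PredictionRecord], objective: str) -> float:
    report = metrics_from_records(records)
    value = getattr(report, objective)
    return float("-inf") if value != value else value  # NaN -> worst


def _stratified_folds(records, k: int, rng: np.random.Generator) -> list[list[int]]:
    strata: dict[tuple[str, str], list[int]] = {}
    for i, rec in enumerate(records):
        strata.setdefault((rec.species_id, rec.label), []).append(i)
    folds: list[list[int]] = [[] for _ in range(k)]
    offset = 0
    for members in strata.values():
        if len(members) < k:
            raise ValueError(
                f"k={k} exceeds the {len(members)} records in stratum; lower k"
            )
        perm = rng.permutation(len(members))
        for j, m in enumerate(perm):
            folds[(offset + j) % k].append(members[m])
        offset += len(members)
    return folds


def tune(plan: TuningPlan, train_set: SequenceSet) -> tuple[dict, list[dict]]:
    """Grid search over hyperparameters with k-fold evaluation.

    The default scheme follows the tool's training protocol literally:
    the training set is partitioned into k folds and each fold is
    itself split ``inner_fraction``/rest for fit/score, the objective
    being averaged over folds. ``standard_cv=True`` switches to
    conventional cross-validation (fit on k-1 folds, score the held-out
    fold). Ties break in grid order; deterministic under ``plan.seed``.
    """
    labels = set(train_set.labels())
    if len(train_set) == 0 or len(labels) < 2:
        raise ValueError("tuning requires a non-empty training set with both labels")
    rng = np.random.default_rng(plan.seed)
    folds = _stratified_folds(train_set.records, plan.k, rng)

    names = list(plan.grid)
    results: list[dict] = []
    best: dict | None = None
    for values in itertools.product(*(plan.grid[n] for n in names)):
        params = dict(zip(names, values))
        fold_scores = []
        for fi, fold in enumerate(folds):
            fold_records = [train_set.records[i] for i in fold]
            if plan.standard_cv:
                fit_records = [train_set.records[i]
                               for fj, f in enumerate(folds) if fj != fi for i in f]
                score_records = fold_records
            else:
                fold_ds = train_set.subset(fold_records)
                from .assembly import split_dataset  # local import, no cycle at module load
                sub = split_dataset(fold_ds, train_fraction=plan.inner_fraction,
                                    seed=plan.seed + 1000 * fi)
                fit_records, score_records = sub.train.records, sub.validation.records
            model = FAMILIES[plan.model_family](random_state=plan.seed, **params)
            model.fit([r.sequence for r in fit_records], [r.label for r in fit_records])
            probs = model.promoter_proba([r.sequence for r in score_records])
            preds = [
                PredictionRecord(r.seq_id, r.species_id, r.label, float(p))
                for r, p in zip(score_records, probs)
            ]
            fold_scores.append(_objective_score(preds, plan.objective))
        entry = {"params": params, "fold_scores": fold_scores,
                 "mean_score": float(np.mean(fold_scores))}
        results.append(entry)
        if best is None or entry["mean_score"] > best["mean_score"]:
            best = entry
    return best["params"], results


def train(
    family: str,
    hyperparameters: dict,
    train_set: SequenceSet,
    seed: int | None = None,
):
    """Fit a fresh estimator of ``family`` with the given hyperparameters.

    The fitted estimator carries ``training_metadata_`` (dataset hash,
    seed, hyperparameters) for provenance.
    """
    if seed is None:
        raise ValueError("seed is required (reproducibility contract)")
    if family not in FAMILIES:
        raise ValueError(f"unknown model family {family!r}")
    model = FAMILIES[family](random_state=seed, **hyperparameters)
    model.fit(train_set.sequences(), train_set.labels())
    digest = hashlib.sha256(
        "\n".join(f"{r.seq_id}\t{r.sequence}\t{r.label}" for r in train_set.records).encode()
    ).hexdigest()
    model.training_metadata_ = {
        "family": family,
        "hyperparameters": dict(hyperparameters),
        "seed": seed,
        "dataset_sha256": digest,
        "n_records": len(train_set),
        "deterministic": True,
    }
    return model


def predict_proba(model, sequences: list[str]) -> np.ndarray:
    """Promoter-class probabilities, order preserving."""
    return np.asarray(model.promoter_proba(sequences), dtype=float)


def predict_records(model, dataset: SequenceSet) -> list[PredictionRecord]:
    probs = predict_proba(model, dataset.sequences())
    return [
        PredictionRecord(r.seq_id, r.species_id, r.label, float(p))
        for r, p in zip(dataset.records, probs)
    ]


def import_predictions(path) -> list[PredictionRecord]:
    """Load externally computed probabilities (schema-validated TSV)."""
    return nio.read_predictions(path)
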