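"""Discriminating-ability scoring: 1-NN with cosine distance, LOOCV, MCC.

A feature set's ability to separate tumor from normal samples is measured
by training a nearest-neighbor classifier on the sample vectors restricted
to that set, evaluating it by leave-one-out cross-validation, and
summarising the confusion counts with the Matthews correlation coefficient
(tumor is the positive class).

Conventions where the method is otherwise under-determined:

* distance ties are broken by the smallest training-sample position, so
  every run is deterministic and permutation tests are well defined;
* the cosine distance to a zero-norm vector is 1 (maximal indifference)
  rather than an error, so constant-zero slices cannot abort a scan;
* the MCC is 0 whenever a factor of its denominator is 0.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .datatypes import LEVELS, NORMAL, TUMOR, ConfusionCounts, OmicsMatrix, TermLevelSets, ValidationError
from .genesets import check_unique_terms

logger = logging.getLogger(__name__)


def cosine_distance(x: Sequence[float], y: Sequence[float]) -> float:
    """One minus the cosine similarity of two equal-length sample vectors.

    Lies in [0, 2]; 0 for parallel vectors, 1 for orthogonal ones, 2 for
    anti-parallel ones.  If either vector has zero norm the distance is 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1 or x.shape != y.shape:
        raise ValidationError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size == 0:
        raise ValidationError("empty vectors have no cosine distance")
    nx = np.linalg.norm(x)
    ny = np.linalg.norm(y)
    if nx == 0.0 or ny == 0.0:
        logger.warning("cosine distance involving a zero-norm vector; returning 1")
        return 1.0
    return float(1.0 - float(np.dot(x, y)) / (nx * ny))


def _cross_distances(train: np.ndarray, queries: np.ndarray) -> np.ndarray:
    """Pairwise cosine distances, queries x training samples.

    Both arguments are feature-by-sample matrices sharing the feature axis.
    Zero-norm columns on either side yield distance 1.
    """
    tn = np.linalg.norm(train, axis=0)
    qn = np.linalg.norm(queries, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        cos = (queries.T @ train) / np.outer(qn, tn)
    zero = (qn == 0)[:, None] | (tn == 0)[None, :]
    if zero.any():
        logger.warning("zero-norm sample vector(s) encountered; distances set to 1")
    cos = np.where(zero, 0.0, cos)
    return 1.0 - cos


class NearestNeighborCosineClassifier:
    """1-nearest-neighbor classifier under cosine distance (sklearn API).

    Samples are rows, features columns, as in scikit-learn.  Distance ties
    go to the smallest training-sample index.  Stateless apart from the
    stored training data, so ``fit`` merely validates and remembers.
    """

    def get_params(self, deep: bool = True) -> dict:
        return {}

    def set_params(self, **params) -> "NearestNeighborCosineClassifier":
        if params:
            raise ValueError(f"unknown parameter(s) {sorted(params)}")
        return self

    def fit(self, X, y) -> "NearestNeighborCosineClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[0] == 0 or X.shape[1] == 0:
            raise ValidationError("training data must be a nonempty 2-D array")
        if len(y) != X.shape[0]:
            raise ValidationError("one label per training sample required")
        self.X_ = X
        self.y_ = y
        self.classes_ = np.unique(y)
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "X_"):
            raise ValidationError("classifier is not fitted")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.X_.shape[1]:
            raise ValidationError(
                f"query has {X.shape[1]} features, training data has {self.X_.shape[1]}"
            )
        dist = _cross_distances(self.X_.T, X.T)
        nn = np.argmin(dist, axis=1)  # argmin takes the smallest index on ties
        return self.y_[nn]

    def score(self, X, y) -> float:
        return float(np.mean(self.predict(X) == np.asarray(y)))


def nna_predict(train: OmicsMatrix, query: Sequence[float], feature_set: Iterable[str] | None = None) -> str:
    """Class label of the training sample nearest (cosine) to `query`.

    `query` must match the restricted feature count; ties are broken by the
    smallest training-sample position.
    """
    sub = train.restrict(feature_set) if feature_set is not None else train.values
    query = np.asarray(query, dtype=float)
    if query.shape != (sub.shape[0],):
        raise ValidationError(
            f"query length {query.size} does not match feature count {sub.shape[0]}"
        )
    clf = NearestNeighborCosineClassifier().fit(sub.T, np.asarray(train.labels))
    return str(clf.predict(query[None, :])[0])


def loocv_confusion(matrix: OmicsMatrix, feature_set: Iterable[str]) -> ConfusionCounts:
    """Leave-one-out 1-NN confusion counts on `matrix` restricted to `feature_set`.

    Each sample is predicted once from all the others; tumor is the
    positive class.
    """
    if matrix.n_samples < 2:
        raise ValidationError("LOOCV needs at least two samples")
    sub = matrix.restrict(feature_set)
    dist = _cross_distances(sub, sub)
    np.fill_diagonal(dist, np.inf)  # never one's own neighbor
    nn = np.argmin(dist, axis=1)
    truth = matrix.tumor_mask
    pred = truth[nn]
    tp = int(np.sum(pred & truth))
    tn = int(np.sum(~pred & ~truth))
    fp = int(np.sum(pred & ~truth))
    fn = int(np.sum(~pred & truth))
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient of a confusion table, in [-1, 1].

    (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)); defined as 0
    when any denominator factor vanishes.
    """
    if c.total == 0:
        raise ValidationError("MCC of an empty confusion table is undefined")
    num = c.tp * c.tn - c.fp * c.fn
    denom = (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    if denom == 0:
        return 0.0
    return num / math.sqrt(denom)


def score_set(matrix: OmicsMatrix, feature_set: Iterable[str]) -> float:
    """LOOCV-NNA MCC of one feature set on one matrix."""
    return mcc(loocv_confusion(matrix, feature_set))


def score_all(matrices: Mapping[str, OmicsMatrix], sets: Sequence[TermLevelSets]) -> pd.DataFrame:
    """MCC of every (term, level) pair.

    `matrices` maps each level name to its OmicsMatrix.  Returns a
    DataFrame indexed by term id with one MCC column per level.
    """
    check_unique_terms(sets)
    for level in LEVELS:
        if level not in matrices:
            raise ValidationError(f"no matrix supplied for level {level!r}")
    rows = {}
    for ts in sets:
        rows[ts.term_id] = [
            score_set(matrices[level], ts.members(level)) for level in LEVELS
        ]
    out = pd.DataFrame.from_dict(rows, orient="index", columns=list(LEVELS))
    out.index.name = "term"
    return out
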