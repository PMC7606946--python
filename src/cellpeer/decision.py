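"""Track-level classification and cluster-level cooperative decisions.

Three classifier families are supported, all exposing a per-class score
vector (non-negative, summing to 1, argmax = predicted label):

* **LDA** — linear discriminant analysis; posteriors are used as scores
  directly.  A singular pooled covariance triggers an automatic
  shrinkage refit (logged).
* **linear SVM** — scores come from a multinomial logistic calibration
  fitted on the training decision values (a linear-kernel SVM's raw
  margins are not probabilities).
* **KNN** — K = 5 nearest neighbors, Euclidean metric on descriptors
  already z-scored upstream; scores are neighbor vote fractions.

Per-cluster cooperative decisions aggregate the member tracks' outputs:

* **majority voting** — the plurality label; ties resolve by maximum
  trustiness restricted to the tied labels, then by lowest label index;
* **maximum trustiness** — the label with the largest per-class sum of
  member score vectors; ties resolve to the lowest label index.

A cluster whose members were all rejected upstream abstains
(``ABSTAIN``), is excluded from the cluster-level confusion matrix and
counted separately.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.linear_model import LogisticRegression
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

logger = logging.getLogger(__name__)

ABSTAIN = "__abstain__"
KNN_K = 5

__all__ = ["ClassifierOutput", "ClusterDecision", "train_classifier",
           "predict_tracks", "majority_vote", "max_trust", "ABSTAIN"]


@dataclass(frozen=True)
class ClassifierOutput:
    """Per-track prediction: label plus a normalized per-class score vector."""

    track_key: tuple[str, int]  # (video_id, track_id)
    label: str
    scores: dict[str, float]


@dataclass
class ClusterDecision:
    cluster_id: int
    members: list[tuple[str, int]]
    maj_vot: str
    max_trust: str
    vote_counts: dict[str, int]
    score_sums: dict[str, float]


class _FittedModel:
    """A fitted classifier restricted to one descriptor subset."""

    def __init__(self, kind: str, estimator, calibrator, classes: list[str],
                 columns: list[str]):
        self.kind = kind
        self.estimator = estimator
        self.calibrator = calibrator
        self.classes = classes
        self.columns = columns

    def predict_scores(self, X: np.ndarray) -> np.ndarray:
        """(n, n_classes) score matrix, rows summing to 1, class order =
        ``self.classes``."""
        if self.kind == "svm":
            d = self.estimator.decision_function(X)
            if d.ndim == 1:
                d = d[:, None]
            proba = self.calibrator.predict_proba(d)
            order = [list(self.calibrator.classes_).index(c) for c in self.classes]
            return proba[:, order]
        proba = self.estimator.predict_proba(X)
        order = [list(self.estimator.classes_).index(c) for c in self.classes]
        return proba[:, order]


def train_classifier(
    train: pd.DataFrame, descriptors: list[str], model_kind: str = "lda"
) -> _FittedModel:
    """Fit LDA / linear SVM / KNN on the given descriptor subset.

    ``train`` must carry a ``class_label`` column and >= 2 classes
    (>= K+1 samples for KNN).  All models expose ``predict_scores``.
    """
    classes = sorted(train["class_label"].unique())
    if len(classes) < 2:
        raise ValueError("training set has a single class")
    X = train[descriptors].to_numpy(dtype=float)
    y = train["class_label"].to_numpy()
    if model_kind == "lda":
        est = LinearDiscriminantAnalysis(solver="svd")
        try:
            with np.errstate(divide="raise", invalid="raise"):
                est.fit(X, y)
                est.predict_proba(X[:1])
        except (FloatingPointError, np.linalg.LinAlgError):
            logger.info("LDA covariance singular: refitting with shrinkage")
            est = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
            est.fit(X, y)
        return _FittedModel("lda", est, None, classes, descriptors)
    if model_kind == "svm":
        est = SVC(kernel="linear", decision_function_shape="ovr")
        est.fit(X, y)
        d = est.decision_function(X)
        if d.ndim == 1:
            d = d[:, None]
        calibrator = LogisticRegression(max_iter=1000)
        calibrator.fit(d, y)
        return _FittedModel("svm", est, calibrator, classes, descriptors)
    if model_kind == "knn":
        if len(train) < KNN_K + 1:
            raise ValueError(f"KNN needs at least {KNN_K + 1} training samples")
        est = KNeighborsClassifier(n_neighbors=KNN_K, metric="euclidean")
        est.fit(X, y)
        return _FittedModel("knn", est, None, classes, descriptors)
    raise ValueError(f"unknown model_kind {model_kind!r}")


def predict_tracks(
    train: pd.DataFrame,
    test: pd.DataFrame,
    subsets: dict[tuple[str, int], list[str]],
    model_kind: str = "lda",
) -> list[ClassifierOutput]:
    """Score every retained test track on its own descriptor subset.

    A classifier is trained per distinct subset and cached, so rows
    sharing a subset reuse one fitted model (the cache hit is logged).
    Rows absent from ``subsets`` (rejected upstream) produce no output.
    """
    if test.empty:
        logger.warning("empty test set: no predictions")
        return []
    cache: dict[tuple[str, ...], _FittedModel] = {}
    outputs: list[ClassifierOutput] = []
    for _, row in test.iterrows():
        key = (row["video_id"], int(row["track_id"]))
        if key not in subsets:
            continue
        cols = tuple(subsets[key])
        if cols in cache:
            model = cache[cols]
            logger.debug("classifier cache hit for subset %s", cols)
        else:
            model = train_classifier(train, list(cols), model_kind)
            cache[cols] = model
        scores = model.predict_scores(row[list(cols)].to_numpy(dtype=float)[None, :])[0]
        label = model.classes[int(np.argmax(scores))]
        outputs.append(ClassifierOutput(
            track_key=key, label=label,
            scores={c: float(s) for c, s in zip(model.classes, scores)},
        ))
    return outputs


def _score_sums(outputs: list[ClassifierOutput]) -> dict[str, float]:
    sums: dict[str, float] = {}
    for o in outputs:
        for c, s in o.scores.items():
            sums[c] = sums.get(c, 0.0) + s
    return sums


def max_trust(outputs: list[ClassifierOutput]) -> str:
    """Cluster label with the largest per-class score sum; empty cluster
    abstains; ties resolve to the lowest label index (sorted order)."""
    if not outputs:
        return ABSTAIN
    sums = _score_sums(outputs)
    best = max(sums.values())
    return sorted(c for c, s in sums.items() if s == best)[0]


def majority_vote(outputs: list[ClassifierOutput]) -> str:
    """Plurality label of a cluster's member tracks.

    Ties resolve by maximum trustiness restricted to the tied labels,
    then by lowest label index (logged); an empty cluster abstains.
    """
    if not outputs:
        return ABSTAIN
    counts: dict[str, int] = {}
    for o in outputs:
        counts[o.label] = counts.get(o.label, 0) + 1
    top = max(counts.values())
    tied = sorted(c for c, n in counts.items() if n == top)
    if len(tied) == 1:
        return tied[0]
    sums = _score_sums(outputs)
    best = max(sums[c] for c in tied)
    winners = sorted(c for c in tied if sums[c] == best)
    if len(winners) > 1:
        logger.info("majority vote tie resolved to lowest label among %s", winners)
    return winners[0]


def decide_clusters(
    outputs: list[ClassifierOutput],
    cluster_of: dict[tuple[str, int], int],
) -> list[ClusterDecision]:
    """Group track outputs by cluster id and apply both decision criteria.

    Tracks with cluster id 0 (unclustered) are excluded.  Clusters listed
    in ``cluster_of`` but with no surviving member abstain.
    """
    members: dict[int, list[ClassifierOutput]] = {}
    for cid in set(cluster_of.values()):
        if cid != 0:
            members[cid] = []
    for o in outputs:
        cid = cluster_of.get(o.track_key, 0)
        if cid != 0:
            members[cid].append(o)
    decisions = []
    for cid in sorted(members):
        outs = members[cid]
        counts: dict[str, int] = {}
        for o in outs:
            counts[o.label] = counts.get(o.label, 0) + 1
        decisions.append(ClusterDecision(
            cluster_id=cid,
            members=[o.track_key for o in outs],
            maj_vot=majority_vote(outs),
            max_trust=max_trust(outs),
            vote_counts=counts,
            score_sums=_score_sums(outs),
        ))
    return decisions
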