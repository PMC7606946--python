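"""End-to-end orchestration: feature extraction, leave-one-experiment-out
evaluation, and the model / results objects.

The driver holds out one video per fold, runs good-teacher selection,
test-sample selection, dynamic feature selection and classification on
the remaining videos, scores the held-out video's tracks, aggregates
per-cluster decisions, and accumulates confusion matrices over folds.
Metrics are overall accuracy (ACC, trace over total) and balanced
accuracy (ACC_b, unweighted mean per-class recall).

Two entry points:

* :func:`run_loeo` — functional interface on an :class:`ExperimentSet`;
* :class:`PeerPrediction` — a model object built from a feature table
  (or directly from an experiment) whose ``fit()`` returns a
  :class:`PeerPredictionResults` with confusion matrices, accuracies,
  per-fold records and a ``summary()`` table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from cellpeer.clusters import accumulation_map, assign_tracks_to_clusters, segment_clusters
from cellpeer.decision import ABSTAIN, decide_clusters, predict_tracks
from cellpeer.dfs import DFSThresholds, dynamic_select, fisher_scores, stepwise_preselect
from cellpeer.motility_features import motility_feature_vector
from cellpeer.selection import (
    descriptor_columns,
    percentile_filter,
    rank_features_auc,
    select_descriptor_subset,
)
from cellpeer.shape_features import Contour, shape_feature_vector, shape_scalars
from cellpeer.synth import SyntheticExperiment
from cellpeer.tracks import (
    ExperimentSet,
    filter_short_tracks,
    flag_outlier_tracks,
    smooth_trajectory,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "EvaluationReport", "PeerPrediction",
           "PeerPredictionResults", "extract_feature_table", "run_loeo", "evaluate"]


@dataclass(frozen=True)
class PipelineConfig:
    """All tunable pipeline parameters, with the conventional defaults.

    Percentile bounds: [th_1, th_2] for good-teacher selection, [th_3,
    th_4] for test-sample selection.  DFS thresholds default per feature
    family (shape: 1.0 / 0.1 / 1.0, motility: 0.9 / 0.1 / 0.2; stepwise
    entry p = 0.3 for both).
    """

    family: str = "motility"  # "shape" | "motility" | "both"
    model_kind: str = "lda"  # "lda" | "svm" | "knn"
    th_1: float = 0.2
    th_2: float = 0.8
    th_3: float = 0.1
    th_4: float = 0.9
    dfs: DFSThresholds | None = None  # None -> family defaults
    min_auc: float = 0.75
    max_features: int = 2
    min_track_points: int = 50
    smoothing: float = 0.99
    cell_radius: float = 15.0
    pixel_size: float | None = None  # None -> experiment's value
    disable_teacher_selection: bool = False
    disable_test_selection: bool = False
    disable_dfs: bool = False
    disable_outlier_flagging: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in ("shape", "motility", "both"):
            raise ValueError("family must be shape|motility|both")
        if self.model_kind not in ("lda", "svm", "knn"):
            raise ValueError("model_kind must be lda|svm|knn")
        if not (0 <= self.th_1 < self.th_2 <= 1 and 0 <= self.th_3 < self.th_4 <= 1):
            raise ValueError("percentile bounds must satisfy 0 <= lo < hi <= 1")

    def dfs_thresholds(self) -> DFSThresholds:
        if self.dfs is not None:
            return self.dfs
        return DFSThresholds.for_family("shape" if self.family == "shape" else "motility")


# ---------------------------------------------------------------------------
# feature extraction


def extract_feature_table(
    experiment: ExperimentSet | SyntheticExperiment,
    config: PipelineConfig = PipelineConfig(),
) -> tuple[pd.DataFrame, dict[tuple[str, int], int]]:
    """Per-track feature table plus the track -> cluster assignment.

    Per video: length-filter the tracks, build the accumulation map and
    cluster assignment, drop unsupervised outlier tracks, smooth, and
    compute the configured descriptor families.  Rows with missing
    descriptors are dropped (logged).
    """
    if isinstance(experiment, SyntheticExperiment):
        experiment = experiment.experiment
    pixel_size = config.pixel_size if config.pixel_size is not None else experiment.pixel_size
    rows: list[dict] = []
    cluster_of: dict[tuple[str, int], int] = {}
    for video in experiment.videos:
        tracks = filter_short_tracks(experiment.tracks_of(video.video_id),
                                     config.min_track_points)
        if not tracks:
            logger.warning("video %s: no tracks after length filter", video.video_id)
            continue
        amap = accumulation_map(tracks, cell_radius=config.cell_radius)
        cmap = segment_clusters(amap, morphology_radius=config.cell_radius)
        assignment = assign_tracks_to_clusters(tracks, cmap)
        cluster_of.update(assignment)
        if not config.disable_outlier_flagging:
            flags = flag_outlier_tracks(tracks)
            tracks = [t for t, bad in zip(tracks, flags) if not bad]
        for traj in tracks:
            key = (traj.video_id, traj.track_id)
            row: dict = {
                "video_id": traj.video_id,
                "track_id": traj.track_id,
                "cluster_id": assignment.get(key, 0),
                "class_label": video.class_label,
            }
            if config.family in ("motility", "both"):
                smoothed = smooth_trajectory(traj, config.smoothing)
                row.update(motility_feature_vector(smoothed, pixel_size=pixel_size))
            if config.family in ("shape", "both"):
                polys = experiment.contours.get(key)
                if polys is None:
                    logger.warning("track %s has no contours: skipped", key)
                    continue
                scalars = [shape_scalars(Contour(p), mode="polygon", pixel_size=pixel_size)
                           for p in polys]
                row.update(shape_feature_vector(scalars))
            rows.append(row)
    table = pd.DataFrame(rows)
    if table.empty:
        raise ValueError("no tracks survived feature extraction")
    desc = descriptor_columns(table)
    complete = table[desc].notna().all(axis=1)
    if (~complete).any():
        logger.info("dropping %d/%d tracks with missing descriptors",
                    int((~complete).sum()), len(table))
        table = table[complete]
    return table.reset_index(drop=True), cluster_of


# ---------------------------------------------------------------------------
# metrics


@dataclass
class EvaluationReport:
    """Confusion matrices and accuracies, single-track and cluster level."""

    labels: list[str]
    single_confusion: pd.DataFrame
    majvot_confusion: pd.DataFrame
    maxtrust_confusion: pd.DataFrame
    abstained_clusters: int = 0
    fold_records: list[dict] = field(default_factory=list)
    skipped_folds: list[dict] = field(default_factory=list)

    @staticmethod
    def _acc(cm: pd.DataFrame) -> float:
        total = cm.to_numpy().sum()
        return float(np.trace(cm.to_numpy()) / total) if total else float("nan")

    @staticmethod
    def _acc_b(cm: pd.DataFrame) -> float:
        m = cm.to_numpy(dtype=float)
        row_sums = m.sum(axis=1)
        present = row_sums > 0
        if not present.any():
            return float("nan")
        recalls = np.diag(m)[present] / row_sums[present]
        return float(recalls.mean())

    @property
    def acc_single(self) -> float:
        return self._acc(self.single_confusion)

    @property
    def acc_b_single(self) -> float:
        return self._acc_b(self.single_confusion)

    @property
    def acc_majvot(self) -> float:
        return self._acc(self.majvot_confusion)

    @property
    def acc_b_majvot(self) -> float:
        return self._acc_b(self.majvot_confusion)

    @property
    def acc_maxtrust(self) -> float:
        return self._acc(self.maxtrust_confusion)

    @property
    def acc_b_maxtrust(self) -> float:
        return self._acc_b(self.maxtrust_confusion)


def _empty_confusion(labels: list[str]) -> pd.DataFrame:
    return pd.DataFrame(np.zeros((len(labels), len(labels)), dtype=int),
                        index=labels, columns=labels)


def evaluate(y_true, y_pred, labels: list[str] | None = None) -> dict:
    """Confusion matrix, ACC and ACC_b for one pair of label sequences.

    ACC = trace/total; ACC_b = unweighted mean of per-class recalls over
    classes present in the truth (a single-class truth degenerates to
    that class's recall, flagged in the output).  Accuracies are
    fractions in [0, 1].
    """
    y_true = list(y_true)
    y_pred = list(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("label sequences differ in length")
    if not y_true:
        raise ValueError("empty input")
    if labels is None:
        labels = sorted(set(y_true) | set(y_pred))
    cm = _empty_confusion(list(labels))
    for t, p in zip(y_true, y_pred):
        cm.loc[t, p] += 1
    report = EvaluationReport(list(labels), cm, _empty_confusion(list(labels)),
                              _empty_confusion(list(labels)))
    degenerate = len(set(y_true)) == 1
    if degenerate:
        logger.warning("single class in truth: ACC_b degenerates to its recall")
    return {
        "confusion": cm,
        "acc": report.acc_single,
        "acc_b": report.acc_b_single,
        "degenerate": degenerate,
    }


# ---------------------------------------------------------------------------
# the LOEO driver


def _zscore(train: pd.DataFrame, test: pd.DataFrame, desc: list[str]):
    mu = train[desc].mean()
    sd = train[desc].std(ddof=0).replace(0.0, 1.0)
    train = train.copy()
    test = test.copy()
    train[desc] = (train[desc] - mu) / sd
    test[desc] = (test[desc] - mu) / sd
    return train, test


def _run_fold(
    train: pd.DataFrame,
    test: pd.DataFrame,
    config: PipelineConfig,
) -> tuple[list, pd.DataFrame, dict]:
    """Steps 4-8 on one fold; returns (outputs, retained test rows, log)."""
    desc = descriptor_columns(train)
    fold_log: dict = {"n_train_in": len(train), "n_test_in": len(test)}

    # AUC descriptor subset + good-teacher percentile filter
    ranked = rank_features_auc(train)
    subset = select_descriptor_subset(ranked, config.min_auc, config.max_features)
    fold_log["auc_subset"] = subset
    if not config.disable_teacher_selection:
        refined = train.loc[percentile_filter(train, subset, config.th_1, config.th_2)]
        if set(refined["class_label"]) == set(train["class_label"]):
            train = refined
        else:
            logger.warning("good-teacher selection removed a class entirely; "
                           "keeping the unfiltered training set for this fold")
    fold_log["n_train_refined"] = len(train)

    # test-sample selection on the held-out video's own quantiles
    if not config.disable_test_selection:
        test = test.loc[percentile_filter(test, subset, config.th_3, config.th_4)]
    fold_log["n_test_refined"] = len(test)

    train, test = _zscore(train, test, desc)

    # stepwise pre-selection + per-row dynamic selection
    thresholds = config.dfs_thresholds()
    if config.disable_dfs:
        pool = desc
        subsets = {(r["video_id"], int(r["track_id"])): pool for _, r in test.iterrows()}
    else:
        pool = stepwise_preselect(train, desc, thresholds.p)
        fisher = fisher_scores(train, pool)
        subsets = {
            (r["video_id"], int(r["track_id"])):
                dynamic_select(train, r, pool, thresholds, fisher=fisher)
            for _, r in test.iterrows()
        }
    fold_log["stepwise_pool"] = list(pool)

    # Steps 7-8: classification
    outputs = predict_tracks(train, test, subsets, config.model_kind)
    return outputs, test, fold_log


def run_loeo(
    experiment: ExperimentSet | SyntheticExperiment,
    config: PipelineConfig = PipelineConfig(),
    features: pd.DataFrame | None = None,
    cluster_of: dict[tuple[str, int], int] | None = None,
) -> EvaluationReport:
    """Leave-one-experiment-out evaluation of the full pipeline.

    Each video is held out once; a fold whose training set loses a class
    entirely is skipped with an error record.  Pass a precomputed
    ``features`` table (+ ``cluster_of``) to skip feature extraction.
    """
    if isinstance(experiment, SyntheticExperiment):
        experiment = experiment.experiment
    if features is None or cluster_of is None:
        features, cluster_of = extract_feature_table(experiment, config)
    labels = experiment.class_labels
    if len(labels) < 2:
        raise ValueError("LOEO needs at least 2 classes")
    report = EvaluationReport(labels, _empty_confusion(labels),
                              _empty_confusion(labels), _empty_confusion(labels))
    video_ids = sorted(features["video_id"].unique())
    for held_out in video_ids:
        truth = experiment.video_label(held_out)
        train = features[features["video_id"] != held_out]
        test = features[features["video_id"] == held_out]
        if set(train["class_label"].unique()) != set(labels):
            report.skipped_folds.append(
                {"video_id": held_out, "reason": "training set lost a class"})
            logger.error("fold %s skipped: training set lost a class", held_out)
            continue
        outputs, retained, fold_log = _run_fold(train, test, config)
        for out in outputs:
            report.single_confusion.loc[truth, out.label] += 1
        decisions = decide_clusters(
            outputs,
            {k: v for k, v in cluster_of.items() if k[0] == held_out},
        )
        for dec in decisions:
            if dec.maj_vot == ABSTAIN:
                report.abstained_clusters += 1
            else:
                report.majvot_confusion.loc[truth, dec.maj_vot] += 1
                report.maxtrust_confusion.loc[truth, dec.max_trust] += 1
        fold_log.update({
            "video_id": held_out,
            "true_label": truth,
            "n_predicted": len(outputs),
            "n_clusters": len(decisions),
        })
        report.fold_records.append(fold_log)
    return report


# ---------------------------------------------------------------------------
# model / results objects


class PeerPrediction:
    """Peer-prediction classification model over a per-track feature table.

    Parameters
    ----------
    features : DataFrame
        One row per track: ``video_id``, ``track_id``, ``cluster_id``,
        ``class_label`` plus descriptor columns.
    config : PipelineConfig
    video_labels : mapping video_id -> class label (inferred from the
        table when omitted).
    cluster_of : mapping (video_id, track_id) -> cluster id (taken from
        the ``cluster_id`` column when omitted).

    ``fit()`` runs the leave-one-experiment-out procedure and returns a
    :class:`PeerPredictionResults`.
    """

    def __init__(
        self,
        features: pd.DataFrame,
        config: PipelineConfig = PipelineConfig(),
        video_labels: dict[str, str] | None = None,
        cluster_of: dict[tuple[str, int], int] | None = None,
    ):
        required = {"video_id", "track_id", "cluster_id", "class_label"}
        missing = required - set(features.columns)
        if missing:
            raise ValueError(f"feature table missing columns {sorted(missing)}")
        self.features = features.reset_index(drop=True)
        self.config = config
        if video_labels is None:
            video_labels = (features.groupby("video_id")["class_label"]
                            .first().to_dict())
        self.video_labels = video_labels
        if cluster_of is None:
            cluster_of = {
                (r["video_id"], int(r["track_id"])): int(r["cluster_id"])
                for _, r in features.iterrows()
            }
        self.cluster_of = cluster_of

    @classmethod
    def from_experiment(
        cls,
        experiment: ExperimentSet | SyntheticExperiment,
        config: PipelineConfig = PipelineConfig(),
    ) -> "PeerPrediction":
        if isinstance(experiment, SyntheticExperiment):
            experiment = experiment.experiment
        features, cluster_of = extract_feature_table(experiment, config)
        labels = {v.video_id: v.class_label for v in experiment.videos}
        return cls(features, config, video_labels=labels, cluster_of=cluster_of)

    def _as_experiment_set(self) -> ExperimentSet:
        from cellpeer.tracks import VideoInfo

        videos = [VideoInfo(video_id=v, class_label=c)
                  for v, c in sorted(self.video_labels.items())]
        return ExperimentSet(videos=videos, trajectories=[], contours={})

    def fit(self) -> "PeerPredictionResults":
        """Run leave-one-experiment-out evaluation."""
        exp = self._as_experiment_set()
        report = run_loeo(exp, self.config, features=self.features,
                          cluster_of=self.cluster_of)
        return PeerPredictionResults(self, report)


class PeerPredictionResults:
    """Results of a fitted :class:`PeerPrediction` model."""

    def __init__(self, model: PeerPrediction, report: EvaluationReport):
        self.model = model
        self.report = report

    @property
    def labels(self) -> list[str]:
        return self.report.labels

    def accuracies(self) -> pd.DataFrame:
        """ACC and ACC_b (percent) at single-track and both cluster levels."""
        r = self.report
        return pd.DataFrame(
            {
                "ACC": [100 * r.acc_single, 100 * r.acc_majvot, 100 * r.acc_maxtrust],
                "ACC_b": [100 * r.acc_b_single, 100 * r.acc_b_majvot,
                          100 * r.acc_b_maxtrust],
            },
            index=["single-track", "maj-vot", "max-trust"],
        )

    def summary(self) -> str:
        r = self.report
        lines = ["Peer-prediction leave-one-experiment-out results",
                 "=" * 49,
                 f"classes:            {', '.join(r.labels)}",
                 f"folds evaluated:    {len(r.fold_records)}"
                 + (f" (skipped {len(r.skipped_folds)})" if r.skipped_folds else ""),
                 f"tracks scored:      {int(r.single_confusion.to_numpy().sum())}",
                 f"clusters decided:   {int(r.majvot_confusion.to_numpy().sum())}"
                 f" (abstained {r.abstained_clusters})",
                 "",
                 self.accuracies().round(2).to_string(),
                 "",
                 "single-track confusion (rows = truth):",
                 r.single_confusion.to_string(),
                 "",
                 "maj-vot cluster confusion:",
                 r.majvot_confusion.to_string()]
        return "\n".join(lines)

    def plot_confusion(self, level: str = "single", ax=None):
        """Heatmap of a confusion matrix (level: single|majvot|maxtrust)."""
        import matplotlib.pyplot as plt

        cm = {"single": self.report.single_confusion,
              "majvot": self.report.majvot_confusion,
              "maxtrust": self.report.maxtrust_confusion}[level]
        if ax is None:
            _, ax = plt.subplots()
        im = ax.imshow(cm.to_numpy(), cmap="Blues")
        ax.set_xticks(range(len(cm.columns)), cm.columns)
        ax.set_yticks(range(len(cm.index)), cm.index)
        ax.set_xlabel("predicted")
        ax.set_ylabel("true")
        for i in range(len(cm.index)):
            for j in range(len(cm.columns)):
                ax.text(j, i, int(cm.iloc[i, j]), ha="center", va="center")
        ax.figure.colorbar(im, ax=ax)
        return ax
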