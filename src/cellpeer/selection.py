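"""Good-teacher and test-sample selection.

Heterogeneous cell populations contain tracks whose behavior is not
representative of their video's class (dying cells, tracking failures,
deviant subpopulations).  Two percentile filters reject them:

* **descriptor ranking** — every descriptor is scored by its pairwise
  class-separation AUC on the training set (rank-sum estimator,
  all-vs-all, direction-corrected with max(AUC, 1-AUC), averaged over
  class pairs) and the top-scoring subset is kept;
* **good-teacher selection** — within each training video, a track is
  retained only if ALL selected descriptors lie inside the closed
  per-video percentile interval [th_1, th_2] (defaults 0.2-0.8);
* **test-sample selection** — the same filter on the held-out video with
  the independent, looser bounds [th_3, th_4] (defaults 0.1-0.9);
  rejected test tracks do not vote in the cluster decision.

Percentiles use the linear-interpolation quantile convention and are
computed per video ("independently calculated in each video").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: columns of a feature table that are annotations, not descriptors
ANNOTATION_COLUMNS = ("video_id", "track_id", "cluster_id", "class_label")

DEFAULT_MIN_AUC = 0.75
# conjunction filtering over many descriptors rejects nearly every track;
# the separability criterion is read narrowly: the top few AUC maximizers
DEFAULT_MAX_FEATURES = 2
_MIN_ROWS_PER_VIDEO = 5

__all__ = ["SelectionThresholds", "descriptor_columns", "rank_features_auc",
           "select_descriptor_subset", "percentile_filter"]


@dataclass(frozen=True)
class SelectionThresholds:
    """Percentile bounds and descriptor-subset rule."""

    th_1: float = 0.2  # training lower percentile
    th_2: float = 0.8  # training upper percentile
    th_3: float = 0.1  # test lower percentile
    th_4: float = 0.9  # test upper percentile
    min_auc: float = DEFAULT_MIN_AUC
    max_features: int = DEFAULT_MAX_FEATURES

    def __post_init__(self) -> None:
        if not (0.0 <= self.th_1 < self.th_2 <= 1.0):
            raise ValueError("need 0 <= th_1 < th_2 <= 1")
        if not (0.0 <= self.th_3 < self.th_4 <= 1.0):
            raise ValueError("need 0 <= th_3 < th_4 <= 1")
        if self.max_features < 2:
            raise ValueError("max_features must be >= 2 (subset floor is top-2)")


def descriptor_columns(table: pd.DataFrame) -> list[str]:
    """Descriptor column names of a feature table (non-annotation columns)."""
    return [c for c in table.columns if c not in ANNOTATION_COLUMNS]


def _pair_auc(a: np.ndarray, b: np.ndarray) -> float:
    """AUC of descriptor values ``b`` against ``a`` via the rank-sum
    (Mann-Whitney) estimator, ties counted half."""
    ranks = pd.Series(np.concatenate([a, b])).rank().to_numpy()
    r_b = ranks[len(a):].sum()
    n_a, n_b = len(a), len(b)
    u = r_b - n_b * (n_b + 1) / 2.0
    return float(u / (n_a * n_b))


def rank_features_auc(train: pd.DataFrame) -> pd.DataFrame:
    """Score every descriptor by mean direction-corrected pairwise AUC.

    For every unordered class pair the AUC is computed with the rank-sum
    estimator; the effective pair score is max(AUC, 1-AUC) (a perfectly
    anti-separated descriptor is as useful as a perfectly separated one);
    the descriptor score is the mean over pairs.  A descriptor constant
    overall scores exactly 0.5 and is logged.

    Returns a DataFrame (descriptor, score) sorted by descending score;
    ties keep column order.
    """
    classes = sorted(train["class_label"].unique())
    if len(classes) < 2:
        raise ValueError("AUC ranking needs at least 2 classes")
    for c in classes:
        if (train["class_label"] == c).sum() < 2:
            raise ValueError(f"class {c!r} has fewer than 2 samples")
    rows = []
    for col in descriptor_columns(train):
        values = train[col].to_numpy(dtype=float)
        if np.nanmax(values) == np.nanmin(values):
            logger.info("descriptor %s is constant: AUC score 0.5", col)
            rows.append((col, 0.5))
            continue
        pair_scores = []
        for i in range(len(classes)):
            for j in range(i + 1, len(classes)):
                a = values[(train["class_label"] == classes[i]).to_numpy()]
                b = values[(train["class_label"] == classes[j]).to_numpy()]
                auc = _pair_auc(a[np.isfinite(a)], b[np.isfinite(b)])
                pair_scores.append(max(auc, 1.0 - auc))
        rows.append((col, float(np.mean(pair_scores))))
    out = pd.DataFrame(rows, columns=["descriptor", "score"])
    return out.sort_values("score", ascending=False, kind="stable").reset_index(drop=True)


def select_descriptor_subset(
    ranked: pd.DataFrame,
    min_auc: float = DEFAULT_MIN_AUC,
    max_features: int = DEFAULT_MAX_FEATURES,
) -> list[str]:
    """Keep descriptors scoring >= ``min_auc``, capped at ``max_features``,
    with a floor of the top-2 by rank."""
    if ranked.empty:
        raise ValueError("empty ranking")
    if max_features < 2:
        raise ValueError("max_features must be >= 2")
    passing = ranked[ranked["score"] >= min_auc]["descriptor"].tolist()
    if len(passing) < 2:
        passing = ranked["descriptor"].head(2).tolist()
        logger.info("descriptor subset fell back to top-2 by rank")
    return passing[:max_features]


def percentile_filter(
    table: pd.DataFrame,
    descriptors: list[str],
    lo: float,
    hi: float,
    group_by_video: bool = True,
) -> pd.Index:
    """Rows whose selected descriptors all lie inside per-video
    percentile bounds.

    Within each video (or globally if ``group_by_video`` is False) the
    lo- and hi-quantiles of each selected descriptor are computed with
    the linear-interpolation convention; a row is retained iff every
    selected descriptor falls inside its closed [q_lo, q_hi] interval.
    Videos with fewer than 5 rows are passed through unfiltered with a
    warning.

    Returns the index of retained rows.
    """
    if not (0.0 <= lo < hi <= 1.0):
        raise ValueError("need 0 <= lo < hi <= 1")
    groups = table.groupby("video_id") if group_by_video else [(None, table)]
    kept: list[pd.Index] = []
    for vid, g in groups:
        if len(g) < _MIN_ROWS_PER_VIDEO:
            logger.warning("video %s has %d rows (< %d): percentile filter skipped",
                           vid, len(g), _MIN_ROWS_PER_VIDEO)
            kept.append(g.index)
            continue
        mask = np.ones(len(g), dtype=bool)
        for col in descriptors:
            values = g[col].to_numpy(dtype=float)
            q_lo, q_hi = np.quantile(values[np.isfinite(values)], [lo, hi])
            mask &= (values >= q_lo) & (values <= q_hi)
        kept.append(g.index[mask])
    if not kept:
        return pd.Index([])
    out = kept[0]
    for idx in kept[1:]:
        out = out.union(idx)
    return table.index.intersection(out)
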