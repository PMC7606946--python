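"""Dynamic feature selection (DFS): a possibly different descriptor
subset for every test track.

A stepwise pre-selection on the training set first caps the candidate
pool; then each test row keeps only the descriptors passing all three of

* **Fisher criterion** (supervised): the multi-class Fisher ratio
  sum_c n_c (mu_c - mu)^2 / sum_c n_c sigma_c^2, normalized by the
  maximum over candidates so the best descriptor always scores 1; a
  descriptor passes when its normalized score >= th_1dfs;
* **Mahalanobis criterion** (unsupervised): the univariate standardized
  distance |x_j - mu_j| / sigma_j of the test value from the pooled
  training distribution, normalized per test row by the maximum over
  candidates; passes when <= th_2dfs;
* **max-posterior criterion** (unsupervised): the maximum over classes of
  the posterior from per-class univariate Gaussians with equal priors;
  passes when >= th_3dfs.

An empty intersection falls back to the Fisher-passing descriptors, then
to the full stepwise pool, so the selected subset is never empty.

The normalization of the Fisher scores and Mahalanobis distances to
[0, 1] makes the conventional thresholds (all in [0, 1]) meaningful;
raw-scale thresholds are available via ``normalize=False``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _stats

logger = logging.getLogger(__name__)

__all__ = ["DFSThresholds", "stepwise_preselect", "fisher_scores",
           "mahalanobis_criterion", "max_posterior_criterion", "dynamic_select"]

#: conventional thresholds per feature family: (Fisher, Mahalanobis, max-posterior, p_enter)
SHAPE_DFS_DEFAULTS = (1.0, 0.1, 1.0, 0.3)
MOTILITY_DFS_DEFAULTS = (0.9, 0.1, 0.2, 0.3)


@dataclass(frozen=True)
class DFSThresholds:
    """The four DFS parameters (all in [0, 1])."""

    th_1dfs: float = 0.9  # Fisher criterion threshold (keep >=)
    th_2dfs: float = 0.1  # Mahalanobis criterion threshold (keep <=)
    th_3dfs: float = 0.2  # max-posterior criterion threshold (keep >=)
    p: float = 0.3  # stepwise F-test entry p-value

    def __post_init__(self) -> None:
        for name in ("th_1dfs", "th_2dfs", "th_3dfs", "p"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")

    @classmethod
    def for_family(cls, family: str) -> "DFSThresholds":
        vals = SHAPE_DFS_DEFAULTS if family == "shape" else MOTILITY_DFS_DEFAULTS
        return cls(*vals)


def _class_codes(labels: pd.Series) -> np.ndarray:
    classes = sorted(labels.unique())
    return labels.map({c: i for i, c in enumerate(classes)}).to_numpy(dtype=float)


def stepwise_preselect(
    train: pd.DataFrame,
    descriptors: list[str],
    p_enter: float = 0.3,
) -> list[str]:
    """Forward stepwise pre-selection of descriptors on the training set.

    Descriptors (z-scored on training) are entered one at a time into an
    ordinary least-squares regression of the numeric class code; the
    candidate with the smallest partial F-test p-value enters while that
    p-value is below ``p_enter``.  Removal is disabled; ties break by
    column order.  If nothing enters, the full descriptor set is returned
    with a warning (the later criteria still prune it).
    """
    y = _class_codes(train["class_label"])
    n = len(train)
    X = {}
    for col in descriptors:
        v = train[col].to_numpy(dtype=float)
        s = v.std(ddof=0)
        X[col] = (v - v.mean()) / s if s > 0 else np.zeros_like(v)

    selected: list[str] = []
    remaining = list(descriptors)
    # design matrix always carries an intercept
    current = np.ones((n, 1))
    rss_current = float(((y - y.mean()) ** 2).sum())
    while remaining:
        best: tuple[float, str, float] | None = None
        for col in remaining:
            cand = np.column_stack([current, X[col]])
            coef, _, rank, _ = np.linalg.lstsq(cand, y, rcond=None)
            if rank < cand.shape[1]:
                continue  # collinear with current model
            rss = float(((y - cand @ coef) ** 2).sum())
            dof = n - cand.shape[1]
            if dof <= 0 or rss <= 0:
                p_val = 0.0
            else:
                f = (rss_current - rss) / (rss / dof)
                p_val = float(_stats.f.sf(f, 1, dof))
            if best is None or p_val < best[0]:
                best = (p_val, col, rss)
        if best is None or best[0] >= p_enter:
            break
        p_val, col, rss = best
        selected.append(col)
        remaining.remove(col)
        current = np.column_stack([current, X[col]])
        rss_current = rss
    if not selected:
        logger.warning("stepwise pre-selection kept nothing at p_enter=%.3g; "
                       "falling back to the full descriptor set", p_enter)
        return list(descriptors)
    return selected


def fisher_scores(
    train: pd.DataFrame, descriptors: list[str], normalize: bool = True
) -> pd.Series:
    """Multi-class Fisher ratio per descriptor, normalized to [0, 1].

    raw_j = sum_c n_c (mu_cj - mu_j)^2 / sum_c n_c sigma_cj^2 (population
    variances).  With ``normalize`` the scores are divided by their
    maximum, so the best descriptor scores exactly 1.  A descriptor with
    zero within-class variance everywhere but separated means gets the
    top raw score; if its class means are also all equal the ratio is 0/0
    and an error is raised.
    """
    labels = train["class_label"]
    classes = sorted(labels.unique())
    if len(classes) < 2:
        raise ValueError("Fisher scores need at least 2 classes")
    raw = {}
    for col in descriptors:
        v = train[col].to_numpy(dtype=float)
        mu = v.mean()
        between = 0.0
        within = 0.0
        for c in classes:
            vc = v[(labels == c).to_numpy()]
            between += len(vc) * (vc.mean() - mu) ** 2
            within += len(vc) * vc.var(ddof=0)
        if within == 0:
            if between == 0:
                raise ValueError(f"descriptor {col}: zero variance and equal class means")
            raw[col] = np.inf
        else:
            raw[col] = between / within
    scores = pd.Series(raw, dtype=float)
    if np.isinf(scores).any():
        finite_max = scores[np.isfinite(scores)].max() if np.isfinite(scores).any() else 1.0
        scores = scores.replace(np.inf, max(finite_max, 1.0) * 10.0)
    if normalize:
        peak = scores.max()
        if peak > 0:
            scores = scores / peak
    return scores


def mahalanobis_criterion(
    train: pd.DataFrame,
    test_row: pd.Series,
    descriptors: list[str],
    normalize: bool = True,
) -> pd.Series:
    """Univariate standardized distance of a test row from the pooled
    training distribution, per descriptor.

    d_j = |x_j - mu_j| / sigma_j; with ``normalize`` the distances are
    divided by their maximum over candidates for this row (so the most
    aberrant descriptor scores 1).  Descriptors with zero training std
    are excluded (NaN) with a warning.
    """
    d = {}
    for col in descriptors:
        v = train[col].to_numpy(dtype=float)
        s = v.std(ddof=0)
        if s == 0:
            logger.warning("descriptor %s has zero training std: excluded from "
                           "Mahalanobis criterion", col)
            d[col] = np.nan
            continue
        d[col] = abs(float(test_row[col]) - v.mean()) / s
    dist = pd.Series(d, dtype=float)
    if normalize:
        peak = np.nanmax(dist.to_numpy()) if np.isfinite(dist).any() else 0.0
        if peak > 0:
            dist = dist / peak
    return dist


def max_posterior_criterion(
    train: pd.DataFrame, test_row: pd.Series, descriptors: list[str]
) -> pd.Series:
    """Maximum class-posterior of each descriptor's test value.

    Each class's training values fit a univariate Gaussian; the posterior
    over classes at x_j uses Bayes' rule with equal priors, computed via
    log-densities so extreme outliers resolve to the nearest class's
    limit rather than 0/0.  The criterion value is the max over classes
    (1/n_classes when all class distributions coincide).
    """
    labels = train["class_label"]
    classes = sorted(labels.unique())
    if len(classes) < 2:
        raise ValueError("max-posterior criterion needs at least 2 classes")
    out = {}
    for col in descriptors:
        v = train[col].to_numpy(dtype=float)
        logdens = []
        for c in classes:
            vc = v[(labels == c).to_numpy()]
            s = vc.std(ddof=0)
            if s == 0:
                s = max(v.std(ddof=0), 1e-12)  # degenerate class: borrow pooled scale
            logdens.append(_stats.norm.logpdf(float(test_row[col]), vc.mean(), s))
        logdens = np.asarray(logdens)
        w = np.exp(logdens - logdens.max())
        out[col] = float(w.max() / w.sum())
    return pd.Series(out, dtype=float)


def dynamic_select(
    train: pd.DataFrame,
    test_row: pd.Series,
    pool: list[str],
    thresholds: DFSThresholds,
    fisher: pd.Series | None = None,
) -> list[str]:
    """Descriptor subset for one test row: the stepwise pool intersected
    with the three criteria.

    Fallback chain on an empty intersection: Fisher-passing descriptors,
    then the full pool (both logged), so the result is never empty.
    ``fisher`` may be passed in to avoid recomputing the (test-row
    independent) Fisher scores for every row.
    """
    if not pool:
        raise ValueError("stepwise pool is empty")
    if fisher is None:
        fisher = fisher_scores(train, pool)
    maha = mahalanobis_criterion(train, test_row, pool)
    post = max_posterior_criterion(train, test_row, pool)
    fisher_pass = [c for c in pool if fisher[c] >= thresholds.th_1dfs]
    subset = [
        c for c in fisher_pass
        if np.isfinite(maha[c]) and maha[c] <= thresholds.th_2dfs
        and post[c] >= thresholds.th_3dfs
    ]
    if subset:
        return subset
    if fisher_pass:
        logger.info("DFS intersection empty: falling back to Fisher-passing set")
        return fisher_pass
    logger.info("DFS intersection and Fisher set empty: falling back to full pool")
    return list(pool)
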