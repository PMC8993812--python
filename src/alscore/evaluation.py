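"""Evaluation and longitudinal analysis.

Multiclass (one-vs-rest) ROC-AUC with bootstrap confidence intervals,
confusion matrices, pairwise R-squared matrices across functions,
per-participant baseline/slope extraction, and treatment-day-zero timeline
alignment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

from .alsfrs import N_CLASSES

logger = logging.getLogger(__name__)

__all__ = [
    "EvalReport",
    "ParticipantTimeline",
    "evaluate_predictions",
    "multiclass_auc",
    "bootstrap_ci",
    "pairwise_r2",
    "participant_slope",
    "align_to_event",
    "confusion_matrix",
]


def multiclass_auc(distributions, labels) -> float:
    """Macro one-vs-rest ROC-AUC over the five score classes.

    For each class that has both positive and negative examples in
    ``labels``, the one-vs-rest AUC is computed using that class's predicted
    probability as the ranking score (midrank tie handling); the unweighted
    mean over those classes is returned.  Classes absent or one-sided in the
    labels are skipped with a logged note.
    """
    p = np.asarray(distributions, dtype=np.float64)
    y = np.asarray(labels)
    if p.ndim != 2 or p.shape[1] != N_CLASSES:
        raise ValueError(f"distributions must have shape (n, {N_CLASSES})")
    if len(np.unique(y)) < 2:
        raise ValueError("labels must contain at least 2 distinct classes")
    aucs, skipped = [], []
    for k in range(N_CLASSES):
        pos = y == k
        if pos.all() or not pos.any():
            skipped.append(k)
            continue
        aucs.append(roc_auc_score(pos.astype(int), p[:, k]))
    if skipped:
        logger.debug("multiclass_auc: skipped one-sided classes %s", skipped)
    return float(np.mean(aucs))


def bootstrap_ci(
    metric,
    records,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int = 0,
    max_redraws: int = 100,
):
    """Percentile bootstrap confidence interval for ``metric(records)``.

    ``records`` is an indexable collection (the resampling unit — recordings
    by default; pass participant-level aggregates to resample participants
    instead, since repeated measures are correlated).  Resamples on which the
    metric is undefined (raises ValueError, e.g. a single-class draw) are
    redrawn; the redraw count is logged.
    """
    n = len(records)
    if n == 0:
        raise ValueError("records must be nonempty")
    rng = np.random.default_rng(seed)
    try:
        records_arr = np.asarray(records)
        fancy = records_arr.shape[0] == n
    except Exception:  # heterogeneous objects
        fancy = False
    values = np.empty(n_boot)
    redraws = 0
    for b in range(n_boot):
        for _attempt in range(max_redraws):
            idx = rng.integers(0, n, size=n)
            sample = records_arr[idx] if fancy else [records[i] for i in idx]
            try:
                values[b] = metric(sample)
                break
            except ValueError:
                redraws += 1
        else:
            raise ValueError(
                f"metric undefined on {max_redraws} consecutive resamples"
            )
    if redraws:
        logger.info("bootstrap_ci: redrew %d undefined resamples", redraws)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(values, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def pairwise_r2(score_table: pd.DataFrame) -> pd.DataFrame:
    """Squared Pearson correlation between every pair of function columns.

    Rows are recordings (or assessments), columns are functions.  Each pair
    uses its pairwise-complete observations; a column with zero variance
    yields NaN against the others (flagged, not fabricated) but 1.0 on the
    diagonal.
    """
    df = pd.DataFrame(score_table)
    r = df.corr(method="pearson", min_periods=3)
    r2 = r**2
    np.fill_diagonal(r2.values, 1.0)
    return r2


@dataclass
class ParticipantTimeline:
    """Ordered (day, score) points for one participant and function."""

    participant_id: str
    function: str
    days: np.ndarray
    scores: np.ndarray
    event_day: int | None = None

    def __post_init__(self):
        self.days = np.asarray(self.days, dtype=np.float64)
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if self.days.shape != self.scores.shape:
            raise ValueError("days and scores must have equal length")
        if len(self.days) > 1 and not (np.diff(self.days) > 0).all():
            raise ValueError("days must be strictly increasing")
        if len(self.scores) and ((self.scores < 0) | (self.scores > 4)).any():
            raise ValueError("scores must lie within [0, 4]")

    @property
    def baseline(self) -> float:
        """Score at the first observation (enrollment)."""
        return float(self.scores[0])


def participant_slope(
    timeline: ParticipantTimeline, min_points: int = 3
) -> tuple[float, float]:
    """Least-squares slope (score units/day) and Pearson r of a timeline.

    Requires at least ``min_points`` observations.  A perfectly constant
    timeline has slope 0 (and r is reported as 0 rather than NaN).
    """
    if len(timeline.days) < min_points:
        raise ValueError(
            f"need at least {min_points} points, got {len(timeline.days)}"
        )
    if np.ptp(timeline.scores) == 0:
        return 0.0, 0.0
    fit = stats.linregress(timeline.days, timeline.scores)
    return float(fit.slope), float(fit.rvalue)


def align_to_event(
    timeline: ParticipantTimeline, event_day: int
) -> tuple[ParticipantTimeline, ParticipantTimeline, ParticipantTimeline]:
    """Re-index a timeline so the event (e.g. treatment start) is day 0.

    Returns (full, pre, post) timelines with days shifted by ``-event_day``;
    ``pre`` holds days < 0 and ``post`` days >= 0.  Pre/post slopes are
    meaningful only when each side has at least 3 points.
    """
    days = timeline.days - event_day
    mk = lambda sel: ParticipantTimeline(
        timeline.participant_id,
        timeline.function,
        days[sel],
        timeline.scores[sel],
        event_day=0,
    )
    full = ParticipantTimeline(
        timeline.participant_id, timeline.function, days, timeline.scores, event_day=0
    )
    return full, mk(days < 0), mk(days >= 0)


@dataclass
class EvalReport:
    """Per-function AUC/CI/confusion results plus the cross-function R2 matrix."""

    auc: dict[str, float]
    ci: dict[str, tuple[float, float]]
    confusion: dict[str, np.ndarray]
    r2_matrix: pd.DataFrame | None
    n_recordings: int
    n_participants: int

    def to_table(self, source_model: str = "") -> pd.DataFrame:
        """Structured report table: function, AUC, 95% CI, source model."""
        rows = [
            {
                "function": f,
                "auc": round(self.auc[f], 3),
                "ci_lo": round(self.ci[f][0], 3),
                "ci_hi": round(self.ci[f][1], 3),
                "source_model": source_model,
            }
            for f in self.auc
        ]
        return pd.DataFrame(rows)


def evaluate_predictions(
    distributions: dict[str, np.ndarray],
    labels: dict[str, np.ndarray],
    n_participants: int,
    n_boot: int = 200,
    seed: int = 0,
    r2_scores: pd.DataFrame | None = None,
) -> EvalReport:
    """Assemble an EvalReport from per-function distributions and labels.

    ``distributions[f]`` has shape (n, 5) and ``labels[f]`` shape (n,) for
    each function name ``f``.  Bootstrap CIs resample recordings.
    """
    auc, ci, confusion = {}, {}, {}
    n_recordings = 0
    for f, p in distributions.items():
        y = np.asarray(labels[f])
        n_recordings = max(n_recordings, len(y))
        auc[f] = multiclass_auc(p, y)
        paired = np.column_stack([p, y])
        ci[f] = bootstrap_ci(
            lambda s: multiclass_auc(s[:, :N_CLASSES], s[:, N_CLASSES].astype(int)),
            paired,
            n_boot=n_boot,
            seed=seed,
        )
        confusion[f] = confusion_matrix(p, y)
    r2 = pairwise_r2(r2_scores) if r2_scores is not None else None
    return EvalReport(auc, ci, confusion, r2, n_recordings, n_participants)


def confusion_matrix(distributions, labels) -> np.ndarray:
    """5x5 confusion counts; rows = true class, columns = predicted.

    The predicted class is the argmax of the distribution; ties resolve to
    the lowest class index.
    """
    p = np.asarray(distributions, dtype=np.float64)
    y = np.asarray(labels, dtype=int)
    pred = p.argmax(axis=1)  # np.argmax returns the first (lowest) max index
    cm = np.zeros((N_CLASSES, N_CLASSES), dtype=int)
    np.add.at(cm, (y, pred), 1)
    return cm
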