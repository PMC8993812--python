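"""Frame-to-recording aggregation and expected-score decoding.

A recording's class distribution is the arithmetic mean of its windows'
normalized frame distributions; the continuous severity score is the
expectation of the class index under that distribution, a value in [0, 4].
Per-class sigmoid activations do not sum to one, so each frame is normalized
into a proper distribution before averaging (normalize-then-average; the
average-then-normalize alternative is available via ``normalize="after"``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alsfrs import N_CLASSES
from .models import FramePrediction, predict_frames

__all__ = [
    "RecordingScore",
    "aggregate_recording",
    "expected_score",
    "score_recording",
    "scores_to_table",
]


@dataclass(frozen=True)
class RecordingScore:
    """Aggregated class distributions and continuous scores for one recording."""

    participant_id: str
    date: int
    functions: tuple[str, ...]
    distributions: np.ndarray  # (n_functions, 5), rows sum to 1
    scores: np.ndarray         # (n_functions,), each in [0, 4]

    def score(self, function: str) -> float:
        return float(self.scores[self.functions.index(function)])

    def distribution(self, function: str) -> np.ndarray:
        return self.distributions[self.functions.index(function)]


def aggregate_recording(
    frame_preds: list[FramePrediction], normalize: str = "before"
) -> np.ndarray:
    """Mean class distribution over a recording's windows, (n_functions, 5).

    ``normalize="before"`` (default) averages the per-frame normalized
    distributions; ``"after"`` averages raw activations and normalizes the
    mean.  Both are invariant to frame order and to duplicating the full
    frame set.
    """
    if not frame_preds:
        raise ValueError("frame_preds must be nonempty")
    functions = frame_preds[0].functions
    if any(p.functions != functions for p in frame_preds):
        raise ValueError("all frames must predict the same function set")
    if normalize == "before":
        mean = np.mean([p.probabilities for p in frame_preds], axis=0)
    elif normalize == "after":
        mean = np.mean([p.activations for p in frame_preds], axis=0)
    else:
        raise ValueError("normalize must be 'before' or 'after'")
    total = mean.sum(axis=-1, keepdims=True)
    return np.where(total > 0, mean / np.where(total > 0, total, 1.0), 1.0 / N_CLASSES)


def expected_score(distribution: np.ndarray) -> np.ndarray:
    """Probability-weighted mean of class indices: ``sum_k k * p_k`` in [0, 4]."""
    p = np.asarray(distribution, dtype=np.float64)
    if p.shape[-1] != N_CLASSES:
        raise ValueError(f"distribution must have {N_CLASSES} entries")
    if not np.allclose(p.sum(axis=-1), 1.0, atol=1e-8):
        raise ValueError("distribution must sum to 1")
    return p @ np.arange(N_CLASSES, dtype=np.float64)


def score_recording(
    model,
    windows: np.ndarray,
    participant_id: str = "",
    date: int = 0,
    normalize: str = "before",
) -> RecordingScore:
    """Full inference for one recording: frames -> distribution -> score.

    ``windows`` holds the recording's featurized context windows; recordings
    too short to produce any window cannot be scored.
    """
    windows = np.asarray(windows, dtype=np.float64)
    if windows.shape[0] == 0:
        raise ValueError(
            "recording produced zero context windows; it is shorter than the "
            "minimum frame duration (960 ms voice / 75 s accelerometer)"
        )
    preds = predict_frames(model, windows)
    dist = aggregate_recording(preds, normalize=normalize)
    return RecordingScore(
        participant_id=participant_id,
        date=date,
        functions=tuple(model.functions_),
        distributions=dist,
        scores=np.asarray(expected_score(dist)),
    )


def scores_to_table(recording_scores: list[RecordingScore]) -> pd.DataFrame:
    """Long-format predictions table: participant_id,date,function,p0..p4,score."""
    rows = []
    for rs in recording_scores:
        for f, function in enumerate(rs.functions):
            rows.append(
                {
                    "participant_id": rs.participant_id,
                    "date": rs.date,
                    "function": function,
                    **{f"p{k}": rs.distributions[f, k] for k in range(N_CLASSES)},
                    "score": rs.scores[f],
                }
            )
    return pd.DataFrame(rows)
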