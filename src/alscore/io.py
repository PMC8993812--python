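"""Data model and readers/writers for assessments, audio and accelerometry.

Dates are handled throughout as integer day indices relative to an arbitrary
per-cohort epoch; calendar parsing, if any, stays inside the readers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .alsfrs import FUNCTIONS, LIMBS

logger = logging.getLogger(__name__)

__all__ = [
    "Assessment",
    "VoiceRecording",
    "AccelRecording",
    "LabeledSample",
    "CohortSplit",
    "read_assessments",
    "write_assessments",
    "read_wav",
    "write_wav",
    "read_accel_csv",
    "write_accel_csv",
    "associate_scores",
    "mean_abs_delta",
    "split_cohort",
]


@dataclass(frozen=True)
class Assessment:
    """One self-reported ALSFRS-R questionnaire: 12 integer scores in 0-4."""

    participant_id: str
    date: int
    scores: dict[str, int]

    def __post_init__(self) -> None:
        if set(self.scores) != set(FUNCTIONS):
            missing = sorted(set(FUNCTIONS) - set(self.scores))
            extra = sorted(set(self.scores) - set(FUNCTIONS))
            raise ValueError(
                f"scores must cover exactly the 12 ALSFRS-R functions; "
                f"missing={missing} unexpected={extra}"
            )
        for name, value in self.scores.items():
            if not (isinstance(value, (int, np.integer)) and 0 <= value <= 4):
                raise ValueError(
                    f"score for {name!r} must be an integer in 0..4, got {value!r}"
                )

    @property
    def total(self) -> int:
        """Global ALSFRS-R score (0-48)."""
        return int(sum(self.scores.values()))


@dataclass
class VoiceRecording:
    """A participant-stamped mono waveform with its sample rate."""

    participant_id: str
    date: int
    waveform: np.ndarray
    sample_rate_hz: float

    def __post_init__(self) -> None:
        self.waveform = np.asarray(self.waveform, dtype=np.float64)
        if self.waveform.ndim not in (1, 2):
            raise ValueError("waveform must be 1-D (mono) or 2-D (channels)")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")

    @property
    def duration_s(self) -> float:
        n = self.waveform.shape[-1] if self.waveform.ndim == 2 else len(self.waveform)
        return n / self.sample_rate_hz


@dataclass
class AccelRecording:
    """Per-limb tri-axial accelerometer series for one exercise session.

    ``limb_series`` maps limb name (subset of LA, LW, RA, RW) to an array of
    shape (3, n_samples) holding the x, y, z axes.  The fifth both-wrists
    exercise is excluded from the data model.
    """

    participant_id: str
    date: int
    limb_series: dict[str, np.ndarray]
    sample_rate_hz: float = 30.0

    def __post_init__(self) -> None:
        if not set(self.limb_series) <= set(LIMBS):
            raise ValueError(
                f"limb keys must be a subset of {LIMBS}, got {sorted(self.limb_series)}"
            )
        if self.sample_rate_hz not in (30.0, 30, 1.0, 1):
            raise ValueError("sample_rate_hz must be 30 or 1")
        for limb, series in self.limb_series.items():
            arr = np.asarray(series, dtype=np.float64)
            if arr.ndim != 2 or arr.shape[0] != 3:
                raise ValueError(f"limb {limb!r}: series must have shape (3, n)")
            self.limb_series[limb] = arr


@dataclass(frozen=True)
class LabeledSample:
    """A recording paired with its nearest-in-time assessment's scores."""

    sample: object  # VoiceRecording or AccelRecording
    labels: dict[str, int]
    delta_days: int  # assessment date - recording date

    def __post_init__(self) -> None:
        if abs(self.delta_days) > 60:
            raise ValueError("|delta_days| must be <= 60")


@dataclass(frozen=True)
class CohortSplit:
    """Participant-level train/validation/test partition."""

    train: frozenset[str]
    validation: frozenset[str]
    test: frozenset[str]
    forced_test: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        sets = (self.train, self.validation, self.test)
        total = sum(len(s) for s in sets)
        if len(self.train | self.validation | self.test) != total:
            raise ValueError("train/validation/test must be pairwise disjoint")
        if not self.forced_test <= self.test:
            raise ValueError("forced_test must be a subset of test")

    def subset_of(self, participant_id: str) -> str:
        for name in ("train", "validation", "test"):
            if participant_id in getattr(self, name):
                return name
        raise KeyError(participant_id)


# ---------------------------------------------------------------------------
# Scores table


def read_assessments(path: str | Path) -> list[Assessment]:
    """Read an ALSFRS-R scores table (CSV) into a list of Assessments.

    The table must have columns ``participant_id,date`` plus one column per
    ALSFRS-R function.  Rows with a score outside {0..4}, a blank score, or a
    non-integer score raise ``ValueError`` naming the offending field.
    """
    df = pd.read_csv(path, dtype={"participant_id": str})
    required = ["participant_id", "date", *FUNCTIONS]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"scores table is malformed: missing columns {missing}")

    out: list[Assessment] = []
    seen: set[tuple[str, int]] = set()
    for idx, row in df.iterrows():
        scores: dict[str, int] = {}
        for name in FUNCTIONS:
            raw = row[name]
            if pd.isna(raw):
                raise ValueError(f"row {idx}: blank score for {name!r}")
            value = float(raw)
            if value != int(value):
                raise ValueError(f"row {idx}: non-integer score for {name!r}: {raw!r}")
            if not 0 <= value <= 4:
                raise ValueError(
                    f"row {idx}: score for {name!r} out of range 0..4: {raw!r}"
                )
            scores[name] = int(value)
        key = (str(row["participant_id"]), int(row["date"]))
        if key in seen:
            raise ValueError(f"duplicate (participant_id, date) pair {key}")
        seen.add(key)
        out.append(Assessment(key[0], key[1], scores))
    return out


def write_assessments(assessments: list[Assessment], path: str | Path) -> None:
    """Write Assessments to CSV; inverse of :func:`read_assessments`."""
    rows = [
        {"participant_id": a.participant_id, "date": a.date, **a.scores}
        for a in assessments
    ]
    pd.DataFrame(rows, columns=["participant_id", "date", *FUNCTIONS]).to_csv(
        path, index=False
    )


# ---------------------------------------------------------------------------
# Audio

def read_wav(path: str | Path) -> tuple[np.ndarray, int]:
    """Read a PCM WAV file into float64 samples in [-1, 1] and its rate.

    Stereo files are returned with shape (2, n); mono with shape (n,).
    """
    rate, data = wavfile.read(path)
    if data.dtype.kind == "i":
        data = data.astype(np.float64) / float(np.iinfo(data.dtype).max)
    elif data.dtype.kind == "u":  # 8-bit unsigned PCM
        data = (data.astype(np.float64) - 128.0) / 128.0
    else:
        data = data.astype(np.float64)
    if data.ndim == 2:
        data = data.T
    return data, int(rate)


def write_wav(path: str | Path, waveform: np.ndarray, rate: int) -> None:
    """Write float samples in [-1, 1] to a 16-bit PCM WAV file."""
    x = np.asarray(waveform, dtype=np.float64)
    if x.ndim == 2:
        x = x.T
    pcm = np.clip(np.round(x * 32767.0), -32768, 32767).astype(np.int16)
    wavfile.write(path, int(rate), pcm)


# ---------------------------------------------------------------------------
# Accelerometer CSV (one file per recording session)
#
# Dialect mirrors an ActiGraph-style per-epoch export:
# columns limb,timestamp,x,y,z with timestamp in seconds from session start.


def read_accel_csv(
    path: str | Path,
    participant_id: str,
    date: int,
    sample_rate_hz: float = 30.0,
) -> AccelRecording:
    """Read one accelerometer session CSV into an AccelRecording."""
    df = pd.read_csv(path)
    required = ["limb", "timestamp", "x", "y", "z"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"accelerometer CSV malformed: missing columns {missing}")
    limb_series: dict[str, np.ndarray] = {}
    for limb, group in df.groupby("limb", sort=False):
        group = group.sort_values("timestamp")
        limb_series[str(limb)] = np.vstack(
            [group["x"].to_numpy(), group["y"].to_numpy(), group["z"].to_numpy()]
        )
    return AccelRecording(participant_id, date, limb_series, sample_rate_hz)


def write_accel_csv(recording: AccelRecording, path: str | Path) -> None:
    """Write an AccelRecording to the limb,timestamp,x,y,z CSV dialect."""
    frames = []
    for limb in LIMBS:
        if limb not in recording.limb_series:
            continue
        xyz = recording.limb_series[limb]
        t = np.arange(xyz.shape[1]) / recording.sample_rate_hz
        frames.append(
            pd.DataFrame(
                {"limb": limb, "timestamp": t, "x": xyz[0], "y": xyz[1], "z": xyz[2]}
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Recording-to-assessment association


def associate_scores(
    samples: list,
    assessments: list[Assessment],
    window_days: int = 60,
) -> list[LabeledSample]:
    """Pair each recording with its nearest same-participant assessment.

    A recording is labeled by the assessment minimizing |assessment date -
    recording date|, provided that distance is at most ``window_days``
    (default 60); otherwise the recording is silently discarded.  When two
    assessments are equidistant the earlier one is chosen.  The mean absolute
    date delta of the retained samples is logged.
    """
    by_participant: dict[str, list[Assessment]] = {}
    for a in assessments:
        by_participant.setdefault(a.participant_id, []).append(a)
    for lst in by_participant.values():
        lst.sort(key=lambda a: a.date)

    labeled: list[LabeledSample] = []
    for sample in samples:
        candidates = by_participant.get(sample.participant_id, [])
        best: Assessment | None = None
        for a in candidates:
            if abs(a.date - sample.date) > window_days:
                continue
            if best is None or abs(a.date - sample.date) < abs(best.date - sample.date):
                best = a
            # equal distance: keep the earlier (already-seen) assessment
        if best is not None:
            labeled.append(
                LabeledSample(sample, dict(best.scores), int(best.date - sample.date))
            )
    if labeled:
        logger.info(
            "associated %d/%d recordings; mean |delta| = %.2f days",
            len(labeled),
            len(samples),
            mean_abs_delta(labeled),
        )
    return labeled


def mean_abs_delta(labeled: list[LabeledSample]) -> float:
    """Mean absolute recording-to-assessment date gap, in days."""
    return float(np.mean([abs(s.delta_days) for s in labeled]))


# ---------------------------------------------------------------------------
# Cohort splitting


def _largest_remainder(n: int, ratios: tuple[float, ...]) -> list[int]:
    """Apportion n items to ratios by the largest-remainder rule."""
    quotas = [n * r for r in ratios]
    counts = [int(np.floor(q)) for q in quotas]
    remainder = n - sum(counts)
    order = np.argsort([-(q - np.floor(q)) for q in quotas], kind="stable")
    for i in order[:remainder]:
        counts[i] += 1
    return counts


def split_cohort(
    participant_ids,
    ratios: tuple[float, float, float] = (0.70, 0.15, 0.15),
    forced_test: set[str] | frozenset[str] = frozenset(),
    seed: int = 0,
) -> CohortSplit:
    """Randomly partition participants into train/validation/test sets.

    Splitting is by participant so no participant's recordings cross splits.
    ``forced_test`` members are placed in the test set unconditionally (as
    done for a treated sub-cohort whose outcomes must be evaluated held-out);
    the remaining participants are apportioned so the overall proportions are
    as close to ``ratios`` as the largest-remainder rule permits.
    Deterministic for a given seed.
    """
    ids = sorted(set(map(str, participant_ids)))
    forced = frozenset(map(str, forced_test))
    if not forced <= set(ids):
        raise ValueError("forced_test must be a subset of participant_ids")
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError(f"ratios must sum to 1, got {ratios}")

    n = len(ids)
    n_train, n_val, n_test = _largest_remainder(n, tuple(ratios))
    remaining = [p for p in ids if p not in forced]
    if len(forced) > n_test:
        # Forced membership exceeds the target test size: keep all forced ids
        # in test and re-apportion the rest between train and validation.
        n_test = len(forced)
        tr, va = ratios[0], ratios[1]
        n_train, n_val = _largest_remainder(
            len(remaining), (tr / (tr + va), va / (tr + va))
        )
    rng = np.random.default_rng(seed)
    remaining = list(np.array(remaining)[rng.permutation(len(remaining))])
    train = remaining[:n_train]
    val = remaining[n_train : n_train + n_val]
    test = remaining[n_train + n_val :]
    return CohortSplit(
        train=frozenset(train),
        validation=frozenset(val),
        test=frozenset(test) | forced,
        forced_test=forced,
    )
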