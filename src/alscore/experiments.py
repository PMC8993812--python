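"""End-to-end experiment pipelines on a (synthetic or real) cohort.

Each experiment runs the full method: featurize recordings, associate each
with its nearest assessment within 60 days, split the cohort by participant
(70:15:15), train a frame-level model with inverse-class-frequency weights
and validation-based model selection, aggregate frame predictions into
recording-level distributions and continuous scores, and evaluate with
macro one-vs-rest multiclass AUC and Spearman correlation against the
generator's latent severities (when the cohort is synthetic).

Training settings here are sized for a desk-scale cohort on one CPU:
learning rate 1e-3 and a reduced epoch count, with features standardized by
training-split statistics.  The estimator defaults themselves retain the
full-scale hyperparameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .accel import fft1hz_features, recording_vm_1hz
from .alsfrs import ACCEL_FUNCTIONS
from .evaluation import multiclass_auc
from .io import associate_scores, split_cohort
from .models import FeatureMLPClassifier, SpectrogramCNNClassifier
from .scoring import aggregate_recording, expected_score
from .models import predict_frames
from .simulate import Cohort
from .voice import logmel_windows

__all__ = ["ExperimentResult", "run_fft1hz_experiment", "run_voice_experiment"]


@dataclass
class ExperimentResult:
    """Held-out evaluation of one end-to-end pipeline."""

    model: object
    auc_per_function: dict[str, float]
    macro_auc: float
    spearman_per_function: dict[str, float]
    n_test_recordings: int
    test_scores: list  # (participant_id, date, function, predicted score, label)


def _split(labeled, seed):
    pids = sorted({s.sample.participant_id for s in labeled})
    split = split_cohort(pids, seed=seed)
    by = {"train": [], "validation": [], "test": []}
    for s in labeled:
        by[split.subset_of(s.sample.participant_id)].append(s)
    return by


def run_fft1hz_experiment(
    cohort: Cohort,
    seed: int = 0,
    epochs: int = 60,
    learning_rate: float = 1e-3,
    hidden_layer_sizes=(64,),
) -> ExperimentResult:
    """Multi-label MLP on FFT-1Hz accelerometer features, 9 functions.

    For the 1 Hz feature variants one recording yields exactly one feature
    vector, so frame-level and recording-level predictions coincide.
    """
    labeled = associate_scores(cohort.accel_recordings, cohort.assessments)
    by = _split(labeled, seed)

    def featurize(samples):
        X = np.stack(
            [fft1hz_features(recording_vm_1hz(s.sample)) for s in samples]
        )
        y = np.stack(
            [[s.labels[f] for f in ACCEL_FUNCTIONS] for s in samples]
        )
        return X, y

    X_tr, y_tr = featurize(by["train"])
    X_va, y_va = featurize(by["validation"])
    X_te, y_te = featurize(by["test"])
    mu, sd = X_tr.mean(axis=0), X_tr.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    X_tr, X_va, X_te = [(X - mu) / sd for X in (X_tr, X_va, X_te)]

    model = FeatureMLPClassifier(
        target_functions=ACCEL_FUNCTIONS,
        hidden_layer_sizes=hidden_layer_sizes,
        learning_rate=learning_rate,
        epochs=epochs,
        random_state=seed,
    ).fit(X_tr, y_tr, validation_data=(X_va, y_va))

    probs = model.predict_frame_distributions(X_te)
    scores = probs @ np.arange(5.0)
    auc_pf, rho_pf, test_rows = {}, {}, []
    for fi, f in enumerate(ACCEL_FUNCTIONS):
        auc_pf[f] = multiclass_auc(probs[:, fi, :], y_te[:, fi])
        latents = np.array(
            [cohort.latent(s.sample.participant_id, f, s.sample.date) for s in by["test"]]
        )
        rho_pf[f] = float(stats.spearmanr(scores[:, fi], latents).statistic)
        for s, sc, lab in zip(by["test"], scores[:, fi], y_te[:, fi]):
            test_rows.append(
                (s.sample.participant_id, s.sample.date, f, float(sc), int(lab))
            )
    return ExperimentResult(
        model=model,
        auc_per_function=auc_pf,
        macro_auc=float(np.mean(list(auc_pf.values()))),
        spearman_per_function=rho_pf,
        n_test_recordings=len(by["test"]),
        test_scores=test_rows,
    )


def run_voice_experiment(
    cohort: Cohort,
    seed: int = 0,
    epochs: int = 8,
    learning_rate: float = 1e-3,
    batch_size: int = 64,
    filters=(8, 16, 32),
) -> ExperimentResult:
    """Voice CNN on 96x64 log-mel windows, single speech-function head.

    Windows from one recording share the recording's speech label; at test
    time frame distributions are averaged per recording before scoring and
    AUC computation, exactly as at full scale.
    """
    labeled = associate_scores(cohort.voice_recordings, cohort.assessments)
    by = _split(labeled, seed)

    def featurize(samples):
        windows, labels, owner = [], [], []
        for j, s in enumerate(samples):
            w = logmel_windows(s.sample)
            windows.append(w)
            labels.extend([s.labels["speech"]] * len(w))
            owner.extend([j] * len(w))
        return np.concatenate(windows), np.asarray(labels), np.asarray(owner)

    X_tr, y_tr, _ = featurize(by["train"])
    X_va, y_va, _ = featurize(by["validation"])
    X_te, _, owner_te = featurize(by["test"])
    mu, sd = X_tr.mean(), X_tr.std()
    X_tr, X_va, X_te = [(X - mu) / sd for X in (X_tr, X_va, X_te)]

    model = SpectrogramCNNClassifier(
        target_functions=("speech",),
        filters=filters,
        learning_rate=learning_rate,
        batch_size=batch_size,
        epochs=epochs,
        random_state=seed,
    ).fit(X_tr, y_tr, validation_data=(X_va, y_va))

    preds = predict_frames(model, X_te)
    rec_dists, rec_labels, latents, rec_scores, test_rows = [], [], [], [], []
    for j, s in enumerate(by["test"]):
        frame_preds = [p for p, o in zip(preds, owner_te) if o == j]
        dist = aggregate_recording(frame_preds)
        score = float(expected_score(dist)[0])
        rec_dists.append(dist[0])
        rec_labels.append(s.labels["speech"])
        rec_scores.append(score)
        latents.append(cohort.latent(s.sample.participant_id, "speech", s.sample.date))
        test_rows.append(
            (s.sample.participant_id, s.sample.date, "speech", score, s.labels["speech"])
        )
    auc = multiclass_auc(np.stack(rec_dists), np.asarray(rec_labels))
    rho = float(stats.spearmanr(rec_scores, latents).statistic)
    return ExperimentResult(
        model=model,
        auc_per_function={"speech": auc},
        macro_auc=auc,
        spearman_per_function={"speech": rho},
        n_test_recordings=len(by["test"]),
        test_scores=test_rows,
    )
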