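"""Synthetic longitudinal ALS cohort generator.

Emulates the structure of a home-monitoring study: participants with
per-function severity trajectories (ALSFRS-R convention, 4 = normal,
0 = worst), periodic self-report visits, more frequent voice and
accelerometer recording sessions paired to assessments within 60 days, and
optional treatment-start events.  Severity trajectories are piecewise-linear
and non-increasing in expectation, with a shared participant-level component
plus group-level components so scores correlate in blocks (bulbar trio,
fine-motor items, lower-limb pair, respiratory trio) the way real ALSFRS-R
subscores do.

Signal generators are deliberately simple but monotone in severity:

* ``synth_voice`` emits a syllable-like amplitude-modulated harmonic signal;
  lower severity scores (worse function) lower the syllable rate, widen
  inter-syllable gaps and add spectral noise and pitch jitter.
* ``synth_accel`` emits bout-structured oscillatory limb movement
  (0.5-2.5 Hz); lower scores reduce movement amplitude and frequency.
  Series represent gravity-compensated dynamic acceleration with additive
  sensor noise.

All randomness flows from the single spec seed through a documented
stream-splitting scheme (``numpy.random.SeedSequence.spawn``): child 0 is
the cohort-level stream, child ``1 + i`` belongs to participant ``i``, and
each participant's recordings draw from further per-event spawns, so any
sub-generator is independently reproducible.

Treatment events shift nothing by default; they exist to exercise day-zero
alignment analyses, not to model a drug effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alsfrs import FUNCTIONS, GROUPS, LIMBS
from .io import AccelRecording, Assessment, VoiceRecording

__all__ = [
    "CohortSpec",
    "Cohort",
    "simulate_cohort",
    "synth_voice",
    "synth_accel",
    "latent_to_score",
    "write_cohort",
]

#: Which latent functions drive each limb's movement signal.
LIMB_DRIVERS: dict[str, tuple[str, ...]] = {
    "LA": GROUPS["lower_limb"],
    "RA": GROUPS["lower_limb"],
    "LW": GROUPS["fine_motor"],
    "RW": GROUPS["fine_motor"],
}


@dataclass
class CohortSpec:
    """Study-design parameters of a synthetic cohort.

    Defaults describe a strong-effect desk-scale cohort: 60 participants
    followed for a year, assessments every ~60 days, recordings every
    ~45 days, mild self-report noise, and severity strongly modulating the
    generated signals.
    """

    n_participants: int = 60
    onset_mix: dict[str, float] = field(
        default_factory=lambda: {"limb": 0.78, "bulbar": 0.15, "respiratory": 0.07}
    )
    baseline_mean: float = 3.3          # per-function score at enrollment
    baseline_sd: float = 0.4
    decline_rate_mean: float = -0.0025  # score units/day (~ -0.9/year)
    decline_rate_sd: float = 0.0015
    group_baseline_sd: float = 0.2      # shared within each function group
    group_slope_sd: float = 0.3         # log-scale slope multiplier spread
    function_noise_sd: float = 0.1      # idiosyncratic per-function offset
    visit_every_days: float = 60.0
    visit_jitter_days: float = 8.0
    recording_every_days: float = 45.0
    follow_up_days: float = 360.0
    reporter_noise: float = 0.05        # probability of a +/-1 mis-report
    effect_strength: float = 1.0        # scales severity -> signal modulation
    voice_duration_s: float = 4.8
    accel_duration_s: float = 80.0
    treatment_fraction: float = 0.3
    treatment_window: tuple[float, float] = (0.3, 0.7)  # of follow-up span
    seed: int = 0


@dataclass
class _LatentParams:
    """Per-participant trajectory parameters (per-function affine in time)."""

    intercepts: dict[str, float]
    slopes: dict[str, float]

    def value(self, function: str, day: float) -> float:
        raw = self.intercepts[function] + self.slopes[function] * day
        return float(np.clip(raw, 0.0, 4.0))


@dataclass
class Cohort:
    """A simulated cohort: data streams plus ground-truth latents."""

    spec: CohortSpec
    assessments: list[Assessment]
    voice_recordings: list[VoiceRecording]
    accel_recordings: list[AccelRecording]
    latent_params: dict[str, _LatentParams]
    treatment_day: dict[str, int]

    def latent(self, participant_id: str, function: str, day: float) -> float:
        """Ground-truth continuous severity for a participant-function-day."""
        return self.latent_params[participant_id].value(function, day)

    @property
    def participant_ids(self) -> list[str]:
        return sorted(self.latent_params)

    def latents_table(self) -> pd.DataFrame:
        """Latent severity of every function at every recording date."""
        rows = []
        seen = set()
        for rec in [*self.voice_recordings, *self.accel_recordings]:
            key = (rec.participant_id, rec.date)
            if key in seen:
                continue
            seen.add(key)
            for f in FUNCTIONS:
                rows.append(
                    {
                        "participant_id": rec.participant_id,
                        "date": rec.date,
                        "function": f,
                        "latent": self.latent(rec.participant_id, f, rec.date),
                    }
                )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Signal generators


def synth_voice(
    severity: float,
    duration_s: float,
    seed,
    sample_rate: int = 8000,
    effect_strength: float = 1.0,
) -> np.ndarray:
    """Severity-modulated syllable-like harmonic waveform at 8 kHz.

    ``severity`` follows the ALSFRS-R convention (4 = normal speech).  The
    signal is a harmonic carrier (f0 ~ 120 Hz) gated by a raised-cosine
    syllable envelope.  As severity decreases: the syllable rate falls from
    3.5 Hz toward 1.5 Hz (longer inter-syllable gaps), pitch jitter grows,
    and broadband noise is mixed in.  Peak amplitude is bounded by 1.
    """
    if not 0.0 <= severity <= 4.0:
        raise ValueError("severity must lie in [0, 4]")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * sample_rate))
    if n == 0:
        return np.empty(0)
    t = np.arange(n) / sample_rate
    impairment = (4.0 - severity) / 4.0 * effect_strength

    syllable_rate = 3.5 - 2.0 * impairment          # Hz
    duty = 0.65 - 0.25 * impairment                 # fraction of cycle voiced
    jitter_sd = 2.0 + 18.0 * impairment             # Hz, pitch wander
    noise_amp = 0.03 + 0.45 * impairment

    # raised-cosine syllable envelope with inter-syllable gaps
    phase = (t * syllable_rate) % 1.0
    env = np.where(phase < duty, 0.5 * (1 - np.cos(2 * np.pi * phase / duty)), 0.0)

    f0 = 120.0 + np.cumsum(rng.normal(0.0, jitter_sd, size=n)) / np.sqrt(
        np.arange(1, n + 1)
    )
    carrier_phase = 2 * np.pi * np.cumsum(f0) / sample_rate
    carrier = np.zeros(n)
    for h, amp in enumerate((1.0, 0.6, 0.4, 0.25, 0.15, 0.1), start=1):
        carrier += amp * np.sin(h * carrier_phase)
    carrier /= 2.5

    noise = rng.normal(0.0, 1.0, size=n)
    x = env * (0.8 * carrier + noise_amp * noise) + 0.01 * noise
    peak = np.abs(x).max()
    if peak > 0.99:
        x *= 0.99 / peak
    return x


def synth_accel(
    severity_per_limb: dict[str, float],
    duration_s: float,
    seed,
    sample_rate: int = 30,
    noise_sd: float = 0.05,
    bout_period_s: float = 60.0,
    bout_duty: float = 0.75,
    effect_strength: float = 1.0,
) -> dict[str, np.ndarray]:
    """Severity-modulated oscillatory limb movement, (3, n) per limb.

    Each limb oscillates at 0.5-2.5 Hz: frequency and amplitude both
    increase with the limb's severity score (4 = vigorous movement).  The
    oscillation is projected onto a random fixed orientation, gated by an
    exercise-bout envelope (on/off cycles emulating prescribed movements
    with rest breaks), and additive sensor noise is applied per axis.
    Series are gravity-compensated dynamic acceleration.
    """
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * sample_rate))
    t = np.arange(n) / sample_rate
    out: dict[str, np.ndarray] = {}
    for limb in sorted(severity_per_limb):
        severity = severity_per_limb[limb]
        if not 0.0 <= severity <= 4.0:
            raise ValueError(f"limb {limb!r}: severity must lie in [0, 4]")
        vigor = severity / 4.0 * effect_strength
        freq = 0.5 + 2.0 * vigor                    # Hz
        amp = 0.05 + 1.0 * vigor                    # g units
        phase0 = rng.uniform(0, 2 * np.pi)
        bout = ((t % bout_period_s) / bout_period_s < bout_duty).astype(float)
        osc = amp * bout * np.sin(2 * np.pi * freq * t + phase0)
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        xyz = direction[:, None] * osc[None, :]
        xyz = xyz + rng.normal(0.0, noise_sd, size=xyz.shape)
        out[limb] = xyz
    return out


def latent_to_score(latent: float, noise_p: float, seed) -> int:
    """Integer self-report of a continuous severity: round, maybe mis-report.

    With probability ``noise_p`` the rounded score is shifted by +/-1
    (symmetric), then clipped to 0..4.
    """
    if not 0.0 <= latent <= 4.0:
        raise ValueError("latent must lie in [0, 4]")
    rng = np.random.default_rng(seed)
    score = int(round(latent))
    if rng.random() < noise_p:
        score += rng.choice((-1, 1))
    return int(np.clip(score, 0, 4))


# ---------------------------------------------------------------------------
# Cohort assembly

_ONSET_TARGETS = {
    "limb": ("fine_motor", "lower_limb"),
    "bulbar": ("bulbar",),
    "respiratory": ("respiratory",),
}


def _draw_latents(spec: CohortSpec, onset: str, rng: np.random.Generator) -> _LatentParams:
    baseline = rng.normal(spec.baseline_mean, spec.baseline_sd)
    slope = -abs(rng.normal(spec.decline_rate_mean, spec.decline_rate_sd))
    intercepts, slopes = {}, {}
    for group, members in GROUPS.items():
        u_g = rng.normal(0.0, spec.group_baseline_sd)
        m_g = float(np.exp(rng.normal(0.0, spec.group_slope_sd)))
        if group in _ONSET_TARGETS[onset]:
            u_g -= 0.5
            m_g *= 1.7
        for f in members:
            e_f = rng.normal(0.0, spec.function_noise_sd)
            c_f = float(np.exp(rng.normal(0.0, 0.15)))
            intercepts[f] = float(np.clip(baseline + u_g + e_f, 0.3, 4.0))
            slopes[f] = slope * m_g * c_f
    return _LatentParams(intercepts, slopes)


def simulate_cohort(spec: CohortSpec) -> Cohort:
    """Generate a full synthetic cohort from a CohortSpec.

    Every recording has at least one same-participant assessment within 60
    days whenever the visit cadence is at most ~120 days (push
    ``visit_every_days`` beyond that to exercise the discard path of score
    association).  Byte-identical for a given spec.
    """
    if spec.n_participants <= 0:
        raise ValueError("n_participants must be positive")
    root = np.random.SeedSequence(spec.seed)
    children = root.spawn(spec.n_participants + 1)
    cohort_rng = np.random.default_rng(children[0])

    onset_names = list(spec.onset_mix)
    onset_p = np.asarray([spec.onset_mix[k] for k in onset_names], dtype=float)
    onset_p /= onset_p.sum()

    assessments: list[Assessment] = []
    voice_recordings: list[VoiceRecording] = []
    accel_recordings: list[AccelRecording] = []
    latent_params: dict[str, _LatentParams] = {}
    treatment_day: dict[str, int] = {}

    treated = cohort_rng.random(spec.n_participants) < spec.treatment_fraction
    onsets = cohort_rng.choice(onset_names, size=spec.n_participants, p=onset_p)

    for i in range(spec.n_participants):
        pid = f"P{i:03d}"
        pseq = children[i + 1]
        p_rng = np.random.default_rng(pseq)
        params = _draw_latents(spec, str(onsets[i]), p_rng)
        latent_params[pid] = params

        # assessment visits
        day = 0.0
        visit_days: list[int] = []
        while day <= spec.follow_up_days:
            visit_days.append(int(round(day)))
            day += spec.visit_every_days + p_rng.normal(0.0, spec.visit_jitter_days)
            day = max(day, (visit_days[-1] + 1))
        for d in visit_days:
            scores = {
                f: latent_to_score(
                    params.value(f, d), spec.reporter_noise, p_rng.integers(2**31)
                )
                for f in FUNCTIONS
            }
            assessments.append(Assessment(pid, d, scores))

        # recording sessions (voice + accelerometer on the same day)
        day = spec.recording_every_days / 2.0
        while day <= spec.follow_up_days:
            d = int(round(day))
            voice_recordings.append(
                VoiceRecording(
                    pid,
                    d,
                    synth_voice(
                        params.value("speech", d),
                        spec.voice_duration_s,
                        p_rng.integers(2**31),
                        effect_strength=spec.effect_strength,
                    ),
                    8000,
                )
            )
            severity_per_limb = {
                limb: float(
                    np.mean([params.value(f, d) for f in LIMB_DRIVERS[limb]])
                )
                for limb in LIMBS
            }
            accel_recordings.append(
                AccelRecording(
                    pid,
                    d,
                    synth_accel(
                        severity_per_limb,
                        spec.accel_duration_s,
                        p_rng.integers(2**31),
                        effect_strength=spec.effect_strength,
                    ),
                    30,
                )
            )
            day += spec.recording_every_days

        if treated[i]:
            lo, hi = spec.treatment_window
            treatment_day[pid] = int(
                round(p_rng.uniform(lo, hi) * spec.follow_up_days)
            )

    return Cohort(
        spec=spec,
        assessments=assessments,
        voice_recordings=voice_recordings,
        accel_recordings=accel_recordings,
        latent_params=latent_params,
        treatment_day=treatment_day,
    )


def write_cohort(cohort: Cohort, out_dir) -> None:
    """Write a cohort to disk in the package's CSV/WAV dialects.

    Layout: ``assessments.csv``, ``voice/<pid>_<day>.wav``,
    ``accel/<pid>_<day>.csv``, ``latents.csv`` and ``treatment_events.csv``.
    """
    from pathlib import Path

    from .io import write_accel_csv, write_assessments, write_wav

    out = Path(out_dir)
    (out / "voice").mkdir(parents=True, exist_ok=True)
    (out / "accel").mkdir(parents=True, exist_ok=True)
    write_assessments(cohort.assessments, out / "assessments.csv")
    for rec in cohort.voice_recordings:
        write_wav(out / "voice" / f"{rec.participant_id}_{rec.date}.wav",
                  rec.waveform, int(rec.sample_rate_hz))
    for rec in cohort.accel_recordings:
        write_accel_csv(rec, out / "accel" / f"{rec.participant_id}_{rec.date}.csv")
    cohort.latents_table().to_csv(out / "latents.csv", index=False)
    pd.DataFrame(
        [{"participant_id": p, "event_day": d} for p, d in sorted(cohort.treatment_day.items())]
    ).to_csv(out / "treatment_events.csv", index=False)
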