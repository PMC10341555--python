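"""Synthetic two-cohort TUG accelerometer data.

Each synthetic subject is a five-phase waist-acceleration trace
(sit-to-stand, walk out, turn, walk back, stand-to-sit) built from
deterministic phase templates plus Gaussian noise:

* transitions are smooth AP/V plateaus of the drawn duration;
* walking is sinusoidal V/AP oscillation at the step frequency
  (cadence / 60) with ML sway at half that frequency;
* the turn carries ML oscillation with 3x the walking ML variance.

Fall-risk subjects receive multiplicative *effect* shifts (for example
``stand_duration x 2.5``), and an SFBBS score is simulated from a noisy
logistic function of those shifts so that the two clinical labelings
agree imperfectly, as real ones do.

The walkway is fixed at 3 m each way, so cadence, step length, gait
speed and the walking-phase durations are mutually consistent.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    AXES,
    PHASES,
    PhaseBounds,
    Recording,
    SubjectLabels,
    read_annotations,
    read_recording,
    write_annotations,
    write_recording,
)

__all__ = [
    "CohortSpec",
    "SyntheticSubject",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
]

_EFFECT_KEYS = {
    "stand_duration",
    "sit_duration",
    "turn_duration",
    "cadence",
    "step_length",
    "gait_speed",
}

# template amplitudes, m/s^2
_TRANSITION_AP = 3.0
_TRANSITION_V = 2.0
_WALK_V = 1.5
_WALK_AP = 0.3
_WALK_ML = 0.4
_TURN_V = 0.6
_TURN_AP = 0.25
_TURN_FREQ_HZ = 1.2
_TURN_ML_DC = 2.0  # centripetal component of a tight 180-degree turn
_TURN_RAMP_FRAC = 0.08
_MIN_PHASE_S = 0.1


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of one synthetic cohort.

    ``phase_duration_means``/``sds`` cover the five phases; the walking
    entries are informational only — the effective walking durations are
    derived from the drawn gait (3 m each way at cadence/60 x
    step_length m/s).  ``effect`` maps a parameter name to the
    multiplicative shift applied to fall-risk subjects.
    """

    n_subjects: int
    fs: float = 30.0
    phase_duration_means: dict = field(
        default_factory=lambda: {
            "sist": 1.5, "walk_out": 3.0, "turn": 2.0, "walk_back": 3.0, "stsi": 1.5,
        }
    )
    phase_duration_sds: dict = field(
        default_factory=lambda: {
            "sist": 0.2, "walk_out": 0.0, "turn": 0.3, "walk_back": 0.0, "stsi": 0.2,
        }
    )
    cadence_mean: float = 110.0
    cadence_sd: float = 8.0
    step_length_mean: float = 0.55
    step_length_sd: float = 0.05
    noise_sd: float = 0.1
    sway_gain_ml: float = 1.0
    fall_risk_fraction: float = 0.2
    effect: dict = field(default_factory=lambda: {"stand_duration": 2.5})
    seed: int = 0
    walkway_m: float = 3.0
    pad_s: float = 1.0

    def __post_init__(self) -> None:
        if self.n_subjects < 0:
            raise ValueError(f"n_subjects must be >= 0, got {self.n_subjects}")
        if not self.fs > 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if set(self.phase_duration_means) != set(PHASES):
            raise ValueError(f"phase_duration_means must cover {PHASES}")
        if set(self.phase_duration_sds) != set(PHASES):
            raise ValueError(f"phase_duration_sds must cover {PHASES}")
        for name, value in [
            ("cadence_mean", self.cadence_mean),
            ("step_length_mean", self.step_length_mean),
            ("walkway_m", self.walkway_m),
        ]:
            if not value > 0:
                raise ValueError(f"{name} must be positive, got {value}")
        for name, value in [
            ("cadence_sd", self.cadence_sd),
            ("step_length_sd", self.step_length_sd),
            ("noise_sd", self.noise_sd),
            ("sway_gain_ml", self.sway_gain_ml),
            ("pad_s", self.pad_s),
            *[(f"phase_duration_sds[{p}]", self.phase_duration_sds[p]) for p in PHASES],
            *[(f"phase_duration_means[{p}]", self.phase_duration_means[p]) for p in PHASES],
        ]:
            if value < 0:
                raise ValueError(f"{name} must be >= 0, got {value}")
        if not 0.0 <= self.fall_risk_fraction <= 1.0:
            raise ValueError(
                f"fall_risk_fraction must be in [0, 1], got {self.fall_risk_fraction}"
            )
        unknown = set(self.effect) - _EFFECT_KEYS
        if unknown:
            raise ValueError(f"unknown effect keys {sorted(unknown)}; allowed: {sorted(_EFFECT_KEYS)}")
        for key, value in self.effect.items():
            if not value > 0:
                raise ValueError(f"effect[{key}] must be positive, got {value}")

    @classmethod
    def community(cls, n_subjects: int = 65, seed: int = 0, **overrides) -> "CohortSpec":
        """Community-dwelling-elderly-like cohort recorded at 30 Hz."""
        return cls(n_subjects=n_subjects, seed=seed, **overrides)

    @classmethod
    def stroke(cls, n_subjects: int = 35, seed: int = 0, **overrides) -> "CohortSpec":
        """Stroke-survivor-like cohort recorded at 45 Hz, slower gait."""
        defaults = dict(
            fs=45.0,
            phase_duration_means={
                "sist": 1.6, "walk_out": 3.3, "turn": 2.0, "walk_back": 3.3, "stsi": 1.6,
            },
            phase_duration_sds={
                "sist": 0.25, "walk_out": 0.0, "turn": 0.3, "walk_back": 0.0, "stsi": 0.25,
            },
            cadence_mean=105.0,
            cadence_sd=10.0,
            step_length_mean=0.52,
            step_length_sd=0.06,
            noise_sd=0.12,
            fall_risk_fraction=13 / 35,
        )
        defaults.update(overrides)
        return cls(n_subjects=n_subjects, seed=seed, **defaults)

    def with_(self, **overrides) -> "CohortSpec":
        return replace(self, **overrides)


@dataclass(frozen=True)
class SyntheticSubject:
    """A generated recording with its ground truth."""

    recording: Recording
    bounds: PhaseBounds
    labels: SubjectLabels
    is_fall_risk: bool
    cadence: float          # steps/min
    step_length: float      # m
    gait_speed: float       # m/s
    phase_durations: dict   # quantized to the sample grid, seconds


def _smoothstep(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def _transition_envelope(n: int, ramp_frac: float = 0.1) -> np.ndarray:
    """Ramped plateau: smoothstep up, hold, smoothstep down."""
    u = (np.arange(n) + 0.5) / n
    ramp = max(ramp_frac, 1.5 / max(n, 2))
    return _smoothstep(u / ramp) * _smoothstep((1.0 - u) / ramp)


def _phase_signals(phase, n, fs, cadence, sway_ml):
    """Noise-free ML/V/AP template of one phase."""
    t = np.arange(n) / fs
    ml = np.zeros(n)
    v = np.zeros(n)
    ap = np.zeros(n)
    step_hz = cadence / 60.0
    if phase == "sist":
        env = _transition_envelope(n)
        ap = _TRANSITION_AP * env
        v = _TRANSITION_V * env
    elif phase == "stsi":
        env = _transition_envelope(n)
        ap = -_TRANSITION_AP * env
        v = -_TRANSITION_V * env
    elif phase in ("walk_out", "walk_back"):
        v = _WALK_V * np.sin(2 * np.pi * step_hz * t)
        ap = _WALK_AP * np.sin(2 * np.pi * step_hz * t + np.pi / 4)
        ml = _WALK_ML * sway_ml * np.sin(np.pi * step_hz * t)
    elif phase == "turn":
        # sqrt(3) x walking ML amplitude -> 3x walking ML sway variance,
        # riding on a ramped centripetal offset
        u = (np.arange(n) + 0.5) / n
        env = np.clip(u / _TURN_RAMP_FRAC, 0, 1) * np.clip((1 - u) / _TURN_RAMP_FRAC, 0, 1)
        ml = (
            math.sqrt(3.0) * _WALK_ML * sway_ml * np.sin(2 * np.pi * _TURN_FREQ_HZ * t)
            + _TURN_ML_DC * env
        )
        v = _TURN_V * np.sin(2 * np.pi * step_hz * t)
        ap = _TURN_AP * np.sin(2 * np.pi * step_hz * t + np.pi / 4)
    else:  # pragma: no cover
        raise ValueError(f"unknown phase {phase!r}")
    return ml, v, ap


def _simulate_subject(spec: CohortSpec, rng: np.random.Generator, index: int) -> SyntheticSubject:
    fs = spec.fs
    risk = bool(rng.random() < spec.fall_risk_fraction)
    shifts = dict(spec.effect) if risk else {}

    draw = lambda mean, sd: float(rng.normal(mean, sd)) if sd > 0 else float(mean)
    d_sist = max(_MIN_PHASE_S, draw(spec.phase_duration_means["sist"], spec.phase_duration_sds["sist"]))
    d_turn = max(_MIN_PHASE_S, draw(spec.phase_duration_means["turn"], spec.phase_duration_sds["turn"]))
    d_stsi = max(_MIN_PHASE_S, draw(spec.phase_duration_means["stsi"], spec.phase_duration_sds["stsi"]))
    cadence = max(20.0, draw(spec.cadence_mean, spec.cadence_sd))
    step_length = max(0.05, draw(spec.step_length_mean, spec.step_length_sd))

    d_sist *= shifts.get("stand_duration", 1.0)
    d_stsi *= shifts.get("sit_duration", 1.0)
    d_turn *= shifts.get("turn_duration", 1.0)
    cadence *= shifts.get("cadence", 1.0)
    step_length *= shifts.get("step_length", 1.0) * shifts.get("gait_speed", 1.0)

    gait_speed = cadence / 60.0 * step_length
    d_walk = spec.walkway_m / gait_speed  # each way

    raw = {"sist": d_sist, "walk_out": d_walk, "turn": d_turn, "walk_back": d_walk, "stsi": d_stsi}
    counts = {p: max(3, int(round(raw[p] * fs))) for p in PHASES}
    durations = {p: counts[p] / fs for p in PHASES}
    tug_seconds = sum(durations.values())

    # SFBBS from a noisy logistic of the applied shifts
    impairment = sum(abs(math.log(k)) for k in shifts.values())
    latent = 1.0 / (1.0 + math.exp(-4.0 * (impairment + rng.normal(0.0, 0.3) - 1.0)))
    sfbbs = int(np.clip(28 - round(latent * 28), 0, 28))

    n_pad = int(round(spec.pad_s * fs))
    parts = {ax: [np.zeros(n_pad)] for ax in AXES}
    starts = {}
    cursor = n_pad
    for phase in PHASES:
        n = counts[phase]
        ml, v, ap = _phase_signals(phase, n, fs, cadence, spec.sway_gain_ml)
        parts["ML"].append(ml)
        parts["V"].append(v)
        parts["AP"].append(ap)
        starts[phase] = (cursor, cursor + n)
        cursor += n
    for ax in AXES:
        parts[ax].append(np.zeros(n_pad))
    acc = {ax: np.concatenate(parts[ax]) for ax in AXES}
    if spec.noise_sd > 0:
        for ax in AXES:
            acc[ax] = acc[ax] + rng.normal(0.0, spec.noise_sd, acc[ax].size)

    return SyntheticSubject(
        recording=Recording(subject_id=f"sub_{index:03d}", fs=fs, acc=acc),
        bounds=PhaseBounds(**starts),
        labels=SubjectLabels.from_scores(tug_seconds, sfbbs),
        is_fall_risk=risk,
        cadence=cadence,
        step_length=step_length,
        gait_speed=gait_speed,
        phase_durations=durations,
    )


def generate_cohort(spec: CohortSpec) -> list:
    """Generate ``spec.n_subjects`` synthetic subjects, deterministically
    for a fixed ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    return [_simulate_subject(spec, rng, i) for i in range(spec.n_subjects)]


def write_cohort(cohort, directory) -> Path:
    """Write recordings, annotations and labels as CSV plus a JSON manifest.

    Emits ``<id>_recording.csv`` and ``<id>_annotations.csv`` per subject
    and one cohort-level ``labels.csv``; returns the manifest path.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    label_rows = []
    for subject in cohort:
        sid = subject.recording.subject_id
        rec_path = directory / f"{sid}_recording.csv"
        ann_path = directory / f"{sid}_annotations.csv"
        write_recording(subject.recording, rec_path)
        write_annotations(subject.bounds, ann_path)
        entries.append(
            {"subject_id": sid, "recording": rec_path.name, "annotations": ann_path.name}
        )
        label_rows.append(
            {
                "subject_id": sid,
                "tug_seconds": subject.labels.tug_seconds,
                "sfbbs_score": subject.labels.sfbbs_score,
                "label_tug": subject.labels.label_tug,
                "label_sfbbs": subject.labels.label_sfbbs,
                "label_multi": subject.labels.label_multi,
            }
        )
    labels_path = directory / "labels.csv"
    pd.DataFrame(
        label_rows,
        columns=[
            "subject_id", "tug_seconds", "sfbbs_score",
            "label_tug", "label_sfbbs", "label_multi",
        ],
    ).to_csv(labels_path, index=False)
    manifest = {
        "fs": cohort[0].recording.fs if cohort else None,
        "labels": labels_path.name,
        "subjects": entries,
    }
    manifest_path = directory / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest_path


def read_cohort(directory):
    """Read back a written cohort.

    Returns ``(subjects, labels)`` where ``subjects`` is a list of
    ``(Recording, PhaseBounds)`` pairs and ``labels`` the labels table.
    """
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    subjects = []
    for entry in manifest["subjects"]:
        rec = read_recording(
            directory / entry["recording"],
            fs=manifest["fs"],
            subject_id=entry["subject_id"],
        )
        bounds = read_annotations(directory / entry["annotations"])
        subjects.append((rec, bounds))
    labels = pd.read_csv(directory / manifest["labels"])
    return subjects, labels
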