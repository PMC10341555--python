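"""The 79-feature vector computed from a segmented TUG recording.

Blocks (numbering follows the shipped schema):

* full-trial entropy block (1-12): MSE mean / MSE SD / complexity index /
  permutation entropy per axis;
* sit-to-stand block (13-34): stand duration plus range, max, RMS,
  max jerk, min, mean jerk, SD per axis;
* walk block (35-45): durations and gait parameters plus RMS per axis,
  computed on the two walking bouts concatenated (turn excluded);
* turn block (46-57): CV, median, range, RMS per axis;
* stand-to-sit block (58-79): sit duration plus range, RMS, min, max,
  max jerk, mean jerk, SD per axis.

Notes on conventions: SDs are population SDs (ddof=0); CVs are in
percent; jerk summaries use the absolute value of the finite-difference
jerk; a degenerate block yields NaN features plus a warning, never a
silently truncated vector.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, filtfilt, find_peaks

from .core import AXES, PhaseBounds, Recording
from .entropy import (
    MseParams,
    PeParams,
    complexity_index,
    mse_mean,
    mse_profile,
    mse_sd,
    permutation_entropy,
)

__all__ = [
    "FEATURE_SCHEMA",
    "FEATURE_NAMES",
    "StepEvents",
    "rms",
    "jerk_series",
    "max_jerk",
    "mean_jerk",
    "descriptive_block",
    "detect_steps",
    "gait_features",
    "extract_features",
    "schema_as_dicts",
]

N_FEATURES = 79


@dataclass(frozen=True)
class FeatureSpec:
    number: int      # 1-based position in the canonical schema
    name: str
    block: str       # full_tug | sist | walk | turn | stsi
    axis: str | None


def _axis_specs(start: int, stem: str, block: str) -> list:
    return [
        FeatureSpec(start + i, f"{stem}_{ax}", block, ax) for i, ax in enumerate(AXES)
    ]


def _build_schema() -> list:
    schema: list = []
    schema += _axis_specs(1, "mse_mean", "full_tug")
    schema += _axis_specs(4, "mse_sd", "full_tug")
    schema += _axis_specs(7, "mse_ci", "full_tug")
    schema += _axis_specs(10, "pe", "full_tug")
    schema.append(FeatureSpec(13, "stand_duration", "sist", None))
    for offset, stem in zip(
        range(14, 34, 3),
        ["sist_range", "sist_max", "sist_rms", "sist_max_jerk", "sist_min",
         "sist_mean_jerk", "sist_sd"],
    ):
        schema += _axis_specs(offset, stem, "sist")
    for number, name in zip(
        range(35, 43),
        ["walk_duration", "cadence", "step_length", "gait_speed",
         "step_time", "stride_time", "cv_step_time", "cv_stride_time"],
    ):
        schema.append(FeatureSpec(number, name, "walk", None))
    schema += _axis_specs(43, "walk_rms", "walk")
    for offset, stem in zip(range(46, 56, 3), ["turn_cv", "turn_median", "turn_range", "turn_rms"]):
        schema += _axis_specs(offset, stem, "turn")
    schema.append(FeatureSpec(58, "sit_duration", "stsi", None))
    for offset, stem in zip(
        range(59, 78, 3),
        ["stsi_range", "stsi_rms", "stsi_min", "stsi_max", "stsi_max_jerk",
         "stsi_mean_jerk", "stsi_sd"],
    ):
        schema += _axis_specs(offset, stem, "stsi")
    assert [s.number for s in schema] == list(range(1, N_FEATURES + 1))
    return schema


FEATURE_SCHEMA = _build_schema()
FEATURE_NAMES = [s.name for s in FEATURE_SCHEMA]
FEATURE_NUMBERS = {s.name: s.number for s in FEATURE_SCHEMA}


def schema_as_dicts() -> list:
    """Schema rows for serialization (number, name, block, axis)."""
    return [
        {"number": s.number, "name": s.name, "block": s.block, "axis": s.axis}
        for s in FEATURE_SCHEMA
    ]


# ---------------------------------------------------------------------------
# Elementary statistics
# ---------------------------------------------------------------------------

def _segment(x) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty segment")
    return x


def rms(segment) -> float:
    """Root mean square, sqrt(mean of squares)."""
    x = _segment(segment)
    return float(np.sqrt(np.mean(x**2)))


def jerk_series(segment, fs: float) -> np.ndarray:
    """Finite-difference jerk: central differences scaled by ``fs``,
    one-sided at the endpoints."""
    x = _segment(segment)
    if x.size < 2:
        raise ValueError("jerk needs at least 2 samples")
    return np.gradient(x) * fs


def max_jerk(segment, fs: float) -> float:
    return float(np.max(np.abs(jerk_series(segment, fs))))


def mean_jerk(segment, fs: float) -> float:
    return float(np.mean(np.abs(jerk_series(segment, fs))))


def descriptive_block(segment) -> dict:
    """Range, max, min, median, SD (ddof=0) and CV (percent) of a segment.

    CV is flagged missing (NaN) when the mean is negligible relative to
    the SD, since SD/|mean| would explode.
    """
    x = _segment(segment)
    sd = float(np.std(x))
    mean = float(np.mean(x))
    if sd == 0.0:
        cv = 0.0
    elif abs(mean) < 1e-9 * sd:
        cv = float("nan")
    else:
        cv = 100.0 * sd / abs(mean)
    return {
        "range": float(np.ptp(x)),
        "max": float(np.max(x)),
        "min": float(np.min(x)),
        "median": float(np.median(x)),
        "sd": sd,
        "cv": cv,
    }


# ---------------------------------------------------------------------------
# Step detection and gait parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StepEvents:
    """Heel-strike proxies detected in the walking bouts.

    ``indices_per_bout`` holds sample indices local to each bout; the
    derived step intervals (s) are diffs within a bout, and stride
    intervals are sums of non-overlapping adjacent step-interval pairs
    (same-foot parity).
    """

    indices_per_bout: tuple
    fs: float

    @property
    def n_events(self) -> int:
        return int(sum(len(idx) for idx in self.indices_per_bout))

    @property
    def step_intervals(self) -> np.ndarray:
        parts = [np.diff(idx) / self.fs for idx in self.indices_per_bout if len(idx) >= 2]
        return np.concatenate(parts) if parts else np.empty(0)

    @property
    def stride_intervals(self) -> np.ndarray:
        strides = []
        for idx in self.indices_per_bout:
            steps = np.diff(idx) / self.fs
            for i in range(0, len(steps) - 1, 2):
                strides.append(steps[i] + steps[i + 1])
        return np.asarray(strides)


def _bandpass(x: np.ndarray, fs: float, low: float, high: float) -> np.ndarray:
    nyq = fs / 2.0
    high = min(high, 0.95 * nyq)
    b, a = butter(2, [low / nyq, high / nyq], btype="band")
    padlen = min(3 * (max(len(a), len(b)) - 1), x.size - 1)
    return filtfilt(b, a, x, padlen=padlen)


def detect_steps(
    walk_segments,
    fs: float,
    band=(0.5, 3.0),
    min_separation_s: float = 0.25,
) -> StepEvents:
    """Detect step events as peaks of the band-passed vertical signal.

    ``walk_segments`` is a sequence of V-axis bout arrays.  Peaks must
    be at least ``min_separation_s`` apart; fewer than 2 events overall
    is an error.
    """
    total = sum(len(np.asarray(seg)) for seg in walk_segments)
    if total < fs:
        raise ValueError(f"walking data of {total / fs:.2f} s too short (need >= 1 s)")
    per_bout = []
    for seg in walk_segments:
        x = _segment(seg)
        filtered = _bandpass(x, fs, *band)
        height = 0.2 * float(np.max(np.abs(filtered))) if filtered.size else 0.0
        peaks, _ = find_peaks(
            filtered, distance=max(1, int(round(min_separation_s * fs))), height=height
        )
        per_bout.append(peaks)
    events = StepEvents(indices_per_bout=tuple(per_bout), fs=fs)
    if events.n_events < 2:
        raise ValueError(f"found {events.n_events} step events, need >= 2")
    return events


def gait_features(events: StepEvents, walk_duration: float, distance: float) -> dict:
    """Gait parameters from detected steps.

    step_time = mean step interval; stride_time = mean stride interval;
    cadence = 60 / step_time (steps/min); gait_speed = distance /
    walk_duration; step_length = distance / number of step events; CVs
    are 100 * SD / mean of the interval sequences (NaN when fewer than
    two intervals are available).
    """
    if events.n_events < 3:
        raise ValueError(f"need >= 3 step events for stride statistics, got {events.n_events}")
    steps = events.step_intervals
    strides = events.stride_intervals

    def _cv(x: np.ndarray) -> float:
        if x.size < 2:
            return float("nan")
        return 100.0 * float(np.std(x)) / float(np.mean(x))

    step_time = float(np.mean(steps))
    return {
        "walk_duration": float(walk_duration),
        "cadence": 60.0 / step_time,
        "step_length": distance / events.n_events,
        "gait_speed": distance / walk_duration,
        "step_time": step_time,
        "stride_time": float(np.mean(strides)) if strides.size else float("nan"),
        "cv_step_time": _cv(steps),
        "cv_stride_time": _cv(strides),
    }


# ---------------------------------------------------------------------------
# Full vector assembly
# ---------------------------------------------------------------------------

def _nan_block(features: dict, names, reason: str) -> None:
    warnings.warn(f"feature block failed ({reason}); emitting NaN", stacklevel=3)
    for name in names:
        features[name] = float("nan")


def _transition_block(features, prefix, rec, interval, duration_name):
    start, end = interval
    features[duration_name] = (end - start) / rec.fs
    for ax in AXES:
        seg = rec.acc[ax][start:end]
        stats = descriptive_block(seg)
        features[f"{prefix}_range_{ax}"] = stats["range"]
        features[f"{prefix}_max_{ax}"] = stats["max"]
        features[f"{prefix}_min_{ax}"] = stats["min"]
        features[f"{prefix}_sd_{ax}"] = stats["sd"]
        features[f"{prefix}_rms_{ax}"] = rms(seg)
        features[f"{prefix}_max_jerk_{ax}"] = max_jerk(seg, rec.fs)
        features[f"{prefix}_mean_jerk_{ax}"] = mean_jerk(seg, rec.fs)


def extract_features(
    rec: Recording,
    bounds: PhaseBounds,
    mse: MseParams = MseParams(),
    pe: PeParams = PeParams(),
    walkway_m: float = 3.0,
) -> dict:
    """Compute the complete 79-feature vector for one subject.

    Returns an ordered mapping with exactly the canonical feature names.
    A failing block produces NaN entries and a warning rather than a
    partial vector.  ``walkway_m`` is the one-way walking distance; the
    walk block uses both bouts concatenated (2 x walkway_m total).
    """
    bounds.check_within(rec.n)
    features: dict = {}

    # full-trial entropy block
    for ax in AXES:
        signal = rec.acc[ax]
        try:
            profile = mse_profile(signal, mse)
            features[f"mse_mean_{ax}"] = mse_mean(profile)
            features[f"mse_sd_{ax}"] = mse_sd(profile)
            features[f"mse_ci_{ax}"] = complexity_index(profile)
        except ValueError as exc:
            _nan_block(features, [f"mse_mean_{ax}", f"mse_sd_{ax}", f"mse_ci_{ax}"], str(exc))
        try:
            features[f"pe_{ax}"] = permutation_entropy(signal, pe)
        except ValueError as exc:
            _nan_block(features, [f"pe_{ax}"], str(exc))

    _transition_block(features, "sist", rec, bounds.sist, "stand_duration")

    # walk block: both bouts, turn excluded
    walk_names = [s.name for s in FEATURE_SCHEMA if s.block == "walk"]
    bouts_v = [rec.acc["V"][slice(*bounds.walk_out)], rec.acc["V"][slice(*bounds.walk_back)]]
    walk_samples = sum(len(b) for b in bouts_v)
    walk_duration = walk_samples / rec.fs
    distance = 2.0 * walkway_m
    try:
        events = detect_steps(bouts_v, rec.fs)
        gait = gait_features(events, walk_duration, distance)
        features.update(gait)
    except ValueError as exc:
        _nan_block(features, [n for n in walk_names if not n.startswith("walk_rms")], str(exc))
        features["walk_duration"] = walk_duration
    for ax in AXES:
        seg = np.concatenate(
            [rec.acc[ax][slice(*bounds.walk_out)], rec.acc[ax][slice(*bounds.walk_back)]]
        )
        features[f"walk_rms_{ax}"] = rms(seg)

    # turn block
    for ax in AXES:
        seg = rec.acc[ax][slice(*bounds.turn)]
        stats = descriptive_block(seg)
        features[f"turn_cv_{ax}"] = stats["cv"]
        features[f"turn_median_{ax}"] = stats["median"]
        features[f"turn_range_{ax}"] = stats["range"]
        features[f"turn_rms_{ax}"] = rms(seg)

    _transition_block(features, "stsi", rec, bounds.stsi, "sit_duration")

    ordered = {name: float(features[name]) for name in FEATURE_NAMES}
    assert len(ordered) == N_FEATURES
    return ordered
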