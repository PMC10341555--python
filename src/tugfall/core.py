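"""Domain types, recording I/O and TUG phase segmentation.

A recording is a triaxial waist-acceleration trace with axes ML
(mediolateral), V (vertical) and AP (anterior-posterior).  A trial is
segmented into five ordered phases: sit-to-stand (``sist``), walk out,
turn, walk back, stand-to-sit (``stsi``), each a half-open 0-based
sample-index interval ``[start, end)``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

AXES = ("ML", "V", "AP")
PHASES = ("sist", "walk_out", "turn", "walk_back", "stsi")

#: TUG duration (s) above which a subject is labelled at fall risk.
TUG_THRESHOLD_S = 12.47
#: SFBBS score below which a subject is labelled at fall risk.
SFBBS_THRESHOLD = 23


class SegmentationError(RuntimeError):
    """Raised when automatic phase detection cannot find five phases."""


@dataclass
class Recording:
    """One subject's triaxial acceleration trace.

    Attributes
    ----------
    subject_id : str
        Opaque identifier.
    fs : float
        Sampling rate in Hz (> 0).
    acc : dict[str, np.ndarray]
        Equal-length acceleration series keyed exactly by ``ML``, ``V``,
        ``AP``.
    """

    subject_id: str
    fs: float
    acc: dict = field(repr=False)

    def __post_init__(self) -> None:
        if not (self.fs > 0 and math.isfinite(self.fs)):
            raise ValueError(f"sampling rate must be positive and finite, got {self.fs}")
        if set(self.acc) != set(AXES):
            raise ValueError(
                f"axis keys must be exactly {set(AXES)}, got {set(self.acc)}"
            )
        self.acc = {ax: np.asarray(self.acc[ax], dtype=float).ravel() for ax in AXES}
        lengths = {ax: a.size for ax, a in self.acc.items()}
        if len(set(lengths.values())) != 1:
            raise ValueError(f"axis series lengths differ: {lengths}")
        if self.n < 2:
            raise ValueError(f"recording needs at least 2 samples, got {self.n}")
        for ax, a in self.acc.items():
            if not np.all(np.isfinite(a)):
                raise ValueError(f"non-finite sample in axis {ax}")

    @property
    def n(self) -> int:
        """Number of samples per axis."""
        return self.acc["ML"].size

    @property
    def duration(self) -> float:
        """Trace duration in seconds."""
        return self.n / self.fs


@dataclass(frozen=True)
class PhaseBounds:
    """Half-open sample-index intervals of the five TUG phases."""

    sist: tuple
    walk_out: tuple
    turn: tuple
    walk_back: tuple
    stsi: tuple

    def __post_init__(self) -> None:
        prev_end = None
        for name in PHASES:
            start, end = getattr(self, name)
            if not (0 <= start < end):
                raise ValueError(f"phase {name}: interval [{start}, {end}) is empty or negative")
            if prev_end is not None and start < prev_end:
                raise ValueError(f"phase {name} starts before the previous phase ends")
            prev_end = end

    def as_dict(self) -> dict:
        return {name: tuple(getattr(self, name)) for name in PHASES}

    def durations(self, fs: float) -> dict:
        """Phase durations in seconds."""
        return {name: (end - start) / fs for name, (start, end) in self.as_dict().items()}

    def check_within(self, n: int) -> None:
        if self.stsi[1] > n:
            raise ValueError(f"phase bounds extend past the recording (n={n})")


@dataclass(frozen=True)
class SubjectLabels:
    """Clinical scores and the three derived binary fall-risk labels."""

    tug_seconds: float
    sfbbs_score: int
    label_tug: int
    label_sfbbs: int
    label_multi: int

    @classmethod
    def from_scores(cls, tug_seconds: float, sfbbs_score: int) -> "SubjectLabels":
        """Derive the three labels from the raw clinical scores.

        A subject is at fall risk on the TUG criterion when the trial
        takes strictly more than 12.47 s, on the SFBBS criterion when
        the score is strictly below 23, and on the multifactor
        criterion when either single criterion flags.
        """
        if not tug_seconds > 0:
            raise ValueError(f"TUG duration must be positive, got {tug_seconds}")
        sfbbs_score = int(sfbbs_score)
        if not 0 <= sfbbs_score <= 28:
            raise ValueError(f"SFBBS score must be in [0, 28], got {sfbbs_score}")
        label_tug = int(tug_seconds > TUG_THRESHOLD_S)
        label_sfbbs = int(sfbbs_score < SFBBS_THRESHOLD)
        return cls(
            tug_seconds=float(tug_seconds),
            sfbbs_score=sfbbs_score,
            label_tug=label_tug,
            label_sfbbs=label_sfbbs,
            label_multi=int(label_tug or label_sfbbs),
        )


# ---------------------------------------------------------------------------
# Recording and annotation I/O
# ---------------------------------------------------------------------------

def read_recording(path, fs: float, axis_order=AXES, subject_id=None) -> Recording:
    """Read a delimited acceleration table into a :class:`Recording`.

    Accepts a headered CSV with columns ``time, ML, V, AP`` (``time``
    optional).  If the axis names are absent from the header, the first
    three numeric columns (after dropping any ``time`` column) are mapped
    to axes following ``axis_order``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"recording file not found: {path}")
    if sorted(axis_order) != sorted(AXES):
        raise ValueError(f"axis_order must be a permutation of {AXES}, got {axis_order}")
    df = pd.read_csv(path, float_precision="round_trip")
    if set(AXES) <= set(df.columns):
        cols = list(AXES)
    else:
        df = df.drop(columns=[c for c in df.columns if str(c).lower() == "time"])
        if df.shape[1] < 3:
            raise ValueError(
                f"expected 3 acceleration columns in {path}, found {df.shape[1]}"
            )
        df = df.iloc[:, :3]
        df.columns = list(axis_order)
        cols = list(AXES)
    try:
        data = df[cols].astype(float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric cell in {path}: {exc}") from exc
    if not np.all(np.isfinite(data.to_numpy())):
        raise ValueError(f"non-finite acceleration value in {path}")
    return Recording(
        subject_id=subject_id or path.stem,
        fs=fs,
        acc={ax: data[ax].to_numpy() for ax in AXES},
    )


def write_recording(rec: Recording, path, include_time: bool = True) -> Path:
    """Write a recording as a headered CSV, round-trippable bit-exactly."""
    path = Path(path)
    df = pd.DataFrame({ax: rec.acc[ax] for ax in AXES})
    if include_time:
        df.insert(0, "time", np.arange(rec.n) / rec.fs)
    df.to_csv(path, index=False)  # pandas emits repr floats: exact round trip
    return path


def read_annotations(path) -> PhaseBounds:
    """Read phase bounds from a CSV with columns ``phase, start, end``."""
    df = pd.read_csv(path)
    required = {"phase", "start", "end"}
    if not required <= set(df.columns):
        raise ValueError(f"annotation file {path} must have columns {required}")
    rows = {str(r.phase): (int(r.start), int(r.end)) for r in df.itertuples()}
    missing = set(PHASES) - set(rows)
    if missing:
        raise ValueError(f"annotation file {path} missing phases: {sorted(missing)}")
    return PhaseBounds(**{name: rows[name] for name in PHASES})


def write_annotations(bounds: PhaseBounds, path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        [(name, start, end) for name, (start, end) in bounds.as_dict().items()],
        columns=["phase", "start", "end"],
    )
    df.to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# Phase segmentation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SegmentationParams:
    """Tuning knobs of the automatic phase detector.

    The stand/sit detector triggers on the smoothed magnitude of the AP
    excursion from the seated baseline; the turn detector looks for the
    window of maximal short-time ML variance between the walking bouts.
    Thresholds are in the signal's own acceleration units (m/s² for the
    synthetic generator).
    """

    ap_threshold: float = 1.47  # ~0.15 g for m/s² signals
    ap_low_threshold: float = 0.6
    min_excursion_s: float = 0.25
    smooth_s: float = 0.2
    turn_smooth_s: float = 0.2
    min_turn_s: float = 0.5
    min_turn_contrast: float = 2.0
    baseline_s: float = 0.5


def _moving_average(x: np.ndarray, width: int) -> np.ndarray:
    width = max(1, width)
    kernel = np.ones(width) / width
    return np.convolve(x, kernel, mode="same")


def _sustained_runs(mask: np.ndarray, min_len: int) -> list:
    """Maximal runs of True at least ``min_len`` long, as (start, end)."""
    runs = []
    start = None
    for i, flag in enumerate(mask):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            if i - start >= min_len:
                runs.append((start, i))
            start = None
    if start is not None and mask.size - start >= min_len:
        runs.append((start, mask.size))
    return runs


def _expand_run(smooth: np.ndarray, start: int, end: int, low: float) -> tuple:
    while start > 0 and smooth[start - 1] > low:
        start -= 1
    while end < smooth.size and smooth[end] > low:
        end += 1
    return start, end


def _fit_turn_changepoints(activity: np.ndarray, min_len: int) -> tuple:
    """Best two-changepoint fit of a low-high-low step profile.

    Minimises the squared error of a piecewise-constant model with a
    common outer level and a distinct inner level, over all interior
    intervals of at least ``min_len`` samples.
    """
    n = activity.size
    cum = np.concatenate([[0.0], np.cumsum(activity)])
    total = cum[-1]
    best = None
    for start in range(1, n - min_len):
        ends = np.arange(start + min_len, n)
        inner_sum = cum[ends] - cum[start]
        n_in = ends - start
        n_out = n - n_in
        score = inner_sum**2 / n_in + (total - inner_sum) ** 2 / n_out
        j = int(np.argmax(score))
        if best is None or score[j] > best[0]:
            best = (score[j], start, int(ends[j]))
    return best[1], best[2]


def segment_phases(
    rec: Recording,
    mode: str = "annotated",
    annotations: PhaseBounds | None = None,
    params: SegmentationParams = SegmentationParams(),
) -> PhaseBounds:
    """Locate the five TUG phases within a recording.

    In ``annotated`` mode the supplied bounds are validated against the
    recording and returned unchanged.  In ``auto`` mode the phases are
    detected from the AP and ML signals:

    1. sit-to-stand: first sustained AP excursion above
       ``ap_threshold`` (relative to the seated baseline), expanded with
       hysteresis down to ``ap_low_threshold``;
    2. stand-to-sit: the symmetric detection at the end of the trial;
    3. turn: the region of maximal short-window ML variance between the
       two transitions, expanded to where the rolling variance falls to
       the midpoint between its peak and the walking floor;
    4. walking bouts: the remaining gaps.

    Raises :class:`SegmentationError` when five non-empty ordered phases
    cannot be found.
    """
    if mode == "annotated":
        if annotations is None:
            raise ValueError("annotated mode requires annotations")
        annotations.check_within(rec.n)
        return annotations
    if mode != "auto":
        raise ValueError(f"mode must be 'annotated' or 'auto', got {mode!r}")
    if rec.duration < 3.0:
        raise SegmentationError(
            f"segmentation failed: recording of {rec.duration:.2f} s is too short"
        )

    fs = rec.fs
    ap = rec.acc["AP"]
    baseline = float(np.median(ap[: max(2, int(params.baseline_s * fs))]))
    smooth = _moving_average(np.abs(ap - baseline), int(round(params.smooth_s * fs)))
    min_len = max(1, int(round(params.min_excursion_s * fs)))
    runs = _sustained_runs(smooth > params.ap_threshold, min_len)
    if len(runs) < 2:
        raise SegmentationError(
            f"segmentation failed: found {len(runs)} sustained AP excursions, need >= 2"
        )
    sist = _expand_run(smooth, *runs[0], params.ap_low_threshold)
    stsi = _expand_run(smooth, *runs[-1], params.ap_low_threshold)
    if stsi[0] <= sist[1]:
        raise SegmentationError("segmentation failed: stand and sit transitions overlap")

    # turn: changepoint fit on smoothed |ML| between the transitions
    ml = rec.acc["ML"][sist[1] : stsi[0]]
    min_len = max(2, int(round(params.min_turn_s * fs)))
    if ml.size <= 3 * min_len:
        raise SegmentationError("segmentation failed: no room for walking phases")
    activity = _moving_average(np.abs(ml), max(2, int(round(params.turn_smooth_s * fs))))
    t_start, t_end = _fit_turn_changepoints(activity, min_len)
    inner = float(activity[t_start:t_end].mean())
    outer = float(np.concatenate([activity[:t_start], activity[t_end:]]).mean())
    if inner <= params.min_turn_contrast * outer:
        raise SegmentationError("segmentation failed: no distinct turn detected")
    turn = (sist[1] + t_start, sist[1] + t_end)

    try:
        return PhaseBounds(
            sist=sist,
            walk_out=(sist[1], turn[0]),
            turn=turn,
            walk_back=(turn[1], stsi[0]),
            stsi=stsi,
        )
    except ValueError as exc:
        raise SegmentationError(f"segmentation failed: {exc}") from exc
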