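"""Labeling, the selector x label x top-k evaluation grid, best-model
selection by mean AUC, and the repeated-feature intersections.

For every resampling split the feature selector runs on the training
portion only; a random-forest classifier is then scored on the held-out
portion for each top-k feature set.  "100-fold cross-validation" is
realised as stratified shuffle-splits (default 100 splits, 20% test),
which supports cohorts far too small for a literal 100-fold partition.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import (
    f1_score,
    precision_score,
    recall_score,
    roc_auc_score,
)
from sklearn.model_selection import ShuffleSplit, StratifiedShuffleSplit

from .core import SubjectLabels
from .features import FEATURE_NUMBERS, extract_features
from .relieff import (
    FeatureMatrix,
    RankedFeatures,
    RelieffParams,
    etc_importance,
    relieff_weights,
    top_k,
)

__all__ = [
    "LABELS",
    "SELECTORS",
    "CvConfig",
    "EvaluationGrid",
    "ImportantFeatureReport",
    "make_labels",
    "build_feature_table",
    "build_label_table",
    "run_grid",
    "select_best",
    "consensus_features",
    "intersect_important",
    "compare_reports",
    "render_report",
    "run_experiment",
]

logger = logging.getLogger(__name__)

LABELS = ("sfbbs", "tug", "multi")
SELECTORS = ("relieff", "etc")


@dataclass(frozen=True)
class CvConfig:
    """Resampling and classifier settings for the evaluation grid."""

    n_splits: int = 100
    test_fraction: float = 0.2
    stratified: bool = True
    k_grid: tuple = (5, 10, 15, 20, 25, 30)
    rf_trees: int = 100
    etc_trees: int = 100
    relieff_k: int = 10
    consensus: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_splits < 2:
            raise ValueError(f"n_splits must be >= 2, got {self.n_splits}")
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError(f"test_fraction must be in (0, 1), got {self.test_fraction}")
        if len(self.k_grid) == 0 or any(k < 1 for k in self.k_grid):
            raise ValueError(f"invalid k_grid {self.k_grid}")
        if not 0.0 < self.consensus <= 1.0:
            raise ValueError(f"consensus must be in (0, 1], got {self.consensus}")
        object.__setattr__(self, "k_grid", tuple(int(k) for k in self.k_grid))


@dataclass
class EvaluationGrid:
    """Mean AUC (and dispersion) per selector x label x k, plus the
    per-split selected feature lists."""

    summary: pd.DataFrame
    selected: dict  # (selector, label, k) -> list of per-split name lists
    feature_names: tuple
    n_splits: int

    def cell(self, selector: str, label: str, k: int) -> pd.Series:
        s = self.summary
        rows = s[(s.selector == selector) & (s.label == label) & (s.k == k)]
        if rows.empty:
            raise KeyError(f"no grid cell for {(selector, label, k)}")
        return rows.iloc[0]


@dataclass
class ImportantFeatureReport:
    """Per-label best-model feature sets, their intersections and the
    features repeated across every clinical labeling (starred)."""

    per_label: dict  # label -> {"relieff": [...], "etc": [...], "intersection": [...]}
    starred: list
    best: dict       # (selector, label) -> {"k": int, "mean_auc": float}


def make_labels(tug_seconds: float, sfbbs_score: int) -> SubjectLabels:
    """Binary fall-risk labels from the two clinical scores."""
    return SubjectLabels.from_scores(tug_seconds, sfbbs_score)


def build_feature_table(subjects, **kwargs) -> pd.DataFrame:
    """Feature vectors for an iterable of ``(Recording, PhaseBounds)``
    pairs, indexed by subject id."""
    rows = {}
    for rec, bounds in subjects:
        rows[rec.subject_id] = extract_features(rec, bounds, **kwargs)
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "subject_id"
    return df


def build_label_table(labels_df: pd.DataFrame) -> pd.DataFrame:
    """Binary label columns (one per clinical criterion) from a table
    with ``subject_id``, ``tug_seconds`` and ``sfbbs_score``."""
    out = {}
    for _, row in labels_df.iterrows():
        lbl = make_labels(row["tug_seconds"], row["sfbbs_score"])
        out[row["subject_id"]] = {
            "sfbbs": lbl.label_sfbbs, "tug": lbl.label_tug, "multi": lbl.label_multi,
        }
    df = pd.DataFrame.from_dict(out, orient="index")
    df.index.name = "subject_id"
    return df


def _impute_train_median(train: np.ndarray, test: np.ndarray):
    """Fill NaNs with training-fold medians (0 for all-NaN columns)."""
    med = np.nanmedian(train, axis=0)
    med = np.where(np.isfinite(med), med, 0.0)
    tr = np.where(np.isnan(train), med, train)
    te = np.where(np.isnan(test), med, test)
    return tr, te


def _draw_split(X, y, cfg: CvConfig, rng: np.random.Generator):
    """One train/test partition with both classes on each side."""
    cls = StratifiedShuffleSplit if cfg.stratified else ShuffleSplit
    for attempt in range(50):
        seed = int(rng.integers(2**31 - 1))
        splitter = cls(n_splits=1, test_size=cfg.test_fraction, random_state=seed)
        train_idx, test_idx = next(splitter.split(X, y))
        if len(np.unique(y[test_idx])) == 2 and len(np.unique(y[train_idx])) == 2:
            return train_idx, test_idx
        logger.info("degenerate split (single-class side), resampling (attempt %d)", attempt + 1)
    raise RuntimeError("could not draw a split with both classes on each side")


def _rank(selector: str, matrix: FeatureMatrix, cfg: CvConfig, seed: int) -> RankedFeatures:
    if selector == "relieff":
        return relieff_weights(matrix, RelieffParams(k=cfg.relieff_k, seed=seed))
    if selector == "etc":
        return etc_importance(matrix, n_trees=cfg.etc_trees, seed=seed)
    raise ValueError(f"unknown selector {selector!r}")


def run_grid(features: pd.DataFrame, labels: pd.DataFrame, cfg: CvConfig = CvConfig()) -> EvaluationGrid:
    """Evaluate every selector x label x top-k cell over resampled splits.

    ``features`` is subjects x feature columns (NaNs allowed; they are
    imputed with training-fold medians inside each split).  ``labels``
    holds one binary column per clinical criterion.  Deterministic for a
    fixed ``cfg.seed``.
    """
    X_all = features.to_numpy(dtype=float)
    names = tuple(features.columns)
    label_cols = [c for c in labels.columns if c in LABELS] or list(labels.columns)

    records = []
    selected: dict = {}
    for li, label in enumerate(label_cols):
        y = labels[label].to_numpy()
        if len(np.unique(y)) < 2:
            raise ValueError(f"label {label!r} has a single class")
        rng = np.random.default_rng([cfg.seed, li])
        metrics = {
            (sel, k): {"auc": [], "precision": [], "recall": [], "f1": []}
            for sel in SELECTORS
            for k in cfg.k_grid
        }
        for sel in SELECTORS:
            for k in cfg.k_grid:
                selected[(sel, label, k)] = []
        for _ in range(cfg.n_splits):
            train_idx, test_idx = _draw_split(X_all, y, cfg, rng)
            X_tr, X_te = _impute_train_median(X_all[train_idx], X_all[test_idx])
            y_tr, y_te = y[train_idx], y[test_idx]
            matrix = FeatureMatrix(X_tr, y_tr, names)
            for sel in SELECTORS:
                ranked = _rank(sel, matrix, cfg, seed=int(rng.integers(2**31 - 1)))
                for k in cfg.k_grid:
                    chosen = top_k(ranked, min(k, len(names)))
                    cols = [names.index(nm) for nm in chosen]
                    clf = RandomForestClassifier(
                        n_estimators=cfg.rf_trees,
                        random_state=int(rng.integers(2**31 - 1)),
                    )
                    clf.fit(X_tr[:, cols], y_tr)
                    proba = clf.predict_proba(X_te[:, cols])[:, 1]
                    pred = (proba >= 0.5).astype(int)
                    cellm = metrics[(sel, k)]
                    cellm["auc"].append(roc_auc_score(y_te, proba))
                    cellm["precision"].append(precision_score(y_te, pred, zero_division=0))
                    cellm["recall"].append(recall_score(y_te, pred, zero_division=0))
                    cellm["f1"].append(f1_score(y_te, pred, zero_division=0))
                    selected[(sel, label, k)].append(list(chosen))
        for sel in SELECTORS:
            for k in cfg.k_grid:
                cellm = metrics[(sel, k)]
                records.append(
                    {
                        "selector": sel,
                        "label": label,
                        "k": k,
                        "mean_auc": float(np.mean(cellm["auc"])),
                        "sd_auc": float(np.std(cellm["auc"])),
                        "mean_precision": float(np.mean(cellm["precision"])),
                        "mean_recall": float(np.mean(cellm["recall"])),
                        "mean_f1": float(np.mean(cellm["f1"])),
                    }
                )
    summary = pd.DataFrame.from_records(records)
    return EvaluationGrid(
        summary=summary, selected=selected, feature_names=names, n_splits=cfg.n_splits
    )


def select_best(grid: EvaluationGrid) -> dict:
    """Argmax-k cell per selector x label; AUC ties go to the smaller k."""
    best: dict = {}
    for (sel, label), sub in grid.summary.groupby(["selector", "label"], sort=False):
        sub = sub.sort_values("k")
        idx = sub["mean_auc"].to_numpy().argmax()  # first max -> smallest k
        row = sub.iloc[idx]
        best[(sel, label)] = {"k": int(row.k), "mean_auc": float(row.mean_auc)}
    return best


def _feature_number(name: str, names) -> int:
    return FEATURE_NUMBERS.get(name, list(names).index(name) + 1)


def consensus_features(grid: EvaluationGrid, selector: str, label: str, k: int,
                       threshold: float = 0.5) -> list:
    """Features appearing in the top-k of at least ``threshold`` of the
    splits, ordered by frequency (ties to the lower schema number)."""
    lists = grid.selected[(selector, label, k)]
    counts: dict = {}
    for split_list in lists:
        for name in split_list:
            counts[name] = counts.get(name, 0) + 1
    n = len(lists)
    members = [name for name, c in counts.items() if c / n >= threshold]
    members.sort(key=lambda nm: (-counts[nm], _feature_number(nm, grid.feature_names)))
    if not members:
        logger.warning("empty consensus set for %s/%s/k=%d", selector, label, k)
    return members


def intersect_important(grid: EvaluationGrid, best: dict | None = None,
                        threshold: float = 0.5) -> ImportantFeatureReport:
    """Per-label intersection of the two best models' consensus feature
    sets, and the features starred across every labeling."""
    if best is None:
        best = select_best(grid)
    labels = sorted({label for (_, label) in best}, key=lambda l: LABELS.index(l) if l in LABELS else 99)
    per_label: dict = {}
    for label in labels:
        sets = {}
        for sel in SELECTORS:
            cell = best[(sel, label)]
            sets[sel] = consensus_features(grid, sel, label, cell["k"], threshold)
        inter = [nm for nm in sets["relieff"] if nm in sets["etc"]]
        inter.sort(key=lambda nm: _feature_number(nm, grid.feature_names))
        per_label[label] = {**sets, "intersection": inter}
    starred = None
    for label in labels:
        s = set(per_label[label]["intersection"])
        starred = s if starred is None else starred & s
    starred = sorted(starred or set(), key=lambda nm: _feature_number(nm, grid.feature_names))
    return ImportantFeatureReport(per_label=per_label, starred=starred, best=best)


def compare_reports(a: ImportantFeatureReport, b: ImportantFeatureReport) -> dict:
    """Cross-cohort intersection of the per-label important-feature sets."""
    labels = [l for l in a.per_label if l in b.per_label]
    out = {
        label: sorted(
            set(a.per_label[label]["intersection"]) & set(b.per_label[label]["intersection"])
        )
        for label in labels
    }
    out["starred"] = sorted(set(a.starred) & set(b.starred))
    return out


def render_report(report: ImportantFeatureReport, grid: EvaluationGrid, outdir) -> Path:
    """Write the AUC summary, best models and intersections as CSV,
    Markdown and JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    grid.summary.to_csv(outdir / "auc_summary.csv", index=False)

    best_rows = [
        {"selector": sel, "label": label, **cell}
        for (sel, label), cell in report.best.items()
    ]
    pd.DataFrame(best_rows, columns=["selector", "label", "k", "mean_auc"]).to_csv(
        outdir / "best_models.csv", index=False
    )

    rows = []
    for label, sets in report.per_label.items():
        for name in sets["intersection"]:
            rows.append(
                {"label": label, "feature": name, "starred": name in report.starred}
            )
    pd.DataFrame(rows, columns=["label", "feature", "starred"]).to_csv(
        outdir / "important_features.csv", index=False
    )

    payload = {
        "best": {f"{sel}/{label}": cell for (sel, label), cell in report.best.items()},
        "per_label": report.per_label,
        "starred": report.starred,
    }
    (outdir / "report.json").write_text(json.dumps(payload, indent=2))

    lines = ["# Fall-risk feature report", "", "## Best models (mean AUC)", ""]
    for (sel, label), cell in report.best.items():
        lines.append(f"- {sel} / {label}: k={cell['k']}, AUC={cell['mean_auc']:.3f}")
    lines += ["", "## Important features per labeling", ""]
    for label, sets in report.per_label.items():
        marked = [
            f"{nm}*" if nm in report.starred else nm for nm in sets["intersection"]
        ]
        lines.append(f"- {label}: {', '.join(marked) if marked else '(empty)'}")
    lines += ["", "`*` = repeated across all clinical labelings", ""]
    (outdir / "report.md").write_text("\n".join(lines))
    return outdir


def run_experiment(cohort, cfg: CvConfig = CvConfig(), threshold: float = 0.5):
    """Full pipeline on a generated cohort: features, labels, grid, best
    models and intersections.  Returns ``(grid, best, report)``."""
    feats = build_feature_table((s.recording, s.bounds) for s in cohort)
    labels = pd.DataFrame(
        {
            "sfbbs": [s.labels.label_sfbbs for s in cohort],
            "tug": [s.labels.label_tug for s in cohort],
            "multi": [s.labels.label_multi for s in cohort],
        },
        index=feats.index,
    )
    grid = run_grid(feats, labels, cfg)
    best = select_best(grid)
    report = intersect_important(grid, best, threshold)
    return grid, best, report
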