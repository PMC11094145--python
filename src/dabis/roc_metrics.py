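"""AUROC measurement layer.

Everything the audit reports flows through this module: binary AUROC
(Mann-Whitney convention, ties count 0.5 per pair), one-vs-rest multi-class
averaging, ROC curves stored at all distinct thresholds, and percentile
bootstrap confidence intervals obtained by resampling whole samples with
replacement.

The AUROC of a binary classifier equals the probability that a uniformly
random positive/negative pair is ranked correctly.  For multi-class
problems the unweighted mean of the per-class one-vs-rest AUROCs is
reported, so every class counts equally regardless of prevalence.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn import metrics as _skmetrics


class DegenerateLabelsError(ValueError):
    """Raised when labels contain fewer than two classes.

    An AUROC is undefined without at least one positive and one negative;
    returning 0.5 silently would mask broken splits, so this is an error.
    """


@dataclasses.dataclass(frozen=True)
class ScoreSet:
    """Per-sample predicted class scores paired with true labels.

    Parameters
    ----------
    scores
        ``(n_samples, n_classes)`` array of unitless scores; higher means
        the class is considered more likely.
    labels
        ``(n_samples,)`` integer array of true class indices.
    class_names
        Ordered class identifiers, one per score column.
    """

    scores: np.ndarray
    labels: np.ndarray
    class_names: tuple

    def __post_init__(self):
        scores = np.asarray(self.scores, dtype=float)
        labels = np.asarray(self.labels)
        if scores.ndim != 2:
            raise ValueError("scores must be a 2-D (n_samples, n_classes) array")
        if scores.shape[0] < 1:
            raise ValueError("ScoreSet requires at least one sample")
        if not np.all(np.isfinite(scores)):
            raise ValueError("scores must be finite")
        if labels.shape != (scores.shape[0],):
            raise ValueError("labels must be 1-D with one entry per score row")
        if len(self.class_names) != scores.shape[1]:
            raise ValueError("class_names must match the number of score columns")
        if labels.min() < 0 or labels.max() >= scores.shape[1]:
            raise ValueError("each label must index a valid class")
        object.__setattr__(self, "scores", scores)
        object.__setattr__(self, "labels", labels.astype(int))
        object.__setattr__(self, "class_names", tuple(self.class_names))

    @property
    def n_samples(self) -> int:
        return self.scores.shape[0]

    @property
    def n_classes(self) -> int:
        return self.scores.shape[1]

    def subset(self, indices: np.ndarray) -> "ScoreSet":
        return ScoreSet(self.scores[indices], self.labels[indices], self.class_names)

    def to_csv(self, path, sample_ids: Optional[Sequence[str]] = None) -> None:
        """Write as CSV with columns sample_id, label, score_<class>."""
        n = self.n_samples
        if sample_ids is None:
            sample_ids = [f"s{i}" for i in range(n)]
        data = {"sample_id": list(sample_ids),
                "label": [self.class_names[i] for i in self.labels]}
        for j, name in enumerate(self.class_names):
            data[f"score_{name}"] = self.scores[:, j]
        pd.DataFrame(data).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ScoreSet":
        df = pd.read_csv(path)
        for col in ("sample_id", "label"):
            if col not in df.columns:
                raise ValueError(f"score CSV is missing required column {col!r}")
        score_cols = [c for c in df.columns if c.startswith("score_")]
        if not score_cols:
            raise ValueError("score CSV has no score_<class> columns")
        class_names = tuple(c[len("score_"):] for c in score_cols)
        name_to_idx = {n: i for i, n in enumerate(class_names)}
        try:
            labels = np.array([name_to_idx[str(v)] for v in df["label"]])
        except KeyError as exc:
            raise ValueError(f"label {exc.args[0]!r} has no score column") from exc
        return cls(df[score_cols].to_numpy(float), labels, class_names)


@dataclasses.dataclass(frozen=True)
class RocCurve:
    """Monotone (FPR, TPR) polyline from (0, 0) to (1, 1)."""

    fpr: np.ndarray
    tpr: np.ndarray

    def __post_init__(self):
        fpr = np.asarray(self.fpr, dtype=float)
        tpr = np.asarray(self.tpr, dtype=float)
        if fpr.shape != tpr.shape or fpr.ndim != 1 or fpr.size < 2:
            raise ValueError("RocCurve needs matching 1-D fpr/tpr with >= 2 points")
        if np.any(np.diff(fpr) < 0) or np.any(np.diff(tpr) < 0):
            raise ValueError("fpr and tpr must be non-decreasing")
        for arr, name in ((fpr, "fpr"), (tpr, "tpr")):
            if arr.min() < -1e-12 or arr.max() > 1 + 1e-12:
                raise ValueError(f"{name} values must lie in [0, 1]")
        if not (abs(fpr[0]) < 1e-12 and abs(tpr[0]) < 1e-12
                and abs(fpr[-1] - 1) < 1e-12 and abs(tpr[-1] - 1) < 1e-12):
            raise ValueError("curve must start at (0,0) and end at (1,1)")
        object.__setattr__(self, "fpr", np.clip(fpr, 0.0, 1.0))
        object.__setattr__(self, "tpr", np.clip(tpr, 0.0, 1.0))

    @property
    def points(self) -> np.ndarray:
        return np.column_stack([self.fpr, self.tpr])

    @property
    def area(self) -> float:
        """Trapezoidal area under the polyline."""
        return float(np.trapezoid(self.tpr, self.fpr))

    def tpr_at(self, grid: np.ndarray) -> np.ndarray:
        """TPR at the given FPR values, linear interpolation in FPR.

        Vertical segments (repeated FPR values) are resolved to their upper
        envelope so the curve reads as a single-valued function.
        """
        grid = np.asarray(grid, dtype=float)
        # upper envelope: keep the max tpr at each distinct fpr
        uniq, inverse = np.unique(self.fpr, return_inverse=True)
        env = np.full(uniq.size, -np.inf)
        np.maximum.at(env, inverse, self.tpr)
        return np.interp(grid, uniq, env)


@dataclasses.dataclass(frozen=True)
class AurocEstimate:
    """Point AUROC with a percentile bootstrap interval.

    The interval is widened where needed so that it always contains the
    full-sample point estimate.
    """

    value: float
    ci_low: float
    ci_high: float
    n_bootstrap: int
    replicates: Optional[np.ndarray] = dataclasses.field(
        default=None, repr=False, compare=False)

    def __post_init__(self):
        if not (0.0 <= self.ci_low <= self.value <= self.ci_high <= 1.0):
            raise ValueError(
                f"invalid interval [{self.ci_low}, {self.ci_high}] "
                f"around {self.value}")

    def to_dict(self) -> dict:
        return {"value": float(self.value), "ci_low": float(self.ci_low),
                "ci_high": float(self.ci_high), "n_bootstrap": int(self.n_bootstrap)}

    @classmethod
    def from_dict(cls, d: dict) -> "AurocEstimate":
        return cls(d["value"], d["ci_low"], d["ci_high"], d["n_bootstrap"])


def _check_binary(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels).astype(int)
    present = np.unique(labels)
    if present.size < 2:
        raise DegenerateLabelsError(
            "degenerate labels: need at least one positive and one negative, "
            f"got classes {present.tolist()}")
    if not np.isin(present, [0, 1]).all():
        raise ValueError("binary labels must be 0/1")
    return labels


def auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Binary AUROC of positive-class scores; ties contribute 0.5 per pair."""
    scores = np.asarray(scores, dtype=float).ravel()
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    labels = _check_binary(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have the same length")
    return float(_skmetrics.roc_auc_score(labels, scores))


def multiclass_auroc(scoreset: ScoreSet) -> float:
    """Unweighted mean of per-class one-vs-rest AUROCs.

    For two classes this reduces to the binary AUROC of the class-1 scores.
    """
    labels = scoreset.labels
    for idx, name in enumerate(scoreset.class_names):
        if not np.any(labels == idx):
            raise DegenerateLabelsError(
                f"class {name!r} is absent from the labels")
    if scoreset.n_classes < 2:
        raise ValueError("multiclass_auroc needs at least 2 classes")
    if scoreset.n_classes == 2:
        return auroc(scoreset.scores[:, 1], (labels == 1).astype(int))
    per_class = [auroc(scoreset.scores[:, c], (labels == c).astype(int))
                 for c in range(scoreset.n_classes)]
    return float(np.mean(per_class))


def roc_curve(scores: np.ndarray, labels: np.ndarray) -> RocCurve:
    """Threshold-sweep ROC curve; its trapezoidal area equals ``auroc``."""
    scores = np.asarray(scores, dtype=float).ravel()
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    labels = _check_binary(labels)
    fpr, tpr, _ = _skmetrics.roc_curve(labels, scores, drop_intermediate=False)
    if fpr[0] > 0 or tpr[0] > 0:
        fpr = np.insert(fpr, 0, 0.0)
        tpr = np.insert(tpr, 0, 0.0)
    return RocCurve(fpr, tpr)


def mean_roc_curve(scoreset: ScoreSet) -> RocCurve:
    """ROC summary curve for a ScoreSet.

    Binary: the class-1 curve.  Multi-class: vertical (TPR) average of the
    one-vs-rest curves over the union FPR grid, matching the one-vs-all
    AUROC up to interpolation.
    """
    if scoreset.n_classes == 2:
        return roc_curve(scoreset.scores[:, 1], (scoreset.labels == 1).astype(int))
    curves = [roc_curve(scoreset.scores[:, c], (scoreset.labels == c).astype(int))
              for c in range(scoreset.n_classes)]
    grid = np.unique(np.concatenate([c.fpr for c in curves]))
    tpr = np.mean([c.tpr_at(grid) for c in curves], axis=0)
    tpr[0], tpr[-1] = 0.0, 1.0
    return RocCurve(grid, np.maximum.accumulate(np.clip(tpr, 0, 1)))


def bootstrap_ci(scoreset: ScoreSet, n_bootstrap: int = 1000,
                 level: float = 0.95, seed: Optional[int] = None,
                 stratified: bool = False) -> AurocEstimate:
    """Percentile bootstrap interval for the one-vs-all AUROC.

    Samples are resampled with replacement at the sample level.  In
    unstratified mode a resample that drops a class entirely is redrawn
    (at most 100 attempts per replicate); stratified mode resamples within
    each class so every class is always present.
    """
    if not (0.0 < level < 1.0):
        raise ValueError("level must be in (0, 1)")
    if n_bootstrap < 1:
        raise ValueError("n_bootstrap must be >= 1")
    point = multiclass_auroc(scoreset)
    rng = np.random.default_rng(seed)
    n = scoreset.n_samples
    labels = scoreset.labels
    classes = np.arange(scoreset.n_classes)
    class_indices = [np.flatnonzero(labels == c) for c in classes]
    reps = np.empty(n_bootstrap)
    for b in range(n_bootstrap):
        if stratified:
            idx = np.concatenate([
                rng.choice(ci, size=ci.size, replace=True)
                for ci in class_indices])
        else:
            for attempt in range(100):
                idx = rng.integers(0, n, size=n)
                if np.isin(classes, labels[idx]).all():
                    break
            else:
                raise RuntimeError(
                    "bootstrap resample kept missing a class after 100 redraws")
        reps[b] = multiclass_auroc(scoreset.subset(idx))
    alpha = 1.0 - level
    lo, hi = np.quantile(reps, [alpha / 2.0, 1.0 - alpha / 2.0])
    return AurocEstimate(value=point, ci_low=float(min(lo, point)),
                         ci_high=float(max(hi, point)),
                         n_bootstrap=n_bootstrap, replicates=reps)
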