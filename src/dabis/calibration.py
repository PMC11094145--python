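"""Bias-corrected external performance calibration.

The shortcut-learning audit yields two test AUROCs: ``P_Source`` from a
model trained normally, and ``P_DABIS`` from an identically configured
model trained and evaluated on shuffled data, which can only have learned
histogram-level acquisition bias.  The calibrated external estimate is

    P_Est = P_Source - P_DABIS + O_bar

where ``O_bar`` is the performance of a purely random model (0.5 for
AUROC).  The same pointwise correction applied to the ROC curves yields a
calibrated curve whose area recovers the scalar formula before
monotonicity rectification.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Optional

import numpy as np
import pandas as pd

from .roc_metrics import AurocEstimate, RocCurve

#: ResultsTable column order (scalar columns)
TABLE_COLUMNS = [
    "source_dataset", "external_dataset", "p_source", "p_dabis", "p_est",
    "p_ext", "delta_source_ext", "delta_est_ext", "shuffled_ext",
]


def _check_unit(name: str, value: float) -> float:
    value = float(value)
    if not (0.0 <= value <= 1.0):
        raise ValueError(f"{name} must lie in [0, 1], got {value}")
    return value


def calibrate_auroc(p_source: float, p_dabis: float, o_bar: float = 0.5) -> float:
    """Bias-corrected external AUROC estimate, clipped to [0, 1].

    Clipping keeps the estimate a valid AUROC; a warning is emitted when
    it fires since it indicates an extreme source/bias combination.
    """
    p_source = _check_unit("p_source", p_source)
    p_dabis = _check_unit("p_dabis", p_dabis)
    o_bar = _check_unit("o_bar", o_bar)
    raw = p_source - p_dabis + o_bar
    if raw < 0.0 or raw > 1.0:
        warnings.warn(f"calibrated estimate {raw:.3f} clipped to [0, 1]")
    return float(np.clip(raw, 0.0, 1.0))


def shortcut_gap(p_dabis_mean: float, o_bar: float = 0.5) -> float:
    """Potential performance drop attributable to acquisition bias.

    The excess of the shuffled-model AUROC over chance: any AUROC above
    ``o_bar`` on shuffled data represents learnable bias.
    """
    return _check_unit("p_dabis_mean", p_dabis_mean) - _check_unit("o_bar", o_bar)


def calibrate_roc(roc_source: RocCurve, roc_dabis: RocCurve) -> RocCurve:
    """Pointwise ROC analogue of the scalar calibration.

    On the union of both curves' FPR breakpoints,
    ``tpr_est(f) = tpr_source(f) - tpr_dabis(f) + f`` (the chance diagonal
    plays the role of ``O_bar``), clipped to [0, 1], rectified to be
    non-decreasing by a running maximum, with endpoints forced to
    (0,0) and (1,1).
    """
    grid = np.unique(np.concatenate([roc_source.fpr, roc_dabis.fpr, [0.0, 1.0]]))
    tpr = roc_source.tpr_at(grid) - roc_dabis.tpr_at(grid) + grid
    tpr = np.clip(tpr, 0.0, 1.0)
    tpr = np.maximum.accumulate(tpr)
    tpr[0], tpr[-1] = 0.0, 1.0
    return RocCurve(grid, tpr)


def estimate_with_ci(p_source: AurocEstimate, p_dabis: AurocEstimate,
                     o_bar: float = 0.5, level: float = 0.95) -> AurocEstimate:
    """Calibrated estimate with a CI from paired bootstrap replicates.

    The scalar formula is applied to bootstrap replicates of the source
    and shuffled-arm AUROCs drawn independently; the percentile interval
    of the calibrated replicates is reported.
    """
    value = calibrate_auroc(p_source.value, p_dabis.value, o_bar)
    rs, rd = p_source.replicates, p_dabis.replicates
    if rs is None or rd is None:
        return AurocEstimate(value, value, value, 0)
    m = min(len(rs), len(rd))
    reps = np.clip(rs[:m] - rd[:m] + o_bar, 0.0, 1.0)
    alpha = 1.0 - level
    lo, hi = np.quantile(reps, [alpha / 2.0, 1.0 - alpha / 2.0])
    return AurocEstimate(value, float(min(lo, value)), float(max(hi, value)),
                         n_bootstrap=m, replicates=reps)


@dataclasses.dataclass
class BiasAuditResult:
    """Complete outcome of one shortcut-learning audit.

    Holds the source, shuffled (DABIS) and calibrated AUROC estimates,
    the random-model baseline, optional external validations, and the
    three ROC curves.  Attachments needed to score external data later
    (trained models, normalisation statistics) ride along outside the
    serialised form.
    """

    p_source: AurocEstimate
    p_dabis: AurocEstimate
    p_est: AurocEstimate
    o_bar: float = 0.5
    p_ext: Optional[AurocEstimate] = None
    p_shuffled_ext: Optional[AurocEstimate] = None
    roc_source: Optional[RocCurve] = None
    roc_dabis: Optional[RocCurve] = None
    roc_est: Optional[RocCurve] = None
    attachments: dict = dataclasses.field(default_factory=dict, repr=False,
                                          compare=False)

    def __post_init__(self):
        _check_unit("o_bar", self.o_bar)
        expect = calibrate_auroc(self.p_source.value, self.p_dabis.value, self.o_bar)
        if abs(self.p_est.value - expect) > 1e-9:
            raise ValueError(
                f"p_est {self.p_est.value} violates the calibration identity "
                f"(expected {expect})")

    def to_dict(self) -> dict:
        d = {"o_bar": self.o_bar}
        for key in ("p_source", "p_dabis", "p_est", "p_ext", "p_shuffled_ext"):
            est = getattr(self, key)
            d[key] = est.to_dict() if est is not None else None
        for key in ("roc_source", "roc_dabis", "roc_est"):
            curve = getattr(self, key)
            d[key] = ({"fpr": curve.fpr.tolist(), "tpr": curve.tpr.tolist()}
                      if curve is not None else None)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "BiasAuditResult":
        def est(k):
            return AurocEstimate.from_dict(d[k]) if d.get(k) else None

        def curve(k):
            return RocCurve(np.array(d[k]["fpr"]), np.array(d[k]["tpr"])) \
                if d.get(k) else None

        return cls(p_source=est("p_source"), p_dabis=est("p_dabis"),
                   p_est=est("p_est"), o_bar=d["o_bar"], p_ext=est("p_ext"),
                   p_shuffled_ext=est("p_shuffled_ext"),
                   roc_source=curve("roc_source"), roc_dabis=curve("roc_dabis"),
                   roc_est=curve("roc_est"))


class ResultsTable:
    """Audit results for several source/external dataset pairs.

    One row per (source dataset instance, external dataset); the column
    set mirrors the standard audit report: P_Source, P_DABIS, P_Est,
    P_Ext, the two performance-gap deltas and the shuffled-external AUROC.
    Rows may carry optional ``<col>_low``/``<col>_high`` CI columns.
    """

    #: slack when validating printed delta columns against their stated
    #: differences; published tables round from unrounded inputs, so two
    #: independently rounded 2-decimal values can disagree by one cent.
    DELTA_TOL = 0.0151

    def __init__(self, rows, validate_deltas: bool = True):
        df = pd.DataFrame(rows)
        if df.empty:
            raise ValueError("ResultsTable requires at least one row")
        missing = [c for c in ("source_dataset", "p_source", "p_dabis", "p_est")
                   if c not in df.columns]
        if missing:
            raise ValueError(f"ResultsTable rows are missing columns {missing}")
        for col in TABLE_COLUMNS:
            if col not in df.columns:
                df[col] = np.nan
        extra = [c for c in df.columns if c not in TABLE_COLUMNS]
        self.df = df[TABLE_COLUMNS + extra]
        if validate_deltas:
            self._validate_deltas()

    def _validate_deltas(self):
        df = self.df
        for dcol, a, b in (("delta_source_ext", "p_source", "p_ext"),
                           ("delta_est_ext", "p_est", "p_ext")):
            mask = df[dcol].notna() & df[a].notna() & df[b].notna()
            bad = np.abs(df.loc[mask, dcol] - (df.loc[mask, a] - df.loc[mask, b]))
            if (bad > self.DELTA_TOL).any():
                raise ValueError(
                    f"{dcol} disagrees with {a} - {b} beyond rounding slack")

    @classmethod
    def from_csv(cls, path, **kw) -> "ResultsTable":
        return cls(pd.read_csv(path), **kw)

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    def with_deltas(self) -> "ResultsTable":
        """Fill the delta columns from the P columns where missing."""
        df = self.df.copy()
        df["delta_source_ext"] = df["delta_source_ext"].fillna(
            df["p_source"] - df["p_ext"])
        df["delta_est_ext"] = df["delta_est_ext"].fillna(df["p_est"] - df["p_ext"])
        return ResultsTable(df, validate_deltas=False)


def aggregate_results(table: ResultsTable) -> pd.Series:
    """Averages row: first across instances of each source dataset, then
    unweighted across datasets, reported at 2 decimals (half-even).

    Blank (NaN) entries are skipped at both stages.
    """
    df = table.df
    numeric = [c for c in TABLE_COLUMNS if c not in
               ("source_dataset", "external_dataset")]
    per_dataset = df.groupby("source_dataset", sort=False)[numeric].mean()
    averages = per_dataset.mean()
    rounded = averages.round(2)
    rounded["source_dataset"] = "Average"
    rounded["external_dataset"] = ""
    return rounded[TABLE_COLUMNS]
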