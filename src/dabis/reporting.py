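"""Report rendering and machine-readable audit reports.

``render_table`` prints the audit results table in the standard column
order (P_Source, P_DABIS, P_Est, P_Ext, the two deltas, Shuffled Ext.)
with an averages row computed by the dataset-first aggregation rule;
confidence intervals render bracketed as ``0.85 [0.85-0.85]``.

``AuditReport`` serialises a full audit — results, configuration and
seeds, software version, per-epoch training trace — so any reported
number is traceable and the run is exactly repeatable.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from .calibration import TABLE_COLUMNS, BiasAuditResult, ResultsTable, \
    aggregate_results

_HEADERS = {
    "source_dataset": "Source Dataset", "external_dataset": "Ext. Dataset",
    "p_source": "P_Source", "p_dabis": "P_DABIS", "p_est": "P_Est",
    "p_ext": "P_Ext", "delta_source_ext": "d(P_Source,P_Ext)",
    "delta_est_ext": "d(P_Est,P_Ext)", "shuffled_ext": "Shuffled Ext.",
}


def _fmt(value, low=None, high=None) -> str:
    """Half-even 2-decimal formatting, CI bracketed when available."""
    if value is None or pd.isna(value):
        return ""
    def r2(v):
        return f"{round(float(v), 2):.2f}"
    if low is not None and high is not None and pd.notna(low) and pd.notna(high):
        return f"{r2(value)} [{r2(low)}-{r2(high)}]"
    return r2(value)


def render_table(table: ResultsTable, fmt: str = "text") -> str:
    """Render the results table plus its averages row.

    ``fmt="text"`` gives an aligned console table, ``fmt="csv"`` a CSV
    document with the same cells.
    """
    avg = aggregate_results(table)
    rows = []
    for _, row in table.df.iterrows():
        cells = {}
        for col in TABLE_COLUMNS:
            if col in ("source_dataset", "external_dataset"):
                cells[col] = "" if pd.isna(row[col]) else str(row[col])
            else:
                cells[col] = _fmt(row[col], row.get(f"{col}_low"),
                                  row.get(f"{col}_high"))
        rows.append(cells)
    rows.append({col: (str(avg[col]) if col in ("source_dataset",
                                                "external_dataset")
                       else _fmt(avg[col])) for col in TABLE_COLUMNS})
    df = pd.DataFrame(rows)[TABLE_COLUMNS].rename(columns=_HEADERS)
    if fmt == "csv":
        return df.to_csv(index=False)
    return df.to_string(index=False)


@dataclasses.dataclass
class AuditReport:
    """Serialised audit: result + provenance (config, seeds, version)."""

    result: BiasAuditResult
    config: dict
    dataset_name: str = ""
    model_weights: Optional[list] = None

    def to_dict(self) -> dict:
        d = {
            "version": __version__,
            "dataset": self.dataset_name,
            "config": self.config,
            "result": self.result.to_dict(),
            "trace_source": self.result.attachments.get("trace_source"),
            "trace_dabis": self.result.attachments.get("trace_dabis"),
        }
        if self.model_weights is not None:
            d["model_weights"] = self.model_weights
        return d

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()), encoding="utf-8")

    @classmethod
    def load(cls, path) -> "AuditReport":
        d = json.loads(Path(path).read_text(encoding="utf-8"))
        result = BiasAuditResult.from_dict(d["result"])
        result.attachments["trace_source"] = d.get("trace_source")
        result.attachments["trace_dabis"] = d.get("trace_dabis")
        report = cls(result=result, config=d["config"],
                     dataset_name=d.get("dataset", ""),
                     model_weights=d.get("model_weights"))
        return report
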