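"""Reading count tables, and serializing analysis reports."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, is_dataclass
from datetime import datetime, timezone

import numpy as np
import pandas as pd

from .table import BilateralTable

__all__ = ["read_count_table", "AnalysisReport", "write_report"]


def read_count_table(path, layout: str = "wide") -> BilateralTable:
    """Read a count table from disk.

    ``layout="wide"``: CSV/TSV with a header of group labels and three
    data rows indexed 0, 1, 2 (responses).  ``layout="flat"``: a single
    line/column of 3g integers in column-major group-by-group order
    (m01, m11, m21, m02, ...); group sizes are derived from the data.
    """
    if layout == "wide":
        return BilateralTable.from_csv(path)
    if layout == "flat":
        raw = pd.read_csv(path, header=None, sep=None, engine="python")
        vec = raw.to_numpy().ravel()
        vec = vec[~pd.isna(vec)]
        return BilateralTable.from_flat(vec)
    raise ValueError("layout must be 'wide' or 'flat'")


def _digest(table: BilateralTable) -> str:
    return hashlib.sha256(table.counts.tobytes()).hexdigest()[:16]


def _jsonable(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        d = asdict(obj)
        d.pop("model", None)
        return _jsonable(d)
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set)):
        return [_jsonable(v) for v in sorted(obj, key=str)] \
            if isinstance(obj, set) else [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


@dataclass
class AnalysisReport:
    """A serializable record of one analysis run."""

    input_digest: str
    config: dict
    results: dict
    version: str = ""
    timestamp: str = ""

    @classmethod
    def from_results(cls, table: BilateralTable, results: dict,
                     config: dict | None = None) -> "AnalysisReport":
        from . import __version__
        return cls(
            input_digest=_digest(table),
            config=config or {},
            results={k: _jsonable(v) for k, v in results.items()},
            version=__version__,
            timestamp=datetime.now(timezone.utc).isoformat(timespec="seconds"),
        )

    def to_json(self) -> str:
        return json.dumps(_jsonable(asdict(self)), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "AnalysisReport":
        return cls(**json.loads(text))

    def to_tsv(self) -> str:
        """Flat TSV block: one row per method, 4-decimal display."""
        lines = ["method\tstatistic\tp_value"]
        for name, res in sorted(self.results.items()):
            stat = res.get("value", res.get("observed_statistic"))
            pval = res.get("p_value")
            stat = "" if stat is None else f"{float(stat):.4f}"
            pval = "" if pval is None else f"{float(pval):.4f}"
            lines.append(f"{name}\t{stat}\t{pval}")
        return "\n".join(lines) + "\n"


def write_report(report: AnalysisReport, path, fmt: str = "json") -> None:
    """Write a report as JSON (full precision) or TSV (4-decimal)."""
    if fmt == "json":
        text = report.to_json()
    elif fmt == "tsv":
        text = report.to_tsv()
    else:
        raise ValueError("format must be 'json' or 'tsv'")
    with open(path, "w") as fh:
        fh.write(text)
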