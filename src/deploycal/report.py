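"""Rendering of deployment and co-occurrence outputs to CSV and JSON."""

from __future__ import annotations

import json
import os

import pandas as pd

from .calibration import ThresholdSet
from .deployment import DeploymentReport

__all__ = ["render_tables", "report_to_json", "report_from_json"]


def _thresholds_dict(t: ThresholdSet) -> dict:
    return {"t3": t.t3, "t4": t.t4, "kind": t.kind}


def report_to_json(report: DeploymentReport) -> dict:
    """A JSON-serializable mirror of the report with unrounded values."""
    payload = {name: df.to_dict(orient="tight") for name, df in report.tables.items()}
    payload["fixed"] = _thresholds_dict(report.fixed)
    payload["limit"] = _thresholds_dict(report.limit)
    return payload


def report_from_json(payload: dict) -> DeploymentReport:
    tables = {
        name: pd.DataFrame.from_dict(payload[name], orient="tight")
        for name in ("batch_table", "lookback_table", "patient_table", "sextant_table", "exam_log")
    }
    return DeploymentReport(
        **tables,
        fixed=ThresholdSet(**payload["fixed"]),
        limit=ThresholdSet(**payload["limit"]),
    )


def render_tables(obj, outdir: str) -> list[str]:
    """Write one CSV per table plus a JSON mirror; returns the written paths.

    Accepts a :class:`DeploymentReport` or a plain DataFrame (e.g. the
    co-occurrence report).  Every percentage column in the tables is
    accompanied by its integer numerator/denominator columns.
    """
    os.makedirs(outdir, exist_ok=True)
    written = []
    if isinstance(obj, DeploymentReport):
        for name, df in obj.tables.items():
            path = os.path.join(outdir, f"{name}.csv")
            df.to_csv(path, index=False)
            written.append(path)
        path = os.path.join(outdir, "report.json")
        with open(path, "w") as fh:
            json.dump(report_to_json(obj), fh, indent=1, default=str)
        written.append(path)
    elif isinstance(obj, pd.DataFrame):
        path = os.path.join(outdir, "cooccurrence.csv")
        obj.to_csv(path, index=False)
        written.append(path)
        path = os.path.join(outdir, "cooccurrence.json")
        with open(path, "w") as fh:
            json.dump(obj.to_dict(orient="tight"), fh, indent=1, default=str)
        written.append(path)
    else:
        raise TypeError(f"cannot render {type(obj).__name__}")
    return written
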