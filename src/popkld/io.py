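"""CSV/JSON readers and writers for the pipeline's file contracts.

Measurement tables are plain CSV (``patient_id, lab_name, value[, context]
[, timestamp]``); reports and binning schemes are JSON.  Every artifact the
CLI writes carries a ``meta`` block (or a sidecar ``*.meta.json`` for CSV)
echoing the effective configuration, the package version, and the seed, so
any output can be reproduced from its own header.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from . import __version__ as _version
from .categorize import BinningScheme
from .selection import PopulationSelectionReport
from .summaries import validate_table

__all__ = [
    "read_measurements",
    "write_frame",
    "read_json",
    "write_json",
    "write_selection_report",
    "read_selection_report",
    "write_binning",
    "read_binning",
]


def read_measurements(path) -> pd.DataFrame:
    """Read and validate a long-format measurement CSV."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"expected measurement file: {path}")
    table = pd.read_csv(path, dtype={"patient_id": str, "lab_name": str})
    if table.empty:
        raise ValueError(f"{path}: no measurement rows")
    try:
        return validate_table(table)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def _meta(config: dict | None, seed=None) -> dict:
    return {"package": "popkld", "version": _version,
            "seed": seed, "config": config or {}}


def write_frame(frame: pd.DataFrame, path, config: dict | None = None,
                seed=None) -> None:
    """Write a CSV plus a ``*.meta.json`` sidecar with the run provenance."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False)
    with open(path.with_suffix(path.suffix + ".meta.json"), "w") as fh:
        json.dump(_meta(config, seed), fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_json(obj: dict, path, config: dict | None = None, seed=None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {"meta": _meta(config, seed), **obj}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path) -> dict:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"expected file: {path}")
    with open(path) as fh:
        return json.load(fh)


def write_selection_report(report: PopulationSelectionReport, path,
                           seed=None) -> None:
    write_json({"report": report.to_dict()}, path,
               config=report.config, seed=seed)


def read_selection_report(path) -> PopulationSelectionReport:
    return PopulationSelectionReport.from_dict(read_json(path)["report"])


def write_binning(scheme: BinningScheme, path, config=None, seed=None) -> None:
    write_json({"binning": scheme.to_dict()}, path, config=config, seed=seed)


def read_binning(path) -> BinningScheme:
    return BinningScheme.from_dict(read_json(path)["binning"])
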