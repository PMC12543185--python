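"""Readers and writers for the package's plain-text and imaging formats.

Tables travel as tidy CSV, parameters as JSON/YAML sidecars, and 4-D runs
optionally as NIfTI (one file per nulled / not-nulled series plus a JSON
sidecar with the paired TR). Deposited per-figure workbooks are read as
XLSX through an explicit sheet/column schema.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .exceptions import SchemaError
from .synthetic import Block, Event, PairedVasoRun, StimulusTimeline

__all__ = [
    "write_timeline",
    "read_timeline",
    "write_paired_run_nifti",
    "read_paired_run_nifti",
    "DEFAULT_XLSX_SCHEMA",
    "load_schema",
    "read_deposited_workbook",
]


def write_timeline(timeline: StimulusTimeline, events_csv, params_json) -> None:
    """Serialize a timeline to an events CSV and a JSON parameter sidecar."""
    timeline.events_frame().to_csv(events_csv, index=False)
    params = {
        "run_duration": timeline.run_duration,
        "paired_tr": timeline.paired_tr,
        "conditions": list(timeline.conditions),
        "blocks": [list(b) for b in timeline.blocks],
    }
    Path(params_json).write_text(json.dumps(params, indent=2))


def read_timeline(events_csv, params_json) -> StimulusTimeline:
    events = pd.read_csv(events_csv)
    params = json.loads(Path(params_json).read_text())
    ev = tuple(Event(r.onset, r.duration, r.theta, r.side)
               for r in events.itertuples())
    blocks = tuple(Block(*b) for b in params["blocks"])
    return StimulusTimeline(ev, blocks, params["run_duration"],
                            params["paired_tr"], tuple(params["conditions"]))


def write_paired_run_nifti(run: PairedVasoRun, nulled_path, not_nulled_path,
                           sidecar_json) -> None:
    """Write one 4-D NIfTI per series (voxels on a 1-D grid) plus a sidecar."""
    for data, path in ((run.nulled, nulled_path), (run.not_nulled, not_nulled_path)):
        img = nib.Nifti1Image(
            np.asarray(data, dtype=np.float32)[:, None, None, :], np.eye(4))
        img.header["pixdim"][4] = run.paired_tr
        nib.save(img, str(path))
    Path(sidecar_json).write_text(json.dumps(
        {"paired_tr": run.paired_tr, "nulled_first": run.nulled_first}, indent=2))


def read_paired_run_nifti(nulled_path, not_nulled_path, sidecar_json) -> PairedVasoRun:
    sidecar = json.loads(Path(sidecar_json).read_text())
    nulled = np.asanyarray(nib.load(str(nulled_path)).dataobj)
    not_nulled = np.asanyarray(nib.load(str(not_nulled_path)).dataobj)
    nulled = nulled.reshape(-1, nulled.shape[-1]).astype(float)
    not_nulled = not_nulled.reshape(-1, not_nulled.shape[-1]).astype(float)
    return PairedVasoRun(nulled, not_nulled, sidecar["paired_tr"],
                         nulled_first=sidecar.get("nulled_first", True))


#: Default sheet/column layout expected in a deposited per-figure workbook.
#: The real workbook's internal layout is the adaptation point: pass a YAML
#: schema with the same structure to remap sheet and column names.
DEFAULT_XLSX_SCHEMA = {
    "behavior": {"sheet": "behavior",
                 "columns": {"subject": "subject", "s90": "S_90", "s15": "S_15"}},
    "laminar": {"sheet": "laminar",
                "columns": {"subject": "subject", "roi": "roi", "depth": "depth",
                            "theta": "theta", "s_fmri": "S_fMRI"}},
    "connectivity": {"sheet": "connectivity",
                     "columns": {"subject": "subject", "pathway": "pathway",
                                 "delta": "delta"}},
    "bcea": {"sheet": "bcea",
             "columns": {"subject": "subject", "theta": "theta", "bcea": "BCEA"}},
}


def load_schema(path=None) -> dict:
    if path is None:
        return DEFAULT_XLSX_SCHEMA
    schema = yaml.safe_load(Path(path).read_text())
    unknown = set(schema) - set(DEFAULT_XLSX_SCHEMA)
    if unknown:
        raise SchemaError(f"unknown schema sections: {sorted(unknown)}")
    return {**DEFAULT_XLSX_SCHEMA, **schema}


def read_deposited_workbook(xlsx_path, which: str, schema: dict | None = None) -> pd.DataFrame:
    """Read one analysis table from a deposited workbook via the schema.

    Raises :class:`SchemaError` listing the sheets found when the expected
    sheet or columns are absent or the file is not a readable workbook.
    """
    schema = schema or DEFAULT_XLSX_SCHEMA
    if which not in schema:
        raise SchemaError(f"unknown analysis {which!r}; choose from {sorted(schema)}")
    path = Path(xlsx_path)
    if not path.exists():
        raise SchemaError(f"workbook not found: {path}")
    try:
        book = pd.ExcelFile(path)
    except Exception as err:
        raise SchemaError(f"could not open {path} as a workbook: {err}") from err
    entry = schema[which]
    if entry["sheet"] not in book.sheet_names:
        raise SchemaError(
            f"sheet {entry['sheet']!r} not found; sheets present: {book.sheet_names}")
    df = book.parse(entry["sheet"])
    missing = [c for c in entry["columns"].values() if c not in df.columns]
    if missing:
        raise SchemaError(
            f"sheet {entry['sheet']!r} lacks columns {missing}; "
            f"found {list(df.columns)}")
    inverse = {v: k for k, v in entry["columns"].items()}
    return df.rename(columns=inverse)[list(entry["columns"])]
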