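"""Text-format I/O: fixation tables, AOI definitions, matrices, reports.

Canonical dialect is comma-separated UTF-8 with a header; tab-separated
input is accepted via ``delimiter="\\t"``.  Column order never matters —
columns are matched by name.  AOI definitions are a JSON (or YAML)
document keyed by stimulus id; region order in the file is the priority
order for overlap resolution.  Square matrices travel as CSV with AOI
labels as both header row and first column, so matrices transcribed
from printed tables can be ingested directly.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .aoi import AOIRegion, AOISet, FixationRecord

__all__ = [
    "FIXATION_COLUMNS",
    "read_fixations",
    "write_fixations",
    "read_aoi_sets",
    "write_aoi_sets",
    "read_matrix_csv",
    "write_matrix_csv",
    "read_vector_csv",
    "write_vector_csv",
    "write_report",
    "read_report",
]

FIXATION_COLUMNS = (
    "participant_id",
    "stimulus_id",
    "start_ms",
    "duration_ms",
    "x_px",
    "y_px",
)
_NUMERIC = ("start_ms", "duration_ms", "x_px", "y_px")

PathLike = Union[str, Path]


class FixationFormatError(ValueError):
    """A fixation table violates the declared column contract."""


def read_fixations(path: PathLike, delimiter: str = ",") -> list[FixationRecord]:
    """Read a fixation table into records grouped by trial, sorted by onset.

    The header must name all six canonical columns (any order, extra
    columns ignored).  Records come back grouped by
    (participant_id, stimulus_id) and sorted by start within each group;
    no row is dropped.
    """
    df = pd.read_csv(path, delimiter=delimiter, dtype={"participant_id": str, "stimulus_id": str})
    missing = [c for c in FIXATION_COLUMNS if c not in df.columns]
    if missing:
        raise FixationFormatError(
            f"{path}: missing required column(s) {missing}; header has {list(df.columns)}"
        )
    for col in _NUMERIC:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            # +2: header line plus 1-based numbering
            raise FixationFormatError(
                f"{path}: non-numeric value {df.loc[bad[0], col]!r} in column "
                f"{col!r} at line {int(bad[0]) + 2}"
            )
        if coerced.isna().any():
            line = int(df.index[coerced.isna()][0]) + 2
            raise FixationFormatError(f"{path}: empty value in column {col!r} at line {line}")
        df[col] = coerced
    df = df.sort_values(
        ["participant_id", "stimulus_id", "start_ms"], kind="stable"
    ).reset_index(drop=True)
    return [
        FixationRecord(
            participant_id=row.participant_id,
            stimulus_id=row.stimulus_id,
            start=float(row.start_ms),
            duration=float(row.duration_ms),
            x=float(row.x_px),
            y=float(row.y_px),
        )
        for row in df.itertuples(index=False)
    ]


def write_fixations(records: Sequence[FixationRecord], path: PathLike, delimiter: str = ",") -> None:
    df = pd.DataFrame(
        {
            "participant_id": [r.participant_id for r in records],
            "stimulus_id": [r.stimulus_id for r in records],
            "start_ms": [r.start for r in records],
            "duration_ms": [r.duration for r in records],
            "x_px": [r.x for r in records],
            "y_px": [r.y for r in records],
        }
    )
    df.to_csv(path, sep=delimiter, index=False)


def read_aoi_sets(path: PathLike) -> dict[str, AOISet]:
    """Read AOI definitions for one or more stimuli from JSON or YAML.

    Document shape: ``{stimulus_id: [{aoi_id, label, x_min, y_min,
    x_max, y_max}, ...], ...}``; list order is region priority.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() in (".yaml", ".yml"):
        doc = yaml.safe_load(text)
    else:
        doc = json.loads(text)
    if not isinstance(doc, Mapping):
        raise ValueError(f"{path}: expected a mapping of stimulus_id to region lists")
    out: dict[str, AOISet] = {}
    for stim, regions in doc.items():
        regs = tuple(
            AOIRegion(
                aoi_id=int(r["aoi_id"]),
                label=str(r.get("label", f"AOI{r['aoi_id']}")),
                x_min=float(r["x_min"]),
                y_min=float(r["y_min"]),
                x_max=float(r["x_max"]),
                y_max=float(r["y_max"]),
            )
            for r in regions
        )
        out[str(stim)] = AOISet(stimulus_id=str(stim), regions=regs)
    return out


def write_aoi_sets(aoi_sets: Mapping[str, AOISet], path: PathLike) -> None:
    doc = {
        stim: [
            {
                "aoi_id": r.aoi_id,
                "label": r.label,
                "x_min": r.x_min,
                "y_min": r.y_min,
                "x_max": r.x_max,
                "y_max": r.y_max,
            }
            for r in aset.regions
        ]
        for stim, aset in aoi_sets.items()
    }
    path = Path(path)
    if path.suffix.lower() in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(doc, sort_keys=False), encoding="utf-8")
    else:
        path.write_text(json.dumps(doc, indent=2), encoding="utf-8")


def read_matrix_csv(path: PathLike, delimiter: str = ",") -> tuple[tuple[str, ...], np.ndarray]:
    """Read a square labelled matrix (labels as header row and first column)."""
    df = pd.read_csv(path, delimiter=delimiter, index_col=0)
    labels = tuple(str(c) for c in df.columns)
    row_labels = tuple(str(i) for i in df.index)
    if labels != row_labels:
        raise ValueError(f"{path}: row labels {row_labels} != column labels {labels}")
    return labels, df.to_numpy(dtype=float)


def write_matrix_csv(
    labels: Sequence[str], M: np.ndarray, path: PathLike, delimiter: str = ","
) -> None:
    pd.DataFrame(np.asarray(M), index=list(labels), columns=list(labels)).to_csv(
        path, sep=delimiter
    )


def read_vector_csv(path: PathLike, delimiter: str = ",") -> tuple[tuple[str, ...], np.ndarray]:
    """Read a labelled vector stored as a one-row CSV under a label header."""
    df = pd.read_csv(path, delimiter=delimiter)
    if len(df) != 1:
        raise ValueError(f"{path}: expected exactly one data row, got {len(df)}")
    return tuple(str(c) for c in df.columns), df.iloc[0].to_numpy(dtype=float)


def write_vector_csv(
    labels: Sequence[str], v: np.ndarray, path: PathLike, delimiter: str = ","
) -> None:
    pd.DataFrame([np.asarray(v)], columns=list(labels)).to_csv(path, sep=delimiter, index=False)


def _flatten_record(rec: Mapping) -> dict:
    flat = {}
    for k, v in rec.items():
        if isinstance(v, (list, tuple)):
            flat[k] = ";".join(repr(float(x)) if isinstance(x, (int, float)) else str(x) for x in v)
        else:
            flat[k] = v
    return flat


def write_report(records: Sequence[Mapping], path: PathLike, format: str = "json") -> None:
    """Write metric report rows as JSON (full precision) or flat CSV.

    JSON round-trips every float exactly (repr precision); in CSV,
    vector-valued fields are semicolon-joined within a cell.
    """
    path = Path(path)
    if format == "json":
        path.write_text(json.dumps(list(records), indent=2), encoding="utf-8")
    elif format == "csv":
        pd.DataFrame([_flatten_record(r) for r in records]).to_csv(path, index=False)
    else:
        raise ValueError(f"unknown report format {format!r}")


def read_report(path: PathLike) -> list[dict]:
    """Read back a report written by :func:`write_report`."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        return json.loads(path.read_text(encoding="utf-8"))
    df = pd.read_csv(path)
    out = []
    for rec in df.to_dict(orient="records"):
        for k, v in list(rec.items()):
            if isinstance(v, str) and ";" in v:
                try:
                    rec[k] = [float(x) for x in v.split(";")]
                except ValueError:
                    pass
        out.append(rec)
    return out
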