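"""Readers and writers for acceleration streams, feature tables and scripts.

Stream files carry one sample per row with keys/columns ``t, x, y, z`` and
an optional ``label`` (t in seconds, accelerations in g, label one of the
five activity strings).  Two on-disk formats are supported and detected by
extension: CSV with a header row, and JSON Lines with one object per line.
Parsing is strict; a malformed row raises :class:`StreamParseError` with
its 1-based line number.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import InvalidInputError, StreamParseError
from .features import FEATURE_COLUMNS
from .simulate import ActivityScriptSegment, LabeledStream

__all__ = [
    "read_stream",
    "write_stream",
    "read_features",
    "write_features",
    "read_script",
]

_STREAM_FIELDS = ("t", "x", "y", "z")


def _rows_to_frame(rows: list[dict], with_label: bool) -> pd.DataFrame:
    cols = {k: [r[k] for r in rows] for k in _STREAM_FIELDS}
    df = pd.DataFrame(cols, dtype=float)
    if with_label:
        df["label"] = [r["label"] for r in rows]
    return df


def _read_stream_csv(path: Path) -> pd.DataFrame:
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            return pd.DataFrame(columns=[*_STREAM_FIELDS, "label"])
        header = [h.strip() for h in header]
        missing = set(_STREAM_FIELDS) - set(header)
        if missing:
            raise StreamParseError(1, f"missing columns {sorted(missing)}")
        with_label = "label" in header
        idx = {name: header.index(name) for name in header}
        rows = []
        for line_no, raw in enumerate(reader, start=2):
            if not raw or (len(raw) == 1 and not raw[0].strip()):
                continue
            if len(raw) < len(header):
                raise StreamParseError(line_no, f"expected {len(header)} fields, got {len(raw)}")
            row = {}
            for name in _STREAM_FIELDS:
                try:
                    row[name] = float(raw[idx[name]])
                except ValueError:
                    raise StreamParseError(
                        line_no, f"non-numeric value {raw[idx[name]]!r} in column {name!r}"
                    ) from None
            if with_label:
                row["label"] = raw[idx["label"]].strip()
            rows.append(row)
    if not rows:
        return pd.DataFrame(columns=[*_STREAM_FIELDS] + (["label"] if with_label else []))
    return _rows_to_frame(rows, with_label)


def _read_stream_jsonl(path: Path) -> pd.DataFrame:
    rows = []
    with_label = False
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise StreamParseError(line_no, f"invalid JSON: {exc.msg}") from None
            row = {}
            for name in _STREAM_FIELDS:
                if name not in obj:
                    raise StreamParseError(line_no, f"missing key {name!r}")
                try:
                    row[name] = float(obj[name])
                except (TypeError, ValueError):
                    raise StreamParseError(
                        line_no, f"non-numeric value {obj[name]!r} for key {name!r}"
                    ) from None
            if "label" in obj:
                row["label"] = str(obj["label"])
                with_label = True
            elif with_label:
                raise StreamParseError(line_no, "row missing 'label' present in earlier rows")
            rows.append(row)
    if not rows:
        return pd.DataFrame(columns=[*_STREAM_FIELDS, "label"])
    return _rows_to_frame(rows, with_label)


def read_stream(path) -> pd.DataFrame:
    """Read an acceleration stream file (CSV or JSONL, by extension)."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        return _read_stream_csv(path)
    if path.suffix.lower() in (".jsonl", ".ndjson", ".json"):
        return _read_stream_jsonl(path)
    raise InvalidInputError(f"unrecognised stream file extension: {path.suffix!r}")


def write_stream(stream, path) -> Path:
    """Write a stream (LabeledStream or t,x,y,z[,label] frame) to CSV/JSONL."""
    path = Path(path)
    df = stream.to_frame() if isinstance(stream, LabeledStream) else pd.DataFrame(stream)
    cols = [c for c in ("t", "x", "y", "z", "label") if c in df.columns]
    df = df.loc[:, cols]
    if path.suffix.lower() == ".csv":
        df.to_csv(path, index=False)
    elif path.suffix.lower() in (".jsonl", ".ndjson", ".json"):
        with open(path, "w") as fh:
            for rec in df.to_dict(orient="records"):
                fh.write(json.dumps(rec) + "\n")
    else:
        raise InvalidInputError(f"unrecognised stream file extension: {path.suffix!r}")
    return path


def write_features(features: pd.DataFrame, path) -> Path:
    """Write a feature table (the 9 canonical columns, optional label)."""
    path = Path(path)
    cols = [*FEATURE_COLUMNS] + (["label"] if "label" in features.columns else [])
    features.loc[:, cols].to_csv(path, index=False)
    return path


def read_features(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(FEATURE_COLUMNS) - set(df.columns)
    if missing:
        raise InvalidInputError(f"feature table missing columns: {sorted(missing)}")
    df[list(FEATURE_COLUMNS)] = df[list(FEATURE_COLUMNS)].astype(float)
    if not np.all(np.isfinite(df[list(FEATURE_COLUMNS)].to_numpy())):
        raise InvalidInputError("feature table contains non-finite values")
    return df


def read_script(path) -> list[ActivityScriptSegment]:
    """Read a scenario script: a YAML list of {activity, duration_s, params}."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, list) or not raw:
        raise InvalidInputError("script must be a non-empty YAML list of segments")
    segments = []
    for i, entry in enumerate(raw):
        if not isinstance(entry, dict) or "activity" not in entry or "duration_s" not in entry:
            raise InvalidInputError(f"script entry {i} must have 'activity' and 'duration_s'")
        segments.append(
            ActivityScriptSegment(
                activity=str(entry["activity"]),
                duration_s=float(entry["duration_s"]),
                params=dict(entry.get("params", {})),
            )
        )
    return segments
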