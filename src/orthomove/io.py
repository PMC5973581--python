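"""Landmark file formats (CSV and JSON) and summary-statistics input.

CSV schema: one landmark per row with columns
``patient_id, timepoint, side, landmark, x, y, z``; ``side`` is "L"/"R"
for sided landmarks and "M" (or empty) for midline ones.  Coordinates
are millimetres in each scan's native frame — no global orientation is
assumed on input.  The JSON format mirrors the same content
hierarchically: patient -> timepoint -> {canonical key: [x, y, z]}.

Readers validate against the landmark vocabulary and report offending
row numbers; writers and readers are mutually inverse on valid data.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .errors import SchemaError
from .landmarks import LandmarkSet, canonical_key, split_key
from .stats import GroupSummary

CSV_COLUMNS = ("patient_id", "timepoint", "side", "landmark", "x", "y", "z")


def read_landmarks(path) -> list[LandmarkSet]:
    """Read landmark sets from a ``.csv`` or ``.json`` file."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        return _read_json(path)
    if path.suffix.lower() == ".csv":
        return _read_csv(path)
    raise SchemaError(f"unsupported landmark file extension: {path.suffix!r}")


def _read_csv(path: Path) -> list[LandmarkSet]:
    df = pd.read_csv(path, dtype={"patient_id": str, "timepoint": str, "side": str})
    missing = set(CSV_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    sets: dict[tuple[str, str], dict] = {}
    problems: list[str] = []
    for row in df.itertuples():
        rownum = row.Index + 2  # 1-based, after the header line
        side = "" if pd.isna(row.side) else str(row.side)
        try:
            key = canonical_key(str(row.landmark), side)
        except SchemaError as exc:
            problems.append(f"row {rownum}: {exc}")
            continue
        bucket = sets.setdefault((str(row.patient_id), str(row.timepoint)), {})
        if key in bucket:
            problems.append(
                f"row {rownum}: duplicate landmark {key!r} for "
                f"patient {row.patient_id!r} {row.timepoint}"
            )
            continue
        bucket[key] = [row.x, row.y, row.z]
    if problems:
        raise SchemaError(f"{path}: " + "; ".join(problems))
    return _build_sets(sets)


def _read_json(path: Path) -> list[LandmarkSet]:
    with open(path) as fh:
        payload = json.load(fh)
    sets: dict[tuple[str, str], dict] = {}
    for patient in payload.get("patients", []):
        pid = str(patient["patient_id"])
        for timepoint, landmarks in patient.get("scans", {}).items():
            bucket = sets.setdefault((pid, timepoint), {})
            for key, xyz in landmarks.items():
                name, side = split_key(key)
                bucket[canonical_key(name, None if side == "M" else side)] = xyz
    return _build_sets(sets)


def _build_sets(sets: dict) -> list[LandmarkSet]:
    out = []
    for (pid, timepoint), points in sorted(sets.items()):
        out.append(LandmarkSet(pid, timepoint, points))
    return out


def write_landmarks(sets: list[LandmarkSet], path) -> None:
    """Write landmark sets to ``.csv`` or ``.json`` (chosen by extension)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload: dict = {"patients": []}
        by_patient: dict[str, dict] = {}
        for ls in sets:
            scans = by_patient.setdefault(ls.patient_id, {})
            scans[ls.timepoint] = {k: p.tolist() for k, p in sorted(ls.points.items())}
        for pid, scans in sorted(by_patient.items()):
            payload["patients"].append({"patient_id": pid, "scans": scans})
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)
        return
    if path.suffix.lower() == ".csv":
        rows = []
        for ls in sets:
            for key, p in sorted(ls.points.items()):
                name, side = split_key(key)
                rows.append(
                    {
                        "patient_id": ls.patient_id,
                        "timepoint": ls.timepoint,
                        "side": side,
                        "landmark": name,
                        "x": repr(float(p[0])),
                        "y": repr(float(p[1])),
                        "z": repr(float(p[2])),
                    }
                )
        pd.DataFrame(rows, columns=list(CSV_COLUMNS)).to_csv(path, index=False)
        return
    raise SchemaError(f"unsupported landmark file extension: {path.suffix!r}")


def pair_timepoints(sets: list[LandmarkSet]) -> dict[str, dict[str, LandmarkSet]]:
    """Group landmark sets as ``patient_id -> {timepoint: set}``."""
    paired: dict[str, dict[str, LandmarkSet]] = {}
    for ls in sets:
        scans = paired.setdefault(ls.patient_id, {})
        if ls.timepoint in scans:
            raise SchemaError(
                f"duplicate scan for patient {ls.patient_id!r} at {ls.timepoint}"
            )
        scans[ls.timepoint] = ls
    return paired


def read_summary_table(path) -> dict[str, tuple[GroupSummary, GroupSummary]]:
    """Read a two-group summary-statistics CSV.

    Columns: ``variable, mean1, sd1, n1, mean2, sd2, n2`` — one row per
    movement variable, so published group tables can be re-analysed
    without raw coordinates.
    """
    df = pd.read_csv(path)
    required = {"variable", "mean1", "sd1", "n1", "mean2", "sd2", "n2"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    out = {}
    for row in df.itertuples():
        out[str(row.variable)] = (
            GroupSummary(row.mean1, row.sd1, int(row.n1)),
            GroupSummary(row.mean2, row.sd2, int(row.n2)),
        )
    return out
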