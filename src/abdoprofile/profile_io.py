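"""Reading and writing digitized landmarks and per-patient result tables.

Formats (fixed dialect: comma delimiter, decimal point, UTF-8):

* landmark table CSV: header ``patient_id,point_label,x,y``, one row per
  point, labels ``P0``..``P8`` (``P7`` optional);
* SVG ingest: a document whose first ``<path>`` consists of a moveto plus
  exactly two quadratic ("Q"/"q") segments; SVG's native y-down axis matches
  the canonical frame, so no flip is applied;
* patient table CSV: one flat row per patient carrying the scalar fields,
  landmark coordinates, metrics and classification labels (column schema in
  the README).  Lines starting with ``#`` are metadata and are skipped.
"""

from __future__ import annotations

import csv
import math
import re
import warnings
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .classify import ProfileClassification
from .errors import ParseError, UnsupportedPathError, ValidationError
from .geometry import Point2D, ProfileLandmarks, ProfileMetrics

__all__ = [
    "PatientRecord",
    "read_landmarks_csv",
    "write_landmarks_csv",
    "read_profile_svg",
    "write_patient_table",
    "read_patient_table",
    "PATIENT_TABLE_COLUMNS",
]

_LANDMARK_HEADER = ["patient_id", "point_label", "x", "y"]
_REQUIRED_LABELS = ("P0", "P1", "P2", "P3", "P4", "P5", "P6", "P8")
_ALL_LABELS = _REQUIRED_LABELS + ("P7",)

_POINT_NAMES = ("p0", "p1", "p2", "p3", "p4", "p5", "p6", "p7", "p8")
_SCALAR_FIELDS = ("sex", "age", "height", "weight", "bmi", "wc", "rhd", "lhd", "shd")
_METRIC_FIELDS = (
    "t1", "t4", "k1", "k2", "r1", "r2", "sup_arc", "inf_arc", "total_arc",
    "area1", "area2", "total_area", "vlow", "ant_pr", "inf_pr",
)
_CLASS_FIELDS = ("criterion1", "criterion2", "antpr_band", "infpr_band", "type_a", "type_b")

PATIENT_TABLE_COLUMNS: tuple[str, ...] = (
    ("patient_id",)
    + _SCALAR_FIELDS
    + tuple(f"{p}_{ax}" for p in _POINT_NAMES for ax in ("x", "y"))
    + _METRIC_FIELDS
    + _CLASS_FIELDS
)


@dataclass
class PatientRecord:
    """One subject: identity, anthropometry, ultrasound and derived profile data."""

    patient_id: str
    sex: str | None = None          # "M" or "F"
    age: float | None = None        # years
    height: float | None = None     # cm
    weight: float | None = None     # kg
    bmi: float | None = None        # kg/m^2
    wc: float | None = None         # cm
    rhd: float | None = None        # mm
    lhd: float | None = None        # mm
    shd: float | None = None        # mm
    landmarks: ProfileLandmarks | None = None
    metrics: ProfileMetrics | None = None
    classification: ProfileClassification | None = None

    def validate(self) -> None:
        if self.sex is not None and self.sex not in ("M", "F"):
            raise ValidationError(f"sex must be 'M' or 'F', got {self.sex!r}")
        if None not in (self.rhd, self.lhd, self.shd):
            if abs(self.shd - (self.rhd + self.lhd)) > 1e-6 * max(1.0, abs(self.shd)):
                raise ValidationError(
                    f"shd ({self.shd}) must equal rhd + lhd ({self.rhd + self.lhd})"
                )
        if None not in (self.height, self.weight, self.bmi):
            implied = self.weight / (self.height / 100.0) ** 2
            if abs(implied - self.bmi) > 0.1:
                raise ValidationError(
                    f"bmi {self.bmi} inconsistent with height/weight (implies {implied:.2f})"
                )


# ---------------------------------------------------------------------------
# Landmark CSV
# ---------------------------------------------------------------------------

def read_landmarks_csv(path: str | Path) -> list[tuple[str, ProfileLandmarks]]:
    """Read, validate and canonically normalize a landmark table.

    Returns ``(patient_id, landmarks)`` pairs in file order.  Malformed rows
    raise :class:`ParseError` with the line number; patients missing required
    labels raise :class:`ValidationError` naming every missing label.
    """
    path = Path(path)
    groups: dict[str, dict[str, tuple[float, float]]] = {}
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError("empty file", line=1)
        if [h.strip() for h in header[:4]] != _LANDMARK_HEADER:
            raise ParseError(
                f"expected header {','.join(_LANDMARK_HEADER)}, got {','.join(header)}",
                line=1,
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < 4:
                raise ParseError(f"expected 4 fields, got {len(row)}", line=lineno)
            pid, label = row[0].strip(), row[1].strip()
            if label not in _ALL_LABELS:
                raise ParseError(f"unknown point label {label!r}", line=lineno)
            try:
                x, y = float(row[2]), float(row[3])
            except ValueError as exc:
                raise ParseError(f"non-numeric coordinate: {exc}", line=lineno)
            pts = groups.setdefault(pid, {})
            if label in pts:
                raise ParseError(f"duplicate label {label} for patient {pid}", line=lineno)
            pts[label] = (x, y)

    problems = []
    for pid, pts in groups.items():
        missing = [lab for lab in _REQUIRED_LABELS if lab not in pts]
        if missing:
            problems.append(f"patient {pid}: missing {', '.join(missing)}")
    if problems:
        raise ValidationError("; ".join(problems))

    return [(pid, ProfileLandmarks.from_raw(pts)) for pid, pts in groups.items()]


def write_landmarks_csv(
    items: Iterable[tuple[str, ProfileLandmarks]],
    path: str | Path,
    meta: dict[str, object] | None = None,
) -> None:
    """Write landmark sets in the table format read_landmarks_csv consumes."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        for k, v in (meta or {}).items():
            fh.write(f"# {k} = {v}\n")
        writer = csv.writer(fh)
        writer.writerow(_LANDMARK_HEADER)
        for pid, lm in items:
            for label in _ALL_LABELS:
                p = getattr(lm, label.lower())
                if p is None:
                    continue
                writer.writerow([pid, label, repr(p.x), repr(p.y)])


# ---------------------------------------------------------------------------
# SVG ingest
# ---------------------------------------------------------------------------

_NUM = r"[-+]?(?:\d+\.?\d*|\.\d+)(?:[eE][-+]?\d+)?"
_TOKEN = re.compile(rf"([MmQqZzLlCcSsTtAaHhVv])|({_NUM})")


def _tokenize_path(d: str) -> list[str]:
    tokens = []
    pos = 0
    for m in _TOKEN.finditer(d):
        tokens.append(m.group(0))
    return tokens


def read_profile_svg(path: str | Path) -> ProfileLandmarks:
    """Extract profile landmarks from a two-quadratic-segment SVG path.

    The first path's anchors/controls map to P0, P5, P3, P6, P2; the
    extremum points P1/P4 are recomputed from the curve (authored files need
    not mark them) and P8 is derived.  Anything but ``M`` + two ``Q``
    segments (optionally ``Z``) is rejected.
    """
    path = Path(path)
    try:
        tree = ET.parse(path)
    except ET.ParseError as exc:
        raise ParseError(f"not well-formed SVG: {exc}")
    elem = None
    for node in tree.iter():
        if node.tag.rsplit("}", 1)[-1] == "path":
            elem = node
            break
    if elem is None or "d" not in elem.attrib:
        raise UnsupportedPathError("no <path> element with a 'd' attribute found")
    tokens = _tokenize_path(elem.attrib["d"])

    i = 0
    cur = (0.0, 0.0)
    anchors: list[tuple[float, float]] = []
    controls: list[tuple[float, float]] = []
    n_segments = 0

    def take_numbers(n: int) -> list[float]:
        nonlocal i
        vals = []
        for _ in range(n):
            if i >= len(tokens) or tokens[i][0].isalpha() and tokens[i] not in ("e", "E"):
                raise UnsupportedPathError("truncated coordinate list in path data")
            vals.append(float(tokens[i]))
            i += 1
        return vals

    while i < len(tokens):
        cmd = tokens[i]
        if not cmd.isalpha() or len(cmd) > 1:
            raise UnsupportedPathError(f"unexpected token {cmd!r} in path data")
        i += 1
        if cmd in ("M", "m"):
            x, y = take_numbers(2)
            if cmd == "m":
                x, y = cur[0] + x, cur[1] + y
            cur = (x, y)
            if anchors:
                raise UnsupportedPathError("multiple subpaths are not supported")
            anchors.append(cur)
        elif cmd in ("Q", "q"):
            while i < len(tokens) and not tokens[i].isalpha():
                cx, cy, x, y = take_numbers(4)
                if cmd == "q":
                    cx, cy, x, y = cur[0] + cx, cur[1] + cy, cur[0] + x, cur[1] + y
                controls.append((cx, cy))
                anchors.append((x, y))
                cur = (x, y)
                n_segments += 1
        elif cmd in ("Z", "z"):
            break
        else:
            raise UnsupportedPathError(
                f"unsupported path command {cmd!r}; only M + quadratic 'Q' segments "
                f"are accepted ({n_segments} quadratic segment(s) seen)"
            )
    if n_segments != 2:
        raise UnsupportedPathError(
            f"expected exactly 2 quadratic segments, found {n_segments}"
        )
    raw = {
        "P0": anchors[0],
        "P5": controls[0],
        "P3": anchors[1],
        "P6": controls[1],
        "P2": anchors[2],
    }
    return ProfileLandmarks.from_raw(raw)


# ---------------------------------------------------------------------------
# Patient table
# ---------------------------------------------------------------------------

def _record_to_row(rec: PatientRecord) -> dict[str, object]:
    row: dict[str, object] = {c: None for c in PATIENT_TABLE_COLUMNS}
    row["patient_id"] = rec.patient_id
    for f in _SCALAR_FIELDS:
        row[f] = getattr(rec, f)
    if rec.landmarks is not None:
        for p in _POINT_NAMES:
            pt = getattr(rec.landmarks, p)
            if pt is not None:
                row[f"{p}_x"], row[f"{p}_y"] = pt.x, pt.y
    if rec.metrics is not None:
        for f in _METRIC_FIELDS:
            row[f] = getattr(rec.metrics, f)
    if rec.classification is not None:
        for f in _CLASS_FIELDS:
            row[f] = getattr(rec.classification, f)
    return row


def write_patient_table(
    records: Sequence[PatientRecord],
    path: str | Path,
    meta: dict[str, object] | None = None,
) -> None:
    """Write patient records as a flat CSV (optionally with '#' metadata lines)."""
    path = Path(path)
    df = pd.DataFrame([_record_to_row(r) for r in records], columns=PATIENT_TABLE_COLUMNS)
    with path.open("w", newline="", encoding="utf-8") as fh:
        for k, v in (meta or {}).items():
            fh.write(f"# {k} = {v}\n")
        df.to_csv(fh, index=False, float_format="%.17g")  # lossless round trip


def _opt_float(v) -> float | None:
    if v is None or (isinstance(v, float) and math.isnan(v)) or v == "":
        return None
    try:
        return float(v)
    except (TypeError, ValueError) as exc:
        raise ParseError(f"expected a number, got {v!r}: {exc}")


def _opt_str(v) -> str | None:
    if v is None or (isinstance(v, float) and math.isnan(v)) or v == "":
        return None
    return str(v)


def read_patient_table(path: str | Path) -> list[PatientRecord]:
    """Read a patient table back into records (lossless for written tables)."""
    path = Path(path)
    df = pd.read_csv(
        path,
        comment="#",
        dtype={"patient_id": str, "sex": str},
        float_precision="round_trip",
    )
    unknown = [c for c in df.columns if c not in PATIENT_TABLE_COLUMNS]
    if unknown:
        warnings.warn(f"ignoring unknown column(s): {', '.join(unknown)}")
    records: list[PatientRecord] = []
    for _, row in df.iterrows():
        rec = PatientRecord(patient_id=str(row["patient_id"]))
        for f in _SCALAR_FIELDS:
            if f in df.columns:
                val = row[f]
                setattr(rec, f, _opt_str(val) if f == "sex" else _opt_float(val))
        point_cols = [f"{p}_{ax}" for p in _POINT_NAMES for ax in ("x", "y")]
        if all(c in df.columns for c in point_cols):
            coords = {c: _opt_float(row[c]) for c in point_cols}
            if all(coords[f"{p}_{ax}"] is not None
                   for p in _POINT_NAMES if p != "p7" for ax in ("x", "y")):
                kw = {
                    p: Point2D(coords[f"{p}_x"], coords[f"{p}_y"])
                    for p in _POINT_NAMES
                    if p != "p7"
                }
                if coords["p7_x"] is not None and coords["p7_y"] is not None:
                    kw["p7"] = Point2D(coords["p7_x"], coords["p7_y"])
                rec.landmarks = ProfileLandmarks(**kw)
        if all(f in df.columns for f in _METRIC_FIELDS):
            vals = {f: _opt_float(row[f]) for f in _METRIC_FIELDS}
            if all(v is not None for v in vals.values()):
                rec.metrics = ProfileMetrics(**vals)
        if all(f in df.columns for f in _CLASS_FIELDS):
            vals = {f: _opt_str(row[f]) for f in _CLASS_FIELDS}
            if all(v is not None for v in vals.values()):
                rec.classification = ProfileClassification(**vals)
        records.append(rec)
    return records
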