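"""Hand-template coordinates, projected-field records, and file I/O.

A *projected field* is the region of the (phantom) hand where a sensation is
experienced when a current pulse is delivered through one nerve-cuff contact.
Participants report it on a fixed 2-D hand-template image; we store positions
in millimetres with the origin at the template's lower-left corner, x
rightward and y upward.

Two kinds of observation exist:

* threshold-level stimulation gives a highly localized percept, digitized as
  a single centroid point;
* maximum-level stimulation (the intensity used for daily feedback) gives an
  extended percept whose outline is drawn as a polygon.

The ordered sequence of threshold-level centroids for one participant and one
electrode contact forms a :class:`Trajectory`, the input to the drift test in
:mod:`fielddrift.drift_stats`.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import shapely.wkt
from shapely.geometry import Polygon as _ShapelyPolygon
from shapely.validation import explain_validity

from .errors import (
    GeometryError,
    InsufficientDataError,
    OrderingError,
    SchemaError,
)

Phase = Literal["pre_pairing", "post_pairing"]
StimLevel = Literal["threshold", "maximum"]

_PHASES = ("pre_pairing", "post_pairing")
_STIM_LEVELS = ("threshold", "maximum")

CSV_COLUMNS = (
    "participant_id",
    "session_time_days",
    "phase",
    "stim_level",
    "centroid_x_mm",
    "centroid_y_mm",
    "extent_wkt",
)


@dataclass(frozen=True)
class HandPoint:
    """A point on the hand template, in millimetres."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise SchemaError(f"hand point coordinates must be finite, got ({self.x}, {self.y})")


@dataclass(frozen=True)
class FieldExtentPolygon:
    """A drawn projected-field outline: a simple closed polygon with positive area.

    Vertices are an ordered ring; the closing edge back to the first vertex is
    implicit. Holes are not representable (drawn outlines are simple curves).
    """

    vertices: tuple[HandPoint, ...]

    def __post_init__(self) -> None:
        if len(self.vertices) < 3:
            raise GeometryError(f"polygon needs >= 3 vertices, got {len(self.vertices)}")
        object.__setattr__(self, "vertices", tuple(self.vertices))
        poly = self.to_shapely()
        if not poly.is_valid:
            raise GeometryError(f"invalid polygon: {explain_validity(poly)}")
        if poly.area <= 0.0:
            raise GeometryError("polygon area must be strictly positive")

    def to_shapely(self) -> _ShapelyPolygon:
        return _ShapelyPolygon([(p.x, p.y) for p in self.vertices])

    @classmethod
    def from_coords(cls, coords: Iterable[tuple[float, float]]) -> "FieldExtentPolygon":
        return cls(tuple(HandPoint(float(x), float(y)) for x, y in coords))


@dataclass(frozen=True)
class ProjectedFieldRecord:
    """One dated observation of where a stimulus was felt on the hand template.

    ``session_time`` is days since the participant's first mapping session.
    ``phase`` records whether the session happened before or after the
    feedback contact was paired with the prosthesis sensor; it is stored, not
    inferred, because the pairing date differs per participant.
    """

    participant_id: str
    session_time: float
    phase: Phase
    stim_level: StimLevel
    centroid: HandPoint | None = None
    extent: FieldExtentPolygon | None = None

    def __post_init__(self) -> None:
        if self.session_time < 0 or not math.isfinite(self.session_time):
            raise SchemaError(f"session_time must be finite and >= 0, got {self.session_time}")
        if self.phase not in _PHASES:
            raise SchemaError(f"phase must be one of {_PHASES}, got {self.phase!r}")
        if self.stim_level not in _STIM_LEVELS:
            raise SchemaError(f"stim_level must be one of {_STIM_LEVELS}, got {self.stim_level!r}")
        if self.stim_level == "threshold" and self.centroid is None:
            raise SchemaError("threshold-level records require a centroid")


@dataclass(frozen=True)
class Trajectory:
    """Time-ordered threshold-level observations for one participant."""

    participant_id: str
    records: tuple[ProjectedFieldRecord, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        times = [r.session_time for r in self.records]
        for a, b in zip(times, times[1:]):
            if b <= a:
                raise OrderingError(
                    f"session times must be strictly increasing, got {a} then {b}"
                )
        for r in self.records:
            if r.stim_level != "threshold":
                raise SchemaError("trajectories hold threshold-level records only")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def centroids(self) -> list[HandPoint]:
        return [r.centroid for r in self.records]  # type: ignore[misc]


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _record_to_row(rec: ProjectedFieldRecord) -> dict:
    return {
        "participant_id": rec.participant_id,
        "session_time_days": rec.session_time,
        "phase": rec.phase,
        "stim_level": rec.stim_level,
        "centroid_x_mm": rec.centroid.x if rec.centroid is not None else None,
        "centroid_y_mm": rec.centroid.y if rec.centroid is not None else None,
        "extent_wkt": rec.extent.to_shapely().wkt if rec.extent is not None else None,
    }


def _row_to_record(row: dict, line: int) -> ProjectedFieldRecord:
    def _num(key: str, required: bool) -> float | None:
        val = row.get(key)
        if val is None or val == "":
            if required:
                raise SchemaError(f"row {line}: missing required value for column '{key}'")
            return None
        try:
            return float(val)
        except (TypeError, ValueError) as exc:
            raise SchemaError(f"row {line}: column '{key}' is not numeric: {val!r}") from exc

    stim_level = row.get("stim_level")
    x = _num("centroid_x_mm", required=stim_level == "threshold")
    y = _num("centroid_y_mm", required=stim_level == "threshold")
    if (x is None) != (y is None):
        raise SchemaError(f"row {line}: centroid_x_mm and centroid_y_mm must both be set or both empty")
    centroid = HandPoint(x, y) if x is not None else None

    extent = None
    wkt = row.get("extent_wkt")
    if wkt not in (None, ""):
        try:
            poly = shapely.wkt.loads(wkt)
        except Exception as exc:
            raise SchemaError(f"row {line}: unparseable extent WKT: {wkt!r}") from exc
        if poly.geom_type != "Polygon":
            raise SchemaError(f"row {line}: extent must be a POLYGON, got {poly.geom_type}")
        extent = FieldExtentPolygon.from_coords(list(poly.exterior.coords)[:-1])

    st = _num("session_time_days", required=True)
    return ProjectedFieldRecord(
        participant_id=str(row["participant_id"]),
        session_time=st,
        phase=row.get("phase"),  # type: ignore[arg-type]
        stim_level=stim_level,  # type: ignore[arg-type]
        centroid=centroid,
        extent=extent,
    )


def _validate_ordering(records: Sequence[ProjectedFieldRecord]) -> None:
    """File rows must be nondecreasing in session_time within a participant,
    and every pre-pairing session must precede every post-pairing one."""
    last_time: dict[str, float] = {}
    max_pre: dict[str, float] = {}
    min_post: dict[str, float] = {}
    for rec in records:
        pid = rec.participant_id
        if pid in last_time and rec.session_time < last_time[pid]:
            raise OrderingError(
                f"participant {pid}: session_time {rec.session_time} after {last_time[pid]}"
            )
        last_time[pid] = rec.session_time
        if rec.phase == "pre_pairing":
            max_pre[pid] = max(max_pre.get(pid, -math.inf), rec.session_time)
        else:
            min_post[pid] = min(min_post.get(pid, math.inf), rec.session_time)
    for pid in max_pre:
        if pid in min_post and max_pre[pid] >= min_post[pid]:
            raise OrderingError(
                f"participant {pid}: pre_pairing sessions must all precede post_pairing sessions"
            )


def read_field_records(path: str | Path, format: str = "csv") -> list[ProjectedFieldRecord]:
    """Read projected-field records from a CSV or JSON file.

    CSV columns: participant_id, session_time_days, phase, stim_level,
    centroid_x_mm, centroid_y_mm, extent_wkt. JSON holds an array of objects
    with the same keys, except the extent is a list of ``[x, y]`` pairs.
    """
    path = Path(path)
    if format == "csv":
        import csv

        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            header = reader.fieldnames or []
            missing = [c for c in CSV_COLUMNS if c not in header]
            if missing:
                raise SchemaError(f"missing required column(s): {', '.join(missing)}")
            records = [_row_to_record(row, i + 2) for i, row in enumerate(reader)]
    elif format == "json":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        if not isinstance(payload, list):
            raise SchemaError("JSON payload must be an array of record objects")
        records = []
        for i, obj in enumerate(payload):
            missing = [c for c in CSV_COLUMNS[:4] if c not in obj]
            if missing:
                raise SchemaError(f"object {i}: missing required key(s): {', '.join(missing)}")
            row = dict(obj)
            extent = row.pop("extent", None)
            if extent:
                row["extent_wkt"] = _ShapelyPolygon(extent).wkt
            records.append(_row_to_record(row, i))
    else:
        raise ValueError(f"unknown format {format!r}; use 'csv' or 'json'")

    _validate_ordering(records)
    return records


def write_field_records(
    records: Sequence[ProjectedFieldRecord], path: str | Path, format: str = "csv"
) -> None:
    """Write records to CSV or JSON; output round-trips through
    :func:`read_field_records` with field-by-field equality and is byte-stable
    for identical input (floats use shortest round-trip repr)."""
    path = Path(path)
    rows = [_record_to_row(r) for r in records]
    if format == "csv":
        import csv

        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.DictWriter(fh, fieldnames=CSV_COLUMNS)
            writer.writeheader()
            for row in rows:
                writer.writerow({k: ("" if v is None else repr(v) if isinstance(v, float) else v)
                                 for k, v in row.items()})
    elif format == "json":
        out = []
        for rec, row in zip(records, rows):
            obj = {k: row[k] for k in CSV_COLUMNS[:6]}
            obj["extent"] = (
                [[p.x, p.y] for p in rec.extent.vertices] if rec.extent is not None else None
            )
            out.append(obj)
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(out, fh, indent=1)
            fh.write("\n")
    else:
        raise ValueError(f"unknown format {format!r}; use 'csv' or 'json'")


def trajectory_from_records(
    records: Iterable[ProjectedFieldRecord], participant_id: str
) -> Trajectory:
    """Extract one participant's threshold-level trajectory, sorted by session time.

    Raises :class:`InsufficientDataError` with fewer than two threshold-level
    records (no displacement can be formed), and :class:`OrderingError` on
    duplicate session times (ordering would be ambiguous).
    """
    sel = [
        r for r in records
        if r.participant_id == participant_id and r.stim_level == "threshold"
    ]
    if len(sel) < 2:
        raise InsufficientDataError(
            f"participant {participant_id}: need >= 2 threshold-level records, got {len(sel)}"
        )
    sel.sort(key=lambda r: r.session_time)
    return Trajectory(participant_id=participant_id, records=tuple(sel))


# ---------------------------------------------------------------------------
# Polygon geometry
# ---------------------------------------------------------------------------

def polygon_area(poly: FieldExtentPolygon) -> float:
    """Area of a field-extent polygon in mm², via the shoelace formula
    (orientation-independent)."""
    return poly.to_shapely().area


def polygon_overlap_fraction(a: FieldExtentPolygon, b: FieldExtentPolygon) -> float:
    """Jaccard overlap area(a ∩ b) / area(a ∪ b), in [0, 1] and symmetric.

    Used to quantify how congruent a projected-field extent is with the sensor
    footprint, or with the same extent measured at a later session.
    """
    sa, sb = a.to_shapely(), b.to_shapely()
    union = sa.union(sb).area
    if union <= 0.0:
        raise GeometryError("degenerate polygons: union has zero area")
    return sa.intersection(sb).area / union
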