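"""Projected-field records, trajectories, polygon geometry, and file I/O."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fielddrift import (
    FieldExtentPolygon,
    HandPoint,
    ProjectedFieldRecord,
    Trajectory,
    polygon_area,
    polygon_overlap_fraction,
    read_field_records,
    trajectory_from_records,
    write_field_records,
)
from fielddrift.errors import (
    GeometryError,
    InsufficientDataError,
    OrderingError,
    SchemaError,
)
from .conftest import make_record, trajectory_from_points


class TestRecordValidation:
    def test_threshold_record_requires_centroid(self):
        with pytest.raises(SchemaError, match="centroid"):
            ProjectedFieldRecord(
                participant_id="P1", session_time=0.0, phase="pre_pairing",
                stim_level="threshold", centroid=None,
            )

    def test_negative_session_time_rejected(self):
        with pytest.raises(SchemaError):
            make_record(t=-1.0)

    def test_nonfinite_point_rejected(self):
        with pytest.raises(SchemaError):
            HandPoint(math.nan, 0.0)

    def test_trajectory_rejects_duplicate_times(self):
        recs = (make_record(t=0.0), make_record(t=0.0, x=1.0))
        with pytest.raises(OrderingError):
            Trajectory(participant_id="P1", records=recs)

    def test_trajectory_rejects_maximum_level(self, unit_square):
        recs = (make_record(t=0.0),
                make_record(t=1.0, level="maximum", extent=unit_square))
        with pytest.raises(SchemaError):
            Trajectory(participant_id="P1", records=recs)


class TestRoundTrip:
    @pytest.mark.parametrize("fmt", ["csv", "json"])
    def test_write_read_identity(self, tmp_path, mixed_records, fmt):
        path = tmp_path / f"records.{fmt}"
        write_field_records(mixed_records, path, format=fmt)
        back = read_field_records(path, format=fmt)
        assert back == mixed_records

    def test_write_is_byte_stable(self, tmp_path, mixed_records):
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        write_field_records(mixed_records, p1, format="csv")
        write_field_records(mixed_records, p2, format="csv")
        assert p1.read_bytes() == p2.read_bytes()

    def test_empty_list_gives_header_only(self, tmp_path):
        path = tmp_path / "empty.csv"
        write_field_records([], path, format="csv")
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 1
        assert read_field_records(path, format="csv") == []

    def test_missing_column_names_it(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("participant_id,session_time_days\nP1,0\n")
        with pytest.raises(SchemaError, match="stim_level"):
            read_field_records(path, format="csv")

    def test_threshold_row_without_centroid_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "participant_id,session_time_days,phase,stim_level,"
            "centroid_x_mm,centroid_y_mm,extent_wkt\n"
            "P1,0,pre_pairing,threshold,,,\n"
        )
        with pytest.raises(SchemaError, match="centroid_x_mm"):
            read_field_records(path, format="csv")

    def test_non_monotone_session_time_rejected(self, tmp_path):
        recs = [make_record(t=10.0), make_record(t=5.0, x=1.0)]
        path = tmp_path / "bad.csv"
        write_field_records(recs, path, format="csv")
        with pytest.raises(OrderingError):
            read_field_records(path, format="csv")

    def test_post_pairing_before_pre_pairing_rejected(self, tmp_path):
        recs = [make_record(t=0.0, phase="post_pairing"),
                make_record(t=10.0, phase="pre_pairing", x=1.0)]
        path = tmp_path / "bad.csv"
        write_field_records(recs, path, format="csv")
        with pytest.raises(OrderingError, match="pre_pairing"):
            read_field_records(path, format="csv")


class TestTrajectoryFromRecords:
    def test_filters_to_threshold_level(self, mixed_records):
        traj = trajectory_from_records(mixed_records, "P1")
        assert len(traj) == 3
        assert all(r.stim_level == "threshold" for r in traj.records)

    def test_sorts_unsorted_input(self):
        recs = [make_record(t=60.0, x=2.0), make_record(t=0.0), make_record(t=30.0, x=1.0)]
        traj = trajectory_from_records(recs, "P1")
        assert [r.session_time for r in traj.records] == [0.0, 30.0, 60.0]

    def test_too_few_threshold_records(self, mixed_records):
        with pytest.raises(InsufficientDataError):
            trajectory_from_records(mixed_records, "P2")

    def test_duplicate_session_time_is_ordering_error(self):
        recs = [make_record(t=0.0), make_record(t=0.0, x=1.0)]
        with pytest.raises(OrderingError):
            trajectory_from_records(recs, "P1")


class TestPolygonGeometry:
    def test_unit_square_area(self, unit_square):
        assert polygon_area(unit_square) == pytest.approx(1.0)

    def test_area_orientation_invariant(self, unit_square):
        reversed_sq = FieldExtentPolygon(tuple(reversed(unit_square.vertices)))
        assert polygon_area(reversed_sq) == pytest.approx(1.0)

    def test_self_intersecting_rejected(self):
        with pytest.raises(GeometryError):
            FieldExtentPolygon.from_coords([(0, 0), (1, 1), (1, 0), (0, 1)])  # bowtie

    def test_too_few_vertices_rejected(self):
        with pytest.raises(GeometryError):
            FieldExtentPolygon.from_coords([(0, 0), (1, 0)])

    def test_irregular_quad_matches_rejection_sampling(self):
        # independent Monte Carlo point-in-polygon oracle
        coords = [(0.0, 0.0), (3.0, 0.5), (2.5, 2.5), (0.5, 2.0)]
        poly = FieldExtentPolygon.from_coords(coords)
        from shapely.geometry import Point, Polygon

        sp = Polygon(coords)
        rng = np.random.default_rng(0)
        pts = rng.uniform([0, 0], [3, 2.5], size=(200_000, 2))
        frac = np.mean([sp.contains(Point(x, y)) for x, y in pts])
        mc_area = frac * 3.0 * 2.5
        assert polygon_area(poly) == pytest.approx(mc_area, rel=0.01)

    def test_overlap_identical_is_one(self, unit_square):
        assert polygon_overlap_fraction(unit_square, unit_square) == pytest.approx(1.0)

    def test_overlap_disjoint_is_zero(self, unit_square):
        far = FieldExtentPolygon.from_coords([(10, 10), (11, 10), (11, 11), (10, 11)])
        assert polygon_overlap_fraction(unit_square, far) == 0.0

    @pytest.mark.parametrize(
        "dx,dy,expected",
        [
            (0.5, 0.0, 0.5 / 1.5),     # intersection 0.5, union 1.5
            (0.5, 0.5, 0.25 / 1.75),   # intersection 0.25, union 1.75
        ],
    )
    def test_overlap_offset_squares(self, unit_square, dx, dy, expected):
        shifted = FieldExtentPolygon.from_coords(
            [(dx, dy), (1 + dx, dy), (1 + dx, 1 + dy), (dx, 1 + dy)]
        )
        got = polygon_overlap_fraction(unit_square, shifted)
        assert got == pytest.approx(expected)
        assert got == pytest.approx(polygon_overlap_fraction(shifted, unit_square))

    @settings(deadline=None, max_examples=50)
    @given(
        dx=st.floats(-50, 50), dy=st.floats(-50, 50),
        angle=st.floats(0, 2 * math.pi),
    )
    def test_area_rigid_motion_invariant(self, dx, dy, angle):
        coords = [(0.0, 0.0), (3.0, 0.5), (2.5, 2.5), (0.5, 2.0)]
        c, s = math.cos(angle), math.sin(angle)
        moved = [(c * x - s * y + dx, s * x + c * y + dy) for x, y in coords]
        a0 = polygon_area(FieldExtentPolygon.from_coords(coords))
        a1 = polygon_area(FieldExtentPolygon.from_coords(moved))
        assert a1 == pytest.approx(a0, rel=1e-9)
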