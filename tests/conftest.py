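import numpy as np
import pytest
from hypothesis import settings

# property tests must be reproducible run to run
settings.register_profile("deterministic", deadline=None, derandomize=True)
settings.load_profile("deterministic")

from fielddrift import (
    DriftModelParams,
    FieldExtentPolygon,
    HandPoint,
    ProjectedFieldRecord,
    Trajectory,
    simulate_trajectory,
)


@pytest.fixture
def unit_square() -> FieldExtentPolygon:
    return FieldExtentPolygon.from_coords([(0, 0), (1, 0), (1, 1), (0, 1)])


def make_record(pid="P1", t=0.0, phase="pre_pairing", level="threshold",
                x=0.0, y=0.0, extent=None) -> ProjectedFieldRecord:
    centroid = HandPoint(x, y) if level == "threshold" or x is not None else None
    return ProjectedFieldRecord(
        participant_id=pid, session_time=t, phase=phase, stim_level=level,
        centroid=centroid, extent=extent,
    )


@pytest.fixture
def mixed_records(unit_square):
    """Five records for P1 (3 threshold + 2 maximum) and one for P2."""
    return [
        make_record(t=0.0, x=0.0, y=0.0),
        make_record(t=10.0, level="maximum", extent=unit_square),
        make_record(t=30.0, x=1.0, y=0.0),
        make_record(t=60.0, phase="post_pairing", x=1.0, y=1.0),
        make_record(t=90.0, phase="post_pairing", level="maximum", extent=unit_square),
        make_record(pid="P2", t=0.0, x=5.0, y=5.0),
    ]


def trajectory_from_points(points, pid="P1") -> Trajectory:
    records = tuple(
        make_record(pid=pid, t=30.0 * i, x=float(x), y=float(y))
        for i, (x, y) in enumerate(points)
    )
    return Trajectory(participant_id=pid, records=records)


@pytest.fixture
def null_trajectory() -> Trajectory:
    params = DriftModelParams(
        start=HandPoint(0, 0), target=HandPoint(10, 0),
        kappa=0.0, step_scale=0.5, n_points=12, seed=42,
    )
    return simulate_trajectory(params)
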