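"""Seeded generators for every input the analysis pipeline consumes.

The study's inputs — projected-field mapping sessions, prosthesis force-sensor
traces, daily usage logs, and a psychophysical observer — are emulated here so
the whole pipeline is testable without the deposited data. All generators are
pure functions of (parameters, seed).

Trajectory model
----------------
Projected-field centroids follow a random walk. Step lengths are half-normal
with scale ``step_scale`` (default 0.5 mm, matching session-to-session
movement of "typically a millimeter or less"). Step directions are von Mises
with concentration ``kappa`` about the instantaneous bearing toward a target
point (the sensor-congruent location): kappa = 0 reduces exactly to
Uniform(0, 2π) — the no-migration null — while growing kappa gives
increasingly directed drift toward the target. This is the simplest
one-parameter alternative family nesting the isotropic null.

Sessions are spaced 30 days apart by default (mapping sessions were weeks to
months apart).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import SchemaError
from .hand_map import HandPoint, ProjectedFieldRecord, Trajectory

#: Default half-normal scale of step lengths, mm.
DEFAULT_STEP_SCALE_MM = 0.5
#: Default spacing between mapping sessions, days.
DEFAULT_SESSION_SPACING_DAYS = 30.0


@dataclass(frozen=True)
class DriftModelParams:
    """Parameters of the projected-field random-walk generator."""

    start: HandPoint
    target: HandPoint
    kappa: float
    step_scale: float
    n_points: int
    seed: int
    session_spacing_days: float = DEFAULT_SESSION_SPACING_DAYS
    participant_id: str = "sim"
    pairing_after_point: int | None = None  # records at or after this index are post_pairing

    def __post_init__(self) -> None:
        if self.kappa < 0:
            raise ValueError(f"kappa must be >= 0, got {self.kappa}")
        if self.step_scale <= 0:
            raise ValueError(f"step_scale must be > 0, got {self.step_scale}")
        if self.n_points < 2:
            raise ValueError(f"n_points must be >= 2, got {self.n_points}")
        if self.session_spacing_days <= 0:
            raise ValueError("session_spacing_days must be > 0")


def simulate_trajectory(params: DriftModelParams) -> Trajectory:
    """Simulate one projected-field trajectory.

    Observations sit at session times 0, s, 2s, ... (s = session spacing).
    Each step has half-normal length and von Mises direction centred on the
    bearing from the current point to the target; kappa = 0 gives isotropic
    directions regardless of the target.
    """
    rng = np.random.default_rng(params.seed)
    split = params.pairing_after_point if params.pairing_after_point is not None else params.n_points
    pts = [params.start]
    x, y = params.start.x, params.start.y
    for _ in range(params.n_points - 1):
        length = abs(rng.normal(0.0, params.step_scale))
        if params.kappa == 0.0:
            theta = rng.uniform(0.0, 2.0 * math.pi)
        else:
            bearing = math.atan2(params.target.y - y, params.target.x - x)
            theta = rng.vonmises(bearing, params.kappa)
        x += length * math.cos(theta)
        y += length * math.sin(theta)
        pts.append(HandPoint(x, y))
    records = tuple(
        ProjectedFieldRecord(
            participant_id=params.participant_id,
            session_time=i * params.session_spacing_days,
            phase="pre_pairing" if i < split else "post_pairing",
            stim_level="threshold",
            centroid=p,
        )
        for i, p in enumerate(pts)
    )
    return Trajectory(participant_id=params.participant_id, records=records)


def simulate_force_trace(
    duration_s: float,
    contact_rate_per_min: float,
    mean_contact_s: float,
    readout_max: float,
    sample_ms: float = 10.0,
    seed: int = 0,
):
    """Simulate a prosthetic thumb force-sensor trace.

    Contact onsets arrive as a Poisson process at ``contact_rate_per_min``;
    each contact is a trapezoidal force profile (10% rise, plateau, 10% fall)
    with exponential duration of mean ``mean_contact_s`` and a plateau level
    uniform on [0.3, 1.0] × readout_max. Contacts never overlap: the next
    onset is drawn after the previous release. Between contacts the readout
    is exactly zero.
    """
    if duration_s <= 0 or mean_contact_s <= 0 or readout_max <= 0 or sample_ms <= 0:
        raise ValueError("duration_s, mean_contact_s, readout_max and sample_ms must be > 0")
    if contact_rate_per_min < 0:
        raise ValueError("contact_rate_per_min must be >= 0")

    from .stim_encoder import ForceTrace

    dt = sample_ms / 1000.0
    n = int(round(duration_s / dt))
    readouts = np.zeros(n, dtype=float)
    if contact_rate_per_min > 0:
        rng = np.random.default_rng(seed)
        rate_per_s = contact_rate_per_min / 60.0
        t = rng.exponential(1.0 / rate_per_s)
        while t < duration_s:
            dur = rng.exponential(mean_contact_s)
            peak = rng.uniform(0.3, 1.0) * readout_max
            _add_trapezoid(readouts, dt, t, dur, peak, readout_max)
            t = t + dur + rng.exponential(1.0 / rate_per_s)
    return ForceTrace(readouts=readouts, readout_max=readout_max, sample_period_ms=sample_ms)


def _add_trapezoid(
    readouts: np.ndarray, dt: float, onset_s: float, dur_s: float, peak: float, cap: float
) -> None:
    i0 = int(math.ceil(onset_s / dt))
    i1 = min(int(math.floor((onset_s + dur_s) / dt)), readouts.size - 1)
    if i1 < i0:
        return
    n = i1 - i0 + 1
    ramp = max(1, int(round(0.1 * n)))
    profile = np.full(n, peak)
    profile[:ramp] = np.linspace(peak / ramp, peak, ramp)
    profile[n - ramp:] = np.linspace(peak, peak / ramp, ramp)
    readouts[i0 : i1 + 1] = np.minimum(profile, cap)


def simulate_usage_log(
    n_days: int,
    mean_wear_h: float,
    mean_actuation_min: float,
    mean_stim_min: float,
    seed: int = 0,
    cv: float = 0.3,
    participant_id: str = "sim",
):
    """Simulate a daily usage log for one participant.

    Per-day wear hours, actuation minutes and stimulation minutes are drawn
    from independent gamma distributions with the stated means and a common
    coefficient of variation ``cv`` (default 0.3, a plausible day-to-day
    spread for habitual prosthesis wear; cv = 0 gives constant values).
    Wear time is clipped to [0, 24] h, and actuation/stimulation are clipped
    so neither exceeds the day's wear time.
    """
    from .usage_analytics import UsageLog

    if n_days < 1:
        raise ValueError(f"n_days must be >= 1, got {n_days}")
    for name, v in (("mean_wear_h", mean_wear_h), ("mean_actuation_min", mean_actuation_min),
                    ("mean_stim_min", mean_stim_min)):
        if v < 0:
            raise ValueError(f"{name} must be >= 0, got {v}")
    if cv < 0:
        raise ValueError(f"cv must be >= 0, got {cv}")

    rng = np.random.default_rng(seed)

    def draw(mean: float) -> np.ndarray:
        if mean == 0 or cv == 0:
            return np.full(n_days, float(mean))
        shape = 1.0 / cv**2
        return rng.gamma(shape, mean / shape, size=n_days)

    wear = np.clip(draw(mean_wear_h), 0.0, 24.0)
    actuation = np.minimum(draw(mean_actuation_min), wear * 60.0)
    stim = np.minimum(draw(mean_stim_min), wear * 60.0)
    return UsageLog.from_arrays(participant_id, wear, actuation, stim)


@dataclass(frozen=True)
class SimulatedSubject:
    """A deterministic psychophysical observer with a fixed detection threshold.

    Reports feeling a single stimulation pulse iff its charge (nC) is at or
    above ``threshold_charge``. A step-function psychometric curve — adequate
    for testing threshold-search procedures, not for modelling response noise.
    """

    threshold_charge: float

    def __post_init__(self) -> None:
        if not (self.threshold_charge > 0):
            raise SchemaError(
                f"threshold_charge must be > 0, got {self.threshold_charge}"
            )

    def feels(self, charge_nc: float) -> bool:
        return charge_nc >= self.threshold_charge


def make_subject(threshold_charge: float) -> SimulatedSubject:
    """Construct a deterministic simulated subject (threshold in nC, > 0)."""
    return SimulatedSubject(threshold_charge=threshold_charge)
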