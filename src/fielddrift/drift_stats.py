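"""Distance-weighted vector strength and its Monte Carlo uniform-direction null.

The scientific question: does a projected field *migrate* over months of
mismatched visuo-tactile experience, or does it merely jitter? Each pair of
consecutive mapping sessions yields a displacement step with distance ``d_j``
(mm) and direction ``theta_j`` (radians). Systematic migration means the
directions share a common component; measurement jitter means they are
isotropic.

The test statistic is the distance-weighted vector strength

    vs = sqrt[(Σ_j d_j sin θ_j)² + (Σ_j d_j cos θ_j)²] / Σ_j d_j

i.e. the length of the resultant of the step vectors divided by the total
path length: 1 when every (nonzero) step points the same way, near 0 when
directions cancel. The null distribution is obtained by Monte Carlo: keep the
observed distances d_j, redraw each direction i.i.d. Uniform(0, 2π), and
recompute vs; the p-value is the upper-tail proportion with an add-one
correction so it is never exactly zero.

Distances are held fixed under the null by design: conditioning on the
observed step sizes isolates the directional structure, which is what
distinguishes migration from jitter. The statistic is invariant to a common
rescaling of all d_j and to a common rotation of all θ_j, so neither the
digitization scale of the hand template nor its orientation affects the test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import InsufficientDataError, UndefinedStatisticError
from .hand_map import Trajectory

TWO_PI = 2.0 * math.pi

#: Monte Carlo resamples used by default for the null distribution.
DEFAULT_N_MC = 10_000


@dataclass(frozen=True)
class Displacement:
    """One trajectory step: distance in mm and direction in radians [0, 2π).

    Directions follow the mathematical convention: 0 along +x, increasing
    counterclockwise.
    """

    d: float
    theta: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.d) and self.d >= 0.0):
            raise ValueError(f"step distance must be finite and >= 0, got {self.d}")
        if not math.isfinite(self.theta):
            raise ValueError(f"step direction must be finite, got {self.theta}")
        object.__setattr__(self, "theta", self.theta % TWO_PI)


@dataclass(frozen=True)
class VectorStrengthResult:
    """Observed vector strength with its Monte Carlo null summary.

    ``p_value`` is the one-sided, add-one-corrected upper-tail probability
    P(null vs >= observed vs); small values indicate directed drift.
    ``prop_null_below`` is the complementary lower-tail proportion, exposed
    because the two tails are easy to confuse when reading reports.
    """

    vs: float
    n_steps: int
    p_value: float
    n_mc: int
    seed: int
    null_vs_quantiles: tuple[float, float, float]  # 5%, 50%, 95%
    prop_null_below: float

    def __post_init__(self) -> None:
        assert 0.0 <= self.vs <= 1.0 + 1e-12
        assert 0.0 < self.p_value <= 1.0
        assert self.n_mc >= 1

    def to_dict(self) -> dict:
        return {
            "vs": self.vs,
            "n_steps": self.n_steps,
            "p_value": self.p_value,
            "n_mc": self.n_mc,
            "seed": self.seed,
            "null_quantiles": list(self.null_vs_quantiles),
            "prop_null_below": self.prop_null_below,
        }


def displacements(traj: Trajectory) -> list[Displacement]:
    """Consecutive-session displacement steps of a trajectory.

    Returns n−1 steps for n observations: d_j is the Euclidean distance
    between consecutive centroids and θ_j = atan2(Δy, Δx) wrapped to [0, 2π).
    """
    if len(traj) < 2:
        raise InsufficientDataError(
            f"need >= 2 observations to form displacements, got {len(traj)}"
        )
    pts = traj.centroids
    out = []
    for a, b in zip(pts, pts[1:]):
        dx, dy = b.x - a.x, b.y - a.y
        out.append(Displacement(d=math.hypot(dx, dy), theta=math.atan2(dy, dx)))
    return out


def _d_theta_arrays(disps: list[Displacement]) -> tuple[np.ndarray, np.ndarray]:
    if not disps:
        raise InsufficientDataError("need >= 1 displacement")
    d = np.array([s.d for s in disps], dtype=float)
    theta = np.array([s.theta for s in disps], dtype=float)
    if d.sum() <= 0.0:
        raise UndefinedStatisticError(
            "all steps have zero length; vector strength is undefined"
        )
    return d, theta


def vector_strength(disps: list[Displacement]) -> float:
    """Distance-weighted vector strength of a set of displacement steps.

    Equals the resultant length of the step vectors over the total path
    length; lies in [0, 1], reaching 1 iff all nonzero steps share one
    direction. Undefined (raises) when every step has zero length.
    """
    d, theta = _d_theta_arrays(disps)
    s = float(np.dot(d, np.sin(theta)))
    c = float(np.dot(d, np.cos(theta)))
    vs = math.hypot(s, c) / float(d.sum())
    return float(_snap_to_unit(vs))


def _snap_to_unit(vs):
    """Clamp to [0, 1] and snap values within 1e-12 of 1 to exactly 1.

    A single step (or perfectly collinear steps) has vs = 1 analytically, but
    floating point can yield 1 ± a few ulp; snapping preserves the guarantee
    that the degenerate one-step test always reports p = 1.
    """
    return np.where(np.asarray(vs) > 1.0 - 1e-12, 1.0, np.minimum(vs, 1.0))[()]


def mc_null(disps: list[Displacement], n_mc: int, seed: int) -> np.ndarray:
    """Null distribution of the vector strength under isotropic directions.

    Keeps the observed distances d_j and pairs them with i.i.d.
    Uniform(0, 2π) directions, n_mc times. Fully reproducible given seed.
    """
    if n_mc < 1:
        raise ValueError(f"n_mc must be >= 1, got {n_mc}")
    d, _ = _d_theta_arrays(disps)
    rng = np.random.default_rng(seed)
    theta = rng.uniform(0.0, TWO_PI, size=(n_mc, d.size))
    s = np.sin(theta) @ d
    c = np.cos(theta) @ d
    return _snap_to_unit(np.hypot(s, c) / d.sum())


def vs_pvalue(vs_obs: float, null_vs: np.ndarray) -> float:
    """Upper-tail Monte Carlo p-value with add-one correction.

    p = (1 + #{null >= observed}) / (n_mc + 1). Ties count toward the tail
    (conservative); the add-one correction keeps p in (0, 1].
    """
    null_vs = np.asarray(null_vs, dtype=float)
    if null_vs.size == 0:
        raise ValueError("null distribution is empty")
    n_ge = int(np.count_nonzero(null_vs >= vs_obs))
    return (1 + n_ge) / (null_vs.size + 1)


def drift_test(traj: Trajectory, n_mc: int = DEFAULT_N_MC, seed: int = 0) -> VectorStrengthResult:
    """Test a projected-field trajectory for directed drift.

    Composes :func:`displacements` → :func:`vector_strength` →
    :func:`mc_null` → :func:`vs_pvalue` and records the seed and resample
    count for reproducibility. A single-step trajectory always yields
    vs = 1 and p = 1: the test has no power with one step.
    """
    disps = displacements(traj)
    vs = vector_strength(disps)
    null = mc_null(disps, n_mc=n_mc, seed=seed)
    p = vs_pvalue(vs, null)
    q05, q50, q95 = np.quantile(null, [0.05, 0.50, 0.95])
    prop_below = float(np.count_nonzero(null < vs)) / null.size
    return VectorStrengthResult(
        vs=vs,
        n_steps=len(disps),
        p_value=p,
        n_mc=n_mc,
        seed=seed,
        null_vs_quantiles=(float(q05), float(q50), float(q95)),
        prop_null_below=prop_below,
    )


@dataclass(frozen=True)
class PolarSummary:
    """Directional histogram of displacement steps (for polar plots).

    ``bin_edges`` has n_bins+1 entries covering [0, 2π); bins are half-open
    [lo, hi). ``mean_distance`` is NaN for empty bins.
    """

    bin_edges: np.ndarray
    counts: np.ndarray
    mean_distance: np.ndarray = field(repr=False)


def polar_summary(disps: list[Displacement], n_bins: int) -> PolarSummary:
    """Bin step directions into equal-width half-open bins starting at 0.

    Counts sum to the number of displacements; each bin also reports the mean
    step distance of the steps it contains.
    """
    if n_bins < 1:
        raise ValueError(f"n_bins must be >= 1, got {n_bins}")
    edges = np.linspace(0.0, TWO_PI, n_bins + 1)
    counts = np.zeros(n_bins, dtype=int)
    sums = np.zeros(n_bins, dtype=float)
    for s in disps:
        idx = min(int(s.theta / TWO_PI * n_bins), n_bins - 1)
        counts[idx] += 1
        sums[idx] += s.d
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return PolarSummary(bin_edges=edges, counts=counts, mean_distance=means)


def step_size_summary(disps: list[Displacement]) -> tuple[float, float]:
    """Median and maximum step distance (mm) — exact order statistics."""
    if not disps:
        raise InsufficientDataError("need >= 1 displacement")
    d = np.array([s.d for s in disps], dtype=float)
    return float(np.median(d)), float(d.max())


def calibrate_test(
    n_steps: int,
    drift_kappa: float,
    step_scale: float,
    n_sims: int,
    alpha: float = 0.05,
    n_mc: int = DEFAULT_N_MC,
    seed: int = 0,
) -> float:
    """Empirical rejection rate of the drift test over simulated trajectories.

    Simulates ``n_sims`` trajectories with ``n_steps`` steps each under the
    drift model of :mod:`fielddrift.synthetic_data` (kappa = 0 is the
    uniform-direction null, so the return value estimates the type-I error
    rate; kappa > 0 estimates power against drift of that concentration) and
    returns the fraction with p <= alpha. Child seeds for the simulations and
    the Monte Carlo nulls are spawned deterministically from ``seed``.
    """
    if n_steps < 1 or n_sims < 1 or n_mc < 1:
        raise ValueError("n_steps, n_sims and n_mc must all be >= 1")
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")

    from .synthetic_data import DriftModelParams, simulate_trajectory
    from .hand_map import HandPoint

    ss = np.random.SeedSequence(seed)
    children = ss.spawn(2 * n_sims)
    n_reject = 0
    for i in range(n_sims):
        sim_seed = int(children[2 * i].generate_state(1)[0] % (2**31))
        mc_seed = int(children[2 * i + 1].generate_state(1)[0] % (2**31))
        params = DriftModelParams(
            start=HandPoint(0.0, 0.0),
            target=HandPoint(10.0, 0.0),
            kappa=drift_kappa,
            step_scale=step_scale,
            n_points=n_steps + 1,
            seed=sim_seed,
        )
        traj = simulate_trajectory(params)
        res = drift_test(traj, n_mc=n_mc, seed=mc_seed)
        if res.p_value <= alpha:
            n_reject += 1
    return n_reject / n_sims
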