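"""Summaries of home-use logs: wear, actuation, and stimulation time.

The prosthesis logs, per day: hours worn, minutes of hand actuation, and
minutes of nerve stimulation. The summaries here mirror how such logs are
reported — mean daily values, cumulative curves over the study, and the
distribution of stimulation frequencies over the encoder's 100-ms epochs.

All logged days enter the means, including zero-wear days; the alternative
(excluding non-wear days) is computable by filtering the underlying frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InsufficientDataError
from .stim_encoder import FREQ_MAX_HZ, FREQ_MIN_HZ, StimulationTrain

USAGE_CSV_COLUMNS = ("participant_id", "day_index", "wear_h", "actuation_min", "stimulation_min")


@dataclass(frozen=True)
class UsageLog:
    """Per-day usage records for one participant.

    ``days`` is a DataFrame with columns day_index, wear_h, actuation_min,
    stimulation_min; wear_h lies in [0, 24] and neither actuation nor
    stimulation can exceed the day's wear time.
    """

    participant_id: str
    days: pd.DataFrame

    def __post_init__(self) -> None:
        required = set(USAGE_CSV_COLUMNS) - {"participant_id"}
        missing = required - set(self.days.columns)
        if missing:
            raise ValueError(f"usage frame missing column(s): {sorted(missing)}")
        d = self.days
        if len(d) == 0:
            raise InsufficientDataError("usage log must contain at least one day")
        if (d["wear_h"] < 0).any() or (d["wear_h"] > 24).any():
            raise ValueError("wear_h must lie in [0, 24]")
        if (d["actuation_min"] < 0).any() or (d["stimulation_min"] < 0).any():
            raise ValueError("actuation_min and stimulation_min must be >= 0")
        wear_min = d["wear_h"] * 60.0
        if (d["actuation_min"] > wear_min + 1e-9).any() or (d["stimulation_min"] > wear_min + 1e-9).any():
            raise ValueError("actuation and stimulation cannot exceed wear time")

    @classmethod
    def from_arrays(
        cls,
        participant_id: str,
        wear_h: np.ndarray,
        actuation_min: np.ndarray,
        stimulation_min: np.ndarray,
    ) -> "UsageLog":
        frame = pd.DataFrame(
            {
                "day_index": np.arange(len(wear_h)),
                "wear_h": np.asarray(wear_h, dtype=float),
                "actuation_min": np.asarray(actuation_min, dtype=float),
                "stimulation_min": np.asarray(stimulation_min, dtype=float),
            }
        )
        return cls(participant_id=participant_id, days=frame)

    def to_csv(self, path) -> None:
        out = self.days.copy()
        out.insert(0, "participant_id", self.participant_id)
        out.to_csv(path, index=False, columns=list(USAGE_CSV_COLUMNS))

    @classmethod
    def read_csv(cls, path) -> list["UsageLog"]:
        frame = pd.read_csv(path)
        missing = set(USAGE_CSV_COLUMNS) - set(frame.columns)
        if missing:
            raise ValueError(f"usage CSV missing column(s): {sorted(missing)}")
        return [
            cls(participant_id=str(pid), days=g.drop(columns="participant_id").reset_index(drop=True))
            for pid, g in frame.groupby("participant_id", sort=True)
        ]


def mean_daily_usage(log: UsageLog) -> float:
    """Mean daily wear time in hours over all logged days."""
    return float(log.days["wear_h"].mean())


def mean_daily_stimulation(log: UsageLog) -> float:
    """Mean daily nerve-stimulation time in minutes over all logged days."""
    return float(log.days["stimulation_min"].mean())


def cumulative_curves(log: UsageLog) -> pd.DataFrame:
    """Running totals of actuation and stimulation minutes over study days.

    Returns a frame with day_index, cumulative_actuation_min and
    cumulative_stimulation_min; both curves are nondecreasing and their final
    values equal the column totals.
    """
    d = log.days.sort_values("day_index")
    return pd.DataFrame(
        {
            "day_index": d["day_index"].to_numpy(),
            "cumulative_actuation_min": d["actuation_min"].cumsum().to_numpy(),
            "cumulative_stimulation_min": d["stimulation_min"].cumsum().to_numpy(),
        }
    )


def epoch_frequency_distribution(
    trains: list[StimulationTrain], n_bins: int = 25
) -> tuple[np.ndarray, np.ndarray, float]:
    """Histogram and median of ON-epoch stimulation frequencies.

    Pools the 100-ms epochs of all trains, drops OFF epochs, and bins the
    remaining frequencies over [5, 30] Hz. Returns (counts, bin_edges,
    median); counts sum to the number of ON epochs and the median is the
    exact order statistic.
    """
    freqs = np.array(
        [e.frequency_hz for train in trains for e in train.epochs if e.on], dtype=float
    )
    if freqs.size == 0:
        raise InsufficientDataError("no ON epochs in any train")
    counts, edges = np.histogram(freqs, bins=n_bins, range=(FREQ_MIN_HZ, FREQ_MAX_HZ))
    return counts, edges, float(np.median(freqs))
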