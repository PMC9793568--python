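"""Closed-loop tactile feedback: force readout → pulse-frequency stimulation.

The prosthetic thumb carries force sensors whose averaged readout drives
electrical stimulation of the residual nerve through one cuff-electrode
contact. Perceived touch magnitude is conveyed by pulse rate: the readout is
mapped linearly onto [5, 30] Hz while in contact, stimulation stops on
release or after 5 s of continuous contact (a safety cap), and each pulse is
a cathodic-first, charge-balanced, asymmetric (10:1) biphasic waveform with a
50 µs interphase delay.

This module simulates that channel: the linear mapping, the 100-ms epoch
encoder with the safety cap, pulse charge arithmetic, the ascending-limits
perceptual-threshold search, and lowest-charge feedback-contact selection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ThresholdNotFoundError
from .synthetic_data import SimulatedSubject

#: Pulse-frequency range conveying contact force, Hz.
FREQ_MIN_HZ = 5.0
FREQ_MAX_HZ = 30.0
#: Safety cap on continuous stimulation within one contact event, s.
STIM_CAP_S = 5.0
#: Encoder epoch length, ms.
EPOCH_MS = 100.0
#: Fixed interphase delay of the biphasic pulse, µs.
INTERPHASE_DELAY_US = 50.0
#: Anodic:cathodic width ratio of the asymmetric charge-balanced pulse.
ASYMMETRY_RATIO = 10.0


@dataclass(frozen=True)
class ForceTrace:
    """A uniformly sampled force-sensor readout sequence.

    ``readouts`` are averaged-sensor values in [0, readout_max]; the absolute
    units are a device calibration, so the encoder treats readouts as a
    normalized scale with ``readout_max`` as its ceiling.
    """

    readouts: np.ndarray
    readout_max: float
    sample_period_ms: float = 10.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "readouts", np.asarray(self.readouts, dtype=float))
        if self.readout_max <= 0:
            raise ValueError(f"readout_max must be > 0, got {self.readout_max}")
        if self.sample_period_ms <= 0:
            raise ValueError(f"sample_period_ms must be > 0, got {self.sample_period_ms}")
        r = self.readouts
        if r.size and (r.min() < 0 or r.max() > self.readout_max):
            raise ValueError("readouts must lie within [0, readout_max]")

    @property
    def duration_s(self) -> float:
        return self.readouts.size * self.sample_period_ms / 1000.0


@dataclass(frozen=True)
class PulseSpec:
    """A cathodic-first, charge-balanced, current-controlled biphasic pulse.

    Only the cathodic phase is free; the anodic phase is 10× wider at 1/10
    the amplitude, so the two phases carry exactly equal charge.
    """

    cathodic_amplitude_ua: float
    cathodic_width_us: float
    interphase_delay_us: float = INTERPHASE_DELAY_US
    asymmetry_ratio: float = ASYMMETRY_RATIO

    def __post_init__(self) -> None:
        if self.cathodic_amplitude_ua <= 0 or self.cathodic_width_us <= 0:
            raise ValueError("cathodic amplitude and width must be > 0")

    @property
    def anodic_amplitude_ua(self) -> float:
        return self.cathodic_amplitude_ua / self.asymmetry_ratio

    @property
    def anodic_width_us(self) -> float:
        return self.cathodic_width_us * self.asymmetry_ratio


@dataclass(frozen=True)
class StimulationEpoch:
    """One 100-ms encoder epoch: frequency 0 (off) or within [5, 30] Hz."""

    start_time_s: float
    frequency_hz: float
    duration_ms: float = EPOCH_MS

    def __post_init__(self) -> None:
        f = self.frequency_hz
        if f != 0.0 and not (FREQ_MIN_HZ <= f <= FREQ_MAX_HZ):
            raise ValueError(f"epoch frequency must be 0 or in [5, 30] Hz, got {f}")

    @property
    def on(self) -> bool:
        return self.frequency_hz > 0.0


@dataclass(frozen=True)
class StimulationTrain:
    """Time-ordered, non-overlapping epochs plus the pulse waveform spec."""

    epochs: tuple[StimulationEpoch, ...]
    pulse_spec: PulseSpec = field(default_factory=lambda: PulseSpec(100.0, 200.0))

    def __post_init__(self) -> None:
        object.__setattr__(self, "epochs", tuple(self.epochs))
        prev_end = -math.inf
        for e in self.epochs:
            if e.start_time_s < prev_end - 1e-9:
                raise ValueError("epochs must be time-ordered and non-overlapping")
            prev_end = e.start_time_s + e.duration_ms / 1000.0

    @property
    def on_epochs(self) -> list[StimulationEpoch]:
        return [e for e in self.epochs if e.on]

    @property
    def total_on_time_s(self) -> float:
        return sum(e.duration_ms for e in self.on_epochs) / 1000.0


def force_to_frequency(readout: float, readout_max: float, in_contact: bool = True) -> float:
    """Linear force-to-frequency mapping of the feedback channel.

    While in contact, readout r maps to 5 + 25·(r / readout_max) Hz, so the
    lightest detected contact (r = 0) already stimulates at 5 Hz and a
    full-scale readout gives 30 Hz. Out of contact the output is 0 Hz.
    Contact detection itself is the caller's job (see :func:`encode_contact`).
    """
    if readout_max <= 0:
        raise ValueError(f"readout_max must be > 0, got {readout_max}")
    if not (0.0 <= readout <= readout_max):
        raise ValueError(f"readout {readout} outside [0, {readout_max}]")
    if not in_contact:
        return 0.0
    return FREQ_MIN_HZ + (FREQ_MAX_HZ - FREQ_MIN_HZ) * (readout / readout_max)


def encode_contact(trace: ForceTrace, deadband: float = 0.0) -> StimulationTrain:
    """Encode a force trace into a 100-ms-epoch stimulation train.

    Samples with readout > ``deadband`` are in contact. Each maximal run of
    in-contact samples is one contact event; its epochs are half-open 100-ms
    windows anchored at the event onset, each carrying the frequency mapped
    from the epoch-mean readout. Within an event, stimulation is capped at
    5 s: epochs past the cap are emitted at 0 Hz until release, and the cap
    re-arms on the next contact event.
    """
    dt_ms = trace.sample_period_ms
    samples_per_epoch = max(1, int(round(EPOCH_MS / dt_ms)))
    cap_epochs = int(round(STIM_CAP_S * 1000.0 / EPOCH_MS))

    in_contact = trace.readouts > deadband
    epochs: list[StimulationEpoch] = []
    i = 0
    n = trace.readouts.size
    while i < n:
        if not in_contact[i]:
            i += 1
            continue
        j = i
        while j < n and in_contact[j]:
            j += 1
        # contact event spans samples [i, j)
        onset_s = i * dt_ms / 1000.0
        for k, lo in enumerate(range(i, j, samples_per_epoch)):
            hi = min(lo + samples_per_epoch, j)
            if k < cap_epochs:
                mean_r = float(trace.readouts[lo:hi].mean())
                freq = force_to_frequency(min(mean_r, trace.readout_max), trace.readout_max)
            else:
                freq = 0.0
            epochs.append(
                StimulationEpoch(start_time_s=onset_s + k * EPOCH_MS / 1000.0, frequency_hz=freq)
            )
        i = j
    return StimulationTrain(epochs=tuple(epochs))


def charge_per_pulse(spec: PulseSpec) -> float:
    """Charge per pulse phase in nC (amplitude µA × width µs / 1000).

    The anodic phase carries the same charge by construction, so this is the
    quantity swept in threshold searches.
    """
    return spec.cathodic_amplitude_ua * spec.cathodic_width_us / 1000.0


def find_threshold(
    subject: SimulatedSubject, start_charge: float, step: float, max_charge: float
) -> float:
    """Perceptual threshold by the ascending method of limits.

    Probes charges start, start+step, start+2·step, ... up to ``max_charge``
    and returns the first charge the subject reports feeling; the overshoot
    relative to the true threshold is therefore below one step. Raises
    :class:`ThresholdNotFoundError` if nothing is felt by the ceiling.
    """
    if not (0 < start_charge <= max_charge):
        raise ValueError("require 0 < start_charge <= max_charge")
    if step <= 0:
        raise ValueError(f"step must be > 0, got {step}")
    k = 0
    while True:
        probe = start_charge + k * step
        if probe > max_charge * (1 + 1e-12):
            raise ThresholdNotFoundError(
                f"no percept reported up to {max_charge} nC (started {start_charge}, step {step})"
            )
        if subject.feels(probe):
            return probe
        k += 1


def select_feedback_contact(thresholds: dict[str, float]) -> str:
    """Pick the cuff contact with the lowest perceptual threshold charge.

    Ties break toward the lexicographically smallest contact identifier so
    selection is deterministic.
    """
    if not thresholds:
        raise ValueError("no contacts with a found threshold")
    return min(thresholds, key=lambda c: (thresholds[c], c))


def max_intensity_spec(threshold_spec: PulseSpec) -> tuple[PulseSpec, float]:
    """Preset used for extent mapping: 20% above threshold charge, at 30 Hz.

    Returns the scaled pulse spec (amplitude × 1.2 at the same width) and the
    stimulation frequency.
    """
    spec = PulseSpec(
        cathodic_amplitude_ua=threshold_spec.cathodic_amplitude_ua * 1.2,
        cathodic_width_us=threshold_spec.cathodic_width_us,
        interphase_delay_us=threshold_spec.interphase_delay_us,
        asymmetry_ratio=threshold_spec.asymmetry_ratio,
    )
    return spec, FREQ_MAX_HZ
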