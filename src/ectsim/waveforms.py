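"""Piecewise-constant electric-field pulse trains.

A pulse protocol is represented as an ordered list of segments, each with a
duration and a signed, spatially uniform electric field. Gaps between pulses
are explicit zero-field segments, so a train is a complete, contiguous time
course starting at t = 0. This representation covers the monopolar protocols
used in conventional electrochemotherapy (e.g. 8 x 100 us at 1 Hz), bursts of
high-frequency bipolar pulses, and nanosecond protocols, as well as arbitrary
user-defined rectangular trains.

Units are SI throughout: seconds and V/m. Convenience conversion from the
lab-facing kV/cm convention is ``1 kV/cm == 1e5 V/m``.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PulseSegment",
    "PulseTrain",
    "make_monopolar_train",
    "make_hf_bipolar_train",
    "field_from_voltage",
    "get_preset",
    "PRESETS",
    "KV_PER_CM",
]

#: one kV/cm expressed in V/m
KV_PER_CM = 1.0e5


class ProtocolError(ValueError):
    """Raised for physically inconsistent protocol definitions."""


@dataclass(frozen=True)
class PulseSegment:
    """A constant-field interval of a pulse train.

    Parameters
    ----------
    duration : float
        Length of the interval in seconds; strictly positive.
    field : float
        Signed electric field in V/m; zero marks a gap.
    """

    duration: float
    field: float = 0.0

    def __post_init__(self) -> None:
        if not (self.duration > 0.0) or not math.isfinite(self.duration):
            raise ProtocolError(f"segment duration must be > 0, got {self.duration!r}")
        if not math.isfinite(self.field):
            raise ProtocolError(f"segment field must be finite, got {self.field!r}")


@dataclass(frozen=True)
class PulseTrain:
    """An ordered sequence of constant-field segments starting at t = 0.

    ``electrode_gap`` and ``source_voltage`` are optional metadata used when a
    protocol is specified by generator voltage over a cuvette gap rather than
    by field strength directly.
    """

    name: str
    segments: tuple[PulseSegment, ...]
    electrode_gap: float | None = None
    source_voltage: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "segments", tuple(self.segments))
        if self.electrode_gap is not None and self.source_voltage is not None:
            expected = abs(self.source_voltage) / self.electrode_gap
            for seg in self.segments:
                if seg.field != 0.0 and not math.isclose(abs(seg.field), expected, rel_tol=1e-9):
                    raise ProtocolError(
                        f"segment field {seg.field} V/m inconsistent with "
                        f"{self.source_voltage} V over {self.electrode_gap} m"
                    )

    @property
    def duration(self) -> float:
        """Total train duration in seconds (sum of segment durations)."""
        return float(sum(seg.duration for seg in self.segments))

    @property
    def on_time(self) -> float:
        """Total time with nonzero applied field, in seconds."""
        return float(sum(seg.duration for seg in self.segments if seg.field != 0.0))

    def field_at(self, t: float) -> float:
        """Signed field at time ``t`` (seconds).

        Segment intervals are half-open ``[start, end)``; times at or beyond
        the end of the train return 0.
        """
        if t < 0.0:
            raise ValueError(f"time must be nonnegative, got {t}")
        elapsed = 0.0
        for seg in self.segments:
            if t < elapsed + seg.duration:
                return seg.field
            elapsed += seg.duration
        return 0.0

    def scaled(self, factor: float) -> "PulseTrain":
        """Return a copy with every segment field multiplied by ``factor``."""
        return replace(
            self,
            segments=tuple(replace(s, field=s.field * factor) for s in self.segments),
            source_voltage=None,
        )

    # -- plain-text serialization ------------------------------------------

    def to_table(self) -> pd.DataFrame:
        """Segments as a DataFrame with columns duration_s, field_V_per_m."""
        return pd.DataFrame(
            {
                "duration_s": [s.duration for s in self.segments],
                "field_V_per_m": [s.field for s in self.segments],
            }
        )

    def to_csv(self, path_or_buf=None):
        """Write the segment table as CSV (duration_s, field_V_per_m)."""
        return self.to_table().to_csv(path_or_buf, index=False)

    @classmethod
    def from_table(cls, table: pd.DataFrame, name: str = "custom") -> "PulseTrain":
        segs = tuple(
            PulseSegment(duration=float(row.duration_s), field=float(row.field_V_per_m))
            for row in table.itertuples()
        )
        return cls(name=name, segments=segs)

    @classmethod
    def from_csv(cls, path_or_buf, name: str = "custom") -> "PulseTrain":
        if isinstance(path_or_buf, str) and "\n" in path_or_buf:
            path_or_buf = io.StringIO(path_or_buf)
        return cls.from_table(pd.read_csv(path_or_buf), name=name)


def field_from_voltage(voltage: float, gap: float) -> float:
    """Convert an applied voltage (V) over an electrode gap (m) to V/m."""
    if not gap > 0.0:
        raise ValueError(f"electrode gap must be positive, got {gap}")
    return voltage / gap


def make_monopolar_train(
    n_pulses: int,
    pulse_duration: float,
    repetition_frequency: float,
    field: float,
    name: str = "monopolar",
) -> PulseTrain:
    """Build a train of identical monopolar rectangular pulses.

    Pulses of ``pulse_duration`` seconds are delivered so that pulse starts
    are ``1/repetition_frequency`` apart; the gap after the final pulse is
    not included (the train ends when the field switches off).
    """
    if n_pulses < 1:
        raise ProtocolError("n_pulses must be >= 1")
    period = 1.0 / repetition_frequency
    if period < pulse_duration:
        raise ProtocolError(
            f"repetition period {period} s shorter than pulse duration {pulse_duration} s"
        )
    gap = period - pulse_duration
    segs: list[PulseSegment] = []
    for i in range(n_pulses):
        segs.append(PulseSegment(pulse_duration, field))
        if i < n_pulses - 1 and gap > 0.0:
            segs.append(PulseSegment(gap, 0.0))
    return PulseTrain(name=name, segments=tuple(segs))


def make_hf_bipolar_train(
    n_bursts: int,
    pulses_per_burst: int,
    phase_duration: float,
    interphase_delay: float,
    interpulse_delay: float,
    burst_repetition_frequency: float,
    field: float,
    name: str = "hf_bipolar",
) -> PulseTrain:
    """Build bursts of short bipolar pulses (high-frequency protocol).

    One bipolar pulse is: positive phase, interphase gap, negative phase,
    interpulse gap — each phase carrying ``field`` / ``-field`` for
    ``phase_duration`` seconds. A burst strings ``pulses_per_burst`` of these
    together; bursts repeat so that burst *starts* are
    ``1/burst_repetition_frequency`` apart. The trailing interpulse gap of the
    last pulse in the train is trimmed so the train ends on a field switch-off.
    """
    if n_bursts < 1 or pulses_per_burst < 1:
        raise ProtocolError("n_bursts and pulses_per_burst must be >= 1")
    pulse_len = 2.0 * phase_duration + interphase_delay + interpulse_delay
    burst_len = pulses_per_burst * pulse_len
    period = 1.0 / burst_repetition_frequency
    if n_bursts > 1 and burst_len > period:
        raise ProtocolError(
            f"burst duration {burst_len} s exceeds burst period {period} s"
        )

    def bipolar_pulse(trailing_gap: bool) -> list[PulseSegment]:
        segs = [PulseSegment(phase_duration, field)]
        if interphase_delay > 0.0:
            segs.append(PulseSegment(interphase_delay, 0.0))
        segs.append(PulseSegment(phase_duration, -field))
        if trailing_gap and interpulse_delay > 0.0:
            segs.append(PulseSegment(interpulse_delay, 0.0))
        return segs

    segs: list[PulseSegment] = []
    for b in range(n_bursts):
        last_burst = b == n_bursts - 1
        for p in range(pulses_per_burst):
            last_pulse = p == pulses_per_burst - 1
            segs.extend(bipolar_pulse(trailing_gap=not (last_burst and last_pulse)))
        if not last_burst:
            inter_burst = period - burst_len
            if inter_burst > 0.0:
                segs.append(PulseSegment(inter_burst, 0.0))
    return PulseTrain(name=name, segments=tuple(segs))


# -- named protocol presets -------------------------------------------------

#: factory for each named protocol at its chosen optimal field strength
_PRESET_BUILDERS = {
    # 50 bursts x 50 bipolar pulses (2/2/2 us), 1 Hz, 1.4 kV/cm
    "hf_50x50": lambda E=1.4 * KV_PER_CM: make_hf_bipolar_train(
        50, 50, 2e-6, 2e-6, 2e-6, 1.0, E, name="hf_50x50"
    ),
    # conventional ECT: 8 x 100 us monopolar, 1 Hz, 1.2 kV/cm
    "mono_8x100us": lambda E=1.2 * KV_PER_CM: make_monopolar_train(
        8, 100e-6, 1.0, E, name="mono_8x100us"
    ),
    # gene-electrotransfer-style: 8 x 5 ms monopolar, 1 Hz, 0.6 kV/cm
    "mono_8x5ms": lambda E=0.6 * KV_PER_CM: make_monopolar_train(
        8, 5e-3, 1.0, E, name="mono_8x5ms"
    ),
    # single 200 ns pulse, 12.6 kV/cm
    "ns_1x200": lambda E=12.6 * KV_PER_CM: make_monopolar_train(
        1, 200e-9, 1.0, E, name="ns_1x200"
    ),
    # 25 x 400 ns at 10 Hz, 3.9 kV/cm
    "ns_25x400": lambda E=3.9 * KV_PER_CM: make_monopolar_train(
        25, 400e-9, 10.0, E, name="ns_25x400"
    ),
}

PRESETS: tuple[str, ...] = tuple(_PRESET_BUILDERS)


def get_preset(name: str, field: float | None = None) -> PulseTrain:
    """Return a named preset protocol, optionally at an overridden field (V/m)."""
    try:
        builder = _PRESET_BUILDERS[name]
    except KeyError:
        raise KeyError(
            f"unknown protocol preset {name!r}; available: {', '.join(PRESETS)}"
        ) from None
    return builder() if field is None else builder(field)
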