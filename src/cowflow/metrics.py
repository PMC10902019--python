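"""TCD-comparable velocity waveform metrics.

Extracts the middle-cerebral-artery (M1) maximal-velocity envelope from a
network solution the same way a transcranial-Doppler-style analysis
samples a 3D simulation — the maximum velocity at three consecutively
spaced stations along the M1 segment, averaged — and reduces envelopes to
the three standard waveform metrics: systolic (cycle maximum),
time-averaged (cycle mean) and end-diastolic (cycle end) velocity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .haemodynamics import NetworkSolution
from .waveforms import SampledWaveform, time_average

__all__ = [
    "METRIC_NAMES",
    "VelocityMetrics",
    "MetricDelta",
    "m1_envelope",
    "extract_metrics",
    "relative_change",
]

METRIC_NAMES = ("systolic", "time_averaged", "end_diastolic")

#: Default station positions along the M1 path (fractions of path length).
DEFAULT_STATION_FRACTIONS = (0.25, 0.50, 0.75)


@dataclass(frozen=True)
class VelocityMetrics:
    """Systolic / time-averaged / end-diastolic envelope velocities (cm/s)."""

    systolic: float
    time_averaged: float
    end_diastolic: float

    def __post_init__(self) -> None:
        if not (self.end_diastolic <= self.time_averaged <= self.systolic):
            raise ValueError(
                "expected end_diastolic <= time_averaged <= systolic, got "
                f"({self.end_diastolic}, {self.time_averaged}, {self.systolic})"
            )

    def as_dict(self) -> dict[str, float]:
        return {
            "systolic": self.systolic,
            "time_averaged": self.time_averaged,
            "end_diastolic": self.end_diastolic,
        }


@dataclass(frozen=True)
class MetricDelta:
    """Relative change (percent) in each metric between two conditions."""

    systolic: float
    time_averaged: float
    end_diastolic: float

    def as_dict(self) -> dict[str, float]:
        return {
            "systolic": self.systolic,
            "time_averaged": self.time_averaged,
            "end_diastolic": self.end_diastolic,
        }


def m1_envelope(
    sol: NetworkSolution,
    m1_segment_ids: Sequence[str],
    station_fractions: Sequence[float] = DEFAULT_STATION_FRACTIONS,
) -> SampledWaveform:
    """Simulated TCD envelope: station-averaged maximal M1 velocity.

    Stations are placed at the given fractions of the concatenated M1
    path length; each station samples the maximal velocity of the segment
    it falls on, and stations are averaged per phase point. In this
    quasi-1D model the velocity is uniform along a segment, so stations
    on the same segment coincide; the three-station interface mirrors the
    constrained-plane sampling used against 3D solutions.
    """
    if not m1_segment_ids:
        raise ValueError("at least one M1 segment id is required")
    if not station_fractions:
        raise ValueError("at least one station is required")
    lengths = []
    v_max = []
    for seg_id in m1_segment_ids:
        if seg_id not in sol.segment_ids:
            raise KeyError(f"segment {seg_id!r} not in solution")
        idx = sol.segment_ids.index(seg_id)
        v_max.append(sol.v_max_cm_s[idx])
    # map path fractions to segments; segments divide the path evenly
    # (the solution does not carry lengths, and M1 is usually one segment)
    n_phase = v_max[0].size
    stations = np.zeros((len(station_fractions), n_phase))
    bounds = np.linspace(0.0, 1.0, len(m1_segment_ids) + 1)
    for i, frac in enumerate(station_fractions):
        if not (0.0 <= frac <= 1.0):
            raise ValueError("station fractions must lie in [0, 1]")
        seg_idx = min(np.searchsorted(bounds, frac, side="right") - 1, len(v_max) - 1)
        stations[i] = v_max[seg_idx]
    return SampledWaveform(stations.mean(axis=0), sol.period, "cm/s")


def extract_metrics(envelope: SampledWaveform, end_diastole: str = "cycle_end") -> VelocityMetrics:
    """Reduce a peak-aligned envelope to its three waveform metrics.

    ``end_diastole`` selects the end-diastolic definition: ``"cycle_end"``
    takes the final phase sample (the instant before the next systolic
    upstroke, for a peak-aligned cycle); ``"late_minimum"`` takes the
    minimum over the last 20% of the cycle.
    """
    v = envelope.values
    systolic = float(np.max(v))
    averaged = time_average(envelope)
    if end_diastole == "cycle_end":
        ed = float(v[-1])
    elif end_diastole == "late_minimum":
        tail = v[int(0.8 * v.size):]
        ed = float(np.min(tail))
    else:
        raise ValueError(f"unknown end_diastole mode {end_diastole!r}")
    return VelocityMetrics(systolic=systolic, time_averaged=averaged, end_diastolic=ed)


def relative_change(rest: VelocityMetrics, stimulus: VelocityMetrics) -> MetricDelta:
    """Per-metric relative change in percent: 100 * (stimulus - rest) / rest."""
    r, s = rest.as_dict(), stimulus.as_dict()
    out = {}
    for name in METRIC_NAMES:
        if not (r[name] > 0):
            raise ValueError(f"rest {name} must be > 0 to define a relative change")
        out[name] = 100.0 * (s[name] - r[name]) / r[name]
    return MetricDelta(**out)
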