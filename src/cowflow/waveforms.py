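"""Duplex-ultrasound waveform processing.

Converts raw per-cardiac-cycle velocity envelopes measured at the four
extracranial inflow arteries (left/right internal carotid, left/right
vertebral) into ensemble-averaged velocity waveforms, volumetric flow
waveforms (Poiseuille conversion), mass-flow boundary waveforms, and the
total cerebral blood flow (tCBF) summary.

All waveforms live on a uniform dimensionless phase grid covering one
cardiac cycle, ``phase = k / N`` for ``k = 0 .. N-1``, with the cycle
duration carried separately in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import interpolate

__all__ = [
    "ARTERIES",
    "SampledWaveform",
    "DuplexRecording",
    "EnsembleWaveform",
    "ensemble_average",
    "poiseuille_flow",
    "time_average",
    "total_cbf",
    "to_mass_flow",
    "read_duplex_csv",
    "read_waveform_csv",
    "write_waveform_csv",
]

#: Inflow artery labels (left/right internal carotid, left/right vertebral).
ARTERIES = ("LICA", "RICA", "LVA", "RVA")

#: Ratio of cross-sectionally averaged velocity to the Doppler envelope
#: (spectral maximum) under a parabolic Poiseuille profile: mean = peak / 2.
ENVELOPE_TO_MEAN_FACTOR = 0.5

#: Smoothing-spline residual budget, as a fraction of the signal RMS.
SPLINE_RMS_TOLERANCE = 0.01

_MIN_SAMPLES = 16


def _uniform_phase(n: int) -> np.ndarray:
    return np.arange(n, dtype=float) / n


@dataclass(frozen=True)
class SampledWaveform:
    """One cardiac cycle of a quantity sampled on a uniform phase grid.

    Parameters
    ----------
    values
        Samples at ``phase = k/N``, ``k = 0..N-1``.
    period
        Cardiac cycle duration in seconds.
    units
        Units tag, e.g. ``"cm/s"``, ``"mL/min"``, ``"kg/s"``, ``"Pa"``.
    """

    values: np.ndarray
    period: float
    units: str

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or values.size < _MIN_SAMPLES:
            raise ValueError(
                f"waveform needs >= {_MIN_SAMPLES} samples, got shape {values.shape}"
            )
        if not np.all(np.isfinite(values)):
            raise ValueError("waveform contains non-finite samples")
        if not (self.period > 0):
            raise ValueError(f"period must be > 0, got {self.period}")
        if not self.units:
            raise ValueError("units tag is required")

    @property
    def n_points(self) -> int:
        return self.values.size

    @property
    def phase(self) -> np.ndarray:
        """Uniform phase grid in [0, 1)."""
        return _uniform_phase(self.values.size)

    def with_values(self, values: np.ndarray, units: str | None = None) -> "SampledWaveform":
        return SampledWaveform(values, self.period, units if units is not None else self.units)


@dataclass(frozen=True)
class DuplexRecording:
    """A duplex-ultrasound recording at one inflow artery.

    ``cycles`` are per-cardiac-cycle velocity envelopes (cm/s), each with
    its own period; ``diameter_mm`` is the B-mode lumen diameter averaged
    over the recording. Envelopes must be antegrade (non-negative).
    """

    artery: str
    cycles: tuple[SampledWaveform, ...]
    diameter_mm: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "cycles", tuple(self.cycles))
        if self.artery not in ARTERIES:
            raise ValueError(f"unknown artery {self.artery!r}; expected one of {ARTERIES}")
        if len(self.cycles) < 1:
            raise ValueError("at least one cardiac cycle is required")
        if not (self.diameter_mm > 0):
            raise ValueError(f"diameter must be > 0 mm, got {self.diameter_mm}")
        for cyc in self.cycles:
            if np.any(cyc.values < 0):
                raise ValueError(
                    f"negative envelope samples in {self.artery} recording; "
                    "inflow envelopes are antegrade"
                )


@dataclass(frozen=True)
class EnsembleWaveform:
    """Peak-aligned ensemble average of several cardiac cycles."""

    waveform: SampledWaveform
    n_cycles: int
    alignment_phase: float

    def __post_init__(self) -> None:
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        n = self.waveform.n_points
        peak_idx = int(np.argmax(self.waveform.values))
        target_idx = int(round(self.alignment_phase * n)) % n
        # peak must sit at the alignment phase, within one grid step
        delta = min((peak_idx - target_idx) % n, (target_idx - peak_idx) % n)
        if delta > 1:
            raise ValueError(
                f"waveform peak at phase index {peak_idx}, expected near {target_idx}"
            )


# ---------------------------------------------------------------------------
# ensemble averaging


def _resample_periodic(cycle: SampledWaveform, n_points: int) -> np.ndarray:
    """Smooth one cycle with a periodic cubic spline and resample it.

    The smoothing budget caps the RMS deviation of the spline from the
    input samples at ``SPLINE_RMS_TOLERANCE`` times the signal RMS, so
    smoothing never distorts the waveform by more than ~1%.
    """
    x = cycle.phase
    y = cycle.values
    # close the cycle for the periodic fit
    x_per = np.append(x, 1.0)
    y_per = np.append(y, y[0])
    rms = float(np.sqrt(np.mean(y**2)))
    s = x_per.size * (SPLINE_RMS_TOLERANCE * rms) ** 2
    tck = interpolate.splrep(x_per, y_per, s=s, per=True)
    return interpolate.splev(_uniform_phase(n_points) % 1.0, tck)


def ensemble_average(
    cycles: Sequence[SampledWaveform],
    n_points: int = 200,
    alignment_phase: float = 0.25,
) -> EnsembleWaveform:
    """Spline-fit, peak-align and ensemble-average cardiac cycles.

    Each cycle is smoothed with a periodic cubic smoothing spline,
    resampled to ``n_points`` on the unit phase grid, circularly shifted
    so its global maximum sits at ``alignment_phase``, and the shifted
    cycles are averaged pointwise. The output period is the arithmetic
    mean of the input periods.
    """
    cycles = list(cycles)
    if not cycles:
        raise ValueError("ensemble_average requires at least one cycle")
    units = cycles[0].units
    target_idx = int(round(alignment_phase * n_points)) % n_points
    aligned = np.empty((len(cycles), n_points))
    for i, cyc in enumerate(cycles):
        if cyc.units != units:
            raise ValueError(f"mixed units: {cyc.units!r} vs {units!r}")
        resampled = _resample_periodic(cyc, n_points)
        peak_idx = int(np.argmax(resampled))
        aligned[i] = np.roll(resampled, target_idx - peak_idx)
    mean_values = aligned.mean(axis=0)
    period = float(np.mean([c.period for c in cycles]))
    waveform = SampledWaveform(mean_values, period, units)
    return EnsembleWaveform(waveform, n_cycles=len(cycles), alignment_phase=alignment_phase)


# ---------------------------------------------------------------------------
# flow conversion and summaries


def poiseuille_flow(
    envelope: EnsembleWaveform | SampledWaveform,
    diameter_mm: float,
    envelope_factor: float = ENVELOPE_TO_MEAN_FACTOR,
) -> SampledWaveform:
    """Convert a velocity-envelope waveform (cm/s) to volume flow (mL/min).

    Assumes a Poiseuille (parabolic) velocity profile: the Doppler
    envelope tracks the profile peak, so the cross-sectional mean is
    ``envelope_factor`` (default 1/2) times the envelope, and

        Q(t) = envelope_factor * V_env(t) * pi * (D/2)^2 .
    """
    if not (diameter_mm > 0):
        raise ValueError(f"diameter must be > 0 mm, got {diameter_mm}")
    wav = envelope.waveform if isinstance(envelope, EnsembleWaveform) else envelope
    if np.any(wav.values < 0):
        raise ValueError("envelope values must be >= 0")
    radius_cm = 0.05 * diameter_mm  # mm -> cm, then /2
    area_cm2 = np.pi * radius_cm**2
    q_ml_s = envelope_factor * wav.values * area_cm2  # cm/s * cm^2 = mL/s
    return SampledWaveform(q_ml_s * 60.0, wav.period, "mL/min")


def time_average(w: SampledWaveform) -> float:
    """Time average of one cycle: the mean over the uniform phase grid."""
    return float(np.mean(w.values))


def total_cbf(flows: Iterable[SampledWaveform]) -> float:
    """Total cerebral blood flow: sum of time-averaged inflow waveforms (mL/min)."""
    flows = list(flows)
    if not flows:
        raise ValueError("total_cbf requires at least one flow waveform")
    return float(sum(time_average(q) for q in flows))


def to_mass_flow(q: SampledWaveform, density_kg_m3: float = 1050.0) -> SampledWaveform:
    """Convert a volume-flow waveform (mL/min) to mass flow (kg/s)."""
    if not (density_kg_m3 > 0):
        raise ValueError(f"density must be > 0, got {density_kg_m3}")
    mdot = q.values * 1e-6 / 60.0 * density_kg_m3  # mL/min -> m^3/s, times rho
    return SampledWaveform(mdot, q.period, "kg/s")


def from_mass_flow(mdot: SampledWaveform, density_kg_m3: float = 1050.0) -> SampledWaveform:
    """Inverse of :func:`to_mass_flow`."""
    if not (density_kg_m3 > 0):
        raise ValueError(f"density must be > 0, got {density_kg_m3}")
    q = mdot.values / density_kg_m3 * 60.0 / 1e-6
    return SampledWaveform(q, mdot.period, "mL/min")


# ---------------------------------------------------------------------------
# CSV interfaces


def read_duplex_csv(
    velocity_csv: str | Path, diameter_csv: str | Path
) -> dict[tuple[str, str], DuplexRecording]:
    """Read long-form duplex recordings.

    ``velocity_csv`` columns: ``artery,condition,cycle,t_seconds,velocity_cm_s``;
    ``diameter_csv`` columns: ``artery,condition,diameter_mm``. Returns a
    mapping ``(artery, condition) -> DuplexRecording``.
    """
    vel = pd.read_csv(velocity_csv)
    dia = pd.read_csv(diameter_csv)
    required = {"artery", "condition", "cycle", "t_seconds", "velocity_cm_s"}
    if not required.issubset(vel.columns):
        raise ValueError(f"velocity CSV must have columns {sorted(required)}")
    dia_map = {
        (row.artery, row.condition): float(row.diameter_mm)
        for row in dia.itertuples(index=False)
    }
    out: dict[tuple[str, str], DuplexRecording] = {}
    for (artery, condition), grp in vel.groupby(["artery", "condition"], sort=False):
        cycles = []
        for _, cyc in grp.groupby("cycle", sort=True):
            cyc = cyc.sort_values("t_seconds")
            t = cyc["t_seconds"].to_numpy(dtype=float)
            v = cyc["velocity_cm_s"].to_numpy(dtype=float)
            period = float(t[-1] - t[0]) * t.size / (t.size - 1)
            cycles.append(SampledWaveform(v, period, "cm/s"))
        key = (str(artery), str(condition))
        if key not in dia_map:
            raise ValueError(f"no diameter entry for {key}")
        out[key] = DuplexRecording(str(artery), tuple(cycles), dia_map[key])
    return out


def write_waveform_csv(
    path: str | Path, w: SampledWaveform, n_cycles: int | None = None
) -> None:
    """Write ``phase,value`` CSV with ``# units=``, ``# period_s=`` metadata lines."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# units={w.units}\n")
        fh.write(f"# period_s={w.period}\n")
        if n_cycles is not None:
            fh.write(f"# n_cycles={n_cycles}\n")
        fh.write("phase,value\n")
        for p, v in zip(w.phase, w.values):
            fh.write(f"{p:.10g},{v:.10g}\n")


def read_waveform_csv(path: str | Path) -> SampledWaveform:
    """Read a waveform CSV written by :func:`write_waveform_csv`."""
    meta: dict[str, str] = {}
    rows: list[tuple[float, float]] = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("#"):
                key, _, val = line[1:].strip().partition("=")
                meta[key.strip()] = val.strip()
            elif line and not line.startswith("phase"):
                p, v = line.split(",")
                rows.append((float(p), float(v)))
    values = np.array([v for _, v in rows])
    return SampledWaveform(values, float(meta["period_s"]), meta["units"])
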