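"""Reproducible synthetic cohorts for the full pipeline.

No participant data accompany the method, so this module generates
cohorts with the statistical structure the analysis assumes: per-artery
duplex inflow recordings calibrated to published group means and
standard deviations at rest, under hypercapnia (flows up ~40%) and
during submaximal exercise (flows near rest); a complete
Circle-of-Willis network template with participant-jittered diameters;
and TCD-style M1 envelopes derived from each participant's own simulated
envelope through a multiplicative bias that is constant within a
participant across conditions — the mechanism by which absolute
velocities disagree between sources while relative changes agree.

Everything is deterministic under a master seed, with independent
substreams per participant, condition and artery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .boundary_conditions import RegionTable, Segment, VascularNetwork, default_region_table
from .comparison import CONDITIONS, ConditionRecord
from .haemodynamics import RheologyParams, SolverConfig
from .metrics import extract_metrics
from .pipeline import ParticipantResult, simulate_condition
from .waveforms import ARTERIES, DuplexRecording, SampledWaveform

__all__ = [
    "CohortConfig",
    "BiasFactors",
    "SyntheticParticipant",
    "synth_network",
    "synth_inlet_recording",
    "synth_tcd_envelope",
    "synth_cohort",
    "cohort_study_records",
]

#: Group mean +/- SD of time-averaged inflow (mL/min) per artery and
#: condition, from published duplex measurements in healthy adults.
FLOW_TABLE: dict[str, dict[str, tuple[float, float]]] = {
    "rest": {"LICA": (268.9, 63.3), "RICA": (218.8, 74.2), "LVA": (74.2, 26.4), "RVA": (56.2, 18.3)},
    "hypercapnia": {"LICA": (374.6, 79.3), "RICA": (308.6, 79.3), "LVA": (119.4, 30.9), "RVA": (97.0, 32.3)},
    "exercise": {"LICA": (272.8, 67.2), "RICA": (262.9, 50.3), "LVA": (79.7, 27.1), "RVA": (68.4, 34.0)},
}

#: Group mean +/- SD heart rate (bpm) per condition.
HR_TABLE: dict[str, tuple[float, float]] = {
    "rest": (68.7, 9.5),
    "hypercapnia": (74.1, 8.1),
    "exercise": (120.4, 21.3),
}

#: Target time-averaged envelope velocity (cm/s) used to size each
#: artery's lumen so that the Poiseuille conversion recovers the drawn flow.
ENVELOPE_TA_VELOCITY = {"LICA": 50.0, "RICA": 50.0, "LVA": 35.0, "RVA": 35.0}


@dataclass(frozen=True)
class BiasFactors:
    """Per-metric multiplicative TCD/CFD bias for one participant."""

    systolic: float
    time_averaged: float
    end_diastolic: float

    def __post_init__(self) -> None:
        if min(self.systolic, self.time_averaged, self.end_diastolic) <= 0:
            raise ValueError("bias factors must be > 0")

    def as_dict(self) -> dict[str, float]:
        return {
            "systolic": self.systolic,
            "time_averaged": self.time_averaged,
            "end_diastolic": self.end_diastolic,
        }


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for cohort generation.

    The TCD bias defaults (systolic 1.5, time-averaged 1.7, end-diastolic
    1.9) sit inside the ranges reported for envelope-TCD versus simulated
    velocities (roughly 33-73%, 62-85% and 85-106% higher respectively);
    they are calibration defaults, not ground truth. ``response_sd`` is
    the between-participant log-scale spread of the condition flow
    response, sized to the reported dispersion of relative velocity
    changes (~25-30 percentage points); ``response_correlation`` couples
    the four arteries' responses within a participant.
    """

    n_participants: int = 12
    flow_table: Mapping[str, Mapping[str, tuple[float, float]]] = field(
        default_factory=lambda: FLOW_TABLE
    )
    hr_table: Mapping[str, tuple[float, float]] = field(default_factory=lambda: HR_TABLE)
    pulsatility: float = 1.2  # (peak - min) / mean of the envelope
    n_harmonics: int = 4
    n_cycle_samples: int = 64  # raw samples per recorded cardiac cycle
    n_cycles: int = 3
    cycle_noise_cv: float = 0.03  # cycle-to-cycle amplitude/period jitter
    bias_means: BiasFactors = field(default_factory=lambda: BiasFactors(1.5, 1.7, 1.9))
    bias_sd: float = 0.15  # between-participant SD of each bias factor
    noise_cv: float = 0.05  # TCD measurement noise (smooth, multiplicative)
    response_sd: float = 0.20
    response_correlation: float = 0.5
    diameter_jitter_cv: float = 0.05
    n_phase: int = 96  # phase resolution of the ensemble/solver stage
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 3:
            raise ValueError("n_participants must be >= 3")
        for name in ("cycle_noise_cv", "bias_sd", "noise_cv", "response_sd", "diameter_jitter_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0 <= self.response_correlation <= 1):
            raise ValueError("response_correlation must lie in [0, 1]")
        for cond, row in self.flow_table.items():
            for artery, (mean, sd) in row.items():
                if mean <= 0 or sd < 0:
                    raise ValueError(f"invalid flow entry {cond}/{artery}")


@dataclass(frozen=True)
class SyntheticParticipant:
    """One synthetic participant with all conditions and ground truth."""

    id: str
    network: VascularNetwork
    recordings: dict[str, dict[str, DuplexRecording]]  # condition -> artery -> recording
    sim_results: dict[str, ParticipantResult]  # condition -> pipeline products
    tcd_envelopes: dict[str, SampledWaveform]  # condition -> biased envelope
    bias: BiasFactors  # ground-truth bias factors
    ground_truth: dict  # drawn flows, response factors, seeds


# ---------------------------------------------------------------------------
# network template


_COW_TEMPLATE: tuple[tuple[str, str, str, float, float, str], ...] = (
    # (id, from, to, length_mm, diameter_mm, name)
    ("L_ICA", "LICA_in", "L_ICA_T", 100.0, 4.6, "left internal carotid"),
    ("R_ICA", "RICA_in", "R_ICA_T", 100.0, 4.6, "right internal carotid"),
    ("L_OPH", "L_ICA_T", "L_oph_out", 30.0, 1.3, "left ophthalmic"),
    ("R_OPH", "R_ICA_T", "R_oph_out", 30.0, 1.3, "right ophthalmic"),
    ("L_VA", "LVA_in", "VB_jn", 80.0, 3.2, "left vertebral"),
    ("R_VA", "RVA_in", "VB_jn", 80.0, 3.0, "right vertebral"),
    ("BA", "VB_jn", "BA_top", 30.0, 3.2, "basilar"),
    ("L_CB", "VB_jn", "L_cb_out", 25.0, 1.6, "left cerebellar"),
    ("R_CB", "VB_jn", "R_cb_out", 25.0, 1.6, "right cerebellar"),
    ("L_PCA_P1", "BA_top", "L_PCA_jn", 8.0, 2.1, "left PCA P1"),
    ("R_PCA_P1", "BA_top", "R_PCA_jn", 8.0, 2.1, "right PCA P1"),
    ("L_PCOA", "L_ICA_T", "L_PCA_jn", 15.0, 1.4, "left posterior communicating"),
    ("R_PCOA", "R_ICA_T", "R_PCA_jn", 15.0, 1.4, "right posterior communicating"),
    ("L_PCA_P2", "L_PCA_jn", "L_pca_out", 30.0, 2.0, "left PCA P2"),
    ("R_PCA_P2", "R_PCA_jn", "R_pca_out", 30.0, 2.0, "right PCA P2"),
    ("L_MCA_M1", "L_ICA_T", "L_MCA_bif", 25.0, 2.9, "left MCA M1"),
    ("R_MCA_M1", "R_ICA_T", "R_MCA_bif", 25.0, 2.9, "right MCA M1"),
    ("L_M2_SUP", "L_MCA_bif", "L_m2s_out", 25.0, 2.2, "left M2 superior"),
    ("L_M2_INF", "L_MCA_bif", "L_m2i_out", 25.0, 2.1, "left M2 inferior"),
    ("R_M2_SUP", "R_MCA_bif", "R_m2s_out", 25.0, 2.2, "right M2 superior"),
    ("R_M2_INF", "R_MCA_bif", "R_m2i_out", 25.0, 2.1, "right M2 inferior"),
    ("L_ACA_A1", "L_ICA_T", "L_ACA_jn", 14.0, 2.3, "left ACA A1"),
    ("R_ACA_A1", "R_ICA_T", "R_ACA_jn", 14.0, 2.3, "right ACA A1"),
    ("ACOA", "L_ACA_jn", "R_ACA_jn", 3.0, 1.5, "anterior communicating"),
    ("L_ACA_A2", "L_ACA_jn", "L_aca_out", 25.0, 2.0, "left ACA A2"),
    ("R_ACA_A2", "R_ACA_jn", "R_aca_out", 25.0, 2.0, "right ACA A2"),
)

_COW_INLETS = {"LICA_in": "LICA", "RICA_in": "RICA", "LVA_in": "LVA", "RVA_in": "RVA"}
_COW_OUTLETS = {
    "L_oph_out": "ophthalmic",
    "R_oph_out": "ophthalmic",
    "L_cb_out": "cerebellum",
    "R_cb_out": "cerebellum",
    "L_pca_out": "left_posterior",
    "R_pca_out": "right_posterior",
    "L_m2s_out": "left_middle",
    "L_m2i_out": "left_middle",
    "R_m2s_out": "right_middle",
    "R_m2i_out": "right_middle",
    "L_aca_out": "anterior",
    "R_aca_out": "anterior",
}


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None) -> np.ndarray | float:
    """Median-1 log-normal multiplier with coefficient of variation ``cv``."""
    if cv == 0:
        return np.ones(size) if size is not None else 1.0
    sigma = np.sqrt(np.log1p(cv**2))
    return np.exp(sigma * rng.standard_normal(size))


def synth_network(
    seed: int | np.random.SeedSequence = 0, jitter_cv: float = 0.05
) -> VascularNetwork:
    """Complete Circle-of-Willis template with log-normally jittered diameters."""
    if jitter_cv < 0:
        raise ValueError("jitter_cv must be >= 0")
    rng = np.random.default_rng(seed)
    factors = _lognormal_factor(rng, jitter_cv, size=len(_COW_TEMPLATE))
    segments = tuple(
        Segment(id=sid, from_node=a, to_node=b, length_mm=ln, diameter_mm=d * f, name=name)
        for (sid, a, b, ln, d, name), f in zip(_COW_TEMPLATE, np.atleast_1d(factors))
    )
    return VascularNetwork(segments, dict(_COW_INLETS), dict(_COW_OUTLETS))


# ---------------------------------------------------------------------------
# envelope shape


def _canonical_shape(n_points: int, n_harmonics: int, pulsatility: float) -> np.ndarray:
    """Mean-1 triphasic arterial envelope shape with given pulsatility.

    A systolic peak with a dicrotic shoulder is synthesised, truncated to
    ``n_harmonics`` Fourier harmonics, and rescaled so that
    (max - min) / mean equals ``pulsatility``. The peak sits at phase 0.25.
    """
    phi = np.arange(n_points) / n_points
    # wrapped Gaussian bumps: systolic peak at 0.25, dicrotic shoulder at 0.55
    raw = np.zeros(n_points)
    for k in (-1, 0, 1):
        raw += np.exp(-((phi - 0.25 + k) ** 2) / (2 * 0.06**2))
        raw += 0.35 * np.exp(-((phi - 0.55 + k) ** 2) / (2 * 0.09**2))
    coeffs = np.fft.rfft(raw)
    coeffs[n_harmonics + 1 :] = 0.0
    smooth = np.fft.irfft(coeffs, n_points)
    fluct = smooth - smooth.mean()
    shape = 1.0 + fluct * (pulsatility / np.ptp(fluct))
    if shape.min() <= 0:
        raise ValueError(f"pulsatility {pulsatility} drives the envelope negative")
    return shape / shape.mean()


def _diameter_for_flow(flow_ml_min: float, v_ta_cm_s: float) -> float:
    """Lumen diameter (mm) so that the Poiseuille conversion of an
    envelope with time average ``v_ta_cm_s`` yields ``flow_ml_min``."""
    area_cm2 = flow_ml_min / (60.0 * 0.5 * v_ta_cm_s)
    return 20.0 * np.sqrt(area_cm2 / np.pi)


def _recording_for_flow(
    artery: str,
    flow_ml_min: float,
    period_s: float,
    cfg: CohortConfig,
    rng: np.random.Generator,
) -> DuplexRecording:
    """Build a multi-cycle duplex recording whose processed flow is ``flow_ml_min``."""
    shape = _canonical_shape(cfg.n_cycle_samples, cfg.n_harmonics, cfg.pulsatility)
    v_ta = ENVELOPE_TA_VELOCITY[artery]
    envelope = v_ta * shape
    diameter = _diameter_for_flow(flow_ml_min, v_ta)
    cycles = []
    for _ in range(cfg.n_cycles):
        amp = _lognormal_factor(rng, cfg.cycle_noise_cv)
        per = period_s * _lognormal_factor(rng, cfg.cycle_noise_cv)
        cycles.append(SampledWaveform(envelope * amp, float(per), "cm/s"))
    return DuplexRecording(artery, tuple(cycles), diameter)


def synth_inlet_recording(
    artery: str,
    condition: str,
    cfg: CohortConfig = CohortConfig(),
    seed: int | np.random.SeedSequence = 0,
) -> DuplexRecording:
    """Draw one artery-condition duplex recording from the cohort statistics.

    The participant's time-averaged flow is drawn from the configured
    normal distribution (truncated at zero) and the recording is built so
    that ensemble averaging plus Poiseuille conversion recovers that flow.
    """
    rng = np.random.default_rng(seed)
    mean, sd = cfg.flow_table[condition][artery]
    flow = _truncated_normal(rng, mean, sd)
    hr_mean, hr_sd = cfg.hr_table[condition]
    period = 60.0 / _truncated_normal(rng, hr_mean, hr_sd, lower=30.0)
    return _recording_for_flow(artery, flow, period, cfg, rng)


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lower: float = 0.0
) -> float:
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if x > lower:
            return float(x)
    raise RuntimeError("truncated-normal rejection sampling failed")


# ---------------------------------------------------------------------------
# TCD bias model


def synth_tcd_envelope(
    sim_envelope: SampledWaveform,
    bias: BiasFactors,
    noise_cv: float = 0.05,
    seed: int | np.random.SeedSequence = 0,
) -> SampledWaveform:
    """Apply the participant's multiplicative TCD bias plus smooth noise.

    The per-phase bias interpolates between the end-diastolic factor (at
    the envelope minimum) and the systolic factor (at the peak), weighted
    by the envelope's normalised excursion, so the systolic metric is
    scaled by exactly the systolic factor and the cycle end by (almost
    exactly) the end-diastolic factor. Noise is a smooth log-normal
    modulation (constant + first harmonic) with per-phase coefficient of
    variation ``noise_cv``, mean-corrected to one.
    """
    rng = np.random.default_rng(seed)
    v = sim_envelope.values
    span = np.ptp(v)
    w = (v - v.min()) / span if span > 0 else np.ones_like(v)
    per_phase_bias = bias.end_diastolic + (bias.systolic - bias.end_diastolic) * w
    if noise_cv > 0:
        sigma = np.sqrt(np.log1p(noise_cv**2))
        z = rng.standard_normal(3)
        phi = sim_envelope.phase
        mod = (z[0] + z[1] * np.cos(2 * np.pi * phi) + z[2] * np.sin(2 * np.pi * phi)) / np.sqrt(3)
        noise = np.exp(sigma * mod - 0.5 * sigma**2)
    else:
        noise = 1.0
    return sim_envelope.with_values(v * per_phase_bias * noise)


def _draw_bias(cfg: CohortConfig, rng: np.random.Generator) -> BiasFactors:
    """Log-normal per-participant bias with mean equal to the configured means."""
    means = cfg.bias_means.as_dict()
    out = {}
    for name, mean in means.items():
        if cfg.bias_sd == 0:
            out[name] = mean
        else:
            cv = cfg.bias_sd / mean
            sigma = np.sqrt(np.log1p(cv**2))
            out[name] = float(mean * np.exp(sigma * rng.standard_normal() - 0.5 * sigma**2))
    return BiasFactors(**out)


# ---------------------------------------------------------------------------
# cohort assembly


def synth_cohort(
    cfg: CohortConfig = CohortConfig(),
    regions: RegionTable | None = None,
    rheology: RheologyParams = RheologyParams(),
) -> list[SyntheticParticipant]:
    """Generate a full cohort and run the simulation pipeline on it.

    Deterministic under ``cfg.master_seed`` with independent substreams
    per participant (and per condition/artery within a participant), so
    regenerating participant k never perturbs the others. Each
    participant's condition flows are their drawn resting flows scaled by
    correlated log-normal response factors centred on the group
    condition-to-rest ratios.
    """
    table = regions if regions is not None else default_region_table()
    solver_cfg = SolverConfig(n_phase=cfg.n_phase)
    root = np.random.SeedSequence(cfg.master_seed)
    participant_seeds = root.spawn(cfg.n_participants)
    cohort: list[SyntheticParticipant] = []
    for i, pseed in enumerate(participant_seeds):
        (net_ss, flow_ss, bias_ss, tcd_ss, resp_ss) = pseed.spawn(5)
        tcd_substreams = dict(zip(CONDITIONS, tcd_ss.spawn(len(CONDITIONS))))
        rng_flow = np.random.default_rng(flow_ss)
        rng_resp = np.random.default_rng(resp_ss)
        network = synth_network(net_ss, cfg.diameter_jitter_cv)
        bias = _draw_bias(cfg, np.random.default_rng(bias_ss))

        rest_flows = {
            a: _truncated_normal(rng_flow, *cfg.flow_table["rest"][a]) for a in ARTERIES
        }
        hr = {c: _truncated_normal(rng_flow, *cfg.hr_table[c], lower=30.0) for c in CONDITIONS}
        response: dict[str, dict[str, float]] = {}
        for cond in CONDITIONS:
            if cond == "rest":
                response[cond] = {a: 1.0 for a in ARTERIES}
                continue
            shared = rng_resp.standard_normal()
            rho = cfg.response_correlation
            response[cond] = {}
            for a in ARTERIES:
                own = rng_resp.standard_normal()
                z = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * own
                ratio = cfg.flow_table[cond][a][0] / cfg.flow_table["rest"][a][0]
                response[cond][a] = float(ratio * np.exp(cfg.response_sd * z - 0.5 * cfg.response_sd**2))

        recordings: dict[str, dict[str, DuplexRecording]] = {}
        sim_results: dict[str, ParticipantResult] = {}
        tcd_envelopes: dict[str, SampledWaveform] = {}
        for cond in CONDITIONS:
            rec_cond: dict[str, DuplexRecording] = {}
            for a in ARTERIES:
                flow = rest_flows[a] * response[cond][a]
                rec_cond[a] = _recording_for_flow(a, flow, 60.0 / hr[cond], cfg, rng_flow)
            recordings[cond] = rec_cond
            result = simulate_condition(
                rec_cond, network, table, rheology, solver_cfg
            )
            sim_results[cond] = result
            tcd_envelopes[cond] = synth_tcd_envelope(
                result.sim_envelope, bias, cfg.noise_cv, seed=tcd_substreams[cond]
            )
        cohort.append(
            SyntheticParticipant(
                id=f"P{i:02d}",
                network=network,
                recordings=recordings,
                sim_results=sim_results,
                tcd_envelopes=tcd_envelopes,
                bias=bias,
                ground_truth={
                    "rest_flows": rest_flows,
                    "response_factors": response,
                    "heart_rate_bpm": hr,
                    "bias": bias.as_dict(),
                },
            )
        )
    return cohort


def cohort_study_records(
    cohort: list[SyntheticParticipant],
) -> dict[str, dict[str, ConditionRecord]]:
    """Reduce a simulated cohort to the comparison module's input format."""
    out: dict[str, dict[str, ConditionRecord]] = {}
    for p in cohort:
        out[p.id] = {}
        for cond in CONDITIONS:
            cfd = extract_metrics(p.sim_results[cond].sim_envelope)
            tcd = extract_metrics(p.tcd_envelopes[cond])
            out[p.id][cond] = ConditionRecord(
                cfd=cfd, tcd=tcd, tcbf_ml_min=p.sim_results[cond].tcbf_ml_min
            )
    return out
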