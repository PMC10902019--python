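"""End-to-end participant pipeline: duplex recordings to M1 envelope.

Chains the processing stages for one participant and condition: ensemble
averaging of the raw duplex cycles, Poiseuille conversion to volumetric
flow, outlet boundary-condition generation, the quasi-steady network
solve, and extraction of the simulated M1 maximal-velocity envelope and
total cerebral blood flow.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .boundary_conditions import (
    RegionTable,
    SplitConfig,
    VascularNetwork,
    build_outlet_splits,
    default_region_table,
)
from .haemodynamics import NetworkSolution, RheologyParams, SolverConfig, solve_network
from .metrics import DEFAULT_STATION_FRACTIONS, m1_envelope
from .waveforms import DuplexRecording, SampledWaveform, ensemble_average, poiseuille_flow, total_cbf

__all__ = ["ParticipantResult", "simulate_condition"]


@dataclass(frozen=True)
class ParticipantResult:
    """Products of one participant-condition simulation."""

    inlet_flows: dict[str, SampledWaveform]  # artery -> mL/min
    tcbf_ml_min: float
    solution: NetworkSolution
    sim_envelope: SampledWaveform  # simulated M1 maximal-velocity envelope, cm/s


def simulate_condition(
    recordings: Mapping[str, DuplexRecording],
    network: VascularNetwork,
    regions: RegionTable | None = None,
    rheology: RheologyParams = RheologyParams(),
    solver_cfg: SolverConfig = SolverConfig(),
    split_cfg: SplitConfig = SplitConfig(),
    m1_segment_ids: Sequence[str] = ("R_MCA_M1",),
    station_fractions: Sequence[float] = DEFAULT_STATION_FRACTIONS,
    alignment_phase: float = 0.25,
) -> ParticipantResult:
    """Run the full flow-conserving simulation for one condition.

    ``recordings`` maps inflow-artery labels to duplex recordings; the
    network's inlet labels must match. Returns inlet flow waveforms, the
    total cerebral blood flow, the network solution, and the simulated
    TCD-style M1 envelope.
    """
    inlet_flows: dict[str, SampledWaveform] = {}
    for artery in network.inlets.values():
        rec = recordings[artery]
        ens = ensemble_average(rec.cycles, n_points=solver_cfg.n_phase, alignment_phase=alignment_phase)
        inlet_flows[artery] = poiseuille_flow(ens, rec.diameter_mm)
    tcbf = total_cbf(inlet_flows.values())
    table = regions if regions is not None else default_region_table()
    splits = build_outlet_splits(network, inlet_flows, table, split_cfg)
    sol = solve_network(network, inlet_flows, splits, rheology, solver_cfg)
    envelope = m1_envelope(sol, m1_segment_ids, station_fractions)
    return ParticipantResult(
        inlet_flows=inlet_flows, tcbf_ml_min=tcbf, solution=sol, sim_envelope=envelope
    )
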