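"""Outflow boundary-condition generation for Circle-of-Willis networks.

Measured inflow is first distributed across seven cerebral outflow
territories (left/right posterior, left/right middle, anterior,
cerebellum, ophthalmic) by a regional fraction table, then split among
the individual outlets of each territory by a Murray's-law rule

    Q_out_i = Q_in_region * d_i^n / sum_j d_j^n ,

with a flow-split exponent n = 2.33 by default. The resulting per-outlet
flow waveforms conserve the measured inflow exactly at every phase point
and can be exported as solver-ready boundary files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

from .waveforms import SampledWaveform, to_mass_flow, write_waveform_csv

__all__ = [
    "REGIONS",
    "Segment",
    "VascularNetwork",
    "RegionTable",
    "SplitConfig",
    "OutletSplit",
    "walnut_distribute",
    "murray_split",
    "build_outlet_splits",
    "extrusion_length",
    "load_network_json",
    "save_network_json",
    "load_region_table_json",
    "export_boundary_conditions",
]

#: The seven cerebral outflow territories.
REGIONS = (
    "left_posterior",
    "right_posterior",
    "left_middle",
    "right_middle",
    "anterior",
    "cerebellum",
    "ophthalmic",
)

#: Default flow-split exponent for the per-outlet Murray's-law split.
DEFAULT_SPLIT_EXPONENT = 2.33

#: Inlet/outlet extrusion length as a multiple of boundary diameter.
DEFAULT_EXTRUSION_MULTIPLIER = 11.0


@dataclass(frozen=True)
class Segment:
    """A uniform cylindrical vessel segment."""

    id: str
    from_node: str
    to_node: str
    length_mm: float
    diameter_mm: float
    name: str = ""

    def __post_init__(self) -> None:
        if not (self.length_mm > 0):
            raise ValueError(f"segment {self.id}: length must be > 0 mm")
        if not (self.diameter_mm > 0):
            raise ValueError(f"segment {self.id}: diameter must be > 0 mm")


@dataclass(frozen=True)
class VascularNetwork:
    """Graph of cylindrical segments with inlet/outlet boundary roles.

    ``inlets`` maps boundary nodes to inflow-artery labels (unique);
    ``outlets`` maps boundary nodes to one of the seven territory labels.
    """

    segments: tuple[Segment, ...]
    inlets: dict[str, str]
    outlets: dict[str, str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "segments", tuple(self.segments))
        nodes = self.nodes
        for node in list(self.inlets) + list(self.outlets):
            if node not in nodes:
                raise ValueError(f"boundary node {node!r} not in network")
        labels = list(self.inlets.values())
        if len(set(labels)) != len(labels):
            raise ValueError("inlet artery labels must be unique")
        for node, region in self.outlets.items():
            if region not in REGIONS:
                raise ValueError(
                    f"outlet {node!r}: unknown region {region!r}; expected one of {REGIONS}"
                )
        if set(self.inlets) & set(self.outlets):
            raise ValueError("a node cannot be both inlet and outlet")
        g = self.to_graph()
        if g.number_of_nodes() and not nx.is_connected(g):
            raise ValueError("network graph must be connected")

    @property
    def nodes(self) -> set[str]:
        out: set[str] = set()
        for seg in self.segments:
            out.add(seg.from_node)
            out.add(seg.to_node)
        return out

    def to_graph(self) -> nx.MultiGraph:
        g = nx.MultiGraph()
        for seg in self.segments:
            g.add_edge(seg.from_node, seg.to_node, key=seg.id, segment=seg)
        return g

    def segment(self, segment_id: str) -> Segment:
        for seg in self.segments:
            if seg.id == segment_id:
                return seg
        raise KeyError(segment_id)

    def outlets_in_region(self, region: str) -> list[str]:
        return [n for n, r in self.outlets.items() if r == region]

    def outlet_diameter(self, node: str) -> float:
        """Diameter of the (single) segment attached to an outlet node."""
        attached = [s for s in self.segments if node in (s.from_node, s.to_node)]
        if len(attached) != 1:
            raise ValueError(f"outlet node {node!r} must terminate exactly one segment")
        return attached[0].diameter_mm


@dataclass(frozen=True)
class RegionTable:
    """Fraction of total cerebral outflow assigned to each territory."""

    fractions: dict[str, float]

    def __post_init__(self) -> None:
        unknown = set(self.fractions) - set(REGIONS)
        if unknown:
            raise ValueError(f"unknown region names: {sorted(unknown)}")
        vals = np.array(list(self.fractions.values()), dtype=float)
        if np.any(vals <= 0):
            raise ValueError("all region fractions must be > 0")
        if abs(vals.sum() - 1.0) > 1e-12:
            raise ValueError(f"region fractions must sum to 1, got {vals.sum()!r}")

    def __getitem__(self, region: str) -> float:
        return self.fractions[region]


def default_region_table() -> RegionTable:
    """Provisional seven-territory fraction table.

    The regional distribution used by the original outflow scheme is not
    published alongside the method; these values are a physiologically
    plausible stand-in (middle cerebral territories dominate) used by the
    synthetic cohort and tests. Supply a study-specific table for real use.
    """
    return RegionTable(
        {
            "anterior": 0.18,
            "left_middle": 0.25,
            "right_middle": 0.25,
            "left_posterior": 0.10,
            "right_posterior": 0.10,
            "cerebellum": 0.09,
            "ophthalmic": 0.03,
        }
    )


@dataclass(frozen=True)
class SplitConfig:
    """Configuration of the per-outlet diameter-power flow split."""

    split_exponent: float = DEFAULT_SPLIT_EXPONENT

    def __post_init__(self) -> None:
        if not (self.split_exponent > 0):
            raise ValueError("split_exponent must be > 0")


@dataclass(frozen=True)
class OutletSplit:
    """Per-outlet share of total outflow and absolute outflow waveforms."""

    fractions: dict[str, float]
    flows: dict[str, SampledWaveform]  # mL/min, positive out of the domain

    def total_outflow(self) -> np.ndarray:
        return np.sum([w.values for w in self.flows.values()], axis=0)


# ---------------------------------------------------------------------------
# operations


def walnut_distribute(
    total_inflow: SampledWaveform, table: RegionTable | Mapping[str, float]
) -> dict[str, SampledWaveform]:
    """Split total inflow across territories by the regional fraction table."""
    if isinstance(table, RegionTable):
        fractions = table.fractions
    else:
        fractions = dict(table)
        total = sum(fractions.values())
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"region fractions must sum to 1, got {total!r}")
    return {
        region: total_inflow.with_values(frac * total_inflow.values)
        for region, frac in fractions.items()
    }


def murray_fractions(
    outlet_diameters: Sequence[float], cfg: SplitConfig = SplitConfig()
) -> np.ndarray:
    """Diameter-power flow-split fractions ``d_i^n / sum_j d_j^n``.

    Powers are computed in log space so that extreme exponents stay
    finite (the largest diameter is factored out before exponentiation).
    """
    d = np.asarray(outlet_diameters, dtype=float)
    if d.size == 0:
        raise ValueError("at least one outlet diameter is required")
    if np.any(d <= 0):
        raise ValueError("outlet diameters must be > 0")
    logw = cfg.split_exponent * np.log(d)
    logw -= logw.max()
    w = np.exp(logw)
    return w / w.sum()


def murray_split(
    region_inflow: SampledWaveform,
    outlet_diameters: Sequence[float],
    cfg: SplitConfig = SplitConfig(),
) -> list[SampledWaveform]:
    """Split one territory's inflow among its outlets by diameter power."""
    fractions = murray_fractions(outlet_diameters, cfg)
    return [region_inflow.with_values(f * region_inflow.values) for f in fractions]


def build_outlet_splits(
    net: VascularNetwork,
    inlet_flows: Mapping[str, SampledWaveform],
    table: RegionTable,
    cfg: SplitConfig = SplitConfig(),
) -> OutletSplit:
    """Distribute total measured inflow to every outlet of the network.

    Total inflow (sum over inlet arteries) is split across territories by
    ``table`` and within each territory across outlets by diameter power.
    Conservation holds at every phase point by construction.
    """
    flows = list(inlet_flows.values())
    if not flows:
        raise ValueError("at least one inlet flow is required")
    total = flows[0].with_values(np.sum([w.values for w in flows], axis=0))
    regional = walnut_distribute(total, table)
    fractions: dict[str, float] = {}
    out_flows: dict[str, SampledWaveform] = {}
    for region, region_flow in regional.items():
        outlets = net.outlets_in_region(region)
        if not outlets:
            raise ValueError(f"region {region!r} has positive fraction but no outlets")
        diam = [net.outlet_diameter(n) for n in outlets]
        local = murray_fractions(diam, cfg)
        for node, frac, flow in zip(outlets, local, murray_split(region_flow, diam, cfg)):
            fractions[node] = float(frac * table[region])
            out_flows[node] = flow
    uncovered = set(net.outlets) - set(out_flows)
    if uncovered:
        missing = {net.outlets[n] for n in uncovered}
        raise ValueError(f"outlets {sorted(uncovered)} have regions {missing} not in table")
    return OutletSplit(fractions, out_flows)


def extrusion_length(
    boundary_diameter_mm: float, multiplier: float = DEFAULT_EXTRUSION_MULTIPLIER
) -> float:
    """Flow-development extrusion length at a boundary: multiplier x diameter."""
    if not (boundary_diameter_mm > 0):
        raise ValueError("boundary diameter must be > 0 mm")
    if multiplier < 0:
        raise ValueError("extrusion multiplier must be >= 0")
    return multiplier * boundary_diameter_mm


# ---------------------------------------------------------------------------
# JSON / CSV interfaces


def load_network_json(path: str | Path) -> VascularNetwork:
    """Load a network description.

    Format: ``{"nodes": [...], "segments": [{"id","from","to","length_mm",
    "diameter_mm","name"}], "inlets": {node: artery}, "outlets": {node: region}}``.
    """
    with open(path, "r", encoding="utf-8") as fh:
        data = json.load(fh)
    segments = tuple(
        Segment(
            id=s["id"],
            from_node=s["from"],
            to_node=s["to"],
            length_mm=float(s["length_mm"]),
            diameter_mm=float(s["diameter_mm"]),
            name=s.get("name", ""),
        )
        for s in data["segments"]
    )
    return VascularNetwork(segments, dict(data["inlets"]), dict(data["outlets"]))


def save_network_json(net: VascularNetwork, path: str | Path) -> None:
    data = {
        "nodes": sorted(net.nodes),
        "segments": [
            {
                "id": s.id,
                "from": s.from_node,
                "to": s.to_node,
                "length_mm": s.length_mm,
                "diameter_mm": s.diameter_mm,
                "name": s.name,
            }
            for s in net.segments
        ],
        "inlets": net.inlets,
        "outlets": net.outlets,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(data, fh, indent=1)


def load_region_table_json(path: str | Path) -> RegionTable:
    """Load ``{region: fraction}``; unknown region names are rejected."""
    with open(path, "r", encoding="utf-8") as fh:
        data = json.load(fh)
    return RegionTable({str(k): float(v) for k, v in data.items()})


def export_boundary_conditions(
    net: VascularNetwork,
    inlet_flows: Mapping[str, SampledWaveform],
    splits: OutletSplit,
    out_dir: str | Path,
    density_kg_m3: float = 1050.0,
    extrusion_multiplier: float = DEFAULT_EXTRUSION_MULTIPLIER,
) -> None:
    """Write per-boundary flow CSVs and an extrusion manifest.

    Each boundary file has columns ``phase,flow_ml_min,massflow_kg_s``;
    the manifest lists every boundary with its diameter and extrusion
    length, consumable by an external 3D solver.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    inlet_by_label = dict(inlet_flows)
    manifest_rows = []

    def _write(node: str, role: str, label: str, q: SampledWaveform) -> None:
        mdot = to_mass_flow(q, density_kg_m3)
        fname = out_dir / f"bc_{node}.csv"
        with open(fname, "w", encoding="utf-8") as fh:
            fh.write(f"# node={node} role={role} label={label}\n")
            fh.write("phase,flow_ml_min,massflow_kg_s\n")
            for p, qv, mv in zip(q.phase, q.values, mdot.values):
                fh.write(f"{p:.10g},{qv:.10g},{mv:.10g}\n")
        d = net.outlet_diameter(node) if role == "outlet" else _inlet_diameter(net, node)
        manifest_rows.append((node, role, label, d, extrusion_length(d, extrusion_multiplier)))

    def _inlet_diameter(net: VascularNetwork, node: str) -> float:
        attached = [s for s in net.segments if node in (s.from_node, s.to_node)]
        return attached[0].diameter_mm

    for node, artery in net.inlets.items():
        _write(node, "inlet", artery, inlet_by_label[artery])
    for node, region in net.outlets.items():
        _write(node, "outlet", region, splits.flows[node])

    with open(out_dir / "manifest.csv", "w", encoding="utf-8") as fh:
        fh.write("node,role,label,diameter_mm,extrusion_mm\n")
        for row in manifest_rows:
            fh.write(f"{row[0]},{row[1]},{row[2]},{row[3]:.6g},{row[4]:.6g}\n")
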