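import numpy as np
import pytest

import cowflow as cf


@pytest.fixture
def constant_flow():
    """Constant 300 mL/min flow waveform on a 32-point phase grid."""
    return cf.SampledWaveform(np.full(32, 300.0), 1.0, "mL/min")


@pytest.fixture
def single_tube():
    """One 100 mm x 4 mm tube from inlet A to outlet B (left middle territory)."""
    seg = cf.Segment("T", "A", "B", 100.0, 4.0)
    net = cf.VascularNetwork((seg,), {"A": "LICA"}, {"B": "left_middle"})
    table = cf.RegionTable({"left_middle": 1.0})
    return net, table


@pytest.fixture
def symmetric_y():
    """Symmetric bifurcation: parent tube splitting into two equal daughters."""
    segs = (
        cf.Segment("P", "A", "J", 50.0, 4.0),
        cf.Segment("D1", "J", "B1", 40.0, 3.0),
        cf.Segment("D2", "J", "B2", 40.0, 3.0),
    )
    net = cf.VascularNetwork(
        segs, {"A": "LICA"}, {"B1": "left_middle", "B2": "right_middle"}
    )
    table = cf.RegionTable({"left_middle": 0.5, "right_middle": 0.5})
    return net, table


@pytest.fixture(scope="session")
def small_cohort():
    """Deterministic 4-participant cohort with the default study conditions."""
    return cf.synth_cohort(cf.CohortConfig(n_participants=4, master_seed=7))


def random_flow_network(rng: np.random.Generator, n_extra: int = 4, with_loop: bool = False):
    """Random connected flow network: a tree plus optional chord edges.

    Returns (network, region table) with one inlet at the root and every
    leaf an outlet, territories assigned round-robin.
    """
    nodes = ["n0"]
    segments = []
    for i in range(1, n_extra + 2):
        parent = nodes[rng.integers(len(nodes))]
        child = f"n{i}"
        segments.append(
            cf.Segment(
                f"s{i}", parent, child,
                float(rng.uniform(10, 80)), float(rng.uniform(1.5, 5.0)),
            )
        )
        nodes.append(child)
    if with_loop and len(nodes) >= 4:
        a, b = rng.choice(len(nodes), size=2, replace=False)
        segments.append(
            cf.Segment(
                "chord", nodes[a], nodes[b],
                float(rng.uniform(10, 80)), float(rng.uniform(1.5, 5.0)),
            )
        )
    degree: dict[str, int] = {}
    for s in segments:
        degree[s.from_node] = degree.get(s.from_node, 0) + 1
        degree[s.to_node] = degree.get(s.to_node, 0) + 1
    leaves = [n for n in nodes[1:] if degree[n] == 1]
    if not leaves:  # chord made every non-root node interior; retry without it
        return random_flow_network(rng, n_extra, with_loop=False)
    regions = [cf.REGIONS[i % len(cf.REGIONS)] for i in range(len(leaves))]
    outlets = dict(zip(leaves, regions))
    used_regions = sorted(set(regions))
    frac = 1.0 / len(used_regions)
    fracs = {r: frac for r in used_regions}
    # make fractions sum exactly to 1
    fracs[used_regions[-1]] = 1.0 - frac * (len(used_regions) - 1)
    net = cf.VascularNetwork(tuple(segments), {"n0": "LICA"}, outlets)
    return net, cf.RegionTable(fracs)
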