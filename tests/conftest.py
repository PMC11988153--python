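import networkx as nx
import numpy as np
import pytest

from pigsna import AnalysisConfig, PenRoster, make_toy_records
from pigsna.proximity import ContactNetwork

T0 = 6 * 3600  # window start, seconds since midnight


@pytest.fixture
def config():
    return AnalysisConfig()


@pytest.fixture
def five_pig_roster():
    return PenRoster("pen1", ("A", "B", "C", "D", "E"), (6.0, 3.0))


@pytest.fixture
def seven_bout_scene(five_pig_roster):
    """Hand-worked scripted scenario with exactly 7 known proximity bouts.

    Scenes are time-disjoint, so only the scripted dyad can interact:

    * S1  A-B at 0.40 m for 120 s                         -> bout 120 s
    * S2  C-D at exactly 0.50 m for 200 s                 -> bout 200 s
    * S3  A-E at 0.20 m, E missing one sample (10 s gap)  -> merged bout 100 s
    * S4  B-C at 0.30 m, C jumps away at one mid sample   -> bouts 45 s + 45 s
    * S5  D-E at 0.40 m for 60 s                          -> bout 60 s
    * S6  A-D at 0.30 m for 30 s                          -> bout 30 s
    * S1 also scripts C lying right next to A-B: excluded by posture filter.

    Mean raw duration = 600/7 s; qualifying (> mean): 120, 200, 100 s.
    """
    script = [
        # S1
        ("A", (T0, T0 + 120), "standing", [(1.0, 1.0)]),
        ("B", (T0, T0 + 120), "standing", [(1.4, 1.0)]),
        ("C", (T0, T0 + 120), "lying", [(1.2, 1.0)]),
        # S2 (exactly at the 0.5 m threshold)
        ("C", (T0 + 200, T0 + 400), "standing", [(1.0, 1.0)]),
        ("D", (T0 + 200, T0 + 400), "standing", [(1.5, 1.0)]),
        # S3 (dropout gap of 10 s bridged by gap_tolerance_s)
        ("A", (T0 + 500, T0 + 600), "standing", [(1.0, 1.0)]),
        ("E", (T0 + 500, T0 + 550), "standing", [(1.2, 1.0)]),
        ("E", (T0 + 560, T0 + 600), "standing", [(1.2, 1.0)]),
        # S4 (failing common sample at T0+750 splits the bout, no merge)
        ("B", (T0 + 700, T0 + 800), "standing", [(1.0, 1.0)]),
        ("C", (T0 + 700, T0 + 745), "standing", [(1.3, 1.0)]),
        ("C", (T0 + 750, T0 + 750), "standing", [(2.5, 1.0)]),
        ("C", (T0 + 755, T0 + 800), "standing", [(1.3, 1.0)]),
        # S5
        ("D", (T0 + 900, T0 + 960), "standing", [(2.0, 2.0)]),
        ("E", (T0 + 900, T0 + 960), "standing", [(2.4, 2.0)]),
        # S6
        ("A", (T0 + 1000, T0 + 1030), "standing", [(0.5, 0.5)]),
        ("D", (T0 + 1000, T0 + 1030), "standing", [(0.8, 0.5)]),
    ]
    records = make_toy_records(script, sampling_interval_s=5.0)
    expected_bouts = {
        ("A", "B", T0, T0 + 120),
        ("C", "D", T0 + 200, T0 + 400),
        ("A", "E", T0 + 500, T0 + 600),
        ("B", "C", T0 + 700, T0 + 745),
        ("B", "C", T0 + 755, T0 + 800),
        ("D", "E", T0 + 900, T0 + 960),
        ("A", "D", T0 + 1000, T0 + 1030),
    }
    expected_qualifying = {
        ("A", "B", T0, T0 + 120),
        ("C", "D", T0 + 200, T0 + 400),
        ("A", "E", T0 + 500, T0 + 600),
    }
    return records, expected_bouts, expected_qualifying


def graph_to_network(g: nx.Graph, pen_id="pen1", day=1, period="early",
                     default_weight=1.0) -> ContactNetwork:
    """Wrap a bare networkx graph as a ContactNetwork (string node names)."""
    h = nx.Graph()
    mapping = {v: str(v) for v in g.nodes}
    h.add_nodes_from(mapping.values())
    for u, v, d in g.edges(data=True):
        h.add_edge(mapping[u], mapping[v], weight=float(d.get("weight", default_weight)))
    roster = PenRoster(pen_id, tuple(sorted(h.nodes, key=lambda s: (len(s), s))))
    return ContactNetwork(pen_id, day, period, h, roster)


def random_weighted_graph(rng: np.random.Generator, n: int, p: float,
                          max_weight: float = 10.0) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                g.add_edge(i, j, weight=float(rng.integers(1, int(max_weight) + 1)))
    return g
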