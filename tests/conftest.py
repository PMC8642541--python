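import numpy as np
import pandas as pd
import pytest

from modcrn.network import InteractionNetwork


def make_network(edges, nodes=()):
    """Build a network from (u, v) or (u, v, score) tuples; default score 0.9."""
    scored = {}
    for e in edges:
        u, v = e[0], e[1]
        s = e[2] if len(e) > 2 else 0.9
        scored[(min(u, v), max(u, v))] = s
    return InteractionNetwork.from_scored_edges(scored, extra_nodes=nodes)


@pytest.fixture
def triangle():
    return make_network([("a", "b"), ("b", "c"), ("a", "c")])


@pytest.fixture
def k4_pendant():
    """K4 on {a,b,c,d} plus pendant p attached to a."""
    base = [(u, v) for i, u in enumerate("abcd") for v in "abcd"[i + 1:]]
    return make_network(base + [("a", "p")])


@pytest.fixture
def small_expr():
    """3 genes x 4 samples (one organ, 2 treated / 2 control)."""
    expr = pd.DataFrame(
        [[5.0, 5.1, 6.0, 6.2], [7.0, 7.0, 7.0, 7.0], [8.0, 8.1, 7.2, 7.1]],
        index=["g1", "g2", "g3"],
        columns=["s1", "s2", "s3", "s4"],
    )
    meta = pd.DataFrame(
        {
            "organ": ["lung"] * 4,
            "treatment": ["control", "control", "treated", "treated"],
        },
        index=pd.Index(expr.columns, name="sample"),
    )
    return expr, meta


def two_organ_meta(n_per_cell=3):
    rows = []
    for organ in ("liver", "lung"):
        for treatment in ("control", "treated"):
            for i in range(1, n_per_cell + 1):
                rows.append((f"{organ}_{treatment}_{i}", organ, treatment))
    df = pd.DataFrame(rows, columns=["sample", "organ", "treatment"])
    return df.set_index("sample")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20231115)
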