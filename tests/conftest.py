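import networkx as nx
import numpy as np
import pytest

from trialnet.network import YearlyNetwork
from trialnet.records_io import AuthorSlot, PublicationRecord
from trialnet.synthetic_data import SimulationConfig, simulate_corpus


def make_record(
    record_id="R0",
    year=1970,
    authors=("A_Ann", "B_Bob", "C_Cyd"),
    subspecialties=None,
    citations=100,
    randomized=True,
    update_index=0,
    pooled=None,
    tier=2,
    equal_contrib=(),
):
    """Convenience constructor for a valid publication record."""
    weights = subspecialties or {"breast": 1.0}
    return PublicationRecord(
        record_id=record_id,
        year=year,
        journal_tier=tier,
        randomized=randomized,
        update_index=update_index,
        pooled_update_indices=pooled,
        citations=citations,
        subspecialty_weights=dict(weights),
        authors=[
            AuthorSlot(raw_name=name, position=i + 1, equal_contrib=(i + 1) in equal_contrib)
            for i, name in enumerate(authors)
        ],
    )


def make_network(edges, node_attrs=None, year=2000, extra_nodes=()):
    """Build a YearlyNetwork from (u, v, weight) triples and attribute dicts.

    ``node_attrs`` maps attribute name -> {node: value}.
    """
    g = nx.MultiGraph()
    for u, v, w in edges:
        g.add_edge(u, v, weight=w, record_id="R0")
    g.add_nodes_from(extra_nodes)
    if node_attrs:
        for name, mapping in node_attrs.items():
            nx.set_node_attributes(g, mapping, name)
    return YearlyNetwork(year=year, graph=g)


@pytest.fixture(scope="session")
def default_corpus():
    """One default-scale synthetic corpus with its ground truth (seed 1)."""
    return simulate_corpus(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def tiny_corpus():
    """A fast, small synthetic corpus (two decades, few papers)."""
    cfg = SimulationConfig(
        seed=7, start_year=1990, end_year=2010, papers_rate_start=0.8, papers_rate_end=2.5,
        team_median_start=4, team_median_end=8, n_subspecialties=4,
    )
    return simulate_corpus(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
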