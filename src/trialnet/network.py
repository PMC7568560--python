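"""Cumulative yearly co-authorship networks and their metrics.

The network is a weighted multigraph: nodes are canonical authors and every
manuscript contributes one edge per unordered pair of its authors, weighted
by the product of the pair's manuscript-specific impact scores divided by the
number of authors on the manuscript.  Dividing by team size damps any single
link on a large multi-author paper while letting the total weight of the
paper's neighbourhood grow linearly with team size.  Duplicate edges between
a pair (from different manuscripts) are kept in the multigraph; all global
metrics run on the *simple-graph view*, where parallel edges collapse to one
with their weights summed.

Networks are discretized by calendar year and cumulative: the network at
year Y contains every author and co-authorship from the start of the corpus
through Y.  :class:`CumulativeNetworkBuilder` supports the incremental
year-by-year construction used by the temporal metric series, which is
guaranteed (and tested) to match building each year from scratch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .careers import NONE_LABEL, compute_careers, primary_label_at
from .impact import ImpactConfig, ImpactLedger, corpus_max_citations, cumulative_impact, manuscript_score
from .records_io import PublicationRecord

__all__ = [
    "YearlyNetwork",
    "CumulativeNetworkBuilder",
    "DegenerateGraphError",
    "coauthorship_weight",
    "build_network",
    "density",
    "density_from_counts",
    "modularity_by_attribute",
    "assortativity_by_attribute",
    "betweenness",
    "pagerank",
    "homophily",
    "concentration",
    "largest_component_share",
    "yearly_metric_series",
    "export_graphml",
]


class DegenerateGraphError(ValueError):
    """Raised when a metric is undefined on the given graph (too small, no
    edges, or a single attribute category)."""


def coauthorship_weight(score_i: float, score_j: float, n_authors: int) -> float:
    """Edge weight for one manuscript pair: ``score_i * score_j / n_authors``."""
    if n_authors < 2:
        raise ValueError("a co-authorship pair requires at least 2 authors")
    return score_i * score_j / n_authors


@dataclass
class YearlyNetwork:
    """The cumulative co-authorship network discretized at ``year``."""

    year: int
    graph: nx.MultiGraph
    _simple: nx.Graph | None = field(default=None, repr=False, compare=False)

    def simple_view(self) -> nx.Graph:
        """Deduplicated pair view: parallel edges merged, weights summed,
        and ``distance = 1 / weight`` attached for shortest-path metrics."""
        if self._simple is None:
            G = nx.Graph()
            G.add_nodes_from(self.graph.nodes(data=True))
            for u, v, d in self.graph.edges(data=True):
                w = d.get("weight", 0.0)
                if G.has_edge(u, v):
                    G[u][v]["weight"] += w
                else:
                    G.add_edge(u, v, weight=w)
            for u, v, d in G.edges(data=True):
                d["distance"] = 1.0 / d["weight"] if d["weight"] > 0 else math.inf
            self._simple = G
        return self._simple

    @property
    def n_authors(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_distinct_pairs(self) -> int:
        return self.simple_view().number_of_edges()


class CumulativeNetworkBuilder:
    """Incrementally grow the cumulative multigraph record by record."""

    def __init__(
        self,
        key_map: Mapping[str, str],
        max_citations: int,
        tier_median_table: Mapping[int, float] | None = None,
        config: ImpactConfig = ImpactConfig(),
    ) -> None:
        self.key_map = key_map
        self.max_citations = max_citations
        self.tier_median_table = tier_median_table
        self.config = config
        self.graph = nx.MultiGraph()

    def add_record(self, rec: PublicationRecord) -> None:
        n = len(rec.authors)
        scored = [
            (
                self.key_map[slot.raw_name],
                manuscript_score(slot, rec, self.max_citations, self.tier_median_table, self.config),
            )
            for slot in rec.authors
        ]
        for key, _ in scored:
            if key not in self.graph:
                self.graph.add_node(key)
        for i in range(n):
            for j in range(i + 1, n):
                ki, si = scored[i]
                kj, sj = scored[j]
                if ki == kj:
                    continue  # merged duplicate listing; no self-loops
                self.graph.add_edge(ki, kj, record_id=rec.record_id, weight=coauthorship_weight(si, sj, n))

    def snapshot(self, year: int, node_attrs: Mapping[str, Mapping[str, object]] | None = None) -> YearlyNetwork:
        """A frozen copy of the current state, labelled with ``year``.

        ``node_attrs`` maps attribute name -> {node: value} (e.g. cumulative
        impact, gender, primary subspecialty at this year).
        """
        G = self.graph.copy()
        if node_attrs:
            for name, values in node_attrs.items():
                nx.set_node_attributes(G, dict(values), name)
        return YearlyNetwork(year=year, graph=G)


def build_network(
    records: Sequence[PublicationRecord],
    key_map: Mapping[str, str],
    up_to_year: int,
    ledger: ImpactLedger | None = None,
    node_attrs: Mapping[str, Mapping[str, object]] | None = None,
    tier_median_table: Mapping[int, float] | None = None,
    config: ImpactConfig = ImpactConfig(),
    max_citations: int | None = None,
) -> YearlyNetwork:
    """Build the cumulative network at ``up_to_year`` from scratch.

    If ``ledger`` is given, each node carries its cumulative ``impact``
    attribute; further per-node attributes can be supplied via
    ``node_attrs``.
    """
    if max_citations is None:
        max_citations = corpus_max_citations(records)
    builder = CumulativeNetworkBuilder(key_map, max_citations, tier_median_table, config)
    for rec in sorted(records, key=lambda r: (r.year, r.record_id)):
        if rec.year <= up_to_year:
            builder.add_record(rec)
    attrs: dict[str, Mapping[str, object]] = {}
    if ledger is not None:
        attrs["impact"] = ledger.total_by_author(up_to_year)
    if node_attrs:
        attrs.update(node_attrs)
    return builder.snapshot(up_to_year, attrs)


# ---------------------------------------------------------------------------
# Global metrics
# ---------------------------------------------------------------------------

def density_from_counts(n_authors: int, n_distinct_pairs: int) -> float:
    """Fraction of realized co-author pairs among all possible pairs."""
    if n_authors < 2:
        raise DegenerateGraphError("density undefined for fewer than 2 authors")
    return n_distinct_pairs / (n_authors * (n_authors - 1) / 2)


def density(net: YearlyNetwork) -> float:
    """Network density on the simple-graph view (multi-edges collapse)."""
    return density_from_counts(net.n_authors, net.n_distinct_pairs)


def _node_communities(net: YearlyNetwork, attribute: str) -> list[set]:
    groups: dict[object, set] = {}
    for n, d in net.graph.nodes(data=True):
        label = d.get(attribute, NONE_LABEL)
        if isinstance(label, tuple):  # equal-split assignment: first tied label
            label = label[0]
        groups.setdefault(label, set()).add(n)
    return list(groups.values())


def modularity_by_attribute(net: YearlyNetwork, attribute: str = "subspecialty") -> float:
    """Weighted Newman modularity of the partition induced by a node attribute.

    The share of edge weight inside each attribute class minus the share
    expected if edges were rewired preserving weighted degrees.  Authors with
    no label form their own ``"None"`` community.
    """
    G = net.simple_view()
    if G.number_of_edges() == 0:
        raise DegenerateGraphError("modularity undefined without edges")
    return nx.community.modularity(G, _node_communities(net, attribute), weight="weight")


def assortativity_by_attribute(
    net: YearlyNetwork, attribute: str = "subspecialty", weighted: bool = True
) -> float:
    """Weighted categorical assortativity coefficient in [-1, 1].

    Computed from the weighted mixing matrix ``e`` over attribute classes:
    ``r = (sum_i e_ii - sum_i a_i b_i) / (1 - sum_i a_i b_i)``.  Positive when
    like connects to like; -1 for a perfectly disassortative (bipartite-like)
    structure.
    """
    G = net.simple_view()
    labels = {}
    for n, d in net.graph.nodes(data=True):
        lab = d.get(attribute, NONE_LABEL)
        labels[n] = lab[0] if isinstance(lab, tuple) else lab
    cats = sorted({labels[n] for n in G})
    if len(cats) < 2:
        raise DegenerateGraphError("assortativity undefined with a single category")
    idx = {c: i for i, c in enumerate(cats)}
    k = len(cats)
    e = [[0.0] * k for _ in range(k)]
    total = 0.0
    for u, v, d in G.edges(data=True):
        w = d["weight"] if weighted else 1.0
        i, j = idx[labels[u]], idx[labels[v]]
        e[i][j] += w
        e[j][i] += w
        total += 2 * w
    if total == 0:
        raise DegenerateGraphError("assortativity undefined without (weighted) edges")
    e = [[x / total for x in row] for row in e]
    trace = sum(e[i][i] for i in range(k))
    a = [sum(row) for row in e]
    b = [sum(e[i][j] for i in range(k)) for j in range(k)]
    ab = sum(a[i] * b[i] for i in range(k))
    if math.isclose(ab, 1.0, abs_tol=1e-15):
        raise DegenerateGraphError("assortativity undefined: all edge mass in one category")
    return (trace - ab) / (1 - ab)


def betweenness(
    net: YearlyNetwork, weighted: bool = True, relative_to_max: bool = False
) -> dict[str, float]:
    """Shortest-path betweenness centrality per author.

    With ``weighted=True`` the path length of an edge is the reciprocal of
    its summed co-authorship weight, so stronger collaborations are shorter
    bridges.  Scores are normalized by the number of node pairs; with
    ``relative_to_max`` they are rescaled so the top author scores 1.
    """
    G = net.simple_view()
    scores = nx.betweenness_centrality(G, weight="distance" if weighted else None, normalized=True)
    if relative_to_max:
        top = max(scores.values(), default=0.0)
        if top > 0:
            scores = {n: s / top for n, s in scores.items()}
    return scores


def pagerank(net: YearlyNetwork, damping: float = 0.85, weighted: bool = True) -> dict[str, float]:
    """Stationary random-walk probability per author; sums to 1.

    Edge weights act as transition propensities on the undirected simple
    view.  Convergence failure past the iteration cap is raised by the solver
    with its residual.
    """
    G = net.simple_view()
    if G.number_of_nodes() == 0:
        raise DegenerateGraphError("pagerank undefined on an empty network")
    return nx.pagerank(G, alpha=damping, weight="weight" if weighted else None, tol=1e-12, max_iter=1000)


def homophily(
    net: YearlyNetwork,
    attribute: str,
    mode: str = "neighbors",
    exclude_values: Iterable[object] = (),
) -> dict[str, float]:
    """Per-author fraction of same-attribute collaboration, in [0, 1].

    ``mode="neighbors"`` counts the share of *distinct* co-authors whose
    attribute matches the ego's; ``mode="outlinks"`` weights each co-author
    by the summed co-authorship weight of the link.  Authors whose own
    attribute is missing or in ``exclude_values``, or who have no co-authors,
    are omitted (homophily is not calculable for them).
    """
    if mode not in ("neighbors", "outlinks"):
        raise ValueError(f"unknown homophily mode {mode!r}")
    excluded = set(exclude_values) | {None}
    G = net.simple_view()
    labels = {}
    for n, d in net.graph.nodes(data=True):
        lab = d.get(attribute)
        labels[n] = lab[0] if isinstance(lab, tuple) else lab
    out: dict[str, float] = {}
    for node in G:
        own = labels.get(node)
        if own in excluded:
            continue
        nbrs = list(G.neighbors(node))
        if not nbrs:
            continue
        if mode == "neighbors":
            matched = sum(1 for m in nbrs if labels.get(m) == own)
            out[node] = matched / len(nbrs)
        else:
            tot = sum(G[node][m]["weight"] for m in nbrs)
            if tot <= 0:
                continue
            matched_w = sum(G[node][m]["weight"] for m in nbrs if labels.get(m) == own)
            out[node] = matched_w / tot
    return out


def concentration(
    net: YearlyNetwork,
    impact_by_author: Mapping[str, float],
    top_fraction: float = 0.10,
) -> tuple[float, float]:
    """Share of links and of impact held by the top ``top_fraction`` of authors.

    Authors are ranked by cumulative impact (ties broken by key), the top
    ``ceil(fraction * n)`` selected, and their share of multigraph edge
    endpoints and of total impact returned.
    """
    if not 0 < top_fraction < 1:
        raise ValueError("top_fraction must be in (0, 1)")
    nodes = list(net.graph.nodes)
    if not nodes:
        raise DegenerateGraphError("concentration undefined on an empty network")
    ranked = sorted(nodes, key=lambda n: (-impact_by_author.get(n, 0.0), n))
    top = set(ranked[: math.ceil(top_fraction * len(nodes))])
    endpoints = 0
    total_endpoints = 0
    for u, v in net.graph.edges():
        endpoints += (u in top) + (v in top)
        total_endpoints += 2
    total_impact = sum(impact_by_author.get(n, 0.0) for n in nodes)
    top_impact = sum(impact_by_author.get(n, 0.0) for n in top)
    link_share = endpoints / total_endpoints if total_endpoints else 0.0
    impact_share = top_impact / total_impact if total_impact > 0 else 0.0
    return link_share, impact_share


def largest_component_share(net: YearlyNetwork) -> float:
    """Fraction of authors inside the largest connected component."""
    n = net.n_authors
    if n == 0:
        raise DegenerateGraphError("empty network")
    return max(len(c) for c in nx.connected_components(net.graph)) / n


# ---------------------------------------------------------------------------
# Temporal series and export
# ---------------------------------------------------------------------------

def yearly_metric_series(
    records: Sequence[PublicationRecord],
    key_map: Mapping[str, str],
    tier_median_table: Mapping[int, float] | None = None,
    config: ImpactConfig = ImpactConfig(),
    gender_by_author: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per-year cumulative network metrics, built incrementally.

    Returns a DataFrame indexed by year with columns ``n_authors``,
    ``n_links`` (multigraph), ``n_pairs`` (distinct), ``density``,
    ``modularity``, ``assortativity``, ``median_pagerank`` and ``lcc_share``.
    Modularity and assortativity use the primary-subspecialty partition in
    force at each year and are NaN where undefined (e.g. a single
    subspecialty present).
    """
    records = sorted(records, key=lambda r: (r.year, r.record_id))
    if not records:
        raise ValueError("empty corpus")
    ledger = cumulative_impact(records, key_map, None, tier_median_table, config)
    careers = compute_careers(records, key_map, ledger)
    max_cit = corpus_max_citations(records)
    builder = CumulativeNetworkBuilder(key_map, max_cit, tier_median_table, config)

    rows = []
    years = range(records[0].year, records[-1].year + 1)
    rec_iter = iter(records)
    pending = next(rec_iter, None)
    for year in years:
        while pending is not None and pending.year <= year:
            builder.add_record(pending)
            pending = next(rec_iter, None)
        attrs: dict[str, Mapping[str, object]] = {
            "impact": ledger.total_by_author(year),
            "subspecialty": {
                a: primary_label_at(c, year) for a, c in careers.items() if c.first_year <= year
            },
        }
        if gender_by_author is not None:
            attrs["gender"] = gender_by_author
        net = builder.snapshot(year, attrs)
        n = net.n_authors
        row: dict[str, float] = {
            "year": year,
            "n_authors": n,
            "n_links": net.graph.number_of_edges(),
            "n_pairs": net.n_distinct_pairs,
        }
        row["density"] = density(net) if n >= 2 else float("nan")
        try:
            row["modularity"] = modularity_by_attribute(net, "subspecialty")
        except DegenerateGraphError:
            row["modularity"] = float("nan")
        try:
            row["assortativity"] = assortativity_by_attribute(net, "subspecialty")
        except DegenerateGraphError:
            row["assortativity"] = float("nan")
        if n >= 1:
            pr = pagerank(net)
            row["median_pagerank"] = float(pd.Series(pr).median())
            row["lcc_share"] = largest_component_share(net)
        else:
            row["median_pagerank"] = float("nan")
            row["lcc_share"] = float("nan")
        rows.append(row)
    return pd.DataFrame(rows).set_index("year")


def export_graphml(net: YearlyNetwork, path: str | Path, simple: bool = True) -> Path:
    """Write the network (simple view by default) to GraphML.

    Tuple-valued equal-split subspecialty labels are flattened to a
    ``|``-joined string for GraphML compatibility.
    """
    G = (net.simple_view() if simple else net.graph).copy()
    for _, d in G.nodes(data=True):
        for k, v in list(d.items()):
            if isinstance(v, tuple):
                d[k] = "|".join(map(str, v))
            elif v is None:
                d[k] = ""
    nx.write_graphml(G, str(path))
    return Path(path)
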