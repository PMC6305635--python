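"""Median-joining network construction over binary haplotypes.

The median-joining (MJ) method builds an intraspecific phylogenetic graph
in two phases.  First a minimum spanning network (MSN) is built: every
link that occurs in at least one minimum spanning tree of the haplotypes
under the (weighted) Hamming distance, optionally relaxed by a tolerance
epsilon.  Then, iteratively, for each triple of mutually linked nodes the
median (site-wise majority, for binary characters) is computed; cheap
medians are added as inferred "median vectors" and the MSN is rebuilt,
until no median can be added.  Finally, obsolete median vectors are
pruned.  The resulting network approximates the minimal Steiner tree
connecting the sampled haplotypes.

Node identity throughout is the state tuple; sampled nodes carry a
frequency/count weight, median vectors are flagged ``median`` and named
mv1, mv2, ... in insertion order.  All tie-prone steps iterate nodes in
lexicographic pattern order, so construction is fully deterministic.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .haplotype_core import (
    DEFAULT_SITE_MAP,
    Haplotype,
    HaplotypeError,
    SiteMap,
    format_haplotype,
)

__all__ = [
    "NetworkParams",
    "HaploNetwork",
    "minimum_spanning_network",
    "median_vector",
    "mj_construct",
    "export_network",
]

logger = logging.getLogger(__name__)

States = tuple[int, ...]


@dataclass(frozen=True)
class NetworkParams:
    """MJ construction parameters.

    Attributes
    ----------
    epsilon
        Weighted-distance tolerance; 0 gives the strict MSN / MJ network,
        larger values admit longer alternative links and costlier medians.
    weights
        Positive integer weight per site; ``None`` means unit weights.
    """

    epsilon: int = 0
    weights: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")
        if self.weights is not None and any(w <= 0 for w in self.weights):
            raise ValueError("site weights must be positive")


@dataclass
class HaploNetwork:
    """A haplotype network: sampled nodes, median vectors and their links.

    Thin wrapper over a :class:`networkx.Graph` whose node keys are state
    tuples.  Node attributes: ``sampled`` (bool), ``weight`` (sampled
    frequency/count), ``label``.  Edge attributes: ``length`` (weighted
    Hamming distance) and ``sites`` (indices of differing sites).
    """

    graph: nx.Graph
    site_map: SiteMap = DEFAULT_SITE_MAP

    @property
    def sampled_nodes(self) -> list[States]:
        return sorted(n for n, d in self.graph.nodes(data=True) if d["sampled"])

    @property
    def median_nodes(self) -> list[States]:
        return sorted(n for n, d in self.graph.nodes(data=True) if not d["sampled"])

    def total_length(self) -> float:
        return sum(d["length"] for _, _, d in self.graph.edges(data=True))

    def is_connected(self) -> bool:
        return nx.is_connected(self.graph)


def _weights(params: NetworkParams, L: int) -> np.ndarray:
    if params.weights is None:
        return np.ones(L)
    if len(params.weights) != L:
        raise HaplotypeError(
            f"{len(params.weights)} site weights for {L} sites"
        )
    return np.asarray(params.weights, dtype=float)


def _wdist(a: States, b: States, w: np.ndarray) -> float:
    return float(sum(wi for ai, bi, wi in zip(a, b, w) if ai != bi))


def _normalise_input(
    haplotypes,
) -> dict[States, tuple[float, str | None]]:
    """Accept {Haplotype: weight}, iterable of Haplotype, or iterable of
    (Haplotype, weight); return {states: (weight, label)}."""
    out: dict[States, tuple[float, str | None]] = {}
    if isinstance(haplotypes, dict):
        items = list(haplotypes.items())
    else:
        items = []
        for entry in haplotypes:
            if (
                isinstance(entry, tuple)
                and len(entry) == 2
                and isinstance(entry[0], (Haplotype, tuple))
                and isinstance(entry[1], (int, float))
            ):
                items.append(entry)
            else:
                items.append((entry, 1.0))
    for h, wt in items:
        states = h.states if isinstance(h, Haplotype) else tuple(h)
        label = h.label if isinstance(h, Haplotype) else None
        prev = out.get(states)
        out[states] = ((prev[0] if prev else 0.0) + float(wt), label or (prev[1] if prev else None))
    if not out:
        raise HaplotypeError("need at least one haplotype")
    lengths = {len(s) for s in out}
    if len(lengths) != 1:
        raise HaplotypeError(f"inconsistent haplotype lengths: {sorted(lengths)}")
    return out


class _DSU:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb


def _msn_links(
    nodes: list[States], w: np.ndarray, epsilon: float
) -> list[tuple[States, States, float]]:
    """Links of the epsilon-relaxed minimum spanning network.

    Length classes are processed in increasing order; a link of length d
    is kept iff its endpoints are not already connected by kept links of
    length < d - epsilon.  With epsilon = 0 this keeps exactly the links
    occurring in at least one minimum spanning tree (the cycle property).
    """
    pairs = [
        (a, b, _wdist(a, b, w)) for a, b in itertools.combinations(sorted(nodes), 2)
    ]
    kept: list[tuple[States, States, float]] = []
    for d in sorted({d for _, _, d in pairs}):
        dsu = _DSU(nodes)
        for a, b, dk in kept:
            if dk < d - epsilon:
                dsu.union(a, b)
        for a, b, dp in pairs:
            if dp == d and dsu.find(a) != dsu.find(b):
                kept.append((a, b, dp))
    return kept


def _build_graph(
    node_info: dict[States, tuple[float, str | None]],
    links: list[tuple[States, States, float]],
    site_map: SiteMap,
    median_names: dict[States, str],
) -> HaploNetwork:
    g = nx.Graph()
    for states in sorted(node_info):
        wt, label = node_info[states]
        sampled = states not in median_names
        g.add_node(
            states,
            sampled=sampled,
            weight=wt if sampled else 0.0,
            label=(median_names.get(states) or label or format_haplotype(states, sep="")),
        )
    for a, b, d in links:
        sites = tuple(i for i, (x, y) in enumerate(zip(a, b)) if x != y)
        g.add_edge(a, b, length=d, sites=sites)
    return HaploNetwork(graph=g, site_map=site_map)


def minimum_spanning_network(
    haplotypes,
    params: NetworkParams = NetworkParams(),
    site_map: SiteMap = DEFAULT_SITE_MAP,
) -> HaploNetwork:
    """Epsilon-relaxed minimum spanning network over sampled haplotypes.

    The result is connected and contains every minimum spanning tree of
    the input under the weighted Hamming distance (plus any links admitted
    by the epsilon relaxation).
    """
    info = _normalise_input(haplotypes)
    L = len(next(iter(info)))
    w = _weights(params, L)
    links = _msn_links(sorted(info), w, float(params.epsilon))
    return _build_graph(info, links, site_map, median_names={})


def median_vector(
    a: Haplotype | States, b: Haplotype | States, c: Haplotype | States
) -> Haplotype:
    """Site-wise majority of three haplotypes (the binary-state median)."""
    sa = a.states if isinstance(a, Haplotype) else tuple(a)
    sb = b.states if isinstance(b, Haplotype) else tuple(b)
    sc = c.states if isinstance(c, Haplotype) else tuple(c)
    if not (len(sa) == len(sb) == len(sc)):
        raise HaplotypeError("median_vector requires equal-length haplotypes")
    return Haplotype(tuple(1 if (x + y + z) >= 2 else 0 for x, y, z in zip(sa, sb, sc)))


def _candidate_medians(
    links: list[tuple[States, States, float]],
    nodes: set[States],
    w: np.ndarray,
) -> dict[States, float]:
    """Median vectors of mutually linked triples, with connection cost."""
    adj: dict[States, set[States]] = {n: set() for n in nodes}
    for a, b, _ in links:
        adj[a].add(b)
        adj[b].add(a)
    cand: dict[States, float] = {}
    for u in sorted(nodes):
        for v, x in itertools.combinations(sorted(adj[u]), 2):
            if u >= v or x not in adj[v]:
                continue  # enumerate each triangle once, from its least node
            m = median_vector(u, v, x).states
            if m in nodes:
                continue
            cost = _wdist(m, u, w) + _wdist(m, v, w) + _wdist(m, x, w)
            if m not in cand or cost < cand[m]:
                cand[m] = cost
    return cand


def mj_construct(
    haplotypes,
    params: NetworkParams = NetworkParams(),
    site_map: SiteMap = DEFAULT_SITE_MAP,
) -> HaploNetwork:
    """Full median-joining network of a weighted haplotype set.

    Iterates MSN construction and median-vector insertion (adding, each
    round, every absent median whose connection cost is within epsilon of
    the round's minimum) until stable, then prunes unsampled nodes of
    degree <= 2 that lie on no shortest path between sampled nodes.
    Frequency weights do not affect the topology, only node attributes.
    """
    info = _normalise_input(haplotypes)
    sampled = set(info)
    L = len(next(iter(info)))
    w = _weights(params, L)
    eps = float(params.epsilon)

    nodes = set(info)
    median_order: list[States] = []
    while True:
        links = _msn_links(sorted(nodes), w, eps)
        cand = _candidate_medians(links, nodes, w)
        if not cand:
            break
        cmin = min(cand.values())
        new = sorted(m for m, cost in cand.items() if cost <= cmin + eps)
        logger.debug(
            "median round: %d candidates, min cost %.1f, adding %d", len(cand), cmin, len(new)
        )
        nodes.update(new)
        median_order.extend(new)

    # Prune: drop unsampled degree-<=2 nodes lying on no sampled-sampled
    # geodesic, rebuilding the MSN after each removal.
    while True:
        links = _msn_links(sorted(nodes), w, eps)
        g = nx.Graph()
        g.add_nodes_from(nodes)
        g.add_weighted_edges_from(links, weight="length")
        dist = dict(nx.all_pairs_dijkstra_path_length(g, weight="length"))
        removed = None
        for m in sorted(nodes - sampled):
            if g.degree[m] > 2:
                continue
            on_geodesic = any(
                abs(dist[s][m] + dist[m][t] - dist[s][t]) < 1e-9
                for s, t in itertools.combinations(sorted(sampled), 2)
            )
            if not on_geodesic:
                removed = m
                break
        if removed is None:
            break
        logger.debug("pruning obsolete median vector %s", format_haplotype(removed, sep=""))
        nodes.discard(removed)

    median_names = {
        m: f"mv{i + 1}"
        for i, m in enumerate(m for m in median_order if m in nodes)
    }
    node_info = {
        n: (info.get(n, (0.0, None))[0], info.get(n, (0.0, None))[1]) for n in nodes
    }
    links = _msn_links(sorted(nodes), w, eps)
    return _build_graph(node_info, links, site_map, median_names)


def _dot_escape(s: str) -> str:
    return s.replace('"', r"\"")


def export_network(
    net: HaploNetwork, path: str | Path, format: str = "tsv"
) -> Path:
    """Write a network as edge-list TSV, Graphviz DOT, or GraphML.

    Sampled nodes carry a size attribute proportional to their frequency
    weight; median vectors are flagged.  Edges are annotated with the
    labels of the differing sites.
    """
    path = Path(path)
    g = net.graph
    sites = net.site_map.sites

    if format == "tsv":
        lines = ["node_a\tnode_b\tlength\tsites_changed"]
        for a, b, d in sorted(g.edges(data=True)):
            changed = ",".join(sites[i] for i in d["sites"])
            lines.append(
                f"{format_haplotype(a, sep='')}\t{format_haplotype(b, sep='')}"
                f"\t{d['length']:g}\t{changed}"
            )
        path.write_text("\n".join(lines) + "\n")
    elif format == "dot":
        max_w = max((d["weight"] for _, d in g.nodes(data=True) if d["sampled"]), default=1.0)
        out = ["graph haplonetwork {", "  node [fontsize=10];"]
        for n in sorted(g.nodes):
            d = g.nodes[n]
            name = _dot_escape(d["label"])
            if d["sampled"]:
                size = 0.3 + 1.2 * (d["weight"] / max_w if max_w > 0 else 0.0)
                out.append(
                    f'  "{name}" [shape=circle, width={size:.3f}, fixedsize=true, '
                    f'tooltip="{format_haplotype(n, sep="")}"];'
                )
            else:
                out.append(f'  "{name}" [shape=point, width=0.08];')
        for a, b, d in sorted(g.edges(data=True)):
            la = _dot_escape(g.nodes[a]["label"])
            lb = _dot_escape(g.nodes[b]["label"])
            changed = _dot_escape(",".join(sites[i] for i in d["sites"]))
            out.append(f'  "{la}" -- "{lb}" [label="{changed}", len={d["length"]:g}];')
        out.append("}")
        path.write_text("\n".join(out) + "\n")
    elif format == "graphml":
        h = nx.Graph()
        max_w = max((d["weight"] for _, d in g.nodes(data=True) if d["sampled"]), default=1.0)
        for n, d in g.nodes(data=True):
            h.add_node(
                format_haplotype(n, sep=""),
                label=d["label"],
                sampled=bool(d["sampled"]),
                weight=float(d["weight"]),
                size=float(d["weight"] / max_w if max_w > 0 else 0.0),
            )
        for a, b, d in g.edges(data=True):
            h.add_edge(
                format_haplotype(a, sep=""),
                format_haplotype(b, sep=""),
                length=float(d["length"]),
                sites_changed=",".join(sites[i] for i in d["sites"]),
            )
        nx.write_graphml(h, path)
    else:
        raise ValueError(f"unknown network format {format!r} (tsv, dot, graphml)")
    return path
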