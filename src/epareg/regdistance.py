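"""Local and global regulatory distances between reactions and EqSets.

Two reactions sharing a metabolite interact through its concentration; the
more reactions consume that metabolite, the more the perturbation is
diluted.  The local distance between distinct reactions is therefore the
minimum consumer count over their shared metabolites (infinite when they
share none); the global distance is the shortest-path length over the
weighted reaction graph.  Any metabolite of a reversible reaction counts as
both a substrate and a product.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx

from .model_io import MetabolicNetwork

INF = math.inf


def consumer_count(net: MetabolicNetwork, metabolite_id: str) -> int:
    """Number of reactions that use the metabolite as a substrate."""
    if metabolite_id not in net.met_index:
        raise KeyError(metabolite_id)
    n = 0
    for r in net.reactions:
        c = r.stoichiometry.get(metabolite_id)
        if c is None:
            continue
        if c < 0 or r.reversible:
            n += 1
    return n


def local_distance(net: MetabolicNetwork, ri: str, rj: str) -> float:
    if ri == rj:
        return 0.0
    shared = net.reaction(ri).metabolites() & net.reaction(rj).metabolites()
    if not shared:
        return INF
    return float(min(consumer_count(net, m) for m in shared))


@dataclass
class RegulatoryGraph:
    reaction_ids: list[str]
    local: dict[tuple[str, str], float]
    dist: dict[str, dict[str, float]]
    consumer_counts: dict[str, int] = field(default_factory=dict)

    def d(self, ri: str, rj: str) -> float:
        """Local (one-arc) distance."""
        if ri == rj:
            return 0.0
        return self.local.get((min(ri, rj), max(ri, rj)), INF)

    def D(self, ri: str, rj: str) -> float:
        """Global (shortest-path) distance."""
        if ri == rj:
            return 0.0
        return self.dist.get(ri, {}).get(rj, INF)

    def eqset_distance(self, x1, x2) -> float:
        """Mean global distance over all ordered cross pairs."""
        x1, x2 = sorted(set(x1)), sorted(set(x2))
        if not x1 or not x2:
            raise ValueError("EqSets must be non-empty")
        total, count = 0.0, 0
        for ri in x1:
            for rj in x2:
                dd = self.D(ri, rj)
                if dd == INF:
                    return INF
                total += dd
                count += 1
        return total / count


def global_distances(net: MetabolicNetwork) -> RegulatoryGraph:
    """All-pairs shortest paths over the local-distance graph."""
    ids = [r.id for r in net.reactions]
    consumers = {m.id: consumer_count(net, m.id) for m in net.metabolites}
    # precompute reactions touching each metabolite to avoid the n^2 scan
    by_met: dict[str, list[str]] = {}
    for r in net.reactions:
        for mid in r.stoichiometry:
            by_met.setdefault(mid, []).append(r.id)
    local: dict[tuple[str, str], float] = {}
    for mid, rlist in by_met.items():
        w = float(consumers[mid])
        for a in range(len(rlist)):
            for b in range(a + 1, len(rlist)):
                key = (min(rlist[a], rlist[b]), max(rlist[a], rlist[b]))
                if w < local.get(key, INF):
                    local[key] = w
    g = nx.Graph()
    g.add_nodes_from(ids)
    g.add_weighted_edges_from((a, b, w) for (a, b), w in local.items())
    dist = {
        src: {dst: float(dd) for dst, dd in lengths.items()}
        for src, lengths in nx.all_pairs_dijkstra_path_length(g, weight="weight")
    }
    return RegulatoryGraph(ids, local, dist, consumers)
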