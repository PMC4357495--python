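"""MCODE-style detection of SNP functional modules (high-order interactions).

A SNP functional module is a group of densely interconnected SNPs in the
interaction network, interpreted as a high-order interaction.  Detection
follows the seed-expansion molecular-complex algorithm of Bader and Hogue:

1. *Vertex weighting* — each node is scored by the core-clustering
   coefficient of its closed neighborhood: the highest k-core of the
   neighborhood graph is found and the weight is k times that core's
   density.
2. *Complex prediction* — the highest-weight unvisited node seeds a module;
   breadth-first expansion includes unvisited neighbors whose weight is at
   least (1 - node_score_cutoff) times the seed weight, up to a depth
   limit.  Visited nodes never join a second module.
3. *Post-processing* — the haircut trims peripheral members to the 2-core;
   optional fluff grows the module by dense neighborhoods.  Modules with
   fewer than two members are discarded.

Modules are reported in descending score (density times size), with
deterministic tie-breaking by SNP id throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx

from .scan import SnpAnnotation

__all__ = ["McodeParams", "SnpModule", "vertex_weights", "find_modules", "annotate_modules"]


@dataclass(frozen=True)
class McodeParams:
    """MCODE tuning parameters; defaults mirror the reference implementation."""

    kcore: int = 2
    degree_cutoff: int = 2
    node_score_cutoff: float = 0.2
    haircut: bool = True
    fluff: bool = False
    fluff_density_cutoff: float = 0.2
    max_depth: int = 100

    def __post_init__(self) -> None:
        if not (0 <= self.node_score_cutoff <= 1):
            raise ValueError("node_score_cutoff must lie in [0, 1]")
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")


@dataclass(frozen=True)
class SnpModule:
    """One detected functional module."""

    members: frozenset[str]
    seed: str
    score: float
    genes_involved: frozenset[str] = field(default_factory=frozenset)


def _density(g: nx.Graph) -> float:
    n = g.number_of_nodes()
    if n < 2:
        return 0.0
    return 2.0 * g.number_of_edges() / (n * (n - 1))


def _highest_kcore(g: nx.Graph) -> tuple[int, nx.Graph]:
    """(k, subgraph) of the highest non-empty k-core of g."""
    if g.number_of_edges() == 0:
        return 0, g.subgraph([])
    core_num = nx.core_number(g)
    k = max(core_num.values())
    nodes = [v for v, c in core_num.items() if c >= k]
    return k, g.subgraph(nodes)


def vertex_weights(net: nx.Graph, params: McodeParams | None = None) -> dict[str, float]:
    """MCODE weight per node: k * density of the neighborhood's top k-core.

    Nodes with degree below ``degree_cutoff`` get weight 0.
    """
    params = params or McodeParams()
    weights: dict[str, float] = {}
    for v in net.nodes:
        if net.degree(v) < params.degree_cutoff:
            weights[v] = 0.0
            continue
        closed = net.subgraph(list(net.neighbors(v)) + [v])
        k, core = _highest_kcore(closed)
        weights[v] = k * _density(core)
    return weights


def _expand(
    net: nx.Graph,
    seed: str,
    weights: dict[str, float],
    visited: set[str],
    params: McodeParams,
) -> set[str]:
    """BFS expansion from seed over unvisited nodes above the score cutoff."""
    threshold = (1.0 - params.node_score_cutoff) * weights[seed]
    members = {seed}
    frontier = [seed]
    for _ in range(params.max_depth):
        nxt: list[str] = []
        for u in frontier:
            for w in net.neighbors(u):
                if w in members or w in visited:
                    continue
                if weights[w] >= threshold:
                    members.add(w)
                    nxt.append(w)
        if not nxt:
            break
        frontier = nxt
    return members


def _haircut(sub: nx.Graph) -> nx.Graph:
    """Trim to the 2-core (repeatedly drops degree-1 members)."""
    return nx.k_core(sub, 2) if sub.number_of_nodes() else sub


def _fluff(net: nx.Graph, members: set[str], params: McodeParams) -> set[str]:
    """Add neighbors whose closed neighborhood is denser than the cutoff."""
    extra: set[str] = set()
    for v in sorted(members):
        for w in net.neighbors(v):
            if w in members or w in extra:
                continue
            closed = net.subgraph(list(net.neighbors(w)) + [w])
            if _density(closed) > params.fluff_density_cutoff:
                extra.add(w)
    return members | extra


def find_modules(net: nx.Graph, params: McodeParams | None = None) -> list[SnpModule]:
    """Detect functional modules, returned in descending score.

    Deterministic: equal-weight seed candidates are taken in ascending SNP
    id order, and module score ties are broken the same way.
    """
    params = params or McodeParams()
    weights = vertex_weights(net, params)
    order = sorted(net.nodes, key=lambda v: (-weights[v], v))
    visited: set[str] = set()
    modules: list[SnpModule] = []
    for seed in order:
        if seed in visited or weights[seed] <= 0.0:
            continue
        members = _expand(net, seed, weights, visited, params)
        visited |= members
        if params.fluff:
            members = _fluff(net, members, params)
        sub = net.subgraph(members).copy()
        if params.haircut:
            sub = _haircut(sub)
        if sub.number_of_nodes() < 2:
            continue
        if not nx.is_connected(sub):
            # the 2-core can split a module; keep the seed's component
            comps = sorted(nx.connected_components(sub), key=lambda c: (-len(c), min(c)))
            keep = next((c for c in comps if seed in c), comps[0])
            sub = sub.subgraph(keep).copy()
            if sub.number_of_nodes() < 2:
                continue
        final_members = frozenset(sub.nodes)
        final_seed = (
            seed
            if seed in final_members
            else min(final_members, key=lambda v: (-weights[v], v))
        )
        modules.append(
            SnpModule(
                members=final_members,
                seed=final_seed,
                score=_density(sub) * sub.number_of_nodes(),
            )
        )
    modules.sort(key=lambda m: (-m.score, min(m.members)))
    return modules


def annotate_modules(
    modules: Sequence[SnpModule], annotations: Sequence[SnpAnnotation]
) -> list[SnpModule]:
    """Fill ``genes_involved`` with the union of member gene ids.

    Intergenic members and members without an annotation contribute
    nothing.
    """
    gene_of = {a.snp_id: a.gene_id for a in annotations}
    out = []
    for mod in modules:
        genes = frozenset(
            g for g in (gene_of.get(s) for s in mod.members) if g is not None
        )
        out.append(SnpModule(mod.members, mod.seed, mod.score, genes))
    return out
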