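"""SNP-SNP interaction network: topology statistics and main-effect ranking.

Filtered interaction records become an undirected graph whose nodes are
SNPs and whose edges are the surviving pairs, weighted by interaction gain.
Edges are treated as unweighted for path computations (path length counts
hops); IG weights are kept as edge metadata.

Main-effect SNPs are ranked by node importance: degree first, betweenness
centrality as tie-break (lexicographic), with an optional weighted-sum
score for sensitivity analysis.
"""

from __future__ import annotations

import warnings
from collections import Counter

import networkx as nx
import pandas as pd

__all__ = [
    "build_network",
    "degree_distribution",
    "shortest_path_distribution",
    "betweenness",
    "rank_main_effect_snps",
]


def build_network(records: pd.DataFrame) -> nx.Graph:
    """Graph with one node per SNP in any record, one edge per pair.

    A duplicated pair keeps the maximum IG and triggers a warning.  An
    empty record table yields an empty graph.
    """
    net = nx.Graph()
    dups = 0
    for snp_a, snp_b, ig in zip(records["snp_a"], records["snp_b"], records["ig"]):
        if snp_a == snp_b:
            raise ValueError(f"self-pair {snp_a!r} in records")
        if net.has_edge(snp_a, snp_b):
            dups += 1
            net[snp_a][snp_b]["ig"] = max(net[snp_a][snp_b]["ig"], float(ig))
        else:
            net.add_edge(snp_a, snp_b, ig=float(ig))
    if dups:
        warnings.warn(f"{dups} duplicate pair(s) collapsed, max IG kept", stacklevel=2)
    return net


def degree_distribution(net: nx.Graph) -> dict[int, int]:
    """Histogram degree -> node count; sums to the number of nodes."""
    return dict(sorted(Counter(d for _, d in net.degree()).items()))


def shortest_path_distribution(net: nx.Graph) -> dict[int, int]:
    """Histogram path length -> connected unordered node-pair count.

    Unweighted BFS shortest paths; disconnected pairs are excluded, so the
    histogram totals the number of connected pairs.
    """
    hist: Counter[int] = Counter()
    for source, lengths in nx.all_pairs_shortest_path_length(net):
        for target, dist in lengths.items():
            if source < target:  # each unordered pair once
                hist[dist] += 1
    return dict(sorted(hist.items()))


def betweenness(net: nx.Graph) -> dict[str, float]:
    """Unnormalized shortest-path betweenness centrality per node."""
    return nx.betweenness_centrality(net, normalized=False)


def rank_main_effect_snps(
    net: nx.Graph,
    k: int,
    weights: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Top-k SNPs by importance, with their degree and betweenness.

    Default ordering is lexicographic: degree descending, then betweenness
    descending, then SNP id ascending.  Passing ``weights = (w_deg, w_btw)``
    instead ranks by the weighted sum of the two scores (each min-max
    normalized over the network).  Requesting more nodes than exist
    returns all of them with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    btw = betweenness(net)
    rows = pd.DataFrame(
        {
            "snp_id": list(net.nodes),
            "degree": [net.degree(v) for v in net.nodes],
            "betweenness": [btw[v] for v in net.nodes],
        }
    )
    if weights is None:
        rows = rows.sort_values(
            ["degree", "betweenness", "snp_id"], ascending=[False, False, True]
        )
    else:
        w_deg, w_btw = weights

        def _norm(s: pd.Series) -> pd.Series:
            span = s.max() - s.min()
            return (s - s.min()) / span if span > 0 else s * 0.0

        rows["score"] = w_deg * _norm(rows["degree"]) + w_btw * _norm(rows["betweenness"])
        rows = rows.sort_values(["score", "snp_id"], ascending=[False, True])
    if k > len(rows):
        warnings.warn(
            f"requested top {k} of {len(rows)} nodes; returning all", stacklevel=2
        )
    out = rows.head(k).reset_index(drop=True)
    out.insert(0, "rank", range(1, len(out) + 1))
    return out
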