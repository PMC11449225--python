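"""Community detection on the core network via igraph.

Six algorithms, run with the edge weights and the stated parameters:
greedy modularity optimization (fast_greedy), short random walks
(walktrap, steps=15), leading eigenvector of the community matrix,
label propagation, multi-level modularity optimization (Louvain) and
Infomap (trials=100). The algorithms themselves are delegated to igraph;
this module only adds parameter plumbing, seeding for the stochastic
methods and a normalized output.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

import igraph as ig
import networkx as nx

__all__ = ["COMMUNITY_METHODS", "CommunityResult", "detect_communities"]

COMMUNITY_METHODS = (
    "fast_greedy",
    "walktrap",
    "leading_eigenvector",
    "label_propagation",
    "louvain",
    "infomap",
)


@dataclass
class CommunityResult:
    method: str
    membership: dict[str, int]
    modularity: float
    n_communities: int


def _to_igraph(network: nx.Graph) -> tuple[ig.Graph, list[str]]:
    nodes = sorted(network.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    edges = [(index[a], index[b]) for a, b in network.edges]
    weights = [
        float(network.edges[a, b].get("weight", 1.0)) for a, b in network.edges
    ]
    g = ig.Graph(n=len(nodes), edges=edges)
    g.es["weight"] = weights
    return g, nodes


def detect_communities(
    network: nx.Graph,
    method: str,
    seed: int | None = None,
    **params,
) -> CommunityResult:
    """Assign every node to one community and report modularity.

    ``params`` are forwarded to the underlying igraph routine; defaults
    follow the stated settings (walktrap ``steps=15``, infomap
    ``trials=100``). ``seed`` makes the stochastic methods (label
    propagation, infomap, louvain) reproducible.
    """
    if method not in COMMUNITY_METHODS:
        raise ValueError(
            f"unknown method {method!r}; choose from {COMMUNITY_METHODS}"
        )
    g, nodes = _to_igraph(network)
    weights = g.es["weight"] if g.ecount() else None
    if seed is not None:
        state = random.getstate()
        random.seed(seed)
    try:
        if method == "fast_greedy":
            clustering = g.community_fastgreedy(
                weights=weights
            ).as_clustering()
        elif method == "walktrap":
            steps = params.pop("steps", 15)
            clustering = g.community_walktrap(
                weights=weights, steps=steps
            ).as_clustering()
        elif method == "leading_eigenvector":
            # The R interface exposes a `steps` argument; the Python binding
            # does not, so any supplied value is accepted and ignored.
            params.pop("steps", None)
            clustering = g.community_leading_eigenvector(weights=weights)
        elif method == "label_propagation":
            clustering = g.community_label_propagation(weights=weights)
        elif method == "louvain":
            clustering = g.community_multilevel(weights=weights)
        else:  # infomap
            trials = params.pop("trials", 100)
            clustering = g.community_infomap(
                edge_weights=weights, trials=trials
            )
    finally:
        if seed is not None:
            random.setstate(state)
    membership = {nodes[i]: int(c) for i, c in enumerate(clustering.membership)}
    modularity = g.modularity(clustering.membership, weights=weights)
    return CommunityResult(
        method=method,
        membership=membership,
        modularity=float(modularity),
        n_communities=len(set(clustering.membership)),
    )
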