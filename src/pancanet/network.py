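"""Interactome first-shell expansion and hub-bottleneck-switch classification.

Seed genes are expanded against a STRING-like weighted interactome: edges
below the confidence cut (0.400, inclusive) are dropped, the first shell of
direct neighbors is capped at 200 interactors, and the network is the
induced subgraph on seeds plus kept interactors. Nodes are then scored with
three centralities — degree (immediate connections), betweenness (shortest
paths through the node, unnormalized Brandes counts with endpoints
excluded) and eigenvector (dominant adjacency eigenvector, L2-normalized) —
and labeled by comparison with the network-wide means: above-average degree
makes a Hub (H), above-average betweenness a Bottleneck (B), above-average
eigenvector a Switch (S). A node above all three means is HBS; an in-network
node above none is NTR ("no topological relevance"); a seed absent from the
network is NA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .core import InvalidParameterError, NonConvergenceError

DEFAULT_MIN_CONFIDENCE = 0.4
DEFAULT_MAX_INTERACTORS = 200

LABELS = ("H", "B", "S", "HB", "HS", "BS", "HBS", "NTR", "NA")


def expand_first_shell(
    seeds: Sequence[str],
    interactome: pd.DataFrame,
    min_confidence: float = DEFAULT_MIN_CONFIDENCE,
    max_interactors: int = DEFAULT_MAX_INTERACTORS,
) -> nx.Graph:
    """Build the first-shell network around ``seeds``.

    Interactome edges with confidence < ``min_confidence`` are dropped
    (boundary inclusive: 0.400 passes a 0.4 cut). Candidate interactors are
    non-seed nodes adjacent to at least one seed; they are ranked by
    (number of seed neighbors, summed confidence to seeds, id) and the top
    ``max_interactors`` kept. The result is the induced subgraph on seeds
    plus kept interactors, with node attribute ``is_seed`` and edge
    attribute ``confidence``. Seeds with no retained edge are left out of
    the graph and listed in ``graph.graph["unconnected_seeds"]``.
    """
    if not seeds:
        raise InvalidParameterError("seeds must be non-empty")
    if max_interactors < 0:
        raise InvalidParameterError("max_interactors must be non-negative")
    seed_set = set(seeds)

    if len(interactome) == 0:
        warnings.warn("empty interactome: returning isolated seeds")
        net = nx.Graph()
        net.add_nodes_from(sorted(seed_set), is_seed=True)
        net.graph["unconnected_seeds"] = []
        return net

    kept_edges = interactome[interactome["confidence"] >= min_confidence]
    full = nx.Graph()
    for a, b, c in kept_edges[["node_a", "node_b", "confidence"]].itertuples(index=False):
        if a == b:
            continue
        full.add_edge(a, b, confidence=float(c))

    # Rank the first shell deterministically.
    n_seed_nbrs: dict[str, int] = {}
    conf_sum: dict[str, float] = {}
    for s in seed_set & set(full.nodes):
        for nbr, data in full[s].items():
            if nbr in seed_set:
                continue
            n_seed_nbrs[nbr] = n_seed_nbrs.get(nbr, 0) + 1
            conf_sum[nbr] = conf_sum.get(nbr, 0.0) + data["confidence"]
    ranked = sorted(
        n_seed_nbrs, key=lambda n: (-n_seed_nbrs[n], -conf_sum[n], n)
    )
    kept = set(ranked[:max_interactors])

    nodes = (seed_set & set(full.nodes)) | kept
    induced = full.subgraph(nodes)
    net = nx.Graph()
    for node in sorted(induced.nodes):
        net.add_node(node, is_seed=node in seed_set)
    net.add_edges_from(induced.edges(data=True))
    # Seeds absent from the confidence-filtered interactome are reported as
    # unconnected; they will be labeled NA downstream.
    net.graph["unconnected_seeds"] = sorted(seed_set - set(full.nodes))
    return net


@dataclass
class CentralityProfile:
    """Per-node degree, betweenness and eigenvector scores plus their
    network-wide means."""

    degree: dict[str, int]
    betweenness: dict[str, float]
    eigenvector: dict[str, float]
    mean_degree: float
    mean_betweenness: float
    mean_eigenvector: float

    def as_frame(self) -> pd.DataFrame:
        nodes = sorted(self.degree)
        return pd.DataFrame(
            {
                "node": nodes,
                "degree": [self.degree[n] for n in nodes],
                "betweenness": [self.betweenness[n] for n in nodes],
                "eigenvector": [self.eigenvector[n] for n in nodes],
            }
        )


def _power_iteration_eigenvector(
    net: nx.Graph, tol: float = 1e-10, max_iter: int = 1000
) -> dict[str, float]:
    """Dominant-eigenvector scores via power iteration on A + I.

    The identity shift leaves eigenvectors unchanged while making the
    iteration converge on bipartite components; on disconnected graphs the
    uniform start converges to the dominant component and nodes outside it
    score ~0. An edgeless graph scores 0 everywhere by convention.
    """
    nodes = sorted(net.nodes)
    n = len(nodes)
    if net.number_of_edges() == 0:
        return {v: 0.0 for v in nodes}
    a = nx.to_numpy_array(net, nodelist=nodes, weight=None)
    x = np.full(n, 1.0 / np.sqrt(n))
    for _ in range(max_iter):
        x_new = a @ x + x
        x_new /= np.linalg.norm(x_new)
        if np.abs(x_new - x).max() < tol:
            x = x_new
            break
        x = x_new
    else:
        n_comp = nx.number_connected_components(net)
        raise NonConvergenceError(
            f"eigenvector power iteration did not converge in {max_iter} "
            f"iterations on a graph with {n} nodes and {n_comp} connected components"
        )
    return {v: float(abs(s)) for v, s in zip(nodes, x)}


def centralities(net: nx.Graph) -> CentralityProfile:
    """Degree, betweenness (exact, unnormalized, endpoints excluded) and
    eigenvector centralities, with means over all network nodes."""
    if net.number_of_nodes() == 0:
        raise InvalidParameterError("network must have at least one node")
    degree = {n: int(d) for n, d in net.degree()}
    betweenness = nx.betweenness_centrality(net, normalized=False)
    eigenvector = _power_iteration_eigenvector(net)
    n = net.number_of_nodes()
    return CentralityProfile(
        degree=degree,
        betweenness={k: float(v) for k, v in betweenness.items()},
        eigenvector=eigenvector,
        mean_degree=sum(degree.values()) / n,
        mean_betweenness=sum(betweenness.values()) / n,
        mean_eigenvector=sum(eigenvector.values()) / n,
    )


def topology_labels(profile: CentralityProfile) -> dict[str, str]:
    """H/B/S combination label for every scored node (strict > vs. the
    network means); NTR when below or at all three means."""
    labels = {}
    for node in profile.degree:
        tag = ""
        if profile.degree[node] > profile.mean_degree:
            tag += "H"
        if profile.betweenness[node] > profile.mean_betweenness:
            tag += "B"
        if profile.eigenvector[node] > profile.mean_eigenvector:
            tag += "S"
        labels[node] = tag or "NTR"
    return labels


def classify_hbs(
    profile: CentralityProfile, seeds: Sequence[str], net: nx.Graph
) -> dict[str, str]:
    """Topology label per seed; seeds absent from the network get NA."""
    labels = topology_labels(profile)
    return {s: labels.get(s, "NA") for s in seeds}


def extract_hbs_subnetwork(net: nx.Graph, labels: Mapping[str, str]) -> nx.Graph:
    """Induced subgraph on all nodes labeled HBS (seeds and interactors)."""
    hbs_nodes = [n for n in net.nodes if labels.get(n) == "HBS"]
    if not hbs_nodes:
        warnings.warn("no HBS nodes: returning an empty network")
    sub = nx.Graph(net.subgraph(hbs_nodes))
    sub.graph.clear()
    return sub


def network_summary(net: nx.Graph) -> dict[str, int]:
    return {"n_nodes": net.number_of_nodes(), "n_edges": net.number_of_edges()}
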