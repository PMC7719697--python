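"""TF-association network (TAR-Net) construction and regulatory-core filtering.

Seed genes (consensus DEGs and ML-selected features) are matched against a
TRRUST-like regulon table: every TF -> target edge whose target is a seed is
retained, together with its regulation mode (activation / repression /
unknown). The *core* filter then keeps only TFs connected to at least two
distinct seed genes, drops seeds orphaned by TF removal, and the edge-mode
tally summarizes which regulation mode dominates the core.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping

import networkx as nx

from .core import REGULATION_MODES, InvalidParameterError, RegulonEdge

SEED_ROLES = ("deg_over", "deg_under", "shared", "feature")


def prospect_tfs(
    seeds: Mapping[str, str], regulons: Iterable[RegulonEdge]
) -> nx.DiGraph:
    """Build the TAR-Net: regulon edges whose target is a seed.

    ``seeds`` maps gene id -> role (one of deg_over, deg_under, shared,
    feature). Node attribute ``roles`` is a frozenset of roles; TFs carry
    the role "tf", and a TF that is itself a seed keeps both roles. Seeds
    with no retained edge are dropped and listed in
    ``graph.graph["dropped_seeds"]``.
    """
    if not seeds:
        raise InvalidParameterError("seeds must be non-empty")
    for gene, role in seeds.items():
        if role not in SEED_ROLES:
            raise InvalidParameterError(f"seed {gene}: unknown role {role!r}")
    regulons = list(regulons)
    net = nx.DiGraph()
    if not regulons:
        warnings.warn("empty regulon table: returning an empty TAR-Net")
    for edge in regulons:
        if edge.mode not in REGULATION_MODES:
            raise InvalidParameterError(
                f"edge {edge.tf}->{edge.target}: unknown mode {edge.mode!r}"
            )
        if edge.target not in seeds:
            continue
        for node in (edge.tf, edge.target):
            if node not in net:
                roles = set()
                if node in seeds:
                    roles.add(seeds[node])
                net.add_node(node, roles=frozenset(roles))
        net.nodes[edge.tf]["roles"] = net.nodes[edge.tf]["roles"] | {"tf"}
        net.add_edge(edge.tf, edge.target, mode=edge.mode)
    net.graph["dropped_seeds"] = sorted(set(seeds) - set(net.nodes))
    return net


def _tf_seed_targets(net: nx.DiGraph, tf: str, degs_only: bool) -> set[str]:
    counted = {"deg_over", "deg_under", "shared"} if degs_only else set(SEED_ROLES)
    return {
        t for t in net.successors(tf)
        if net.nodes[t]["roles"] & counted
    }


def core_filter(
    net: nx.DiGraph, min_deg_connections: int = 2, degs_only: bool = False
) -> nx.DiGraph:
    """Keep TFs connected to >= ``min_deg_connections`` distinct seed genes,
    then seeds still targeted by at least one retained TF.

    With ``degs_only`` the connection tally counts only DEG-role seeds,
    not ML features. The operation is idempotent and its output is a
    subgraph of its input.
    """
    if min_deg_connections < 1:
        raise InvalidParameterError("min_deg_connections must be >= 1")
    tfs = {n for n in net.nodes if "tf" in net.nodes[n]["roles"]}
    kept_tfs = {
        tf for tf in tfs
        if len(_tf_seed_targets(net, tf, degs_only)) >= min_deg_connections
    }
    seeds = {n for n in net.nodes if net.nodes[n]["roles"] - {"tf"}}
    kept_seeds = {
        s for s in seeds
        if any(p in kept_tfs for p in net.predecessors(s)) or s in kept_tfs
    }
    kept = kept_tfs | kept_seeds
    out = nx.DiGraph(net.subgraph(kept))
    out.graph.clear()
    # Single-pass cascade is sufficient: removing orphan seeds cannot strip
    # a retained TF below threshold, because retained seeds include every
    # target of a retained TF.
    for tf in kept_tfs:
        still = _tf_seed_targets(out, tf, degs_only)
        assert len(still) >= min_deg_connections, (
            f"core_filter invariant violated for TF {tf}"
        )
    return out


def edge_mode_tally(net: nx.DiGraph) -> dict[str, int]:
    """Exact counts of activation / repression / unknown edges."""
    tally = {mode: 0 for mode in REGULATION_MODES}
    for _, _, mode in net.edges(data="mode"):
        tally[mode] += 1
    return tally


def mode_proportions(tally: Mapping[str, int]) -> dict[str, float]:
    """Tally normalized to proportions (all zero for an empty network)."""
    total = sum(tally.values())
    if total == 0:
        return {mode: 0.0 for mode in REGULATION_MODES}
    return {mode: tally.get(mode, 0) / total for mode in REGULATION_MODES}
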