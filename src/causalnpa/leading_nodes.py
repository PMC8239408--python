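"""Leading-node decomposition and reporting subnetwork extraction.

Leading nodes (LNs) are the smallest set of nodes that together account for
at least 80% of the NPA (the contribution of a node being the fraction of
the sum of squared coefficients it carries). Each LN also carries an
activation direction: the sign of its fitted coefficient. The LN set can be
extracted into a compact subnetwork for reporting, with flagged "indirect"
edges standing in for directed paths of the full network between nodes that
are not directly connected.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd

from .network_model import FunctionalNetwork, ModelError
from .npa_scoring import ScoreResult

#: tolerance for the inclusive cumulative-contribution threshold; absorbs the
#: floating-point shortfall of sums like 8 x 0.1
_CUM_TOL = 1e-9


def leading_nodes(result: ScoreResult, threshold: float = 0.8) -> pd.DataFrame:
    """Smallest contribution-ranked node prefix reaching the threshold.

    Rows (node_id, contribution, cumulative, direction) are sorted by
    contribution descending with lexicographic tie-break; the threshold is
    inclusive (a prefix summing to exactly the threshold stops). Direction is
    the sign of the node's coefficient. Raises on an unperturbed result
    (NPA = 0) or a threshold outside (0, 1].
    """
    if not 0 < threshold <= 1:
        raise ModelError(f"threshold must lie in (0, 1], got {threshold}")
    if result.npa <= 0 or result.contributions is None:
        raise ModelError("no perturbation to decompose (NPA = 0)")
    rows = sorted(
        ((node, frac) for node, frac in result.contributions.items() if frac > 0),
        key=lambda item: (-item[1], item[0]),
    )
    records = []
    cumulative = 0.0
    for node, frac in rows:
        cumulative += frac
        c = result.coefficients.values[node]
        direction = "activated" if c > 0 else ("inactivated" if c < 0 else "neutral")
        records.append({"node_id": node, "contribution": frac, "cumulative": cumulative,
                        "direction": direction})
        if cumulative >= threshold - _CUM_TOL:
            break
    report = pd.DataFrame(records, columns=["node_id", "contribution", "cumulative", "direction"])
    report.attrs["threshold"] = threshold
    return report


def _merged_digraph(net: FunctionalNetwork) -> nx.DiGraph:
    g = nx.DiGraph()
    g.add_nodes_from(net.nodes)
    for e in net.edges:
        if g.has_edge(e.source, e.target):
            g[e.source][e.target]["signs"].add(e.sign)
        else:
            g.add_edge(e.source, e.target, signs={e.sign})
    return g


def _hop_sign(signs: set[int]) -> tuple[int, bool]:
    """Resolve the sign of a merged hop; ambiguous when parallel signs conflict."""
    if len(signs) == 1:
        return next(iter(signs)), False
    return max(signs), True


def extract_subnetwork(
    net: FunctionalNetwork,
    nodes: set[str] | list[str],
    extras: set[str] | list[str] = (),
    max_path_length: int = 4,
) -> FunctionalNetwork:
    """Induced subgraph on ``nodes | extras`` plus flagged indirect edges.

    For an ordered pair with no direct edge but a directed path of length
    <= ``max_path_length`` in the full network, an edge flagged ``indirect``
    is added whose sign is the product of the signs along one shortest path;
    ambiguity across equal-length paths (or conflicting parallel signs on a
    hop) is flagged and logged. Direct edges are copied verbatim, so indirect
    edges never connect nodes that are already directly connected.
    """
    keep = set(nodes) | set(extras)
    unknown = sorted(k for k in keep if k not in net.nodes)
    if unknown:
        raise ModelError(f"unknown node ids: {unknown}")
    sub = FunctionalNetwork(provenance=dict(net.provenance) | {"subnetwork_of": net.n_nodes})
    for nid in sorted(keep):
        sub.add_node(net.nodes[nid])
    direct: set[tuple[str, str]] = set()
    for e in net.edges:
        if e.source in keep and e.target in keep:
            sub.add_edge(e.source, e.target, e.sign, e.weight, evidence=list(e.evidence), merge=False)
            direct.add((e.source, e.target))
    full = _merged_digraph(net)
    for u in sorted(keep):
        lengths = nx.single_source_shortest_path_length(full, u, cutoff=max_path_length)
        for v in sorted(keep):
            if v == u or (u, v) in direct or lengths.get(v, max_path_length + 1) < 2:
                continue
            if v not in lengths:
                continue
            paths = list(nx.all_shortest_paths(full, u, v))
            products = []
            ambiguous = False
            for path in paths:
                prod = 1
                for a, b in zip(path, path[1:]):
                    s, amb = _hop_sign(full[a][b]["signs"])
                    prod *= s
                    ambiguous = ambiguous or amb
                products.append(prod)
            if len(set(products)) > 1:
                ambiguous = True
                sub.log.append(
                    f"indirect edge {u} -> {v}: {len(paths)} shortest paths with conflicting sign products"
                )
            sub.add_edge(u, v, products[0], evidence=[], merge=False, indirect=True, ambiguous=ambiguous)
    return sub


def subnetwork_from_report(
    net: FunctionalNetwork,
    report: pd.DataFrame,
    result: ScoreResult,
    extras: set[str] | list[str] = (),
    max_path_length: int = 4,
) -> FunctionalNetwork:
    """Extract the LN subnetwork and attach signed direction node attributes."""
    sub = extract_subnetwork(net, set(report["node_id"]), extras, max_path_length)
    directions = {
        nid: int(np.sign(result.coefficients.values.get(nid, 0.0))) for nid in sub.nodes
    }
    sub.provenance["direction"] = directions
    return sub
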