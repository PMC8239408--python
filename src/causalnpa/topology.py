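"""Hub and bottleneck diagnostics of the functional layer.

Hubs are nodes with high total degree (in + out, parallel evidence-bearing
edges counted separately); bottlenecks are nodes with high betweenness
centrality, computed on the simple graph obtained by merging parallel
edges. Both diagnostics return ranked tables (value descending, ties broken
lexicographically, ranks from 1).
"""

from __future__ import annotations

from collections import Counter

import networkx as nx
import pandas as pd

from .network_model import FunctionalNetwork, ModelError


def _ranked(values: dict[str, float], top_n: int | None) -> pd.DataFrame:
    rows = sorted(values.items(), key=lambda item: (-item[1], item[0]))
    if top_n is not None:
        rows = rows[:top_n]
    df = pd.DataFrame(rows, columns=["node_id", "value"])
    df["rank"] = range(1, len(df) + 1)
    return df


def degree_table(net: FunctionalNetwork, top_n: int | None = None) -> pd.DataFrame:
    """Total incident edge count per node (parallel edges counted separately)."""
    if top_n is not None and top_n < 1:
        raise ModelError("top_n must be >= 1")
    counts: Counter[str] = Counter()
    for nid in net.nodes:
        counts[nid] = 0
    for e in net.edges:
        counts[e.source] += 1
        counts[e.target] += 1
    df = _ranked({k: float(v) for k, v in counts.items()}, top_n)
    df["value"] = df["value"].astype(int)
    df.attrs["convention"] = "total degree; parallel (incl. conflicting-sign) edges counted separately"
    return df


def betweenness_table(
    net: FunctionalNetwork, top_n: int | None = None, directed: bool = False
) -> pd.DataFrame:
    """Normalised betweenness centrality on the merged simple graph.

    Normalisation divides by the number of ordered (directed) or unordered
    (undirected) node pairs excluding the focal node; the convention used is
    recorded in ``df.attrs['convention']``.
    """
    if top_n is not None and top_n < 1:
        raise ModelError("top_n must be >= 1")
    g = net.to_simple_graph(directed=directed)
    bc = nx.betweenness_centrality(g, normalized=True)
    df = _ranked(bc, top_n)
    kind = "directed" if directed else "undirected"
    pairs = "(n-1)(n-2)" if directed else "(n-1)(n-2)/2"
    df.attrs["convention"] = (
        f"{kind} betweenness on simple graph (parallel edges merged), normalised by {pairs}"
    )
    return df


def betweenness_both_conventions(
    net: FunctionalNetwork, top_n: int | None = None
) -> dict[str, pd.DataFrame]:
    """Betweenness under both directed and undirected conventions.

    The printed reference tables for this kind of network do not state their
    convention, so both are reported and the match can be identified
    empirically.
    """
    return {
        "undirected": betweenness_table(net, top_n, directed=False),
        "directed": betweenness_table(net, top_n, directed=True),
    }
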