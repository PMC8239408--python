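"""Two-layer causal model: signed functional network plus transcript layer.

The *functional layer* is a signed directed multigraph compiled from curated
causal statements: nodes are canonical BEL terms, edges carry a sign
(+1 for increases/directlyIncreases, -1 for decreases/directlyDecreases,
0 for association) and the merged evidence behind them. The *transcript
layer* maps a subset of nodes -- the inferable nodes (iNodes) -- to signed
differential-expression gene signatures, so that node activity can be
inferred from a transcriptomic profile.

Only signed (sign != 0) edges participate in scoring; association edges are
retained for topology and visualisation.
"""

from __future__ import annotations

import json
import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .bel_parser import (
    FUNCTION_NAMES,
    BelStatement,
    BelTerm,
    parse_statement,
    serialize_term,
)

logger = logging.getLogger(__name__)

RELATION_SIGN = {
    "increases": 1,
    "directlyIncreases": 1,
    "decreases": -1,
    "directlyDecreases": -1,
    "association": 0,
}
SIGN_RELATION = {1: "increases", -1: "decreases", 0: "association"}


class ModelError(ValueError):
    """Raised when a model cannot be assembled or is unscoreable."""


@dataclass(frozen=True)
class CausalNode:
    id: str
    kind: str
    collapsed_label: str


@dataclass
class CausalEdge:
    source: str
    target: str
    sign: int
    weight: float = 1.0
    evidence: list = field(default_factory=list)
    indirect: bool = False
    ambiguous: bool = False


class FunctionalNetwork:
    """Signed directed multigraph of canonical causal terms with merged evidence."""

    def __init__(self, provenance: Mapping | None = None):
        self.nodes: dict[str, CausalNode] = {}
        self.edges: list[CausalEdge] = []
        self.provenance: dict = dict(provenance or {})
        self.log: list[str] = []
        self._edge_index: dict[tuple[str, str, int], CausalEdge] = {}

    # -- construction -----------------------------------------------------
    def add_node(self, node: CausalNode) -> None:
        existing = self.nodes.get(node.id)
        if existing is not None and existing != node:
            raise ModelError(f"node {node.id!r} already present with different attributes")
        self.nodes[node.id] = node

    def add_edge(
        self,
        source: str,
        target: str,
        sign: int,
        weight: float = 1.0,
        evidence: Iterable | None = None,
        merge: bool = True,
        indirect: bool = False,
        ambiguous: bool = False,
    ) -> CausalEdge:
        if source not in self.nodes or target not in self.nodes:
            raise ModelError(f"edge endpoints must exist as nodes: {source!r} -> {target!r}")
        if weight <= 0:
            raise ModelError("edge weight must be positive")
        key = (source, target, sign)
        ev = list(evidence or [])
        if merge and key in self._edge_index:
            edge = self._edge_index[key]
            edge.evidence.extend(ev)
            return edge
        edge = CausalEdge(source, target, sign, weight, ev, indirect=indirect, ambiguous=ambiguous)
        self.edges.append(edge)
        self._edge_index[key] = edge
        return edge

    # -- views ------------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def scoring_edges(self) -> list[CausalEdge]:
        """Edges of the scoring subgraph (sign != 0)."""
        return [e for e in self.edges if e.sign != 0]

    def node_ids(self) -> list[str]:
        return sorted(self.nodes)

    def to_multidigraph(self) -> nx.MultiDiGraph:
        g = nx.MultiDiGraph()
        for node in self.nodes.values():
            g.add_node(node.id, kind=node.kind, collapsed_label=node.collapsed_label)
        for e in self.edges:
            g.add_edge(e.source, e.target, sign=e.sign, weight=e.weight, indirect=e.indirect)
        return g

    def to_simple_graph(self, directed: bool = False) -> nx.Graph | nx.DiGraph:
        """Merge parallel edges into a simple (di)graph; edge attr ``signs`` holds the set."""
        g: nx.Graph | nx.DiGraph = nx.DiGraph() if directed else nx.Graph()
        g.add_nodes_from(self.nodes)
        for e in self.edges:
            if g.has_edge(e.source, e.target):
                g[e.source][e.target]["signs"].add(e.sign)
            else:
                g.add_edge(e.source, e.target, signs={e.sign})
        return g

    def conflicting_pairs(self) -> list[tuple[str, str]]:
        """Ordered node pairs connected by both a positive and a negative edge."""
        signs: dict[tuple[str, str], set[int]] = {}
        for e in self.edges:
            signs.setdefault((e.source, e.target), set()).add(e.sign)
        return sorted(pair for pair, ss in signs.items() if {1, -1} <= ss)


# ---------------------------------------------------------------------------
# compilation
# ---------------------------------------------------------------------------


def collapsed_label(term: BelTerm) -> str:
    """Gene-level label used by variant collapsing.

    r(X), p(X), p(X, pmod(...)) and act(p(X)) all map to the bare ``NS:value``
    of the gene; every other term keeps its canonical id.
    """
    if term.function in ("protein", "rna"):
        return f"{term.namespace}:{term.value}"
    if term.function == "activity" and term.inner and term.inner[0].function in ("protein", "rna"):
        return collapsed_label(term.inner[0])
    return serialize_term(term)


def _node_from_term(term: BelTerm) -> CausalNode:
    return CausalNode(id=serialize_term(term), kind=term.function, collapsed_label=collapsed_label(term))


def compile_network(statements: Sequence[BelStatement], merge_duplicates: bool = True) -> FunctionalNetwork:
    """Compile parsed statements into the functional layer.

    One node per distinct canonical term; duplicate (source, target, sign)
    edges are merged with concatenated evidence; pairs carrying both signs
    are kept as parallel edges and reported in the compile log.
    """
    net = FunctionalNetwork(provenance={"n_statements": len(statements)})
    if not statements:
        warnings.warn("compiling an empty statement list: resulting network is empty")
        net.log.append("warning: empty statement list")
        return net
    for stmt in statements:
        subj = _node_from_term(stmt.subject)
        obj = _node_from_term(stmt.object)
        net.add_node(subj)
        net.add_node(obj)
        sign = RELATION_SIGN[stmt.relation]
        evidence = [{
            "citation": {"source": stmt.citation.source, "evidence": stmt.citation.evidence},
            "annotations": {k: list(v) if isinstance(v, tuple) else v for k, v in stmt.annotations.items()},
            "relation": stmt.relation,
        }]
        net.add_edge(subj.id, obj.id, sign, evidence=evidence, merge=merge_duplicates)
    for source, target in net.conflicting_pairs():
        net.log.append(f"conflicting signs retained as parallel edges: {source} -> {target}")
    return net


def network_to_statements(net: FunctionalNetwork) -> list[BelStatement]:
    """Re-express a compiled network as one statement per edge (canonical relations)."""
    statements = []
    for e in net.edges:
        stmt = parse_statement(f"{e.source} {SIGN_RELATION[e.sign]} {e.target}")
        statements.append(stmt)
    return statements


def node_type_census(net: FunctionalNetwork) -> dict[str, int]:
    """Count nodes by outermost term function; counts partition the node set."""
    census = {name: 0 for name in sorted(FUNCTION_NAMES)}
    counts = Counter(node.kind for node in net.nodes.values())
    for kind, count in counts.items():
        census[kind] = census.get(kind, 0) + count
    return census


def edge_sign_census(net: FunctionalNetwork) -> dict[str, int]:
    """Causal (signed) vs non-causal (association) edge counts."""
    causal = sum(1 for e in net.edges if e.sign != 0)
    return {"causal": causal, "association": net.n_edges - causal}


def collapse_molecular_variants(net: FunctionalNetwork) -> FunctionalNetwork:
    """Merge RNA / protein / modified-protein / protein-activity variants of a gene.

    Edges are re-attached to the collapsed nodes; duplicates merge; self-loops
    created by collapsing are dropped and logged.
    """
    out = FunctionalNetwork(provenance=dict(net.provenance) | {"collapsed": True})
    groups: dict[str, list[CausalNode]] = {}
    mapping: dict[str, str] = {}
    for node in net.nodes.values():
        mapping[node.id] = node.collapsed_label
        groups.setdefault(node.collapsed_label, []).append(node)
    for label, members in groups.items():
        if len(members) == 1 and members[0].id == label:
            kind = members[0].kind  # untouched node (process, chemical, ...)
        elif any(n.kind in ("protein", "activity") for n in members):
            kind = "protein"
        elif any(n.kind == "rna" for n in members):
            kind = "rna"
        else:
            kind = members[0].kind
        out.add_node(CausalNode(id=label, kind=kind, collapsed_label=label))
    for e in net.edges:
        s, t = mapping[e.source], mapping[e.target]
        if s == t:
            out.log.append(f"dropped self-loop created by collapsing: {e.source} -> {e.target}")
            continue
        out.add_edge(s, t, e.sign, e.weight, evidence=list(e.evidence), merge=True)
    return out


# ---------------------------------------------------------------------------
# transcript layer
# ---------------------------------------------------------------------------


class TranscriptLayer:
    """Map from iNode ids to signed gene signatures.

    Gene identifiers are case-normalised to upper for matching; the original
    spelling is preserved for output.
    """

    def __init__(self, signatures: Mapping[str, Sequence[tuple[str, int]]]):
        self.signatures: dict[str, list[tuple[str, int]]] = {}
        self._original_case: dict[str, str] = {}
        for inode, genes in signatures.items():
            seen: set[str] = set()
            entry: list[tuple[str, int]] = []
            for gene, sign in genes:
                g = gene.upper()
                if g in seen:
                    raise ModelError(f"duplicate gene {gene!r} in signature of iNode {inode!r}")
                if sign not in (1, -1):
                    raise ModelError(f"gene sign must be +1 or -1, got {sign!r} for {gene!r}")
                seen.add(g)
                entry.append((g, int(sign)))
                self._original_case.setdefault(g, gene)
            self.signatures[inode] = entry

    def __len__(self) -> int:
        return len(self.signatures)

    def __contains__(self, inode: str) -> bool:
        return inode in self.signatures

    def genes(self) -> set[str]:
        return {g for sig in self.signatures.values() for g, _ in sig}

    def subset(self, inodes: Iterable[str]) -> "TranscriptLayer":
        return TranscriptLayer({i: self.signatures[i] for i in inodes})

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TranscriptLayer":
        df = pd.read_csv(path, sep="\t", dtype={"inode_id": str, "gene_id": str})
        required = {"inode_id", "gene_id", "sign"}
        if not required <= set(df.columns):
            raise ModelError(f"transcript layer TSV must have columns {sorted(required)}, got {list(df.columns)}")
        signatures: dict[str, list[tuple[str, int]]] = {}
        for row in df.itertuples(index=False):
            signatures.setdefault(row.inode_id, []).append((row.gene_id, int(row.sign)))
        return cls(signatures)

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            {"inode_id": inode, "gene_id": self._original_case.get(g, g), "sign": s}
            for inode, sig in sorted(self.signatures.items())
            for g, s in sig
        ]
        pd.DataFrame(rows, columns=["inode_id", "gene_id", "sign"]).to_csv(path, sep="\t", index=False)


@dataclass
class TwoLayerModel:
    """Functional network paired with the transcript layer restricted to its nodes."""

    network: FunctionalNetwork
    layer: TranscriptLayer
    dropped_inodes: tuple[str, ...] = ()

    @property
    def inodes(self) -> list[str]:
        return sorted(self.layer.signatures)


def attach_transcript_layer(
    net: FunctionalNetwork, layer: TranscriptLayer, strict: bool = False
) -> TwoLayerModel:
    """Pair a compiled network with a transcript layer.

    In strict mode an iNode id absent from the network is an error; otherwise
    such ids are dropped with a warning listing them. Zero usable iNodes make
    the model unscoreable.
    """
    unknown = sorted(i for i in layer.signatures if i not in net.nodes)
    if unknown and strict:
        raise ModelError(f"transcript layer names nodes absent from the network: {unknown}")
    if unknown:
        warnings.warn(f"dropping {len(unknown)} transcript-layer entries naming absent nodes: {unknown}")
    usable = [i for i in layer.signatures if i in net.nodes]
    if not usable:
        raise ModelError("model unscoreable: no transcript-layer iNode matches a network node")
    return TwoLayerModel(network=net, layer=layer.subset(usable), dropped_inodes=tuple(unknown))


# ---------------------------------------------------------------------------
# serialisation: GraphML / SIF / JSON
# ---------------------------------------------------------------------------


def write_graphml(net: FunctionalNetwork, path: str | Path) -> None:
    g = nx.MultiDiGraph()
    for node in net.nodes.values():
        g.add_node(node.id, kind=node.kind, collapsed_label=node.collapsed_label)
    for e in net.edges:
        g.add_edge(
            e.source,
            e.target,
            sign=e.sign,
            weight=e.weight,
            relation=SIGN_RELATION[e.sign],
            evidence=json.dumps(e.evidence),
            indirect=e.indirect,
            ambiguous=e.ambiguous,
        )
    nx.write_graphml(g, str(path))


def read_graphml(path: str | Path) -> FunctionalNetwork:
    g = nx.read_graphml(str(path), force_multigraph=True)
    net = FunctionalNetwork(provenance={"source": str(path)})
    for node_id, data in g.nodes(data=True):
        net.add_node(CausalNode(id=node_id, kind=data.get("kind", "abundance"),
                                collapsed_label=data.get("collapsed_label", node_id)))
    for s, t, data in g.edges(data=True):
        net.add_edge(
            s, t, int(data["sign"]), float(data.get("weight", 1.0)),
            evidence=json.loads(data.get("evidence", "[]")),
            merge=False,
            indirect=bool(data.get("indirect", False)),
            ambiguous=bool(data.get("ambiguous", False)),
        )
    return net


def write_sif(net: FunctionalNetwork, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for e in net.edges:
            fh.write(f"{e.source}\t{SIGN_RELATION[e.sign]}\t{e.target}\n")


def write_json_graph(net: FunctionalNetwork, path: str | Path) -> None:
    payload = {
        "nodes": [
            {"id": n.id, "kind": n.kind, "collapsed_label": n.collapsed_label}
            for n in (net.nodes[i] for i in net.node_ids())
        ],
        "edges": [
            {
                "source": e.source, "target": e.target, "sign": e.sign, "weight": e.weight,
                "evidence": e.evidence, "indirect": e.indirect, "ambiguous": e.ambiguous,
            }
            for e in net.edges
        ],
        "provenance": net.provenance,
        "log": net.log,
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n", encoding="utf-8")


def read_json_graph(path: str | Path) -> FunctionalNetwork:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    net = FunctionalNetwork(provenance=payload.get("provenance", {}))
    for n in payload["nodes"]:
        net.add_node(CausalNode(id=n["id"], kind=n["kind"], collapsed_label=n["collapsed_label"]))
    for e in payload["edges"]:
        net.add_edge(
            e["source"], e["target"], int(e["sign"]), float(e.get("weight", 1.0)),
            evidence=e.get("evidence", []), merge=False,
            indirect=bool(e.get("indirect", False)), ambiguous=bool(e.get("ambiguous", False)),
        )
    net.log = list(payload.get("log", []))
    return net


def load_network(path: str | Path) -> FunctionalNetwork:
    """Load a network from .bel (parse + compile), .json or .graphml."""
    path = Path(path)
    if path.suffix == ".bel":
        from .bel_parser import parse_document

        with open(path, encoding="utf-8") as fh:
            return compile_network(parse_document(fh))
    if path.suffix == ".json":
        return read_json_graph(path)
    if path.suffix == ".graphml":
        return read_graphml(path)
    raise ModelError(f"unrecognised network format: {path.suffix!r} (expected .bel, .json or .graphml)")
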