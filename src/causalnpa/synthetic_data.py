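"""Synthetic two-layer models and expression profiles with controlled consistency.

The generators make every stage of the pipeline testable without any
external data: random signed networks whose node ids are valid causal terms
(``p(SYN:n003)``), disjoint signed gene signatures, and expression profiles
in two modes. *Consistent* profiles are built from latent coefficients
``c*`` propagated sign-coherently through the backbone (child value = parent
value x edge sign, breadth-first from one root per component), so that at
zero noise the generated data are exactly representable by the model and
coefficient recovery is an identity. *Null* profiles are i.i.d. normal noise
with no network structure. The gene universe of every profile includes 50%
decoy genes outside the transcript layer, mimicking the off-signature bulk
of a genome-wide profile that transcript-layer permutation draws from.

All generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

import json
import math
from collections import deque
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .network_model import (
    CausalNode,
    FunctionalNetwork,
    ModelError,
    TranscriptLayer,
    TwoLayerModel,
    attach_transcript_layer,
)
from .npa_scoring import ExpressionProfile


@dataclass
class SyntheticTruth:
    """Latent generating state stored alongside each profile for recovery tests."""

    c_star: dict[str, float]
    mode: str
    tau: float
    seed: int

    def to_json(self, path: str | Path) -> None:
        payload = {"c_star": self.c_star, "mode": self.mode, "tau": self.tau, "seed": self.seed}
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n", encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        d = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(c_star=d["c_star"], mode=d["mode"], tau=d["tau"], seed=d["seed"])


def generate_network(
    n_nodes: int, n_edges: int, p_negative: float = 0.3, seed: int = 0, acyclic: bool = False
) -> FunctionalNetwork:
    """Random signed directed network without self-loops.

    By default edges are uniform random distinct ordered pairs, each sign -1
    with probability ``p_negative``. With ``acyclic=True`` the undirected
    skeleton is a random recursive forest (needs n_edges <= n_nodes - 1),
    which guarantees the signed graph is balanced: sign-coherent latent
    coefficients then satisfy every edge exactly, so consistent-mode profiles
    are exactly representable by the model. End-to-end calibration and power
    studies use the acyclic form for that reason.
    """
    max_edges = n_nodes * (n_nodes - 1)
    if n_edges > max_edges:
        raise ModelError(f"cannot place {n_edges} distinct directed edges on {n_nodes} nodes (max {max_edges})")
    if acyclic and n_edges > n_nodes - 1:
        raise ModelError(f"an acyclic skeleton on {n_nodes} nodes holds at most {n_nodes - 1} edges")
    rng = np.random.default_rng(seed)
    ids = [f"p(SYN:n{i:03d})" for i in range(n_nodes)]
    net = FunctionalNetwork(provenance={"generator": "generate_network", "seed": seed, "acyclic": acyclic})
    for i, nid in enumerate(ids):
        net.add_node(CausalNode(id=nid, kind="protein", collapsed_label=f"SYN:n{i:03d}"))
    evidence = [{"citation": {"source": "synthetic", "evidence": ""}, "annotations": {}}]
    signs = np.where(rng.random(n_edges) < p_negative, -1, 1)
    if acyclic:
        order = rng.permutation(n_nodes)
        for k in range(n_edges):
            a, b = int(order[int(rng.integers(k + 1))]), int(order[k + 1])
            if rng.random() < 0.5:
                a, b = b, a
            net.add_edge(ids[a], ids[b], int(signs[k]), evidence=list(evidence))
    else:
        chosen = rng.choice(max_edges, size=n_edges, replace=False)
        for flat, sign in zip(sorted(chosen.tolist()), signs.tolist()):
            i, j = divmod(flat, n_nodes - 1)
            if j >= i:
                j += 1  # skip the diagonal
            net.add_edge(ids[i], ids[j], int(sign), evidence=list(evidence))
    return net


def generate_transcript_layer(
    net: FunctionalNetwork,
    frac_inodes: float = 0.5,
    genes_per_inode: int = 5,
    p_negative_sign: float = 0.3,
    seed: int = 0,
) -> TranscriptLayer:
    """Disjoint signed synthetic gene signatures for a random node subset."""
    if not 0 < frac_inodes <= 1:
        raise ModelError("frac_inodes must lie in (0, 1]")
    if genes_per_inode < 1:
        raise ModelError("genes_per_inode must be >= 1")
    rng = np.random.default_rng(seed)
    node_ids = net.node_ids()
    k = math.ceil(frac_inodes * len(node_ids))
    inodes = sorted(rng.choice(node_ids, size=k, replace=False).tolist())
    signatures: dict[str, list[tuple[str, int]]] = {}
    counter = 0
    for inode in inodes:
        sig = []
        for _ in range(genes_per_inode):
            sign = -1 if rng.random() < p_negative_sign else 1
            sig.append((f"SYNG{counter:04d}", sign))
            counter += 1
        signatures[inode] = sig
    return TranscriptLayer(signatures)


def _propagate_latent(net: FunctionalNetwork, rng: np.random.Generator, scale: float) -> dict[str, float]:
    """Sign-coherent latent coefficients: BFS, child = parent x edge sign.

    One random root per connected component of the scoring subgraph (isolated
    nodes form their own components); the first-visited parent wins where
    multiple parents or conflicting parallel edges reach a node.
    """
    # undirected adjacency with a deterministic merged sign per unordered pair
    adj: dict[str, dict[str, int]] = {nid: {} for nid in net.nodes}
    for e in net.scoring_edges():
        adj[e.source].setdefault(e.target, e.sign)
        adj[e.target].setdefault(e.source, e.sign)
    c_star: dict[str, float] = {}
    for start in net.node_ids():
        if start in c_star:
            continue
        # collect the whole component, then root it at a random member
        component = []
        stack = [start]
        seen = {start}
        while stack:
            u = stack.pop()
            component.append(u)
            for v in adj[u]:
                if v not in seen:
                    seen.add(v)
                    stack.append(v)
        component.sort()
        root = component[int(rng.integers(len(component)))]
        value = scale * float(rng.uniform(0.8, 1.2)) * (1.0 if rng.random() < 0.5 else -1.0)
        c_star[root] = value
        queue = deque([root])
        while queue:
            u = queue.popleft()
            for v in sorted(adj[u]):
                if v not in c_star:
                    c_star[v] = c_star[u] * adj[u][v]
                    queue.append(v)
    return c_star


def generate_profile(
    model: TwoLayerModel,
    mode: str = "consistent",
    scale: float = 1.0,
    tau: float = 0.1,
    seed: int = 0,
) -> tuple[ExpressionProfile, SyntheticTruth]:
    """Expression profile with controlled model consistency.

    consistent -- beta_g = s_xg * c*(x) + normal(0, tau^2) for signature
    genes, where c* is sign-coherently propagated; null -- beta i.i.d.
    normal(0, tau^2) with c* = 0. Both modes add 50% decoy genes (noise
    only) and record tau^2 as the per-gene variance.
    """
    if tau < 0:
        raise ModelError("noise level tau must be >= 0")
    if mode not in ("consistent", "null"):
        raise ModelError(f"mode must be 'consistent' or 'null', got {mode!r}")
    if not model.layer.signatures:
        raise ModelError("model has no iNodes")
    rng = np.random.default_rng(seed)
    var = tau * tau
    data: dict[str, tuple[float, float]] = {}
    if mode == "consistent":
        c_star = _propagate_latent(model.network, rng, scale)
        for inode in sorted(model.layer.signatures):
            for gene, sign in model.layer.signatures[inode]:
                data[gene] = (sign * c_star[inode] + tau * rng.standard_normal(), var)
    else:
        c_star = {nid: 0.0 for nid in model.network.nodes}
        for inode in sorted(model.layer.signatures):
            for gene, _ in model.layer.signatures[inode]:
                data[gene] = (tau * rng.standard_normal(), var)
    n_decoys = math.ceil(0.5 * len(data))
    for i in range(n_decoys):
        data[f"DECOY{i:04d}"] = (tau * rng.standard_normal(), var)
    profile = ExpressionProfile(data)
    return profile, SyntheticTruth(c_star=c_star, mode=mode, tau=tau, seed=seed)


def generate_model(
    n_nodes: int = 15,
    n_edges: int = 14,
    p_negative: float = 0.5,
    frac_inodes: float = 0.8,
    genes_per_inode: int = 5,
    p_negative_sign: float = 0.3,
    seed: int = 0,
    acyclic: bool = True,
) -> TwoLayerModel:
    """Network + transcript layer + attachment in one call.

    The defaults are the reference study conditions for end-to-end
    simulations: a 15-node spanning-tree backbone (balanced by construction,
    so consistent data are exactly representable), balanced edge signs (a
    sign-diverse activity pattern, which is what gives backbone rewiring its
    discriminating power), and transcript-layer coverage of 80% of nodes
    with 5 genes per signature -- densely annotated, as scoring-oriented
    curated networks are.
    """
    net = generate_network(n_nodes, n_edges, p_negative, seed=seed, acyclic=acyclic)
    layer = generate_transcript_layer(net, frac_inodes, genes_per_inode, p_negative_sign, seed=seed + 1)
    return attach_transcript_layer(net, layer)


# ---------------------------------------------------------------------------
# fixture suite
# ---------------------------------------------------------------------------

WORKED_EXAMPLE_BEL = """\
# Ethanol / agrin / shh worked example: three causal statements on microcephaly.
SET Citation = {"PubMed", "synthetic worked example", "WE-1"}
SET Evidence = "Exposure to ethanol, or knockdown of agrin or shha, reduces larval brain volume."
SET Species = "7955"
a(CHEBI:ethanol) increases path(MESHD:Microcephaly)
act(p(ZFIN:agrn)) decreases path(MESHD:Microcephaly)
act(p(ZFIN:shha)) decreases path(MESHD:Microcephaly)
"""


def write_fixture_suite(directory: str | Path, seed: int = 0) -> dict:
    """Write the worked-example BEL fixture plus a scoreable 10-node toy model.

    Returns (and writes as ``manifest.json``) a manifest listing the files
    and the seeds they were generated from; regeneration with the same seed
    is byte-identical.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    (directory / "worked_example.bel").write_text(WORKED_EXAMPLE_BEL, encoding="utf-8")

    from .network_model import compile_network, network_to_statements
    from .bel_parser import serialize_statement

    raw_net = generate_network(n_nodes=10, n_edges=9, seed=seed, acyclic=True)
    statements = network_to_statements(raw_net)
    bel_lines = [serialize_statement(s) for s in statements]
    (directory / "toy_network.bel").write_text("\n".join(bel_lines) + "\n", encoding="utf-8")
    # build the layer against the BEL round-trip of the network: a statement
    # per edge cannot express isolated nodes, so the layer must not name them
    net = compile_network(statements)
    layer = generate_transcript_layer(net, frac_inodes=0.5, genes_per_inode=5, seed=seed + 1)
    model = attach_transcript_layer(net, layer)
    model.layer.to_tsv(directory / "toy_layer.tsv")

    prof_c, truth_c = generate_profile(model, mode="consistent", tau=0.1, seed=seed + 10)
    prof_n, truth_n = generate_profile(model, mode="null", tau=0.1, seed=seed + 11)
    prof_c.to_tsv(directory / "toy_profile_consistent.tsv")
    prof_n.to_tsv(directory / "toy_profile_null.tsv")
    truth_c.to_json(directory / "toy_truth_consistent.json")
    truth_n.to_json(directory / "toy_truth_null.json")

    manifest = {
        "seed": seed,
        "files": sorted(
            p.name for p in directory.iterdir() if p.name != "manifest.json"
        ),
        "toy_model": {"n_nodes": 10, "n_edges": 9, "frac_inodes": 0.5, "genes_per_inode": 5},
        "profiles": {
            "toy_profile_consistent.tsv": {"mode": "consistent", "tau": 0.1, "seed": seed + 10},
            "toy_profile_null.tsv": {"mode": "null", "tau": 0.1, "seed": seed + 11},
        },
    }
    (directory / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return manifest
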