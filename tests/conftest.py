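import pytest

from causalnpa import (
    ExpressionProfile,
    FunctionalNetwork,
    TranscriptLayer,
    attach_transcript_layer,
    compile_network,
    parse_statement,
)
from causalnpa.network_model import CausalNode

WORKED_EXAMPLE_STATEMENTS = [
    "a(CHEBI:ethanol) → path(MESHD:Microcephaly)",
    "act(p(ZFIN:agrn)) −| path(MESHD:Microcephaly)",
    "act(p(ZFIN:shha)) -| path(MESHD:Microcephaly)",
]


@pytest.fixture
def worked_example_network() -> FunctionalNetwork:
    """The ethanol/agrn/shha microcephaly example: 4 nodes, 3 edges (+1, -1, -1)."""
    return compile_network([parse_statement(s) for s in WORKED_EXAMPLE_STATEMENTS])


def chain_network(signs: list[int], prefix: str = "x") -> FunctionalNetwork:
    """Directed chain x0 -> x1 -> ... with the given edge signs."""
    net = FunctionalNetwork()
    for i in range(len(signs) + 1):
        nid = f"p(SYN:{prefix}{i})"
        net.add_node(CausalNode(nid, "protein", f"SYN:{prefix}{i}"))
    for i, sign in enumerate(signs):
        net.add_edge(f"p(SYN:{prefix}{i})", f"p(SYN:{prefix}{i+1})", sign, evidence=[{}])
    return net


@pytest.fixture
def two_node_conflict_model():
    """Single edge x->y with sign -1 and both endpoints anchored at activity 1."""
    net = chain_network([-1])
    layer = TranscriptLayer({"p(SYN:x0)": [("G1", 1)], "p(SYN:x1)": [("G2", 1)]})
    model = attach_transcript_layer(net, layer)
    profile = ExpressionProfile({"G1": (1.0, 0.0), "G2": (1.0, 0.0)})
    return model, profile
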