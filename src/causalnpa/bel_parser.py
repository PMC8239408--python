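"""Parser and serializer for a BEL 1.0 subset.

Biological Expression Language (BEL) encodes causal biological knowledge as
subject--relation--object triples. A *term* names a biological entity at some
level of organisation -- an abundance ``a(CHEBI:ethanol)``, a protein
``p(ZFIN:lef1)``, an activity wrapping a protein ``act(p(ZFIN:gbx2))``, a
biological process ``bp(GOBP:"cell proliferation")`` -- with the entity drawn
from a controlled vocabulary (namespace) such as ZFIN, GOBP, MESHD, CHEBI or
HGNC. A *statement* relates two terms with one of five causal relations
(``increases``, ``directlyIncreases``, ``decreases``, ``directlyDecreases``,
``association``).

The grammar here covers nine term functions and five relations -- enough for
literature-curated toxicity networks built from single-gene evidence -- and
fails loudly on anything else. Typographic arrows (``→``, ``−|``) and curly
quotes, common in print, are normalised before tokenisation.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

logger = logging.getLogger(__name__)

# short token -> canonical function name
FUNCTION_TOKENS: dict[str, str] = {
    "a": "abundance",
    "p": "protein",
    "r": "rna",
    "m": "microRNA",
    "bp": "biologicalProcess",
    "path": "pathology",
    "complex": "complexAbundance",
    "act": "activity",
    "pmod": "proteinModification",
}
FUNCTION_NAMES = set(FUNCTION_TOKENS.values())
_SHORT: dict[str, str] = {v: k for k, v in FUNCTION_TOKENS.items()}
# long names are accepted on input as well
_TOKEN_TO_FUNCTION = dict(FUNCTION_TOKENS) | {v: v for v in FUNCTION_TOKENS.values()}

#: functions an activity may wrap
MOLECULAR_FUNCTIONS = {"abundance", "protein", "rna", "microRNA", "complexAbundance"}

RELATIONS = (
    "increases",
    "directlyIncreases",
    "decreases",
    "directlyDecreases",
    "association",
)
SYMBOLIC_RELATIONS: dict[str, str] = {
    "->": "increases",
    "=>": "directlyIncreases",
    "-|": "decreases",
    "=|": "directlyDecreases",
    "--": "association",
}

# typographic glyph normalisation applied before any tokenisation
_GLYPH_SUBS = (
    ("→", "->"),   # →
    ("⊣", "-|"),   # ⊣
    ("−", "-"),    # − (minus sign)
    ("“", '"'),
    ("”", '"'),
    ("‘", "'"),
    ("’", "'"),
)


def _normalize_glyphs(text: str) -> str:
    for src, dst in _GLYPH_SUBS:
        text = text.replace(src, dst)
    return text


class BelSyntaxError(ValueError):
    """Base class for BEL parse failures."""


class UnbalancedParenthesesError(BelSyntaxError):
    pass


class UnknownFunctionError(BelSyntaxError):
    pass


class EmptyNameError(BelSyntaxError):
    """Namespace or value missing where one is required."""


class UnknownRelationError(BelSyntaxError):
    pass


class BelDocumentError(ValueError):
    """Statement-level failure inside a document, annotated with line number."""


@dataclass(frozen=True)
class BelTerm:
    """One BEL term: a function applied to a namespaced name and/or inner terms."""

    function: str
    namespace: str | None = None
    value: str | None = None
    inner: tuple["BelTerm", ...] = ()

    @property
    def canonical_id(self) -> str:
        """Canonical single-line serialisation (short function tokens, minimal quoting)."""
        return serialize_term(self)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.canonical_id


@dataclass(frozen=True)
class Citation:
    """Provenance of a statement: source identifier plus optional evidence sentence."""

    source: str = ""
    evidence: str = ""


@dataclass(frozen=True)
class BelStatement:
    subject: BelTerm
    relation: str
    object: BelTerm
    annotations: Mapping[str, object] = field(default_factory=dict)
    citation: Citation = field(default_factory=Citation)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return serialize_statement(self)


# ---------------------------------------------------------------------------
# term parsing
# ---------------------------------------------------------------------------

_NAME_RE = re.compile(r'[^\s(),:"]+')
_BARE_VALUE_RE = re.compile(r"\w+")


def _tokenize(text: str) -> list[tuple[str, str, int]]:
    """Lex a term into (kind, text, position) tokens.

    Kinds: NAME, STRING, and the literals ``( ) , :``.
    """
    tokens: list[tuple[str, str, int]] = []
    i, n = 0, len(text)
    while i < n:
        ch = text[i]
        if ch.isspace():
            i += 1
            continue
        if ch in "(),:":
            tokens.append((ch, ch, i))
            i += 1
            continue
        if ch == '"':
            j = text.find('"', i + 1)
            if j < 0:
                raise BelSyntaxError(f"unterminated quote starting at position {i}: {text[i:]!r}")
            tokens.append(("STRING", text[i + 1 : j], i))
            i = j + 1
            continue
        m = _NAME_RE.match(text, i)
        assert m is not None
        tokens.append(("NAME", m.group(), i))
        i = m.end()
    return tokens


def _parse_term_tokens(tokens: list[tuple[str, str, int]], pos: int, source: str) -> tuple[BelTerm, int]:
    if pos >= len(tokens) or tokens[pos][0] != "NAME":
        raise BelSyntaxError(f"expected a function token in {source!r}")
    kind, token, at = tokens[pos]
    if token not in _TOKEN_TO_FUNCTION:
        raise UnknownFunctionError(f"unknown function token {token!r} at position {at} in {source!r}")
    function = _TOKEN_TO_FUNCTION[token]
    pos += 1
    if pos >= len(tokens) or tokens[pos][0] != "(":
        raise UnbalancedParenthesesError(f"expected '(' after {token!r} in {source!r}")
    pos += 1

    namespace: str | None = None
    value: str | None = None
    inner: list[BelTerm] = []
    expect_arg = True
    while True:
        if pos >= len(tokens):
            raise UnbalancedParenthesesError(f"unbalanced parentheses in {source!r}")
        k, t, at = tokens[pos]
        if k == ")":
            if expect_arg and (namespace is not None or value is not None or inner):
                raise BelSyntaxError(f"trailing comma at position {at} in {source!r}")
            pos += 1
            break
        if not expect_arg:
            if k != ",":
                raise BelSyntaxError(f"expected ',' or ')' at position {at} in {source!r}")
            pos += 1
            expect_arg = True
            continue
        # an argument: nested term, ns:value pair, or bare/quoted value
        if k == "NAME" and pos + 1 < len(tokens) and tokens[pos + 1][0] == "(":
            term, pos = _parse_term_tokens(tokens, pos, source)
            inner.append(term)
        elif k == "NAME" and pos + 1 < len(tokens) and tokens[pos + 1][0] == ":":
            if value is not None or namespace is not None:
                raise BelSyntaxError(f"multiple name arguments in {source!r}")
            namespace = t
            if pos + 2 >= len(tokens) or tokens[pos + 2][0] not in ("NAME", "STRING"):
                raise EmptyNameError(f"empty value after namespace {t!r} in {source!r}")
            value = tokens[pos + 2][1]
            pos += 3
        elif k == ":":
            raise EmptyNameError(f"empty namespace at position {at} in {source!r}")
        elif k in ("NAME", "STRING"):
            if value is not None or namespace is not None:
                raise BelSyntaxError(f"multiple name arguments in {source!r}")
            value = t
            pos += 1
        else:
            raise BelSyntaxError(f"unexpected token {t!r} at position {at} in {source!r}")
        expect_arg = False
    return BelTerm(function=function, namespace=namespace, value=value, inner=tuple(inner)), pos


def _validate_term(term: BelTerm, parent: BelTerm | None = None) -> None:
    f = term.function
    if f == "activity":
        if term.namespace is not None or term.value is not None or len(term.inner) != 1:
            raise BelSyntaxError(f"activity must wrap exactly one molecular term: {serialize_term(term)!r}")
        if term.inner[0].function not in MOLECULAR_FUNCTIONS:
            raise BelSyntaxError(
                f"activity may only wrap a molecular term, got {term.inner[0].function}: {serialize_term(term)!r}"
            )
    elif f == "proteinModification":
        if parent is None or parent.function != "protein":
            raise BelSyntaxError(f"proteinModification only occurs inside protein terms: {serialize_term(term)!r}")
        if not term.value:
            raise EmptyNameError(f"proteinModification requires a modification code: {serialize_term(term)!r}")
        if term.inner:
            raise BelSyntaxError("proteinModification takes no inner terms")
    elif f == "complexAbundance":
        named = term.namespace is not None and bool(term.value)
        if not named and len(term.inner) < 2:
            raise BelSyntaxError(
                f"complexAbundance needs a namespaced name or at least two components: {serialize_term(term)!r}"
            )
    else:
        if not term.namespace:
            raise EmptyNameError(f"{f} requires namespace:value, namespace missing in {serialize_term(term)!r}")
        if not term.value:
            raise EmptyNameError(f"{f} requires namespace:value, value missing in {serialize_term(term)!r}")
        if term.inner and f != "protein":
            raise BelSyntaxError(f"{f} takes no inner terms: {serialize_term(term)!r}")
        if f == "protein":
            for sub in term.inner:
                if sub.function != "proteinModification":
                    raise BelSyntaxError(f"protein inner terms must be proteinModification: {serialize_term(term)!r}")
    for sub in term.inner:
        _validate_term(sub, term)


def parse_term(text: str) -> BelTerm:
    """Parse a single BEL term.

    Whitespace outside quoted strings is ignored; quoted values are preserved
    verbatim (including case). Raises a :class:`BelSyntaxError` subclass
    naming the offending span on malformed input.
    """
    text = _normalize_glyphs(text)
    if not text.strip():
        raise BelSyntaxError("empty term")
    depth = 0
    in_quote = False
    for ch in text:
        if in_quote:
            in_quote = ch != '"'
        elif ch == '"':
            in_quote = True
        elif ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise UnbalancedParenthesesError(f"unbalanced parentheses in {text!r}")
    if depth != 0:
        raise UnbalancedParenthesesError(f"unbalanced parentheses in {text!r}")
    tokens = _tokenize(text)
    term, pos = _parse_term_tokens(tokens, 0, text)
    if pos != len(tokens):
        raise BelSyntaxError(f"trailing tokens after term in {text!r}")
    _validate_term(term)
    return term


def _quote_if_needed(value: str) -> str:
    if _BARE_VALUE_RE.fullmatch(value):
        return value
    return f'"{value}"'


def serialize_term(term: BelTerm) -> str:
    parts: list[str] = []
    if term.namespace is not None:
        parts.append(f"{term.namespace}:{_quote_if_needed(term.value or '')}")
    elif term.value is not None:
        parts.append(_quote_if_needed(term.value))
    parts.extend(serialize_term(t) for t in term.inner)
    return f"{_SHORT[term.function]}({','.join(parts)})"


# ---------------------------------------------------------------------------
# statement parsing
# ---------------------------------------------------------------------------

_WORD_RE = re.compile(r"[A-Za-z]+")


def _find_relations(line: str) -> list[tuple[int, int, str]]:
    """Locate relation tokens at parenthesis depth 0, outside quotes."""
    hits: list[tuple[int, int, str]] = []
    depth = 0
    in_quote = False
    i = 0
    n = len(line)
    while i < n:
        ch = line[i]
        if in_quote:
            if ch == '"':
                in_quote = False
            i += 1
            continue
        if ch == '"':
            in_quote = True
            i += 1
            continue
        if ch == "(":
            depth += 1
            i += 1
            continue
        if ch == ")":
            depth -= 1
            if depth < 0:
                raise UnbalancedParenthesesError(f"unbalanced parentheses in {line!r}")
            i += 1
            continue
        if depth == 0:
            sym = line[i : i + 2]
            if sym in SYMBOLIC_RELATIONS:
                hits.append((i, i + 2, SYMBOLIC_RELATIONS[sym]))
                i += 2
                continue
            if ch.isalpha() and (i == 0 or line[i - 1].isspace()):
                m = _WORD_RE.match(line, i)
                assert m is not None
                word = m.group()
                boundary = m.end() == n or line[m.end()].isspace()
                if word in RELATIONS and boundary:
                    hits.append((i, m.end(), word))
                i = m.end()
                continue
        i += 1
    if depth != 0:
        raise UnbalancedParenthesesError(f"unbalanced parentheses in {line!r}")
    return hits


def parse_statement(line: str) -> BelStatement:
    """Parse one statement line: ``subject relation object``.

    Relations are accepted in symbolic (``->``, ``=>``, ``-|``, ``=|``, ``--``)
    and word form; typographic arrows are normalised first. The returned
    statement has empty annotations and citation; :func:`parse_document`
    fills those from the surrounding SET state.
    """
    line = _normalize_glyphs(line).strip()
    hits = _find_relations(line)
    if not hits:
        raise UnknownRelationError(f"no relation token found in {line!r}")
    if len(hits) > 1:
        raise UnknownRelationError(f"multiple relation tokens in {line!r}")
    start, end, relation = hits[0]
    subject_text = line[:start].strip()
    object_text = line[end:].strip()
    if not subject_text or not object_text:
        raise BelSyntaxError(f"missing subject or object in {line!r}")
    return BelStatement(
        subject=parse_term(subject_text),
        relation=relation,
        object=parse_term(object_text),
        annotations={},
        citation=Citation(),
    )


def serialize_statement(stmt: BelStatement) -> str:
    """Canonical one-line form with word-form relation; inverted by parse_statement."""
    return f"{serialize_term(stmt.subject)} {stmt.relation} {serialize_term(stmt.object)}"


# ---------------------------------------------------------------------------
# document parsing (OpenBEL-style script)
# ---------------------------------------------------------------------------

_BRACED_LIST_RE = re.compile(r"\{(.*)\}\s*$", re.S)
_QUOTED_ITEM_RE = re.compile(r'"([^"]*)"')


def _parse_set_value(raw: str) -> str | tuple[str, ...]:
    raw = raw.strip()
    m = _BRACED_LIST_RE.match(raw)
    if m:
        return tuple(_QUOTED_ITEM_RE.findall(m.group(1)))
    if raw.startswith('"') and raw.endswith('"') and len(raw) >= 2:
        return raw[1:-1]
    return raw


def _citation_from_parts(parts: str | tuple[str, ...]) -> Citation:
    if isinstance(parts, str):
        return Citation(source=parts)
    if len(parts) >= 3:
        return Citation(source=f"{parts[0]}:{parts[2]}")
    if parts:
        return Citation(source=":".join(parts))
    return Citation()


def parse_document(stream: Iterable[str]) -> list[BelStatement]:
    """Parse a BEL script: DEFINE/SET/UNSET preamble plus statement lines.

    Each returned statement carries a snapshot of the annotation state active
    at its line and the citation from the most recent ``SET Citation``.
    UNSET of an annotation that was never set logs a warning; a statement
    line that fails to parse raises :class:`BelDocumentError` with its line
    number.
    """
    statements: list[BelStatement] = []
    annotations: dict[str, object] = {}
    citation = Citation()
    for lineno, raw in enumerate(stream, start=1):
        line = _normalize_glyphs(raw).strip()
        if not line or line.startswith("#") or line.startswith("//"):
            continue
        if line.upper().startswith("DEFINE "):
            continue  # namespace/annotation definitions: tolerated, not resolved
        if line.startswith("UNSET "):
            key = line[len("UNSET ") :].strip()
            if key.lower() == "all":
                annotations.clear()
                citation = Citation()
            elif key == "Citation":
                citation = Citation()
            elif key in annotations:
                del annotations[key]
            else:
                logger.warning("line %d: UNSET of annotation %r that was never set", lineno, key)
            continue
        if line.startswith("SET "):
            body = line[len("SET ") :]
            if "=" not in body:
                raise BelDocumentError(f"line {lineno}: malformed SET line {line!r}")
            key, _, raw_value = body.partition("=")
            key = key.strip()
            value = _parse_set_value(raw_value)
            if key == "Citation":
                citation = _citation_from_parts(value)
            elif key in ("Evidence", "SupportingText"):
                citation = replace(citation, evidence=value if isinstance(value, str) else " ".join(value))
            else:
                annotations[key] = value
            continue
        try:
            stmt = parse_statement(line)
        except BelSyntaxError as exc:
            raise BelDocumentError(f"line {lineno}: {exc}") from exc
        statements.append(replace(stmt, annotations=dict(annotations), citation=citation))
    return statements


# ---------------------------------------------------------------------------
# JSON-lines interchange
# ---------------------------------------------------------------------------


def term_to_dict(term: BelTerm) -> dict:
    return {
        "function": term.function,
        "namespace": term.namespace,
        "value": term.value,
        "inner": [term_to_dict(t) for t in term.inner],
    }


def term_from_dict(data: Mapping) -> BelTerm:
    return BelTerm(
        function=data["function"],
        namespace=data.get("namespace"),
        value=data.get("value"),
        inner=tuple(term_from_dict(t) for t in data.get("inner", ())),
    )


def statement_to_dict(stmt: BelStatement) -> dict:
    return {
        "subject": term_to_dict(stmt.subject),
        "relation": stmt.relation,
        "object": term_to_dict(stmt.object),
        "annotations": {k: list(v) if isinstance(v, tuple) else v for k, v in stmt.annotations.items()},
        "citation": {"source": stmt.citation.source, "evidence": stmt.citation.evidence},
    }


def statement_from_dict(data: Mapping) -> BelStatement:
    annotations = {k: tuple(v) if isinstance(v, list) else v for k, v in data.get("annotations", {}).items()}
    cit = data.get("citation", {})
    return BelStatement(
        subject=term_from_dict(data["subject"]),
        relation=data["relation"],
        object=term_from_dict(data["object"]),
        annotations=annotations,
        citation=Citation(source=cit.get("source", ""), evidence=cit.get("evidence", "")),
    )
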