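"""Entity-merged dependency parsing and semantic relation extraction.

Recognized entities are merged into single parse tokens ("chronic arthritis"
becomes the token ``chronic_arthritis``) so that grammatical relations hold
directly between medical concepts.  Dependency triples (governor, dependent,
relation) come from a pluggable parser adapter; the bundled adapter replays
deterministic CoNLL-U fixtures keyed by question id, so no external parser is
ever required.  A triple whose two endpoints both carry a semantic type is
lifted to a semantic relation; those type pairs drive the semantic features
and the type-pair network.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Protocol

from .errors import ParseFixtureError
from .lexicon import AnnotatedQuestion

__all__ = [
    "ParseToken", "DependencyTriple", "SemanticRelation",
    "merge_entities", "parse_dependencies", "extract_semantic_relations",
    "ParserAdapter", "ConlluFixtureAdapter", "bundled_fixture_adapter",
]


@dataclass(frozen=True)
class ParseToken:
    """One token of the entity-merged sentence (1-based ``index``)."""

    index: int
    form: str
    pos: str
    chunk_ref: int


@dataclass(frozen=True)
class DependencyTriple:
    governor: ParseToken
    dependent: ParseToken
    relation: str

    def __post_init__(self) -> None:
        if self.governor.index == self.dependent.index:
            raise ValueError("governor and dependent must differ")
        if not self.relation:
            raise ValueError("empty relation label")


@dataclass(frozen=True)
class SemanticRelation:
    """A dependency link whose endpoints are both mapped entities."""

    dependent_type: str
    governor_type: str
    relation: str
    dependent_surface: str
    governor_surface: str


def merge_entities(aq: AnnotatedQuestion) -> list[ParseToken]:
    """One parse token per chunk; multi-word entities joined with ``_``."""
    return [
        ParseToken(index=i + 1, form="_".join(c.surface.lower().split()), pos="", chunk_ref=i)
        for i, c in enumerate(aq.chunks)
    ]


class ParserAdapter(Protocol):
    """Contract for dependency parsers over entity-merged tokens.

    ``parse`` must return every dependency triple plus the tokens with POS
    filled in; each non-root token appears as the dependent of exactly one
    triple (the parse is a tree).
    """

    def parse(self, qid: str, tokens: list[ParseToken]) -> tuple[list[DependencyTriple], list[ParseToken]]:
        ...


def parse_dependencies(
    tokens: list[ParseToken], adapter: ParserAdapter, qid: str = ""
) -> tuple[list[DependencyTriple], list[ParseToken]]:
    """Run the adapter and enforce the tree contract on its output."""
    if not tokens:
        raise ValueError("no tokens to parse")
    triples, tagged = adapter.parse(qid, tokens)
    dep_counts: dict[int, int] = {}
    for t in triples:
        dep_counts[t.dependent.index] = dep_counts.get(t.dependent.index, 0) + 1
    roots = [tok for tok in tagged if dep_counts.get(tok.index, 0) == 0]
    bad = [i for i, c in dep_counts.items() if c != 1]
    if bad or len(roots) != 1 and len(tagged) > 1:
        raise ParseFixtureError(
            f"{qid or '<question>'}: adapter output is not a dependency tree "
            f"(multi-headed tokens {bad}, {len(roots)} root(s))"
        )
    return triples, tagged


@dataclass
class _FixtureSentence:
    forms: list[str]
    pos: list[str]
    heads: list[int]
    deprels: list[str]


class ConlluFixtureAdapter:
    """Deterministic parser adapter backed by a CoNLL-U file.

    Sentences are keyed by a ``# qid = <qid>`` comment.  The FORM column must
    agree with the entity-merged token forms, otherwise the fixture and the
    annotation have diverged and the adapter fails loudly.
    """

    def __init__(self, source: str | Path | None = None, text: str | None = None) -> None:
        if text is None:
            if source is None:
                raise ValueError("either a path or raw text is required")
            text = Path(source).read_text("utf-8")
        self.sentences = _read_conllu(text)

    def parse(self, qid: str, tokens: list[ParseToken]) -> tuple[list[DependencyTriple], list[ParseToken]]:
        sent = self.sentences.get(qid)
        if sent is None:
            raise ParseFixtureError(f"no fixture parse for qid {qid!r}")
        if len(sent.forms) != len(tokens):
            raise ParseFixtureError(
                f"{qid}: fixture has {len(sent.forms)} tokens, annotation has {len(tokens)}"
            )
        for i, (tok, form) in enumerate(zip(tokens, sent.forms)):
            if tok.form != form:
                raise ParseFixtureError(
                    f"{qid}: token {i + 1} differs: annotation {tok.form!r} vs fixture {form!r}"
                )
        tagged = [replace(tok, pos=sent.pos[i]) for i, tok in enumerate(tokens)]
        triples = [
            DependencyTriple(governor=tagged[h - 1], dependent=tagged[i], relation=rel)
            for i, (h, rel) in enumerate(zip(sent.heads, sent.deprels))
            if h != 0
        ]
        return triples, tagged


def _read_conllu(text: str) -> dict[str, _FixtureSentence]:
    """Minimal CoNLL-U reader: ID, FORM, UPOS-or-XPOS, HEAD, DEPREL."""
    sentences: dict[str, _FixtureSentence] = {}
    qid: str | None = None
    current: _FixtureSentence | None = None

    def flush() -> None:
        nonlocal qid, current
        if current is not None and current.forms:
            if qid is None:
                raise ParseFixtureError("CoNLL-U sentence without a '# qid =' comment")
            sentences[qid] = current
        qid, current = None, None

    for line in text.splitlines():
        line = line.rstrip()
        if not line:
            flush()
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if body.startswith("qid"):
                qid = body.split("=", 1)[1].strip()
            continue
        cols = line.split("\t")
        if len(cols) < 8:
            raise ParseFixtureError(f"short CoNLL-U row: {line!r}")
        tid = cols[0]
        if "-" in tid or "." in tid:  # ranges / empty nodes irrelevant here
            continue
        if current is None:
            current = _FixtureSentence([], [], [], [])
        pos = cols[3] if cols[3] != "_" else cols[4]
        current.forms.append(cols[1])
        current.pos.append("" if pos == "_" else pos)
        current.heads.append(int(cols[6]))
        current.deprels.append(cols[7])
    flush()
    return sentences


def bundled_fixture_adapter() -> ConlluFixtureAdapter:
    """Adapter over the worked-example parses shipped with the package."""
    text = resources.files("simq.data").joinpath("examples.conllu").read_text("utf-8")
    return ConlluFixtureAdapter(text=text)


def extract_semantic_relations(
    triples: list[DependencyTriple], aq: AnnotatedQuestion
) -> list[SemanticRelation]:
    """Keep triples whose two endpoints are mapped entities, as type pairs.

    Output order follows triple order; triples touching an unmapped word are
    skipped (never emitted with an empty type).
    """
    relations = []
    for t in triples:
        gov_chunk = aq.chunks[t.governor.chunk_ref]
        dep_chunk = aq.chunks[t.dependent.chunk_ref]
        if gov_chunk.semantic_type and dep_chunk.semantic_type:
            relations.append(SemanticRelation(
                dependent_type=dep_chunk.semantic_type,
                governor_type=gov_chunk.semantic_type,
                relation=t.relation,
                dependent_surface=dep_chunk.surface,
                governor_surface=gov_chunk.surface,
            ))
    return relations
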