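"""Binary feature representations of a question.

Six compositional representations are supported, each a *set* of namespaced
feature strings (binary semantics — a feature is present or absent, never
weighted):

==== =========================================================================
B    bag of words: ``word:`` + raw lowercased token
N    normalized words: ``norm:`` + stemmed token
C    concepts: ``cui:`` + concept id of every recognized entity
P    N plus joint word/POS features ``posw:form/TAG`` over parse tokens
NC   N plus C
NCT  NC plus semantic-type pairs ``typepair:GovType→DepType`` from the
     dependency-derived semantic relations (spaces rendered as ``_``)
==== =========================================================================

Namespace prefixes keep the feature spaces disjoint, so a word that happens
to look like a concept id can never collide with a ``cui:`` feature.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field

from .corpus import Question
from .dependency import (
    ParserAdapter, SemanticRelation, ParseToken,
    extract_semantic_relations, merge_entities, parse_dependencies,
)
from .errors import FeatureInputError, SimQError
from .lexicon import AnnotatedQuestion, Lexicon, annotate, normalize

logger = logging.getLogger(__name__)


class FeatureKind(str, enum.Enum):
    B = "B"
    N = "N"
    C = "C"
    P = "P"
    NC = "NC"
    NCT = "NCT"

    @classmethod
    def parse(cls, value: "FeatureKind | str") -> "FeatureKind":
        if isinstance(value, FeatureKind):
            return value
        try:
            return cls[value.upper()]
        except KeyError:
            raise SimQError(f"unknown feature kind: {value!r}") from None


@dataclass(frozen=True)
class FeatureSet:
    """The binary feature set of one question under one representation."""

    qid: str
    kind: FeatureKind
    features: frozenset[str]

    def __len__(self) -> int:
        return len(self.features)


def _type_label(semantic_type: str) -> str:
    return semantic_type.replace(" ", "_")


def build_features(
    aq: AnnotatedQuestion,
    kind: FeatureKind | str,
    relations: list[SemanticRelation] | None = None,
    parse_tokens: list[ParseToken] | None = None,
) -> FeatureSet:
    """Build one question's feature set for the requested representation.

    ``relations`` is required (may be an empty list) for NCT; ``parse_tokens``
    with POS tags is required for P.  Passing ``None`` for a required input is
    an explicit error, never a silent downgrade to a weaker representation.
    """
    kind = FeatureKind.parse(kind)
    feats: set[str] = set()

    def add_words() -> None:
        feats.update(f"word:{t.lower()}" for t in aq.tokens)

    def add_norms() -> None:
        feats.update(f"norm:{normalize(t)}" for t in aq.tokens)

    def add_cuis() -> None:
        feats.update(f"cui:{c.cui}" for c in aq.entity_chunks())

    if kind is FeatureKind.B:
        add_words()
    elif kind is FeatureKind.N:
        add_norms()
    elif kind is FeatureKind.C:
        add_cuis()
    elif kind is FeatureKind.P:
        if parse_tokens is None:
            raise FeatureInputError("kind P requires POS-tagged parse tokens")
        add_norms()
        for tok in parse_tokens:
            if not tok.pos:
                raise FeatureInputError(f"parse token {tok.form!r} lacks a POS tag")
            form = "_".join(normalize(w) for w in tok.form.split("_"))
            feats.add(f"posw:{form}/{tok.pos}")
    elif kind is FeatureKind.NC:
        add_norms()
        add_cuis()
    elif kind is FeatureKind.NCT:
        if relations is None:
            raise FeatureInputError("kind NCT requires semantic relations (may be empty)")
        add_norms()
        add_cuis()
        for rel in relations:
            feats.add(f"typepair:{_type_label(rel.governor_type)}→{_type_label(rel.dependent_type)}")
    return FeatureSet(qid=aq.qid, kind=kind, features=frozenset(feats))


@dataclass
class CorpusFeatures:
    """Per-question feature sets plus the questions that could not be built."""

    kind: FeatureKind
    by_qid: dict[str, FeatureSet] = field(default_factory=dict)
    skipped: list[tuple[str, str]] = field(default_factory=list)  # (qid, reason)


def build_corpus_features(
    questions: list[Question],
    lexicon: Lexicon,
    kind: FeatureKind | str,
    adapter: ParserAdapter | None = None,
    strict: bool = False,
) -> CorpusFeatures:
    """Annotate and featurize a whole corpus.

    The parser adapter is consulted only for kinds that need it (P, NCT).
    Questions that fail to annotate or parse are reported and skipped; with
    ``strict`` any failure raises instead.
    """
    kind = FeatureKind.parse(kind)
    needs_parse = kind in (FeatureKind.P, FeatureKind.NCT)
    if needs_parse and adapter is None:
        raise FeatureInputError(f"kind {kind.value} requires a parser adapter")
    out = CorpusFeatures(kind=kind)
    for q in questions:
        try:
            aq = annotate(q.text, lexicon, qid=q.qid, category=q.category)
            relations: list[SemanticRelation] | None = None
            tagged: list[ParseToken] | None = None
            if needs_parse:
                tokens = merge_entities(aq)
                triples, tagged = parse_dependencies(tokens, adapter, qid=q.qid)
                relations = extract_semantic_relations(triples, aq)
            out.by_qid[q.qid] = build_features(aq, kind, relations=relations, parse_tokens=tagged)
        except SimQError as exc:
            if strict:
                raise
            logger.warning("skipping %s: %s", q.qid, exc)
            out.skipped.append((q.qid, str(exc)))
    return out
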