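"""Concept lexicon, tokenization, normalization and dictionary annotation.

A question is annotated against a term lexicon that maps surface strings to
concept identifiers (CUI, pattern ``C`` + digits) and coarse semantic types
(e.g. "Pharmacologic Substance").  The annotator chunks the question into
non-overlapping segments: each chunk is either one recognized medical entity
(possibly multi-word) or one unmapped word.  Unmapped words are kept so the
sentence's syntactic structure survives chunking.

Matching is greedy leftmost-longest over *normalized* tokens, so surface
variants like "glands" hit a lexicon term "gland".  Normalization lowercases
and applies a small rule-based stemmer for plurals and past tenses, with a
bundled exception table for irregular and non-plural forms.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

from .errors import EmptyQuestionError, LexiconError

logger = logging.getLogger(__name__)

_CUI_RE = re.compile(r"^C[0-9]+$")
_EDGE_PUNCT = "?.!,;:\"'()"

#: minimum stem length left behind by any suffix rule
_MIN_STEM = 3


def _load_exceptions() -> dict[str, str]:
    text = resources.files("simq.data").joinpath("norm_exceptions.tsv").read_text("utf-8")
    table = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        token, normal = line.split("\t")[:2]
        table[token] = normal
    return table


_EXCEPTIONS: dict[str, str] | None = None


def _exceptions() -> dict[str, str]:
    global _EXCEPTIONS
    if _EXCEPTIONS is None:
        _EXCEPTIONS = _load_exceptions()
    return _EXCEPTIONS


def tokenize(text: str) -> list[str]:
    """Whitespace tokenization with edge punctuation stripped from each token.

    Internal punctuation is preserved ("a,b" stays one token); tokens that are
    punctuation-only disappear.  Raises :class:`EmptyQuestionError` if nothing
    survives.
    """
    tokens = []
    for raw in text.split():
        tok = raw.strip(_EDGE_PUNCT)
        if tok:
            tokens.append(tok)
    if not tokens:
        raise EmptyQuestionError("empty question")
    return tokens


def normalize(token: str) -> str:
    """Normalize one token: lowercase plus plural/past-tense suffix stripping.

    The exception table wins over the rules (irregular plurals, non-plural
    ``-s`` words such as "arthritis", and ``-e``-stem verbs such as "caused").
    Rules are applied to a fixed point so the function is idempotent.
    """
    tok = token.lower()
    exc = _exceptions()
    if tok in exc:
        return exc[tok]
    while True:
        nxt = _strip_suffix(tok)
        if nxt == tok:
            return tok
        tok = nxt
        if tok in exc:
            return exc[tok]


def _strip_suffix(tok: str) -> str:
    if tok.endswith("ies") and len(tok) > 4:
        return tok[:-3] + "y"
    if tok.endswith("ied") and len(tok) > 4:
        return tok[:-3] + "y"
    if tok.endswith("es") and len(tok) - 2 >= _MIN_STEM:
        base = tok[:-2]
        if base.endswith(("s", "x", "z", "ch", "sh")):
            return base
    if tok.endswith("ed") and len(tok) - 2 >= _MIN_STEM:
        return tok[:-2]
    if tok.endswith("s") and not tok.endswith("ss") and len(tok) - 1 >= _MIN_STEM:
        return tok[:-1]
    return tok


def normalize_term(term: str) -> str:
    """Normalize a (possibly multi-word) lexicon term, one token at a time."""
    return " ".join(normalize(t) for t in term.split())


@dataclass(frozen=True)
class LexiconEntry:
    """One surface term mapped to a concept identifier and a semantic type."""

    term: str
    cui: str
    semantic_type: str

    def __post_init__(self) -> None:
        if not self.term or self.term != " ".join(self.term.split()):
            raise ValueError(f"term not whitespace-normalized: {self.term!r}")
        if not _CUI_RE.match(self.cui):
            raise ValueError(f"malformed cui: {self.cui!r}")
        if not self.semantic_type:
            raise ValueError("empty semantic type")


@dataclass
class Lexicon:
    """Term → entries mapping with case-insensitive, normalized lookup.

    A term may carry several entries (concept ambiguity); file order is
    preserved and the first entry wins downstream.
    """

    entries: dict[str, list[LexiconEntry]] = field(default_factory=dict)
    skipped_lines: list[int] = field(default_factory=list)

    @property
    def max_term_tokens(self) -> int:
        return max((len(t.split()) for t in self.entries), default=0)

    def add(self, entry: LexiconEntry) -> None:
        key = normalize_term(entry.term.lower())
        bucket = self.entries.setdefault(key, [])
        if not any(e.cui == entry.cui for e in bucket):
            bucket.append(entry)

    def lookup(self, normalized_term: str) -> list[LexiconEntry]:
        return self.entries.get(normalized_term, [])

    def __len__(self) -> int:
        return sum(len(v) for v in self.entries.values())


def load_lexicon(path: str | Path) -> Lexicon:
    """Load a TSV lexicon (columns term, cui, semantic_type).

    ``#`` lines are comments; a header row is auto-detected by its second
    column not looking like a CUI.  Rows with a malformed CUI are skipped and
    reported by line number.  A lexicon with zero valid rows is an error.
    """
    path = Path(path)
    if not path.exists():
        raise LexiconError(f"lexicon file not found: {path}")
    return parse_lexicon(path.read_text("utf-8").splitlines(), source=str(path))


def parse_lexicon(lines: Iterable[str], source: str = "<memory>") -> Lexicon:
    lex = Lexicon()
    first_data_row = True
    for lineno, line in enumerate(lines, start=1):
        line = line.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) < 3:
            lex.skipped_lines.append(lineno)
            continue
        term, cui, stype = (c.strip() for c in cols[:3])
        if first_data_row and not _CUI_RE.match(cui):
            first_data_row = False  # header row
            continue
        first_data_row = False
        if not term or not _CUI_RE.match(cui) or not stype:
            lex.skipped_lines.append(lineno)
            continue
        lex.add(LexiconEntry(term=" ".join(term.lower().split()), cui=cui, semantic_type=stype))
    if lex.skipped_lines:
        logger.warning(
            "%s: skipped %d malformed lexicon row(s) at line(s) %s",
            source, len(lex.skipped_lines), lex.skipped_lines,
        )
    if len(lex) == 0:
        raise LexiconError(f"{source}: zero valid rows in lexicon")
    return lex


def bundled_lexicon() -> Lexicon:
    """The small lexicon shipped with the package (covers all worked examples)."""
    text = resources.files("simq.data").joinpath("lexicon.tsv").read_text("utf-8")
    return parse_lexicon(text.splitlines(), source="simq.data/lexicon.tsv")


@dataclass(frozen=True)
class Chunk:
    """One annotated segment: an entity (cui + type) or a single unmapped word.

    ``start_token``/``end_token`` are 0-based half-open indices into the
    question's token sequence.
    """

    surface: str
    normalized: str
    cui: str
    semantic_type: str
    start_token: int
    end_token: int

    def __post_init__(self) -> None:
        if (self.cui == "") != (self.semantic_type == ""):
            raise ValueError("cui and semantic_type must be both empty or both set")
        if not self.start_token < self.end_token:
            raise ValueError("empty chunk span")

    @property
    def is_entity(self) -> bool:
        return self.cui != ""


@dataclass
class AnnotatedQuestion:
    qid: str
    text: str
    tokens: list[str]
    chunks: list[Chunk]
    category: str | None = None

    def entity_chunks(self) -> list[Chunk]:
        return [c for c in self.chunks if c.is_entity]


def annotate(text: str, lexicon: Lexicon, qid: str = "", category: str | None = None) -> AnnotatedQuestion:
    """Chunk a question by greedy leftmost-longest dictionary matching.

    At each token position, window sizes from ``max_term_tokens`` down to 1
    are tried against the lexicon over normalized tokens; a hit emits an
    entity chunk carrying the term's first lexicon entry, otherwise the token
    becomes a plain chunk.  Chunks partition the token sequence.
    """
    tokens = tokenize(text)
    norm = [normalize(t) for t in tokens]
    chunks: list[Chunk] = []
    pos = 0
    n = len(tokens)
    max_w = max(lexicon.max_term_tokens, 1)
    while pos < n:
        matched = False
        for w in range(min(max_w, n - pos), 0, -1):
            key = " ".join(norm[pos:pos + w])
            entries = lexicon.lookup(key)
            if entries:
                entry = entries[0]  # first entry wins on ambiguity
                chunks.append(Chunk(
                    surface=" ".join(tokens[pos:pos + w]),
                    normalized=key,
                    cui=entry.cui,
                    semantic_type=entry.semantic_type,
                    start_token=pos,
                    end_token=pos + w,
                ))
                pos += w
                matched = True
                break
        if not matched:
            chunks.append(Chunk(
                surface=tokens[pos],
                normalized=norm[pos],
                cui="",
                semantic_type="",
                start_token=pos,
                end_token=pos + 1,
            ))
            pos += 1
    return AnnotatedQuestion(qid=qid, text=text, tokens=tokens, chunks=chunks, category=category)


def render_chunks(aq: AnnotatedQuestion) -> str:
    """Render chunks as ``surface/cui/type`` joined by `` | `` (surfaces lowercased)."""
    return " | ".join(f"{c.surface.lower()}/{c.cui}/{c.semantic_type}" for c in aq.chunks)


def parse_chunk_string(rendered: str) -> list[tuple[str, str, str]]:
    """Inverse of :func:`render_chunks`: (surface, cui, type) triples."""
    out = []
    for part in rendered.split(" | "):
        surface, cui, stype = part.rsplit("/", 2)
        out.append((surface, cui, stype))
    return out
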