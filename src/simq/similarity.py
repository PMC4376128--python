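"""Dice and cosine similarity over binary feature sets, and ranked retrieval.

Both scores live in [0, 1]: 0 means the questions share no features, 1 means
identical feature sets.  For binary (set) representations they reduce to set
arithmetic:

    dice(A, B)   = 2|A ∩ B| / (|A| + |B|)
    cosine(A, B) = |A ∩ B| / sqrt(|A| |B|)

Retrieval scores a query against every archived question exhaustively and
returns the top-k; no indexing shortcuts are taken at this scale.
"""

from __future__ import annotations

import json
import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

from .errors import KindMismatchError, SimQError
from .features import FeatureKind, FeatureSet

logger = logging.getLogger(__name__)

Scorer = Callable[[FeatureSet, FeatureSet], float]


def _check_kinds(q1: FeatureSet, q2: FeatureSet) -> None:
    if q1.kind is not q2.kind:
        raise KindMismatchError(f"cannot compare kinds {q1.kind.value} and {q2.kind.value}")


def dice(q1: FeatureSet, q2: FeatureSet) -> float:
    """Dice coefficient; 0 by convention when both sets are empty."""
    _check_kinds(q1, q2)
    total = len(q1) + len(q2)
    if total == 0:
        logger.debug("dice of two empty feature sets (%s, %s) -> 0", q1.qid, q2.qid)
        return 0.0
    return 2.0 * len(q1.features & q2.features) / total


def cosine(q1: FeatureSet, q2: FeatureSet) -> float:
    """Binary-vector cosine; 0 by convention when either set is empty."""
    _check_kinds(q1, q2)
    if not q1.features or not q2.features:
        return 0.0
    return len(q1.features & q2.features) / math.sqrt(len(q1) * len(q2))


SCORERS: dict[str, Scorer] = {"dice": dice, "cosine": cosine}


def get_scorer(algorithm: str | Scorer) -> Scorer:
    if callable(algorithm):
        return algorithm
    try:
        return SCORERS[algorithm]
    except KeyError:
        raise SimQError(f"unknown similarity algorithm: {algorithm!r}") from None


@dataclass
class QuestionIndex:
    """The archive a new question is scored against."""

    kind: FeatureKind
    entries: dict[str, FeatureSet] = field(default_factory=dict)
    categories: dict[str, str] = field(default_factory=dict)

    def add(self, fs: FeatureSet, category: str | None = None) -> None:
        if fs.kind is not self.kind:
            raise KindMismatchError(
                f"index kind {self.kind.value} cannot hold a {fs.kind.value} feature set"
            )
        self.entries[fs.qid] = fs
        if category is not None:
            self.categories[fs.qid] = category

    def __len__(self) -> int:
        return len(self.entries)

    def save(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(json.dumps({"kind": self.kind.value, "n": len(self)}) + "\n")
            for qid in sorted(self.entries):
                rec = {"qid": qid, "features": sorted(self.entries[qid].features)}
                if qid in self.categories:
                    rec["category"] = self.categories[qid]
                fh.write(json.dumps(rec, ensure_ascii=False) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "QuestionIndex":
        lines = Path(path).read_text("utf-8").splitlines()
        if not lines:
            raise SimQError(f"empty index file: {path}")
        header = json.loads(lines[0])
        index = cls(kind=FeatureKind.parse(header["kind"]))
        for line in lines[1:]:
            if not line.strip():
                continue
            rec = json.loads(line)
            fs = FeatureSet(qid=rec["qid"], kind=index.kind, features=frozenset(rec["features"]))
            index.add(fs, category=rec.get("category"))
        return index


@dataclass(frozen=True)
class RetrievalResult:
    qid: str
    score: float
    rank: int

    @property
    def score_4dp(self) -> float:
        return round(self.score, 4)


def rank_similar(
    query: FeatureSet,
    index: QuestionIndex,
    k: int,
    algorithm: str | Scorer = "dice",
    exclude_self: bool = False,
) -> list[RetrievalResult]:
    """Score the whole archive, return the top-k (ties broken by qid).

    Ranking uses full-precision scores; callers render them to 4 decimals.
    A query whose qid is present in the index is kept unless ``exclude_self``.
    """
    if k < 1:
        raise SimQError(f"k must be >= 1, got {k}")
    if not index.entries:
        raise SimQError("cannot rank against an empty index")
    if query.kind is not index.kind:
        raise KindMismatchError(
            f"query kind {query.kind.value} does not match index kind {index.kind.value}"
        )
    scorer = get_scorer(algorithm)
    scored = [
        (scorer(query, fs), qid)
        for qid, fs in index.entries.items()
        if not (exclude_self and qid == query.qid)
    ]
    scored.sort(key=lambda pair: (-pair[0], pair[1]))
    return [
        RetrievalResult(qid=qid, score=score, rank=i + 1)
        for i, (score, qid) in enumerate(scored[:k])
    ]


def recommend_categories(
    results: list[RetrievalResult], index: QuestionIndex, m: int
) -> list[str]:
    """Most frequent topic categories among the retrieved questions.

    Count ties break alphabetically; results without a category are ignored.
    """
    if m < 1:
        raise SimQError(f"m must be >= 1, got {m}")
    counts = Counter(
        index.categories[r.qid] for r in results if r.qid in index.categories
    )
    ordered = sorted(counts.items(), key=lambda item: (-item[1], item[0]))
    return [category for category, _ in ordered[:m]]
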