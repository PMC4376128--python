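"""Question corpus I/O: JSONL (qid/text/category) or TSV with the same columns."""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

from .errors import SimQError


@dataclass(frozen=True)
class Question:
    qid: str
    text: str
    category: str | None = None


def load_corpus(path: str | Path) -> list[Question]:
    """Load a corpus file; format chosen by extension (.jsonl/.json vs TSV)."""
    path = Path(path)
    if not path.exists():
        raise SimQError(f"corpus file not found: {path}")
    if path.suffix in {".jsonl", ".json"}:
        questions = list(_iter_jsonl(path))
    else:
        questions = list(_iter_tsv(path))
    seen: set[str] = set()
    for q in questions:
        if q.qid in seen:
            raise SimQError(f"duplicate qid in corpus: {q.qid}")
        seen.add(q.qid)
    return questions


def _iter_jsonl(path: Path) -> Iterator[Question]:
    for lineno, line in enumerate(path.read_text("utf-8").splitlines(), 1):
        if not line.strip():
            continue
        try:
            rec = json.loads(line)
        except json.JSONDecodeError as exc:
            raise SimQError(f"{path}:{lineno}: invalid JSON ({exc})") from exc
        yield Question(qid=str(rec["qid"]), text=str(rec["text"]), category=rec.get("category"))


def _iter_tsv(path: Path) -> Iterator[Question]:
    lines = path.read_text("utf-8").splitlines()
    start = 0
    if lines and lines[0].split("\t")[0].strip().lower() == "qid":
        start = 1
    for line in lines[start:]:
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) < 2:
            raise SimQError(f"{path}: corpus row needs qid and text: {line!r}")
        category = cols[2].strip() if len(cols) > 2 and cols[2].strip() else None
        yield Question(qid=cols[0].strip(), text=cols[1].strip(), category=category)


def save_corpus(questions: list[Question], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for q in questions:
            rec: dict = {"qid": q.qid, "text": q.text}
            if q.category is not None:
                rec["category"] = q.category
            fh.write(json.dumps(rec) + "\n")
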