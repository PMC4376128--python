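"""Retrieval evaluation: per-seed confusion counts and macro-averaged P/R/F.

A seed question is scored against a fixed candidate pool; candidates at or
above a score threshold count as retrieved positives.  Against a human gold
standard this yields per-seed TP/FP/TN/FN (summing to the pool size),
precision, recall and F-score, which are then macro-averaged over seeds —
fractional mean counts are expected and reported as such.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import TextIO

from .errors import EvaluationError
from .features import FeatureSet
from .similarity import QuestionIndex, Scorer, get_scorer

__all__ = [
    "GoldStandard", "SeedEval", "EvalResult",
    "load_gold", "retrieve_positives", "confusion", "precision_recall_f",
    "evaluate_run", "write_report",
]


@dataclass
class GoldStandard:
    """Seed → relevant-candidate mapping over a fixed candidate pool."""

    relevant: dict[str, set[str]]
    pool: set[str]

    def __post_init__(self) -> None:
        for seed, rel in self.relevant.items():
            if seed in self.pool:
                raise EvaluationError(f"seed {seed!r} must not be in the candidate pool")
            missing = rel - self.pool
            if missing:
                raise EvaluationError(
                    f"gold candidates for seed {seed!r} not in pool: {sorted(missing)}"
                )


def load_gold(path: str | Path, pool: set[str]) -> GoldStandard:
    """Read a TSV of ``seed_qid<TAB>relevant_qid`` pairs."""
    relevant: dict[str, set[str]] = {}
    for line in Path(path).read_text("utf-8").splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        seed, rel = line.split("\t")[:2]
        relevant.setdefault(seed.strip(), set()).add(rel.strip())
    if not relevant:
        raise EvaluationError(f"no gold pairs in {path}")
    return GoldStandard(relevant=relevant, pool=pool)


def retrieve_positives(
    seed: FeatureSet,
    index: QuestionIndex,
    algorithm: str | Scorer,
    threshold: float,
) -> set[str]:
    """All candidate qids scoring at or above the threshold."""
    if not 0.0 <= threshold <= 1.0:
        raise EvaluationError(f"threshold must be in [0, 1], got {threshold}")
    scorer = get_scorer(algorithm)
    return {qid for qid, fs in index.entries.items() if scorer(seed, fs) >= threshold}


def confusion(
    retrieved: set[str], relevant: set[str], pool: set[str]
) -> tuple[int, int, int, int]:
    """(TP, FP, TN, FN) over the pool."""
    if not retrieved <= pool:
        raise EvaluationError(f"retrieved qids outside pool: {sorted(retrieved - pool)}")
    if not relevant <= pool:
        raise EvaluationError(f"relevant qids outside pool: {sorted(relevant - pool)}")
    tp = len(retrieved & relevant)
    fp = len(retrieved - relevant)
    fn = len(relevant - retrieved)
    tn = len(pool) - tp - fp - fn
    return tp, fp, tn, fn


def precision_recall_f(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    """P, R, F1 with the zero-denominator convention (metric = 0)."""
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return precision, recall, f


@dataclass(frozen=True)
class SeedEval:
    seed: str
    tp: int
    fp: int
    tn: int
    fn: int
    precision: float
    recall: float
    f_score: float


@dataclass
class EvalResult:
    """Per-seed rows plus macro-averages (arithmetic means over seeds)."""

    per_seed: list[SeedEval] = field(default_factory=list)
    algorithm: str = ""
    kind: str = ""
    threshold: float = 0.0

    def _mean(self, attr: str) -> float:
        return sum(getattr(s, attr) for s in self.per_seed) / len(self.per_seed)

    @property
    def mean_tp(self) -> float: return self._mean("tp")

    @property
    def mean_fp(self) -> float: return self._mean("fp")

    @property
    def mean_tn(self) -> float: return self._mean("tn")

    @property
    def mean_fn(self) -> float: return self._mean("fn")

    @property
    def mean_precision(self) -> float: return self._mean("precision")

    @property
    def mean_recall(self) -> float: return self._mean("recall")

    @property
    def mean_f(self) -> float: return self._mean("f_score")


def evaluate_run(
    seeds: dict[str, FeatureSet],
    gold: GoldStandard,
    index: QuestionIndex,
    algorithm: str | Scorer = "dice",
    threshold: float = 0.5,
) -> EvalResult:
    """Evaluate every seed against the pool and macro-average the metrics.

    The index must hold exactly the candidate pool.  Every seed needs a gold
    entry; missing seeds are an error, never silently scored against nothing.
    """
    missing = [qid for qid in seeds if qid not in gold.relevant]
    if missing:
        raise EvaluationError(f"seeds missing from gold standard: {sorted(missing)}")
    if set(index.entries) != gold.pool:
        raise EvaluationError("index does not match the gold candidate pool")
    algo_name = algorithm if isinstance(algorithm, str) else getattr(algorithm, "__name__", "custom")
    result = EvalResult(
        algorithm=algo_name,
        kind=next(iter(seeds.values())).kind.value if seeds else "",
        threshold=threshold,
    )
    for qid in sorted(seeds):
        retrieved = retrieve_positives(seeds[qid], index, algorithm, threshold)
        tp, fp, tn, fn = confusion(retrieved, gold.relevant[qid], gold.pool)
        p, r, f = precision_recall_f(tp, fp, fn)
        result.per_seed.append(SeedEval(qid, tp, fp, tn, fn, p, r, f))
    return result


_REPORT_COLUMNS = [
    "algorithm", "kind", "threshold",
    "mean_tp", "mean_fp", "mean_tn", "mean_fn",
    "precision_pct", "recall_pct", "f_score_pct",
]


def write_report(results: list[EvalResult], out: TextIO) -> None:
    """TSV report, one row per (algorithm, kind); percentages to 1 decimal.

    The threshold is always echoed so reported counts are interpretable.
    """
    writer = csv.writer(out, delimiter="\t", lineterminator="\n")
    writer.writerow(_REPORT_COLUMNS)
    for res in results:
        writer.writerow([
            res.algorithm, res.kind, f"{res.threshold:g}",
            f"{res.mean_tp:.2f}", f"{res.mean_fp:.2f}",
            f"{res.mean_tn:.2f}", f"{res.mean_fn:.2f}",
            f"{100 * res.mean_precision:.1f}",
            f"{100 * res.mean_recall:.1f}",
            f"{100 * res.mean_f:.1f}",
        ])
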