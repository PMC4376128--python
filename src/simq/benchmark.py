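"""End-to-end benchmark wiring: synthetic dataset → features → evaluation.

Convenience layer used by the CLI, the test suite and the reproduction
script: it builds the candidate-pool index and the per-seed feature sets for
a feature kind, then runs the macro-averaged retrieval evaluation for each
requested representation.
"""

from __future__ import annotations

from .errors import SimQError
from .evaluation import EvalResult, GoldStandard, evaluate_run
from .features import FeatureKind, FeatureSet, build_corpus_features
from .similarity import QuestionIndex
from .synthetic import SynthConfig, SynthDataset, generate_dataset

ALL_KINDS = [FeatureKind.B, FeatureKind.N, FeatureKind.C,
             FeatureKind.P, FeatureKind.NC, FeatureKind.NCT]


def dataset_features(
    ds: SynthDataset, kind: FeatureKind | str
) -> tuple[dict[str, FeatureSet], QuestionIndex, GoldStandard]:
    """(seed feature sets, candidate-pool index, gold standard) for one kind."""
    kind = FeatureKind.parse(kind)
    built = build_corpus_features(
        ds.questions, ds.lexicon(), kind, adapter=ds.adapter(), strict=True
    )
    seed_set = set(ds.seed_qids)
    index = QuestionIndex(kind=kind)
    seeds: dict[str, FeatureSet] = {}
    categories = {q.qid: q.category for q in ds.questions if q.category}
    for qid, fs in built.by_qid.items():
        if qid in seed_set:
            seeds[qid] = fs
        else:
            index.add(fs, category=categories.get(qid))
    relevant: dict[str, set[str]] = {qid: set() for qid in ds.seed_qids}
    for seed, rel in ds.gold_pairs:
        relevant[seed].add(rel)
    gold = GoldStandard(relevant=relevant, pool=set(index.entries))
    return seeds, index, gold


def run_benchmark(
    config: SynthConfig = SynthConfig(),
    kinds: list[FeatureKind] | None = None,
    algorithm: str = "dice",
    threshold: float = 0.5,
) -> dict[FeatureKind, EvalResult]:
    """Evaluate each feature kind on the synthetic benchmark."""
    if config.n_clusters == 0:
        raise SimQError("benchmark needs at least one paraphrase cluster")
    ds = generate_dataset(config)
    results: dict[FeatureKind, EvalResult] = {}
    for kind in kinds or ALL_KINDS:
        seeds, index, gold = dataset_features(ds, kind)
        results[kind] = evaluate_run(seeds, gold, index, algorithm=algorithm, threshold=threshold)
    return results
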