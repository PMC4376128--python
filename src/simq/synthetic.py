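"""Deterministic synthetic fixtures: lexicon, corpus, gold standard, parses.

The generator emulates the structure that concept-level features are meant to
exploit: *paraphrase clusters* whose members describe the same complaint with
different surface wording (they share concept ids and semantic-type patterns,
not words), and *distractors* that overlap a cluster lexically (shared filler
words plus the first word of its entity terms) while sharing zero concept
ids.  Bag-of-words similarity is therefore pulled toward distractors and away
from true paraphrases, while concept features collapse each synonym group.

Questions are built from a fixed subject-verb-object template with six slots
(auxiliary, possessive, subject entity, verb entity, object entity, adverb),
each slot a synonym group.  The cluster seed always uses a group's canonical
form; other members switch to an alternate form per slot with probability
``synonym_rate``.  Every question's dependency parse follows directly from
the template, so CoNLL-U fixtures cover the full corpus by construction.
All output is a pure function of the configuration: same config, same bytes.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .corpus import Question, save_corpus
from .dependency import ConlluFixtureAdapter
from .errors import SimQError
from .lexicon import Lexicon, parse_lexicon

#: fixed semantic-type inventory used by generated concepts
TYPE_INVENTORY = [
    "Food",
    "Disease or Syndrome",
    "Sign or Symptom",
    "Functional Concept",
    "Spatial Concept",
    "Body Location or Region",
    "Pharmacologic Substance",
    "Finding",
    "Qualitative Concept",
    "Temporal Concept",
]

_SUBJ_TYPES = ["Disease or Syndrome", "Sign or Symptom", "Finding", "Food", "Pharmacologic Substance"]
_OBJ_TYPES = ["Body Location or Region", "Qualitative Concept", "Temporal Concept", "Spatial Concept", "Finding"]
_CATEGORIES = [
    "Diet and Nutrition", "Diseases and Conditions", "Womens Health",
    "Mental Health", "Medication",
]

# unmapped filler groups, shared by every question; first form is canonical
_AUX = ["could", "can", "would", "will", "might"]
_POSS = ["my", "our", "her", "his", "their"]
_TAIL = ["today", "often", "lately", "daily", "weekly"]

_SUBJ_STEMS = [("malady", "flare"), ("ailment", "bout"), ("disorder", "spell")]
_VERB_STEMS = ["trigger", "provoke", "worsen"]
_OBJ_STEMS = [("tender", "spot"), ("sore", "patch"), ("achy", "zone")]


@dataclass(frozen=True)
class SynthConfig:
    n_clusters: int = 10
    cluster_size: int = 3
    n_distractors: int = 20
    synonym_rate: float = 0.8
    rng_seed: int = 42

    def __post_init__(self) -> None:
        if min(self.n_clusters, self.cluster_size, self.n_distractors) < 0:
            raise SimQError("counts must be non-negative")
        if not 0.0 <= self.synonym_rate <= 1.0:
            raise SimQError("synonym_rate must be in [0, 1]")
        if self.n_clusters > 0 and self.cluster_size < 2:
            raise SimQError("cluster_size must be >= 2 so gold pairs exist")


@dataclass(frozen=True)
class _Concept:
    cui: str
    semantic_type: str
    forms: tuple[str, ...]  # forms[0] is canonical


@dataclass
class SynthDataset:
    config: SynthConfig
    lexicon_text: str
    questions: list[Question] = field(default_factory=list)
    gold_pairs: list[tuple[str, str]] = field(default_factory=list)
    conllu_text: str = ""
    seed_qids: list[str] = field(default_factory=list)

    def lexicon(self) -> Lexicon:
        return parse_lexicon(self.lexicon_text.splitlines(), source="<synthetic>")

    def adapter(self) -> ConlluFixtureAdapter:
        return ConlluFixtureAdapter(text=self.conllu_text)

    def pool_qids(self) -> set[str]:
        return {q.qid for q in self.questions} - set(self.seed_qids)


def _cluster_concepts(i: int) -> tuple[_Concept, _Concept, _Concept]:
    subj = _Concept(
        cui=f"C10{i:04d}",
        semantic_type=_SUBJ_TYPES[i % len(_SUBJ_TYPES)],
        forms=tuple(f"{a}{i} {b}{i}" for a, b in _SUBJ_STEMS),
    )
    verb = _Concept(
        cui=f"C30{i:04d}",
        semantic_type="Functional Concept",
        forms=tuple(f"{s}{i}" for s in _VERB_STEMS),
    )
    obj = _Concept(
        cui=f"C20{i:04d}",
        semantic_type=_OBJ_TYPES[i % len(_OBJ_TYPES)],
        forms=tuple(f"{a}{i} {b}{i}" for a, b in _OBJ_STEMS),
    )
    return subj, verb, obj


def _distractor_concepts(d: int, target: int) -> tuple[_Concept, _Concept]:
    """Decoy entities sharing one surface word with the target cluster."""
    subj_word = f"{_SUBJ_STEMS[0][0]}{target}"
    obj_word = f"{_OBJ_STEMS[0][0]}{target}"
    decoy_subj = _Concept(
        cui=f"C80{d:04d}",
        semantic_type=TYPE_INVENTORY[(d + 4) % len(TYPE_INVENTORY)],
        forms=(f"{subj_word} lump{d}", f"knot{d} gristle{d}"),
    )
    decoy_obj = _Concept(
        cui=f"C90{d:04d}",
        semantic_type=TYPE_INVENTORY[(d + 7) % len(TYPE_INVENTORY)],
        forms=(f"{obj_word} bump{d}", f"crease{d} fold{d}"),
    )
    return decoy_subj, decoy_obj


def _pick(rng: random.Random, forms: tuple[str, ...] | list[str], rate: float) -> str:
    """Canonical form, or an alternate with probability ``rate``."""
    if len(forms) > 1 and rng.random() < rate:
        return rng.choice(forms[1:])
    return forms[0]


def _conllu_block(qid: str, slots: list[str]) -> str:
    forms = ["_".join(s.split()) for s in slots]
    pos = ["MD", "PRP$", "NN", "VB", "NN", "RB"]
    heads = [4, 3, 4, 0, 4, 4]
    rels = ["aux", "nmod:poss", "nsubj", "root", "dobj", "advmod"]
    lines = [f"# qid = {qid}"]
    for i in range(6):
        lines.append(
            f"{i + 1}\t{forms[i]}\t_\t{pos[i]}\t_\t_\t{heads[i]}\t{rels[i]}\t_\t_"
        )
    return "\n".join(lines) + "\n"


def generate_dataset(config: SynthConfig = SynthConfig()) -> SynthDataset:
    """Generate the full fixture set deterministically from the config."""
    rng = random.Random(config.rng_seed)
    lex_rows: list[str] = []
    questions: list[Question] = []
    gold_pairs: list[tuple[str, str]] = []
    conllu_blocks: list[str] = []
    seed_qids: list[str] = []

    def add_concept(c: _Concept) -> None:
        for form in c.forms:
            lex_rows.append(f"{form}\t{c.cui}\t{c.semantic_type}")

    for i in range(config.n_clusters):
        subj, verb, obj = _cluster_concepts(i)
        for c in (subj, verb, obj):
            add_concept(c)
        category = _CATEGORIES[i % len(_CATEGORIES)]
        for m in range(config.cluster_size):
            qid = f"q{i:03d}-{m}"
            if m == 0:
                slots = [_AUX[0], _POSS[0], subj.forms[0], verb.forms[0], obj.forms[0], _TAIL[0]]
                seed_qids.append(qid)
            else:
                rate = config.synonym_rate
                slots = [
                    _pick(rng, _AUX, rate),
                    _pick(rng, _POSS, rate),
                    _pick(rng, subj.forms, rate),
                    _pick(rng, verb.forms, rate),
                    _pick(rng, obj.forms, rate),
                    _pick(rng, _TAIL, rate),
                ]
                gold_pairs.append((f"q{i:03d}-0", qid))
            questions.append(Question(qid=qid, text=" ".join(slots) + "?", category=category))
            conllu_blocks.append(_conllu_block(qid, slots))

    for d in range(config.n_distractors):
        target = d % config.n_clusters if config.n_clusters else 0
        decoy_subj, decoy_obj = _distractor_concepts(d, target)
        add_concept(decoy_subj)
        add_concept(decoy_obj)
        qid = f"d{d:03d}"
        slots = [_AUX[0], _POSS[0], decoy_subj.forms[0], f"buzz{d}", decoy_obj.forms[0], _TAIL[0]]
        questions.append(Question(
            qid=qid, text=" ".join(slots) + "?",
            category=_CATEGORIES[d % len(_CATEGORIES)],
        ))
        conllu_blocks.append(_conllu_block(qid, slots))

    bundled = resources.files("simq.data").joinpath("lexicon.tsv").read_text("utf-8")
    lexicon_text = bundled.rstrip("\n") + "\n" + "\n".join(lex_rows) + ("\n" if lex_rows else "")
    return SynthDataset(
        config=config,
        lexicon_text=lexicon_text,
        questions=questions,
        gold_pairs=gold_pairs,
        conllu_text="\n".join(conllu_blocks),
        seed_qids=seed_qids,
    )


def write_dataset(ds: SynthDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write lexicon.tsv, corpus.jsonl, gold.tsv and parses.conllu."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "lexicon": out_dir / "lexicon.tsv",
        "corpus": out_dir / "corpus.jsonl",
        "gold": out_dir / "gold.tsv",
        "conllu": out_dir / "parses.conllu",
    }
    paths["lexicon"].write_text(ds.lexicon_text, encoding="utf-8")
    save_corpus(ds.questions, paths["corpus"])
    paths["gold"].write_text(
        "".join(f"{s}\t{r}\n" for s, r in ds.gold_pairs), encoding="utf-8"
    )
    paths["conllu"].write_text(ds.conllu_text, encoding="utf-8")
    return paths
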