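"""Synthetic annotated-corpus generator.

Emits corpora in the same unified XML dialect as the real DDI data so the
whole pipeline (parsing, blinding, training, scoring) is exercisable with no
external download.  Each sentence is built around one focal drug pair whose
class is signalled by a multi-token trigger phrase placed between the
entities when the sampled inter-entity distance allows it (after them
otherwise); filler tokens come from a closed lexicon so the vocabulary stays
desk-scale.  Knobs: class proportions (defaulting to the published imbalance
of the DDI corpus), the inter-entity token-distance distribution (modes at
2, 4 and 6 like the real corpus), bystander-mention rate (the drug0 path),
trigger-swap noise, provenance mix, and a discontinuous-mention rate to
exercise the preprocessing drop filter.

:func:`generate_position_task` builds a corpus where the label depends only
on the inter-entity distance band and no lexical feature is informative —
the cleanest possible probe of the position embeddings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .corpus import CandidatePair, ClassLabel, Document, EntityMention, Sentence

#: Per-class trigger phrases.  Each phrase contains at least one content word
#: unique to its class, so the class of a focal pair is decidable from the
#: sentence's trigger alone (when noise is off).
TRIGGERS: dict[str, tuple[tuple[str, ...], ...]] = {
    "advice": (
        ("should", "not", "be", "used", "in", "combination", "with"),
        ("caution", "is", "advised", "when", "combining"),
    ),
    "effect": (
        ("may", "enhance", "the", "hypotensive", "properties", "of"),
        ("potentiates", "the", "sedative", "action", "of"),
    ),
    "int": (
        ("interacts", "with",),
        ("shows", "an", "interaction", "with"),
    ),
    "mechanism": (
        ("increases", "the", "serum", "concentration", "of"),
        ("inhibits", "the", "hepatic", "metabolism", "of"),
    ),
    "other": (
        ("was", "evaluated", "separately", "from"),
        ("has", "no", "documented", "relationship", "to"),
    ),
}

#: Closed filler lexicon; disjoint from every trigger's identifying words.
FILLERS = (
    "the", "of", "in", "patients", "receiving", "during", "therapy",
    "treatment", "daily", "oral", "single", "dose", "study", "data",
    "observed", "reported", "after", "before", "a", "this", "these",
    "several", "findings", "results", "clinical", "trial", "subjects",
    "healthy", "volunteers", "period",
)

_NAME_PREFIXES = ("ami", "vera", "keto", "pheno", "cipro", "flu", "ritona",
                  "carba", "meto", "lova")
_NAME_SUFFIXES = ("odarone", "pamil", "conazole", "barbital", "floxacin",
                  "oxetine", "vir", "mazepine", "prolol", "statin")

#: Default class mix: the published positive-type imbalance of the DDI corpus
#: (advice 20.9%, effect 41.1%, int 5.6%, mechanism 32.3% of positives),
#: with half of all candidate pairs non-interacting.
DEFAULT_PROPORTIONS = {
    "advice": 0.1045,
    "effect": 0.2055,
    "int": 0.028,
    "mechanism": 0.1615,
    "other": 0.5,
}

#: Default inter-entity token-distance distribution: modes at 2, 4, 6 with a
#: truncated tail of longer-range pairs.
DEFAULT_DISTANCES = {
    2: 0.25, 3: 0.08, 4: 0.16, 5: 0.08, 6: 0.13, 7: 0.05, 8: 0.06,
    10: 0.05, 12: 0.04, 14: 0.04, 18: 0.03, 22: 0.02, 30: 0.01,
}


def drug_lexicon(size: int) -> list[str]:
    names = [p + s for s in _NAME_SUFFIXES for p in _NAME_PREFIXES]
    if size > len(names):
        names = names + [f"{n}{i}" for i, n in enumerate(names)]
    return names[:size]


@dataclass(frozen=True)
class GeneratorConfig:
    n_documents: int = 20
    sentences_per_doc: tuple[int, int] = (2, 5)
    class_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PROPORTIONS)
    )
    distance_distribution: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_DISTANCES)
    )
    drug_lexicon_size: int = 40
    multiword_name_rate: float = 0.2
    extra_mention_rate: float = 0.3
    include_secondary_pairs: bool = True
    noise_rate: float = 0.0
    provenance_mix: dict[str, float] = field(
        default_factory=lambda: {"drugbank": 0.77, "medline": 0.23}
    )
    discontinuous_pair_rate: float = 0.0

    def validate(self) -> None:
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-3:
            raise ValueError(f"class proportions sum to {total}, expected 1")
        if not (0 <= self.noise_rate < 1):
            raise ValueError("noise rate must lie in [0, 1)")
        if any(d < 1 for d in self.distance_distribution):
            raise ValueError("entity distances must be >= 1")
        if abs(sum(self.distance_distribution.values()) - 1.0) > 1e-3:
            raise ValueError("distance distribution must sum to 1")
        for cls in self.class_proportions:
            ClassLabel.from_string(cls)


class _SentenceBuilder:
    """Accumulates tokens and entity word-ranges, then renders text+offsets."""

    def __init__(self) -> None:
        self.words: list[str] = []
        self.entities: list[tuple[list[tuple[int, int]], str]] = []

    def add_words(self, words: Sequence[str]) -> None:
        self.words.extend(words)

    def add_entity(self, name_words: Sequence[str]) -> int:
        start = len(self.words)
        self.words.extend(name_words)
        self.entities.append(([(start, len(self.words) - 1)], " ".join(name_words)))
        return len(self.entities) - 1

    def add_discontinuous_entity(
        self, first: Sequence[str], connector: Sequence[str], second: Sequence[str]
    ) -> int:
        """E.g. 'ganglionic [or peripheral] blocking agents': two char spans."""
        a0 = len(self.words)
        self.words.extend(first)
        a1 = len(self.words) - 1
        self.words.extend(connector)
        b0 = len(self.words)
        self.words.extend(second)
        b1 = len(self.words) - 1
        text = " ".join(list(first) + list(second))
        self.entities.append(([(a0, a1), (b0, b1)], text))
        return len(self.entities) - 1

    def render(self, sent_id: str) -> tuple[str, list[EntityMention]]:
        starts: list[int] = []
        pos = 0
        for w in self.words:
            starts.append(pos)
            pos += len(w) + 1
        text = " ".join(self.words)
        mentions = []
        for k, (word_spans, surface) in enumerate(self.entities):
            spans = [
                (starts[w0], starts[w1] + len(self.words[w1]) - 1)
                for w0, w1 in word_spans
            ]
            mentions.append(
                EntityMention(id=f"{sent_id}.e{k}", text=surface, spans=spans)
            )
        return text, mentions


def _sample_categorical(rng: np.random.Generator, table: dict) -> object:
    keys = sorted(table)
    probs = np.array([table[k] for k in keys], dtype=float)
    probs = probs / probs.sum()
    return keys[rng.choice(len(keys), p=probs)]


def _fillers(rng: np.random.Generator, k: int) -> list[str]:
    return [FILLERS[i] for i in rng.integers(0, len(FILLERS), size=int(k))]


def _drug_name(rng: np.random.Generator, lexicon: list[str], multiword_rate: float) -> list[str]:
    name = [lexicon[rng.integers(0, len(lexicon))]]
    if rng.random() < multiword_rate:
        name.append("sodium" if rng.random() < 0.5 else "hydrochloride")
    return name


def _build_sentence(
    sent_id: str,
    cfg: GeneratorConfig,
    lexicon: list[str],
    rng: np.random.Generator,
) -> Sentence:
    label = ClassLabel.from_string(str(_sample_categorical(rng, cfg.class_proportions)))
    trigger_class = label.value
    if cfg.noise_rate > 0 and rng.random() < cfg.noise_rate:
        others = sorted(set(TRIGGERS) - {label.value})
        trigger_class = others[rng.integers(0, len(others))]
    phrases = TRIGGERS[trigger_class]
    trigger = list(phrases[rng.integers(0, len(phrases))])
    distance = int(_sample_categorical(rng, cfg.distance_distribution))

    b = _SentenceBuilder()
    b.add_words(_fillers(rng, rng.integers(0, 4)))
    discontinuous = rng.random() < cfg.discontinuous_pair_rate
    if discontinuous:
        e1_idx = b.add_discontinuous_entity(
            [lexicon[rng.integers(0, len(lexicon))]],
            ["or", lexicon[rng.integers(0, len(lexicon))]],
            ["type", "agents"],
        )
    else:
        e1_idx = b.add_entity(_drug_name(rng, lexicon, cfg.multiword_name_rate))
    # gap sized so the post-blinding token distance equals `distance`
    gap = distance - 1
    trailing_trigger = None
    if len(trigger) <= gap:
        offset = int(rng.integers(0, gap - len(trigger) + 1))
        b.add_words(_fillers(rng, offset))
        b.add_words(trigger)
        b.add_words(_fillers(rng, gap - len(trigger) - offset))
    else:
        b.add_words(_fillers(rng, gap))
        trailing_trigger = trigger
    e2_idx = b.add_entity(_drug_name(rng, lexicon, cfg.multiword_name_rate))
    if trailing_trigger is not None:
        b.add_words(trailing_trigger)
    bystander_idx = None
    if rng.random() < cfg.extra_mention_rate:
        b.add_words(["and"])
        bystander_idx = b.add_entity(_drug_name(rng, lexicon, cfg.multiword_name_rate))
        b.add_words(["was", "also", "given"])
    b.add_words(_fillers(rng, rng.integers(1, 4)) + ["."])

    text, mentions = b.render(sent_id)
    sent = Sentence(id=sent_id, text=text, entities=mentions)
    e1, e2 = mentions[e1_idx], mentions[e2_idx]
    sent.pairs.append(CandidatePair(id=f"{sent_id}.p0", e1=e1, e2=e2, label=label))
    if bystander_idx is not None and cfg.include_secondary_pairs:
        by = mentions[bystander_idx]
        for k, ent in enumerate((e1, e2), start=1):
            first, second = (ent, by) if ent.start <= by.start else (by, ent)
            sent.pairs.append(
                CandidatePair(
                    id=f"{sent_id}.p{k}", e1=first, e2=second, label=ClassLabel.OTHER
                )
            )
    return sent


def generate_corpus(cfg: GeneratorConfig, seed: int = 0) -> list[Document]:
    """Deterministic synthetic corpus; same (cfg, seed) gives identical output."""
    cfg.validate()
    rng = np.random.default_rng(seed)
    lexicon = drug_lexicon(cfg.drug_lexicon_size)
    docs = []
    for i in range(cfg.n_documents):
        prov = str(_sample_categorical(rng, cfg.provenance_mix))
        doc = Document(id=f"d{i}", provenance=prov)
        lo, hi = cfg.sentences_per_doc
        for j in range(int(rng.integers(lo, hi + 1))):
            doc.sentences.append(_build_sentence(f"d{i}.s{j}", cfg, lexicon, rng))
        docs.append(doc)
    return docs


@dataclass(frozen=True)
class DistanceBand:
    lo: int
    hi: int
    label: str


DEFAULT_BANDS = (DistanceBand(5, 7, "effect"), DistanceBand(11, 14, "mechanism"))


def generate_position_task(
    n_sentences: int = 400,
    bands: tuple[DistanceBand, ...] = DEFAULT_BANDS,
    seed: int = 0,
    sentences_per_doc: int = 10,
    total_tokens: int = 22,
) -> list[Document]:
    """Corpus where only the inter-entity distance band determines the label.

    Every non-entity token is a random filler and every sentence has exactly
    ``total_tokens`` tokens, so no lexical or length feature carries label
    information; the shortest default band starts at distance 5, beyond the
    reach of convolution windows of width <= 5 that would otherwise see both
    entities at once.
    """
    if len(bands) < 2:
        raise ValueError("need at least 2 distance bands")
    ordered = sorted(bands, key=lambda b: b.lo)
    for a, b in zip(ordered, ordered[1:]):
        if b.lo <= a.hi:
            raise ValueError(f"distance bands overlap: {a} and {b}")
    max_d = max(b.hi for b in bands)
    if total_tokens < max_d + 2 + 3 + 1:
        raise ValueError(
            f"total_tokens={total_tokens} too small for distance {max_d}"
        )
    rng = np.random.default_rng(seed)
    lexicon = drug_lexicon(20)
    docs: list[Document] = []
    doc = None
    for i in range(n_sentences):
        if i % sentences_per_doc == 0:
            doc = Document(id=f"p{i // sentences_per_doc}", provenance="synthetic")
            docs.append(doc)
        band = bands[int(rng.integers(0, len(bands)))]
        d = int(rng.integers(band.lo, band.hi + 1))
        b = _SentenceBuilder()
        prefix = int(rng.integers(0, 4))
        b.add_words(_fillers(rng, prefix))
        e1_idx = b.add_entity([lexicon[rng.integers(0, len(lexicon))]])
        b.add_words(_fillers(rng, d - 1))
        e2_idx = b.add_entity([lexicon[rng.integers(0, len(lexicon))]])
        # suffix fillers bring every sentence to the same fixed length, so
        # neither sentence length nor padding correlates with the band
        b.add_words(_fillers(rng, total_tokens - prefix - d - 2))
        sent_id = f"{doc.id}.s{i % sentences_per_doc}"
        text, mentions = b.render(sent_id)
        sent = Sentence(id=sent_id, text=text, entities=mentions)
        sent.pairs.append(
            CandidatePair(
                id=f"{sent_id}.p0",
                e1=mentions[e1_idx],
                e2=mentions[e2_idx],
                label=ClassLabel.from_string(band.label),
            )
        )
        doc.sentences.append(sent)
    return docs
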