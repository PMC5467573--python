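"""Instance generation: entity blinding, cleaning/tokenization, padding.

Every candidate pair in a sentence becomes one classification instance.  The
two paired mentions are replaced by the labels ``drug1`` and ``drug2`` and all
remaining drug mentions by ``drug0`` (entity blinding), the text is lower-cased
with special characters separated into their own tokens, and the token
sequence is padded with the auxiliary token ``"0"`` to a fixed length.

Pairs involving a discontinuous mention are removed (and counted): they are a
rare annotation phenomenon that the model does not attempt to represent.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from .corpus import CandidatePair, ClassLabel, Document, Sentence

PAD_TOKEN = "0"
E1_LABEL = "drug1"
E2_LABEL = "drug2"
BYSTANDER_LABEL = "drug0"

#: Ordered (pattern, replacement) text rules applied after lower-casing.
#: Contractions are split off as their own tokens; every remaining special
#: character is separated by whitespace (kept, not deleted); runs of
#: whitespace collapse.  The rule list is data so it can be audited/swapped.
DEFAULT_RULES: tuple[tuple[str, str], ...] = (
    (r"n't\b", " n't"),
    (r"'(s|ve|re|d|ll|m)\b", r" '\1"),
    (r"([^a-z0-9\s'])", r" \1 "),
    (r"\s{2,}", " "),
)


@dataclass(frozen=True)
class TokenizerConfig:
    lowercase: bool = True
    rules: tuple[tuple[str, str], ...] = DEFAULT_RULES

    def compiled(self) -> list[tuple[re.Pattern, str]]:
        return [(re.compile(p), r) for p, r in self.rules]


DEFAULT_TOKENIZER = TokenizerConfig()


@dataclass
class BlindedInstance:
    """One blinded, tokenized candidate pair.

    ``tokens[p1] == "drug1"`` and ``tokens[p2] == "drug2"`` always hold;
    ``true_length`` is the token count before padding.
    """

    tokens: list[str]
    p1: int
    p2: int
    label: ClassLabel
    sentence_id: str
    pair_id: str
    provenance: str
    true_length: int

    @property
    def entity_distance(self) -> int:
        return self.p2 - self.p1


@dataclass
class InstanceStats:
    """Bookkeeping for silently-but-countedly filtered pairs."""

    n_pairs: int = 0
    n_instances: int = 0
    n_dropped_discontinuous: int = 0
    n_dropped_overlap: int = 0
    n_truncated: int = 0
    n_dropped_truncation: int = 0

    def merge(self, other: "InstanceStats") -> None:
        for f in self.__dataclass_fields__:
            setattr(self, f, getattr(self, f) + getattr(other, f))


def clean_and_tokenize(text: str, cfg: TokenizerConfig = DEFAULT_TOKENIZER) -> list[str]:
    """Lower-case, separate special characters, and split on whitespace."""
    if cfg.lowercase:
        text = text.lower()
    for pattern, repl in cfg.compiled():
        text = pattern.sub(repl, text)
    return text.split()


class OverlappingPairError(ValueError):
    """The two paired mentions overlap in the text; the instance is unusable."""


def _covering_span(spans: Sequence[tuple[int, int]]) -> tuple[int, int]:
    return spans[0][0], spans[-1][1]


def blind_entities(sentence: Sentence, pair: CandidatePair) -> str:
    """Replace the paired mentions by drug1/drug2 and bystanders by drug0.

    Replacement happens on the raw sentence text, before tokenization, so
    multi-word drug names collapse into single tokens.  Overlap resolution:
    the paired entities always win over a bystander replacement; among
    bystanders, longer spans are replaced first and spans overlapping an
    already-claimed region are skipped.
    """
    if pair.e1.discontinuous or pair.e2.discontinuous:
        raise ValueError(
            f"pair {pair.id}: discontinuous paired mention cannot be blinded"
        )
    s1, e1 = pair.e1.spans[0]
    s2, e2 = pair.e2.spans[0]
    if s1 <= e2 and s2 <= e1:
        raise OverlappingPairError(
            f"pair {pair.id}: mentions {pair.e1.id} and {pair.e2.id} overlap"
        )
    repls: list[tuple[int, int, str]] = [(s1, e1, E1_LABEL), (s2, e2, E2_LABEL)]
    claimed = [(s1, e1), (s2, e2)]
    bystander_spans: list[tuple[int, int]] = []
    for ent in sentence.entities:
        if ent.id in (pair.e1.id, pair.e2.id):
            continue
        bystander_spans.extend(ent.spans)
    # longest first so nested mentions resolve deterministically
    bystander_spans.sort(key=lambda se: (-(se[1] - se[0]), se[0]))
    for s, e in bystander_spans:
        if any(s <= ce and cs <= e for cs, ce in claimed):
            continue
        repls.append((s, e, BYSTANDER_LABEL))
        claimed.append((s, e))
    text = sentence.text
    for s, e, token in sorted(repls, key=lambda r: -r[0]):
        text = text[:s] + token + text[e + 1 :]
    return text


@dataclass
class PaddedTokens:
    tokens: list[str]
    p1: int | None
    p2: int | None
    true_length: int
    truncated: bool = False


def pad_to_length(
    tokens: Sequence[str],
    n: int,
    p1: int | None = None,
    p2: int | None = None,
) -> PaddedTokens:
    """Pad with the auxiliary token "0" to length exactly ``n``.

    Sequences longer than ``n`` are truncated from the tail; if that would
    lose either blinded entity, the window is centered on the two entities
    instead.  If the entities are further apart than ``n`` tokens both cannot
    be kept and ``p2`` comes back as ``None``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    tokens = list(tokens)
    L = len(tokens)
    if L <= n:
        return PaddedTokens(tokens + [PAD_TOKEN] * (n - L), p1, p2, L)
    start = 0
    if p1 is not None and p2 is not None and p2 >= n:
        lo = max(0, p2 - n + 1)
        hi = min(p1, L - n)
        if lo <= hi:
            start = min(max((p1 + p2) // 2 - n // 2, lo), hi)
        else:  # entities further apart than the window: keep drug1
            start = min(p1, L - n)
    window = tokens[start : start + n]
    new_p1 = new_p2 = None
    if p1 is not None:
        new_p1 = p1 - start if start <= p1 < start + n else None
    if p2 is not None:
        new_p2 = p2 - start if start <= p2 < start + n else None
    return PaddedTokens(window, new_p1, new_p2, n, truncated=True)


def generate_instances(
    doc: Document,
    cfg: TokenizerConfig = DEFAULT_TOKENIZER,
) -> tuple[list[BlindedInstance], InstanceStats]:
    """One unpadded instance per candidate pair of the document.

    Pairs with a discontinuous paired mention, or whose two mentions overlap
    in the text, are dropped and counted in the returned stats.
    """
    out: list[BlindedInstance] = []
    stats = InstanceStats()
    for sent in doc.sentences:
        for pair in sent.pairs:
            stats.n_pairs += 1
            if pair.e1.discontinuous or pair.e2.discontinuous:
                stats.n_dropped_discontinuous += 1
                continue
            try:
                blinded = blind_entities(sent, pair)
            except OverlappingPairError:
                stats.n_dropped_overlap += 1
                continue
            tokens = clean_and_tokenize(blinded, cfg)
            try:
                p1 = tokens.index(E1_LABEL)
                p2 = tokens.index(E2_LABEL)
            except ValueError:
                # blinding label swallowed by an overlapping replacement
                stats.n_dropped_overlap += 1
                continue
            out.append(
                BlindedInstance(
                    tokens=tokens,
                    p1=p1,
                    p2=p2,
                    label=pair.label,
                    sentence_id=sent.id,
                    pair_id=pair.id,
                    provenance=doc.provenance,
                    true_length=len(tokens),
                )
            )
            stats.n_instances += 1
    return out, stats


def corpus_to_instances(
    docs: Iterable[Document],
    cfg: TokenizerConfig = DEFAULT_TOKENIZER,
) -> tuple[list[BlindedInstance], InstanceStats]:
    """Instances for a whole corpus, with merged drop statistics."""
    all_instances: list[BlindedInstance] = []
    stats = InstanceStats()
    for doc in docs:
        inst, s = generate_instances(doc, cfg)
        all_instances.extend(inst)
        stats.merge(s)
    return all_instances, stats


def write_instances_jsonl(instances: Iterable[BlindedInstance], path) -> None:
    """Line-delimited interchange format: one instance per line."""
    import json

    with open(path, "w") as fh:
        for inst in instances:
            fh.write(
                json.dumps(
                    {
                        "tokens": inst.tokens,
                        "p1": inst.p1,
                        "p2": inst.p2,
                        "label": inst.label.value,
                        "sentence_id": inst.sentence_id,
                        "pair_id": inst.pair_id,
                        "provenance": inst.provenance,
                        "true_length": inst.true_length,
                    }
                )
                + "\n"
            )


def read_instances_jsonl(path) -> list[BlindedInstance]:
    import json

    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            d = json.loads(line)
            out.append(
                BlindedInstance(
                    tokens=d["tokens"],
                    p1=d["p1"],
                    p2=d["p2"],
                    label=ClassLabel.from_string(d["label"]),
                    sentence_id=d["sentence_id"],
                    pair_id=d["pair_id"],
                    provenance=d["provenance"],
                    true_length=d["true_length"],
                )
            )
    return out


def pad_instances(
    instances: Iterable[BlindedInstance], n: int
) -> tuple[list[BlindedInstance], InstanceStats]:
    """Pad every instance to length ``n`` (dropping those whose entity pair
    cannot fit in an ``n``-token window)."""
    out: list[BlindedInstance] = []
    stats = InstanceStats()
    for inst in instances:
        padded = pad_to_length(inst.tokens, n, inst.p1, inst.p2)
        if padded.truncated:
            stats.n_truncated += 1
        if padded.p1 is None or padded.p2 is None:
            stats.n_dropped_truncation += 1
            continue
        out.append(
            replace(
                inst,
                tokens=padded.tokens,
                p1=padded.p1,
                p2=padded.p2,
                true_length=padded.true_length,
            )
        )
    return out, stats
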