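"""Word and position embedding tables and instance encoding.

Each padded instance of length ``n`` becomes an input matrix
``X in R^{n x (me + 2 md)}``: row ``i`` concatenates the word vector of token
``i`` with two position vectors indexed by the shifted relative distances of
token ``i`` to the two blinded entities.  Raw distances live in
``(-n+1, n-1)``; the affine shift ``d -> d + n`` maps them into ``[1, 2n-1]``
so they can index the position tables ``Wd1, Wd2 in R^{(2n-1) x md}``.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Union

import numpy as np

from .preprocess import PAD_TOKEN, BlindedInstance

UNK_TOKEN = "<unk>"


@dataclass(frozen=True)
class Vocabulary:
    """Dense token->index map with reserved padding and unknown entries."""

    index: dict[str, int]

    @property
    def size(self) -> int:
        return len(self.index)

    @property
    def pad_index(self) -> int:
        return self.index[PAD_TOKEN]

    @property
    def unk_index(self) -> int:
        return self.index[UNK_TOKEN]

    def __getitem__(self, token: str) -> int:
        return self.index.get(token, self.index[UNK_TOKEN])

    def __contains__(self, token: str) -> bool:
        return token in self.index

    def tokens(self) -> list[str]:
        return sorted(self.index, key=self.index.get)


def build_vocabulary(instances: Iterable[BlindedInstance]) -> Vocabulary:
    """Vocabulary over all training tokens, order-independent (sorted).

    Index 0 is the padding token "0", index 1 the unknown token; all other
    tokens follow in sorted order, so two shuffles of the same instance list
    produce identical vocabularies.
    """
    tokens: set[str] = set()
    n_inst = 0
    for inst in instances:
        n_inst += 1
        tokens.update(inst.tokens)
    if n_inst == 0:
        raise ValueError("cannot build a vocabulary from zero instances")
    tokens.discard(PAD_TOKEN)
    tokens.discard(UNK_TOKEN)
    index = {PAD_TOKEN: 0, UNK_TOKEN: 1}
    for i, tok in enumerate(sorted(tokens), start=2):
        index[tok] = i
    return Vocabulary(index)


def init_random_embeddings(
    vocab_size: int, me: int, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Word table with entries i.i.d. uniform on (-1, +1), seeded."""
    if me < 1:
        raise ValueError("embedding dimension must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.uniform(-1.0, 1.0, size=(vocab_size, me))


# --- word2vec vector-file formats (text and binary) ----------------------


def read_word2vec(path: Union[str, Path]) -> tuple[list[str], np.ndarray]:
    """Read a word2vec vector file, auto-detecting text vs binary encoding."""
    path = Path(path)
    with open(path, "rb") as fh:
        header = fh.readline()
        try:
            count_s, dim_s = header.split()
            count, dim = int(count_s), int(dim_s)
        except ValueError:
            raise ValueError(f"{path}: unreadable word2vec header {header!r}") from None
        start = fh.tell()
        rest = fh.read()
    # text rows decode as ascii floats; binary rows contain raw float32
    try:
        text = rest.decode("utf-8")
        tokens, rows = [], []
        for line in text.splitlines():
            if not line.strip():
                continue
            parts = line.rstrip().split(" ")
            if len(parts) != dim + 1:
                raise ValueError(f"{path}: row for {parts[0]!r} has wrong width")
            tokens.append(parts[0])
            rows.append([float(x) for x in parts[1:]])
        if len(tokens) != count:
            raise ValueError(f"{path}: header promises {count} rows, found {len(tokens)}")
        return tokens, np.asarray(rows, dtype=np.float32)
    except (UnicodeDecodeError, ValueError):
        pass
    tokens, rows = [], []
    vec_bytes = 4 * dim
    pos = 0
    for _ in range(count):
        tok_end = rest.index(b" ", pos)
        token = rest[pos:tok_end].decode("utf-8").lstrip("\n")
        vec = np.frombuffer(rest, dtype="<f4", count=dim, offset=tok_end + 1)
        tokens.append(token)
        rows.append(vec)
        pos = tok_end + 1 + vec_bytes
    return tokens, np.asarray(rows, dtype=np.float32)


def write_word2vec(
    path: Union[str, Path], tokens: list[str], matrix: np.ndarray, binary: bool = False
) -> Path:
    """Write vectors in word2vec text or binary format (used for fixtures)."""
    matrix = np.asarray(matrix, dtype=np.float32)
    with open(path, "wb") as fh:
        fh.write(f"{len(tokens)} {matrix.shape[1]}\n".encode())
        for tok, row in zip(tokens, matrix):
            if binary:
                fh.write(tok.encode() + b" " + struct.pack(f"<{len(row)}f", *row))
            else:
                fh.write((tok + " " + " ".join(repr(float(x)) for x in row) + "\n").encode())
    return Path(path)


def load_pretrained(
    path: Union[str, Path],
    vocab: Vocabulary,
    me: int | None = None,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, float]:
    """Word table seeded from a pre-trained vector file.

    Vocabulary tokens found in the file take their pre-trained vector; all
    others (including the blinding labels and the padding token, which no
    external model knows) are drawn uniform on (-1, +1).  Returns the matrix
    and the covered fraction of the vocabulary.  The whole table remains
    trainable: vectors are fine-tuned during training.
    """
    tokens, pretrained = read_word2vec(path)
    if len(tokens) and me is not None and pretrained.shape[1] != me:
        raise ValueError(
            f"pretrained vectors have dimension {pretrained.shape[1]}, expected {me}"
        )
    dim = me if me is not None else (pretrained.shape[1] if len(tokens) else None)
    if dim is None:
        raise ValueError("empty vector file and no embedding dimension given")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    We = init_random_embeddings(vocab.size, dim, rng)
    lookup = {t: i for i, t in enumerate(tokens)}
    covered = 0
    for tok, idx in vocab.index.items():
        row = lookup.get(tok)
        if row is not None:
            We[idx] = pretrained[row]
            covered += 1
    return We, covered / vocab.size


# --- position indices and encoding ----------------------------------------


def relative_position_index(i: int, p: int, n: int) -> int:
    """Shifted relative position of token ``i`` w.r.t. entity position ``p``.

    The raw distance ``i - p`` in ``(-n+1, n-1)`` maps affinely to
    ``[1, 2n-1]`` via ``(i - p) + n`` (so a zero distance maps to ``n``).
    """
    if not (0 <= i < n and 0 <= p < n):
        raise ValueError(f"positions must lie in [0, {n}): got i={i}, p={p}")
    return i - p + n


@dataclass
class EncodedInstance:
    word_indices: np.ndarray  # (n,) int
    pos1_indices: np.ndarray  # (n,) int in [1, 2n-1]
    pos2_indices: np.ndarray  # (n,) int in [1, 2n-1]
    label_index: int


def encode_indices(inst: BlindedInstance, vocab: Vocabulary, n: int) -> EncodedInstance:
    """Index arrays for one padded instance (the model's internal input)."""
    if len(inst.tokens) != n:
        raise ValueError(f"instance not padded to n={n} (length {len(inst.tokens)})")
    word = np.fromiter((vocab[t] for t in inst.tokens), dtype=np.int64, count=n)
    i = np.arange(n, dtype=np.int64)
    return EncodedInstance(
        word_indices=word,
        pos1_indices=i - inst.p1 + n,
        pos2_indices=i - inst.p2 + n,
        label_index=inst.label.index,
    )


def encode(
    inst: BlindedInstance,
    vocab: Vocabulary,
    We: np.ndarray,
    Wd1: np.ndarray | None = None,
    Wd2: np.ndarray | None = None,
) -> np.ndarray:
    """Materialize the input matrix ``X`` of shape ``n x (me + 2 md)``.

    With position embeddings disabled (``Wd1 is None`` or ``md == 0``), X is
    just the word part of shape ``n x me``.
    """
    n = len(inst.tokens)
    enc = encode_indices(inst, vocab, n)
    parts = [We[enc.word_indices]]
    if Wd1 is not None and Wd2 is not None and Wd1.shape[1] > 0:
        # position tables are 1-indexed by the shifted distance
        parts.append(Wd1[enc.pos1_indices - 1])
        parts.append(Wd2[enc.pos2_indices - 1])
    return np.concatenate(parts, axis=1)
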