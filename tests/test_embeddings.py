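"""Vocabulary, embedding tables, position indices and instance encoding."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ddicnn.corpus import ClassLabel
from ddicnn.embeddings import (
    Vocabulary,
    build_vocabulary,
    encode,
    encode_indices,
    init_random_embeddings,
    load_pretrained,
    read_word2vec,
    relative_position_index,
    write_word2vec,
)
from ddicnn.preprocess import BlindedInstance, pad_instances


def _inst(tokens, p1, p2, label=ClassLabel.EFFECT):
    return BlindedInstance(
        tokens=list(tokens), p1=p1, p2=p2, label=label,
        sentence_id="s", pair_id="p", provenance="synthetic",
        true_length=len(tokens),
    )


def test_vocabulary_size_counts_distinct_tokens_plus_reserved():
    inst = _inst(["drug1", "a", "b", "b", "drug2"], 0, 4)
    vocab = build_vocabulary([inst])
    # a, b, drug1, drug2 plus padding "0" and unknown
    assert vocab.size == 4 + 2
    assert vocab.pad_index != vocab.unk_index


def test_vocabulary_is_order_independent():
    insts = [_inst(["drug1", t, "drug2"], 0, 2) for t in "zebra apple mango".split()]
    assert build_vocabulary(insts) == build_vocabulary(insts[::-1])


def test_oov_token_routes_to_unknown_index():
    vocab = build_vocabulary([_inst(["drug1", "x", "drug2"], 0, 2)])
    assert vocab["never-seen"] == vocab.unk_index


def test_empty_instance_list_is_an_error():
    with pytest.raises(ValueError):
        build_vocabulary([])


def test_random_embeddings_range_seed_and_moments():
    We = init_random_embeddings(400, 300, seed=1)
    assert We.shape == (400, 300)
    assert np.all(We > -1) and np.all(We < 1)
    assert np.array_equal(We, init_random_embeddings(400, 300, seed=1))
    # uniform(-1,1): mean 0, sd 1/sqrt(3); N = 120000 entries
    tol = 3 * (1 / np.sqrt(3)) / np.sqrt(We.size)
    assert abs(We.mean()) < tol


def test_word2vec_text_and_binary_dialects_agree(tmp_path):
    rng = np.random.default_rng(0)
    tokens = ["alpha", "beta", "gamma"]
    mat = rng.normal(size=(3, 5)).astype(np.float32)
    t_path = write_word2vec(tmp_path / "v.txt", tokens, mat, binary=False)
    b_path = write_word2vec(tmp_path / "v.bin", tokens, mat, binary=True)
    toks_t, mat_t = read_word2vec(t_path)
    toks_b, mat_b = read_word2vec(b_path)
    assert toks_t == toks_b == tokens
    np.testing.assert_array_equal(mat_t, mat_b)
    np.testing.assert_array_equal(mat_t, mat)


def test_load_pretrained_covers_known_tokens_and_reports_coverage(tmp_path):
    vocab = build_vocabulary([_inst(["drug1", "alpha", "beta", "drug2"], 0, 3)])
    rng = np.random.default_rng(3)
    mat = rng.normal(size=(2, 4)).astype(np.float32)
    path = write_word2vec(tmp_path / "v.txt", ["alpha", "beta"], mat)
    We, coverage = load_pretrained(path, vocab, me=4, seed=0)
    assert We.shape == (vocab.size, 4)
    np.testing.assert_allclose(We[vocab["alpha"]], mat[0], rtol=1e-6)
    np.testing.assert_allclose(We[vocab["beta"]], mat[1], rtol=1e-6)
    assert coverage == pytest.approx(2 / vocab.size)
    # blinding labels were not in the file: random but inside (-1, 1)
    assert np.all(np.abs(We[vocab["drug1"]]) < 1)


def test_load_pretrained_dimension_mismatch_is_an_error(tmp_path):
    vocab = build_vocabulary([_inst(["drug1", "alpha", "drug2"], 0, 2)])
    path = write_word2vec(tmp_path / "v.txt", ["alpha"], np.zeros((1, 7), np.float32))
    with pytest.raises(ValueError, match="dimension"):
        load_pretrained(path, vocab, me=4)


def test_empty_vector_file_behaves_as_random_init(tmp_path):
    vocab = build_vocabulary([_inst(["drug1", "alpha", "drug2"], 0, 2)])
    path = tmp_path / "empty.txt"
    path.write_bytes(b"0 4\n")
    We, coverage = load_pretrained(path, vocab, me=4, seed=9)
    assert coverage == 0.0
    np.testing.assert_array_equal(We, init_random_embeddings(vocab.size, 4, seed=9))


def test_relative_position_examples():
    # a word two tokens right of drug1 and four left of drug2 (n = 128)
    assert relative_position_index(10, 8, 128) == 130
    assert relative_position_index(10, 14, 128) == 124
    assert relative_position_index(7, 7, 128) == 128  # zero distance -> n
    assert relative_position_index(127, 0, 128) == 255  # endpoint n-1 -> 2n-1
    assert relative_position_index(0, 127, 128) == 1  # endpoint -n+1 -> 1
    with pytest.raises(ValueError):
        relative_position_index(128, 0, 128)


@settings(derandomize=True, max_examples=200)
@given(st.integers(2, 200), st.data())
def test_shifted_position_indices_stay_in_range(n, data):
    i = data.draw(st.integers(0, n - 1))
    p = data.draw(st.integers(0, n - 1))
    assert 1 <= relative_position_index(i, p, n) <= 2 * n - 1


def test_encode_shapes_with_and_without_position_embeddings():
    inst = _inst(["drug1", "x", "drug2", "0", "0"], 0, 2)
    vocab = build_vocabulary([inst])
    rng = np.random.default_rng(0)
    We = init_random_embeddings(vocab.size, 300, rng)
    n = 5
    Wd1 = rng.uniform(-1, 1, (2 * n - 1, 5))
    Wd2 = rng.uniform(-1, 1, (2 * n - 1, 5))
    X = encode(inst, vocab, We, Wd1, Wd2)
    assert X.shape == (5, 300 + 2 * 5)
    X0 = encode(inst, vocab, We)
    assert X0.shape == (5, 300)
    # word part of the drug1 row is exactly its word vector
    np.testing.assert_array_equal(X[inst.p1, :300], We[vocab["drug1"]])
    # row i concatenates We ⊕ Wd1 ⊕ Wd2 at the shifted indices
    i = 3
    np.testing.assert_array_equal(
        X[i],
        np.concatenate(
            [We[vocab["0"]], Wd1[(i - 0 + n) - 1], Wd2[(i - 2 + n) - 1]]
        ),
    )


def test_encode_is_pure_and_padding_rows_share_one_vector(small_instances):
    n = max(i.true_length for i in small_instances)
    padded, _ = pad_instances(small_instances, n)
    vocab = build_vocabulary(padded)
    We = init_random_embeddings(vocab.size, 12, seed=0)
    inst = max(padded, key=lambda i: n - i.true_length)
    X1 = encode(inst, vocab, We)
    X2 = encode(inst, vocab, We)
    np.testing.assert_array_equal(X1, X2)
    for row in range(inst.true_length, n):
        np.testing.assert_array_equal(X1[row], We[vocab.pad_index])


def test_encoded_position_indices_in_range_over_corpus(small_instances):
    n = max(i.true_length for i in small_instances)
    padded, _ = pad_instances(small_instances, n)
    vocab = build_vocabulary(padded)
    for inst in padded:
        enc = encode_indices(inst, vocab, n)
        for arr in (enc.pos1_indices, enc.pos2_indices):
            assert arr.min() >= 1 and arr.max() <= 2 * n - 1
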