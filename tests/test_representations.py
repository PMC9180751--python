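import itertools

import numpy as np
import pytest

import icfcoder as ic
from icfcoder.representations import (
    HashingContextualEncoder,
    RepresentationError,
    StaticEmbeddingModel,
    embed_definition,
    represent,
    train_static_embeddings,
)


def toy_model(vectors: dict) -> StaticEmbeddingModel:
    vocab = list(vectors)
    return StaticEmbeddingModel(vocab, np.array([vectors[w] for w in vocab], float))


# ---------------------------------------------------------------------------
# skipgram trainer
# ---------------------------------------------------------------------------

def test_trainer_dimension_and_vocab(tmp_path):
    path = tmp_path / "c.txt"
    path.write_text("the cat sat\nthe dog sat\nthe cat ran\n")
    model = train_static_embeddings(str(path), n=20, epochs=2, seed=1, n_buckets=500)
    assert model.dimension == 20
    for word in ("the", "cat", "dog", "sat", "ran"):
        assert word in model


def test_trainer_deterministic(tmp_path):
    path = tmp_path / "c.txt"
    path.write_text("\n".join("alpha beta gamma delta" for _ in range(20)))
    m1 = train_static_embeddings(str(path), n=10, epochs=2, seed=9, n_buckets=200)
    m2 = train_static_embeddings(str(path), n=10, epochs=2, seed=9, n_buckets=200)
    assert m1.vocab == m2.vocab
    np.testing.assert_array_equal(m1.vectors, m2.vectors)


def test_trainer_empty_corpus_errors(tmp_path):
    path = tmp_path / "empty.txt"
    path.write_text("")
    with pytest.raises(RepresentationError, match="empty"):
        train_static_embeddings(str(path))


def test_identical_contexts_yield_similar_vectors(tmp_path):
    """Two words occurring only in identical contexts end up closer than the
    average vocabulary pair."""
    frames = [("the", "road"), ("a", "path"), ("one", "lane")]
    others = ["cat", "dog", "house", "tree", "river"]
    lines = []
    for i in range(120):
        f = frames[i % len(frames)]
        lines.append(f"{f[0]} {['wug', 'dax'][i % 2]} {f[1]}")
        o = others[i % len(others)]
        lines.append(f"{o} sits near {o}")
        lines.append(f"green {o} falls")
    path = tmp_path / "toy.txt"
    path.write_text("\n".join(lines))
    m = train_static_embeddings(str(path), n=15, epochs=30, seed=4, subword=False, window=2)

    def cos(a, b):
        va, vb = m.lookup(a), m.lookup(b)
        return float(va @ vb / (np.linalg.norm(va) * np.linalg.norm(vb)))

    avg = np.mean([cos(a, b) for a, b in itertools.combinations(m.vocab, 2)])
    assert cos("wug", "dax") > avg


def test_word2vec_text_round_trip(tmp_path):
    path = tmp_path / "c.txt"
    path.write_text("some words to embed here\nmore words appear here\n")
    model = train_static_embeddings(str(path), n=8, epochs=1, seed=2, n_buckets=100)
    out = tmp_path / "model.w2v"
    model.save(str(out))
    assert out.read_text().splitlines()[0] == f"{len(model.vocab)} 8"
    restored = StaticEmbeddingModel.load(str(out))
    assert restored.vocab == model.vocab
    np.testing.assert_allclose(restored.vectors, model.vectors, atol=1e-5)
    # subword fallback survives reload
    assert restored.subword_fallback
    np.testing.assert_allclose(
        restored.lookup("unseenword"), model.lookup("unseenword"), atol=1e-5
    )


# ---------------------------------------------------------------------------
# represent()
# ---------------------------------------------------------------------------

def test_static_plain_is_token_mean():
    model = toy_model({"aa": (1.0, 0.0), "bb": (0.0, 1.0)})
    rep = represent("aa bb", mode="static_plain", model_or_encoder=model)
    np.testing.assert_allclose(rep.vector, [0.5, 0.5])


def test_static_oracle_concatenates_action_and_context():
    model = toy_model({"aa": (1.0, 0.0), "bb": (0.0, 1.0)})
    rep = represent("aa bb", action_span=(0, 2), mode="static_oracle", model_or_encoder=model)
    np.testing.assert_allclose(rep.vector, [1.0, 0.0, 0.0, 1.0])


def test_static_oracle_action_covering_all_tokens_zeroes_context_half():
    model = toy_model({"aa": (1.0, 0.0), "bb": (0.0, 1.0)})
    rep = represent("aa bb", action_span=(0, 5), mode="static_oracle", model_or_encoder=model)
    np.testing.assert_allclose(rep.vector, [0.5, 0.5, 0.0, 0.0])


def test_oracle_mode_requires_action_span():
    model = toy_model({"aa": (1.0, 0.0)})
    with pytest.raises(RepresentationError, match="action_span"):
        represent("aa", mode="static_oracle", model_or_encoder=model)


def test_empty_mention_errors():
    model = toy_model({"aa": (1.0, 0.0)})
    with pytest.raises(RepresentationError):
        represent("", mode="static_plain", model_or_encoder=model)


def test_dimension_table_all_modes(tiny_model):
    """plain = n, oracle = 2n for static; contextual dims unchanged by oracle."""
    enc = HashingContextualEncoder(dimension=32)
    text = "Pt ambulated 300 feet with a walker"
    span = (3, 12)
    expected = {
        "static_plain": tiny_model.dimension,
        "static_oracle": 2 * tiny_model.dimension,
        "ctx_plain": 32,
        "ctx_oracle": 32,
    }
    for mode, dim in expected.items():
        model = tiny_model if mode.startswith("static") else enc
        rep = represent(text, span, mode, model)
        assert rep.vector.shape == (dim,)
        assert np.all(np.isfinite(rep.vector))


def test_static_representation_is_linear_in_token_vectors(tiny_model):
    scaled = StaticEmbeddingModel(
        tiny_model.vocab, 3.0 * tiny_model.vectors,
        None if tiny_model.bucket_vectors is None else 3.0 * tiny_model.bucket_vectors,
        tiny_model.minn, tiny_model.maxn,
    )
    text = "Pt ambulated 300 feet with a walker"
    for mode in ("static_plain", "static_oracle"):
        r1 = represent(text, (3, 12), mode, tiny_model)
        r2 = represent(text, (3, 12), mode, scaled)
        np.testing.assert_allclose(r2.vector, 3.0 * r1.vector, atol=1e-10)


# ---------------------------------------------------------------------------
# contextual encoder stub
# ---------------------------------------------------------------------------

def test_hashing_encoder_deterministic_and_contextual():
    enc = HashingContextualEncoder(dimension=16)
    a = enc.encode("cold pack applied")
    b = enc.encode("cold pack applied")
    np.testing.assert_array_equal(a, b)
    c = enc.encode("cold symptoms described")
    assert not np.allclose(a[0], c[0])  # same word, different context


def test_ctx_oracle_single_token_action_equals_token_vector():
    enc = HashingContextualEncoder(dimension=16)
    text = "Pt ambulated today"
    mat = enc.encode(text)
    rep = represent(text, (3, 12), "ctx_oracle", enc)  # span covers 'ambulated'
    np.testing.assert_allclose(rep.vector, mat[1])


# ---------------------------------------------------------------------------
# definition embeddings
# ---------------------------------------------------------------------------

def test_definition_single_word_and_order_invariance():
    model = toy_model({"mobility": (1.0, 2.0), "other": (3.0, 4.0),
                       "or": (5.0, 6.0), "unspecified": (7.0, 8.0)})
    np.testing.assert_allclose(embed_definition("mobility", model), [1.0, 2.0])
    v1 = embed_definition("Mobility other or unspecified", model)
    v2 = embed_definition("unspecified or other Mobility", model)
    np.testing.assert_allclose(v1, v2)
    np.testing.assert_allclose(v1, np.mean([[1, 2], [3, 4], [5, 6], [7, 8]], axis=0))


def test_definition_all_oov_without_fallback_errors():
    model = toy_model({"aa": (1.0, 0.0)})
    assert not model.subword_fallback
    with pytest.raises(RepresentationError, match="out of vocabulary"):
        embed_definition("completely unknown words", model)


def test_definition_via_contextual_encoder():
    enc = HashingContextualEncoder(dimension=12)
    v = embed_definition("Mobility other or unspecified", enc)
    assert v.shape == (12,)
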