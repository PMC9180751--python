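"""Fixed-length vector representations for mentions and category definitions.

A mention (optionally with the location of one Action component — the
*Action oracle*) is turned into a vector under one of four strategies:

``static_plain``
    mean of the static word vectors of every token in the mention (dim n).
``static_oracle``
    mean of the Action tokens' vectors concatenated with the mean of all
    other tokens' vectors (dim 2n).
``ctx_plain``
    mean of contextualized token vectors over the whole mention.
``ctx_oracle``
    mean of the contextualized vectors of Action tokens only; because each
    contextual vector is already conditioned on the full mention, the
    dimensionality does not change.

Category definition strings are embedded as the mean of their token vectors
under the same normalization as mentions.

Static embeddings are trained with skipgram + negative sampling and
fastText-style character n-gram buckets, implemented here in numpy behind
:func:`train_static_embeddings`; models round-trip through the word2vec
text format (plus an optional ``.subword`` companion file carrying the
n-gram bucket vectors so out-of-vocabulary fallback survives reload).

The contextualized encoder is a pluggable interface
(:class:`ContextualEncoder`); :class:`HashingContextualEncoder` is a
deterministic stand-in that mixes hash-derived token vectors with their
sentence context, so the full pipeline is testable without any pretrained
weights.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass
from typing import Optional, Protocol, Sequence, Union

import numpy as np

from .textprep import normalize, tokenize

MODES = ("static_plain", "static_oracle", "ctx_plain", "ctx_oracle")


class RepresentationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Static embeddings
# ---------------------------------------------------------------------------

def _char_ngrams(word: str, minn: int, maxn: int) -> list[str]:
    w = f"<{word}>"
    out = []
    for n in range(minn, maxn + 1):
        out.extend(w[i : i + n] for i in range(len(w) - n + 1))
    return out


def _bucket(ngram: str, n_buckets: int) -> int:
    h = hashlib.blake2b(ngram.encode("utf-8"), digest_size=8).digest()
    return int.from_bytes(h, "little") % n_buckets


class StaticEmbeddingModel:
    """Word -> vector map with optional character n-gram fallback."""

    def __init__(
        self,
        vocab: Sequence[str],
        vectors: np.ndarray,
        bucket_vectors: Optional[np.ndarray] = None,
        minn: int = 3,
        maxn: int = 6,
        corpus_id: str = "",
    ):
        self.index = {w: i for i, w in enumerate(vocab)}
        self.vocab = list(vocab)
        self.vectors = np.asarray(vectors, dtype=np.float64)
        self.bucket_vectors = None if bucket_vectors is None else np.asarray(bucket_vectors, float)
        self.minn, self.maxn = minn, maxn
        self.corpus_id = corpus_id

    @property
    def dimension(self) -> int:
        return self.vectors.shape[1]

    @property
    def subword_fallback(self) -> bool:
        return self.bucket_vectors is not None

    def __contains__(self, word: str) -> bool:
        return word in self.index

    def lookup(self, word: str) -> Optional[np.ndarray]:
        """Vector for a word; subword average for OOV words when fallback is
        on, else None."""
        i = self.index.get(word)
        if i is not None:
            return self.vectors[i]
        if self.bucket_vectors is None:
            return None
        grams = _char_ngrams(word, self.minn, self.maxn)
        if not grams:
            return np.zeros(self.dimension)
        ids = [_bucket(g, len(self.bucket_vectors)) for g in grams]
        return self.bucket_vectors[ids].mean(axis=0)

    # --- word2vec text format ------------------------------------------
    def save(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"{len(self.vocab)} {self.dimension}\n")
            for w, v in zip(self.vocab, self.vectors):
                fh.write(w + " " + " ".join(f"{x:.6g}" for x in v) + "\n")
        if self.bucket_vectors is not None:
            with open(path + ".subword", "w", encoding="utf-8") as fh:
                fh.write(f"{len(self.bucket_vectors)} {self.dimension} {self.minn} {self.maxn}\n")
                for v in self.bucket_vectors:
                    fh.write(" ".join(f"{x:.6g}" for x in v) + "\n")

    @classmethod
    def load(cls, path: str, corpus_id: str = "") -> "StaticEmbeddingModel":
        import os

        with open(path, encoding="utf-8") as fh:
            n_words, dim = map(int, fh.readline().split())
            vocab, rows = [], []
            for _ in range(n_words):
                parts = fh.readline().rstrip("\n").split(" ")
                vocab.append(parts[0])
                rows.append([float(x) for x in parts[1 : dim + 1]])
        buckets = minn = maxn = None
        if os.path.exists(path + ".subword"):
            with open(path + ".subword", encoding="utf-8") as fh:
                nb, dim2, minn, maxn = map(int, fh.readline().split())
                buckets = np.array(
                    [[float(x) for x in fh.readline().split()] for _ in range(nb)]
                )
        return cls(vocab, np.array(rows), buckets, minn or 3, maxn or 6, corpus_id)


def train_static_embeddings(
    corpus_path: str,
    n: int = 300,
    *,
    window: int = 5,
    negatives: int = 5,
    epochs: int = 5,
    lr: float = 0.05,
    min_count: int = 1,
    subword: bool = True,
    n_buckets: int = 20000,
    minn: int = 3,
    maxn: int = 6,
    seed: int = 1,
    batch_size: int = 1024,
) -> StaticEmbeddingModel:
    """Train skipgram embeddings with negative sampling on a one-sentence-
    per-line corpus.

    Word inputs are composed fastText-style as the average of the word
    vector and its hashed character n-gram bucket vectors, so rare and
    unseen words inherit morphological structure.  Deterministic given
    ``seed``.
    """
    with open(corpus_path, encoding="utf-8") as fh:
        sentences = [line.split() for line in fh if line.strip()]
    if not sentences:
        raise RepresentationError(f"embedding corpus {corpus_path!r} is empty")

    counts: dict[str, int] = {}
    for s in sentences:
        for w in s:
            counts[w] = counts.get(w, 0) + 1
    vocab = sorted((w for w, c in counts.items() if c >= min_count), key=lambda w: (-counts[w], w))
    if not vocab:
        raise RepresentationError("no words above min_count")
    index = {w: i for i, w in enumerate(vocab)}
    V = len(vocab)

    rng = np.random.default_rng(seed)
    # per-word padded n-gram bucket ids
    if subword:
        gram_lists = [[_bucket(g, n_buckets) for g in _char_ngrams(w, minn, maxn)] for w in vocab]
        max_g = max((len(g) for g in gram_lists), default=0) or 1
        gram_ids = np.zeros((V, max_g), dtype=np.int64)
        gram_mask = np.zeros((V, max_g))
        for i, g in enumerate(gram_lists):
            gram_ids[i, : len(g)] = g
            gram_mask[i, : len(g)] = 1.0
        denom = 1.0 + gram_mask.sum(axis=1)
        Wb = (rng.random((n_buckets, n)) - 0.5) / n
    else:
        gram_ids = gram_mask = Wb = None
        denom = np.ones(V)

    Wv = (rng.random((V, n)) - 0.5) / n
    Wo = np.zeros((V, n))

    # skipgram training pairs with dynamic window
    centers, contexts = [], []
    for s in sentences:
        ids = [index[w] for w in s if w in index]
        for i, c in enumerate(ids):
            win = int(rng.integers(1, window + 1))
            for j in range(max(0, i - win), min(len(ids), i + win + 1)):
                if j != i:
                    centers.append(c)
                    contexts.append(ids[j])
    centers = np.array(centers, dtype=np.int64)
    contexts = np.array(contexts, dtype=np.int64)
    if len(centers) == 0:
        raise RepresentationError("corpus too small to form any skipgram pairs")

    freqs = np.array([counts[w] for w in vocab], dtype=np.float64) ** 0.75
    noise = freqs / freqs.sum()

    def sigmoid(z):
        return 1.0 / (1.0 + np.exp(-np.clip(z, -30.0, 30.0)))

    n_pairs = len(centers)
    total_batches = max(1, epochs * ((n_pairs + batch_size - 1) // batch_size))
    batch_no = 0
    for epoch in range(epochs):
        order = rng.permutation(n_pairs)
        for start in range(0, n_pairs, batch_size):
            # linear learning-rate decay, word2vec-style
            lr_t = lr * max(1.0 - batch_no / total_batches, 1e-4)
            batch_no += 1
            idx = order[start : start + batch_size]
            c, o = centers[idx], contexts[idx]
            B = len(c)
            neg = rng.choice(V, size=(B, negatives), p=noise)

            if subword:
                h = (Wv[c] + (Wb[gram_ids[c]] * gram_mask[c][:, :, None]).sum(axis=1)) / denom[c][:, None]
            else:
                h = Wv[c]

            pos_s = sigmoid(np.einsum("bn,bn->b", h, Wo[o]))
            neg_s = sigmoid(np.einsum("bn,bkn->bk", h, Wo[neg]))

            g_pos = pos_s - 1.0  # dL/d(score)
            g_neg = neg_s
            grad_h = g_pos[:, None] * Wo[o] + np.einsum("bk,bkn->bn", g_neg, Wo[neg])

            np.add.at(Wo, o, -lr_t * g_pos[:, None] * h)
            np.add.at(Wo, neg.ravel(), -lr_t * (g_neg[:, :, None] * h[:, None, :]).reshape(-1, n))

            grad_in = grad_h / denom[c][:, None]
            np.add.at(Wv, c, -lr_t * grad_in)
            if subword:
                contrib = (grad_in[:, None, :] * gram_mask[c][:, :, None]).reshape(-1, n)
                np.add.at(Wb, gram_ids[c].ravel(), -lr_t * contrib)

    if subword:
        composed = (Wv + (Wb[gram_ids] * gram_mask[:, :, None]).sum(axis=1)) / denom[:, None]
    else:
        composed = Wv
    return StaticEmbeddingModel(vocab, composed, Wb, minn, maxn, corpus_id=corpus_path)


# ---------------------------------------------------------------------------
# Contextual encoder interface + deterministic stub
# ---------------------------------------------------------------------------

class ContextualEncoder(Protocol):
    """Anything that maps text to one vector per token, deterministically."""

    dimension: int

    def encode(self, text: str) -> np.ndarray:  # (n_tokens, dimension)
        ...


class HashingContextualEncoder:
    """Deterministic pseudo-contextual encoder for tests and offline runs.

    Each token gets a fixed pseudo-random unit vector derived from a stable
    hash of its lowercased form; the emitted vector mixes in the mean of the
    neighboring tokens' base vectors, so identical tokens in different
    contexts receive different vectors while identical texts always encode
    identically.  Not a trained model — a plumbing substitute with the same
    interface contract.
    """

    def __init__(self, dimension: int = 768, context_weight: float = 0.3, window: int = 2):
        self.dimension = dimension
        self.context_weight = context_weight
        self.window = window

    def _base(self, token: str) -> np.ndarray:
        digest = hashlib.blake2b(token.lower().encode("utf-8"), digest_size=8).digest()
        rng = np.random.default_rng(int.from_bytes(digest, "little"))
        v = rng.standard_normal(self.dimension)
        return v / np.linalg.norm(v)

    def encode(self, text: str) -> np.ndarray:
        tokens = tokenize(text).tokens
        if not tokens:
            return np.zeros((0, self.dimension))
        base = np.stack([self._base(t) for t in tokens])
        out = np.empty_like(base)
        for i in range(len(tokens)):
            lo, hi = max(0, i - self.window), min(len(tokens), i + self.window + 1)
            neigh = [j for j in range(lo, hi) if j != i]
            ctx = base[neigh].mean(axis=0) if neigh else np.zeros(self.dimension)
            out[i] = base[i] + self.context_weight * ctx
        return out


# ---------------------------------------------------------------------------
# Mention representations
# ---------------------------------------------------------------------------

@dataclass
class MentionRepresentation:
    vector: np.ndarray
    mode: str


def expected_dimension(mode: str, model_or_encoder) -> int:
    d = model_or_encoder.dimension
    return 2 * d if mode == "static_oracle" else d


def _static_mean(tokens: list[str], model: StaticEmbeddingModel, what: str) -> np.ndarray:
    vecs = [v for v in (model.lookup(t) for t in tokens) if v is not None]
    if not vecs:
        if tokens:
            warnings.warn(f"all {what} tokens out of vocabulary; using zero vector")
        return np.zeros(model.dimension)
    return np.mean(vecs, axis=0)


def represent(
    mention_text: str,
    action_span: Optional[Union[tuple, "object"]] = None,
    mode: str = "static_plain",
    model_or_encoder=None,
    normalize_static: bool = True,
) -> MentionRepresentation:
    """Build the fixed-length vector for one (mention, optional Action).

    ``action_span`` is a (start, end) character interval into
    ``mention_text`` (anything with .start/.end also works); it is required
    in the two oracle modes.  Tokens overlapping the Action span count as
    Action tokens.  Degenerate oracle case: when the Action covers every
    token, the non-Action half is the zero vector.
    """
    if mode not in MODES:
        raise RepresentationError(f"unknown mode {mode!r}; valid modes: {MODES}")
    oracle = mode.endswith("_oracle")
    if oracle and action_span is None:
        raise RepresentationError(f"mode {mode} requires an action_span")

    tok = tokenize(mention_text)
    if not tok.tokens:
        raise RepresentationError("cannot represent an empty mention")

    if action_span is not None:
        a_start = getattr(action_span, "start", None)
        a_end = getattr(action_span, "end", None)
        if a_start is None:
            a_start, a_end = action_span
        if not (0 <= a_start < a_end <= len(mention_text)):
            raise RepresentationError(
                f"action span [{a_start}, {a_end}) outside mention of length {len(mention_text)}"
            )
        in_action = [s < a_end and e > a_start for (s, e) in tok.char_spans]
        if oracle and not any(in_action):
            raise RepresentationError("action span covers no tokens")

    if mode.startswith("static"):
        tokens = normalize(tok.tokens) if normalize_static else tok.tokens
        if mode == "static_plain":
            vec = _static_mean(tokens, model_or_encoder, "mention")
        else:
            act = [t for t, f in zip(tokens, in_action) if f]
            rest = [t for t, f in zip(tokens, in_action) if not f]
            act_v = _static_mean(act, model_or_encoder, "action")
            rest_v = (
                np.zeros(model_or_encoder.dimension)
                if not rest
                else _static_mean(rest, model_or_encoder, "context")
            )
            vec = np.concatenate([act_v, rest_v])
    else:
        mat = model_or_encoder.encode(mention_text)
        if mat.shape[0] != len(tok.tokens):
            raise RepresentationError(
                "contextual encoder token count does not match the tokenizer"
            )
        if mode == "ctx_plain":
            vec = mat.mean(axis=0)
        else:
            vec = mat[np.array(in_action)].mean(axis=0)

    if not np.all(np.isfinite(vec)):
        raise RepresentationError("non-finite values in representation")
    return MentionRepresentation(vector=vec, mode=mode)


def embed_definition(definition_text: str, model_or_encoder, normalize_static: bool = True) -> np.ndarray:
    """Mean token vector for a category definition string.

    Uses the same normalization as mention text for static models.  Raises
    when every token is out of vocabulary and subword fallback is off.
    """
    if not definition_text.strip():
        raise RepresentationError("empty definition text")
    if isinstance(model_or_encoder, StaticEmbeddingModel):
        tokens = tokenize(definition_text).tokens
        if normalize_static:
            tokens = normalize(tokens)
        vecs = [v for v in (model_or_encoder.lookup(t) for t in tokens) if v is not None]
        if not vecs:
            raise RepresentationError(
                f"all tokens of definition {definition_text!r} are out of vocabulary "
                "and subword fallback is off"
            )
        return np.mean(vecs, axis=0)
    mat = model_or_encoder.encode(definition_text)
    if mat.shape[0] == 0:
        raise RepresentationError("definition produced no tokens")
    return mat.mean(axis=0)
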