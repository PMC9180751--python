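"""The two ICF coding models: classification and candidate selection.

*Classification* assigns a category by similarity to previously labeled
training instances: a multi-class Support Vector Machine over mention
representation vectors (one-vs-rest, linear kernel by default).

*Candidate selection* ranks the categories themselves: a feed-forward
network takes the mention representation together with each category's
definition embedding and produces a *conditional* category embedding —
a representation of the category conditioned on this specific mention.
Each conditional category embedding is compared with the mention vector by
cosine similarity, and the highest-scoring category is selected.  The
network depth/width schedule follows the representation mode: three
transformations of width equal to the mention dimension for static modes
(300 plain / 600 with the Action oracle at full embedding scale), one
transformation of width 768 for contextualized features.

Both coders only ever emit codes from their label set; ties break to the
first code in label-set order.  Training is deterministic given the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
from sklearn.svm import LinearSVC

from .corpus import AnnotatedCorpus
from .representations import MentionRepresentation, embed_definition, represent
from .schema import LabelSet, load_label_set


class CoderError(ValueError):
    pass


def _as_matrix(instances) -> tuple[np.ndarray, list[str], Optional[str]]:
    """Stack (representation, code) pairs; enforce uniform dimensionality."""
    if not instances:
        raise CoderError("no training instances")
    vecs, codes, mode = [], [], None
    for rep, code in instances:
        if isinstance(rep, MentionRepresentation):
            if mode is None:
                mode = rep.mode
            elif rep.mode != mode:
                raise CoderError(f"mixed representation modes: {mode} vs {rep.mode}")
            vecs.append(np.asarray(rep.vector, float))
        else:
            vecs.append(np.asarray(rep, float))
        codes.append(code)
    dims = {v.shape[0] for v in vecs}
    if len(dims) != 1:
        raise CoderError(f"mixed representation dimensions: {sorted(dims)}")
    return np.stack(vecs), codes, mode


def _rep_vector(representation) -> np.ndarray:
    if isinstance(representation, MentionRepresentation):
        return np.asarray(representation.vector, float)
    return np.asarray(representation, float)


# ---------------------------------------------------------------------------
# Classification coder (SVM)
# ---------------------------------------------------------------------------

@dataclass
class ClassifierConfig:
    C: float = 1.0
    loss: str = "squared_hinge"
    balanced: bool = False
    standardize: bool = True  # SVMs are scale-sensitive; embeddings are not unit-scaled
    max_iter: int = 5000
    seed: int = 1


class ClassifierCoder:
    def __init__(self, label_set: LabelSet, config: ClassifierConfig,
                 classes: Sequence[str], coef: np.ndarray, intercept: np.ndarray,
                 train_counts: dict[str, int],
                 scaler_mean: Optional[np.ndarray] = None,
                 scaler_scale: Optional[np.ndarray] = None):
        self.label_set = label_set
        self.config = config
        self.classes = [str(c) for c in classes]
        self.coef = np.ascontiguousarray(coef, float)
        self.intercept = np.ascontiguousarray(intercept, float)
        self.train_counts = dict(train_counts)
        self.scaler_mean = None if scaler_mean is None else np.asarray(scaler_mean, float)
        self.scaler_scale = None if scaler_scale is None else np.asarray(scaler_scale, float)

    @property
    def mode_dimension(self) -> int:
        return self.coef.shape[1]

    def decision_scores(self, x: np.ndarray) -> np.ndarray:
        raw = self.coef @ x + self.intercept
        if len(self.classes) == 2:
            # liblinear stores one hyperplane for binary problems
            return np.array([-raw[0], raw[0]])
        return raw

    def predict(self, representation) -> dict:
        x = _rep_vector(representation)
        if x.shape[0] != self.mode_dimension:
            raise CoderError(
                f"representation dim {x.shape[0]} != model dim {self.mode_dimension}"
            )
        if self.scaler_mean is not None:
            x = (x - self.scaler_mean) / self.scaler_scale
        scores = self.decision_scores(x)
        best = int(np.argmax(scores))
        return {"code": self.classes[best], "scores": dict(zip(self.classes, scores.tolist()))}

    # --- persistence ----------------------------------------------------
    def save(self, path: str) -> None:
        payload = {
            "kind": "classifier",
            "config": asdict(self.config),
            "domain_id": self.label_set.domain_id,
            "classes": self.classes,
            "coef": self.coef.tolist(),
            "intercept": self.intercept.tolist(),
            "train_counts": self.train_counts,
            "scaler_mean": None if self.scaler_mean is None else self.scaler_mean.tolist(),
            "scaler_scale": None if self.scaler_scale is None else self.scaler_scale.tolist(),
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path: str) -> "ClassifierCoder":
        with open(path, encoding="utf-8") as fh:
            p = json.load(fh)
        return cls(
            load_label_set(p["domain_id"]), ClassifierConfig(**p["config"]), p["classes"],
            np.array(p["coef"]), np.array(p["intercept"]), p["train_counts"],
            p.get("scaler_mean"), p.get("scaler_scale"),
        )


def train_classifier(instances, label_set: LabelSet,
                     config: Optional[ClassifierConfig] = None) -> ClassifierCoder:
    """Fit the SVM coder on (representation, code) pairs.

    Requires at least two distinct codes and a uniform representation mode;
    deterministic given ``config.seed``.
    """
    config = config or ClassifierConfig()
    X, codes, _ = _as_matrix(instances)
    for c in codes:
        if c not in label_set:
            raise CoderError(f"training label {c!r} not in label set {label_set.domain_id}")
    if len(set(codes)) < 2:
        raise CoderError("training data contains a single class; need >= 2 distinct codes")
    mean = scale = None
    if config.standardize:
        mean = X.mean(axis=0)
        scale = np.maximum(X.std(axis=0), 1e-8)
        X = (X - mean) / scale
    svm = LinearSVC(
        C=config.C,
        loss=config.loss,
        class_weight="balanced" if config.balanced else None,
        max_iter=config.max_iter,
        random_state=config.seed,
    )
    svm.fit(X, codes)
    coef, intercept = svm.coef_, svm.intercept_
    counts: dict[str, int] = {}
    for c in codes:
        counts[c] = counts.get(c, 0) + 1
    return ClassifierCoder(label_set, config, list(svm.classes_), coef, intercept, counts,
                           mean, scale)


def predict(coder: ClassifierCoder, representation) -> dict:
    return coder.predict(representation)


# ---------------------------------------------------------------------------
# Candidate selection coder (feed-forward net over definition embeddings)
# ---------------------------------------------------------------------------

@dataclass
class SelectorConfig:
    n_layers: Optional[int] = None   # default by mode: static -> 3, ctx -> 1
    hidden: Optional[int] = None     # default: mention representation dim
    activation: str = "relu"         # relu | linear
    init: str = "random"             # random | identity (pair identity with linear)
    lr: float = 0.01
    epochs: int = 100
    temperature: float = 0.1
    loss: str = "softmax_cosine"     # softmax_cosine | hinge
    hinge_margin: float = 0.2
    holdout_fraction: float = 0.1
    patience: int = 8
    batch_size: int = 64
    seed: int = 1


def default_n_layers(mode: Optional[str]) -> int:
    return 1 if (mode or "").startswith("ctx") else 3


class CandidateSelectorCoder:
    """Cosine ranker over network-conditioned category definition embeddings."""

    def __init__(self, label_set: LabelSet, definition_vectors: dict[str, np.ndarray],
                 rep_dim: int, config: Optional[SelectorConfig] = None,
                 mode: Optional[str] = None):
        self.label_set = label_set
        self.config = config or SelectorConfig()
        self.mode = mode
        missing = [c for c in label_set.codes if c not in definition_vectors]
        if missing:
            raise CoderError(f"missing definition vector(s) for code(s): {', '.join(missing)}")
        self.codes = list(label_set.codes)
        self.def_matrix = np.stack([np.asarray(definition_vectors[c], float) for c in self.codes])
        self.rep_dim = rep_dim
        d_def = self.def_matrix.shape[1]
        h = self.config.hidden or rep_dim
        L = self.config.n_layers or default_n_layers(mode)
        widths = [rep_dim + d_def] + [h] * (L - 1) + [rep_dim]
        rng = np.random.default_rng(self.config.seed)
        self.weights, self.biases = [], []
        for i in range(L):
            fan_in, fan_out = widths[i], widths[i + 1]
            if self.config.init == "identity":
                W = np.zeros((fan_in, fan_out))
                if i == 0:
                    # pass the definition part of the input through
                    if d_def > fan_out:
                        raise CoderError("identity init requires def dim <= output dim")
                    W[rep_dim : rep_dim + d_def, :d_def] = np.eye(d_def)
                else:
                    m = min(fan_in, fan_out)
                    W[:m, :m] = np.eye(m)
            else:
                W = rng.standard_normal((fan_in, fan_out)) * np.sqrt(2.0 / fan_in)
            self.weights.append(W)
            self.biases.append(np.zeros(fan_out))

    # --- forward ---------------------------------------------------------
    def _act(self, z: np.ndarray) -> np.ndarray:
        return np.maximum(z, 0.0) if self.config.activation == "relu" else z

    def _forward(self, X: np.ndarray, keep: bool = False):
        acts = [X]
        h = X
        for i, (W, b) in enumerate(zip(self.weights, self.biases)):
            z = h @ W + b
            h = self._act(z) if i < len(self.weights) - 1 else z
            if keep:
                acts.append(h)
        return (h, acts) if keep else h

    def conditional_embeddings(self, mention_vec: np.ndarray) -> np.ndarray:
        """(K, rep_dim) conditional category embeddings for one mention.

        Conditioning uses the unit-normalized mention vector (its direction),
        so cosine scores are invariant to positive rescaling of the input.
        """
        K = len(self.codes)
        unit = mention_vec / max(np.linalg.norm(mention_vec), 1e-12)
        X = np.concatenate(
            [np.broadcast_to(unit, (K, self.rep_dim)), self.def_matrix], axis=1
        )
        return self._forward(X)

    def cosine_scores(self, mention_vec: np.ndarray) -> np.ndarray:
        E = self.conditional_embeddings(mention_vec)
        mn = np.linalg.norm(mention_vec)
        en = np.linalg.norm(E, axis=1)
        return (E @ mention_vec) / (mn * np.maximum(en, 1e-12))

    def select(self, representation) -> dict:
        x = _rep_vector(representation)
        if x.shape[0] != self.rep_dim:
            raise CoderError(f"representation dim {x.shape[0]} != model dim {self.rep_dim}")
        if np.linalg.norm(x) == 0:
            raise CoderError("zero-vector representation: cosine similarity undefined")
        scores = self.cosine_scores(x)
        best = int(np.argmax(scores))  # argmax takes the first max: label-set order
        return {"code": self.codes[best], "scores": dict(zip(self.codes, scores.tolist()))}

    # alias so both coders expose .predict
    predict = select

    # --- training --------------------------------------------------------
    def _loss_grad(self, M: np.ndarray, y: np.ndarray):
        """Mean loss and parameter gradients for a batch of mentions M (B, d)
        with gold indices y."""
        B, K = M.shape[0], len(self.codes)
        cfg = self.config
        M = M / np.maximum(np.linalg.norm(M, axis=1, keepdims=True), 1e-12)
        X = np.concatenate(
            [np.repeat(M, K, axis=0), np.tile(self.def_matrix, (B, 1))], axis=1
        )
        E, acts = self._forward(X, keep=True)  # (B*K, d)
        Mrep = np.repeat(M, K, axis=0)
        mn = np.linalg.norm(Mrep, axis=1)
        en = np.maximum(np.linalg.norm(E, axis=1), 1e-12)
        dots = np.einsum("ij,ij->i", Mrep, E)
        s = (dots / (mn * en)).reshape(B, K)

        if cfg.loss == "softmax_cosine":
            z = s / cfg.temperature
            z -= z.max(axis=1, keepdims=True)
            p = np.exp(z)
            p /= p.sum(axis=1, keepdims=True)
            loss = -np.mean(np.log(p[np.arange(B), y] + 1e-12))
            ds = p.copy()
            ds[np.arange(B), y] -= 1.0
            ds /= cfg.temperature * B
        else:  # pairwise hinge against the gold category
            gold = s[np.arange(B), y][:, None]
            margin = np.maximum(0.0, cfg.hinge_margin - gold + s)
            margin[np.arange(B), y] = 0.0
            loss = margin.sum() / B
            ds = (margin > 0).astype(float)
            ds[np.arange(B), y] = -ds.sum(axis=1)
            ds /= B

        ds_flat = ds.reshape(-1)
        # d cos / d E
        dE = (Mrep / (mn * en)[:, None] - (dots / (mn * en**3))[:, None] * E) * ds_flat[:, None]

        grads_W = [np.zeros_like(W) for W in self.weights]
        grads_b = [np.zeros_like(b) for b in self.biases]
        delta = dE
        for i in reversed(range(len(self.weights))):
            a_prev = acts[i]
            if i < len(self.weights) - 1 and self.config.activation == "relu":
                delta = delta * (acts[i + 1] > 0)
            grads_W[i] = a_prev.T @ delta
            grads_b[i] = delta.sum(axis=0)
            delta = delta @ self.weights[i].T
        return loss, grads_W, grads_b

    def _evaluate_loss(self, M: np.ndarray, y: np.ndarray) -> float:
        return self._loss_grad(M, y)[0]

    def fit(self, instances) -> list[float]:
        """Train on (representation, code) pairs; returns the loss curve.

        Adam optimizer; early stopping on a held-out fraction of the
        training instances (best weights restored).
        """
        cfg = self.config
        M, codes, mode = _as_matrix(instances)
        if mode is not None and self.mode is None:
            self.mode = mode
        if M.shape[1] != self.rep_dim:
            raise CoderError(f"instance dim {M.shape[1]} != selector dim {self.rep_dim}")
        code_index = {c: i for i, c in enumerate(self.codes)}
        try:
            y = np.array([code_index[c] for c in codes])
        except KeyError as e:
            raise CoderError(f"training label {e.args[0]!r} not in label set") from None

        rng = np.random.default_rng(cfg.seed)
        order = rng.permutation(len(y))
        n_hold = max(1, int(len(y) * cfg.holdout_fraction)) if len(y) >= 10 else 0
        hold, train = order[:n_hold], order[n_hold:]
        Mt, yt = M[train], y[train]
        Mh, yh = (M[hold], y[hold]) if n_hold else (Mt, yt)

        mW = [np.zeros_like(W) for W in self.weights]
        vW = [np.zeros_like(W) for W in self.weights]
        mb = [np.zeros_like(b) for b in self.biases]
        vb = [np.zeros_like(b) for b in self.biases]
        b1, b2, eps = 0.9, 0.999, 1e-8
        t = 0

        best_loss = np.inf
        best_weights = None
        bad_epochs = 0
        curve = []
        for epoch in range(cfg.epochs):
            perm = rng.permutation(len(yt))
            epoch_loss = 0.0
            n_batches = 0
            for start in range(0, len(yt), cfg.batch_size):
                idx = perm[start : start + cfg.batch_size]
                loss, gW, gb = self._loss_grad(Mt[idx], yt[idx])
                epoch_loss += loss
                n_batches += 1
                t += 1
                for i in range(len(self.weights)):
                    mW[i] = b1 * mW[i] + (1 - b1) * gW[i]
                    vW[i] = b2 * vW[i] + (1 - b2) * gW[i] ** 2
                    mb[i] = b1 * mb[i] + (1 - b1) * gb[i]
                    vb[i] = b2 * vb[i] + (1 - b2) * gb[i] ** 2
                    lr_t = cfg.lr * np.sqrt(1 - b2**t) / (1 - b1**t)
                    self.weights[i] -= lr_t * mW[i] / (np.sqrt(vW[i]) + eps)
                    self.biases[i] -= lr_t * mb[i] / (np.sqrt(vb[i]) + eps)
            curve.append(epoch_loss / max(n_batches, 1))
            hold_loss = self._evaluate_loss(Mh, yh)
            if hold_loss < best_loss - 1e-6:
                best_loss = hold_loss
                best_weights = ([W.copy() for W in self.weights], [b.copy() for b in self.biases])
                bad_epochs = 0
            else:
                bad_epochs += 1
                if bad_epochs >= cfg.patience:
                    break
        if best_weights is not None:
            self.weights, self.biases = best_weights
        return curve

    # --- persistence ----------------------------------------------------
    def save(self, path: str) -> None:
        payload = {
            "kind": "selector",
            "config": asdict(self.config),
            "domain_id": self.label_set.domain_id,
            "mode": self.mode,
            "rep_dim": self.rep_dim,
            "codes": self.codes,
            "def_matrix": self.def_matrix.tolist(),
            "weights": [W.tolist() for W in self.weights],
            "biases": [b.tolist() for b in self.biases],
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path: str) -> "CandidateSelectorCoder":
        with open(path, encoding="utf-8") as fh:
            p = json.load(fh)
        label_set = load_label_set(p["domain_id"])
        defs = {c: np.array(v) for c, v in zip(p["codes"], p["def_matrix"])}
        coder = cls(label_set, defs, p["rep_dim"], SelectorConfig(**p["config"]), p["mode"])
        coder.weights = [np.array(W) for W in p["weights"]]
        coder.biases = [np.array(b) for b in p["biases"]]
        return coder


def train_selector(instances, definition_vectors: dict[str, np.ndarray],
                   label_set: LabelSet, config: Optional[SelectorConfig] = None
                   ) -> CandidateSelectorCoder:
    """Train the candidate-selection network; see
    :class:`CandidateSelectorCoder`."""
    M, _, mode = _as_matrix(instances)
    coder = CandidateSelectorCoder(label_set, definition_vectors, M.shape[1], config, mode)
    coder.loss_curve = coder.fit(instances)
    return coder


def select(coder: CandidateSelectorCoder, representation) -> dict:
    return coder.select(representation)


# ---------------------------------------------------------------------------
# Corpus -> training instances
# ---------------------------------------------------------------------------

@dataclass
class CodingInstance:
    mention_id: str
    doc_id: str
    representation: MentionRepresentation
    gold: str


def build_instances(corpus: AnnotatedCorpus, mode: str, model_or_encoder,
                    label_set: Optional[LabelSet] = None) -> list[CodingInstance]:
    """One coding instance per gold Action component.

    In non-oracle modes every Action of a multi-Action mention shares the
    mention-level representation (with its own label), preserving instance
    counts; in oracle modes each Action contributes its own span.  Mentions
    without Actions carry no labels and are skipped.
    """
    label_set = label_set or load_label_set(corpus.domain_id)
    docs = {d.doc_id: d for d in corpus.documents}
    out = []
    for m in corpus.mentions:
        if not m.actions:
            continue
        text = m.text(docs[m.doc_id])
        shared = None
        if not mode.endswith("_oracle"):
            shared = represent(text, None, mode, model_or_encoder)
        for a in m.actions:
            if mode.endswith("_oracle"):
                rel = (a.span.start - m.span.start, a.span.end - m.span.start)
                rep = represent(text, rel, mode, model_or_encoder)
            else:
                rep = shared
            out.append(CodingInstance(m.mention_id, m.doc_id, rep, a.label))
    return out


def definition_vectors_for(label_set: LabelSet, model_or_encoder) -> dict[str, np.ndarray]:
    """Embed every category definition in the label set."""
    return {c.code: embed_definition(c.definition_text, model_or_encoder) for c in label_set}


def write_predictions(path: str, instances: Sequence[CodingInstance],
                      results: Sequence[dict], top_k: int = 3) -> None:
    """TSV audit trail: instance id, gold, predicted, top-k scores."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("mention_id\tdoc_id\tgold\tpredicted\ttop_scores\n")
        for inst, res in zip(instances, results):
            top = sorted(res["scores"].items(), key=lambda kv: -kv[1])[:top_k]
            top_s = ",".join(f"{c}:{s:.4f}" for c, s in top)
            fh.write(f"{inst.mention_id}\t{inst.doc_id}\t{inst.gold}\t{res['code']}\t{top_s}\n")
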