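"""Synthetic gold-annotated corpora with the statistical shape of the study data.

Real disability-claim documents cannot be shared, so every other module is
exercised on generated corpora that emulate the published dataset structure:
per-category Action frequencies (heavily skewed; e.g. d570 alone accounts
for 43.6% of Self-Care/Domestic Life Actions), a geometric number of
mentions per document, a small fraction of mentions with no Action
component (5.4% Mobility / 3.4% Self-Care/Domestic Life), multi-Action
mentions, optional Assistance/Quantification phrases, document-level
grouping by claimant, and OCR-style character noise.

Mentions are rendered from per-category phrase templates (shipped as
editable JSON).  Template markup: ``<a>...</a>`` wraps the Action phrase
(``<a neg>`` for negated Actions of the d570-scope labels), ``<s>``
Assistance, ``<q>`` Quantification; every rendered slot becomes a component
with exact character offsets.  Action vocabulary is category-specific by
default; ``shared_vocab_fraction`` mixes a common phrase pool into mentions
to probe confusable regimes.

What this generator does NOT emulate: real clinical syntax and discourse,
misspellings beyond the OCR confusion table, category boundary ambiguity,
or annotator disagreement.  Recovery results on synthetic corpora therefore
bound pipeline correctness, not real-data accuracy.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

import numpy as np

from . import textprep
from .corpus import (
    ActionComponent,
    ActivityMention,
    AnnotatedCorpus,
    AssistanceComponent,
    Document,
    QuantificationComponent,
    Span,
)
from .schema import load_label_set

NEGATION_PROB = 0.15


def _study_counts() -> dict:
    raw = resources.files("icfcoder.data").joinpath("study_counts.json").read_text("utf-8")
    return json.loads(raw)


def study_category_proportions(domain_id: str) -> dict[str, float]:
    """Per-category Action proportions as printed in the dataset tables."""
    counts = _study_counts()[domain_id]["categories"]
    total = sum(v["count"] for v in counts.values())
    return {c: v["count"] / total for c, v in counts.items()}


def uniform_proportions(domain_id: str) -> dict[str, float]:
    codes = load_label_set(domain_id).codes
    return {c: 1.0 / len(codes) for c in codes}


@dataclass
class SyntheticConfig:
    """Generation parameters; defaults reproduce the published dataset shape."""

    domain_id: str = "MOBILITY"
    n_documents: int = 100
    seed: int = 1
    category_proportions: Optional[dict[str, float]] = None  # default: study tables
    mentions_per_doc_mean: Optional[float] = None  # default 9.8 Mobility / 12.1 SC/DL
    p_empty_doc: Optional[float] = None           # default 0.131 / 0.134
    p_zero_action: Optional[float] = None         # default 0.054 / 0.034
    multi_action_extra_mean: Optional[float] = None  # default 0.367 / 0.207
    ocr_noise_rate: float = 0.0
    doc_type_mix: Optional[dict[str, float]] = None  # default all-CE / half-half
    shared_vocab_fraction: float = 0.0

    def resolved(self) -> "SyntheticConfig":
        s = _study_counts()[self.domain_id]
        out = SyntheticConfig(**{**self.__dict__})
        if out.category_proportions is None:
            out.category_proportions = study_category_proportions(self.domain_id)
        if out.mentions_per_doc_mean is None:
            out.mentions_per_doc_mean = s["n_mentions"] / s["n_documents_with_mentions"]
        if out.p_empty_doc is None:
            out.p_empty_doc = 1.0 - s["n_documents_with_mentions"] / s["n_documents"]
        if out.p_zero_action is None:
            out.p_zero_action = 1.0 - s["n_mentions_with_action"] / s["n_mentions"]
        if out.multi_action_extra_mean is None:
            out.multi_action_extra_mean = s["n_actions"] / s["n_mentions_with_action"] - 1.0
        if out.doc_type_mix is None:
            out.doc_type_mix = {"CE": 1.0} if self.domain_id == "MOBILITY" else {"CE": 0.5, "EHR": 0.5}
        out.validate()
        return out

    def validate(self) -> None:
        if self.category_proportions is not None:
            total = sum(self.category_proportions.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"category proportions sum to {total}, not 1")
        for name in ("p_empty_doc", "p_zero_action", "ocr_noise_rate", "shared_vocab_fraction"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")


# ---------------------------------------------------------------------------
# Lexicon
# ---------------------------------------------------------------------------

_MARK_RE = re.compile(r"<(a|s|q)( neg)?>(.*?)</\1>", re.DOTALL)


def render_template(template: str) -> tuple[str, list[tuple[str, int, int, bool]]]:
    """Strip markers; return (text, [(kind, start, end, negated), ...])."""
    out = []
    spans = []
    pos = 0
    cursor = 0
    for m in _MARK_RE.finditer(template):
        out.append(template[cursor : m.start()])
        pos += m.start() - cursor
        body = m.group(3)
        spans.append((m.group(1), pos, pos + len(body), m.group(2) is not None))
        out.append(body)
        pos += len(body)
        cursor = m.end()
    out.append(template[cursor:])
    return "".join(out), spans


@dataclass
class CategoryLexicon:
    domain_id: str
    categories: dict[str, dict] = field(default_factory=dict)
    filler_sentences: list[str] = field(default_factory=list)
    no_action_mentions: list[str] = field(default_factory=list)
    shared_phrases: list[str] = field(default_factory=list)

    def validate_against(self, domain_id: str) -> None:
        label_set = load_label_set(domain_id)
        missing = [c for c in label_set.codes if c not in self.categories]
        if missing:
            raise ValueError(f"lexicon missing categories: {', '.join(missing)}")
        for code in label_set.codes:
            n = len(self.categories[code].get("templates", []))
            if n < 5:
                raise ValueError(f"lexicon category {code} has {n} templates; >= 5 required")

    def templates(self, code: str, negated: bool = False) -> list[str]:
        entry = self.categories[code]
        if negated:
            return entry.get("negated_templates", []) or entry["templates"]
        return entry["templates"]

    def all_template_texts(self) -> list[str]:
        texts = []
        for entry in self.categories.values():
            for t in entry.get("templates", []) + entry.get("negated_templates", []):
                texts.append(render_template(t)[0])
        return texts


def load_lexicon(domain_id: str) -> CategoryLexicon:
    raw = resources.files("icfcoder.data").joinpath("lexicons.json").read_text("utf-8")
    data = json.loads(raw)[domain_id]
    lex = CategoryLexicon(
        domain_id=domain_id,
        categories=data["categories"],
        filler_sentences=data["filler_sentences"],
        no_action_mentions=data["no_action_mentions"],
        shared_phrases=data.get("shared_phrases", []),
    )
    lex.validate_against(domain_id)
    return lex


# ---------------------------------------------------------------------------
# Corpus generation
# ---------------------------------------------------------------------------

def _sample_mention(cfg: SyntheticConfig, lex: CategoryLexicon, rng, codes, probs):
    """Render one mention; returns (text, actions, assists, quants) with
    mention-relative offsets."""
    fragments = []
    actions, assists, quants = [], [], []
    n_actions = 1 + rng.geometric(1.0 / (1.0 + cfg.multi_action_extra_mean)) - 1
    offset = 0
    for i in range(n_actions):
        code = codes[rng.choice(len(codes), p=probs)]
        negated = False
        entry = lex.categories[code]
        if entry.get("negated_templates") and rng.random() < NEGATION_PROB:
            negated = True
        pool = lex.templates(code, negated)
        text, spans = render_template(pool[rng.choice(len(pool))])
        if i > 0:
            offset += len(" and ")
        for kind, s, e, neg in spans:
            if kind == "a":
                actions.append((code, s + offset, e + offset, neg or negated))
            elif kind == "s":
                assists.append((s + offset, e + offset))
            else:
                quants.append((s + offset, e + offset))
        fragments.append(text)
        offset += len(text)
    text = " and ".join(fragments)
    if cfg.shared_vocab_fraction and rng.random() < cfg.shared_vocab_fraction:
        text = text + " " + lex.shared_phrases[rng.choice(len(lex.shared_phrases))]
    return text, actions, assists, quants


def generate_corpus(config: SyntheticConfig, lexicon: Optional[CategoryLexicon] = None) -> AnnotatedCorpus:
    """Generate a fully valid annotated corpus; deterministic given the seed."""
    cfg = config.resolved()
    lex = lexicon or load_lexicon(cfg.domain_id)
    lex.validate_against(cfg.domain_id)
    rng = np.random.default_rng(cfg.seed)
    codes = [c for c in cfg.category_proportions]
    probs = np.array([cfg.category_proportions[c] for c in codes])
    probs = probs / probs.sum()
    type_names = sorted(cfg.doc_type_mix)
    type_probs = np.array([cfg.doc_type_mix[t] for t in type_names], float)
    type_probs /= type_probs.sum()

    documents, mentions = [], []
    mention_serial = 0
    for i in range(cfg.n_documents):
        doc_id = f"doc{i:05d}"
        doc_type = type_names[rng.choice(len(type_names), p=type_probs)]
        n_m = 0 if rng.random() < cfg.p_empty_doc else int(rng.geometric(1.0 / cfg.mentions_per_doc_mean))
        parts: list[str] = []
        pos = 0

        def append_sentence(s: str) -> int:
            nonlocal pos
            start = pos
            parts.append(s + ". ")
            pos += len(s) + 2
            return start

        append_sentence(lex.filler_sentences[rng.choice(len(lex.filler_sentences))])
        for _ in range(n_m):
            mention_serial += 1
            if rng.random() < cfg.p_zero_action:
                text = lex.no_action_mentions[rng.choice(len(lex.no_action_mentions))]
                start = append_sentence(text)
                mentions.append(
                    ActivityMention(f"m{mention_serial:06d}", doc_id, Span(start, start + len(text)))
                )
            else:
                text, acts, assists, quants = _sample_mention(cfg, lex, rng, codes, probs)
                start = append_sentence(text)
                mentions.append(
                    ActivityMention(
                        f"m{mention_serial:06d}",
                        doc_id,
                        Span(start, start + len(text)),
                        actions=[
                            ActionComponent(Span(start + s, start + e), code, neg)
                            for code, s, e, neg in acts
                        ],
                        assistance=[
                            AssistanceComponent(Span(start + s, start + e), text[s:e])
                            for s, e in assists
                        ],
                        quantifications=[
                            QuantificationComponent(Span(start + s, start + e), text[s:e])
                            for s, e in quants
                        ],
                    )
                )
            if rng.random() < 0.5:
                append_sentence(lex.filler_sentences[rng.choice(len(lex.filler_sentences))])
        documents.append(Document(doc_id, f"clm{i:05d}", doc_type, "".join(parts).rstrip()))

    corpus = AnnotatedCorpus(
        domain_id=cfg.domain_id,
        documents=documents,
        mentions=mentions,
        provenance={"generator": "icfcoder.synthetic", "seed": str(cfg.seed)},
    )
    if cfg.ocr_noise_rate > 0:
        corpus = inject_ocr_noise(corpus, cfg.ocr_noise_rate, cfg.seed + 1)
    return corpus


# ---------------------------------------------------------------------------
# OCR noise
# ---------------------------------------------------------------------------

#: character confusions typical of OCR output
OCR_CONFUSIONS = {
    "l": "1", "1": "l", "O": "0", "0": "O", "o": "0", "S": "5", "5": "S",
    "B": "8", "e": "c", "a": "o", "n": "r", "t": "f", "i": ";", "m": "rn",
}
_INSERTIONS = ". ,'-"


def _noisy_text(text: str, rate: float, rng, protected_spans) -> tuple[str, np.ndarray, int]:
    """Mutate characters at the given per-character rate.

    Returns (new_text, newpos, n_mutations) where newpos[i] is the new
    offset of old offset i (length n+1).  No annotated span is ever fully
    deleted: a deletion that would empty a span is demoted to substitution.
    """
    n = len(text)
    ops = np.full(n, "keep", dtype=object)
    hit = rng.random(n) < rate
    kinds = rng.choice(["sub", "del", "ins"], size=n, p=[0.7, 0.15, 0.15])
    ops[hit] = kinds[hit]
    # protect spans from complete deletion
    for (s, e) in protected_spans:
        idx = np.arange(s, e)
        if len(idx) and np.all(ops[idx] == "del"):
            ops[idx[0]] = "sub"

    out = []
    newpos = np.zeros(n + 1, dtype=np.int64)
    n_mut = 0
    length = 0
    for i, ch in enumerate(text):
        newpos[i] = length
        op = ops[i]
        if op == "keep":
            out.append(ch)
            length += 1
        elif op == "sub":
            sub = OCR_CONFUSIONS.get(ch)
            if sub is None:
                sub = _INSERTIONS[int(rng.integers(len(_INSERTIONS)))]
            out.append(sub)
            length += len(sub)
            n_mut += 1
        elif op == "del":
            n_mut += 1
        else:  # ins: keep the char, then insert one after it
            ins = _INSERTIONS[int(rng.integers(len(_INSERTIONS)))]
            out.append(ch + ins)
            length += 1 + len(ins)
            n_mut += 1
    newpos[n] = length
    return "".join(out), newpos, n_mut


def inject_ocr_noise(corpus: AnnotatedCorpus, rate: float, seed: int = 1) -> AnnotatedCorpus:
    """Return a copy of the corpus with OCR-style character noise.

    Substitutions/deletions/insertions are drawn from a confusion table at
    the given per-character rate; every annotation offset is remapped so all
    spans remain consistent with the mutated text.
    """
    if not (0.0 <= rate <= 1.0):
        raise ValueError(f"noise rate {rate} outside [0, 1]")
    if rate == 0.0:
        return corpus
    rng = np.random.default_rng(seed)
    new_docs, new_mentions = [], []
    total_mut = 0
    by_doc = {d.doc_id: [] for d in corpus.documents}
    for m in corpus.mentions:
        by_doc[m.doc_id].append(m)
    for d in corpus.documents:
        protected = []
        for m in by_doc[d.doc_id]:
            protected.append((m.span.start, m.span.end))
            for comp in m.actions + m.assistance + m.quantifications:
                protected.append((comp.span.start, comp.span.end))
        text, newpos, n_mut = _noisy_text(d.text, rate, rng, protected)
        total_mut += n_mut
        new_docs.append(Document(d.doc_id, d.claimant_id, d.doc_type, text))

        def remap(s: Span) -> Span:
            return Span(int(newpos[s.start]), int(newpos[s.end]))

        for m in by_doc[d.doc_id]:
            new_mentions.append(
                ActivityMention(
                    m.mention_id,
                    m.doc_id,
                    remap(m.span),
                    actions=[ActionComponent(remap(a.span), a.label, a.negated) for a in m.actions],
                    assistance=[
                        AssistanceComponent(remap(c.span), text[newpos[c.span.start]: newpos[c.span.end]])
                        for c in m.assistance
                    ],
                    quantifications=[
                        QuantificationComponent(remap(c.span), text[newpos[c.span.start]: newpos[c.span.end]])
                        for c in m.quantifications
                    ],
                )
            )
    prov = dict(corpus.provenance)
    prov["ocr_noise_rate"] = str(rate)
    prov["ocr_mutations"] = str(total_mut)
    return AnnotatedCorpus(corpus.domain_id, new_docs, new_mentions, prov)


# ---------------------------------------------------------------------------
# Embedding-training corpus
# ---------------------------------------------------------------------------

def generate_embedding_corpus(config: SyntheticConfig, path: str,
                              lexicon: Optional[CategoryLexicon] = None,
                              template_repeats: int = 3) -> int:
    """Write a normalized one-sentence-per-line corpus covering the lexicon
    vocabulary; returns the line count (>= n_documents)."""
    cfg = config.resolved()
    lex = lexicon or load_lexicon(cfg.domain_id)
    texts = []
    for _ in range(template_repeats):
        texts.extend(lex.all_template_texts())
        texts.extend(lex.no_action_mentions)
        texts.extend(lex.filler_sentences)
        texts.extend(lex.shared_phrases)
    corpus = generate_corpus(SyntheticConfig(**{**cfg.__dict__, "ocr_noise_rate": 0.0}), lex)
    texts.extend(d.text for d in corpus.documents)
    return textprep.write_embedding_corpus(texts, path)


# ---------------------------------------------------------------------------
# Deterministic fixture realizing the published dataset summary counts
# ---------------------------------------------------------------------------

def study_shaped_fixture(domain_id: str):
    """Synthetic stand-in corpus realizing the published dataset counts exactly.

    Builds a deterministic corpus whose document / mention / Action totals,
    per-category Action counts and document-level train/test assignment
    reproduce the study's printed summary tables, with template-rendered
    text standing in for the unshareable source documents.  Returns
    ``(corpus, assignment)`` where ``assignment`` maps doc_id to
    "train"/"test" for the documents used in the experiments.

    Bookkeeping detail mirrored from the published tables: for Mobility the
    annotated documents with mentions (251) exceed the train+test documents
    (203+45); the surplus documents carry only mentions without Action
    components and stay outside the split.
    """
    s = _study_counts()[domain_id]
    lex = load_lexicon(domain_id)
    n_zero = s["n_mentions"] - s["n_mentions_with_action"]
    merges = s["n_actions"] - s["n_mentions_with_action"]
    n_unassigned_with = (
        s["n_documents_with_mentions"] - s["n_train_documents"] - s["n_test_documents"]
    )
    n_empty = s["n_documents"] - s["n_documents_with_mentions"]

    # (code, side) action groups in table order; carve multi-Action mentions
    groups = []
    for code, v in s["categories"].items():
        groups.append([code, "train", v["train"], 0])
        groups.append([code, "test", v["test"], 0])
    remaining = merges
    for g in groups:
        if remaining <= 0:
            break
        take = min(remaining, g[2] // 2)
        g[3] = take
        remaining -= take
    assert remaining == 0, "cannot realize multi-Action mention count"

    documents: list[Document] = []
    mentions: list[ActivityMention] = []
    assignment: dict[str, str] = {}
    doc_parts: dict[str, list] = {}
    doc_pos: dict[str, int] = {}

    def new_doc(doc_id: str, side: Optional[str]) -> None:
        documents.append(Document(doc_id, f"clm-{doc_id}", "CE", ""))
        doc_parts[doc_id] = []
        doc_pos[doc_id] = 0
        if side:
            assignment[doc_id] = side

    side_docs = {"train": [], "test": []}
    for i in range(s["n_train_documents"]):
        doc_id = f"{domain_id[:3].lower()}-train-{i:04d}"
        new_doc(doc_id, "train")
        side_docs["train"].append(doc_id)
    for i in range(s["n_test_documents"]):
        doc_id = f"{domain_id[:3].lower()}-test-{i:04d}"
        new_doc(doc_id, "test")
        side_docs["test"].append(doc_id)
    extra_docs = []
    for i in range(n_unassigned_with):
        doc_id = f"{domain_id[:3].lower()}-extra-{i:04d}"
        new_doc(doc_id, None)
        extra_docs.append(doc_id)

    def add_mention(doc_id: str, codes_for_mention: Optional[list[str]], serial: int) -> None:
        pos = doc_pos[doc_id]
        if codes_for_mention is None:
            pool = lex.no_action_mentions
            text = pool[serial % len(pool)]
            acts = []
        else:
            fragments, acts, offset = [], [], 0
            for j, code in enumerate(codes_for_mention):
                pool = lex.templates(code)
                t, spans = render_template(pool[serial % len(pool)])
                if j > 0:
                    offset += len(" and ")
                acts.extend(
                    (code, a + offset, b + offset) for kind, a, b, _neg in spans if kind == "a"
                )
                fragments.append(t)
                offset += len(t)
            text = " and ".join(fragments)
        doc_parts[doc_id].append(text + ". ")
        mentions.append(
            ActivityMention(
                f"{domain_id[:3].lower()}-m{serial:06d}",
                doc_id,
                Span(pos, pos + len(text)),
                actions=[ActionComponent(Span(pos + a, pos + b), code) for code, a, b in acts],
            )
        )
        doc_pos[doc_id] += len(text) + 2

    serial = 0
    rr = {"train": 0, "test": 0}
    for code, side, count, n_double in groups:
        specs = [[code, code]] * n_double + [[code]] * (count - 2 * n_double)
        for codes_for_mention in specs:
            docs = side_docs[side]
            doc_id = docs[rr[side] % len(docs)]
            rr[side] += 1
            add_mention(doc_id, codes_for_mention, serial)
            serial += 1

    # zero-Action mentions: surplus documents first, rest spread over the split
    zero_targets = list(extra_docs)
    all_assigned = side_docs["train"] + side_docs["test"]
    for i in range(n_zero - len(extra_docs)):
        zero_targets.append(all_assigned[i % len(all_assigned)])
    for doc_id in zero_targets[:n_zero]:
        add_mention(doc_id, None, serial)
        serial += 1

    for i in range(n_empty):
        doc_id = f"{domain_id[:3].lower()}-empty-{i:04d}"
        new_doc(doc_id, None)
        doc_parts[doc_id].append(lex.filler_sentences[i % len(lex.filler_sentences)] + ". ")

    for d in documents:
        d.text = "".join(doc_parts[d.doc_id]).rstrip()
    corpus = AnnotatedCorpus(
        domain_id=domain_id,
        documents=documents,
        mentions=mentions,
        provenance={"generator": "icfcoder.synthetic.study_shaped_fixture"},
    )
    return corpus, assignment
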