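"""Span-level data model and I/O for corpora annotated with activity mentions.

An *activity mention* is a self-contained span of document text describing a
person's functioning within the Mobility or Self-Care/Domestic Life chapters
of the ICF Activities and Participation domain.  Inside a mention, zero or
more *Action* components name the specific activities performed (each Action
carries the ICF category label), and optional *Assistance* (device, person,
structure) and *Quantification* (distance, time, count) components capture
how the activity was performed.

Offsets are 0-based half-open character offsets into the document text, the
usual standoff convention.

Two on-disk dialects are supported:

* ``json`` — a single file mirroring the data model 1:1.
* ``standoff`` — a directory with one ``.txt`` + one ``.ann`` per document
  plus a ``corpus.json`` metadata file.  The ``.ann`` dialect is brat-like:
  mentions and components are typed text-bound annotations (``T`` lines),
  ``HasComponent`` relations (``R`` lines) attach components to their
  mention, ``Category`` / ``Negated`` attributes (``A`` lines) carry the
  label and negation, and a note line preserves the mention id.

This module also provides span-level inter-annotator agreement (F-1), the
corpus-statistics report (document / mention / Action counts, per-category
frequencies and train/test splits), and an advisory exclusion linter that
flags annotations matching hypothetical / provider-education / work-duty
cues, which the annotation guidelines exclude.
"""

from __future__ import annotations

import json
import os
import re
from collections import Counter
from dataclasses import dataclass, field, asdict
from typing import Iterable, Optional

from .schema import LabelSet, load_label_set

DOC_TYPES = ("CE", "EHR")
#: labels for which negation is captured on the Action component
NEGATABLE_CODES = ("d570", "MANAGE_MED", "THERAPY")


class CorpusValidationError(ValueError):
    def __init__(self, problems: list[str]):
        self.problems = list(problems)
        super().__init__("corpus validation failed:\n" + "\n".join(self.problems))


@dataclass(frozen=True, order=True)
class Span:
    """0-based half-open character interval."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid span [{self.start}, {self.end})")

    def contains(self, other: "Span") -> bool:
        return self.start <= other.start and other.end <= self.end

    def overlaps(self, other: "Span") -> bool:
        return self.start < other.end and other.start < self.end


@dataclass
class Document:
    doc_id: str
    claimant_id: str
    doc_type: str
    text: str


@dataclass
class ActionComponent:
    span: Span
    label: str
    negated: bool = False


@dataclass
class AssistanceComponent:
    span: Span
    text: str = ""


@dataclass
class QuantificationComponent:
    span: Span
    text: str = ""


@dataclass
class ActivityMention:
    mention_id: str
    doc_id: str
    span: Span
    actions: list[ActionComponent] = field(default_factory=list)
    assistance: list[AssistanceComponent] = field(default_factory=list)
    quantifications: list[QuantificationComponent] = field(default_factory=list)

    def text(self, document: Document) -> str:
        return document.text[self.span.start : self.span.end]


@dataclass
class AnnotatedCorpus:
    domain_id: str
    documents: list[Document] = field(default_factory=list)
    mentions: list[ActivityMention] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def document(self, doc_id: str) -> Document:
        for d in self.documents:
            if d.doc_id == doc_id:
                return d
        raise KeyError(doc_id)

    def mentions_of(self, doc_id: str) -> list[ActivityMention]:
        return [m for m in self.mentions if m.doc_id == doc_id]


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def validate_corpus(corpus: AnnotatedCorpus, label_set: Optional[LabelSet] = None) -> None:
    """Raise :class:`CorpusValidationError` listing every integrity problem."""
    if label_set is None:
        label_set = load_label_set(corpus.domain_id)
    problems: list[str] = []

    docs: dict[str, Document] = {}
    seen_pairs = set()
    for d in corpus.documents:
        if d.doc_id in docs:
            problems.append(f"document {d.doc_id}: duplicate doc_id")
        docs[d.doc_id] = d
        if not d.text:
            problems.append(f"document {d.doc_id}: empty text")
        if d.doc_type not in DOC_TYPES:
            problems.append(f"document {d.doc_id}: doc_type {d.doc_type!r} not in {DOC_TYPES}")
        pair = (d.claimant_id, d.doc_type)
        if pair in seen_pairs:
            problems.append(
                f"document {d.doc_id}: second {d.doc_type} document for claimant {d.claimant_id}"
            )
        seen_pairs.add(pair)

    seen_mentions = set()
    for m in corpus.mentions:
        mid = m.mention_id
        if mid in seen_mentions:
            problems.append(f"mention {mid}: duplicate mention_id")
        seen_mentions.add(mid)
        doc = docs.get(m.doc_id)
        if doc is None:
            problems.append(f"mention {mid}: references unknown document {m.doc_id}")
            continue
        if m.span.end > len(doc.text):
            problems.append(f"mention {mid}: span end {m.span.end} > text length {len(doc.text)}")
            continue
        for kind, comps in (
            ("action", m.actions),
            ("assistance", m.assistance),
            ("quantification", m.quantifications),
        ):
            for i, comp in enumerate(comps):
                if not m.span.contains(comp.span):
                    problems.append(f"mention {mid}: {kind} component {i} outside mention span")
        for i, a in enumerate(m.actions):
            if a.label not in label_set:
                problems.append(
                    f"mention {mid}: action {i} label {a.label!r} not in label set "
                    f"{label_set.domain_id}"
                )
            elif a.negated and a.label not in NEGATABLE_CODES:
                problems.append(
                    f"mention {mid}: action {i} negated but label {a.label} is outside "
                    f"the negation scope {NEGATABLE_CODES}"
                )

    if problems:
        raise CorpusValidationError(problems)


# ---------------------------------------------------------------------------
# JSON dialect
# ---------------------------------------------------------------------------

def _span_to_obj(s: Span) -> dict:
    return {"start": s.start, "end": s.end}


def corpus_to_obj(corpus: AnnotatedCorpus) -> dict:
    return {
        "domain_id": corpus.domain_id,
        "provenance": dict(corpus.provenance),
        "documents": [asdict(d) for d in corpus.documents],
        "mentions": [
            {
                "mention_id": m.mention_id,
                "doc_id": m.doc_id,
                "span": _span_to_obj(m.span),
                "actions": [
                    {"span": _span_to_obj(a.span), "label": a.label, "negated": a.negated}
                    for a in m.actions
                ],
                "assistance": [
                    {"span": _span_to_obj(c.span), "text": c.text} for c in m.assistance
                ],
                "quantifications": [
                    {"span": _span_to_obj(c.span), "text": c.text} for c in m.quantifications
                ],
            }
            for m in corpus.mentions
        ],
    }


def corpus_from_obj(obj: dict) -> AnnotatedCorpus:
    def span(o):
        return Span(o["start"], o["end"])

    mentions = [
        ActivityMention(
            mention_id=m["mention_id"],
            doc_id=m["doc_id"],
            span=span(m["span"]),
            actions=[
                ActionComponent(span(a["span"]), a["label"], a.get("negated", False))
                for a in m.get("actions", [])
            ],
            assistance=[
                AssistanceComponent(span(c["span"]), c.get("text", ""))
                for c in m.get("assistance", [])
            ],
            quantifications=[
                QuantificationComponent(span(c["span"]), c.get("text", ""))
                for c in m.get("quantifications", [])
            ],
        )
        for m in obj.get("mentions", [])
    ]
    return AnnotatedCorpus(
        domain_id=obj["domain_id"],
        documents=[Document(**d) for d in obj.get("documents", [])],
        mentions=mentions,
        provenance=dict(obj.get("provenance", {})),
    )


# ---------------------------------------------------------------------------
# Standoff dialect
# ---------------------------------------------------------------------------

_COMPONENT_TYPES = {
    "Action": "actions",
    "Assistance": "assistance",
    "Quantification": "quantifications",
}


def _write_standoff_doc(doc: Document, mentions: list[ActivityMention], ann_path: str) -> None:
    lines = []
    tid = rid = aid = nid = 0

    def fragment(span: Span) -> str:
        return doc.text[span.start : span.end].replace("\n", " ")

    for m in mentions:
        tid += 1
        m_tid = f"T{tid}"
        lines.append(f"{m_tid}\tActivityMention {m.span.start} {m.span.end}\t{fragment(m.span)}")
        nid += 1
        lines.append(f"#{nid}\tAnnotatorNotes {m_tid}\tmention_id={m.mention_id}")
        for a in m.actions:
            tid += 1
            c_tid = f"T{tid}"
            lines.append(f"{c_tid}\tAction {a.span.start} {a.span.end}\t{fragment(a.span)}")
            rid += 1
            lines.append(f"R{rid}\tHasComponent Arg1:{m_tid} Arg2:{c_tid}")
            aid += 1
            lines.append(f"A{aid}\tCategory {c_tid} {a.label}")
            if a.negated:
                aid += 1
                lines.append(f"A{aid}\tNegated {c_tid}")
        for kind, comps in (("Assistance", m.assistance), ("Quantification", m.quantifications)):
            for c in comps:
                tid += 1
                c_tid = f"T{tid}"
                lines.append(f"{c_tid}\t{kind} {c.span.start} {c.span.end}\t{fragment(c.span)}")
                rid += 1
                lines.append(f"R{rid}\tHasComponent Arg1:{m_tid} Arg2:{c_tid}")
    with open(ann_path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + ("\n" if lines else ""))


def _read_standoff_doc(doc: Document, ann_path: str) -> list[ActivityMention]:
    spans: dict[str, tuple[str, Span]] = {}
    notes: dict[str, str] = {}
    categories: dict[str, str] = {}
    negated: set[str] = set()
    relations: list[tuple[str, str]] = []
    problems: list[str] = []

    with open(ann_path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            aid = parts[0]
            if aid.startswith("T"):
                ann_type, s, e = parts[1].split(" ")
                start, end = int(s), int(e)
                if end > len(doc.text) or start < 0 or start >= end:
                    problems.append(
                        f"{os.path.basename(ann_path)}:{aid}: span {start}..{end} out of "
                        f"bounds for text of length {len(doc.text)}"
                    )
                    continue
                spans[aid] = (ann_type, Span(start, end))
            elif aid.startswith("R"):
                _, arg1, arg2 = parts[1].split(" ")
                relations.append((arg1.split(":")[1], arg2.split(":")[1]))
            elif aid.startswith("A"):
                fields = parts[1].split(" ")
                if fields[0] == "Category":
                    categories[fields[1]] = fields[2]
                elif fields[0] == "Negated":
                    negated.add(fields[1])
            elif aid.startswith("#"):
                m = re.match(r"AnnotatorNotes (\S+)", parts[1])
                if m and len(parts) > 2 and parts[2].startswith("mention_id="):
                    notes[m.group(1)] = parts[2][len("mention_id=") :]

    mentions: dict[str, ActivityMention] = {}
    for tid, (ann_type, span) in spans.items():
        if ann_type == "ActivityMention":
            mentions[tid] = ActivityMention(
                mention_id=notes.get(tid, f"{doc.doc_id}:{tid}"), doc_id=doc.doc_id, span=span
            )
    for parent, child in relations:
        if parent not in mentions:
            problems.append(f"{os.path.basename(ann_path)}:{parent}: relation parent is not a mention")
            continue
        if child not in spans:
            problems.append(f"{os.path.basename(ann_path)}:{child}: dangling component reference")
            continue
        ann_type, span = spans[child]
        mention = mentions[parent]
        if ann_type == "Action":
            if child not in categories:
                problems.append(f"{os.path.basename(ann_path)}:{child}: Action without Category attribute")
                continue
            mention.actions.append(ActionComponent(span, categories[child], child in negated))
        elif ann_type == "Assistance":
            mention.assistance.append(AssistanceComponent(span, doc.text[span.start : span.end]))
        elif ann_type == "Quantification":
            mention.quantifications.append(QuantificationComponent(span, doc.text[span.start : span.end]))
        else:
            problems.append(f"{os.path.basename(ann_path)}:{child}: unknown component type {ann_type}")
    if problems:
        raise CorpusValidationError(problems)
    # deterministic order: by T index
    order = {tid: i for i, tid in enumerate(spans)}
    return [mentions[tid] for tid in sorted(mentions, key=order.get)]


# ---------------------------------------------------------------------------
# read/write entry points
# ---------------------------------------------------------------------------

def write_corpus(corpus: AnnotatedCorpus, path: str, format: str = "json") -> None:
    """Serialize a corpus; ``format`` is ``json`` (one file) or ``standoff``
    (a directory of ``.txt``/``.ann`` pairs plus ``corpus.json`` metadata)."""
    if format == "json":
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(corpus_to_obj(corpus), fh, ensure_ascii=False, indent=1)
    elif format == "standoff":
        os.makedirs(path, exist_ok=True)
        meta = {
            "domain_id": corpus.domain_id,
            "provenance": dict(corpus.provenance),
            "documents": [
                {"doc_id": d.doc_id, "claimant_id": d.claimant_id, "doc_type": d.doc_type}
                for d in corpus.documents
            ],
        }
        with open(os.path.join(path, "corpus.json"), "w", encoding="utf-8") as fh:
            json.dump(meta, fh, indent=1)
        for d in corpus.documents:
            with open(os.path.join(path, f"{d.doc_id}.txt"), "w", encoding="utf-8") as fh:
                fh.write(d.text)
            _write_standoff_doc(d, corpus.mentions_of(d.doc_id), os.path.join(path, f"{d.doc_id}.ann"))
    else:
        raise ValueError(f"unknown corpus format {format!r}; use 'json' or 'standoff'")


def read_corpus(path: str, format: str = "json", validate: bool = True) -> AnnotatedCorpus:
    if format == "json":
        with open(path, encoding="utf-8") as fh:
            corpus = corpus_from_obj(json.load(fh))
    elif format == "standoff":
        with open(os.path.join(path, "corpus.json"), encoding="utf-8") as fh:
            meta = json.load(fh)
        documents, mentions = [], []
        for entry in meta["documents"]:
            with open(os.path.join(path, f"{entry['doc_id']}.txt"), encoding="utf-8") as fh:
                text = fh.read()
            doc = Document(entry["doc_id"], entry["claimant_id"], entry["doc_type"], text)
            documents.append(doc)
            ann_path = os.path.join(path, f"{entry['doc_id']}.ann")
            if os.path.exists(ann_path):
                mentions.extend(_read_standoff_doc(doc, ann_path))
        corpus = AnnotatedCorpus(
            domain_id=meta["domain_id"],
            documents=documents,
            mentions=mentions,
            provenance=dict(meta.get("provenance", {})),
        )
    else:
        raise ValueError(f"unknown corpus format {format!r}; use 'json' or 'standoff'")
    if validate:
        validate_corpus(corpus)
    return corpus


# ---------------------------------------------------------------------------
# Inter-annotator agreement
# ---------------------------------------------------------------------------

def _as_items(annotations) -> list[tuple]:
    items = []
    for a in annotations:
        if isinstance(a, ActivityMention):
            items.append((a.doc_id, a.span.start, a.span.end, None))
        elif isinstance(a, tuple):
            if len(a) == 3:
                items.append((a[0], a[1], a[2], None))
            else:
                items.append(tuple(a[:4]))
        else:
            raise TypeError(f"cannot interpret annotation {a!r}")
    return items


def iaa_f1(annotations_a, annotations_b, match_policy: str = "exact_span",
           documents: Optional[Iterable[str]] = None) -> dict:
    """Span-level agreement between two annotators, as precision/recall/F-1.

    ``annotations_a`` is the reference.  Items are ``ActivityMention`` objects
    or ``(doc_id, start, end[, label])`` tuples; when labels are present they
    must agree for a match.  ``match_policy``: ``exact_span`` (identical
    offsets) or ``overlap`` (any character overlap, maximum one-to-one
    matching, so the match count is symmetric).  Both empty -> all 1.0.
    """
    if match_policy not in ("exact_span", "overlap"):
        raise ValueError(f"unknown match_policy {match_policy!r}")
    a = _as_items(annotations_a)
    b = _as_items(annotations_b)
    if documents is not None:
        docset = set(documents)
        stray = sorted({it[0] for it in a + b} - docset)
        if stray:
            raise ValueError(f"annotations reference documents outside the shared set: {stray}")
    if not a and not b:
        return {"precision": 1.0, "recall": 1.0, "f1": 1.0}
    if not a or not b:
        return {"precision": 0.0, "recall": 0.0, "f1": 0.0}

    tp = 0
    if match_policy == "exact_span":
        ca, cb = Counter(a), Counter(b)
        tp = sum(min(ca[k], cb[k]) for k in ca)
    else:
        # maximum one-to-one matching on the overlap graph, per document
        from scipy.sparse import csr_matrix
        from scipy.sparse.csgraph import maximum_bipartite_matching

        by_doc_a: dict = {}
        by_doc_b: dict = {}
        for it in a:
            by_doc_a.setdefault(it[0], []).append(it)
        for it in b:
            by_doc_b.setdefault(it[0], []).append(it)
        for doc_id, items_a in by_doc_a.items():
            items_b = by_doc_b.get(doc_id, [])
            if not items_b:
                continue
            rows, cols = [], []
            for i, (_, s, e, lab) in enumerate(items_a):
                for j, (_, bs, be, blab) in enumerate(items_b):
                    if be <= s or bs >= e:
                        continue
                    if lab is not None and blab is not None and lab != blab:
                        continue
                    rows.append(i)
                    cols.append(j)
            if not rows:
                continue
            graph = csr_matrix(
                ([1] * len(rows), (rows, cols)), shape=(len(items_a), len(items_b))
            )
            match = maximum_bipartite_matching(graph, perm_type="column")
            tp += int((match != -1).sum())
    precision = tp / len(b)
    recall = tp / len(a)
    f1 = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
    return {"precision": precision, "recall": recall, "f1": f1}


# ---------------------------------------------------------------------------
# Corpus statistics (the dataset-report quantities)
# ---------------------------------------------------------------------------

@dataclass
class CategoryStats:
    count: int
    pct: Optional[float]  # % of all Actions, one decimal
    train: Optional[int] = None
    test: Optional[int] = None
    train_pct: Optional[int] = None  # % of the category's total, integer
    test_pct: Optional[int] = None


@dataclass
class CorpusStats:
    n_documents: int
    n_documents_with_mentions: int
    n_mentions: int
    n_mentions_with_action: int
    pct_mentions_with_action: Optional[float]
    n_actions: int
    per_category: dict[str, CategoryStats]
    n_train_documents: Optional[int] = None
    n_test_documents: Optional[int] = None
    n_train_actions: Optional[int] = None
    n_test_actions: Optional[int] = None


def _pct(count: int, total: int, digits: int = 1) -> Optional[float]:
    if total == 0:
        return None
    return round(100.0 * count / total, digits)


def corpus_stats(corpus: AnnotatedCorpus, split_plan=None) -> CorpusStats:
    """Compute the dataset-report quantities.

    Percentage conventions: mentions-with-Action uses the mention total as
    denominator; category percentages use the Action total (one decimal);
    per-category train/test percentages use the category's own total
    (integers).  Undefined percentages (empty denominators) are ``None``.

    ``split_plan`` is an optional mapping ``doc_id -> "train"|"test"`` (or an
    object with such an ``assignment`` attribute).
    """
    assignment = getattr(split_plan, "assignment", split_plan)

    docs_with = {m.doc_id for m in corpus.mentions}
    n_mentions = len(corpus.mentions)
    n_with_action = sum(1 for m in corpus.mentions if m.actions)
    action_counts: Counter = Counter()
    train_counts: Counter = Counter()
    test_counts: Counter = Counter()
    n_train_actions = n_test_actions = 0
    for m in corpus.mentions:
        side = assignment.get(m.doc_id) if assignment else None
        for a in m.actions:
            action_counts[a.label] += 1
            if side == "train":
                train_counts[a.label] += 1
                n_train_actions += 1
            elif side == "test":
                test_counts[a.label] += 1
                n_test_actions += 1
    n_actions = sum(action_counts.values())

    label_set = load_label_set(corpus.domain_id)
    per_category: dict[str, CategoryStats] = {}
    for code in label_set.codes:
        c = action_counts.get(code, 0)
        stats = CategoryStats(count=c, pct=_pct(c, n_actions))
        if assignment:
            tr, te = train_counts.get(code, 0), test_counts.get(code, 0)
            stats.train, stats.test = tr, te
            stats.train_pct = None if c == 0 else round(100.0 * tr / c)
            stats.test_pct = None if c == 0 else round(100.0 * te / c)
        per_category[code] = stats

    out = CorpusStats(
        n_documents=len(corpus.documents),
        n_documents_with_mentions=len(docs_with),
        n_mentions=n_mentions,
        n_mentions_with_action=n_with_action,
        pct_mentions_with_action=_pct(n_with_action, n_mentions),
        n_actions=n_actions,
        per_category=per_category,
    )
    if assignment:
        sides = Counter(assignment.values())
        out.n_train_documents = sides.get("train", 0)
        out.n_test_documents = sides.get("test", 0)
        out.n_train_actions = n_train_actions
        out.n_test_actions = n_test_actions
    return out


# ---------------------------------------------------------------------------
# Exclusion linter
# ---------------------------------------------------------------------------

#: default cue lexicons for annotation-guideline exclusions: hypothetical
#: statements, education given by the provider, and habitual work duties.
DEFAULT_EXCLUSION_CUES: dict[str, list[str]] = {
    "hypothetical": ["if", "would be able", "unless", "in case of", "hypothetically"],
    "education": ["educated on", "was instructed", "instructed on", "taught how", "was shown how"],
    "work_duty": ["his job", "her job", "work duties", "job involves", "job requires", "at work involves"],
}


def lint_exclusions(corpus: AnnotatedCorpus, cue_lexicons: Optional[dict] = None) -> list[dict]:
    """Flag mentions whose text matches exclusion cues, for annotator review.

    Advisory only: never mutates the corpus.  Returns a list of warning dicts
    with mention_id, doc_id, the cue class and the matching cue.
    """
    cues = DEFAULT_EXCLUSION_CUES if cue_lexicons is None else cue_lexicons
    compiled = {
        kind: [re.compile(r"\b" + re.escape(c) + r"\b", re.IGNORECASE) for c in cue_list]
        for kind, cue_list in cues.items()
    }
    docs = {d.doc_id: d for d in corpus.documents}
    warnings = []
    for m in corpus.mentions:
        text = m.text(docs[m.doc_id])
        for kind, patterns in compiled.items():
            for pat, cue in zip(patterns, cues[kind]):
                if pat.search(text):
                    warnings.append(
                        {"mention_id": m.mention_id, "doc_id": m.doc_id, "kind": kind, "cue": cue}
                    )
    return warnings
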