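"""Experimental protocol: splits, cross-validation, metrics, significance.

The train/test split is made at the *document* level (all mentions of a
document travel together, controlling for within-document correlation), with
the constraint that the test side contains at least a minimum fraction
(default 20%) of the instances of every category.  The split search uses
seeded randomized restarts followed by greedy repair and fails explicitly,
naming the deficient category, when the constraint is infeasible.

Evaluation reports per-category precision / recall / F-1 (one-vs-rest
confusion counts) and macro F-1, the unweighted mean of per-category F-1.
Categories with zero gold *and* zero predicted instances are excluded from
the macro mean.  Significance between two systems on the same test set is a
paired bootstrap over test instances (default 1,000 replicates): the
one-sided p-value is the proportion of replicates in which system A fails
to beat system B.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Union

import numpy as np
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support

from .corpus import AnnotatedCorpus
from .schema import LabelSet, load_label_set


class EvaluationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Document-level splitting
# ---------------------------------------------------------------------------

@dataclass
class SplitPlan:
    assignment: dict[str, str]            # doc_id -> "train" | "test"
    per_category_test_fraction: dict[str, float]
    min_test_fraction: float
    seed: int
    trials_used: int = 0

    @property
    def train_docs(self) -> list[str]:
        return [d for d, s in self.assignment.items() if s == "train"]

    @property
    def test_docs(self) -> list[str]:
        return [d for d, s in self.assignment.items() if s == "test"]


def _doc_category_counts(corpus: AnnotatedCorpus) -> dict[str, dict[str, int]]:
    counts: dict[str, dict[str, int]] = {d.doc_id: {} for d in corpus.documents}
    for m in corpus.mentions:
        for a in m.actions:
            counts[m.doc_id][a.label] = counts[m.doc_id].get(a.label, 0) + 1
    return counts


def _test_fractions(doc_counts, test_docs, totals) -> dict[str, float]:
    got: dict[str, int] = {c: 0 for c in totals}
    for d in test_docs:
        for c, n in doc_counts[d].items():
            got[c] += n
    return {c: got[c] / totals[c] for c in totals}


def make_split(corpus: AnnotatedCorpus, min_test_fraction: float = 0.2, seed: int = 1,
               test_doc_fraction: float = 0.2, max_trials: int = 10000) -> SplitPlan:
    """Document-level train/test split with >= ``min_test_fraction`` of each
    category's instances in the test set.

    Randomized restarts maximize the worst category's slack; a greedy repair
    pass then moves the most helpful training documents into the test set.
    Raises :class:`EvaluationError` naming the deficient category when the
    constraint cannot be met.
    """
    doc_counts = _doc_category_counts(corpus)
    doc_ids = [d.doc_id for d in corpus.documents]
    totals: dict[str, int] = {}
    for per_doc in doc_counts.values():
        for c, n in per_doc.items():
            totals[c] = totals.get(c, 0) + n
    if not totals:
        raise EvaluationError("corpus has no labeled Action instances to split")
    if len(doc_ids) < 2:
        raise EvaluationError(
            "cannot satisfy the test-coverage constraint with fewer than 2 documents"
        )

    rng = np.random.default_rng(seed)
    n_test = max(1, round(test_doc_fraction * len(doc_ids)))
    n_test = min(n_test, len(doc_ids) - 1)

    def worst(fracs):
        return min(fracs.values())

    best_set: Optional[set] = None
    best_score = -np.inf
    trials = 0
    for trials in range(1, max_trials + 1):
        test = set(rng.choice(doc_ids, size=n_test, replace=False).tolist())
        fr = _test_fractions(doc_counts, test, totals)
        score = worst(fr)
        if score > best_score:
            best_score, best_set = score, test
        if score >= min_test_fraction:
            break
        if trials >= 200 and best_score >= min_test_fraction:
            break

    test = set(best_set)
    fr = _test_fractions(doc_counts, test, totals)
    # greedy repair: pull in the train document richest in the worst category
    for _ in range(len(doc_ids)):
        if worst(fr) >= min_test_fraction:
            break
        deficient = min(fr, key=fr.get)
        candidates = [d for d in doc_ids if d not in test and doc_counts[d].get(deficient, 0) > 0]
        if not candidates or len(test) >= len(doc_ids) - 1:
            raise EvaluationError(
                f"cannot reach a {min_test_fraction:.0%} test fraction for category "
                f"{deficient!r} ({totals[deficient]} instance(s)); its instances are "
                "confined to documents that must remain in training"
            )
        move = max(candidates, key=lambda d: doc_counts[d].get(deficient, 0))
        test.add(move)
        fr = _test_fractions(doc_counts, test, totals)
    if worst(fr) < min_test_fraction:
        deficient = min(fr, key=fr.get)
        raise EvaluationError(
            f"split search exhausted without covering category {deficient!r} "
            f"at {min_test_fraction:.0%} in the test set"
        )

    assignment = {d: ("test" if d in test else "train") for d in doc_ids}
    return SplitPlan(assignment, fr, min_test_fraction, seed, trials)


@dataclass
class FoldPlan:
    k: int
    fold_of: dict[str, int]  # doc_id -> fold index
    seed: int

    def fold_docs(self, i: int) -> list[str]:
        return [d for d, f in self.fold_of.items() if f == i]


def make_folds(doc_ids: Sequence[str], k: int = 10, seed: int = 1) -> FoldPlan:
    """Balanced document-level folds (sizes differ by at most one)."""
    doc_ids = list(doc_ids)
    if k > len(doc_ids):
        raise EvaluationError(f"k={k} exceeds the number of documents ({len(doc_ids)})")
    rng = np.random.default_rng(seed)
    order = sorted(doc_ids)
    rng.shuffle(order)
    return FoldPlan(k, {d: i % k for i, d in enumerate(order)}, seed)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    per_category: dict[str, dict]   # code -> precision/recall/f1/support
    macro_f1: float
    included_codes: list[str]       # codes entering the macro mean
    confusion: np.ndarray = field(repr=False, default=None)
    confusion_codes: list[str] = field(default_factory=list)


def evaluate(gold: Sequence[str], predicted: Sequence[str], label_set: LabelSet) -> EvalReport:
    """Per-category P/R/F-1 from one-vs-rest confusion counts, plus macro F-1.

    Categories absent from both gold and predictions are excluded from the
    macro mean (their row is still reported with support 0 and f1 None).
    """
    if len(gold) != len(predicted):
        raise EvaluationError(f"gold ({len(gold)}) and predicted ({len(predicted)}) differ in length")
    codes = list(label_set.codes)
    for seq, name in ((gold, "gold"), (predicted, "predicted")):
        stray = sorted(set(seq) - set(codes))
        if stray:
            raise EvaluationError(f"{name} labels outside the label set: {stray}")
    if not gold:
        raise EvaluationError("empty evaluation set")

    p, r, f1, support = precision_recall_fscore_support(
        gold, predicted, labels=codes, zero_division=0
    )
    pred_counts = {c: 0 for c in codes}
    for c in predicted:
        pred_counts[c] += 1

    per_category: dict[str, dict] = {}
    included = []
    for i, c in enumerate(codes):
        present = support[i] > 0 or pred_counts[c] > 0
        per_category[c] = {
            "precision": float(p[i]) if present else None,
            "recall": float(r[i]) if present else None,
            "f1": float(f1[i]) if present else None,
            "support": int(support[i]),
        }
        if present:
            included.append(c)
    macro = float(np.mean([per_category[c]["f1"] for c in included]))
    cm = confusion_matrix(gold, predicted, labels=codes)
    return EvalReport(per_category, macro, included, cm, codes)


def report_to_obj(report: EvalReport) -> dict:
    return {
        "macro_f1": report.macro_f1,
        "included_codes": report.included_codes,
        "per_category": report.per_category,
        "confusion": report.confusion.tolist() if report.confusion is not None else None,
        "confusion_codes": report.confusion_codes,
    }


# ---------------------------------------------------------------------------
# Bootstrap significance
# ---------------------------------------------------------------------------

@dataclass
class SignificanceResult:
    delta: float       # observed metric_a - metric_b
    p_value: float     # one-sided: P(a does not beat b)
    replicates: int
    seed: int
    two_sided: bool = False


def bootstrap_compare(
    gold: Sequence[str],
    pred_a: Sequence[str],
    pred_b: Sequence[str],
    label_set: LabelSet,
    metric: Union[str, Callable] = "macro_f1",
    replicates: int = 1000,
    seed: int = 1,
    unit: str = "instance",
    doc_ids: Optional[Sequence[str]] = None,
    two_sided: bool = False,
) -> SignificanceResult:
    """Paired bootstrap comparison of two systems on one test set.

    The default resampling unit is the instance (the NLP convention for
    paired system comparison); pass ``unit="document"`` with aligned
    ``doc_ids`` to resample documents instead.  One-sided p = proportion of
    replicates with (metric_a - metric_b) <= 0, i.e., the test that A beats
    B; ``two_sided=True`` doubles-and-caps using |delta|.
    """
    if replicates < 1:
        raise EvaluationError("replicates must be >= 1")
    if not (len(gold) == len(pred_a) == len(pred_b)):
        raise EvaluationError("gold, pred_a and pred_b must be aligned")

    if callable(metric):
        m = metric
    elif metric == "macro_f1":
        def m(g, p):
            return evaluate(g, p, label_set).macro_f1
    else:
        raise EvaluationError(f"unknown metric {metric!r}")

    gold = list(gold)
    pred_a = list(pred_a)
    pred_b = list(pred_b)
    delta_obs = m(gold, pred_a) - m(gold, pred_b)

    rng = np.random.default_rng(seed)
    n = len(gold)
    if unit == "document":
        if doc_ids is None:
            raise EvaluationError("document-level bootstrap requires doc_ids")
        by_doc: dict[str, list[int]] = {}
        for i, d in enumerate(doc_ids):
            by_doc.setdefault(d, []).append(i)
        docs = sorted(by_doc)
    elif unit != "instance":
        raise EvaluationError(f"unknown bootstrap unit {unit!r}")

    worse = 0
    for _ in range(replicates):
        if unit == "instance":
            idx = rng.integers(0, n, size=n)
        else:
            chosen = rng.choice(len(docs), size=len(docs), replace=True)
            idx = np.array([i for d in chosen for i in by_doc[docs[d]]])
        g = [gold[i] for i in idx]
        a = [pred_a[i] for i in idx]
        b = [pred_b[i] for i in idx]
        d_rep = m(g, a) - m(g, b)
        if two_sided:
            if abs(d_rep) >= abs(delta_obs) and np.sign(d_rep) != np.sign(delta_obs):
                worse += 1
        else:
            if d_rep <= 0:
                worse += 1
    p = worse / replicates
    if two_sided:
        p = min(1.0, 2 * p)
    return SignificanceResult(delta_obs, p, replicates, seed, two_sided)


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CrossValidationResult:
    fold_reports: list[EvalReport]
    mean_macro_f1: float
    mean_per_category_f1: dict[str, float]
    fold_plan: FoldPlan


def cross_validate(instances, coder_factory: Callable, label_set: LabelSet,
                   k: int = 10, seed: int = 1) -> CrossValidationResult:
    """Document-level k-fold cross-validation over coding instances.

    ``instances`` are objects with ``doc_id``, ``representation`` and
    ``gold`` attributes (see ``coders.build_instances``);
    ``coder_factory(train_instances)`` returns a trained coder exposing
    ``predict(representation) -> {"code": ...}``.  Metrics are averaged
    unweighted across folds.
    """
    instances = list(instances)
    doc_ids = sorted({inst.doc_id for inst in instances})
    plan = make_folds(doc_ids, k, seed)
    reports = []
    for fold in range(k):
        test_docs = set(plan.fold_docs(fold))
        train = [i for i in instances if i.doc_id not in test_docs]
        test = [i for i in instances if i.doc_id in test_docs]
        if not test:
            continue
        coder = coder_factory([(i.representation, i.gold) for i in train])
        preds = [coder.predict(i.representation)["code"] for i in test]
        reports.append(evaluate([i.gold for i in test], preds, label_set))
    if not reports:
        raise EvaluationError("no non-empty folds")
    mean_macro = float(np.mean([r.macro_f1 for r in reports]))
    per_cat: dict[str, list[float]] = {}
    for r in reports:
        for c in r.included_codes:
            per_cat.setdefault(c, []).append(r.per_category[c]["f1"])
    mean_per_cat = {c: float(np.mean(v)) for c, v in per_cat.items()}
    return CrossValidationResult(reports, mean_macro, mean_per_cat, plan)
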