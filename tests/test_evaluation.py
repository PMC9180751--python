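import numpy as np
import pytest

import icfcoder as ic
from icfcoder.corpus import (
    ActionComponent,
    ActivityMention,
    AnnotatedCorpus,
    Document,
    Span,
)
from icfcoder.evaluation import EvaluationError, make_folds


def corpus_from_doc_labels(doc_labels, domain="MOBILITY"):
    """One document per entry; each label becomes a 1-Action mention."""
    docs, mentions = [], []
    serial = 0
    for d, labels in enumerate(doc_labels):
        text = ("pt walks daily. " * max(1, len(labels))).strip()
        docs.append(Document(f"d{d}", f"c{d}", "CE", text))
        for j, label in enumerate(labels):
            serial += 1
            start = j * len("pt walks daily. ")
            mentions.append(
                ActivityMention(
                    f"m{serial}", f"d{d}", Span(start, start + 14),
                    actions=[ActionComponent(Span(start + 3, start + 8), label)],
                )
            )
    return AnnotatedCorpus(domain, docs, mentions)


# ---------------------------------------------------------------------------
# evaluate()
# ---------------------------------------------------------------------------

def test_perfect_predictions_macro_one(mobility_labels):
    gold = ["d450", "d410", "d450", "OTHER"]
    assert ic.evaluate(gold, list(gold), mobility_labels).macro_f1 == 1.0


def test_hand_computed_f1s(mobility_labels):
    """gold AABB vs pred ABBB: F1(A) = 2/3, F1(B) = 0.8, macro = 0.7333."""
    report = ic.evaluate(
        ["d450", "d450", "d410", "d410"], ["d450", "d410", "d410", "d410"], mobility_labels
    )
    assert report.per_category["d450"]["f1"] == pytest.approx(2 / 3)
    assert report.per_category["d410"]["f1"] == pytest.approx(0.8)
    assert report.macro_f1 == pytest.approx(0.73333, abs=1e-4)
    assert report.included_codes == ["d410", "d450"]


def test_single_class_predictions_on_balanced_set(mobility_labels):
    report = ic.evaluate(
        ["d450", "d450", "d410", "d410"], ["d450"] * 4, mobility_labels
    )
    assert report.per_category["d450"]["f1"] == pytest.approx(2 / 3)
    assert report.per_category["d410"]["f1"] == 0.0
    assert report.macro_f1 == pytest.approx(1 / 3)


def test_absent_categories_excluded_from_macro(mobility_labels):
    report = ic.evaluate(["d450", "d410"], ["d450", "d410"], mobility_labels)
    assert set(report.included_codes) == {"d450", "d410"}
    assert report.per_category["d435"]["f1"] is None
    assert report.per_category["d435"]["support"] == 0


def test_evaluate_errors(mobility_labels):
    with pytest.raises(EvaluationError, match="length"):
        ic.evaluate(["d450"], [], mobility_labels)
    with pytest.raises(EvaluationError, match="outside the label set"):
        ic.evaluate(["d450"], ["nope"], mobility_labels)


# ---------------------------------------------------------------------------
# make_split
# ---------------------------------------------------------------------------

def test_split_satisfies_constraint_and_is_seeded():
    corpus = ic.generate_corpus(
        ic.SyntheticConfig(domain_id="MOBILITY", n_documents=100, seed=21,
                           category_proportions=ic.uniform_proportions("MOBILITY"))
    )
    plan = ic.make_split(corpus, 0.2, seed=3)
    assert min(plan.per_category_test_fraction.values()) >= 0.2
    assert set(plan.assignment.values()) == {"train", "test"}
    plan2 = ic.make_split(corpus, 0.2, seed=3)
    assert plan2.assignment == plan.assignment


def test_split_single_document_infeasible():
    corpus = corpus_from_doc_labels([["d450", "d410"]])
    with pytest.raises(EvaluationError, match="fewer than 2 documents"):
        ic.make_split(corpus, 0.2, seed=0)


def test_split_reports_deficient_category():
    # d450 and d410 each confined to one of the two documents: whichever side
    # a document lands on, the other category gets nothing
    corpus = corpus_from_doc_labels([["d450"] * 4, ["d410"] * 4])
    with pytest.raises(EvaluationError, match="d4"):
        ic.make_split(corpus, 0.2, seed=0)


# ---------------------------------------------------------------------------
# folds
# ---------------------------------------------------------------------------

def test_folds_balanced_partition():
    docs = [f"d{i}" for i in range(23)]
    plan = make_folds(docs, k=10, seed=1)
    sizes = [len(plan.fold_docs(i)) for i in range(10)]
    assert sum(sizes) == 23
    assert max(sizes) - min(sizes) <= 1
    assert make_folds(list(reversed(docs)), k=10, seed=1).fold_of == plan.fold_of


def test_folds_k_exceeds_documents():
    with pytest.raises(EvaluationError, match="exceeds"):
        make_folds(["d1", "d2"], k=3, seed=0)


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def test_bootstrap_identical_predictions_p_one(mobility_labels):
    gold = ["d450", "d410"] * 20
    pred = ["d450", "d450"] * 20
    res = ic.bootstrap_compare(gold, pred, list(pred), mobility_labels,
                               replicates=100, seed=5)
    assert res.p_value == 1.0
    assert res.delta == 0.0


def test_bootstrap_deterministic(mobility_labels):
    rng = np.random.default_rng(6)
    gold = [("d450", "d410")[i] for i in rng.integers(0, 2, 100)]
    pred_a = list(gold)
    pred_b = [("d450", "d410")[i] for i in rng.integers(0, 2, 100)]
    r1 = ic.bootstrap_compare(gold, pred_a, pred_b, mobility_labels, replicates=200, seed=7)
    r2 = ic.bootstrap_compare(gold, pred_a, pred_b, mobility_labels, replicates=200, seed=7)
    assert r1.p_value == r2.p_value


def test_bootstrap_monotone_in_system_strength(mobility_labels):
    """A system correct everywhere a weaker one is (and more) never gets a
    larger p against the same baseline."""
    rng = np.random.default_rng(8)
    gold = [("d450", "d410", "d430")[i] for i in rng.integers(0, 3, 150)]
    baseline = [("d450", "d410", "d430")[i] for i in rng.integers(0, 3, 150)]
    weak = [g if i % 2 == 0 else b for i, (g, b) in enumerate(zip(gold, baseline))]
    strong = list(gold)  # agrees with weak wherever weak is right, fixes the rest
    p_strong = ic.bootstrap_compare(gold, strong, baseline, mobility_labels,
                                    replicates=300, seed=9).p_value
    p_weak = ic.bootstrap_compare(gold, weak, baseline, mobility_labels,
                                  replicates=300, seed=9).p_value
    assert p_strong <= p_weak


def test_bootstrap_replicates_validation(mobility_labels):
    with pytest.raises(EvaluationError, match="replicates"):
        ic.bootstrap_compare(["d450"], ["d450"], ["d450"], mobility_labels, replicates=0)


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

class MemorizingCoder:
    """Exact-match lookup: perfect on seen vectors, clueless elsewhere."""

    def __init__(self, pairs):
        self.table = {tuple(np.asarray(x).tolist()): y for x, y in pairs}
        self.default = pairs[0][1]

    def predict(self, representation):
        key = tuple(np.asarray(representation).tolist())
        return {"code": self.table.get(key, self.default), "scores": {}}


def _instances(doc_labels, seed=0):
    """CodingInstance-like records with doc-unique vectors."""
    from icfcoder.coders import CodingInstance

    rng = np.random.default_rng(seed)
    out = []
    for d, labels in enumerate(doc_labels):
        for j, label in enumerate(labels):
            out.append(CodingInstance(f"m{d}-{j}", f"d{d}", rng.standard_normal(4), label))
    return out


def test_cross_validate_bookkeeping():
    inst = _instances([["d450"], ["d410"], ["d450"], ["d410"]])
    res = ic.cross_validate(inst, MemorizingCoder, ic.load_label_set("MOBILITY"), k=2, seed=1)
    assert len(res.fold_reports) == 2
    assert 0.0 <= res.mean_macro_f1 <= 1.0


def test_memorizer_does_not_generalize_across_folds():
    inst = _instances([["d450", "d410"]] * 6, seed=2)
    res = ic.cross_validate(inst, MemorizingCoder, ic.load_label_set("MOBILITY"), k=3, seed=3)
    assert res.mean_macro_f1 < 1.0
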