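import os

import pytest

import icfcoder as ic


@pytest.fixture(scope="session")
def mobility_labels():
    return ic.load_label_set("MOBILITY")


@pytest.fixture(scope="session")
def scdl_labels():
    return ic.load_label_set("SELFCARE_DOMESTIC")


@pytest.fixture(scope="session")
def small_corpus():
    """Small generated Mobility corpus with the study-shaped defaults."""
    return ic.generate_corpus(ic.SyntheticConfig(domain_id="MOBILITY", n_documents=8, seed=42))


@pytest.fixture(scope="session")
def tiny_model(tmp_path_factory):
    """Small static embedding model trained on a generated corpus."""
    cfg = ic.SyntheticConfig(
        domain_id="MOBILITY",
        n_documents=25,
        seed=5,
        category_proportions=ic.uniform_proportions("MOBILITY"),
    )
    path = tmp_path_factory.mktemp("emb") / "sentences.txt"
    ic.generate_embedding_corpus(cfg, str(path))
    return ic.train_static_embeddings(str(path), n=20, epochs=3, seed=5, n_buckets=2000)


@pytest.fixture(scope="session")
def mobility_experiment(tmp_path_factory):
    """End-to-end label-recovery experiment on a synthetic Mobility corpus.

    Uniform category proportions give every category enough instances
    (>= 50 per category in expectation) to estimate per-category F-1; the
    default lexicon's Action vocabulary is category-specific.  Both coders
    are trained in both static modes on a constraint-satisfying document
    split and evaluated on the held-out documents.
    """
    cfg = ic.SyntheticConfig(
        domain_id="MOBILITY",
        n_documents=120,
        seed=7,
        category_proportions=ic.uniform_proportions("MOBILITY"),
    )
    corpus = ic.generate_corpus(cfg)
    emb_path = str(tmp_path_factory.mktemp("recovery") / "sentences.txt")
    ic.generate_embedding_corpus(cfg, emb_path)
    model = ic.train_static_embeddings(emb_path, n=50, epochs=5, seed=2, n_buckets=5000)
    label_set = ic.load_label_set("MOBILITY")
    plan = ic.make_split(corpus, 0.2, seed=11)
    defs = ic.definition_vectors_for(label_set, model)

    results = {}
    predictions = {}
    for mode in ("static_oracle", "static_plain"):
        instances = ic.build_instances(corpus, mode, model)
        train = [i for i in instances if plan.assignment[i.doc_id] == "train"]
        test = [i for i in instances if plan.assignment[i.doc_id] == "test"]
        pairs = [(i.representation, i.gold) for i in train]
        gold = [i.gold for i in test]
        clf = ic.train_classifier(pairs, label_set, ic.ClassifierConfig(seed=1))
        clf_pred = [clf.predict(i.representation)["code"] for i in test]
        sel = ic.train_selector(pairs, defs, label_set, ic.SelectorConfig(seed=1, epochs=60))
        sel_pred = [sel.select(i.representation)["code"] for i in test]
        results[mode] = {
            "classifier": ic.evaluate(gold, clf_pred, label_set).macro_f1,
            "selector": ic.evaluate(gold, sel_pred, label_set).macro_f1,
        }
        predictions[mode] = {"gold": gold, "classifier": clf_pred, "selector": sel_pred}
    return {
        "corpus": corpus,
        "model": model,
        "label_set": label_set,
        "plan": plan,
        "results": results,
        "predictions": predictions,
    }
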