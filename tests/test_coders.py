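import numpy as np
import pytest

import icfcoder as ic
from icfcoder.coders import (
    CandidateSelectorCoder,
    CoderError,
    SelectorConfig,
    train_classifier,
    train_selector,
)


def gaussian_instances(codes, n_per_class, dim, seed, spread=0.05, means=None):
    """Well-separated labeled clusters with one unit-norm mean per code.

    Pass ``means`` to draw additional (e.g. held-out) samples from the same
    clusters."""
    rng = np.random.default_rng(seed)
    if means is None:
        means = {c: rng.standard_normal(dim) for c in codes}
        for c in codes:
            means[c] /= np.linalg.norm(means[c])
    out = []
    for c in codes:
        for _ in range(n_per_class):
            out.append((means[c] + spread * rng.standard_normal(dim), c))
    rng.shuffle(out)
    return out, means


# ---------------------------------------------------------------------------
# classifier
# ---------------------------------------------------------------------------

def test_classifier_separable_two_class(mobility_labels):
    inst, _ = gaussian_instances(["d450", "d475"], 30, 10, seed=0)
    clf = train_classifier(inst, mobility_labels)
    preds = [clf.predict(x)["code"] for x, _ in inst]
    assert preds == [y for _, y in inst]


def test_classifier_deterministic(mobility_labels):
    inst, _ = gaussian_instances(["d450", "d475", "d410"], 20, 8, seed=1)
    probes = [x for x, _ in gaussian_instances(["d450", "d475", "d410"], 5, 8, seed=2)[0]]
    p1 = [train_classifier(inst, mobility_labels).predict(x)["code"] for x in probes]
    p2 = [train_classifier(inst, mobility_labels).predict(x)["code"] for x in probes]
    assert p1 == p2


def test_classifier_sixteen_class_recovery(scdl_labels):
    codes = list(scdl_labels.codes)
    train, means = gaussian_instances(codes, 40, 32, seed=3)
    test, _ = gaussian_instances(codes, 10, 32, seed=4, means=means)
    clf = train_classifier(train, scdl_labels)
    preds = [clf.predict(x)["code"] for x, _ in test]
    report = ic.evaluate([y for _, y in test], preds, scdl_labels)
    assert report.macro_f1 >= 0.95


def test_classifier_agrees_with_nearest_centroid(mobility_labels):
    codes = ["d450", "d410", "d430", "d470"]
    train, means = gaussian_instances(codes, 30, 16, seed=5)
    probes, _ = gaussian_instances(codes, 25, 16, seed=6, means=means)
    clf = train_classifier(train, mobility_labels)
    agree = 0
    for x, _ in probes:
        centroid = min(means, key=lambda c: np.linalg.norm(x - means[c]))
        if clf.predict(x)["code"] == centroid:
            agree += 1
    assert agree / len(probes) >= 0.9
    # probing at an exact cluster mean recovers that cluster's code
    for c in codes:
        assert clf.predict(means[c])["code"] == c


def test_classifier_predictions_in_label_set(mobility_labels):
    inst, _ = gaussian_instances(["d450", "d475"], 10, 6, seed=7)
    clf = train_classifier(inst, mobility_labels)
    rng = np.random.default_rng(8)
    for _ in range(100):
        assert clf.predict(rng.standard_normal(6))["code"] in mobility_labels


def test_classifier_input_errors(mobility_labels):
    with pytest.raises(CoderError, match="single class"):
        train_classifier([(np.ones(3), "d450"), (np.zeros(3), "d450")], mobility_labels)
    with pytest.raises(CoderError, match="dimensions"):
        train_classifier([(np.ones(3), "d450"), (np.zeros(4), "d475")], mobility_labels)
    with pytest.raises(CoderError, match="not in label set"):
        train_classifier([(np.ones(3), "d450"), (np.zeros(3), "zzz")], mobility_labels)
    inst, _ = gaussian_instances(["d450", "d475"], 5, 6, seed=9)
    clf = train_classifier(inst, mobility_labels)
    with pytest.raises(CoderError, match="dim"):
        clf.predict(np.ones(7))


def test_classifier_save_load_round_trip(tmp_path, mobility_labels):
    inst, _ = gaussian_instances(["d450", "d475", "d410"], 15, 8, seed=10)
    clf = train_classifier(inst, mobility_labels)
    path = tmp_path / "clf.json"
    clf.save(str(path))
    restored = ic.ClassifierCoder.load(str(path))
    rng = np.random.default_rng(11)
    for _ in range(30):
        x = rng.standard_normal(8)
        got, want = restored.predict(x), clf.predict(x)
        assert got["code"] == want["code"]
        for c in want["scores"]:
            assert got["scores"][c] == pytest.approx(want["scores"][c], abs=1e-12)


# ---------------------------------------------------------------------------
# candidate selector
# ---------------------------------------------------------------------------

def random_definitions(label_set, dim, seed):
    rng = np.random.default_rng(seed)
    return {c: rng.standard_normal(dim) for c in label_set.codes}


def test_untrained_identity_selector_is_raw_cosine(mobility_labels):
    dim = 12
    defs = random_definitions(mobility_labels, dim, 0)
    coder = CandidateSelectorCoder(
        mobility_labels, defs, dim, SelectorConfig(init="identity", activation="linear")
    )
    rng = np.random.default_rng(1)
    for _ in range(50):
        x = rng.standard_normal(dim)
        raw = {
            c: float(defs[c] @ x / (np.linalg.norm(defs[c]) * np.linalg.norm(x)))
            for c in mobility_labels.codes
        }
        res = coder.select(x)
        assert res["code"] == max(mobility_labels.codes, key=lambda c: raw[c])
        for c in mobility_labels.codes:
            assert res["scores"][c] == pytest.approx(raw[c])


def test_identity_selector_cosine_extremes(mobility_labels):
    dim = 6
    defs = {c: np.zeros(dim) for c in mobility_labels.codes}
    for i, c in enumerate(mobility_labels.codes):
        defs[c][i % dim] = 1.0
    coder = CandidateSelectorCoder(
        mobility_labels, defs, dim, SelectorConfig(init="identity", activation="linear")
    )
    x = np.zeros(dim)
    x[0] = 2.0  # parallel to the first code's definition
    res = coder.select(x)
    first = mobility_labels.codes[0]
    assert res["scores"][first] == pytest.approx(1.0)
    assert res["code"] == first  # ties on the repeated axes break to label-set order
    orth = mobility_labels.codes[1]
    assert res["scores"][orth] == pytest.approx(0.0)


def test_selector_scores_invariant_to_rescaling(mobility_labels):
    defs = random_definitions(mobility_labels, 10, 2)
    coder = CandidateSelectorCoder(mobility_labels, defs, 10, SelectorConfig(seed=3))
    rng = np.random.default_rng(4)
    for _ in range(20):
        x = rng.standard_normal(10)
        s1 = coder.select(x)["scores"]
        s2 = coder.select(5.7 * x)["scores"]
        for c in s1:
            assert s1[c] == pytest.approx(s2[c], abs=1e-10)


def test_selector_argmax_matches_bruteforce(mobility_labels):
    defs = random_definitions(mobility_labels, 10, 5)
    coder = CandidateSelectorCoder(mobility_labels, defs, 10, SelectorConfig(seed=6))
    rng = np.random.default_rng(7)
    for _ in range(200):
        x = rng.standard_normal(10)
        res = coder.select(x)
        E = coder.conditional_embeddings(x)
        cos = [
            float(E[i] @ x / (max(np.linalg.norm(E[i]), 1e-12) * np.linalg.norm(x)))
            for i in range(len(mobility_labels.codes))
        ]
        assert res["code"] == mobility_labels.codes[int(np.argmax(cos))]
        assert all(-1.0 - 1e-9 <= s <= 1.0 + 1e-9 for s in res["scores"].values())


def test_selector_training_recovers_separable_data(mobility_labels):
    codes = list(mobility_labels.codes)
    train, means = gaussian_instances(codes, 25, 24, seed=8)
    test, _ = gaussian_instances(codes, 8, 24, seed=9, means=means)
    defs = {c: means[c] + 0.1 * np.random.default_rng(10).standard_normal(24) for c in codes}
    coder = train_selector(train, defs, mobility_labels, SelectorConfig(seed=11, epochs=40))
    preds = [coder.select(x)["code"] for x, _ in test]
    report = ic.evaluate([y for _, y in test], preds, mobility_labels)
    assert report.macro_f1 >= 0.9


def test_selector_deterministic(mobility_labels):
    inst, _ = gaussian_instances(["d450", "d475", "d410"], 15, 8, seed=12)
    defs = random_definitions(mobility_labels, 8, 13)
    probes = [x for x, _ in gaussian_instances(["d450", "d475"], 5, 8, seed=14)[0]]
    cfg = SelectorConfig(seed=15, epochs=10)
    s1 = train_selector(inst, defs, mobility_labels, cfg)
    s2 = train_selector(inst, defs, mobility_labels, cfg)
    assert [s1.select(x)["code"] for x in probes] == [s2.select(x)["code"] for x in probes]


def test_selector_errors(mobility_labels):
    defs = random_definitions(mobility_labels, 6, 16)
    missing = dict(defs)
    del missing["d435"]
    with pytest.raises(CoderError, match="d435"):
        CandidateSelectorCoder(mobility_labels, missing, 6)
    coder = CandidateSelectorCoder(mobility_labels, defs, 6, SelectorConfig(seed=17))
    with pytest.raises(CoderError, match="zero-vector"):
        coder.select(np.zeros(6))
    with pytest.raises(CoderError, match="dim"):
        coder.select(np.ones(7))


def test_selector_save_load_round_trip(tmp_path, mobility_labels):
    inst, _ = gaussian_instances(["d450", "d475", "d410"], 10, 8, seed=18)
    defs = random_definitions(mobility_labels, 8, 19)
    coder = train_selector(inst, defs, mobility_labels, SelectorConfig(seed=20, epochs=5))
    path = tmp_path / "sel.json"
    coder.save(str(path))
    restored = CandidateSelectorCoder.load(str(path))
    rng = np.random.default_rng(21)
    for _ in range(20):
        x = rng.standard_normal(8)
        np.testing.assert_allclose(
            list(restored.select(x)["scores"].values()),
            list(coder.select(x)["scores"].values()),
            atol=1e-9,
        )


# ---------------------------------------------------------------------------
# corpus -> instances
# ---------------------------------------------------------------------------

def test_build_instances_counts_and_modes(small_corpus, tiny_model):
    n_actions = sum(len(m.actions) for m in small_corpus.mentions)
    for mode in ("static_plain", "static_oracle"):
        instances = ic.build_instances(small_corpus, mode, tiny_model)
        assert len(instances) == n_actions  # one instance per gold Action
        dim = tiny_model.dimension * (2 if mode == "static_oracle" else 1)
        assert all(i.representation.vector.shape == (dim,) for i in instances)


def test_multi_action_mentions_share_plain_representation(small_corpus, tiny_model):
    instances = ic.build_instances(small_corpus, "static_plain", tiny_model)
    by_mention = {}
    for i in instances:
        by_mention.setdefault(i.mention_id, []).append(i.representation.vector)
    multi = [v for v in by_mention.values() if len(v) > 1]
    assert multi, "expected some multi-Action mentions in the generated corpus"
    for vecs in multi:
        for v in vecs[1:]:
            np.testing.assert_array_equal(v, vecs[0])
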