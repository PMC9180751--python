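# icfcoder

Automated ICF coding of functional status information in clinical free text.

Clinical notes describe how patients actually function — walking, dressing,
managing medications — in free prose that resists standardized analysis. The
WHO International Classification of Functioning, Disability and Health (ICF)
provides the coding frame: this package assigns **second-level ICF
categories** from the *Mobility* (Chapter 4) and *Self-Care / Domestic Life*
(Chapters 5–6) parts of the Activities and Participation domain to *activity
mentions* — self-contained spans describing a patient performing an activity.
It is aimed at clinical-NLP researchers and at teams processing functional
evidence in disability assessment, where such mentions are extracted from
scanned, OCR-noisy claim documents.

## Data model and label sets

An activity mention may contain one or more **Action** components (the
sub-span naming the activity — the unit that receives the ICF label), plus
optional **Assistance** (device, person) and **Quantification** (distance,
time) components. The Mobility label set has 13 labels (d410–d475 minus
d465, plus `OTHER`); Self-Care/Domestic Life has 16, including two SNOMED CT
extension labels that split patient engagement in treatment out of the
overly broad d570 *Looking after one's health*: *Manage medication*
(285033005) and *Therapy* (709007004). Corpora round-trip through a
brat-style standoff dialect and a JSON dialect; inter-annotator agreement is
measured as span-level F-1.

## Coding models

Given a mention (and optionally the *Action oracle* — the known location of
the Action span), a fixed-length representation is built from word
embeddings:

| mode            | vector                                                   | dim |
|-----------------|----------------------------------------------------------|-----|
| `static_plain`  | mean of static word vectors of the mention               | n   |
| `static_oracle` | [mean(Action tokens) ‖ mean(other tokens)]               | 2n  |
| `ctx_plain`     | mean of contextualized token vectors                     | d   |
| `ctx_oracle`    | mean of contextualized Action-token vectors              | d   |

Static vectors come from a skipgram + negative-sampling trainer with
fastText-style character n-gram buckets (word2vec text format I/O); the
contextualized encoder is a pluggable interface with a deterministic
hash-based stub for offline use. Two coders map representations to codes:

* **Classification** — a linear SVM (one-vs-rest) over the representation,
  i.e. labeling by similarity to previously observed samples.
* **Candidate selection** — a feed-forward network that takes the mention
  vector together with each category's **definition embedding** (the mean
  word vector of its definition string) and produces *conditional* category
  embeddings; the category whose conditional embedding has the highest
  cosine similarity to the mention vector is selected:
  `ĉ = argmax_c cos(m, DNN(m, d_c))`.

Evaluation follows a document-level train/test split constrained so every
category keeps ≥ 20% of its instances in the test set, 10-fold
cross-validation for development, per-category and macro-averaged F-1, and
paired bootstrap significance testing (1,000 replicates).

Because the original disability-claim corpora cannot be shared, the package
ships a synthetic-corpus generator whose defaults reproduce the published
dataset shape (category skew, mentions per document, multi-Action rates,
OCR-style character noise), so the full pipeline is testable offline.

## Worked example

```python
import icfcoder as ic

cfg = ic.SyntheticConfig(domain_id="MOBILITY", n_documents=120, seed=7,
                         category_proportions=ic.uniform_proportions("MOBILITY"))
corpus = ic.generate_corpus(cfg)
ic.generate_embedding_corpus(cfg, "sentences.txt")
model = ic.train_static_embeddings("sentences.txt", n=50, epochs=5, seed=2)

labels = ic.load_label_set("MOBILITY")
plan = ic.make_split(corpus, min_test_fraction=0.2, seed=11)
inst = ic.build_instances(corpus, "static_oracle", model)
train = [(i.representation, i.gold) for i in inst if plan.assignment[i.doc_id] == "train"]
test = [i for i in inst if plan.assignment[i.doc_id] == "test"]

clf = ic.train_classifier(train, labels)
report = ic.evaluate([i.gold for i in test],
                     [clf.predict(i.representation)["code"] for i in test], labels)
print(f"classification macro F1 = {report.macro_f1:.3f} on {len(test)} instances")

sel = ic.train_selector(train, ic.definition_vectors_for(labels, model), labels)
sel_report = ic.evaluate([i.gold for i in test],
                         [sel.select(i.representation)["code"] for i in test], labels)
print(f"candidate selection macro F1 = {sel_report.macro_f1:.3f}")
```

Output:

```
classification macro F1 = 0.994 on 370 instances
candidate selection macro F1 = 0.980
```

On this synthetic corpus the Action vocabulary is category-specific, so
recovery is near-perfect with the Action oracle; without it (mode
`static_plain`) macro F-1 drops to ~0.69/0.65 because multi-Action mentions
share one representation and context words dilute the signal — the same
qualitative pattern the methods show on real data (classification ≥
candidate selection; oracle ≥ plain).

A `icf-coder` CLI wraps the same pipeline (`generate`, `train-embeddings`,
`train`, `predict`, `evaluate`, `stats`, `iaa`); every run directory gets
its serialized configuration and seed.

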