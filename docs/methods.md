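# Methods

## Task and scope

The package assigns second-level ICF categories to activity mentions — text
spans describing a patient performing Mobility or Self-Care/Domestic Life
activities. The unit that carries a label is the **Action** component inside
a mention; a mention may hold zero, one, or several Actions. ICF qualifier
assignment, detection of mentions in raw text, and third/fourth-level codes
are out of scope.

The label inventories are fixed: 13 Mobility labels and 16 Self-Care/
Domestic Life labels. d465 (*Moving around using equipment*) is excluded
because equipment use is modeled as an Assistance component, so the action
itself reduces to d455; "other specified"/"unspecified" ICF codes are never
used — the catch-all is a non-ICF token `OTHER`. Two SNOMED CT-derived
labels, *Manage medication* (285033005) and *Therapy* (709007004), separate
patient engagement in pharmacological and non-pharmacological treatment
from the broad d570. Negation is recorded on Actions only for the
d570-scope labels (suicide/self-harm, substance use, treatment
non-compliance), where it is clinically load-bearing.

Each category carries a `definition_text` used for candidate selection. The
d-code strings shipped here are WHO-style short definitions written for
this package; ICF editions differ in wording, so the JSON label-set loader
lets users substitute their preferred edition. The `OTHER` labels use the
fixed strings "Mobility other or unspecified" / "Self-care or domestic life
other or unspecified", and the SNOMED labels use their concept names
("Ability to manage medication", "Compliance behavior to the therapeutic
regimen").

## Text normalization

Tokenization is rule-based (regex alternation: placeholders, URLs, dates,
times, numbers, words, single characters) with exact source offsets; any
callable with the same contract can replace it. Normalization substitutes
`[NUMBER]`, `[URL]`, `[DATE]`, `[TIME]` before lowercasing, and is
idempotent. Only pure-numeric tokens map to `[NUMBER]`; mixed forms such as
`300'` keep their measurement mark because unit cues are clinically
meaningful. The detection regexes ship in `textprep.py` and are part of the
package version, so normalized corpora are reproducible. Normalization is
applied both to embedding-training corpora and to mention/definition text
for static embeddings; the contextual encoder receives raw text (flag
`normalize_static` switches this).

## Representations

Four strategies build fixed-length vectors (n = static dimension, d =
contextual dimension): `static_plain` (mean over all tokens, n),
`static_oracle` (mean of Action tokens concatenated with mean of the
remaining tokens, 2n), `ctx_plain` (mean of contextual token vectors, d),
`ctx_oracle` (mean of contextual Action-token vectors only, d — the vectors
are already conditioned on the full mention). Degenerate cases are defined
explicitly: when the Action covers every token, the non-Action half is the
zero vector (keeps dimensionality, signals "no context"); out-of-vocabulary
tokens without subword fallback are skipped from means, with a zero vector
plus warning if nothing remains. Punctuation tokens are included in means
by default.

The static trainer is skipgram with negative sampling (window 5 with
dynamic shrinking, 5 negatives, unigram^0.75 noise distribution, linear
learning-rate decay from 0.05) plus fastText-style hashed character n-gram
buckets (3–6 chars, 20k buckets by default): a word's input vector is the
average of its word vector and its n-gram bucket vectors, and unseen words
fall back to the bucket average. Training is deterministic given the seed.
Models serialize to word2vec text format; bucket vectors go to a
`.subword` companion file so fallback survives reload.

The contextualized encoder is an interface (`encode(text) -> one vector per
token`, deterministic). The shipped `HashingContextualEncoder` derives a
unit vector per token from a stable hash and mixes in the mean of
neighboring tokens' base vectors, giving context-sensitive, reproducible
vectors with no trained weights; it exists so the contextual code paths are
fully exercisable offline, and it makes no claim to linguistic quality.

## Coders

**Classification** is a linear SVM (one-vs-rest, squared hinge, C = 1.0,
class weighting off — all exposed in `ClassifierConfig`). Inputs are
standardized (per-feature mean/variance from the training set, stored with
the model): margin-based losses with a fixed C are scale-sensitive, and
embedding means are not unit-scaled.

**Candidate selection** conditions each category's definition embedding on
the mention: the network input is the unit-normalized mention vector
concatenated with the definition vector; the output is a conditional
category embedding of the mention's dimensionality, scored by cosine
against the mention vector, argmax wins, ties break to label-set order.
Conditioning on the *direction* of the mention vector makes cosine scores
exactly invariant to positive rescaling of the input. The depth/width
schedule follows the representation: three transformations of width equal
to the mention dimension for static modes (300 plain / 600 oracle at the
full 300-dimensional scale — "3-layer" is read as three hidden
transformations of the stated width), one transformation of width 768 for
contextual features. Activation ReLU on all but the last transformation;
`init="identity"` (paired with linear activation) passes the definition
through unchanged, so an untrained network reduces to raw
cosine-to-definition ranking — a useful baseline and test anchor.

Training minimizes cross-entropy over softmax of cosine scores with
temperature 0.1 (a pairwise hinge loss is available), with Adam (lr 0.01),
batches of 64, at most 100 epochs, and early stopping on a 10% holdout of
the training instances (patience 8, best weights restored). Deterministic
given the seed.

Instances are built one per gold Action. In non-oracle modes all Actions of
a multi-Action mention share the mention-level representation with their
own labels — preserving the published instance counts, and intentionally
making the non-oracle problem partly unlearnable (identical inputs,
different labels), which is the structural reason the Action oracle helps.

## Evaluation protocol

Splits are by document (all mentions of a document travel together), with
every category required to keep ≥ 20% (configurable) of its instances in
the test side. The search runs seeded randomized restarts (≤ 10,000)
maximizing the worst category's coverage, then greedily moves the training
document richest in the deficient category into the test set; infeasibility
is reported naming the category. Cross-validation uses balanced
document-level folds (k = 10 by default; sizes differ by ≤ 1).

Metrics: per-category precision/recall/F-1 from one-vs-rest confusion
counts and macro F-1 (unweighted mean). Categories with zero gold and zero
predicted instances are excluded from the macro mean — with per-fold
evaluation, rare categories can be absent from a fold and would otherwise
contribute undefined terms. Significance is a paired bootstrap over test
instances (the unit is the instance, the usual convention for paired system
comparison; document-level resampling is available via `unit="document"`);
the one-sided p-value is the fraction of 1,000 replicates in which system A
fails to beat system B on the chosen metric (macro F-1 by default; the
statistic is the difference in macro F-1). Identical systems therefore get
p = 1 under the one-sided definition; a two-sided variant is provided.

Inter-annotator agreement is span-level F-1 with one-to-one matching:
`exact_span` (default; label must also match when items carry labels) or
`overlap`. Overlap matching uses maximum bipartite matching on the overlap
graph rather than a left-to-right greedy pass, because the maximum match
count is symmetric under swapping annotators (greedy matching is not) and
deterministic.

## Synthetic data

The generator emulates the published dataset structure so that every module
is testable without any real clinical text. Defaults are derived from the
published summary tables: per-category Action proportions (e.g. Walking
23.0% of Mobility Actions; d570 43.6% of Self-Care/Domestic Life Actions),
geometric mentions-per-document (means ≈ 9.8 / 12.1 for documents with
mentions), the fraction of documents without mentions (≈ 0.13), of mentions
without Actions (5.4% / 3.4%), and the multi-Action rate (mean extra
Actions per action-bearing mention 0.367 / 0.207, geometric). Mobility
documents are all consultative-examination reports; Self-Care/Domestic Life
mixes report types evenly. One document per claimant, so the
one-document-per-(claimant, type) constraint holds by construction.

Mentions render from per-category phrase templates (≥ 5 per category,
editable JSON) whose Action/Assistance/Quantification slots become
components with exact offsets; d570-scope categories include negated
variants used 15% of the time. Action vocabulary is category-specific by
default; `shared_vocab_fraction` appends phrases from a shared pool to
probe confusable regimes. OCR noise applies substitutions from a confusion
table (l↔1, O↔0, m→rn, ...), deletions and insertions at a per-character
rate, with all annotation offsets remapped; a deletion that would erase an
annotated span entirely is demoted to a substitution so span invariants
always hold.

`study_shaped_fixture` is a separate, deterministic builder that realizes
the published summary counts *exactly* (document/mention/Action totals,
per-category frequencies, train/test columns) with template-rendered text —
a synthetic stand-in for the unshareable corpora, used by the statistics
report checks and the acceptance script. One bookkeeping subtlety mirrored
from the published tables: for Mobility, documents with mentions (251)
exceed train+test documents (248); the surplus documents carry only
Action-less mentions and stay outside the split, which is the only reading
consistent with the per-category train/test sums.

What the generator does **not** emulate: real clinical syntax, discourse
structure, spelling variation beyond the OCR table, genuine category
boundary ambiguity, or annotator disagreement. Synthetic recovery results
(macro F-1 ≈ 0.95–1.0 with the Action oracle at 120 documents, 50-dim
embeddings) therefore validate pipeline correctness and the qualitative
method orderings — classification ≥ candidate selection, oracle ≥ plain —
not expected accuracy on real notes, where reported performance is far
lower.

## Numerical and design choices

* Offsets are 0-based half-open character offsets everywhere.
* Skipgram sigmoid arguments are clipped to ±30; the learning rate decays
  linearly over all batches.
* Cosine denominators are floored at 1e-12; a zero mention vector is an
  error at selection time (cosine undefined).
* Ties in both coders resolve deterministically (argmax takes the first
  maximum, i.e. label-set order).
* Percentages in the statistics report follow the published table style:
  category shares to one decimal, per-category train/test shares as
  integers; undefined percentages (zero denominators) are `None`.
* Problem sizes in tests and the acceptance script (120 documents, 50-dim
  embeddings, 60 selector epochs) were chosen as the smallest configuration
  at which the recovery experiment is comfortably stable across seeds.
* Seeds are explicit arguments everywhere; the CLI default seed is a fixed
  documented constant, never wall-clock.

## Known limitations

* The packaged ICF definition strings are a stand-in for a specific ICF
  edition's wording; candidate-selection behavior depends mildly on them.
* The hash-based contextual encoder is a plumbing substitute for a trained
  encoder; contextual-mode results on synthetic data say nothing about what
  a pretrained clinical encoder would achieve.
* The skipgram trainer is tuned for small corpora used here; for
  multi-hundred-million-word corpora a native implementation would be the
  practical choice behind the same model interface.
* `iaa_f1`'s overlap policy counts matches only; fragmentary agreement
  (one long span vs. two short ones) counts as a single match.
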