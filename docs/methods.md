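# Methods

`medcascade` extracts medication information from hospital discharge
summaries.  Six field types are recognized — medication name (`m`),
dosage (`do`), mode of administration (`mo`), frequency (`f`), duration
(`du`), and reason (`r`) — and assembled into *entries*, each a single
medication event carrying one name, up to five non-name fields, and a
context label `ln` marking whether the event appears in a medication
list or in running narrative.

## Document model and pre-processing

Documents are plain text, tokenized per line on whitespace.  A token is
addressed as `line:token` with 1-based line numbers (blank lines count)
and 0-based token indices; spans are inclusive at both ends, so a
single-token field has identical start and end coordinates.  Punctuation
stays attached to its token; field texts are normalized by lowercasing
and stripping trailing `, . ;` from each token, which is why the span
covering `mg,` reads `0.4 mg`.

Section headings are lines opening with a run of capital letters and a
colon.  Candidate headings are collected over a training corpus and kept
when they occur more than a frequency threshold (default 3); at
segmentation time each recognized heading opens a section running to the
next heading.  Fields detected inside excluded sections (default FAMILY
HISTORY and ALLERGIES, where medication mentions are not considered
patient medications) are dropped from system output *after* detection, so
a misdetected section boundary degrades output gracefully instead of
hiding text from the taggers.  The excluded headings are always
recognized as section starts even when rarer than the threshold: the
exclusion list comes from the annotation guidelines, not from corpus
statistics, and on small corpora the frequency filter would otherwise
silently disable the exclusion rule.

POS tags are consumed only as categorical features, through a pluggable
interface.  The bundled default is a deterministic rule tagger
(closed-class word table, suffix rules, digit/punctuation shapes), so the
pipeline runs with no external model; any Penn-style tagger can be
substituted per line of text.

## Field detection

Detection is IOB sequence labeling with maximum-entropy (multinomial
logistic) classifiers, decoded greedily left to right; each token's
features may include the one and two previously predicted tags.  Ties in
the argmax are broken by the tagset's fixed label order with `O` last,
and a repair pass rewrites any orphan `I-x` to `B-x` (the alternative —
relabeling to `O` — deletes evidence, so repair is preferred).

The cascade comprises:

- **find_name** — 3 labels (`B-m`, `I-m`, `O`);
- **context_type** — a binary list/narrative classifier applied to each
  detected name occurrence, using the section, the comma and token counts
  of the name's line, the name itself, its line position, and adjacent
  words;
- **find_others** — 11 labels over the five non-name types, with
  features that reference the detected names.

The single-pass alternative **find_all** is one 13-way tagger over all
six types.  It cannot use features that depend on a previous module's
output, so the name-proximity features are disabled there; its `ln`
labels still come from the context classifier, since complete entries
need them.

Feature families (names carry the family prefix, so ablating a family
removes exactly its features):

- **F1** — word uni/bi/trigrams in a ±2 token window (window radius
  configurable).
- **F2** — POS of the token and neighbors, prefixes/suffixes of length
  1–4, token length, capitalization class, digit shape, containing
  section; in the non-name configuration also a dosage-pattern flag
  (number followed by a unit in {mg, mcg, g, ml, units}) and, when
  detected names are available, proximity features: whether the token
  lies inside a name, the token-stream gap to the previous and the next
  (look-ahead) name when on the same line, and the signed line distance
  to the nearest name.  Proximity matters because non-name fields sit
  within a few tokens of their medication while lookalike phrases in
  plain narrative ("admitted for severe headache", "stayed for 10 days")
  do not.
- **F3** — the previous one and two predicted IOB tags.
- **F4** — gazetteer flags: whether an n-gram (n = 1..3) containing the
  token occurs in a medication-name lexicon.  F4a uses the lexicon built
  from training gold; F4b adds an external drug list and implies F4a.

Numeric features (counts, positions, distances) are emitted both raw and
bucketed (0, 1, 2, 3–5, 6+) so a purely binary feature representation
remains possible.

Training minimizes L2-penalized multinomial logistic loss (strength 1.0,
lbfgs, tolerance 1e-6, at most 500 iterations — the learner's own
defaults, since no canonical values exist for this task).  Training-time
F3 features use gold tags (teacher forcing); find_others trains with gold
name locations and predicts with detected ones.  Fewer than two observed
labels yield a constant classifier.  Training and decoding are
deterministic given data order and seed.

## Field linking

Each detected non-name field is linked to the closest prior medication
name unless the closest subsequent name is nearer by strictly more than
a margin (default two lines), in which case the subsequent name wins;
with no prior name the subsequent one is used (and symmetrically).
Distances are measured in lines between span starts; same-line distance
is 0.  Fields in a document containing no name at all are discarded.

When several fields of one type link to the same name, the name yields
as many entries as the maximum per-type multiplicity: within each type
the fields are ordered by absolute line distance from the name (token
distance breaking ties) and the i-th nearest fills entry i; unfilled
slots are `nm`.  This concrete multi-field rule is one reasonable
instantiation of behavior that is underdetermined in general; it is
isolated behind `LinkConfig` so it can be replaced wholesale.

## Evaluation

A system field exactly matches a gold field when type, start, and end
coincide.  *Vertical* metrics score fields per type (and pooled), with
fields deduplicated by (type, span) within a document; precision and
recall are defined as 0 on an empty denominator.  *Horizontal* metrics
score whole entries: a match requires all six slots to agree (absent with
absent, present with exact match), with greedy one-to-one matching in
document order.  The context label is excluded from horizontal matching
by default and reported separately as context accuracy; a switch includes
it.  Percentages are reported to one decimal.

Two systems are compared with an approximate randomization test: each
document's pair of outputs is swapped with probability 0.5, the corpus
|ΔF| recomputed, and p = (i+1)/(n+1) over n = 10,000 shuffles (i counts
pseudo-differences at least as large as the observed one; the +1
smoothing keeps p positive).  The absolute difference makes the test
two-sided.  Per-document match counts are precomputed, so shuffles are
O(documents) aggregations; an exhaustive 2^D enumeration is available for
small document sets and is used to calibrate the sampler in tests.  A
Bonferroni helper (α/m) adjusts thresholds for families of comparisons.

## Synthetic corpus

Clinical gold data for this task is access-restricted, so the package
ships a seeded generator whose output exercises every pipeline stage.
Documents have headed sections: an admission diagnosis, two narrative
sections whose sentences embed medications ("Because of severe headache
she was started on Aprizolvex 25 mg twice a day ..."), an occasional
excluded FAMILY HISTORY/ALLERGIES section containing a drug mention that
is deliberately absent from the gold, and a DISCHARGE MEDICATIONS list
with lines like `Aprizolvex 25 mg, po, bid, for 10 days,`.  Gold entries
are emitted with exact span coordinates and round-trip through the
annotation reader/writer.

Default conditions, chosen once:

- **Entry density.**  Poisson mean 8.5 entries/document — one quarter of
  the ≈34 names per long document seen in reference corpora of this
  task, keeping test corpora small while preserving structure.
- **Field mix.**  Per-entry presence probabilities follow the per-name
  ratios of the reference data: dosage 0.52, frequency 0.47, mode 0.39,
  duration 0.06, reason 0.16; 70% of entries are list-context.
- **Vocabulary.**  ~300 invented brand-style drug names (all
  non-clinical), composed from fixed syllable inventories — large enough
  that small training samples leave most names unseen, as with real
  prescribing vocabularies.  Duration phrases are built compositionally
  ("for a total of 21 days", "until symptoms resolve") and reasons are
  1–4 token adjective/noun phrases over ~40 nouns, so the two fields are
  longer and far more lexically variable than the closed-class
  dosage/mode/frequency fields — reproducing the well-known difficulty
  ordering among the six types.
- **Confounders.**  Filler sentences include non-medication temporal and
  complaint phrases ("he stayed in the unit for 10 days") drawn from the
  same inventories as the true duration/reason fields, plus capitalized
  proper nouns (clinicians, hospitals, services) so neither lexical
  identity nor capitalization alone solves detection.  A small typo rate
  (0.01) perturbs filler tokens only.

What the generator does *not* emulate: clinically plausible prescribing,
misspelled or abbreviated drug names, OCR noise, cross-document
vocabulary drift, or annotation disagreement.  Tests passing on this
corpus demonstrate that the machinery is correct and that the expected
qualitative phenomena appear; they do not predict absolute scores on
real clinical text, which is substantially harder (notably for name
recall and for duration/reason boundaries).

## Experiment harnesses

Both experiments split documents by a seeded shuffle (held-out fraction
0.3) and train on the first k documents of the training pool.  The
learning curve trains at several fractions with and without the external
drug list and reports held-out horizontal F.  The cascade-versus-
single-pass harness trains both architectures per fraction on identical
splits and attaches an approximate-randomization p to each pairing.  On
the default synthetic conditions the two architectures converge to
statistically indistinguishable scores at full training size (both
field-detection routes approach their ceiling on this corpus); the
external-list advantage at small training sizes and the monotone
learning curves are reproduced robustly.

## Numerical and degenerate-input choices

- Posterior computation subtracts the max log-score before
  exponentiation; probabilities sum to 1 within 1e-9.
- Randomization comparisons use `>= observed - 1e-12` to keep exact ties
  counted under floating-point noise.
- Empty documents tokenize to a single empty line; empty annotation
  files parse to empty entry lists; a tagger failure on a line yields
  "UNK" POS labels for that line rather than an error.
- All-punctuation tokens survive text normalization as their raw
  lowercased form, so spans never normalize to empty text.
- `problem sizes`: the default test and acceptance runs use 100-document
  corpora (≈8.5 entries each) for system-level checks and 6–25 documents
  for calibration fixtures; these sizes are the package's chosen study
  conditions for the synthetic corpus.
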