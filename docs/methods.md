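# Methods

## Task and model

The package classifies the sentences of a medical abstract into
{Population, Intervention, Outcome, Background, StudyDesign, Other} and then
selects at most one sentence per abstract for each of the three PICO
elements P, I, O. Sentences may carry several labels at once (a sentence can
introduce both the population and the intervention).

The statistical stage is a linear-chain conditional random field over the
sentence sequence of an abstract:

    P(Y | X) = (1/Z_X) exp( Σ_t Σ_k λ_k f_k(y_{t-1}, y_t, x, t) )

with binary observation features (each token of a sentence's feature bag
crossed with its label, plus a constant bias token) and label-bigram
transition features. Weights are estimated by maximum likelihood with a
Gaussian prior — the objective adds −‖λ‖²/(2σ²) — using exact
forward–backward gradients and L-BFGS. Decoding is Viterbi. The CRF is
implemented inside the package on numpy/scipy; training batches sequences of
equal length so the forward–backward recursions run vectorized across
abstracts (training 800 abstracts takes a few seconds on one CPU).

### Features

Per sentence, ten features in three families:

* **semantic** — f1 demographic hits (age/race/gender terms), f2 disorder
  hits, f3 procedure/chemical/drug hits, f4 outcome-cue hits. These come
  from flat-file lexicons with greedy longest-phrase matching; a token
  counts for at most one category (categories are disjoint by
  construction). The shipped lexicons are this package's own curated lists
  (~100 terms per category) sized for synthetic and desk-scale corpora —
  there is no published reference inventory for the outcome-cue list in
  particular — and are user-replaceable; a production deployment would
  substitute a full clinical vocabulary (UMLS semantic groups).
* **structural** — f5 title overlap, f6 keyword overlap, f7 normalized
  header, f8 length in words, f9 grouped position code.
* **lexical** — f10, one `word|POS` unigram per token. POS tags come from a
  compact rule tagger (closed-class lookup plus suffix rules); the bag of
  words only needs stable, roughly correct tags, and no full tagger is
  available as a dependency here.

Semantic counts additionally enter the feature bag as categorical tokens —
`MPt_k` (demographic), `MP_k` (disorder), `MI_k` (intervention), `MT_k`
(title overlap) — so that "three demographic hits" is one reusable symbol
rather than a numeric value that disperses the feature alphabet.

### Header normalization and grouping

Raw section headers are uppercased, trimmed and mapped onto the four common
headers (OBJECTIVE, METHOD, RESULTS, CONCLUSION) through an extensible
variant table; unknown spellings degrade to NOHEADING with a warning rather
than failing, since real collections contain dozens of idiosyncratic
headers. The grouped position code f9 assigns every sentence of a headed
section its section's code — 3, 6, 12, 14, roughly the cumulative average
section sizes — which clusters the structural vocabulary; sentences without
a header keep their own 1-based index, capped at 14, so positional
information survives in unstructured abstracts.

Unstructured *training* abstracts are pseudo-structured: headers are
fabricated from gold labels (Background→OBJECTIVE; P/I/StudyDesign→METHOD;
Outcome→RESULTS; Other→CONCLUSION) so the structural features stay
informative. Test abstracts never get pseudo-headers (gold labels are
unavailable then); unstructured test abstracts keep NOHEADING, and the rule
stage exists precisely because the statistical stage is weaker there. For
the same reason, cross-validation folds are pseudo-structured only on their
training side.

### Multi-label training and test-time repetition

A training sentence with several gold labels occupies consecutive duplicate
positions in its sequence, one per label (the standard training-file
layout). At test time each sentence is duplicated `reps` times (default 3,
matching the number of classes of interest) before Viterbi decoding, and
the labels decoded for the copies are pooled into the sentence's candidate
set. Transition context differs across copies — the first copy still sees
the previous sentence, the last sees the next — which is what lets
identical observations receive different labels. The plain (reps=1) decode
is always included in the pool: repetition is meant to *add* plausible
candidates for the downstream scorer to arbitrate, so it must never lose
the baseline prediction (pooling only the copies' labels would not
guarantee that, since a middle copy sees only identical neighbours).

### Selection

Per element and abstract, candidates are ranked by
`wTotal = wPoM + wPoT + wCo + wSe`:

* `wPoM` = 2 if the sentence is where the element typically lives —
  METHOD section / first third (unstructured) for P and I, RESULTS / last
  third for O — else 0. The 2-vs-0 weighting nudges without dominating.
* `wPoT` = f5 (title overlap).
* `wCo` = 2 when the candidate set contains both P and I (P/I scoring
  only): sentences covering both elements are preferred.
* `wSe` = f1+f2 for P, f3 for I, f4 for O.

The O rule is this package's construction by symmetry with P and I: O has a
single semantic feature (f4) and typically sits in RESULTS / the last
third; coexistence does not apply. Ties break to the earliest sentence —
element statements tend to open their section — making selection
deterministic. An element with no candidate anywhere in the abstract is a
*missed abstract*, the input to the rule stage.

### Rule stage

For each missed P or I element, every sentence is tested against a
three-clause disjunction (strong semantic evidence anywhere; weak evidence
in METHOD; weak disorder/procedure evidence within the first three
sentences of an unstructured abstract — index < 4, 1-based). The strong
threshold 3 reflects the average semantic-feature value in Population
sentences; both thresholds are configurable, and lowering the strong
threshold can only enlarge the hit set (the rules are monotone in f1, f2,
f3). Sentences whose rules fire compete through the same wTotal scorer,
with the fired elements as the candidate set. The stage never touches a
non-empty statistical selection, so element-wise combined recall is ≥ the
statistical stage's by construction; its cost is precision, since broad
rules also fire on abstracts that genuinely lack the element.

## Evaluation

Precision = TP/(TP+FP), Recall = TP/(TP+FN), F = 2PR/(P+R). Two modes, and
every report names its mode: **sentence-level** counts each
(sentence, label) pair; **abstract-level** judges the single selected
sentence per element — TP when it carries the element's gold label, FP when
it does not, FN when a gold-bearing abstract gets no or a wrong selection.
A selected sentence with several gold labels is a TP for each element it
matches. Zero-denominator metrics are reported as *undefined* (None), never
as 0 or NaN; where a macro average needs a number, undefined contributes 0.
k-fold cross-validation partitions abstracts (never sentences) with a
seeded shuffle.

## Synthetic data

The generator emulates: the skewed sentence-label distribution of a
realistic mixed collection (P .068, I .058, O .366, Other .279,
StudyDesign .020, Background .209), a 314/800 structured fraction,
header-spelling noise (a known variant instead of the common header, p=0.3),
titles built from the abstract's P/I terms (so title overlap is
informative), and class-conditional vocabulary governed by one
signal-strength dial `s`: with probability `s` a sentence draws terms from
its class vocabulary and lands in its typical position, otherwise it is
uniformly placed filler. Cross-class overlap is deliberate and mirrors how
abstracts are written: Background sentences often name the condition and
population under discussion, Outcome sentences restate the condition and
intervention being evaluated, and concluding sentences may name the
recommended intervention. This shared vocabulary is what transmits the
label skew into depressed P/I recall — with class-private vocabularies even
a rare class would be trivially separable and the skew would not matter.
Sentence lengths are uniform on 8–25 words, abstracts 6–12 sentences,
multi-label (P∧I) sentences occur at rate 0.05. Everything derives from one
seed; a given spec reproduces the corpus byte for byte.

What the generator does *not* emulate: real biomedical syntax and discourse
(sentences are shuffled term/filler bags), annotation inconsistency,
abbreviation/synonym variation beyond the lexicon lists, and
non-therapeutic abstracts where the Intervention concept itself is absent.
Passing tests therefore demonstrate that the pipeline's machinery — feature
extraction, training, decoding, selection, rules, accounting — behaves as
specified under the corpus's statistical shape, not that a particular
F-score would be attained on any real collection.

## Numerical and design choices

* Gaussian prior variance 10 (the best-performing setting of the model
  experiments); training proportion 1.0; L-BFGS capped at 200 iterations,
  gradient tolerance 1e-4. Optimization is deterministic (zero
  initialization), so identical inputs give identical models.
* Thirds boundaries use the ceiling convention: the first third takes
  ⌈L/3⌉ sentences, the last ⌊L/3⌋; abstracts shorter than 3 sentences are
  all "first third".
* Unknown feature tokens at test time are ignored; candidate sets are never
  empty (Viterbi always labels); selection and rule ties break to the
  earliest index.
* Unknown headers warn and degrade to NOHEADING; empty sentences are
  rejected at feature extraction.
* Experiment sizes in the test suite: the signal-recovery and imbalance
  checks train on 800 abstracts (the reference training size) with held-out
  sets of 200–400 abstracts, where rare-class recall estimates are stable;
  smaller shared fixtures (100–150 abstracts) exercise the machinery
  elsewhere.

## Known limitations

* The lexicons are small curated stand-ins; real deployments need a
  clinical vocabulary, and lexicon coverage directly bounds f1–f4 quality.
* No rule stage exists for the Outcome element (its statistical recall is
  already high; broad O rules would mostly add false positives).
* The rule stage's precision degrades on collections rich in abstracts that
  lack a P or I element, since threshold rules cannot tell "missed" from
  "not applicable".
* The CRF uses binary observation features only; no embeddings, character
  n-grams or dependency features.
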