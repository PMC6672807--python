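# Methods

This note documents the models and procedures implemented in `ecrfpop`, the
defaults chosen where the design was open, and what the synthetic data can
and cannot show.

## Concept mapping

A terminology is a flat table of concepts — namespaced identifier, one of
seven semantic categories (`medical_problem`, `test`, `treatment`,
`body_structure`, `observable`, `qualifier`, `value`), preferred term, and
synonyms. Matching operates on normalized strings: NFKC + casefold, with
whitespace and punctuation removed, so comparison is effectively
character-level in both Latin and CJK scripts. Similarity is the
Dice-normalized longest common subsequence, `2·LCS(a,b)/(|a|+|b|)`: exact
synonyms score 1.0, and a single character edit in a term of length n costs
roughly `2/(2n±1)`, so the default threshold of **0.8** tolerates one or two
edits in typical clinical terms while rejecting unrelated words. LCS itself
is the classic O(nm) dynamic programme; the test suite checks it against a
brute-force subsequence-enumeration oracle. Candidates are ranked by score,
then longer matched synonym, then lexicographic concept id (pure
determinism; no linguistic claim), one result per concept, at most `top_k`
(default 5). Alternative normalizations of LCS exist (e.g. by max length);
the Dice form was chosen because it is symmetric, length-balanced, and makes
the one-edit cost easy to reason about.

## Extraction pipeline

The pipeline is deliberately deterministic — dictionary and rules, no
trained components — so that identical inputs always give identical outputs
and every behavior is unit-testable.

- **Segmentation.** Sentences split on `。，；！？ . ; ! ?` and newlines.
  One necessary refinement: an ASCII period *between two digits* is treated
  as a decimal point, never a terminator, otherwise measured values
  ("0.5 cm") would be severed from their observables. Tokens are words and
  numbers; CJK runs tokenize as single characters; punctuation marks are
  their own tokens.
- **Entity recognition.** Per sentence, every token window up to 6 tokens
  wide is a candidate. Exact normalized-synonym hits form a first tier;
  remaining windows are scored by the LCS mapper at the configured
  threshold. Overlaps resolve within each tier to the longer span, then the
  higher score, then the leftmost — so "ventricular septal defect" always
  beats a nested "septal defect", and an exact hit is never displaced by a
  fuzzy window that swallowed a neighbouring word. Numeric tokens become
  `value` mentions.
- **Assertion.** A mention is `absent` when a negation cue appears within a
  5-token window before it (pre-cues: *no, not, without, denies, 无, 否认,
  未见, …*) or after it (post-cues: *absent, negative, …*) in the same
  sentence, with the scope terminated by an intervening comma or adversative
  conjunction (*but, however, 但是, …*). This is the ConText convention;
  the cue lists are configuration, extensible per deployment. Everything
  else is `present`. "Not mentioned" is deliberately *not* a mention-level
  label: it emerges at the form level from the absence of any mention.
- **Relations.** Seven typed category signatures (problem–treatment,
  problem–test, problem–problem, bodystructure–observable,
  problem–observable, observable–qualifier, observable–value). For each
  type, each right-argument mention links to the nearest left-argument
  mention in the same sentence within 12 tokens, preferring the preceding
  one on ties; a mention heads at most one relation per type. Nearest
  pairing is a stand-in for syntactic attachment; it is exact on the
  clause-per-finding sentences the generator emits and approximate on
  free text.
- **Value association.** Each numeric token attaches to the nearest
  *preceding* observable in its sentence (falling back to the nearest
  following one), captures an adjacent unit token from a configurable unit
  list (cm, mm, %, °C, bpm, …), and inherits a related problem from an
  existing problem–observable (preferred) or bodystructure–observable
  relation on that observable. Numbers with no observable in their sentence
  are dropped and logged, never fatal.

All offsets are 0-based half-open character spans into the raw document, so
`text[span]` reproduces the surface exactly; this is the contract the
form-level "back to source" provenance relies on.

## Forms and prepopulation

A form has 3–4 sections: tri-state true/false elements split by source
document (section I answers only from the admission record, section II only
from the imaging report), multiple choice, and fill-in-the-blank. Bindings
tie each element to concepts: a single concept for tri-states, an ordered
(label, concept) list for choices, and an observable + related-problem pair
plus expected unit for blanks. `validate_bindings` guarantees before any
prepopulation that every referenced concept exists and sits in an
admissible category.

Prepopulation rules, per kind:

- **true/false**: no mention of the bound concept in the element's source
  documents → `not_mentioned`; otherwise the resolved assertion decides
  true/false. Conflicting assertions across mentions are resolved by the
  configured policy — default **last mention wins** in document order (later
  statements in clinical notes tend to be conclusions), `present_wins`
  available — and logged.
- **multiple choice**: an option is selected iff its concept resolves to
  present; the selection is an order-free label set.
- **fill-in-the-blank**: among value assignments whose observable maps to
  the bound observable, those whose related problem matches the bound
  problem are preferred (the problem filter is waived when no candidate
  carries a problem); first in document order wins among survivors, logged
  when plural. A unit differing from the expected unit is flagged but the
  value is still filled.

Provenance spans accompany every non-empty answer (the deciding mentions'
spans, per-option spans, or the value's source span); empty and
not-mentioned answers carry none. Prepopulation is idempotent and pure.

Scoring equality, used identically for accuracy, agreement counting and
adjudication: tri-states compare exactly; choices compare as sets; blanks
compare numerically within 1e-9 after exact unit match, two empty blanks
being equal.

## Evaluation statistics

- **Gold standard**: two independent entry sets are compared element-wise;
  agreements become gold, disagreements are taken from a third resolver
  (an error if the resolver is silent). The inter-operator consistency rate
  is `100·n_agree/n_total`, half-up to 2 decimals.
- **Group comparison**: outcomes (per-participant accuracy, mean seconds
  per case) are compared as `MD = mean(ln b) − mean(ln a)` with Welch's
  two-sided t test and a Welch–Satterthwaite 95% CI; `exp(MD)` is exactly
  the ratio of geometric means (identity-tested), and headline percent
  changes round half-up to integers. A pooled equal-variance variant sits
  behind a flag; Welch is the default because group variances are not
  assumed equal. No multiplicity correction is applied. Raw-scale medians
  and IQRs are reported alongside, as is conventional for skewed outcomes.
- **Error taxonomy** (assisted arm only, requires a prepopulated baseline):
  final == gold → no error; final ≠ gold and final == prefill → error
  *without* modification (commission); final ≠ gold and final ≠ prefill →
  error *with* modification (cognitive). The three labels partition the
  elements by construction. Percentages are shares of each kind's error
  total, half-up to 2 decimals, undefined (None) when a kind has no errors.

## Synthetic data: what it emulates, what it does not

`generate_case` draws, per element, whether a finding is mentioned
(`finding_prevalence`, default **0.6** — findings on a purpose-built form
are usually discussed either way), and if mentioned whether it is negated
(`negation_prob`, default **0.3**, a typical negation share in clinical
narratives). Affirmed/negated states render through small English sentence
templates into the element's source document; blanks draw a uniform value
from a per-observable range (lesion size 0.2–1.5 cm by default) and render
an observable-of-problem measurement sentence. Surface noise: a
non-preferred synonym with probability **0.2**, one random character edit
(delete/substitute/duplicate) with probability **0.05**. A blank's value is
planted only when the tri-state element bound to its related problem (same
document, if the form has one) drew true, so gold answers can never
contradict each other. All randomness flows from explicit seeds
(`numpy.random.SeedSequence` children per case), making cohorts
byte-reproducible.

The generator emulates the *structure* of short clinical narratives —
asserted and negated findings, observable–value–unit statements, synonym
and typo variation, a two-document case layout — not their language.
Passing tests therefore demonstrate the pipeline's contracts (recovery of
planted facts under controlled noise), not clinical-grade NER performance
on real, ungoverned prose with anaphora, abbreviation, or temporality.

The participant model reviews one element at a time: a wrong prefill is
noticed with `p_notice_error` and, once noticed, corrected to gold with
`p_fix_correct` (otherwise changed to a uniformly drawn wrong value
excluding gold and the current value); a correct prefill is spuriously
broken with `p_spurious_change`. Defaults — assisted arm 0.55 / 0.85 /
0.01; manual arm (reviewing an empty form) 1.0 / 0.90 / 0.05 — were set
once as plausible review behavior; the commission-error mechanism, not the
particular rates, is the object of study. Section times are lognormal
(right-skewed, as human response times are), with manual medians of roughly
26/49/10/18 s per section and assisted medians about one third lower,
σ = 0.35 throughout.

The in-silico trial (`run_experiment`) uses 60 cases and 12 participants
per arm by default, the scale the package's own simulations and the
acceptance script report at; tests use smaller cohorts (6–80 cases) chosen
to keep Monte-Carlo intervals tight for each property under test.

## Numerical and degenerate-input choices

- Table percentages round half-up (`decimal.Decimal`), never banker's
  rounding; headline percent changes round half-up to integers.
- `lcs_similarity` on two empty strings, `consistency_rate` with zero
  total, log comparison with a non-positive value, and a taxonomy call
  without a prepopulated baseline are errors, not silent defaults.
- Empty documents yield empty extractions; empty text maps to no
  candidates; a terminator-free sentence spans all of its non-whitespace
  text.
- Homonymous exact hits resolve to the lexicographically smallest concept
  id; all tie-breaks in the package are total orders, so every output is a
  pure function of (inputs, seed).

## Known limitations

- Rule-based extraction has no notion of syntax: long coordinated sentences
  can defeat nearest-neighbour relation pairing, and negation scope is
  token-window based.
- The terminology fixture is a 29-concept demonstration vocabulary, not a
  SNOMED-CT or RadLex distribution; identifiers in the `SYN:` namespace are
  synthetic.
- The behavior model is stationary — no learning, fatigue, or order
  effects across a session — and assumes single-pass section entry.
- Multi-word units and ranges ("0.4–0.6 cm") are not parsed; the first
  numeric token wins.
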