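# Methods

## Annotation model

A document is raw Unicode text with two standoff layers of labeled,
half-open character intervals (0-based, over code points; BRAT files use
the same convention). The PII layer has thirteen classes — FirstName,
LastName, Occupation, Company, Location, FullDate, DatePart,
HealthCareUnit, PersonalID (the Chilean RUN), ID, PhoneNumber, Email, Age —
and is required to be non-overlapping: replacement of overlapping intervals
is ill-defined. A repair helper (`resolve_pii_overlaps`) keeps the longer
span of each overlapping pair. The clinical layer (Disease, BodyPart,
Medication) may nest or overlap freely, which is the normal situation in
clinical text (a body part inside a disease phrase). Cross-layer overlap is
permitted; its interaction with masking is defined below. Every span caches
its surface string and every loading path re-slices the text and compares,
so offset drift is detected at the boundary, never propagated. Input text
is read as UTF-8 and never normalized — normalization would silently move
offsets.

## Masking and offset maps

Masking replaces each PII span with a bracketed English class-name
placeholder (`[Last Name]`, `[Full Date]`, ...). The table is overridable
per run (e.g. for Spanish-style tags). Because placeholder length differs
from span length, the edit is captured as an `OffsetMap`: an ordered list
of copied and replaced segments tiling the source text. The map is monotone
by construction; positions inside a replaced interval map to the
replacement's start (configurably its end), and maps compose. The text is
rebuilt in one pass from untouched pieces plus replacement strings — a
single edit script over the immutable source, so no offset ever moves under
a later edit.

Clinical spans are remapped through the offset map. A clinical span
strictly inside a PII span cannot survive masking; the default policy drops
it with a warning (a hard-error mode exists). A clinical span partially
overlapping PII is clipped to its longest contiguous non-PII residue,
preserving as much clinical signal as the mask allows; clips are logged.

## Pseudonymization rules

Each PII class has one rule; all rules run behind the same replacement
engine as masking and emit audit records (original span, surrogate, rule,
random draws consumed).

- **Names.** Gender is inferred by membership in the shipped lists of 100
  common Chilean female/male first names; when inferable, the surrogate is
  drawn from the same-gender list, otherwise from the union. Last names
  draw uniformly from a 100-name list. The original is excluded, casing is
  mirrored (all-caps stays all-caps), multi-word names draw one distinct
  replacement per word.
- **Occupations, companies, healthcare units.** Static lookup tables map
  surfaces to category placeholders in the spirit of ISCO major groups for
  occupations (`técnico`, `operario`, ...), industry categories for
  companies (`una constructora`, `un centro educativo`, ...) and
  institution categories for healthcare units (`un hospital`, `una
  clínica`, ...). Lookups are case-insensitive; misses use the total
  fallbacks `trabajador`, `una empresa`, `un hospital`. The shipped
  occupation table holds ~170 hand-audited Chilean occupation surfaces;
  users can ship their own tables (plain two-column TSV) for their corpus.
- **Locations.** Five location types — region, city/comuna, street, named
  place, country — each with a word list of real Chilean values; the type
  of a surface comes from a surface→type table, unknown types yield
  `un lugar`. The enumeration of types is a toolkit choice; the lists are
  replaceable.
- **Dates.** Full dates (numeric day-first by default — the Chilean
  convention — with a month-first switch and a `>12` auto-detect; or
  textual `26 de marzo de 2021`) shift by a per-document constant day
  offset, then the year is wrapped cyclically into the window 2017–2023.
  The rendering preserves the input's separator, zero-padding style, 2- vs
  4-digit year and month-name casing. Date parts resample: weekdays to a
  uniformly different weekday, lone months/years to different values inside
  the window, day/month pairs shift with the document offset. Unparseable
  surfaces fall back to masking and are flagged in the audit trail.
- **Ages.** The integer in the surface shifts by a per-entity draw of
  ±1–5 years, clamped to 18–90 (plausible working ages); surrounding span
  text is preserved verbatim. When a clamped draw would reproduce the
  original value the sign is flipped, so surrogates never equal originals.
- **RUN.** A random 7–8 digit body in a contemporary adult range with the
  check character computed by the standard modulo-11 scheme (weights 2–7
  cycling from the least significant digit; remainder 11 → `0`, 10 → `K`);
  thousands-dot and hyphen layout copied from the input.
- **IDs, phones.** Character-class-preserving randomization for IDs
  (digit→digit, upper→upper, lower→lower, punctuation copied); phones keep
  the `+56` prefix and the mobile `9` marker and randomize the remaining
  digits in place.
- **Emails.** No structure worth preserving beyond rough length: a random
  pronounceable local part at the reserved domain `example.com`.

### Randomness, consistency and privacy

Every draw comes from a generator seeded by a stable SHA-256 hash of the
master seed and a scope key. For most classes the key is (document id,
class, surface), which makes identical surfaces within a document map to
identical surrogates *by construction* and makes output order-invariant
across the corpus; with corpus-wide consistency the key drops the document
id. Ages are keyed per entity (each mention shifts independently). The
per-document day offset keeps intervals between full dates intact unless a
year-wrap intervenes — chosen over per-entity shifts because clinical
timelines are part of the signal the pseudonymized corpus should retain.

The engine additionally enforces a document-local privacy guarantee: no
original PII surface of length ≥ 4 may occur as a substring anywhere in the
output. Random rules re-draw (bounded) when a candidate collides with any
original surface of the document, including containment of the span's own
surface (e.g. `9/4/2018` inside `19/4/2018`); the day offset is re-drawn
when an offset-dependent date surrogate would collide, escalating to
year-moving magnitudes (366–720 days) when a bare-year surface elsewhere in
the document pins the year. Table-lookup classes emit fixed category
placeholders and need no guard. The guard is skipped for corpus-scope
memoized classes, where one-surface-one-surrogate takes precedence.

## Evaluation

Span matching defaults to exact (start, end, label): the pairwise-F1
agreement literature the measure comes from uses strict matching, and exact
matching makes the score symmetric — P(A,B)=R(B,A) and F1(A,B)=F1(B,A) —
which an agreement coefficient needs. An overlap mode (same label,
intersecting intervals, greedy one-to-one by maximal overlap, ties to the
earlier start) is available for sensitivity analysis. Reports carry
per-class rows (support counted on the reference argument) and a
`Global (micro avg)` row recomputed from pooled TP/FP/FN; precision or
recall with an empty denominator is reported as 0, the common NER
convention, and the report footer says so. NER evaluation is the same
machinery with gold as the fixed reference role, defaulting to the clinical
layer.

## Corpus statistics

The tokenizer takes maximal runs of word characters (accents included) as
tokens and each remaining non-space character as its own token, keeping
offsets so the text reconstructs exactly. Vocabulary is counted on
case-folded surfaces; lexical diversity is 100·V/N; mean ± sd summaries use
the population (n) denominator; annotated-token counts count a token once
even under nesting. Because the tokenizer is a toolkit choice, absolute
token and vocabulary counts are only comparable between corpora processed
by this toolkit — the shipped reference constants for the restricted
occupational-health corpus are therefore checked for *internal* arithmetic
consistency (the diversity and tokens-per-document ratios follow from the
printed counts; the per-class frequencies sum to the printed layer totals),
not for tokenizer-dependent reproduction.

## Synthetic corpus generator

The generator emulates the register of occupational-health admission
notes: short template sentences (admission circumstance, occupation and
employer, event date, symptoms, referrals, contact data), one entity per
sentence, with disease phrases occasionally realized as `head de bodypart`
carrying a nested BodyPart span. Its defaults are the study conditions:
subcorpus split 1,614/1,787 accident vs disease, per-class mix proportional
to the published frequency table (so rare classes like Email at 2/15,479
are genuinely rare), entities per document drawn from a clamped Gaussian
with mean 8.6 and sd 5.7 on 1–30, dates in 2017–2023. Class counts per
document are a single multinomial draw; nested body parts consume BodyPart
allocations so realized counts equal the draw exactly. About 12 % of
occupation/company/unit/location surfaces are drawn from outside the
shipped tables to exercise the fallback rules. Template wording avoids
every annotatable surface, since text outside spans is never rewritten and
no de-identifier could repair such a collision.

What the generator does *not* emulate: misspellings, non-standard
abbreviations, free word order, PII embedded mid-sentence without a cueing
phrase, and discourse structure. Passing pipelines on synthetic data
therefore demonstrates mechanical correctness (offsets, determinism,
privacy of annotated spans, metric arithmetic), not detection-level realism
— PII spans are inputs to this toolkit, never predicted.

The noise model (`corrupt_annotations`) drops, jitters, or duplicates
spans with per-class probabilities, producing a pseudo second annotator or
pseudo predictor whose expected metrics are analytic: drop-only noise at
rate d gives recall 1−d with precision 1; spurious-only noise lowers
precision and leaves recall at 1. This calibration is what the acceptance
checks measure.

## Numerical and design choices

- Degenerate inputs: empty corpora are errors for statistics; documents
  must be non-empty; an `.ann` with no annotations is a valid empty layer.
- Tie-breaks: overlap matching prefers larger overlap, then earlier start;
  clipping prefers the longest residue, then the earliest; BRAT output
  orders spans by (start, end, label) with ids T1..Tn, making writing
  canonical and round trips byte-stable.
- Problem sizes in the self-checks (10,000 RUN draws, 1,000 scanned
  documents, 500 oracle trials, 260 documents ≈ 2,270 spans for the
  noise-recovery band, 100 round-trip corpora) give the binomial bands
  quoted in the tests at 3σ while keeping the whole suite within seconds.
- The restricted source corpus is available only on request; every check
  that would need it is either recast as internal arithmetic over its
  published summary constants or exercised on the synthetic generator. The
  census functions (`reference.corpus_census`) reproduce the published
  counting directly should the data be obtained.

## Known limitations

- The privacy guard is document-local and substring-based; it does not
  model paraphrase or inference re-identification, and surfaces shorter
  than 4 characters (bare day numbers, 2-letter initials) are outside its
  guarantee.
- Date surrogates can break cross-date intervals when a year-wrap fires or
  when the collision guard escalates the offset; the audit trail makes such
  documents identifiable.
- BIO export is per class and flattens same-class nesting to the outermost
  span, an inherent limit of flat BIO.
- The shipped resource tables are seeds, not a census of Chilean
  occupations or institutions; production use should extend them from the
  target corpus vocabulary.
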