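# clindeid

A de-identification toolkit for Spanish clinical narratives, built around
the occupational-health anamneses that mutual-insurance clinics record at
patient admission. Such texts mix clinical content (diseases, body parts,
medications — often nested, as in *esguince de **tobillo***) with dense
personally identifiable information (PII): occupations, employers, dates,
ages, names, the Chilean national identification number (RUN), phone
numbers, healthcare units, locations and emails. Thirteen PII classes and
three clinical entity classes are modelled as standoff character-interval
annotations over the raw text.

The toolkit provides, for corpus builders and clinical-NLP researchers:

- **Masking** — every PII span is replaced by its bracketed class name
  (`Dr. Gonzalez` → `Dr. [Last Name]`), with exact offset remapping of the
  clinical layer.
- **Pseudonymization** — every PII span is replaced by a realistic
  surrogate of the same class: names resampled from lists of 100 common
  Chilean first/last names with gender and casing preserved; occupations,
  companies and healthcare units generalized through lookup tables to
  category placeholders (`mecánico industrial` → `técnico`, a school →
  `un centro educativo`, a named hospital → `un hospital`) with total
  fallbacks (`trabajador`, `una empresa`, `un hospital`, `un lugar`);
  dates shifted by a per-document day offset and wrapped into 2017–2023;
  ages shifted ±1–5 years; RUNs regenerated with valid modulo-11 check
  digits; IDs and phones randomized structure-preservingly. Deterministic
  under a seed, with a replacement audit trail.
- **Evaluation** — pairwise span-F1 for inter-annotator agreement and
  entity-level precision/recall/F1 for NER output, exact or overlap
  matching, per class and micro-averaged.
- **Corpus statistics** — token and vocabulary counts, lexical diversity
  (100·V/N), per-class frequencies, tokens-per-entity and
  entities-per-document distributions.
- **Synthetic corpus generation** — seeded Spanish anamnesis documents with
  gold PII and clinical annotations (including nesting), so every stage is
  testable without access to restricted clinical data, plus a calibrated
  noise model for exercising the evaluation machinery.

Interchange formats: BRAT standoff (`.txt` + `.ann`), JSON-lines, and
per-class CoNLL BIO export.

## Worked example

```bash
clindeid synth --n-docs 5 --seed 1 --out corpus.jsonl
clindeid pseudo --in corpus.jsonl --out pseudo.jsonl --seed 42 --audit audit.tsv
clindeid mask  --in corpus.jsonl --out masked.jsonl
clindeid iaa   --a corpus.jsonl --b corpus.jsonl --mode exact
```

The agreement report of a corpus against itself prints all-perfect scores
with the per-class supports of the generated corpus:

```
class                  support       P       R      F1
Global (micro avg)          10    1.00    1.00    1.00
Occupation                   4    1.00    1.00    1.00
Age                          3    1.00    1.00    1.00
FullDate                     3    1.00    1.00    1.00
[matching: exact; empty-denominator P/R reported as 0]
```

and `audit.tsv` records one line per substitution, e.g.

```
doc_id       class       start  end  surface          surrogate    rule
synth-00002  Occupation  54     69   médico cirujano  profesional  Occupation
synth-00002  Age         101    108  38 años          34 años      Age
synth-00002  FullDate    151    161  01/04/2020       22/04/2020   FullDate
```

In Python the same pipeline is three calls:

```python
from clindeid import GeneratorConfig, SurrogateConfig, generate_corpus
from clindeid.pseudo import pseudonymize_document

corpus = generate_corpus(GeneratorConfig(seed=1, n_documents=5))
out = pseudonymize_document(corpus[0], SurrogateConfig.default(seed=42))
print(out.text)                      # surrogate text
print(out.replacement_records[0])   # who replaced what, and how
```

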