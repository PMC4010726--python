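# ephysminer

Semi-automated extraction of neuron electrophysiology measurements from
HTML journal articles.

Basic biophysical measurements — resting membrane potential (V_rest),
input resistance (R_in), membrane time constant (τ_m), spike threshold,
amplitude, and width — are reported across thousands of papers with
heterogeneous terminology and formatting, and most of the structured
numbers live in data tables of the form

|            | RMP (mV)        | R_in (MΩ)   |
|------------|-----------------|-------------|
| mitral cell| −55.1 ± 2.0 (10)| 120 ± 11 (10)|
| granule cell| −71.2 ± 1.4 (9)| 480 ± 40 (9) |

`ephysminer` turns such articles into queryable measurement records for
curators, modelers, and meta-analysts. The pipeline:

1. **Ingest** — parse article HTML into titled sections and dense table
   grids (rowspan/colspan contents replicated into every covered cell).
2. **Annotate** — flag header-like cells (majority-alphabetic text, or
   first-row/column labels), fuzzily match each header against a dual
   lexicon — 28 electrophysiological measurement concepts and a list of
   neuron types with NeuroLex-style identifiers, each with synonyms —
   and map every data cell to its (neuron, concept) pair. The match
   score is `max` of four similarity metrics on normalized strings
   (sequence ratio, token-span substring ratio, token-sort ratio,
   token-set ratio), scaled to 0–100 with a default threshold of 80.
3. **Parse values** — decompose cell strings right to left through the
   `XX ± YY (ZZ)` / `XX (LL–HH)` grammar into mean, error term
   (deliberately unresolved between SD and SEM), sample size, and range.
4. **Recognize neurons** — rank candidate neuron types for the article
   by bag-of-words synonym frequencies (multi-word synonyms counted as
   contiguous n-grams), as a top-k "best guess" to seed curation.
5. **Extract metadata** — species, strain, electrode type, preparation
   type, junction-potential correction (phrase presence plus
   sentence-scope negation), recording temperature (cue-sentence
   numeric/"room" patterns), and animal age (postnatal-day patterns),
   from the methods section and optional MeSH term sidecars, via an
   auditable rule inventory. Every assignment carries a verbatim
   evidence span.
6. **Assemble, store, export** — normotypic (neuron, concept, value,
   metadata) records with position-unique keys, SQLite persistence,
   CSV/JSON export/import, and conjunctive querying.

Manual corrections enter through **curation overlay** files that
overwrite algorithmic header assignments (the original call is kept for
audit), mirroring how expert validation works in practice.

A **synthetic corpus generator** emits articles in exactly this shape —
with configurable header-typo and synonym-choice noise, value-dialect
mixes, and metadata templates — together with complete ground truth, so
every stage is measurable without downloading a single paper. The
**evaluation harness** scores concept-assignment accuracy, neuron top-k
accuracy, and per-concept metadata accuracy with exact (Clopper–Pearson)
95% binomial confidence intervals, always reporting numerator and
denominator.

## Worked example

```python
from ephysminer import (
    default_vocabulary, parse_article, annotate_table,
    extract_methods_section, extract_metadata, assemble_records,
)

html = open("article.html").read()          # any well-formed article HTML
vocab = default_vocabulary()                # 28 concepts + neuron types

article = parse_article(html)
annotated = annotate_table(article.tables[0], vocab, threshold=80)
metadata = extract_metadata(extract_methods_section(article), article.mesh_terms)
records = assemble_records(annotated, article, metadata)
for r in records:
    print(r.neuron_id, r.concept_id, r.value.mean, r.value.error_value, r.value.n)
```

On the table shown above this prints (ids from the packaged vocabulary):

```
syn0000004 rmp -55.1 2.0 10
syn0000004 rin 120.0 11.0 10
syn0000005 rmp -71.2 1.4 9
syn0000005 rin 480.0 40.0 9
```

i.e. four records: mitral-cell V_rest −55.1 ± 2.0 mV over 10 cells,
mitral-cell R_in 120 ± 11 MΩ, and the granule-cell pair — each linked to
the article's metadata and ready for export.

The same flow is available from the shell:

```bash
ephysminer generate --seed 3 --n 2 --out corpus/
ephysminer parse --in corpus/article_0000.html --mesh corpus/article_0000.mesh.txt --out art.json
ephysminer neurons --in art.json --top 3
ephysminer metadata --in art.json --out metadata.json
ephysminer evaluate --corpus corpus/ --out report.json
```

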