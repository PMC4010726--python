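# Methods

This note documents the models, rules, and numerical choices behind
`ephysminer`, what the synthetic-data generator does and does not
emulate, and the known limitations.

## The extraction model

The pipeline assumes that the structured numbers of a cellular
electrophysiology article live in its data tables, and that a table can
be read as a grid in which one axis enumerates measurement concepts and
the other enumerates neuron types (or experimental conditions). This is
a deliberate narrowing: prose and figures carry most published values,
but tables are the only substrate where header-to-cell alignment makes
fully unsupervised extraction tractable and where a curator's time is
best spent on validation rather than discovery.

### Header detection

A cell is header-like when alphabetic characters exceed half of its
non-whitespace characters, or when it sits in the first row or column
and contains at least one letter. The 0.5 cutoff is a package choice:
measurement strings ("−65.2 ± 1.3 (12)") are overwhelmingly
non-alphabetic, and terse labels ("+/+", "Rin") are rescued by the
first-row/column clause.

### Fuzzy concept matching

Headers are matched against synonym lists with a composite score in
[0, 100]: the maximum of four metrics computed on normalized strings
(case-folded, punctuation collapsed, short parenthetical unit
annotations such as "(MΩ)" stripped):

- plain sequence ratio (`difflib.SequenceMatcher`);
- best token-span substring ratio — the shorter string against every
  contiguous *token* span of the longer. Spans are token-aligned rather
  than raw character windows so that "ahp" does not score 100 against
  the tail of "fahp";
- token-sort ratio (tokens sorted before comparison);
- token-set ratio (shared-token subset comparison).

`max` keeps the composite monotone in each component and auditable: a
high score can always be attributed to one named metric. Identical
normalized strings score exactly 100. The default threshold is 80,
exposed everywhere as a parameter; it is an operating point, not a
tuned constant.

Candidate ranking breaks score ties in favor of an exact synonym hit
first, then longer matched synonym, then lexicographic id. The
exact-first refinement matters whenever one entry's synonym is nested
in another's ("sag" vs "sag amplitude"): without it, the longer
containing synonym would win a 100–100 tie against the header's own
exact synonym.

The known failure mode is a header naming a concept absent from the
lexicon: "EPSP amplitude" crosses the threshold against an existing
"… amplitude" concept. This is by design — the matcher proposes, the
curation overlay disposes — and extending the 28-concept lexicon is the
long-term fix.

### Namespaces, orientation, cell mapping

Each header cell is matched independently against the concept and the
neuron namespaces; the higher best score claims the cell, ties going to
the concept namespace. Orientation is resolved by counting concept
assignments in row 0 versus column 0 (strict majority for rows;
ties → concepts-in-columns). Data cells then inherit the concept of
their column and the neuron of their row (or transposed). A cell can
never receive two concepts or two neurons, because each line contributes
at most one assignment.

Condition handling is conservative: all lines are treated as normotypic
unless a label matches a small deny-list ("ko", "-/-", "mutant", "tx")
or a curation overlay marks it. Identifying manipulated conditions is
fundamentally a curator judgment; the deny-list only automates the
unambiguous cases.

### Value grammar

Cell strings are parsed right to left: trailing parenthesized group
first (integer → sample size; separated pair → range; lone decimal →
error-term dialect, logged as a guess), then a ±-suffixed error term,
then the remaining leading number as the mean. Normalization maps
Unicode minus and sign-dashes to ASCII hyphens, unifies "+/-" spellings
to ±, canonicalizes in-parenthesis dashes to the en-dash range token,
and removes thousands separators; it is idempotent. The error term is
stored as `unresolved` between SD and SEM — tables rarely say which,
and a wrong guess silently corrupts downstream variance estimates; a
curation overlay can resolve it. Unit suffixes are stripped and survive
only in `raw_text`; unit conversion and magnitude plausibility checks
are out of scope.

### Neuron recognition

Articles are reduced to n-gram counts over case-folded alphanumeric
tokens (n up to the longest neuron synonym, capped at 6). A neuron
type's score is the summed count of its synonyms as contiguous n-grams.
Counting phrases rather than unordered word bags prevents "cell" from
cross-firing between "mitral cell" and "granule cell". No stemming and
no acronym expansion ("MCs" is not recognized): exact token match keeps
the ranking auditable. A scope flag optionally restricts counting to
abstract + results sections, which removes introduction/discussion
mentions of other neuron types; the default is full text.

### Metadata rules

The rule inventory covers species, strain (strain implies species),
electrode type, preparation type, junction-potential correction,
recording temperature, and animal age. MeSH-term rules fire on exact
membership in the article's term list; regex rules fire
case-insensitively on the methods text; when both fire with different
labels, the MeSH hit wins the primary slot (curated indexing beats
pattern guessing) and all candidates are reported. Negation scope for
the junction potential is the containing sentence, segmented by a
deterministic splitter with abbreviation guards ("e.g.", "ca.",
"approx.", "Fig.", …). Temperature is only read from sentences bearing
a recording/experiment cue ("record", "experiment", "perform",
"maintain"), which is what keeps slice-storage temperatures ("stored at
4°C") out of the record; the cue list is a package choice. Age is
stored in postnatal days only; embryonic and week/month expressions are
recognized as evidence but left unconverted rather than converted by a
guessed gestation/rounding rule.

## Synthetic corpus

The generator emulates the studied article shape: heading-delimited
sections, a methods section instantiated from the same sentence
patterns the metadata rules target (including distractors such as a
storage-temperature sentence), a results section in which one focal
neuron type is mentioned (9 times) more often than up to three
distractors (2 mentions each), and 1–3 tables per article with headers
drawn from vocabulary synonyms and cells formatted through the value
grammar. Defaults: 50 articles, orientation transposed with
probability 0.25, non-canonical synonym use 0.3, typo rate 0 (raised
explicitly in degradation experiments), value-dialect mix
(±n 0.45, ± only 0.2, range 0.15, mean only 0.1, missing 0.1), and
per-concept metadata inclusion 0.9 — chosen as a realistic mix of how
such tables are actually formatted. Distractor neurons whose synonyms
are embedded in the focal neuron's name (e.g. "granule cell" inside
"dentate gyrus granule cell") are excluded at selection time, since
every focal mention would otherwise feed the distractor's count and
top-1 recovery would not be well defined. Typos are substitution-only,
applied per character at header level — the simplest noise that drives
fuzzy scores below 100.

What the generator does **not** emulate: publisher-specific HTML
quirks, tables mixing several condition axes, values in prose or
figures, abbreviation-heavy neuron naming, multi-language text, and
OCR artifacts. Perfect scores on synthetic corpora therefore certify
the pipeline's internal consistency — that each stage inverts the
generating grammar it claims to handle — not its recall on arbitrary
published HTML, where accuracy is bounded by vocabulary coverage and
formatting diversity.

## Evaluation

Concept-assignment accuracy counts ground-truth header cells (not
articles) as the denominator. Neuron recognition reports top-k success
per article; top-3 ⊇ top-1 by construction. Metadata accuracy is
per-concept over articles, an absent true value counting as correct
only when the extractor also reports absence. Intervals are exact
Clopper–Pearson (beta-quantile) at 95%, preferred over asymptotic
intervals because per-concept counts are small; exactness makes them
conservative, so simulated coverage sits at or above the nominal level.
All fractions are reported with numerator and denominator.

Problem sizes in the shipped checks — 10,000 grammar samples for the
round trip, 50 noise-free articles for end-to-end recovery, 20 seeds ×
3 articles for the typo-degradation sweep, 30-article corpora in the
acceptance script — were chosen so the full suite runs in a few minutes
on one CPU while keeping denominators in the hundreds.

## Packaged vocabulary and rules

The default vocabulary ships 28 measurement concepts (resting membrane
potential, input resistance, membrane time constant, spike threshold /
amplitude / peak / width / half-width / rise / decay, rheobase, the AHP
family, ADP, sag, adaptation, firing rates, F–I slope, latency, ISI
statistics, capacitance, access resistance) with common header
synonyms, and a starter list of 30 neuron types. `sao830368389` (CA1
pyramidal cell) is the one widely cited NeuroLex identifier included;
the remaining `syn…` ids are synthetic package-local placeholders, and
users mining real corpora should extend or replace the neuron list with
their own NeuroLex export via `load_vocabulary`. Capacitance and F–I
slope are carried with `dimensionless` unit tags because the unit
vocabulary is documentation, not algebra. The metadata rule file mirrors
the categorical rule inventory (species, strains, electrode, preparation)
and is user-replaceable.

## Known limitations

- Vocabulary coverage bounds recall; unknown concepts either fall below
  threshold (silent miss) or false-match a neighbor (the EPSP case).
- The bag-of-words recognizer cannot separate neuron types that are
  only distinguished by context, and ignores acronyms.
- Protocol/calculation differences between labs (e.g. spike amplitude
  from threshold vs from rest) are not normalized; records carry a free
  `note` field and curation status instead.
- Tables whose layout is neither concepts-in-columns nor
  concepts-in-rows (nested header bands spanning both axes) are mapped
  line-by-line and may need overlay correction.
- The CSV export does not carry evidence spans; round-tripping through
  CSV preserves record fields but drops evidence (JSON export keeps it).
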