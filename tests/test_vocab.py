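"""Vocabulary loading, invariants, and fuzzy matching behavior."""

import json

import pytest
from hypothesis import given, settings, strategies as st

from ephysminer.vocab import (
    ConceptVocabulary,
    DuplicateIdentifierError,
    DuplicateSynonymError,
    EphysConcept,
    MissingVocabularyFile,
    NeuronTypeEntry,
    TermMatch,
    VocabularyError,
    composite_match_score,
    default_vocabulary,
    load_vocabulary,
    match_term,
    normalize_term,
)


# ---------------------------------------------------------------------------
# loading & invariants
# ---------------------------------------------------------------------------


def test_default_vocabulary_has_28_concepts(vocab):
    assert len(vocab.concepts) == 28
    assert len(vocab.neuron_types) >= 10
    # the six most commonly cited measurements are all present
    names = {c.canonical_name for c in vocab.concepts}
    for required in (
        "resting membrane potential",
        "input resistance",
        "membrane time constant",
        "spike amplitude",
        "spike width",
        "spike threshold",
    ):
        assert required in names


def test_load_vocabulary_missing_file(tmp_path):
    with pytest.raises(MissingVocabularyFile):
        load_vocabulary(tmp_path / "nope.json")


def test_load_vocabulary_zero_concepts(tmp_path):
    p = tmp_path / "v.json"
    p.write_text(json.dumps({"version": "1", "concepts": [], "neuron_types": []}))
    with pytest.raises(VocabularyError):
        load_vocabulary(p)


def test_duplicate_synonym_across_concepts_rejected():
    mk = lambda cid: EphysConcept(
        concept_id=cid, canonical_name=f"name {cid}",
        synonyms=frozenset({f"name {cid}", "shared synonym"}),
        unit_dimension="voltage",
    )
    with pytest.raises(DuplicateSynonymError):
        ConceptVocabulary(concepts=[mk("a"), mk("b")])


def test_duplicate_concept_id_rejected():
    mk = lambda name: EphysConcept(
        concept_id="dup", canonical_name=name,
        synonyms=frozenset({name}), unit_dimension="time",
    )
    with pytest.raises(DuplicateIdentifierError):
        ConceptVocabulary(concepts=[mk("one"), mk("two")])


def test_canonical_name_always_a_synonym():
    c = EphysConcept(
        concept_id="x", canonical_name="some name",
        synonyms=frozenset({"alias"}), unit_dimension="time",
    )
    assert "some name" in c.synonyms


# ---------------------------------------------------------------------------
# composite score
# ---------------------------------------------------------------------------


def test_identity_scores_100():
    assert composite_match_score("input resistance", "input resistance") == 100.0
    # identical after case-folding / whitespace collapse
    assert composite_match_score("Input  Resistance", "input resistance") == 100.0


def test_unit_annotation_is_noise():
    assert composite_match_score("input resistance (MΩ)", "input resistance") == 100.0


def test_abbreviation_scores_below_spelled_out_form():
    abbrev = composite_match_score("Rin (MΩ)", "input resistance")
    spelled = composite_match_score("input resistance (MΩ)", "input resistance")
    assert abbrev < 100.0
    assert abbrev < spelled


def test_epsp_amplitude_false_match_reaches_threshold():
    # with no EPSP concept in the lexicon, "EPSP amplitude" resembles
    # "spike amplitude" strongly enough to cross the default threshold —
    # the known failure mode that curation overlays exist to fix
    assert composite_match_score("EPSP amplitude", "spike amplitude") >= 80.0


def test_empty_input_rejected():
    with pytest.raises(ValueError):
        composite_match_score("", "x")
    with pytest.raises(ValueError):
        composite_match_score("x", "   ")


@settings(deadline=None, max_examples=200)
@given(
    a=st.text(alphabet="abcdefgh ", min_size=1, max_size=20),
    b=st.text(alphabet="abcdefgh ", min_size=1, max_size=20),
)
def test_score_symmetric_and_bounded(a, b):
    if not normalize_term(a) or not normalize_term(b):
        return
    s1 = composite_match_score(a, b)
    s2 = composite_match_score(b, a)
    assert s1 == s2
    assert 0.0 <= s1 <= 100.0
    assert composite_match_score(a, a) == 100.0


# ---------------------------------------------------------------------------
# match_term
# ---------------------------------------------------------------------------


def test_rmp_synonym_hits_resting_membrane_potential(vocab):
    matches = match_term("rmp", vocab.concepts, 80)
    assert matches[0].target_id == "rmp"
    assert matches[0].score == 100.0


def test_gibberish_matches_nothing(vocab):
    assert match_term("zzqx", vocab.concepts, 80) == []


def test_empty_term_gives_empty_result(vocab):
    assert match_term("", vocab.concepts, 80) == []
    assert match_term("  ()  ", vocab.concepts, 80) == []


def test_match_term_deterministic(vocab):
    a = match_term("spike amplitude", vocab.concepts, 60)
    b = match_term("spike amplitude", vocab.concepts, 60)
    assert a == b


def test_exact_synonym_outranks_containing_synonym(vocab):
    # "sag" is an exact synonym of the sag ratio; "sag amplitude" merely
    # contains it, so the exact entry must rank first despite being shorter
    matches = match_term("sag", vocab.concepts, 80)
    assert matches[0].target_id == "sag_ratio"


def _brute_force(term, entries, threshold):
    """Independent oracle: exhaustively score every synonym of every entry
    with composite_match_score and apply the documented ordering rules."""
    results = []
    norm = normalize_term(term)
    if not norm:
        return []
    for entry in entries:
        target = getattr(entry, "concept_id", None) or entry.neuron_id
        best = None
        for syn in sorted(entry.synonyms):
            if not normalize_term(syn):
                continue
            s = composite_match_score(term, syn)
            key = (int(normalize_term(syn) == norm), s, len(syn))
            if best is None or key > best[0]:
                best = (key, syn, s)
        if best and best[2] >= threshold:
            results.append((best[2], best[0][0], best[1], target))
    results.sort(key=lambda t: (-t[0], -t[1], -len(t[2]), t[3]))
    return [(t[3], t[2], t[0]) for t in results]


@pytest.mark.parametrize(
    "term",
    ["rmp", "input resistance", "spike amp", "tau", "granule cell",
     "mitral cells", "ahp", "sag amplitude", "resistance", "cell"],
)
def test_match_term_equals_exhaustive_scoring(vocab, term):
    entries = (vocab.concepts + vocab.neuron_types[:22])[:50]
    got = match_term(term, entries, 70)
    expected = _brute_force(term, entries, 70)
    assert [(m.target_id, m.matched_synonym, m.score) for m in got] == expected


def test_raising_threshold_shrinks_match_set(vocab):
    term = "spike amplitude"
    for lo, hi in [(50, 70), (70, 85), (85, 100)]:
        low_ids = {m.target_id for m in match_term(term, vocab.concepts, lo)}
        high_ids = {m.target_id for m in match_term(term, vocab.concepts, hi)}
        assert high_ids <= low_ids
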