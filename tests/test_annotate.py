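"""Header detection, concept/neuron assignment, orientation, curation."""

import pytest

from ephysminer.annotate import (
    CurationError,
    annotate_table,
    apply_curation,
    detect_header_cells,
    resolve_orientation,
    HeaderAssignment,
)
from ephysminer.ingest import RawTable, parse_article
from ephysminer.synth import GenerationParams, generate_article


def _table(grid):
    return RawTable(table_id=0, caption="", grid=tuple(tuple(r) for r in grid))


EXAMPLE = _table(
    [
        ["Neuron type", "RMP (mV)", "input resistance (MΩ)"],
        ["olfactory bulb mitral cell", "-55.1 ± 2.0 (10)", "120 ± 11 (10)"],
        ["olfactory bulb granule cell", "-71.2 ± 1.4 (9)", "480 ± 40 (9)"],
    ]
)


def test_header_detection_rules():
    mask = detect_header_cells(EXAMPLE)
    assert mask[0][1] is True            # "RMP (mV)": mostly alphabetic
    assert mask[1][1] is False           # numeric data cell
    assert mask[1][0] is True            # row label
    # first-row/column cells need at least one letter
    t = _table([["", "1", "2"], ["3", "4", "5"]])
    m = detect_header_cells(t)
    assert not any(any(row) for row in m)


def test_annotate_maps_cells_to_neuron_concept_pairs(vocab):
    at = annotate_table(EXAMPLE, vocab, 80)
    assert at.orientation == "concepts_in_columns"
    assert at.cell_map[(1, 1)] == ("syn0000004", "rmp", None)
    assert at.cell_map[(1, 2)] == ("syn0000004", "rin", None)
    assert at.cell_map[(2, 1)] == ("syn0000005", "rmp", None)
    assert at.cell_map[(2, 2)] == ("syn0000005", "rin", None)


def test_all_numeric_table_gets_no_assignments(vocab):
    t = _table([["1", "2"], ["3", "4"]])
    at = annotate_table(t, vocab, 80)
    assert at.assignments == []
    assert at.cell_map == {}


def test_cell_never_maps_to_two_concepts_or_neurons(vocab):
    at = annotate_table(EXAMPLE, vocab, 80)
    for (r, c), (neuron, concept, cond) in at.cell_map.items():
        assert isinstance(neuron, (str, type(None)))
        assert isinstance(concept, (str, type(None)))


# -- orientation -------------------------------------------------------------


def _assign(kind, r, c, target="rmp"):
    return HeaderAssignment(r, c, kind, target_id=target, score=100.0)


def test_orientation_columns_when_concepts_in_row0():
    a = [_assign("ephys_concept", 0, i) for i in (1, 2, 3)]
    t = _table([["", "a", "b", "c"], ["x", "1", "2", "3"]])
    assert resolve_orientation(a, t) == "concepts_in_columns"


def test_orientation_tie_goes_to_columns():
    a = [_assign("ephys_concept", 0, 1), _assign("ephys_concept", 1, 0, "rin")]
    t = _table([["", "a"], ["b", "1"]])
    assert resolve_orientation(a, t) == "concepts_in_columns"


def test_transposed_synthetic_table_resolves_to_rows(vocab):
    params = GenerationParams(
        seed=4, n_articles=1, typo_rate=0.0, synonym_use_prob=0.0,
        orientation_mix=1.0,
    )
    html, _, truth = generate_article(params, 0, vocab=vocab)
    art = parse_article(html)
    for raw, tt in zip(art.tables, truth.tables):
        at = annotate_table(raw, vocab, 80)
        assert tt.orientation == "concepts_in_rows"
        assert at.orientation == "concepts_in_rows"


def test_noise_free_cell_map_equals_ground_truth(vocab):
    params = GenerationParams(seed=9, n_articles=1, typo_rate=0.0, synonym_use_prob=0.0)
    html, _, truth = generate_article(params, 2, vocab=vocab)
    art = parse_article(html)
    for raw, tt in zip(art.tables, truth.tables):
        at = annotate_table(raw, vocab, 80)
        for (r, c), h in tt.header_truth.items():
            got = at.assignment_at(r, c)
            assert got is not None
            assert (got.assigned_kind, got.target_id) == (h["kind"], h["target_id"])


# -- curation ---------------------------------------------------------------


def test_overlay_unassigning_header_drops_column(vocab):
    epsp = _table(
        [
            ["Neuron type", "EPSP amplitude (mV)"],
            ["olfactory bulb mitral cell", "4.2 ± 0.5 (7)"],
        ]
    )
    at = annotate_table(epsp, vocab, 80)
    # EPSP amplitude is not in the lexicon, so the fuzzy matcher lands on
    # some existing "... amplitude" concept — a false positive by design
    wrong = at.assignment_at(0, 1)
    assert wrong.assigned_kind == "ephys_concept"
    assert "amp" in wrong.target_id
    assert at.cell_map[(1, 1)][1] == wrong.target_id
    fixed = apply_curation(
        at, [{"table_id": 0, "row": 0, "col": 1, "assigned_kind": "unassigned"}]
    )
    assert (1, 1) not in fixed.cell_map or fixed.cell_map[(1, 1)][1] is None
    got = fixed.assignment_at(0, 1)
    assert got.source == "curated"
    assert got.previous.target_id == wrong.target_id  # audit trail


def test_empty_overlay_is_identity(vocab):
    at = annotate_table(EXAMPLE, vocab, 80)
    same = apply_curation(at, [])
    assert same.cell_map == at.cell_map
    assert [(a.row, a.col, a.assigned_kind, a.target_id) for a in same.assignments] == [
        (a.row, a.col, a.assigned_kind, a.target_id) for a in at.assignments
    ]


def test_curation_idempotent(vocab):
    overlay = [{"table_id": 0, "row": 0, "col": 1, "assigned_kind": "unassigned"}]
    at = annotate_table(EXAMPLE, vocab, 80)
    once = apply_curation(at, overlay)
    twice = apply_curation(once, overlay)
    assert once.cell_map == twice.cell_map
    a1 = once.assignment_at(0, 1)
    a2 = twice.assignment_at(0, 1)
    assert (a1.assigned_kind, a1.source) == (a2.assigned_kind, a2.source)
    assert a2.previous is not None and a2.previous.source == "algorithmic"


def test_overlay_bad_position_raises(vocab):
    at = annotate_table(EXAMPLE, vocab, 80)
    with pytest.raises(CurationError) as err:
        apply_curation(at, [{"table_id": 0, "row": 9, "col": 0, "assigned_kind": "unassigned"}])
    assert "(9, 0)" in str(err.value)


def test_condition_overlay_marks_column(vocab):
    geno = _table(
        [
            ["Parameter", "+/+", "stg/stg"],
            ["resting membrane potential", "-60 ± 1 (5)", "-50 ± 2 (5)"],
        ]
    )
    at = annotate_table(geno, vocab, 80)
    curated = apply_curation(
        at,
        [
            {"table_id": 0, "row": 0, "col": 2, "assigned_kind": "condition",
             "condition_label": "stg/stg"},
        ],
    )
    assert curated.cell_map[(1, 2)][2] == "stg/stg"
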