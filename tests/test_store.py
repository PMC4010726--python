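"""Record assembly, store constraints, querying, persistence, export."""

import random

import pytest

from ephysminer.annotate import annotate_table
from ephysminer.ingest import Article, RawTable
from ephysminer.metadata import MetadataRecord
from ephysminer.store import (
    DuplicatePositionError,
    MeasurementRecord,
    RecordStore,
    UnknownIdentifierError,
    assemble_records,
    export_csv,
    export_json,
    import_csv,
    import_json,
    CSV_COLUMNS,
)
from ephysminer.values import ParsedValue


def _table(grid):
    return RawTable(table_id=0, caption="", grid=tuple(tuple(r) for r in grid))


@pytest.fixture
def annotated_2x3(vocab):
    grid = [
        ["Parameter", "resting membrane potential", "input resistance", "membrane time constant"],
        ["olfactory bulb mitral cell", "-55.1 ± 2.0 (10)", "120 ± 11 (10)", "22 ± 3 (10)"],
        ["olfactory bulb granule cell", "-71.2 ± 1.4 (9)", "480 ± 40 (9)", "30 ± 4 (9)"],
    ]
    return annotate_table(_table(grid), vocab, 80)


@pytest.fixture
def article():
    return Article(pmid="12345678")


def test_cross_product_assembly(annotated_2x3, article):
    records = assemble_records(annotated_2x3, article, MetadataRecord())
    assert len(records) == 6
    pairs = {(r.neuron_id, r.concept_id) for r in records}
    assert len(pairs) == 6


def test_unparseable_cell_skipped(vocab, article):
    grid = [
        ["Parameter", "resting membrane potential", "input resistance", "membrane time constant"],
        ["olfactory bulb mitral cell", "-55.1 ± 2.0", "n.d.", "22 ± 3"],
        ["olfactory bulb granule cell", "-71.2 ± 1.4", "480 ± 40", "30 ± 4"],
    ]
    at = annotate_table(_table(grid), vocab, 80)
    records = assemble_records(at, article, MetadataRecord())
    assert len(records) == 5


def test_non_normotypic_condition_excluded(vocab, article):
    from ephysminer.annotate import apply_curation

    # genotype columns: measurements from the same neuron under wild-type
    # ("+/+") and mutant ("stg/stg") conditions; only normotypic data
    # become records
    grid = [
        ["Parameter", "olfactory bulb mitral cell", "stg/stg"],
        ["resting membrane potential", "-60 ± 1 (5)", "-50 ± 2 (5)"],
    ]
    at = annotate_table(_table(grid), vocab, 80)
    curated = apply_curation(
        at,
        [{"table_id": 0, "row": 0, "col": 2, "assigned_kind": "condition",
          "condition_label": "stg/stg"}],
    )
    assert curated.cell_map[(1, 2)][2] == "stg/stg"
    records = assemble_records(curated, article, MetadataRecord())
    assert [(r.row, r.col) for r in records] == [(1, 1)]
    assert records[0].value.mean == -60.0


def _record(i, vocab):
    return MeasurementRecord(
        pmid="12345678", table_id=0, row=1, col=i,
        neuron_id="syn0000004", concept_id="rmp",
        value=ParsedValue(mean=-60.0 - i, error_value=1.0, n=5),
    )


def test_duplicate_position_rejected(vocab):
    store = RecordStore(vocab=vocab)
    store.insert(_record(1, vocab))
    with pytest.raises(DuplicatePositionError):
        store.insert(_record(1, vocab))


def test_unknown_identifier_in_filter_raises(vocab):
    store = RecordStore(vocab=vocab)
    store.insert(_record(1, vocab))
    with pytest.raises(UnknownIdentifierError):
        store.query(neuron_id="sao_does_not_exist")


def test_query_conjunction_equals_linear_scan(vocab):
    rng = random.Random(7)
    store = RecordStore(vocab=vocab)
    neurons = [n.neuron_id for n in vocab.neuron_types[:5]]
    concepts = [c.concept_id for c in vocab.concepts[:5]]
    rows = []
    for i in range(60):
        rec = MeasurementRecord(
            pmid=str(10000000 + i % 7), table_id=i % 3, row=i // 3, col=i % 5,
            neuron_id=rng.choice(neurons), concept_id=rng.choice(concepts),
            value=ParsedValue(mean=float(i)),
        )
        store.insert(rec)
        rows.append(rec)
    got = store.query(neuron_id=neurons[0], concept_id=concepts[1])
    expected = [
        r for r in rows
        if r.neuron_id == neurons[0] and r.concept_id == concepts[1]
    ]
    assert sorted(got, key=lambda r: r.position) == sorted(
        expected, key=lambda r: r.position
    )
    assert store.query() == store.all()


def _seeded_store(vocab, n=12, seed=3):
    rng = random.Random(seed)
    store = RecordStore(vocab=vocab)
    for i in range(n):
        md = MetadataRecord(
            species="Rats", strain="Wistar", electrode_type="Patch-clamp",
            preparation_type="In vitro", jp_corrected="not_corrected",
            temperature=(33.0, 35.0) if i % 2 else 32.0,
            age_low_days=14, age_high_days=21,
        )
        store.insert(
            MeasurementRecord(
                pmid=str(20000000 + i), table_id=0, row=1, col=1,
                neuron_id=rng.choice(vocab.neuron_types).neuron_id,
                concept_id=rng.choice(vocab.concepts).concept_id,
                value=ParsedValue(
                    mean=round(rng.uniform(-80, 200), 1),
                    error_value=round(rng.uniform(0.1, 9), 1),
                    n=rng.randint(3, 30),
                ),
                metadata=md,
            )
        )
    return store


def test_csv_round_trip(vocab, tmp_path):
    store = _seeded_store(vocab)
    path = tmp_path / "records.csv"
    export_csv(store, path)
    lines = path.read_text().splitlines()
    assert lines[0] == ",".join(CSV_COLUMNS)
    assert len(lines) == len(store) + 1
    back = import_csv(path, vocab=vocab)
    for a, b in zip(store.all(), back.all()):
        assert a.position == b.position
        assert (a.neuron_id, a.concept_id) == (b.neuron_id, b.concept_id)
        assert a.value.mean == b.value.mean
        assert a.value.error_value == b.value.error_value
        assert a.value.n == b.value.n
        assert a.metadata.temperature == b.metadata.temperature
        assert a.metadata.strain == b.metadata.strain


def test_empty_store_exports_header_only(vocab, tmp_path):
    path = tmp_path / "empty.csv"
    export_csv(RecordStore(vocab=vocab), path)
    assert path.read_text().splitlines() == [",".join(CSV_COLUMNS)]


def test_json_round_trip(vocab, tmp_path):
    store = _seeded_store(vocab, seed=9)
    path = tmp_path / "records.json"
    export_json(store, path)
    back = import_json(path, vocab=vocab)
    assert len(back) == len(store)
    for a, b in zip(store.all(), back.all()):
        assert a.value == b.value or (
            a.value.mean == b.value.mean
            and a.value.error_value == b.value.error_value
        )


def test_malformed_csv_reports_line(vocab, tmp_path):
    path = tmp_path / "bad.csv"
    good = _seeded_store(vocab, n=2)
    export_csv(good, path)
    lines = path.read_text().splitlines()
    lines[2] = lines[2].replace(lines[2].split(",")[8], "not-a-number", 1)
    path.write_text("\n".join(lines) + "\n")
    from ephysminer.store import ImportError_

    with pytest.raises(ImportError_) as err:
        import_csv(path, vocab=vocab)
    assert "line 3" in str(err.value)


def test_sqlite_round_trip(vocab, tmp_path):
    store = _seeded_store(vocab, seed=4)
    db = tmp_path / "records.db"
    store.save(db)
    back = RecordStore.load(db, vocab=vocab)
    assert len(back) == len(store)
    for a, b in zip(store.all(), back.all()):
        assert a.position == b.position
        assert a.value.mean == b.value.mean
        assert a.metadata.to_dict() == b.metadata.to_dict()
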