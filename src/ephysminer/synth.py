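"""Synthetic article corpus with full ground truth.

Generates HTML articles that look like the slice-physiology papers the
pipeline targets: a title and abstract, a methods section built from the
same sentence patterns the metadata rules recognize, a results section
that mentions one focal neuron type more often than a few distractors,
and 1–3 data tables whose headers are drawn from vocabulary synonyms and
whose cells are formatted summary statistics.  Every stochastic choice is
recorded as ground truth, so the pipeline can be scored exactly; the seed
fully determines the output bytes.

Noise knobs: ``synonym_use_prob`` picks non-canonical synonyms for
headers, ``typo_rate`` substitutes characters inside header text.  Both
default to zero-ish, realistic settings and are raised explicitly in
degradation experiments.
"""

from __future__ import annotations

import hashlib
import json
import random
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

from .metadata import MetadataRecord
from .values import ParsedValue, format_data_string
from .vocab import ConceptVocabulary, EphysConcept, NeuronTypeEntry, default_vocabulary

__all__ = [
    "GenerationParams",
    "TableTruth",
    "GroundTruth",
    "generate_article",
    "generate_corpus",
    "load_manifest",
    "jp_sentence",
    "JP_TEMPLATES",
    "values_equal",
]

DIALECTS = ("pm_n", "pm_only", "range", "mean_only", "missing")


@dataclass(frozen=True)
class GenerationParams:
    seed: int = 0
    n_articles: int = 50
    tables_per_article: tuple[int, int] = (1, 3)
    orientation_mix: float = 0.25        # P(concepts_in_rows)
    synonym_use_prob: float = 0.3        # P(header uses a non-canonical synonym)
    typo_rate: float = 0.0               # per-character substitution prob in headers
    value_dialect_mix: tuple[float, ...] = (0.45, 0.2, 0.15, 0.1, 0.1)
    metadata_template_mix: float = 0.9   # per-concept inclusion probability
    distractor_neuron_mentions: int = 2

    def __post_init__(self) -> None:
        for p in (
            self.orientation_mix,
            self.synonym_use_prob,
            self.typo_rate,
            self.metadata_template_mix,
            *self.value_dialect_mix,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if len(self.value_dialect_mix) != len(DIALECTS):
            raise ValueError("value_dialect_mix must have 5 weights")
        if sum(self.value_dialect_mix) <= 0:
            raise ValueError("value_dialect_mix must have positive mass")


@dataclass
class TableTruth:
    table_id: int
    n_rows: int
    n_cols: int
    orientation: str
    # (row, col) -> {"kind", "target_id"}
    header_truth: dict[tuple[int, int], dict] = field(default_factory=dict)
    # (row, col) -> ParsedValue dict, or None for an unparseable placeholder
    cell_truth: dict[tuple[int, int], Optional[dict]] = field(default_factory=dict)


@dataclass
class GroundTruth:
    pmid: str
    focal_neuron_ids: list[str]
    tables: list[TableTruth]
    metadata: dict
    mesh_terms: list[str]

    def to_dict(self) -> dict:
        return {
            "pmid": self.pmid,
            "focal_neuron_ids": list(self.focal_neuron_ids),
            "tables": [
                {
                    "table_id": t.table_id,
                    "n_rows": t.n_rows,
                    "n_cols": t.n_cols,
                    "orientation": t.orientation,
                    "header_truth": {
                        f"{r},{c}": v for (r, c), v in sorted(t.header_truth.items())
                    },
                    "cell_truth": {
                        f"{r},{c}": v for (r, c), v in sorted(t.cell_truth.items())
                    },
                }
                for t in self.tables
            ],
            "metadata": self.metadata,
            "mesh_terms": list(self.mesh_terms),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        tables = []
        for t in d["tables"]:
            tables.append(
                TableTruth(
                    table_id=t["table_id"],
                    n_rows=t["n_rows"],
                    n_cols=t["n_cols"],
                    orientation=t["orientation"],
                    header_truth={
                        tuple(map(int, k.split(","))): v
                        for k, v in t["header_truth"].items()
                    },
                    cell_truth={
                        tuple(map(int, k.split(","))): v
                        for k, v in t["cell_truth"].items()
                    },
                )
            )
        return cls(
            pmid=d["pmid"],
            focal_neuron_ids=list(d["focal_neuron_ids"]),
            tables=tables,
            metadata=d["metadata"],
            mesh_terms=list(d["mesh_terms"]),
        )


def values_equal(a: ParsedValue, truth: dict) -> bool:
    """Field equality between a parsed value and a ground-truth value dict
    (raw_text excluded — the formatted string is the carrier, not a field)."""
    return (
        a.mean == truth["mean"]
        and a.error_value == truth.get("error_value")
        and a.n == truth.get("n")
        and a.range_low == truth.get("range_low")
        and a.range_high == truth.get("range_high")
    )


def _value_dict(v: ParsedValue) -> dict:
    return {
        "mean": v.mean,
        "error_value": v.error_value,
        "n": v.n,
        "range_low": v.range_low,
        "range_high": v.range_high,
    }


# --- value synthesis -------------------------------------------------------

_DIM_RANGES = {
    "voltage": (-80.0, 80.0),
    "resistance": (40.0, 400.0),
    "time": (0.5, 40.0),
    "frequency": (1.0, 80.0),
    "current": (20.0, 400.0),
    "dimensionless": (0.1, 3.0),
}


def _round1(x: float) -> float:
    return round(x, 1)


def _synth_value(rng: random.Random, concept: EphysConcept, dialect: str) -> Optional[ParsedValue]:
    lo, hi = _DIM_RANGES[concept.unit_dimension]
    mean = _round1(rng.uniform(lo, hi))
    if dialect == "missing":
        return None
    if dialect == "mean_only":
        return ParsedValue(mean=mean)
    if dialect == "range":
        spread_a = _round1(abs(mean) * rng.uniform(0.05, 0.3) + 0.1)
        spread_b = _round1(abs(mean) * rng.uniform(0.05, 0.3) + 0.1)
        low, high = _round1(mean - spread_a), _round1(mean + spread_b)
        return ParsedValue(mean=mean, range_low=min(low, high), range_high=max(low, high))
    error = _round1(abs(mean) * rng.uniform(0.02, 0.2))
    if error == 0.0:
        error = 0.1
    if dialect == "pm_only":
        return ParsedValue(mean=mean, error_value=error)
    return ParsedValue(mean=mean, error_value=error, n=rng.randint(5, 30))


def _apply_typos(rng: random.Random, text: str, typo_rate: float) -> str:
    if typo_rate <= 0:
        return text
    letters = "abcdefghijklmnopqrstuvwxyz"
    out = []
    for ch in text:
        if ch.isalpha() and rng.random() < typo_rate:
            out.append(rng.choice([c for c in letters if c != ch.lower()]))
        else:
            out.append(ch)
    return "".join(out)


def _header_text(
    rng: random.Random, entry, params: GenerationParams
) -> str:
    synonyms = sorted(entry.synonyms)
    canonical = entry.canonical_name
    if rng.random() < params.synonym_use_prob and len(synonyms) > 1:
        choices = [s for s in synonyms if s != canonical]
        text = rng.choice(choices)
    else:
        text = canonical
    return _apply_typos(rng, text, params.typo_rate)


# --- metadata synthesis ----------------------------------------------------

JP_TEMPLATES = (
    "The liquid junction potential was {neg}corrected.",
    "Reported voltages were {neg}corrected for the liquid junction potential.",
    "Membrane potentials were {neg}adjusted for the junction potential.",
    "Data were {neg}compensated for the liquid junction potential.",
)


def jp_sentence(corrected: bool, template_index: int = 0) -> str:
    """A junction-potential methods sentence; the negation cue flips it."""
    tmpl = JP_TEMPLATES[template_index % len(JP_TEMPLATES)]
    return tmpl.format(neg="" if corrected else "not ")


_STRAINS = (
    ("Wistar", "Rats, Wistar", "Rats", "rats"),
    ("Sprague-Dawley", "Rats, Sprague-Dawley", "Rats", "rats"),
    ("Long-Evans", "Rats, Long-Evans", "Rats", "rats"),
    ("C57BL", "Mice, Inbred C57BL", "Mice", "mice"),
    ("BALB C", "Mice, Inbred BALB C", "Mice", "mice"),
)


def _synth_methods(
    rng: random.Random, params: GenerationParams
) -> tuple[str, dict, list[str]]:
    """Methods text, ground-truth metadata dict, MeSH sidecar terms."""
    include = lambda: rng.random() < params.metadata_template_mix
    sentences: list[str] = []
    mesh: list[str] = []
    truth: dict = {
        "species": None,
        "strain": None,
        "electrode_type": None,
        "preparation_type": None,
        "jp_corrected": "unknown",
        "temperature": None,
        "age_low_days": None,
        "age_high_days": None,
    }

    animal_word = "animals"
    if include():
        strain, strain_mesh, species, word = rng.choice(_STRAINS)
        truth["strain"] = strain
        truth["species"] = species
        mesh += [strain_mesh, species]
        animal_word = word
        sentences.append(f"Experiments used {word}.")

    if include():
        lo = rng.randint(5, 20)
        hi = lo + rng.randint(0, 14)
        truth["age_low_days"], truth["age_high_days"] = lo, hi
        if hi == lo:
            sentences.append(f"Recordings were obtained from P{lo} {animal_word}.")
        elif rng.random() < 0.5:
            sentences.append(f"We used P{lo}-P{hi} {animal_word}.")
        else:
            sentences.append(f"We used P{lo}-{hi} {animal_word}.")

    if include():
        truth["preparation_type"] = "In vitro"
        sentences.append("Acute slices were prepared with a vibratome.")
        sentences.append("Slices were stored at 4°C before use.")

    if include():
        truth["electrode_type"] = "Patch-clamp"
        sentences.append(
            "Whole-cell patch-clamp recordings were obtained with borosilicate pipettes."
        )
        mesh.append("Patch-clamp techniques")
    else:
        sentences.append("Signals were amplified and digitized at 10 kHz.")

    if include():
        kind = rng.choice(("value", "range", "room"))
        if kind == "value":
            t = rng.randint(30, 37)
            truth["temperature"] = float(t)
            sentences.append(f"Recordings were performed at {t}°C.")
        elif kind == "range":
            lo = rng.randint(30, 35)
            hi = lo + rng.randint(1, 3)
            truth["temperature"] = [float(lo), float(hi)]
            sentences.append(f"Recordings were performed at {lo}-{hi}°C.")
        else:
            truth["temperature"] = "room"
            sentences.append("Experiments were performed at room temperature.")

    jp_state = rng.choice(("corrected", "not_corrected", "unknown"))
    if jp_state != "unknown":
        truth["jp_corrected"] = jp_state
        sentences.append(
            jp_sentence(jp_state == "corrected", rng.randrange(len(JP_TEMPLATES)))
        )

    return " ".join(sentences), truth, mesh


# --- table synthesis -------------------------------------------------------


def _synth_table(
    rng: random.Random,
    table_id: int,
    neurons: list[NeuronTypeEntry],
    concepts: list[EphysConcept],
    params: GenerationParams,
) -> tuple[str, TableTruth]:
    transposed = rng.random() < params.orientation_mix
    orientation = "concepts_in_rows" if transposed else "concepts_in_columns"
    n_lines = len(neurons)  # data lines
    n_props = len(concepts)

    # logical layout: rows = neurons, cols = concepts; transpose at render
    header_truth: dict[tuple[int, int], dict] = {}
    cell_truth: dict[tuple[int, int], Optional[dict]] = {}

    concept_headers = [_header_text(rng, c, params) for c in concepts]
    neuron_headers = [_header_text(rng, n, params) for n in neurons]
    weights = list(params.value_dialect_mix)
    cells: list[list[str]] = []
    for i in range(n_lines):
        row = []
        for j in range(n_props):
            dialect = rng.choices(DIALECTS, weights=weights)[0]
            value = _synth_value(rng, concepts[j], dialect)
            row.append("n.d." if value is None else format_data_string(value))
            r, c = (i + 1, j + 1) if not transposed else (j + 1, i + 1)
            cell_truth[(r, c)] = None if value is None else _value_dict(value)
        cells.append(row)

    if not transposed:
        grid = [["Parameter"] + concept_headers]
        for i in range(n_lines):
            grid.append([neuron_headers[i]] + cells[i])
        for j, c in enumerate(concepts):
            header_truth[(0, j + 1)] = {"kind": "ephys_concept", "target_id": c.concept_id}
        for i, n in enumerate(neurons):
            header_truth[(i + 1, 0)] = {"kind": "neuron_type", "target_id": n.neuron_id}
        n_rows, n_cols = n_lines + 1, n_props + 1
    else:
        grid = [["Parameter"] + neuron_headers]
        for j in range(n_props):
            grid.append([concept_headers[j]] + [cells[i][j] for i in range(n_lines)])
        for j, c in enumerate(concepts):
            header_truth[(j + 1, 0)] = {"kind": "ephys_concept", "target_id": c.concept_id}
        for i, n in enumerate(neurons):
            header_truth[(0, i + 1)] = {"kind": "neuron_type", "target_id": n.neuron_id}
        n_rows, n_cols = n_props + 1, n_lines + 1

    rows_html = []
    for r, row in enumerate(grid):
        cells_html = "".join(
            f"<{'th' if (r == 0 or c == 0) else 'td'}>{cell}</{'th' if (r == 0 or c == 0) else 'td'}>"
            for c, cell in enumerate(row)
        )
        rows_html.append(f"<tr>{cells_html}</tr>")
    html = (
        f"<table><caption>Table {table_id + 1}. Intrinsic membrane properties.</caption>"
        + "".join(rows_html)
        + "</table>"
    )
    truth = TableTruth(
        table_id=table_id,
        n_rows=n_rows,
        n_cols=n_cols,
        orientation=orientation,
        header_truth=header_truth,
        cell_truth=cell_truth,
    )
    return html, truth


# --- article assembly ------------------------------------------------------


def _tokens(text: str) -> tuple[str, ...]:
    import re as _re

    return tuple(_re.findall(r"[a-z0-9]+", text.casefold()))


def _synonym_embedded(entry: NeuronTypeEntry, focal_name: str) -> bool:
    """True if any synonym of ``entry`` occurs as a contiguous token run
    inside ``focal_name``."""
    focal_toks = _tokens(focal_name)
    for syn in entry.synonyms:
        toks = _tokens(syn)
        if not toks:
            continue
        for i in range(len(focal_toks) - len(toks) + 1):
            if focal_toks[i : i + len(toks)] == toks:
                return True
    return False


def generate_article(
    params: GenerationParams,
    index: int,
    vocab: Optional[ConceptVocabulary] = None,
) -> tuple[str, list[str], GroundTruth]:
    """Generate one article: ``(html, mesh_terms, ground_truth)``.

    Deterministic under ``(params.seed, index)``.
    """
    if vocab is None:
        vocab = default_vocabulary()
    if not vocab.concepts or not vocab.neuron_types:
        raise ValueError("vocabulary must hold at least one concept and neuron type")
    rng = random.Random(f"ephysminer:{params.seed}:{index}")
    pmid = str(10000000 + params.seed % 1000 * 10000 + index)

    neurons_pool = sorted(vocab.neuron_types, key=lambda n: n.neuron_id)
    focal = rng.choice(neurons_pool)
    # a distractor must not own a synonym embedded in the focal name:
    # every focal mention would feed that distractor's count too, and
    # top-1 recovery of the focal neuron would no longer be well defined
    others = [
        n
        for n in neurons_pool
        if n.neuron_id != focal.neuron_id
        and not _synonym_embedded(n, focal.canonical_name)
    ]
    rng.shuffle(others)
    n_distract = min(3, len(others))
    distractors = others[:n_distract]

    n_tables = rng.randint(*params.tables_per_article)
    concepts_pool = sorted(vocab.concepts, key=lambda c: c.concept_id)

    tables_html: list[str] = []
    table_truths: list[TableTruth] = []
    table_neurons_all: set[str] = set()
    for t in range(n_tables):
        n_neurons = rng.randint(1, min(3, 1 + len(distractors)))
        table_neurons = [focal] + distractors[: n_neurons - 1]
        n_concepts = rng.randint(2, min(4, len(concepts_pool)))
        table_concepts = rng.sample(concepts_pool, n_concepts)
        html_t, truth_t = _synth_table(rng, t, table_neurons, table_concepts, params)
        tables_html.append(html_t)
        table_truths.append(truth_t)
        table_neurons_all.update(n.neuron_id for n in table_neurons)

    methods_text, metadata_truth, mesh = _synth_methods(rng, params)

    focal_mentions = 8
    results_sentences = []
    for k in range(focal_mentions):
        results_sentences.append(
            f"The {focal.canonical_name} population showed stable responses in trial {k + 1}."
        )
    for d in distractors:
        for _ in range(params.distractor_neuron_mentions):
            results_sentences.append(
                f"For comparison we refer to published data on the {d.canonical_name}."
            )
    results_text = " ".join(results_sentences)

    abstract = (
        f"We characterized intrinsic membrane properties of the "
        f"{focal.canonical_name} using intracellular recordings."
    )
    intro = (
        "Intrinsic electrophysiological properties vary widely across neuron "
        "types and constrain circuit function."
    )

    html = f"""<html>
<head>
<title>Intrinsic properties of the {focal.canonical_name}</title>
<meta name="citation_pmid" content="{pmid}"/>
</head>
<body>
<h1>Intrinsic properties of the {focal.canonical_name}</h1>
<h2>Abstract</h2>
<p>{abstract}</p>
<h2>Introduction</h2>
<p>{intro}</p>
<h2>Methods</h2>
<p>{methods_text}</p>
<h2>Results</h2>
<p>{results_text}</p>
{''.join(tables_html)}
<h2>Discussion</h2>
<p>The measurements are consistent with earlier reports.</p>
</body>
</html>
"""
    truth = GroundTruth(
        pmid=pmid,
        focal_neuron_ids=[focal.neuron_id],
        tables=table_truths,
        metadata=metadata_truth,
        mesh_terms=mesh,
    )
    return html, mesh, truth


def generate_corpus(
    params: GenerationParams,
    out_dir: str | Path,
    vocab: Optional[ConceptVocabulary] = None,
    force: bool = False,
) -> dict:
    """Write ``n_articles`` HTML files plus MeSH sidecars and a manifest.

    Returns the manifest dict.  Refuses a non-empty output directory
    unless ``force`` is set.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if any(out.iterdir()) and not force:
        raise FileExistsError(f"output directory {out} is not empty (use force)")
    articles = []
    for i in range(params.n_articles):
        html, mesh, truth = generate_article(params, i, vocab=vocab)
        stem = f"article_{i:04d}"
        (out / f"{stem}.html").write_text(html, encoding="utf-8")
        (out / f"{stem}.mesh.txt").write_text(
            "".join(t + "\n" for t in mesh), encoding="utf-8"
        )
        articles.append({"stem": stem, "truth": truth.to_dict()})
    body = {
        "params": asdict(params),
        "articles": articles,
    }
    digest = hashlib.sha256(
        json.dumps(body, sort_keys=True, ensure_ascii=False).encode("utf-8")
    ).hexdigest()
    manifest = {**body, "digest": digest}
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=1, ensure_ascii=False, sort_keys=True),
        encoding="utf-8",
    )
    return manifest


def load_manifest(path: str | Path) -> dict:
    return json.loads(Path(path).read_text(encoding="utf-8"))
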