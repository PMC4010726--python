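"""Scoring pipeline outputs against ground truth.

Three evaluation designs cover the three automated stages: header/concept
assignment accuracy (correct (kind, target) over all true header cells),
neuron-recognition top-k accuracy (focal neuron among the k best-ranked
candidates, per article), and per-concept metadata accuracy with exact
95% binomial confidence intervals.  All fractions are reported with their
numerator and denominator so small corpora read honestly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from scipy import stats

from .annotate import AnnotatedTable, annotate_table
from .ingest import Article, extract_methods_section, parse_article
from .metadata import MetadataRecord, extract_metadata
from .neurons import rank_article_neurons, top_k
from .store import assemble_records
from .synth import GroundTruth, load_manifest, values_equal
from .values import ParsedValue
from .vocab import ConceptVocabulary, DEFAULT_MATCH_THRESHOLD, default_vocabulary

__all__ = [
    "Fraction",
    "EvaluationReport",
    "binomial_ci",
    "score_concept_assignment",
    "score_neuron_topk",
    "score_metadata",
    "evaluate_corpus",
]

METADATA_FIELDS = (
    "species",
    "strain",
    "electrode_type",
    "preparation_type",
    "jp_corrected",
    "temperature",
    "age_low_days",
    "age_high_days",
)


@dataclass(frozen=True)
class Fraction:
    numerator: int
    denominator: int

    @property
    def value(self) -> float:
        return self.numerator / self.denominator if self.denominator else 0.0

    def __str__(self) -> str:
        return f"{self.value:.1%} ({self.numerator}/{self.denominator})"


@dataclass
class EvaluationReport:
    concept_accuracy: Fraction
    neuron_topk: dict[int, Fraction]
    metadata_accuracy: dict[str, tuple[Fraction, float, float]]
    record_recovery: Fraction
    per_article: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "concept_accuracy": {
                "fraction": self.concept_accuracy.value,
                "numerator": self.concept_accuracy.numerator,
                "denominator": self.concept_accuracy.denominator,
            },
            "neuron_topk": {
                str(k): {
                    "fraction": f.value,
                    "numerator": f.numerator,
                    "denominator": f.denominator,
                }
                for k, f in self.neuron_topk.items()
            },
            "metadata_accuracy": {
                concept: {
                    "fraction": f.value,
                    "numerator": f.numerator,
                    "denominator": f.denominator,
                    "ci_low": lo,
                    "ci_high": hi,
                }
                for concept, (f, lo, hi) in self.metadata_accuracy.items()
            },
            "record_recovery": {
                "fraction": self.record_recovery.value,
                "numerator": self.record_recovery.numerator,
                "denominator": self.record_recovery.denominator,
            },
            "per_article": self.per_article,
        }

    def summary(self) -> str:
        lines = [f"concept assignment: {self.concept_accuracy}"]
        for k in sorted(self.neuron_topk):
            lines.append(f"neuron top-{k}: {self.neuron_topk[k]}")
        for concept in sorted(self.metadata_accuracy):
            f, lo, hi = self.metadata_accuracy[concept]
            lines.append(f"metadata {concept}: {f} [95% CI {lo:.3f}, {hi:.3f}]")
        lines.append(f"record recovery: {self.record_recovery}")
        return "\n".join(lines)


def binomial_ci(
    successes: int, trials: int, level: float = 0.95
) -> tuple[float, float]:
    """Clopper–Pearson exact binomial confidence interval.

    Exactness is conservative, which suits the small per-concept counts
    this harness reports.  The interval always contains successes/trials.
    """
    if trials < 1:
        raise ValueError("trials must be >= 1")
    if not 0 <= successes <= trials:
        raise ValueError("successes outside [0, trials]")
    alpha = 1.0 - level
    if successes == 0:
        low = 0.0
    else:
        low = float(stats.beta.ppf(alpha / 2, successes, trials - successes + 1))
    if successes == trials:
        high = 1.0
    else:
        high = float(stats.beta.ppf(1 - alpha / 2, successes + 1, trials - successes))
    return low, high


def score_concept_assignment(
    predicted: Sequence[Sequence[AnnotatedTable]],
    truths: Sequence[GroundTruth],
) -> Fraction:
    """Fraction of true header cells whose predicted (kind, target) match.

    The denominator counts ground-truth header cells (concept and neuron
    headers alike) over the whole corpus.
    """
    if len(predicted) != len(truths):
        raise ValueError(
            f"article sets differ: {len(predicted)} predicted vs {len(truths)} truth"
        )
    num = den = 0
    for tables, truth in zip(predicted, truths):
        by_id = {t.raw.table_id: t for t in tables}
        for t_truth in truth.tables:
            annotated = by_id.get(t_truth.table_id)
            for (r, c), expect in t_truth.header_truth.items():
                den += 1
                if annotated is None:
                    continue
                got = annotated.assignment_at(r, c)
                if (
                    got is not None
                    and got.assigned_kind == expect["kind"]
                    and got.target_id == expect["target_id"]
                ):
                    num += 1
    return Fraction(num, den)


def score_neuron_topk(
    rankings: Sequence[Sequence[str]],
    truths: Sequence[GroundTruth],
    ks: Sequence[int] = (1, 3),
) -> dict[int, Fraction]:
    """Per-k success fraction: any focal neuron among the first k ids."""
    if len(rankings) != len(truths):
        raise ValueError("article sets differ")
    out: dict[int, Fraction] = {}
    for k in ks:
        if k < 1:
            raise ValueError("k must be >= 1")
        hits = sum(
            1
            for ids, truth in zip(rankings, truths)
            if set(ids[:k]) & set(truth.focal_neuron_ids)
        )
        out[k] = Fraction(hits, len(truths))
    return out


def _metadata_field_equal(got, expected) -> bool:
    if isinstance(expected, list):
        expected = tuple(expected)
    if isinstance(got, list):
        got = tuple(got)
    return got == expected


def score_metadata(
    predicted: Sequence[MetadataRecord],
    truths: Sequence[GroundTruth],
    level: float = 0.95,
) -> dict[str, tuple[Fraction, float, float]]:
    """Per-concept accuracy with exact binomial confidence intervals.

    Every article counts for every concept; an absent true value is a
    success only if the extractor also reports absence.
    """
    if len(predicted) != len(truths):
        raise ValueError("article sets differ")
    out: dict[str, tuple[Fraction, float, float]] = {}
    for concept in METADATA_FIELDS:
        num = 0
        for record, truth in zip(predicted, truths):
            if _metadata_field_equal(
                getattr(record, concept), truth.metadata.get(concept)
            ):
                num += 1
        frac = Fraction(num, len(truths))
        lo, hi = binomial_ci(num, len(truths), level) if truths else (0.0, 0.0)
        out[concept] = (frac, lo, hi)
    return out


def _score_records(
    tables: Sequence[AnnotatedTable],
    article: Article,
    metadata: MetadataRecord,
    truth: GroundTruth,
) -> Fraction:
    truth_cells = {}
    for t in truth.tables:
        # a true record exists where the cell has a value and its table
        # lines carry both a neuron and a concept (always true here)
        for (r, c), v in t.cell_truth.items():
            if v is not None:
                truth_cells[(t.table_id, r, c)] = v
    num = 0
    for annotated in tables:
        for rec in assemble_records(annotated, article, metadata):
            key = (rec.table_id, rec.row, rec.col)
            expect = truth_cells.get(key)
            if expect is None:
                continue
            t_truth = next(
                t for t in truth.tables if t.table_id == rec.table_id
            )
            expect_header = _expected_pair(t_truth, rec.row, rec.col)
            if (
                expect_header == (rec.neuron_id, rec.concept_id)
                and values_equal(rec.value, expect)
            ):
                num += 1
    return Fraction(num, len(truth_cells))


def _expected_pair(t_truth, row: int, col: int) -> tuple[str, str]:
    neuron = concept = None
    for (r, c), h in t_truth.header_truth.items():
        if h["kind"] == "neuron_type" and (
            r == row or c == col
        ):
            neuron = h["target_id"]
        if h["kind"] == "ephys_concept" and (r == row or c == col):
            concept = h["target_id"]
    return neuron, concept


def evaluate_corpus(
    corpus_dir: str | Path,
    manifest_path: Optional[str | Path] = None,
    vocab: Optional[ConceptVocabulary] = None,
    threshold: float = DEFAULT_MATCH_THRESHOLD,
    ks: Sequence[int] = (1, 3),
) -> EvaluationReport:
    """Run the full pipeline over a generated corpus and score every stage."""
    corpus_dir = Path(corpus_dir)
    if manifest_path is None:
        manifest_path = corpus_dir / "manifest.json"
    manifest = load_manifest(manifest_path)
    if vocab is None:
        vocab = default_vocabulary()

    all_tables: list[list[AnnotatedTable]] = []
    truths: list[GroundTruth] = []
    rankings: list[list[str]] = []
    metadata_records: list[MetadataRecord] = []
    rec_num = rec_den = 0
    per_article = []

    for entry in manifest["articles"]:
        stem = entry["stem"]
        truth = GroundTruth.from_dict(entry["truth"])
        html = (corpus_dir / f"{stem}.html").read_text(encoding="utf-8")
        mesh_path = corpus_dir / f"{stem}.mesh.txt"
        mesh = (
            [ln.strip() for ln in mesh_path.read_text(encoding="utf-8").splitlines() if ln.strip()]
            if mesh_path.exists()
            else []
        )
        article = parse_article(html, mesh_terms=mesh)
        tables = [annotate_table(t, vocab, threshold) for t in article.tables]
        ranking = rank_article_neurons(article, vocab)
        methods = extract_methods_section(article)
        metadata = extract_metadata(methods, mesh)

        all_tables.append(tables)
        truths.append(truth)
        rankings.append(ranking.ids())
        metadata_records.append(metadata)

        rec_frac = _score_records(tables, article, metadata, truth)
        rec_num += rec_frac.numerator
        rec_den += rec_frac.denominator
        per_article.append(
            {
                "stem": stem,
                "pmid": truth.pmid,
                "top1_hit": bool(set(ranking.ids()[:1]) & set(truth.focal_neuron_ids)),
                "records": [rec_frac.numerator, rec_frac.denominator],
            }
        )

    return EvaluationReport(
        concept_accuracy=score_concept_assignment(all_tables, truths),
        neuron_topk=score_neuron_topk(rankings, truths, ks),
        metadata_accuracy=score_metadata(metadata_records, truths),
        record_recovery=Fraction(rec_num, rec_den),
        per_article=per_article,
    )
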