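"""Controlled vocabularies and fuzzy term matching.

Two lexicons drive the extraction pipeline: a set of electrophysiological
measurement concepts (resting membrane potential, input resistance, ...)
with the synonyms authors use for them in table headers, and a set of
neuron types with NeuroLex-style identifiers and synonyms.  Free text from
table headers is matched against synonym lists with a composite fuzzy
score so that "Rin (MOhm)", "R_in" and "input resistance" all resolve to
the same concept.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field
from difflib import SequenceMatcher
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "EphysConcept",
    "NeuronTypeEntry",
    "ConceptVocabulary",
    "TermMatch",
    "VocabularyError",
    "MissingVocabularyFile",
    "DuplicateIdentifierError",
    "DuplicateSynonymError",
    "EmptySynonymListError",
    "load_vocabulary",
    "default_vocabulary",
    "normalize_term",
    "composite_match_score",
    "match_term",
]

UNIT_DIMENSIONS = frozenset(
    {"voltage", "resistance", "time", "frequency", "current", "dimensionless"}
)


class VocabularyError(ValueError):
    """Base class for vocabulary validation failures."""


class MissingVocabularyFile(VocabularyError):
    pass


class DuplicateIdentifierError(VocabularyError):
    pass


class DuplicateSynonymError(VocabularyError):
    pass


class EmptySynonymListError(VocabularyError):
    pass


@dataclass(frozen=True)
class EphysConcept:
    """One electrophysiological measurement concept.

    ``unit_dimension`` is the physical dimension of the measurement
    (voltage, resistance, time, frequency, current or dimensionless); it is
    carried as documentation, not used for unit conversion.
    """

    concept_id: str
    canonical_name: str
    synonyms: frozenset[str]
    unit_dimension: str
    definition: str = ""
    reporting_recommendation: str = ""

    def __post_init__(self) -> None:
        if not self.synonyms:
            raise EmptySynonymListError(
                f"concept {self.concept_id!r} has no synonyms"
            )
        if self.canonical_name not in self.synonyms:
            object.__setattr__(
                self, "synonyms", self.synonyms | {self.canonical_name}
            )
        if self.unit_dimension not in UNIT_DIMENSIONS:
            raise VocabularyError(
                f"concept {self.concept_id!r}: unknown unit dimension "
                f"{self.unit_dimension!r}"
            )


@dataclass(frozen=True)
class NeuronTypeEntry:
    """One canonical neuron type with a NeuroLex-style identifier."""

    neuron_id: str
    canonical_name: str
    synonyms: frozenset[str]
    brain_region: str = ""

    def __post_init__(self) -> None:
        if not self.synonyms:
            raise EmptySynonymListError(
                f"neuron type {self.neuron_id!r} has no synonyms"
            )
        if self.canonical_name not in self.synonyms:
            object.__setattr__(
                self, "synonyms", self.synonyms | {self.canonical_name}
            )


@dataclass(frozen=True)
class TermMatch:
    """A scored match of a free-text term against one vocabulary entry."""

    target_id: str
    matched_synonym: str
    score: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 100.0:
            raise ValueError(f"score {self.score} outside [0, 100]")


@dataclass
class ConceptVocabulary:
    """The dual lexicon: measurement concepts plus neuron types.

    Concept and neuron namespaces are independent: a synonym string may
    appear in both, but never under two different ids within one namespace.
    """

    concepts: list[EphysConcept] = field(default_factory=list)
    neuron_types: list[NeuronTypeEntry] = field(default_factory=list)
    version: str = "0"

    def __post_init__(self) -> None:
        self._check_unique("concept", [(c.concept_id, c.synonyms) for c in self.concepts])
        self._check_unique(
            "neuron type", [(n.neuron_id, n.synonyms) for n in self.neuron_types]
        )

    @staticmethod
    def _check_unique(kind: str, entries: list[tuple[str, frozenset[str]]]) -> None:
        seen_ids: set[str] = set()
        owner: dict[str, str] = {}
        for entry_id, synonyms in entries:
            if entry_id in seen_ids:
                raise DuplicateIdentifierError(f"duplicate {kind} id {entry_id!r}")
            seen_ids.add(entry_id)
            for syn in synonyms:
                key = normalize_term(syn)
                if key in owner and owner[key] != entry_id:
                    raise DuplicateSynonymError(
                        f"synonym {syn!r} maps to both {owner[key]!r} and "
                        f"{entry_id!r} in the {kind} namespace"
                    )
                owner[key] = entry_id

    def concept(self, concept_id: str) -> EphysConcept:
        for c in self.concepts:
            if c.concept_id == concept_id:
                return c
        raise KeyError(concept_id)

    def neuron(self, neuron_id: str) -> NeuronTypeEntry:
        for n in self.neuron_types:
            if n.neuron_id == neuron_id:
                return n
        raise KeyError(neuron_id)


_KNOWN_CONCEPT_FIELDS = {
    "id",
    "canonical_name",
    "synonyms",
    "unit_dimension",
    "definition",
    "reporting_recommendation",
}
_KNOWN_NEURON_FIELDS = {"id", "canonical_name", "synonyms", "brain_region"}


def load_vocabulary(path: str | Path) -> ConceptVocabulary:
    """Load a vocabulary from a JSON file.

    The schema is a JSON object with keys ``version``, ``concepts`` and
    ``neuron_types``; each concept record carries ``id``, ``canonical_name``,
    ``synonyms`` (non-empty list), ``unit_dimension`` and optional
    ``definition`` / ``reporting_recommendation``; neuron records carry
    ``id``, ``canonical_name``, ``synonyms`` and optional ``brain_region``.
    Unknown fields are ignored with a warning.

    Raises
    ------
    MissingVocabularyFile
        If ``path`` does not exist.
    DuplicateIdentifierError, DuplicateSynonymError, EmptySynonymListError
        On invariant violations.
    VocabularyError
        If the file holds no concepts at all.
    """
    path = Path(path)
    if not path.exists():
        raise MissingVocabularyFile(str(path))
    raw = json.loads(path.read_text(encoding="utf-8"))
    return _vocabulary_from_dict(raw, source=str(path))


def _vocabulary_from_dict(raw: dict, source: str = "<dict>") -> ConceptVocabulary:
    concepts = []
    for rec in raw.get("concepts", []):
        unknown = set(rec) - _KNOWN_CONCEPT_FIELDS
        if unknown:
            warnings.warn(
                f"{source}: ignoring unknown concept fields {sorted(unknown)}"
            )
        concepts.append(
            EphysConcept(
                concept_id=rec["id"],
                canonical_name=rec["canonical_name"],
                synonyms=frozenset(rec.get("synonyms", [])),
                unit_dimension=rec["unit_dimension"],
                definition=rec.get("definition", ""),
                reporting_recommendation=rec.get("reporting_recommendation", ""),
            )
        )
    if not concepts:
        raise VocabularyError(f"{source}: vocabulary defines zero concepts")
    neurons = []
    for rec in raw.get("neuron_types", []):
        unknown = set(rec) - _KNOWN_NEURON_FIELDS
        if unknown:
            warnings.warn(
                f"{source}: ignoring unknown neuron fields {sorted(unknown)}"
            )
        neurons.append(
            NeuronTypeEntry(
                neuron_id=rec["id"],
                canonical_name=rec["canonical_name"],
                synonyms=frozenset(rec.get("synonyms", [])),
                brain_region=rec.get("brain_region", ""),
            )
        )
    return ConceptVocabulary(
        concepts=concepts,
        neuron_types=neurons,
        version=str(raw.get("version", "0")),
    )


def default_vocabulary() -> ConceptVocabulary:
    """The packaged default vocabulary (28 concepts, starter neuron list)."""
    ref = resources.files("ephysminer.data").joinpath("vocabulary.json")
    raw = json.loads(ref.read_text(encoding="utf-8"))
    return _vocabulary_from_dict(raw, source="packaged vocabulary")


# ---------------------------------------------------------------------------
# Fuzzy matching
# ---------------------------------------------------------------------------

_PAREN_UNIT = re.compile(r"\(([^()]*)\)")
_NON_ALNUM = re.compile(r"[^a-z0-9]+")
_WS = re.compile(r"\s+")


def _strip_unit_parens(s: str) -> str:
    # drop parenthetical groups that carry no letters beyond a unit-like
    # token, e.g. "(mV)", "(MΩ)", "(ms)"; keep informative parentheticals
    def repl(m: re.Match) -> str:
        inner = m.group(1).strip()
        if len(inner) <= 6 and not " " in inner:
            return " "
        return m.group(0)

    return _PAREN_UNIT.sub(repl, s)


from functools import lru_cache


@lru_cache(maxsize=65536)
def normalize_term(s: str) -> str:
    """Case-fold, strip short parenthetical unit annotations, collapse
    punctuation and whitespace to single spaces."""
    s = _strip_unit_parens(s)
    s = s.casefold()
    s = _NON_ALNUM.sub(" ", s)
    return _WS.sub(" ", s).strip()


def _ratio(a: str, b: str) -> float:
    return 100.0 * SequenceMatcher(None, a, b).ratio()


def _best_substring_ratio(a: str, b: str) -> float:
    """Best similarity of the shorter string against any contiguous token
    span of the longer one (detects embedded terms such as "mitral cell"
    inside "olfactory bulb mitral cell").  Spans are token-aligned so that
    "ahp" does not score 100 against the tail of "fahp"."""
    short, long = (a, b) if len(a) <= len(b) else (b, a)
    toks = long.split()
    if not short or not toks:
        return 0.0
    best = 0.0
    for i in range(len(toks)):
        for j in range(i, len(toks)):
            span = " ".join(toks[i : j + 1])
            if len(span) > len(short) + max(8, len(short)):
                break
            best = max(best, _ratio(short, span))
            if best == 100.0:
                return best
    return best


def _token_sort_ratio(a: str, b: str) -> float:
    return _ratio(" ".join(sorted(a.split())), " ".join(sorted(b.split())))


def _token_set_ratio(a: str, b: str) -> float:
    ta, tb = set(a.split()), set(b.split())
    sect = ta & tb
    s_sect = " ".join(sorted(sect))
    s1 = " ".join(sorted(sect) + sorted(ta - tb)).strip()
    s2 = " ".join(sorted(sect) + sorted(tb - ta)).strip()
    if sect:
        return max(_ratio(s_sect, s1), _ratio(s_sect, s2), _ratio(s1, s2))
    return _ratio(s1, s2)


def composite_match_score(a: str, b: str) -> float:
    """Composite fuzzy similarity of two terms on a 0-100 scale.

    The score is the maximum of four component metrics computed on the
    normalized strings: the plain sequence ratio (exact-ish match), the
    best-substring ratio (one term embedded in the other), the token-sorted
    ratio (misordered words) and the token-set ratio (shared word subset).
    Identical strings after normalization score exactly 100.  Symmetric in
    its arguments.

    Raises ``ValueError`` if either input is empty after whitespace
    collapse.
    """
    na, nb = normalize_term(a), normalize_term(b)
    if not na or not nb:
        raise ValueError("composite_match_score requires non-empty inputs")
    if na == nb:
        return 100.0
    if na > nb:  # symmetric: canonical argument order for the cache
        na, nb = nb, na
    return _composite_normalized(na, nb)


@lru_cache(maxsize=262144)
def _composite_normalized(na: str, nb: str) -> float:
    return max(
        _ratio(na, nb),
        _best_substring_ratio(na, nb),
        _token_sort_ratio(na, nb),
        _token_set_ratio(na, nb),
    )


DEFAULT_MATCH_THRESHOLD = 80.0


def match_term(
    term: str,
    entries: Sequence[EphysConcept | NeuronTypeEntry],
    threshold: float = DEFAULT_MATCH_THRESHOLD,
) -> list[TermMatch]:
    """Match a free-text term against every synonym of every entry.

    Returns one :class:`TermMatch` per entry whose best synonym score
    reaches ``threshold``, sorted by score descending.  Score ties are
    broken first in favor of an exact (normalized-identical) synonym hit,
    then by longer matched synonym, then lexicographic target id — so a
    header that *is* a synonym of one entry always outranks an entry it
    merely resembles.  An empty term yields an empty list.
    """
    if not 0.0 <= threshold <= 100.0:
        raise ValueError(f"threshold {threshold} outside [0, 100]")
    norm = normalize_term(term)
    if not norm:
        return []
    scored: list[tuple[float, int, TermMatch]] = []
    for entry in entries:
        target_id = (
            entry.concept_id if isinstance(entry, EphysConcept) else entry.neuron_id
        )
        best: tuple[int, float, int, str] | None = None  # (exact, score, len, syn)
        for syn in sorted(entry.synonyms):
            syn_norm = normalize_term(syn)
            if not syn_norm:
                continue
            score = composite_match_score(term, syn)
            cand = (int(syn_norm == norm), score, len(syn), syn)
            if best is None or cand[:3] > best[:3]:
                best = cand
        if best is not None and best[1] >= threshold:
            scored.append((best[1], best[0], TermMatch(target_id, best[3], best[1])))
    scored.sort(
        key=lambda t: (-t[0], -t[1], -len(t[2].matched_synonym), t[2].target_id)
    )
    return [m for _, _, m in scored]
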