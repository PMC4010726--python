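"""Rule-based extraction of methodological metadata.

Experimental conditions strongly shape electrophysiological measurements
(recording temperature, animal age, junction-potential handling, species
and strain, electrode and preparation type), so each article's methods
section is mined with a small, auditable rule inventory rather than a
trained classifier.  Categorical concepts combine regular-expression hits
in the methods text with exact MeSH-term membership; junction-potential
correction is the presence of the phrase plus sentence-scope negation;
temperature and age come from numeric patterns in cue-bearing sentences.

Every emitted field carries an evidence span that is a verbatim substring
of the input, so a curator can audit any assignment.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

__all__ = [
    "ExtractionRule",
    "MetadataRecord",
    "load_rules",
    "default_rules",
    "sentence_split",
    "detect_junction_potential",
    "parse_temperature",
    "parse_animal_age",
    "classify_categorical",
    "extract_metadata",
]

CATEGORICAL_CONCEPTS = ("species", "strain", "electrode_type", "preparation_type")


@dataclass(frozen=True)
class ExtractionRule:
    concept: str
    value_label: str
    method: str  # {"regex", "mesh", "both"}
    pattern: Optional[str] = None
    mesh_term: Optional[str] = None
    implies_species: Optional[str] = None

    def __post_init__(self) -> None:
        if self.method not in ("regex", "mesh", "both"):
            raise ValueError(f"bad method {self.method!r}")
        if (self.pattern is not None) != (self.method in ("regex", "both")):
            raise ValueError(
                f"rule {self.value_label!r}: pattern present iff method uses regex"
            )
        if (self.mesh_term is not None) != (self.method in ("mesh", "both")):
            raise ValueError(
                f"rule {self.value_label!r}: mesh_term present iff method uses mesh"
            )


@dataclass
class MetadataRecord:
    species: Optional[str] = None
    strain: Optional[str] = None
    electrode_type: Optional[str] = None
    preparation_type: Optional[str] = None
    jp_corrected: str = "unknown"  # {"corrected", "not_corrected", "unknown"}
    temperature: Optional[object] = None  # float | (low, high) | "room"
    age_low_days: Optional[int] = None
    age_high_days: Optional[int] = None
    # concept -> verbatim source span; categorical concepts may also carry
    # runner-up labels under "<concept>:candidates"
    evidence: dict[str, str] = field(default_factory=dict)
    candidates: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (
            self.age_low_days is not None
            and self.age_high_days is not None
            and self.age_low_days > self.age_high_days
        ):
            raise ValueError("age_low_days > age_high_days")

    def to_dict(self) -> dict:
        temp = self.temperature
        if isinstance(temp, tuple):
            temp = list(temp)
        return {
            "species": self.species,
            "strain": self.strain,
            "electrode_type": self.electrode_type,
            "preparation_type": self.preparation_type,
            "jp_corrected": self.jp_corrected,
            "temperature": temp,
            "age_low_days": self.age_low_days,
            "age_high_days": self.age_high_days,
            "evidence": dict(self.evidence),
            "candidates": {k: list(v) for k, v in self.candidates.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MetadataRecord":
        temp = d.get("temperature")
        if isinstance(temp, list):
            temp = tuple(temp)
        return cls(
            species=d.get("species"),
            strain=d.get("strain"),
            electrode_type=d.get("electrode_type"),
            preparation_type=d.get("preparation_type"),
            jp_corrected=d.get("jp_corrected", "unknown"),
            temperature=temp,
            age_low_days=d.get("age_low_days"),
            age_high_days=d.get("age_high_days"),
            evidence=dict(d.get("evidence", {})),
            candidates={k: list(v) for k, v in d.get("candidates", {}).items()},
        )


def load_rules(path: str | Path) -> list[ExtractionRule]:
    raw = json.loads(Path(path).read_text(encoding="utf-8"))
    return [ExtractionRule(**rec) for rec in raw["rules"]]


def default_rules() -> list[ExtractionRule]:
    """The packaged rule inventory for categorical metadata."""
    ref = resources.files("ephysminer.data").joinpath("metadata_rules.json")
    raw = json.loads(ref.read_text(encoding="utf-8"))
    return [ExtractionRule(**rec) for rec in raw["rules"]]


# ---------------------------------------------------------------------------
# Sentence splitting
# ---------------------------------------------------------------------------

_ABBREVIATIONS = (
    "e.g.", "i.e.", "ca.", "approx.", "fig.", "figs.", "et al.", "vs.", "cf.",
)


def sentence_split(text: str) -> list[str]:
    """Deterministic sentence segmentation on final punctuation.

    A ``.``, ``!`` or ``?`` followed by whitespace (or end of text) closes
    a sentence, unless the period terminates a guarded abbreviation
    ("e.g.", "ca.", "approx.", "Fig.", ...).  Decimal points never split
    because they are followed by a digit.  Every returned sentence is a
    verbatim (stripped) substring of the input.
    """
    if not text.strip():
        return []
    sentences: list[str] = []
    start = 0
    n = len(text)
    for m in re.finditer(r"[.!?]", text):
        end = m.end()
        if end < n and not text[end].isspace():
            continue
        if m.group(0) == ".":
            tail = text[start:end].lower()
            if any(tail.endswith(a) for a in _ABBREVIATIONS):
                continue
        piece = text[start:end].strip()
        if piece:
            sentences.append(piece)
        start = end
    rest = text[start:].strip()
    if rest:
        sentences.append(rest)
    return sentences


# ---------------------------------------------------------------------------
# Junction potential
# ---------------------------------------------------------------------------

_NEGATION = re.compile(r"\b(not|no|without|uncorrected|un-corrected)\b", re.IGNORECASE)
_JP = re.compile(r"junction\s+potentials?", re.IGNORECASE)


def detect_junction_potential(methods: str) -> str:
    """Classify junction-potential handling from the methods text.

    "junction potential" absent → ``unknown``; present with a negation cue
    in the same sentence → ``not_corrected``; present without negation →
    ``corrected``.  The first mentioning sentence decides.
    """
    for sentence in sentence_split(methods):
        if _JP.search(sentence):
            if _NEGATION.search(sentence):
                return "not_corrected"
            return "corrected"
    return "unknown"


# ---------------------------------------------------------------------------
# Recording temperature
# ---------------------------------------------------------------------------

_TEMP_CUES = re.compile(r"\b(record|experiment|perform|maintain)\w*", re.IGNORECASE)
_TEMP_RANGE = re.compile(
    r"(\d{1,2}(?:\.\d+)?)\s*[-–—]\s*(\d{1,2}(?:\.\d+)?)\s*°?\s*C\b"
)
_TEMP_SINGLE = re.compile(r"(\d{1,2}(?:\.\d+)?)\s*°?\s*C\b")
_ROOM = re.compile(r"room\s+temperature", re.IGNORECASE)


def parse_temperature(methods: str):
    """Recording temperature from cue-bearing sentences.

    Only sentences containing a recording/experiment cue are searched, so
    slice-storage or solution temperatures in other sentences are ignored.
    Returns a float, an inclusive (low, high) tuple, the string "room", or
    None, plus the evidence sentence: ``(value, evidence)``.
    """
    for sentence in sentence_split(methods):
        if not _TEMP_CUES.search(sentence):
            continue
        m = _TEMP_RANGE.search(sentence)
        if m:
            lo, hi = float(m.group(1)), float(m.group(2))
            if lo <= hi:
                return (lo, hi), sentence
        m = _TEMP_SINGLE.search(sentence)
        if m:
            return float(m.group(1)), sentence
        if _ROOM.search(sentence):
            return "room", sentence
    return None, None


# ---------------------------------------------------------------------------
# Animal age
# ---------------------------------------------------------------------------

_AGE_RANGE = re.compile(r"\bP(\d{1,3})\s*[-–—]\s*P?(\d{1,3})\b")
_AGE_SINGLE = re.compile(r"\bP(\d{1,3})\b")
_AGE_UNCONVERTED = re.compile(
    r"\bE\d{1,3}\b|\b\d+\s*(?:-|–)?\s*\d*\s*(?:week|month)s?(?:-|\s)old\b|\baged\s+\d+\s*(?:week|month)s?\b",
    re.IGNORECASE,
)


def parse_animal_age(methods: str):
    """Postnatal-day age from P-number patterns.

    "P14-P21" and "P7-10" give (low, high); a bare "P12" gives (12, 12).
    Embryonic and week/month expressions are recognized but not converted:
    they land in the evidence with both fields absent.  Returns
    ``((low, high) | None, evidence | None)``.
    """
    for sentence in sentence_split(methods):
        m = _AGE_RANGE.search(sentence)
        if m:
            lo, hi = int(m.group(1)), int(m.group(2))
            if lo <= hi:
                return (lo, hi), sentence
        m = _AGE_SINGLE.search(sentence)
        if m:
            d = int(m.group(1))
            return (d, d), sentence
    for sentence in sentence_split(methods):
        if _AGE_UNCONVERTED.search(sentence):
            return None, sentence
    return None, None


# ---------------------------------------------------------------------------
# Categorical concepts
# ---------------------------------------------------------------------------


def _find_evidence(methods: str, pattern: str) -> Optional[str]:
    m = re.search(pattern, methods, re.IGNORECASE)
    if not m:
        return None
    return m.group(0)


def classify_categorical(
    methods: str,
    mesh_terms: Sequence[str],
    rules: Optional[Sequence[ExtractionRule]] = None,
) -> tuple[dict[str, str], dict[str, str], dict[str, list[str]]]:
    """Assign species, strain, electrode type and preparation type.

    MeSH-method rules fire on exact term membership; regex rules on
    case-insensitive pattern match in the methods text; "both" fires on
    either.  When several rules for one concept fire, every candidate is
    reported and the primary slot goes to the highest-priority firing rule
    — MeSH hits outrank regex hits, then packaged rule order decides.  A
    strain hit implies its species.

    Returns ``(labels, evidence, candidates)`` keyed by concept.
    """
    if rules is None:
        rules = default_rules()
    mesh_set = set(mesh_terms)
    fired: dict[str, list[tuple[int, int, ExtractionRule, str]]] = {}
    for order, rule in enumerate(rules):
        mesh_hit = rule.mesh_term in mesh_set if rule.mesh_term else False
        regex_ev = _find_evidence(methods, rule.pattern) if rule.pattern else None
        if not mesh_hit and regex_ev is None:
            continue
        # priority 0 = mesh evidence, 1 = regex-only
        priority = 0 if mesh_hit else 1
        evidence = rule.mesh_term if mesh_hit else regex_ev
        fired.setdefault(rule.concept, []).append((priority, order, rule, evidence))

    labels: dict[str, str] = {}
    evidence: dict[str, str] = {}
    candidates: dict[str, list[str]] = {}
    for concept, hits in fired.items():
        hits.sort(key=lambda t: (t[0], t[1]))
        _, _, best, ev = hits[0]
        labels[concept] = best.value_label
        evidence[concept] = ev
        if len(hits) > 1:
            candidates[concept] = [h[2].value_label for h in hits]
        if best.implies_species and "species" not in labels:
            labels["species"] = best.implies_species
            evidence["species"] = ev
    # a strain hit may imply species even if a species rule also fired later
    return labels, evidence, candidates


def extract_metadata(
    methods: str,
    mesh_terms: Sequence[str] = (),
    rules: Optional[Sequence[ExtractionRule]] = None,
) -> MetadataRecord:
    """Run the full rule inventory over one methods section."""
    labels, evidence, candidates = classify_categorical(methods, mesh_terms, rules)
    record = MetadataRecord(
        species=labels.get("species"),
        strain=labels.get("strain"),
        electrode_type=labels.get("electrode_type"),
        preparation_type=labels.get("preparation_type"),
        candidates=candidates,
    )
    record.evidence.update(evidence)

    record.jp_corrected = detect_junction_potential(methods)
    if record.jp_corrected != "unknown":
        for sentence in sentence_split(methods):
            if _JP.search(sentence):
                record.evidence["junction_potential"] = sentence
                break

    temp, temp_ev = parse_temperature(methods)
    if temp is not None:
        record.temperature = temp
        record.evidence["recording_temperature"] = temp_ev

    age, age_ev = parse_animal_age(methods)
    if age is not None:
        record.age_low_days, record.age_high_days = age
    if age_ev is not None:
        record.evidence["animal_age"] = age_ev

    return record
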