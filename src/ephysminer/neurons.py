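"""Bag-of-words neuron-type recognition.

An article's full text is reduced to n-gram frequencies (word order
otherwise discarded) and every neuron type is scored by how often its
synonyms occur as contiguous n-grams.  Multi-word synonyms are counted as
contiguous phrases, not unordered word bags, so "granule cell" does not
collect credit from stray occurrences of "cell".  The ranked list is a
"best guess" to seed manual curation, not a final call.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional

from .ingest import Article
from .vocab import ConceptVocabulary

__all__ = [
    "TermFrequency",
    "NeuronCandidateRanking",
    "build_term_frequency",
    "rank_neuron_candidates",
    "top_k",
    "article_scope_text",
    "rank_article_neurons",
    "vocabulary_max_ngram",
    "tokenize",
]

_TOKEN = re.compile(r"[a-z0-9]+")

MAX_NGRAM_CAP = 6


@dataclass
class TermFrequency:
    """n-gram counts over case-folded alphanumeric tokens."""

    counts: dict[str, int] = field(default_factory=dict)
    token_total: int = 0
    max_n: int = 1


@dataclass
class NeuronCandidateRanking:
    entries: list[tuple[str, float]] = field(default_factory=list)
    tie_rule_applied: bool = False

    def ids(self) -> list[str]:
        return [nid for nid, _ in self.entries]


def tokenize(text: str) -> list[str]:
    """Maximal alphanumeric runs, case-folded."""
    return _TOKEN.findall(text.casefold())


def build_term_frequency(text: str, max_n: int = 1) -> TermFrequency:
    """Count all contiguous n-grams up to ``max_n`` tokens."""
    if max_n < 1:
        raise ValueError("max_n must be >= 1")
    tokens = tokenize(text)
    counts: dict[str, int] = {}
    for n in range(1, max_n + 1):
        for i in range(len(tokens) - n + 1):
            gram = " ".join(tokens[i : i + n])
            counts[gram] = counts.get(gram, 0) + 1
    return TermFrequency(counts=counts, token_total=len(tokens), max_n=max_n)


def vocabulary_max_ngram(vocab: ConceptVocabulary) -> int:
    """Length in tokens of the longest neuron synonym, capped."""
    longest = 1
    for entry in vocab.neuron_types:
        for syn in entry.synonyms:
            longest = max(longest, len(tokenize(syn)))
    return min(longest, MAX_NGRAM_CAP)


def rank_neuron_candidates(
    tf: TermFrequency, vocab: ConceptVocabulary
) -> NeuronCandidateRanking:
    """Score each neuron type by summed synonym n-gram counts.

    score(neuron) = sum over its synonyms of counts[synonym], the synonym
    case-folded and tokenized the same way as the document.  Zero-score
    neurons are excluded.  Ties are broken by greater total matched-synonym
    length, then lexicographic neuron id, so output is deterministic.
    """
    scored: list[tuple[float, int, str]] = []
    for entry in vocab.neuron_types:
        score = 0
        matched_len = 0
        for syn in sorted(entry.synonyms):
            gram = " ".join(tokenize(syn))
            hit = tf.counts.get(gram, 0)
            if hit:
                score += hit
                matched_len += len(gram)
        if score > 0:
            scored.append((score, matched_len, entry.neuron_id))
    scored.sort(key=lambda t: (-t[0], -t[1], t[2]))
    tie = any(
        a[0] == b[0] for a, b in zip(scored, scored[1:])
    )
    return NeuronCandidateRanking(
        entries=[(nid, float(score)) for score, _, nid in scored],
        tie_rule_applied=tie,
    )


def top_k(ranking: NeuronCandidateRanking, k: int) -> list[str]:
    if k < 1:
        raise ValueError("k must be >= 1")
    return ranking.ids()[:k]


_ABSTRACT_RESULTS = re.compile(r"^(abstract|results?)\b", re.IGNORECASE)


def article_scope_text(article: Article, scope: str = "full") -> str:
    """Text selector for ranking: full text (default) or abstract+results
    only, which drops introduction/discussion mentions of other neurons."""
    if scope == "full":
        return article.full_text()
    if scope == "abstract_results":
        parts = [
            body
            for title, body in article.sections
            if _ABSTRACT_RESULTS.match(re.sub(r"^[\d.\s]+", "", title.strip()))
        ]
        return "\n".join(parts)
    raise ValueError(f"unknown scope {scope!r}")


def rank_article_neurons(
    article: Article,
    vocab: ConceptVocabulary,
    scope: str = "full",
    max_n: Optional[int] = None,
) -> NeuronCandidateRanking:
    """Convenience: tokenize an article at the right n-gram order and rank."""
    if max_n is None:
        max_n = vocabulary_max_ngram(vocab)
    tf = build_term_frequency(article_scope_text(article, scope), max_n=max_n)
    return rank_neuron_candidates(tf, vocab)
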