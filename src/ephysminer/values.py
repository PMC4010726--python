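"""Parsing of summary-statistic strings from table cells.

Published tables report measurements in a small family of dialects, most
commonly ``XX ± YY (ZZ)`` with mean, error term and sample size, and
occasionally ``XX (LL–HH)`` with a range.  The error term is deliberately
left unresolved between standard deviation and standard error — tables
rarely say which, and guessing would corrupt downstream meta-analysis.

Parsing proceeds right to left: a trailing parenthesized group is consumed
first (an integer is a sample size, a separated pair is a range, a lone
decimal is an alternative error-term dialect), then a ``±``-suffixed error
term, and whatever numeric token remains at the front is the mean.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Optional

__all__ = [
    "ParsedValue",
    "ParseFailure",
    "normalize_numeric_text",
    "parse_data_string",
    "format_data_string",
]

log = logging.getLogger(__name__)

PLUS_MINUS = "±"   # ±
RANGE_DASH = "–"   # – (en dash, canonical range separator)


@dataclass(frozen=True)
class ParsedValue:
    """Structured decomposition of one data-cell string."""

    mean: float
    error_value: Optional[float] = None
    error_type: str = "unresolved"  # {"unresolved", "sd", "sem"}
    n: Optional[int] = None
    range_low: Optional[float] = None
    range_high: Optional[float] = None
    raw_text: str = ""

    def __post_init__(self) -> None:
        if self.error_type not in ("unresolved", "sd", "sem"):
            raise ValueError(f"bad error_type {self.error_type!r}")
        if (self.range_low is None) != (self.range_high is None):
            raise ValueError("range_low and range_high must be paired")
        if self.range_low is not None and self.range_low > self.range_high:
            raise ValueError("range_low > range_high")
        if self.n is not None and self.n < 1:
            raise ValueError("n must be >= 1")


@dataclass(frozen=True)
class ParseFailure:
    """Typed non-value result for cells with no parseable leading number."""

    raw_text: str
    reason: str = "no leading numeric token"


_THOUSANDS = re.compile(r"(?<=\d),(?=\d{3}\b)")
_UNIT_SUFFIX = re.compile(
    r"\s*(mV|ms|MΩ|Mohm|MOhms|GΩ|Gohm|pF|nF|pA|nA|Hz|kHz|s|%)\s*$",
    re.IGNORECASE,
)


def normalize_numeric_text(s: str) -> str:
    """Canonicalize the numeric micro-syntax of a cell string.

    Unicode minus and en-dash-as-sign become ASCII hyphens; the ``+/-``
    spellings unify to ``±``; dashes between digits inside parentheses
    unify to the en-dash range token; thousands separators are removed and
    whitespace collapsed.  Idempotent.
    """
    s = s.replace("−", "-")  # unicode minus
    s = re.sub(r"\+\s*/\s*[-−]", PLUS_MINUS, s)
    s = _THOUSANDS.sub("", s)
    # en/em dash leading a number outside parens is a sign
    s = re.sub(r"(?<![\d)])[–—](?=\s*\d)", _sign_or_range, s)
    # any dash variant between two numbers inside parentheses is a range
    s = re.sub(
        r"(\(\s*-?\d[\d.]*\s*)[-–—](\s*-?\d)", r"\1" + RANGE_DASH + r"\2", s
    )
    s = re.sub(r"\s+", " ", s).strip()
    return s


def _sign_or_range(m: re.Match) -> str:
    return "-"


_TRAILING_PAREN = re.compile(r"\(([^()]*)\)\s*$")
_NUMBER = r"[-+]?\d+(?:\.\d+)?"
_RANGE_PAIR = re.compile(
    rf"^\s*({_NUMBER})\s*(?:{RANGE_DASH}|-|to|—)\s*({_NUMBER})\s*$"
)
_INT = re.compile(r"^\s*n?\s*=?\s*(\d+)\s*$")
_DECIMAL = re.compile(rf"^\s*({_NUMBER})\s*$")
_PM_TAIL = re.compile(rf"{re.escape(PLUS_MINUS)}\s*({_NUMBER})\s*$")
_LEAD_NUMBER = re.compile(rf"^\s*({_NUMBER})\s*$")


def parse_data_string(s: str) -> ParsedValue | ParseFailure:
    """Parse one cell string into a :class:`ParsedValue`.

    Never raises on arbitrary text: strings with no leading numeric token
    (``"n.d."``, em-dash placeholders, empty cells) come back as a
    :class:`ParseFailure` carrying the raw text.
    """
    raw = s
    text = normalize_numeric_text(s)
    text = _UNIT_SUFFIX.sub("", text).strip()

    n: Optional[int] = None
    range_low = range_high = None
    error_value: Optional[float] = None

    # 1. trailing parenthesized group, right to left
    m = _TRAILING_PAREN.search(text)
    if m:
        inner = m.group(1)
        mi = _INT.match(inner)
        mr = _RANGE_PAIR.match(inner)
        md = _DECIMAL.match(inner)
        if mr:
            lo, hi = float(mr.group(1)), float(mr.group(2))
            if lo <= hi:
                range_low, range_high = lo, hi
                text = text[: m.start()].strip()
        elif mi:
            n = int(mi.group(1))
            if n >= 1:
                text = text[: m.start()].strip()
            else:
                n = None
        elif md:
            # dialect guess: parenthesized lone decimal as error term
            error_value = float(md.group(1))
            text = text[: m.start()].strip()
            log.info("dialect guess: parenthesized decimal as error in %r", raw)

    # 2. plus-minus-suffixed error term
    m = _PM_TAIL.search(text)
    if m:
        pm_error = float(m.group(1))
        if error_value is None:
            error_value = pm_error
        text = text[: m.start()].strip()

    # 3. remaining leading number is the mean
    m = _LEAD_NUMBER.match(text)
    if not m:
        return ParseFailure(raw_text=raw)
    mean = float(m.group(1))
    return ParsedValue(
        mean=mean,
        error_value=error_value,
        n=n,
        range_low=range_low,
        range_high=range_high,
        raw_text=raw,
    )


def _fmt_num(x: float) -> str:
    if float(x) == int(x) and abs(x) < 1e15:
        return str(int(x))
    return repr(float(x))


def format_data_string(v: ParsedValue | ParseFailure) -> str:
    """Emit the canonical textual form of a parsed value.

    Inverse of :func:`parse_data_string` on all fields except
    ``error_type`` (which has no textual form) and ``raw_text``.
    """
    if isinstance(v, ParseFailure):
        raise ValueError("cannot format a parse failure")
    parts = [_fmt_num(v.mean)]
    if v.error_value is not None:
        parts.append(f"{PLUS_MINUS} {_fmt_num(v.error_value)}")
    if v.range_low is not None:
        parts.append(f"({_fmt_num(v.range_low)}{RANGE_DASH}{_fmt_num(v.range_high)})")
    elif v.n is not None:
        parts.append(f"({v.n})")
    return " ".join(parts)
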