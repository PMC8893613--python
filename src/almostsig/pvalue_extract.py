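"""P-value tokens in the trailing context of phrase hits.

A "direct referral" is a P value printed within the first 100 characters
after a phrase occurrence, usually in parentheses — e.g. "the drug effect
was almost significantly lower in group b (p = 0.052)". This module finds
the first such token in each hit's window, parses it (plain decimals and
power-of-ten notation), and buckets the value into three bands:

* ``below``: value < 0.05
* ``mid``: 0.05 <= value <= 0.15 (both boundaries closed)
* ``above``: value > 0.15

Comparator-only statements like "p < 0.06" are parsed too; the numeric
literal is used for banding and the comparator retained for auditability.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .corpus_io import ArticleRecord
from .phrase_match import PhraseHit
from .prevalence_stats import proportion_ci

__all__ = [
    "PValueMention",
    "extract_window",
    "parse_pvalue",
    "categorize",
    "extract_mentions",
    "summarize_pvalues",
    "format_pvalue",
    "DEFAULT_WINDOW",
]

DEFAULT_WINDOW = 100

CATEGORIES = ("below", "mid", "above")

# mantissa: 0.052 | .06 | 3 ; power-of-ten tail: "× 10-3", "x 10^-3", "e-3"
_MANTISSA = r"(?:\d+\.\d+|\.\d+|\d+)"
_TOKEN_RE = re.compile(
    rf"""
    (?<![a-z0-9])                      # "p" must start a word ("bp=..." is not a P)
    \(?\s*
    p(?:[\s-]?values?)?                # p / p value / p-values ...
    \s*(?P<cmp>=|<=|>=|≤|≥|<|>)\s*
    (?P<mant>{_MANTISSA})
    (?:\s*(?:×|x|e)\s*(?:10\s*\^?\s*)?(?P<exp>[-+]?\d+))?
    """,
    re.VERBOSE,
)

_CMP_CANON = {"≤": "<=", "≥": ">="}


@dataclass(frozen=True)
class PValueMention:
    """One parsed P-value token tied to the phrase hit it follows."""

    article_id: str
    phrase: str
    value: float
    comparator: str
    raw_token: str
    distance: int
    category: str


def extract_window(text_norm: str, hit: PhraseHit, width: int = DEFAULT_WINDOW) -> str:
    """The up-to-``width`` characters directly following the hit."""
    return text_norm[hit.end_offset : hit.end_offset + width]


def parse_pvalue(window: str) -> tuple[float, str, str, int] | None:
    """First P-value token in the window, or ``None``.

    Returns ``(value, comparator, raw_token, distance)`` where ``distance``
    is the character offset of the token within the window. Tokens whose
    numeric literal exceeds 1 (percentages, ratios) are rejected and the
    scan continues past them.
    """
    pos = 0
    while True:
        m = _TOKEN_RE.search(window, pos)
        if m is None:
            return None
        value = float(m.group("mant"))
        if m.group("exp") is not None:
            exp = int(m.group("exp"))
            value *= 10.0**exp
        if 0.0 <= value <= 1.0:
            comparator = _CMP_CANON.get(m.group("cmp"), m.group("cmp"))
            return value, comparator, m.group(0).strip(), m.start()
        pos = m.end()


def categorize(value: float) -> str:
    """Band a P value: below < 0.05 <= mid <= 0.15 < above."""
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"P value {value} outside [0, 1]")
    if value < 0.05:
        return "below"
    if value <= 0.15:
        return "mid"
    return "above"


def extract_mentions(
    records: dict[str, ArticleRecord] | list[ArticleRecord],
    hits: pd.DataFrame,
    width: int = DEFAULT_WINDOW,
) -> pd.DataFrame:
    """Run window extraction + parsing over a hit table.

    Returns one row per hit with a parseable token: columns ``article_id,
    phrase, raw_token, comparator, value, distance, category``.
    """
    if not isinstance(records, dict):
        records = {r.id: r for r in records}
    rows = []
    for tup in hits.itertuples(index=False):
        rec = records[tup.article_id]
        window = rec.text_norm[tup.end : tup.end + width]
        parsed = parse_pvalue(window)
        if parsed is None:
            continue
        value, comparator, raw_token, distance = parsed
        rows.append(
            {
                "article_id": tup.article_id,
                "phrase": tup.phrase,
                "raw_token": raw_token,
                "comparator": comparator,
                "value": value,
                "distance": distance,
                "category": categorize(value),
            }
        )
    cols = ["article_id", "phrase", "raw_token", "comparator", "value", "distance", "category"]
    return pd.DataFrame(rows, columns=cols)


def summarize_pvalues(
    mentions: pd.DataFrame, n_windows: int | None = None
) -> dict:
    """Distributional summary of extracted P values.

    Quantiles use linear interpolation between order statistics. Category
    proportions come with continuity-corrected 95% CIs. ``n_windows`` — the
    number of phrase hits whose windows were searched — turns into an
    ``extraction_rate`` when provided. Empty input yields ``n == 0`` and
    NaN statistics.
    """
    n = len(mentions)
    out: dict = {"n": n, "extraction_rate": np.nan}
    if n_windows:
        out["extraction_rate"] = n / n_windows
    if n == 0:
        out.update(
            median=np.nan,
            quantiles={q: np.nan for q in (5, 25, 75, 95)},
            categories={
                c: {"n": 0, "proportion": np.nan, "ci_low": np.nan, "ci_high": np.nan}
                for c in CATEGORIES
            },
        )
        return out
    values = mentions["value"].to_numpy()
    out["median"] = float(np.median(values))
    out["quantiles"] = {
        q: float(np.percentile(values, q, method="linear")) for q in (5, 25, 75, 95)
    }
    cats = {}
    for c in CATEGORIES:
        k = int((mentions["category"] == c).sum())
        prop, lo, hi = proportion_ci(k, n)
        cats[c] = {"n": k, "proportion": prop, "ci_low": lo, "ci_high": hi}
    out["categories"] = cats
    return out


def format_pvalue(
    value: float,
    comparator: str = "=",
    decimals: int = 3,
    style: str = "paren",
) -> str:
    """Canonical printer for P-value tokens (inverse of :func:`parse_pvalue`).

    ``style`` is one of ``paren`` ("(p = 0.052)"), ``bare`` ("p = 0.052"),
    ``naked_decimal`` ("p = .052"), or ``sci`` ("p = 5.2 × 10-2").
    Formatting then re-parsing recovers the value to printed precision.
    """
    if style == "sci":
        if value <= 0:
            raise ValueError("sci style needs a positive value")
        exp = int(np.floor(np.log10(value)))
        mant = value / 10.0**exp
        return f"p {comparator} {mant:.{decimals}f} × 10{exp:+d}".replace("+", "")
    text = f"{value:.{decimals}f}"
    if style == "naked_decimal":
        text = text.lstrip("0") if value < 1 else text
    token = f"p {comparator} {text}"
    return f"({token})" if style == "paren" else token
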