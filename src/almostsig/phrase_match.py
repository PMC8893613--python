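"""Phrase dictionary loading and exact multi-pattern matching.

Matching is plain substring matching over the normalized text — the in-memory
equivalent of running ``grep -F`` with a fixed phrase list — implemented with
an Aho–Corasick automaton so a single pass over each document finds every
occurrence of every phrase, including overlapping occurrences of different
phrases and repeated occurrences of the same phrase.

No word-boundary requirement is imposed by default; a ``word_boundary``
option is available for sensitivity analysis.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .corpus_io import ArticleRecord, normalize_text

logger = logging.getLogger(__name__)

__all__ = [
    "PhraseDictionary",
    "PhraseHit",
    "load_dictionary",
    "default_dictionary",
    "scan_document",
    "scan_corpus",
]

_DEFAULT_RESOURCE = "phrases_synthetic.txt"


@dataclass(frozen=True)
class PhraseHit:
    """One exact match: ``text_norm[start_offset:end_offset] == phrase``.

    ``subsumed_by`` names a strictly longer phrase whose match span strictly
    contains this one (e.g. "marginally significant" inside
    "only marginally significant"); ``None`` when no such match exists.
    """

    article_id: str
    phrase: str
    start_offset: int
    end_offset: int
    subsumed_by: str | None = None


class _AhoCorasick:
    """Multi-pattern string automaton (goto/fail/output construction)."""

    def __init__(self, patterns: Sequence[str]):
        self._goto: list[dict[str, int]] = [{}]
        self._fail: list[int] = [0]
        self._out: list[list[str]] = [[]]
        for pat in patterns:
            self._insert(pat)
        self._build_failure_links()

    def _insert(self, pat: str) -> None:
        state = 0
        for ch in pat:
            nxt = self._goto[state].get(ch)
            if nxt is None:
                nxt = len(self._goto)
                self._goto.append({})
                self._fail.append(0)
                self._out.append([])
                self._goto[state][ch] = nxt
            state = nxt
        self._out[state].append(pat)

    def _build_failure_links(self) -> None:
        queue: deque[int] = deque()
        for state in self._goto[0].values():
            queue.append(state)
        while queue:
            state = queue.popleft()
            for ch, nxt in self._goto[state].items():
                queue.append(nxt)
                f = self._fail[state]
                while f and ch not in self._goto[f]:
                    f = self._fail[f]
                self._fail[nxt] = self._goto[f].get(ch, 0) if self._goto[f].get(ch, 0) != nxt else 0
                self._out[nxt] = self._out[nxt] + self._out[self._fail[nxt]]

    def finditer(self, text: str):
        """Yield ``(end_index_exclusive, pattern)`` for every occurrence."""
        state = 0
        for i, ch in enumerate(text):
            while state and ch not in self._goto[state]:
                state = self._fail[state]
            state = self._goto[state].get(ch, 0)
            for pat in self._out[state]:
                yield i + 1, pat


@dataclass(frozen=True)
class PhraseDictionary:
    """Ordered, deduplicated list of normalized phrases plus its automaton."""

    phrases: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.phrases:
            raise ValueError("phrase dictionary is empty")
        if len(set(self.phrases)) != len(self.phrases):
            raise ValueError("phrase dictionary contains duplicates")
        for p in self.phrases:
            if normalize_text(p) != p:
                raise ValueError(f"phrase not in normal form: {p!r}")
        object.__setattr__(self, "_automaton", _AhoCorasick(self.phrases))

    def __len__(self) -> int:
        return len(self.phrases)

    def __contains__(self, phrase: str) -> bool:
        return phrase in set(self.phrases)

    @property
    def automaton(self) -> _AhoCorasick:
        return self._automaton  # type: ignore[attr-defined]


def load_dictionary(path: str | Path) -> PhraseDictionary:
    """Load a phrase dictionary: one phrase per line, ``#`` comments allowed.

    Phrases are normalized; duplicates (after normalization) are collapsed
    with a warning, order of first appearance preserved. A phrase that
    normalizes to the empty string, or an entirely empty file, is an error.
    """
    path = Path(path)
    phrases: list[str] = []
    seen: set[str] = set()
    n_dupes = n_blank = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if stripped.startswith("#"):
                continue
            if not stripped:
                n_blank += 1
                continue
            phrase = normalize_text(stripped)
            if not phrase:
                raise ValueError(f"{path}:{lineno}: phrase normalizes to empty")
            if phrase in seen:
                n_dupes += 1
                logger.warning("%s:%d: duplicate phrase %r collapsed", path, lineno, phrase)
                continue
            seen.add(phrase)
            phrases.append(phrase)
    if not phrases:
        raise ValueError(f"{path}: no phrases found")
    if n_dupes or n_blank:
        logger.info("%s: %d duplicates collapsed, %d blank lines", path, n_dupes, n_blank)
    return PhraseDictionary(tuple(phrases))


def default_dictionary() -> PhraseDictionary:
    """The shipped 505-entry dictionary.

    A synthetic stand-in for the curated 505-phrase list: it contains the
    published high-frequency phrases verbatim plus systematic variants
    generated from the same linguistic templates.
    """
    ref = resources.files("almostsig").joinpath("data", _DEFAULT_RESOURCE)
    with resources.as_file(ref) as path:
        d = load_dictionary(path)
    assert len(d) == 505
    return d


def _annotate_subsumption(hits: list[PhraseHit]) -> list[PhraseHit]:
    """Mark hits whose span is strictly contained in another hit's span."""
    out: list[PhraseHit] = []
    for h in hits:
        container: PhraseHit | None = None
        for other in hits:
            if other is h:
                continue
            if (
                other.start_offset <= h.start_offset
                and h.end_offset <= other.end_offset
                and (other.end_offset - other.start_offset) > (h.end_offset - h.start_offset)
            ):
                if container is None or (
                    other.end_offset - other.start_offset
                    > container.end_offset - container.start_offset
                ):
                    container = other
        out.append(
            PhraseHit(
                h.article_id,
                h.phrase,
                h.start_offset,
                h.end_offset,
                container.phrase if container else None,
            )
        )
    return out


def _word_bounded(text: str, start: int, end: int) -> bool:
    before_ok = start == 0 or not text[start - 1].isalnum()
    after_ok = end == len(text) or not text[end].isalnum()
    return before_ok and after_ok


def scan_document(
    record: ArticleRecord,
    dictionary: PhraseDictionary,
    word_boundary: bool = False,
) -> list[PhraseHit]:
    """All dictionary matches in one document, sorted by (offset, phrase)."""
    text = record.text_norm
    raw: list[PhraseHit] = []
    for end, phrase in dictionary.automaton.finditer(text):
        start = end - len(phrase)
        if word_boundary and not _word_bounded(text, start, end):
            continue
        raw.append(PhraseHit(record.id, phrase, start, end))
    raw.sort(key=lambda h: (h.start_offset, h.phrase))
    return _annotate_subsumption(raw)


def scan_corpus(
    records: Iterable[ArticleRecord],
    dictionary: PhraseDictionary,
    word_boundary: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Scan a corpus; return the hit table and a per-document summary.

    Returns
    -------
    hits : DataFrame
        Columns ``article_id, phrase, start, end, subsumed_by`` — one row
        per occurrence.
    summary : DataFrame
        Columns ``article_id, pub_year, pub_month, n_hits, phrase_positive``
        — one row per document, in input order.

    Document-level counts use "at least once" (``phrase_positive``); the hit
    table keeps every occurrence, so total hits can exceed the number of
    phrase-positive documents. Duplicate article ids are an error.
    """
    hit_rows: list[dict] = []
    summary_rows: list[dict] = []
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"duplicate article id {rec.id!r}")
        seen.add(rec.id)
        hits = scan_document(rec, dictionary, word_boundary=word_boundary)
        for h in hits:
            hit_rows.append(
                {
                    "article_id": h.article_id,
                    "phrase": h.phrase,
                    "start": h.start_offset,
                    "end": h.end_offset,
                    "subsumed_by": h.subsumed_by,
                }
            )
        summary_rows.append(
            {
                "article_id": rec.id,
                "pub_year": rec.pub_year,
                "pub_month": rec.pub_month,
                "n_hits": len(hits),
                "phrase_positive": len(hits) > 0,
            }
        )
    hit_cols = ["article_id", "phrase", "start", "end", "subsumed_by"]
    hits_df = pd.DataFrame(hit_rows, columns=hit_cols)
    summary_df = pd.DataFrame(
        summary_rows,
        columns=["article_id", "pub_year", "pub_month", "n_hits", "phrase_positive"],
    )
    return hits_df, summary_df


def phrase_document_counts(
    hits: pd.DataFrame, exclude_subsumed: bool = False
) -> pd.DataFrame:
    """Documents containing each phrase at least once (frequency table).

    With ``exclude_subsumed=True``, occurrences strictly contained in a
    longer phrase's match are not counted — the "longest-only" variant.
    Returns columns ``phrase, n_documents`` sorted by descending count then
    phrase.
    """
    if hits.empty:
        return pd.DataFrame(columns=["phrase", "n_documents"])
    sel = hits if not exclude_subsumed else hits[hits["subsumed_by"].isna()]
    counts = (
        sel.drop_duplicates(["article_id", "phrase"])
        .groupby("phrase")
        .size()
        .rename("n_documents")
        .reset_index()
    )
    return counts.sort_values(
        ["n_documents", "phrase"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
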