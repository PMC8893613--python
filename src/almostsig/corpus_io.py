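"""Reading, filtering and normalizing article records; writing result tables.

An :class:`ArticleRecord` is one full-text document with an identifier and a
publication date. Records are filtered to the study window (January 1990
through September 2020) and their text is normalized once, up front, so that
every downstream stage — phrase scanning, window extraction, P-value parsing —
operates on the same canonical string.
"""

from __future__ import annotations

import csv
import json
import logging
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ArticleRecord",
    "CorpusStats",
    "CorpusFormatError",
    "normalize_text",
    "read_corpus",
    "write_table",
    "YEAR_MIN",
    "YEAR_MAX",
    "LAST_MONTH",
]

#: Inclusive study window: January 1990 through September 2020.
YEAR_MIN = 1990
YEAR_MAX = 2020
LAST_MONTH = 9  # of YEAR_MAX

# Quote variants mapped to their ASCII counterparts; dash variants to "-".
# The multiplication sign U+00D7 is deliberately NOT touched: the P-value
# grammar needs it to recognize scientific notation like "1.2 × 10-3".
_CHAR_MAP = str.maketrans(
    {
        "‘": "'",
        "’": "'",
        "‚": "'",
        "‛": "'",
        "“": '"',
        "”": '"',
        "„": '"',
        "‟": '"',
        "–": "-",
        "—": "-",
        "−": "-",
    }
)


class CorpusFormatError(ValueError):
    """Raised for malformed corpus files (missing fields, bad years, empty input)."""


def normalize_text(text_raw: str) -> str:
    """Canonicalize raw article text.

    Lowercases, strips combining diacritical marks (canonical decomposition),
    maps curly quotes to ASCII quotes and en/em dashes to hyphens, and
    collapses every whitespace run (including newlines and non-breaking
    spaces) to a single space. Total and idempotent.
    """
    text = unicodedata.normalize("NFD", text_raw.lower())
    text = "".join(c for c in text if not unicodedata.combining(c))
    text = text.translate(_CHAR_MAP)
    return " ".join(text.split())


@dataclass(frozen=True)
class ArticleRecord:
    """One document: identifier, publication date, raw and normalized text."""

    id: str
    pub_year: int
    text_raw: str
    pub_month: int | None = None
    text_norm: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if self.pub_month is not None and not 1 <= self.pub_month <= 12:
            raise ValueError(f"pub_month {self.pub_month} outside 1-12")
        if not self.text_norm:
            object.__setattr__(self, "text_norm", normalize_text(self.text_raw))


@dataclass
class CorpusStats:
    """Bookkeeping for one corpus read: kept + dropped == read, always."""

    n_read: int = 0
    n_kept: int = 0
    n_dropped: int = 0


def _in_window(year: int, month: int | None) -> bool:
    if not YEAR_MIN <= year <= YEAR_MAX:
        return False
    if year == YEAR_MAX and month is not None and month > LAST_MONTH:
        return False
    return True


def _build_record(row: dict, idx: int) -> ArticleRecord:
    for key in ("id", "year", "text"):
        if key not in row or row[key] in (None, ""):
            raise CorpusFormatError(f"row {idx}: missing required field {key!r}")
    try:
        year = int(row["year"])
    except (TypeError, ValueError) as exc:
        raise CorpusFormatError(f"row {idx}: unparseable year {row['year']!r}") from exc
    month_val = row.get("month")
    month = None
    if month_val not in (None, ""):
        try:
            month = int(month_val)
        except (TypeError, ValueError) as exc:
            raise CorpusFormatError(
                f"row {idx}: unparseable month {month_val!r}"
            ) from exc
    return ArticleRecord(
        id=str(row["id"]), pub_year=year, pub_month=month, text_raw=str(row["text"])
    )


def _iter_rows(path: Path, format: str) -> Iterator[dict]:
    if format == "jsonl":
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                if line.strip():
                    yield json.loads(line)
    elif format == "csv":
        with open(path, encoding="utf-8", newline="") as fh:
            yield from csv.DictReader(fh)
    elif format == "txt_dir":
        # Directory of <id>.txt files with a sidecar dates.csv (id,year[,month]).
        dates_path = Path(path) / "dates.csv"
        if not dates_path.exists():
            raise CorpusFormatError(f"txt_dir corpus needs a sidecar {dates_path}")
        with open(dates_path, encoding="utf-8", newline="") as fh:
            for row in csv.DictReader(fh):
                txt = Path(path) / f"{row.get('id', '')}.txt"
                if not txt.exists():
                    raise CorpusFormatError(f"missing text file {txt}")
                row = dict(row)
                row["text"] = txt.read_text(encoding="utf-8")
                yield row
    else:
        raise ValueError(f"unknown corpus format {format!r}")


def read_corpus(
    path: str | Path,
    format: str | None = None,
    stats: CorpusStats | None = None,
) -> list[ArticleRecord]:
    """Read article records and apply the study time-frame filter.

    Parameters
    ----------
    path
        Corpus file (JSONL or CSV with columns ``id, year, text`` and
        optional ``month``) or a directory of ``<id>.txt`` files with a
        ``dates.csv`` sidecar.
    format
        One of ``{"jsonl", "csv", "txt_dir"}``; inferred from the path
        when omitted.
    stats
        Optional :class:`CorpusStats` to fill with read/kept/dropped counts.

    Records dated outside January 1990 – September 2020 are dropped (records
    without a month are filtered at year level). Raises
    :class:`CorpusFormatError` on malformed rows or an empty corpus.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        if path.is_dir():
            format = "txt_dir"
        elif path.suffix == ".csv":
            format = "csv"
        else:
            format = "jsonl"

    stats = stats if stats is not None else CorpusStats()
    records: list[ArticleRecord] = []
    seen: set[str] = set()
    for idx, row in enumerate(_iter_rows(path, format)):
        stats.n_read += 1
        rec = _build_record(row, idx)
        if rec.id in seen:
            raise CorpusFormatError(f"row {idx}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        if _in_window(rec.pub_year, rec.pub_month):
            records.append(rec)
            stats.n_kept += 1
        else:
            stats.n_dropped += 1
    if stats.n_read == 0:
        raise CorpusFormatError(f"empty corpus: {path}")
    logger.info(
        "corpus %s: read=%d kept=%d dropped=%d",
        path,
        stats.n_read,
        stats.n_kept,
        stats.n_dropped,
    )
    return records


def write_table(
    rows: pd.DataFrame | Sequence[dict] | Iterable[dict],
    path: str | Path,
    sort_by: str | list[str] | None = None,
) -> pd.DataFrame:
    """Write a result table as UTF-8 CSV with a deterministic row order.

    ``sort_by`` names the key column(s); when given, rows are sorted on them
    (stable) so two runs on the same input produce byte-identical files.
    Returns the frame actually written.
    """
    frame = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(list(rows))
    if sort_by is not None and len(frame):
        frame = frame.sort_values(sort_by, kind="mergesort").reset_index(drop=True)
    frame.to_csv(path, index=False, encoding="utf-8", lineterminator="\n")
    return frame
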