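"""Reading, deduplicating and filtering bibliographic export records.

Bibliographic databases export search results as tab-delimited tables with a
header row, typically in batches of at most a few hundred records.  This
module parses one or more such files into :class:`BibRecord` objects, removes
duplicate entries and applies the screening filters (abstract availability,
publication-year window, document type, language) that define the working
corpus, producing a per-filter removal report.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "BibRecord",
    "ExportDialect",
    "FilterReport",
    "read_export",
    "write_export",
    "deduplicate",
    "filter_records",
]


@dataclass(frozen=True)
class BibRecord:
    """A single bibliographic entry.

    ``doc_type`` is normalised to one of ``{"article", "review", "other"}``
    and ``language`` is case-folded.  ``abstract`` is ``None`` when the
    database holds no abstract for the record; ``year`` is ``None`` when the
    exported year field could not be parsed as an integer.
    """

    record_id: str
    title: str
    abstract: str | None = None
    year: int | None = None
    citations: int = 0
    doc_type: str = "other"
    language: str = "english"

    def __post_init__(self) -> None:
        if self.citations < 0:
            raise ValueError(f"citations must be >= 0, got {self.citations}")


@dataclass(frozen=True)
class ExportDialect:
    """Column-label mapping for a tab-delimited bibliographic export.

    Defaults follow the Web-of-Science-style two-letter field tags
    (UT unique id, TI title, AB abstract, PY year, TC times cited,
    DT document type, LA language); every label and the delimiter are
    configurable.
    """

    id_col: str = "UT"
    title_col: str = "TI"
    abstract_col: str = "AB"
    year_col: str = "PY"
    citations_col: str = "TC"
    doc_type_col: str = "DT"
    language_col: str = "LA"
    delimiter: str = "\t"

    @property
    def columns(self) -> list[str]:
        return [
            self.id_col,
            self.title_col,
            self.abstract_col,
            self.year_col,
            self.citations_col,
            self.doc_type_col,
            self.language_col,
        ]


@dataclass
class FilterReport:
    """Accounting of a :func:`filter_records` pass.

    ``removed`` maps filter name to the number of records it removed; a
    record failing several filters is attributed to the first failing filter
    in declared order, so ``n_input == n_retained + sum(removed.values())``.
    """

    n_input: int = 0
    n_retained: int = 0
    removed: dict[str, int] = field(default_factory=dict)

    def check(self) -> None:
        assert self.n_input == self.n_retained + sum(self.removed.values())


_DOC_TYPE_MAP = {
    "article": "article",
    "review": "review",
    "article; early access": "article",
    "review; early access": "review",
}


def _normalise_doc_type(raw: str | None) -> str:
    if raw is None:
        return "other"
    return _DOC_TYPE_MAP.get(raw.strip().lower(), raw.strip().lower() or "other")


def _cell(row: pd.Series, col: str) -> str | None:
    if col not in row.index:
        return None
    value = row[col]
    if pd.isna(value):
        return None
    text = str(value).strip()
    return text or None


def read_export(
    path: str | Path,
    dialect: ExportDialect | None = None,
) -> list[BibRecord]:
    """Read one tab-delimited export file into a list of records.

    Rows missing both the unique id and the title are skipped with a logged
    warning.  A missing abstract yields a record with ``abstract=None``;
    an unparseable year yields ``year=None`` (excluded later by the year
    filter); a missing citation count is read as 0.  Batches from multiple
    files are concatenable with plain list addition.
    """
    dialect = dialect or ExportDialect()
    path = Path(path)
    frame = pd.read_csv(
        path, sep=dialect.delimiter, dtype=str, keep_default_na=True, engine="python"
    )
    records: list[BibRecord] = []
    for i, row in frame.iterrows():
        record_id = _cell(row, dialect.id_col)
        title = _cell(row, dialect.title_col)
        if record_id is None and title is None:
            logger.warning("%s row %d: no record id and no title, skipped", path, i)
            continue
        year_raw = _cell(row, dialect.year_col)
        year: int | None
        try:
            year = int(float(year_raw)) if year_raw is not None else None
        except ValueError:
            logger.warning("%s row %d: unparseable year %r", path, i, year_raw)
            year = None
        cites_raw = _cell(row, dialect.citations_col)
        try:
            citations = max(0, int(float(cites_raw))) if cites_raw is not None else 0
        except ValueError:
            citations = 0
        records.append(
            BibRecord(
                record_id=record_id or f"title:{title}",
                title=title or "",
                abstract=_cell(row, dialect.abstract_col),
                year=year,
                citations=citations,
                doc_type=_normalise_doc_type(_cell(row, dialect.doc_type_col)),
                language=(_cell(row, dialect.language_col) or "english").lower(),
            )
        )
    return records


def write_export(
    records: Iterable[BibRecord],
    path: str | Path,
    dialect: ExportDialect | None = None,
) -> None:
    """Write records back in the configured export format (fixture support)."""
    dialect = dialect or ExportDialect()
    rows = []
    for r in records:
        rows.append(
            {
                dialect.id_col: r.record_id,
                dialect.title_col: r.title,
                dialect.abstract_col: r.abstract if r.abstract is not None else "",
                dialect.year_col: r.year if r.year is not None else "",
                dialect.citations_col: r.citations,
                dialect.doc_type_col: r.doc_type,
                dialect.language_col: r.language,
            }
        )
    frame = pd.DataFrame(rows, columns=dialect.columns)
    frame.to_csv(path, sep=dialect.delimiter, index=False)


def _normalise_title(title: str) -> str:
    return " ".join(title.casefold().split())


def deduplicate(records: Sequence[BibRecord]) -> list[BibRecord]:
    """Remove duplicate records, keeping the first occurrence.

    Duplicates are identified by ``record_id``; records whose id is the
    synthesised title fallback (no id in the export) are compared by
    case-folded, whitespace-normalised title.  Output order is preserved and
    the operation is idempotent.
    """
    seen_ids: set[str] = set()
    seen_titles: set[str] = set()
    out: list[BibRecord] = []
    for r in records:
        if r.record_id.startswith("title:"):
            key = _normalise_title(r.title)
            if key in seen_titles:
                continue
            seen_titles.add(key)
        else:
            if r.record_id in seen_ids:
                continue
            seen_ids.add(r.record_id)
        out.append(r)
    return out


def filter_records(
    records: Sequence[BibRecord],
    require_abstract: bool = True,
    year_range: tuple[int, int] | None = (2000, 2020),
    doc_types: set[str] | None = frozenset({"article", "review"}),
    languages: set[str] | None = frozenset({"english"}),
) -> tuple[list[BibRecord], FilterReport]:
    """Apply the corpus screening filters in declared order.

    Filter order: abstract presence, year window, document type, language.
    A record failing several filters is counted against the first failing
    one.  Records with an unparseable (``None``) year are excluded by the
    year filter with a logged warning.  Pass ``None`` (or ``False`` for
    ``require_abstract``) to disable a filter.
    """
    if year_range is not None and year_range[0] > year_range[1]:
        raise ValueError(f"year_range min > max: {year_range}")
    report = FilterReport(n_input=len(records))
    report.removed = {"abstract": 0, "year": 0, "doc_type": 0, "language": 0}
    retained: list[BibRecord] = []
    for r in records:
        if require_abstract and r.abstract is None:
            report.removed["abstract"] += 1
            continue
        if year_range is not None:
            if r.year is None:
                logger.warning("record %s has no parseable year; removed", r.record_id)
                report.removed["year"] += 1
                continue
            if not (year_range[0] <= r.year <= year_range[1]):
                report.removed["year"] += 1
                continue
        if doc_types is not None and r.doc_type not in doc_types:
            report.removed["doc_type"] += 1
            continue
        if languages is not None and r.language not in languages:
            report.removed["language"] += 1
            continue
        retained.append(r)
    report.n_retained = len(retained)
    report.check()
    return retained, report
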