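"""Parsing of spontaneous-report tables in the FAERS ASCII dialect.

FAERS distributes quarterly ASCII extracts as ``$``-separated tables.  Two of
them matter for drug/side-effect association mining: the DRUG table (one row
per drug mentioned in a case, with a role code marking the primary suspect)
and the REAC table (one row per reported reaction term).  This module parses
both into typed records and joins them into ``(drug, reaction, report count)``
triples restricted to primary-suspect roles.

Normalization is deliberately light: drug names and reaction terms are
uppercased and internal whitespace is collapsed.  Mapping trade names to
ingredients is out of scope; a user-supplied synonym table can be applied via
:func:`apply_synonyms` before building triples.
"""

from __future__ import annotations

import csv
import gzip
import io
import logging
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

_WS = re.compile(r"\s+")

#: Role codes treated as "primary suspect" by default (FAERS convention).
DEFAULT_PS_TOKENS = ("PS",)


class ConfigurationError(ValueError):
    """A declared column is missing from the input header."""


def _normalize(text: str) -> str:
    return _WS.sub(" ", text.strip()).upper()


@dataclass(frozen=True)
class DrugRecord:
    """One row of the DRUG table: a drug mentioned in a case report."""

    case_id: str
    drug_name: str
    role_code: str  # "primary_suspect" or "other"

    @property
    def is_primary_suspect(self) -> bool:
        return self.role_code == "primary_suspect"


@dataclass(frozen=True)
class ReactionRecord:
    """One row of the REAC table: a reaction term reported in a case."""

    case_id: str
    reaction_term: str


@dataclass
class TableDialect:
    """Field separator and column names for a FAERS-style delimited table.

    FAERS ASCII files use ``$`` as the separator; other exports use tabs or
    commas.  Column names are declared explicitly because they drifted across
    FAERS eras (e.g. ``ISR`` vs ``primaryid``).
    """

    separator: str = "$"
    case_id_col: str = "primaryid"
    drug_name_col: str = "drugname"
    role_code_col: str = "role_cod"
    reaction_col: str = "pt"
    ps_tokens: Sequence[str] = DEFAULT_PS_TOKENS


@dataclass
class ParseReport:
    """Counters accumulated while parsing: rows kept, dropped, malformed."""

    n_rows: int = 0
    n_kept: int = 0
    n_dropped: int = 0


def _open_text(source: str | Path | IO[str]) -> IO[str]:
    if hasattr(source, "read"):
        return source  # type: ignore[return-value]
    path = Path(source)
    if path.suffix == ".gz":
        return io.TextIOWrapper(gzip.open(path, "rb"), encoding="utf-8")
    return open(path, "r", encoding="utf-8")


def _reader(stream: IO[str], dialect: TableDialect, required: Sequence[str]):
    rdr = csv.DictReader(stream, delimiter=dialect.separator)
    if rdr.fieldnames is None:
        return rdr  # empty file: caller sees no rows
    for col in required:
        if col not in rdr.fieldnames:
            raise ConfigurationError(
                f"declared column {col!r} not found in header {rdr.fieldnames}"
            )
    return rdr


def parse_drug_table(
    source: str | Path | IO[str],
    dialect: TableDialect | None = None,
    report: ParseReport | None = None,
) -> list[DrugRecord]:
    """Parse a DRUG table into records, dropping rows with missing fields.

    Rows missing any of the case id, drug name or role code are dropped and
    counted in ``report.n_dropped`` rather than raising.
    """
    dialect = dialect or TableDialect()
    report = report if report is not None else ParseReport()
    ps = {t.upper() for t in dialect.ps_tokens}
    records: list[DrugRecord] = []
    stream = _open_text(source)
    rdr = _reader(
        stream, dialect, [dialect.case_id_col, dialect.drug_name_col, dialect.role_code_col]
    )
    for row in rdr:
        report.n_rows += 1
        try:
            case = (row.get(dialect.case_id_col) or "").strip()
            name = _normalize(row.get(dialect.drug_name_col) or "")
            role = (row.get(dialect.role_code_col) or "").strip().upper()
        except Exception:  # pragma: no cover - defensive against ragged rows
            report.n_dropped += 1
            continue
        if not case or not name or not role:
            report.n_dropped += 1
            continue
        records.append(
            DrugRecord(
                case_id=case,
                drug_name=name,
                role_code="primary_suspect" if role in ps else "other",
            )
        )
        report.n_kept += 1
    if report.n_dropped:
        logger.info("parse_drug_table: dropped %d incomplete rows", report.n_dropped)
    return records


def parse_reac_table(
    source: str | Path | IO[str],
    dialect: TableDialect | None = None,
    report: ParseReport | None = None,
) -> list[ReactionRecord]:
    """Parse a REAC table into records; duplicates are retained as given."""
    dialect = dialect or TableDialect()
    report = report if report is not None else ParseReport()
    records: list[ReactionRecord] = []
    stream = _open_text(source)
    rdr = _reader(stream, dialect, [dialect.case_id_col, dialect.reaction_col])
    for row in rdr:
        report.n_rows += 1
        case = (row.get(dialect.case_id_col) or "").strip()
        term = _normalize(row.get(dialect.reaction_col) or "")
        if not case or not term:
            report.n_dropped += 1
            continue
        records.append(ReactionRecord(case_id=case, reaction_term=term))
        report.n_kept += 1
    if report.n_dropped:
        logger.info("parse_reac_table: dropped %d incomplete rows", report.n_dropped)
    return records


def apply_synonyms(
    drugs: Iterable[DrugRecord], synonyms: Mapping[str, str]
) -> list[DrugRecord]:
    """Rename drugs through a user-supplied synonym table (normalized keys)."""
    table = {_normalize(k): _normalize(v) for k, v in synonyms.items()}
    return [
        DrugRecord(d.case_id, table.get(d.drug_name, d.drug_name), d.role_code)
        for d in drugs
    ]


def build_triples(
    drugs: Sequence[DrugRecord], reactions: Sequence[ReactionRecord]
) -> list[tuple[str, str, int]]:
    """Join DRUG and REAC records on case id into report-count triples.

    Only primary-suspect drug records contribute.  Within one case, a
    ``(drug, reaction)`` combination counts once no matter how many duplicate
    rows mention it — FAERS repeats drug rows per dose/lot, and the count is
    meant to be the number of *reports*, not rows.  Output is sorted by
    ``(drug_name, reaction_term)``.
    """
    reac_by_case: dict[str, set[str]] = {}
    for r in reactions:
        reac_by_case.setdefault(r.case_id, set()).add(r.reaction_term)

    seen: set[tuple[str, str, str]] = set()
    counts: Counter[tuple[str, str]] = Counter()
    for d in drugs:
        if not d.is_primary_suspect:
            continue
        for term in reac_by_case.get(d.case_id, ()):
            key = (d.case_id, d.drug_name, term)
            if key in seen:
                continue
            seen.add(key)
            counts[(d.drug_name, term)] += 1
    return sorted((name, term, c) for (name, term), c in counts.items())


def write_triples(
    triples: Sequence[tuple[str, str, int]], path: str | Path
) -> None:
    """Write triples as tab-separated ``drug<TAB>term<TAB>count`` lines."""
    with open(path, "w", encoding="utf-8") as fh:
        for name, term, c in triples:
            fh.write(f"{name}\t{term}\t{c}\n")


def read_triples(path: str | Path) -> list[tuple[str, str, int]]:
    """Read triples written by :func:`write_triples`."""
    out: list[tuple[str, str, int]] = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            name, term, c = line.split("\t")
            out.append((name, term, int(c)))
    return out
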