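"""Readers and writers for spontaneous adverse-event report tables.

Two on-disk dialects are supported:

* the FAERS quarterly ASCII layout — four dollar-delimited tables (DEMO,
  DRUG, REAC, OUTC) with a header line naming the columns and no quoting
  or escaping, as published by the FDA; and
* a single-file ICSR interchange CSV, one row per (report, drug, event)
  with demographics repeated, convenient for spreadsheets and ad-hoc
  inspection.

Both dialects round-trip losslessly through the in-memory
:class:`ReportSet` (for the interchange CSV, losslessly for reports that
carry at least one drug and one reaction, since the row grid is the
cartesian product of the two).

Dates arrive in FAERS as ``yyyymmdd`` and are frequently partial
(``yyyymm00`` or ``yyyy0000``).  Partial dates are truncated to the first
valid day and the retained precision (``"day"``, ``"month"`` or
``"year"``) is kept on the row, so year-level trend analyses remain
possible without pretending to day-level knowledge.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path

logger = logging.getLogger(__name__)

ROLE_CODES = frozenset({"PS", "SS", "C", "I"})
OUTCOME_CODES = frozenset({"DE", "LT", "HO", "DS", "CA", "RI", "OT"})
SEX_CODES = frozenset({"M", "F", "UNK"})
AGE_UNITS = frozenset({"YR", "MON", "DY"})

DEMO_COLUMNS = ["PRIMARYID", "CASEID", "CASEVERSION", "FDA_DT", "AGE",
                "AGE_COD", "SEX", "REPORTER_COUNTRY"]
DRUG_COLUMNS = ["PRIMARYID", "DRUG_SEQ", "ROLE_COD", "DRUGNAME"]
REAC_COLUMNS = ["PRIMARYID", "PT"]
OUTC_COLUMNS = ["PRIMARYID", "OUTC_COD"]

ICSR_COLUMNS = ["primary_id", "case_id", "case_version", "receipt_date",
                "age_years", "sex", "reporter_country", "role_code",
                "drug_name_verbatim", "preferred_term", "outcome_codes"]

DAYS_PER_YEAR = 365.25


class FaersParseError(ValueError):
    """A malformed line or header in a dollar-delimited FAERS table."""


class DialectError(ValueError):
    """Content not representable in the requested on-disk dialect."""


class SchemaError(ValueError):
    """Missing, unexpected or duplicated columns in an interchange file."""


@dataclass(frozen=True)
class DemoRow:
    """One DEMO line: demographics for one submitted report version."""

    primary_id: str
    case_id: str
    case_version: int
    receipt_date: date | None = None
    date_precision: str | None = None  # "day" | "month" | "year" | None
    age_value: float | None = None
    age_unit: str | None = None  # YR | MON | DY
    sex: str = "UNK"
    reporter_country: str | None = None

    @property
    def age_years(self) -> float | None:
        """Age normalised to years (MON/12, DY/365.25)."""
        if self.age_value is None:
            return None
        if self.age_unit == "MON":
            return self.age_value / 12.0
        if self.age_unit == "DY":
            return self.age_value / DAYS_PER_YEAR
        return self.age_value


@dataclass(frozen=True)
class DrugRow:
    primary_id: str
    drug_seq: int
    role_code: str  # PS | SS | C | I
    drug_name_verbatim: str


@dataclass(frozen=True)
class ReacRow:
    primary_id: str
    preferred_term: str


@dataclass(frozen=True)
class OutcRow:
    primary_id: str
    outcome_code: str  # DE | LT | HO | DS | CA | RI | OT


@dataclass
class ReportSet:
    """All rows of the four report tables for one loaded extract."""

    demo: list[DemoRow] = field(default_factory=list)
    drugs: list[DrugRow] = field(default_factory=list)
    reactions: list[ReacRow] = field(default_factory=list)
    outcomes: list[OutcRow] = field(default_factory=list)
    #: per-table counts of lines skipped in lenient mode
    skipped: dict[str, int] = field(default_factory=dict)

    def primary_ids(self) -> set[str]:
        return {r.primary_id for r in self.demo}

    def orphan_ids(self) -> set[str]:
        """primary_ids referenced by drug/reac/outc rows but absent from demo."""
        known = self.primary_ids()
        orphans: set[str] = set()
        for rows in (self.drugs, self.reactions, self.outcomes):
            orphans.update(r.primary_id for r in rows if r.primary_id not in known)
        return orphans

    def validate(self, mode: str = "strict") -> None:
        """Check ReportSet invariants (unique primary_ids, no orphans in strict)."""
        seen: set[str] = set()
        for r in self.demo:
            if r.primary_id in seen:
                raise ValueError(f"duplicate primary_id in DEMO: {r.primary_id}")
            seen.add(r.primary_id)
        orphans = self.orphan_ids()
        if orphans:
            if mode == "strict":
                raise ValueError(
                    f"{len(orphans)} primary_id(s) missing from DEMO, e.g. "
                    f"{sorted(orphans)[:3]}")
            logger.warning("%d orphan primary_id(s) without a DEMO row", len(orphans))


def parse_fda_date(text: str) -> tuple[date | None, str | None]:
    """Parse a ``yyyymmdd`` date, truncating partial dates.

    Returns ``(date, precision)`` where precision is ``"day"``,
    ``"month"`` (day given as 00) or ``"year"`` (month and day 00);
    blank input yields ``(None, None)``.  Raises ValueError for anything
    else — callers decide whether that is fatal.
    """
    text = text.strip()
    if not text:
        return None, None
    if len(text) != 8 or not text.isdigit():
        raise ValueError(f"not a yyyymmdd date: {text!r}")
    y, m, d = int(text[:4]), int(text[4:6]), int(text[6:8])
    if m == 0 and d == 0:
        return date(y, 1, 1), "year"
    if d == 0:
        return date(y, m, 1), "month"
    return date(y, m, d), "day"


def format_fda_date(d: date | None, precision: str | None) -> str:
    if d is None:
        return ""
    if precision == "year":
        return f"{d.year:04d}0000"
    if precision == "month":
        return f"{d.year:04d}{d.month:02d}00"
    return f"{d.year:04d}{d.month:02d}{d.day:02d}"


def _parse_iso_partial(text: str) -> tuple[date | None, str | None]:
    """Parse ISO dates allowing the partial forms yyyy and yyyy-mm."""
    text = text.strip()
    if not text:
        return None, None
    parts = text.split("-")
    if len(parts) == 1:
        return date(int(parts[0]), 1, 1), "year"
    if len(parts) == 2:
        return date(int(parts[0]), int(parts[1]), 1), "month"
    return date.fromisoformat(text), "day"


def _format_iso_partial(d: date | None, precision: str | None) -> str:
    if d is None:
        return ""
    if precision == "year":
        return f"{d.year:04d}"
    if precision == "month":
        return f"{d.year:04d}-{d.month:02d}"
    return d.isoformat()


# ---------------------------------------------------------------------------
# FAERS quarterly ASCII dialect
# ---------------------------------------------------------------------------

def _read_table(path: str | Path, columns: list[str], mode: str,
                skipped: dict[str, int], table: str):
    """Yield field lists for each data line of one dollar-delimited table."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").rstrip("\r")
        if header.split("$") != columns:
            raise FaersParseError(
                f"{path.name}: header {header!r} does not match expected "
                f"columns {'$'.join(columns)}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("$")
            if len(fields) != len(columns):
                msg = (f"{path.name}, line {lineno}: expected "
                       f"{len(columns)} dollar-delimited fields, got {len(fields)}")
                if mode == "strict":
                    raise FaersParseError(msg)
                logger.warning("skipping malformed line: %s", msg)
                skipped[table] = skipped.get(table, 0) + 1
                continue
            yield lineno, path.name, fields


def _lenient_skip(mode, skipped, table, msg):
    if mode == "strict":
        raise ValueError(msg)
    logger.warning("skipping row: %s", msg)
    skipped[table] = skipped.get(table, 0) + 1


def read_faers_ascii(demo_path, drug_path, reac_path, outc_path,
                     mode: str = "strict") -> ReportSet:
    """Load the four FAERS quarterly ASCII tables into a :class:`ReportSet`.

    In ``strict`` mode any malformed line, unknown code or undated DEMO
    row raises; in ``lenient`` mode offending rows are logged, skipped
    and counted in ``ReportSet.skipped``.
    """
    if mode not in {"strict", "lenient"}:
        raise ValueError(f"mode must be 'strict' or 'lenient', got {mode!r}")
    rs = ReportSet()

    for lineno, fname, f in _read_table(demo_path, DEMO_COLUMNS, mode,
                                        rs.skipped, "demo"):
        where = f"{fname}, line {lineno}"
        try:
            receipt, precision = parse_fda_date(f[3])
        except ValueError as exc:
            if mode == "strict":
                raise FaersParseError(f"{where}: {exc}") from exc
            logger.warning("%s: %s — receipt date flagged missing", where, exc)
            receipt, precision = None, None
        age_txt, unit = f[4].strip(), f[5].strip().upper() or None
        age = None
        if age_txt:
            try:
                age = float(age_txt)
                if age < 0:
                    raise ValueError("negative age")
            except ValueError:
                _lenient_skip(mode, rs.skipped, "demo",
                              f"{where}: bad AGE {age_txt!r}")
                continue
        if unit is not None and unit not in AGE_UNITS:
            _lenient_skip(mode, rs.skipped, "demo", f"{where}: bad AGE_COD {unit!r}")
            continue
        sex = f[6].strip().upper() or "UNK"
        if sex not in SEX_CODES:
            _lenient_skip(mode, rs.skipped, "demo", f"{where}: bad SEX {sex!r}")
            continue
        try:
            version = int(f[2])
            if version < 0:
                raise ValueError
        except ValueError:
            _lenient_skip(mode, rs.skipped, "demo",
                          f"{where}: bad CASEVERSION {f[2]!r}")
            continue
        rs.demo.append(DemoRow(
            primary_id=f[0].strip(), case_id=f[1].strip(), case_version=version,
            receipt_date=receipt, date_precision=precision,
            age_value=age, age_unit=unit if age is not None else None,
            sex=sex, reporter_country=f[7].strip() or None))

    for lineno, fname, f in _read_table(drug_path, DRUG_COLUMNS, mode,
                                        rs.skipped, "drug"):
        where = f"{fname}, line {lineno}"
        role = f[2].strip().upper()
        if role not in ROLE_CODES:
            _lenient_skip(mode, rs.skipped, "drug", f"{where}: bad ROLE_COD {role!r}")
            continue
        try:
            seq = int(f[1])
            if seq <= 0:
                raise ValueError
        except ValueError:
            _lenient_skip(mode, rs.skipped, "drug", f"{where}: bad DRUG_SEQ {f[1]!r}")
            continue
        rs.drugs.append(DrugRow(primary_id=f[0].strip(), drug_seq=seq,
                                role_code=role, drug_name_verbatim=f[3].strip()))

    for lineno, fname, f in _read_table(reac_path, REAC_COLUMNS, mode,
                                        rs.skipped, "reac"):
        pt = f[1].strip()
        if not pt:
            _lenient_skip(mode, rs.skipped, "reac",
                          f"{fname}, line {lineno}: empty PT")
            continue
        rs.reactions.append(ReacRow(primary_id=f[0].strip(), preferred_term=pt))

    for lineno, fname, f in _read_table(outc_path, OUTC_COLUMNS, mode,
                                        rs.skipped, "outc"):
        code = f[1].strip().upper()
        if code not in OUTCOME_CODES:
            _lenient_skip(mode, rs.skipped, "outc",
                          f"{fname}, line {lineno}: bad OUTC_COD {code!r}")
            continue
        rs.outcomes.append(OutcRow(primary_id=f[0].strip(), outcome_code=code))

    rs.validate(mode)
    return rs


def _check_dollar_free(*values: str) -> None:
    for v in values:
        if "$" in v:
            raise DialectError(
                f"value {v!r} contains the dollar field delimiter and cannot "
                "be represented in the FAERS ASCII dialect")


def write_faers_ascii(report_set: ReportSet, out_dir: str | Path) -> dict[str, Path]:
    """Write the four dollar-delimited tables; deterministic row order.

    Rows are sorted by primary_id then sequence so two calls on equal
    inputs produce byte-identical files.  A literal dollar sign anywhere
    in the content is a :class:`DialectError` (the dialect has no
    escaping).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {name: out_dir / f"{name.upper()}.txt"
             for name in ("demo", "drug", "reac", "outc")}

    with open(paths["demo"], "w", encoding="utf-8", newline="\n") as fh:
        fh.write("$".join(DEMO_COLUMNS) + "\n")
        for r in sorted(report_set.demo, key=lambda r: r.primary_id):
            age = "" if r.age_value is None else f"{r.age_value:g}"
            unit = r.age_unit or ""
            country = r.reporter_country or ""
            _check_dollar_free(r.primary_id, r.case_id, country)
            fh.write("$".join([
                r.primary_id, r.case_id, str(r.case_version),
                format_fda_date(r.receipt_date, r.date_precision),
                age, unit, r.sex, country]) + "\n")

    with open(paths["drug"], "w", encoding="utf-8", newline="\n") as fh:
        fh.write("$".join(DRUG_COLUMNS) + "\n")
        for r in sorted(report_set.drugs, key=lambda r: (r.primary_id, r.drug_seq)):
            _check_dollar_free(r.primary_id, r.drug_name_verbatim)
            fh.write("$".join([r.primary_id, str(r.drug_seq), r.role_code,
                               r.drug_name_verbatim]) + "\n")

    with open(paths["reac"], "w", encoding="utf-8", newline="\n") as fh:
        fh.write("$".join(REAC_COLUMNS) + "\n")
        for r in sorted(report_set.reactions,
                        key=lambda r: (r.primary_id, r.preferred_term)):
            _check_dollar_free(r.primary_id, r.preferred_term)
            fh.write("$".join([r.primary_id, r.preferred_term]) + "\n")

    with open(paths["outc"], "w", encoding="utf-8", newline="\n") as fh:
        fh.write("$".join(OUTC_COLUMNS) + "\n")
        for r in sorted(report_set.outcomes,
                        key=lambda r: (r.primary_id, r.outcome_code)):
            _check_dollar_free(r.primary_id)
            fh.write("$".join([r.primary_id, r.outcome_code]) + "\n")

    return paths


# ---------------------------------------------------------------------------
# single-file ICSR interchange CSV
# ---------------------------------------------------------------------------

def write_icsr_csv(report_set: ReportSet, path: str | Path) -> Path:
    """Write the one-file interchange CSV: one row per (report, drug, event).

    Demographics and the semicolon-joined outcome codes are repeated on
    every row of a report.  Reports with no drug row or no reaction row
    cannot be represented on the cartesian row grid and raise
    :class:`DialectError`.
    """
    path = Path(path)
    drugs_by_id: dict[str, list[DrugRow]] = {}
    for r in sorted(report_set.drugs, key=lambda r: (r.primary_id, r.drug_seq)):
        drugs_by_id.setdefault(r.primary_id, []).append(r)
    reac_by_id: dict[str, list[str]] = {}
    for r in sorted(report_set.reactions,
                    key=lambda r: (r.primary_id, r.preferred_term)):
        terms = reac_by_id.setdefault(r.primary_id, [])
        if r.preferred_term not in terms:
            terms.append(r.preferred_term)
    outc_by_id: dict[str, list[str]] = {}
    for r in sorted(report_set.outcomes,
                    key=lambda r: (r.primary_id, r.outcome_code)):
        codes = outc_by_id.setdefault(r.primary_id, [])
        if r.outcome_code not in codes:
            codes.append(r.outcome_code)

    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(ICSR_COLUMNS)
        for demo in sorted(report_set.demo, key=lambda r: r.primary_id):
            pid = demo.primary_id
            if pid not in drugs_by_id or pid not in reac_by_id:
                raise DialectError(
                    f"report {pid} has no drug or no reaction row; it cannot "
                    "be represented in the interchange CSV")
            age = demo.age_years
            outc = ";".join(outc_by_id.get(pid, []))
            for drug in drugs_by_id[pid]:
                for term in reac_by_id[pid]:
                    writer.writerow([
                        pid, demo.case_id, demo.case_version,
                        _format_iso_partial(demo.receipt_date, demo.date_precision),
                        "" if age is None else f"{age:g}",
                        demo.sex, demo.reporter_country or "",
                        drug.role_code, drug.drug_name_verbatim, term, outc])
    return path


def read_icsr_csv(path: str | Path) -> ReportSet:
    """Read the interchange CSV back into a :class:`ReportSet`.

    Drug sequence numbers are regenerated in order of first appearance
    within each report; ages are interpreted as years.
    """
    path = Path(path)
    rs = ReportSet()
    demo_seen: dict[str, DemoRow] = {}
    drug_seen: dict[str, dict[tuple[str, str], int]] = {}
    reac_seen: dict[str, list[str]] = {}
    outc_seen: dict[str, list[str]] = {}

    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise SchemaError(f"{path.name}: empty file") from None
        missing = [c for c in ICSR_COLUMNS if c not in header]
        if missing:
            raise SchemaError(f"{path.name}: missing mandatory column(s) "
                              f"{', '.join(missing)}")
        if header != ICSR_COLUMNS:
            raise SchemaError(f"{path.name}: unexpected column layout {header}")
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not v for v in row):
                continue
            if row == ICSR_COLUMNS:
                raise SchemaError(f"{path.name}, line {lineno}: duplicated "
                                  "header row")
            if len(row) != len(ICSR_COLUMNS):
                raise SchemaError(f"{path.name}, line {lineno}: expected "
                                  f"{len(ICSR_COLUMNS)} columns, got {len(row)}")
            rec = dict(zip(ICSR_COLUMNS, row))
            pid = rec["primary_id"]
            if pid not in demo_seen:
                receipt, precision = _parse_iso_partial(rec["receipt_date"])
                age = float(rec["age_years"]) if rec["age_years"] else None
                sex = rec["sex"].strip().upper() or "UNK"
                if sex not in SEX_CODES:
                    raise SchemaError(f"{path.name}, line {lineno}: bad sex {sex!r}")
                demo_seen[pid] = DemoRow(
                    primary_id=pid, case_id=rec["case_id"],
                    case_version=int(rec["case_version"]),
                    receipt_date=receipt, date_precision=precision,
                    age_value=age, age_unit="YR" if age is not None else None,
                    sex=sex, reporter_country=rec["reporter_country"] or None)
                drug_seen[pid] = {}
                reac_seen[pid] = []
                outc_seen[pid] = [c for c in rec["outcome_codes"].split(";") if c]
                for code in outc_seen[pid]:
                    if code not in OUTCOME_CODES:
                        raise SchemaError(f"{path.name}, line {lineno}: bad "
                                          f"outcome code {code!r}")
            role = rec["role_code"].strip().upper()
            if role not in ROLE_CODES:
                raise SchemaError(f"{path.name}, line {lineno}: bad role {role!r}")
            key = (role, rec["drug_name_verbatim"])
            if key not in drug_seen[pid]:
                drug_seen[pid][key] = len(drug_seen[pid]) + 1
            term = rec["preferred_term"].strip()
            if not term:
                raise SchemaError(f"{path.name}, line {lineno}: empty "
                                  "preferred_term")
            if term not in reac_seen[pid]:
                reac_seen[pid].append(term)

    for pid, demo in demo_seen.items():
        rs.demo.append(demo)
        for (role, name), seq in drug_seen[pid].items():
            rs.drugs.append(DrugRow(primary_id=pid, drug_seq=seq,
                                    role_code=role, drug_name_verbatim=name))
        for term in reac_seen[pid]:
            rs.reactions.append(ReacRow(primary_id=pid, preferred_term=term))
        for code in outc_seen[pid]:
            rs.outcomes.append(OutcRow(primary_id=pid, outcome_code=code))
    rs.validate("strict")
    return rs


def sorted_report_set(rs: ReportSet) -> ReportSet:
    """Canonical ordering of all four tables (for equality comparisons)."""
    return ReportSet(
        demo=sorted(rs.demo, key=lambda r: r.primary_id),
        drugs=sorted(rs.drugs, key=lambda r: (r.primary_id, r.drug_seq)),
        reactions=sorted(rs.reactions, key=lambda r: (r.primary_id, r.preferred_term)),
        outcomes=sorted(rs.outcomes, key=lambda r: (r.primary_id, r.outcome_code)),
    )
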