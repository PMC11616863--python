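"""Data model and I/O for FAERS-style quarterly safety-report tables.

The FDA Adverse Event Reporting System (FAERS) publishes quarterly snapshots
as ``$``-delimited ASCII files, one per table: patient demographics and
administration (DEMO), drugs (DRUG), coded adverse events (REAC), outcomes
(OUTC), therapy dates (THER) and indications (INDI).  Records across tables
are linked by PRIMARYID; the same case (CASEID) recurs across quarters as
follow-up versions, so analyses must first deduplicate.

This module reads those files, deduplicates by the standard rule (keep the
most recent FDA_DT per CASEID, ties broken by the higher PRIMARYID),
assembles per-case report objects, normalizes ages to years, applies a
user-supplied MedDRA preferred-term (PT) to system-organ-class (SOC) map,
and splits a deduplicated quarter into a target-drug cohort and its
background.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from datetime import date
from typing import Iterable, Mapping, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: canonical column sets per table; extra columns are preserved, these are expected
TABLE_COLUMNS: dict[str, tuple[str, ...]] = {
    "demo": ("PRIMARYID", "CASEID", "FDA_DT", "EVENT_DT", "AGE", "AGE_COD",
             "SEX", "OCCP_COD", "REPORTER_COUNTRY"),
    "drug": ("PRIMARYID", "DRUG_SEQ", "ROLE_COD", "DRUGNAME", "PROD_AI"),
    "reac": ("PRIMARYID", "PT"),
    "outc": ("PRIMARYID", "OUTC_COD"),
    "ther": ("PRIMARYID", "DSG_DRUG_SEQ", "START_DT", "END_DT"),
    "indi": ("PRIMARYID", "INDI_PT"),
}

#: columns whose absence is a hard error
MANDATORY_COLUMNS: dict[str, tuple[str, ...]] = {
    "demo": ("PRIMARYID", "CASEID"),
    "drug": ("PRIMARYID",),
    "reac": ("PRIMARYID",),
    "outc": ("PRIMARYID",),
    "ther": ("PRIMARYID",),
    "indi": ("PRIMARYID",),
}

OUTCOME_CODES = frozenset({"DE", "LT", "HO", "DS", "CA", "RI", "OT"})


class DataError(RuntimeError):
    """Raised for malformed or inconsistent input data."""


class MissingColumnError(DataError):
    """A mandatory column is absent from an input file."""


@dataclass
class RawTables:
    """The six FAERS-style tables of one (or several merged) quarter(s).

    All cells are kept as strings; empty string means missing.  ``skipped``
    counts unparseable data lines per table (wrong field count), which are
    logged and dropped rather than treated as fatal.
    """

    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    outc: pd.DataFrame
    ther: pd.DataFrame
    indi: pd.DataFrame
    skipped: dict[str, int] = field(default_factory=dict)

    def table(self, name: str) -> pd.DataFrame:
        return getattr(self, name)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(TABLE_COLUMNS)


class DrugEntry(NamedTuple):
    drugname: str
    prod_ai: str
    role_cod: str
    drug_seq: str


@dataclass
class CaseReport:
    """One deduplicated safety report with its linked records."""

    primaryid: str
    caseid: str
    fda_dt: str
    event_dt: str
    age_years: float            # NaN when missing
    sex: str                    # "F", "M" or ""
    occupation: str             # OCCP_COD or ""
    country: str
    outcomes: frozenset[str]
    events: frozenset[str]      # MedDRA PTs
    drugs: list[DrugEntry]
    therapy_starts: list[tuple[str, str]]   # (drug_seq, start_dt raw string)
    indications: frozenset[str]
    report_year: Optional[int]


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

def _read_dollar_table(path, name: str) -> tuple[pd.DataFrame, int]:
    mandatory = MANDATORY_COLUMNS.get(name, ("PRIMARYID",))
    with open(path, "r", encoding="utf-8", errors="replace") as fh:
        header = fh.readline().rstrip("\r\n")
        cols = [c.strip().upper() for c in header.split("$")]
        for col in mandatory:
            if col not in cols:
                raise MissingColumnError(
                    f"{path}: mandatory column {col!r} missing from {name.upper()} header"
                )
        rows: list[list[str]] = []
        skipped = 0
        for line in fh:
            line = line.rstrip("\r\n")
            if not line:
                continue
            parts = line.split("$")
            if len(parts) != len(cols):
                skipped += 1
                continue
            rows.append(parts)
    if skipped:
        logger.warning("%s: skipped %d malformed line(s)", path, skipped)
    df = pd.DataFrame(rows, columns=cols, dtype=str) if rows else \
        pd.DataFrame({c: pd.Series(dtype=str) for c in cols})
    return df, skipped


def read_quarter(paths: Mapping[str, "str | bytes | object"]) -> RawTables:
    """Read one quarter's tables from ``$``-delimited files.

    Parameters
    ----------
    paths
        Mapping with keys ``demo, drug, reac, outc, ther, indi`` to file
        paths.  Column names are matched case-insensitively; data lines with
        the wrong field count are skipped and counted, missing mandatory
        columns raise :class:`MissingColumnError`.
    """
    frames: dict[str, pd.DataFrame] = {}
    skipped: dict[str, int] = {}
    for name in TABLE_COLUMNS:
        if name not in paths:
            raise DataError(f"no path given for table {name.upper()}")
        frames[name], skipped[name] = _read_dollar_table(paths[name], name)
    return RawTables(**frames, skipped=skipped)


# ---------------------------------------------------------------------------
# deduplication
# ---------------------------------------------------------------------------

def _comparable(series: pd.Series) -> pd.Series:
    """Sort key: numeric when every value parses as a number, else the string."""
    as_num = pd.to_numeric(series, errors="coerce")
    if not as_num.isna().any():
        return as_num
    return series.astype(str)


def deduplicate(demo: pd.DataFrame) -> pd.DataFrame:
    """Keep one DEMO record per CASEID.

    The kept record has maximal (FDA_DT, PRIMARYID): the most recent FDA
    receipt date wins, and among equal dates the higher PRIMARYID (the later
    version) wins.  Idempotent; empty input passes through.
    """
    if demo.empty:
        return demo.copy()
    work = demo.assign(
        _fda=_comparable(demo["FDA_DT"]),
        _pid=_comparable(demo["PRIMARYID"]),
    )
    work = work.sort_values(["_fda", "_pid"], kind="mergesort")
    work = work.drop_duplicates("CASEID", keep="last")
    out = work.drop(columns=["_fda", "_pid"]).reset_index(drop=True)
    return out


def deduplicate_tables(tables: RawTables) -> RawTables:
    """Deduplicate DEMO and restrict every other table to surviving PRIMARYIDs."""
    demo = deduplicate(tables.demo)
    keep = set(demo["PRIMARYID"])
    out = {"demo": demo}
    for name in ("drug", "reac", "outc", "ther", "indi"):
        df = tables.table(name)
        out[name] = df[df["PRIMARYID"].isin(keep)].reset_index(drop=True)
    return RawTables(**out, skipped=dict(tables.skipped))


# ---------------------------------------------------------------------------
# age normalization
# ---------------------------------------------------------------------------

_AGE_FACTORS = {
    "DEC": 10.0,
    "YR": 1.0,
    "MON": 1.0 / 12.0,
    "WK": 1.0 / 52.18,
    "DY": 1.0 / 365.25,
    "HR": 1.0 / 8766.0,
}


def normalize_age(age, age_cod: str = "") -> float:
    """Convert a FAERS (AGE, AGE_COD) pair to years.

    Unit codes: DEC decades, YR years, MON months, WK weeks, DY days, HR
    hours.  A present age with a missing/unknown code is assumed to be in
    years (logged).  Negative or unparseable ages map to NaN.
    """
    try:
        value = float(age)
    except (TypeError, ValueError):
        return float("nan")
    if np.isnan(value):
        return float("nan")
    if value < 0:
        logger.warning("negative age %r discarded", age)
        return float("nan")
    code = (age_cod or "").strip().upper()
    if code not in _AGE_FACTORS:
        if code:
            logger.warning("unknown AGE_COD %r, assuming years", age_cod)
        else:
            logger.debug("missing AGE_COD with age present, assuming years")
        code = "YR"
    return value * _AGE_FACTORS[code]


# ---------------------------------------------------------------------------
# dates
# ---------------------------------------------------------------------------

def date_precision(raw: str) -> str:
    """Classify a FAERS date string: 'day', 'month', 'year' or 'missing'.

    FAERS dates are digit strings YYYYMMDD; partial dates are truncated
    (YYYYMM or YYYY)."""
    s = (raw or "").strip()
    if not s.isdigit():
        return "missing"
    if len(s) == 8:
        return "day"
    if len(s) == 6:
        return "month"
    if len(s) == 4:
        return "year"
    return "missing"


def parse_date(raw: str) -> Optional[date]:
    """Parse a full-precision YYYYMMDD string; partial/missing dates give None."""
    if date_precision(raw) != "day":
        return None
    s = raw.strip()
    try:
        return date(int(s[:4]), int(s[4:6]), int(s[6:8]))
    except ValueError:
        return None


# ---------------------------------------------------------------------------
# MedDRA PT -> SOC map
# ---------------------------------------------------------------------------

UNMAPPED = None  #: sentinel returned for PTs absent from the map


@dataclass
class MedDRAMap:
    """Case-insensitive preferred-term to primary system-organ-class lookup.

    MedDRA itself is licensed, so the dictionary content is always supplied
    by the user (2-column TSV ``pt<TAB>soc``).  Unmapped PTs are recorded in
    an audit list, never silently dropped.
    """

    pt_to_soc: dict[str, str]
    unmapped: list[str] = field(default_factory=list)

    @staticmethod
    def _key(pt: str) -> str:
        return " ".join(pt.strip().split()).lower()

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "MedDRAMap":
        return cls({cls._key(pt): soc.strip() for pt, soc in pairs})

    @classmethod
    def from_tsv(cls, path) -> "MedDRAMap":
        pairs = []
        with open(path, "r", encoding="utf-8") as fh:
            for i, line in enumerate(fh):
                line = line.rstrip("\r\n")
                if not line:
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    raise DataError(f"{path}:{i + 1}: expected 2 tab-separated columns")
                if i == 0 and parts[0].strip().lower() == "pt" \
                        and parts[1].strip().lower() == "soc":
                    continue  # optional header
                pairs.append((parts[0], parts[1]))
        return cls.from_pairs(pairs)

    def lookup(self, pt: str) -> Optional[str]:
        soc = self.pt_to_soc.get(self._key(pt), UNMAPPED)
        if soc is UNMAPPED:
            self.unmapped.append(pt)
        return soc


def map_pt_to_soc(pt: str, mapping: MedDRAMap) -> Optional[str]:
    """Map one PT to its primary SOC; returns None (and audits) when unmapped."""
    return mapping.lookup(pt)


# ---------------------------------------------------------------------------
# case assembly and cohort construction
# ---------------------------------------------------------------------------

def _rows_by_pid(df: pd.DataFrame, cols: Sequence[str]) -> dict[str, list[tuple]]:
    out: dict[str, list[tuple]] = defaultdict(list)
    if df.empty:
        return out
    for row in df[list(("PRIMARYID",) + tuple(cols))].itertuples(index=False):
        out[row[0]].append(row[1:])
    return out


def _get(df: pd.DataFrame, col: str) -> pd.Series:
    if col in df.columns:
        return df[col].fillna("")
    return pd.Series([""] * len(df), index=df.index)


def assemble_cases(tables: RawTables) -> list[CaseReport]:
    """Join the six tables into per-report objects, one per DEMO record.

    Non-DEMO records whose PRIMARYID has no DEMO row are dropped (they belong
    to deduplicated-away versions)."""
    demo = tables.demo
    drugs = _rows_by_pid(tables.drug, ("DRUGNAME", "PROD_AI", "ROLE_COD", "DRUG_SEQ"))
    reacs = _rows_by_pid(tables.reac, ("PT",))
    outcs = _rows_by_pid(tables.outc, ("OUTC_COD",))
    thers = _rows_by_pid(tables.ther, ("DSG_DRUG_SEQ", "START_DT"))
    indis = _rows_by_pid(tables.indi, ("INDI_PT",))

    cases: list[CaseReport] = []
    frame = pd.DataFrame({
        "pid": _get(demo, "PRIMARYID"), "caseid": _get(demo, "CASEID"),
        "fda": _get(demo, "FDA_DT"), "evt": _get(demo, "EVENT_DT"),
        "age": _get(demo, "AGE"), "cod": _get(demo, "AGE_COD"),
        "sex": _get(demo, "SEX"), "occ": _get(demo, "OCCP_COD"),
        "cty": _get(demo, "REPORTER_COUNTRY"),
    })
    for r in frame.itertuples(index=False):
        pid = r.pid
        year = int(r.fda[:4]) if date_precision(r.fda) != "missing" else None
        cases.append(CaseReport(
            primaryid=pid,
            caseid=r.caseid,
            fda_dt=r.fda,
            event_dt=r.evt,
            age_years=normalize_age(r.age, r.cod) if r.age else float("nan"),
            sex=r.sex.strip().upper(),
            occupation=r.occ.strip().upper(),
            country=r.cty.strip().upper(),
            outcomes=frozenset(o[0].strip().upper() for o in outcs.get(pid, ())
                               if o[0].strip()),
            events=frozenset(e[0].strip() for e in reacs.get(pid, ()) if e[0].strip()),
            drugs=[DrugEntry(d[0], d[1], d[2].strip().upper(), d[3])
                   for d in drugs.get(pid, ())],
            therapy_starts=[(t[0], t[1]) for t in thers.get(pid, ())],
            indications=frozenset(i[0].strip() for i in indis.get(pid, ())
                                  if i[0].strip()),
            report_year=year,
        ))
    return cases


def drug_matches(entry: DrugEntry, synonyms: Sequence[str], mode: str = "substring") -> bool:
    """True when a DRUG record names any synonym (over DRUGNAME and PROD_AI).

    ``mode='substring'`` is a case-insensitive containment test (FAERS drug
    names carry dose/form suffixes); ``mode='exact'`` requires equality after
    trimming."""
    fields = (entry.drugname or "", entry.prod_ai or "")
    for syn in synonyms:
        s = syn.strip().lower()
        if not s:
            continue
        for f in fields:
            fl = f.strip().lower()
            if (mode == "exact" and fl == s) or (mode != "exact" and s in fl):
                return True
    return False


def build_cohort(
    tables: RawTables,
    synonyms: Sequence[str],
    role: str = "PS",
    reporter_filter: Optional[set[str]] = None,
    date_range: Optional[tuple[int, int]] = None,
    match: str = "substring",
) -> tuple[list[CaseReport], list[CaseReport]]:
    """Split a deduplicated quarter into target-drug cases and background.

    A case is a target when at least one DRUG record has the requested
    ROLE_COD (default PS, primary suspect) and names one of the synonyms.
    ``reporter_filter`` (a set of OCCP_COD values) and ``date_range``
    (inclusive YYYYMMDD bounds on FDA_DT) are applied to both sets, so target
    and background always partition the filtered reports.
    """
    if not synonyms:
        raise ValueError("synonyms must be non-empty")
    cases = assemble_cases(tables)
    if date_range is not None:
        lo, hi = date_range
        cases = [c for c in cases
                 if c.fda_dt.strip().isdigit()
                 and lo <= int(c.fda_dt.strip()[:8].ljust(8, "0")) <= hi]
    if reporter_filter is not None:
        wanted = {o.strip().upper() for o in reporter_filter}
        cases = [c for c in cases if c.occupation in wanted]
    role = role.strip().upper()
    target, background = [], []
    for c in cases:
        hit = any(d.role_cod == role and drug_matches(d, synonyms, match)
                  for d in c.drugs)
        (target if hit else background).append(c)
    if not target:
        logger.warning("build_cohort: no reports matched the target drug; "
                       "downstream signal tables will be empty")
    return target, background
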