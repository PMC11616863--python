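"""Descriptive summaries of a report cohort: demographics, outcomes, years.

Outcome codes follow FAERS: DE death, LT life-threatening, HO
hospitalization, DS disability, CA congenital anomaly, RI required
intervention, OT other.  A report may carry several outcomes; for tabulation
the most severe one is selected as the report's final endpoint, using a
configurable severity order (default DE > LT > DS > RI > HO > CA > OT —
only "death first" is canonical, the rest is a documented convention).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .faers import CaseReport

DEFAULT_OUTCOME_ORDER = ("DE", "LT", "DS", "RI", "HO", "CA", "OT")

#: age bins in years: [0,18), [18,60), [60,85], (85,inf); label "NA" for missing
AGE_BIN_LABELS = ("<18", "18-59.9", "60-85", ">85", "NA")

NA = "NA"


def percent(n: float, total: float, decimals: int = 1) -> float:
    """Percentage of ``total``, rounded; the package-wide rendering rule."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round(100.0 * n / total, decimals)


@dataclass
class OutcomeHierarchy:
    """Severity order over outcome codes, most severe first.

    Codes absent from the order (unknown codes) rank after every listed one,
    alphabetically."""

    order: tuple[str, ...] = DEFAULT_OUTCOME_ORDER

    def __post_init__(self) -> None:
        if len(set(self.order)) != len(self.order):
            raise ValueError("outcome hierarchy contains duplicates")

    def rank(self, code: str) -> tuple[int, str]:
        try:
            return (self.order.index(code), code)
        except ValueError:
            return (len(self.order), code)


def most_severe_outcome(outcomes: Iterable[str],
                        hierarchy: Optional[OutcomeHierarchy] = None) -> Optional[str]:
    """Collapse a report's outcome set to its single worst code (None if empty)."""
    hierarchy = hierarchy or OutcomeHierarchy()
    codes = [c for c in outcomes if c]
    if not codes:
        return None
    return min(codes, key=hierarchy.rank)


def age_bin(age_years: float) -> str:
    """Assign an age in years to the reporting bins; 85.0 belongs to 60-85."""
    if age_years is None or math.isnan(age_years):
        return NA
    if age_years < 18:
        return "<18"
    if age_years < 60:
        return "18-59.9"
    if age_years <= 85:
        return "60-85"
    return ">85"


@dataclass
class DescriptiveSummary:
    """Counts and percentages per block; every block sums to the cohort size
    (missing values appear as an explicit NA row)."""

    total: int
    sex: dict[str, tuple[int, float]] = field(default_factory=dict)
    age: dict[str, tuple[int, float]] = field(default_factory=dict)
    occupation: dict[str, tuple[int, float]] = field(default_factory=dict)
    countries: dict[str, tuple[int, float]] = field(default_factory=dict)
    outcomes: dict[str, tuple[int, float]] = field(default_factory=dict)
    years: dict[int, int] = field(default_factory=dict)

    def blocks(self) -> dict[str, dict]:
        return {"SEX": self.sex, "AGE": self.age, "REPORTING_OFFICER": self.occupation,
                "REPORTING_COUNTRY": self.countries, "OUTCOMES": self.outcomes}


_KNOWN_OCCUPATIONS = ("MD", "OT", "PH", "CN")


def summarize(cases: Sequence[CaseReport],
              hierarchy: Optional[OutcomeHierarchy] = None,
              country_top_k: int = 8) -> DescriptiveSummary:
    """Tabulate sex, age bins, reporter occupation, top countries, final
    outcomes and yearly report counts for a cohort.

    Occupation codes outside MD/OT/PH/CN are pooled as "other groups";
    missing values form an NA row in each block.  Percentages are over the
    cohort size at one decimal.  Countries beyond the top k are pooled so
    the block still sums to the total.
    """
    hierarchy = hierarchy or OutcomeHierarchy()
    total = len(cases)
    out = DescriptiveSummary(total=total)
    if total == 0:
        return out

    def pct_block(counter: Counter, keys: Iterable) -> dict:
        return {k: (counter[k], percent(counter[k], total)) for k in keys}

    sex = Counter("F" if c.sex == "F" else "M" if c.sex == "M" else NA for c in cases)
    out.sex = pct_block(sex, [k for k in ("F", "M", NA) if sex[k]])

    ages = Counter(age_bin(c.age_years) for c in cases)
    out.age = pct_block(ages, [k for k in AGE_BIN_LABELS if ages[k]])

    occ = Counter()
    for c in cases:
        code = c.occupation
        if not code:
            occ[NA] += 1
        elif code in _KNOWN_OCCUPATIONS:
            occ[code] += 1
        else:
            occ["other groups"] += 1
    out.occupation = pct_block(occ, list(_KNOWN_OCCUPATIONS) + ["other groups", NA])
    out.occupation = {k: v for k, v in out.occupation.items() if v[0]}

    countries = Counter(c.country or NA for c in cases)
    top = [k for k, _ in countries.most_common(country_top_k)]
    rest = total - sum(countries[k] for k in top)
    out.countries = pct_block(countries, top)
    if rest:
        out.countries["other"] = (rest, percent(rest, total))

    final = Counter(most_severe_outcome(c.outcomes, hierarchy) or NA for c in cases)
    order = [c for c in hierarchy.order if final[c]]
    extra = sorted(k for k in final if k not in hierarchy.order and k != NA)
    out.outcomes = pct_block(final, order + extra + ([NA] if final[NA] else []))

    years = Counter(c.report_year for c in cases if c.report_year is not None)
    out.years = dict(sorted(years.items()))
    return out
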