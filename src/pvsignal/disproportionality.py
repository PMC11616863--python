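"""Disproportionality statistics for spontaneous-report signal detection.

Each (drug, event) pair defines a four-fold table over the deduplicated
database::

                      target event    other events
    target drug            a               b
    other drugs            c               d

The reporting odds ratio ROR = ad/bc with a Woolf (log-normal) 95% CI,
exp(ln ROR ± 1.96·sqrt(1/a + 1/b + 1/c + 1/d)), and the proportional
reporting ratio PRR = [a/(a+b)] / [c/(c+d)] with
exp(ln PRR ± 1.96·sqrt(1/a − 1/(a+b) + 1/c − 1/(c+d))) plus a Pearson χ²
(1 df) are the classical frequentist disproportionality measures.  A term is
flagged as a signal when, with at least ``min_a`` reports (default 3),
either the ROR CI lower bound exceeds 1 or PRR ≥ 2 with χ² ≥ 4.

Counting unit: ``report`` counts reports mentioning the term (a ≤ cohort
size); ``event`` counts (report, term) mentions, so b/d are the remaining
mentions.  Which unit was used is recorded on every result.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, replace
from typing import Iterable, NamedTuple, Optional, Sequence

from .faers import CaseReport, MedDRAMap

Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class ContingencyTable:
    """Four-fold counts for one (drug, term) pair."""

    a: float
    b: float
    c: float
    d: float

    @property
    def n(self) -> float:
        return self.a + self.b + self.c + self.d

    def cells(self) -> tuple[float, float, float, float]:
        return (self.a, self.b, self.c, self.d)


class Estimate(NamedTuple):
    value: float
    low: float
    high: float

    @property
    def defined(self) -> bool:
        return not math.isnan(self.value)


_UNDEFINED = Estimate(float("nan"), float("nan"), float("nan"))


@dataclass
class SignalResult:
    """All statistics for one PT or SOC term."""

    term: str
    level: str                   # "PT" or "SOC"
    a: int
    ror: float
    ror_low: float
    ror_high: float
    prr: float
    prr_low: float
    prr_high: float
    chi2: float
    ror_signal: bool
    prr_signal: bool
    signal: bool
    pct: float                   # 100·a / total event mentions in the cohort
    unit: str = "report"
    zero_corrected: bool = False
    listed_on_label: Optional[bool] = None


# ---------------------------------------------------------------------------
# elementary statistics
# ---------------------------------------------------------------------------

def _corrected(table: ContingencyTable, zero_policy: str) -> Optional[ContingencyTable]:
    """Apply the zero-cell policy; None means the statistic is undefined."""
    if min(table.cells()) > 0:
        return table
    if zero_policy == "haldane":
        # Haldane–Anscombe: add 0.5 to every cell when any cell is zero
        return ContingencyTable(*(x + 0.5 for x in table.cells()))
    return None


def ror(table: ContingencyTable, zero_policy: str = "haldane") -> Estimate:
    """Reporting odds ratio ad/bc with Woolf 95% CI (log-symmetric).

    Zero cells are handled by ``zero_policy``: ``'haldane'`` adds 0.5 to all
    four cells, ``'skip'`` marks the statistic undefined (NaN triple)."""
    t = _corrected(table, zero_policy)
    if t is None:
        return _UNDEFINED
    a, b, c, d = t.cells()
    est = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return Estimate(est, est * math.exp(-Z95 * se), est * math.exp(Z95 * se))


def prr(table: ContingencyTable, zero_policy: str = "haldane") -> Estimate:
    """Proportional reporting ratio with its log-normal 95% CI."""
    t = _corrected(table, zero_policy)
    if t is None:
        return _UNDEFINED
    a, b, c, d = t.cells()
    est = (a / (a + b)) / (c / (c + d))
    se = math.sqrt(1 / a - 1 / (a + b) + 1 / c - 1 / (c + d))
    return Estimate(est, est * math.exp(-Z95 * se), est * math.exp(Z95 * se))


def chi_square(table: ContingencyTable, yates: bool = False) -> float:
    """Pearson χ² (1 df) with expected counts from the fixed margins.

    Computed on the raw counts (no zero-cell correction); a zero margin makes
    the statistic undefined (NaN).  ``yates`` enables the continuity
    correction (off by default)."""
    a, b, c, d = table.cells()
    n = a + b + c + d
    row1, row2, col1, col2 = a + b, c + d, a + c, b + d
    if min(row1, row2, col1, col2) == 0 or n == 0:
        return float("nan")
    expected = (row1 * col1 / n, row1 * col2 / n, row2 * col1 / n, row2 * col2 / n)
    stat = 0.0
    for obs, exp in zip((a, b, c, d), expected):
        diff = abs(obs - exp)
        if yates:
            diff = max(0.0, diff - 0.5)
        stat += diff * diff / exp
    return stat


def evaluate_signal(
    a: float,
    ror_ci_low: float,
    prr_value: float,
    chi2: float,
    min_a: int = 3,
) -> tuple[bool, bool, bool]:
    """Apply the signal thresholds.

    ROR rule: a ≥ min_a and the 95% CI lower bound strictly above 1.
    PRR rule: a ≥ min_a, PRR ≥ 2 and χ² ≥ 4 (both inclusive).
    A term is a signal when either rule fires; NaN statistics never fire.
    """
    enough = a >= min_a
    ror_signal = bool(enough and not math.isnan(ror_ci_low) and ror_ci_low > 1.0)
    prr_signal = bool(enough and not math.isnan(prr_value) and not math.isnan(chi2)
                      and prr_value >= 2.0 and chi2 >= 4.0)
    return ror_signal, prr_signal, ror_signal or prr_signal


def percent_of_events(a: float, total_events: float) -> float:
    """Share of all event mentions, as a percentage at 2 decimals."""
    if total_events <= 0:
        raise ValueError("total_events must be positive")
    return round(100.0 * a / total_events, 2)


def ci_geometric_mean(low: float, high: float) -> float:
    """Midpoint of a log-symmetric CI: the point estimate implied by its bounds."""
    return math.sqrt(low * high)


# ---------------------------------------------------------------------------
# term extraction and table construction
# ---------------------------------------------------------------------------

def _case_terms(case: CaseReport, level: str, mapping: Optional[MedDRAMap]) -> frozenset[str]:
    if level == "PT":
        return case.events
    if mapping is None:
        raise ValueError("SOC-level analysis requires a MedDRA map")
    socs = {mapping.lookup(pt) for pt in case.events}
    socs.discard(None)  # unmapped PTs are audited by the map, excluded here
    return frozenset(socs)


def _counts(cases: Sequence[CaseReport], level: str,
            mapping: Optional[MedDRAMap]) -> tuple[Counter, int]:
    """Per-term report counts and the total number of (report, term) pairs."""
    counts: Counter = Counter()
    pairs = 0
    for case in cases:
        terms = _case_terms(case, level, mapping)
        pairs += len(terms)
        counts.update(terms)
    return counts, pairs


def build_contingency(
    target_cases: Sequence[CaseReport],
    background_cases: Sequence[CaseReport],
    term: str,
    level: str = "PT",
    unit: str = "report",
    mapping: Optional[MedDRAMap] = None,
) -> ContingencyTable:
    """Four-fold table for a single term (see module docstring for units)."""
    tc, tp = _counts(target_cases, level, mapping)
    bc, bp = _counts(background_cases, level, mapping)
    a = tc.get(term, 0)
    c = bc.get(term, 0)
    if unit == "event":
        return ContingencyTable(a, tp - a, c, bp - c)
    return ContingencyTable(a, len(target_cases) - a, c, len(background_cases) - c)


def analyze(
    target_cases: Sequence[CaseReport],
    background_cases: Sequence[CaseReport],
    level: str = "PT",
    unit: str = "report",
    mapping: Optional[MedDRAMap] = None,
    min_a: int = 3,
    zero_policy: str = "haldane",
    yates: bool = False,
) -> list[SignalResult]:
    """Compute ROR/PRR/χ² and signal flags for every term in the target cohort.

    At SOC level each report contributes each SOC at most once, so ``a``
    never exceeds the cohort size.  The percentage column always uses the
    total number of (report, term) mentions in the target cohort as its
    denominator, mirroring how adverse-event shares are conventionally
    reported.
    """
    if unit not in ("report", "event"):
        raise ValueError(f"unknown counting unit {unit!r}")
    tc, tp = _counts(target_cases, level, mapping)
    bc, bp = _counts(background_cases, level, mapping)
    n_t, n_b = len(target_cases), len(background_cases)

    results: list[SignalResult] = []
    for term in sorted(tc):
        a = tc[term]
        c = bc.get(term, 0)
        if unit == "event":
            table = ContingencyTable(a, tp - a, c, bp - c)
        else:
            table = ContingencyTable(a, n_t - a, c, n_b - c)
        corrected = min(table.cells()) == 0
        r = ror(table, zero_policy)
        p = prr(table, zero_policy)
        x2 = chi_square(table, yates)
        rs, ps, sig = evaluate_signal(a, r.low, p.value, x2, min_a)
        results.append(SignalResult(
            term=term, level=level, a=a,
            ror=r.value, ror_low=r.low, ror_high=r.high,
            prr=p.value, prr_low=p.low, prr_high=p.high,
            chi2=x2,
            ror_signal=rs, prr_signal=ps, signal=sig,
            pct=percent_of_events(a, tp) if tp else 0.0,
            unit=unit, zero_corrected=corrected,
        ))
    return results


# ---------------------------------------------------------------------------
# ranking and label comparison
# ---------------------------------------------------------------------------

def rank_signals(results: Iterable[SignalResult], by: str = "frequency",
                 k: Optional[int] = None) -> list[SignalResult]:
    """Top-k signal terms, by report count or by signal strength.

    ``by='frequency'`` sorts on descending a, ties by descending ROR then
    term; ``by='strength'`` sorts on descending ROR, ties by descending a
    then term.  Only flagged signals are ranked; k beyond the available
    signals returns them all."""
    sigs = [r for r in results if r.signal]

    def ror_key(r: SignalResult) -> float:
        return r.ror if not math.isnan(r.ror) else -math.inf

    if by == "frequency":
        sigs.sort(key=lambda r: (-r.a, -ror_key(r), r.term))
    elif by == "strength":
        sigs.sort(key=lambda r: (-ror_key(r), -r.a, r.term))
    else:
        raise ValueError(f"unknown ranking {by!r}")
    return sigs if k is None else sigs[:max(k, 0)]


def compare_to_label(results: Sequence[SignalResult],
                     label_pts: Iterable[str]) -> list[SignalResult]:
    """Flag each term as listed/unlisted against a drug-label PT list.

    Matching is case-insensitive after whitespace normalization.  An empty
    label list flags everything unlisted (logged upstream)."""
    listed = {" ".join(t.strip().split()).lower() for t in label_pts if t.strip()}
    return [replace(r, listed_on_label=" ".join(r.term.strip().split()).lower() in listed)
            for r in results]


def count_unlisted(results: Iterable[SignalResult]) -> int:
    """Number of terms flagged as absent from the label."""
    return sum(1 for r in results if r.listed_on_label is False)
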