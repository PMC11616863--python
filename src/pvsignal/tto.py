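"""Time-to-onset (TTO) analysis: latency extraction, Weibull fit, failure type.

TTO for a report is the number of days from the earliest therapy start of
the suspect drug to the event date.  Only day-precision dates are used —
partial FAERS dates (YYYY or YYYYMM) are excluded rather than imputed — and
non-positive latencies are excluded as inconsistent.

The latency distribution is summarized by median/IQR/range and by a
two-parameter Weibull fit (scale α in days, shape β) obtained by maximum
likelihood without censoring; 95% CIs come from the observed Fisher
information on (ln α, ln β) with a normal approximation.  The shape
parameter classifies the hazard trend: β < 1 with its CI entirely below 1 is
an early-failure pattern (decreasing hazard — most events shortly after
treatment start), a CI containing 1 is random (constant hazard), β > 1 with
the CI above 1 is wear-out (increasing hazard).
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.stats import weibull_min

from .faers import CaseReport, drug_matches, parse_date

logger = logging.getLogger(__name__)

DEFAULT_BIN_EDGES = (30, 60, 90, 180, 360)


@dataclass
class TTOSample:
    """Observed onset latencies in days (all ≥ 1) plus exclusion bookkeeping."""

    days: np.ndarray
    exclusions: Counter = field(default_factory=Counter)

    @property
    def n(self) -> int:
        return int(len(self.days))


@dataclass
class WeibullFit:
    alpha: float                      # scale, days
    alpha_ci: tuple[float, float]
    beta: float                       # shape, dimensionless
    beta_ci: tuple[float, float]
    loglik: float
    n: int
    failure_type: str                 # early | random | wear-out | indeterminate
    converged: bool


# ---------------------------------------------------------------------------
# extraction
# ---------------------------------------------------------------------------

def compute_tto(cases: Sequence[CaseReport], drug_synonyms: Sequence[str],
                match: str = "substring") -> TTOSample:
    """Extract per-case onset latency for the suspect drug.

    THER records are linked to DRUG records via the drug sequence number;
    the earliest full-precision therapy start among records belonging to a
    matching drug is used.  Cases are excluded (and counted by reason) when
    the event date or every linked start date lacks day precision, or when
    the latency is below one day.
    """
    days: list[int] = []
    excl: Counter = Counter()
    for case in cases:
        event = parse_date(case.event_dt)
        if event is None:
            excl["event_date_missing_or_partial"] += 1
            continue
        seqs = {d.drug_seq for d in case.drugs if drug_matches(d, drug_synonyms, match)}
        starts = [parse_date(raw) for seq, raw in case.therapy_starts if seq in seqs]
        starts = [s for s in starts if s is not None]
        if not starts:
            excl["therapy_start_missing_or_partial"] += 1
            continue
        tto = (event - min(starts)).days
        if tto < 1:
            excl["non_positive"] += 1
            continue
        days.append(tto)
    return TTOSample(days=np.asarray(days, dtype=float), exclusions=excl)


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------

def summarize_tto(sample: TTOSample) -> dict[str, float]:
    """Median, quartiles (linear-interpolation convention), min and max."""
    if sample.n == 0:
        return {k: float("nan") for k in ("n", "median", "q1", "q3", "min", "max")} | {"n": 0}
    d = sample.days
    q1, med, q3 = np.percentile(d, [25, 50, 75], method="linear")
    return {"n": sample.n, "median": float(med), "q1": float(q1), "q3": float(q3),
            "min": float(d.min()), "max": float(d.max())}


# ---------------------------------------------------------------------------
# Weibull maximum likelihood
# ---------------------------------------------------------------------------

def _weibull_nll(log_alpha: float, log_beta: float, x: np.ndarray) -> float:
    alpha, beta = math.exp(log_alpha), math.exp(log_beta)
    z = x / alpha
    return -float(np.sum(np.log(beta / alpha) + (beta - 1) * np.log(z) - z ** beta))


def _observed_information(log_alpha: float, log_beta: float,
                          x: np.ndarray, h: float = 1e-4) -> np.ndarray:
    """Hessian of the negative log-likelihood in (ln α, ln β), central differences."""
    p = np.array([log_alpha, log_beta])
    hess = np.empty((2, 2))
    for i in range(2):
        for j in range(2):
            pp = p.copy(); pp[i] += h; pp[j] += h
            pm = p.copy(); pm[i] += h; pm[j] -= h
            mp = p.copy(); mp[i] -= h; mp[j] += h
            mm = p.copy(); mm[i] -= h; mm[j] -= h
            hess[i, j] = (_weibull_nll(*pp, x) - _weibull_nll(*pm, x)
                          - _weibull_nll(*mp, x) + _weibull_nll(*mm, x)) / (4 * h * h)
    return hess


_Z95 = 1.959963984540054


def fit_weibull(sample: TTOSample, min_n: int = 20) -> WeibullFit:
    """Two-parameter Weibull MLE (no censoring) with Fisher-information CIs.

    Below ``min_n`` observations the fit is refused (indeterminate with a
    warning) — the normal approximation is not trustworthy there.  The fit is
    deterministic given the sample.
    """
    nan_ci = (float("nan"), float("nan"))
    if sample.n < min_n:
        logger.warning("fit_weibull: n=%d < %d, refusing to fit", sample.n, min_n)
        return WeibullFit(float("nan"), nan_ci, float("nan"), nan_ci,
                          float("nan"), sample.n, "indeterminate", False)
    x = np.asarray(sample.days, dtype=float)
    try:
        beta, _, alpha = weibull_min.fit(x, floc=0)
        la, lb = math.log(alpha), math.log(beta)
        loglik = -_weibull_nll(la, lb, x)
        info = _observed_information(la, lb, x)
        cov = np.linalg.inv(info)
        se_la, se_lb = math.sqrt(cov[0, 0]), math.sqrt(cov[1, 1])
    except (ValueError, np.linalg.LinAlgError, OverflowError) as exc:
        logger.warning("fit_weibull: did not converge (%s)", exc)
        return WeibullFit(float("nan"), nan_ci, float("nan"), nan_ci,
                          float("nan"), sample.n, "indeterminate", False)
    alpha_ci = (alpha * math.exp(-_Z95 * se_la), alpha * math.exp(_Z95 * se_la))
    beta_ci = (beta * math.exp(-_Z95 * se_lb), beta * math.exp(_Z95 * se_lb))
    fit = WeibullFit(alpha, alpha_ci, beta, beta_ci, loglik, sample.n, "", True)
    fit.failure_type = classify_failure(fit)
    return fit


def classify_failure(fit: WeibullFit) -> str:
    """Hazard-trend class from the shape parameter and its 95% CI."""
    if not fit.converged or math.isnan(fit.beta):
        return "indeterminate"
    lo, hi = fit.beta_ci
    if lo <= 1.0 <= hi:
        return "random"
    if fit.beta < 1.0 and hi < 1.0:
        return "early"
    if fit.beta > 1.0 and lo > 1.0:
        return "wear-out"
    return "indeterminate"


# ---------------------------------------------------------------------------
# onset-interval binning
# ---------------------------------------------------------------------------

def bin_tto(sample: TTOSample,
            edges: Sequence[int] = DEFAULT_BIN_EDGES) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Right-closed onset intervals [1,e1], (e1,e2], …, (e_last, ∞).

    Returns (labels, counts, percentages); percentages are over the sample
    size and sum to 100 (up to rounding) for any non-empty sample."""
    edges = list(edges)
    if any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError("bin edges must be strictly increasing")
    idx = np.searchsorted(edges, sample.days, side="left")
    counts = np.bincount(idx, minlength=len(edges) + 1).astype(int)
    labels = []
    prev = 1
    for e in edges:
        labels.append(f"{prev}-{e}")
        prev = e + 1
    labels.append(f">{edges[-1]}")
    if sample.n:
        pct = np.round(100.0 * counts / sample.n, 2)
    else:
        pct = np.zeros_like(counts, dtype=float)
    return labels, counts, pct
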