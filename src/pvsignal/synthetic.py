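"""FAERS-like synthetic data with known ground truth.

Generates the six quarterly tables with the structural quirks the real
system has — duplicate CASEIDs re-submitted under a later PRIMARYID, partial
and missing event dates, demographic and outcome mixes, multiple drugs per
report — plus a fully known ground truth so every downstream stage
(deduplication, cohort construction, disproportionality statistics,
time-to-onset) has an oracle.

Planted drug–event associations are parameterized directly as a true
reporting odds ratio: among target-drug reports the event probability is
p1 = odds1/(1+odds1) with odds1 = true_ror · p0/(1−p0), and p0 among the
background, so the population odds ratio of the report-level four-fold
table equals ``true_ror`` exactly and confidence-interval coverage tests
are exact in expectation.

Onset latencies are drawn from a Weibull(scale α days, shape β) and
discretized by ceiling to at least one day (report dates have day
resolution).  Default parameters mirror a realistic elderly
antiplatelet-drug cohort: mostly ≥60-year-old patients, Japan-dominated
reporting, Weibull(162.3, 0.61) early-failure onset profile.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .faers import RawTables, TABLE_COLUMNS, MedDRAMap

_EPOCH = np.datetime64("2004-01-01")


@dataclass(frozen=True)
class PlantedSignal:
    """One drug–event association to plant: the event's baseline probability
    among background reports and the true reporting odds ratio for the
    target drug."""

    pt: str
    true_ror: float
    baseline_event_prob: float

    def target_prob(self) -> float:
        if not (0.0 < self.baseline_event_prob < 1.0):
            raise ValueError(
                f"planted signal {self.pt!r}: baseline_event_prob must be in (0,1)")
        if not (self.true_ror > 0.0 and np.isfinite(self.true_ror)):
            raise ValueError(f"planted signal {self.pt!r}: true_ror must be finite > 0")
        odds = self.true_ror * self.baseline_event_prob / (1.0 - self.baseline_event_prob)
        p1 = odds / (1.0 + odds)
        if p1 >= 1.0:
            raise ValueError(f"planted signal {self.pt!r}: infeasible (p1 >= 1)")
        return p1


DEFAULT_PLANTED = (
    PlantedSignal("Cardiac failure", 8.0, 0.005),
    PlantedSignal("Anaemia", 4.5, 0.010),
    PlantedSignal("Tachycardia", 6.0, 0.004),
    PlantedSignal("Headache", 1.0, 0.020),   # null association
)

DEFAULT_BACKGROUND_PTS = (
    ("Nausea", 0.060), ("Diarrhoea", 0.050), ("Dizziness", 0.045),
    ("Fatigue", 0.040), ("Vomiting", 0.035), ("Rash", 0.030),
    ("Pyrexia", 0.030), ("Dyspnoea", 0.028), ("Pruritus", 0.025),
    ("Fall", 0.022), ("Abdominal pain", 0.022), ("Insomnia", 0.018),
    ("Arthralgia", 0.018), ("Oedema peripheral", 0.016), ("Malaise", 0.015),
    ("Palpitations", 0.012), ("Gastrointestinal haemorrhage", 0.008),
    ("Renal impairment", 0.008), ("Hepatic function abnormal", 0.006),
    ("Cerebral infarction", 0.004),
)

FILLER_PT = "Drug ineffective"

#: synthetic stand-in PT→SOC assignments for the generator's own vocabulary
#: (MedDRA itself is licensed and never bundled; this map is synthetic and
#: covers only terms this module can emit)
SYNTHETIC_PT_TO_SOC = {
    "Cardiac failure": "Cardiac disorders",
    "Tachycardia": "Cardiac disorders",
    "Palpitations": "Cardiac disorders",
    "Anaemia": "Blood and lymphatic system disorders",
    "Headache": "Nervous system disorders",
    "Dizziness": "Nervous system disorders",
    "Cerebral infarction": "Nervous system disorders",
    "Nausea": "Gastrointestinal disorders",
    "Diarrhoea": "Gastrointestinal disorders",
    "Vomiting": "Gastrointestinal disorders",
    "Abdominal pain": "Gastrointestinal disorders",
    "Gastrointestinal haemorrhage": "Gastrointestinal disorders",
    "Fatigue": "General disorders and administration site conditions",
    "Pyrexia": "General disorders and administration site conditions",
    "Malaise": "General disorders and administration site conditions",
    "Oedema peripheral": "General disorders and administration site conditions",
    "Drug ineffective": "General disorders and administration site conditions",
    "Rash": "Skin and subcutaneous tissue disorders",
    "Pruritus": "Skin and subcutaneous tissue disorders",
    "Dyspnoea": "Respiratory, thoracic and mediastinal disorders",
    "Fall": "Injury, poisoning and procedural complications",
    "Insomnia": "Psychiatric disorders",
    "Arthralgia": "Musculoskeletal and connective tissue disorders",
    "Renal impairment": "Renal and urinary disorders",
    "Hepatic function abnormal": "Hepatobiliary disorders",
}

BACKGROUND_DRUGS = ("ASPIRIN", "METFORMIN", "WARFARIN", "ATORVASTATIN",
                    "CLOPIDOGREL", "LISINOPRIL", "OMEPRAZOLE", "AMLODIPINE")


@dataclass
class SyntheticConfig:
    """Generator parameters; the defaults are the study conditions emulated."""

    n_reports: int = 20_000
    target_drug_fraction: float = 0.05
    planted_signals: tuple[PlantedSignal, ...] = DEFAULT_PLANTED
    background_pts: tuple[tuple[str, float], ...] = DEFAULT_BACKGROUND_PTS
    duplicate_rate: float = 0.05
    sex_probs: dict = field(default_factory=lambda: {"M": 0.559, "F": 0.311, "": 0.130})
    age_bin_probs: dict = field(default_factory=lambda: {
        "<18": 0.002, "18-59.9": 0.126, "60-85": 0.589, ">85": 0.064, "": 0.219})
    occupation_probs: dict = field(default_factory=lambda: {
        "MD": 0.330, "OT": 0.132, "PH": 0.063, "CN": 0.125, "LW": 0.015, "": 0.335})
    country_probs: dict = field(default_factory=lambda: {
        "JP": 0.496, "US": 0.114, "KR": 0.080, "DE": 0.069, "ES": 0.040,
        "PH": 0.031, "GB": 0.027, "CN": 0.025, "IT": 0.050, "FR": 0.040, "BR": 0.028})
    outcome_probs: dict = field(default_factory=lambda: {
        "HO": 0.374, "DE": 0.162, "LT": 0.075, "DS": 0.015, "RI": 0.007, "OT": 0.244})
    tto_scale: float = 162.3           # Weibull α, days
    tto_shape: float = 0.61            # Weibull β
    partial_date_rate: float = 0.10    # event date truncated to YYYYMM
    missing_date_rate: float = 0.05    # event date absent
    target_drug_names: tuple[str, ...] = ("CILOSTAZOL", "PLETAL")
    target_active_ingredient: str = "CILOSTAZOL"
    background_drugs: tuple[str, ...] = BACKGROUND_DRUGS
    concomitant_rate: float = 0.30
    seed: int = 0

    def validate(self) -> None:
        probs = [self.target_drug_fraction, self.duplicate_rate,
                 self.partial_date_rate, self.missing_date_rate,
                 self.concomitant_rate]
        probs += [p for _, p in self.background_pts]
        for block in (self.sex_probs, self.age_bin_probs, self.occupation_probs,
                      self.country_probs):
            probs += list(block.values())
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if self.tto_scale <= 0 or self.tto_shape <= 0:
            raise ValueError("Weibull scale and shape must be positive")
        for sig in self.planted_signals:
            sig.target_prob()  # raises when infeasible


@dataclass
class GroundTruth:
    """Everything the generator knows: per-report memberships and latencies,
    per-signal true parameters and realized four-fold counts (unique
    reports), and duplicate bookkeeping."""

    reports: pd.DataFrame    # caseid, primaryid, is_target, onset_day, onset_cont, event_precision
    planted: dict[str, dict]
    n_reports: int
    n_duplicates: int
    duplicate_caseids: list[str]
    config: SyntheticConfig


def synthetic_meddra_map() -> MedDRAMap:
    """A MedDRA-style PT→SOC map covering the generator's vocabulary (synthetic)."""
    return MedDRAMap.from_pairs(SYNTHETIC_PT_TO_SOC.items())


def write_synthetic_meddra_map(path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("pt\tsoc\n")
        for pt, soc in sorted(SYNTHETIC_PT_TO_SOC.items()):
            fh.write(f"{pt}\t{soc}\n")


def _dates_to_str(arr: np.ndarray) -> np.ndarray:
    return np.char.replace(np.datetime_as_string(arr, unit="D"), "-", "")


_AGE_RANGES = {"<18": (1, 17), "18-59.9": (18, 59), "60-85": (60, 85), ">85": (86, 99)}


def generate(config: SyntheticConfig) -> tuple[RawTables, GroundTruth]:
    """Draw one synthetic quarter; fully reproducible from ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_reports

    primaryid = np.array([str(100001 + i) for i in range(n)])
    caseid = np.array([str(500001 + i) for i in range(n)])
    is_target = rng.random(n) < config.target_drug_fraction

    # --- events -----------------------------------------------------------
    events: list[list[str]] = [[] for _ in range(n)]
    planted_truth: dict[str, dict] = {}
    planted_names = {s.pt for s in config.planted_signals}
    for sig in config.planted_signals:
        p1 = sig.target_prob()
        p = np.where(is_target, p1, sig.baseline_event_prob)
        has = rng.random(n) < p
        for i in np.flatnonzero(has):
            events[i].append(sig.pt)
        a = int(np.sum(has & is_target))
        c = int(np.sum(has & ~is_target))
        planted_truth[sig.pt] = {
            "true_ror": sig.true_ror, "baseline_event_prob": sig.baseline_event_prob,
            "target_event_prob": p1,
            "a": a, "b": int(is_target.sum()) - a,
            "c": c, "d": int((~is_target).sum()) - c,
        }
    for pt, prob in config.background_pts:
        if pt in planted_names:
            raise ValueError(f"background PT {pt!r} collides with a planted signal")
        has = rng.random(n) < prob
        for i in np.flatnonzero(has):
            events[i].append(pt)
    for i in range(n):           # every report must carry at least one event
        if not events[i]:
            events[i].append(FILLER_PT)

    # --- demographics -----------------------------------------------------
    def draw(block: dict) -> np.ndarray:
        keys = list(block)
        p = np.array([block[k] for k in keys], dtype=float)
        p = p / p.sum()
        return rng.choice(np.array(keys, dtype=object), size=n, p=p)

    sex = draw(config.sex_probs)
    agebin = draw(config.age_bin_probs)
    occupation = draw(config.occupation_probs)
    country = draw(config.country_probs)

    age = np.full(n, "", dtype=object)
    age_cod = np.full(n, "", dtype=object)
    unit_pick = rng.random(n)
    for i in range(n):
        b = agebin[i]
        if b == "":
            continue
        lo, hi = _AGE_RANGES[b]
        years = int(rng.integers(lo, hi + 1))
        if unit_pick[i] < 0.90:
            age[i], age_cod[i] = str(years), "YR"
        elif unit_pick[i] < 0.95:
            age[i], age_cod[i] = f"{years / 10:.1f}", "DEC"
        else:
            age[i], age_cod[i] = str(years * 12), "MON"

    # --- dates ------------------------------------------------------------
    start_off = rng.integers(0, 7300, n)                      # therapy start, 2004..2023
    onset_cont = config.tto_scale * rng.weibull(config.tto_shape, n)
    onset_day = np.maximum(1, np.ceil(onset_cont)).astype(int)
    start = _EPOCH + start_off.astype("timedelta64[D]")
    event = start + onset_day.astype("timedelta64[D]")
    fda = event + rng.integers(7, 121, n).astype("timedelta64[D]")
    start_str = _dates_to_str(start)
    event_str = _dates_to_str(event).astype(object)
    fda_str = _dates_to_str(fda)

    u = rng.random(n)
    partial = u < config.partial_date_rate
    missing = (u >= config.partial_date_rate) & \
              (u < config.partial_date_rate + config.missing_date_rate)
    precision = np.full(n, "day", dtype=object)
    for i in np.flatnonzero(partial):
        event_str[i] = event_str[i][:6]
        precision[i] = "month"
    for i in np.flatnonzero(missing):
        event_str[i] = ""
        precision[i] = "missing"

    # --- drugs, outcomes, indications -------------------------------------
    target_name = rng.choice(np.array(config.target_drug_names, dtype=object),
                             size=n, p=None if len(config.target_drug_names) != 2
                             else [0.7, 0.3])
    bg_name = rng.choice(np.array(config.background_drugs, dtype=object), size=n)
    conc = rng.random(n) < config.concomitant_rate
    conc_name = rng.choice(np.array(config.background_drugs, dtype=object), size=n)

    outc_codes = list(config.outcome_probs)
    outc_draw = rng.random((n, len(outc_codes)))
    outc_p = np.array([config.outcome_probs[c] for c in outc_codes])
    indi_target = rng.random(n)
    indi_bg = rng.choice(np.array(["Hypertension", "Diabetes mellitus",
                                   "Atrial fibrillation", "Pain", "Prophylaxis"],
                                  dtype=object), size=n)
    # child rows per report (without PRIMARYID) so duplicates can re-emit them
    per_report: dict[str, list[list[tuple]]] = {t: [] for t in
                                                ("drug", "ther", "reac", "outc", "indi")}
    for i in range(n):
        if is_target[i]:
            name, ai = target_name[i], config.target_active_ingredient
            indi = ("Intermittent claudication" if indi_target[i] < 0.85
                    else "Peripheral arterial occlusive disease")
        else:
            name, ai = bg_name[i], bg_name[i]
            indi = indi_bg[i]
        drugs_i = [("1", "PS", name, ai)]
        if conc[i]:
            drugs_i.append(("2", "C", conc_name[i], conc_name[i]))
        per_report["drug"].append(drugs_i)
        per_report["ther"].append([("1", start_str[i], "")])
        per_report["indi"].append([(indi,)])
        per_report["reac"].append([(pt,) for pt in events[i]])
        per_report["outc"].append([(code,) for j, code in enumerate(outc_codes)
                                   if outc_draw[i, j] < outc_p[j]])

    def flatten(name: str, pids: Sequence[str], idx: Sequence[int]) -> list[tuple]:
        return [(pids[k],) + r for k, i in enumerate(idx) for r in per_report[name][i]]

    all_idx = list(range(n))
    drug_rows = flatten("drug", primaryid, all_idx)
    ther_rows = flatten("ther", primaryid, all_idx)
    reac_rows = flatten("reac", primaryid, all_idx)
    outc_rows = flatten("outc", primaryid, all_idx)
    indi_rows = flatten("indi", primaryid, all_idx)

    demo = pd.DataFrame({
        "PRIMARYID": primaryid, "CASEID": caseid, "FDA_DT": fda_str,
        "EVENT_DT": event_str.astype(str), "AGE": age.astype(str),
        "AGE_COD": age_cod.astype(str), "SEX": sex.astype(str),
        "OCCP_COD": occupation.astype(str),
        "REPORTER_COUNTRY": country.astype(str),
    }, dtype=str)

    # --- duplicate emissions ----------------------------------------------
    dup_idx = np.flatnonzero(rng.random(n) < config.duplicate_rate)
    same_dt = rng.random(len(dup_idx)) < 0.2
    dup_delay = rng.integers(30, 301, len(dup_idx))
    dup_demo_rows = []
    dup_pids = []
    for k, i in enumerate(dup_idx):
        new_pid = str(900001 + i)
        dup_pids.append(new_pid)
        new_fda = fda_str[i] if same_dt[k] else \
            _dates_to_str(np.array([fda[i] + np.timedelta64(int(dup_delay[k]), "D")]))[0]
        row = demo.iloc[i].copy()
        row["PRIMARYID"] = new_pid
        row["FDA_DT"] = new_fda
        dup_demo_rows.append(row)
    drug_rows += flatten("drug", dup_pids, dup_idx)
    ther_rows += flatten("ther", dup_pids, dup_idx)
    reac_rows += flatten("reac", dup_pids, dup_idx)
    outc_rows += flatten("outc", dup_pids, dup_idx)
    indi_rows += flatten("indi", dup_pids, dup_idx)
    if dup_demo_rows:
        demo = pd.concat([demo, pd.DataFrame(dup_demo_rows)], ignore_index=True)

    def frame(rows, cols):
        return pd.DataFrame(rows, columns=list(cols), dtype=str) if rows else \
            pd.DataFrame({c: pd.Series(dtype=str) for c in cols})

    tables = RawTables(
        demo=demo,
        drug=frame(drug_rows, TABLE_COLUMNS["drug"]),
        reac=frame(reac_rows, TABLE_COLUMNS["reac"]),
        outc=frame(outc_rows, TABLE_COLUMNS["outc"]),
        ther=frame(ther_rows, TABLE_COLUMNS["ther"]),
        indi=frame(indi_rows, TABLE_COLUMNS["indi"]),
        skipped={},
    )
    truth = GroundTruth(
        reports=pd.DataFrame({
            "caseid": caseid, "primaryid": primaryid, "is_target": is_target,
            "onset_day": onset_day, "onset_cont": onset_cont,
            "event_precision": precision.astype(str),
        }),
        planted=planted_truth,
        n_reports=n,
        n_duplicates=len(dup_idx),
        duplicate_caseids=[caseid[i] for i in dup_idx],
        config=config,
    )
    return tables, truth


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

FILE_NAMES = {name: f"{name.upper()}.txt" for name in TABLE_COLUMNS}


def write_quarter(tables: RawTables, out_dir) -> dict[str, str]:
    """Write the six tables as ``$``-delimited files; byte-stable per input."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {}
    for name in TABLE_COLUMNS:
        df = tables.table(name)
        path = os.path.join(out_dir, FILE_NAMES[name])
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("$".join(df.columns) + "\n")
            for row in df.itertuples(index=False):
                fh.write("$".join("" if pd.isna(v) else str(v) for v in row) + "\n")
        paths[name] = path
    return paths


def write_ground_truth(truth: GroundTruth, out_dir) -> dict[str, str]:
    """Ground truth as TSVs: per-report memberships and per-signal parameters."""
    os.makedirs(out_dir, exist_ok=True)
    reports_path = os.path.join(out_dir, "ground_truth_reports.tsv")
    truth.reports.to_csv(reports_path, sep="\t", index=False, lineterminator="\n")
    planted_path = os.path.join(out_dir, "ground_truth_planted.tsv")
    rows = [{"pt": pt, **vals} for pt, vals in truth.planted.items()]
    pd.DataFrame(rows).to_csv(planted_path, sep="\t", index=False, lineterminator="\n")
    return {"reports": reports_path, "planted": planted_path}
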