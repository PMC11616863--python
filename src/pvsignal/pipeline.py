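"""End-to-end orchestration: read → dedup → cohort → descriptives → signals
→ SOC aggregation → ranking/label comparison → time-to-onset, from one
config, with per-stage record counts in a run manifest.

Runs are deterministic: the only randomness is the synthetic generator's
seed, and outputs carry no timestamps, so identical config + inputs give
byte-identical output files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd
import yaml

from . import __version__
from .faers import (DataError, MedDRAMap, RawTables, build_cohort,
                    deduplicate_tables, read_quarter)
from .descriptives import DescriptiveSummary, OutcomeHierarchy, summarize
from .disproportionality import (SignalResult, analyze, compare_to_label,
                                 count_unlisted, rank_signals)
from .synthetic import (SyntheticConfig, PlantedSignal, generate,
                        synthetic_meddra_map, write_ground_truth, write_quarter)
from .tto import DEFAULT_BIN_EDGES, bin_tto, compute_tto, fit_weibull, summarize_tto

logger = logging.getLogger(__name__)


class ConfigError(RuntimeError):
    """Invalid or inconsistent run configuration."""


@dataclass
class RunConfig:
    """One pipeline run: either a FAERS quarter directory or a synthetic draw."""

    out_dir: str
    input_dir: Optional[str] = None
    synthetic: Optional[SyntheticConfig] = None
    drug_synonyms: Sequence[str] = ("cilostazol", "pletal")
    meddra_map_path: Optional[str] = None
    label_pts: Sequence[str] = ()
    role: str = "PS"
    reporter_filter: Optional[Sequence[str]] = None
    date_range: Optional[tuple[int, int]] = None
    unit: str = "report"
    min_a: int = 3
    zero_policy: str = "haldane"
    yates: bool = False
    match: str = "substring"
    top_k: int = 30
    tto_bins: Sequence[int] = DEFAULT_BIN_EDGES
    outcome_order: Optional[Sequence[str]] = None
    seed: int = 0

    def validate(self) -> None:
        if (self.input_dir is None) == (self.synthetic is None):
            raise ConfigError("exactly one of input_dir or synthetic must be set")
        if not self.drug_synonyms:
            raise ConfigError("drug_synonyms must be non-empty")
        if self.min_a < 1:
            raise ConfigError("min_a must be positive")
        if self.unit not in ("report", "event"):
            raise ConfigError(f"unknown counting unit {self.unit!r}")


def _read_lines(path: str) -> list[str]:
    with open(path, "r", encoding="utf-8") as fh:
        return [ln.strip() for ln in fh if ln.strip()]


def load_config(path: str) -> RunConfig:
    """Parse a YAML run config (keys mirror :class:`RunConfig`)."""
    try:
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
    except (OSError, yaml.YAMLError) as exc:
        raise ConfigError(f"cannot read config {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError("config must be a YAML mapping")
    base = os.path.dirname(os.path.abspath(path))

    def resolve(p: Optional[str]) -> Optional[str]:
        if p is None:
            return None
        return p if os.path.isabs(p) else os.path.join(base, p)

    kwargs = dict(raw)
    syn_cfg = kwargs.pop("synthetic", None)
    if syn_cfg is not None:
        planted = [PlantedSignal(**p) if isinstance(p, dict) else PlantedSignal(*p)
                   for p in syn_cfg.pop("planted_signals", [])]
        sc = SyntheticConfig(**syn_cfg) if not planted else \
            SyntheticConfig(planted_signals=tuple(planted), **syn_cfg)
        kwargs["synthetic"] = sc
    for key in ("drug_synonyms_file", "label_pts_file"):
        if key in kwargs:
            kwargs[key.removesuffix("_file")] = _read_lines(resolve(kwargs.pop(key)))
    for key in ("input_dir", "meddra_map_path", "out_dir"):
        if kwargs.get(key):
            kwargs[key] = resolve(kwargs[key])
    if "date_range" in kwargs and kwargs["date_range"] is not None:
        kwargs["date_range"] = tuple(int(v) for v in kwargs["date_range"])
    try:
        cfg = RunConfig(**kwargs)
    except TypeError as exc:
        raise ConfigError(f"bad config key: {exc}") from exc
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# output writers (2-decimal TSV rendering + full-precision JSON companions)
# ---------------------------------------------------------------------------

def _fmt(x: float, nd: int = 2) -> str:
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return "NA"
    return f"{x:.{nd}f}"


def write_signals_tsv(results: Sequence[SignalResult], path: str,
                      full_precision_path: Optional[str] = None) -> None:
    cols = ("term", "level", "a", "ror", "ror_low", "ror_high", "prr", "prr_low",
            "prr_high", "chi2", "ror_signal", "prr_signal", "signal", "pct",
            "listed_on_label")
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in results:
            listed = "" if r.listed_on_label is None else str(r.listed_on_label)
            fh.write("\t".join([
                r.term, r.level, str(r.a), _fmt(r.ror), _fmt(r.ror_low),
                _fmt(r.ror_high), _fmt(r.prr), _fmt(r.prr_low), _fmt(r.prr_high),
                _fmt(r.chi2), str(r.ror_signal), str(r.prr_signal), str(r.signal),
                _fmt(r.pct), listed,
            ]) + "\n")
    if full_precision_path:
        payload = [dataclasses.asdict(r) for r in results]
        with open(full_precision_path, "w", encoding="utf-8", newline="\n") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True, allow_nan=True)
            fh.write("\n")


def write_descriptives_tsv(summary: DescriptiveSummary, path: str,
                           years_path: str) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("block\tcategory\tn\tpct\n")
        for block, rows in summary.blocks().items():
            for cat, (cnt, pct) in rows.items():
                fh.write(f"{block}\t{cat}\t{cnt}\t{pct:.1f}\n")
    with open(years_path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("year\tn\n")
        for year, cnt in summary.years.items():
            fh.write(f"{year}\t{cnt}\n")


# ---------------------------------------------------------------------------
# the run itself
# ---------------------------------------------------------------------------

def _config_hash(config: RunConfig) -> str:
    # out_dir is where results land, not part of the analysis definition
    payload = dataclasses.asdict(config)
    payload.pop("out_dir", None)
    blob = json.dumps(payload, default=str, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()


def run(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the manifest (also written as JSON)."""
    config.validate()
    os.makedirs(config.out_dir, exist_ok=True)
    counts: dict[str, int] = {}

    # stage 1: acquire raw tables
    if config.synthetic is not None:
        syn = dataclasses.replace(config.synthetic, seed=config.seed)
        tables, truth = generate(syn)
        write_ground_truth(truth, config.out_dir)
        mapping = (MedDRAMap.from_tsv(config.meddra_map_path)
                   if config.meddra_map_path else synthetic_meddra_map())
    else:
        names = ("demo", "drug", "reac", "outc", "ther", "indi")
        paths = {}
        for name in names:
            hits = [f for f in sorted(os.listdir(config.input_dir))
                    if f.lower().startswith(name) and f.lower().endswith(".txt")]
            if not hits:
                raise DataError(f"no {name.upper()}*.txt in {config.input_dir}")
            paths[name] = os.path.join(config.input_dir, hits[0])
        tables = read_quarter(paths)
        mapping = (MedDRAMap.from_tsv(config.meddra_map_path)
                   if config.meddra_map_path else None)
    counts["parsed_demo"] = len(tables.demo)

    # stage 2: dedup
    tables = deduplicate_tables(tables)
    counts["after_dedup"] = len(tables.demo)

    # stage 3: cohort
    reporter = set(config.reporter_filter) if config.reporter_filter else None
    target, background = build_cohort(
        tables, config.drug_synonyms, role=config.role,
        reporter_filter=reporter, date_range=config.date_range,
        match=config.match)
    counts["cohort_target"] = len(target)
    counts["cohort_background"] = len(background)

    # stage 4: descriptives
    hierarchy = (OutcomeHierarchy(tuple(config.outcome_order))
                 if config.outcome_order else OutcomeHierarchy())
    summary = summarize(target, hierarchy)
    write_descriptives_tsv(summary,
                           os.path.join(config.out_dir, "descriptives.tsv"),
                           os.path.join(config.out_dir, "yearly_counts.tsv"))

    # stage 5/6: PT and SOC signals
    pt_results = analyze(target, background, level="PT", unit=config.unit,
                         min_a=config.min_a, zero_policy=config.zero_policy,
                         yates=config.yates)
    if config.label_pts:
        pt_results = compare_to_label(pt_results, config.label_pts)
    write_signals_tsv(pt_results, os.path.join(config.out_dir, "pt_signals.tsv"),
                      os.path.join(config.out_dir, "pt_signals.json"))
    counts["pt_signals"] = sum(r.signal for r in pt_results)

    soc_results: list[SignalResult] = []
    if mapping is not None:
        soc_results = analyze(target, background, level="SOC", unit=config.unit,
                              mapping=mapping, min_a=config.min_a,
                              zero_policy=config.zero_policy, yates=config.yates)
        write_signals_tsv(soc_results,
                          os.path.join(config.out_dir, "soc_signals.tsv"),
                          os.path.join(config.out_dir, "soc_signals.json"))
        counts["soc_signals"] = sum(r.signal for r in soc_results)
        counts["unmapped_pts"] = len(set(mapping.unmapped))
    else:
        logger.warning("no MedDRA map given: SOC-level analysis skipped")

    # stage 7: ranking + label comparison
    top_freq = rank_signals(pt_results, by="frequency", k=config.top_k)
    top_strength = rank_signals(pt_results, by="strength", k=config.top_k)
    rows = [{"ranking": "frequency", "rank": i + 1, **dataclasses.asdict(r)}
            for i, r in enumerate(top_freq)]
    rows += [{"ranking": "strength", "rank": i + 1, **dataclasses.asdict(r)}
             for i, r in enumerate(top_strength)]
    pd.DataFrame(rows).to_csv(os.path.join(config.out_dir, "top_signals.tsv"),
                              sep="\t", index=False, lineterminator="\n",
                              float_format="%.4f")
    if config.label_pts:
        counts["unlisted_in_top_frequency"] = count_unlisted(top_freq)
        counts["unlisted_in_top_strength"] = count_unlisted(top_strength)

    # stage 8: time-to-onset
    sample = compute_tto(target, config.drug_synonyms, match=config.match)
    counts["tto_available"] = sample.n
    stats = summarize_tto(sample)
    fit = fit_weibull(sample)
    with open(os.path.join(config.out_dir, "tto_summary.tsv"), "w",
              encoding="utf-8", newline="\n") as fh:
        fh.write("n\tmedian\tq1\tq3\tmin\tmax\talpha\talpha_low\talpha_high"
                 "\tbeta\tbeta_low\tbeta_high\tfailure_type\n")
        fh.write("\t".join([
            str(stats["n"]), _fmt(stats["median"]), _fmt(stats["q1"]),
            _fmt(stats["q3"]), _fmt(stats["min"]), _fmt(stats["max"]),
            _fmt(fit.alpha), _fmt(fit.alpha_ci[0]), _fmt(fit.alpha_ci[1]),
            _fmt(fit.beta), _fmt(fit.beta_ci[0]), _fmt(fit.beta_ci[1]),
            fit.failure_type,
        ]) + "\n")
    labels, bin_counts, bin_pct = bin_tto(sample, config.tto_bins)
    with open(os.path.join(config.out_dir, "tto_bins.tsv"), "w",
              encoding="utf-8", newline="\n") as fh:
        fh.write("interval_days\tn\tpct\n")
        for lab, cnt, pct in zip(labels, bin_counts, bin_pct):
            fh.write(f"{lab}\t{cnt}\t{pct:.2f}\n")
    for reason, cnt in sample.exclusions.items():
        counts[f"tto_excluded_{reason}"] = cnt

    manifest = {
        "version": __version__,
        "config_sha256": _config_hash(config),
        "seed": config.seed,
        "unit": config.unit,
        "quantile_convention": "linear interpolation between order statistics",
        "counts": counts,
        "outputs": sorted(f for f in os.listdir(config.out_dir)
                          if f.endswith((".tsv", ".json")) and f != "manifest.json"),
    }
    with open(os.path.join(config.out_dir, "manifest.json"), "w",
              encoding="utf-8", newline="\n") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return manifest
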