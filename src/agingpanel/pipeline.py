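"""Config-driven orchestration of the full analysis.

One run reproduces the published workflow shape: per-gene adjusted screening
of the candidate list on a discovery cohort, panel selection with VIF
vetting, an additive panel model, stratified evaluation on every cohort,
harmonic-mean + BH integration of the per-stratum p-values across cohorts,
and a random-gene-set null on the discovery cohort — all consolidated into
one structured, reproducible report keyed by cohort and stratum labels.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time as _time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from . import __version__
from .io_cohort import (
    GRADE_GLEASON,
    GRADE_RISK,
    Cohort,
    CohortError,
    assemble_cohort,
    read_clinical,
    read_expression,
    zscore_genes,
)
from .integrate import integrate_subgroups
from .panel_eval import (
    AXIS_AGE,
    AXIS_GRADE,
    AXIS_RISK,
    StratumSpec,
    evaluate_strata,
    fit_panel,
    linear_predictor,
)
from .randnull import random_panel_null
from .screen import Panel, screen_genes, select_panel

logger = logging.getLogger("agingpanel")


class ConfigError(ValueError):
    pass


@dataclass
class CohortEntry:
    name: str
    expression_path: str
    clinical_path: str
    grade_kind: str = GRADE_GLEASON
    endpoint_label: str = "time-to-event"
    columns: dict = field(default_factory=dict)
    transpose: bool = False
    zscore: bool = False


@dataclass
class RunConfig:
    cohorts: list[CohortEntry]
    candidate_list_path: str
    discovery_cohort: str
    alpha: float = 0.05
    vif_threshold: float = 5.0
    age_cutoff: float = 60.0
    axes: list[str] = field(default_factory=lambda: [AXIS_GRADE, AXIS_AGE])
    adjust_covariates: list[str] = field(default_factory=lambda: ["grade", "age"])
    null_repetitions: int = 1000
    seed: int = 0
    out_dir: str = "agingpanel_run"

    def __post_init__(self) -> None:
        names = [c.name for c in self.cohorts]
        if len(set(names)) != len(names):
            raise ConfigError("duplicate cohort names in config")
        if self.discovery_cohort not in names:
            raise ConfigError(
                f"discovery cohort {self.discovery_cohort!r} not among "
                f"configured cohorts {names}")
        for ax in self.axes:
            if ax not in (AXIS_GRADE, AXIS_AGE, AXIS_RISK):
                raise ConfigError(f"unknown stratification axis {ax!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        cohorts = [CohortEntry(
            name=c["name"],
            expression_path=c["expression"],
            clinical_path=c["clinical"],
            grade_kind=c.get("grade_kind", GRADE_GLEASON),
            endpoint_label=c.get("endpoint_label", "time-to-event"),
            columns=c.get("columns", {}) or {},
            transpose=bool(c.get("transpose", False)),
            zscore=bool(c.get("zscore", False)),
        ) for c in raw["cohorts"]]
        return cls(
            cohorts=cohorts,
            candidate_list_path=raw["candidates"],
            discovery_cohort=raw["discovery"],
            alpha=float(raw.get("alpha", 0.05)),
            vif_threshold=float(raw.get("vif_threshold", 5.0)),
            age_cutoff=float(raw.get("age_cutoff", 60.0)),
            axes=list(raw.get("axes", [AXIS_GRADE, AXIS_AGE])),
            adjust_covariates=list(raw.get("adjust_covariates", ["grade", "age"])),
            null_repetitions=int(raw.get("null_repetitions", 1000)),
            seed=int(raw.get("seed", 0)),
            out_dir=str(raw.get("out", "agingpanel_run")),
        )

    def config_hash(self) -> str:
        payload = json.dumps(self, default=lambda o: o.__dict__, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_cohort(entry: CohortEntry) -> Cohort:
    expr = read_expression(entry.expression_path, transpose=entry.transpose)
    if entry.zscore:
        expr = zscore_genes(expr)
    clin = read_clinical(entry.clinical_path, entry.grade_kind, entry.columns)
    return assemble_cohort(expr, clin, entry.name, entry.endpoint_label)


def read_candidates(path: str | Path) -> list[str]:
    genes = [line.strip() for line in Path(path).read_text().splitlines()]
    genes = [g for g in genes if g and not g.startswith("#")]
    if not genes:
        raise ConfigError(f"candidate list {path} is empty")
    return genes


def _specs_for(cohort: Cohort, config: RunConfig) -> list[StratumSpec]:
    """Axes applicable to this cohort's grade encoding."""
    specs = []
    for ax in config.axes:
        if ax == AXIS_AGE:
            specs.append(StratumSpec(AXIS_AGE, age_cutoff=config.age_cutoff))
        elif ax == AXIS_GRADE and cohort.clinical.grade_kind == GRADE_GLEASON:
            specs.append(StratumSpec(AXIS_GRADE))
        elif ax == AXIS_RISK and cohort.clinical.grade_kind == GRADE_RISK:
            specs.append(StratumSpec(AXIS_RISK))
        else:
            logger.info("cohort %s: axis %r not applicable to grade encoding %r",
                        cohort.name, ax, cohort.clinical.grade_kind)
    return specs


def run_discovery(config: RunConfig, cohort: Cohort) -> tuple[Panel, dict]:
    """Screen -> select -> adjusted panel fit -> stratified evaluation."""
    screen = screen_genes(cohort, read_candidates(config.candidate_list_path),
                          config.adjust_covariates, config.alpha)
    panel = select_panel(screen.records, cohort, alpha=config.alpha,
                         vif_threshold=config.vif_threshold,
                         adjust_covariates=config.adjust_covariates)
    fragment = {
        "cohort": cohort.name,
        "screen_records": [r.to_dict() for r in screen.records],
        "missing_genes": screen.missing_genes,
        "panel": panel.to_dict(),
        "panel_fit": None,
        "strata": [],
        "risk_scores": {},
        "warnings": [],
    }
    if len(panel) == 0:
        fragment["warnings"].append("empty panel: no gene passed screening; "
                                    "downstream validation skipped")
        return panel, fragment
    adjusted_fit = fit_panel(cohort, panel, config.adjust_covariates)
    fragment["panel_fit"] = adjusted_fit.to_dict()
    fragment["risk_scores"] = linear_predictor(cohort, adjusted_fit)
    strata = evaluate_strata(cohort, panel, _specs_for(cohort, config))
    fragment["strata"] = [s.to_dict() for s in strata]
    return panel, fragment


def run_validation(config: RunConfig, panel: Panel, cohort: Cohort) -> dict:
    """Stratified panel evaluation of one validation cohort."""
    if len(panel) == 0:
        raise ConfigError("run_validation: empty panel")
    missing = [g for g in panel.genes if g not in set(cohort.expression.gene_ids)]
    if missing:
        raise CohortError(
            f"validation cohort {cohort.name!r} missing panel gene(s): {missing}")
    strata = evaluate_strata(cohort, panel, _specs_for(cohort, config))
    return {"cohort": cohort.name, "strata": [s.to_dict() for s in strata]}


def _collect_subgroup_ps(fragments: Sequence[dict]) -> dict[str, list[float]]:
    """Per-(axis,label) lists of analyzable per-cohort global Wald p-values."""
    table: dict[str, list[float]] = {}
    for frag in fragments:
        for s in frag["strata"]:
            if not s["analyzable"] or not np.isfinite(s["global_wald_p"]):
                continue
            key = f'{s["axis"]}:{s["label"]}'
            table.setdefault(key, []).append(float(s["global_wald_p"]))
    return table


def run_all(config: RunConfig, cohorts: Sequence[Cohort] | None = None) -> dict:
    """Full pipeline; returns the consolidated report dictionary.

    ``cohorts`` may supply already-assembled cohorts (e.g. simulated ones);
    otherwise every configured cohort is loaded from disk.
    """
    t0 = _time.perf_counter()
    if cohorts is None:
        cohorts = [load_cohort(e) for e in config.cohorts]
    by_name = {c.name: c for c in cohorts}
    for entry in config.cohorts:
        if entry.name not in by_name:
            raise ConfigError(f"cohort {entry.name!r} was not provided/loadable")
    discovery = by_name[config.discovery_cohort]
    logger.info("run_all: seed=%d config_hash=%s", config.seed, config.config_hash())

    report: dict = {
        "software_version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": json.loads(json.dumps(config, default=lambda o: o.__dict__)),
        "stages": {},
        "warnings": [],
    }

    t = _time.perf_counter()
    panel, discovery_frag = run_discovery(config, discovery)
    logger.info("stage discovery: %.2fs", _time.perf_counter() - t)
    report["stages"]["discovery"] = discovery_frag

    if len(panel) == 0:
        report["warnings"].append("empty panel; validation, integration and "
                                  "random null skipped")
        return report

    t = _time.perf_counter()
    validation_frags = []
    for cohort in cohorts:
        if cohort.name == discovery.name:
            continue
        validation_frags.append(run_validation(config, panel, cohort))
    logger.info("stage validation: %.2fs", _time.perf_counter() - t)
    report["stages"]["validation"] = validation_frags

    t = _time.perf_counter()
    subgroup_ps = _collect_subgroup_ps([discovery_frag] + validation_frags)
    if subgroup_ps:
        integration = integrate_subgroups(subgroup_ps)
        report["stages"]["integration"] = [r.to_dict() for r in integration]
    else:
        report["stages"]["integration"] = []
        report["warnings"].append("no analyzable strata; integration skipped")
    logger.info("stage integration: %.2fs", _time.perf_counter() - t)

    t = _time.perf_counter()
    crude_fit = fit_panel(discovery, panel, ())
    null = random_panel_null(
        discovery, k=len(panel), repetitions=config.null_repetitions,
        observed_p=float(crude_fit.global_wald_p), seed=config.seed)
    report["stages"]["random_null"] = null.to_dict()
    logger.info("stage random_null: %.2fs", _time.perf_counter() - t)

    logger.info("run_all: total %.2fs", _time.perf_counter() - t0)
    return report


# ---------------------------------------------------------------------------
# Report serialization
# ---------------------------------------------------------------------------


def report_json(report: dict) -> str:
    """Canonical (byte-stable for a fixed config+seed) JSON rendering."""
    return json.dumps(report, sort_keys=True, indent=1, allow_nan=True)


def write_report(report: dict, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(report_json(report))
    (out / "summary.txt").write_text(render_summary(report))
    disc = report["stages"].get("discovery")
    if disc and disc["screen_records"]:
        lines = ["gene\tcrude_hr\tcrude_p\tadj_hr\tadj_p\tn_used"]
        for r in disc["screen_records"]:
            lines.append(f'{r["gene"]}\t{r["crude_hr"]:.6g}\t{r["crude_p"]:.6g}'
                         f'\t{r["adj_hr"]:.6g}\t{r["adj_p"]:.6g}\t{r["n_used"]}')
        (out / "screen_records.tsv").write_text("\n".join(lines) + "\n")
    strata_rows = ["cohort\taxis\tlabel\tn\tn_events\tglobal_wald_p\tanalyzable"]
    frags = [disc] if disc else []
    frags += report["stages"].get("validation", [])
    for frag in frags:
        for s in frag.get("strata", []):
            strata_rows.append(
                f'{frag["cohort"]}\t{s["axis"]}\t{s["label"]}\t{s["n"]}'
                f'\t{s["n_events"]}\t{s["global_wald_p"]:.6g}\t{s["analyzable"]}')
    (out / "strata.tsv").write_text("\n".join(strata_rows) + "\n")
    return out / "report.json"


def render_summary(report: dict) -> str:
    """Human-readable digest; every number is read from the report fields."""
    lines = [
        f"agingpanel {report['software_version']} run summary",
        f"seed={report['seed']} config_hash={report['config_hash']}",
        "",
    ]
    disc = report["stages"].get("discovery")
    if disc:
        panel = disc["panel"]
        lines.append(f"discovery cohort: {disc['cohort']}")
        lines.append(f"screened candidates: {len(disc['screen_records'])} "
                     f"(missing from matrix: {len(disc['missing_genes'])})")
        lines.append(f"selected panel (alpha={panel['alpha']:g}): "
                     f"{', '.join(panel['genes']) or '(empty)'}")
        if disc.get("panel_fit"):
            fit = disc["panel_fit"]
            lines.append(f"adjusted panel model: global Wald p = "
                         f"{fit['global_wald_p']:.3g} "
                         f"(df={fit['global_df']}, n={fit['n']})")
        lines.append("")
    for res in report["stages"].get("integration", []):
        lines.append(f"integration {res['subgroup']}: raw harmonic-mean p = "
                     f"{res['raw_integrated_p']:.4g}, FDR-adjusted p = "
                     f"{res['fdr_adjusted_p']:.4g} "
                     f"(m={res['family_size']}, cohorts={len(res['cohort_ps'])})")
    null = report["stages"].get("random_null")
    if null:
        lines.append("")
        lines.append(f"random {null['panel_size']}-gene null "
                     f"(R={null['repetitions']}): observed p = "
                     f"{null['observed_p']:.3g}, nominal p = {null['nominal_p']:.4g}")
    for w in report.get("warnings", []):
        lines.append(f"WARNING: {w}")
    return "\n".join(lines) + "\n"
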