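"""Multivariable additive panel models on whole cohorts and within strata.

The same fitting stage serves training (on the discovery cohort) and
validation (on independent cohorts): one additive Cox model whose inputs are
all panel genes, optionally plus adjustment covariates, with a global Wald
test over the gene terms. Stratified evaluation partitions a cohort by a
clinical axis — Gleason grade (low = 3+3/3+4 vs the rest), chronological age
(<= cutoff vs >), or cytogenetic risk (favorable vs unfavorable) — and
refits the panel model within each stratum. Within-stratum fits are
unadjusted by default; a flag re-enables adjustment by the non-stratifying
covariate for sensitivity analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .coxcore import Design, CoxFit, fit_cox
from .io_cohort import (
    GRADE_GLEASON,
    GRADE_RISK,
    RISK_FAVORABLE,
    RISK_UNFAVORABLE,
    Cohort,
    CohortError,
)
from .screen import Panel

logger = logging.getLogger("agingpanel")

AXIS_GRADE = "grade"
AXIS_AGE = "age"
AXIS_RISK = "risk"

#: Gleason pairs forming the clinically least-aggressive (low-grade) group
LOW_GLEASON_PAIRS = {(3, 3), (3, 4)}

AGE_CUTOFF_PC = 60.0
AGE_CUTOFF_AML = 56.0


@dataclass
class StratumSpec:
    """One stratification axis; the rule assigns every sample to one stratum."""

    axis: str                      # AXIS_GRADE, AXIS_AGE or AXIS_RISK
    age_cutoff: float | None = None

    def __post_init__(self) -> None:
        if self.axis not in (AXIS_GRADE, AXIS_AGE, AXIS_RISK):
            raise CohortError(f"unknown stratification axis {self.axis!r}")
        if self.axis == AXIS_AGE and self.age_cutoff is None:
            raise CohortError("age stratification requires a cutoff")

    def labels_for(self, cohort: Cohort) -> np.ndarray:
        d = cohort.clinical.data
        if self.axis == AXIS_AGE:
            c = self.age_cutoff
            return np.where(d["age"].to_numpy(float) <= c,
                            f"age<={c:g}", f"age>{c:g}")
        if self.axis == AXIS_GRADE:
            if cohort.clinical.grade_kind != GRADE_GLEASON:
                raise CohortError("grade axis requires Gleason-encoded clinical data")
            pairs = list(zip(d["gleason_major"], d["gleason_minor"]))
            return np.where([tuple(p) in LOW_GLEASON_PAIRS for p in pairs],
                            "low_gleason", "high_gleason")
        if cohort.clinical.grade_kind != GRADE_RISK:
            raise CohortError("risk axis requires risk-encoded clinical data")
        return np.where(d["risk_category"] == RISK_FAVORABLE,
                        RISK_FAVORABLE, RISK_UNFAVORABLE)

    def stratum_names(self) -> list[str]:
        if self.axis == AXIS_AGE:
            c = self.age_cutoff
            return [f"age<={c:g}", f"age>{c:g}"]
        if self.axis == AXIS_GRADE:
            return ["low_gleason", "high_gleason"]
        return [RISK_FAVORABLE, RISK_UNFAVORABLE]


@dataclass
class StratumResult:
    axis: str
    label: str
    n: int
    n_events: int
    fit: CoxFit | None
    global_wald_p: float
    analyzable: bool
    reason: str = ""

    def to_dict(self) -> dict:
        return {
            "axis": self.axis, "label": self.label,
            "n": self.n, "n_events": self.n_events,
            "global_wald_p": self.global_wald_p,
            "analyzable": self.analyzable, "reason": self.reason,
            "fit": self.fit.to_dict() if self.fit is not None else None,
        }


def fit_panel(cohort: Cohort, panel: Panel,
              adjust_covariates: Sequence[str] = ()) -> CoxFit:
    """One additive Cox model over all panel genes (plus covariates if any),
    with the global Wald test taken over the gene terms."""
    if len(panel) == 0:
        raise CohortError("fit_panel: empty panel")
    missing = [g for g in panel.genes if g not in set(cohort.expression.gene_ids)]
    if missing:
        raise CohortError(
            f"cohort {cohort.name!r} is missing panel gene(s): {missing}")
    X = cohort.expression.rows_for(panel.genes)
    Z = cohort.covariate_matrix(adjust_covariates)
    design = Design(
        np.hstack([X, Z]), cohort.time, cohort.event,
        term_names=list(panel.genes) + list(adjust_covariates),
        gene_terms=list(panel.genes),
    )
    return fit_cox(design, global_terms=list(panel.genes))


def linear_predictor(cohort: Cohort, fit: CoxFit,
                     genes_only: bool = True) -> dict[str, float]:
    """Per-patient risk score: the fitted linear predictor sum beta_g x_g."""
    terms = fit.global_terms if genes_only else fit.term_names
    idx = [fit.term_names.index(t) for t in terms]
    X = cohort.expression.rows_for([t for t in terms])
    scores = X @ fit.beta[idx]
    return {s: float(v) for s, v in zip(cohort.sample_ids, scores)}


def stratify(cohort: Cohort, spec: StratumSpec) -> dict[str, Cohort | None]:
    """Disjoint exhaustive partition of the cohort under the stratum rule.

    Strata with zero samples or zero events are returned as ``None`` (marked
    not-analyzable downstream) so the remaining strata still proceed.
    """
    labels = spec.labels_for(cohort)
    out: dict[str, Cohort | None] = {}
    ids = np.asarray(cohort.sample_ids)
    for name in spec.stratum_names():
        members = list(ids[labels == name])
        if not members:
            logger.warning("stratify(%s/%s): empty stratum", cohort.name, name)
            out[name] = None
            continue
        n_ev = int(cohort.event[labels == name].sum())
        if n_ev == 0:
            logger.warning("stratify(%s/%s): no events (n=%d)",
                           cohort.name, name, len(members))
            out[name] = None
            continue
        out[name] = cohort.subset(members, name=f"{cohort.name}/{name}")
        logger.info("stratify(%s): %s n=%d events=%d",
                    cohort.name, name, len(members), n_ev)
    return out


def stratum_sizes(cohort: Cohort, spec: StratumSpec) -> dict[str, int]:
    """Per-stratum sample counts under the rule (including empty strata)."""
    labels = spec.labels_for(cohort)
    return {name: int((labels == name).sum()) for name in spec.stratum_names()}


def evaluate_strata(
    cohort: Cohort,
    panel: Panel,
    specs: Sequence[StratumSpec],
    adjust_covariates: Sequence[str] = (),
) -> list[StratumResult]:
    """Fit the panel model within every analyzable stratum of every spec.

    Fit failures surface as flagged results (``analyzable=False``), never
    silently.
    """
    results: list[StratumResult] = []
    labels_by_spec = {id(s): s.labels_for(cohort) for s in specs}
    for spec in specs:
        labels = labels_by_spec[id(spec)]
        strata = stratify(cohort, spec)
        for name in spec.stratum_names():
            mask = labels == name
            n = int(mask.sum())
            n_ev = int(cohort.event[mask].sum())
            sub = strata[name]
            if sub is None:
                results.append(StratumResult(spec.axis, name, n, n_ev, None,
                                             float("nan"), False,
                                             "empty or zero-event stratum"))
                continue
            try:
                fit = fit_panel(sub, panel, adjust_covariates)
            except (CohortError, np.linalg.LinAlgError) as exc:
                results.append(StratumResult(spec.axis, name, n, n_ev, None,
                                             float("nan"), False, str(exc)))
                continue
            ok = fit.converged
            results.append(StratumResult(
                spec.axis, name, n, n_ev, fit, float(fit.global_wald_p),
                ok, "" if ok else ",".join(fit.flags)))
    return results
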