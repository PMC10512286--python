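"""Per-gene adjusted Cox screening of a candidate list and panel selection.

Each candidate gene is fitted twice against the cohort's endpoint: crude
(gene alone) and adjusted (gene + grade + age, or whatever covariates are
requested), keeping both p-values so the two-stage funnel — crude p < alpha,
then adjusted p < alpha — is reproducible from a single pass. Selection
thresholds the (adjusted, by default) per-gene hazard p-value at alpha with
no multiple-testing correction, which is the discovery convention this
pipeline mirrors; a Benjamini-Hochberg switch is available for users who
want it. Selected genes are then jointly checked for multicollinearity via
VIF before they are declared a panel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .coxcore import Design, fit_cox, vif
from .io_cohort import Cohort

logger = logging.getLogger("agingpanel")


class ScreenError(ValueError):
    pass


class PanelCollinearityError(ValueError):
    """Raised when a selected panel fails the VIF threshold."""


@dataclass
class ScreenRecord:
    gene: str
    crude_hr: float
    crude_p: float
    adj_hr: float
    adj_p: float
    n_used: int

    def to_dict(self) -> dict:
        return {
            "gene": self.gene,
            "crude_hr": self.crude_hr, "crude_p": self.crude_p,
            "adj_hr": self.adj_hr, "adj_p": self.adj_p,
            "n_used": self.n_used,
        }


@dataclass
class ScreenResult:
    records: list[ScreenRecord]
    missing_genes: list[str]
    adjust_covariates: list[str]
    cohort_name: str


@dataclass
class Panel:
    """Ordered gene panel surviving the screen, with selection provenance."""

    genes: list[str]
    alpha: float
    adjust_covariates: list[str]
    vif_values: dict[str, float]
    source_cohort: str

    def __len__(self) -> int:
        return len(self.genes)

    def to_dict(self) -> dict:
        return {
            "genes": self.genes,
            "alpha": self.alpha,
            "adjust_covariates": self.adjust_covariates,
            "vif_values": self.vif_values,
            "source_cohort": self.source_cohort,
        }


def _single_gene_fit(cohort: Cohort, gene: str,
                     covariates: Sequence[str]) -> tuple[float, float]:
    x = cohort.expression.rows_for([gene])
    Z = cohort.covariate_matrix(covariates)
    X = np.hstack([x, Z])
    names = [gene] + list(covariates)
    design = Design(X, cohort.time, cohort.event, names, gene_terms=[gene])
    fit = fit_cox(design)
    term = fit.term(gene)
    if not fit.converged:
        logger.warning("screen: non-converged fit for gene %s (%s)",
                       gene, ",".join(fit.flags))
        return float("nan"), float("nan")
    return term["hr"], term["wald_p"]


def screen_genes(
    cohort: Cohort,
    candidates: Sequence[str],
    adjust_covariates: Sequence[str] = ("grade", "age"),
    alpha: float = 0.05,
) -> ScreenResult:
    """Crude and adjusted univariable Cox fits for every present candidate.

    Candidates absent from the expression matrix are collected in a side
    report rather than silently dropped; zero present candidates is an error.
    Screening is per-gene independent: candidate order only orders records.
    """
    if not candidates:
        raise ScreenError("empty candidate list")
    present = [g for g in candidates if g in set(cohort.expression.gene_ids)]
    missing = [g for g in candidates if g not in set(cohort.expression.gene_ids)]
    if not present:
        raise ScreenError("no candidate gene present in the expression matrix")
    if missing:
        logger.info("screen_genes(%s): %d candidate(s) missing from matrix: %s",
                    cohort.name, len(missing), missing[:5])
    records = []
    for gene in present:
        crude_hr, crude_p = _single_gene_fit(cohort, gene, [])
        if adjust_covariates:
            adj_hr, adj_p = _single_gene_fit(cohort, gene, adjust_covariates)
        else:
            adj_hr, adj_p = crude_hr, crude_p
        records.append(ScreenRecord(gene, crude_hr, crude_p, adj_hr, adj_p,
                                    cohort.n_samples))
    return ScreenResult(records, missing, list(adjust_covariates), cohort.name)


def bh_gene_selection(records: Sequence[ScreenRecord], alpha: float,
                      use_adjusted: bool = True) -> list[ScreenRecord]:
    """Optional BH-corrected selection across the screened candidates."""
    from .integrate import bh_fdr  # local import to avoid a cycle

    ps = [r.adj_p if use_adjusted else r.crude_p for r in records]
    adj = bh_fdr(ps)
    return [r for r, q in zip(records, adj) if q < alpha]


def select_panel(
    records: Sequence[ScreenRecord],
    cohort: Cohort,
    alpha: float = 0.05,
    use_adjusted: bool = True,
    vif_threshold: float = 5.0,
    bh_correct: bool = False,
    adjust_covariates: Sequence[str] = ("grade", "age"),
) -> Panel:
    """Threshold the screen at alpha and vet the selection for collinearity.

    Returns an empty panel (with a warning) when nothing passes; raises
    ``PanelCollinearityError`` if any pairwise-joint VIF reaches the
    threshold.
    """
    if not records:
        raise ScreenError("select_panel: no screen records")
    if bh_correct:
        selected = bh_gene_selection(records, alpha, use_adjusted)
    else:
        selected = [r for r in records
                    if np.isfinite(r.adj_p if use_adjusted else r.crude_p)
                    and (r.adj_p if use_adjusted else r.crude_p) < alpha]
    selected.sort(key=lambda r: (r.adj_p if use_adjusted else r.crude_p, r.gene))
    genes = [r.gene for r in selected]
    covs = list(adjust_covariates)
    if not genes:
        logger.warning("select_panel: no gene passed alpha=%.3g; empty panel", alpha)
        return Panel([], alpha, covs, {}, cohort.name)

    vif_values: dict[str, float] = {}
    if len(genes) >= 2:
        X = cohort.expression.rows_for(genes)
        report = vif(X, names=genes, threshold=vif_threshold)
        vif_values = {g: report[g]["vif"] for g in genes}
        failing = [g for g in genes if not report[g]["passes"]]
        if failing:
            raise PanelCollinearityError(
                f"panel rejected: VIF >= {vif_threshold} for gene(s) {failing}")
    return Panel(genes, alpha, covs, vif_values, cohort.name)
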