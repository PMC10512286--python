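import numpy as np
import pytest

import agingpanel as ap
from agingpanel.io_cohort import CohortError
from agingpanel.panel_eval import (
    AXIS_AGE,
    AXIS_GRADE,
    StratumSpec,
    evaluate_strata,
    fit_panel,
    linear_predictor,
    stratify,
    stratum_sizes,
)
from agingpanel.screen import Panel, screen_genes
from agingpanel.simulate import SimConfig, simulate_cohort, with_overrides
from conftest import make_cohort, merge_cohorts


def _panel(genes):
    return Panel(list(genes), alpha=0.05, adjust_covariates=[],
                 vif_values={}, source_cohort="test")


def test_single_gene_panel_reduces_to_crude_screen_fit(toy_cohort):
    rec = screen_genes(toy_cohort, ["G0"], adjust_covariates=()).records[0]
    fit = fit_panel(toy_cohort, _panel(["G0"]))
    assert fit.global_wald_p == pytest.approx(rec.crude_p, abs=1e-10)
    assert np.exp(fit.beta[0]) == pytest.approx(rec.crude_hr, abs=1e-10)


def test_empty_panel_and_missing_gene_are_errors(toy_cohort):
    with pytest.raises(CohortError, match="empty"):
        fit_panel(toy_cohort, _panel([]))
    with pytest.raises(CohortError, match="MISSING"):
        fit_panel(toy_cohort, _panel(["G0", "MISSING"]))


def test_stratification_is_a_partition(pc_cohort):
    spec = StratumSpec(AXIS_AGE, age_cutoff=60.0)
    strata = stratify(pc_cohort, spec)
    ids = []
    for sub in strata.values():
        if sub is not None:
            ids.extend(sub.sample_ids)
    sizes = stratum_sizes(pc_cohort, spec)
    assert sum(sizes.values()) == pc_cohort.n_samples
    assert sorted(ids) == sorted(pc_cohort.sample_ids)  # multiset equality


def test_age_cutoff_below_minimum_flags_empty_stratum(pc_cohort, caplog):
    spec = StratumSpec(AXIS_AGE, age_cutoff=0.5)
    strata = stratify(pc_cohort, spec)
    assert strata["age<=0.5"] is None
    assert strata["age>0.5"] is not None
    results = evaluate_strata(pc_cohort, _panel(["CD44"]), [spec])
    flagged = [r for r in results if not r.analyzable]
    assert len(flagged) == 1 and flagged[0].n == 0


def test_all_inclusive_stratum_equals_whole_cohort_fit(pc_cohort):
    panel = _panel(["CD44", "GADD45B"])
    spec = StratumSpec(AXIS_AGE, age_cutoff=200.0)  # everyone "younger"
    results = evaluate_strata(pc_cohort, panel, [spec])
    whole = fit_panel(pc_cohort, panel)
    analyzable = [r for r in results if r.analyzable]
    assert len(analyzable) == 1
    assert analyzable[0].n == pc_cohort.n_samples
    assert analyzable[0].global_wald_p == pytest.approx(
        whole.global_wald_p, abs=1e-12)


def test_strata_sizes_sum_to_cohort_in_results(pc_cohort):
    results = evaluate_strata(pc_cohort, _panel(["CD44"]),
                              [StratumSpec(AXIS_GRADE)])
    assert sum(r.n for r in results) == pc_cohort.n_samples


def test_zero_event_stratum_marked_not_analyzable():
    cohort = make_cohort(n=40, seed=2)
    # push all events into the low-age half
    d = cohort.clinical.data
    d.loc[d["age"] > d["age"].median(), "event"] = 0
    if d["event"].sum() == 0:
        d.loc[0, "event"] = 1
    results = evaluate_strata(cohort, _panel(["G0"]),
                              [StratumSpec(AXIS_AGE,
                                           age_cutoff=float(d["age"].median()))])
    assert any(not r.analyzable for r in results)
    assert any(r.analyzable for r in results)


def test_stratum_specific_effect_is_localized():
    """An effect planted only in the high-Gleason stratum shows up there and
    not in the low-Gleason stratum."""
    genes = ["P1", "P2", "P3", "P4"]
    high_cfg = SimConfig(
        n_samples=200, n_genes=20, candidate_genes=genes,
        signal_genes={g: float(np.log(0.4)) for g in genes},
        grade_probs={"4+3": 0.5, "4+5": 0.5}, gamma_grade=0.0,
        target_censoring=0.4, name="high")
    low_cfg = with_overrides(high_cfg, signal_genes={},
                             grade_probs={"3+3": 0.4, "3+4": 0.6}, name="low")
    hits = 0
    for s in range(100):
        high = simulate_cohort(with_overrides(high_cfg, seed=8000 + s)).cohort
        low = simulate_cohort(with_overrides(low_cfg, seed=9000 + s)).cohort
        merged = merge_cohorts(high, low)
        results = {r.label: r for r in
                   evaluate_strata(merged, _panel(genes), [StratumSpec(AXIS_GRADE)])}
        if (results["high_gleason"].global_wald_p < 0.05
                and results["low_gleason"].global_wald_p > 0.05):
            hits += 1
    assert hits >= 80


def test_linear_predictor_scores_every_patient(pc_cohort):
    fit = fit_panel(pc_cohort, _panel(["CD44", "STAT3"]))
    scores = linear_predictor(pc_cohort, fit)
    assert set(scores) == set(pc_cohort.sample_ids)
    x = pc_cohort.expression.rows_for(["CD44", "STAT3"])
    expected = x @ fit.beta[:2]
    np.testing.assert_allclose(
        [scores[s] for s in pc_cohort.sample_ids], expected)
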