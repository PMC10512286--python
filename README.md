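# agingpanel

Survival biomarker panel discovery and cross-cohort validation for
transcriptomic gene signatures, built around covariate-adjusted Cox
proportional-hazards modelling.

## The problem

Given a curated candidate gene list (for example, genes implicated in
biological aging), per-cohort normalized expression matrices, and clinical
tables with a right-censored time-to-event endpoint (time to biochemical
recurrence in prostate cancer, overall survival in AML), the pipeline asks:
which candidates carry prognostic information beyond established clinical
factors, do they work as one additive panel, in which patient subgroups is
the association concentrated, and is the panel better than chance?

The workflow, aimed at computational biologists doing survival biomarker
work, is:

1. **Screening.** For each candidate gene *g*, fit univariable Cox models
   `h(t | x) = h0(t) exp(β_g x_g)` crude and adjusted for grade (Gleason sum
   or binary cytogenetic risk) and chronological age; keep genes with
   adjusted hazard p < α (default 0.05, uncorrected by design, with an
   optional Benjamini–Hochberg switch).
2. **Panel selection.** Vet the surviving genes jointly for
   multicollinearity with variance inflation factors, `VIF_j = 1/(1−R²_j)`,
   rejecting panels with any VIF ≥ 5.
3. **Additive panel model.** Fit one multivariable model over all panel
   genes (± covariates) and report the global Wald statistic
   `β_S' Cov(β_S)⁻¹ β_S ~ χ²(|S|)` over the gene terms, plus per-patient
   risk scores `Σ β̂_g x_g`.
4. **Stratified validation.** Partition each cohort by grade (Gleason
   3+3/3+4 vs higher), age (≤ cutoff vs >), or cytogenetic risk, and refit
   the panel within each stratum, on the discovery and validation cohorts.
5. **Integration.** Combine each subgroup's per-cohort stratified Wald
   p-values with the harmonic mean `n / Σ(1/p_i)` and BH-adjust across the
   subgroup family (m = 4).
6. **Random-model null.** Compare the panel's global Wald p against R
   panels of the same size drawn uniformly from all genes in the matrix;
   the nominal p is the fraction of random panels that reach or outperform
   it.

Everything is estimated by a from-scratch Newton–Raphson maximizer of the
Efron (or Breslow) partial likelihood with observed-information standard
errors; a seeded proportional-hazards simulator generates cohorts with
known planted effects so every stage is testable end to end.

## Worked example

```python
import numpy as np
import agingpanel as ap

# a prostate-like synthetic discovery cohort: n=138, ~25% events,
# four planted prognostic genes among 52 candidates in a 1000-gene universe
sim = ap.simulate_cohort(ap.preset("pc_like", seed=1))
cohort = sim.cohort
print(cohort.n_samples, cohort.n_events)        # 138 38

res = ap.screen_genes(cohort, ap.EXAMPLE_CANDIDATE_GENES)
panel = ap.select_panel(res.records, cohort)
print(panel.genes)
# ['STAT3', 'CD44', 'AGING24', 'GADD45B', 'AGING29']
print(max(panel.vif_values.values()))           # 1.21  (all well under 5)

fit = ap.fit_panel(cohort, panel, ("grade", "age"))
print(fit.global_wald_p)                        # 2.45e-09
```

At this sample size the screen recovers three of the four planted genes
(the weakest, GFAP at hazard ratio 1.30, is underpowered at n=138) plus two
false positives — the expected behaviour of an uncorrected α=0.05 screen of
52 candidates. The adjusted additive panel model is jointly highly
significant. The same objects drive stratified evaluation
(`ap.evaluate_strata`), cross-cohort integration
(`ap.integrate_subgroups`), and the random-panel null
(`ap.random_panel_null`), or run the whole workflow from a YAML config:

```bash
agingpanel simulate --preset pc_like --seed 17 --out cohort1/
agingpanel run-all --config run.yaml --seed 17 --out results/
```

which writes `report.json`, `screen_records.tsv`, `strata.tsv` and a
human-readable `summary.txt`.

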