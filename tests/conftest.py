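import numpy as np
import pandas as pd
import pytest

import agingpanel as ap
from agingpanel.io_cohort import GRADE_GLEASON, ClinicalTable, ExpressionMatrix


def make_cohort(n=60, n_genes=6, seed=0, beta=None, censor_rate=0.5,
                name="toy", grade_kind=GRADE_GLEASON):
    """Small hand-built cohort with optional single-gene effect."""
    rng = np.random.default_rng(seed)
    genes = [f"G{i}" for i in range(n_genes)]
    samples = [f"S{i:03d}" for i in range(n)]
    values = rng.standard_normal((n_genes, n))
    eta = np.zeros(n)
    if beta:
        for g, b in beta.items():
            eta += b * values[genes.index(g)]
    T = rng.exponential(1.0 / np.exp(eta))
    C = rng.exponential(1.0 / censor_rate, n)
    time = np.minimum(T, C)
    event = (T <= C).astype(int)
    clin = pd.DataFrame({
        "sample_id": samples, "time": time, "event": event,
        "age": rng.normal(60, 8, n),
    })
    if grade_kind == GRADE_GLEASON:
        majors = rng.choice([3, 4], n)
        clin["gleason_major"] = majors
        clin["gleason_minor"] = rng.choice([3, 4], n)
    else:
        clin["risk_category"] = rng.choice(["favorable", "unfavorable"], n)
    expr = ExpressionMatrix(genes, samples, values)
    return ap.assemble_cohort(expr, ClinicalTable(clin, grade_kind), name)


def merge_cohorts(a, b, name="merged"):
    """Stack two cohorts sharing a gene list into one (distinct sample ids)."""
    assert a.expression.gene_ids == b.expression.gene_ids
    ids = [f"A_{s}" for s in a.sample_ids] + [f"B_{s}" for s in b.sample_ids]
    values = np.hstack([a.expression.values, b.expression.values])
    expr = ExpressionMatrix(list(a.expression.gene_ids), ids, values)
    ca = a.clinical.data.copy()
    ca["sample_id"] = [f"A_{s}" for s in ca["sample_id"]]
    cb = b.clinical.data.copy()
    cb["sample_id"] = [f"B_{s}" for s in cb["sample_id"]]
    clin = ClinicalTable(pd.concat([ca, cb], ignore_index=True),
                         a.clinical.grade_kind)
    return ap.assemble_cohort(expr, clin, name)


@pytest.fixture(scope="session")
def toy_cohort():
    return make_cohort(seed=11, beta={"G0": -0.7})


@pytest.fixture(scope="session")
def pc_cohort():
    """One prostate-like synthetic cohort with the preset's planted effects."""
    return ap.simulate_cohort(ap.preset("pc_like", seed=42)).cohort
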