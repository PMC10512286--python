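import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

import agingpanel as ap
from agingpanel.coxcore import (
    BRESLOW,
    EFRON,
    Design,
    DesignError,
    _loglik_ties,
    _prepare,
    fit_cox,
    log_partial_likelihood,
    score_test_at_zero,
    vif,
    wald_global,
)


def _toy_design(seed=0, n=80, p=2):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    eta = 0.6 * X[:, 0]
    T = rng.exponential(1.0 / np.exp(eta))
    C = rng.exponential(1.5, n)
    return Design(X, np.minimum(T, C), (T <= C).astype(int),
                  [f"x{j}" for j in range(p)])


def test_sign_symmetry_of_covariate():
    d = _toy_design(seed=1, p=1)
    fit = fit_cox(d)
    d_neg = Design(-d.X, d.time, d.event, ["x0"])
    fit_neg = fit_cox(d_neg)
    assert fit_neg.beta[0] == pytest.approx(-fit.beta[0], abs=1e-10)
    assert fit_neg.wald_p[0] == pytest.approx(fit.wald_p[0], abs=1e-12)
    assert fit_neg.log_partial_likelihood == pytest.approx(
        fit.log_partial_likelihood, abs=1e-10)


def test_rescaling_covariate_rescales_beta_only():
    d = _toy_design(seed=2, p=1)
    fit = fit_cox(d)
    c = 7.5
    fit_scaled = fit_cox(Design(d.X * c, d.time, d.event, ["x0"]))
    assert fit_scaled.beta[0] == pytest.approx(fit.beta[0] / c, rel=1e-8)
    assert fit_scaled.wald_p[0] == pytest.approx(fit.wald_p[0], abs=1e-10)


def test_newton_matches_golden_section_on_six_subjects():
    time = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
    event = np.array([1, 1, 1, 1, 1, 1])
    x = np.array([[1.0], [0.0], [1.0], [0.0], [0.0], [1.0]])
    d = Design(x, time, event, ["x"])
    fit = fit_cox(d)
    res = minimize_scalar(lambda b: -log_partial_likelihood(d, np.array([b])),
                          bounds=(-10, 10), method="bounded",
                          options={"xatol": 1e-8})
    assert fit.beta[0] == pytest.approx(res.x, abs=1e-4)


def test_matches_lifelines_including_ties():
    lifelines = pytest.importorskip("lifelines")
    d = _toy_design(seed=3, n=120, p=3)
    tied_time = np.ceil(d.time * 4)  # force tied event times
    for t in (d.time, tied_time):
        design = Design(d.X, t, d.event, d.term_names)
        fit = fit_cox(design)
        df = pd.DataFrame(d.X, columns=d.term_names)
        df["T"], df["E"] = t, d.event
        cph = lifelines.CoxPHFitter().fit(df, "T", "E")
        np.testing.assert_allclose(fit.beta, cph.params_.values, atol=1e-6)
        np.testing.assert_allclose(fit.se, cph.standard_errors_.values, atol=1e-6)


def test_score_test_equals_logrank_for_binary_covariate():
    lifelines = pytest.importorskip("lifelines")
    from lifelines.statistics import logrank_test

    rng = np.random.default_rng(5)
    for _ in range(5):
        n = rng.integers(10, 20)
        x = rng.integers(0, 2, n).astype(float)
        if x.std() == 0:
            continue
        time = rng.permutation(np.arange(1, n + 1)).astype(float)  # no ties
        event = rng.integers(0, 2, n)
        if event.sum() == 0:
            continue
        d = Design(x[:, None], time, event, ["g"])
        stat, _ = score_test_at_zero(d)
        lr = logrank_test(time[x == 0], time[x == 1],
                          event[x == 0], event[x == 1])
        assert stat == pytest.approx(lr.test_statistic, abs=1e-8)


def test_efron_and_breslow_agree_without_ties():
    d = _toy_design(seed=7, p=2)
    t, dd, X, tied = _prepare(d)
    assert not tied
    beta = np.array([0.3, -0.2])
    ll_e, g_e, i_e = _loglik_ties(beta, t, dd, X, EFRON)
    ll_b, g_b, i_b = _loglik_ties(beta, t, dd, X, BRESLOW)
    assert ll_e == pytest.approx(ll_b, abs=1e-12)
    np.testing.assert_allclose(g_e, g_b, atol=1e-12)
    fit_e = fit_cox(d, ties=EFRON)
    fit_b = fit_cox(d, ties=BRESLOW)
    np.testing.assert_allclose(fit_e.beta, fit_b.beta, atol=1e-10)


def test_likelihood_never_decreases_from_null():
    for seed in range(6):
        d = _toy_design(seed=seed)
        fit = fit_cox(d)
        assert fit.log_partial_likelihood >= fit.log_likelihood_null - 1e-10


def test_constant_column_is_hard_error():
    d = _toy_design(seed=8, p=2)
    X = d.X.copy()
    X[:, 1] = 2.0
    with pytest.raises(DesignError, match="constant"):
        Design(X, d.time, d.event, ["a", "b"])


def test_separation_yields_flagged_fit_not_exception():
    # perfectly separating covariate: all early events in one group
    time = np.array([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
    event = np.array([1, 1, 1, 0, 0, 0])
    x = np.array([[1.0], [1.0], [1.0], [0.0], [0.0], [0.0]])
    fit = fit_cox(Design(x, time, event, ["x"]))
    assert not fit.converged
    assert set(fit.flags) & {"separation", "max-iterations", "quasi-separation",
                             "singular-information"}


def test_global_wald_single_term_equals_per_term():
    d = _toy_design(seed=9, p=2)
    fit = fit_cox(d)
    stat, df, p = wald_global(fit, ["x0"])
    assert df == 1
    assert stat == pytest.approx(fit.wald_z[0] ** 2, rel=1e-12)
    assert p == pytest.approx(fit.wald_p[0], abs=1e-12)
    with pytest.raises(DesignError):
        wald_global(fit, ["nope"])
    with pytest.raises(DesignError):
        wald_global(fit, [])


def test_global_wald_is_chi_square_calibrated_under_null():
    # 3 null gene terms: mean of the global Wald statistic ~ chi2(3) mean = 3
    stats = []
    for seed in range(500):
        rng = np.random.default_rng(10_000 + seed)
        n = 100
        X = rng.standard_normal((n, 3))
        T = rng.exponential(1.0, n)
        C = rng.exponential(2.0, n)
        d = Design(X, np.minimum(T, C), (T <= C).astype(int), ["a", "b", "c"])
        fit = fit_cox(d)
        if fit.converged:
            stats.append(fit.global_wald_stat)
    se = np.sqrt(6.0 / len(stats))  # chi2(3) variance = 6
    assert abs(np.mean(stats) - 3.0) < 3 * se


def test_vif_orthogonal_duplicated_and_correlated():
    rng = np.random.default_rng(12)
    # columns orthogonal to each other and to the intercept
    q, _ = np.linalg.qr(np.column_stack([np.ones(200),
                                         rng.standard_normal((200, 3))]))
    report = vif(q[:, 1:], names=["a", "b", "c"])
    for term in report.values():
        assert term["vif"] == pytest.approx(1.0, abs=1e-10)
        assert term["passes"]
    # duplicated column -> infinite VIF flag
    x = rng.standard_normal(50)
    report = vif(np.column_stack([x, x]), names=["a", "b"])
    assert np.isinf(report["a"]["vif"]) and not report["a"]["passes"]
    # correlation 0.6 -> VIF ~ 1/(1-0.36) = 1.5625
    z = rng.standard_normal(10_000)
    x1 = z
    x2 = 0.6 * z + np.sqrt(1 - 0.36) * rng.standard_normal(10_000)
    report = vif(np.column_stack([x1, x2]), names=["a", "b"])
    assert report["a"]["vif"] == pytest.approx(1.5625, rel=0.05)
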