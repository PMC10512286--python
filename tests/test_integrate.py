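import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from agingpanel.integrate import (
    AS_PRINTED,
    IntegrationError,
    bh_fdr,
    harmonic_mean_p,
    integrate_subgroups,
)

p_values = st.floats(min_value=1e-6, max_value=1.0, allow_nan=False)


def test_harmonic_mean_closed_forms():
    # three-value form 3xyz/(xy+yz+xz) on the higher-Gleason cohort p-values
    x, y, z = 0.007, 0.049, 0.011
    expected3 = 3 * x * y * z / (x * y + y * z + x * z)
    assert harmonic_mean_p([x, y, z]) == pytest.approx(expected3, rel=1e-12)
    assert harmonic_mean_p([x, y, z]) == pytest.approx(0.01180, abs=5e-6)
    # two-value form 2xy/(x+y) on the AML older-age p-values
    a, b = 0.008, 0.01
    assert harmonic_mean_p([a, b]) == pytest.approx(2 * a * b / (a + b), rel=1e-12)
    assert harmonic_mean_p([a, b]) == pytest.approx(0.008889, abs=5e-7)


def test_harmonic_mean_audit_variant_uses_printed_constant():
    x, y, z = 0.007, 0.049, 0.011
    assert harmonic_mean_p([x, y, z], variant=AS_PRINTED) == pytest.approx(
        2 * x * y * z / (x * y + y * z + x * z), rel=1e-12)
    assert harmonic_mean_p([x, y], variant=AS_PRINTED) == pytest.approx(
        harmonic_mean_p([x, y]), rel=1e-12)


def test_harmonic_mean_rejects_nonpositive():
    with pytest.raises(IntegrationError):
        harmonic_mean_p([0.0, 0.5])
    with pytest.raises(IntegrationError):
        harmonic_mean_p([])


@settings(derandomize=True, max_examples=200)
@given(p=p_values, n=st.integers(min_value=1, max_value=6))
def test_harmonic_mean_idempotent(p, n):
    assert harmonic_mean_p([p] * n) == pytest.approx(p, rel=1e-12)


@settings(derandomize=True, max_examples=200)
@given(ps=st.lists(p_values, min_size=1, max_size=6))
def test_harmonic_mean_bounded_by_inputs(ps):
    hm = harmonic_mean_p(ps)
    assert min(ps) - 1e-15 <= hm <= max(ps) + 1e-15


@settings(derandomize=True, max_examples=200)
@given(ps=st.lists(st.floats(min_value=1e-6, max_value=0.5),
                   min_size=2, max_size=5),
       idx=st.integers(min_value=0, max_value=4),
       bump=st.floats(min_value=1e-3, max_value=0.4))
def test_harmonic_mean_strictly_increasing_in_each_argument(ps, idx, bump):
    idx = idx % len(ps)
    bigger = list(ps)
    bigger[idx] = ps[idx] + bump
    assert harmonic_mean_p(bigger) > harmonic_mean_p(ps)


def _bh_brute(ps):
    """Direct BH definition: sort, p(i)*m/i, monotone from the top, cap 1."""
    m = len(ps)
    order = sorted(range(m), key=lambda i: ps[i])
    adj = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, ps[i] * m / rank)
        adj[i] = running
    return adj


def test_bh_hand_worked_example():
    out = bh_fdr([0.005, 0.012, 0.2, 0.9])
    np.testing.assert_allclose(out, [0.02, 0.024, 0.26666666666666666, 0.9],
                               rtol=1e-12)


def test_bh_single_and_tied_inputs():
    assert bh_fdr([0.3]) == [0.3]
    np.testing.assert_allclose(bh_fdr([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])


def test_bh_matches_brute_force_on_random_vectors():
    rng = np.random.default_rng(77)
    for _ in range(1000):
        ps = rng.uniform(0, 1, rng.integers(1, 11)).tolist()
        assert bh_fdr(ps) == _bh_brute(ps)


def test_bh_matches_statsmodels():
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(78)
    for _ in range(200):
        ps = rng.uniform(0, 1, rng.integers(1, 11))
        ours = bh_fdr(ps)
        _, theirs, _, _ = multipletests(ps, method="fdr_bh")
        np.testing.assert_allclose(ours, theirs, rtol=0, atol=1e-12)


def test_bh_rejects_out_of_range():
    with pytest.raises(IntegrationError):
        bh_fdr([0.5, 1.5])
    with pytest.raises(IntegrationError):
        bh_fdr([])


def test_integration_family_reproduces_published_adjustments():
    family = {
        "grade-high": [0.007, 0.049, 0.011],
        "age-younger": [0.019, 0.029, 0.0019],
        "grade-low": [0.5, 0.5, 0.5],
        "age-older": [0.5, 0.5, 0.5],
    }
    results = {r.subgroup: r for r in integrate_subgroups(family)}
    assert results["age-younger"].fdr_adjusted_p == pytest.approx(0.0196, abs=5e-4)
    assert results["grade-high"].fdr_adjusted_p == pytest.approx(0.0236, abs=5e-4)
    for r in results.values():
        assert min(r.cohort_ps) <= r.raw_integrated_p <= max(r.cohort_ps)
        assert r.fdr_adjusted_p >= r.raw_integrated_p
        assert r.family_size == 4


def test_single_subgroup_single_cohort_passes_through():
    (result,) = integrate_subgroups({"only": [0.31]})
    assert result.raw_integrated_p == 0.31
    assert result.fdr_adjusted_p == 0.31


def test_integration_is_cohort_order_equivariant():
    a = integrate_subgroups({"g": [0.01, 0.2, 0.05], "h": [0.5, 0.4]})
    b = integrate_subgroups({"g": [0.2, 0.05, 0.01], "h": [0.4, 0.5]})
    for ra, rb in zip(a, b):
        assert ra.raw_integrated_p == pytest.approx(rb.raw_integrated_p, rel=1e-12)
        assert ra.fdr_adjusted_p == pytest.approx(rb.fdr_adjusted_p, rel=1e-12)
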