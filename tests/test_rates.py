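"""Saturation filters, the mu = d/2T arithmetic, summaries and bootstrap."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from codonrates.distances import PairwiseEstimate
from codonrates.rates import (ANGIOSPERM_SCENARIO, CONIFER_SCENARIO,
                              CladeSummary, DivergenceScenario, FilterPolicy,
                              apply_filters, apportion_lineage_rates,
                              bootstrap_ci, clade_summary, fold_change_table,
                              substitution_rate)


def _est(pair_id="g", status="ok", **kw):
    defaults = dict(dN=0.05, dS=0.2, d4=0.18, omega=0.25)
    defaults.update(kw)
    return PairwiseEstimate(pair_id, "GY94-ML", status, **defaults)


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------


def test_empty_input_gives_empty_output():
    kept, ledger = apply_filters([], FilterPolicy(0.5))
    assert kept == [] and len(ledger) == 0


def test_saturated_ds_dropped_with_reason():
    kept, ledger = apply_filters([_est("a", dS=0.6)], FilterPolicy(max_dS=0.5))
    assert kept == []
    assert ledger.iloc[0]["reason"] == "max_dS"


def test_filter_rule_order_and_reasons():
    ests = [
        _est("undef", status="undefined_ratio", dS=0.0, omega=None),
        _est("fail", status="failed", dN=None, dS=None, omega=None),
        _est("satur", dS=5.0),
        _est("fast", dS=3.0, dN=6.0),
        _est("keep", dS=3.0, dN=0.2),
    ]
    kept, ledger = apply_filters(ests, FilterPolicy(max_dS=4.0, max_dN=5.0))
    assert [e.pair_id for e in kept] == ["keep"]
    reasons = dict(zip(ledger["pair_id"], ledger["reason"]))
    assert reasons == {"undef": "undefined_ratio", "fail": "failed",
                       "satur": "max_dS", "fast": "max_dN"}


def test_lowering_threshold_never_keeps_more():
    rng = np.random.default_rng(0)
    ests = [_est(f"g{i}", dS=float(rng.gamma(2, 0.2))) for i in range(50)]
    kept_counts = [len(apply_filters(ests, FilterPolicy(max_dS=x))[0])
                   for x in (1.0, 0.5, 0.3, 0.1)]
    assert kept_counts == sorted(kept_counts, reverse=True)


# ---------------------------------------------------------------------------
# mu = d / 2T
# ---------------------------------------------------------------------------


def test_slow_clade_synonymous_rate():
    r = substitution_rate(0.1908, CONIFER_SCENARIO)
    assert round(r.mu * 1e9, 2) == 0.68
    assert round(r.mu_low * 1e9, 2) == 0.60  # T_high = 160 My
    assert r.mu_high * 1e9 == pytest.approx(0.795, abs=1e-3)  # T_low = 120 My


def test_fast_clade_synonymous_rate():
    r = substitution_rate(2.1846, ANGIOSPERM_SCENARIO)
    assert round(r.mu * 1e9, 2) == 9.93


def test_zero_distance_gives_zero_rate():
    assert substitution_rate(0.0, CONIFER_SCENARIO).mu == 0.0


def test_negative_inputs_rejected():
    with pytest.raises(ValueError):
        substitution_rate(-0.1, CONIFER_SCENARIO)
    with pytest.raises(ValueError):
        DivergenceScenario(0.0, 1.0, 2.0)
    with pytest.raises(ValueError):
        DivergenceScenario(140e6, 120e6, 160e6, rho=0.5)


def test_lineage_apportionment_reproduces_known_split():
    mu_slow, mu_fast = apportion_lineage_rates(2.1846, ANGIOSPERM_SCENARIO)
    assert round(mu_slow * 1e9, 2) == 2.84
    assert round(mu_fast * 1e9, 2) == 17.02


def test_symmetric_apportionment_matches_plain_rate():
    sym = DivergenceScenario(140e6, 120e6, 160e6, rho=1.0)
    mu_slow, mu_fast = apportion_lineage_rates(0.1908, sym)
    assert mu_slow == mu_fast == pytest.approx(substitution_rate(0.1908, sym).mu)


@settings(max_examples=100, derandomize=True)
@given(
    d=st.floats(0.001, 10.0),
    t=st.floats(1e6, 1e9),
    rho=st.floats(1.0, 20.0),
)
def test_apportionment_conserves_total_divergence(d, t, rho):
    sc = DivergenceScenario(t, t, t, rho=rho)
    mu_slow, mu_fast = apportion_lineage_rates(d, sc)
    assert (mu_slow + mu_fast) * t == pytest.approx(d, rel=1e-12)


@settings(max_examples=100, derandomize=True)
@given(d=st.floats(0.001, 10.0), t=st.floats(1e6, 1e9))
def test_rate_is_linear_in_distance_and_inverse_in_time(d, t):
    sc = DivergenceScenario(t, t, t)
    sc2 = DivergenceScenario(2 * t, 2 * t, 2 * t)
    assert substitution_rate(2 * d, sc).mu == pytest.approx(
        2 * substitution_rate(d, sc).mu)
    assert substitution_rate(d, sc2).mu == pytest.approx(
        substitution_rate(d, sc).mu / 2)


# ---------------------------------------------------------------------------
# summaries and fold changes
# ---------------------------------------------------------------------------


def test_single_gene_summary_equals_that_gene():
    s = clade_summary([_est("only")], "c")
    assert (s.mean_dS, s.mean_dN, s.mean_omega) == (0.2, 0.05, 0.25)
    assert s.n_genes == 1 and s.frac_omega_gt1 == 0.0


def test_summary_uses_mean_of_per_gene_ratios():
    """omega = {0.1, 0.9} with dS = {1.0, 0.1}: the mean of ratios is 0.5
    while the ratio of means would be ~0.173 - the summary must report the
    former."""
    ests = [
        _est("g1", dS=1.0, dN=0.1, omega=0.1),
        _est("g2", dS=0.1, dN=0.09, omega=0.9),
    ]
    s = clade_summary(ests, "c")
    assert s.mean_omega == pytest.approx(0.5)
    assert s.mean_omega != pytest.approx((0.1 + 0.09) / 1.1, abs=0.01)


def test_empty_summary_rejected():
    with pytest.raises(ValueError):
        clade_summary([], "c")


def _table1_summaries():
    a = CladeSummary("conifer", 3723, 0.1908, 0.1769, 0.0492, 0.3137, 0.0268)
    b = CladeSummary("angiosperm", 4080, 2.1846, 2.0057, 0.2019, 0.0924, 0.0)
    return a, b


def test_identical_summaries_give_unit_folds():
    a, _ = _table1_summaries()
    rows = {r.quantity: r for r in fold_change_table(a, a, CONIFER_SCENARIO,
                                                     CONIFER_SCENARIO)}
    assert all(r.fold == 1.0 for r in rows.values())


def test_fold_change_table_reproduces_published_style_ratios():
    a, b = _table1_summaries()
    rows = {r.quantity: r for r in
            fold_change_table(a, b, CONIFER_SCENARIO, ANGIOSPERM_SCENARIO)}
    assert rows["dS"].label == "11.4:1"
    assert rows["dN"].label == "4.1:1"
    assert rows["muS"].label == "14.6:1"
    assert rows["muN"].label == "5.2:1"
    assert rows["omega"].label == "1:3.4"


def test_zero_denominator_gives_typed_absence():
    a, b = _table1_summaries()
    import dataclasses

    a0 = dataclasses.replace(a, mean_dS=0.0)
    rows = {r.quantity: r for r in
            fold_change_table(a0, b, CONIFER_SCENARIO, ANGIOSPERM_SCENARIO)}
    assert rows["dS"].ratio is None and rows["dS"].label is None


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------


def test_constant_values_give_zero_width_interval():
    mean, lo, hi = bootstrap_ci([0.3] * 10, seed=1)
    assert mean == lo == hi == pytest.approx(0.3)


def test_bootstrap_is_deterministic_under_seed():
    values = list(np.random.default_rng(0).normal(size=50))
    assert bootstrap_ci(values, seed=5) == bootstrap_ci(values, seed=5)
    assert bootstrap_ci(values, seed=5) != bootstrap_ci(values, seed=6)


def test_bootstrap_needs_two_values():
    with pytest.raises(ValueError):
        bootstrap_ci([1.0], seed=0)
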