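"""Annotation transfer and the category-level selection statistics."""

import numpy as np
import pytest

from codonrates.categories import (across_category_heterogeneity,
                                   compare_categories_between_clades,
                                   logistic_trend_test,
                                   ranked_segmentation_test,
                                   transfer_annotations)

from oracles import fisher_two_sided, mann_whitney_exact_p


# ---------------------------------------------------------------------------
# transfer
# ---------------------------------------------------------------------------


def test_confident_hit_copies_terms():
    ann = transfer_annotations({"g1": ("ref1", 1e-10)},
                               {"ref1": {"GO:A", "GO:B"}})
    assert ann[0].terms == {"GO:A", "GO:B"}


def test_weak_hit_transfers_nothing():
    ann = transfer_annotations({"g1": ("ref1", 1e-3)}, {"ref1": {"GO:A"}})
    assert ann[0].terms == frozenset()


def test_missing_reference_logs_warning_and_leaves_empty(caplog):
    import logging

    with caplog.at_level(logging.WARNING, logger="codonrates.categories"):
        ann = transfer_annotations({"g1": ("ghost", 1e-10)}, {})
    assert ann[0].terms == frozenset()
    assert any("ghost" in r.message for r in caplog.records)


def test_self_match_round_trip_recovers_planted_labels():
    reference = {f"g{i}": {f"GO:{i % 3}"} for i in range(9)}
    hits = {g: (g, 1e-60) for g in reference}
    ann = {a.gene_id: a.terms for a in transfer_annotations(hits, reference)}
    assert ann == {g: frozenset(t) for g, t in reference.items()}


# ---------------------------------------------------------------------------
# Mann-Whitney between clades
# ---------------------------------------------------------------------------


def _values(rng, n, shift=0.0):
    return {f"g{i}": float(v) for i, v in enumerate(rng.normal(shift, 1, n))}


def test_identical_distributions_are_not_significant(rng):
    vals = _values(rng, 30)
    ann = {g: {"GO:X"} for g in vals}
    res = compare_categories_between_clades(vals, dict(vals), ann)
    assert res[0].p > 0.9
    assert res[0].direction == "none"


def test_shifted_clade_detected_with_direction(rng):
    a = {f"a{i}": float(v) for i, v in enumerate(rng.normal(0.5, 0.2, 50))}
    b = {f"b{i}": float(v) for i, v in enumerate(rng.normal(0.3, 0.2, 50))}
    ann = {g: {"GO:X"} for g in list(a) + list(b)}
    res = compare_categories_between_clades(a, b, ann)
    assert res[0].p < 0.001
    assert res[0].direction == "a-high"


def test_small_category_skipped_with_reason(rng):
    a = {"a1": 0.1}
    b = {f"b{i}": float(i) for i in range(5)}
    ann = {g: {"GO:X"} for g in list(a) + list(b)}
    res = compare_categories_between_clades(a, b, ann)
    assert res[0].p is None and res[0].note == "below_min_size"


def test_exact_small_sample_p_matches_enumeration(rng):
    x = [1.3, 2.1, 0.4, 3.3]
    y = [0.9, 1.7, 2.8, 0.1]
    a = {f"a{i}": v for i, v in enumerate(x)}
    b = {f"b{i}": v for i, v in enumerate(y)}
    ann = {g: {"GO:X"} for g in list(a) + list(b)}
    res = compare_categories_between_clades(a, b, ann)
    assert res[0].p == pytest.approx(mann_whitney_exact_p(x, y), abs=1e-9)


def test_result_invariant_to_monotone_transformation(rng):
    a = _values(rng, 25, 0.4)
    b = {f"h{i}": float(v) for i, v in enumerate(rng.normal(0, 1, 25))}
    ann = {g: {"GO:X"} for g in list(a) + list(b)}
    p1 = compare_categories_between_clades(a, b, ann)[0].p
    fa = {g: np.exp(v) for g, v in a.items()}
    fb = {g: np.exp(v) for g, v in b.items()}
    p2 = compare_categories_between_clades(fa, fb, ann)[0].p
    assert p1 == pytest.approx(p2, rel=1e-9)


# ---------------------------------------------------------------------------
# Kruskal-Wallis heterogeneity
# ---------------------------------------------------------------------------


def test_identical_category_multisets_give_zero_h():
    vals = {"a1": 1.0, "a2": 2.0, "a3": 3.0, "b1": 1.0, "b2": 2.0, "b3": 3.0}
    ann = {g: ({"GO:A"} if g.startswith("a") else {"GO:B"}) for g in vals}
    res = across_category_heterogeneity(vals, ann)
    assert res.statistic == pytest.approx(0.0, abs=1e-9)


def test_shifted_category_detected(rng):
    vals = {}
    ann = {}
    for i, v in enumerate(rng.normal(0, 1, 30)):
        vals[f"a{i}"] = float(v)
        ann[f"a{i}"] = {"GO:A"}
    for i, v in enumerate(rng.normal(2, 1, 30)):  # 2 SD shift
        vals[f"b{i}"] = float(v)
        ann[f"b{i}"] = {"GO:B"}
    assert across_category_heterogeneity(vals, ann).p < 0.01


def test_fewer_than_two_categories_rejected():
    vals = {"a1": 1.0, "a2": 2.0}
    ann = {g: {"GO:A"} for g in vals}
    with pytest.raises(ValueError):
        across_category_heterogeneity(vals, ann)


# ---------------------------------------------------------------------------
# ranked segmentation test
# ---------------------------------------------------------------------------


def _planted_ranking(n=200, top=20):
    """Genes ranked by value; the planted category occupies the top decile."""
    vals = {f"g{i:03d}": float(n - i) for i in range(n)}
    ann = {f"g{i:03d}": ({"GO:TOP"} if i < top else {"GO:BG"}) for i in range(n)}
    return vals, ann


def test_interleaved_category_is_null():
    vals = {f"g{i:03d}": float(100 - i) for i in range(100)}
    ann = {f"g{i:03d}": ({"GO:EVEN"} if i % 2 == 0 else {"GO:ODD"})
           for i in range(100)}
    res = {r.term: r for r in ranked_segmentation_test(vals, ann)}
    assert res["GO:EVEN"].p_adj > 0.5


def test_planted_top_decile_detected_high():
    vals, ann = _planted_ranking()
    res = {r.term: r for r in ranked_segmentation_test(vals, ann)}
    assert res["GO:TOP"].p_adj < 0.05
    assert res["GO:TOP"].direction == "high"


def test_single_partition_matches_hypergeometric_enumeration():
    from scipy import stats

    table = [[10, 0], [0, 10]]
    assert stats.fisher_exact(table)[1] == pytest.approx(
        fisher_two_sided(table), rel=1e-9)


def test_absent_category_skipped():
    vals = {"g1": 1.0, "g2": 0.5}
    ann = {"g1": {"GO:A"}, "g2": {"GO:A"}, "zz": {"GO:GONE"}}
    res = {r.term: r for r in ranked_segmentation_test(vals, ann)}
    assert res["GO:GONE"].note == "absent_from_ranking"


# ---------------------------------------------------------------------------
# logistic trend test
# ---------------------------------------------------------------------------


def test_logistic_detects_planted_category_with_positive_slope():
    vals, ann = _planted_ranking()
    res = {r.term: r for r in logistic_trend_test(vals, ann)}
    assert res["GO:TOP"].p_adj < 0.05
    assert res["GO:TOP"].direction == "high"
    assert res["GO:TOP"].statistic > 0


def test_category_covering_all_genes_is_degenerate():
    vals = {f"g{i}": float(i) for i in range(20)}
    ann = {g: {"GO:ALL"} for g in vals}
    res = {r.term: r for r in logistic_trend_test(vals, ann)}
    assert res["GO:ALL"].p is None
    assert res["GO:ALL"].note == "degenerate_membership"


def test_null_membership_is_uncalibrated_nowhere(rng):
    """With membership independent of rank, slopes stay near zero and small
    p-values appear at roughly the nominal rate."""
    ps = []
    for rep in range(50):
        r = np.random.default_rng(rep)
        vals = {f"g{i}": float(v) for i, v in enumerate(r.normal(size=60))}
        member = r.choice(list(vals), size=20, replace=False)
        ann = {g: ({"GO:X"} if g in member else {"GO:BG"}) for g in vals}
        res = {x.term: x for x in logistic_trend_test(vals, ann)}
        ps.append(res["GO:X"].p)
    assert np.mean(np.array(ps) < 0.05) < 0.2
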