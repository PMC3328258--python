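"""Estimator core: NG86 counting (vs hand enumeration and an independent
library implementation), F3x4 frequencies, GY94 ML behaviour, d4."""

import numpy as np
import pytest

from codonrates import model, simulate
from codonrates.alignment import CodonAlignment, filter_columns
from codonrates.distances import (_NONSYN_DIFF, _SYN_DIFF, _SYN_SITES,
                                  OptimizerPolicy, _log_likelihood,
                                  _pattern_counts, d4_distance,
                                  f3x4_frequencies, gy94_ml_estimate,
                                  ng86_estimate)


def _aln(a, b, pair_id="x"):
    return filter_columns(CodonAlignment(pair_id, a, b))


def _raw(a, b):
    return CodonAlignment("x", a, b)


def _sim_aln(n, t, kappa, omega, seed):
    a, b, _ = simulate.simulate_codon_pair(
        simulate.SimRegime(n, t, kappa, omega, seed=seed)
    )
    return filter_columns(CodonAlignment(f"s{seed}", a, b))


# ---------------------------------------------------------------------------
# NG86
# ---------------------------------------------------------------------------


def test_synonymous_site_fraction_of_phenylalanine_codon():
    # TTT: only the third-position change to TTC is synonymous -> 1/3 site
    assert _SYN_SITES[model.CODON_INDEX["TTT"]] == pytest.approx(1.0 / 3.0)


def test_single_synonymous_difference_counted():
    i, j = model.CODON_INDEX["TTT"], model.CODON_INDEX["TTC"]
    assert _SYN_DIFF[i, j] == 1.0 and _NONSYN_DIFF[i, j] == 0.0


def test_two_position_difference_averages_over_pathways():
    # TTT -> GTA: path via GTT gives (nonsyn, syn), path via TTA gives
    # (nonsyn, nonsyn); averaging the two orderings -> 0.5 syn, 1.5 nonsyn
    i, j = model.CODON_INDEX["TTT"], model.CODON_INDEX["GTA"]
    assert _SYN_DIFF[i, j] == pytest.approx(0.5)
    assert _NONSYN_DIFF[i, j] == pytest.approx(1.5)


def test_identical_sequences_are_undefined_ratio():
    orf = "GATTTCAAA" * 20
    est = ng86_estimate(_aln(orf, orf))
    assert est.status == "undefined_ratio"
    assert est.dN == est.dS == 0.0


def test_site_counts_partition_all_positions():
    aln = _sim_aln(200, 0.4, 2.0, 0.5, seed=1)
    est = ng86_estimate(aln)
    assert est.S_sites + est.N_sites == pytest.approx(3 * aln.kept_codons)


def test_ng86_matches_independent_library_implementation():
    """Agreement with the Nei-Gojobori implementation in Bio.codonalign."""
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        from Bio.codonalign.codonseq import CodonSeq, cal_dn_ds
    for seed in (3, 4, 5):
        a, b, _ = simulate.simulate_codon_pair(
            simulate.SimRegime(300, 0.3, 2.0, 0.4, seed=seed)
        )
        dn_ref, ds_ref = cal_dn_ds(CodonSeq(a), CodonSeq(b), method="NG86")
        est = ng86_estimate(_aln(a, b))
        assert est.dN == pytest.approx(dn_ref, abs=1e-6)
        assert est.dS == pytest.approx(ds_ref, abs=1e-6)


def test_ambiguous_codons_skipped_and_tallied():
    a = "GATTTCAAA" * 20
    b = "GATTTNAAA" + "GATTTCAAA" * 19
    est = ng86_estimate(filter_columns(CodonAlignment("n", a, b),))
    assert est.skipped_codons == 1


def test_omega_one_regime_centers_on_one():
    """Under the estimator's own assumptions (no transition bias) the NG86
    dN/dS centers on 1 at neutrality."""
    omegas = []
    for seed in range(100):
        est = ng86_estimate(_sim_aln(2000, 0.2, 1.0, 1.0, seed=200 + seed))
        omegas.append(est.omega)
    # standard NG86 counts mutations to stop codons as non-synonymous sites,
    # which leaves a small conservative offset; the mean still centers on 1
    assert abs(np.mean(omegas) - 1.0) < 0.05


# ---------------------------------------------------------------------------
# F3x4
# ---------------------------------------------------------------------------


def test_uniform_composition_gives_uniform_sense_frequencies():
    seq = "AAACCCGGGTTT"  # every nucleotide once per position
    pi = f3x4_frequencies(_raw(seq, seq))
    assert np.allclose(pi, 1.0 / 61.0)


def test_degenerate_composition_concentrates_on_one_codon():
    seq = "ATG" * 10
    pi = f3x4_frequencies(_raw(seq, seq))
    assert pi[model.CODON_INDEX["ATG"]] == pytest.approx(1.0)


def test_frequencies_sum_to_one(rng):
    for seed in range(5):
        aln = _sim_aln(100, 0.5, 2.0, 0.3, seed=seed)
        assert f3x4_frequencies(aln).sum() == pytest.approx(1.0, abs=1e-12)


# ---------------------------------------------------------------------------
# GY94 ML
# ---------------------------------------------------------------------------


def test_ml_on_identical_sequences_is_zero_divergence():
    orf = "GATTTCAAACCA" * 20
    est = gy94_ml_estimate(_aln(orf, orf))
    assert est.status == "undefined_ratio"
    assert est.t == 0.0 and est.dN == 0.0 and est.dS == 0.0


def test_ml_estimate_is_invariant_to_sequence_swap():
    a, b, _ = simulate.simulate_codon_pair(
        simulate.SimRegime(300, 0.5, 2.0, 0.3, seed=6)
    )
    fwd = gy94_ml_estimate(_aln(a, b))
    rev = gy94_ml_estimate(_aln(b, a))
    assert fwd.omega == pytest.approx(rev.omega, rel=1e-3)
    assert fwd.t == pytest.approx(rev.t, rel=1e-3)


def test_reported_mle_beats_a_coarse_grid(sim_alignment_500):
    est = gy94_ml_estimate(sim_alignment_500)
    from codonrates.distances import _kept_codon_indices

    pairs, _ = _kept_codon_indices(sim_alignment_500)
    counts = _pattern_counts(pairs)
    i, j = np.nonzero(counts)
    nz = (i, j, counts[i, j])
    pi = f3x4_frequencies(sim_alignment_500)
    pi = np.maximum(pi, 1e-8)
    pi /= pi.sum()
    best = _log_likelihood(nz, pi, est.kappa, est.omega, est.t)
    assert best == pytest.approx(est.lnL, abs=1e-6)
    for ft in np.linspace(0.6, 1.4, 5):
        for fk in np.linspace(0.6, 1.4, 5):
            for fw in np.linspace(0.6, 1.4, 5):
                lnl = _log_likelihood(nz, pi, est.kappa * fk, est.omega * fw,
                                      est.t * ft)
                assert lnl <= best + 1e-6


def test_estimated_divergence_increases_with_simulated_divergence():
    medians = []
    for t in (0.1, 0.3, 0.6, 1.2):
        ts = [gy94_ml_estimate(_sim_aln(200, t, 2.0, 0.3, seed=50 + r)).t
              for r in range(8)]
        medians.append(np.median(ts))
    assert medians == sorted(medians)


def test_ml_and_ng86_agree_at_low_divergence():
    """Cross-method concordance: at dS ~ 0.1 the counting and likelihood
    estimates of dN and dS differ by less than 20%."""
    ratios_dn, ratios_ds = [], []
    for seed in range(15):
        aln = _sim_aln(500, 0.15, 2.0, 0.3, seed=400 + seed)
        ml = gy94_ml_estimate(aln)
        ng = ng86_estimate(aln)
        ratios_dn.append(ml.dN / ng.dN)
        ratios_ds.append(ml.dS / ng.dS)
    assert abs(np.mean(ratios_dn) - 1.0) < 0.2
    assert abs(np.mean(ratios_ds) - 1.0) < 0.2


# ---------------------------------------------------------------------------
# d4
# ---------------------------------------------------------------------------


def test_fourfold_column_qualifies_and_counts_transversion():
    # GGA vs GGC: glycine family, identical prefix, A<->C transversion;
    # GAT (Asp) filler columns are not 4-fold degenerate and do not qualify
    import math

    filler4d = "GGT" * 40  # identical glycine columns anchor the site count
    non4d = "GAT" * 10
    d4, n4 = d4_distance(_aln(non4d + filler4d + "GGA",
                              non4d + filler4d + "GGC"))
    assert n4 == 41
    q = 1.0 / 41.0
    expected = -0.5 * math.log(1.0 - q) - 0.25 * math.log(1.0 - 2.0 * q)
    assert d4 == pytest.approx(expected)


def test_leucine_with_different_first_position_does_not_qualify():
    filler = "GGA" * 40
    d4, n4 = d4_distance(_aln(filler + "TTA", filler + "CTA"))
    assert n4 == 40  # only the GGA filler columns qualify
    assert d4 == pytest.approx(0.0)


def test_no_qualifying_sites_is_typed_absence():
    aln = _aln("ATGTGGATGTGGATGTGGATGTGGATGTGGATGTGG" * 3,
               "ATGTGGATGTGGATGTGGATGTGGATGTGGATGTGG" * 3)
    d4, n4 = d4_distance(aln)
    assert d4 is None and n4 == 0


def test_d4_tracks_synonymous_divergence_under_neutrality():
    ratios = []
    for seed in range(15):
        aln = _sim_aln(2000, 0.6, 2.0, 1.0, seed=seed)
        ml = gy94_ml_estimate(aln)
        d4, _ = d4_distance(aln)
        ratios.append(d4 / ml.dS)
    assert abs(np.mean(ratios) - 1.0) < 0.1
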