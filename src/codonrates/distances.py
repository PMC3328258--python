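"""Pairwise evolutionary distances from filtered codon alignments.

Two routes to dN/dS are provided and kept deliberately independent:

* :func:`ng86_estimate` - the Nei-Gojobori counting estimator: synonymous
  site fractions by enumerating each codon's nine single-nucleotide
  neighbours, differences averaged over all shortest substitution pathways
  (paths through stop codons excluded), Jukes-Cantor multiple-hit
  correction.
* :func:`gy94_ml_estimate` - maximum likelihood under the reversible
  Goldman-Yang codon model with F3x4 codon frequencies, maximising
  L(t, kappa, omega) over the pair and converting the MLE into dN and dS
  through the synonymous fraction of the stationary substitution flow
  (the mutational-opportunity site definition).

:func:`d4_distance` restricts to third positions of 4-fold degenerate codon
families (both codons in a 4D family with identical first two positions)
and applies a Kimura two-parameter correction by default.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np
from scipy.optimize import minimize

from . import model
from .alignment import CodonAlignment

Status = Literal["ok", "undefined_ratio", "failed"]


@dataclass(frozen=True)
class PairwiseEstimate:
    pair_id: str
    method: str
    status: Status
    t: Optional[float] = None
    kappa: Optional[float] = None
    omega: Optional[float] = None
    dN: Optional[float] = None
    dS: Optional[float] = None
    d4: Optional[float] = None
    n4D: int = 0
    S_sites: Optional[float] = None
    N_sites: Optional[float] = None
    lnL: Optional[float] = None
    skipped_codons: int = 0


# ---------------------------------------------------------------------------
# NG86 lookup tables (built once at import)
# ---------------------------------------------------------------------------

_NUC = "ACGT"


def _syn_site_fractions() -> np.ndarray:
    """Per-codon synonymous site count: of the 9 single-nucleotide
    neighbours, the synonymous fraction at each position (changes to stop
    codons count as non-synonymous), summed over the three positions."""
    out = np.zeros(model.N_SENSE)
    for i, codon in enumerate(model.SENSE_CODONS):
        s = 0.0
        for pos in range(3):
            for nt in _NUC:
                if nt == codon[pos]:
                    continue
                neigh = codon[:pos] + nt + codon[pos + 1 :]
                if neigh in model.AMINO_ACID and \
                        model.AMINO_ACID[neigh] == model.AMINO_ACID[codon]:
                    s += 1.0 / 3.0
        out[i] = s
    return out


def _classify_step(c_from: str, c_to: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) contribution of one substitution step."""
    aa_from = model.AMINO_ACID.get(c_from)
    aa_to = model.AMINO_ACID.get(c_to)
    if aa_from is not None and aa_to is not None and aa_from == aa_to:
        return 1.0, 0.0
    return 0.0, 1.0


def _pathway_differences() -> tuple[np.ndarray, np.ndarray]:
    """Average (syn, nonsyn) difference counts for every ordered codon pair,
    over all shortest substitution pathways with equal weights; pathways
    with stop-codon intermediates are excluded (all-blocked pairs fall back
    to including them, with stop steps counted as non-synonymous)."""
    syn = np.zeros((model.N_SENSE, model.N_SENSE))
    non = np.zeros((model.N_SENSE, model.N_SENSE))
    for i, ci in enumerate(model.SENSE_CODONS):
        for j, cj in enumerate(model.SENSE_CODONS):
            if i == j:
                continue
            positions = [k for k in range(3) if ci[k] != cj[k]]
            paths = []
            for order in itertools.permutations(positions):
                cur = ci
                steps = []
                blocked = False
                for pos in order:
                    nxt = cur[:pos] + cj[pos] + cur[pos + 1 :]
                    steps.append((cur, nxt))
                    if nxt not in model.AMINO_ACID and nxt != cj:
                        blocked = True
                    cur = nxt
                paths.append((blocked, steps))
            valid = [steps for blocked, steps in paths if not blocked]
            if not valid:
                valid = [steps for _, steps in paths]
            s_tot = n_tot = 0.0
            for steps in valid:
                for c_from, c_to in steps:
                    s, n = _classify_step(c_from, c_to)
                    s_tot += s
                    n_tot += n
            syn[i, j] = s_tot / len(valid)
            non[i, j] = n_tot / len(valid)
    return syn, non


_SYN_SITES = _syn_site_fractions()
_SYN_DIFF, _NONSYN_DIFF = _pathway_differences()


def _jukes_cantor(p: float) -> Optional[float]:
    if p < 0:
        return None
    if p >= 0.75:
        return None
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def _kept_codon_indices(alignment: CodonAlignment) -> tuple[list[tuple[int, int]], int]:
    """Indices of comparable kept columns; codons containing N (or any
    non-sense codon) are skipped and tallied."""
    pairs = []
    skipped = 0
    for ca, cb in alignment.kept_columns():
        ia = model.CODON_INDEX.get(ca)
        ib = model.CODON_INDEX.get(cb)
        if ia is None or ib is None:
            skipped += 1
            continue
        pairs.append((ia, ib))
    return pairs, skipped


def ng86_estimate(alignment: CodonAlignment) -> PairwiseEstimate:
    """Nei-Gojobori counting estimate of dN and dS with JC correction."""
    pairs, skipped = _kept_codon_indices(alignment)
    if not pairs:
        raise ValueError(f"{alignment.pair_id}: no comparable codon columns")
    ia = np.array([p[0] for p in pairs])
    ib = np.array([p[1] for p in pairs])
    n_codons = len(pairs)
    s_sites = 0.5 * (_SYN_SITES[ia].sum() + _SYN_SITES[ib].sum())
    n_sites = 3.0 * n_codons - s_sites
    sd = _SYN_DIFF[ia, ib].sum()
    nd = _NONSYN_DIFF[ia, ib].sum()
    if sd == 0.0 and nd == 0.0:
        return PairwiseEstimate(alignment.pair_id, "NG86", "undefined_ratio",
                                t=0.0, dN=0.0, dS=0.0,
                                S_sites=s_sites, N_sites=n_sites,
                                skipped_codons=skipped)
    ds = _jukes_cantor(sd / s_sites) if s_sites > 0 else None
    dn = _jukes_cantor(nd / n_sites) if n_sites > 0 else None
    if ds is None or dn is None:
        return PairwiseEstimate(alignment.pair_id, "NG86", "failed",
                                S_sites=s_sites, N_sites=n_sites,
                                skipped_codons=skipped)
    t = 3.0 * (ds * s_sites + dn * n_sites) / (3.0 * n_codons)
    if ds == 0.0:
        return PairwiseEstimate(alignment.pair_id, "NG86", "undefined_ratio",
                                t=t, dN=dn, dS=0.0,
                                S_sites=s_sites, N_sites=n_sites,
                                skipped_codons=skipped)
    return PairwiseEstimate(alignment.pair_id, "NG86", "ok", t=t,
                            omega=dn / ds, dN=dn, dS=ds,
                            S_sites=s_sites, N_sites=n_sites,
                            skipped_codons=skipped)


# ---------------------------------------------------------------------------
# F3x4 frequencies
# ---------------------------------------------------------------------------


def f3x4_frequencies(alignment: CodonAlignment) -> np.ndarray:
    """Sense-codon frequencies as products of position-specific nucleotide
    frequencies pooled over both sequences, renormalised over the 61 sense
    codons."""
    counts = np.zeros((3, 4))
    nuc_index = {n: i for i, n in enumerate(_NUC)}
    n_seen = 0
    for ca, cb in alignment.kept_columns():
        for codon in (ca, cb):
            if any(c not in nuc_index for c in codon):
                continue
            n_seen += 1
            for pos in range(3):
                counts[pos, nuc_index[codon[pos]]] += 1
    if n_seen == 0:
        raise ValueError("no codon columns to estimate frequencies from")
    pos_freq = counts / counts.sum(axis=1, keepdims=True)
    pi = np.array(
        [
            pos_freq[0, nuc_index[c[0]]]
            * pos_freq[1, nuc_index[c[1]]]
            * pos_freq[2, nuc_index[c[2]]]
            for c in model.SENSE_CODONS
        ]
    )
    total = pi.sum()
    if total <= 0:
        raise ValueError("degenerate position frequencies")
    return pi / total


# ---------------------------------------------------------------------------
# GY94 maximum likelihood
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OptimizerPolicy:
    n_starts: int = 3
    lnl_tol: float = 1e-8
    t_bounds: tuple[float, float] = (1e-5, 50.0)
    kappa_bounds: tuple[float, float] = (0.05, 50.0)
    omega_bounds: tuple[float, float] = (1e-4, 50.0)
    pi_floor: float = 1e-8  # numerical floor so the eigendecomposition is defined


def _pattern_counts(pairs: list[tuple[int, int]]) -> np.ndarray:
    counts = np.zeros((model.N_SENSE, model.N_SENSE))
    for ia, ib in pairs:
        counts[ia, ib] += 1.0
    return counts


def _log_likelihood(counts_nz, pi, kappa, omega, t) -> float:
    eig = model.eigensystem(pi, kappa, omega)
    p = eig.probabilities(t)
    i_idx, j_idx, c = counts_nz
    joint = pi[i_idx] * p[i_idx, j_idx]
    if np.any(joint <= 0):
        return -np.inf
    return float((c * np.log(joint)).sum())


def distances_from_mle(pi: np.ndarray, kappa: float, omega: float,
                       t: float) -> tuple[float, float]:
    """(dN, dS) from an MLE via synonymous flow fractions."""
    rho_s = model.synonymous_flow_fraction(pi, kappa, omega)
    rho_s1 = model.synonymous_flow_fraction(pi, kappa, 1.0)
    ds = t * rho_s / (3.0 * rho_s1)
    dn = t * (1.0 - rho_s) / (3.0 * (1.0 - rho_s1))
    return dn, ds


def gy94_ml_estimate(
    alignment: CodonAlignment,
    init: tuple[float, float, float] | None = None,
    policy: OptimizerPolicy = OptimizerPolicy(),
) -> PairwiseEstimate:
    """Maximum-likelihood (t, kappa, omega) for one pair, with F3x4
    frequencies, plus the derived dN, dS and log-likelihood."""
    pairs, skipped = _kept_codon_indices(alignment)
    if not pairs:
        raise ValueError(f"{alignment.pair_id}: no comparable codon columns")
    counts = _pattern_counts(pairs)
    pi = f3x4_frequencies(alignment)
    pi = np.maximum(pi, policy.pi_floor)
    pi = pi / pi.sum()
    n_diff = counts.sum() - np.trace(counts)
    s_approx = 3.0 * model.synonymous_flow_fraction(pi, 2.0, 1.0) * len(pairs)
    if n_diff == 0:
        return PairwiseEstimate(alignment.pair_id, "GY94-ML", "undefined_ratio",
                                t=0.0, dN=0.0, dS=0.0,
                                S_sites=s_approx, N_sites=3.0 * len(pairs) - s_approx,
                                skipped_codons=skipped)
    i_idx, j_idx = np.nonzero(counts)
    counts_nz = (i_idx, j_idx, counts[i_idx, j_idx])

    if init is None:
        ng = ng86_estimate(alignment)
        t0 = ng.t if ng.t and ng.t > 0 else max(n_diff / len(pairs), 0.05)
        init = (t0, 2.0, 0.4)
    lo = np.log([policy.t_bounds[0], policy.kappa_bounds[0], policy.omega_bounds[0]])
    hi = np.log([policy.t_bounds[1], policy.kappa_bounds[1], policy.omega_bounds[1]])

    def objective(x):
        t, kappa, omega = np.exp(x)
        lnl = _log_likelihood(counts_nz, pi, kappa, omega, t)
        if not np.isfinite(lnl):
            return 1e12  # finite penalty keeps the finite-difference gradient defined
        return -lnl

    t0, k0, w0 = init
    starts = [
        (t0, k0, w0),
        (max(2.0 * t0, 0.5), 1.0, 0.1),
        (max(0.5 * t0, 0.05), 4.0, 1.0),
    ][: max(policy.n_starts, 1)]
    best = None
    for start in starts:
        x0 = np.clip(np.log(start), lo, hi)
        res = minimize(objective, x0, method="L-BFGS-B",
                       bounds=list(zip(lo, hi)),
                       options={"ftol": policy.lnl_tol, "maxiter": 500})
        if not np.isfinite(res.fun):
            continue
        if best is None or res.fun < best.fun - 1e-12:
            best = res
    if best is None or not best.success and not np.isfinite(best.fun):
        return PairwiseEstimate(alignment.pair_id, "GY94-ML", "failed",
                                skipped_codons=skipped)
    t_hat, kappa_hat, omega_hat = np.exp(best.x)
    dn, ds = distances_from_mle(pi, kappa_hat, omega_hat, t_hat)
    rho_s1 = model.synonymous_flow_fraction(pi, kappa_hat, 1.0)
    s_sites = 3.0 * rho_s1 * len(pairs)
    n_sites = 3.0 * len(pairs) - s_sites
    lnl = -best.fun
    if ds <= 1e-9:
        return PairwiseEstimate(alignment.pair_id, "GY94-ML", "undefined_ratio",
                                t=float(t_hat), kappa=float(kappa_hat),
                                dN=float(dn), dS=float(ds),
                                S_sites=s_sites, N_sites=n_sites, lnL=lnl,
                                skipped_codons=skipped)
    return PairwiseEstimate(alignment.pair_id, "GY94-ML", "ok",
                            t=float(t_hat), kappa=float(kappa_hat),
                            omega=float(dn / ds), dN=float(dn), dS=float(ds),
                            S_sites=s_sites, N_sites=n_sites, lnL=lnl,
                            skipped_codons=skipped)


# ---------------------------------------------------------------------------
# 4-fold degenerate distance
# ---------------------------------------------------------------------------


def d4_distance(
    alignment: CodonAlignment, correction: Literal["K2P", "JC"] = "K2P"
) -> tuple[Optional[float], int]:
    """Distance restricted to 4-fold degenerate third positions.

    A column qualifies iff both codons belong to a 4-fold degenerate family
    and their first two positions are identical across the pair.  Returns
    (d4, n4D); d4 is None when no site qualifies or the correction is not
    defined (saturation).
    """
    n4d = 0
    transitions = 0
    transversions = 0
    for ca, cb in alignment.kept_columns():
        if ca not in model.CODON_INDEX or cb not in model.CODON_INDEX:
            continue
        if ca[:2] != cb[:2] or ca[:2] not in model.FOURFOLD_PREFIXES:
            continue
        n4d += 1
        if ca[2] != cb[2]:
            if model.is_transition(ca[2], cb[2]):
                transitions += 1
            else:
                transversions += 1
    if n4d == 0:
        return None, 0
    p = transitions / n4d
    q = transversions / n4d
    if correction == "JC":
        return _jukes_cantor(p + q), n4d
    a1 = 1.0 - 2.0 * p - q
    a2 = 1.0 - 2.0 * q
    if a1 <= 0 or a2 <= 0:
        return None, n4d
    return -0.5 * math.log(a1) - 0.25 * math.log(a2), n4d


def estimates_table(estimates: list[PairwiseEstimate]):
    """Per-gene estimates TSV layout."""
    import pandas as pd

    cols = ["pair_id", "method", "t", "kappa", "omega", "dN", "dS", "d4",
            "n4D", "S_sites", "N_sites", "lnL", "status"]
    rows = [{c: getattr(e, c if c != "status" else "status") for c in cols}
            for e in estimates]
    return pd.DataFrame(rows, columns=cols)
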