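"""Codon substitution model shared by the simulator and the estimators.

Implements a reversible 61-state (sense codons, standard nuclear genetic
code) rate matrix of the Goldman-Yang type: an off-diagonal rate is zero
unless the two codons differ at exactly one nucleotide, and otherwise equals
``pi_j * kappa^[transition] * omega^[nonsynonymous]``.  The matrix is scaled
so that one unit of branch length ``t`` equals one expected substitution per
codon at stationarity.

Transition probabilities ``P(t) = exp(Qt)`` are computed by eigendecomposition
of the similarity-transformed symmetric matrix ``diag(sqrt(pi)) Q
diag(1/sqrt(pi))``, which is exact for reversible matrices and numerically
stable.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from Bio.Data import CodonTable

_TABLE = CodonTable.unambiguous_dna_by_id[1]

STOP_CODONS: tuple[str, ...] = tuple(sorted(_TABLE.stop_codons))
SENSE_CODONS: tuple[str, ...] = tuple(sorted(_TABLE.forward_table))
N_SENSE = len(SENSE_CODONS)  # 61
CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(SENSE_CODONS)}
AMINO_ACID: dict[str, str] = dict(_TABLE.forward_table)

_NUC = "ACGT"
_PURINES = frozenset("AG")


def is_transition(a: str, b: str) -> bool:
    """True when the single-nucleotide change a->b is a transition."""
    return (a in _PURINES) == (b in _PURINES) and a != b


def _build_masks() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    single = np.zeros((N_SENSE, N_SENSE), dtype=bool)
    transition = np.zeros((N_SENSE, N_SENSE), dtype=bool)
    synonymous = np.zeros((N_SENSE, N_SENSE), dtype=bool)
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            if i == j:
                continue
            diffs = [k for k in range(3) if ci[k] != cj[k]]
            if len(diffs) != 1:
                continue
            k = diffs[0]
            single[i, j] = True
            transition[i, j] = is_transition(ci[k], cj[k])
            synonymous[i, j] = AMINO_ACID[ci] == AMINO_ACID[cj]
    return single, transition, synonymous


SINGLE_DIFF, TRANSITION, SYNONYMOUS = _build_masks()


def _fourfold_prefixes() -> frozenset[str]:
    out = set()
    for n1 in _NUC:
        for n2 in _NUC:
            fam = [n1 + n2 + n3 for n3 in _NUC]
            if all(c in AMINO_ACID for c in fam):
                aas = {AMINO_ACID[c] for c in fam}
                if len(aas) == 1:
                    out.add(n1 + n2)
    return frozenset(out)


#: two-nucleotide prefixes whose whole third-position family is sense and
#: encodes a single amino acid (the 4-fold degenerate families)
FOURFOLD_PREFIXES: frozenset[str] = _fourfold_prefixes()


def uniform_sense_frequencies() -> np.ndarray:
    """Uniform distribution over the 61 sense codons."""
    return np.full(N_SENSE, 1.0 / N_SENSE)


def validate_frequencies(pi: np.ndarray) -> np.ndarray:
    pi = np.asarray(pi, dtype=float)
    if pi.shape != (N_SENSE,):
        raise ValueError(f"codon frequency vector must have length {N_SENSE}")
    if not np.all(np.isfinite(pi)) or np.any(pi < 0):
        raise ValueError("codon frequencies must be finite and non-negative")
    if abs(pi.sum() - 1.0) > 1e-12:
        raise ValueError("codon frequencies must sum to 1 within 1e-12")
    return pi


def build_rate_matrix(pi: np.ndarray, kappa: float, omega: float) -> np.ndarray:
    """Scaled reversible codon rate matrix Q.

    Rows sum to zero; ``sum_i pi_i * (-q_ii) == 1`` so branch lengths are in
    expected substitutions per codon.
    """
    pi = validate_frequencies(pi)
    if not np.isfinite(kappa) or kappa <= 0:
        raise ValueError("kappa must be finite and > 0")
    if not np.isfinite(omega) or omega < 0:
        raise ValueError("omega must be finite and >= 0")
    rate = np.where(SINGLE_DIFF, 1.0, 0.0)
    rate = rate * np.where(TRANSITION, kappa, 1.0)
    rate = rate * np.where(SYNONYMOUS | ~SINGLE_DIFF, 1.0, omega)
    q = rate * pi[np.newaxis, :]
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    scale = -(pi * np.diag(q)).sum()
    if scale <= 0:
        raise ValueError("degenerate rate matrix (zero total flow)")
    return q / scale


def synonymous_flow_fraction(pi: np.ndarray, kappa: float, omega: float) -> float:
    """Fraction of the stationary substitution flow that is synonymous.

    With ``omega = 1`` this is the mutational-opportunity proportion of
    synonymous sites; three times that value is the per-codon synonymous
    site count.
    """
    pi = validate_frequencies(pi)
    rate = np.where(SINGLE_DIFF, 1.0, 0.0)
    rate = rate * np.where(TRANSITION, kappa, 1.0)
    rate = rate * np.where(SYNONYMOUS | ~SINGLE_DIFF, 1.0, omega)
    flow = pi[:, np.newaxis] * rate * pi[np.newaxis, :]
    total = flow[SINGLE_DIFF].sum()
    syn = flow[SINGLE_DIFF & SYNONYMOUS].sum()
    return float(syn / total)


class _Eigensystem:
    """Reversible-matrix eigendecomposition reused across branch lengths."""

    __slots__ = ("eigvals", "left", "right")

    def __init__(self, q: np.ndarray, pi: np.ndarray):
        sqrt_pi = np.sqrt(np.maximum(pi, 1e-300))
        b = (sqrt_pi[:, np.newaxis] * q) / sqrt_pi[np.newaxis, :]
        b = 0.5 * (b + b.T)  # enforce exact symmetry
        w, v = np.linalg.eigh(b)
        self.eigvals = w
        self.right = v / sqrt_pi[:, np.newaxis]  # D^{-1/2} V
        self.left = v.T * sqrt_pi[np.newaxis, :]  # V^T D^{1/2}

    def probabilities(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt), clipped to [0, 1] against round-off."""
        if t < 0:
            raise ValueError("branch length must be >= 0")
        p = (self.right * np.exp(self.eigvals * t)) @ self.left
        return np.clip(p, 0.0, 1.0)


@lru_cache(maxsize=8)
def _cached_eigensystem(pi_key: bytes, kappa: float, omega: float) -> _Eigensystem:
    pi = np.frombuffer(pi_key, dtype=float)
    return _Eigensystem(build_rate_matrix(pi, kappa, omega), pi)


def eigensystem(pi: np.ndarray, kappa: float, omega: float) -> _Eigensystem:
    """Cached eigendecomposition keyed on (pi, kappa, omega)."""
    pi = validate_frequencies(pi)
    return _cached_eigensystem(pi.tobytes(), float(kappa), float(omega))


def transition_probabilities(
    pi: np.ndarray, kappa: float, omega: float, t: float
) -> np.ndarray:
    """P(t) under the scaled codon model."""
    return eigensystem(pi, kappa, omega).probabilities(t)
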