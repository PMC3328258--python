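"""Independent brute-force oracles used only by the tests.

Deliberately naive reimplementations, structured differently from the
package code so that agreement is evidence rather than tautology.
"""

from __future__ import annotations

import itertools
import math

STOPS = {"TAA", "TAG", "TGA"}
COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def six_frame_orfs(seq: str, min_codons: int = 1, strands: str = "forward"):
    """Every maximal ATG->stop ORF, as (start, end, frame) on the forward
    strand, by scanning each ATG and walking to the next in-frame stop,
    keeping only ORFs not extendable to an earlier ATG."""
    results = set()
    strand_seqs = [(1, seq)] + ([(-1, revcomp(seq))] if strands == "both" else [])
    for strand, s in strand_seqs:
        n = len(s)
        for i in range(n - 2):
            if s[i : i + 3] != "ATG":
                continue
            # walk to next in-frame stop
            j = i
            stop = None
            while j + 3 <= n:
                if s[j : j + 3] in STOPS:
                    stop = j + 3
                    break
                j += 3
            if stop is None:
                continue
            # maximal: no in-frame ATG between the previous stop and i
            k = i - 3
            maximal = True
            while k >= 0:
                c = s[k : k + 3]
                if c in STOPS:
                    break
                if c == "ATG":
                    maximal = False
                    break
                k -= 3
            if not maximal:
                continue
            if (stop - i) // 3 < min_codons:
                continue
            frame = i % 3 + 1
            if strand == 1:
                results.add((i, stop, frame))
            else:
                results.add((n - stop, n - i, -frame))
    return results


def smith_waterman_score(a: str, b: str, matrix, open_gap: float,
                         extend_gap: float) -> float:
    """Textbook affine-gap local alignment (Gotoh), best score only.

    Gap of length k costs open_gap + (k - 1) * extend_gap, matching an
    aligner whose first gapped position scores -open_gap.
    """
    n, m = len(a), len(b)
    NEG = -1e18
    best = 0.0
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (vertical)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (horizontal)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - open_gap, E[i][j - 1] - extend_gap)
            F[i][j] = max(H[i - 1][j] - open_gap, F[i - 1][j] - extend_gap)
            diag = H[i - 1][j - 1] + matrix[a[i - 1], b[j - 1]]
            H[i][j] = max(0.0, diag, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def fisher_two_sided(table) -> float:
    """Two-sided Fisher exact p by enumerating the hypergeometric support
    and summing probabilities <= that of the observed table."""
    (a, b), (c, d) = table
    row1, row2 = a + b, c + d
    col1 = a + c
    n = row1 + row2

    def log_comb(n_, k_):
        return (math.lgamma(n_ + 1) - math.lgamma(k_ + 1)
                - math.lgamma(n_ - k_ + 1))

    def prob(x):
        return math.exp(log_comb(row1, x) + log_comb(row2, col1 - x)
                        - log_comb(n, col1))

    lo = max(0, col1 - row2)
    hi = min(row1, col1)
    p_obs = prob(a)
    return sum(p for x in range(lo, hi + 1)
               if (p := prob(x)) <= p_obs * (1 + 1e-9))


def mann_whitney_exact_p(x, y) -> float:
    """Two-sided exact Mann-Whitney p by enumerating every assignment of
    the pooled observations to the two groups (no ties assumed)."""
    pooled = list(x) + list(y)
    nx = len(x)

    def u_stat(xs, ys):
        return sum(1.0 for xi in xs for yi in ys if xi > yi)

    u_obs = u_stat(x, y)
    mean_u = nx * len(y) / 2.0
    dev_obs = abs(u_obs - mean_u)
    count = total = 0
    for combo in itertools.combinations(range(len(pooled)), nx):
        xs = [pooled[i] for i in combo]
        ys = [pooled[i] for i in range(len(pooled)) if i not in combo]
        total += 1
        if abs(u_stat(xs, ys) - mean_u) >= dev_obs - 1e-9:
            count += 1
    return count / total
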