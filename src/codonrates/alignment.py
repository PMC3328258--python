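"""Filtered codon-level pairwise alignment.

ORFs are translated, the proteins are aligned globally (BLOSUM62, affine
gaps, free end gaps so that truncated fragments are not forced to stretch),
and the alignment is mapped back to codons.  Columns are then filtered:
gap columns are removed, and short gap-free islands - aligned runs so short
that their homology is doubtful - are removed too.  Alignments left with
fewer than a minimum number of codons are discarded outright.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq

GAP = "---"


@dataclass(frozen=True)
class AlignScoring:
    matrix: str = "BLOSUM62"
    open_gap: float = 11.0
    extend_gap: float = 1.0
    free_end_gaps: bool = True


@dataclass(frozen=True)
class ColumnPolicy:
    """min_run_codons: gap-free runs of at most this many codon columns are
    dropped as unreliable; min_alignment_codons: alignments keeping fewer
    codons than this are discarded."""

    min_run_codons: int = 3
    min_alignment_codons: int = 30


@dataclass(frozen=True)
class CodonAlignment:
    """A pairwise codon alignment with a per-column keep/drop mask.

    aligned_a/aligned_b are gapped codon strings (gap = '---'); the mask
    holds None for kept columns or a drop reason ('gap' | 'short_run').
    """

    pair_id: str
    aligned_a: str
    aligned_b: str
    column_mask: tuple[Optional[str], ...] = ()
    discarded: bool = False
    discard_reason: str = ""

    def __post_init__(self):
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned sequences must have equal length")
        if len(self.aligned_a) % 3 != 0:
            raise ValueError("aligned length must be a multiple of 3")
        mask = self.column_mask or tuple([None] * self.n_columns)
        if len(mask) != self.n_columns:
            raise ValueError("column mask length must equal codon columns")
        object.__setattr__(self, "column_mask", tuple(mask))

    @property
    def n_columns(self) -> int:
        return len(self.aligned_a) // 3

    def column(self, i: int) -> tuple[str, str]:
        return self.aligned_a[3 * i : 3 * i + 3], self.aligned_b[3 * i : 3 * i + 3]

    @property
    def kept_codons(self) -> int:
        return sum(1 for m in self.column_mask if m is None)

    def kept_columns(self) -> list[tuple[str, str]]:
        return [self.column(i) for i in range(self.n_columns)
                if self.column_mask[i] is None]

    def ungapped(self, which: str) -> str:
        seq = self.aligned_a if which == "a" else self.aligned_b
        return seq.replace("-", "")


_STOPS = frozenset(("TAA", "TAG", "TGA"))


def _check_orf(name: str, orf: str) -> str:
    if len(orf) % 3 != 0:
        raise ValueError(f"{name}: ORF length must be a multiple of 3")
    if orf[-3:] in _STOPS:
        orf = orf[:-3]  # terminal stop is not aligned
    if not orf:
        raise ValueError(f"{name}: ORF must have at least one codon")
    for i in range(0, len(orf), 3):
        if orf[i : i + 3] in _STOPS:
            raise ValueError(f"{name}: internal stop codon at nucleotide {i}")
    return orf


def align_codons(
    orf_a: str,
    orf_b: str,
    pair_id: str = "",
    scoring: AlignScoring = AlignScoring(),
) -> CodonAlignment:
    """Protein-guided global codon alignment of two stop-free ORFs.

    Deterministic: of co-optimal alignments the aligner's first traceback is
    taken, which prefers aligned residues over gaps and opens gaps in the
    first sequence before the second.
    """
    orf_a = _check_orf("orf_a", orf_a.upper())
    orf_b = _check_orf("orf_b", orf_b.upper())
    prot_a = str(Seq(orf_a).translate())
    prot_b = str(Seq(orf_b).translate())
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(scoring.matrix)
    aligner.open_gap_score = -scoring.open_gap
    aligner.extend_gap_score = -scoring.extend_gap
    if scoring.free_end_gaps:
        aligner.end_gap_score = 0.0
    aln = aligner.align(prot_a, prot_b)[0]
    gapped_a = []
    gapped_b = []
    ia = ib = 0
    col_a, col_b = str(aln[0]), str(aln[1])
    for ca, cb in zip(col_a, col_b):
        if ca == "-":
            gapped_a.append(GAP)
        else:
            gapped_a.append(orf_a[3 * ia : 3 * ia + 3])
            ia += 1
        if cb == "-":
            gapped_b.append(GAP)
        else:
            gapped_b.append(orf_b[3 * ib : 3 * ib + 3])
            ib += 1
    return CodonAlignment(pair_id, "".join(gapped_a), "".join(gapped_b))


def filter_columns(
    alignment: CodonAlignment, policy: ColumnPolicy = ColumnPolicy()
) -> CodonAlignment:
    """Recompute the column mask: gap columns out, short gap-free islands
    out, whole alignment discarded when too little is left.  Idempotent -
    the mask is always derived afresh from the aligned strings."""
    n = alignment.n_columns
    is_gap = [GAP in alignment.column(i) for i in range(n)]
    mask: list[Optional[str]] = ["gap" if g else None for g in is_gap]
    i = 0
    while i < n:
        if is_gap[i]:
            i += 1
            continue
        j = i
        while j < n and not is_gap[j]:
            j += 1
        if j - i <= policy.min_run_codons:
            for k in range(i, j):
                mask[k] = "short_run"
        i = j
    out = replace(alignment, column_mask=tuple(mask),
                  discarded=False, discard_reason="")
    if out.kept_codons < policy.min_alignment_codons:
        out = replace(out, discarded=True, discard_reason="too_short")
    return out


def filter_report(alignments: list[CodonAlignment]):
    import pandas as pd

    rows = []
    for a in alignments:
        reasons = [m for m in a.column_mask if m is not None]
        rows.append(
            {
                "pair_id": a.pair_id,
                "kept_codons": a.kept_codons,
                "dropped_gap": reasons.count("gap"),
                "dropped_short_run": reasons.count("short_run"),
                "discarded_flag": a.discarded,
            }
        )
    return pd.DataFrame(
        rows, columns=["pair_id", "kept_codons", "dropped_gap",
                       "dropped_short_run", "discarded_flag"]
    )
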