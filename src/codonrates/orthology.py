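"""1:1 orthologue inference by reciprocal best hit (RBH).

Hits come either from ingested precomputed similarity searches in BLAST
tabular format (authoritative when provided) or from the built-in exact
Smith-Waterman local-alignment search, which scores with BLOSUM62 affine
gaps and reports approximate Karlin-Altschul e-values using the standard
ungapped BLOSUM62 constants (lambda = 0.318, K = 0.134).  The default
acceptance threshold is e <= 1e-20.

Ties for the best hit in either direction are resolved conservatively: an
ambiguous best hit disqualifies the gene, keeping the output strictly 1:1.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from Bio.Align import PairwiseAligner, substitution_matrices

DEFAULT_E_MAX = 1e-20
_KA_LAMBDA = 0.318
_KA_K = 0.134


@dataclass(frozen=True)
class HitRecord:
    query_id: str
    subject_id: str
    bitscore: float
    evalue: float
    query_interval: tuple[int, int] = (0, 0)
    subject_interval: tuple[int, int] = (0, 0)
    frame: int = 0

    def __post_init__(self):
        if self.evalue < 0:
            raise ValueError("e-value must be >= 0")


@dataclass(frozen=True)
class OrthologPair:
    id_a: str
    id_b: str
    evidence: tuple[HitRecord, HitRecord]


# ---------------------------------------------------------------------------
# BLAST tabular ingestion (outfmt-6 dialect, 12 columns)
# ---------------------------------------------------------------------------

_OUTFMT6_COLS = 12


def read_blast_tabular(path: str | os.PathLike) -> list[HitRecord]:
    """Parse a 12-column BLAST tabular file.

    File coordinates are 1-based inclusive and converted to the internal
    0-based half-open convention; a subject interval with start > end marks
    a minus-strand hit (frame -1).
    """
    hits = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != _OUTFMT6_COLS:
                raise ValueError(
                    f"{path}: line {lineno}: expected {_OUTFMT6_COLS} columns, "
                    f"got {len(fields)}"
                )
            try:
                qstart, qend = int(fields[6]), int(fields[7])
                sstart, send = int(fields[8]), int(fields[9])
                evalue = float(fields[10])
                bitscore = float(fields[11])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
            if evalue < 0:
                raise ValueError(f"{path}: line {lineno}: negative e-value")
            frame = 0
            if sstart > send:
                sstart, send = send, sstart
                frame = -1
            hits.append(
                HitRecord(
                    query_id=fields[0],
                    subject_id=fields[1],
                    bitscore=bitscore,
                    evalue=evalue,
                    query_interval=(qstart - 1, qend),
                    subject_interval=(sstart - 1, send),
                    frame=frame,
                )
            )
    return hits


# ---------------------------------------------------------------------------
# built-in local alignment search
# ---------------------------------------------------------------------------


def _make_aligner(open_gap: float, extend_gap: float) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -open_gap
    aligner.extend_gap_score = -extend_gap
    return aligner


def karlin_altschul_evalue(score: float, m: int, n: int) -> float:
    """Approximate e-value for a raw local-alignment score."""
    bits = (_KA_LAMBDA * score - math.log(_KA_K)) / math.log(2.0)
    return m * n * 2.0 ** (-bits)


def local_align_search(
    queries: Sequence[tuple[str, str]],
    subjects: Sequence[tuple[str, str]],
    e_max: float = DEFAULT_E_MAX,
    open_gap: float = 11.0,
    extend_gap: float = 1.0,
) -> list[HitRecord]:
    """Exact best local alignment for every query x subject protein pair.

    Returns only hits with e-value <= e_max.  Intended for the moderate set
    sizes of a two-species study; quadratic in the number of sequences.
    """
    aligner = _make_aligner(open_gap, extend_gap)
    hits = []
    for qid, qseq in queries:
        for sid, sseq in subjects:
            if not qseq or not sseq:
                continue
            score = aligner.score(qseq, sseq)
            evalue = karlin_altschul_evalue(score, len(qseq), len(sseq))
            if evalue > e_max:
                continue
            aln = aligner.align(qseq, sseq)[0]
            tblocks, qblocks = aln.aligned
            qiv = (int(tblocks[0][0]), int(tblocks[-1][1]))
            siv = (int(qblocks[0][0]), int(qblocks[-1][1]))
            bits = (_KA_LAMBDA * score - math.log(_KA_K)) / math.log(2.0)
            hits.append(
                HitRecord(qid, sid, round(bits, 2), evalue, qiv, siv, frame=0)
            )
    return hits


# ---------------------------------------------------------------------------
# reciprocal best hit
# ---------------------------------------------------------------------------


def _best_hsp_per_pair(hits: Iterable[HitRecord]) -> dict[tuple[str, str], HitRecord]:
    best: dict[tuple[str, str], HitRecord] = {}
    for h in hits:
        key = (h.query_id, h.subject_id)
        cur = best.get(key)
        if cur is None or (h.evalue, -h.bitscore) < (cur.evalue, -cur.bitscore):
            best[key] = h
    return best


def _unique_best_per_query(
    per_pair: dict[tuple[str, str], HitRecord], e_max: float
) -> dict[str, HitRecord]:
    by_query: dict[str, list[HitRecord]] = {}
    for (q, _), h in per_pair.items():
        if h.evalue <= e_max:
            by_query.setdefault(q, []).append(h)
    best: dict[str, HitRecord] = {}
    for q, hs in by_query.items():
        hs.sort(key=lambda h: (h.evalue, -h.bitscore, h.subject_id))
        if len(hs) > 1 and (hs[0].evalue, hs[0].bitscore) == (hs[1].evalue, hs[1].bitscore):
            continue  # ambiguous best hit: excluded, stays 1:1
        best[q] = hs[0]
    return best


def reciprocal_best_hits(
    hits_ab: Iterable[HitRecord],
    hits_ba: Iterable[HitRecord],
    e_max: float = DEFAULT_E_MAX,
) -> list[OrthologPair]:
    """Pairs (a, b) where b is a's unique best hit and vice versa, both with
    e-value <= e_max."""
    best_ab = _unique_best_per_query(_best_hsp_per_pair(hits_ab), e_max)
    best_ba = _unique_best_per_query(_best_hsp_per_pair(hits_ba), e_max)
    pairs = []
    for a, hab in sorted(best_ab.items()):
        b = hab.subject_id
        hba = best_ba.get(b)
        if hba is not None and hba.subject_id == a:
            pairs.append(OrthologPair(a, b, (hab, hba)))
    return pairs


# ---------------------------------------------------------------------------
# pair list I/O
# ---------------------------------------------------------------------------


def write_ortholog_pairs(pairs: Iterable[OrthologPair], path) -> None:
    frame = pd.DataFrame(
        [
            {
                "id_a": p.id_a,
                "id_b": p.id_b,
                "evalue_ab": p.evidence[0].evalue,
                "evalue_ba": p.evidence[1].evalue,
            }
            for p in pairs
        ],
        columns=["id_a", "id_b", "evalue_ab", "evalue_ba"],
    )
    frame.to_csv(path, sep="\t", index=False)


def read_ortholog_list(path) -> list[tuple[str, str]]:
    """Externally supplied 1:1 orthologue list: TSV with id_a, id_b columns
    (stand-in for precomputed orthologue predictions)."""
    frame = pd.read_csv(path, sep="\t")
    if not {"id_a", "id_b"}.issubset(frame.columns):
        raise ValueError(f"{path}: expected columns id_a, id_b")
    return list(zip(frame["id_a"].astype(str), frame["id_b"].astype(str)))
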