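"""ORF enumeration and the two selection strategies used for cDNA inputs.

Full-length cDNA sets are handled with start-to-stop ORFs plus
homology-ranked selection (best similarity hit wins; longest ORF as a
fallback when nothing has a hit).  Fragmented EST-cluster consensus
sequences may lack the start and/or stop codon, so for those the ORF is
chosen by reading-frame agreement with a reference similarity hit, and
open-ended ORFs at sequence boundaries are considered.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import pandas as pd
from Bio.Seq import Seq

from .io import SequenceRecord

STOPS = frozenset(("TAA", "TAG", "TGA"))

_FRAME_ORDER = {1: 0, 2: 1, 3: 2, -1: 3, -2: 4, -3: 5}


class NoOrfError(ValueError):
    """The sequence has no ORF structure at all (distinct from 'no hit')."""


@dataclass(frozen=True)
class OrfRecord:
    """A candidate coding region on a parent transcript.

    start/end are 0-based half-open on the forward strand of the parent;
    ``codons`` is the in-frame nucleotide string as read (reverse-complemented
    for negative frames).  A terminal stop, when present, is included.
    """

    parent_id: str
    frame: int
    start: int
    end: int
    codons: str
    has_start: bool
    has_stop: bool

    def __post_init__(self):
        if (self.end - self.start) % 3 != 0:
            raise ValueError("ORF span must be a multiple of 3")
        if len(self.codons) != self.end - self.start:
            raise ValueError("codons length must equal end - start")
        if self.has_start and not self.codons.startswith("ATG"):
            raise ValueError("has_start ORF must begin with ATG")
        if self.has_stop and self.codons[-3:] not in STOPS:
            raise ValueError("has_stop ORF must end with a stop codon")

    @property
    def n_codons(self) -> int:
        return len(self.codons) // 3

    @property
    def key(self) -> str:
        return f"{self.parent_id}:{self.frame:+d}:{self.start}-{self.end}"

    def coding_codons(self) -> str:
        """The codon string with any terminal stop removed."""
        if self.has_stop:
            return self.codons[:-3]
        return self.codons


def _orfs_on_strand(
    record: SequenceRecord,
    seq: str,
    strand: int,
    min_codons: int,
    include_open_ended: bool,
) -> list[OrfRecord]:
    length = len(record.seq)
    out = []
    seen: set[tuple[int, int, int]] = set()

    def emit(offset: int, c_start: int, c_end: int, has_start: bool, has_stop: bool):
        """codon indices [c_start, c_end) within the frame at this offset"""
        if c_end - c_start < min_codons:
            return
        s = offset + 3 * c_start
        e = offset + 3 * c_end
        codons = seq[s:e]
        if strand == 1:
            start, end, frame = s, e, offset + 1
        else:
            start, end, frame = length - e, length - s, -(offset + 1)
        key = (start, end, frame)
        if key in seen:
            return
        seen.add(key)
        out.append(OrfRecord(record.id, frame, start, end, codons, has_start, has_stop))

    for offset in range(3):
        m = (len(seq) - offset) // 3
        codons = [seq[offset + 3 * i : offset + 3 * i + 3] for i in range(m)]
        region_start = 0
        last_stop = -1
        for i, codon in enumerate(codons + [None]):
            at_end = codon is None
            if not at_end and codon not in STOPS:
                continue
            # region [region_start, i]; i is a stop index or m (sequence end)
            stop_incl = i + 1 if not at_end else i
            atg = next((j for j in range(region_start, i) if codons[j] == "ATG"), None)
            if not at_end and atg is not None:
                emit(offset, atg, stop_incl, True, True)
            if include_open_ended:
                if region_start == 0 and (atg is None or atg != 0):
                    # 5'-truncated candidate from the sequence boundary
                    emit(offset, 0, stop_incl, codons[:1] == ["ATG"], not at_end)
                if at_end and region_start <= i - 1:
                    if atg is not None:
                        emit(offset, atg, i, True, False)
                    elif region_start > 0:
                        pass  # lacks both ends away from boundaries: not a candidate
            if not at_end:
                last_stop = i
                region_start = i + 1
    return out


def find_orfs(
    record: SequenceRecord,
    min_codons: int = 1,
    strands: Literal["forward", "both"] = "forward",
    include_open_ended: bool = False,
) -> list[OrfRecord]:
    """Enumerate maximal ORFs, sorted by length desc, then start, then frame.

    Start-to-stop ORFs run from the first ATG after the previous in-frame
    stop through the stop codon.  With ``include_open_ended`` candidates
    missing the start and/or stop at sequence boundaries are added (for
    truncated EST-cluster fragments).  Inputs are oriented cDNA by default,
    so only forward frames are scanned unless ``strands='both'``.
    """
    if min_codons < 1:
        raise ValueError("min_codons must be >= 1")
    if strands not in ("forward", "both"):
        raise ValueError("strands must be 'forward' or 'both'")
    orfs = _orfs_on_strand(record, record.seq, 1, min_codons, include_open_ended)
    if strands == "both":
        rc = str(Seq(record.seq).reverse_complement())
        orfs += _orfs_on_strand(record, rc, -1, min_codons, include_open_ended)
    orfs.sort(key=lambda o: (-o.n_codons, o.start, _FRAME_ORDER[o.frame]))
    return orfs


@dataclass(frozen=True)
class OrfHit:
    """A similarity hit supporting one enumerated ORF."""

    orf_key: str
    evalue: float
    bitscore: float


def select_orf_by_homology(
    orfs: Sequence[OrfRecord],
    hits: Iterable[OrfHit],
    fallback_longest: bool = True,
) -> tuple[OrfRecord, str] | None:
    """Pick the ORF owning the best similarity hit; homology outranks length.

    Best hit = lowest e-value, ties by higher bitscore, then longer ORF,
    then smaller start.  With no hits at all, the longest ORF is returned
    when ``fallback_longest`` is set (rule = "longest"), else None.
    """
    if not orfs:
        raise NoOrfError("no ORF structure in sequence")
    by_key = {o.key: o for o in orfs}
    best = None
    for hit in hits:
        orf = by_key.get(hit.orf_key)
        if orf is None:
            raise KeyError(f"hit references unknown ORF {hit.orf_key}")
        cand = (hit.evalue, -hit.bitscore, -orf.n_codons, orf.start, orf)
        if best is None or cand[:4] < best[:4]:
            best = cand
    if best is not None:
        return best[4], "homology"
    if fallback_longest:
        return orfs[0], "longest"  # find_orfs order: longest, then smaller start
    return None


@dataclass(frozen=True)
class ReferenceHit:
    """A similarity hit locating the coding frame on a fragment: the aligned
    interval on the fragment (0-based half-open, forward strand) and the
    reading frame it implies."""

    start: int
    end: int
    frame: int


def select_orf_by_reference_frame(
    record: SequenceRecord,
    reference_hit: ReferenceHit,
    orfs: Sequence[OrfRecord],
) -> OrfRecord | None:
    """Among ORFs in the hit's frame, return the one overlapping the hit
    interval the most; None when no ORF shares the frame (the fragment is
    then excluded downstream)."""
    if not (0 <= reference_hit.start < reference_hit.end <= len(record.seq)):
        raise ValueError("reference hit interval outside the record")
    best = None
    for orf in orfs:
        if orf.frame != reference_hit.frame:
            continue
        ov = min(orf.end, reference_hit.end) - max(orf.start, reference_hit.start)
        if ov <= 0:
            continue
        cand = (-ov, -orf.n_codons, orf.start, orf)
        if best is None or cand[:3] < best[:3]:
            best = cand
    return None if best is None else best[3]


def orf_report(selected: Iterable[tuple[str, OrfRecord, str]]) -> pd.DataFrame:
    """ORF report with 1-based inclusive coordinates for human consumption."""
    rows = [
        {
            "parent_id": parent,
            "frame": orf.frame,
            "start1": orf.start + 1,
            "end1": orf.end,
            "n_codons": orf.n_codons,
            "has_start": orf.has_start,
            "has_stop": orf.has_stop,
            "selection_rule": rule,
        }
        for parent, orf, rule in selected
    ]
    return pd.DataFrame(
        rows,
        columns=["parent_id", "frame", "start1", "end1", "n_codons",
                 "has_start", "has_stop", "selection_rule"],
    )
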