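"""Open-reading-frame detection and SSR placement relative to ORFs.

An ORF is an ATG start codon followed, in the same reading frame, by a
stop codon (TAA, TAG or TGA) at a distance of at least ``min_orf_len``
nt, with no in-frame stop codon in between.  The reported span runs from
the first base of the ATG to the last base before the stop codon, so its
length is a multiple of 3 and excludes the stop.

Two start-codon conventions are supported for maximal stop-to-stop
segments that contain several ATGs:

* ``"longest"`` (default): the first in-frame ATG after the previous
  in-frame stop — the standard ORF convention;
* ``"innermost"``: the last in-frame ATG before the stop, i.e. the ATG
  with no further ATG between it and the stop.

When ORFs in different reading frames (or strands) overlap, the longer
one is kept and the shorter discarded, resolved greedily by descending
length over the whole candidate set (ties broken by smaller start, then
forward strand, then frame).

SSRs are then classified as ``inside`` (span fully within a retained
ORF), ``outside`` (disjoint from all retained ORFs) or ``bridging``
(partial overlap); bridging SSRs are excluded from the inside/outside
statistics downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .sequence_io import SequenceRecord
from .ssr_engine import SSRLocus

__all__ = [
    "ORFRegion",
    "PlacementCall",
    "find_orfs",
    "resolve_overlaps",
    "classify_placement",
    "orf_fraction",
]

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
START_CODON = "ATG"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, slots=True)
class ORFRegion:
    """One predicted open reading frame.

    ``start``/``end`` are 0-based half-open on the FORWARD strand
    regardless of the ORF's strand; ``frame`` is the codon offset (0/1/2)
    on the ORF's own strand.  ``length == end - start`` counts coding
    bases only (stop codon excluded).
    """

    seq_id: str
    strand: str  # "+" | "-"
    frame: int
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.frame not in (0, 1, 2):
            raise ValueError(f"frame must be 0, 1 or 2, got {self.frame}")
        if self.end <= self.start:
            raise ValueError("empty ORF span")
        if (self.end - self.start) % 3:
            raise ValueError("ORF length must be a multiple of 3")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True, slots=True)
class PlacementCall:
    """Placement of one SSR relative to the retained ORF set."""

    ssr: SSRLocus
    status: str  # "inside" | "outside" | "bridging"

    def __post_init__(self) -> None:
        if self.status not in ("inside", "outside", "bridging"):
            raise ValueError(f"invalid placement status {self.status!r}")


def _scan_strand(
    seq: str, min_orf_len: int, start_rule: str
) -> list[tuple[int, int, int]]:
    """Candidate ORFs on one strand of ``seq``: ``(frame, start, end)``.

    Coordinates are in the coordinate system of ``seq`` itself; codons
    containing N match neither ATG nor any stop codon (ATG/TAA/TAG/TGA
    contain no N, so plain equality suffices).
    """
    out: list[tuple[int, int, int]] = []
    n = len(seq)
    for frame in range(3):
        first_atg: int | None = None
        last_atg: int | None = None
        for pos in range(frame, n - 2, 3):
            codon = seq[pos : pos + 3]
            if codon in STOP_CODONS:
                atg = first_atg if start_rule == "longest" else last_atg
                if atg is not None and pos - atg >= min_orf_len:
                    out.append((frame, atg, pos))
                first_atg = last_atg = None
            elif codon == START_CODON:
                if first_atg is None:
                    first_atg = pos
                last_atg = pos
    return out


def find_orfs(
    record: SequenceRecord,
    min_orf_len: int = 100,
    strands: str = "both",
    start_rule: str = "longest",
    resolve: bool = True,
) -> list[ORFRegion]:
    """Find ORFs of at least ``min_orf_len`` coding nt in a record.

    ``strands`` is ``"both"`` (all six frames; appropriate for unoriented
    genomic sequence such as BAC ends) or ``"forward"`` (three frames;
    for oriented transcripts).  With ``resolve=True`` (default) the
    cross-frame overlap rule is applied before returning; set it to
    ``False`` to obtain raw candidates.
    """
    if min_orf_len < 3:
        raise ValueError("min_orf_len must be >= 3")
    if strands not in ("both", "forward"):
        raise ValueError(f"strands must be 'both' or 'forward', got {strands!r}")
    if start_rule not in ("longest", "innermost"):
        raise ValueError(f"start_rule must be 'longest' or 'innermost', got {start_rule!r}")

    seq = record.residues
    candidates: list[ORFRegion] = []
    for frame, start, end in _scan_strand(seq, min_orf_len, start_rule):
        candidates.append(ORFRegion(record.id, "+", frame, start, end))
    if strands == "both":
        rc = _revcomp(seq)
        n = len(seq)
        for frame, start, end in _scan_strand(rc, min_orf_len, start_rule):
            # map reverse-strand span back to forward coordinates
            candidates.append(ORFRegion(record.id, "-", frame, n - end, n - start))
    if resolve:
        return resolve_overlaps(candidates)
    candidates.sort(key=lambda o: (o.start, o.end, o.strand, o.frame))
    return candidates


def resolve_overlaps(candidates: Sequence[ORFRegion]) -> list[ORFRegion]:
    """Keep the longer of any pair of overlapping ORFs.

    Greedy retention by descending length (ties: smaller start, then
    ``+`` strand, then lower frame); a candidate overlapping any
    already-retained ORF is discarded.  Output is order-independent of
    the input and sorted by position.
    """
    by_seq: dict[str, list[ORFRegion]] = {}
    for c in candidates:
        by_seq.setdefault(c.seq_id, []).append(c)
    retained: list[ORFRegion] = []
    for seq_id in sorted(by_seq):
        group = sorted(
            by_seq[seq_id],
            key=lambda o: (-o.length, o.start, 0 if o.strand == "+" else 1, o.frame),
        )
        kept: list[ORFRegion] = []
        for cand in group:
            if all(cand.end <= k.start or cand.start >= k.end for k in kept):
                kept.append(cand)
        retained.extend(kept)
    retained.sort(key=lambda o: (o.seq_id, o.start, o.end))
    return retained


def classify_placement(
    ssrs: Iterable[SSRLocus], orfs: Sequence[ORFRegion]
) -> list[PlacementCall]:
    """Classify each SSR as inside, outside or bridging the retained ORFs.

    The three statuses are mutually exclusive and exhaustive; bridging
    SSRs (partial overlap with an ORF boundary) are flagged so downstream
    tests can discard them.
    """
    orfs_by_seq: dict[str, list[ORFRegion]] = {}
    for orf in orfs:
        orfs_by_seq.setdefault(orf.seq_id, []).append(orf)
    calls: list[PlacementCall] = []
    for ssr in ssrs:
        status = "outside"
        for orf in orfs_by_seq.get(ssr.seq_id, ()):
            if ssr.start >= orf.start and ssr.end <= orf.end:
                status = "inside"
                break
            if ssr.start < orf.end and ssr.end > orf.start:
                status = "bridging"
                break
        calls.append(PlacementCall(ssr=ssr, status=status))
    return calls


def orf_fraction(orfs: Iterable[ORFRegion], total_bp: int) -> float:
    """Fraction of dataset base pairs covered by retained ORFs.

    Retained ORFs never overlap, so coverage is the plain sum of lengths.
    """
    if total_bp <= 0:
        raise ValueError("total_bp must be positive")
    return sum(o.length for o in orfs) / total_bp
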