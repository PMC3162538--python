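"""Perfect and compound microsatellite detection with canonical motif classes.

Detection follows the MISA-style convention: a perfect SSR is a maximal,
leftmost-anchored run of whole repeat units, reported only at its
primitive (shortest) unit length.  The default thresholds — total repeat
length >= 12 nt AND >= 3 repeat units — mean a dinucleotide needs 6 units,
a trinucleotide 4, and tetra- through octanucleotides 3.

Motif classes group a repeat unit with its cyclic rotations ONLY; a motif
and its reverse complement are distinct classes (AG and CT are different
classes).  This yields 6 dinucleotide and 20 trinucleotide classes.  Note
that many SSR tools additionally merge reverse complements; this package
deliberately does not.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Sequence

from .sequence_io import SequenceRecord

__all__ = [
    "SSRLocus",
    "SSRSearchConfig",
    "canonical_motif",
    "motif_classes",
    "is_primitive",
    "detect_perfect_ssrs",
    "group_compound_ssrs",
    "scan_dataset",
]

_ACGT = frozenset("ACGT")


def is_primitive(unit: str) -> bool:
    """True if ``unit`` is not a whole-number repetition of a shorter motif."""
    return (unit + unit).find(unit, 1) == len(unit)


@lru_cache(maxsize=65536)
def canonical_motif(unit: str) -> str:
    """Canonical class label: the lexicographically smallest cyclic rotation.

    Rotation only — reverse complements are NOT merged, so e.g.
    ``canonical_motif("TC") == "CT"`` while ``canonical_motif("GA") == "AG"``.

    Raises ``ValueError`` for units containing characters outside ACGT or
    units that are repetitions of a shorter motif (those belong to the
    shorter motif's class).
    """
    if not unit or not _ACGT.issuperset(unit):
        raise ValueError(f"motif unit must be non-empty over ACGT, got {unit!r}")
    if not is_primitive(unit):
        raise ValueError(f"{unit!r} is a repetition of a shorter motif")
    doubled = unit + unit
    return min(doubled[i : i + len(unit)] for i in range(len(unit)))


@lru_cache(maxsize=None)
def motif_classes(unit_len: int) -> tuple[str, ...]:
    """All canonical motif classes of a given unit length, sorted.

    Homopolymeric and sub-motif-repetition units are excluded (they are
    not primitive at this length).  There are 6 classes for ``unit_len=2``
    and 20 for ``unit_len=3``.
    """
    classes = {
        canonical_motif("".join(p))
        for p in itertools.product("ACGT", repeat=unit_len)
        if is_primitive("".join(p))
    }
    return tuple(sorted(classes))


@dataclass(frozen=True, slots=True)
class SSRLocus:
    """One detected microsatellite.

    ``start``/``end`` are 0-based half-open on the forward strand.  For a
    perfect locus ``end - start == unit_len * n_units``.  A compound locus
    spans from the first to the last of its perfect ``members`` (gap
    sequence included in the span), carries ``unit_len == 0`` and
    ``n_units`` equal to the summed member unit counts.
    """

    seq_id: str
    start: int
    end: int
    unit_len: int
    motif_observed: str
    n_units: int
    kind: str = "perfect"  # "perfect" | "compound"
    members: tuple["SSRLocus", ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in ("perfect", "compound"):
            raise ValueError(f"kind must be perfect or compound, got {self.kind!r}")
        if self.end <= self.start:
            raise ValueError("empty SSR span")
        if self.kind == "perfect":
            if self.total_len != self.unit_len * self.n_units:
                raise ValueError(
                    f"perfect SSR span {self.total_len} != "
                    f"unit_len {self.unit_len} x n_units {self.n_units}"
                )
        else:
            if len(self.members) < 2:
                raise ValueError("compound SSR needs >= 2 members")

    @property
    def total_len(self) -> int:
        return self.end - self.start

    @property
    def motif_class(self) -> str:
        if self.kind == "perfect":
            return canonical_motif(self.motif_observed)
        return "+".join(m.motif_class for m in self.members)


@dataclass(frozen=True, slots=True)
class SSRSearchConfig:
    """Search thresholds.

    ``min_total_len`` and ``min_units`` act as a conjunction: a run
    qualifies only if it has at least ``min_units`` whole units AND spans
    at least ``min_total_len`` nt.  ``d_max`` is the maximum interruption
    (nt) between consecutive perfect loci merged into a compound SSR.
    Mononucleotide runs are excluded by default (``unit_len_min=2``) but
    the k range may be widened to 1-10.
    """

    min_total_len: int = 12
    min_units: int = 3
    unit_len_min: int = 2
    unit_len_max: int = 8
    d_max: int = 100

    def __post_init__(self) -> None:
        if not (1 <= self.unit_len_min <= self.unit_len_max <= 10):
            raise ValueError("unit length range must satisfy 1 <= min <= max <= 10")
        if self.min_total_len < self.unit_len_min:
            raise ValueError("min_total_len must be >= smallest unit length")
        if self.min_units < 1:
            raise ValueError("min_units must be >= 1")
        if self.d_max < 0:
            raise ValueError("d_max must be >= 0")

    def min_units_for(self, unit_len: int) -> int:
        return max(self.min_units, -(-self.min_total_len // unit_len))


@lru_cache(maxsize=None)
def _unit_pattern(unit_len: int) -> re.Pattern[str]:
    # Leftmost greedy whole-unit repetition; N never matches.
    return re.compile(rf"([ACGT]{{{unit_len}}})\1+")


def detect_perfect_ssrs(
    record: SequenceRecord, cfg: SSRSearchConfig | None = None
) -> list[SSRLocus]:
    """Detect all perfect microsatellites in one record.

    Each reported locus is a maximal leftmost run of whole units meeting
    the configured thresholds.  A run whose unit is a repetition of a
    shorter motif (e.g. ACAC at k=4) is reported only at the shorter unit
    length.  Runs never cross an N.  Loci of different unit lengths may
    overlap; loci of the same unit length never do.  Output is sorted by
    start position (ties by unit length).
    """
    cfg = cfg or SSRSearchConfig()
    seq = record.residues
    loci: list[SSRLocus] = []
    for k in range(cfg.unit_len_min, cfg.unit_len_max + 1):
        need_units = cfg.min_units_for(k)
        if need_units * k > len(seq):
            continue
        for m in _unit_pattern(k).finditer(seq):
            unit = m.group(1)
            if not is_primitive(unit):
                continue
            n_units = (m.end() - m.start()) // k
            if n_units < need_units:
                continue
            loci.append(
                SSRLocus(
                    seq_id=record.id,
                    start=m.start(),
                    end=m.start() + n_units * k,
                    unit_len=k,
                    motif_observed=unit,
                    n_units=n_units,
                )
            )
    loci.sort(key=lambda l: (l.start, l.unit_len))
    return loci


def group_compound_ssrs(
    perfect: Sequence[SSRLocus], cfg: SSRSearchConfig | None = None
) -> tuple[list[SSRLocus], list[SSRLocus]]:
    """Partition perfect loci into stand-alone perfect and compound SSRs.

    Consecutive perfect loci on the same sequence whose gap is at most
    ``cfg.d_max`` nt (overlaps count as gap <= 0) are merged into one
    compound locus; its members are removed from the perfect list.  The
    two output lists partition the input.
    """
    cfg = cfg or SSRSearchConfig()
    perfect = sorted(perfect, key=lambda l: (l.seq_id, l.start, l.unit_len))
    perfect_only: list[SSRLocus] = []
    compound: list[SSRLocus] = []
    chain: list[SSRLocus] = []

    def flush() -> None:
        if len(chain) >= 2:
            compound.append(
                SSRLocus(
                    seq_id=chain[0].seq_id,
                    start=chain[0].start,
                    end=max(m.end for m in chain),
                    unit_len=0,
                    motif_observed="",
                    n_units=sum(m.n_units for m in chain),
                    kind="compound",
                    members=tuple(chain),
                )
            )
        elif chain:
            perfect_only.append(chain[0])
        chain.clear()

    for locus in perfect:
        if chain and (
            locus.seq_id != chain[-1].seq_id
            or locus.start - max(m.end for m in chain) > cfg.d_max
        ):
            flush()
        chain.append(locus)
    flush()
    return perfect_only, compound


def scan_dataset(
    records: Iterable[SequenceRecord], cfg: SSRSearchConfig | None = None
) -> tuple[list[SSRLocus], list[SSRLocus]]:
    """Detect and compound-group SSRs over a whole dataset.

    Returns ``(perfect_only, compound)``.
    """
    cfg = cfg or SSRSearchConfig()
    all_perfect: list[SSRLocus] = []
    for rec in records:
        all_perfect.extend(detect_perfect_ssrs(rec, cfg))
    return group_compound_ssrs(all_perfect, cfg)
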