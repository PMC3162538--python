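"""Sequence dataset I/O and composition summaries.

Sequences are held as plain uppercase strings over the DNA alphabet
``{A, C, G, T, N}``.  Internally every coordinate in this package is
0-based half-open; exported files (GFF3, TSV) use 1-based inclusive
coordinates, following genome-annotation convention.
"""

from __future__ import annotations

import gzip
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

__all__ = [
    "SequenceRecord",
    "DatasetSummary",
    "FastaParseError",
    "read_fasta",
    "write_fasta",
    "summarize_dataset",
    "write_summary_tsv",
    "write_features_gff3",
    "read_features_gff3",
]

_VALID_RESIDUES = frozenset("ACGTN")
_RESIDUE_RE = re.compile(r"[^ACGTN]")


class FastaParseError(ValueError):
    """Raised when a FASTA file is malformed or contains illegal residues."""


@dataclass(frozen=True, slots=True)
class SequenceRecord:
    """A single nucleotide sequence belonging to a named dataset.

    Parameters
    ----------
    id
        Non-empty identifier, unique within its dataset.
    residues
        Uppercase nucleotide string over ``{A, C, G, T, N}``.
    dataset
        Dataset label, e.g. ``"BES"``, ``"EST"`` or ``"synthetic"``.
    """

    id: str
    residues: str
    dataset: str = "default"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if len(self.residues) < 1:
            raise ValueError(f"{self.id}: sequence must contain at least one residue")
        bad = _RESIDUE_RE.search(self.residues)
        if bad is not None:
            raise FastaParseError(
                f"record {self.id!r}: illegal residue {bad.group()!r} "
                f"at offset {bad.start()}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True, slots=True)
class DatasetSummary:
    """Dataset-level size and composition totals.

    ``gc_fraction`` is computed over A/C/G/T only; N bases are excluded
    from the denominator.  ``base_counts`` keeps the raw per-base tallies
    so downstream code can build zero-order compositional expectations.
    """

    dataset: str
    n_records: int
    total_bp: int
    gc_fraction: float
    base_counts: Mapping[str, int] = field(default_factory=dict)

    @property
    def total_mbp(self) -> float:
        return self.total_bp / 1e6

    @property
    def base_freqs(self) -> dict[str, float]:
        """Frequencies of A/C/G/T among non-N bases."""
        acgt = sum(self.base_counts.get(b, 0) for b in "ACGT")
        if acgt == 0:
            raise ValueError(f"dataset {self.dataset!r} has no A/C/G/T bases")
        return {b: self.base_counts.get(b, 0) / acgt for b in "ACGT"}


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path: str | Path, dataset: str = "default") -> list[SequenceRecord]:
    """Read a (optionally gzipped) FASTA file into :class:`SequenceRecord` s.

    Residues are uppercased; file order is preserved.  Raises
    :class:`FastaParseError` on empty files, duplicate ids or residues
    outside ``{A, C, G, T, N}``.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    with _open_text(path) as handle:
        for entry in SeqIO.parse(handle, "fasta"):
            if not entry.id:
                raise FastaParseError(f"{path}: FASTA entry with empty header")
            if entry.id in seen:
                raise FastaParseError(f"{path}: duplicate record id {entry.id!r}")
            seen.add(entry.id)
            records.append(
                SequenceRecord(entry.id, str(entry.seq).upper(), dataset=dataset)
            )
    if not records:
        raise FastaParseError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records to FASTA (60-column wrapped), preserving order."""
    bio = [_BioSeqRecord(Seq(r.residues), id=r.id, description="") for r in records]
    with _open_text(path, "wt") as handle:
        SeqIO.write(bio, handle, "fasta")


def summarize_dataset(records: Sequence[SequenceRecord]) -> DatasetSummary:
    """Totals and GC content for a set of records from one dataset.

    GC fraction = (#G + #C) / (#A + #C + #G + #T); N excluded.
    """
    if not records:
        raise ValueError("summarize_dataset requires at least one record")
    counts = {b: 0 for b in "ACGTN"}
    for rec in records:
        for base in "ACGTN":
            counts[base] += rec.residues.count(base)
    acgt = sum(counts[b] for b in "ACGT")
    if acgt == 0:
        raise ValueError("dataset contains only N bases; GC content undefined")
    gc = (counts["G"] + counts["C"]) / acgt
    return DatasetSummary(
        dataset=records[0].dataset,
        n_records=len(records),
        total_bp=sum(len(r) for r in records),
        gc_fraction=gc,
        base_counts=counts,
    )


def write_summary_tsv(summaries: Sequence[DatasetSummary], path: str | Path) -> None:
    """TSV report: dataset, n_records, total_bp, total_mbp, gc_percent.

    Mbp and GC are printed to 2 and 1 decimals respectively, mirroring the
    usual presentation of dataset tables; underlying values stay at full
    precision in :class:`DatasetSummary`.
    """
    with open(path, "w") as fh:
        fh.write("dataset\tn_records\ttotal_bp\ttotal_mbp\tgc_percent\n")
        for s in summaries:
            fh.write(
                f"{s.dataset}\t{s.n_records}\t{s.total_bp}\t"
                f"{s.total_mbp:.2f}\t{100 * s.gc_fraction:.1f}\n"
            )


# ---------------------------------------------------------------------------
# GFF3 export / import of SSR and ORF features
# ---------------------------------------------------------------------------

_SOURCE = "ssrmine"


def _gff3_escape(value: str) -> str:
    return value.replace(";", "%3B").replace("=", "%3D").replace(",", "%2C")


def write_features_gff3(ssrs, orfs, path: str | Path, seq_lengths: Mapping[str, int]) -> None:
    """Write microsatellite and ORF features as GFF3.

    Coordinates are converted from the internal 0-based half-open spans to
    GFF3's 1-based inclusive columns.  ``seq_lengths`` maps every referenced
    sequence id to its length and is used for bounds validation and the
    ``##sequence-region`` pragmas.
    """
    lines = ["##gff-version 3"]
    for seq_id in sorted(seq_lengths):
        lines.append(f"##sequence-region {seq_id} 1 {seq_lengths[seq_id]}")

    def check_bounds(seq_id: str, start: int, end: int, what: str) -> None:
        if seq_id not in seq_lengths:
            raise ValueError(f"{what} references unknown sequence {seq_id!r}")
        if not (0 <= start < end <= seq_lengths[seq_id]):
            raise ValueError(
                f"{what} span [{start},{end}) outside sequence {seq_id!r} "
                f"of length {seq_lengths[seq_id]}"
            )

    for i, ssr in enumerate(ssrs):
        check_bounds(ssr.seq_id, ssr.start, ssr.end, "SSR")
        attrs = [
            f"ID=ssr{i:05d}",
            f"motif_class={_gff3_escape(ssr.motif_class)}",
            f"motif_observed={_gff3_escape(ssr.motif_observed)}",
            f"unit_len={ssr.unit_len}",
            f"n_units={ssr.n_units}",
            f"kind={ssr.kind}",
        ]
        if ssr.kind == "compound":
            members = "|".join(
                f"{m.start}-{m.end}/{m.motif_observed}/{m.n_units}" for m in ssr.members
            )
            attrs.append(f"members={members}")
        lines.append(
            f"{ssr.seq_id}\t{_SOURCE}\tmicrosatellite\t{ssr.start + 1}\t{ssr.end}"
            f"\t.\t+\t.\t{';'.join(attrs)}"
        )
    for i, orf in enumerate(orfs):
        check_bounds(orf.seq_id, orf.start, orf.end, "ORF")
        attrs = [f"ID=orf{i:05d}", f"frame={orf.frame}"]
        lines.append(
            f"{orf.seq_id}\t{_SOURCE}\tORF\t{orf.start + 1}\t{orf.end}"
            f"\t.\t{orf.strand}\t0\t{';'.join(attrs)}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_features_gff3(path: str | Path):
    """Re-read a GFF3 written by :func:`write_features_gff3`.

    Returns ``(ssrs, orfs)`` with coordinates converted back to 0-based
    half-open spans.  Only the two feature types this package emits are
    interpreted.
    """
    from .ssr_engine import SSRLocus
    from .orf_engine import ORFRegion

    ssrs: list[SSRLocus] = []
    orfs: list[ORFRegion] = []
    for raw in Path(path).read_text().splitlines():
        if not raw or raw.startswith("#"):
            continue
        cols = raw.split("\t")
        if len(cols) != 9:
            raise ValueError(f"malformed GFF3 line: {raw!r}")
        seq_id, _src, ftype, start1, end1, _score, strand, _phase, attr_col = cols
        start, end = int(start1) - 1, int(end1)
        attrs = dict(item.split("=", 1) for item in attr_col.split(";") if item)
        if ftype == "microsatellite":
            kind = attrs["kind"]
            members: tuple = ()
            if kind == "compound":
                parsed = []
                for chunk in attrs["members"].split("|"):
                    span, unit, n = chunk.split("/")
                    ms, me = (int(x) for x in span.split("-"))
                    parsed.append(
                        SSRLocus(
                            seq_id=seq_id, start=ms, end=me, unit_len=len(unit),
                            motif_observed=unit, n_units=int(n), kind="perfect",
                        )
                    )
                members = tuple(parsed)
            ssrs.append(
                SSRLocus(
                    seq_id=seq_id,
                    start=start,
                    end=end,
                    unit_len=int(attrs["unit_len"]),
                    motif_observed=attrs["motif_observed"],
                    n_units=int(attrs["n_units"]),
                    kind=kind,
                    members=members,
                )
            )
        elif ftype == "ORF":
            orfs.append(
                ORFRegion(
                    seq_id=seq_id, strand=strand, frame=int(attrs["frame"]),
                    start=start, end=end,
                )
            )
    return ssrs, orfs
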