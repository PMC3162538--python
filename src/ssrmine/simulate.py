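"""Synthetic inputs with exact ground truth for every pipeline stage.

The generators emulate the statistical structure of the study system:

* sequence datasets (BAC-end-like genomic sequence, EST-like transcript
  sequence) with planted microsatellites and ORFs at configurable GC
  content, motif-class spectrum and inside-ORF enrichment;
* marker x population screening matrices with per-repeat-class
  polymorphism probabilities;
* marker x accession transferability matrices whose success
  probabilities decay from the source species (carrot) through
  congeneric (*Daucus*) to confamilial (Apiaceae) accessions;
* diploid genotype tables drawn from known allele-frequency vectors.

Every generator is a pure function of its spec (seed included), and each
returns the generating ground truth alongside the data so downstream
modules have exact expected answers.  Background sequence is sampled
from a zero-order composition model and rejection-filtered: a record is
re-drawn until the package's own detectors recover exactly the planted
features — so the emitted ground truth is exact by construction, with no
accidental above-threshold repeats or ORFs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .sequence_io import SequenceRecord
from .ssr_engine import (
    SSRLocus,
    SSRSearchConfig,
    detect_perfect_ssrs,
    group_compound_ssrs,
    motif_classes,
)
from .orf_engine import ORFRegion, find_orfs, START_CODON, STOP_CODONS
from .diversity import GenotypeTable
from .marker_panel import (
    REPEAT_CLASSES,
    ScreeningMatrix,
    TransferMatrix,
    TRANSFER_GROUPS,
    bin_repeat_class,
)

__all__ = [
    "SequenceSimSpec",
    "PanelSimSpec",
    "SimulatedSequences",
    "gen_sequences",
    "gen_screening_matrix",
    "gen_transfer_matrix",
    "gen_genotypes",
    "BES_PRESET",
    "EST_PRESET",
]

_BASES = np.array(list("ACGT"))

# Sense codons usable for ORF interiors: no stop, and no ATG so that the
# planted start codon is unambiguous under either start rule.
_INTERIOR_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in STOP_CODONS and a + b + c != START_CODON
]


@dataclass(frozen=True)
class SequenceSimSpec:
    """Specification for a synthetic sequence dataset.

    Defaults are scaled-down counterparts of a BAC-end-like genomic
    dataset: ~38% GC, repeat-type mix dominated by tri- and
    tetranucleotides, few compound repeats, and a quarter of repeats
    falling inside open reading frames.
    """

    seed: int
    n_records: int = 60
    length_mean: int = 700
    length_sd: int = 120
    gc_fraction: float = 0.383
    n_ssrs: int = 60
    unit_len_probs: Mapping[int, float] = field(
        default_factory=lambda: {2: 0.17, 3: 0.42, 4: 0.24, 5: 0.11, 6: 0.03, 7: 0.017, 8: 0.013}
    )
    extra_units_mean: float = 1.5
    compound_fraction: float = 0.05
    n_orfs: int = 40
    orf_length_mean: int = 210
    min_orf_len: int = 100
    inside_orf_prob: float = 0.25
    strands: str = "both"
    dataset: str = "synthetic"
    search: SSRSearchConfig = field(default_factory=SSRSearchConfig)

    def __post_init__(self) -> None:
        total = sum(self.unit_len_probs.values())
        if not np.isclose(total, 1.0, atol=1e-6):
            raise ValueError("unit_len_probs must sum to 1")
        if not (0 <= self.gc_fraction <= 1):
            raise ValueError("gc_fraction must be in [0, 1]")
        if not (0 <= self.inside_orf_prob <= 1):
            raise ValueError("inside_orf_prob must be in [0, 1]")
        if self.orf_length_mean < self.min_orf_len:
            raise ValueError("orf_length_mean must be >= min_orf_len")
        expected_feature_bp = self.n_orfs * (self.orf_length_mean + 60) + self.n_ssrs * 40
        budget = self.n_records * self.length_mean
        if expected_feature_bp > 0.7 * budget:
            raise ValueError(
                "infeasible spec: planted features exceed the available sequence space"
            )


# Presets mirroring the study's two mineable datasets at reduced scale.
BES_PRESET = dict(
    gc_fraction=0.383, dataset="BES",
    unit_len_probs={2: 0.17, 3: 0.42, 4: 0.24, 5: 0.11, 6: 0.03, 7: 0.017, 8: 0.013},
    inside_orf_prob=0.25, compound_fraction=0.03,
)
EST_PRESET = dict(
    gc_fraction=0.423, dataset="EST",
    unit_len_probs={2: 0.25, 3: 0.50, 4: 0.16, 5: 0.035, 6: 0.048, 7: 0.004, 8: 0.003},
    inside_orf_prob=0.45, compound_fraction=0.03, strands="forward",
)


@dataclass(frozen=True)
class SimulatedSequences:
    """A generated dataset plus its exact ground truth."""

    records: list[SequenceRecord]
    perfect: list[SSRLocus]
    compound: list[SSRLocus]
    orfs: list[ORFRegion]


def _rand_bases(rng: np.random.Generator, n: int, gc: float) -> list[str]:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return list(rng.choice(_BASES, size=n, p=p))


def _rand_unit(rng: np.random.Generator, spec: SequenceSimSpec) -> tuple[str, int]:
    ks = sorted(spec.unit_len_probs)
    probs = np.array([spec.unit_len_probs[k] for k in ks])
    k = int(rng.choice(ks, p=probs / probs.sum()))
    classes = motif_classes(k)
    cls = classes[int(rng.integers(len(classes)))]
    rot = int(rng.integers(k))
    unit = cls[rot:] + cls[:rot]
    n_units = spec.search.min_units_for(k) + int(rng.poisson(spec.extra_units_mean))
    return unit, n_units


def _guard(rng: np.random.Generator, forbidden: str) -> str:
    choices = [b for b in "ACGT" if b != forbidden]
    return choices[int(rng.integers(len(choices)))]


class _Block:
    """A pre-built sequence block with feature spans relative to its start."""

    __slots__ = ("seq", "ssr_spans", "orf_spans", "has_ssr")

    def __init__(self, seq, ssr_spans=(), orf_spans=(), has_ssr=False):
        self.seq = seq
        self.ssr_spans = list(ssr_spans)  # (rel_start, unit, n_units)
        self.orf_spans = list(orf_spans)  # (rel_start, coding_len)
        self.has_ssr = has_ssr


def _ssr_block(rng: np.random.Generator, spec: SequenceSimSpec) -> _Block:
    unit, n_units = _rand_unit(rng, spec)
    body = unit * n_units
    left = _guard(rng, unit[-1])
    right = _guard(rng, unit[0])
    return _Block(left + body + right, ssr_spans=[(1, unit, n_units)], has_ssr=True)


def _compound_block(rng: np.random.Generator, spec: SequenceSimSpec) -> _Block:
    u1, n1 = _rand_unit(rng, spec)
    while True:
        u2, n2 = _rand_unit(rng, spec)
        if u2 != u1:
            break
    gap_len = int(rng.integers(2, 11))
    gap = [_guard(rng, u1[0])] + _rand_bases(rng, gap_len - 2, spec.gc_fraction)
    gap.append(_guard(rng, u2[-1]))
    seq = (
        _guard(rng, u1[-1]) + u1 * n1 + "".join(gap) + u2 * n2 + _guard(rng, u2[0])
    )
    s1 = 1
    s2 = 1 + len(u1) * n1 + gap_len
    return _Block(seq, ssr_spans=[(s1, u1, n1), (s2, u2, n2)], has_ssr=True)


def _interior_codon_probs(gc: float) -> np.ndarray:
    # zero-order composition restricted to the allowed sense codons, so
    # ORF interiors track the dataset's GC target
    p = {"A": (1 - gc) / 2, "C": gc / 2, "G": gc / 2, "T": (1 - gc) / 2}
    w = np.array([p[c[0]] * p[c[1]] * p[c[2]] for c in _INTERIOR_CODONS])
    return w / w.sum()


def _orf_block(
    rng: np.random.Generator, spec: SequenceSimSpec, embed_ssr: bool
) -> _Block:
    """An ATG...stop block, optionally with an SSR embedded in the frame.

    The interior is built from sense codons containing neither stops nor
    ATG; when an SSR is spliced in, the layout is re-drawn until the
    coding frame stays free of stops and internal ATGs and the SSR's
    immediate neighbours cannot extend the repeat.
    """
    extra_codons = max(0, int(rng.poisson((spec.orf_length_mean - spec.min_orf_len) / 3)))
    coding_len = spec.min_orf_len + 3 * extra_codons
    coding_len += (-coding_len) % 3  # multiple of 3
    codon_probs = _interior_codon_probs(spec.gc_fraction)
    for _ in range(200):
        n_codons = coding_len // 3 - 1
        interior = "".join(
            _INTERIOR_CODONS[i]
            for i in rng.choice(len(_INTERIOR_CODONS), size=n_codons, p=codon_probs)
        )
        coding = START_CODON + interior
        ssr_spans = []
        if embed_ssr:
            unit, n_units = _rand_unit(rng, spec)
            body = unit * n_units
            if len(body) + 8 > coding_len - 3:
                continue  # repeat too long for this ORF; redraw
            offset = int(rng.integers(4, coding_len - len(body) - 3))
            chars = list(coding)
            chars[offset : offset + len(body)] = body
            # guard the flanks against repeat extension
            chars[offset - 1] = _guard(rng, unit[-1])
            chars[offset + len(body)] = _guard(rng, unit[0])
            coding = "".join(chars)
            if coding[:3] != START_CODON:
                continue
            codons = [coding[i : i + 3] for i in range(3, coding_len, 3)]
            if any(c in STOP_CODONS or c == START_CODON for c in codons):
                continue
            ssr_spans = [(offset, unit, n_units)]
        stop = sorted(STOP_CODONS)[int(rng.integers(3))]
        left = _guard(rng, "")  # plain random base; keeps upstream frame noisy
        seq = left + coding + stop
        return _Block(
            seq,
            ssr_spans=[(1 + off, u, n) for off, u, n in ssr_spans],
            orf_spans=[(1, coding_len)],
            has_ssr=bool(ssr_spans),
        )
    raise RuntimeError("could not build an ORF block for this spec")


def _assemble_record(
    rng: np.random.Generator,
    spec: SequenceSimSpec,
    rec_id: str,
    blocks: list[_Block],
) -> tuple[SequenceRecord, list[SSRLocus], list[ORFRegion]]:
    order = list(rng.permutation(len(blocks))) if blocks else []
    blocks = [blocks[i] for i in order]
    # Background long enough that separate planted SSRs never compound-merge.
    sep = spec.search.d_max + 5
    target = int(rng.normal(spec.length_mean, spec.length_sd))
    needed = sum(len(b.seq) for b in blocks) + sep * max(0, len(blocks) - 1) + 20
    length = max(target, needed)
    spare = length - needed
    cuts = np.sort(rng.integers(0, spare + 1, size=len(blocks) + 1)) if spare > 0 else np.zeros(len(blocks) + 1, int)
    pads = np.diff(np.concatenate([[0], cuts, [spare]]))

    pieces: list[str] = []
    pos = 0
    ssrs: list[SSRLocus] = []
    orfs: list[ORFRegion] = []
    for i, block in enumerate(blocks):
        pad = int(pads[i]) + (10 if i == 0 else sep)
        pieces.append("".join(_rand_bases(rng, pad, spec.gc_fraction)))
        pos += pad
        for rel, unit, n_units in block.ssr_spans:
            start = pos + rel
            ssrs.append(
                SSRLocus(
                    seq_id=rec_id, start=start, end=start + len(unit) * n_units,
                    unit_len=len(unit), motif_observed=unit, n_units=n_units,
                )
            )
        for rel, coding_len in block.orf_spans:
            start = pos + rel
            orfs.append(
                ORFRegion(
                    seq_id=rec_id, strand="+", frame=start % 3,
                    start=start, end=start + coding_len,
                )
            )
        pieces.append(block.seq)
        pos += len(block.seq)
    tail = int(pads[-1]) + 10 if blocks else length
    pieces.append("".join(_rand_bases(rng, tail, spec.gc_fraction)))
    record = SequenceRecord(rec_id, "".join(pieces), dataset=spec.dataset)
    ssrs.sort(key=lambda l: (l.start, l.unit_len))
    return record, ssrs, orfs


def gen_sequences(spec: SequenceSimSpec) -> SimulatedSequences:
    """Generate a sequence dataset with exact planted SSR/ORF ground truth.

    Deterministic given the spec (which carries the seed).  Each record
    is re-drawn until the package's detectors recover exactly the planted
    perfect SSRs and ORFs, so the returned ground truth is guaranteed
    consistent with detection under ``spec.search`` thresholds and
    ``spec.min_orf_len``/``spec.strands``.
    """
    rng = np.random.default_rng(spec.seed)
    # Distribute features over records.  SSRs flagged "inside" are paired
    # with ORF slots directly (at most one per ORF), so the realized
    # inside fraction tracks ``inside_orf_prob`` regardless of how ORFs
    # scatter over records; overflow falls back to free placement.
    orf_rec = rng.integers(spec.n_records, size=spec.n_orfs)
    ssr_inside = rng.random(spec.n_ssrs) < spec.inside_orf_prob
    ssr_compound = (rng.random(spec.n_ssrs) < spec.compound_fraction) & ~ssr_inside
    inside_ids = np.flatnonzero(ssr_inside)
    n_hosted = min(len(inside_ids), spec.n_orfs)
    hosted_orfs = rng.choice(spec.n_orfs, size=n_hosted, replace=False) if n_hosted else np.array([], int)
    orf_hosts_ssr = np.zeros(spec.n_orfs, dtype=bool)
    orf_hosts_ssr[hosted_orfs] = True
    ssr_rec = rng.integers(spec.n_records, size=spec.n_ssrs)
    # overflow inside-SSRs (more inside flags than ORFs) become free
    for idx in inside_ids[n_hosted:]:
        ssr_inside[idx] = False

    records: list[SequenceRecord] = []
    perfect: list[SSRLocus] = []
    orfs: list[ORFRegion] = []
    for r in range(spec.n_records):
        rec_id = f"{spec.dataset}_{r:04d}"
        my_orfs = np.flatnonzero(orf_rec == r)
        my_ssrs = np.flatnonzero((ssr_rec == r) & ~ssr_inside)
        for attempt in range(400):
            blocks: list[_Block] = []
            free_specs: list[str] = [
                "compound" if ssr_compound[idx] else "free" for idx in my_ssrs
            ]
            embed_flags = [bool(orf_hosts_ssr[i]) for i in my_orfs]
            for flag in embed_flags:
                blocks.append(_orf_block(rng, spec, embed_ssr=flag))
            for kind in free_specs:
                if kind == "compound":
                    blocks.append(_compound_block(rng, spec))
                elif kind == "free":
                    blocks.append(_ssr_block(rng, spec))
            record, truth_ssrs, truth_orfs = _assemble_record(rng, spec, rec_id, blocks)
            det_ssrs = detect_perfect_ssrs(record, spec.search)
            if [(s.start, s.end, s.unit_len) for s in det_ssrs] != [
                (s.start, s.end, s.unit_len) for s in truth_ssrs
            ]:
                continue
            det_orfs = find_orfs(
                record, min_orf_len=spec.min_orf_len, strands=spec.strands
            )
            if [(o.start, o.end, o.strand) for o in det_orfs] != [
                (o.start, o.end, o.strand) for o in sorted(truth_orfs, key=lambda o: o.start)
            ]:
                continue
            break
        else:
            raise RuntimeError(
                f"could not realize record {rec_id} after 400 attempts; "
                "spec likely leaves too little background space"
            )
        records.append(record)
        perfect.extend(truth_ssrs)
        orfs.extend(truth_orfs)
    perfect_only, compound = group_compound_ssrs(perfect, spec.search)
    return SimulatedSequences(
        records=records,
        perfect=perfect_only,
        compound=compound,
        orfs=sorted(orfs, key=lambda o: (o.seq_id, o.start)),
    )


# ---------------------------------------------------------------------------
# Marker panels
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PanelSimSpec:
    """Specification for synthetic marker-panel datasets.

    Defaults mirror the study's headline magnitudes: 300 markers (156
    from an enriched genomic library, 144 from BAC ends) screened in 7 F2
    populations; 23 accessions in three transferability groups with
    success probabilities 0.86/0.58/0.41; 65 diploid individuals at 10
    diversity loci.  Screening calls are drawn independently per
    population with per-repeat-class codominant/dominant probabilities
    that increase with repeat number.
    """

    seed: int
    n_markers: int = 300
    n_gssr: int = 156
    n_populations: int = 7
    class_call_probs: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "<6": (0.06, 0.04),
            "6-10": (0.09, 0.05),
            "11-15": (0.16, 0.08),
            ">15": (0.12, 0.07),
        }
    )
    ambiguous_rate: float = 0.04
    no_amp_rate: float = 0.05
    missing_rate: float = 0.02
    gssr_extra_units_mean: float = 6.0
    bssr_extra_units_mean: float = 1.5
    transfer_group_sizes: tuple[int, int, int] = (8, 8, 7)
    transfer_success: tuple[float, float, float] = (0.86, 0.58, 0.41)
    expected_size_range: tuple[int, int] = (120, 420)
    size_jitter: int = 30
    off_size_prob_given_fail: float = 0.3
    n_individuals: int = 65
    n_loci: int = 10
    allele_count_range: tuple[int, int] = (10, 29)
    dirichlet_alpha: float = 1.0
    genotype_missing_rate: float = 0.02
    allele_freqs: Sequence[Sequence[float]] | None = None

    def __post_init__(self) -> None:
        for cls, (c, d) in self.class_call_probs.items():
            if cls not in REPEAT_CLASSES:
                raise ValueError(f"unknown repeat class {cls!r}")
            if not (0 <= c and 0 <= d):
                raise ValueError("call probabilities must be >= 0")
            if c + d + self.ambiguous_rate + self.no_amp_rate + self.missing_rate > 1:
                raise ValueError(f"call probabilities for {cls!r} exceed 1")
        if any(s < 1 for s in self.transfer_group_sizes):
            raise ValueError("transfer group sizes must be >= 1")
        if any(not 0 <= p <= 1 for p in self.transfer_success):
            raise ValueError("transfer success probabilities must be in [0, 1]")


def _marker_frame(rng: np.random.Generator, spec: PanelSimSpec) -> pd.DataFrame:
    ids, sources, units = [], [], []
    for i in range(spec.n_markers):
        gssr = i < spec.n_gssr
        ids.append(f"{'gssr' if gssr else 'bssr'}{i + 1:03d}")
        sources.append("GSSR" if gssr else "BSSR")
        mean = spec.gssr_extra_units_mean if gssr else spec.bssr_extra_units_mean
        units.append(3 + int(rng.poisson(mean)))
    return pd.DataFrame({"source": sources, "total_units": units}, index=pd.Index(ids, name="marker"))


def gen_screening_matrix(spec: PanelSimSpec) -> ScreeningMatrix:
    """Draw a marker x population screening matrix from the spec.

    Calls are independent across populations given the marker's repeat
    class.  Deterministic given the seed.
    """
    rng = np.random.default_rng(spec.seed)
    info = _marker_frame(rng, spec)
    pops = [f"pop{i + 1}" for i in range(spec.n_populations)]
    calls = pd.DataFrame(index=info.index, columns=pops, dtype=object)
    for marker, row in info.iterrows():
        c, d = spec.class_call_probs[bin_repeat_class(row["total_units"])]
        probs = np.array(
            [
                spec.missing_rate,
                spec.ambiguous_rate,
                spec.no_amp_rate,
                c,
                d,
            ]
        )
        probs = np.append(probs, 1 - probs.sum())  # monomorphic remainder
        labels = ["missing", "ambiguous", "no_amplification", "codominant", "dominant", "monomorphic"]
        draws = rng.choice(len(labels), size=spec.n_populations, p=probs)
        calls.loc[marker] = [labels[i] for i in draws]
    return ScreeningMatrix(calls=calls, marker_info=info)


def gen_transfer_matrix(spec: PanelSimSpec) -> TransferMatrix:
    """Draw a transferability matrix with group-structured success rates."""
    rng = np.random.default_rng(spec.seed + 1)
    info = _marker_frame(np.random.default_rng(spec.seed), spec)
    expected = pd.Series(
        rng.integers(*spec.expected_size_range, size=spec.n_markers).astype(float),
        index=info.index,
    )
    acc_names, acc_groups = [], []
    for group, size in zip(TRANSFER_GROUPS, spec.transfer_group_sizes):
        for j in range(size):
            acc_names.append(f"{group}_{j + 1}")
            acc_groups.append(group)
    success_p = {
        g: p for g, p in zip(TRANSFER_GROUPS, spec.transfer_success)
    }
    sizes: dict[str, list[tuple[float, ...]]] = {}
    for acc, group in zip(acc_names, acc_groups):
        col: list[tuple[float, ...]] = []
        for marker in info.index:
            if rng.random() < success_p[group]:
                frag = expected[marker] + rng.integers(-spec.size_jitter, spec.size_jitter + 1)
                col.append((float(frag),))
            elif rng.random() < spec.off_size_prob_given_fail:
                sign = 1 if rng.random() < 0.5 else -1
                frag = expected[marker] + sign * (101 + rng.integers(0, 150))
                col.append((float(max(frag, 50.0)),))
            else:
                col.append(())
        sizes[acc] = col
    return TransferMatrix(
        sizes=pd.DataFrame(sizes, index=info.index),
        expected_size=expected,
        accession_groups=pd.Series(acc_groups, index=acc_names),
        marker_source=info["source"],
    )


def gen_genotypes(spec: PanelSimSpec) -> tuple[GenotypeTable, dict[str, dict]]:
    """Draw a diploid genotype table from known allele-frequency vectors.

    Returns the table and, per locus, the generating parameters
    (``sizes``, ``freqs`` and the population value ``1 - sum(p^2)``).
    When ``spec.allele_freqs`` is given it fixes the frequency vectors;
    otherwise vectors are Dirichlet draws with
    ``spec.allele_count_range`` alleles.
    """
    rng = np.random.default_rng(spec.seed + 2)
    truth: dict[str, dict] = {}
    loci = [f"locus{i + 1:02d}" for i in range(
        len(spec.allele_freqs) if spec.allele_freqs is not None else spec.n_loci
    )]
    for i, locus in enumerate(loci):
        if spec.allele_freqs is not None:
            freqs = np.asarray(spec.allele_freqs[i], dtype=float)
            if not np.isclose(freqs.sum(), 1.0):
                raise ValueError(f"allele frequencies for {locus} must sum to 1")
        else:
            k = int(rng.integers(spec.allele_count_range[0], spec.allele_count_range[1] + 1))
            freqs = rng.dirichlet(np.full(k, spec.dirichlet_alpha))
        base = int(rng.integers(140, 400))
        sizes = base + 2 * np.arange(len(freqs))
        truth[locus] = {
            "sizes": sizes.astype(float),
            "freqs": freqs,
            "gene_diversity": float(1 - (freqs**2).sum()),
        }
    individuals = [f"ind{i + 1:03d}" for i in range(spec.n_individuals)]
    frame = pd.DataFrame(index=individuals, columns=loci, dtype=object)
    for locus in loci:
        params = truth[locus]
        for ind in individuals:
            if rng.random() < spec.genotype_missing_rate:
                frame.at[ind, locus] = None
            else:
                pair = rng.choice(params["sizes"], size=2, p=params["freqs"])
                frame.at[ind, locus] = (float(pair[0]), float(pair[1]))
    return GenotypeTable(genotypes=frame), truth
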