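"""Per-locus diversity statistics from diploid microsatellite genotypes.

Expected heterozygosity (gene diversity) is estimated per locus from the
allele frequencies p_i over the n non-missing gene copies as

    He = n / (n - 1) * (1 - sum_i p_i^2)

i.e. Nei's unbiased small-sample estimator (the convention of standard
population-genetics software such as Arlequin); the uncorrected
1 - sum p_i^2 is available via ``unbiased=False``.  Alleles are
identified by exact fragment size in bp (capillary-resolution data).
Missing genotypes simply drop out of a locus's gene-copy count; no
imputation is performed.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeTable",
    "LocusDiversity",
    "PanelSummary",
    "locus_diversity",
    "panel_summary",
    "diversity_table",
]


@dataclass(frozen=True)
class GenotypeTable:
    """Individual x locus diploid allele sizes.

    ``genotypes`` is a DataFrame indexed by individual with one column
    per locus; cells are ``(allele1, allele2)`` tuples of sizes in bp
    (homozygotes repeat the size) or ``None`` for missing.
    """

    genotypes: pd.DataFrame

    def __post_init__(self) -> None:
        for locus in self.genotypes.columns:
            for ind, cell in self.genotypes[locus].items():
                if cell is None:
                    continue
                if len(cell) != 2:
                    raise ValueError(
                        f"{ind}/{locus}: genotype must hold exactly 2 alleles"
                    )
                if any(a <= 0 for a in cell):
                    raise ValueError(f"{ind}/{locus}: allele sizes must be positive")

    @property
    def loci(self) -> pd.Index:
        return self.genotypes.columns

    @property
    def individuals(self) -> pd.Index:
        return self.genotypes.index

    def alleles(self, locus: str) -> list[float]:
        """All non-missing gene copies at a locus, in table order."""
        out: list[float] = []
        for cell in self.genotypes[locus]:
            if cell is not None:
                out.extend(cell)
        return out

    def to_tsv(self, path: str | Path) -> None:
        """Long-format TSV: individual, locus, allele1, allele2 ('-' = missing)."""
        with open(path, "w") as fh:
            fh.write("individual\tlocus\tallele1\tallele2\n")
            for ind in self.individuals:
                for locus in self.loci:
                    cell = self.genotypes.at[ind, locus]
                    a1, a2 = ("-", "-") if cell is None else (
                        f"{cell[0]:g}", f"{cell[1]:g}"
                    )
                    fh.write(f"{ind}\t{locus}\t{a1}\t{a2}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GenotypeTable":
        raw = pd.read_csv(path, sep="\t", dtype=str)
        needed = {"individual", "locus", "allele1", "allele2"}
        if not needed.issubset(raw.columns):
            raise ValueError(f"{path}: expected columns {sorted(needed)}")
        cells: dict[tuple[str, str], tuple[float, float] | None] = {}
        for _, row in raw.iterrows():
            key = (row["individual"], row["locus"])
            if row["allele1"] == "-" or row["allele2"] == "-":
                cells[key] = None
            else:
                cells[key] = (float(row["allele1"]), float(row["allele2"]))
        individuals = list(dict.fromkeys(raw["individual"]))
        loci = list(dict.fromkeys(raw["locus"]))
        frame = pd.DataFrame(index=individuals, columns=loci, dtype=object)
        for (ind, locus), cell in cells.items():
            frame.at[ind, locus] = cell
        frame = frame.where(frame.notna(), None)
        return cls(genotypes=frame)


@dataclass(frozen=True, slots=True)
class LocusDiversity:
    """Diversity statistics for one locus."""

    locus: str
    n_copies: int
    n_alleles: int
    size_min: float
    size_max: float
    he: float


def locus_diversity(
    table: GenotypeTable, locus: str, unbiased: bool = True
) -> LocusDiversity:
    """Allele count, size range and expected heterozygosity at one locus."""
    if locus not in table.loci:
        raise KeyError(f"locus {locus!r} not in table")
    copies = table.alleles(locus)
    n = len(copies)
    if n < 2:
        raise ValueError(f"locus {locus!r}: need >= 2 gene copies, have {n}")
    counts = Counter(copies)
    sum_p2 = sum((c / n) ** 2 for c in counts.values())
    he = 1.0 - sum_p2
    if unbiased:
        he *= n / (n - 1)
    return LocusDiversity(
        locus=locus,
        n_copies=n,
        n_alleles=len(counts),
        size_min=min(copies),
        size_max=max(copies),
        he=he,
    )


@dataclass(frozen=True, slots=True)
class PanelSummary:
    """Panel-level totals over per-locus diversity statistics."""

    n_loci: int
    total_alleles: int
    size_min: float
    size_max: float
    mean_n_alleles: float
    sd_n_alleles: float
    mean_he: float
    sd_he: float


def panel_summary(stats: Sequence[LocusDiversity]) -> PanelSummary:
    """Sum allele counts, pool the size range, and average NA and He.

    Standard deviations use the n-1 denominator (as in summary rows of
    published diversity tables); they are NaN with a single locus.
    """
    if not stats:
        raise ValueError("need at least one locus")
    n_alleles = np.array([s.n_alleles for s in stats], dtype=float)
    he = np.array([s.he for s in stats], dtype=float)
    sd = lambda x: float(np.std(x, ddof=1)) if len(x) > 1 else math.nan
    return PanelSummary(
        n_loci=len(stats),
        total_alleles=int(n_alleles.sum()),
        size_min=min(s.size_min for s in stats),
        size_max=max(s.size_max for s in stats),
        mean_n_alleles=float(n_alleles.mean()),
        sd_n_alleles=sd(n_alleles),
        mean_he=float(he.mean()),
        sd_he=sd(he),
    )


def diversity_table(
    table: GenotypeTable, unbiased: bool = True
) -> pd.DataFrame:
    """Per-locus diversity DataFrame plus ``total``/``mean`` rows."""
    per_locus = [locus_diversity(table, locus, unbiased) for locus in table.loci]
    rows = [
        {
            "locus": s.locus, "n_alleles": s.n_alleles,
            "size_min": s.size_min, "size_max": s.size_max, "he": s.he,
        }
        for s in per_locus
    ]
    summary = panel_summary(per_locus)
    rows.append(
        {
            "locus": "total", "n_alleles": summary.total_alleles,
            "size_min": summary.size_min, "size_max": summary.size_max,
            "he": math.nan,
        }
    )
    rows.append(
        {
            "locus": "mean", "n_alleles": summary.mean_n_alleles,
            "size_min": math.nan, "size_max": math.nan, "he": summary.mean_he,
        }
    )
    return pd.DataFrame(rows).set_index("locus")
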