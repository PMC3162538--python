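"""F2 marker screening, polymorphism index, transferability and segregation.

The polymorphism index (PI) of a marker screened across ``n`` F2
populations is

    PI = 100 * (2C + D) / (2 * (n - nd))

where C and D are the numbers of populations in which the marker
segregated codominantly and dominantly, and nd the number of populations
with no information for that marker.  A marker codominant everywhere
scores 100; dominant everywhere scores 50; monomorphic everywhere scores
0.  Ambiguous band patterns and amplification failures count as NOT
polymorphic but are still scored populations (they do not enter nd);
only truly missing evaluations count as nd.  This nd rule follows the
scoring convention that ambiguous patterns were recorded as monomorphic,
and is configurable via ``nd_calls``.

Cross-taxa transferability is judged by amplicon size: an accession
"succeeds" for a marker when at least one observed fragment lies within
``size_window`` bp (default 100) of the expected size in the source
species; fragments present but all outside the window are non-specific
("off-size") and count as failures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CALL_CODES",
    "ScreeningMatrix",
    "TransferMatrix",
    "SegregationResult",
    "compute_pi",
    "polymorphism_summary",
    "bin_repeat_class",
    "pi_vs_repeats",
    "segregation_chisq",
    "transfer_summary",
    "interspecific_allele_count",
]

# One-letter TSV codes for screening calls.
CALL_CODES = {
    "C": "codominant",
    "D": "dominant",
    "M": "monomorphic",
    "A": "ambiguous",
    "N": "no_amplification",
    "-": "missing",
}
_CALL_TO_CODE = {v: k for k, v in CALL_CODES.items()}
POLYMORPHIC_CALLS = frozenset({"codominant", "dominant"})

REPEAT_CLASSES = ("<6", "6-10", "11-15", ">15")


def bin_repeat_class(total_units: int) -> str:
    """Repeat-number class of a marker: ``<6``, ``6-10``, ``11-15``, ``>15``.

    ``total_units`` is the summed unit count over all perfect SSRs in the
    marker's amplicon (a marker carrying (AT)6 and (CTT)5 totals 11 and
    falls in ``11-15``).
    """
    if total_units < 0:
        raise ValueError("total_units must be >= 0")
    if total_units < 6:
        return "<6"
    if total_units <= 10:
        return "6-10"
    if total_units <= 15:
        return "11-15"
    return ">15"


@dataclass(frozen=True)
class ScreeningMatrix:
    """Marker x population polymorphism calls with marker metadata.

    ``calls`` is a DataFrame (index = marker ids, columns = population
    ids) of call strings from :data:`CALL_CODES` values.  ``marker_info``
    is indexed identically with columns ``source`` (``GSSR``/``BSSR``)
    and ``total_units``.
    """

    calls: pd.DataFrame
    marker_info: pd.DataFrame

    def __post_init__(self) -> None:
        bad = set(np.unique(self.calls.to_numpy())) - set(CALL_CODES.values())
        if bad:
            raise ValueError(f"unknown screening calls: {sorted(bad)}")
        if not self.calls.index.equals(self.marker_info.index):
            raise ValueError("calls and marker_info must share the same marker index")
        if (self.marker_info["total_units"] < 0).any():
            raise ValueError("total_units must be >= 0")

    @property
    def markers(self) -> pd.Index:
        return self.calls.index

    @property
    def populations(self) -> pd.Index:
        return self.calls.columns

    def to_tsv(self, path: str | Path) -> None:
        out = self.marker_info.copy()
        for pop in self.calls.columns:
            out[pop] = self.calls[pop].map(_CALL_TO_CODE)
        out.to_csv(path, sep="\t", index_label="marker")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ScreeningMatrix":
        raw = pd.read_csv(path, sep="\t", index_col="marker", dtype=str)
        info = raw[["source", "total_units"]].copy()
        info["total_units"] = info["total_units"].astype(int)
        pops = [c for c in raw.columns if c not in ("source", "total_units")]
        calls = raw[pops].apply(lambda col: col.map(CALL_CODES))
        if calls.isna().any().any():
            bad = raw[pops].stack()[calls.stack().isna()].unique()
            raise ValueError(f"unknown call codes in {path}: {sorted(bad)}")
        return cls(calls=calls, marker_info=info)


def compute_pi(
    calls: Sequence[str] | pd.Series, nd_calls: frozenset[str] = frozenset({"missing"})
) -> float:
    """Polymorphism index of one marker row; NaN when every population is nd."""
    calls = list(calls)
    n = len(calls)
    if n < 1:
        raise ValueError("need at least one population")
    unknown = set(calls) - set(CALL_CODES.values())
    if unknown:
        raise ValueError(f"unknown calls: {sorted(unknown)}")
    nd = sum(1 for c in calls if c in nd_calls)
    if nd == n:
        return math.nan
    c = sum(1 for x in calls if x == "codominant")
    d = sum(1 for x in calls if x == "dominant")
    return 100.0 * (2 * c + d) / (2 * (n - nd))


def _is_polymorphic(row: pd.Series) -> pd.Series:
    return row.isin(POLYMORPHIC_CALLS)


def polymorphism_summary(matrix: ScreeningMatrix) -> dict:
    """Counts/percents of polymorphic markers, overall, by source, per population."""
    poly = matrix.calls.isin(POLYMORPHIC_CALLS)
    n_poly_pops = poly.sum(axis=1)
    n_markers = len(matrix.markers)
    out: dict = {
        "n_markers": n_markers,
        "polymorphic_ge1": int((n_poly_pops >= 1).sum()),
        "polymorphic_ge1_pct": 100 * (n_poly_pops >= 1).mean(),
        "polymorphic_ge2": int((n_poly_pops >= 2).sum()),
        "polymorphic_ge2_pct": 100 * (n_poly_pops >= 2).mean(),
        "by_source": {},
        "per_population_pct": {
            pop: 100 * poly[pop].mean() for pop in matrix.populations
        },
    }
    for source, info in matrix.marker_info.groupby("source"):
        sub = n_poly_pops.loc[info.index]
        out["by_source"][source] = {
            "n_markers": len(info),
            "polymorphic_ge1": int((sub >= 1).sum()),
            "polymorphic_ge1_pct": 100 * (sub >= 1).mean(),
            "polymorphic_ge2": int((sub >= 2).sum()),
        }
    return out


def pi_vs_repeats(
    matrix: ScreeningMatrix, nd_calls: frozenset[str] = frozenset({"missing"})
) -> dict:
    """Correlation/regression of PI on repeat-unit number, plus class profile.

    Returns Pearson r and its two-sided p, the least-squares slope and
    intercept of PI on total repeat units, and a per-repeat-class table
    of mean PI and percent of markers polymorphic in >= 1 population.
    Raises when fewer than 3 markers have a defined PI or the predictor
    has zero variance; r is NaN when PI has zero variance.
    """
    pi = matrix.calls.apply(lambda row: compute_pi(row, nd_calls), axis=1)
    units = matrix.marker_info["total_units"].astype(float)
    ok = pi.notna()
    if ok.sum() < 3:
        raise ValueError("need >= 3 markers with defined PI")
    x, y = units[ok], pi[ok]
    if x.nunique() == 1:
        raise ValueError("zero variance in repeat units; correlation undefined")
    if y.nunique() == 1:
        r = p = slope = intercept = math.nan
    else:
        r, p = stats.pearsonr(x, y)
        reg = stats.linregress(x, y)
        slope, intercept = reg.slope, reg.intercept

    poly_ge1 = matrix.calls.isin(POLYMORPHIC_CALLS).sum(axis=1) >= 1
    classes = matrix.marker_info["total_units"].map(bin_repeat_class)
    rows = []
    for cls in REPEAT_CLASSES:
        mask = classes == cls
        rows.append(
            {
                "repeat_class": cls,
                "n_markers": int(mask.sum()),
                "mean_pi": float(pi[mask].mean()) if mask.any() else math.nan,
                "pct_polymorphic": 100 * float(poly_ge1[mask].mean()) if mask.any() else math.nan,
            }
        )
    return {
        "pearson_r": float(r),
        "p": float(p),
        "slope": float(slope),
        "intercept": float(intercept),
        "n": int(ok.sum()),
        "per_class": pd.DataFrame(rows).set_index("repeat_class"),
        "pi": pi,
    }


@dataclass(frozen=True, slots=True)
class SegregationResult:
    chi2: float
    df: int
    p: float
    distorted: bool


def segregation_chisq(
    counts: Sequence[int], mode: str, alpha: float = 0.01
) -> SegregationResult:
    """F2 segregation-distortion test.

    ``mode="codominant"`` tests 3 genotype counts (A:H:B) against 1:2:1
    (df = 2); ``mode="dominant"`` tests 2 phenotype counts against 3:1
    (df = 1).  Distortion is declared at p < ``alpha`` (default 0.01).
    """
    counts = np.asarray(counts, dtype=float)
    if (counts < 0).any() or counts.sum() <= 0:
        raise ValueError("counts must be non-negative with positive total")
    if mode == "codominant":
        ratio = np.array([1.0, 2.0, 1.0])
    elif mode == "dominant":
        ratio = np.array([3.0, 1.0])
    else:
        raise ValueError(f"mode must be codominant or dominant, got {mode!r}")
    if len(counts) != len(ratio):
        raise ValueError(f"{mode} mode expects {len(ratio)} counts")
    expected = counts.sum() * ratio / ratio.sum()
    chi2, p = stats.chisquare(f_obs=counts, f_exp=expected)
    return SegregationResult(
        chi2=float(chi2), df=len(counts) - 1, p=float(p), distorted=bool(p < alpha)
    )


# ---------------------------------------------------------------------------
# Transferability
# ---------------------------------------------------------------------------

TRANSFER_GROUPS = ("carota", "daucus_non_carota", "non_daucus")


@dataclass(frozen=True)
class TransferMatrix:
    """Marker x accession amplification outcomes with fragment sizes.

    ``sizes`` is a DataFrame (markers x accessions) whose cells are
    tuples of observed fragment sizes in bp (empty tuple = no
    amplification).  ``expected_size`` gives the carrot-expected amplicon
    size per marker; ``accession_groups`` labels each accession with one
    of :data:`TRANSFER_GROUPS`.
    """

    sizes: pd.DataFrame
    expected_size: pd.Series
    accession_groups: pd.Series
    marker_source: pd.Series | None = None

    def __post_init__(self) -> None:
        if not self.sizes.index.equals(self.expected_size.index):
            raise ValueError("sizes and expected_size must share the marker index")
        if not self.sizes.columns.equals(self.accession_groups.index):
            raise ValueError("sizes columns and accession_groups must match")
        bad = set(self.accession_groups) - set(TRANSFER_GROUPS)
        if bad:
            raise ValueError(f"unknown accession groups: {sorted(bad)}")

    def success(self, size_window: float = 100.0) -> pd.DataFrame:
        """Boolean success matrix: some fragment within the size window."""
        expected = self.expected_size
        data = {
            acc: [
                any(abs(s - expected[m]) <= size_window for s in self.sizes.at[m, acc])
                for m in self.sizes.index
            ]
            for acc in self.sizes.columns
        }
        return pd.DataFrame(data, index=self.sizes.index, columns=self.sizes.columns)

    def outcome(self, size_window: float = 100.0) -> pd.DataFrame:
        """Categorical outcomes: ``expected_size`` / ``off_size`` / ``none``."""
        success = self.success(size_window)
        has_frag = self.sizes.map(bool)
        out = pd.DataFrame("none", index=self.sizes.index, columns=self.sizes.columns)
        out[has_frag] = "off_size"
        out[success] = "expected_size"
        return out

    def to_tsv(self, path: str | Path) -> None:
        out = pd.DataFrame(index=self.sizes.index)
        out["expected_size"] = self.expected_size
        if self.marker_source is not None:
            out["source"] = self.marker_source
        for acc in self.sizes.columns:
            col = self.sizes[acc].map(
                lambda cell: ",".join(str(int(s)) for s in cell) if cell else "-"
            )
            out[f"{acc}|{self.accession_groups[acc]}"] = col
        out.to_csv(path, sep="\t", index_label="marker")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TransferMatrix":
        raw = pd.read_csv(path, sep="\t", index_col="marker", dtype=str)
        expected = raw.pop("expected_size").astype(float)
        source = raw.pop("source") if "source" in raw.columns else None
        groups, sizes = {}, {}
        for col in raw.columns:
            acc, group = col.rsplit("|", 1)
            groups[acc] = group
            sizes[acc] = raw[col].map(
                lambda cell: ()
                if cell in ("-", "", None) or pd.isna(cell)
                else tuple(float(x) for x in str(cell).split(","))
            )
        return cls(
            sizes=pd.DataFrame(sizes, index=raw.index),
            expected_size=expected,
            accession_groups=pd.Series(groups),
            marker_source=source,
        )


def transfer_summary(
    matrix: TransferMatrix, size_window: float = 100.0, high_rate: float = 0.8
) -> dict:
    """Transferability report across accession groups.

    Includes per-accession success counts/percents, per-group mean
    success, markers succeeding in every accession of the nested sets
    (all carrot accessions; all *Daucus*, i.e. carrot plus non-carrot
    *Daucus*; all accessions), and the number of markers succeeding in at
    least ``high_rate`` of the non-carrot accessions.
    """
    success = matrix.success(size_window)
    groups = matrix.accession_groups
    per_accession = pd.DataFrame(
        {
            "group": groups,
            "n_success": success.sum(axis=0),
            "pct_success": 100 * success.mean(axis=0),
        }
    )
    per_group = per_accession.groupby("group")["pct_success"].mean().to_dict()
    group_cells = {
        g: int(success.loc[:, groups == g].sum().sum()) for g in TRANSFER_GROUPS
    }

    carota = groups.index[groups == "carota"]
    daucus = groups.index[groups.isin(["carota", "daucus_non_carota"])]
    non_carrot = groups.index[groups != "carota"]
    all_acc = groups.index
    n_nc = len(non_carrot)
    threshold = math.ceil(high_rate * n_nc - 1e-9)
    return {
        "n_markers": len(matrix.sizes.index),
        "n_accessions": len(all_acc),
        "n_cells": success.size,
        "n_success_cells": int(success.sum().sum()),
        "pct_success_cells": 100 * float(success.to_numpy().mean()),
        "per_accession": per_accession,
        "per_group_mean_pct": per_group,
        "per_group_success_cells": group_cells,
        "all_carota": int(success[carota].all(axis=1).sum()) if len(carota) else 0,
        "all_daucus": int(success[daucus].all(axis=1).sum()) if len(daucus) else 0,
        "all_accessions": int(success[all_acc].all(axis=1).sum()),
        "high_transfer_threshold": threshold,
        "high_transfer_markers": int(
            (success[non_carrot].sum(axis=1) >= threshold).sum()
        )
        if n_nc
        else 0,
    }


def interspecific_allele_count(sizes: Sequence[float], resolution: float = 3.0) -> int:
    """Distinct alleles among fragment sizes at a gel's resolving limit.

    Single-linkage clustering: sizes closer than ``resolution`` bp merge
    into one allele; the count is the number of resulting clusters.
    Empty input gives 0.
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    values = sorted(float(s) for s in sizes)
    if not values:
        return 0
    return 1 + sum(
        1 for a, b in zip(values, values[1:]) if b - a >= resolution
    )
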