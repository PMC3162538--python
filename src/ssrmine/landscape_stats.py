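"""Repeat-landscape tables and hypothesis tests.

This module reproduces the analytical layer that sits on top of SSR and
ORF detection: per-repeat-type distribution tables (counts, mean unit
numbers, densities per Mbp, most frequent motifs), compositional
expectations for motif classes, chi-square goodness-of-fit tests of the
observed motif spectrum against those expectations, inside/outside-ORF
placement tests, and Welch t-tests comparing repeat features between
datasets.

Expected motif-class probabilities use a zero-order (mononucleotide)
composition model: the probability of a class is proportional to the sum
over its distinct rotations of the product of per-base frequencies.
Since all rotations of a unit share one base multiset, this reduces to
(number of distinct rotations) x (product of base frequencies),
normalized over the primitive classes of that unit length.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .sequence_io import DatasetSummary
from .ssr_engine import SSRLocus, motif_classes
from .orf_engine import PlacementCall

__all__ = [
    "GofResult",
    "TTestResult",
    "ssr_density",
    "repeat_type_table",
    "expected_motif_probs",
    "chisq_gof",
    "motif_spectrum_gof",
    "placement_gof",
    "compare_datasets",
    "format_p",
]

REPEAT_TYPE_NAMES = {
    1: "Mononucleotide", 2: "Dinucleotide", 3: "Trinucleotide",
    4: "Tetranucleotide", 5: "Pentanucleotide", 6: "Hexanucleotide",
    7: "Heptanucleotide", 8: "Octanucleotide", 9: "Nonanucleotide",
    10: "Decanucleotide",
}


@dataclass(frozen=True, slots=True)
class GofResult:
    """Chi-square goodness-of-fit result with the underlying counts."""

    label: str
    chi2: float
    df: int
    p: float
    observed: Mapping[str, int]
    expected: Mapping[str, float]


@dataclass(frozen=True, slots=True)
class TTestResult:
    """Welch two-sample t-test with group means."""

    metric: str
    t: float
    df: float
    p: float
    mean_a: float
    mean_b: float
    n_a: int
    n_b: int


def format_p(p: float, floor: float = 1e-4) -> str:
    """Render a p-value to 4 decimals, floor-displayed as ``< 0.0001``."""
    return "< 0.0001" if p < floor else f"{p:.4f}"


def ssr_density(count: int, total_mbp: float) -> float:
    """SSR density in loci per Mbp."""
    if total_mbp <= 0:
        raise ValueError("total_mbp must be positive")
    return count / total_mbp


def repeat_type_table(
    perfect: Sequence[SSRLocus],
    compound: Sequence[SSRLocus] = (),
    summary: DatasetSummary | None = None,
    unit_len_range: tuple[int, int] = (2, 8),
    n_top_motifs: int = 3,
) -> pd.DataFrame:
    """Per-repeat-type distribution table for one dataset.

    Rows cover each unit length in ``unit_len_range``, a ``Compound``
    row, and a ``Total perfect`` row.  Percentages are of total perfect
    loci; densities are per Mbp of the dataset and are left as NaN when
    ``summary`` is omitted (appropriate for enriched-library data, which
    is not a random genomic sample and has no meaningful density).
    """
    lo, hi = unit_len_range
    total_perfect = len(perfect)
    mbp = summary.total_mbp if summary is not None else None
    rows = []
    for k in range(lo, hi + 1):
        loci = [l for l in perfect if l.unit_len == k]
        counts = Counter(l.motif_class for l in loci)
        top = ", ".join(f"{m}({c})" for m, c in counts.most_common(n_top_motifs))
        rows.append(
            {
                "repeat_type": REPEAT_TYPE_NAMES.get(k, f"k={k}"),
                "unit_len": k,
                "count": len(loci),
                "percent": 100 * len(loci) / total_perfect if total_perfect else 0.0,
                "mean_units": float(np.mean([l.n_units for l in loci])) if loci else math.nan,
                "mean_len": float(np.mean([l.total_len for l in loci])) if loci else math.nan,
                "density": ssr_density(len(loci), mbp) if mbp else math.nan,
                "top_motifs": top,
            }
        )
    rows.append(
        {
            "repeat_type": "Total perfect",
            "unit_len": 0,
            "count": total_perfect,
            "percent": 100.0 if total_perfect else 0.0,
            "mean_units": float(np.mean([l.n_units for l in perfect])) if perfect else math.nan,
            "mean_len": float(np.mean([l.total_len for l in perfect])) if perfect else math.nan,
            "density": ssr_density(total_perfect, mbp) if mbp else math.nan,
            "top_motifs": "",
        }
    )
    rows.append(
        {
            "repeat_type": "Compound",
            "unit_len": 0,
            "count": len(compound),
            "percent": 100 * len(compound) / total_perfect if total_perfect else 0.0,
            "mean_units": math.nan,
            "mean_len": float(np.mean([l.total_len for l in compound])) if compound else math.nan,
            "density": ssr_density(len(compound), mbp) if mbp else math.nan,
            "top_motifs": "",
        }
    )
    return pd.DataFrame(rows).set_index("repeat_type")


def expected_motif_probs(
    base_freqs: Mapping[str, float] | DatasetSummary, unit_len: int
) -> pd.Series:
    """Zero-order compositional expectation over canonical motif classes.

    ``base_freqs`` maps A/C/G/T to frequencies (or pass a
    :class:`DatasetSummary`, whose non-N base frequencies are used).
    Each class's probability is proportional to the summed probability of
    its distinct rotations under independent per-base draws; the vector
    is normalized to sum to 1 over the primitive classes of ``unit_len``.
    """
    if isinstance(base_freqs, DatasetSummary):
        base_freqs = base_freqs.base_freqs
    freqs = {b: float(base_freqs[b]) for b in "ACGT"}
    if any(f < 0 for f in freqs.values()) or abs(sum(freqs.values()) - 1) > 1e-6:
        raise ValueError("base frequencies must be non-negative and sum to 1")
    classes = motif_classes(unit_len)
    weights = {}
    for cls in classes:
        rotations = {cls[i:] + cls[:i] for i in range(unit_len)}
        prob_one = math.prod(freqs[b] for b in cls)
        weights[cls] = len(rotations) * prob_one
    total = sum(weights.values())
    if total <= 0:
        raise ValueError(
            "degenerate base composition: every motif class has zero probability"
        )
    return pd.Series({c: w / total for c, w in weights.items()}, name=f"k{unit_len}")


def chisq_gof(
    observed: Mapping[str, int], expected_probs: Mapping[str, float], label: str = ""
) -> GofResult:
    """Chi-square goodness of fit of class counts against a probability vector.

    Classes absent from ``observed`` count as zero.  ``df`` is the number
    of classes minus one.  Raises if any expected count is zero (pool
    classes first).
    """
    probs = pd.Series(expected_probs, dtype=float)
    if len(probs) < 2:
        raise ValueError("need at least 2 classes")
    obs = pd.Series({c: int(observed.get(c, 0)) for c in probs.index}, dtype=float)
    extra = set(observed) - set(probs.index)
    if extra:
        raise ValueError(f"observed classes not in expectation: {sorted(extra)}")
    total = obs.sum()
    if total <= 0:
        raise ValueError("total observed count must be positive")
    exp = probs * total
    if (exp == 0).any():
        zero = list(exp.index[exp == 0])
        raise ValueError(f"expected count of 0 for {zero}; pool classes before testing")
    chi2, p = stats.chisquare(f_obs=obs.to_numpy(), f_exp=exp.to_numpy())
    return GofResult(
        label=label,
        chi2=float(chi2),
        df=len(probs) - 1,
        p=float(p),
        observed={c: int(v) for c, v in obs.items()},
        expected={c: float(v) for c, v in exp.items()},
    )


def motif_spectrum_gof(
    perfect: Iterable[SSRLocus],
    summary: DatasetSummary,
    unit_len: int,
    label: str = "",
) -> GofResult:
    """Observed motif-class spectrum at one unit length vs composition.

    Convenience wrapper combining :func:`expected_motif_probs` and
    :func:`chisq_gof` for one dataset.
    """
    observed = Counter(
        l.motif_class for l in perfect if l.kind == "perfect" and l.unit_len == unit_len
    )
    probs = expected_motif_probs(summary, unit_len)
    return chisq_gof(observed, probs, label=label or f"{summary.dataset} k={unit_len}")


def placement_gof(
    placements: Sequence[PlacementCall],
    orf_frac: float,
    unit_len_range: tuple[int, int] = (2, 8),
) -> pd.DataFrame:
    """Inside/outside-ORF chi-square tests per repeat type and overall.

    ``orf_frac`` is the fraction of dataset bp inside retained ORFs (the
    compositional expectation for "inside").  Bridging calls are excluded
    before testing (two classes, df = 1).  Rows with no usable placements
    have NaN statistics.
    """
    if not (0 < orf_frac < 1):
        raise ValueError("orf_frac must lie strictly between 0 and 1")
    usable = [c for c in placements if c.status != "bridging"]
    n_bridging = len(placements) - len(usable)

    def row(label: str, calls: Sequence[PlacementCall]) -> dict:
        n = len(calls)
        inside = sum(1 for c in calls if c.status == "inside")
        outside = n - inside
        if n == 0:
            chi2 = p = math.nan
        else:
            chi2, p = stats.chisquare(
                f_obs=[inside, outside], f_exp=[n * orf_frac, n * (1 - orf_frac)]
            )
        return {
            "repeat_type": label, "n": n, "inside": inside, "outside": outside,
            "expected_inside": n * orf_frac,
            "chi2": float(chi2), "df": 1, "p": float(p),
        }

    lo, hi = unit_len_range
    rows = [
        row(
            REPEAT_TYPE_NAMES.get(k, f"k={k}"),
            [c for c in usable if c.ssr.kind == "perfect" and c.ssr.unit_len == k],
        )
        for k in range(lo, hi + 1)
    ]
    rows.append(row("Total", usable))
    table = pd.DataFrame(rows).set_index("repeat_type")
    table.attrs["n_bridging"] = n_bridging
    return table


def compare_datasets(
    a: Sequence[float], b: Sequence[float], metric: str = ""
) -> TTestResult:
    """Welch two-sample t-test between two sets of per-locus values.

    Identical constant samples (zero variance, equal means) give p = 1 by
    convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both samples must have n >= 2")
    with warnings.catch_warnings():
        # constant samples trip scipy's precision-loss warning; the nan
        # result is converted to the documented convention below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(a, b, equal_var=False)
    t, p = float(res.statistic), float(res.pvalue)
    df = float(res.df)
    if math.isnan(t):
        if math.isclose(a.mean(), b.mean()):
            t, p = 0.0, 1.0
        else:  # zero variance, different means: certain difference
            t, p = math.copysign(math.inf, a.mean() - b.mean()), 0.0
    return TTestResult(
        metric=metric, t=t, df=df, p=p,
        mean_a=float(a.mean()), mean_b=float(b.mean()), n_a=len(a), n_b=len(b),
    )
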