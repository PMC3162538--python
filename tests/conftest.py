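"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the implementation's regex code
paths: they are plain nested loops over candidate (start, unit-length)
anchors, used to certify the detectors on random sequences.
"""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import settings

from ssrmine import SSRSearchConfig

settings.register_profile("repeatable", derandomize=True, deadline=None)
settings.load_profile("repeatable")
from ssrmine.ssr_engine import is_primitive

BASES = "ACGT"


def random_sequence(rng: np.random.Generator, length: int, gc: float = 0.4) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list(BASES), size=length, p=p))


def repeat_rich_sequence(rng: np.random.Generator, length: int) -> str:
    """Random sequence salted with repeat runs around the thresholds.

    Inserts perfect runs (some below, some above the detection
    thresholds, some with non-primitive units, occasionally adjacent) so
    that edge cases are actually exercised; coordinates are NOT tracked —
    the oracle defines the truth.
    """
    seq = list(random_sequence(rng, length))
    n_inserts = max(3, length // 250)
    for _ in range(n_inserts):
        k = int(rng.integers(1, 9))
        unit = "".join(rng.choice(list(BASES), size=k))
        n_units = int(rng.integers(2, 9))
        pos = int(rng.integers(0, max(1, length - k * n_units)))
        seq[pos : pos + k * n_units] = list(unit * n_units)
    return "".join(seq[:length])


def oracle_perfect_ssrs(seq: str, cfg: SSRSearchConfig) -> list[tuple[int, int, int, str]]:
    """Brute-force perfect-SSR scan: ``(start, end, k, unit)`` tuples.

    For every unit length k, walks anchors left to right; at each anchor
    counts whole-unit matches by direct string comparison.  Any run of
    >= 2 whole units is consumed (the walk resumes after it, so same-k
    loci never overlap and anchoring is leftmost); a consumed run is
    reported when it meets both thresholds and its unit is primitive.
    """
    found = []
    n = len(seq)
    for k in range(cfg.unit_len_min, cfg.unit_len_max + 1):
        need = max(cfg.min_units, math.ceil(cfg.min_total_len / k))
        pos = 0
        while pos + 2 * k <= n:
            unit = seq[pos : pos + k]
            if "N" in unit:
                pos += 1
                continue
            count = 1
            while seq[pos + count * k : pos + (count + 1) * k] == unit:
                count += 1
            if count < 2:
                pos += 1
                continue
            end = pos + count * k
            if count >= need and is_primitive(unit):
                found.append((pos, end, k, unit))
            pos = end
    found.sort(key=lambda t: (t[0], t[2]))
    return found


def oracle_orfs_forward(seq: str, min_len: int) -> list[tuple[int, int, int]]:
    """Brute-force forward-strand ORF candidates ``(frame, start, end)``.

    Walks each frame codon by codon; an ORF opens at the first ATG after
    the previous in-frame stop and closes at the next stop, reported
    when the coding distance is >= ``min_len``.
    """
    stops = {"TAA", "TAG", "TGA"}
    out = []
    for frame in range(3):
        atg_open = None
        for pos in range(frame, len(seq) - 2, 3):
            codon = seq[pos : pos + 3]
            if codon in stops:
                if atg_open is not None and pos - atg_open >= min_len:
                    out.append((frame, atg_open, pos))
                atg_open = None
            elif codon == "ATG" and atg_open is None:
                atg_open = pos
    return sorted(out, key=lambda t: (t[1], t[2]))


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)
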