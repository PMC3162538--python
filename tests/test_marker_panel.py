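"""Polymorphism index, screening summaries, segregation and transferability."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ssrmine import (
    ScreeningMatrix,
    bin_repeat_class,
    compute_pi,
    interspecific_allele_count,
    pi_vs_repeats,
    polymorphism_summary,
    segregation_chisq,
    transfer_summary,
)
from ssrmine.marker_panel import CALL_CODES, TransferMatrix

CALLS = list(CALL_CODES.values())


def _row(c=0, d=0, m=0, a=0, n=0, nd=0):
    return (
        ["codominant"] * c + ["dominant"] * d + ["monomorphic"] * m
        + ["ambiguous"] * a + ["no_amplification"] * n + ["missing"] * nd
    )


class TestComputePi:
    @pytest.mark.parametrize(
        "row,expected",
        [
            (_row(c=7), 100.0),                 # codominant everywhere
            (_row(m=7), 0.0),                   # monomorphic everywhere
            (_row(c=1, d=2, m=2, nd=2), 40.0),  # 100*(2+2)/(2*(7-2))
            (_row(d=7), 50.0),                  # dominant everywhere
            (_row(c=2, a=3, n=2), 100 * 4 / 14),  # ambiguous/no-amp are scored, not nd
        ],
    )
    def test_worked_values(self, row, expected):
        assert compute_pi(row) == pytest.approx(expected)

    def test_all_missing_is_undefined(self):
        assert math.isnan(compute_pi(_row(nd=7)))

    @given(
        st.lists(st.sampled_from(CALLS), min_size=1, max_size=12)
    )
    @settings(max_examples=300, deadline=None)
    def test_bounded_and_monotone(self, calls):
        pi = compute_pi(calls)
        if math.isnan(pi):
            assert all(c == "missing" for c in calls)
            return
        assert 0.0 <= pi <= 100.0
        # PI = 100 iff codominant in every scored population
        scored = [c for c in calls if c != "missing"]
        if pi == 100.0:
            assert scored and all(c == "codominant" for c in scored)
        # upgrading one non-codominant scored call to codominant never lowers PI
        for i, c in enumerate(calls):
            if c not in ("codominant", "missing"):
                upgraded = calls.copy()
                upgraded[i] = "codominant"
                assert compute_pi(upgraded) >= pi
                break


class TestPolymorphismSummary:
    def _matrix(self, rows, sources=None, units=None):
        calls = pd.DataFrame(
            rows,
            index=[f"m{i}" for i in range(len(rows))],
            columns=[f"p{j}" for j in range(len(rows[0]))],
        )
        info = pd.DataFrame(
            {
                "source": sources or ["GSSR"] * len(rows),
                "total_units": units or [8] * len(rows),
            },
            index=calls.index,
        )
        return ScreeningMatrix(calls=calls, marker_info=info)

    def test_all_monomorphic(self):
        s = polymorphism_summary(self._matrix([_row(m=7)] * 4))
        assert s["polymorphic_ge1"] == 0 and s["polymorphic_ge2"] == 0

    def test_toy_counts_by_hand(self):
        matrix = self._matrix(
            [_row(c=2, m=5), _row(d=1, m=6), _row(m=7)],
            sources=["GSSR", "BSSR", "GSSR"],
        )
        s = polymorphism_summary(matrix)
        assert s["n_markers"] == 3
        assert s["polymorphic_ge1"] == 2
        assert s["polymorphic_ge2"] == 1
        assert s["polymorphic_ge1_pct"] == pytest.approx(100 * 2 / 3)
        assert s["by_source"]["GSSR"]["polymorphic_ge1"] == 1
        assert s["by_source"]["BSSR"]["polymorphic_ge1"] == 1
        # per-population percents: population p0 has C,D,M -> 2/3
        assert s["per_population_pct"]["p0"] == pytest.approx(100 * 2 / 3)

    def test_invariant_to_ordering(self, rng):
        rows = [
            [CALLS[i] for i in rng.integers(0, len(CALLS), size=7)] for _ in range(40)
        ]
        m1 = self._matrix(rows)
        s1 = polymorphism_summary(m1)
        perm = rng.permutation(40)
        m2 = ScreeningMatrix(
            calls=m1.calls.iloc[perm, ::-1], marker_info=m1.marker_info.iloc[perm]
        )
        s2 = polymorphism_summary(m2)
        for key in ("polymorphic_ge1", "polymorphic_ge2", "n_markers"):
            assert s1[key] == s2[key]

    def test_tsv_roundtrip(self, tmp_path, rng):
        rows = [
            [CALLS[i] for i in rng.integers(0, len(CALLS), size=5)] for _ in range(20)
        ]
        m1 = self._matrix(rows, units=list(rng.integers(3, 25, size=20)))
        path = tmp_path / "screen.tsv"
        m1.to_tsv(path)
        m2 = ScreeningMatrix.from_tsv(path)
        pd.testing.assert_frame_equal(m1.calls, m2.calls, check_names=False)
        pd.testing.assert_frame_equal(m1.marker_info, m2.marker_info, check_names=False)


class TestRepeatClassesAndRegression:
    @pytest.mark.parametrize(
        "units,cls",
        [(0, "<6"), (5, "<6"), (6, "6-10"), (10, "6-10"), (11, "11-15"),
         (15, "11-15"), (16, ">15"), (40, ">15")],
    )
    def test_bin_boundaries(self, units, cls):
        assert bin_repeat_class(units) == cls

    def test_summed_units_of_multi_ssr_amplicon(self):
        # a marker carrying (AT)6 and (CTT)5 totals 11 repeat units
        assert bin_repeat_class(6 + 5) == "11-15"

    def _matrix_with_trend(self, rng, n=300):
        units = rng.integers(3, 25, size=n)
        rows = []
        for u in units:
            p_poly = min(0.9, 0.02 * u)
            row = [
                "codominant" if rng.random() < p_poly else "monomorphic"
                for _ in range(7)
            ]
            rows.append(row)
        calls = pd.DataFrame(
            rows, index=[f"m{i}" for i in range(n)],
            columns=[f"p{j}" for j in range(7)],
        )
        info = pd.DataFrame(
            {"source": ["GSSR"] * n, "total_units": units}, index=calls.index
        )
        return ScreeningMatrix(calls=calls, marker_info=info)

    def test_positive_correlation_recovered(self, rng):
        report = pi_vs_repeats(self._matrix_with_trend(rng))
        assert report["pearson_r"] > 0
        assert report["p"] < 0.05
        assert report["slope"] > 0
        per_class = report["per_class"]
        assert set(per_class.index) == {"<6", "6-10", "11-15", ">15"}
        assert (
            per_class.loc[">15", "mean_pi"] > per_class.loc["<6", "mean_pi"]
        )

    def test_constant_pi_reports_undefined_r(self):
        calls = pd.DataFrame(
            [_row(m=7)] * 5, index=[f"m{i}" for i in range(5)],
            columns=[f"p{j}" for j in range(7)],
        )
        info = pd.DataFrame(
            {"source": ["GSSR"] * 5, "total_units": [3, 7, 12, 18, 22]},
            index=calls.index,
        )
        report = pi_vs_repeats(ScreeningMatrix(calls=calls, marker_info=info))
        assert math.isnan(report["pearson_r"])

    def test_perfect_linear_toy_data(self):
        # markers whose codominant count rises stepwise with units
        rows = [_row(c=c, m=7 - c) for c in (1, 2, 3, 4)]
        calls = pd.DataFrame(
            rows, index=[f"m{i}" for i in range(4)], columns=[f"p{j}" for j in range(7)]
        )
        info = pd.DataFrame(
            {"source": ["GSSR"] * 4, "total_units": [5, 10, 15, 20]}, index=calls.index
        )
        report = pi_vs_repeats(ScreeningMatrix(calls=calls, marker_info=info))
        assert report["pearson_r"] == pytest.approx(1.0)


class TestSegregation:
    def test_perfect_ratios_not_distorted(self):
        assert segregation_chisq([25, 50, 25], "codominant").chi2 == pytest.approx(0)
        assert segregation_chisq([75, 25], "dominant").chi2 == pytest.approx(0)

    def test_hand_arithmetic_distorted(self):
        res = segregation_chisq([10, 50, 40], "codominant")
        assert res.chi2 == pytest.approx(18.0)
        assert res.df == 2
        assert res.distorted

    def test_threshold_is_p_below_alpha(self):
        # chi2 = 6.88 on df 2 -> p ~ 0.032: not distorted at alpha 0.01
        res = segregation_chisq([14, 60, 26], "codominant")
        assert 0.01 < res.p < 0.05
        assert not res.distorted


class TestTransfer:
    def _matrix(self, success_grid, expected=200.0):
        # success_grid: markers x accessions of bool; successes get the
        # expected size, failures get nothing
        groups = ["carota"] * 2 + ["daucus_non_carota"] * 2 + ["non_daucus"] * 2
        acc = [f"a{i}" for i in range(6)]
        markers = [f"m{i}" for i in range(len(success_grid))]
        sizes = pd.DataFrame(
            [
                [(expected,) if cell else () for cell in row]
                for row in success_grid
            ],
            index=markers, columns=acc,
        )
        return TransferMatrix(
            sizes=sizes,
            expected_size=pd.Series(expected, index=markers),
            accession_groups=pd.Series(groups, index=acc),
        )

    def test_all_success(self):
        m = self._matrix([[True] * 6] * 3)
        rep = transfer_summary(m)
        assert rep["pct_success_cells"] == 100.0
        assert rep["all_accessions"] == 3
        assert rep["all_carota"] == 3

    def test_counts_by_hand(self):
        grid = [
            [True, True, True, True, True, True],
            [True, True, True, False, True, False],
            [False, True, False, False, False, False],
        ]
        rep = transfer_summary(m := self._matrix(grid))
        assert rep["n_success_cells"] == 6 + 4 + 1
        assert rep["all_carota"] == 2
        assert rep["all_daucus"] == 1
        assert rep["all_accessions"] == 1
        # group cell counts partition the overall success count
        assert sum(rep["per_group_success_cells"].values()) == rep["n_success_cells"]

    def test_off_size_fragment_is_failure(self):
        m = self._matrix([[True] * 6])
        sizes = m.sizes.copy()
        sizes.iloc[0, 0] = (340.0,)  # 140 bp off expected 200
        m2 = TransferMatrix(sizes, m.expected_size, m.accession_groups)
        out = m2.outcome(size_window=100)
        assert out.iloc[0, 0] == "off_size"
        rep = transfer_summary(m2)
        assert rep["n_success_cells"] == 5

    def test_size_window_boundary_inclusive(self):
        m = self._matrix([[True] * 6])
        sizes = m.sizes.copy()
        sizes.iloc[0, 0] = (300.0,)  # exactly +100
        m2 = TransferMatrix(sizes, m.expected_size, m.accession_groups)
        assert bool(m2.success(100).iloc[0, 0])

    def test_high_transfer_threshold_at_80pct(self):
        # 4 non-carrot accessions -> threshold ceil(0.8*4) = 4; with the
        # study's 15 the threshold is 12 (12/15 = 80% counts as high)
        assert math.ceil(0.8 * 15 - 1e-9) == 12
        grid = [[True, True, True, True, True, False]]
        rep = transfer_summary(self._matrix(grid), high_rate=0.75)
        # 3 of 4 non-carrot successes = 75% -> counted at threshold 3
        assert rep["high_transfer_threshold"] == 3
        assert rep["high_transfer_markers"] == 1

    def test_tsv_roundtrip(self, tmp_path, rng):
        grid = rng.random((12, 6)) < 0.6
        m1 = self._matrix(grid.tolist())
        path = tmp_path / "transfer.tsv"
        m1.to_tsv(path)
        m2 = TransferMatrix.from_tsv(path)
        pd.testing.assert_frame_equal(m1.success(), m2.success(), check_names=False)
        assert (m1.accession_groups == m2.accession_groups).all()


class TestAlleleCount:
    @pytest.mark.parametrize(
        "sizes,expected",
        [
            ([200, 200, 200], 1),
            ([200, 201, 210], 2),  # 200/201 merge below the 3 bp limit
            ([], 0),
            ([200, 202, 204, 206], 1),  # chained single linkage
            ([200, 203, 206], 3),
            ([150.0], 1),
        ],
    )
    def test_single_linkage_clusters(self, sizes, expected):
        assert interspecific_allele_count(sizes, resolution=3) == expected

    def test_matches_bruteforce_clustering(self, rng):
        for _ in range(50):
            sizes = sorted(rng.integers(100, 160, size=rng.integers(1, 25)).tolist())
            got = interspecific_allele_count(sizes, resolution=3)
            clusters = 1
            for a, b in zip(sizes, sizes[1:]):
                if b - a >= 3:
                    clusters += 1
            assert got == clusters
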