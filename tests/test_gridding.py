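"""Tests for trap gridding, treatment exclusion, medians and filters."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import spreadwait as sw
from spreadwait.gridding import Status
from spreadwait.simulate import TreatmentEvent


def _traps(rows):
    return pd.DataFrame(rows, columns=["trap_id", "x", "y", "year", "count"])


class TestExcludeTreated:
    def test_same_year_record_dropped_other_years_kept(self):
        traps = _traps([(1, 0.0, 0.0, 2000, 3), (1, 0.0, 0.0, 2001, 4)])
        treat = [TreatmentEvent(x=1400.0, y=0.0, radius_m=0.0, year=2000)]
        out = sw.exclude_treated(traps, treat)
        assert out["year"].tolist() == [2001]

    def test_boundary_trap_exactly_at_radius_kept(self):
        traps = _traps([(1, 1500.0, 0.0, 2000, 3)])
        treat = [TreatmentEvent(x=0.0, y=0.0, radius_m=0.0, year=2000)]
        assert len(sw.exclude_treated(traps, treat)) == 1

    def test_disc_radius_extends_the_footprint(self):
        # 2400 m from center but only 1400 m from a 1000 m disc edge
        traps = _traps([(1, 2400.0, 0.0, 2000, 3)])
        treat = [TreatmentEvent(x=0.0, y=0.0, radius_m=1000.0, year=2000)]
        assert len(sw.exclude_treated(traps, treat)) == 0

    def test_negative_radius_rejected(self):
        with pytest.raises(ValueError):
            sw.exclude_treated(_traps([]), [], radius=-1.0)

    def test_matches_brute_force_scan(self, rng):
        traps = _traps(
            [
                (i, rng.uniform(0, 20000), rng.uniform(0, 20000),
                 int(rng.integers(1995, 2005)), int(rng.integers(0, 5)))
                for i in range(100)
            ]
        )
        discs = [
            TreatmentEvent(
                x=float(rng.uniform(0, 20000)),
                y=float(rng.uniform(0, 20000)),
                radius_m=float(rng.uniform(0, 2000)),
                year=int(rng.integers(1995, 2005)),
            )
            for _ in range(5)
        ]
        out = sw.exclude_treated(traps, discs)
        survivors = {
            (row.trap_id, row.year)
            for row in traps.itertuples()
            if not any(
                row.year == d.year
                and np.hypot(row.x - d.x, row.y - d.y) < d.radius_m + 1500.0
                for d in discs
            )
        }
        assert {(r.trap_id, r.year) for r in out.itertuples()} == survivors


class TestAssignQuadrats:
    def test_origin_and_halfopen_edges(self):
        grid = sw.GridSpec(cell_size=5000.0, n_rows=4, n_cols=4)
        traps = _traps(
            [(1, 0.0, 0.0, 2000, 0), (2, 5000.0, 0.0, 2000, 0)]
        )
        out = sw.assign_quadrats(traps, grid)
        assert out.loc[0, ["row", "col"]].tolist() == [0, 0]
        assert out.loc[1, ["row", "col"]].tolist() == [0, 1]

    def test_out_of_extent_dropped(self):
        grid = sw.GridSpec(cell_size=5000.0, n_rows=2, n_cols=2)
        traps = _traps([(1, -1.0, 0.0, 2000, 0), (2, 1.0, 10001.0, 2000, 0)])
        assert len(sw.assign_quadrats(traps, grid)) == 0

    def test_matches_rectangle_membership_oracle(self, rng):
        grid = sw.GridSpec(x0=-3000.0, y0=2000.0, cell_size=5000.0, n_rows=6, n_cols=5)
        traps = _traps(
            [
                (i, rng.uniform(-3000, 22000), rng.uniform(2000, 32000), 2000, 0)
                for i in range(1000)
            ]
        )
        out = sw.assign_quadrats(traps, grid)
        for row in out.itertuples():
            xlo = grid.x0 + row.col * grid.cell_size
            ylo = grid.y0 + row.row * grid.cell_size
            assert xlo <= row.x < xlo + grid.cell_size
            assert ylo <= row.y < ylo + grid.cell_size


class TestMedianSeries:
    @pytest.mark.parametrize(
        "counts, expected",
        [([0, 0, 3], 0.0), ([1, 2, 3, 10], 2.5), ([5], 5.0)],
    )
    def test_median_conventions(self, counts, expected):
        grid = sw.GridSpec(cell_size=5000.0, n_rows=1, n_cols=1)
        traps = _traps([(i, 100.0, 100.0, 2000, c) for i, c in enumerate(counts)])
        series = sw.median_series(traps, grid, years=np.array([2000]))
        assert series[(0, 0)].median[0] == expected

    def test_years_without_traps_are_missing(self):
        grid = sw.GridSpec(cell_size=5000.0, n_rows=1, n_cols=1)
        traps = _traps([(0, 1.0, 1.0, 2000, 2), (0, 1.0, 1.0, 2002, 4)])
        s = sw.median_series(traps, grid, years=np.arange(2000, 2003))[(0, 0)]
        assert np.isnan(s.median[1]) and s.n_traps[1] == 0
        assert s.total_catch == 6

    def test_matches_sort_based_oracle(self, rng):
        grid = sw.GridSpec(cell_size=5000.0, n_rows=3, n_cols=3)
        traps = _traps(
            [
                (i, rng.uniform(0, 15000), rng.uniform(0, 15000),
                 int(rng.integers(2000, 2003)), int(rng.integers(0, 40)))
                for i in range(300)
            ]
        )
        annotated = sw.assign_quadrats(traps, grid)
        series = sw.median_series(annotated, grid, years=np.arange(2000, 2003))
        for (r, c), s in series.items():
            for yi, year in enumerate(s.years):
                vals = sorted(
                    row.count
                    for row in annotated.itertuples()
                    if row.row == r and row.col == c and row.year == year
                )
                if not vals:
                    assert np.isnan(s.median[yi])
                    continue
                n = len(vals)
                want = (
                    vals[n // 2]
                    if n % 2
                    else 0.5 * (vals[n // 2 - 1] + vals[n // 2])
                )
                assert s.median[yi] == want

    @settings(max_examples=25, deadline=None)
    @given(perm_seed=st.integers(0, 10_000))
    def test_permutation_invariance(self, perm_seed):
        rng = np.random.default_rng(123)
        grid = sw.GridSpec(cell_size=5000.0, n_rows=2, n_cols=2)
        traps = _traps(
            [
                (i, rng.uniform(0, 10000), rng.uniform(0, 10000),
                 int(rng.integers(2000, 2002)), int(rng.integers(0, 9)))
                for i in range(60)
            ]
        )
        shuffled = traps.sample(
            frac=1.0, random_state=perm_seed, ignore_index=True
        )
        a = sw.median_series(traps, grid, years=np.arange(2000, 2002))
        b = sw.median_series(shuffled, grid, years=np.arange(2000, 2002))
        assert a.keys() == b.keys()
        for key in a:
            np.testing.assert_array_equal(a[key].median, b[key].median)
            assert a[key].total_catch == b[key].total_catch


class TestDetectionAndFilters:
    def _series(self, medians, start=1985, totals=None):
        medians = np.asarray(medians, float)
        return sw.QuadratSeries(
            row=0,
            col=0,
            years=np.arange(start, start + len(medians)),
            median=medians,
            n_traps=(~np.isnan(medians)).astype(int),
            total_catch=int(totals if totals is not None else np.nansum(medians) * 3),
        )

    @pytest.mark.parametrize(
        "medians, expected",
        [
            ([0, 0, 1, 5], 1987),
            ([0, 0.5, 2], 1987),
            ([0, 0, 0], None),
            ([np.nan, 0, 3], 1987),
        ],
    )
    def test_first_detection_year(self, medians, expected):
        assert sw.first_detection_year(self._series(medians)) == expected

    def test_low_catch_excluded_first(self):
        s = self._series([2, 2, 2], totals=9)  # pre-established AND low catch
        assert (
            sw.apply_inclusion_filters(s).status is Status.EXCLUDED_LOW_CATCH
        )

    def test_pre_established_when_first_record_positive(self):
        s = self._series([2, 0, 0], totals=50)
        st_ = sw.apply_inclusion_filters(s)
        assert st_.status is Status.EXCLUDED_PRE_ESTABLISHED

    def test_leading_missing_years_carry_no_record(self):
        s = self._series([np.nan, np.nan, 2, 0], totals=50)
        assert (
            sw.apply_inclusion_filters(s).status
            is Status.EXCLUDED_PRE_ESTABLISHED
        )

    def test_eligible_quadrat_included(self):
        s = self._series([0, 0, 3, 8], totals=50)
        assert sw.apply_inclusion_filters(s).status is Status.INCLUDED

    def test_filters_idempotent(self):
        s = self._series([0, 1, 4], totals=40)
        first = sw.apply_inclusion_filters(s)
        second = sw.apply_inclusion_filters(s)
        assert first.status is second.status
        assert first.detection_year == second.detection_year

    def test_median_sum_variant(self):
        s = self._series([0, 2, 3], totals=100)
        st_raw = sw.apply_inclusion_filters(s, low_catch_on_medians=False)
        st_med = sw.apply_inclusion_filters(s, low_catch_on_medians=True)
        assert st_raw.status is Status.INCLUDED
        assert st_med.status is Status.EXCLUDED_LOW_CATCH  # sum of medians 5 < 10
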