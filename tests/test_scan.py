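import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pbscan.scan import (
    branch_length,
    call_peaks,
    fst_site_components,
    genome_fst,
    pbs,
    pbs_threshold,
    peaks_frame,
    sliding_scan,
    window_fst,
)

from _oracles import fst_components_oracle


def _one_hot(n, j):
    v = np.zeros(2 * n + 1)
    v[j] = 1.0
    return v


class TestFstComponents:
    def test_certain_fixed_difference_gives_fst_one(self):
        n1, n2 = 4, 4
        eta = np.full((9, 9), 1.0 / 81)
        a, d = fst_site_components(
            _one_hot(n1, 8)[None], _one_hot(n2, 0)[None], eta, n1, n2
        )
        assert a[0] == pytest.approx(1.0, abs=1e-12)
        assert d[0] == pytest.approx(1.0, abs=1e-12)

    def test_equal_intermediate_frequencies(self):
        # p1 = p2 = 0.5 with n = 2: N = -2 * (0.25/3) = -1/6, D = 0.5
        n = 2
        eta = np.full((5, 5), 1.0 / 25)
        a, d = fst_site_components(_one_hot(n, 2)[None], _one_hot(n, 2)[None], eta, n, n)
        assert a[0] == pytest.approx(-1.0 / 6.0, abs=1e-12)
        assert d[0] == pytest.approx(0.5, abs=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.integers(2, 4), st.integers(2, 4), st.integers(0, 10_000))
    def test_matches_double_loop_oracle(self, n1, n2, seed):
        rng = np.random.default_rng(seed)
        saf1 = rng.random(2 * n1 + 1)
        saf2 = rng.random(2 * n2 + 1)
        eta = rng.random((2 * n1 + 1, 2 * n2 + 1))
        eta /= eta.sum()
        a, d = fst_site_components(saf1[None], saf2[None], eta, n1, n2)
        ao, do = fst_components_oracle(saf1, saf2, eta, n1, n2)
        assert a[0] == pytest.approx(ao, abs=1e-10)
        assert d[0] == pytest.approx(do, abs=1e-10)

    def test_flat_inputs_equal_uniform_average(self):
        n1, n2 = 3, 3
        J = 2 * n1 + 1
        saf = np.ones(J)
        eta = np.full((J, J), 1.0 / J**2)
        a, d = fst_site_components(saf[None], saf[None], eta, n1, n2)
        ao, do = fst_components_oracle(saf, saf, eta, n1, n2)
        assert a[0] == pytest.approx(ao, abs=1e-12)
        assert d[0] == pytest.approx(do, abs=1e-12)


class TestWindowFst:
    def test_a_equals_d_gives_one(self):
        assert window_fst(np.array([0.3, 0.7]), np.array([0.3, 0.7])) == 1.0

    def test_ratio_of_sums_not_mean_of_ratios(self):
        a, d = np.array([0.5, 0.0]), np.array([1.0, 1.0])
        assert window_fst(a, d) == 0.25  # mean of ratios would also be 0.25 here
        a, d = np.array([0.5, 0.1]), np.array([1.0, 0.1])
        assert window_fst(a, d) == pytest.approx(0.6 / 1.1)
        assert window_fst(a, d) != pytest.approx((0.5 + 1.0) / 2)

    def test_zero_denominator_is_missing(self):
        assert np.isnan(window_fst(np.array([0.0]), np.array([0.0])))


class TestBranchLengthAndPbs:
    def test_zero(self):
        assert branch_length(0.0) == 0.0

    def test_half(self):
        assert branch_length(0.5) == pytest.approx(math.log(2), abs=1e-6)

    def test_negative_clamped(self):
        assert branch_length(-0.01) == 0.0

    def test_fst_one_is_infinite(self):
        assert branch_length(1.0) == float("inf")

    def test_pbs_zero(self):
        assert pbs(0.0, 0.0, 0.0) == 0.0

    def test_pbs_worked_example_from_genomewide_fsts(self):
        # trio 0.044 / 0.040 / 0.016 -> 0.0348, near the genome-wide mean 0.034
        val = pbs(0.044, 0.040, 0.016)
        assert val == pytest.approx(0.034845, abs=1e-5)

    def test_pbs_equal_fst_closed_form(self):
        f = 0.1
        assert pbs(f, f, f) == pytest.approx(-math.log(1 - f) / 2, abs=1e-12)
        assert pbs(f, f, f) == pytest.approx(0.052680, abs=1e-6)

    def test_pbs_missing_propagates(self):
        assert np.isnan(pbs(float("nan"), 0.1, 0.1))

    def test_pbs_symmetric_in_nonfocal_pair(self):
        assert pbs(0.03, 0.05, 0.01) == pbs(0.05, 0.03, 0.01)

    def test_pbs_focal_swap_follows_formula(self):
        # swapping focal i with j: PBS_j = (T_ij + T_jk - T_ik) / 2
        t = {k: branch_length(v) for k, v in zip("abc", (0.03, 0.05, 0.01))}
        assert pbs(0.03, 0.01, 0.05) == pytest.approx(
            (t["a"] + t["c"] - t["b"]) / 2
        )


def _components_for(positions, value=0.01):
    a = np.full(len(positions), value)
    d = np.ones(len(positions))
    return {"ij": (a, d), "ik": (a, d), "jk": (a, d)}


class TestSlidingScan:
    def test_tiling_when_window_equals_step(self):
        positions = np.arange(1, 10_001, 100)
        win = sliding_scan(positions, _components_for(positions), window=1000,
                           step=1000, chrom_length=10_000, min_sites=1)
        assert win["n_sites"].sum() == len(positions)
        assert (win["end"] - win["start"] == 1000).all()

    def test_site_contributes_to_expected_windows(self):
        positions = np.array([55_000])
        win = sliding_scan(positions, _components_for(positions), window=50_000,
                           step=10_000, chrom_length=100_000, min_sites=1)
        containing = win.loc[win["n_sites"] == 1, "start"].to_numpy()
        assert list(containing) == [10_001, 20_001, 30_001, 40_001, 50_001]

    def test_empty_chromosome_has_no_windows(self):
        win = sliding_scan(np.array([]), _components_for(np.array([])),
                           window=1000, step=500)
        assert len(win) == 0

    def test_window_fst_matches_per_window_recomputation(self, rng):
        positions = np.sort(rng.choice(200_000, size=500, replace=False) + 1)
        a = rng.random(500) * 0.1
        d = rng.random(500) + 0.5
        comps = {"ij": (a, d), "ik": (a, d), "jk": (a, d)}
        win = sliding_scan(positions, comps, window=20_000, step=5_000,
                           chrom_length=200_000, min_sites=1)
        for _, row in win.iloc[::7].iterrows():
            m = (positions >= row["start"]) & (positions < row["end"])
            if m.sum() == 0:
                assert np.isnan(row["fst_ij"])
            else:
                assert row["fst_ij"] == pytest.approx(a[m].sum() / d[m].sum(), rel=1e-9)

    def test_min_sites_windows_are_missing(self):
        positions = np.array([100, 50_000])
        win = sliding_scan(positions, _components_for(positions), window=10_000,
                           step=10_000, chrom_length=50_000, min_sites=2)
        assert win["pbs"].isna().all()

    def test_warns_when_window_not_multiple_of_step(self):
        positions = np.array([10, 20])
        with pytest.warns(UserWarning, match="multiple"):
            sliding_scan(positions, _components_for(positions), window=1000,
                         step=300, chrom_length=1000, min_sites=1)


def _window_frame(starts, pbs_values, window=50_000, chrom="1"):
    starts = np.asarray(starts)
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": starts,
            "end": starts + window,
            "n_sites": 50,
            "fst_ij": 0.05,
            "fst_ik": 0.05,
            "fst_jk": 0.05,
            "pbs": pbs_values,
        }
    )


class TestCallPeaks:
    def _background(self, rng, n=2000):
        starts = 1 + 10_000 * np.arange(n)
        return starts, rng.normal(0.03, 0.005, size=n)

    def test_no_window_above_threshold_means_no_peaks(self):
        win = _window_frame([1, 10_001, 20_001], [0.1, 0.1, 0.1])
        assert call_peaks(win, top_fraction=0.5, min_windows=6) == []

    def test_single_cluster_called_with_correct_size(self, rng):
        starts, vals = self._background(rng)
        vals[100:110] = 1.0 + np.arange(10) * 0.01  # 10 contiguous top windows
        vals[600:603] = 0.9  # 3 top windows >= 1 Mb away: below min_windows
        win = _window_frame(starts, vals)
        peaks = call_peaks(win, top_fraction=0.01, min_windows=6,
                           merge_distance=1_000_000)
        assert len(peaks) == 1
        assert peaks[0].n_top_windows == 10
        assert peaks[0].start == starts[109]  # best window seeds the peak

    def test_two_distant_clusters_sorted_by_best_pbs(self, rng):
        starts, vals = self._background(rng)
        vals[100:107] = 0.8
        vals[500:507] = 1.2  # 4 Mb away, higher PBS
        win = _window_frame(starts, vals)
        peaks = call_peaks(win, top_fraction=0.01, min_windows=6,
                           merge_distance=1_000_000)
        assert len(peaks) == 2
        assert peaks[0].best_pbs > peaks[1].best_pbs
        assert peaks[0].start == starts[500]

    def test_quantile_strict_count(self, rng):
        vals = rng.permutation(np.linspace(0, 1, 1000))
        thr = pbs_threshold(vals, top_fraction=0.01)
        n_above = int((vals > thr).sum())
        assert n_above in (10, 11)

    def test_warns_for_too_few_windows(self):
        with pytest.warns(UserWarning, match="windows"):
            pbs_threshold(np.arange(10.0), top_fraction=0.001)

    def test_peaks_frame_reports_kb(self):
        peaks = call_peaks(
            _window_frame([1 + 10_000 * i for i in range(100)],
                          [1.0] * 7 + [0.0] * 93),
            top_fraction=0.1, min_windows=6,
        )
        frame = peaks_frame(peaks)
        assert frame["position_kb"].iloc[0] == pytest.approx(0.001)
        assert frame["windows"].iloc[0] == 7


def test_genome_fst_is_ratio_of_sums(rng):
    a, d = rng.random(100), rng.random(100) + 0.5
    assert genome_fst(a, d) == pytest.approx(a.sum() / d.sum())
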