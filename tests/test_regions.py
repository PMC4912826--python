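"""Sliding-window PP_int, candidate peaks, region selection and variance."""

import numpy as np
import pandas as pd
import pytest

from pigwas import (
    QTLRegionScan,
    build_windows,
    compute_pp_int,
    find_candidate_peaks,
    region_variance,
    select_regions,
)
from pigwas.mixture import PosteriorSamples


def make_map(positions, chromosomes=None):
    m = len(positions)
    chromosomes = np.ones(m, dtype=int) if chromosomes is None else chromosomes
    return pd.DataFrame(
        {
            "marker_id": [f"S{j}" for j in range(m)],
            "chromosome": chromosomes,
            "position_bp": positions,
            "allele_1": "A",
            "allele_2": "B",
        }
    )


def make_samples(delta, g=None, u=None, n_ind=4):
    delta = np.asarray(delta, dtype=np.uint8)
    T, m = delta.shape
    g = np.zeros((T, m)) if g is None else np.asarray(g, float)
    u = np.zeros((T, n_ind)) if u is None else np.asarray(u, float)
    z = np.ones(T)
    return PosteriorSamples(
        g=g, delta=delta, u=u, mu=z, sigma2_g0=z, pi0=z, sigma2_u=z, sigma2_e=z
    )


def brute_force_pp_int(windows, delta):
    """Independent per-window, per-cycle double loop."""
    out = []
    for _, win in windows.iterrows():
        T = delta.shape[0]
        hits = 0
        for t in range(T):
            any_large = False
            for j in range(int(win.marker_lo), int(win.marker_hi)):
                if delta[t, j] == 1:
                    any_large = True
                    break
            hits += any_large
        out.append(hits / T)
    return np.array(out)


class TestBuildWindows:
    def test_anchored_at_each_marker(self):
        mm = make_map([1_000_000, 1_500_000])
        win = build_windows(mm, 1_000_000)
        assert len(win) == 2
        assert win.iloc[0]["n_markers"] == 2  # [1.0, 2.0) Mb holds both
        assert win.iloc[1]["n_markers"] == 1
        assert win.iloc[0]["end_bp"] - win.iloc[0]["start_bp"] == 1_000_000

    def test_single_marker(self):
        win = build_windows(make_map([42]), 1_000_000)
        assert len(win) == 1 and win.iloc[0]["n_markers"] == 1

    def test_window_count_equals_marker_count_per_chromosome(self):
        mm = make_map(
            [10, 20, 30, 10, 40], chromosomes=np.array([1, 1, 1, 2, 2])
        )
        win = build_windows(mm, 25)
        assert len(win) == 5
        assert win.groupby("chromosome").size().to_dict() == {1: 3, 2: 2}

    def test_half_open_boundary(self):
        # marker exactly at start + length is excluded
        win = build_windows(make_map([100, 1_000_100]), 1_000_000)
        assert win.iloc[0]["n_markers"] == 1

    def test_unsorted_map_rejected(self):
        mm = make_map([200, 100])
        with pytest.raises(ValueError, match="sorted"):
            build_windows(mm, 1000)


class TestPPInt:
    def test_worked_example(self):
        # cycles x markers {0,0},{1,0},{0,1},{1,1}: 3 of 4 cycles hit
        mm = make_map([100, 200])
        win = build_windows(mm, 1_000)
        delta = np.array([[0, 0], [1, 0], [0, 1], [1, 1]])
        out = compute_pp_int(win, make_samples(delta))
        assert out["pp_int"].iloc[0] == pytest.approx(0.75)

    def test_all_zero_indicators(self):
        win = build_windows(make_map([100, 200]), 1_000)
        out = compute_pp_int(win, np.zeros((5, 2), dtype=np.uint8))
        assert (out["pp_int"] == 0).all()

    def test_single_marker_window_equals_inclusion_frequency(self, rng):
        positions = np.sort(rng.choice(10_000_000, 30, replace=False)) + 1
        mm = make_map(positions)
        delta = (rng.random((100, 30)) < 0.3).astype(np.uint8)
        win = compute_pp_int(build_windows(mm, 1), make_samples(delta))
        assert np.allclose(win["pp_int"], delta.mean(axis=0))

    def test_matches_brute_force_oracle(self, rng):
        positions = np.sort(rng.choice(5_000_000, 50, replace=False)) + 1
        mm = make_map(positions)
        delta = (rng.random((200, 50)) < 0.1).astype(np.uint8)
        win = compute_pp_int(build_windows(mm, 500_000), make_samples(delta))
        assert np.array_equal(
            win["pp_int"].to_numpy(), brute_force_pp_int(win, delta)
        )

    def test_nested_window_monotonicity(self, rng):
        positions = np.sort(rng.choice(8_000_000, 60, replace=False)) + 1
        mm = make_map(positions)
        delta = (rng.random((80, 60)) < 0.15).astype(np.uint8)
        small = compute_pp_int(build_windows(mm, 400_000), make_samples(delta))
        big = compute_pp_int(build_windows(mm, 2_000_000), make_samples(delta))
        assert (big["pp_int"].to_numpy() >= small["pp_int"].to_numpy()).all()

    def test_empty_samples_rejected(self):
        win = build_windows(make_map([100]), 1000)
        with pytest.raises(ValueError):
            compute_pp_int(win, np.zeros((0, 1), dtype=np.uint8))


class TestPeaksAndRegions:
    def windows_track(self, pp, starts=None, length=1000):
        starts = np.arange(len(pp)) * 500 + 1 if starts is None else np.asarray(starts)
        return pd.DataFrame(
            {
                "chromosome": 1,
                "start_bp": starts,
                "end_bp": starts + length,
                "marker_lo": np.arange(len(pp)),
                "marker_hi": np.arange(len(pp)) + 1,
                "n_markers": 1,
                "pp_int": pp,
            }
        )

    def test_one_peak_of_two_windows(self):
        win = self.windows_track([0.5, 0.85, 0.9, 0.5])
        peaks = find_candidate_peaks(win, 0.8)
        assert len(peaks) == 1 and list(peaks[0]) == [1, 2]

    def test_gap_splits_peaks(self):
        win = self.windows_track([0.9, 0.1, 0.1, 0.1, 0.95])
        peaks = find_candidate_peaks(win, 0.8)
        assert len(peaks) == 2

    def test_nothing_above_threshold_gives_no_regions(self):
        win = self.windows_track([0.2, 0.5, 0.79])
        peaks = find_candidate_peaks(win, 0.8)
        assert peaks == []
        assert len(select_regions(win, peaks)) == 0

    def test_highest_pp_int_window_selected(self):
        win = self.windows_track([0.85, 0.92, 0.83])
        regions = select_regions(win, find_candidate_peaks(win, 0.8))
        assert len(regions) == 1
        assert regions.iloc[0]["pp_int"] == 0.92

    def test_tie_broken_to_smaller_start(self):
        win = self.windows_track([0.9, 0.9])
        regions = select_regions(win, find_candidate_peaks(win, 0.8))
        assert regions.iloc[0]["start_bp"] == win["start_bp"].min()

    def test_one_window_peak(self):
        win = self.windows_track([0.1, 0.95, 0.1])
        regions = select_regions(win, find_candidate_peaks(win, 0.8))
        assert len(regions) == 1 and regions.iloc[0]["pp_int"] == 0.95


class TestRegionVariance:
    def test_hand_calculation_single_marker(self):
        X = np.array([[0.0], [1.0], [2.0], [1.0]])
        samples = make_samples(np.ones((1, 1)), g=np.ones((1, 1)))
        out = region_variance(X, samples, 0, 1)
        assert out["variance_mean"] == pytest.approx(0.5)  # population var
        assert out["variance_sd"] == 0.0

    def test_zero_effects_zero_variance(self, rng):
        X = rng.integers(0, 3, (10, 4)).astype(float)
        samples = make_samples(np.zeros((6, 4)), g=np.zeros((6, 4)), n_ind=10)
        out = region_variance(X, samples, 1, 3)
        assert out["variance_mean"] == 0.0 and out["variance_sd"] == 0.0
        assert out["n_cycles_skipped"] == 6  # total variance is zero too

    def test_whole_genome_region_proportion_one_without_polygenics(self, rng):
        X = rng.integers(0, 3, (15, 6)).astype(float)
        g = rng.standard_normal((8, 6))
        samples = make_samples(np.ones((8, 6)), g=g, n_ind=15)
        out = region_variance(X, samples, 0, 6)
        assert out["variance_proportion"] == pytest.approx(1.0)
        assert out["n_cycles_skipped"] == 0


def test_scan_recovers_planted_regions(planted_sim, planted_fit):
    d = planted_sim
    rs = QTLRegionScan(window_lengths=(1_000_000,), threshold=0.8)
    rs.fit(planted_fit.samples_, d["marker_map"], genotypes=d["genotypes"].values)
    reg = rs.regions_
    # one planted region per chromosome 1-2; both must be overlapped
    for c, s, _ in d["truth"].true_region_spans:
        hit = (
            (reg["chromosome"] == c)
            & (reg["start_bp"] <= s)
            & (reg["end_bp"] > s)
        )
        assert hit.any()
    # QTL-free chromosomes stay quiet
    assert not reg["chromosome"].isin([3, 4]).any()
    assert ((reg["variance_proportion"] > 0) & (reg["variance_proportion"] < 1)).all()
    # threshold validation
    with pytest.raises(ValueError):
        QTLRegionScan(threshold=1.01).fit(
            planted_fit.samples_, d["marker_map"]
        )
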