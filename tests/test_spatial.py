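"""Fisher-z distance binning: oracles, conservation, significance."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lfpspace import electrode_distances, grid_layout
from lfpspace.preprocess import build_epoch_grid, zscore_channels
from lfpspace.recording import Recording
from lfpspace.spatial import (
    DistanceBins,
    array_average_function,
    bin_by_distance,
    correlation_significance,
    epoch_correlation_matrix,
    fisher_z,
    inverse_fisher_z,
    narrowband_distance_functions,
    session_distance_function,
)


class TestFisherZ:
    def test_closed_form_values(self):
        assert fisher_z(0.0) == 0.0
        assert fisher_z(0.5) == pytest.approx(0.5 * np.log(3), abs=1e-12)
        assert fisher_z(0.5) == pytest.approx(0.5493, abs=1e-4)

    @settings(deadline=None, derandomize=True)
    @given(st.floats(-0.999, 0.999))
    def test_odd_symmetry_and_roundtrip(self, r):
        assert fisher_z(-r) == pytest.approx(-fisher_z(r), abs=1e-12)
        assert inverse_fisher_z(fisher_z(r)) == pytest.approx(r, abs=1e-12)

    def test_unit_correlation_clipped(self):
        z = fisher_z(1.0)
        assert np.isfinite(z)
        assert z == pytest.approx(np.arctanh(1 - 1e-7))


class TestEpochCorrelation:
    def _rec(self, sig, fs=1000.0):
        rec = Recording(signal=sig, fs=fs)
        return rec, build_epoch_grid(rec, sig.shape[1] / fs)

    def test_identical_channels(self):
        x = np.random.default_rng(0).standard_normal(1000)
        rec, grid = self._rec(np.vstack([x, x]))
        c = epoch_correlation_matrix(rec, grid, 0)
        assert c[0, 1] == pytest.approx(1.0)

    def test_negated_channel(self):
        x = np.random.default_rng(1).standard_normal(1000)
        rec, grid = self._rec(np.vstack([x, -x]))
        assert epoch_correlation_matrix(rec, grid, 0)[0, 1] == pytest.approx(-1.0)

    def test_independent_noise_null_bound(self):
        rng = np.random.default_rng(2)
        rec, grid = self._rec(rng.standard_normal((2, 10_000)))
        assert abs(epoch_correlation_matrix(rec, grid, 0)[0, 1]) < 0.04

    def test_invalid_epoch_refused(self):
        sig = np.zeros((2, 1000))
        valid = np.ones(1000, bool)
        valid[5] = False
        rec = Recording(signal=sig, fs=1000.0, valid=valid)
        grid = build_epoch_grid(rec, 1.0)
        with pytest.raises(ValueError):
            epoch_correlation_matrix(rec, grid, 0)


class TestBinningOracle:
    def test_constant_correlation_field(self):
        layout = grid_layout(3, 3)
        d = electrode_distances(layout)
        bins = DistanceBins.for_layout(layout)
        r0 = 0.4
        corr = np.full((9, 9), r0)
        np.fill_diagonal(corr, 1.0)
        mean_z, counts = bin_by_distance(corr, d, bins)
        assert np.allclose(mean_z[counts > 0], np.arctanh(r0), atol=1e-12)

    def test_corner_electrode_neighbor_count(self):
        layout = grid_layout(4, 4)
        d = electrode_distances(layout)
        bins = DistanceBins.for_layout(layout)
        corr = np.eye(16) * 0.5 + 0.5
        _, counts = bin_by_distance(corr, d, bins)
        # corner electrode 0: partners within 600 um are (0,1),(1,0),(1,1)
        assert counts[0, 0] == 3

    def test_weighted_average_arithmetic(self):
        z = np.array([[1.0], [2.0]])
        c = np.array([[4], [1]])
        mean_z, counts = array_average_function(z, c)
        assert mean_z[0] == pytest.approx(1.2)
        assert counts[0] == 5

    def test_equal_counts_reduce_to_unweighted_mean(self):
        rng = np.random.default_rng(0)
        z = rng.standard_normal((5, 3))
        c = np.full((5, 3), 7)
        mean_z, _ = array_average_function(z, c)
        assert np.allclose(mean_z, z.mean(axis=0))

    def test_all_empty_bin_marked_missing(self):
        z = np.array([[np.nan, 1.0]])
        c = np.array([[0, 2]])
        mean_z, counts = array_average_function(z, c)
        assert np.isnan(mean_z[0]) and counts[0] == 0

    def test_toy_layout_matches_bruteforce_pair_loop(self, toy_layout):
        """Array-level weighted bin means equal an explicit loop over
        every electrode pair, to 1e-12."""
        rng = np.random.default_rng(4)
        sig = rng.standard_normal((16, 2000))
        rec = zscore_channels(Recording(signal=sig, fs=1000.0))
        grid = build_epoch_grid(rec, 2.0)
        dcf = session_distance_function(rec, toy_layout, grid)

        d = electrode_distances(toy_layout)
        corr = np.corrcoef(sig)
        bins = DistanceBins.for_layout(toy_layout)
        # brute force: per source, per bin, average z over its pairs;
        # then count-weighted average over sources
        n_bins = bins.n_bins
        num = np.zeros(n_bins)
        den = np.zeros(n_bins)
        for src in range(16):
            for b in range(n_bins):
                zs = [
                    np.arctanh(corr[src, j])
                    for j in range(16)
                    if j != src
                    and bins.edges[b] < d[src, j] <= bins.edges[b + 1]
                ]
                if zs:
                    num[b] += np.mean(zs) * len(zs)
                    den[b] += len(zs)
        brute = num / np.where(den > 0, den, np.nan)
        assert np.allclose(dcf.mean_z[0], brute, atol=1e-12, equal_nan=True)
        assert np.array_equal(dcf.counts[0], den.astype(int))

    def test_count_conservation(self, toy_layout):
        """Sum of array-level counts = 2 x number of pairs (each pair
        seen once from each of its two sources)."""
        rng = np.random.default_rng(5)
        rec = zscore_channels(
            Recording(signal=rng.standard_normal((16, 1000)), fs=1000.0)
        )
        grid = build_epoch_grid(rec, 1.0)
        dcf = session_distance_function(rec, toy_layout, grid)
        assert dcf.counts[0].sum() == 2 * (16 * 15 // 2)


class TestSignificance:
    def test_zero_z_never_flagged(self):
        (_, _), flag = correlation_significance(0.0, 10_000)
        assert not flag

    def test_half_width_closed_form(self):
        (lo, hi), flag = correlation_significance(0.5, 10_000)
        half = 1.96 / np.sqrt(9997)
        assert hi - lo == pytest.approx(2 * half, abs=1e-12)
        assert half == pytest.approx(0.0196, abs=1e-4)
        assert flag

    def test_small_effect_small_n_not_significant(self):
        (lo, hi), flag = correlation_significance(0.01, 100)
        assert (hi - lo) / 2 == pytest.approx(0.199, abs=1e-3)
        assert not flag

    def test_tiny_n_rejected(self):
        with pytest.raises(ValueError):
            correlation_significance(0.5, 3)


class TestNarrowband:
    def test_shared_inband_sinusoid_fully_correlated(self):
        t = np.arange(0, 4.0, 1 / 500.0)
        base = np.sin(2 * np.pi * 10.0 * t)
        rng = np.random.default_rng(6)
        sig = np.vstack([base + 0.01 * rng.standard_normal(len(t)) for _ in range(4)])
        layout = grid_layout(2, 2)
        rec = zscore_channels(Recording(signal=sig, fs=500.0))
        grid = build_epoch_grid(rec, 4.0)
        fns = narrowband_distance_functions(
            rec, layout, grid, {"theta": (5.0, 15.0)}
        )
        r = inverse_fisher_z(fns["theta"].mean_z[0])
        assert np.nanmin(r) > 0.99

    def test_band_specific_spatial_structure(self):
        """Long-range structure placed only in the low band appears in
        the low-band function and not in the high band."""
        from lfpspace.simulate import GeneratorParams, StateParams, generate_epoch

        layout = grid_layout(3, 3)
        sp = StateParams(
            sigma_global=(1.0, 0.0),
            sigma_spatial=(0.0, 0.0),
            sigma_local=(0.0, 1.0),
            ell_um=2000.0,
        )
        params = GeneratorParams(
            band_edges=((2.0, 8.0), (60.0, 120.0)),
            fs=500.0,
            epoch_s=4.0,
            states={"SWS": sp, "NULL": sp, "REM_AWAKE": sp},
            dropout_rate_hz=0.0,
        )
        block = generate_epoch(layout, "SWS", params, seed=7)
        rec = zscore_channels(Recording(signal=block, fs=500.0))
        grid = build_epoch_grid(rec, 4.0)
        fns = narrowband_distance_functions(
            rec, layout, grid, {"low": (2.0, 8.0), "high": (60.0, 120.0)}
        )
        r_low = inverse_fisher_z(np.nanmean(fns["low"].mean_z))
        r_high = inverse_fisher_z(np.nanmean(fns["high"].mean_z))
        assert r_low > 0.9
        assert abs(r_high) < 0.3

    def test_invalid_band_edges_rejected(self):
        rec = Recording(signal=np.zeros((2, 100)), fs=100.0)
        grid = build_epoch_grid(rec, 1.0)
        layout = grid_layout(1, 2)
        with pytest.raises(ValueError):
            narrowband_distance_functions(rec, layout, grid, {"bad": (10.0, 60.0)})
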