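"""Generator contracts: determinism, event statistics, rendering physics."""

import numpy as np
import pytest
from scipy.optimize import curve_fit

from phluorin.core import CellGeometry
from phluorin.morphometry import MaximaParams, count_local_maxima
from phluorin.synthetic import (
    AcquisitionParams,
    SimEvent,
    make_cell_geometry,
    make_node_profile,
    make_sheath_layout,
    make_track_profile,
    render_stack,
    sample_events,
)


@pytest.fixture(scope="module")
def geometry():
    return make_cell_geometry(shape=(64, 64), seed=1)


class TestSampleEvents:
    def test_zero_rate_gives_no_events(self, geometry):
        assert sample_events(0.0, 0.5, 600.0, geometry, seed=0) == []

    def test_poisson_count_statistics(self, geometry):
        """Counts over many seeds match the Poisson mean and variance."""
        lam = 60.0
        counts = np.array(
            [
                len(sample_events(60.0, 0.5, 60.0, geometry, seed=s))
                for s in range(10_000)
            ]
        )
        se_mean = np.sqrt(lam / counts.size)
        assert abs(counts.mean() - lam) <= 3 * se_mean
        se_var = np.sqrt((2 * lam**2 + lam) / counts.size)
        assert abs(counts.var(ddof=1) - lam) <= 3 * se_var

    def test_full_fusion_count_over_growth_period(self, geometry):
        """23 events/min at 80% full fusion for 48 h averages 52,992 events."""
        expected = 23.0 * 0.8 * 48 * 60
        counts = [
            sum(
                1
                for ev in sample_events(
                    23.0, 0.8, 48 * 3600.0, geometry, seed=s
                )
                if ev.mode == "full_fusion"
            )
            for s in range(20)
        ]
        se = np.sqrt(expected / len(counts))  # thinned Poisson
        assert abs(np.mean(counts) - expected) <= 3 * se

    def test_positions_inside_mask_and_compartments(self, geometry):
        events = sample_events(40.0, 0.8, 120.0, geometry, seed=3)
        for ev in events:
            row = int(round(ev.y_um / 0.1))
            col = int(round(ev.x_um / 0.1))
            assert geometry.cell_mask[row, col]
            expected = (
                "soma" if geometry.soma_mask[row, col] else "processes_sheet"
            )
            assert ev.compartment == expected

    def test_separation_constraints_enforced(self, geometry):
        events = sample_events(
            8.0, 0.8, 60.0, geometry, seed=5,
            min_separation_um=2.0, min_onset_gap_s=2.0,
        )
        for i, a in enumerate(events):
            for b in events[:i]:
                assert np.hypot(a.x_um - b.x_um, a.y_um - b.y_um) >= 2.0
                assert abs(a.t_start_s - b.t_start_s) >= 2.0

    def test_empty_geometry_rejected(self):
        empty = CellGeometry(np.zeros((16, 16), bool), np.zeros((16, 16), bool))
        with pytest.raises(ValueError):
            sample_events(10.0, 0.5, 60.0, empty, seed=0)


class TestRenderStack:
    def test_determinism_bit_identical(self, geometry):
        params = AcquisitionParams(n_frames=30, image_shape=(64, 64))
        events = sample_events(20.0, 0.8, 6.0, geometry, seed=2)
        a = render_stack(params, geometry, events, seed=9)
        b = render_stack(params, geometry, events, seed=9)
        assert np.array_equal(a.stack.data, b.stack.data)
        assert a.truth.equals(b.truth)
        c = render_stack(params, geometry, events, seed=10)
        assert not np.array_equal(a.stack.data, c.stack.data)

    def test_truth_rows_match_events(self, geometry):
        params = AcquisitionParams(n_frames=30, image_shape=(64, 64))
        events = sample_events(20.0, 0.8, 6.0, geometry, seed=2)
        result = render_stack(params, geometry, events, seed=0)
        assert len(result.truth) == len(events)
        assert list(result.truth["mode"]) == [ev.mode for ev in events]

    def test_static_noiseless_stack_is_background(self, geometry):
        params = AcquisitionParams(
            n_frames=10, image_shape=(64, 64), noise_sd=0.0,
            background_level=150.0,
        )
        result = render_stack(params, geometry, [], seed=0)
        expected = 150.0 * geometry.cell_mask
        for frame in result.stack.data:
            assert np.array_equal(frame, expected)

    def test_full_fusion_mass_conserved_peak_decreasing(self, geometry):
        """With decay off, spreading conserves summed intensity while the
        peak pixel strictly decreases."""
        params = AcquisitionParams(
            n_frames=24, image_shape=(64, 64), noise_sd=0.0,
            background_level=100.0,
        )
        ev = SimEvent(
            x_um=3.2, y_um=3.2, t_start_s=1.0, mode="full_fusion",
            amplitude_sd=50.0, decay_tau_s=np.inf, diffusion_um2_s=0.01,
            border_decay_ratio=0.89,
        )
        result = render_stack(params, geometry, [ev], seed=0)
        background = 100.0 * geometry.cell_mask
        above = (result.stack.data - background[None]).sum(axis=(1, 2))
        onset = int(result.truth["onset_frame"].iloc[0])
        assert np.allclose(above[onset:], above[onset], rtol=2e-3)
        peaks = result.stack.data[onset:].max(axis=(1, 2))
        assert np.all(np.diff(peaks) < 0)

    def test_kiss_and_run_width_constant_amplitude_decays(self, geometry):
        """Per-frame Gaussian-fit oracle: fixed width within 1%, decaying
        amplitude."""
        params = AcquisitionParams(
            n_frames=20, image_shape=(64, 64), noise_sd=0.0,
            background_level=100.0,
        )
        ev = SimEvent(
            x_um=3.2, y_um=3.2, t_start_s=0.5, mode="kiss_and_run",
            amplitude_sd=50.0, decay_tau_s=1.5,
        )
        result = render_stack(params, geometry, [ev], seed=0)
        onset = int(result.truth["onset_frame"].iloc[0])

        def fit_frame(frame):
            r, c = 32, 32
            patch = frame[r - 6:r + 7, c - 6:c + 7] - 100.0
            yy, xx = np.mgrid[0:13, 0:13]

            def g(coords, amp, y0, x0, sigma):
                y, x = coords
                return amp * np.exp(
                    -((y - y0) ** 2 + (x - x0) ** 2) / (2 * sigma**2)
                )

            popt, _ = curve_fit(
                g, (yy.ravel(), xx.ravel()), patch.ravel(),
                p0=(patch.max(), 6, 6, 1.0),
            )
            return popt[0], abs(popt[3])

        fits = [fit_frame(result.stack.data[k]) for k in range(onset, onset + 6)]
        widths = np.array([w for _, w in fits])
        amps = np.array([a for a, _ in fits])
        assert np.ptp(widths) / widths.mean() < 0.01
        assert np.all(np.diff(amps) < 0)

    def test_kiss_and_run_border_never_gains(self, geometry):
        """Non-spreading: the 250-500 nm annulus gains nothing after the
        peak frame (noiseless limit)."""
        params = AcquisitionParams(
            n_frames=20, image_shape=(64, 64), noise_sd=0.0,
            background_level=100.0,
        )
        ev = SimEvent(
            x_um=3.2, y_um=3.2, t_start_s=0.5, mode="kiss_and_run",
            amplitude_sd=50.0, decay_tau_s=1.5,
        )
        result = render_stack(params, geometry, [ev], seed=0)
        onset = int(result.truth["onset_frame"].iloc[0])
        yy, xx = np.mgrid[0:64, 0:64]
        dist = np.hypot(yy - 32, xx - 32) * 0.1
        annulus = (dist > 0.25) & (dist <= 0.5)
        border = result.stack.data[:, annulus].mean(axis=1)
        center_peak = result.stack.data[onset].max() - 100.0
        gain = border[onset + 1:] - border[onset]
        assert np.all(gain < 0.05 * center_peak)

    def test_event_outside_frame_rejected(self, geometry):
        params = AcquisitionParams(n_frames=10, image_shape=(64, 64))
        ev = SimEvent(
            x_um=50.0, y_um=3.0, t_start_s=0.5, mode="kiss_and_run",
            amplitude_sd=10.0, decay_tau_s=1.0,
        )
        with pytest.raises(ValueError):
            render_stack(params, geometry, [ev], seed=0)

    def test_event_after_acquisition_rejected(self, geometry):
        params = AcquisitionParams(n_frames=10, image_shape=(64, 64))
        ev = SimEvent(
            x_um=3.2, y_um=3.2, t_start_s=99.0, mode="kiss_and_run",
            amplitude_sd=10.0, decay_tau_s=1.0,
        )
        with pytest.raises(ValueError):
            render_stack(params, geometry, [ev], seed=0)


class TestSheathLayout:
    def test_uniform_half_for_l12(self):
        sheaths = make_sheath_layout([12.0], 1.0, 100_000, seed=0)
        frac = np.mean(
            (sheaths[0].event_positions_um <= 3.0)
            | (sheaths[0].event_positions_um >= 9.0)
        )
        se = np.sqrt(0.5 * 0.5 / 100_000)
        assert abs(frac - 0.5) <= 3 * se

    def test_short_sheath_all_paranodal(self):
        sheaths = make_sheath_layout([6.0], 1.0, 500, seed=1)
        s = sheaths[0].event_positions_um
        assert np.all((s <= 3.0) | (s >= 3.0))  # margins cover the sheath

    def test_enriched_fraction_matches_closed_form(self):
        """Paranodal odds multiplier 3 on L=30: p = 3·6 / (3·6 + 24)."""
        sheaths = make_sheath_layout([30.0], 3.0, 100_000, seed=2)
        s = sheaths[0].event_positions_um
        frac = np.mean((s <= 3.0) | (s >= 27.0))
        p = 18.0 / 42.0
        se = np.sqrt(p * (1 - p) / 100_000)
        assert abs(frac - p) <= 3 * se

    def test_invalid_lengths_rejected(self):
        with pytest.raises(ValueError):
            make_sheath_layout([0.0], 1.0, 5, seed=0)


class TestNodeProfiles:
    def test_mature_peak_counts(self):
        profile, label = make_node_profile("mature", noise_sd=0.0, seed=0)
        assert label == "mature"
        params = MaximaParams(smoothing_sigma_points=0)
        assert count_local_maxima(profile.caspr, params) == 2
        assert count_local_maxima(profile.ankg, params) == 1

    def test_cluster_other_channel_flat(self):
        profile, _ = make_node_profile(
            "cluster", noise_sd=0.0, seed=0, cluster_channel="caspr"
        )
        assert np.ptp(profile.ankg) == 0.0
        assert np.ptp(profile.caspr) > 0

    def test_heminode_one_peak_each(self):
        profile, _ = make_node_profile("heminode", noise_sd=0.0, seed=0)
        params = MaximaParams(smoothing_sigma_points=0)
        assert count_local_maxima(profile.caspr, params) == 1
        assert count_local_maxima(profile.ankg, params) == 1

    def test_track_profile_separation(self):
        x, y = make_track_profile(1.0, noise_sd=0.0)
        peaks = np.where(
            (y[1:-1] > y[:-2]) & (y[1:-1] > y[2:])
        )[0] + 1
        assert len(peaks) == 2
        assert abs((x[peaks[1]] - x[peaks[0]]) - 1.0) <= 0.05
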