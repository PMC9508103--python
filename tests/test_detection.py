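"""Detection stage: bleach correction, ΔF/F, the event criteria."""

import numpy as np
import pytest

from conftest import match_events
from phluorin.core import CellGeometry, TimeLapseStack
from phluorin.detection import (
    DetectionParams,
    assign_compartment,
    compute_dff,
    correct_bleaching,
    detect_events,
    event_frequency,
)
from phluorin.synthetic import (
    AcquisitionParams,
    SimEvent,
    make_cell_geometry,
    render_stack,
    sample_events,
)

PX = 0.1
DT = 0.25


@pytest.fixture(scope="module")
def geometry():
    return make_cell_geometry(shape=(128, 128), seed=0)


def _benchmark_stack(geometry, seed, amplitude=(8.0, 14.0), noise_sd=10.0):
    params = AcquisitionParams(
        n_frames=120, image_shape=(128, 128), noise_sd=noise_sd
    )
    events = sample_events(
        10.0, 0.8, params.duration_s - 6.0, geometry, seed=seed,
        amplitude_sd_range=amplitude,
        min_separation_um=3.0, min_onset_gap_s=3.0,
    )
    events = [ev for ev in events if ev.t_start_s >= 1.5]
    result = render_stack(params, geometry, events, seed=seed + 7000)
    truth = result.truth[result.truth["t_start_s"] >= 1.5]
    return result.stack, truth


class TestBleachCorrection:
    def test_recovers_tau_and_flattens(self, geometry):
        params = AcquisitionParams(
            n_frames=240, image_shape=(128, 128), noise_sd=0.0,
            bleach_tau_s=30.0,
        )
        stack = render_stack(params, geometry, [], seed=0).stack
        corrected, fit = correct_bleaching(stack)
        assert abs(fit.tau_s - 30.0) / 30.0 < 0.01
        means = corrected.data.mean(axis=(1, 2))
        assert np.ptp(means) / means[0] < 1e-3

    def test_constant_stack_untouched(self):
        stack = TimeLapseStack(np.full((10, 16, 16), 7.0), DT, PX)
        corrected, fit = correct_bleaching(stack)
        assert fit.tau_s == np.inf
        assert np.array_equal(corrected.data, stack.data)

    def test_scale_equivariance(self, geometry):
        params = AcquisitionParams(
            n_frames=60, image_shape=(128, 128), noise_sd=0.0,
            bleach_tau_s=20.0,
        )
        stack = render_stack(params, geometry, [], seed=0).stack
        base, _ = correct_bleaching(stack)
        scaled, _ = correct_bleaching(stack.copy_with(stack.data * 3.7))
        assert np.allclose(scaled.data, 3.7 * base.data, rtol=1e-5)

    def test_nonpositive_mean_rejected(self):
        stack = TimeLapseStack(np.zeros((10, 8, 8)), DT, PX)
        with pytest.raises(ValueError):
            correct_bleaching(stack)


class TestDff:
    def test_constant_stack_all_zero(self):
        stack = TimeLapseStack(np.full((8, 8, 8), 5.0), DT, PX)
        assert np.array_equal(compute_dff(stack).data, np.zeros((8, 8, 8)))

    def test_two_level_pixel_arithmetic(self):
        """A pixel alternating 1 and 3 has mean 2 → ΔF/F of ∓0.5."""
        data = np.ones((8, 4, 4))
        data[1::2] = 3.0
        dff = compute_dff(TimeLapseStack(data, DT, PX)).data
        assert np.allclose(dff[0::2], -0.5)
        assert np.allclose(dff[1::2], 0.5)

    def test_zero_mean_pixels_flagged_zero(self):
        data = np.zeros((8, 4, 4))
        data[:, 0, 0] = 2.0
        dff = compute_dff(TimeLapseStack(data, DT, PX)).data
        assert np.array_equal(dff[:, 1:, :], np.zeros((8, 3, 4)))

    def test_dff_peak_at_truth_peak(self, geometry):
        params = AcquisitionParams(
            n_frames=60, image_shape=(128, 128), noise_sd=0.0
        )
        ev = SimEvent(
            x_um=6.4, y_um=6.4, t_start_s=5.0, mode="kiss_and_run",
            amplitude_sd=20.0, decay_tau_s=1.5,
        )
        result = render_stack(params, geometry, [ev], seed=0)
        dff = compute_dff(result.stack).data
        peak_frame = int(np.argmax(dff[:, 64, 64]))
        assert abs(peak_frame - int(result.truth["onset_frame"].iloc[0])) <= 1


class TestDetectEvents:
    def test_constant_stack_no_events(self, geometry):
        params = AcquisitionParams(
            n_frames=40, image_shape=(128, 128), noise_sd=0.0
        )
        stack = render_stack(params, geometry, [], seed=0).stack
        assert detect_events(stack, DetectionParams(), geometry) == []

    def test_strong_events_recovered_exactly(self, geometry):
        """Well-separated 12-SD events: every one found, at the right
        pixel and frame, with nothing else."""
        stack, truth = _benchmark_stack(geometry, seed=42,
                                        amplitude=(12.0, 12.0))
        detections = detect_events(stack, DetectionParams(), geometry)
        assert len(detections) == len(truth)
        tp, fp, fn = match_events(detections, truth,
                                  tol_um=PX + 1e-9, tol_frames=1)
        assert (tp, fp, fn) == (len(truth), 0, 0)

    def test_noiseless_onsets_and_positions_exact(self, geometry):
        """Brute-force oracle on a noiseless stack: matched detections sit
        within a pixel of truth with the exact onset frame."""
        params = AcquisitionParams(
            n_frames=80, image_shape=(128, 128), noise_sd=0.0
        )
        events = sample_events(
            6.0, 0.0, 14.0, geometry, seed=3,
            min_separation_um=3.0, min_onset_gap_s=2.0,
        )
        for ev in events:
            ev.t_start_s += 2.0
        result = render_stack(params, geometry, events, seed=1)
        detections = detect_events(result.stack, DetectionParams(), geometry)
        tp, _, fn = match_events(detections, result.truth,
                                 tol_um=PX + 1e-9, tol_frames=0)
        assert fn == 0 and tp == len(result.truth)

    def test_low_amplitude_not_detected(self, geometry):
        """The SD criterion: 1-SD bumps are indistinguishable from noise."""
        stack, truth = _benchmark_stack(geometry, seed=17,
                                        amplitude=(1.0, 1.0))
        detections = detect_events(stack, DetectionParams(), geometry)
        tp, _, _ = match_events(detections, truth)
        assert tp <= max(1, int(0.1 * len(truth)))

    def test_noise_only_false_positive_bound(self, geometry):
        """Regression bound: expected false positives ≤ 1 per default stack."""
        params = AcquisitionParams(
            n_frames=240, image_shape=(128, 128), noise_sd=10.0
        )
        total = 0
        for seed in range(6):
            stack = render_stack(params, geometry, [], seed=100 + seed).stack
            total += len(detect_events(stack, DetectionParams(), geometry))
        assert total <= 6

    def test_scale_invariance(self, geometry):
        stack, _ = _benchmark_stack(geometry, seed=5)
        base = detect_events(stack, DetectionParams(), geometry)
        scaled = detect_events(
            stack.copy_with(stack.data * 11.0), DetectionParams(), geometry
        )
        assert len(base) == len(scaled)
        for a, b in zip(base, scaled):
            assert a.onset_frame == b.onset_frame
            assert np.allclose(a.centroid_um, b.centroid_um, atol=1e-6)

    def test_drifting_punctum_rejected_as_motile(self, geometry):
        """A punctum moving 2 μm during its lifetime fails the
        non-motility criterion."""
        params = AcquisitionParams(
            n_frames=60, image_shape=(128, 128), noise_sd=5.0
        )
        base = render_stack(params, geometry, [], seed=3).stack
        data = base.data.copy()
        yy, xx = np.mgrid[0:128, 0:128]
        onset, n_live = 20, 16
        for k in range(onset, onset + n_live):
            # drifts 2 μm along x over its lifetime, decaying slowly
            cx = 64 + (k - onset) * (2.0 / PX) / n_live
            amp = 80.0 * np.exp(-(k - onset) * DT / 4.0)
            data[k] += amp * np.exp(
                -((yy - 64.0) ** 2 + (xx - cx) ** 2) / (2 * 1.0**2)
            )
        stack = base.copy_with(data)
        detections = detect_events(stack, DetectionParams(), geometry,
                                   return_rejected=True)
        near = [
            ev for ev in detections
            if abs(ev.centroid_um[1] - 6.4) < 1.0
            and onset - 2 <= ev.onset_frame <= onset + n_live + 4
        ]
        assert near, "the implanted punctum should at least be a candidate"
        assert all(not ev.accepted for ev in near)
        assert any(ev.reject_reason == "motile" for ev in near)

    def test_mask_shape_mismatch_rejected(self, geometry):
        params = AcquisitionParams(n_frames=20, image_shape=(64, 64))
        small = make_cell_geometry(shape=(64, 64), seed=0)
        stack = render_stack(params, small, [], seed=0).stack
        with pytest.raises(ValueError):
            detect_events(stack, DetectionParams(), geometry)


class TestCompartmentsAndFrequency:
    def test_assign_matches_truth(self, geometry):
        stack, truth = _benchmark_stack(geometry, seed=23)
        detections = detect_events(stack, DetectionParams(), geometry)
        assign_compartment(detections, geometry, PX)
        checked = 0
        for ev in detections:
            dist = np.hypot(
                truth["x_um"] - ev.centroid_um[0],
                truth["y_um"] - ev.centroid_um[1],
            )
            j = dist.idxmin()
            if dist[j] <= 0.5:
                assert ev.compartment == truth.loc[j, "compartment"]
                checked += 1
        assert checked >= 3

    def test_soma_and_process_pixels(self, geometry):
        from types import SimpleNamespace

        soma_rc = np.argwhere(geometry.soma_mask)[0]
        proc_rc = np.argwhere(geometry.cell_mask & ~geometry.soma_mask)[0]
        events = []
        for r, c in (soma_rc, proc_rc):
            events.append(SimpleNamespace(centroid_um=(c * PX, r * PX),
                                          compartment=""))
        assign_compartment(events, geometry, PX)
        assert events[0].compartment == "soma"
        assert events[1].compartment == "processes_sheet"

    def test_frequency_arithmetic(self):
        assert event_frequency([1] * 12, 60.0) == 12.0
        assert event_frequency([], 60.0) == 0.0
        with pytest.raises(ValueError):
            event_frequency([], 0.0)

    def test_frequency_by_compartment(self):
        from types import SimpleNamespace

        events = [SimpleNamespace(compartment="soma")] * 2 + [
            SimpleNamespace(compartment="processes_sheet")
        ] * 4
        out = event_frequency(events, 120.0, by_compartment=True)
        assert out["overall"] == 3.0
        assert out["soma"] == 1.0
        assert out["processes_sheet"] == 2.0

    def test_poisson_rate_recovered(self):
        """Sampling at 23/min and counting back recovers the rate."""
        geometry = make_cell_geometry(shape=(64, 64), seed=2)
        rates = [
            event_frequency(
                sample_events(23.0, 0.8, 60.0, geometry, seed=s), 60.0
            )
            for s in range(400)
        ]
        se = np.sqrt(23.0 / len(rates))
        assert abs(np.mean(rates) - 23.0) <= 3 * se
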