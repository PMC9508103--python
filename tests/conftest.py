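"""Shared helpers: ground-truth matching and single-event rendering."""

from __future__ import annotations

from types import SimpleNamespace

import numpy as np
import pytest

from phluorin.core import CellGeometry
from phluorin.synthetic import AcquisitionParams, SimEvent, render_stack


def match_events(detections, truth_df, tol_um=1.0, tol_frames=3):
    """Greedy unique matching of detections to truth rows.

    Returns ``(tp, fp, fn)``; each truth row can absorb one detection.
    """
    matched: set = set()
    tp = fp = 0
    for ev in detections:
        dx = truth_df["x_um"].to_numpy() - ev.centroid_um[0]
        dy = truth_df["y_um"].to_numpy() - ev.centroid_um[1]
        dist = np.hypot(dx, dy)
        dt = np.abs(truth_df["onset_frame"].to_numpy() - ev.onset_frame)
        ok = (dist <= tol_um) & (dt <= tol_frames)
        order = np.argsort(dist)
        hit = None
        for j in order:
            if ok[j] and truth_df.index[j] not in matched:
                hit = truth_df.index[j]
                break
        if hit is None:
            fp += 1
        else:
            matched.add(hit)
            tp += 1
    fn = len(truth_df) - len(matched)
    return tp, fp, fn


def render_single_event(
    mode: str,
    seed: int,
    amplitude_sd: float = 10.0,
    noise_sd: float = 10.0,
    decay_tau_s: float | None = None,
    border_decay_ratio: float = float("nan"),
    n_frames: int = 48,
    onset_frame: int = 8,
):
    """One event centred in a small all-cell field; returns (stack, stub, event).

    The stub carries the attributes the fusion-trace extractor needs
    (centroid and onset/end frames) taken from ground truth, bypassing the
    detector so classification is tested in isolation.
    """
    shape = (36, 36)
    geom = CellGeometry(np.ones(shape, bool), np.zeros(shape, bool))
    params = AcquisitionParams(
        n_frames=n_frames, image_shape=shape, noise_sd=noise_sd
    )
    tau = decay_tau_s if decay_tau_s is not None else (
        2.0 if mode == "full_fusion" else 1.2
    )
    event = SimEvent(
        x_um=1.8,
        y_um=1.8,
        t_start_s=onset_frame * params.frame_interval_s,
        mode=mode,
        amplitude_sd=amplitude_sd,
        decay_tau_s=tau,
        diffusion_um2_s=0.01 if mode == "full_fusion" else 0.0,
        border_decay_ratio=border_decay_ratio,
    )
    result = render_stack(params, geom, [event], seed=seed)
    stub = SimpleNamespace(
        centroid_um=(event.x_um, event.y_um),
        onset_frame=onset_frame,
        end_frame=onset_frame + int(3.0 * tau / params.frame_interval_s),
    )
    return result.stack, stub, event


@pytest.fixture
def single_event_renderer():
    return render_single_event
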