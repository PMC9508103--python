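"""Exocytotic event detection in pHluorin time-lapse stacks.

The detection criteria follow the assay's operational definition of an
exocytotic event: a non-motile, Gaussian-shaped punctum whose ROI-mean
intensity rises at least ``sd_threshold`` (default 4) standard deviations
above its local baseline — the mean and SD of the same ROI over the
``baseline_window_frames`` (default 4) frames preceding onset — and stays
supra-threshold for ``min_persistence_frames`` (default 3) consecutive
frames.  The event ROI is the connected region above one third of the peak
pixel's ΔF/F.  Candidates failing a 2-D Gaussian fit at the peak frame or
moving more than ``max_displacement_um`` during their lifetime are
rejected.  Stacks are assumed registered; bleaching is removed first by
dividing out an exponential fit to the frame-wise spatial mean.

Because every threshold is expressed in SD units on ΔF/F-normalised or
baseline-relative quantities, detection is invariant to rescaling the
whole stack by a positive constant.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.optimize import curve_fit
from skimage.feature import peak_local_max
from skimage.measure import label as cc_label

from .core import CellGeometry, IntensityTrace, TimeLapseStack

__all__ = [
    "DetectionParams",
    "DetectedEvent",
    "BleachFit",
    "correct_bleaching",
    "compute_dff",
    "detect_events",
    "assign_compartment",
    "event_frequency",
]

logger = logging.getLogger(__name__)


@dataclass
class DetectionParams:
    """Thresholds of the event-detection criteria."""

    sd_threshold: float = 4.0
    baseline_window_frames: int = 4
    min_persistence_frames: int = 3
    roi_fraction_of_max: float = 1.0 / 3.0
    gaussian_fit_min_r2: float = 0.8
    max_displacement_um: float = 0.5
    min_separation_um: float = 1.0
    candidate_snr: float = 5.0  # pre-threshold on peak ΔF/F in robust-SD units
    max_roi_radius_um: float = 1.5

    def __post_init__(self) -> None:
        if not (self.sd_threshold > 0):
            raise ValueError("sd_threshold must be > 0")
        if self.baseline_window_frames < 1:
            raise ValueError("baseline_window_frames must be >= 1")
        if self.min_persistence_frames < 1:
            raise ValueError("min_persistence_frames must be >= 1")
        if not (0 < self.roi_fraction_of_max < 1):
            raise ValueError("roi_fraction_of_max must be in (0, 1)")


@dataclass
class BleachFit:
    """Exponential photobleaching fit to the frame-wise spatial mean."""

    amplitude: float
    tau_s: float
    offset: float
    converged: bool

    def curve(self, times_s: np.ndarray) -> np.ndarray:
        if not math.isfinite(self.tau_s):
            return np.full_like(np.asarray(times_s, dtype=float),
                                self.amplitude + self.offset)
        return self.amplitude * np.exp(-np.asarray(times_s) / self.tau_s) + self.offset


@dataclass
class DetectedEvent:
    """One accepted (or rejected, with reason) exocytotic event."""

    centroid_um: tuple[float, float]  # (x, y)
    t_onset_s: float
    t_peak_s: float
    onset_frame: int
    peak_frame: int
    end_frame: int  # last supra-threshold frame
    roi_pixels: np.ndarray  # (n, 2) array of (row, col)
    trace: IntensityTrace | None
    amplitude_sd: float
    baseline_F0: float
    baseline_sd: float
    compartment: str = "unassigned"
    motile_flag: bool = False
    reject_reason: str = ""  # empty for accepted events

    @property
    def accepted(self) -> bool:
        return self.reject_reason == ""


def correct_bleaching(
    stack: TimeLapseStack,
) -> tuple[TimeLapseStack, BleachFit]:
    """Divide out an exponential photobleaching trend.

    Fits ``mean(t) = A·exp(−t/τ) + C`` to the frame-wise spatial mean and
    divides each frame by the fitted curve normalised to its t = 0 value.
    When the fit does not converge, or the decay is negligible, the stack is
    returned unchanged with ``τ = ∞``.
    """
    means = stack.data.mean(axis=(1, 2))
    if np.any(means <= 0):
        raise ValueError("whole-field mean must be positive in every frame")
    t = stack.times_s
    span = means[0] - means[-1]
    # Negligible decay (incl. constant stacks): no correction.
    if span <= 1e-12 * max(means[0], 1.0) or np.ptp(means) <= 1e-12 * means[0]:
        return stack, BleachFit(0.0, math.inf, float(means.mean()), True)

    def model(tt, a, tau, c):
        return a * np.exp(-tt / tau) + c

    try:
        p0 = (max(span, 1e-9), max(t[-1] / 3.0, stack.frame_interval_s), means[-1])
        popt, _ = curve_fit(
            model,
            t,
            means,
            p0=p0,
            bounds=([0.0, stack.frame_interval_s / 10.0, 0.0], [np.inf] * 3),
            maxfev=20000,
        )
    except (RuntimeError, ValueError):
        logger.warning("bleach fit did not converge; returning uncorrected stack")
        return stack, BleachFit(0.0, math.inf, float(means.mean()), False)
    a, tau, c = popt
    fitted = model(t, a, tau, c)
    if np.any(fitted <= 0):
        logger.warning("bleach fit produced non-positive curve; not correcting")
        return stack, BleachFit(0.0, math.inf, float(means.mean()), False)
    corrected = stack.data / (fitted / fitted[0])[:, None, None]
    return stack.copy_with(corrected), BleachFit(float(a), float(tau), float(c), True)


def compute_dff(stack: TimeLapseStack) -> TimeLapseStack:
    """ΔF/F with the per-pixel all-time average as the reference.

    ``out(t, p) = (F(t, p) − F̄(p)) / F̄(p)``.  Pixels whose temporal mean
    is zero (outside the cell) are set to 0.
    """
    mean = stack.data.mean(axis=0)
    zero = mean == 0
    if zero.any():
        logger.debug("%d zero-mean pixels set to 0 in ΔF/F", int(zero.sum()))
    safe = np.where(zero, 1.0, mean)
    dff = (stack.data - mean[None]) / safe[None]
    dff[:, zero] = 0.0
    return stack.copy_with(dff)


def _fit_gaussian2d(patch: np.ndarray, valid: np.ndarray | None = None) -> float:
    """R² of a symmetric 2-D Gaussian + offset fit to a small patch.

    ``valid`` restricts the fit (and R²) to a pixel subset, e.g. the cell
    mask, so puncta truncated by thin processes are judged on membrane
    pixels only.
    """
    h, w = patch.shape
    yy, xx = np.mgrid[0:h, 0:w]
    if valid is None:
        valid = np.ones((h, w), dtype=bool)
    if valid.sum() < 8:
        return 0.0
    yy, xx = yy[valid].astype(float), xx[valid].astype(float)
    z = patch[valid].astype(float)

    def model(coords, amp, y0, x0, sigma, off):
        y, x = coords
        return amp * np.exp(-((y - y0) ** 2 + (x - x0) ** 2) / (2 * sigma**2)) + off

    p0 = (
        float(z.max() - np.median(z)),
        (h - 1) / 2.0,
        (w - 1) / 2.0,
        max(1.0, h / 6.0),
        float(np.median(z)),
    )
    try:
        popt, _ = curve_fit(
            model,
            (yy, xx),
            z,
            p0=p0,
            bounds=(
                [0.0, -1.0, -1.0, 0.3, -np.inf],
                [np.inf, h, w, max(h, w), np.inf],
            ),
            maxfev=5000,
        )
    except (RuntimeError, ValueError):
        return 0.0
    resid = z - model((yy, xx), *popt)
    ss_tot = np.sum((z - z.mean()) ** 2)
    if ss_tot == 0:
        return 0.0
    return float(1.0 - np.sum(resid**2) / ss_tot)


def _grow_roi(
    frame: np.ndarray,
    peak_rc: tuple[int, int],
    fraction: float,
    mask: np.ndarray,
    max_radius_px: int,
) -> np.ndarray:
    """Connected region ≥ ``fraction`` of the peak pixel, containing the peak."""
    r, c = peak_rc
    h, w = frame.shape
    r0, r1 = max(r - max_radius_px, 0), min(r + max_radius_px + 1, h)
    c0, c1 = max(c - max_radius_px, 0), min(c + max_radius_px + 1, w)
    window = frame[r0:r1, c0:c1]
    thr = fraction * frame[r, c]
    above = (window >= thr) & mask[r0:r1, c0:c1]
    labels = cc_label(above, connectivity=1)
    lab = labels[r - r0, c - c0]
    if lab == 0:
        return np.array([[r, c]])
    rows, cols = np.nonzero(labels == lab)
    return np.column_stack([rows + r0, cols + c0])


def _find_onset(
    trace: np.ndarray,
    peak: int,
    params: DetectionParams,
) -> tuple[int, int, float, float] | None:
    """Locate the supra-threshold run containing ``peak``.

    Returns ``(onset, end, F0, sd)`` using the baseline window immediately
    preceding onset, or None when no valid run exists (including events
    starting within the first baseline window, which cannot have one).
    """
    bw = params.baseline_window_frames
    n = trace.size
    for onset in range(bw, peak + 1):
        base = trace[onset - bw : onset]
        f0 = float(base.mean())
        sd = float(base.std(ddof=1)) if bw > 1 else 0.0
        thr = f0 + params.sd_threshold * sd
        # Strict rise above F0 matters in the noiseless limit, where the
        # baseline SD (hence the threshold margin) is exactly zero.
        if trace[onset] < thr or trace[onset] <= f0:
            continue
        end = onset
        while end + 1 < n and trace[end + 1] >= thr and trace[end + 1] > f0:
            end += 1
        if end < peak:
            continue  # run does not reach the candidate peak
        if end - onset + 1 < params.min_persistence_frames:
            return None
        return onset, end, f0, sd
    return None


def detect_events(
    stack: TimeLapseStack,
    params: DetectionParams | None = None,
    geometry: CellGeometry | None = None,
    return_rejected: bool = False,
) -> list[DetectedEvent]:
    """Detect exocytotic events in a bleach-corrected stack.

    Candidate puncta are local ΔF/F maxima inside the cell mask; each is
    grown into a ⅓-of-max connected ROI, its ROI-mean trace thresholded
    against the 4-frame pre-onset baseline, and accepted only if the rise
    reaches ``sd_threshold`` SDs, persists ``min_persistence_frames``
    frames, looks Gaussian at the peak, and does not move more than
    ``max_displacement_um``.  Duplicates within ``min_separation_um`` are
    merged keeping the brighter event.
    """
    params = params or DetectionParams()
    if geometry is not None and geometry.cell_mask.shape != stack.frame_shape:
        raise ValueError("mask shape does not match stack frames")
    mask = (
        geometry.cell_mask
        if geometry is not None
        else np.ones(stack.frame_shape, dtype=bool)
    )
    px = stack.pixel_size_um
    dt = stack.frame_interval_s
    # ΔF/F is meaningless on pixels without baseline fluorescence (outside
    # the cell the temporal mean is ~0 and the quotient explodes); zero it
    # there so shape and motion checks see only membrane signal.
    dff = compute_dff(stack).data.copy()
    dff[:, ~mask] = 0.0

    inside = dff[:, mask]
    med = np.median(inside)
    robust_sd = 1.4826 * np.median(np.abs(inside - med))
    if robust_sd <= 0:
        robust_sd = float(inside.std()) or 1e-12
    thr_abs = med + params.candidate_snr * robust_sd
    min_dist_px = max(1, int(round(params.min_separation_um / px)))
    max_roi_px = max(2, int(round(params.max_roi_radius_um / px)))

    # Collect per-frame candidate maxima and link them into tracks.
    tracks: list[dict] = []  # each: {rc, frame, value, members}
    open_tracks: list[dict] = []
    for t in range(stack.n_frames):
        peaks = peak_local_max(
            dff[t],
            min_distance=min_dist_px,
            threshold_abs=thr_abs,
            labels=mask.astype(int),
            exclude_border=False,
        )
        still_open = []
        matched = set()
        for tr in open_tracks:
            if t - tr["last_frame"] <= 2:
                still_open.append(tr)
        open_tracks = still_open
        for r, c in peaks:
            val = dff[t, r, c]
            best = None
            for tr in open_tracks:
                rr, cc = tr["rc"]
                if (rr - r) ** 2 + (cc - c) ** 2 <= min_dist_px**2:
                    best = tr
                    break
            if best is None:
                tr = {
                    "rc": (int(r), int(c)),
                    "peak_frame": t,
                    "peak_value": float(val),
                    "last_frame": t,
                    "frames": [(t, int(r), int(c))],
                }
                open_tracks.append(tr)
                tracks.append(tr)
            else:
                best["last_frame"] = t
                best["frames"].append((t, int(r), int(c)))
                if val > best["peak_value"]:
                    best["peak_value"] = float(val)
                    best["peak_frame"] = t
                    best["rc"] = (int(r), int(c))

    events: list[DetectedEvent] = []
    for tr in tracks:
        r, c = tr["rc"]
        p = tr["peak_frame"]
        roi = _grow_roi(dff[p], (r, c), params.roi_fraction_of_max, mask, max_roi_px)
        trace = stack.data[:, roi[:, 0], roi[:, 1]].mean(axis=1)

        def _reject(reason: str, onset=p, end=p, f0=math.nan, sd=math.nan, amp=math.nan,
                    motile=False) -> DetectedEvent:
            return DetectedEvent(
                centroid_um=(c * px, r * px),
                t_onset_s=onset * dt,
                t_peak_s=p * dt,
                onset_frame=onset,
                peak_frame=p,
                end_frame=end,
                roi_pixels=roi,
                trace=None,
                amplitude_sd=amp,
                baseline_F0=f0,
                baseline_sd=sd,
                motile_flag=motile,
                reject_reason=reason,
            )

        found = _find_onset(trace, p, params)
        if found is None:
            events.append(_reject("no_valid_onset_run"))
            continue
        onset, end, f0, sd = found
        if sd > 0:
            amplitude_sd = (trace[p] - f0) / sd
        else:
            amplitude_sd = math.inf if trace[p] > f0 else 0.0
        if amplitude_sd < params.sd_threshold:
            events.append(_reject("below_sd_threshold", onset, end, f0, sd,
                                  amplitude_sd))
            continue

        # Gaussian shape check at the peak frame (on ΔF/F).  The patch is
        # lightly smoothed first: a Gaussian punctum stays Gaussian while
        # pixel noise drops, so R² measures shape rather than read noise.
        half = 4
        r0, r1 = max(r - half, 0), min(r + half + 1, stack.frame_shape[0])
        c0, c1 = max(c - half, 0), min(c + half + 1, stack.frame_shape[1])
        patch = gaussian_filter(dff[p], 1.0)[r0:r1, c0:c1]
        r2 = _fit_gaussian2d(patch, valid=mask[r0:r1, c0:c1])
        if r2 < params.gaussian_fit_min_r2:
            events.append(_reject("not_gaussian", onset, end, f0, sd, amplitude_sd))
            continue

        # Motion check: ΔF/F-weighted centroid near the peak pixel per frame.
        win = 3
        centroids = []
        for t in range(onset, end + 1):
            rr0, rr1 = max(r - win, 0), min(r + win + 1, stack.frame_shape[0])
            cc0, cc1 = max(c - win, 0), min(c + win + 1, stack.frame_shape[1])
            patch = np.clip(dff[t, rr0:rr1, cc0:cc1], 0, None)
            tot = patch.sum()
            if tot <= 0:
                continue
            yy, xx = np.mgrid[rr0:rr1, cc0:cc1]
            centroids.append(((patch * yy).sum() / tot, (patch * xx).sum() / tot))
        motile = False
        if len(centroids) >= 2:
            cen = np.array(centroids)
            ref = cen[np.argmin(np.abs(np.arange(onset, onset + len(cen)) - p))]
            disp = np.sqrt(((cen - ref) ** 2).sum(axis=1)).max() * px
            motile = disp > params.max_displacement_um
        # A drifting punctum also betrays itself through its candidate-maxima
        # path across the whole track, which can outlive the local ROI run:
        # check both the maximal excursion from the peak and the net
        # first-to-last drift (robust to the track splitting mid-drift).
        if not motile and len(tr["frames"]) >= 2:
            path = np.array([(fr_r, fr_c) for _, fr_r, fr_c in tr["frames"]],
                            dtype=float)
            spread = np.sqrt(((path - (r, c)) ** 2).sum(axis=1)).max() * px
            net = np.hypot(*(path[-1] - path[0])) * px
            motile = max(spread, net) > params.max_displacement_um
        if motile:
            events.append(_reject("motile", onset, end, f0, sd, amplitude_sd,
                                  motile=True))
            continue

        # Sub-pixel centroid from the peak-frame ROI (ΔF/F weighted).
        w = np.clip(dff[p, roi[:, 0], roi[:, 1]], 0, None)
        if w.sum() > 0:
            cy = float((w * roi[:, 0]).sum() / w.sum())
            cx = float((w * roi[:, 1]).sum() / w.sum())
        else:
            cy, cx = float(r), float(c)

        events.append(
            DetectedEvent(
                centroid_um=(cx * px, cy * px),
                t_onset_s=onset * dt,
                t_peak_s=p * dt,
                onset_frame=onset,
                peak_frame=p,
                end_frame=end,
                roi_pixels=roi,
                trace=IntensityTrace(np.arange(stack.n_frames) * dt, trace),
                amplitude_sd=float(amplitude_sd),
                baseline_F0=f0,
                baseline_sd=sd,
            )
        )

    accepted = [e for e in events if e.accepted]
    accepted = _merge_duplicates(accepted, params.min_separation_um)
    if return_rejected:
        return accepted + [e for e in events if not e.accepted]
    return accepted


def _merge_duplicates(
    events: list[DetectedEvent], min_separation_um: float
) -> list[DetectedEvent]:
    """Merge temporally-overlapping events closer than ``min_separation_um``."""
    kept: list[DetectedEvent] = []
    for ev in sorted(events, key=lambda e: -(e.amplitude_sd
                                             if math.isfinite(e.amplitude_sd)
                                             else 1e18)):
        dup = False
        for other in kept:
            d = math.hypot(
                ev.centroid_um[0] - other.centroid_um[0],
                ev.centroid_um[1] - other.centroid_um[1],
            )
            overlap = not (
                ev.end_frame < other.onset_frame or other.end_frame < ev.onset_frame
            )
            if d < min_separation_um and overlap:
                dup = True
                break
        if not dup:
            kept.append(ev)
    return sorted(kept, key=lambda e: (e.onset_frame, e.centroid_um))


def assign_compartment(
    events: list[DetectedEvent],
    geometry: CellGeometry,
    pixel_size_um: float,
) -> list[DetectedEvent]:
    """Set each event's compartment from its centroid pixel.

    Soma when the centroid pixel lies in the soma mask, processes/sheet when
    elsewhere inside the cell; centroids outside the cell mask are flagged
    ``unassigned`` with a warning.
    """
    rows, cols = geometry.cell_mask.shape
    for ev in events:
        x_um, y_um = ev.centroid_um
        col = int(round(x_um / pixel_size_um))
        row = int(round(y_um / pixel_size_um))
        if not (0 <= row < rows and 0 <= col < cols) or not geometry.cell_mask[
            row, col
        ]:
            logger.warning("event centroid outside cell mask; unassigned")
            ev.compartment = "unassigned"
        elif geometry.soma_mask[row, col]:
            ev.compartment = "soma"
        else:
            ev.compartment = "processes_sheet"
    return events


def event_frequency(
    events: list,
    duration_s: float,
    by_compartment: bool = False,
):
    """Events per cell per minute, optionally split by compartment."""
    if not (duration_s > 0):
        raise ValueError("duration must be > 0")
    per_min = 60.0 / duration_s
    if not by_compartment:
        return len(events) * per_min
    out: dict[str, float] = {"overall": len(events) * per_min}
    for comp in ("soma", "processes_sheet", "unassigned"):
        out[comp] = sum(
            1 for e in events if getattr(e, "compartment", None) == comp
        ) * per_min
    return out
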