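"""Seeded, ground-truthed synthetic pHluorin imaging.

This module emulates the statistical structure of widefield pHluorin
time-lapse imaging of cultured oligodendrocytes: Gaussian puncta appearing
on a cell-shaped mask at Poisson-distributed times, an exponential
photobleaching trend on the background, and additive Gaussian read noise.
Every generated object carries its ground truth so the detection,
classification and spatial modules can be benchmarked without raw data.

Event phenotypes
----------------
Full-vesicle fusion releases the reporter into the plasma membrane: the
rendered event is the sum of a diffraction-limited confined component and a
wider membrane-pool component that spreads slowly (mass-conserving growth of
its spatial variance) while its total intensity decays.  The pool's
intensity half-life is drawn, per event, relative to the confined
component's from the observed full-fusion border-decay-ratio population
(0.89 ± 0.14), so the downstream border/center half-life ratio of simulated
full-fusion events clusters where real ones do.  Kiss-and-run keeps the
reporter confined: a single diffraction-limited Gaussian whose amplitude
decays with no spreading, leaving the 250–500 nm annulus at the noise floor.

Amplitudes are specified in multiples of the camera noise SD so the
detector's SD-based criteria are exactly interpretable.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.draw import disk as draw_disk
from skimage.draw import line as draw_line
from skimage.morphology import dilation, disk as disk_footprint

from .core import CellGeometry, TimeLapseStack
from .morphometry import NodeProfile
from .spatial import DEFAULT_PARANODE_MARGIN_UM, Sheath

logger = logging.getLogger(__name__)

__all__ = [
    "AcquisitionParams",
    "SimEvent",
    "SimulationResult",
    "make_cell_geometry",
    "sample_events",
    "render_stack",
    "make_sheath_layout",
    "make_node_profile",
    "make_track_profile",
]

#: Width (σ, μm) of the membrane pool released by a full-fusion event at its
#: peak, before convolution with the PSF.  An emulation parameter: wide
#: enough that the 250-500 nm annulus carries real signal while the pool's
#: per-pixel contribution inside the 250 nm disk stays small (so the center
#: trace is dominated by the confined component and the border/center
#: half-life ratio reflects the pool's drawn half-life).
FULL_FUSION_POOL_SIGMA_UM = 0.33

#: Fraction of a full-fusion event's peak intensity in the confined
#: (diffraction-limited) component; the rest is the spreading pool.
FULL_FUSION_CONFINED_FRACTION = 0.85

#: Mean and SD of the per-event pool/confined half-life ratio for
#: full-fusion events (matches the observed full-fusion population).
BORDER_RATIO_MU = 0.89
BORDER_RATIO_SIGMA = 0.14


@dataclass
class AcquisitionParams:
    """Imaging parameters of the emulated widefield acquisition."""

    frame_interval_s: float = 0.25
    n_frames: int = 240
    pixel_size_um: float = 0.1
    image_shape: tuple[int, int] = (128, 128)
    background_level: float = 200.0
    noise_sd: float = 10.0
    bleach_tau_s: float = math.inf
    psf_sigma_um: float = 0.1

    def __post_init__(self) -> None:
        if not (self.frame_interval_s > 0):
            raise ValueError("frame_interval_s must be > 0")
        if not (self.pixel_size_um > 0):
            raise ValueError("pixel_size_um must be > 0")
        if not (self.noise_sd >= 0):
            raise ValueError("noise_sd must be >= 0")
        if self.n_frames < 8:
            raise ValueError("n_frames must be >= 8")
        if not (self.psf_sigma_um > 0):
            raise ValueError("psf_sigma_um must be > 0")
        if not (self.bleach_tau_s > 0):
            raise ValueError("bleach_tau_s must be > 0 (inf = no bleaching)")
        if not all(np.isfinite([self.background_level, self.noise_sd])):
            raise ValueError("non-finite acquisition parameter")

    @property
    def duration_s(self) -> float:
        return self.n_frames * self.frame_interval_s


@dataclass
class SimEvent:
    """Ground truth for one simulated exocytotic event."""

    x_um: float
    y_um: float
    t_start_s: float
    mode: str  # "full_fusion" or "kiss_and_run"
    amplitude_sd: float
    decay_tau_s: float
    diffusion_um2_s: float = 0.0
    compartment: str = "processes_sheet"
    border_decay_ratio: float = float("nan")  # full-fusion pool half-life ratio

    def __post_init__(self) -> None:
        if self.mode not in ("full_fusion", "kiss_and_run"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not (self.amplitude_sd > 0):
            raise ValueError("amplitude_sd must be > 0")
        if self.mode == "full_fusion" and not (self.diffusion_um2_s > 0):
            raise ValueError("full_fusion events need diffusion_um2_s > 0")
        if self.mode == "kiss_and_run" and self.diffusion_um2_s != 0:
            raise ValueError("kiss_and_run events must have diffusion 0")


@dataclass
class SimulationResult:
    """A rendered stack with its event ground truth."""

    stack: TimeLapseStack
    truth: pd.DataFrame
    events: list[SimEvent]
    seed: int


def make_cell_geometry(
    shape: tuple[int, int] = (128, 128),
    pixel_size_um: float = 0.1,
    soma_radius_um: float = 2.0,
    n_processes: int = 10,
    seed: int = 0,
    label: str = "synthetic_oligodendrocyte",
) -> CellGeometry:
    """An oligodendrocyte-shaped binary mask: a round soma with radial processes.

    Processes radiate from the soma at jittered angles with varying lengths,
    mimicking a pre-myelinating cell; the mask is purely synthetic.
    """
    rng = np.random.default_rng(seed)
    rows, cols = shape
    cy, cx = (rows - 1) / 2.0, (cols - 1) / 2.0
    soma_r_px = soma_radius_um / pixel_size_um

    soma = np.zeros(shape, dtype=bool)
    rr, cc = draw_disk((cy, cx), soma_r_px, shape=shape)
    soma[rr, cc] = True

    cell = soma.copy()
    max_r = min(rows, cols) / 2.0 - 2
    angles = np.linspace(0, 2 * np.pi, n_processes, endpoint=False)
    angles = angles + rng.uniform(-0.15, 0.15, size=n_processes)
    lengths = rng.uniform(0.55, 0.95, size=n_processes) * max_r
    for ang, length in zip(angles, lengths):
        r0 = int(round(cy + soma_r_px * 0.8 * np.sin(ang)))
        c0 = int(round(cx + soma_r_px * 0.8 * np.cos(ang)))
        r1 = int(round(cy + length * np.sin(ang)))
        c1 = int(round(cx + length * np.cos(ang)))
        r1 = min(max(r1, 0), rows - 1)
        c1 = min(max(c1, 0), cols - 1)
        rr, cc = draw_line(r0, c0, r1, c1)
        cell[rr, cc] = True
    cell = dilation(cell, disk_footprint(2))
    cell |= soma
    return CellGeometry(cell_mask=cell, soma_mask=soma, label=label)


def _positions_from_mask(
    rng: np.random.Generator, mask: np.ndarray, n: int, pixel_size_um: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Draw ``n`` uniform sub-pixel positions over the True pixels of ``mask``."""
    ys, xs = np.nonzero(mask)
    idx = rng.integers(0, ys.size, size=n)
    jitter_y = rng.uniform(-0.5, 0.5, size=n)
    jitter_x = rng.uniform(-0.5, 0.5, size=n)
    y_um = (ys[idx] + jitter_y) * pixel_size_um
    x_um = (xs[idx] + jitter_x) * pixel_size_um
    return x_um, y_um, xs[idx], ys[idx]


def sample_events(
    rate_per_min: float,
    full_fraction: float,
    duration_s: float,
    geometry: CellGeometry,
    seed: int,
    pixel_size_um: float = 0.1,
    amplitude_sd_range: tuple[float, float] = (8.0, 14.0),
    full_decay_tau_s: float = 2.0,
    kr_decay_tau_s: float = 1.2,
    diffusion_um2_s: float = 0.01,
    min_separation_um: float | None = None,
    min_onset_gap_s: float | None = None,
) -> list[SimEvent]:
    """Draw a Poisson set of ground-truth events on a cell geometry.

    The event count is Poisson(rate × duration/60), onsets are uniform on
    [0, duration), positions uniform over the cell mask, and the fusion mode
    is Bernoulli(``full_fraction``).  Optional minimum spatial/temporal
    separations thin the sample by resampling offending events (used to
    build well-separated benchmark stacks; ``None`` leaves pure
    Poisson/uniform statistics).
    """
    if not (0 <= full_fraction <= 1):
        raise ValueError("full_fraction must be in [0, 1]")
    if rate_per_min < 0:
        raise ValueError("rate_per_min must be >= 0")
    geometry.require_nonempty()
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n = int(rng.poisson(rate_per_min * duration_s / 60.0))
    if n == 0:
        return []

    x_um, y_um, px, py = _positions_from_mask(
        rng, geometry.cell_mask, n, pixel_size_um
    )
    t_start = rng.uniform(0.0, duration_s, size=n)
    is_full = rng.random(n) < full_fraction
    amplitude = rng.uniform(*amplitude_sd_range, size=n)
    tau_jitter = np.exp(rng.normal(0.0, 0.1, size=n))
    ratios = np.clip(
        rng.normal(BORDER_RATIO_MU, BORDER_RATIO_SIGMA, size=n), 0.3, 1.5
    )

    if min_onset_gap_s is not None and n > 1:
        # Uniform onsets conditional on all gaps >= min_onset_gap_s: sorted
        # uniforms on the gap-shrunk interval plus deterministic offsets.
        # Draws exceeding the feasible count are truncated (the constrained
        # mode is a benchmark-layout generator, not a Poisson process).
        n_max = int(duration_s / min_onset_gap_s) + 1
        if n > n_max:
            logger.warning(
                "truncating %d events to %d to honour onset gaps", n, n_max
            )
            n = n_max
            x_um, y_um, px, py = x_um[:n], y_um[:n], px[:n], py[:n]
            t_start = t_start[:n]
            is_full, amplitude = is_full[:n], amplitude[:n]
            tau_jitter, ratios = tau_jitter[:n], ratios[:n]
        slack = duration_s - (n - 1) * min_onset_gap_s
        base = np.sort(rng.uniform(0.0, slack, size=n))
        t_start = base + min_onset_gap_s * np.arange(n)

    if min_separation_um is not None:
        # Sequential rejection resampling of positions, restarting the whole
        # layout when greedy placement wedges.
        for _restart in range(50):
            placed = True
            for i in range(n):
                for _ in range(1000):
                    d2 = (x_um[:i] - x_um[i]) ** 2 + (y_um[:i] - y_um[i]) ** 2
                    if i == 0 or d2.min() >= min_separation_um**2:
                        break
                    xi, yi, pxi, pyi = _positions_from_mask(
                        rng, geometry.cell_mask, 1, pixel_size_um
                    )
                    x_um[i], y_um[i], px[i], py[i] = xi[0], yi[0], pxi[0], pyi[0]
                else:
                    placed = False
                    break
            if placed:
                break
            x_um, y_um, px, py = _positions_from_mask(
                rng, geometry.cell_mask, n, pixel_size_um
            )
        else:
            raise ValueError("could not satisfy spatial separation")

    events = []
    for i in range(n):
        full = bool(is_full[i])
        tau = (full_decay_tau_s if full else kr_decay_tau_s) * tau_jitter[i]
        events.append(
            SimEvent(
                x_um=float(x_um[i]),
                y_um=float(y_um[i]),
                t_start_s=float(t_start[i]),
                mode="full_fusion" if full else "kiss_and_run",
                amplitude_sd=float(amplitude[i]),
                decay_tau_s=float(tau),
                diffusion_um2_s=diffusion_um2_s if full else 0.0,
                compartment=(
                    "soma" if geometry.soma_mask[py[i], px[i]] else "processes_sheet"
                ),
                border_decay_ratio=float(ratios[i]) if full else float("nan"),
            )
        )
    return events


def _render_gaussian(
    frame: np.ndarray, x_px: float, y_px: float, peak: float, sigma_px: float
) -> None:
    """Add a 2-D Gaussian (evaluated analytically at pixel centres) in place."""
    if peak == 0.0:
        return
    rows, cols = frame.shape
    half = int(math.ceil(6.0 * sigma_px))
    r0 = max(int(math.floor(y_px)) - half, 0)
    r1 = min(int(math.ceil(y_px)) + half + 1, rows)
    c0 = max(int(math.floor(x_px)) - half, 0)
    c1 = min(int(math.ceil(x_px)) + half + 1, cols)
    if r0 >= r1 or c0 >= c1:
        return
    yy = np.arange(r0, r1)[:, None] - y_px
    xx = np.arange(c0, c1)[None, :] - x_px
    frame[r0:r1, c0:c1] += peak * np.exp(
        -(yy**2 + xx**2) / (2.0 * sigma_px**2)
    )


def render_stack(
    params: AcquisitionParams,
    geometry: CellGeometry,
    events: list[SimEvent],
    seed: int,
) -> SimulationResult:
    """Render events onto a background stack with bleaching and read noise.

    ``stack(t) = background · mask · exp(−t/bleach_tau) + Σ events + noise``.
    Event kinetics are evaluated at frame midpoints with the onset snapped to
    the nearest frame.  Kiss-and-run events keep a fixed diffraction-limited
    width while their amplitude decays; full-fusion events additionally carry
    a wider membrane pool whose spatial variance grows as ``σ² + 2 D Δt``
    (mass-conserving spreading) while its total intensity decays with its own
    half-life (see module docstring).
    """
    if geometry.cell_mask.shape != params.image_shape:
        raise ValueError("geometry mask shape does not match image_shape")
    rows, cols = params.image_shape
    px = params.pixel_size_um
    dt = params.frame_interval_s
    unit = params.noise_sd if params.noise_sd > 0 else 1.0

    for ev in events:
        if not (0 <= ev.t_start_s < params.duration_s):
            raise ValueError("event onset outside acquisition duration")
        col = int(round(ev.x_um / px))
        row = int(round(ev.y_um / px))
        if not (0 <= row < rows and 0 <= col < cols):
            raise ValueError("event outside frame")
        if not geometry.cell_mask[row, col]:
            raise ValueError("event position outside cell mask")

    times = np.arange(params.n_frames) * dt
    bleach = (
        np.exp(-times / params.bleach_tau_s)
        if math.isfinite(params.bleach_tau_s)
        else np.ones_like(times)
    )
    data = (
        params.background_level
        * geometry.cell_mask.astype(float)[None, :, :]
        * bleach[:, None, None]
    ).copy()

    psf_px = params.psf_sigma_um / px
    pool_sigma0_sq_um2 = FULL_FUSION_POOL_SIGMA_UM**2 + params.psf_sigma_um**2
    truth_rows = []
    for idx, ev in enumerate(events):
        onset = int(round(ev.t_start_s / dt))
        onset = min(onset, params.n_frames - 1)
        x_px, y_px = ev.x_um / px, ev.y_um / px
        amp = ev.amplitude_sd * unit
        full = ev.mode == "full_fusion"
        f_conf = FULL_FUSION_CONFINED_FRACTION if full else 1.0
        pool_total0 = (
            (1.0 - f_conf) * amp * 2.0 * math.pi * pool_sigma0_sq_um2 / px**2
            if full
            else 0.0
        )
        pool_tau = ev.decay_tau_s * ev.border_decay_ratio if full else math.inf
        for k in range(onset, params.n_frames):
            t_mid = (k - onset + 0.5) * dt
            conf_decay = (
                math.exp(-t_mid / ev.decay_tau_s)
                if math.isfinite(ev.decay_tau_s)
                else 1.0
            )
            conf_peak = f_conf * amp * conf_decay
            if full:
                var_um2 = pool_sigma0_sq_um2 + 2.0 * ev.diffusion_um2_s * t_mid
                pool_decay = (
                    math.exp(-t_mid / pool_tau) if math.isfinite(pool_tau) else 1.0
                )
                pool_total = pool_total0 * pool_decay
                pool_peak = pool_total / (2.0 * math.pi * var_um2 / px**2)
                pool_sigma_px = math.sqrt(var_um2) / px
            else:
                pool_peak = 0.0
            if conf_peak < 1e-4 * unit and (not full or pool_peak < 1e-4 * unit):
                break
            _render_gaussian(data[k], x_px, y_px, conf_peak, psf_px)
            if full:
                _render_gaussian(data[k], x_px, y_px, pool_peak, pool_sigma_px)
        truth_rows.append(
            {
                "event_id": idx,
                "x_um": ev.x_um,
                "y_um": ev.y_um,
                "t_start_s": ev.t_start_s,
                "onset_frame": onset,
                "mode": ev.mode,
                "amplitude_sd": ev.amplitude_sd,
                "decay_tau_s": ev.decay_tau_s,
                "diffusion_um2_s": ev.diffusion_um2_s,
                "border_decay_ratio": ev.border_decay_ratio,
                "compartment": ev.compartment,
            }
        )

    if params.noise_sd > 0:
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        data += rng.normal(0.0, params.noise_sd, size=data.shape)

    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "event_id",
            "x_um",
            "y_um",
            "t_start_s",
            "onset_frame",
            "mode",
            "amplitude_sd",
            "decay_tau_s",
            "diffusion_um2_s",
            "border_decay_ratio",
            "compartment",
        ],
    )
    stack = TimeLapseStack(
        data=data, frame_interval_s=dt, pixel_size_um=px
    )
    return SimulationResult(stack=stack, truth=truth, events=list(events), seed=seed)


def make_sheath_layout(
    lengths_um: list[float],
    enrichment: float,
    n_events_per_sheath: int | list[int],
    seed: int,
    margin_um: float = DEFAULT_PARANODE_MARGIN_UM,
) -> list[Sheath]:
    """Simulated sheaths with events placed along their 1-D axis.

    ``enrichment`` multiplies the event density inside the paranodal margins
    relative to the internode (1 = uniform), after which the density is
    renormalised.  With paranodal length ``Lp = min(2·margin, L)`` the
    paranodal hit probability is ``e·Lp / (e·Lp + (L − Lp))``.
    """
    if any(length <= 0 for length in lengths_um):
        raise ValueError("sheath lengths must be > 0")
    if enrichment <= 0:
        raise ValueError("enrichment must be > 0")
    if isinstance(n_events_per_sheath, int):
        n_events = [n_events_per_sheath] * len(lengths_um)
    else:
        n_events = list(n_events_per_sheath)
    if len(n_events) != len(lengths_um):
        raise ValueError("n_events_per_sheath length mismatch")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    sheaths = []
    for i, (length, n) in enumerate(zip(lengths_um, n_events)):
        lp = min(2.0 * margin_um, length)
        li = length - lp
        p_para = enrichment * lp / (enrichment * lp + li)
        in_para = rng.random(n) < p_para
        pos = np.empty(n)
        u = rng.random(n)
        # Paranodal region: [0, m] ∪ [L − m, L] (or the whole sheath if L ≤ 2m).
        if lp >= length:
            pos = u * length
        else:
            m = margin_um
            para_pos = np.where(u[in_para] < 0.5,
                                2 * u[in_para] * m,
                                length - m + (2 * u[in_para] - 1) * m)
            pos[in_para] = para_pos
            pos[~in_para] = m + u[~in_para] * li
        sheaths.append(
            Sheath(
                length_um=length,
                event_positions_um=np.clip(pos, 0.0, length),
                paranode_margin_um=margin_um,
                sheath_id=f"sheath_{i}",
            )
        )
    return sheaths


def _gaussian_1d(x: np.ndarray, center: float, sigma: float) -> np.ndarray:
    return np.exp(-((x - center) ** 2) / (2.0 * sigma**2))


def make_node_profile(
    node_class: str,
    length_um: float = 8.0,
    peak_sigma_um: float = 0.3,
    noise_sd: float = 0.0,
    seed: int = 0,
    spacing_um: float = 0.05,
    amplitude: float = 100.0,
    baseline: float = 10.0,
    caspr_gap_um: float = 1.2,
    cluster_channel: str = "caspr",
) -> tuple[NodeProfile, str]:
    """A dual-channel (Caspr/AnkG) line-scan profile with known node class.

    * ``mature``: two Caspr peaks flanking one central AnkG peak,
    * ``heminode``: one Caspr peak with one adjacent AnkG peak,
    * ``cluster``: a single peak in ``cluster_channel`` only.
    """
    if node_class not in ("mature", "heminode", "cluster"):
        raise ValueError(f"unknown node class {node_class!r}")
    if length_um < 4 * peak_sigma_um + 2 * caspr_gap_um:
        raise ValueError("profile too short to separate peaks")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    x = np.arange(0.0, length_um + spacing_um / 2, spacing_um)
    mid = length_um / 2.0
    caspr = np.full_like(x, baseline)
    ankg = np.full_like(x, baseline)
    if node_class == "mature":
        caspr += amplitude * _gaussian_1d(x, mid - caspr_gap_um, peak_sigma_um)
        caspr += amplitude * _gaussian_1d(x, mid + caspr_gap_um, peak_sigma_um)
        ankg += amplitude * _gaussian_1d(x, mid, peak_sigma_um)
    elif node_class == "heminode":
        caspr += amplitude * _gaussian_1d(x, mid - caspr_gap_um / 2, peak_sigma_um)
        ankg += amplitude * _gaussian_1d(x, mid + caspr_gap_um / 2, peak_sigma_um)
    else:
        target = caspr if cluster_channel == "caspr" else ankg
        target += amplitude * _gaussian_1d(x, mid, peak_sigma_um)
    if noise_sd > 0:
        caspr = caspr + rng.normal(0.0, noise_sd, size=x.size)
        ankg = ankg + rng.normal(0.0, noise_sd, size=x.size)
    return NodeProfile(positions_um=x, caspr=caspr, ankg=ankg), node_class


def make_track_profile(
    separation_um: float,
    length_um: float | None = None,
    peak_sigma_um: float = 0.15,
    spacing_um: float = 0.05,
    noise_sd: float = 0.0,
    seed: int = 0,
    amplitude: float = 100.0,
    baseline: float = 10.0,
) -> tuple[np.ndarray, np.ndarray]:
    """A perpendicular line scan across two parallel intensity tracks.

    Emulates an MBP-stained sheath cross-section: two Gaussian tracks whose
    centre-to-centre distance is the sheath diameter.  Returns
    ``(positions_um, intensity)``.
    """
    if separation_um <= 0:
        raise ValueError("separation must be > 0")
    if length_um is None:
        length_um = separation_um + 8 * peak_sigma_um + 1.0
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    x = np.arange(0.0, length_um + spacing_um / 2, spacing_um)
    mid = length_um / 2.0
    y = np.full_like(x, baseline)
    y += amplitude * _gaussian_1d(x, mid - separation_um / 2, peak_sigma_um)
    y += amplitude * _gaussian_1d(x, mid + separation_um / 2, peak_sigma_um)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=x.size)
    return x, y
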