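"""Shared containers: calibrated image stacks, cell geometry, intensity traces.

Conventions used throughout the package:

* pixel indices are 0-based; physical coordinates are micrometres measured
  from the centre of the image's top-left pixel,
* all geometry is carried in micrometres internally; conversion to pixels
  happens only at render/extract boundaries,
* stacks are ``(frames, rows, cols)`` float arrays in arbitrary fluorescence
  units (AU).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["TimeLapseStack", "CellGeometry", "IntensityTrace"]


@dataclass
class TimeLapseStack:
    """A single-channel fluorescence movie with physical calibration.

    Parameters
    ----------
    data:
        ``(frames, rows, cols)`` array of intensities (AU).
    frame_interval_s:
        Time between consecutive frames, seconds.
    pixel_size_um:
        Side length of a pixel, micrometres.
    """

    data: np.ndarray
    frame_interval_s: float
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("stack data must be 3-D (frames, rows, cols)")
        if self.data.shape[0] < 8:
            raise ValueError("stack must have at least 8 frames")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("stack contains non-finite values")
        if not (self.frame_interval_s > 0):
            raise ValueError("frame_interval_s must be > 0")
        if not (self.pixel_size_um > 0):
            raise ValueError("pixel_size_um must be > 0")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[1], self.data.shape[2]

    @property
    def times_s(self) -> np.ndarray:
        """Start time of each frame, seconds."""
        return np.arange(self.n_frames) * self.frame_interval_s

    def copy_with(self, data: np.ndarray) -> "TimeLapseStack":
        return TimeLapseStack(
            data=data,
            frame_interval_s=self.frame_interval_s,
            pixel_size_um=self.pixel_size_um,
        )


@dataclass
class CellGeometry:
    """Binary cell footprint and soma masks on the imaging grid.

    ``soma_mask`` must be a subset of ``cell_mask``; both are boolean
    ``(rows, cols)`` images.  Events are placed inside ``cell_mask`` and
    assigned to the soma compartment when their centroid falls inside
    ``soma_mask``.
    """

    cell_mask: np.ndarray
    soma_mask: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.cell_mask = np.asarray(self.cell_mask, dtype=bool)
        self.soma_mask = np.asarray(self.soma_mask, dtype=bool)
        if self.cell_mask.shape != self.soma_mask.shape:
            raise ValueError("cell_mask and soma_mask shapes differ")
        if self.cell_mask.ndim != 2:
            raise ValueError("masks must be 2-D")
        if np.any(self.soma_mask & ~self.cell_mask):
            raise ValueError("soma_mask must be a subset of cell_mask")

    def require_nonempty(self) -> None:
        if not self.cell_mask.any():
            raise ValueError("cell_mask is empty; cannot place events")
        if not self.soma_mask.any():
            raise ValueError("soma_mask is empty")


@dataclass
class IntensityTrace:
    """A 1-D intensity time series for one ROI."""

    times_s: np.ndarray
    values: np.ndarray
    reference: str = "raw"  # "raw" or "dff"

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times_s.shape != self.values.shape or self.times_s.ndim != 1:
            raise ValueError("times and values must be equal-length 1-D arrays")
        if self.times_s.size > 1 and not np.all(np.diff(self.times_s) > 0):
            raise ValueError("times must be strictly increasing")
        if self.reference not in ("raw", "dff"):
            raise ValueError(f"unknown trace reference {self.reference!r}")

    def __len__(self) -> int:
        return self.times_s.size

    def shifted(self, t0: float) -> "IntensityTrace":
        """Return the same trace with the time origin moved to ``t0``."""
        return IntensityTrace(self.times_s - t0, self.values.copy(), self.reference)
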