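"""Readers and writers for the pipeline's on-disk artifacts.

Conventions: multi-page TIFF stacks (16-bit unsigned, one page per frame)
with a JSON sidecar holding the physical calibration and the intensity
scale factor; tables as comma-separated UTF-8 CSV with a header row and
floats serialised with 17 significant digits so write → read → write is
byte-identical; small structured outputs as JSON.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .core import CellGeometry, TimeLapseStack
from .spatial import Sheath

__all__ = [
    "write_stack",
    "read_stack",
    "write_mask",
    "read_mask",
    "events_to_dataframe",
    "write_events_csv",
    "read_events_csv",
    "write_sheaths_csv",
    "read_sheaths_csv",
    "write_json",
    "read_json",
]

FLOAT_FORMAT = "%.17g"

EVENT_COLUMNS = [
    "event_id",
    "centroid_x_um",
    "centroid_y_um",
    "t_onset_s",
    "t_peak_s",
    "onset_frame",
    "peak_frame",
    "end_frame",
    "amplitude_sd",
    "baseline_F0",
    "compartment",
    "motile_flag",
    "reject_reason",
]

CLASSIFY_COLUMNS = [
    "t_half_center_s",
    "t_half_border_s",
    "border_decay_ratio",
    "fusion_mode",
    "fit_r2_center",
    "fit_r2_border",
    "classify_flag",
    "model_source",
]


def write_stack(path: str | Path, stack: TimeLapseStack) -> None:
    """16-bit multi-page TIFF plus ``<stem>.json`` calibration sidecar."""
    path = Path(path)
    lo = float(stack.data.min())
    hi = float(stack.data.max())
    scale = 65535.0 / (hi - lo) if hi > lo else 1.0
    scaled = np.round((stack.data - lo) * scale).astype(np.uint16)
    tifffile.imwrite(path, scaled, photometric="minisblack")
    sidecar = {
        "pixel_size_um": stack.pixel_size_um,
        "frame_interval_s": stack.frame_interval_s,
        "intensity_offset": lo,
        "intensity_scale": scale,
    }
    path.with_suffix(".json").write_text(
        json.dumps(sidecar, indent=2, sort_keys=True) + "\n"
    )


def read_stack(path: str | Path) -> TimeLapseStack:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    raw = tifffile.imread(path).astype(float)
    data = raw / sidecar["intensity_scale"] + sidecar["intensity_offset"]
    return TimeLapseStack(
        data=data,
        frame_interval_s=sidecar["frame_interval_s"],
        pixel_size_um=sidecar["pixel_size_um"],
    )


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    tifffile.imwrite(Path(path), mask.astype(np.uint8), photometric="minisblack")


def read_mask(path: str | Path) -> np.ndarray:
    return tifffile.imread(Path(path)) > 0


def events_to_dataframe(events: list, calls: list | None = None,
                        model=None) -> pd.DataFrame:
    """Tabulate detected events, optionally with fusion-mode calls."""
    rows = []
    for i, ev in enumerate(events):
        rows.append(
            {
                "event_id": i,
                "centroid_x_um": ev.centroid_um[0],
                "centroid_y_um": ev.centroid_um[1],
                "t_onset_s": ev.t_onset_s,
                "t_peak_s": ev.t_peak_s,
                "onset_frame": ev.onset_frame,
                "peak_frame": ev.peak_frame,
                "end_frame": ev.end_frame,
                "amplitude_sd": ev.amplitude_sd,
                "baseline_F0": ev.baseline_F0,
                "compartment": ev.compartment,
                "motile_flag": ev.motile_flag,
                "reject_reason": ev.reject_reason,
            }
        )
    df = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    if calls is not None:
        df["t_half_center_s"] = [
            c.fit_center.half_life_s if c.fit_center and c.fit_center.valid
            else math.nan
            for c in calls
        ]
        df["t_half_border_s"] = [
            c.fit_border.half_life_s if c.fit_border and c.fit_border.valid
            else math.nan
            for c in calls
        ]
        df["border_decay_ratio"] = [c.ratio for c in calls]
        df["fusion_mode"] = [c.mode for c in calls]
        df["fit_r2_center"] = [
            c.fit_center.r2 if c.fit_center else math.nan for c in calls
        ]
        df["fit_r2_border"] = [
            c.fit_border.r2 if c.fit_border else math.nan for c in calls
        ]
        df["classify_flag"] = [c.flag for c in calls]
        df["model_source"] = model.source if model is not None else ""
    return df


def write_events_csv(path: str | Path, df: pd.DataFrame) -> None:
    df.to_csv(Path(path), index=False, float_format=FLOAT_FORMAT)


def read_events_csv(path: str | Path) -> pd.DataFrame:
    # round_trip parsing keeps write → read → write byte-identical
    return pd.read_csv(Path(path), float_precision="round_trip")


def write_sheaths_csv(path: str | Path, sheaths: list[Sheath]) -> None:
    """One row per event (``sheath_id, cell_id, length_um, event_position_um``);
    empty sheaths contribute a row with an empty position."""
    rows = []
    for sh in sheaths:
        if sh.n_events == 0:
            rows.append(
                {
                    "sheath_id": sh.sheath_id,
                    "cell_id": sh.cell_id,
                    "length_um": sh.length_um,
                    "event_position_um": math.nan,
                }
            )
        for s in sh.event_positions_um:
            rows.append(
                {
                    "sheath_id": sh.sheath_id,
                    "cell_id": sh.cell_id,
                    "length_um": sh.length_um,
                    "event_position_um": s,
                }
            )
    pd.DataFrame(
        rows, columns=["sheath_id", "cell_id", "length_um", "event_position_um"]
    ).to_csv(Path(path), index=False, float_format=FLOAT_FORMAT)


def read_sheaths_csv(
    path: str | Path, margin_um: float | None = None
) -> list[Sheath]:
    df = pd.read_csv(Path(path))
    sheaths = []
    for (sid, cid, length), group in df.groupby(
        ["sheath_id", "cell_id", "length_um"], dropna=False, sort=False
    ):
        pos = group["event_position_um"].dropna().to_numpy()
        kwargs = {} if margin_um is None else {"paranode_margin_um": margin_um}
        sheaths.append(
            Sheath(
                length_um=float(length),
                event_positions_um=pos,
                sheath_id=str(sid),
                cell_id="" if pd.isna(cid) else str(cid),
                **kwargs,
            )
        )
    return sheaths


def write_json(path: str | Path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
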