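"""End-to-end pipeline runs: simulate → detect → classify → spatial/budget.

A run is described by a JSON config (validated strictly — unknown keys are
rejected), executed stage by stage into an output directory, and summarised
by a manifest recording the config hash, package version, and a SHA-256
checksum of every artifact each stage wrote.  Re-running an identical
config reproduces identical checksums for the deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__, io
from .core import CellGeometry
from .detection import DetectionParams, assign_compartment, correct_bleaching, \
    detect_events, event_frequency
from .fusion import RatioModel, classify_events
from .morphometry import BudgetParams, CoverageInputs, format_budget_printed, \
    membrane_budget, myelin_coverage, relative_coverage
from .spatial import summarize_spatial
from .synthetic import AcquisitionParams, make_cell_geometry, make_sheath_layout, \
    render_stack, sample_events

__all__ = ["RunConfig", "RunManifest", "run_pipeline", "DEMO_CONFIG"]

logger = logging.getLogger(__name__)

STAGE_ORDER = ["simulate", "detect", "classify", "spatial", "coverage", "budget"]

#: A minimal config exercising every stage in a few seconds.
DEMO_CONFIG: dict = {
    "seed": 7,
    "stages": ["simulate", "detect", "classify", "spatial", "budget"],
    "simulate": {
        "rate_per_min": 8.0,
        "full_fraction": 0.8,
        "acquisition": {"n_frames": 120, "image_shape": [128, 128]},
        "geometry": {"shape": [128, 128]},
        "min_separation_um": 3.0,
        "min_onset_gap_s": 3.0,
        "sheaths": {"lengths_um": [30.0] * 10, "enrichment": 1.0,
                    "n_events_per_sheath": 12},
    },
    "detect": {},
    "classify": {},
    "spatial": {},
    "budget": {},
}


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    seed: int
    stages: list[str]
    blocks: dict

    ALLOWED_TOP = {"seed", "stages", "log_level"} | set(STAGE_ORDER)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        unknown = set(raw) - cls.ALLOWED_TOP
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "seed" not in raw:
            raise ValueError("config needs a top-level seed")
        stages = raw.get("stages", [s for s in STAGE_ORDER if s in raw])
        bad = [s for s in stages if s not in STAGE_ORDER]
        if bad:
            raise ValueError(f"unknown stages: {bad}")
        stages = [s for s in STAGE_ORDER if s in stages]
        return cls(seed=int(raw["seed"]), stages=stages,
                   blocks={s: dict(raw.get(s, {})) for s in stages})


@dataclass
class RunManifest:
    config_hash: str
    version: str
    stages: dict = field(default_factory=dict)
    started: float = 0.0
    finished: float = 0.0

    def to_dict(self) -> dict:
        return {
            "config_hash": self.config_hash,
            "version": self.version,
            "stages": self.stages,
            "started": self.started,
            "finished": self.finished,
        }


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_hash(raw: dict) -> str:
    return hashlib.sha256(
        json.dumps(raw, sort_keys=True, separators=(",", ":")).encode()
    ).hexdigest()


def _pop(block: dict, key, default=None):
    return block.pop(key) if key in block else default


def _require_empty(block: dict, stage: str) -> None:
    if block:
        raise ValueError(f"unknown keys in {stage!r} block: {sorted(block)}")


def run_pipeline(raw_config: dict, outdir: str | Path) -> RunManifest:
    """Execute the configured stages in order and write ``manifest.json``.

    A stage failure halts the run with the failing stage named; outputs of
    the failed stage keep a ``.partial`` suffix.
    """
    config = RunConfig.from_dict(raw_config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config_hash=_config_hash(raw_config),
        version=__version__,
        started=time.time(),
    )

    state: dict = {"seed": config.seed}
    for stage in config.stages:
        block = dict(config.blocks.get(stage, {}))
        written: list[Path] = []
        try:
            _STAGES[stage](block, state, outdir, written)
        except Exception as exc:
            for path in written:
                if path.exists():
                    path.rename(path.with_suffix(path.suffix + ".partial"))
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        manifest.stages[stage] = {
            "outputs": {p.name: _sha256(p) for p in written}
        }
    manifest.finished = time.time()
    io.write_json(outdir / "manifest.json", manifest.to_dict())
    return manifest


def _stage_simulate(block, state, outdir, written):
    acq_kwargs = _pop(block, "acquisition", {})
    if "image_shape" in acq_kwargs:
        acq_kwargs["image_shape"] = tuple(acq_kwargs["image_shape"])
    params = AcquisitionParams(**acq_kwargs)
    geo_kwargs = _pop(block, "geometry", {})
    if "shape" in geo_kwargs:
        geo_kwargs["shape"] = tuple(geo_kwargs["shape"])
    geometry = make_cell_geometry(
        **geo_kwargs, pixel_size_um=params.pixel_size_um, seed=state["seed"]
    )
    rate = _pop(block, "rate_per_min", 23.0)
    full_fraction = _pop(block, "full_fraction", 0.8)
    margin_s = 2.0 * params.frame_interval_s * 4  # keep onsets clear of edges
    events = sample_events(
        rate,
        full_fraction,
        max(params.duration_s - 2 * margin_s, params.frame_interval_s),
        geometry,
        seed=state["seed"] + 1,
        pixel_size_um=params.pixel_size_um,
        min_separation_um=_pop(block, "min_separation_um"),
        min_onset_gap_s=_pop(block, "min_onset_gap_s"),
    )
    for ev in events:
        ev.t_start_s += margin_s
    sheath_cfg = _pop(block, "sheaths")
    _require_empty(block, "simulate")

    result = render_stack(params, geometry, events, seed=state["seed"] + 2)
    io.write_stack(outdir / "stack.tif", result.stack)
    io.write_mask(outdir / "cell_mask.tif", geometry.cell_mask)
    io.write_mask(outdir / "soma_mask.tif", geometry.soma_mask)
    result.truth.to_csv(outdir / "truth.csv", index=False,
                        float_format=io.FLOAT_FORMAT)
    written += [outdir / n for n in
                ("stack.tif", "stack.json", "cell_mask.tif", "soma_mask.tif",
                 "truth.csv")]
    if sheath_cfg is not None:
        sheaths = make_sheath_layout(
            sheath_cfg["lengths_um"],
            sheath_cfg.get("enrichment", 1.0),
            sheath_cfg.get("n_events_per_sheath", 10),
            seed=state["seed"] + 3,
        )
        io.write_sheaths_csv(outdir / "sheaths.csv", sheaths)
        written.append(outdir / "sheaths.csv")
        state["sheaths"] = sheaths
    state.update(stack=result.stack, geometry=geometry, truth=result.truth)


def _stage_detect(block, state, outdir, written):
    stack_path = _pop(block, "stack")
    mask_path = _pop(block, "mask")
    soma_path = _pop(block, "soma")
    det_kwargs = _pop(block, "params", {})
    _require_empty(block, "detect")
    stack = io.read_stack(stack_path) if stack_path else state.get("stack")
    if stack is None:
        raise ValueError("detect stage needs a stack (run simulate or set 'stack')")
    if mask_path:
        geometry = CellGeometry(
            io.read_mask(mask_path),
            io.read_mask(soma_path) if soma_path
            else io.read_mask(mask_path) & False,
        )
    else:
        geometry = state.get("geometry")
    corrected, bleach = correct_bleaching(stack)
    events = detect_events(corrected, DetectionParams(**det_kwargs), geometry)
    if geometry is not None:
        assign_compartment(events, geometry, corrected.pixel_size_um)
    df = io.events_to_dataframe(events)
    io.write_events_csv(outdir / "events.csv", df)
    freq = event_frequency(events, corrected.data.shape[0]
                           * corrected.frame_interval_s, by_compartment=True)
    io.write_json(outdir / "frequency.json",
                  {**freq, "bleach_tau_s": bleach.tau_s})
    written += [outdir / "events.csv", outdir / "frequency.json"]
    state.update(events=events, corrected=corrected)


def _stage_classify(block, state, outdir, written):
    fit_population = _pop(block, "fit_population", False)
    _require_empty(block, "classify")
    events = state.get("events")
    stack = state.get("corrected") or state.get("stack")
    if events is None or stack is None:
        raise ValueError("classify stage needs detect outputs")
    calls, model = classify_events(stack, events, fit_population=fit_population)
    df = io.events_to_dataframe(events, calls, model)
    io.write_events_csv(outdir / "events_classified.csv", df)
    written.append(outdir / "events_classified.csv")
    state["calls"] = calls


def _stage_spatial(block, state, outdir, written):
    sheaths_path = _pop(block, "sheaths")
    weighting = _pop(block, "weighting", "per_sheath_mean")
    margin = _pop(block, "margin_um", None)
    _require_empty(block, "spatial")
    sheaths = (
        io.read_sheaths_csv(sheaths_path, margin)
        if sheaths_path
        else state.get("sheaths")
    )
    if sheaths is None:
        raise ValueError("spatial stage needs a sheath table")
    summary = summarize_spatial(sheaths, weighting)
    io.write_json(outdir / "summary.json", summary.to_dict())
    written.append(outdir / "summary.json")


def _stage_coverage(block, state, outdir, written):
    test = CoverageInputs(**_pop(block, "test"))
    ref = CoverageInputs(**_pop(block, "reference"))
    _require_empty(block, "coverage")
    payload = {
        "test_product": myelin_coverage(test),
        "reference_product": myelin_coverage(ref),
        "ratio": relative_coverage(test, ref),
    }
    io.write_json(outdir / "coverage.json", payload)
    written.append(outdir / "coverage.json")


def _stage_budget(block, state, outdir, written):
    params = BudgetParams(**_pop(block, "params", {}))
    _require_empty(block, "budget")
    budget = membrane_budget(params)
    io.write_json(
        outdir / "budget.json",
        {"exact": budget, "printed": format_budget_printed(budget)},
    )
    written.append(outdir / "budget.json")


_STAGES = {
    "simulate": _stage_simulate,
    "detect": _stage_detect,
    "classify": _stage_classify,
    "spatial": _stage_spatial,
    "coverage": _stage_coverage,
    "budget": _stage_budget,
}
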