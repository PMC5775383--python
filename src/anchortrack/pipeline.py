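"""End-to-end run orchestration: simulate -> segment -> trace -> classify.

A run renders the synthetic chip frame by frame (so a full 1495-anchor
time-lapse never needs to be held in memory), detects and tracks cells in
the red tracker channel, extracts background-subtracted Delta I traces
from the green channel, computes the skewness series and the HP/LP split,
scores viability from the endpoint nuclei/dead-stain frames, and writes
every table plus a JSON report.  All randomness derives from one seed, and
every output file records the configuration hash and seed, so a stored
config reproduces a run byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import chip_model, kinetics, segmentation, subpopulations
from .chip_model import ChipLayout, OccupancyTable, build_layout
from .errors import InvalidInputError
from .kinetics import CellTrace
from .synthetic_timelapse import (
    CHANNELS,
    PRESETS,
    CellTruth,
    ConditionPreset,
    ImagingParams,
    generate_population,
    render_frame,
    write_truth,
)

logger = logging.getLogger("anchortrack")


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce one run."""

    preset: str = "R5"
    seed: int = 0
    rows: int = chip_model.DEFAULT_ROWS
    cols: int = chip_model.DEFAULT_COLS
    pitch_um: float = chip_model.DEFAULT_PITCH_UM
    anchor_radius_um: float = chip_model.DEFAULT_ANCHOR_RADIUS_UM
    droplet_volume_nl: float = chip_model.DEFAULT_DROPLET_VOLUME_NL
    pixel_size_um: float = 1.0
    read_noise_sd: float = 5.0
    blur_sigma_px: float = 1.0
    duration_h: float = 62.0
    interval_h: float = 2.0
    sigma_multiplier: float = subpopulations.DEFAULT_SIGMA_MULTIPLIER
    preset_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.preset not in PRESETS:
            raise InvalidInputError(
                f"unknown preset {self.preset!r}; choose from {sorted(PRESETS)}"
            )
        if self.interval_h <= 0 or self.duration_h < 0:
            raise InvalidInputError("time grid must be positive")

    def condition(self) -> ConditionPreset:
        base = PRESETS[self.preset]
        if self.preset_overrides:
            from dataclasses import replace

            base = replace(base, **self.preset_overrides)
        return base

    def layout(self) -> ChipLayout:
        return build_layout(
            rows=self.rows,
            cols=self.cols,
            pitch_um=self.pitch_um,
            anchor_radius_um=self.anchor_radius_um,
            droplet_volume_nl=self.droplet_volume_nl,
        )

    def imaging(self) -> ImagingParams:
        n = int(round(self.duration_h / self.interval_h)) + 1
        grid = tuple(k * self.interval_h for k in range(n))
        return ImagingParams(
            pixel_size_um=self.pixel_size_um,
            read_noise_sd=self.read_noise_sd,
            blur_sigma_px=self.blur_sigma_px,
            time_grid_h=grid,
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    @property
    def config_hash(self) -> str:
        canonical = yaml.safe_dump(asdict(self), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:12]


@dataclass
class RunReport:
    """Headline numbers of one pipeline run."""

    preset: str
    seed: int
    config_hash: str
    n_anchors: int
    lambda_hat: float
    single_cell_fraction: float
    n_cells_analyzed: int
    viability: float
    median_r_squared: float
    threshold: float
    n_hp: int
    hp_percentage: float
    hp_specific_productivity: float
    skewness_series: list[float]
    time_grid_h: list[float]
    group_stats: dict

    def to_json(self, path: str | Path) -> None:
        payload = {k: _jsonable(v) for k, v in asdict(self).items()}
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def _jsonable(v):
    if isinstance(v, float) and np.isnan(v):
        return None
    if isinstance(v, (np.floating, np.integer)):
        return v.item()
    if isinstance(v, list):
        return [_jsonable(x) for x in v]
    if isinstance(v, dict):
        return {k: _jsonable(x) for k, x in v.items()}
    return v


def _write_csv(df: pd.DataFrame, path: Path, config: RunConfig) -> None:
    header = f"# config={config.config_hash} seed={config.seed}\n"
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False)


def analyze_stack(
    red_frames,
    green_frames,
    layout: ChipLayout,
    time_grid_h: tuple[float, ...],
    pixel_size_um: float = 1.0,
) -> tuple[list[CellTrace], list]:
    """Segment, track and trace an in-memory (or lazily iterable) stack.

    ``red_frames``/``green_frames`` are iterated frame by frame, so a
    generator that renders on demand works as well as an array.  Only
    anchors holding exactly one detected cell at the first frame enter the
    analysis, mirroring the single-cell droplet selection.
    """
    detections_per_frame = []
    for idx, (red, green) in enumerate(zip(red_frames, green_frames)):
        dets = segmentation.detect_cells(
            red, layout, pixel_size_um=pixel_size_um, frame=idx
        )
        kinetics.measure_intensities(dets, green, layout, pixel_size_um)
        for d in dets:
            d.release_mask()
        detections_per_frame.append(dets)
        logger.debug("frame %d: %d detections", idx, len(dets))
    if all(len(d) == 0 for d in detections_per_frame):
        return [], detections_per_frame
    tracks = segmentation.track_cells(detections_per_frame)
    frame0_counts: dict[int, int] = {}
    for d in detections_per_frame[0]:
        frame0_counts[d.anchor_id] = frame0_counts.get(d.anchor_id, 0) + 1
    single = {a for a, c in frame0_counts.items() if c == 1}
    kept = [t for t in tracks if t.anchor_id in single and 0 in t.detections]
    traces = [kinetics.extract_trace(t, time_grid_h) for t in kept]
    return traces, detections_per_frame


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> RunReport:
    """Execute a full simulated experiment and optionally write artifacts."""
    layout = config.layout()
    preset = config.condition()
    imaging = config.imaging()
    n_frames = len(imaging.time_grid_h)
    logger.info(
        "run %s seed=%d: %d anchors, %d frames",
        config.preset, config.seed, layout.n_anchors, n_frames,
    )

    stage = "simulate"
    try:
        truths = generate_population(layout, preset, config.seed)

        stage = "segment/trace"
        red_stream = (
            render_frame(truths, layout, k, "red_tracker", imaging, config.seed)
            for k in range(n_frames)
        )
        green_stream = (
            render_frame(truths, layout, k, "green_gfp", imaging, config.seed)
            for k in range(n_frames)
        )
        traces, detections_per_frame = analyze_stack(
            red_stream, green_stream, layout, imaging.time_grid_h,
            config.pixel_size_um,
        )

        stage = "viability"
        last = n_frames - 1
        blue = render_frame(truths, layout, last, "blue_nuclei", imaging, config.seed)
        dead = render_frame(truths, layout, last, "red_dead", imaging, config.seed)
        all_cell_dets = segmentation.detect_cells(
            blue, layout, pixel_size_um=config.pixel_size_um, frame=last
        )
        viability, _ = segmentation.score_viability(dead, all_cell_dets)

        stage = "occupancy"
        counts = np.zeros(layout.n_anchors, dtype=int)
        for d in all_cell_dets:
            counts[d.anchor_id] += 1
        occupancy = OccupancyTable(counts=counts)
        lambda_hat, _ = chip_model.fit_poisson(occupancy)
        single_fraction = float((counts == 1).mean())

        stage = "classify"
        if traces:
            summary = kinetics.summarize_population(traces)
            skew = summary.skewness
            r2_median = float(np.median([t.r_squared for t in traces]))
        else:
            skew = np.full(n_frames, np.nan)
            r2_median = float("nan")
        threshold = float("nan")
        n_hp = 0
        hp_pct = float("nan")
        hp_prod = float("nan")
        group_stats: dict = {}
        labels = np.zeros(len(traces), dtype=bool)
        if len(traces) >= subpopulations.MIN_THRESHOLD_SAMPLE:
            final = np.array([t.delta_final for t in traces])
            threshold = subpopulations.compute_threshold(
                final, sigma_multiplier=config.sigma_multiplier
            )
            cls = subpopulations.classify_hp(traces, threshold)
            labels = cls.labels
            n_hp = cls.n_hp
            hp_pct = cls.hp_percentage
            hp_prod = cls.hp_specific_productivity
            if 2 <= n_hp <= len(traces) - 2:
                areas = np.array([t.area_um2 for t in traces])
                morph = subpopulations.compare_morphology(labels, areas)
                group_stats["morphology"] = {
                    "statistic_name": morph.statistic_name,
                    "statistic": morph.statistic,
                    "p_value": morph.p_value,
                    **morph.effect_summary,
                }
                prod = subpopulations.wilcoxon_rank_sum(
                    final[labels], final[~labels]
                ) if n_hp >= 2 and len(traces) - n_hp >= 2 else None
                if prod is not None:
                    group_stats["hp_vs_lp_final_delta"] = {
                        "statistic_name": prod.statistic_name,
                        "statistic": prod.statistic,
                        "p_value": prod.p_value,
                    }
    except Exception:
        logger.exception("pipeline failed in stage %r", stage)
        raise

    report = RunReport(
        preset=config.preset,
        seed=config.seed,
        config_hash=config.config_hash,
        n_anchors=layout.n_anchors,
        lambda_hat=lambda_hat,
        single_cell_fraction=single_fraction,
        n_cells_analyzed=len(traces),
        viability=viability,
        median_r_squared=r2_median,
        threshold=threshold,
        n_hp=n_hp,
        hp_percentage=hp_pct,
        hp_specific_productivity=hp_prod,
        skewness_series=[float(s) for s in skew],
        time_grid_h=[float(t) for t in imaging.time_grid_h],
        group_stats=group_stats,
    )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        config.to_yaml(out / "config.yaml")
        write_truth(truths, out / "truth.csv")
        det_rows = [
            (d.frame, d.anchor_id, d.x_um, d.y_um, d.area_um2, d.eq_diameter_um,
             d.i_cell, d.i_back)
            for dets in detections_per_frame
            for d in dets
        ]
        _write_csv(
            pd.DataFrame(
                det_rows,
                columns=["frame", "anchor_id", "x_um", "y_um", "area_um2",
                         "eq_diam_um", "I_cell", "I_back"],
            ),
            out / "detections.csv",
            config,
        )
        _write_csv(kinetics.traces_to_frame(traces), out / "traces.csv", config)
        fits = kinetics.fits_to_frame(traces)
        fits["is_hp"] = labels if len(traces) else []
        _write_csv(fits, out / "fits.csv", config)
        occupancy.to_csv(out / "occupancy.csv", layout)
        report.to_json(out / "report.json")
    return report
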