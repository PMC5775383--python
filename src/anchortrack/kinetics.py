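"""Background-subtracted GFP traces and per-cell linear kinetics.

For each tracked cell and frame the green-channel signal is reduced to

    I = I_cell - I_back,        Delta I = I(t) - I_0,

where I_cell is the mean green intensity over the cell mask, I_back the
mean over the rest of the cell's anchor disk, and I_0 the value at the
first frame.  Both statistics are per-pixel means, so I does not scale
with cell area and high-producer calls reflect production rate rather
than size.  Per-cell production rates come from ordinary least squares of
Delta I on time; under transient transfection these traces are close to
linear (median r^2 above 0.9 on realistic noise).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .chip_model import ChipLayout
from .errors import AnchortrackError, InvalidInputError
from .segmentation import CellTrack, DetectedCell

#: Masks are dilated by this margin (um) before being excluded from the
#: background region, so the blur halo around a cell does not leak into
#: I_back.
BACKGROUND_EXCLUSION_MARGIN_UM = 3.0


def measure_intensities(
    detections: list[DetectedCell],
    green_frame: np.ndarray,
    layout: ChipLayout,
    pixel_size_um: float = 1.0,
) -> None:
    """Fill ``i_cell`` and ``i_back`` on each detection from one green frame.

    I_back is the mean over the detection's anchor disk excluding every
    detection mask in that anchor (dilated by a small margin).
    """
    img = np.asarray(green_frame)
    by_anchor: dict[int, list[DetectedCell]] = {}
    for det in detections:
        by_anchor.setdefault(det.anchor_id, []).append(det)
    px = pixel_size_um
    r_px = layout.anchor_radius_um / px
    for anchor_id, dets in by_anchor.items():
        cx, cy = layout.centers_um[anchor_id] / px
        x0 = max(int(np.floor(cx - r_px)) - 1, 0)
        x1 = min(int(np.ceil(cx + r_px)) + 1, img.shape[1])
        y0 = max(int(np.floor(cy - r_px)) - 1, 0)
        y1 = min(int(np.ceil(cy + r_px)) + 1, img.shape[0])
        yy, xx = np.mgrid[y0:y1, x0:x1]
        in_disk = (xx + 0.5 - cx) ** 2 + (yy + 0.5 - cy) ** 2 <= r_px**2
        exclude = np.zeros_like(in_disk)
        margin_px = BACKGROUND_EXCLUSION_MARGIN_UM / px
        for det in dets:
            if det.mask is None:
                raise InvalidInputError("detections must retain pixel masks")
            det_r = det.eq_diameter_um / 2 / px + margin_px
            dcx, dcy = det.x_um / px, det.y_um / px
            exclude |= (xx + 0.5 - dcx) ** 2 + (yy + 0.5 - dcy) ** 2 <= det_r**2
        background = in_disk & ~exclude
        if not background.any():
            raise AnchortrackError(
                f"anchor {anchor_id}: no background pixels left in the anchor "
                "disk; check layout/pixel-size configuration"
            )
        crop = img[y0:y1, x0:x1].astype(np.float64, copy=False)
        back_mean = crop[background].mean()
        for det in dets:
            det.i_cell = float(
                img[det.mask[:, 0], det.mask[:, 1]].astype(np.float64).mean()
            )
            det.i_back = float(back_mean)


@dataclass
class CellTrace:
    """Per-cell background-subtracted green time series and its linear fit."""

    track_id: int
    anchor_id: int
    time_h: np.ndarray
    i_cell: np.ndarray
    i_back: np.ndarray
    intensity: np.ndarray  # I = I_cell - I_back
    delta: np.ndarray  # Delta I = I(t) - I_0
    slope: float = np.nan
    intercept: float = np.nan
    r_squared: float = np.nan
    area_um2: float = np.nan  # initial (first detected frame) cell area

    @property
    def i0(self) -> float:
        return float(self.intensity[0])

    @property
    def delta_final(self) -> float:
        return float(self.delta[-1])


def delta_trace(intensity: np.ndarray) -> np.ndarray:
    """Delta I(t) = I(t) - I(0); identically 0 at the first frame."""
    intensity = np.asarray(intensity, dtype=float)
    return intensity - intensity[0]


def fit_linear(time_h: np.ndarray, delta: np.ndarray) -> tuple[float, float, float]:
    """OLS of Delta I on t: (slope, intercept, r^2).

    r^2 is the squared Pearson correlation, defined as 0 for a constant
    series (no variance to explain).
    """
    t = np.asarray(time_h, dtype=float)
    y = np.asarray(delta, dtype=float)
    if t.size < 3:
        raise InvalidInputError("need at least 3 time points for a linear fit")
    if np.ptp(y) == 0:
        return 0.0, float(y[0]), 0.0
    slope, intercept = np.polyfit(t, y, 1)
    r = np.corrcoef(t, y)[0, 1]
    return float(slope), float(intercept), float(r**2)


def _interpolate_missing(
    time_h: np.ndarray, values: dict[int, float], n_frames: int
) -> np.ndarray:
    """Linearly interpolate frames without a detection (gaps at the ends are
    extended from the nearest observation)."""
    frames = np.array(sorted(values))
    obs = np.array([values[f] for f in frames])
    return np.interp(np.arange(n_frames), frames, obs)


def extract_trace(
    track: CellTrack,
    time_grid_h: tuple[float, ...] | np.ndarray,
) -> CellTrace:
    """Assemble a trace from a track whose detections carry measured
    intensities (see :func:`measure_intensities`)."""
    n = len(time_grid_h)
    if not track.detections:
        raise InvalidInputError("empty track")
    t = np.asarray(time_grid_h, dtype=float)
    i_cell = _interpolate_missing(
        t, {f: d.i_cell for f, d in track.detections.items()}, n
    )
    i_back = _interpolate_missing(
        t, {f: d.i_back for f, d in track.detections.items()}, n
    )
    if np.isnan(i_cell).any() or np.isnan(i_back).any():
        raise InvalidInputError(
            "track detections carry unmeasured intensities; run "
            "measure_intensities on every frame first"
        )
    intensity = i_cell - i_back
    delta = delta_trace(intensity)
    slope, intercept, r2 = fit_linear(t, delta)
    first_frame = min(track.detections)
    return CellTrace(
        track_id=track.track_id,
        anchor_id=track.anchor_id,
        time_h=t,
        i_cell=i_cell,
        i_back=i_back,
        intensity=intensity,
        delta=delta,
        slope=slope,
        intercept=intercept,
        r_squared=r2,
        area_um2=track.detections[first_frame].area_um2,
    )


def extract_traces(
    tracks: list[CellTrack],
    green_frames: np.ndarray | list[np.ndarray],
    layout: ChipLayout,
    time_grid_h: tuple[float, ...],
    pixel_size_um: float = 1.0,
) -> list[CellTrace]:
    """Measure + assemble traces from an in-memory green stack (small chips;
    large runs stream :func:`measure_intensities` frame by frame)."""
    for frame_idx, frame in enumerate(green_frames):
        dets = [
            t.detections[frame_idx]
            for t in tracks
            if frame_idx in t.detections
        ]
        measure_intensities(dets, frame, layout, pixel_size_um)
    return [extract_trace(t, time_grid_h) for t in tracks]


@dataclass
class PopulationSummary:
    """Pointwise population statistics of Delta I."""

    time_h: np.ndarray
    mean_delta: np.ndarray
    mean_deviation: np.ndarray  # M.D.(t) = mean |Delta I - mean Delta I|
    skewness: np.ndarray  # bias-adjusted g1(t); NaN for n < 3
    n_cells: int


def summarize_population(traces: list[CellTrace]) -> PopulationSummary:
    """Mean Delta I(t), mean deviation, and bias-adjusted skewness g1(t)."""
    if not traces:
        raise InvalidInputError("no traces to summarize")
    deltas = np.vstack([tr.delta for tr in traces])
    t = traces[0].time_h
    mean = deltas.mean(axis=0)
    md = np.abs(deltas - mean).mean(axis=0)
    n = len(traces)
    if n >= 3:
        # Delta I(0) = 0 identically, so g1(0) is NaN by construction
        with np.errstate(invalid="ignore"):
            g1 = stats.skew(deltas, axis=0, bias=False)
    else:
        g1 = np.full(t.shape, np.nan)
    return PopulationSummary(
        time_h=t, mean_delta=mean, mean_deviation=md, skewness=np.asarray(g1),
        n_cells=n,
    )


def traces_to_frame(traces: list[CellTrace]) -> pd.DataFrame:
    """Long-format traces table (track_id, anchor_id, t_h, I_cell, I_back,
    I, dI)."""
    rows = []
    for tr in traces:
        for k, t in enumerate(tr.time_h):
            rows.append(
                (tr.track_id, tr.anchor_id, t, tr.i_cell[k], tr.i_back[k],
                 tr.intensity[k], tr.delta[k])
            )
    return pd.DataFrame(
        rows, columns=["track_id", "anchor_id", "t_h", "I_cell", "I_back", "I", "dI"]
    )


def fits_to_frame(traces: list[CellTrace]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (tr.track_id, tr.anchor_id, tr.slope, tr.intercept, tr.r_squared,
             tr.area_um2)
            for tr in traces
        ],
        columns=["track_id", "anchor_id", "slope", "intercept", "r2", "area_um2"],
    )
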