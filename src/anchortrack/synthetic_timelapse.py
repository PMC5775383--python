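"""Forward model: synthetic multi-channel time-lapse stacks with ground truth.

The generator emulates the transfection experiment: CHO-S cells are
Poisson-loaded into anchor droplets, immobilized in agarose (so they do not
move between frames), and imaged every 2 h for 62 h in four channels:

* ``red_tracker`` — CellTracker dye, constant brightness; retained by live
  cells only, so it defines the population entering kinetic analysis.
* ``green_gfp``  — GFP; the in-cell signal rises linearly in time with a
  per-cell slope.  A minority high-producer (HP) subpopulation has a
  several-fold larger slope and >=15% larger diameter.
* ``blue_nuclei`` — nuclear stain, all cells (viability denominator).
* ``red_dead``   — dead stain, dead cells only.

Images are rendered as anti-aliased disks on a flat background, optionally
Gaussian-blurred, with additive Gaussian read noise; all intensities are
clipped to the camera bit depth.  Each (frame, channel) gets its own
deterministic random stream derived from the base seed, so rendering one
frame at a time is bit-identical to rendering the whole stack.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
import json

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage

from .chip_model import ChipLayout, poisson_load
from .errors import FormatError, InvalidGeometryError, InvalidInputError

CHANNELS = ("red_tracker", "green_gfp", "blue_nuclei", "red_dead")

DEFAULT_TIME_GRID_H = tuple(float(t) for t in range(0, 63, 2))  # 0..62 h


@dataclass(frozen=True)
class ConditionPreset:
    """Generator parameters for one transfection condition.

    The three named presets mirror the lipoplex charge-ratio conditions:
    HP prevalence falls from R+/- 5 to R+/- 1.5 while the HP-specific
    production rate rises (~1.5x for R+/- 1.5), and HP diameters are >=15%
    larger than the rest of the population.
    """

    name: str
    hp_prevalence: float
    lp_slope_mean: float = 8.0  # intensity counts / h
    lp_slope_sd: float = 1.5
    hp_slope_multiplier: float = 4.0
    hp_diameter_multiplier: float = 1.15
    nonproducer_fraction: float = 0.0
    viability: float = 1.0
    lam: float = 0.45  # mean cells / droplet

    def __post_init__(self) -> None:
        for name in ("hp_prevalence", "nonproducer_fraction", "viability"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidInputError(f"{name} must be in [0, 1], got {v}")
        if self.hp_slope_multiplier < 1 or self.hp_diameter_multiplier < 1:
            raise InvalidInputError("multipliers must be >= 1")
        if self.lp_slope_mean < 0 or self.lp_slope_sd < 0 or self.lam < 0:
            raise InvalidInputError("slopes and lam must be >= 0")


#: Condition presets named after the lipoplex charge ratios they emulate.
PRESETS: dict[str, ConditionPreset] = {
    "R5": ConditionPreset(name="R5", hp_prevalence=0.1527, viability=0.75),
    "R3": ConditionPreset(name="R3", hp_prevalence=0.0872, viability=0.71),
    "R1.5": ConditionPreset(
        name="R1.5",
        hp_prevalence=0.0488,
        viability=0.88,
        hp_slope_multiplier=6.0,  # ~1.5x the HP-specific rate of R5/R3
    ),
}


@dataclass(frozen=True)
class ImagingParams:
    """Camera/optics model for rendering."""

    pixel_size_um: float = 1.0
    bit_depth: int = 16
    background: float = 100.0  # counts
    read_noise_sd: float = 5.0  # counts
    blur_sigma_px: float = 1.0
    tracker_intensity: float = 1000.0  # counts above background
    stain_intensity: float = 1000.0
    time_grid_h: tuple[float, ...] = DEFAULT_TIME_GRID_H
    #: quantize to integer camera counts; disable for noise-free algebraic
    #: checks where sub-count exactness matters
    quantize: bool = True
    #: anti-alias disk edges with partial pixel coverage; disable (hard
    #: binary disks) for checks that require the in-mask mean to equal the
    #: nominal cell intensity exactly
    antialias: bool = True

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise InvalidInputError("pixel size must be > 0")
        if len(self.time_grid_h) == 0:
            raise InvalidInputError("time grid must be nonempty")

    @property
    def max_count(self) -> int:
        return 2**self.bit_depth - 1

    def frame_shape(self, layout: ChipLayout) -> tuple[int, int]:
        w, h = layout.fov_um
        return (
            int(round(h / self.pixel_size_um)),
            int(round(w / self.pixel_size_um)),
        )


# LP diameters: truncated normal, exercising the 10-25 um cell gate on
# both sides.
LP_DIAMETER_MEAN_UM = 13.0
LP_DIAMETER_SD_UM = 1.5
LP_DIAMETER_RANGE_UM = (8.0, 27.0)

# Baseline in-cell green signal (above background) at t = 0.
I0_RANGE = (10.0, 30.0)


@dataclass
class CellTruth:
    """Ground truth for one synthetic cell."""

    cell_id: int
    anchor_id: int
    x_um: float
    y_um: float
    diameter_um: float
    is_hp: bool
    slope: float  # green counts / h
    i0_true: float  # green counts above background at t = 0
    is_viable: bool


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float
) -> float:
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo < x < hi:
            return float(x)
    return float(np.clip(mean, lo, hi))


def generate_population(
    layout: ChipLayout,
    preset: ConditionPreset,
    seed: int | np.random.Generator,
) -> list[CellTruth]:
    """Poisson-load the chip and draw per-cell ground truth.

    Each cell is HP with probability ``hp_prevalence``; HP slope and
    diameter are an LP draw scaled by the preset multipliers.  Non-viable
    cells and non-producers have slope 0.  Cells within an anchor are
    placed without overlap (they are solid objects in agarose).
    """
    rng = np.random.default_rng(seed)
    occupancy = poisson_load(layout, preset.lam, rng)
    truths: list[CellTruth] = []
    cell_id = 0
    for anchor_id in np.flatnonzero(occupancy.counts > 0):
        cx, cy = layout.centers_um[anchor_id]
        placed: list[tuple[float, float, float]] = []
        for _ in range(int(occupancy.counts[anchor_id])):
            is_hp = bool(rng.random() < preset.hp_prevalence)
            diameter = _truncated_normal(
                rng, LP_DIAMETER_MEAN_UM, LP_DIAMETER_SD_UM, *LP_DIAMETER_RANGE_UM
            )
            slope = _truncated_normal(
                rng, preset.lp_slope_mean, preset.lp_slope_sd, 0.0, np.inf
            )
            if is_hp:
                diameter *= preset.hp_diameter_multiplier
                slope *= preset.hp_slope_multiplier
            elif rng.random() < preset.nonproducer_fraction:
                slope = 0.0
            is_viable = bool(rng.random() < preset.viability)
            if not is_viable:
                slope = 0.0
            max_r = layout.anchor_radius_um - diameter / 2 - 2.0
            if max_r <= 0:
                raise InvalidGeometryError(
                    f"cell of diameter {diameter:.1f} um does not fit in an "
                    f"anchor of radius {layout.anchor_radius_um} um"
                )
            x = y = 0.0
            for _ in range(200):
                r = max_r * np.sqrt(rng.random())
                theta = rng.random() * 2 * np.pi
                x, y = cx + r * np.cos(theta), cy + r * np.sin(theta)
                if all(
                    np.hypot(x - px, y - py) >= (diameter + pd_) / 2 + 3.0
                    for px, py, pd_ in placed
                ):
                    break
            placed.append((x, y, diameter))
            truths.append(
                CellTruth(
                    cell_id=cell_id,
                    anchor_id=int(anchor_id),
                    x_um=x,
                    y_um=y,
                    diameter_um=diameter,
                    is_hp=is_hp,
                    slope=slope,
                    i0_true=float(rng.uniform(*I0_RANGE)),
                    is_viable=is_viable,
                )
            )
            cell_id += 1
    return truths


def _cell_amplitude(cell: CellTruth, channel: str, t_h: float) -> float:
    """In-cell signal above background for one channel at time t."""
    if channel == "red_tracker":
        return np.nan if not cell.is_viable else 1.0  # scaled by params
    if channel == "green_gfp":
        return cell.i0_true + cell.slope * t_h
    if channel == "blue_nuclei":
        return 1.0
    if channel == "red_dead":
        return np.nan if cell.is_viable else 1.0
    raise InvalidInputError(f"unknown channel {channel!r}")


def render_frame(
    truths: list[CellTruth],
    layout: ChipLayout,
    frame_index: int,
    channel: str,
    params: ImagingParams = ImagingParams(),
    seed: int = 0,
) -> np.ndarray:
    """Render one channel of one frame (uint16).

    The random stream is derived from (seed, frame_index, channel), so
    streaming frame-by-frame reproduces ``render_timelapse`` exactly.
    """
    if channel not in CHANNELS:
        raise InvalidInputError(f"unknown channel {channel!r}")
    t_h = params.time_grid_h[frame_index]
    shape = params.frame_shape(layout)
    # float32 suffices for integer camera counts; the non-quantized path is
    # used for exact algebraic checks and keeps full double precision
    dtype = np.float32 if params.quantize else np.float64
    if params.read_noise_sd > 0:
        rng = np.random.default_rng([seed, frame_index, CHANNELS.index(channel)])
        img = rng.standard_normal(shape, dtype=dtype)
        img *= params.read_noise_sd
        img += params.background
    else:
        img = np.full(shape, params.background, dtype=dtype)
    px = params.pixel_size_um
    for cell in truths:
        amp = _cell_amplitude(cell, channel, t_h)
        if np.isnan(amp):
            continue
        if channel in ("red_tracker",):
            amp *= params.tracker_intensity
        elif channel in ("blue_nuclei", "red_dead"):
            amp *= params.stain_intensity
        r_px = cell.diameter_um / 2 / px
        cx, cy = cell.x_um / px, cell.y_um / px
        pad = int(np.ceil(r_px + 3 * params.blur_sigma_px + 2))
        x0, x1 = int(np.floor(cx)) - pad, int(np.floor(cx)) + pad + 1
        y0, y1 = int(np.floor(cy)) - pad, int(np.floor(cy)) + pad + 1
        if x0 < 0 or y0 < 0 or x1 > shape[1] or y1 > shape[0]:
            raise InvalidGeometryError(
                f"cell {cell.cell_id} extends outside the field of view"
            )
        yy, xx = np.mgrid[y0:y1, x0:x1]
        dist = np.hypot(xx + 0.5 - cx, yy + 0.5 - cy)
        if params.antialias:
            coverage = np.clip(r_px + 0.5 - dist, 0.0, 1.0)
        else:
            coverage = (dist <= r_px).astype(dtype)
        patch = amp * coverage
        if params.blur_sigma_px > 0:
            patch = ndimage.gaussian_filter(patch, params.blur_sigma_px)
        img[y0:y1, x0:x1] += patch
    if params.quantize:
        np.rint(img, out=img)
        np.clip(img, 0, params.max_count, out=img)
        return img.astype(np.uint16)
    return np.clip(img, 0, params.max_count)


@dataclass
class TimeLapseStack:
    """An in-memory multi-channel frame sequence."""

    channels: dict[str, np.ndarray]  # name -> (T, H, W)
    time_grid_h: tuple[float, ...]
    pixel_size_um: float

    def __post_init__(self) -> None:
        shapes = {a.shape for a in self.channels.values()}
        if len(shapes) > 1:
            raise InvalidInputError("all channels must share one shape")
        for arr in self.channels.values():
            if arr.shape[0] != len(self.time_grid_h):
                raise InvalidInputError("frame count must match time grid")

    @property
    def n_frames(self) -> int:
        return len(self.time_grid_h)


def render_timelapse(
    truths: list[CellTruth],
    layout: ChipLayout,
    params: ImagingParams = ImagingParams(),
    seed: int = 0,
    channels: tuple[str, ...] = CHANNELS,
) -> TimeLapseStack:
    """Render the full stack (small chips; large chips should stream with
    :func:`render_frame`)."""
    data = {
        ch: np.stack(
            [
                render_frame(truths, layout, t, ch, params, seed)
                for t in range(len(params.time_grid_h))
            ]
        )
        for ch in channels
    }
    return TimeLapseStack(
        channels=data,
        time_grid_h=params.time_grid_h,
        pixel_size_um=params.pixel_size_um,
    )


TRUTH_COLUMNS = [
    "cell_id",
    "anchor_id",
    "x_um",
    "y_um",
    "diameter_um",
    "is_hp",
    "slope",
    "i0_true",
    "is_viable",
]


def write_truth(truths: list[CellTruth], path: str | Path) -> None:
    """Write ground truth as CSV (header-only when the list is empty).

    Floats use 17 significant digits so the table round-trips exactly.
    """
    df = pd.DataFrame([asdict(t) for t in truths], columns=TRUTH_COLUMNS)
    df.to_csv(path, index=False, float_format=lambda v: format(v, ".17g"))


def read_truth(path: str | Path) -> list[CellTruth]:
    df = pd.read_csv(path, float_precision="round_trip")
    if list(df.columns) != TRUTH_COLUMNS:
        raise FormatError(f"unexpected truth table columns: {list(df.columns)}")
    return [
        CellTruth(
            cell_id=int(r.cell_id),
            anchor_id=int(r.anchor_id),
            x_um=float(r.x_um),
            y_um=float(r.y_um),
            diameter_um=float(r.diameter_um),
            is_hp=bool(r.is_hp),
            slope=float(r.slope),
            i0_true=float(r.i0_true),
            is_viable=bool(r.is_viable),
        )
        for r in df.itertuples()
    ]


def write_stack(stack: TimeLapseStack, path: str | Path) -> None:
    """Write a stack as a multi-page TIFF, frame-major then channel, with
    channel order and the time grid recorded in the TIFF description."""
    names = list(stack.channels)
    pages = [
        stack.channels[ch][t]
        for t in range(stack.n_frames)
        for ch in names
    ]
    meta = {
        "channels": names,
        "time_grid_h": list(stack.time_grid_h),
        "pixel_size_um": stack.pixel_size_um,
    }
    tifffile.imwrite(str(path), np.stack(pages), description=json.dumps(meta))


def read_stack(path: str | Path) -> TimeLapseStack:
    with tifffile.TiffFile(str(path)) as tif:
        try:
            meta = json.loads(tif.pages[0].description)
            names = meta["channels"]
            time_grid = tuple(float(t) for t in meta["time_grid_h"])
            pixel_size = float(meta["pixel_size_um"])
        except (KeyError, ValueError, TypeError) as exc:
            raise FormatError(f"malformed stack metadata in {path}") from exc
        pages = tif.asarray()
    n_ch = len(names)
    if pages.shape[0] != n_ch * len(time_grid):
        raise FormatError(
            f"expected {n_ch * len(time_grid)} pages, found {pages.shape[0]}"
        )
    channels = {
        ch: pages[i::n_ch] for i, ch in enumerate(names)
    }
    return TimeLapseStack(
        channels=channels, time_grid_h=time_grid, pixel_size_um=pixel_size
    )
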