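"""Cell detection, size gating, anchor assignment, tracking, viability.

Cells are detected in the CellTracker (red) channel: the frame is globally
thresholded (Otsu by default), connected components are extracted, and
components whose equivalent diameter falls inside the 10-25 um gate
(inclusive at both bounds) are kept as cells.  Each detection is assigned
to the anchor whose disk contains its centroid; detections outside every
anchor are discarded.

Because the cells are immobilized in agarose, tracking reduces to greedy
nearest-centroid matching within each anchor across frames; tracks that
miss more than 10% of frames are dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage import measure
from skimage.filters import threshold_otsu

from .chip_model import ChipLayout
from .errors import InvalidInputError

GATE_MIN_DIAMETER_UM = 10.0
GATE_MAX_DIAMETER_UM = 25.0
DEFAULT_MATCH_RADIUS_UM = 10.0
DEFAULT_MIN_COMPLETENESS = 0.9


@dataclass
class DetectedCell:
    """One gated connected component in one frame."""

    frame: int
    x_um: float
    y_um: float
    area_um2: float
    eq_diameter_um: float
    anchor_id: int
    mask: np.ndarray | None  # (n_pixels, 2) array of (row, col), image coords
    i_cell: float = np.nan  # mask-mean green; filled by kinetics
    i_back: float = np.nan  # anchor-background green; filled by kinetics

    def release_mask(self) -> None:
        """Drop pixel coordinates once intensities have been measured."""
        self.mask = None


def passes_gate(
    eq_diameter_um: float,
    lo: float = GATE_MIN_DIAMETER_UM,
    hi: float = GATE_MAX_DIAMETER_UM,
) -> bool:
    """Size gate on equivalent diameter, inclusive at both bounds."""
    return lo <= eq_diameter_um <= hi


def detect_cells(
    red_frame: np.ndarray,
    layout: ChipLayout,
    pixel_size_um: float = 1.0,
    frame: int = 0,
    threshold: float | None = None,
    gate_um: tuple[float, float] = (GATE_MIN_DIAMETER_UM, GATE_MAX_DIAMETER_UM),
) -> list[DetectedCell]:
    """Detect gated cells in one red-channel frame.

    ``threshold`` overrides the default global Otsu threshold.  A blank or
    saturated frame yields zero detections with a warning rather than an
    error.
    """
    img = np.asarray(red_frame)
    if np.ptp(img) == 0:
        warnings.warn("blank or saturated frame: no detections", stacklevel=2)
        return []
    thr = threshold_otsu(img) if threshold is None else threshold
    binary = img > thr
    fg_fraction = binary.mean()
    if fg_fraction == 0 or fg_fraction > 0.5:
        warnings.warn(
            f"degenerate threshold (foreground fraction {fg_fraction:.2f}): "
            "no detections",
            stacklevel=2,
        )
        return []
    labels = measure.label(binary, connectivity=2)
    detections: list[DetectedCell] = []
    for region in measure.regionprops(labels):
        eq_diam = region.equivalent_diameter_area * pixel_size_um
        if not passes_gate(eq_diam, *gate_um):
            continue
        cy, cx = region.centroid  # (row, col) in pixels
        x_um = (cx + 0.5) * pixel_size_um
        y_um = (cy + 0.5) * pixel_size_um
        anchor = layout.anchor_of(x_um, y_um)
        if anchor is None:
            continue
        detections.append(
            DetectedCell(
                frame=frame,
                x_um=x_um,
                y_um=y_um,
                area_um2=region.area * pixel_size_um**2,
                eq_diameter_um=eq_diam,
                anchor_id=anchor,
                mask=region.coords,
            )
        )
    return detections


@dataclass
class CellTrack:
    """One cell followed across frames within a single anchor."""

    track_id: int
    anchor_id: int
    detections: dict[int, DetectedCell]  # frame -> detection
    n_frames: int

    @property
    def completeness(self) -> float:
        return len(self.detections) / self.n_frames

    @property
    def centroid_um(self) -> tuple[float, float]:
        xs = [d.x_um for d in self.detections.values()]
        ys = [d.y_um for d in self.detections.values()]
        return float(np.mean(xs)), float(np.mean(ys))


def track_cells(
    detections_per_frame: list[list[DetectedCell]],
    match_radius_um: float = DEFAULT_MATCH_RADIUS_UM,
    min_completeness: float = DEFAULT_MIN_COMPLETENESS,
) -> list[CellTrack]:
    """Greedy nearest-centroid tracking within anchors.

    For each frame, detections are matched to existing tracks in the same
    anchor in order of increasing distance (ties broken by smallest track
    id); matches beyond ``match_radius_um`` start new tracks.  Tracks seen
    in fewer than ``min_completeness`` of frames are discarded.
    """
    if not detections_per_frame:
        raise InvalidInputError("need at least one frame of detections")
    n_frames = len(detections_per_frame)
    tracks: list[CellTrack] = []
    # last known position per open track
    last_pos: dict[int, tuple[float, float]] = {}
    for frame_idx, dets in enumerate(detections_per_frame):
        by_anchor: dict[int, list[DetectedCell]] = {}
        for d in dets:
            by_anchor.setdefault(d.anchor_id, []).append(d)
        for anchor_id, anchor_dets in by_anchor.items():
            candidates = [
                t for t in tracks
                if t.anchor_id == anchor_id and frame_idx not in t.detections
            ]
            # all (distance, track, detection) pairs within radius
            pairs = []
            for det in anchor_dets:
                for t in candidates:
                    lx, ly = last_pos[t.track_id]
                    dist = float(np.hypot(det.x_um - lx, det.y_um - ly))
                    if dist <= match_radius_um:
                        pairs.append((dist, t.track_id, t, det))
            pairs.sort(key=lambda p: (p[0], p[1]))
            used_tracks: set[int] = set()
            used_dets: set[int] = set()
            for dist, tid, t, det in pairs:
                if tid in used_tracks or id(det) in used_dets:
                    continue
                t.detections[frame_idx] = det
                last_pos[tid] = (det.x_um, det.y_um)
                used_tracks.add(tid)
                used_dets.add(id(det))
            for det in anchor_dets:
                if id(det) in used_dets:
                    continue
                tid = len(tracks)
                tracks.append(
                    CellTrack(
                        track_id=tid,
                        anchor_id=anchor_id,
                        detections={frame_idx: det},
                        n_frames=n_frames,
                    )
                )
                last_pos[tid] = (det.x_um, det.y_um)
    kept = [t for t in tracks if t.completeness >= min_completeness]
    for new_id, t in enumerate(kept):
        t.track_id = new_id
    return kept


def score_viability(
    dead_frame: np.ndarray,
    detections: list[DetectedCell],
    sigma_factor: float = 3.0,
) -> tuple[float, list[bool]]:
    """Classify each detection live/dead from the dead-stain channel.

    A cell is dead when its mask-mean dead-channel signal exceeds the
    background mean + ``sigma_factor`` x background SD, the background being
    all pixels outside every detection mask.  Returns (viable_fraction,
    per-cell viability flags); the fraction is NaN when there are no
    detections.
    """
    img = np.asarray(dead_frame, dtype=float)
    if not detections:
        return float("nan"), []
    bg_mask = np.ones(img.shape, dtype=bool)
    for det in detections:
        if det.mask is None:
            raise InvalidInputError("detections must retain pixel masks")
        bg_mask[det.mask[:, 0], det.mask[:, 1]] = False
    bg = img[bg_mask]
    cutoff = bg.mean() + sigma_factor * bg.std()
    flags = []
    for det in detections:
        signal = img[det.mask[:, 0], det.mask[:, 1]].mean()
        flags.append(bool(signal <= cutoff))
    return float(np.mean(flags)), flags
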