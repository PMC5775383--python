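"""Anchor-array layout and Poisson cell-loading statistics.

The culture chip is a shallow chamber patterned with a rectangular grid of
capillary "anchors" — locally deepened wells that each trap one ~2 nL
aqueous droplet.  Cells suspended in the aqueous phase are captured at
random, so the number of cells per droplet is Poisson distributed; under
the experimental loading density (lambda ~ 0.45 cells/droplet) about 30%
of droplets hold exactly one cell, and only those enter single-cell
analysis.

Coordinates are in micrometres, origin at the image top-left; anchors are
indexed row-major from 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .errors import InvalidGeometryError, InvalidInputError

# Default geometry. 1495 anchors = 65 x 23; the anchor radius realizes a
# 2 nL cylinder at the chip's 135 um total depth (pi r^2 x 135 um ~ 2e6 um^3).
DEFAULT_ROWS = 65
DEFAULT_COLS = 23
DEFAULT_PITCH_UM = 200.0
DEFAULT_ANCHOR_RADIUS_UM = 68.7
DEFAULT_DROPLET_VOLUME_NL = 2.0
DEFAULT_LAMBDA = 0.45


@dataclass(frozen=True)
class ChipLayout:
    """Geometry of the anchor array."""

    rows: int
    cols: int
    pitch_um: float
    anchor_radius_um: float
    droplet_volume_nl: float
    centers_um: np.ndarray  # (n_anchors, 2) as (x, y)
    fov_um: tuple[float, float]  # (width, height)

    @property
    def n_anchors(self) -> int:
        return self.rows * self.cols

    def anchor_of(self, x_um: float, y_um: float) -> int | None:
        """Anchor index whose disk contains (x, y), or None."""
        col = int(round((x_um - self.pitch_um / 2) / self.pitch_um))
        row = int(round((y_um - self.pitch_um / 2) / self.pitch_um))
        if not (0 <= row < self.rows and 0 <= col < self.cols):
            return None
        idx = row * self.cols + col
        cx, cy = self.centers_um[idx]
        if (x_um - cx) ** 2 + (y_um - cy) ** 2 <= self.anchor_radius_um**2:
            return idx
        return None

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "rows": self.rows,
            "cols": self.cols,
            "pitch_um": self.pitch_um,
            "anchor_radius_um": self.anchor_radius_um,
            "droplet_volume_nl": self.droplet_volume_nl,
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ChipLayout":
        payload = yaml.safe_load(Path(path).read_text())
        return build_layout(**payload)


def build_layout(
    rows: int = DEFAULT_ROWS,
    cols: int = DEFAULT_COLS,
    pitch_um: float = DEFAULT_PITCH_UM,
    anchor_radius_um: float = DEFAULT_ANCHOR_RADIUS_UM,
    droplet_volume_nl: float = DEFAULT_DROPLET_VOLUME_NL,
) -> ChipLayout:
    """Build a rectangular anchor grid; the default preset realizes the
    1495-anchor chip."""
    if rows < 1 or cols < 1:
        raise InvalidInputError("rows and cols must be >= 1")
    if droplet_volume_nl <= 0:
        raise InvalidInputError("droplet volume must be > 0")
    if pitch_um <= 2 * anchor_radius_um:
        raise InvalidGeometryError(
            f"pitch {pitch_um} um would overlap anchors of radius "
            f"{anchor_radius_um} um"
        )
    jj, ii = np.meshgrid(np.arange(cols), np.arange(rows))
    centers = np.column_stack(
        [
            pitch_um / 2 + jj.ravel() * pitch_um,
            pitch_um / 2 + ii.ravel() * pitch_um,
        ]
    ).astype(float)
    fov = (cols * pitch_um, rows * pitch_um)
    return ChipLayout(
        rows=rows,
        cols=cols,
        pitch_um=pitch_um,
        anchor_radius_um=anchor_radius_um,
        droplet_volume_nl=droplet_volume_nl,
        centers_um=centers,
        fov_um=fov,
    )


@dataclass
class OccupancyTable:
    """Per-anchor cell counts plus the fitted Poisson mean."""

    counts: np.ndarray  # (n_anchors,) int
    lambda_hat: float | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.ndim != 1:
            raise InvalidInputError("counts must be one-dimensional")
        if (self.counts < 0).any():
            raise InvalidInputError("counts must be >= 0")

    @property
    def n_anchors(self) -> int:
        return self.counts.size

    def histogram(self) -> np.ndarray:
        """Count-of-counts: histogram()[k] = number of anchors with k cells."""
        return np.bincount(self.counts)

    def to_csv(self, path: str | Path, layout: ChipLayout) -> None:
        df = pd.DataFrame(
            {
                "anchor_id": np.arange(self.n_anchors),
                "row": np.arange(self.n_anchors) // layout.cols,
                "col": np.arange(self.n_anchors) % layout.cols,
                "x_um": layout.centers_um[:, 0],
                "y_um": layout.centers_um[:, 1],
                "n_cells": self.counts,
            }
        )
        df.to_csv(path, index=False)


def poisson_load(
    layout: ChipLayout, lam: float, seed: int | np.random.Generator
) -> OccupancyTable:
    """Load the chip at mean occupancy ``lam`` cells/droplet (i.i.d. Poisson)."""
    if lam < 0:
        raise InvalidInputError("lambda must be >= 0")
    rng = np.random.default_rng(seed)
    counts = rng.poisson(lam, size=layout.n_anchors)
    return OccupancyTable(counts=counts)


def fit_poisson(table: OccupancyTable) -> tuple[float, np.ndarray]:
    """Poisson maximum-likelihood fit of an occupancy table.

    Returns (lambda_hat, pmf) where lambda_hat is the sample mean (the
    Poisson MLE) and pmf is the fitted probability mass over the observed
    support 0..max(count), normalized over that support.
    """
    if table.n_anchors < 1:
        raise InvalidInputError("empty occupancy table")
    lam = float(table.counts.mean())
    support = np.arange(table.counts.max() + 1)
    pmf = stats.poisson.pmf(support, lam)
    pmf = pmf / pmf.sum()
    table.lambda_hat = lam
    return lam, pmf


def occupancy_probability(lam: float, k: int) -> float:
    """P(exactly k cells in a droplet) under Poisson(lambda)."""
    if lam < 0:
        raise InvalidInputError("lambda must be >= 0")
    if not float(k).is_integer() or k < 0:
        raise InvalidInputError("k must be a non-negative integer")
    return float(stats.poisson.pmf(int(k), lam))


def select_single_cell_droplets(counts: OccupancyTable | np.ndarray) -> np.ndarray:
    """Anchor ids (0-based) of droplets containing exactly one cell."""
    arr = counts.counts if isinstance(counts, OccupancyTable) else np.asarray(counts)
    return np.flatnonzero(arr == 1)
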