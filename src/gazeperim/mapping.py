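"""Back-projection of binarized time series into retinotopic field maps.

Every sample carries a retinotopic coordinate (s - p); flags accumulate into
an N x M grid of 1-degree cells (integer-degree edges).  A cell's value is
the fraction of its samples flagged as loss; cells with too few samples are
unsampled (NaN).  The same machinery produces TFCE, RNN and ground-truth
maps so they are spatially comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence, Tuple

import numpy as np

from .errors import ConfigError, MalformedRecordError
from .observer import TrackingRecord


@dataclass(frozen=True)
class GridSpec:
    """Retinotopic grid: integer-degree cell edges, origin at the fovea."""

    x_halfwidth: float = 24.0
    y_halfwidth: float = 14.0   # field half-height 13.5 rounded out to keep integer edges
    cell_size: float = 1.0
    min_count: int = 1
    flip_sign: bool = False     # use (p - s) instead of (s - p)

    def __post_init__(self) -> None:
        if self.cell_size <= 0 or self.x_halfwidth <= 0 or self.y_halfwidth <= 0:
            raise ConfigError("grid extents and cell size must be positive")
        if self.min_count < 1:
            raise ConfigError("min_count must be >= 1")

    @property
    def nx(self) -> int:
        return int(round(2 * self.x_halfwidth / self.cell_size))

    @property
    def ny(self) -> int:
        return int(round(2 * self.y_halfwidth / self.cell_size))

    @property
    def n_cells(self) -> int:
        return self.nx * self.ny

    def cell_centers(self) -> Tuple[np.ndarray, np.ndarray]:
        """(x_centers[nx], y_centers[ny]) in degrees."""
        xs = -self.x_halfwidth + self.cell_size * (np.arange(self.nx) + 0.5)
        ys = -self.y_halfwidth + self.cell_size * (np.arange(self.ny) + 0.5)
        return xs, ys


@dataclass
class VisualFieldMap:
    """Per-cell loss probability (NaN where unsampled) plus sample counts."""

    grid_spec: GridSpec
    flagged: np.ndarray      # (ny, nx) int, flagged samples per cell
    counts: np.ndarray       # (ny, nx) int, total samples per cell
    dropped: int = 0         # samples outside the grid extent

    @property
    def sampled_mask(self) -> np.ndarray:
        return self.counts >= self.grid_spec.min_count

    @property
    def grid(self) -> np.ndarray:
        """Loss probability per cell; NaN where unsampled."""
        with np.errstate(invalid="ignore", divide="ignore"):
            g = self.flagged / self.counts
        g = np.where(self.sampled_mask, g, np.nan)
        return g


def retinotopic_coords(record: TrackingRecord, spec: GridSpec) -> Tuple[np.ndarray, np.ndarray]:
    """Per-sample retinotopic coordinates (B_x, B_y) = (s - p) (or flipped)."""
    rx = np.asarray(record.s_x) - np.asarray(record.p_x)
    ry = np.asarray(record.s_y) - np.asarray(record.p_y)
    if spec.flip_sign:
        rx, ry = -rx, -ry
    return rx, ry


def backproject_coords(
    flags: np.ndarray,
    rx: np.ndarray,
    ry: np.ndarray,
    spec: GridSpec = GridSpec(),
) -> VisualFieldMap:
    """Accumulate flags at retinotopic coordinates into a field map."""
    flags = np.asarray(flags)
    if not (len(flags) == len(rx) == len(ry)):
        raise MalformedRecordError(
            f"flags ({len(flags)}) and coordinates ({len(rx)}, {len(ry)}) misaligned"
        )
    ix = np.floor((rx + spec.x_halfwidth) / spec.cell_size).astype(int)
    iy = np.floor((ry + spec.y_halfwidth) / spec.cell_size).astype(int)
    inside = (ix >= 0) & (ix < spec.nx) & (iy >= 0) & (iy < spec.ny)
    dropped = int(len(flags) - inside.sum())
    lin = iy[inside] * spec.nx + ix[inside]
    counts = np.bincount(lin, minlength=spec.n_cells).reshape(spec.ny, spec.nx)
    flagged = np.bincount(lin, weights=flags[inside].astype(float),
                          minlength=spec.n_cells).reshape(spec.ny, spec.nx)
    return VisualFieldMap(grid_spec=spec, flagged=flagged.astype(int),
                          counts=counts, dropped=dropped)


def backproject(flags, record: TrackingRecord, spec: GridSpec = GridSpec()) -> VisualFieldMap:
    """Back-project one record's flags (BinarySeries or array) into a map."""
    from .tfce import BinarySeries  # local import: avoids a module cycle

    values = flags.flags if isinstance(flags, BinarySeries) else flags
    rx, ry = retinotopic_coords(record, spec)
    return backproject_coords(np.asarray(values), rx, ry, spec)


def merge_maps(maps: Iterable[VisualFieldMap]) -> VisualFieldMap:
    """Cell-wise accumulation of several maps on the same grid."""
    maps = list(maps)
    if not maps:
        raise ConfigError("no maps to merge")
    spec = maps[0].grid_spec
    if any(m.grid_spec != spec for m in maps):
        raise ConfigError("cannot merge maps with different grid specs")
    return VisualFieldMap(
        grid_spec=spec,
        flagged=sum(m.flagged for m in maps),
        counts=sum(m.counts for m in maps),
        dropped=sum(m.dropped for m in maps),
    )


def ground_truth_map(
    records: Sequence[TrackingRecord] | TrackingRecord,
    spec: GridSpec = GridSpec(),
) -> VisualFieldMap:
    """Back-project the a-priori occlusion flags of one or more records."""
    if isinstance(records, TrackingRecord):
        records = [records]
    return merge_maps(backproject(r.occluded, r, spec) for r in records)


def mean_deviation(vfmap: VisualFieldMap) -> float:
    """Coverage-corrected mean loss probability: sum over sampled cells of
    the cell value, divided by the total number of grid cells."""
    n = vfmap.grid_spec.n_cells
    if n == 0:
        raise ConfigError("empty grid")
    g = vfmap.grid
    total = np.nansum(g[vfmap.sampled_mask])
    return float(total / n)
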