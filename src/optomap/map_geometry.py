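"""Density maps on a fixed grid, watershed regions, and region distances.

All downstream statistics (trial densities, significance maps, entropy
curves, MI conditionals) live on one square grid spanning the padded
bounding box of the training embedding (default 210 x 210 cells, matching
the arbitrary-unit map size used for the published videos). Watershed
basins of the negated smoothed density define the map's regions; the
5-pixel mode-assignment rule for trials uses Euclidean distances to region
edges computed on this grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.segmentation import watershed as _watershed

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class MapGrid:
    """Square analysis grid over the behavior map."""

    x_min: float
    x_max: float
    y_min: float
    y_max: float
    resolution: int = 210

    @classmethod
    def from_points(cls, points: np.ndarray, resolution: int = 210,
                    pad: float = 0.10) -> "MapGrid":
        pts = points[np.all(np.isfinite(points), axis=1)]
        lo = pts.min(axis=0)
        hi = pts.max(axis=0)
        span = np.maximum(hi - lo, 1e-9)
        lo = lo - pad * span
        hi = hi + pad * span
        return cls(x_min=float(lo[0]), x_max=float(hi[0]),
                   y_min=float(lo[1]), y_max=float(hi[1]), resolution=resolution)

    @property
    def n_cells(self) -> int:
        return self.resolution ** 2

    def cell_indices(self, points: np.ndarray) -> np.ndarray:
        """(ix, iy) integer cell coordinates for each point, clipped to the grid."""
        pts = np.atleast_2d(points)
        fx = (pts[:, 0] - self.x_min) / (self.x_max - self.x_min)
        fy = (pts[:, 1] - self.y_min) / (self.y_max - self.y_min)
        ix = np.clip((fx * self.resolution).astype(int), 0, self.resolution - 1)
        iy = np.clip((fy * self.resolution).astype(int), 0, self.resolution - 1)
        return np.column_stack([ix, iy])

    def histogram(self, points: np.ndarray) -> np.ndarray:
        """Raw occupancy counts on the grid (rows index x, columns y)."""
        if len(points) == 0:
            return np.zeros((self.resolution, self.resolution))
        idx = self.cell_indices(points)
        H = np.zeros((self.resolution, self.resolution))
        np.add.at(H, (idx[:, 0], idx[:, 1]), 1.0)
        return H


@dataclass
class DensityMap:
    """Normalized, Gaussian-smoothed occupancy density p(x, y)."""

    values: np.ndarray
    grid: MapGrid
    sigma: float
    n_points: int

    @property
    def empty(self) -> bool:
        return self.n_points == 0


def smooth_and_normalize(counts: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian-smooth a histogram and renormalize to unit mass."""
    out = ndimage.gaussian_filter(counts, sigma, mode="constant")
    total = out.sum()
    if total > 0:
        out = out / total
    return out


def density_map(points: np.ndarray, grid: MapGrid, sigma: float = 1.5) -> DensityMap:
    """Histogram the points, convolve with an isotropic Gaussian, renormalize."""
    pts = np.atleast_2d(points) if len(points) else np.empty((0, 2))
    pts = pts[np.all(np.isfinite(pts), axis=1)] if len(pts) else pts
    counts = grid.histogram(pts)
    n = int(counts.sum())
    if n == 0:
        log.warning("density_map called with zero valid points")
        return DensityMap(values=counts, grid=grid, sigma=sigma, n_points=0)
    return DensityMap(values=smooth_and_normalize(counts, sigma), grid=grid,
                      sigma=sigma, n_points=n)


@dataclass
class RegionSet:
    """Watershed regionization of the map: 0 = background, 1..m = regions."""

    labels: np.ndarray            # (res, res) int
    grid: MapGrid
    names: dict = field(default_factory=dict)  # optional label -> name overrides

    @property
    def region_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    def mask(self, region_id: int) -> np.ndarray:
        return self.labels == region_id

    def apply_overrides(self, overrides: dict) -> "RegionSet":
        """Apply a human-curation file: {"names": {id: name}, "merge": [[a, b], ...]}."""
        labels = self.labels.copy()
        for group in overrides.get("merge", []):
            keep = int(group[0])
            for other in group[1:]:
                labels[labels == int(other)] = keep
        names = {int(k): v for k, v in overrides.get("names", {}).items()}
        return RegionSet(labels=labels, grid=self.grid, names=names)


def watershed_regions(density: DensityMap, min_density_quantile: float = 0.35,
                      min_peak_distance: int = 3) -> RegionSet:
    """Watershed of the negated smoothed density, seeded at its local maxima.

    Cells whose density falls below the given quantile of the positive
    density values become background; every above-threshold cell belongs to
    exactly one connected basin.
    """
    vals = density.values
    pos = vals[vals > 0]
    if pos.size == 0 or np.ptp(vals) < 1e-15:
        log.warning("flat density map: returning a single region")
        return RegionSet(labels=np.ones_like(vals, dtype=int), grid=density.grid)
    thresh = np.quantile(pos, min_density_quantile)
    mask = vals >= thresh
    peaks = peak_local_max(vals, min_distance=min_peak_distance, labels=mask,
                           exclude_border=False)
    markers = np.zeros_like(vals, dtype=int)
    for i, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = i
    if markers.max() == 0:
        return RegionSet(labels=mask.astype(int), grid=density.grid)
    labels = _watershed(-vals, markers=markers, mask=mask)
    return RegionSet(labels=labels, grid=density.grid)


def region_distance_transform(regions: RegionSet, region_id: int) -> np.ndarray:
    """Euclidean distance (grid pixels) from every cell to the region's nearest cell."""
    mask = regions.mask(region_id)
    if not mask.any():
        return np.full(mask.shape, np.inf)
    return ndimage.distance_transform_edt(~mask)


def distance_to_region(point_cell: tuple[int, int], region_id: int,
                       regions: RegionSet,
                       _cache: dict | None = None) -> float:
    """Distance in pixels from a grid cell to a region (0 if inside)."""
    if _cache is not None and region_id in _cache:
        dt = _cache[region_id]
    else:
        dt = region_distance_transform(regions, region_id)
        if _cache is not None:
            _cache[region_id] = dt
    return float(dt[point_cell[0], point_cell[1]])
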