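"""Gaussian-smoothed 3-D density maps built from localization clusters.

A segment's point cloud is binned onto a cubic grid (each localization
increments its nearest voxel by 1) and convolved with an isotropic
unit-mass Gaussian whose width matches the mean localization precision,
so voxel intensities stay on a localizations-per-voxel scale. The body
of the map — the set of voxels used for all geometric measurements — is
defined by an iso-contour threshold placed one standard deviation of the
background population above the background mode.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError

DEFAULT_VOXEL_SIZE_NM = 25.0
#: grid padding around the cloud, in units of sigma
DEFAULT_PADDING_SIGMA = 5.0


class DegenerateGeometryError(ValueError):
    """Too few / degenerate points for a 3-D geometric measurement."""


@dataclass
class DensityMap:
    """A 3-D intensity grid with physical origin and voxel size.

    data is indexed [ix, iy, iz]; voxel (i, j, k) is centred at
    origin + (i+.5, j+.5, k+.5) * voxel_size.
    """

    data: np.ndarray
    origin: np.ndarray
    voxel_size: float
    sigma: float | None = None
    iso_threshold: float | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("density grid must be 3-D")
        if self.voxel_size <= 0:
            raise ValueError("voxel size must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def voxel_centers(self, mask: np.ndarray | None = None) -> np.ndarray:
        """Physical centres (nm) of all voxels, or of those where mask is True."""
        if mask is None:
            mask = np.ones(self.shape, dtype=bool)
        idx = np.argwhere(mask)
        return self.origin + (idx + 0.5) * self.voxel_size

    def body_mask(self, threshold: float | None = None) -> np.ndarray:
        thr = self.iso_threshold if threshold is None else threshold
        if thr is None:
            raise ValueError("iso_threshold not set")
        return self.data >= thr

    def center_of_mass(self, threshold: float | None = None) -> np.ndarray:
        """Intensity-weighted centre of mass (nm) over the body voxels."""
        mask = self.body_mask(threshold) if (threshold is not None or
                                             self.iso_threshold is not None) \
            else self.data > 0
        w = np.where(mask, self.data, 0.0)
        total = w.sum()
        if total <= 0:
            raise DegenerateGeometryError("empty map body")
        com_idx = np.array(ndimage.center_of_mass(w))
        return self.origin + (com_idx + 0.5) * self.voxel_size

    def with_threshold(self) -> "DensityMap":
        return replace(self, iso_threshold=iso_threshold(self))


# ---------------------------------------------------------------------------
# construction


def rasterize(
    coords: np.ndarray,
    voxel_size: float = DEFAULT_VOXEL_SIZE_NM,
    padding: float | None = None,
    origin: np.ndarray | None = None,
    shape: tuple[int, int, int] | None = None,
) -> DensityMap:
    """Bin a point cloud onto a count grid (nearest voxel += 1 per point).

    With origin/shape omitted, the grid covers the cloud's bounding box
    plus ``padding`` nm on every side. The grid total always equals the
    number of points (points outside an explicit grid would be dropped;
    none are when the grid is auto-sized).
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    if coords.size == 0:
        raise ValueError("cannot rasterize an empty cluster")
    if voxel_size <= 0:
        raise ValueError("voxel size must be positive")
    if padding is None:
        padding = 2 * voxel_size
    if origin is None:
        origin = coords.min(axis=0) - padding
    origin = np.asarray(origin, dtype=float)
    if shape is None:
        upper = coords.max(axis=0) + padding
        shape = tuple(np.maximum(np.ceil((upper - origin) / voxel_size).astype(int), 1))
    idx = np.floor((coords - origin) / voxel_size).astype(int)
    keep = np.all((idx >= 0) & (idx < np.array(shape)), axis=1)
    idx = idx[keep]
    grid = np.zeros(shape, dtype=float)
    np.add.at(grid, (idx[:, 0], idx[:, 1], idx[:, 2]), 1.0)
    return DensityMap(grid, origin, voxel_size)


def convolve_gaussian(counts: DensityMap, sigma: float) -> DensityMap:
    """Smooth a count grid with a unit-mass isotropic 3-D Gaussian.

    sigma is in nm; with the unit-mass kernel the total intensity equals
    the localization count up to boundary truncation, so densities are
    comparable across maps.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    smoothed = ndimage.gaussian_filter(
        counts.data, sigma=sigma / counts.voxel_size, mode="constant", truncate=4.0)
    return DensityMap(smoothed, counts.origin.copy(), counts.voxel_size, sigma=sigma)


def cluster_sigma(precisions_lat: np.ndarray, precisions_ax: np.ndarray,
                  scale: float = 1.0) -> float:
    """Kernel width from the pooled mean localization precision (nm)."""
    pooled = np.concatenate([np.ravel(precisions_lat), np.ravel(precisions_ax)])
    return scale * float(np.mean(pooled))


def build_map(
    coords: np.ndarray,
    sigma: float,
    voxel_size: float = DEFAULT_VOXEL_SIZE_NM,
    padding: float | None = None,
    origin: np.ndarray | None = None,
    shape: tuple[int, int, int] | None = None,
    set_threshold: bool = True,
) -> DensityMap:
    """Rasterize + convolve + (optionally) set the iso-contour threshold."""
    if padding is None and origin is None:
        padding = DEFAULT_PADDING_SIGMA * sigma
    m = rasterize(coords, voxel_size, padding, origin, shape)
    m = convolve_gaussian(m, sigma)
    if set_threshold:
        m = replace(m, iso_threshold=iso_threshold(m))
    return m


# ---------------------------------------------------------------------------
# threshold


def iso_threshold(m: DensityMap) -> float:
    """One-sigma-above-background iso-contour threshold.

    The background mode of the voxel-intensity histogram
    (Freedman-Diaconis bins) is shifted to zero; the threshold is the
    standard deviation of the sub-mode (background) population, on the
    shifted scale — i.e. mode + background sigma on the raw scale.
    """
    vals = m.data.ravel()
    if np.ptp(vals) == 0:
        raise ValueError("constant map has no background peak")
    q75, q25 = np.percentile(vals, [75, 25])
    iqr = q75 - q25
    if iqr > 0:
        width = 2 * iqr / len(vals) ** (1 / 3)
        nbins = max(int(np.ceil(np.ptp(vals) / width)), 10)
    else:
        nbins = 100
    nbins = min(nbins, 100_000)
    hist, edges = np.histogram(vals, bins=nbins)
    # smooth before locating the peak: with fine bins the raw argmax
    # fluctuates by several bin widths and biases the background split
    if len(hist) >= 5:
        kernel = np.ones(5) / 5.0
        hist = np.convolve(hist, kernel, mode="same")
    imax = int(np.argmax(hist))
    mode = 0.5 * (edges[imax] + edges[imax + 1])
    below = vals[vals <= mode] - mode
    if len(below) < 2:
        sigma_bg = 0.0
    else:
        # background assumed symmetric about the mode; reflect the lower tail
        sigma_bg = float(np.sqrt(np.mean(below ** 2)))
    return mode + sigma_bg


# ---------------------------------------------------------------------------
# geometry


def surface_area(m: DensityMap, threshold: float | None = None) -> float:
    """Convex-hull surface area (nm^2) over above-threshold voxel centres."""
    mask = m.body_mask(threshold)
    pts = m.voxel_centers(mask)
    return hull_area(pts)


def hull_area(points: np.ndarray) -> float:
    """Sum of the triangle areas on the convex hull of a 3-D point set."""
    points = np.asarray(points, dtype=float)
    if len(points) < 4:
        raise DegenerateGeometryError("convex hull needs >= 4 points")
    try:
        hull = ConvexHull(points)
    except QhullError as e:
        raise DegenerateGeometryError(f"degenerate point set: {e}") from e
    return float(hull.area)


def body_volume(m: DensityMap, threshold: float | None = None) -> float:
    """Body volume (nm^3): above-threshold voxel count x voxel_size^3."""
    mask = m.body_mask(threshold)
    return float(mask.sum()) * m.voxel_size ** 3


# ---------------------------------------------------------------------------
# grid alignment


def common_frame(maps: list[DensityMap]) -> list[DensityMap]:
    """Re-embed maps (sharing one voxel size) onto a single enclosing grid.

    Maps built with the same voxel size but different origins are padded
    with zeros into one grid frame so voxel-wise comparisons (overlap,
    correlation) are meaningful. Origins must differ by integer numbers
    of voxels up to rounding; sub-voxel offsets are rounded.
    """
    v = maps[0].voxel_size
    if any(abs(m.voxel_size - v) > 1e-9 for m in maps):
        raise ValueError("maps must share a voxel size")
    lo = np.min([m.origin for m in maps], axis=0)
    hi = np.max([m.origin + np.array(m.shape) * v for m in maps], axis=0)
    shape = tuple(np.ceil((hi - lo) / v - 1e-9).astype(int))
    out = []
    for m in maps:
        off = np.round((m.origin - lo) / v).astype(int)
        grid = np.zeros(shape)
        sl = tuple(slice(o, o + s) for o, s in zip(off, m.shape))
        grid[sl] = m.data
        out.append(DensityMap(grid, lo.copy(), v, sigma=m.sigma,
                              iso_threshold=m.iso_threshold))
    return out
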