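"""Filtering, merging, drift correction and clustering of single-molecule localizations.

Localization tables are pandas DataFrames with the canonical columns

    x_nm, y_nm, z_nm, frame, psf_photons, cutout_photons, z_offset_nm,
    lat_prec_nm, ax_prec_nm, round

(one row per detected emission event, coordinates and precisions in nm).
The processing chain mirrors a typical 3-D STORM pipeline for oligo-FISH
walks: a geometric-mean goodness-of-fit filter on three per-event quality
metrics, collapse of repeated detections of one blinking event across
consecutive frames, rejection of events with poor axial precision,
fiducial-based drift correction, and DBSCAN segmentation of the surviving
events into per-segment point clouds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import DBSCAN

LOC_COLUMNS = [
    "x_nm", "y_nm", "z_nm", "frame", "psf_photons", "cutout_photons",
    "z_offset_nm", "lat_prec_nm", "ax_prec_nm", "round",
]

#: events below this goodness-of-fit rank are rejected
QUALITY_RANK_THRESHOLD = 0.8
#: events with axial precision worse than this (nm) are rejected
MAX_AXIAL_PRECISION_NM = 100.0
#: camera pixel size used by the repeat-merging rule (nm)
DEFAULT_PIXEL_SIZE_NM = 100.0
#: maximum frame span of a merged blinking event
MERGE_MAX_FRAME_SPAN = 7
#: maximum lateral excursion (pixels) within a merged event
MERGE_MAX_PIXELS = 2.0
#: DBSCAN neighbourhood radius (nm)
DEFAULT_CLUSTER_EPS_NM = 150.0
DEFAULT_CLUSTER_MIN_POINTS = 10


class InvalidMetricError(ValueError):
    """A quality metric fell outside the normalized [0, 1] range."""


@dataclass
class FiducialTrack:
    """Per-frame trajectory of one fiducial marker.

    positions has shape (n_frames, 3) in nm; entries where ``valid`` is
    False are ignored (marker not detected in that frame).
    """

    marker_id: str
    frames: np.ndarray
    positions: np.ndarray
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=int)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.valid is None:
            self.valid = np.ones(len(self.frames), dtype=bool)
        self.valid = np.asarray(self.valid, dtype=bool)
        if not self.valid.any():
            raise ValueError(f"fiducial {self.marker_id} has no valid frames")
        if not np.isfinite(self.positions[self.valid]).all():
            raise ValueError(f"fiducial {self.marker_id} has non-finite positions")


@dataclass
class LocalizationCluster:
    """A DBSCAN-extracted cloud of localizations for one genomic segment."""

    events: pd.DataFrame
    label: int
    segment_id: str | None = None
    is_noise: bool = False

    def __post_init__(self):
        if not self.is_noise and len(self.events) == 0:
            raise ValueError("non-noise cluster must have members")

    def __len__(self) -> int:
        return len(self.events)

    @property
    def coords(self) -> np.ndarray:
        return self.events[["x_nm", "y_nm", "z_nm"]].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# quality filter


def rank_normalize(values: np.ndarray, invert: bool = False) -> np.ndarray:
    """Min-max scale the ranks of ``values`` onto [0, 1].

    Rank scaling makes the three raw quality metrics (a photon ratio, a
    photon count, and an axial offset in nm) commensurate regardless of
    units. ``invert=True`` is for metrics where smaller raw values mean
    higher quality (the axial offset).
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n == 0:
        return np.empty(0)
    if n == 1:
        return np.ones(1)
    order = np.argsort(values, kind="stable")
    ranks = np.empty(n, dtype=float)
    ranks[order] = np.arange(n)
    scaled = ranks / (n - 1)
    return 1.0 - scaled if invert else scaled


def score_quality(m1, m2, m3):
    """Geometric mean of three normalized quality metrics.

    Each metric must already be self-normalized to [0, 1]; the returned
    rank is ``(m1*m2*m3)**(1/3)``. Events with rank below
    :data:`QUALITY_RANK_THRESHOLD` are rejected downstream.
    """
    m1, m2, m3 = (np.asarray(m, dtype=float) for m in (m1, m2, m3))
    for i, m in enumerate((m1, m2, m3), start=1):
        if np.any((m < 0) | (m > 1) | ~np.isfinite(m)):
            raise InvalidMetricError(f"metric {i} outside [0, 1]")
    return np.cbrt(m1 * m2 * m3)


def filter_quality(locs: pd.DataFrame, threshold: float = QUALITY_RANK_THRESHOLD) -> pd.DataFrame:
    """Apply the three-metric goodness-of-fit filter to a localization table.

    Metrics: (1) psf_photons / cutout_photons, (2) cutout_photons,
    (3) |z_offset| (inverted — smaller is better). Each is rank-normalized
    over the table before the geometric mean is taken.
    """
    if len(locs) == 0:
        return locs.copy()
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(
            locs["cutout_photons"].to_numpy() > 0,
            locs["psf_photons"].to_numpy() / locs["cutout_photons"].to_numpy(),
            0.0,
        )
    m1 = rank_normalize(ratio)
    m2 = rank_normalize(locs["cutout_photons"].to_numpy())
    m3 = rank_normalize(np.abs(locs["z_offset_nm"].to_numpy()), invert=True)
    rank = score_quality(m1, m2, m3)
    out = locs.loc[rank >= threshold].copy()
    out["quality_rank"] = rank[rank >= threshold]
    return out


# ---------------------------------------------------------------------------
# repeat merging


def merge_repeats(locs: pd.DataFrame, pixel_size: float = DEFAULT_PIXEL_SIZE_NM) -> pd.DataFrame:
    """Collapse repeated detections of a single blinking event.

    Runs of events in consecutive frames (no gap > 1 frame, total span
    <= 7 frames) whose lateral positions stay within 2 pixels of the run
    start are merged into one event at the precision-weighted mean
    position; photon counts are summed, precisions combined as
    1/sqrt(sum(1/s^2)).
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    if len(locs) == 0:
        return locs.copy()
    frames = locs["frame"].to_numpy()
    if np.any(np.diff(frames) < 0):
        raise ValueError("localizations must be sorted by frame")

    max_dist = MERGE_MAX_PIXELS * pixel_size
    x = locs["x_nm"].to_numpy()
    y = locs["y_nm"].to_numpy()

    groups = np.full(len(locs), -1, dtype=int)
    n_groups = 0
    # greedy scan: each event joins the most recent open run it fits
    open_runs: list[dict] = []  # each: {'g', 'x0', 'y0', 'start', 'last'}
    for i in range(len(locs)):
        f = frames[i]
        open_runs = [r for r in open_runs
                     if f - r["last"] <= 1 and f - r["start"] <= MERGE_MAX_FRAME_SPAN - 1]
        assigned = False
        for r in open_runs:
            if np.hypot(x[i] - r["x0"], y[i] - r["y0"]) <= max_dist:
                groups[i] = r["g"]
                r["last"] = f
                assigned = True
                break
        if not assigned:
            groups[i] = n_groups
            open_runs.append({"g": n_groups, "x0": x[i], "y0": y[i], "start": f, "last": f})
            n_groups += 1

    if n_groups == len(locs):
        return locs.copy()

    rows = []
    df = locs.reset_index(drop=True)
    for g in range(n_groups):
        members = df.loc[groups == g]
        if len(members) == 1:
            rows.append(members.iloc[0])
            continue
        w_lat = 1.0 / members["lat_prec_nm"].to_numpy() ** 2
        w_ax = 1.0 / members["ax_prec_nm"].to_numpy() ** 2
        merged = members.iloc[0].copy()
        merged["x_nm"] = np.average(members["x_nm"], weights=w_lat)
        merged["y_nm"] = np.average(members["y_nm"], weights=w_lat)
        merged["z_nm"] = np.average(members["z_nm"], weights=w_ax)
        merged["psf_photons"] = members["psf_photons"].sum()
        merged["cutout_photons"] = members["cutout_photons"].sum()
        merged["lat_prec_nm"] = 1.0 / np.sqrt(w_lat.sum())
        merged["ax_prec_nm"] = 1.0 / np.sqrt(w_ax.sum())
        merged["z_offset_nm"] = members["z_offset_nm"].mean()
        rows.append(merged)
    out = pd.DataFrame(rows).reset_index(drop=True)
    return out.sort_values("frame", kind="stable").reset_index(drop=True)


def filter_axial(locs: pd.DataFrame, max_precision: float = MAX_AXIAL_PRECISION_NM) -> pd.DataFrame:
    """Drop events whose axial precision is worse than ``max_precision`` nm.

    The boundary is inclusive: precision exactly at the cutoff is kept.
    """
    return locs.loc[locs["ax_prec_nm"] <= max_precision].copy()


# ---------------------------------------------------------------------------
# drift correction


def drift_correct(
    locs: pd.DataFrame,
    fiducials: list[FiducialTrack],
    window: int = 1000,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Subtract fiducial centre-of-mass drift from all localizations.

    The recording is split into non-overlapping windows of ``window``
    frames. In each window the centre of mass of all valid fiducial
    positions is computed; its displacement relative to the first window
    is the drift for that window. Drift is linearly interpolated between
    window centres before subtraction, and windows without fiducial
    coverage are interpolated from their neighbours (flagged in the
    trace). Returns (corrected table, drift trace).
    """
    if not fiducials:
        raise ValueError("drift correction requires at least one fiducial track")
    if window < 1:
        raise ValueError("window must be >= 1 frame")
    frames = locs["frame"].to_numpy()
    f_lo = min(int(frames.min()) if len(frames) else 0,
               int(min(t.frames[t.valid].min() for t in fiducials)))
    f_hi = max(int(frames.max()) if len(frames) else 0,
               int(max(t.frames[t.valid].max() for t in fiducials)))
    edges = np.arange(f_lo, f_hi + window + 1, window)
    centers = 0.5 * (edges[:-1] + edges[1:] - 1)

    com = np.full((len(centers), 3), np.nan)
    for w in range(len(centers)):
        pts = []
        for t in fiducials:
            sel = t.valid & (t.frames >= edges[w]) & (t.frames < edges[w + 1])
            if sel.any():
                pts.append(t.positions[sel].mean(axis=0))
        if pts:
            com[w] = np.mean(pts, axis=0)
    covered = ~np.isnan(com[:, 0])
    if not covered.any():
        raise ValueError("no fiducial coverage in any window")
    # fill gaps by linear interpolation over window centres
    interpolated = ~covered
    for k in range(3):
        com[:, k] = np.interp(centers, centers[covered], com[covered, k])
    drift = com - com[covered][0]

    trace = pd.DataFrame({
        "window_start": edges[:-1], "window_center": centers,
        "dx_nm": drift[:, 0], "dy_nm": drift[:, 1], "dz_nm": drift[:, 2],
        "interpolated": interpolated,
    })

    out = locs.copy()
    if len(locs):
        per_event = np.column_stack([
            np.interp(frames, centers, drift[:, k]) for k in range(3)
        ])
        out[["x_nm", "y_nm", "z_nm"]] = out[["x_nm", "y_nm", "z_nm"]].to_numpy() - per_event
    return out, trace


def apply_drift(locs: pd.DataFrame, trace: pd.DataFrame) -> pd.DataFrame:
    """Re-inject a recorded drift trace (inverse of :func:`drift_correct`)."""
    out = locs.copy()
    frames = locs["frame"].to_numpy()
    centers = trace["window_center"].to_numpy()
    drift = trace[["dx_nm", "dy_nm", "dz_nm"]].to_numpy()
    per_event = np.column_stack([
        np.interp(frames, centers, drift[:, k]) for k in range(3)
    ])
    out[["x_nm", "y_nm", "z_nm"]] = out[["x_nm", "y_nm", "z_nm"]].to_numpy() + per_event
    return out


# ---------------------------------------------------------------------------
# clustering


def extract_clusters(
    locs: pd.DataFrame,
    max_distance: float = DEFAULT_CLUSTER_EPS_NM,
    min_points: int = DEFAULT_CLUSTER_MIN_POINTS,
) -> list[LocalizationCluster]:
    """Segment localizations into clusters with DBSCAN.

    eps = ``max_distance`` (nm), minPts = ``min_points``. Clusters are
    returned largest first, followed by one noise pseudo-cluster (label
    -1) if any events were unassigned.
    """
    if max_distance <= 0:
        raise ValueError("max_distance must be positive")
    if min_points < 1:
        raise ValueError("min_points must be >= 1")
    if len(locs) == 0:
        return []
    xyz = locs[["x_nm", "y_nm", "z_nm"]].to_numpy(dtype=float)
    labels = DBSCAN(eps=max_distance, min_samples=min_points).fit_predict(xyz)
    clusters = []
    for lab in sorted(set(labels) - {-1}):
        clusters.append(LocalizationCluster(
            events=locs.loc[labels == lab].copy(), label=int(lab)))
    clusters.sort(key=len, reverse=True)
    if (labels == -1).any():
        clusters.append(LocalizationCluster(
            events=locs.loc[labels == -1].copy(), label=-1, is_noise=True))
    return clusters


def process(
    locs: pd.DataFrame,
    fiducials: list[FiducialTrack] | None = None,
    quality_threshold: float = QUALITY_RANK_THRESHOLD,
    max_axial_precision: float = MAX_AXIAL_PRECISION_NM,
    pixel_size: float = DEFAULT_PIXEL_SIZE_NM,
    eps: float = DEFAULT_CLUSTER_EPS_NM,
    min_points: int = DEFAULT_CLUSTER_MIN_POINTS,
    drift_window: int = 1000,
) -> tuple[list[LocalizationCluster], pd.DataFrame | None]:
    """Full chain: quality filter -> merge -> axial filter -> drift -> DBSCAN."""
    locs = locs.sort_values("frame", kind="stable").reset_index(drop=True)
    locs = filter_quality(locs, quality_threshold)
    locs = merge_repeats(locs, pixel_size)
    locs = filter_axial(locs, max_axial_precision)
    trace = None
    if fiducials:
        locs, trace = drift_correct(locs, fiducials, drift_window)
    return extract_clusters(locs, eps, min_points), trace
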