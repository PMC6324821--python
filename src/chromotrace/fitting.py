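"""Rigid fitting of bead-chain models into imaging density maps.

The probe map rho^P is rendered from a bead model on the target map's
grid (one count per bead, smoothed with the target's kernel width) and
compared with the target rho^T through the cross-correlation coefficient

    CCC = sum_i (rho_i^P - mean^P)(rho_i^T - mean^T)
          / sqrt( sum_i (rho_i^P - mean^P)^2  sum_i (rho_i^T - mean^T)^2 )

over all voxels i of the common grid; 1 is a perfect match. Candidate
placements are generated by uniform random rotation + translation inside
the map bounding box and locally optimized by steepest ascent on the
CCC over the 6 pose parameters (a coarse multi-resolution search on a
bead-sampled surrogate of the same objective precedes the ascent to keep
the search tractable). Each fit is also scored by a connectivity score

    ConS = 1 - d_P,COM / max(d_P,COM)

rewarding placements whose terminal bead lies near the centre of mass of
the interface with the genomically adjacent segment, and ranked by
CombScore = ConS + 2 * CCC; fits at or above the 95th percentile of
CombScore are flagged for flexible refinement.

The model-fitting surface follows the estimator/results convention:
``IMGRModel(model_ensemble, target_map, ...).fit(seed=...)`` returns an
:class:`IMGRResults` carrying the scored fit table, the selected fits
and a ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from .density import DensityMap
from .modeling import BeadModel

DEFAULT_N_PLACEMENTS = 100
DEFAULT_PERCENTILE = 95.0
DEFAULT_INTERFACE_CUTOFF_NM = 50.0


class NoInterfaceError(ValueError):
    """The two bodies are farther apart than the interface cutoff."""


# ---------------------------------------------------------------------------
# rendering and scores


def render_beads(coords: np.ndarray, like: DensityMap,
                 sigma: float | None = None) -> DensityMap:
    """Render a bead cloud as a probe density map on ``like``'s grid.

    Each bead increments its nearest voxel by 1; the grid is smoothed
    with ``sigma`` (defaults to the target map's kernel width) so probe
    and target intensities are commensurate. Beads outside the grid are
    dropped (they simply contribute nothing).
    """
    if sigma is None:
        sigma = like.sigma
    if sigma is None or sigma <= 0:
        raise ValueError("rendering needs a positive sigma")
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    idx = np.floor((coords - like.origin) / like.voxel_size).astype(int)
    keep = np.all((idx >= 0) & (idx < np.array(like.shape)), axis=1)
    grid = np.zeros(like.shape)
    if keep.any():
        ii = idx[keep]
        np.add.at(grid, (ii[:, 0], ii[:, 1], ii[:, 2]), 1.0)
        grid = ndimage.gaussian_filter(grid, sigma / like.voxel_size,
                                       mode="constant", truncate=4.0)
    return DensityMap(grid, like.origin.copy(), like.voxel_size, sigma=sigma)


def ccc(map_p: DensityMap, map_t: DensityMap) -> float:
    """Voxel-wise Pearson cross-correlation between two maps on one grid.

    The raw value can be negative for anti-correlated maps; scoring
    floors it at 0 (see :func:`score_ccc`).
    """
    if map_p.shape != map_t.shape:
        raise ValueError("maps must share a grid")
    a = map_p.data.ravel()
    b = map_t.data.ravel()
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("constant map has no correlation")
    return float(a @ b / (na * nb))


def score_ccc(raw: float) -> float:
    """CCC on the 0-1 scoring scale (negative raw values floor at 0)."""
    return max(0.0, raw)


def interface_com(map_a: DensityMap, map_b: DensityMap,
                  cutoff: float = DEFAULT_INTERFACE_CUTOFF_NM) -> np.ndarray:
    """Centre of mass of A-body voxels within ``cutoff`` nm of the B body.

    Raises :class:`NoInterfaceError` when no A-body voxel lies within
    the cutoff of any B-body voxel (ConS is then undefined for the pair).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if map_a.shape != map_b.shape or not np.allclose(map_a.origin, map_b.origin):
        from .density import common_frame
        map_a, map_b = common_frame([map_a, map_b])
    body_a = map_a.body_mask()
    body_b = map_b.body_mask()
    if not body_a.any() or not body_b.any():
        raise ValueError("empty body")
    dist_to_b = ndimage.distance_transform_edt(
        ~body_b, sampling=map_a.voxel_size)
    sel = body_a & (dist_to_b <= cutoff)
    if not sel.any():
        raise NoInterfaceError(
            f"bodies have no interface within {cutoff} nm")
    w = np.where(sel, map_a.data, 0.0)
    com_idx = np.array(ndimage.center_of_mass(w))
    return map_a.origin + (com_idx + 0.5) * map_a.voxel_size


def connectivity_score(d_values: np.ndarray) -> np.ndarray:
    """ConS_i = 1 - d_i / max_j d_j over an ensemble of fits.

    The fit with the maximal endpoint-to-interface distance scores 0;
    an all-zero ensemble degenerates to all-1 (flagged by the caller).
    """
    d = np.asarray(d_values, dtype=float)
    if d.size == 0:
        raise ValueError("empty distance ensemble")
    if (d < 0).any():
        raise ValueError("distances must be non-negative")
    dmax = d.max()
    if dmax == 0:
        return np.ones_like(d)
    return 1.0 - d / dmax


# ---------------------------------------------------------------------------
# pose search


@dataclass
class FitResult:
    """One scored rigid placement of a bead model in a density map."""

    rotation: np.ndarray        # (3, 3)
    translation: np.ndarray     # (3,)
    ccc: float                  # floored at 0 for scoring
    ccc_raw: float
    cons: float = 0.0
    combscore: float = 0.0
    d_pcom: float = np.nan      # endpoint-to-interface distance (nm)
    connectivity_defined: bool = False
    model_id: int = 0
    placement_id: int = 0
    selected: bool = False

    def apply(self, model: BeadModel) -> BeadModel:
        return model.transformed(self.rotation, self.translation)


def _pose_coords(coords_centered, rotvec, translation):
    R = Rotation.from_rotvec(rotvec).as_matrix()
    return coords_centered @ R.T + translation


class _SurrogateScore:
    """Mean pre-smoothed target intensity sampled at bead positions.

    The cross term of the probe-target correlation equals the target
    convolved with the probe kernel evaluated at the beads; since the
    probe's self-term is nearly pose-invariant, maximizing this bead
    sample tracks maximizing CCC at a fraction of the cost.
    """

    def __init__(self, target: DensityMap, extra_sigma_vox: float):
        sm = ndimage.gaussian_filter(target.data, extra_sigma_vox, mode="constant")
        self.grid = sm
        self.origin = target.origin
        self.voxel = target.voxel_size

    def __call__(self, coords):
        vox = (coords - self.origin) / self.voxel - 0.5
        vals = ndimage.map_coordinates(self.grid, vox.T, order=1, mode="constant")
        return float(vals.mean())


def optimize_pose_ccc(
    model: BeadModel,
    target: DensityMap,
    rotvec0: np.ndarray,
    translation0: np.ndarray,
    max_iter: int = 200,
    dccc_tol: float = 1e-4,
    step0: float | None = None,
):
    """Steepest ascent on CCC over the 6 pose parameters.

    Central-difference numeric gradient with step halving; stops when an
    accepted step improves CCC by less than ``dccc_tol`` or after
    ``max_iter`` iterations. Returns (rotvec, translation, ccc_raw).
    """
    center = model.coords.mean(axis=0)
    cc = model.coords - center

    def val(p):
        coords = _pose_coords(cc, p[:3], p[3:])
        return ccc(render_beads(coords, target), target)

    p = np.concatenate([rotvec0, translation0])
    f = val(p)
    step = step0 if step0 is not None else target.voxel_size
    h = np.array([0.02, 0.02, 0.02] + [0.25 * target.voxel_size] * 3)
    for _ in range(max_iter):
        g = np.zeros(6)
        for k in range(6):
            e = np.zeros(6)
            e[k] = h[k]
            g[k] = (val(p + e) - val(p - e)) / (2 * h[k])
        gn = np.linalg.norm(g)
        if gn == 0:
            break
        direction = g / gn
        scale = np.array([0.05, 0.05, 0.05] + [step] * 3)
        improved = False
        trial_scale = 1.0
        for _ in range(8):
            cand = p + direction * scale * trial_scale
            fc = val(cand)
            if fc > f:
                improved = True
                gain = fc - f
                p, f = cand, fc
                break
            trial_scale *= 0.5
        if not improved or gain < dccc_tol:
            break
    return p[:3], p[3:], f


def rigid_fit(
    model: BeadModel,
    target: DensityMap,
    n_placements: int = DEFAULT_N_PLACEMENTS,
    seed: int | np.random.Generator = 0,
    neighbor_map: DensityMap | None = None,
    terminal: str = "end",
    percentile: float = DEFAULT_PERCENTILE,
    interface_cutoff: float = DEFAULT_INTERFACE_CUTOFF_NM,
    coarse_iters: int = 120,
    polish_iters: int = 200,
    model_id: int = 0,
) -> list[FitResult]:
    """Random placements + local CCC ascent; score CCC, ConS, CombScore.

    Each of ``n_placements`` placements draws a uniform random rotation
    and a translation uniform in the map bounding box, runs a coarse
    surrogate search (heavily-smoothed then native resolution) and a
    final steepest ascent on the true CCC. With a ``neighbor_map``, the
    interface centre of mass is computed once and d_P,COM measured from
    the terminal bead (``terminal`` = 'start' | 'end', the end adjacent
    to that neighbor); ConS is assigned ensemble-wide, CombScore =
    ConS + 2*CCC, and fits at or above the CombScore ``percentile`` are
    marked selected.
    """
    if n_placements < 1:
        raise ValueError("n_placements must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    extent = np.array(target.shape) * target.voxel_size
    diam = float(np.linalg.norm(np.ptp(model.coords, axis=0)))
    if diam > 3.0 * float(np.linalg.norm(extent)):
        import warnings
        warnings.warn("model diameter exceeds 3x map extent; check scales")

    center = model.coords.mean(axis=0)
    cc = model.coords - center
    sigma_vox = (target.sigma or target.voxel_size) / target.voxel_size
    coarse = _SurrogateScore(target, 3.0 * sigma_vox)
    fine = _SurrogateScore(target, sigma_vox)

    results = []
    for pid in range(n_placements):
        rot = Rotation.random(random_state=np.random.RandomState(
            int(rng.integers(2 ** 31 - 1))))
        rotvec = rot.as_rotvec()
        trans = target.origin + rng.uniform(size=3) * extent

        p0 = np.concatenate([rotvec, trans])
        for surrogate in (coarse, fine):
            res = minimize(
                lambda p: -surrogate(_pose_coords(cc, p[:3], p[3:])),
                p0, method="Nelder-Mead",
                options={"maxiter": coarse_iters, "xatol": 1e-2,
                         "fatol": 1e-8, "adaptive": True})
            p0 = res.x
        rotvec, trans, raw = optimize_pose_ccc(
            model, target, p0[:3], p0[3:], max_iter=polish_iters)
        R = Rotation.from_rotvec(rotvec).as_matrix()
        # net transform acting on original coordinates
        results.append(FitResult(
            rotation=R, translation=trans - R @ center,
            ccc=score_ccc(raw), ccc_raw=raw,
            model_id=model_id, placement_id=pid))

    # connectivity
    if neighbor_map is not None:
        try:
            icom = interface_com(target, neighbor_map, cutoff=interface_cutoff)
        except NoInterfaceError:
            icom = None
        if icom is not None:
            term_idx = 0 if terminal == "start" else model.n_beads - 1
            d = np.array([
                np.linalg.norm(r.apply(model).coords[term_idx] - icom)
                for r in results])
            cons = connectivity_score(d)
            for r, dv, cv in zip(results, d, cons):
                r.d_pcom = float(dv)
                r.cons = float(cv)
                r.connectivity_defined = True
    for r in results:
        r.combscore = r.cons + 2.0 * r.ccc
    cut = np.percentile([r.combscore for r in results], percentile)
    for r in results:
        r.selected = r.combscore >= cut
    return results


# ---------------------------------------------------------------------------
# estimator / results surface


class IMGRModel:
    """Integrative modeling of a genomic region: fit bead models to a map.

    Parameters
    ----------
    models : list of BeadModel
        Candidate conformations (e.g. a restraint-model ensemble).
    target : DensityMap
        The segment's imaging density map (iso-threshold set).
    neighbor : DensityMap, optional
        Density map of the genomically adjacent segment, enabling the
        connectivity score.
    restraints, partition, config : optional
        Passed through to flexible refinement when ``fit(refine=True)``.
    """

    def __init__(self, models, target, neighbor=None, terminal="end",
                 restraints=None, partition=None, config=None):
        self.models = list(models)
        self.target = target
        self.neighbor = neighbor
        self.terminal = terminal
        self.restraints = restraints
        self.partition = partition
        self.config = config

    def fit(self, n_placements: int = DEFAULT_N_PLACEMENTS,
            percentile: float = DEFAULT_PERCENTILE,
            seed: int = 0, refine: bool = False, **rigid_kwargs) -> "IMGRResults":
        rng = np.random.default_rng(seed)
        all_fits = []
        for mid, model in enumerate(self.models):
            all_fits.extend(rigid_fit(
                model, self.target, n_placements=n_placements, seed=rng,
                neighbor_map=self.neighbor, terminal=self.terminal,
                percentile=percentile, model_id=mid, **rigid_kwargs))
        # percentile re-applied over the pooled model x placement ensemble
        cut = np.percentile([f.combscore for f in all_fits], percentile)
        for f in all_fits:
            f.selected = f.combscore >= cut
        refinement = None
        if refine:
            from .refine import flexible_refine
            best = max(all_fits, key=lambda f: f.combscore)
            start_model = best.apply(self.models[best.model_id])
            refinement = flexible_refine(
                start_model, self.target, self.restraints,
                self.partition, config=self.config,
                seed=int(rng.integers(2 ** 31 - 1)))
        return IMGRResults(self, all_fits, refinement)


@dataclass
class IMGRResults:
    """Scored rigid-fit ensemble (and optional refinement) for one segment."""

    model: IMGRModel
    fits: list[FitResult]
    refinement: object | None = None

    @property
    def table(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "model_id": f.model_id, "placement_id": f.placement_id,
            "ccc": f.ccc, "ccc_raw": f.ccc_raw, "cons": f.cons,
            "combscore": f.combscore, "d_pcom_nm": f.d_pcom,
            "connectivity_defined": f.connectivity_defined,
            "selected": f.selected,
        } for f in self.fits])

    @property
    def best(self) -> FitResult:
        return max(self.fits, key=lambda f: f.combscore)

    @property
    def best_model(self) -> BeadModel:
        b = self.best
        return b.apply(self.model.models[b.model_id])

    def summary(self) -> str:
        t = self.table
        lines = [
            "IMGR rigid-fit results",
            "======================",
            f"models x placements : {t.model_id.nunique()} x "
            f"{t.placement_id.nunique()} = {len(t)} fits",
            f"CCC    best / median: {t.ccc.max():.4f} / {t.ccc.median():.4f}",
        ]
        if t.connectivity_defined.any():
            lines.append(
                f"ConS   best / median: {t.cons.max():.4f} / {t.cons.median():.4f}")
        lines.append(
            f"CombScore best      : {t.combscore.max():.4f} "
            f"(ConS + 2*CCC)")
        lines.append(f"selected (>= p95)   : {int(t.selected.sum())} fits")
        if self.refinement is not None:
            r = self.refinement
            lines.append(
                f"refined CCC         : {r.final_ccc:.4f} "
                f"(start {r.start_ccc:.4f}), clash score {r.clash_score:.2f}")
        return "\n".join(lines)
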