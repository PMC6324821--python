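"""Restraint-based bead-chain modeling from normalized contact matrices.

A genomic region is represented as a chain of beads at a fixed genomic
resolution (10 kb per bead by default). Normalized contact frequencies
are turned into spatial restraints by z-scoring log frequencies within
each genomic-distance stratum: strongly enriched pairs receive
upper-bound harmonic restraints (pulled together), strongly depleted
pairs lower-bound restraints (kept apart), with target distances
interpolated between bead contact (2r) and a maximum distance as a
decreasing function of the z-score. Adjacent beads are tied by harmonic
bonds and all non-adjacent pairs repel below 2r (excluded volume).
Conformational ensembles are produced by minimizing the restraint
energy from random starting coordinates and keeping the lowest-energy
models.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.spatial.distance import pdist, squareform

DEFAULT_BIN_SIZE_BP = 10_000
DEFAULT_BEAD_RADIUS_NM = 15.0
DEFAULT_FORCE_CONSTANT = 0.01  # energy / nm^2


@dataclass
class BeadModel:
    """One chromatin conformation at fixed genomic resolution."""

    coords: np.ndarray          # (n, 3) nm
    radius: float = DEFAULT_BEAD_RADIUS_NM
    bin_size: int = DEFAULT_BIN_SIZE_BP
    chrom: str = "chr19"
    start: int = 0
    segment_id: str | None = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be (n, 3)")
        if not np.isfinite(self.coords).all():
            raise ValueError("bead coordinates must be finite")
        if self.radius <= 0:
            raise ValueError("bead radius must be positive")

    @property
    def n_beads(self) -> int:
        return len(self.coords)

    def bead_intervals(self) -> pd.DataFrame:
        starts = self.start + np.arange(self.n_beads) * self.bin_size
        return pd.DataFrame({"bead": np.arange(self.n_beads), "chrom": self.chrom,
                             "start": starts, "end": starts + self.bin_size})

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "BeadModel":
        return replace(self, coords=self.coords @ np.asarray(rotation).T
                       + np.asarray(translation))


@dataclass
class RestraintSet:
    """Harmonic pair restraints plus global bond / excluded-volume terms.

    ``pairs`` has columns i, j, kind ('lb' | 'ub' | 'bond'), d0_nm, k.
    Excluded volume acts between every non-adjacent bead pair below
    2 * bead_radius with force constant k_ev.
    """

    pairs: pd.DataFrame
    n_beads: int
    bead_radius: float = DEFAULT_BEAD_RADIUS_NM
    k_ev: float = DEFAULT_FORCE_CONSTANT
    bin_size: int = DEFAULT_BIN_SIZE_BP

    def __post_init__(self):
        p = self.pairs
        if len(p):
            if (p["i"] == p["j"]).any():
                raise ValueError("restraints must join distinct beads")
            if (p["d0_nm"] <= 0).any() or (p["k"] < 0).any():
                raise ValueError("d0 must be > 0 and k >= 0")
            bonds = p[p["kind"] == "bond"]
            if len(bonds) and (np.abs(bonds["i"] - bonds["j"]) != 1).any():
                raise ValueError("connectivity bonds must join adjacent beads")

    def of_kind(self, kind: str) -> pd.DataFrame:
        return self.pairs[self.pairs["kind"] == kind]


def restraints_from_contacts(
    matrix: np.ndarray,
    bin_size: int = DEFAULT_BIN_SIZE_BP,
    bead_radius: float = DEFAULT_BEAD_RADIUS_NM,
    z_cutoff: float = 1.0,
    z_scale: float = 6.0,
    min_stratum_sd: float = 0.2,
    max_distance: float | None = None,
    k: float = DEFAULT_FORCE_CONSTANT,
    k_bond: float = DEFAULT_FORCE_CONSTANT,
    k_ev: float = DEFAULT_FORCE_CONSTANT,
) -> RestraintSet:
    """Transform a normalized contact matrix into a restraint set.

    Log frequencies are z-scored within each genomic-distance stratum
    (matrix diagonal). Pairs with z > ``z_cutoff`` get upper-bound
    harmonic restraints, z < -``z_cutoff`` lower-bound restraints; the
    equilibrium distance decreases with z from ``max_distance`` (default
    8 bead radii) down to bead contact 2r at z >= ``z_scale``. Adjacent
    beads always receive connectivity bonds at d0 = 2r.
    """
    matrix = np.asarray(matrix, dtype=float)
    n = matrix.shape[0]
    if matrix.ndim != 2 or matrix.shape[1] != n:
        raise ValueError("contact matrix must be square")
    if not np.allclose(matrix, matrix.T, atol=1e-8):
        raise ValueError("contact matrix must be symmetric")
    if (matrix < 0).any():
        raise ValueError("contact matrix must be non-negative")
    if max_distance is None:
        max_distance = 8.0 * bead_radius

    with np.errstate(divide="ignore"):
        logm = np.log(matrix)

    rows = []
    d_lo, d_hi = 2.0 * bead_radius, float(max_distance)

    def d0_of(z):
        # decreasing in z, flat at d_max up to the cutoff: marginally enriched
        # pairs are only held within d_max, and d0 tightens towards bead
        # contact (2r) as enrichment approaches z_scale; depleted pairs are
        # kept at least d_max apart
        t = np.clip((z - z_cutoff) / (z_scale - z_cutoff), 0.0, 1.0)
        return d_hi - (d_hi - d_lo) * t

    for sep in range(2, n):  # adjacent pairs handled by bonds
        vals = np.array([logm[i, i + sep] for i in range(n - sep)])
        finite = np.isfinite(vals)
        if finite.sum() < 2:
            continue
        mu, sd = vals[finite].mean(), vals[finite].std()
        # a stratum whose frequencies barely vary (all-in-contact short
        # separations, all-zero long ones) carries no positional signal;
        # z-scoring it would inflate noise into restraints
        if sd < min_stratum_sd:
            continue
        for i in range(n - sep):
            if not finite[i]:
                continue
            z = (vals[i] - mu) / sd
            if z > z_cutoff:
                rows.append((i, i + sep, "ub", d0_of(z), k))
            elif z < -z_cutoff:
                rows.append((i, i + sep, "lb", d0_of(z), k))
    for i in range(n - 1):
        rows.append((i, i + 1, "bond", d_lo, k_bond))
    pairs = pd.DataFrame(rows, columns=["i", "j", "kind", "d0_nm", "k"])
    return RestraintSet(pairs=pairs, n_beads=n, bead_radius=bead_radius,
                        k_ev=k_ev, bin_size=bin_size)


# ---------------------------------------------------------------------------
# restraint energy


def _pair_arrays(restraints: RestraintSet):
    p = restraints.pairs
    return (p["i"].to_numpy(int), p["j"].to_numpy(int),
            p["kind"].to_numpy(), p["d0_nm"].to_numpy(float), p["k"].to_numpy(float))


def restraint_energy(coords: np.ndarray, restraints: RestraintSet,
                     grad: bool = False):
    """Harmonic restraint energy (lb + ub + bond + excluded volume).

    With ``grad=True`` returns (components dict, gradient array).
    """
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    n = len(coords)
    if n != restraints.n_beads:
        raise ValueError("coordinate count does not match restraint set")
    i, j, kind, d0, k = _pair_arrays(restraints)
    comp = {"lb": 0.0, "ub": 0.0, "bond": 0.0, "ev": 0.0}
    g = np.zeros_like(coords) if grad else None

    if len(i):
        diff = coords[i] - coords[j]
        d = np.linalg.norm(diff, axis=1)
        d = np.maximum(d, 1e-9)
        dev = np.zeros_like(d)
        lb = (kind == "lb") & (d < d0)
        ub = (kind == "ub") & (d > d0)
        bond = kind == "bond"
        dev[lb] = d[lb] - d0[lb]
        dev[ub] = d[ub] - d0[ub]
        dev[bond] = d[bond] - d0[bond]
        e_pair = k * dev ** 2
        comp["lb"] = float(e_pair[lb].sum())
        comp["ub"] = float(e_pair[ub].sum())
        comp["bond"] = float(e_pair[bond].sum())
        if grad:
            coeff = 2.0 * k * dev / d
            f = coeff[:, None] * diff
            np.add.at(g, i, f)
            np.add.at(g, j, -f)

    # excluded volume: all non-adjacent pairs closer than 2r
    two_r = 2.0 * restraints.bead_radius
    dm = squareform(pdist(coords))
    iu, ju = np.triu_indices(n, k=2)
    d = np.maximum(dm[iu, ju], 1e-9)
    close = d < two_r
    if close.any():
        dev = d[close] - two_r
        comp["ev"] = float((restraints.k_ev * dev ** 2).sum())
        if grad:
            diff = coords[iu[close]] - coords[ju[close]]
            coeff = 2.0 * restraints.k_ev * dev / d[close]
            f = coeff[:, None] * diff
            np.add.at(g, iu[close], f)
            np.add.at(g, ju[close], -f)

    comp["total"] = comp["lb"] + comp["ub"] + comp["bond"] + comp["ev"]
    return (comp, g) if grad else comp


def model_ensemble(
    restraints: RestraintSet,
    n_models: int = 5000,
    n_keep: int = 1000,
    seed: int | np.random.Generator = 0,
    maxiter: int = 150,
    chrom: str = "chr19",
    start: int = 0,
    segment_id: str | None = None,
) -> tuple[list[BeadModel], np.ndarray]:
    """Generate conformations by minimizing the restraint energy.

    ``n_models`` random starting configurations are relaxed with L-BFGS;
    the ``n_keep`` lowest-energy models are returned together with their
    (sorted) final energies — the models that best satisfy the input
    restraints.
    """
    if n_keep > n_models:
        raise ValueError("n_keep must not exceed n_models")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = restraints.n_beads
    box = 2.0 * restraints.bead_radius * max(n ** (1 / 3) * 2.0, 4.0)

    def objective(x):
        comp, g = restraint_energy(x.reshape(-1, 3), restraints, grad=True)
        return comp["total"], g.ravel()

    models, energies = [], []
    for m in range(n_models):
        # random-walk start keeps bonds near their rest length
        steps = rng.normal(size=(n, 3))
        steps /= np.linalg.norm(steps, axis=1, keepdims=True)
        x0 = np.cumsum(steps * 2.0 * restraints.bead_radius, axis=0)
        x0 += rng.uniform(-box / 8, box / 8, size=3)
        res = minimize(objective, x0.ravel(), jac=True, method="L-BFGS-B",
                       options={"maxiter": maxiter})
        coords = res.x.reshape(-1, 3)
        models.append(coords)
        energies.append(restraint_energy(coords, restraints)["total"])

    order = np.argsort(energies, kind="stable")[:n_keep]
    kept = [BeadModel(models[o], radius=restraints.bead_radius,
                      bin_size=restraints.bin_size, chrom=chrom, start=start,
                      segment_id=segment_id) for o in order]
    return kept, np.asarray(energies)[order]


def ensemble_contact_map(models: list[BeadModel], cutoff: float) -> np.ndarray:
    """Fraction of models in which each bead pair lies within ``cutoff`` nm."""
    if not models:
        raise ValueError("empty ensemble")
    n = models[0].n_beads
    if any(m.n_beads != n for m in models):
        raise ValueError("inconsistent bead counts across models")
    acc = np.zeros((n, n))
    for m in models:
        dm = squareform(pdist(m.coords))
        acc += (dm <= cutoff)
    acc /= len(models)
    np.fill_diagonal(acc, 1.0)
    return acc
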