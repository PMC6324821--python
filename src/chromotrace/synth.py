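"""Synthetic ground truth for end-to-end testing of the walk pipeline.

Generates chromatin bead chains with a plantable two-block arrangement
(a compact central block of segments 3-7 and peripheral end segments
whose termini lie near each other — the geometry reported for the imaged
8.16 Mb walk), simulates the localization tables a 3-D STORM acquisition
of those chains would produce (Poisson event counts per bead, lateral
precision ~11 nm and axial ~47 nm, uniform background, linear stage
drift shared with fiducial markers, correlated per-event quality
metrics), and derives ensemble contact matrices, so that every pipeline
stage can be exercised and validated against planted truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist, squareform

from .localizations import LOC_COLUMNS, FiducialTrack
from .metrics import SegmentRecord
from .modeling import BeadModel, DEFAULT_BEAD_RADIUS_NM

#: the nine walk-step sizes (bp), 360 kb - 1.8 Mb, totalling 8.16 Mb
PAPER_SEGMENT_SIZES_BP = (
    1_200_000, 360_000, 960_000, 1_800_000, 720_000,
    600_000, 840_000, 900_000, 780_000,
)
PAPER_REGION = ("chr19", 7_400_000, 15_560_000)
DEFAULT_LATERAL_SIGMA_NM = 11.0
DEFAULT_AXIAL_SIGMA_NM = 47.0


class PackingError(RuntimeError):
    """Requested chain cannot be packed into the confinement sphere."""


def make_chain(
    n_beads: int,
    bond_length: float = 30.0,
    confinement_radius: float = 500.0,
    seed: int | np.random.Generator = 0,
    min_separation: float | None = None,
    center: np.ndarray | None = None,
    max_retries: int = 200,
) -> BeadModel:
    """Self-avoiding fixed-bond random walk inside a sphere.

    Every bond has exactly ``bond_length``; non-successive beads stay at
    least ``min_separation`` apart (default 0.8 bond lengths) and all
    beads stay within ``confinement_radius`` of ``center``.
    """
    if n_beads < 2:
        raise ValueError("a chain needs >= 2 beads")
    if bond_length <= 0 or confinement_radius <= 0:
        raise ValueError("lengths must be positive")
    if min_separation is None:
        min_separation = 0.8 * bond_length
    # crude sphere-packing feasibility: each bead excludes ~(min_sep/2)^3
    if n_beads * (min_separation / 2) ** 3 > 0.5 * confinement_radius ** 3:
        raise PackingError(
            f"{n_beads} beads at separation {min_separation} nm do not fit "
            f"in a {confinement_radius} nm sphere")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    center = np.zeros(3) if center is None else np.asarray(center, dtype=float)

    for _ in range(max_retries):
        pts = [center + _random_unit(rng) * rng.uniform(0, 0.3 * confinement_radius)]
        ok = True
        for _ in range(n_beads - 1):
            placed = False
            for _ in range(100):
                cand = pts[-1] + _random_unit(rng) * bond_length
                if np.linalg.norm(cand - center) > confinement_radius:
                    continue
                if len(pts) > 1:
                    d = np.linalg.norm(np.asarray(pts[:-1]) - cand, axis=1)
                    if (d < min_separation).any():
                        continue
                pts.append(cand)
                placed = True
                break
            if not placed:
                ok = False
                break
        if ok:
            return BeadModel(np.asarray(pts))
    raise PackingError("failed to grow a self-avoiding chain; relax parameters")


def _random_unit(rng) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


# ---------------------------------------------------------------------------
# planted walk geometry


@dataclass
class SyntheticNucleus:
    """Planted ground truth for one diploid nucleus."""

    homologs: dict[str, list[BeadModel]]          # homolog id -> per-segment chains
    segments: dict[str, list[SegmentRecord]]
    drift_nm: np.ndarray = field(default_factory=lambda: np.zeros(3))
    background_fraction: float = 0.0
    seed: int = 0

    @property
    def central_block(self) -> tuple[int, ...]:
        """0-based indices of the compact central segments (CS3-CS7)."""
        return (2, 3, 4, 5, 6)


def make_walk(
    seed: int | np.random.Generator = 0,
    segment_sizes: tuple[int, ...] = PAPER_SEGMENT_SIZES_BP,
    bp_per_bead: int = 100_000,
    bond_length: float = 60.0,
    central_radius: float = 220.0,
    peripheral_shell: float = 420.0,
    peripheral_spread: float = 160.0,
    homolog_id: str = "H1",
    nucleus_id: str = "N1",
) -> tuple[list[BeadModel], list[SegmentRecord]]:
    """One homolog's 9-segment walk with the planted two-block layout.

    Segments 3-7 (indices 2-6) are compact and packed around the walk
    centre; segments 1, 2, 8, 9 sit on a peripheral shell with the two
    walk ends (segments 1 and 9, then 2 and 8) placed near each other —
    centre separated from the ends, ends mutually proximal.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    chrom, region_start, _ = PAPER_REGION
    central = {2, 3, 4, 5, 6}

    # peripheral anchors: ends share a direction, so CS1/CS9 (and CS2/CS8)
    # end up mutually close while the central block sits at the origin
    u = _random_unit(rng)
    perp = np.cross(u, _random_unit(rng))
    perp /= np.linalg.norm(perp)
    anchors = {
        0: u * peripheral_shell + perp * 0.25 * peripheral_spread,
        8: u * peripheral_shell - perp * 0.25 * peripheral_spread,
        1: u * peripheral_shell + perp * 1.2 * peripheral_spread,
        7: u * peripheral_shell - perp * 1.2 * peripheral_spread,
    }

    models, records = [], []
    gstart = region_start
    for k, size in enumerate(segment_sizes):
        n_beads = max(2, int(round(size / bp_per_bead)))
        if k in central:
            anchor = rng.normal(scale=0.25 * central_radius, size=3)
            radius = central_radius
            bond = bond_length
        else:
            anchor = anchors[k] + rng.normal(scale=0.15 * peripheral_spread, size=3)
            radius = 1.6 * central_radius  # looser, larger peripheral bodies
            bond = 1.4 * bond_length
        chain = make_chain(n_beads, bond_length=bond, confinement_radius=radius,
                           seed=rng, center=anchor)
        chain.chrom = chrom
        chain.start = gstart
        chain.bin_size = bp_per_bead
        chain.segment_id = f"CS{k + 1}"
        models.append(chain)
        records.append(SegmentRecord(
            segment_id=f"CS{k + 1}", chrom=chrom, start=gstart,
            end=gstart + size, homolog_id=homolog_id, nucleus_id=nucleus_id))
        gstart += size
    return models, records


def make_nucleus(
    seed: int = 0,
    n_homologs: int = 2,
    drift_nm: np.ndarray | None = None,
    background_fraction: float = 0.02,
    **walk_kwargs,
) -> SyntheticNucleus:
    """A diploid nucleus: independent planted walks for each homolog."""
    rng = np.random.default_rng(seed)
    homologs, segments = {}, {}
    offsets = [np.zeros(3)] + [
        _random_unit(rng) * 3000.0 for _ in range(n_homologs - 1)]
    for h in range(n_homologs):
        hid = f"H{h + 1}"
        models, records = make_walk(seed=rng, homolog_id=hid, **walk_kwargs)
        for m in models:
            m.coords = m.coords + offsets[h]
        homologs[hid] = models
        segments[hid] = records
    drift = np.array([30.0, -20.0, 15.0]) if drift_nm is None \
        else np.asarray(drift_nm, dtype=float)
    return SyntheticNucleus(homologs=homologs, segments=segments,
                            drift_nm=drift,
                            background_fraction=background_fraction, seed=seed)


# ---------------------------------------------------------------------------
# localization simulation


def simulate_localizations(
    model: BeadModel,
    events_per_bead: float = 40.0,
    lat_sigma: float = DEFAULT_LATERAL_SIGMA_NM,
    ax_sigma: float = DEFAULT_AXIAL_SIGMA_NM,
    background_fraction: float = 0.0,
    drift_nm: np.ndarray | None = None,
    n_frames: int = 20_000,
    round_id: int = 1,
    seed: int | np.random.Generator = 0,
    n_fiducials: int = 3,
    fiducial_noise_nm: float = 1.0,
) -> tuple[pd.DataFrame, list[FiducialTrack]]:
    """Simulate the localization table an acquisition of ``model`` yields.

    Per bead, a Poisson(``events_per_bead``) number of events displaced
    by axis-wise Gaussian noise (lateral sigma ~11 nm, axial ~47 nm, the
    precisions typical of 3-D STORM imaging of oligo-FISH signals);
    uniform background events at ``background_fraction`` of the total;
    a linear drift ramping to ``drift_nm`` over the recording applied to
    all events and to ``n_fiducials`` synthetic fiducial tracks. Quality
    metrics are driven by one latent per-event quality (background
    events drawn low) so the goodness-of-fit filter preferentially
    removes background.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    drift = np.zeros(3) if drift_nm is None else np.asarray(drift_nm, dtype=float)

    counts = rng.poisson(events_per_bead, size=model.n_beads)
    n_sig = int(counts.sum())
    pos = np.repeat(model.coords, counts, axis=0)
    if n_sig:
        pos = pos + np.column_stack([
            rng.normal(scale=lat_sigma, size=n_sig),
            rng.normal(scale=lat_sigma, size=n_sig),
            rng.normal(scale=ax_sigma, size=n_sig),
        ])
    n_bg = rng.poisson(background_fraction * max(n_sig, 1)) if background_fraction > 0 else 0
    if n_bg:
        lo = model.coords.min(axis=0) - 500.0
        hi = model.coords.max(axis=0) + 500.0
        bg = rng.uniform(lo, hi, size=(n_bg, 3))
        pos = np.vstack([pos, bg]) if n_sig else bg
    n = n_sig + n_bg
    if n == 0:
        empty = pd.DataFrame({c: pd.Series(dtype=float) for c in LOC_COLUMNS})
        return empty, _fiducial_tracks(rng, np.zeros((0, 3)), drift, n_frames,
                                       n_fiducials, fiducial_noise_nm)

    frames = np.sort(rng.integers(0, n_frames, size=n))
    frac = frames / max(n_frames - 1, 1)
    pos = pos + frac[:, None] * drift

    # latent quality: signal high, background low; the three metrics are
    # strongly concordant with it so the rank-based goodness-of-fit filter
    # removes background preferentially rather than at random
    latent = np.concatenate([
        np.clip(rng.beta(8, 2, size=n_sig), 0, 1),
        np.clip(rng.beta(2, 8, size=n_bg), 0, 1),
    ])
    cutout = 2000.0 * (0.2 + latent) * np.exp(rng.normal(scale=0.05, size=n))
    psf = cutout * np.clip(0.2 + 0.75 * latent + rng.normal(scale=0.02, size=n),
                           0.05, 0.99)
    z_off = rng.choice([-1.0, 1.0], size=n) * (1.2 - latent) * 100.0 \
        * np.exp(rng.normal(scale=0.05, size=n))

    lat_prec = np.clip(rng.normal(lat_sigma, 1.5, size=n), 3.0, None)
    ax_prec = np.clip(rng.normal(ax_sigma, 6.0, size=n), 10.0, None)

    df = pd.DataFrame({
        "x_nm": pos[:, 0], "y_nm": pos[:, 1], "z_nm": pos[:, 2],
        "frame": frames, "psf_photons": psf, "cutout_photons": cutout,
        "z_offset_nm": z_off, "lat_prec_nm": lat_prec, "ax_prec_nm": ax_prec,
        "round": round_id,
    })
    center = model.coords.mean(axis=0)
    tracks = _fiducial_tracks(rng, center[None, :], drift, n_frames,
                              n_fiducials, fiducial_noise_nm)
    return df, tracks


def _fiducial_tracks(rng, around, drift, n_frames, n_fiducials, noise):
    base = around.mean(axis=0) if len(around) else np.zeros(3)
    tracks = []
    frames = np.arange(n_frames)
    frac = frames / max(n_frames - 1, 1)
    for k in range(n_fiducials):
        anchor = base + rng.uniform(-2000, 2000, size=3)
        positions = anchor + frac[:, None] * drift \
            + rng.normal(scale=noise, size=(n_frames, 3))
        tracks.append(FiducialTrack(marker_id=f"F{k + 1}", frames=frames,
                                    positions=positions))
    return tracks


def simulate_nucleus_localizations(
    nucleus: SyntheticNucleus,
    events_per_bead: float = 40.0,
    seed: int | None = None,
    **kwargs,
) -> dict[tuple[str, str], tuple[pd.DataFrame, list[FiducialTrack]]]:
    """Localization table + fiducials per (homolog, segment).

    Event totals scale with bead count, so larger genomic segments yield
    proportionally more localizations.
    """
    rng = np.random.default_rng(nucleus.seed if seed is None else seed)
    out = {}
    for hid, models in nucleus.homologs.items():
        for m in models:
            out[(hid, m.segment_id)] = simulate_localizations(
                m, events_per_bead=events_per_bead,
                background_fraction=nucleus.background_fraction,
                drift_nm=nucleus.drift_nm, seed=rng, **kwargs)
    return out


# ---------------------------------------------------------------------------
# contact matrices


def contacts_from_ensemble(models: list[BeadModel], cutoff: float) -> np.ndarray:
    """Fraction of conformations with each bead pair within ``cutoff`` nm.

    Symmetric, entries in [0, 1], unit diagonal.
    """
    if not models:
        raise ValueError("need at least one model")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    n = models[0].n_beads
    if any(m.n_beads != n for m in models):
        raise ValueError("inconsistent bead counts across models")
    acc = np.zeros((n, n))
    for m in models:
        dm = squareform(pdist(m.coords))
        acc += dm <= cutoff
    acc /= len(models)
    np.fill_diagonal(acc, 1.0)
    return acc


def perturbed_ensemble(model: BeadModel, n_models: int, noise_nm: float,
                       seed: int | np.random.Generator = 0) -> list[BeadModel]:
    """Conformational ensemble as i.i.d. Gaussian perturbations of a chain."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = []
    for _ in range(n_models):
        coords = model.coords + rng.normal(scale=noise_nm, size=model.coords.shape)
        out.append(BeadModel(coords, radius=model.radius, bin_size=model.bin_size,
                             chrom=model.chrom, start=model.start,
                             segment_id=model.segment_id))
    return out


def write_run(
    out_dir: str | Path,
    nucleus: SyntheticNucleus,
    events_per_bead: float = 40.0,
    contact_cutoff: float = 150.0,
    n_contact_models: int = 50,
    contact_noise_nm: float = 40.0,
) -> Path:
    """Write a full synthetic run directory with a JSON manifest.

    Emits per-homolog localization CSVs, one fiducial CSV, BED segment
    definitions, ground-truth XYZ chains, a contact TSV for the whole
    walk of homolog H1, and run.json recording the generator settings.
    """
    from . import io as ctio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(nucleus.seed)
    tables = simulate_nucleus_localizations(nucleus, events_per_bead=events_per_bead)
    manifest = {"seed": nucleus.seed, "events_per_bead": events_per_bead,
                "drift_nm": nucleus.drift_nm.tolist(),
                "background_fraction": nucleus.background_fraction, "files": {}}
    fiducials_written = False
    for (hid, sid), (df, tracks) in tables.items():
        p = out / f"locs_{hid}_{sid}.csv"
        ctio.write_localizations(p, df)
        manifest["files"][p.name] = "localizations"
        if not fiducials_written:
            fp = out / "fiducials.csv"
            ctio.write_fiducials(fp, tracks)
            manifest["files"][fp.name] = "fiducials"
            fiducials_written = True
    for hid, records in nucleus.segments.items():
        p = out / f"segments_{hid}.bed"
        ctio.write_bed(p, records)
        manifest["files"][p.name] = "segments"
    for hid, models in nucleus.homologs.items():
        for m in models:
            p = out / f"truth_{hid}_{m.segment_id}.xyz"
            ctio.write_xyz(p, m)
            manifest["files"][p.name] = "truth_model"
    ens = perturbed_ensemble(nucleus.homologs["H1"][0], n_contact_models,
                             contact_noise_nm, seed=rng)
    contacts = contacts_from_ensemble(ens, contact_cutoff)
    p = out / "contacts_H1_CS1.tsv"
    ctio.write_contacts(p, contacts, bin_size=nucleus.homologs["H1"][0].bin_size)
    manifest["files"][p.name] = "contacts"
    mp = out / "run.json"
    mp.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return mp
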