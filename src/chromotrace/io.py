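"""Readers and writers for the pipeline's on-disk formats.

Localization and fiducial tables are plain CSV with mandatory headers;
genomic segments use BED (0-based half-open); density maps are CCP4/MRC
mode-2 float32 (via gemmi) with the voxel size in the unit cell and the
physical origin in header words 50-52; bead models are whitespace XYZ
tables with a PDB-like writer for visualization; contact matrices and
restraints are TSV. All writers are deterministic (fixed float
formatting) so identical runs hash identically.
"""

from __future__ import annotations

from pathlib import Path

import gemmi
import numpy as np
import pandas as pd

from .density import DensityMap
from .localizations import LOC_COLUMNS, FiducialTrack
from .metrics import SegmentRecord
from .modeling import BeadModel, RestraintSet

FIDUCIAL_COLUMNS = ["marker_id", "frame", "x_nm", "y_nm", "z_nm"]
FLOAT_FMT = "%.6g"


class FormatError(ValueError):
    """An input file does not match the documented schema."""


# ---------------------------------------------------------------------------
# localization / fiducial tables


def read_localizations(path: str | Path) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    missing = set(LOC_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing localization columns {sorted(missing)}")
    if not np.isfinite(df[["x_nm", "y_nm", "z_nm"]].to_numpy()).all():
        raise FormatError(f"{path}: non-finite coordinates")
    if (df["lat_prec_nm"] <= 0).any() or (df["ax_prec_nm"] <= 0).any():
        raise FormatError(f"{path}: precisions must be positive")
    if (df["psf_photons"] > df["cutout_photons"]).any() or (df["psf_photons"] < 0).any():
        raise FormatError(f"{path}: photon counts violate cutout >= psf >= 0")
    return df


def write_localizations(path: str | Path, df: pd.DataFrame) -> None:
    df[LOC_COLUMNS].to_csv(path, index=False, float_format=FLOAT_FMT)


def read_fiducials(path: str | Path) -> list[FiducialTrack]:
    df = pd.read_csv(path)
    missing = set(FIDUCIAL_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing fiducial columns {sorted(missing)}")
    tracks = []
    for mid, grp in df.groupby("marker_id", sort=True):
        grp = grp.sort_values("frame")
        tracks.append(FiducialTrack(
            marker_id=str(mid), frames=grp["frame"].to_numpy(int),
            positions=grp[["x_nm", "y_nm", "z_nm"]].to_numpy(float)))
    return tracks


def write_fiducials(path: str | Path, tracks: list[FiducialTrack]) -> None:
    rows = []
    for t in tracks:
        sel = t.valid
        rows.append(pd.DataFrame({
            "marker_id": t.marker_id, "frame": t.frames[sel],
            "x_nm": t.positions[sel, 0], "y_nm": t.positions[sel, 1],
            "z_nm": t.positions[sel, 2]}))
    pd.concat(rows).to_csv(path, index=False, float_format=FLOAT_FMT)


# ---------------------------------------------------------------------------
# BED segments


def read_bed(path: str | Path, homolog_id: str = "H1",
             nucleus_id: str = "N1") -> list[SegmentRecord]:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 3:
        raise FormatError(f"{path}: BED needs chrom, start, end")
    records = []
    for k, row in df.iterrows():
        name = str(row[3]) if df.shape[1] > 3 else f"CS{k + 1}"
        records.append(SegmentRecord(
            segment_id=name, chrom=str(row[0]), start=int(row[1]),
            end=int(row[2]), homolog_id=homolog_id, nucleus_id=nucleus_id))
    return records


def write_bed(path: str | Path, records: list[SegmentRecord]) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.segment_id}\n")


# ---------------------------------------------------------------------------
# density maps (CCP4/MRC via gemmi)

_ORIGIN_WORDS = (50, 51, 52)


def write_map(path: str | Path, m: DensityMap) -> None:
    """Write a density map as CCP4/MRC mode 2 (float32).

    Grid axes X, Y, Z map to the file's fastest-to-slowest axes; the
    voxel size is carried by the unit cell and the physical origin (nm,
    stored as Angstrom-agnostic floats) by header words 50-52.
    """
    nx, ny, nz = m.shape
    grid = gemmi.FloatGrid(nx, ny, nz)
    np.array(grid, copy=False)[:] = m.data.astype(np.float32)
    grid.unit_cell = gemmi.UnitCell(nx * m.voxel_size, ny * m.voxel_size,
                                    nz * m.voxel_size, 90, 90, 90)
    ccp4 = gemmi.Ccp4Map()
    ccp4.grid = grid
    ccp4.update_ccp4_header()
    for w, v in zip(_ORIGIN_WORDS, m.origin):
        ccp4.set_header_float(w, float(v))
    ccp4.write_ccp4_map(str(path))


def read_map(path: str | Path, sigma: float | None = None,
             iso_threshold: float | None = None) -> DensityMap:
    ccp4 = gemmi.read_ccp4_map(str(path))
    data = np.array(ccp4.grid, copy=True).astype(float)
    sp = ccp4.grid.spacing
    if abs(sp[0] - sp[1]) > 1e-6 or abs(sp[0] - sp[2]) > 1e-6:
        raise FormatError(f"{path}: anisotropic voxels unsupported")
    origin = np.array([ccp4.header_float(w) for w in _ORIGIN_WORDS])
    return DensityMap(data, origin, float(sp[0]), sigma=sigma,
                      iso_threshold=iso_threshold)


# ---------------------------------------------------------------------------
# bead models


def write_xyz(path: str | Path, model: BeadModel) -> None:
    df = model.bead_intervals()
    df["x_nm"] = model.coords[:, 0]
    df["y_nm"] = model.coords[:, 1]
    df["z_nm"] = model.coords[:, 2]
    df[["bead", "chrom", "start", "x_nm", "y_nm", "z_nm"]].to_csv(
        path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_xyz(path: str | Path, radius: float | None = None,
             segment_id: str | None = None) -> BeadModel:
    df = pd.read_csv(path, sep=r"\s+")
    for col in ("bead", "chrom", "start", "x_nm", "y_nm", "z_nm"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing XYZ column {col}")
    df = df.sort_values("bead")
    starts = df["start"].to_numpy(int)
    bin_size = int(starts[1] - starts[0]) if len(starts) > 1 else 10_000
    kwargs = {} if radius is None else {"radius": radius}
    return BeadModel(df[["x_nm", "y_nm", "z_nm"]].to_numpy(float),
                     bin_size=bin_size, chrom=str(df["chrom"].iloc[0]),
                     start=int(starts[0]), segment_id=segment_id, **kwargs)


def write_pdb(path: str | Path, model: BeadModel, chain_id: str = "A") -> None:
    """PDB-like writer for visualization (one CA pseudo-atom per bead).

    Coordinates are written in nm/10 so typical chains fit the fixed
    columns; records are for display only, not a crystallographic model.
    """
    with open(path, "w") as fh:
        for k, (x, y, z) in enumerate(model.coords / 10.0, start=1):
            fh.write(
                f"ATOM  {k:5d}  CA  BED {chain_id}{k:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C\n")
        for k in range(1, model.n_beads):
            fh.write(f"CONECT{k:5d}{k + 1:5d}\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# contact matrices and restraints


def write_contacts(path: str | Path, matrix: np.ndarray,
                   bin_size: int = 10_000) -> None:
    n = matrix.shape[0]
    with open(path, "w") as fh:
        fh.write(f"# bin_size={bin_size}\n")
        pd.DataFrame(matrix, columns=[f"b{i}" for i in range(n)]).to_csv(
            fh, sep="\t", index=False, float_format=FLOAT_FMT)


def read_contacts(path: str | Path) -> tuple[np.ndarray, int]:
    with open(path) as fh:
        first = fh.readline()
        bin_size = 10_000
        if first.startswith("#"):
            bin_size = int(first.strip().split("=")[1])
            df = pd.read_csv(fh, sep="\t")
        else:
            fh.seek(0)
            df = pd.read_csv(fh, sep="\t")
    return df.to_numpy(float), bin_size


def write_restraints(path: str | Path, restraints: RestraintSet) -> None:
    with open(path, "w") as fh:
        fh.write(f"# n_beads={restraints.n_beads} "
                 f"bead_radius={restraints.bead_radius} "
                 f"k_ev={restraints.k_ev} bin_size={restraints.bin_size}\n")
        restraints.pairs.to_csv(fh, sep="\t", index=False, float_format=FLOAT_FMT)


def read_restraints(path: str | Path) -> RestraintSet:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise FormatError(f"{path}: missing restraint metadata line")
        meta = dict(tok.split("=") for tok in header[1:].split())
        pairs = pd.read_csv(fh, sep="\t")
    return RestraintSet(pairs=pairs, n_beads=int(meta["n_beads"]),
                        bead_radius=float(meta["bead_radius"]),
                        k_ev=float(meta["k_ev"]), bin_size=int(meta["bin_size"]))
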