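"""Configuration-driven pipeline runs with reproducible manifests.

A run is described by a single JSON config (unknown keys rejected); the
requested stages execute in dependency order — simulate -> locproc ->
densmap -> metrics, with imgr independent — and every output file is
recorded in ``manifest.json`` with its SHA-256 content hash, so
identical config + seed reproduce identical manifests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import density, localizations as locproc, metrics as sm, synth
from .fitting import IMGRModel
from .modeling import restraints_from_contacts, model_ensemble
from .refine import RefinementConfig, RigidBodyPartition

STAGES = ("simulate", "locproc", "densmap", "metrics", "imgr")


@dataclass
class RunConfig:
    """All tunable parameters of a pipeline run, with imaging defaults.

    The constants of the processing chain (0.8 quality rank, 100 nm
    axial cutoff, 150 nm clustering radius, 50 nm interface cutoff, 100
    rigid placements, 95th percentile, 50-cycle / 1000 K / 100+200-step
    / 0.001-dCCC annealing schedule) are all explicit keys.
    """

    stages: list = field(default_factory=lambda: ["simulate", "locproc",
                                                  "densmap", "metrics"])
    seed: int = 0
    out_dir: str = "chromotrace_run"
    log_level: str = "INFO"
    # simulation scale
    n_nuclei: int = 2
    events_per_bead: float = 80.0
    bp_per_bead: int = 200_000
    background_fraction: float = 0.02
    # locproc
    quality_threshold: float = locproc.QUALITY_RANK_THRESHOLD
    max_axial_precision_nm: float = locproc.MAX_AXIAL_PRECISION_NM
    pixel_size_nm: float = locproc.DEFAULT_PIXEL_SIZE_NM
    cluster_eps_nm: float = locproc.DEFAULT_CLUSTER_EPS_NM
    cluster_min_points: int = locproc.DEFAULT_CLUSTER_MIN_POINTS
    drift_window_frames: int = 1000
    # densmap
    voxel_size_nm: float = 50.0
    sigma_scale: float = 1.0
    # imgr
    interface_cutoff_nm: float = 50.0
    n_placements: int = 100
    fit_percentile: float = 95.0
    imgr_n_beads: int = 40
    imgr_n_models: int = 40
    imgr_n_keep: int = 8
    sa_max_cycles: int = 50
    sa_t_max: float = 1000.0
    sa_heat_steps: int = 100
    sa_cool_steps: int = 200
    sa_dccc_tol: float = 0.001
    cg_steps: int = 200

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        bad = set(cfg.stages) - set(STAGES)
        if bad:
            raise ValueError(f"unknown stages: {sorted(bad)}")
        return cfg

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and write a hashed run manifest."""
    from . import io as ctio

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"config": config.to_dict(), "outputs": {}}
    stages = list(config.stages)

    def record(path: Path):
        manifest["outputs"][str(path.relative_to(out))] = _sha256(path)

    nuclei = None
    tables = None
    maps = None       # (nucleus, homolog) -> (records, [DensityMap])

    need_sim = bool({"simulate", "locproc", "densmap", "metrics"} & set(stages))
    if need_sim:
        nuclei = [synth.make_nucleus(
            seed=config.seed + i, bp_per_bead=config.bp_per_bead,
            background_fraction=config.background_fraction)
            for i in range(config.n_nuclei)]

    if "simulate" in stages:
        run_json = synth.write_run(out / "simulated", nuclei[0],
                                   events_per_bead=config.events_per_bead)
        for p in sorted(run_json.parent.iterdir()):
            record(p)

    if {"locproc", "densmap", "metrics"} & set(stages):
        tables = {}
        rows = []
        for i, nuc in enumerate(nuclei):
            sim = synth.simulate_nucleus_localizations(
                nuc, events_per_bead=config.events_per_bead)
            for (hid, sid), (df, tracks) in sim.items():
                clusters, trace = locproc.process(
                    df, fiducials=tracks,
                    quality_threshold=config.quality_threshold,
                    max_axial_precision=config.max_axial_precision_nm,
                    pixel_size=config.pixel_size_nm,
                    eps=config.cluster_eps_nm,
                    min_points=config.cluster_min_points,
                    drift_window=config.drift_window_frames)
                main = next((c for c in clusters if not c.is_noise), None)
                tables[(f"N{i + 1}", hid, sid)] = main
                rows.append({"nucleus": f"N{i + 1}", "homolog": hid,
                             "segment": sid,
                             "n_locs": 0 if main is None else len(main)})
        if "locproc" in stages:
            p = out / "clusters.tsv"
            pd.DataFrame(rows).to_csv(p, sep="\t", index=False)
            record(p)

    if {"densmap", "metrics"} & set(stages):
        maps = {}
        measure_rows = []
        for i, nuc in enumerate(nuclei):
            nid = f"N{i + 1}"
            for hid, records in nuc.segments.items():
                seg_maps = []
                for rec in records:
                    cl = tables[(nid, hid, rec.segment_id)]
                    if cl is None:
                        raise RuntimeError(
                            f"no cluster recovered for {nid}/{hid}/{rec.segment_id}")
                    sigma = config.sigma_scale * density.cluster_sigma(
                        cl.events["lat_prec_nm"], cl.events["ax_prec_nm"])
                    m = density.build_map(cl.coords, sigma,
                                          voxel_size=config.voxel_size_nm)
                    seg_maps.append(m)
                    a, v, psi = sm.shape_features(m)
                    measure_rows.append({
                        "nucleus": nid, "homolog": hid,
                        "segment": rec.segment_id, "area_nm2": a,
                        "volume_nm3": v, "sphericity": psi,
                        "threshold": m.iso_threshold})
                maps[(nid, hid)] = (records, seg_maps)
        if "densmap" in stages:
            p = out / "measures.tsv"
            pd.DataFrame(measure_rows).to_csv(p, sep="\t", index=False,
                                              float_format="%.6g")
            record(p)
            nid, hid = "N1", "H1"
            for rec, m in zip(*maps[(nid, hid)]):
                mp = out / f"map_{nid}_{hid}_{rec.segment_id}.mrc"
                ctio.write_map(mp, m)
                record(mp)

    if "metrics" in stages:
        homologs = {(nid, hid): v for (nid, hid), v in maps.items()}
        features = sm.build_feature_table(homologs)
        p = out / "features.tsv"
        features.to_csv(p, sep="\t", index=False, float_format="%.6g")
        record(p)
        scores, evr, labels = sm.pca_classify(features, seed=config.seed)
        pca_df = features[["nucleus", "homolog", "segment"]].copy()
        pca_df["pc1"] = scores[:, 0]
        pca_df["pc2"] = scores[:, 1]
        pca_df["cluster"] = labels
        p = out / "pca.tsv"
        with open(p, "w") as fh:
            fh.write(f"# explained_variance_ratio={evr[0]:.6g},{evr[1]:.6g}\n")
            pca_df.to_csv(fh, sep="\t", index=False, float_format="%.6g")
        record(p)
        prof_rows = []
        for nid in sorted({n for n, _ in maps}):
            sub = pca_df[pca_df.nucleus == nid]
            h = sorted(sub.homolog.unique())
            if len(h) == 2:
                l1 = sub[sub.homolog == h[0]].sort_values("segment").cluster.to_numpy()
                l2 = sub[sub.homolog == h[1]].sort_values("segment").cluster.to_numpy()
                if len(l1) == sm.N_SEGMENTS:
                    prof_rows.append([nid] + list(sm.compartment_profile(l1, l2)))
        if prof_rows:
            p = out / "profiles.tsv"
            pd.DataFrame(prof_rows, columns=["nucleus"] + [
                f"CS{i}" for i in range(1, 10)]).to_csv(p, sep="\t", index=False)
            record(p)

    if "imgr" in stages:
        rng = np.random.default_rng(config.seed)
        truth = synth.make_chain(config.imgr_n_beads, bond_length=40.0,
                                 confinement_radius=300.0, seed=rng)
        target = density.build_map(truth.coords, sigma=40.0,
                                   voxel_size=config.voxel_size_nm)
        ens = synth.perturbed_ensemble(truth, 30, 25.0, seed=rng)
        contacts = synth.contacts_from_ensemble(ens, cutoff=120.0)
        restraints = restraints_from_contacts(contacts, bead_radius=truth.radius)
        models, energies = model_ensemble(
            restraints, n_models=config.imgr_n_models,
            n_keep=config.imgr_n_keep, seed=rng, maxiter=60)
        res = IMGRModel(
            models[:2], target,
            restraints=restraints,
            partition=RigidBodyPartition.uniform(config.imgr_n_beads, 4),
            config=RefinementConfig(
                max_cycles=config.sa_max_cycles, t_max=config.sa_t_max,
                heat_steps=config.sa_heat_steps, cool_steps=config.sa_cool_steps,
                dccc_tol=config.sa_dccc_tol, cg_steps=config.cg_steps),
        ).fit(n_placements=min(config.n_placements, 20),
              percentile=config.fit_percentile,
              seed=int(rng.integers(2 ** 31 - 1)))
        p = out / "imgr_fits.tsv"
        res.table.to_csv(p, sep="\t", index=False, float_format="%.6g")
        record(p)
        from . import io as _io
        p = out / "imgr_best.xyz"
        _io.write_xyz(p, res.best_model)
        record(p)

    mp = out / "manifest.json"
    mp.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
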