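# chromotrace

Single-nucleus chromosome-walk analysis and integrative modeling of genomic
regions (IMGR).

Sequential oligonucleotide-FISH super-resolution imaging ("chromosome
walking") traces a multi-megabase region of a chromosome segment by segment
inside single nuclei, producing one 3-D localization point cloud per
genomic segment per homolog. `chromotrace` is for researchers analyzing
such data end to end: it turns raw localization tables into per-segment
density maps and structural statistics, classifies segments into
compartment-like states, compares homologs, and fits Hi-C-derived bead
models of the same region into the imaging maps — rigid search followed by
flexible refinement — so that sequence-based and imaging-based views of the
same chromatin can be reconciled in one model.

## The methods at its core

**Density maps.** A segment's filtered, drift-corrected, DBSCAN-clustered
localizations are binned on a cubic grid and convolved with an isotropic
Gaussian matched to the mean localization precision:
ρ_i = Σ_n Z/((σ√2π)³) · exp(−((x−x_n)² + (y−y_n)² + (z−z_n)²)/2σ²).
The measured body is the iso-contour one background-σ above the background
mode.

**Structural metrics.** For each pair of the 9 segments, the distance score
DS (distance between intensity-weighted centres of mass) and entanglement
score ES (shared body voxels over the smaller body, ∈ [0,1]); per segment,
convex-hull area A_P, body volume V_P and sphericity
ψ = π^(1/3)(6V_P)^(2/3)/A_P. Each is corrected for genomic size by a
power-law fit a·x^b and z-scored; PCA + 2-means on the 19-dimensional
feature vectors separates segments into cluster 1 (larger, less spherical,
active-like) and cluster 2. Homologs are compared by compartment-state
profiles in {1, 0, −1} and by the ellipticity ratio — larger over smaller
of the two homologs' ellipsoid axis ratios — tested against a
1,000-random-pair null by Mann–Whitney.

**IMGR.** Bead-chain models derived from normalized contact matrices
(10 kb per bead) are rigidly fitted into a segment's map: 100 random
placements, local optimization of the cross-correlation coefficient

CCC = Σ_i (ρ_i^P − ρ̄^P)(ρ_i^T − ρ̄^T) / √(Σ_i (ρ_i^P − ρ̄^P)² Σ_i (ρ_i^T − ρ̄^T)²),

a connectivity score ConS = 1 − d_P,COM/max(d_P,COM) rewarding fits whose
chain end lies near the 50 nm interface with the adjacent segment, ranking
by CombScore = ConS + 2·CCC, and selection of the 95th percentile. Selected
fits are refined by simulated annealing over rigid sub-bodies under
restraints (E = W1·E_CCC + W2(E_H_LB + E_H_UB + E_C) + W3·E_EV; 50 cycles
of 0 → 1000 K → 0, stop at ΔCCC < 0.001, conjugate-gradient finish), scored
by CCC and the clash score (bead pairs closer than 2r per 1,000 beads).

A synthetic-data module generates ground-truth chains with a plantable
two-block arrangement, simulated acquisitions (lateral precision ~11 nm,
axial ~47 nm, background, drift, fiducials) and ensemble contact matrices,
so the full pipeline is testable without external data. See
`docs/methods.md` for assumptions, defaults and limitations.

## Worked example

```python
import numpy as np
from scipy.spatial.transform import Rotation
from chromotrace import synth, density, metrics, fitting, localizations as lp

# simulate one diploid nucleus and process homolog H1
nucleus = synth.make_nucleus(seed=1)
sim = synth.simulate_nucleus_localizations(nucleus, events_per_bead=80)
maps = []
for rec in nucleus.segments["H1"]:
    table, fiducials = sim[("H1", rec.segment_id)]
    clusters, trace = lp.process(table, fiducials=fiducials)   # filter, merge,
    cloud = next(c for c in clusters if not c.is_noise)        # drift, DBSCAN
    sigma = density.cluster_sigma(cloud.events["lat_prec_nm"],
                                  cloud.events["ax_prec_nm"])
    maps.append(density.build_map(cloud.coords, sigma, voxel_size=50.0))

ds, es = metrics.pairwise_matrices(maps)
a, v, psi = metrics.shape_features(maps[0])
print(f"CS1: area {a:.3g} nm^2, volume {v:.3g} nm^3, sphericity {psi:.3f}")
print(f"DS(CS1, CS5) = {ds[0,4]:.0f} nm   ES(CS4, CS5) = {es[3,4]:.2f}")
print(metrics.two_block_partition(ds))

# IMGR: fit a bead model into a map rendered at a hidden pose
chain = synth.make_chain(50, bond_length=40, confinement_radius=350, seed=3)
posed = chain.transformed(Rotation.random(random_state=5).as_matrix(),
                          np.array([100., -50., 80.]))
target = density.build_map(posed.coords, sigma=40, voxel_size=25)
print(fitting.IMGRModel([chain], target).fit(n_placements=100, seed=11).summary())
```

prints

```
CS1: area 8.34e+05 nm^2, volume 6.88e+07 nm^3, sphericity 0.973
DS(CS1, CS5) = 324 nm   ES(CS4, CS5) = 0.43
[2 2 1 1 1 1 1 2 2]
IMGR rigid-fit results
======================
models x placements : 1 x 100 = 100 fits
CCC    best / median: 0.9992 / 0.8900
CombScore best      : 1.9983 (ConS + 2*CCC)
selected (>= p95)   : 5 fits
```

CS1 is a near-spherical body ~0.07 µm³ in volume; the centre of segment 1
sits ~324 nm from segment 5, and segments 4 and 5 share 43% of the smaller
body's voxels. Hierarchical clustering of the single-nucleus DS matrix
already separates the planted central block (segments 3–7, label 1) from
the peripheral ends (label 2). The rigid fit recovers the hidden pose
almost exactly: best CCC 0.999 against a median of 0.89 over the 100 random
placements, with the top 5 fits flagged for refinement.

A command-line interface wraps the same operations
(`chromotrace simulate | locproc | densmap | metrics | imgr | all`);
`chromotrace all --seed 1 --out run/` executes the configured stages and
writes a manifest with content hashes, so identical config and seed
reproduce identical outputs.

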