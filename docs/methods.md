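# Methods

`chromotrace` analyzes sequential super-resolution imaging of a chromosomal
"walk" — a region imaged segment by segment with oligonucleotide FISH probes
on a 3-D single-molecule localization microscope — and integrates the
resulting density maps with contact-derived bead models (IMGR: integrative
modeling of genomic regions). This note records the models, the numerical
choices behind each stage, what the synthetic generator does and does not
emulate, and the known limitations.

## Localization processing

A localization table carries, per detected emission event, the fitted 3-D
position (nm), acquisition frame, PSF and cutout photon counts, the axial
offset between the fitted position and the objective piezo, and
Cramér–Rao-derived lateral/axial precisions (these arrive precomputed; PSF
fitting is out of scope).

**Quality filter.** Three per-event metrics — PSF/cutout photon ratio, cutout
photons, and |axial offset| (inverted) — are each self-normalized to [0, 1]
by rank-based min–max scaling over the acquisition, and combined as a
geometric mean, `(m1·m2·m3)^(1/3)`. Events with rank < 0.8 are rejected.
Rank scaling was chosen because the three raw metrics live on incommensurate
scales (a ratio, a count, a length); any monotone recalibration of a metric
then leaves the filter unchanged. A consequence worth knowing: because ranks
are uniform by construction, the filter always removes a substantial fixed
share of events (20% when the three metrics are perfectly concordant, more
when they disagree); it is a relative filter, not an absolute one.

**Repeat merging.** Events whose lateral position stays within 2 pixels
(pixel = 100 nm) over consecutive frames (no gap > 1 frame, total span ≤ 7
frames) are treated as one blinking event. The merged event sits at the
precision-weighted mean position; photon counts are summed and precisions
combined as `1/sqrt(Σ 1/s²)` (the photon-pooling choice is a convention —
averaging would also be defensible; summation matches the physical picture
of one fluorophore detected repeatedly).

**Axial filter.** Events with axial precision worse than 100 nm are removed;
the boundary is inclusive (exactly 100 nm is kept).

**Drift correction.** The recording is split into fixed 1,000-frame windows;
the centre of mass of all valid fiducial positions per window, relative to
the first window, is the drift estimate, linearly interpolated between
window centres and subtracted. Windows without fiducial coverage are
interpolated from neighbours and flagged in the returned trace; no fiducials
at all is an error. The trace makes the correction exactly invertible, which
the tests exploit.

**Clustering.** DBSCAN (scikit-learn) with eps = 150 nm and minPts = 10 by
default. The eps value doubles as the alpha radius of the overlap proxy
below. minPts is not dictated by the measurement physics; 10 suppresses
background at the event densities the generator produces.

## Density maps

Clustered localizations are binned on a cubic grid (default voxel 25 nm;
each event increments its nearest voxel by 1) and convolved with an
isotropic unit-mass Gaussian, ρ_i = Σ_n Z/((σ√(2π))³) exp(−d²/2σ²). With
the unit-mass normalization the map integral equals the localization count
(up to boundary truncation < 1% at ≥ 5σ padding; the default padding is 5σ),
so intensities are comparable across segments. σ defaults to the pooled mean
of the lateral and axial precisions of the cluster (proportionality constant
1.0, configurable); pooling is a compromise for an anisotropic instrument —
per-axis kernels are deliberately not used, trading some axial blur for a
single isotropic scale.

**Iso-contour threshold.** The voxel-intensity histogram (Freedman–Diaconis
bins, smoothed with a 5-bin moving average before peak-picking — the raw
argmax of a fine histogram is too noisy) locates the background mode; the
threshold is that mode plus the RMS deviation of the sub-mode population
(one background sigma after shifting the background peak to zero). The body
of a map is every voxel at or above threshold.

**Geometry.** Surface area is the convex-hull area over above-threshold
voxel centres (SciPy Qhull); volume is the above-threshold voxel count times
voxel³. Both therefore describe the same body, which keeps the sphericity
ψ = π^(1/3)(6V)^(2/3)/A internally consistent; ψ = 1 for a sphere, ≈ 0.806
for a cube. Convex-hull area underestimates concave bodies — a known bias
shared with the measurement convention it reproduces.

## Structural metrics

For the 9 segments of a homolog: DS (distance score) is the Euclidean
distance between intensity-weighted body centres of mass; ES (entanglement
score) the fraction of shared above-threshold voxels relative to the smaller
body, computed after re-embedding both maps on a common grid frame. Area,
volume and sphericity complete the five measures.

**Size correction.** Each measure is compared with a power-law expectation
a·x^b fitted by ordinary least squares in log–log space — DS and ES against
the genomic separation of segment midpoints, shape measures against segment
length — and expressed as z = (observed − expected)/s_res with s_res the
linear-scale residual SD pooled over the fitting population (not
distance-binned; at 9 segments per homolog binning would starve the strata).
ES values of 0 are floored at 10⁻⁶ for the log-space fit.

**Classification.** The 19-dimensional z-feature vectors (8 DS-z, 8 ES-z,
area-z, volume-z, ψ-z) enter a PCA. The columns are already
population-standardized z-scores, so PCA centres but does not rescale them
(rescaling would mask exactly the variance the z-scores encode). Two-group
assignment is 2-means on the first two PC scores with fixed-seed k-means++
initialization; "cluster 1" is by convention the group with larger mean
volume-z (the active-like, larger/less-spherical group). Homolog comparison
maps two 9-long label vectors to a compartment-state profile in {1, 0, −1}
(both cluster 1 / split / both cluster 2); profile matrices are clustered by
average-linkage Euclidean hierarchical clustering.

**Overlap.** The alpha-shape spatial overlap between re-imaged clusters is
approximated on a 25 nm occupancy grid dilated by a 150 nm ball: the
directed fraction of one cluster's events inside the other's dilated body,
averaged over both directions, optionally after centroid alignment. Voxel
dilation was preferred to an exact alpha-complex because it is directly
countable and testable; at alpha = 6 voxels the two differ negligibly for
blob-like clusters.

**Ellipticity.** Homolog clouds are fitted by a moment-based ellipsoid
(principal axes from the covariance eigendecomposition; semi-axes
√(3λ) — the uniform-solid convention, immaterial because only the ratio of
the two largest axes is used). The ellipticity score is that ratio (≥ 1);
the ellipticity ratio of a nucleus is the larger homolog score over the
smaller. Significance against a random-pair null: 1,000 ratios of homolog
pairs drawn from the pooled population, compared with the within-nucleus
ratios by a two-sided Mann–Whitney test. An algebraic least-squares
ellipsoid fit was considered and rejected: for clouds of thousands of
points the moment fit is unbiased for the axis ratio and has no failure
modes near degeneracy.

## Restraint-based modeling

Contact matrices (normalized, symmetric, one row per 10 kb bead by default)
are transformed into restraints by z-scoring log contact frequencies within
each genomic-distance stratum. Strata whose log-frequency SD is below 0.2
are skipped: where nearly every pair is in contact (short separations) or
none is, z-scoring only amplifies noise into spurious restraints. Pairs with
z > 1 receive upper-bound harmonic restraints, z < −1 lower-bound ones; the
equilibrium distance falls linearly from d_max (default 8 bead radii) at the
cutoff to bead contact 2r at z = 6. The slope constant (z_scale = 6) was
calibrated so that conformations typical of the generating ensemble satisfy
their own restraints to within a few nm — a steeper map plants restraint
minima far from any generating conformation. Adjacent beads get bonds at
d0 = 2r; excluded volume acts between all non-adjacent pairs below 2r. All
force constants default to 0.01 energy/nm².

This generator is a deliberately simple stand-in exercising the fitting
stages; it does not reproduce a production restraint-modeling pipeline's
optimization or scoring. Ensembles are produced by L-BFGS relaxation of
random self-avoiding starts; of n_models conformations the n_keep
lowest-energy models (best restraint satisfaction) are retained — 5,000 and
1,000 by default.

## Rigid fitting

The probe map ρ^P renders each bead as a unit count on the target's grid,
smoothed with the target's σ, so probe and target are commensurate. The CCC
is the Pearson correlation over all voxels of the common grid; the printed
formula's denominator is read with the square root of the standard Pearson
form (without it, a perfect self-match would not score 1). Raw CCC can be
negative; scoring floors it at 0 and keeps the raw value in diagnostics.

Each of 100 random placements (uniform random rotation, translation uniform
in the map bounding box) is locally optimized: two Nelder–Mead passes on a
surrogate objective — the mean of the (extra-)smoothed target sampled at
bead positions, first at 3σ (wide basins) then at σ — followed by steepest
ascent on the true CCC with central-difference gradients and step halving
(stop at ΔCCC < 10⁻⁴ or 200 iterations). The surrogate equals the
probe–target cross term of the correlation up to the pose-invariant probe
self-term, so it ranks poses like the CCC at a small fraction of the cost;
the final ascent runs on the exact objective.

The connectivity score needs the interface with the genomically adjacent
segment: target-body voxels within 50 nm of the neighbour body (Euclidean
distance transform), intensity-weighted COM. d_P,COM is measured from the
terminal bead genomically adjacent to that neighbour; ConS = 1 − d/max(d)
over the fit ensemble, the worst fit scoring exactly 0; an all-zero distance
ensemble degenerates to all-1 and is flagged. Bodies farther than the cutoff
raise a no-interface signal and ConS is recorded as undefined (CombScore
then reduces to 2·CCC with ConS stored as 0 and a flag). Fits are ranked by
CombScore = ConS + 2·CCC; the 95th percentile of the pooled
model × placement ensemble (pooling chosen over per-model percentiles) is
flagged for refinement.

The estimator surface is `IMGRModel(models, target, …).fit(…) →
IMGRResults` with the scored fit table, best fit/model, and a `summary()`.

## Flexible refinement

The fit is partitioned into rigid bodies (user-supplied borders or uniform;
automatic domain calling is out of scope). The reported energy is

E = W1·E_CCC + W2·(E_H_LB + E_H_UB + E_C) + W3·E_EV,

with E_CCC the negative sum of per-body CCCs, harmonic lower/upper bounds,
bonds, and excluded volume vanishing at 2r. Defaults W1 = 100, W2 = W3 = 1:
CCC is O(1) per body while the harmonic terms carry energy units, and the
uncited "default" weights of the protocol this emulates are not public, so
the map weight was set where the two term families exchange comparably.

Optimization is simulated annealing over body poses rather than literal
molecular dynamics: per temperature step every body attempts one move —
proposed along its net force direction (analytic restraint forces plus the
interpolated gradient of the smoothed target, emulating displacement "in
the direction that maximizes the correlation") with thermal noise, accepted
by Metropolis on E with k_B = 0.02 energy/K. Each cycle heats 0 → 1000 K
over ≤ 100 steps and cools back over ≤ 200; at most 50 cycles, stopping
early when the best whole-model CCC improves by < 0.001 in a cycle; each
cycle re-heats from the best configuration so far, making progress
monotone. Two numerical choices deserve note: (i) the SA objective uses the
whole-model CCC (cached per-body renders, one re-render per move) instead
of the per-body sum of the reported decomposition — independent per-body
correlations against the full map are maximized by every body covering the
map's main mass, a degenerate optimum; (ii) the conjugate-gradient finish
(200 steps at W1 = W2 = W3 = 1, then 200 with W1 = 0) uses the
density-gradient force of standard flexible fitting for the map term while
E_CCC is always reported from exact per-body correlations.

The returned model maximizes CCC over the refinement trajectory, ties
broken by lower clash score (CLS: non-adjacent bead pairs with d < 2r per
1,000 beads). Divergent (non-finite) energies raise immediately with the
offending components.

## Synthetic data

The generator plants the geometry the analysis is meant to detect: nine
segments (0.36–1.8 Mb, 8.16 Mb total) as self-avoiding fixed-bond random
walks, segments 3–7 compact around the walk centre, segments 1, 2, 8, 9 on
a peripheral shell with the two walk ends placed mutually close. Simulated
acquisitions draw Poisson event counts per bead (so localization totals
grow with genomic size), displace events with lateral σ = 11 nm and axial
σ = 47 nm (the precision regime of the instrument class emulated), add
uniform background at a configurable fraction (default 2%), and apply a
linear drift shared with three synthetic fiducial tracks. Per-event quality
metrics are driven by one latent quality variable, high for signal and low
for background, so the rank filter removes background preferentially.

Not emulated: blinking kinetics and duty cycles, optics/PSF structure,
repeat-detection statistics (frames are drawn uniformly, so the merge stage
sees few true repeats), chromatic or stage-settling effects, and realistic
Hi-C noise (ligation artifacts, coverage bias). Passing tests therefore
demonstrate the correctness and calibration of the computations, not
robustness to every artifact of real acquisitions.

## Problem sizes and defaults

Test and acceptance runs use walks at 100–200 kb per bead (4–18 beads per
segment), 30–80 events per bead, 50 nm voxels for pipeline maps and 25 nm
for single-segment geometry, 50-bead chains for fitting studies, and
ensembles of tens of models except for the 5,000 → 1,000 retention check,
which runs at 10 beads. These sizes were chosen as the smallest at which
every contract is informative; all are configuration keys, and the defaults
scale to larger studies without code changes.

## Known limitations

- The convex-hull area (and hence ψ) is biased for strongly concave bodies.
- ES depends on the common-grid re-embedding; sub-voxel origin offsets are
  rounded to the nearest voxel.
- The power-law correction assumes a single scaling regime across the size
  range fitted; no break-point detection is attempted.
- The restraint transform is a simplified stand-in; its absolute distance
  calibration (d_max, z_scale) is heuristic, and only rank-level structure
  should be interpreted from the resulting ensembles.
- SA refinement is stochastic; the dCCC stopping rule bounds but does not
  guarantee the number of cycles used, and results at fixed seed are
  reproducible but seed-sensitive in the third decimal of CCC.
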