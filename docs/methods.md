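# Methods

## Scope and assumptions

The package consumes lesion data already registered to a common template:
either per-lesion binary masks with voxel spacing, or a centroid table in
template mm. Image registration, segmentation and radiological review are
upstream of this package and out of scope. The atlas is a 3-D integer
label volume; voxel `(i, j, k)` is taken to have its centre at
`(i·sx, j·sy, k·sz)` with no affine rotation — a diagonal spacing map is
exact for template-space inputs and keeps every geometric test exact.

Lesions are reduced to points (unweighted centroids of foreground
voxel centres). All spatial reasoning is within one patient; pooling
centroids across brains into one graph is never done, because inter-brain
distances are meaningless.

## Multi-scale graphs

The Rips 1-skeleton uses a strict inequality `d < s` (distance exactly
equal to the scale is not an edge) and Euclidean distance between
centroids. The scale grid defaults to 10–90 mm in 5 mm steps: 10 mm is
roughly the diameter above which two lesions clearly do not touch, and
90 mm approaches the hemispheric extent, beyond which graphs are near
complete and uninformative. Only the graph at each grid scale is used —
no higher simplices, persistence diagrams or homology.

### Node metrics and their conventions

- Degree centrality is normalised by `n − 1` so it lies in [0, 1]. The
  raw neighbour count is exposed as a diagnostic
  (`sddam.metrics.raw_degree`), but a [0, 1] scale is forced by the fact
  that `ci` averages `dc` with an eigenvector entry that is itself ≤ 1.
- Eigenvector centrality is computed by power iteration on `A + I`
  (identical eigenvectors; the shift removes the sign oscillation of
  bipartite components), converged to 1e-10 within 10,000 iterations and
  scaled to unit Euclidean norm over all nodes. On disconnected graphs
  mass concentrates on the component with the largest leading eigenvalue
  and other components approach zero — the convention of the common graph
  libraries. An edgeless graph (including a single lesion) scores all
  zeros: the leading eigenvalue is 0 and the recursive definition is
  uninformative, and zero is continuous with the single-node case.
- Clustering uses `cc = 2T / (deg(deg − 1))` with `cc = 0` when
  `deg < 2` (the standard convention for the vanishing denominator).
- `ci = (dc + ec)/2` exactly; single-lesion patients therefore have
  all-zero trajectories, which are legal throughout.

### Summaries and filtering

Trajectory summaries support `max` and `mean` over scales. The high-level
filter (high-clustering `cc > 0.9`, high-importance `ci > 0.8`, strict
inequalities) defaults to `max`: a lesion counts as high-level if it ever
exceeds the threshold at any scale. The heatmap subsets instead use the
`mean` over scales with a 0.5 cut, which is a separate convention from
the filter and configurable independently. Whether filtered sets should
be formed per-lesion over the max, per-(lesion, scale) record, or on the
mean trajectory is genuinely open; both modes are first-class and reports
carry the mode used.

## Morphology

Volume is foreground voxel count × voxel volume (mm³). Radius is the
equivalent-sphere radius `(3V/4π)^{1/3}`: across reference min/max
radius–volume pairs this sphere relation holds to better than 1%, which
is what fixed the definition (the source tool for the reference values is
not otherwise specified). Units are mm and mm³ throughout. Default bins
are half-open `[lo, hi)` with width-2 sub-bins below 10 mm radius and
finer volume bins below 700 mm³, because most lesions are small; edges
are configurable. A published grouping of radii as "0–4 and 5–10" leaves
(4, 5) unaccounted; contiguous half-open intervals avoid that gap.

## Distribution statistics

The voxel-proportion null assigns each ROI an expected rate
`p_e = voxels(ROI) / voxels(all ROIs)`. The two-tailed z-test is

    z = (p̂ − p_e) / SE,  p = 2(1 − Φ(|z|)),  no continuity correction.

Two SE conventions exist and differ materially when `p̂` is far from
`p_e` (13.47 vs 18.99 on the same flagship inputs). The default evaluates
SE at the observed proportion, which is the form consistent with the
reference tables; `se_mode="expected"` evaluates it at `p_e`. Reports and
the run log always name the mode. Degenerate observed proportions (0 or
1) in observed mode report `z = ∓∞` with `p = 0` rather than erroring,
mirroring how zero-count regions appear in the reference tables. For
filtered subsets, `n` is the subset size, so rates are shares of the
filtered set. Lesions are treated as independent draws over voxels — no
spatially correlated null — and multiplicity is Bonferroni only.

## Synthetic data

The generator exists because the underlying clinical cohort is not
deposited; it emulates its coarse statistics, not its biology:

- Atlas: `n` Voronoi cells of random seed voxels inside an ellipsoid
  inscribed in the grid (default 30 regions, 48³ voxels at 2 mm →
  a ~96 mm pseudo-brain). Regions are contiguous, non-empty, non-
  overlapping.
- Uniform placement: voxel-uniform draws over the mask with optional
  per-region intensity multipliers and within-voxel jitter. This is the
  exact generative counterpart of the voxel-proportion null, so the test
  should be calibrated on it, and a multiplier ≠ 1 is recoverable ground
  truth.
- Clustered placement: Thomas process (Poisson parents uniform over the
  mask, Poisson(5) offspring per parent, isotropic Gaussian displacement,
  default σ = 2 mm, off-mask offspring snapped to the nearest in-mask
  voxel centre). Chosen as the standard, easily parameterised clustered
  point process; nothing biological is claimed.
- Cohort scale: Poisson(20) lesions per patient (the reference cohort's
  stated mean), volumes log-normal with μ = 5.35, σ = 1.5 in log-mm³
  (mean ≈ 650 mm³ with a heavy right tail reaching ~5·10⁴ at cohort
  size). Placement and volume are independent.
- All randomness flows from one `numpy` Generator seeded once;
  every fixture is bit-reproducible.

What passing tests on these cohorts show: the pipeline's arithmetic is
correct, the test is calibrated under its own null, enrichment of the
size injected is detectable, and clustered growth is separable from
uniform growth by small-scale clustering coefficients. What they do not
show: anything about real lesion biology, real atlas geometry (region
shapes and sizes differ), segmentation error, or spatial correlation
between lesions of the same patient under the null.

## Numerical choices

- Nearest-voxel ROI assignment rounds half to even per axis (numpy
  default), documented so ties are deterministic. Centroids that round to
  background carry no region, are excluded from region tables, and are
  counted in a logged warning.
- Power iteration tolerance 1e-10 (Euclidean difference between
  successive unit vectors), max 10,000 iterations; non-convergence raises
  an error naming the scale and patient.
- Ten-range histograms on [0, 1] close the last bin on the right so a
  value of exactly 1.0 is counted.
- Distance thresholding computes one pairwise distance matrix per patient
  and thresholds it per scale, which makes nestedness exact by
  construction.
- Problem sizes in the calibration runs (10,000 binomial replicates at
  n = 4000; 100 enrichment seeds; 60 clustered/uniform pairs of
  4-patient cohorts) give Monte-Carlo standard errors comfortably inside
  the asserted bands while keeping each run in seconds.

## Known limitations

- The expected-SE and observed-SE test forms disagree for extreme
  regions; the package defaults to the table-consistent observed form but
  cannot resolve which a given external report used unless stated.
- The Wald test with observed SE degenerates (infinite z) at counts of 0
  or n; that is reported, not patched (no continuity correction by
  design, since none reproduces the reference values).
- Voronoi pseudo-atlases have roughly equal-sized convex regions, unlike
  real anatomy; per-region power in real atlases will vary with region
  size.
- NIfTI affines are reduced to their spacing; oblique or rotated volumes
  are not supported.
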