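# Methods

## Data model and conventions

Volumes are 3D scalar grids in MRC2014 (mode 2 float for density, integer
modes for labels) with isotropic voxels; headers store Angstrom, the API
works in nanometres. Axis order is (z, y, x); a voxel's physical position is
its center, (index + 0.5)·voxel. The density sign convention is fixed
project-wide: **lower value = higher mass density**, as in energy-filtered
cryo-tomograms, so all thresholding selects voxels ≤ t. Boundaries (vesicles,
plasma membrane, microtubules, SER, MVBs) carry one integer label per
*instance*, because contact counting needs instance identity; the class and
geometry live in a catalog table. Vesicle labels cover lumen and membrane
together, matching how vesicles are segmented manually in practice.

## Linker detection

### Threshold schedule

25 evenly spaced levels from mu − 3 sigma to mu, where mu and sigma are the
mean and sd of density over unlabeled voxels at least 2 voxels from any
boundary. The count and span are fixed for reproducibility; a noise-free
volume has sigma = 0 and raises an explicit error (the pipeline then falls
back to a range-based schedule spanning the density range below the
cytoplasm level, and records that it did).

### Hierarchical connectivity segmentation

At each level, ascending from the densest: 6-connected components of
{value ≤ t, unlabeled}; a component's contacts are the boundary instances
with a labeled voxel in the 6-neighborhood of any component voxel. A
component is accepted when it contacts exactly two boundaries; its voxels
are claimed, and any laxer-level component containing claimed voxels is
skipped. Claiming-by-containment rather than literal voxel masking prevents
the halo left around a masked core from being re-accepted as a second
segment. Components contacting ≥ 3 boundaries that never had an accepted
descendant are emitted once, at the laxest level, as class `multi`;
components that never reach two contacts are not emitted. 6-connectivity is
used throughout — conservative, and immune to diagonal leaks through
one-voxel gaps.

Classification: two vesicle-kind contacts → `connector` (the pair's kinds,
e.g. DCV vs SV, are recorded so mixed pairs can be reported separately);
exactly one plasma-membrane contact → `tether`; vesicle–microtubule and
vesicle–SER pairs are connectors with the kinds recorded, never tethers.

### Size filter

Accepted segments need ≥ 3 voxels and ≤ 320 nm³ (at 3.2 nm voxels, about 10
voxels). The cap is applied in nm³ using the volume's actual voxel size.
Filtering only *reclassifies* (`rejected_small` / `rejected_large`); nothing
is deleted, so the audit trail and ground-truth matching remain complete.
Note that a straight filament longer than ~30 nm at one-voxel thickness
intrinsically exceeds the volume cap; the cap trades recall for a low
false-positive rate, which is why recovery statistics are computed against
all detected 2-bound segments, with the filter class reported alongside.

### Protrusions

1-bound segments, segmented at a single threshold — the mean density over
the membrane voxels (outermost labeled shell) of the listed vesicles — so
that counts per vesicle are comparable. The same size filter applies.

### Length modes

Contact regions are the boundary voxels 6-adjacent to the segment.

* **B2C** (membrane edge to edge): minimum pairwise distance between the two
  contact regions, measured between voxel *faces*: the minimum
  center-to-center distance minus one voxel, floored at zero. Voxel centers
  sit half a voxel inside each surface, so the raw center-to-center minimum
  carries a systematic +1 voxel bias; the face correction makes a straight
  bridge across a 20-nm gap measure 20 nm and bounds the per-segment error
  by one voxel.
* **C2C**: distance between the centroids of the two contact regions
  (always ≥ B2C).
* **B-max**: maximum over segment voxels of the distance to the nearest
  contact voxel; used for protrusion length.

## Morphometrics

* **Layer occupancy**: Euclidean distance transform from the plasma
  membrane; layer k is the 1-voxel-thick distance band ((k−1)·v, k·v].
  Occupancy is vesicle voxels over vesicle + cytoplasm voxels in the layer;
  other boundary kinds are excluded from both numerator and denominator.
* **Proximal vesicles**: a vesicle is proximal when its surface lies within
  45 nm of the membrane. Surface-to-surface distances between labeled
  objects are estimated as the minimum center-to-center distance minus one
  voxel (floored at zero), for the same half-voxel reason as B2C. Membrane
  area counts cytosol-facing voxel faces of membrane voxels within 250 nm of
  any vesicle (the window is configurable; marching-cubes areas are out of
  scope). The area convention assumes the membrane slab sits at a volume
  face, as the generator places it, so only its cytosolic side has exposed
  faces.
* **Radial traces**: the volume is resampled 4× finer with cubic-spline
  interpolation; concentric shells of one *original* voxel thickness are
  built inward (negative indices) and outward from the sphere surface, and
  the mean density per shell is recorded. Shell thickness on the original
  grid (evaluated on the magnified grid) was chosen over magnified-grid
  thickness; the trace shape is insensitive to this at 4×.
* **Lumen classification** (thresholds are package choices, exposed as
  arguments, since the distinction is made visually in practice): dense iff
  the interior lumen shells (at least two shells inside the membrane
  minimum) average below cytoplasm mean − 1 sd; within dense, a halo is
  present iff some shell strictly between the membrane minimum and the core
  minimum rises to ≥ cytoplasm mean − 0.5 sd; otherwise light. A perfectly
  flat trace is classified light. Dense-core vesicle selection keeps dense
  vesicles with diameters in [70, 90] nm.
* **Curvature**: polylines resampled to equal chordal spacing d (0.5 µm
  default); per-triple curvature is the inverse circumradius, κ = 1/R,
  collinear triples contributing zero; the per-polyline *maximum* is
  reported. The chord-angle conversion 2 arcsin(κd/2)/d ≥ κ expresses the
  same bend as turning angle per unit length for comparison with
  chord-sampled measurements.

## Statistics

Zero-truncated Poisson: P(k) = λ^k/((e^λ−1)k!), evaluated in log space; the
rate is recovered from an observed mean m > 1 by Brent root finding on
m = λ/(1−e^{−λ}) (bracket (0, m]; the mean function is increasing and
bounded below by 1). Expected bin masses use the moment estimate of λ, not
the MLE. Counts are pooled into {1}…{5}, {6–8}, {>8} before the G-test
(G = 2Σ f ln(f/f̂), df = bins − 1, expected rescaled to the observed total,
0·ln 0 = 0). The two-sample t-test from summaries uses the pooled (Student)
variance by default — the form that reproduces published p-values computed
from such summaries — with Welch available via a flag. The 2×2 chi-square is
uncorrected, df = 1. Pearson correlation uses the t-transform p-value with
n − 2 df.

## The phantom generator

The generator emulates the *measurable structure* of a denoised bouton
tomogram: spherical vesicles (synaptic ~40 nm; medium 50–120 nm as dense
core with/without a light halo, or light lumen), a plasma membrane rendered
as a slab at the low-z volume face, microtubules as hollow tubes
(12.5/7.5 nm outer/inner radius) along polylines, thin linker filaments of
controlled gap length, membrane-attached protrusion rods, and additive
i.i.d. Gaussian noise applied to density only (labels stay exact).

Density defaults: cytoplasm 0, membranes −2 (arbitrary units), linkers and
protrusions at membrane density — protein filaments image at least as dense
as lipid bilayers — and dense cores at −1.2. SNR is defined as membrane
contrast over noise sd.

Linker gap lengths are drawn from a normal truncated below at 2 voxels (the
shortest linker with guaranteed cytoplasmic voxel support), with the parent
parameters solved numerically so the *realised* distribution has exactly the
requested mean and sd (defaults 15.5 ± 7.7 nm for connectors, 19.8 ± 11.7 nm
for tethers). Connector topology is `pairs` (default), `chain`, or `star`;
placement is rejection sampling with a cap of 1000 attempts per object and
explicit failure, never silent truncation. Vesicles joined by a connector
are placed at exactly surface gap + radii apart; tethered vesicles at
exactly their gap above the membrane.

Two geometric consistency rules keep the ground truth well defined: objects
not joined by a linker keep a minimum surface separation (default 6 voxels,
so that membrane halos produced by low-pass filtering cannot fuse across
objects), and linkers sharing a vesicle subtend at least 80°, so distinct
linkers have disjoint voxel support. Linkers are rasterised as a cylinder of
the requested radius (2.4 nm default) unioned with a voxel-traversal line
that crosses one voxel face at a time — this guarantees the rendered linker
is 6-connected and face-adjacent to both boundary labels, which a thin
cylinder alone does not.

What the phantom does **not** emulate: the missing wedge, CTF, reconstruction
artifacts, anisotropic resolution, actin networks, SER sheet geometry, and
the spatially correlated noise of real detectors. Passing recovery tests on
phantoms therefore demonstrates the correctness of the segmentation,
measurement and statistics machinery under known geometry and additive
noise — not detection performance on raw instrument data.

The optional Gaussian low-pass (`smooth_stand_in`) stands in for the
edge-preserving denoising used upstream of such analyses; it is *not*
equivalent. Gaussian smoothing bleeds membrane density into a 1–2 voxel
unlabeled halo, which is why heavy smoothing degrades tether detection next
to large flat membranes. The recovery experiments use sigma = half a voxel
(1.6 nm at 3.2 nm voxels), which suppresses voxel noise without creating
long-range halos; noise-free volumes are segmented directly.

## Problem sizes and numerical choices

Recovery experiments use 160³ voxel phantoms (512 nm cube at 3.2 nm voxels)
with 100 vesicles in 50 connector pairs — large enough for ≥ 50 connectors
with the full length distribution, small enough to run in tens of seconds.
The ZTP type-I calibration uses 200 replicates of n = 257 counts. Root
finding tolerances are 1e−12 (inversion residuals ~1e−13); the G-test bins
follow the fixed pooling above; radial-trace fidelity is judged against a
10× supersampled direct radial average, with per-shell deviations measured
as a fraction of the trace's dynamic range (a relative criterion is
meaningless near zero-density shells). All randomness flows from a single
seed through `numpy.random.default_rng`; reports are byte-identical across
runs with the same config.

## Known limitations

* The 320 nm³ volume cap rejects long thin linkers by construction; recovery
  is therefore reported against all detected 2-bound segments with filter
  classes attached.
* B2C and C2C are voxel-grid estimators; sub-voxel accuracy is limited to
  about one voxel regardless of interpolation.
* Tether detection under heavy Gaussian smoothing is structurally impaired
  (membrane halo aggregation); use light smoothing or edge-preserving
  denoising upstream.
* The chord-angle curvature conversion is exact only for sampling on a
  circular arc; for irregular curves it is an approximation tied to the
  0.5 µm spacing convention.
* `multi` segments are localised but not split into their 2-bound parts.
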