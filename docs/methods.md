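# Methods

This note documents the models, conventions and numerical choices behind
`gliovasc`, in the spirit of a methods supplement: what each stage assumes,
which parameters matter, and what the synthetic benchmark does and does not
establish about real tissue.

## Conventions

Arrays are `(c, z, y, x)` with 0-based voxel indices; physical coordinates
are voxel-center positions in µm, with the center of voxel *i* at
*i*·voxel_size. `voxel_size` is ordered (z, y, x) and may be anisotropic;
every distance-bearing operation (EDT, marching cubes, PSF construction,
profile sampling) receives the spacing explicitly. All randomness flows
from a single integer seed through named `SeedSequence` substreams, so a
run is bit-reproducible.

## Synthetic confocal generator

The generator emulates 60-µm-class tissue blocks (default scene
64×128×128 µm at 0.5 µm isotropic voxels — desk-scale, but deep enough in z
for 3D morphometry) containing:

- **Vessel tree.** A declarative list of capsule segments (start, end,
  radius 1–30 µm) with declared branch nodes. `build_vessel_tree` validates
  radii, containment, connectivity, branch-node incidence
  (daughters + 1 incident segments) and rejects non-adjacent segments
  closer than the sum of radii. `make_branching_tree` constructs connected
  trees with a requested count of primary/secondary/tertiary junctions
  (trunks joined by a spine; the interior tee joints are themselves primary
  junctions and are included in the ground truth).
- **Basement membrane (COL-IV).** The shell −t_shell < s ≤ 0 of the signed
  surface distance s = d(centerline) − r; default t_shell = 1.5 µm.
  Fenestration removes 2×2 µm surface patches by a Bernoulli draw per
  patch. The per-patch uniform is drawn once per (tree, seed), so a sweep
  over `gap_fraction` at fixed seed yields *nested* gap sets — marginally
  still Bernoulli(gap), but monotone per seed, which is what a
  dose-response readout should see. The true gap fraction is stored as the
  zeroed/total patch-count ratio.
- **Endothelium (CD31).** At light-microscopy resolution the endothelial
  lining and the membrane are apposed, so coincident CD31 occupies the same
  shell band (t_endo defaults to t_shell); the non-coincident remainder is
  displaced to the band just beneath the membrane. Patches are assigned
  coincident/displaced by a greedy controller that tracks the requested
  *voxel-count* coincidence fraction (patch counts alone would be biased
  because inner-band patches hold fewer voxels). Ground-truth overlap is
  always recomputed by brute-force voxel counting of the ideal masks.
- **Cells.** Nuclei are Gaussian spheres (σ = diameter/4, default diameter
  7 µm) placed by rejection sampling with a minimum center distance of one
  diameter, outside vessels. CD3 and Iba-1 cells are soft-edged uniform
  spheres (uniform marker expression over the cell body; a 0.5 µm linear
  edge ramp) and each carries a DAPI nucleus. T cells are placed at voxels
  whose EDT to the CD31 mask matches each requested distance within half a
  voxel; the stored true distance is the exact EDT value at the chosen
  voxel. Myeloid MHCII amplitudes are drawn from a two-component Gaussian
  mixture (defaults 20 ± 5 vs 50 ± 5, 50/50 — a 6-SD separation) with the
  component label stored per cell.
- **Niches.** In `tumor_mass` mode GFAP fills one half-volume (the nest) at
  the reference intensity and the stroma half receives diffuse MHCII at 0.6×
  the reference plus the myeloid cells (which are placed in the stroma);
  the half-volumes are the ground-truth niche masks. `protoplasmic` mode
  scatters GFAP blobs and defines no niches.
- **Optics.** A separate stage blurs with an anisotropic Gaussian PSF
  (defaults σ = 0.75/0.35/0.35 µm z/y/x, a mid-NA confocal regime at these
  voxel sizes) and applies Poisson-scaled shot noise plus additive Gaussian
  read noise (defaults scale 1.0, sd 2.0 at reference intensity 100),
  clipping at zero. The ideal render is kept separate so oracles can use
  noise-free masks.

What the generator does **not** emulate: realistic vessel tortuosity and
tapering, astrocyte morphology, depth-dependent attenuation and scattering,
chromatic shifts, or spatially varying background. Passing the benchmark
therefore demonstrates correctness of the measurement pipeline on its
stated geometry, not robustness to every artifact of patient material.

## Restoration

Deconvolution is Richardson–Lucy with a parametric Gaussian PSF (kernel
truncated at 4σ, normalized; a σ below half a voxel triggers an
undersampling warning). The implementation uses FFT convolution with a
flat initial estimate; where the re-blurred estimate predicts essentially
no photons (below 10⁻¹² of the image peak) the multiplicative correction
is left at zero rather than divided out, which keeps the iteration stable
on empty background. Non-negativity is preserved every iteration and flux
is conserved to well under 1% for structures away from the borders. The
stage is optional and off by default for synthetic scenes rendered without
blur. Blind deconvolution and measured PSFs are out of scope.

## Segmentation

Masks are Gaussian-smoothed (default σ 0.5 µm), thresholded (Otsu by
default — deterministic and parameter-free; an absolute override is
recorded), labeled with 26-connectivity, and filtered by a minimum unit
volume (default 50 µm³, operationalizing "cell-size particles"). Volume is
voxel counting; surface area is marching cubes on the binary unit smoothed
by one voxel — raw binary marching cubes overestimates curved surfaces by
~8% (staircase artifact), while the smoothed 0.5-level set recovers a
10-µm sphere's area within ~1%.

Nucleus detection is single-scale Laplacian-of-Gaussian matched to the
expected diameter (σ = d/4), with a relative response threshold (20% of
the maximum, making counts invariant to global intensity scaling) and
exact Euclidean greedy non-maximum suppression at 0.7·d (Chebyshev-window
suppression would silently drop diagonal neighbors). The stereological
dissector tiles the guarded volume with half-open boxes so each spot counts
in exactly one box and guard-zone spots are excluded.

## Vessel morphometry

The vessel mask is resampled to isotropic voxels, morphologically closed
(default ball radius 2 µm — the fenestration patch scale; the shipped
pipeline scenario uses 4 µm because Bernoulli gaps cluster into wider
holes at gap fractions ≈ 0.2), hole-filled so the membrane encloses a
solid lumen, thinned with 3D skeletonization, and traced into a graph:
nodes are endpoints or 26-connected junction-voxel clusters, edges carry
ordered centerline points with per-point radius from the EDT of the filled
mask. Terminal spurs shorter than 1.5× the local radius are pruned and
pass-through nodes dissolved.

Caliber is 2×EDT radius per centerline point, summarized per edge by the
median; bins default to ≤ 5 µm (small, anchored to the silent-collateral
definition), 5–10 µm (medium, a declared default) and > 10 µm (large).
Junctions within a 3 µm fusion radius merge before classification — a
w-shape is two close bifurcations — and daughters = emanating − 1 with
2/3/≥4 mapping to primary/secondary/tertiary. One wording conflict is
resolved explicitly: secondary junctions are read as *three* daughter
branches (the daughter-count reading), tertiary as four or more.

## Wall integrity

Fenestration is read from single 1-µm optical slices (the mean of the
planes spanning 1 µm when the z pitch is finer). Wall lines of 40 µm are
tiled without overlap along the mask boundary contour with a seeded
starting phase — automated placement replacing manual tracing. Intensity
is sampled bilinearly at 1 µm arc-length steps; *relative fluorescence* is
normalized per profile to its own maximum (a declared convention — the
alternative per-image or per-cohort normalizations would break scale
invariance of single traces); profiles are truncated to their first 27 µm;
the metric is the per-profile *population* SD (divisor N, declared to
avoid N vs N−1 ambiguity). An intact membrane yields SD ≈ 0 (interpolation
error < 0.02) and the group mean rises monotonically with gap fraction.

## Barrier overlap

Overlap is voxel-based on the two masks (mirroring a colocalization-
channel workflow), not mesh–mesh intersection. Fractions are reported
relative to COL-IV, to CD31 and to their union, since the normalization
basis of a published "percent overlap" is ambiguous; the Venn triple and
intersection volume use the strict intersection and are symmetric in the
arguments. An optional symmetric distance tolerance (off by default; one
voxel offered) accounts for the membrane and endothelium being apposed,
not identical, layers.

## Immune infiltration

CD3 spots must coincide with a DAPI spot within one cell radius (a T cell
must have a nucleus). Distance is measured from the cell centroid to the
CD31 mask surface via anisotropy-aware EDT (0 inside or touching);
centroid-to-surface is declared because membrane-to-membrane would hinge
on an ambiguous cell radius. Contact (extravasating) is distance ≤ 2 µm —
a declared, configurable operationalization; distance statistics are over
migrated cells only. Whether intravascular (luminal) cells should be
excluded from totals is left to the caller; the synthetic scenes place
none.

## Myeloid histocytometry

Cells are the Iba-1 mask split by nearest-DAPI-seed assignment (seeds must
lie within half a nucleus diameter of the mask); equidistant voxels go to
the first seed deterministically. The gating basis is the per-cell *mean*
MHCII (not max; declared), gated by 1D Otsu (scale-invariant) or an
absolute override. The niche map smooths GFAP and MHCII at σ = 10 µm,
rescales each by a robust (99.5th-percentile, clipped) maximum, marks
voxels below the background level in *both* channels as background, and
assigns the rest by argmax with ties to the nest. The background parameter
is interpreted as a relative level on the [0,1] density rather than an
empirical voxel quantile: with sparse foreground the median voxel is ~0
and an empirical quantile would classify nothing as background. TSR is the
nest/stroma volume ratio (error on zero stroma); per-niche vessel
statistics attribute vessel voxels and skeleton points to the niche
containing them.

## Statistics

`compare_two`: an F-test on the variance ratio (two-tailed, α = 0.05)
routes to the pooled-variance or Welch t-test (two-tailed). Under a
seeded normal null this two-stage procedure's type-I error stays within
0.05 ± 0.02 (checked over 2000 replicates). `compare_many`: Shapiro–Wilk
per group (α = 0.05) routes to one-way ANOVA with Tukey HSD or Dunnett
(first group = control), or to Kruskal–Wallis with Dunn's rank tests under
Šidák adjustment (implemented directly, with tie correction). The routing
is a declared policy — the underlying publications state only that tests
were chosen "accordingly" — and every result records which branch fired.
Stars follow *p<0.05 / **p<0.01 / ***p<0.001 / ****p<0.0001 as a pure
function of adjusted p. Group summaries are mean ± SEM. Pearson
correlations drop missing values pairwise and flag constant columns as
undefined rather than reporting 0.

## Pipeline and determinism

`run_pipeline` validates the YAML config against a declared schema
(unknown keys are rejected before any stage runs), executes the stages in
dependency order, caches artifacts in the output directory, and assembles
one JSON report with provenance (config, its hash, seed, version — no
timestamps). Reports and CSV tables are byte-identical across reruns with
equal config and seed; OME-TIFF image artifacts embed a writer-generated
UUID and are excluded from that guarantee. The shipped scenario completes
in well under two minutes on one CPU.

## Problem sizes

Benchmarks use desk-scale scenes chosen to keep the full suite fast while
leaving each estimate well-conditioned: tubes in 48–96 µm blocks for
caliber recovery, a 22-junction tree in 64×192×192 µm for noisy taxonomy
recovery, 20 wall traces × 27 µm for the fenestration sweep, 500 nuclei
for counting, 300 myeloid cells for gating, and 2000 null replicates for
test calibration.

## Known limitations

- Topology recovery assumes segment lengths > ~4× radius; heavily
  fenestrated masks need a closing radius matched to the largest expected
  gap cluster, and the closing slightly rounds junction concavities.
- The fenestration metric is 2D (slice-based), as in the tracing protocol
  it automates; a surface-based 3D fenestration map is out of scope.
- Histocytometry assumes roughly convex, nucleus-bearing cells; ramified
  processes are attributed by proximity, not morphology.
- The Bernoulli-patch fenestration model is a stand-in with one dial, not
  an inference about fenestration geometry in tissue.
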