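# gliovasc

Quantification of the 3D vascular microenvironment in human glioblastoma
(GBM) from multichannel confocal volumes.

High-grade gliomas remodel their vasculature: calibers grow, single (y/t-
shaped) bifurcations proliferate, the collagen-IV basement membrane becomes
fenestrated, the CD31 endothelium decouples from the membrane, T cells stall
at or cross the vessel wall, and Iba-1⁺ myeloid cells (GAMMs — glioma-
associated microglia and macrophages) split into an MHCII-High stromal and
an MHCII-Low tumor-nest phenotype. `gliovasc` turns immunofluorescence
z-stacks (DAPI / GFAP / COL-IV / CD31 / Iba-1 / MHCII / CD3) into the
corresponding measurements:

- **Vessel morphometry** — 3D skeletonization; per-point caliber
  *d* = 2·EDT(centerline); small/medium/large binning; junction taxonomy by
  daughter count (2 = primary, 3 = secondary, ≥ 4 = tertiary); silent
  collaterals (*d* ≤ 5 µm, too narrow for blood-cell passage).
- **Wall integrity** — luminance profiles along 40-µm wall traces in 1-µm
  optical slices, harmonized to the first 27 µm; fenestration read out as
  the per-trace SD of relative fluorescence *I(s)/max I*.
- **Barrier coincidence** — voxelwise COL-IV/CD31 overlap fractions and
  Venn volumes of the two isosurface masks.
- **Immune infiltration** — CD3⁺ cell detection (nucleus-checked), distance
  to the endothelium by Euclidean distance transform, classification into
  extravasating (≤ 2 µm contact) vs migrated.
- **Histocytometry** — nucleus-seeded GAMM segmentation, per-cell mean
  intensities, MHCII-High gating, tumor-nest/stroma niche partition and the
  tumor–stroma ratio TSR = V(nest)/V(stroma), with per-niche vessel stats.
- **Statistics** — Welch/Student routing by variance F-test,
  ANOVA/Kruskal–Wallis with Tukey/Dunnett/Dunn–Šidák post-hocs, Pearson
  correlation matrices, mean ± SEM summaries.

Because patient volumes are not publicly deposited, the package ships a
synthetic confocal generator (`gliovasc.synthetic`) that renders vessel
trees with controllable calibers, branch orders, membrane gap fraction,
endothelium coincidence, nuclei, T cells at exact distances, and
mixture-MHCII myeloid cells — with complete ground truth — so every stage
is testable end to end.

## Worked example

```python
import numpy as np
from gliovasc import synthetic as syn, segmentation as seg, morphometry as morph

spec = syn.make_branching_tree((64, 128, 128), n_primary=4, n_secondary=1,
                               n_tertiary=1)
tree = syn.build_vessel_tree(spec)
volume, gt = syn.render_volume(tree, syn.RenderParams(), seed=2)
noisy = syn.apply_optics(volume, psf_sigmas=(0.75, 0.35, 0.35),
                         noise=(1.0, 2.0), seed=2)

mask = seg.make_mask(noisy["COLIV"], volume.voxel_size, source_channel="COLIV")
skel = morph.skeletonize_vessels(mask)
records, totals = morph.classify_branch_points(skel)
print(gt.tree.branch_class_counts())
print({k: totals[k] for k in ("primary", "secondary", "tertiary")})
```

prints

```
{'primary': 4, 'secondary': 1, 'tertiary': 1}
{'primary': 4, 'secondary': 1, 'tertiary': 1}
```

i.e. the full threshold → skeletonize → classify pipeline recovers the
generated junction taxonomy exactly, even with PSF blur and Poisson–
Gaussian noise applied.

The same workflow is available from a shell:

```bash
gliovasc simulate --out out/            # synthetic volume + ground truth
gliovasc run-all --out out/             # full pipeline, report.json + CSVs
gliovasc vessels out/volume.ome.tif --out out/edges.csv
```

`run-all` executes simulate → (optional deconvolve) → segment → vessels →
walls → overlap → tcells → myeloid → stats on one reproducible seed; the
report and all CSVs are byte-identical across reruns with the same config.

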