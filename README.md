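# chromodomain3d

Quantitative 3D morphometry of H3K27ac chromatin domains in multi-channel
super-resolution microscopy Z-stacks.

Active enhancers carry the histone mark H3K27ac. In structured-illumination
(SIM) images of cell nuclei, H3K27ac accumulates in discrete chromatin
domains whose shape and position report on chromatin state: compact,
near-spherical ("closed") domains versus larger, elongated ("open") ones,
and peripheral (lamina-proximal) versus interior localization. In hormone
signalling studies these domains are imaged together with a DAPI nuclear
counterstain and an estrogen-receptor (ERα) channel, and the questions are
quantitative: how large and how spherical are the domains, how far from the
nuclear boundary do they sit, and how tightly does ER binding track H3K27ac
within them, across treatment conditions?

`chromodomain3d` implements that analysis as a tested, reusable pipeline:

1. **Z interpolation** — raw stacks sample 0.06 μm laterally but 0.15 μm
   axially; two weighted-average slides
   (`I = 2/3·I_near + 1/3·I_far`) are inserted per gap, giving a uniform
   0.05 μm axial grid (N slides → 3N−2).
2. **Nucleus segmentation** — per slide: DAPI gate (> 500 ADU), 8-connected
   components (top 15), hole-fill / 10 dilations / hole-fill, then a size
   (≥ 100,000 px) and circularity (4πA/P² > 0.4) filter; Sobel boundary
   extraction; slides stacked into a 3D mask.
3. **Channel alignment** — the systematic ER-vs-H3K27ac lateral offset is
   found by exhaustive integer-shift Pearson cross-correlation and undone.
4. **Domain detection** — the detection threshold is the 99.9th percentile
   of the *extranuclear* H3K27ac intensities (the value exceeded by the top
   0.1% of background); in-nucleus voxels above it are grouped into 3D
   26-connected components, refined (hole fill, two dilations, hole fill),
   clipped to the nucleus, and kept if 10–100,000 voxels.
5. **Per-domain features** — volume (voxels and μm³); sphericity
   φ = π^⅓ (6V)^⅔ / S with S from a marching-cubes mesh at physical
   spacing; Pearson correlation of per-voxel H3K27ac and ER intensities;
   anisotropy-aware distance from the domain centroid to the nearest
   nuclear-boundary voxel; principal-axis length.
6. **Statistics** — one-sided Welch t-tests and per-batch t summaries;
   Kruskal–Wallis omnibus gating Bonferroni-corrected pairwise
   Mann–Whitney U tests; Shapiro–Wilk / Kolmogorov–Smirnov normality
   annotation; per-cell Gini indices of each feature as a heterogeneity
   measure; four-class volume distributions; length-vs-volume regression.

A fully ground-truthed **synthetic stack generator** (ellipsoidal nucleus,
sphere/tube domain populations, tunable H3K27ac–ER coupling ρ, PSF blur,
camera noise, known channel shift) makes every stage verifiable without
microscope data; see `docs/methods.md` for the imaging model.

## Worked example

```python
from chromodomain3d.synthetic_data import SyntheticSpec, generate_experiment
from chromodomain3d.pipeline import synthetic_pipeline_config, run_pipeline
import pandas as pd

generate_experiment("demo", ["open_rich", "closed_rich"], n_cells=2, n_batches=1,
                    seed=1, base_spec=SyntheticSpec(channel_shift=(2, -3)))
config = synthetic_pipeline_config(manifest="demo/manifest.csv", out_dir="demo/out")
report = run_pipeline(config)

features = pd.read_csv("demo/out/features.csv")
print(features.groupby("condition")[["volume_um3", "sphericity", "correlation",
                                     "boundary_distance_um"]].mean().round(3))
print("estimated ER shift (dy, dx):", report["cells"]["batch0/cell0/open_rich"]["shift"])
battery = report["statistics"]["batteries"]["volume_um3"]["pairwise"][0]
print("volume, open_rich vs closed_rich: U=%.0f, Bonferroni p=%.2e"
      % (battery["statistic"], battery["corrected_p"]))
```

prints

```
             volume_um3  sphericity  correlation  boundary_distance_um
condition
closed_rich       0.493       0.971        0.083                 0.845
open_rich         0.915       0.878        0.117                 1.262
estimated ER shift (dy, dx): [2, -3]
volume, open_rich vs closed_rich: U=309, Bonferroni p=6.68e-06
```

The open-rich condition shows larger, less spherical domains that sit
deeper in the nucleus and couple more tightly to ER — and the generator's
deliberately injected 2-pixel-down, 3-pixel-left ER offset is recovered
exactly before any cross-channel feature is computed.

The same stages are available from the shell:

```bash
chromodomain3d simulate --out demo --conditions open_rich,closed_rich --shift 2 -3
chromodomain3d interpolate --in stack.tif --out stack_interp.tif
chromodomain3d segment-nuclei --in stack_interp.tif --out nucleus.tif
chromodomain3d align --in stack_interp.tif --out aligned.tif --report shift.json
chromodomain3d detect-domains --in aligned.tif --nucleus nucleus.tif --table domains.csv
chromodomain3d run --config pipeline.yaml
```

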