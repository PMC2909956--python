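# leafmorph

3D morphometry of leaf tissues from cell-wall-stained confocal and
multiphoton z-stacks.

Leaf phenotyping usually stops at surface area and epidermal cell
counts, because the internal tissues — palisade and spongy mesophyll —
are hidden from 2D imaging. When a cleared, wall-stained leaf is
optically sectioned through its full thickness, every tissue becomes
measurable: `leafmorph` turns such a stack (bright cell walls, dark
lumina and airspaces) into leaf thickness, volumetric tissue
proportions, per-tissue cell densities, per-cell dimensions (volume,
length, width, maximum cross-section area, surface area), estimates of
the intercellular airspace, and total cell surface area per tissue
volume — plus a per-cell 3D structural model.

It is written for plant scientists running quantitative leaf-growth or
phenotyping studies on Arabidopsis-like dicot leaves, where stacks are
acquired at strongly anisotropic voxels (e.g. 0.22 × 0.22 × 0.8 μm).

## Pipeline

For a stack `I(x, y, z)` with the z axis running adaxial → abaxial:

1. **Wall mask** — 1-D k-means (k = 2) on voxel intensities, Lloyd
   iterations from fixed quantile initialisation; wall = brightest
   cluster, threshold = midpoint of the top two centers. In one
   dimension this converges to the partition minimising within-cluster
   sum of squares for bimodal stacks.
2. **Tissue bands** — per-xy-column leaf surfaces (first/last wall
   signal along z, median-filtered), then three internal boundaries
   — adaxial epidermis | palisade | spongy | abaxial epidermis — from
   horizontal wall-sheet detection snapped to band-thickness priors,
   or from user polylines drawn in the xz view (guided mode).
3. **Cells** — 26-connected components of the non-wall leaf interior;
   optional user seed points split under-segmented components by
   watershed on the interior distance transform. Components are
   classified cell vs intercellular space (ICS) by volume, in-plane
   solidity and exterior connectivity, and assigned the tissue holding
   the majority of their voxels.
4. **Morphometry** — thickness `(z_ab − z_ad)·dz`; tissue fractions;
   densities per mm² of leaf and per mm³ of tissue; per-cell volume,
   length (z extent), width (max xy Feret diameter), max xy area, and
   surface area from a smoothed marching-cubes isosurface (sphere test
   within 0.5% of `4πr²`). The airspace of a mesophyll band is
   estimated by bookkeeping: `V_ics = V_tissue − n·V̄`, with `V̄` the
   mean wall-inclusive cell volume; `SA:V = Σ surface / V_tissue`
   in mm² mm⁻³.

Because no annotated real stacks are publicly deposited, validation is
built in: `leafmorph.phantom` generates synthetic leaves with complete
voxel ground truth (per-cell labels, airspace network, wall mask, band
map) and a realistic optics model (anisotropic blur, depth attenuation,
photon + read noise). Every pipeline stage is tested as a recovery
experiment against that truth.

## Worked example

```python
import leafmorph as lm

spec = lm.LeafPhantomSpec(
    field_um=(64.0, 64.0),
    band_um=(12.0, 24.0, 24.0, 12.0),          # adaxial epi/palisade/spongy/abaxial epi
    cell_diameter_um={"adaxial_epidermis": 16.0, "palisade": 13.0,
                      "spongy": 12.0, "abaxial_epidermis": 14.0},
    geometry=lm.VoxelGeometry(0.4, 0.4, 0.8),  # μm
    seed=1,
)
stack, truth = lm.generate_phantom(spec)

wall = lm.kmeans_threshold(stack)
bands = lm.delineate_tissues(stack, wall, priors=spec.band_um)
labels = lm.classify_components(lm.segment_cells(wall, bands, spec.geometry), bands)
report = lm.summarize(bands, labels, spec.geometry)
```

Output of this exact run:

```
threshold: 95.8   cluster centers [22.6, 168.9]
thickness: 72.0 ± 0.00 μm   (rel. range 0.0000)
proportions: {adaxial_epidermis: 0.167, palisade: 0.333, spongy: 0.333, abaxial_epidermis: 0.167}
cell counts: {adaxial_epidermis: 21, palisade: 53, spongy: 66, abaxial_epidermis: 26}
density mm^-2: {adaxial_epidermis: 5127, palisade: 12939, spongy: 16113, abaxial_epidermis: 6348}
ICS fraction: {palisade: 0.0, spongy: 0.265}
SA:V mm^2 mm^-3: {palisade: 315.7, spongy: 225.7}
```

The ground truth for the same phantom
(`lm.ground_truth_morphometrics(truth)`) reports a spongy airspace
fraction of 0.252 (direct voxel count) and SA:V of 317.1 / 237.4
mm² mm⁻³, so the image-based estimates land within a few percent. The
measured thickness equals the constructed 72 μm leaf exactly, and the
SA:V values are high compared with mature mesophyll (tens of
mm² mm⁻³) simply because this small test phantom uses small cells —
surface per volume scales inversely with cell size.

Real stacks enter the same way through
`lm.read_stack("stack.tif", geometry=lm.VoxelGeometry(0.22, 0.22, 0.8))`.

## Command line

```sh
leafmorph generate --project demo --preset arabidopsis_mature --seed 1
leafmorph segment  --project demo --stack-id phantom_seed1
leafmorph measure  --project demo --stack-id phantom_seed1
leafmorph model    --project demo --stack-id phantom_seed1 --tissues palisade
leafmorph report   --project demo --stack-id phantom_seed1
```

Each command writes into a project layout (`raw/`, `treated/`,
`measurements/` plus a JSON manifest) and drops a run record (config,
version, timing) beside its outputs; stacks are multi-page TIFF with
embedded voxel size, label volumes 16-bit TIFF, tables CSV with unit
header comments, meshes OBJ with one group per cell, and volumes can be
exported to NIfTI-1 for external slice viewers.

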