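# Methods

This note documents the models, conventions and numerical choices
behind `leafmorph`, in the order the pipeline runs, and states what the
synthetic validation does and does not establish about real data.

## Coordinate and unit conventions

Stacks are addressed `(x, y, z)` with z the optical-section axis,
increasing from the adaxial (upper) toward the abaxial (lower) leaf
surface; datasets acquired abaxial-first are flipped on load
(`read_stack(..., flip_z=True)`). On disk, multi-page TIFF pages are
z-slices in `(z, y, x)` order. Voxel indices are 0-based, z-intervals
half-open `[start, end)`, and the physical position of a voxel centre
is `index · voxel_size + half voxel`. All physical quantities derive
from the `VoxelGeometry` in μm and are never silently rescaled; NIfTI
exports keep μm pixdims as-is (documented, rather than rescaled to mm,
because microscopy slice viewers accept raw pixdims). Cell densities
convert to mm⁻²/mm⁻³ and surface area per tissue volume to mm² mm⁻³
(1 μm⁻¹ = 1000 mm² mm⁻³).

## Wall thresholding

Voxel intensities are clustered by weighted 1-D k-means over the
intensity histogram (exact for integer dtypes), k = 2 by default.
Centers start at evenly spaced quantiles (25th/75th), Lloyd iterations
run to a 1e-6 center tolerance, ties at a cluster midpoint join the
lower cluster, and the wall mask is the brightest cluster. The
reported threshold is the midpoint of the top two centers. The
implementation is deterministic; the `seed` argument exists only for
interface stability. For bimodal wall-stained stacks the converged
solution coincides with the exhaustive within-cluster-SSE minimiser
over sorted splits, which the test suite verifies against a brute-force
oracle. A constant-intensity stack is a hard error.

## Tissue delineation

Leaf surfaces are found per xy column as the first and last wall voxel
along z, after removing small noise components (26-connected, < 64
voxels) and a radius-1 morphological closing; surface maps are
median-filtered over a 5 × 5 column window to suppress single-column
jitter. Internal boundaries in automated mode come from horizontal
wall-sheet detection: at a cell-layer interface nearly the whole
z-slice is wall, so runs of slices whose wall fraction exceeds 0.8
(measured on the pre-closing mask, since closing inflates slices next
to thick airspace walls) mark interface planes, with the run centre as
the boundary. Candidate runs are snapped to band-thickness priors
(defaults 10/40/40/10% of local thickness; configurable), which
disambiguates intra-band layer interfaces from band boundaries; absent
a plausible candidate the prior position is used. Guided mode takes
per-boundary polylines in the xz plane, interpolates them across x and
applies them to all y — the faithful path when automated placement is
not trusted. Boundaries are forced strictly increasing per column, and
the band order is fixed: adaxial epidermis, palisade, spongy, abaxial
epidermis.

## Cell segmentation and classification

Non-wall voxels between the surfaces are grouped by 26-connectivity
(anisotropic z-spacing makes diagonal lumen connections common; wall
continuity uses 6-connectivity where checked). Wall gaps a single
voxel wide would merge neighbouring cells, so the wall mask is closed
with a radius-1 structuring element in **all three axes** before
labeling: at dz ≈ 0.8 μm the dominant leak path is axial, through the
thin horizontal walls between stacked cells, and an xy-only closing
leaves several-fold higher cell-count error. The closing acts as a
connectivity veto only — voxels it removed are afterwards returned to
their nearest component (capped at one voxel diagonal), so component
volumes stay unbiased. Components smaller than 20 μm³ or thinner than
2 μm along any axis are below the sampling resolution of the imaging
this package targets and are reabsorbed into wall.

User seed points (μm coordinates, from semi-automated inspection)
falling inside one component split it by watershed on the interior
Euclidean distance transform with anisotropic sampling; splitting
conserves voxels exactly. Labels are ordered by component centroid
(z, then y, then x) for stability. Components touching the xy stack
border are flagged: they count toward densities (truncation does not
bias a count) but are excluded from dimension statistics (truncation
biases sizes).

Classification: each component takes the tissue holding the majority
of its voxels — a 3D criterion, so a palisade cell that looks ambiguous
in a single xz section is still classified by where it lies. A
component is intercellular space when it is much larger than a
plausible cell (default ceiling 8× the median component volume) *and*
lobed in-plane (solidity of its largest xy cross-section below 0.4), or
when it reaches the ambient exterior beyond the leaf surfaces. A
second pass reclassifies sub-cell-sized components (below
max(50 μm³, ¼ median)) whose **raw-mask** connectivity joins an
airspace component: these are corridor fragments pinched off by the
closing, not cells — a genuinely enclosed small cell keeps its own raw
component. All thresholds are configurable.

## Morphometry

* **Thickness** at an xy position is `(z_abaxial − z_adaxial) · dz`,
  taken as the median over a 5 × 5 column block; the summary reports
  mean, SD and the within-stack relative range `(max − min)/mean`,
  which is the quality-control statistic for intra-stack consistency.
* **Tissue proportions** are band voxel counts over leaf voxel counts
  and sum to 1 by construction.
* **Per-cell dimensions**: volume = component voxels × voxel volume;
  length = z extent; width = the maximum Feret diameter over xy
  sections, measured on voxel outlines (pixel corners), so an a×b-pixel
  rectangle yields the full physical diagonal; max area = largest
  single xy cross-section. Surface area comes from marching cubes with
  physical vertex spacing on a lightly pre-smoothed mask (σ = 1 voxel),
  which places the level set at sub-voxel positions: a digitised
  r = 5 μm sphere at 0.2 μm voxels measures within 0.5% of 4πr²,
  whereas raw binary meshing overestimates by ~9% and naive voxel-face
  counting by ~50% (face counting is therefore not used for
  reporting). Sharp corners are rounded by the smoothing, so a cube
  reads a few percent low — acceptable for cells, which are rounded.
* **Wall-inclusive cell volume**: every wall voxel inside the leaf is
  attributed to its nearest cell (anisotropy-aware), so each cell's
  "territory" runs to the wall midline — the quantity an
  outline-traced cell yields, and the one that is robust to where the
  intensity threshold cuts the blurred wall flanks. Reported volume
  statistics use these territories (excluding border cells); the raw
  lumen volume remains available per cell.
* **Airspace estimate**: for a mesophyll band,
  `V_tissue = fraction × thickness × field area`,
  `V_ics = V_tissue − n · V̄`, where n counts cells with centroid in
  the field (including border cells) and `V̄` is the mean
  wall-inclusive volume of those same cells — truncated border
  territories are then balanced by cells protruding in from outside
  the field. Because airspace keeps no wall share, cell territories
  plus airspace account for the band exactly on ground-truth labels,
  which is what makes the estimator consistent with direct voxel
  counts. A small negative difference is floored at zero with a
  warning; a deficit beyond 5% of `V_tissue` is an error flagging
  inconsistent inputs.
* **Surface area per tissue volume** sums per-cell isosurface areas
  over the band volume; **airspace-contact fraction** of a cell is
  face-area based: every exposed voxel face counts as airspace-facing
  when airspace lies within one wall thickness (default 2 μm) beyond
  it, measured by a distance transform from the airspace voxels. It
  returns undefined (not 0) when no airspace class exists.

## The leaf phantom

The phantom provides the ground truth that real stacks lack. Cells
are nearest-seed (Voronoi) regions of Poisson-disc-sampled seed points,
built per cell layer: one columnar layer per epidermis, the configured
number of layers for palisade (round/columnar) and spongy (lobed).
Seeds are sampled over the field plus a one-diameter margin, so border
cells are genuine truncations of complete cells — the imaged field is
a crop of a continuing leaf, as in reality. Spongy lobedness displaces
the assignment coordinates by a smooth random field (control points
every 3.5 μm). Walls are thresholds on the Lipschitz margin
`m = (d₂ − d₁)/2` between the two nearest seeds (half the nominal
2 μm wall on each side of an interface), plus horizontal walls at every
layer interface; the outer epidermal walls get the full wall thickness,
as the cuticle-bearing periclinal walls are visibly thicker in real
stacks and a one-slice surface wall would not survive attenuation.

Airspace is carved along the inter-cell corridors of a mesophyll band
at a fixed physical caliber (half-width 1.25 μm); a smooth selector
field chooses *which* corridors are carved, and its threshold is
binary-searched until the band's airspace fraction hits the target
(tolerance 0.01) — more airspace means more channels, never
unresolvably thin ones. A 1.4 μm single-wall shell separates lumina
from airspace. Degenerate products of the construction — lumina below
20 μm³ or thinner than 2 μm in any axis, isolated air pockets below
125 μm³ — are reabsorbed into wall; a closure-repair pass guarantees
that no lumen touches airspace, a foreign lumen, or the exterior, even
diagonally. The partition wall ∪ cells ∪ airspace = leaf interior is
exact by construction and asserted in tests.

All geometry is defined in physical coordinates on fixed control
grids, so one spec and seed rasterise to consistent structures at
different voxel sizes; this is what the resolution-consistency
experiment (dz 0.8 vs 0.4 μm: thickness within 1.6 μm, mean cell
volumes within 5%) exercises. Generation is deterministic per seed.

**Optics.** The image renders walls at intensity 200, lumina 12,
background 5 on an 8-bit scale, then applies an anisotropic Gaussian
blur (σ = 0.25 μm lateral, 0.55 μm axial — the two-photon PSF scale of
a NA 1.2 water objective at 790 nm), multiplicative exponential depth
attenuation (10⁻³ μm⁻¹; non-descanned multiphoton detection loses
little signal in depth), Poisson photon noise and Gaussian read noise
(σ = 3). These defaults emulate the image quality that makes simple
thresholding viable on real multiphoton data — continuous bright
walls, cells closed at top and bottom; confocal-grade degradation
(stronger attenuation and noise) can be dialled in but is not the
validated default.

**Presets.** `arabidopsis_mature` (bands 15/60/60/15 μm ≈ the 150 μm
leaf-blade thickness scale at the end of expansion; two palisade and
two spongy layers; spongy airspace 0.25), `arabidopsis_young` (thinner
bands, smaller cells, airspace 0.12), `apple` (denser, smaller cells
and spongy airspace 0.38, the cellular organisation that distinguishes
apple from Arabidopsis leaves). Wall thickness (2 μm rendered),
corridor caliber and airspace connectivity are plausible values chosen
for resolvability at the emulated sampling, not literature
measurements.

## What the validation shows — and does not

Passing recovery tests show the pipeline correctly measures stacks
whose signal obeys the phantom's assumptions: additive-noise bimodal
intensities, flat leaf, closed walls thicker than ~1.4 μm, airspace as
a channel network. Real leaves add curvature of the blade, veins and
trichomes (absent here; veins would appear as unclassified texture),
stain heterogeneity, mounting-induced compression, and cell walls that
locally thin below resolution — none of which the phantom emulates, so
field data still require the guided delineation mode and seed-assisted
splitting that the package exposes. On noiseless phantoms recovery is
exact (band boundaries and counts); under default optics, cell-count
error averages ~2% over ten seeds (occasionally up to ~5% on a single
realisation, from lobed cells pinched at a waist), median per-cell
Jaccard ≈ 0.99, airspace fraction agrees with direct voxel counts to
≈ 0.015, and mean cell volumes to ≈ 1–2%.

## Problem sizes

The test-suite phantom is a 64 × 64 μm field, 72 μm leaf at
0.4 × 0.4 × 0.8 μm voxels (~2.6 M voxels, ~170 cells), small enough
that a full generate–segment–measure cycle runs in seconds while
keeping realistic proportions between cell diameter, wall thickness
and voxel size. The quality-control script uses a 256 × 256 pixel
field at the acquisition voxel size (0.22 × 0.22 × 0.8 μm) and the
full 150 μm mature-leaf architecture (~12.8 M voxels). Batch users
can scale `field_um` freely; memory grows linearly in voxel count and
the full-field 1024 × 1024 acquisition format (~0.2 G voxels) is best
processed per-tile.

## Known limitations

* Automated internal boundaries assume near-flat leaves; strongly
  curved or obliquely mounted samples need guided mode (surfaces are
  still found per column, so thickness tolerates moderate tilt).
* The ICS classifier's volume ceiling and solidity floor are tuned for
  mesophyll architectures where airspace forms one large lobed
  network; tissues with many medium, isolated lacunae would need the
  exterior-connectivity rule or manual thresholds.
* Surface areas of sharply faceted objects read a few percent low due
  to pre-mesh smoothing; for cells this is negligible against
  segmentation uncertainty.
* Length is defined along the stack z axis, not each cell's principal
  axis; for strongly inclined cells the two differ.
* The per-cell airspace-contact fraction is voxel-face based, not
  mesh-patch based; its resolution is one voxel face.
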