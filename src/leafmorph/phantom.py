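"""Synthetic leaf phantoms with complete voxel ground truth.

The phantom emulates what a cell-wall-stained leaf looks like in a
multiphoton/confocal z-stack — bright continuous walls, dark cell
lumina and intercellular airspace — over the four-band architecture of
a dicot leaf blade: adaxial epidermis (one layer of pavement-like
cells), palisade mesophyll (round/columnar cells, default two layers),
spongy mesophyll (lobed, loosely arranged cells with a connected
airspace network, default two layers), abaxial epidermis.

Cells are grown from Poisson-disc-sampled seed points as
nearest-seed regions per cell layer, so walls are equidistant surfaces;
spongy lobedness comes from a smooth random displacement of the
assignment coordinates.  Airspace is carved along the inter-cell wall
corridors of the spongy (optionally palisade) band until the target
volume fraction is met.  All geometry is defined in physical (μm)
coordinates on fixed control grids, so the same spec and seed rasterise
to consistent structures at different voxel sizes.

Ground truth (band map, per-cell labels, airspace labels, wall mask) is
computed before the optics model — anisotropic Gaussian blur,
exponential depth attenuation along z, Poisson photon noise plus
Gaussian read noise — degrades the image.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, replace
from functools import cached_property
import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.interpolate import RegularGridInterpolator
from scipy.spatial import cKDTree

from . import morphometry
from .morphometry import LeafMorphometrics, cell_density
from .segment import MESOPHYLL, TISSUES, CellLabelVolume, TissueBandMap, _component_table
from .stack_io import ImageStack, VoxelGeometry

__all__ = [
    "LeafPhantomSpec",
    "GroundTruth",
    "PRESETS",
    "preset",
    "generate_phantom",
    "ground_truth_morphometrics",
]

_CONN26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class LeafPhantomSpec:
    """Parameters of one synthetic leaf stack.

    Band thicknesses, cell diameters, wall thickness and optics are all
    in μm; ``ics_fraction`` is the target airspace volume fraction per
    mesophyll band.  Defaults describe a mature Arabidopsis blade:
    bands summing to 150 μm (the leaf-blade scale at the end of
    expansion), two palisade and two spongy cell layers.
    """

    field_um: tuple[float, float] = (56.32, 56.32)
    band_um: tuple[float, float, float, float] = (15.0, 60.0, 60.0, 15.0)
    palisade_layers: int = 2
    spongy_layers: int = 2
    cell_diameter_um: dict[str, float] = field(default_factory=lambda: {
        "adaxial_epidermis": 22.0, "palisade": 16.0,
        "spongy": 14.0, "abaxial_epidermis": 18.0,
    })
    lobedness: float = 0.5
    ics_fraction: dict[str, float] = field(default_factory=lambda: {
        "palisade": 0.0, "spongy": 0.25,
    })
    wall_thickness_um: float = 2.0
    #: half-width of carved airspace channels (μm); channels keep this
    #: caliber and the target fraction is met by carving more or fewer
    #: of the inter-cell corridors, as in loosely packed spongy tissue
    corridor_halfwidth_um: float = 1.25
    #: thickness of the single wall between a cell lumen and airspace
    #: (μm); thinner than two abutting cell walls but thick enough to
    #: stay resolvable at the axial sampling of the emulated microscope
    air_wall_um: float = 1.4
    blur_sigma_um: tuple[float, float] = (0.25, 0.55)  # (lateral, axial)
    attenuation_per_um: float = 0.001
    read_noise: float = 3.0
    photon_noise: bool = True
    wall_intensity: float = 200.0
    lumen_intensity: float = 12.0
    background_intensity: float = 5.0
    geometry: VoxelGeometry = field(default_factory=lambda: VoxelGeometry(0.22, 0.22, 0.8))
    pad_um: float = 4.0
    #: lumina shards below this volume are reabsorbed into wall — no
    #: real cell lumen is this small at any imaging scale
    min_lumen_um3: float = 20.0
    #: isolated airspace pockets below this volume are filled back to
    #: wall: spongy airspace is a connected channel network, and a
    #: disconnected micro-pocket would be indistinguishable from a cell
    min_air_um3: float = 125.0
    seed: int = 0
    #: control-point spacing of the lobedness displacement field (μm)
    lobe_scale_um: float = 3.5
    ics_tolerance: float = 0.01

    def validate(self) -> None:
        if any(b <= 0 for b in self.band_um):
            raise ValueError("band thicknesses must be positive")
        for tissue, f in self.ics_fraction.items():
            if not (0 <= f < 1):
                raise ValueError(f"ICS target for {tissue} must be in [0, 1)")
        for tissue, d in self.cell_diameter_um.items():
            band = self.band_um[TISSUES.index(tissue)]
            if d <= 0:
                raise ValueError(f"cell diameter for {tissue} must be positive")
            if tissue in MESOPHYLL and d > band:
                raise ValueError(
                    f"{tissue} cell diameter {d} μm exceeds band thickness {band} μm")
        if self.wall_thickness_um <= 0:
            raise ValueError("wall thickness must be positive")
        if self.pad_um < 2 * self.geometry.dz:
            raise ValueError("padding must leave at least 2 background slices")

    @property
    def thickness_um(self) -> float:
        return float(sum(self.band_um))

    def layer_count(self, tissue: str) -> int:
        if tissue == "palisade":
            return self.palisade_layers
        if tissue == "spongy":
            return self.spongy_layers
        return 1


def _arabidopsis_mature() -> LeafPhantomSpec:
    return LeafPhantomSpec()


def _arabidopsis_young() -> LeafPhantomSpec:
    return LeafPhantomSpec(
        band_um=(8.0, 22.0, 22.0, 8.0),
        cell_diameter_um={"adaxial_epidermis": 11.0, "palisade": 8.0,
                          "spongy": 7.5, "abaxial_epidermis": 10.0},
        ics_fraction={"palisade": 0.0, "spongy": 0.12},
        lobedness=0.35,
    )


def _apple() -> LeafPhantomSpec:
    # denser cells and a larger spongy airspace than Arabidopsis
    return LeafPhantomSpec(
        band_um=(12.0, 55.0, 70.0, 13.0),
        cell_diameter_um={"adaxial_epidermis": 15.0, "palisade": 11.0,
                          "spongy": 10.0, "abaxial_epidermis": 13.0},
        ics_fraction={"palisade": 0.05, "spongy": 0.38},
        lobedness=0.6,
    )


PRESETS = {
    "arabidopsis_mature": _arabidopsis_mature,
    "arabidopsis_young": _arabidopsis_young,
    "apple": _apple,
}


def preset(name: str, **overrides) -> LeafPhantomSpec:
    """A named phantom preset, optionally with field overrides."""
    try:
        spec = PRESETS[name]()
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")
    return replace(spec, **overrides) if overrides else spec


# ---------------------------------------------------------------------------
# Ground truth container
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Voxel ground truth of a phantom.

    ``labels`` holds the classified component volume (cells then
    airspace components, wall/background 0); the partition invariant
    wall ∪ cells ∪ airspace = leaf interior holds exactly, and every
    cell lumen is closed (never touches the leaf exterior).
    """

    bands: TissueBandMap
    labels: CellLabelVolume
    wall_mask: np.ndarray
    geometry: VoxelGeometry
    spec: LeafPhantomSpec

    @property
    def thickness_um(self) -> np.ndarray:
        """True per-column leaf thickness field (μm)."""
        return self.bands.thickness_steps().astype(float) * self.geometry.dz

    def ics_voxel_fraction(self, tissue: str) -> float:
        """Realised airspace fraction of a mesophyll band, by voxel count."""
        i = TISSUES.index(tissue)
        lo = self.bands.boundaries[0, 0, i]
        hi = self.bands.boundaries[0, 0, i + 1]
        band = self.labels.labels[:, :, lo:hi]
        ics_ids = self.labels.labels_of_class("ics")
        n_band = band.size
        if n_band == 0:
            return 0.0
        return float(np.isin(band, ics_ids).sum() / n_band)

    @cached_property
    def cell_records(self) -> pd.DataFrame:
        """Per-cell true morphometrics, measured directly on the labels."""
        recs = [morphometry.cell_dimensions(self.labels, int(cid))
                for cid in self.labels.labels_of_class("cell")]
        return pd.DataFrame([r.__dict__ for r in recs])


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _poisson_disc_xy(rng: np.random.Generator, fx: float, fy: float,
                     diameter: float) -> np.ndarray:
    """Dart-throwing blue-noise seed points over the xy field (μm).

    Spacing ~0.85× the requested mean cell diameter.  Points are drawn
    over the field plus a one-diameter margin on every side, so cells at
    the image border are genuine truncations of complete cells — the
    imaged field is a crop of a continuing leaf, exactly as in a real
    stack.  The draw sequence depends only on the physical field and
    diameter, never on the voxel grid, so seed layouts are identical
    across rasterisations.
    """
    min_dist = 0.85 * diameter
    mrg = diameter
    ex, ey = fx + 2 * mrg, fy + 2 * mrg
    n_target = max(1, math.ceil(ex * ey / (0.82 * diameter**2)))
    attempts = 60 * n_target
    pts: list[np.ndarray] = []
    for _ in range(attempts):
        cand = rng.random(2) * (ex, ey) - mrg
        if all((cand[0] - p[0])**2 + (cand[1] - p[1])**2 >= min_dist**2 for p in pts):
            pts.append(cand)
            if len(pts) >= n_target:
                break
    if not pts:
        pts = [np.array([fx / 2, fy / 2])]
    return np.asarray(pts)


def _split_layers(lo: int, hi: int, n: int) -> list[tuple[int, int]]:
    edges = np.rint(np.linspace(lo, hi, n + 1)).astype(int)
    return [(int(edges[i]), int(edges[i + 1])) for i in range(n)]


def _closure_repair(cell_labels: np.ndarray, lumen: np.ndarray,
                    air: np.ndarray, wall: np.ndarray,
                    max_iter: int = 4) -> None:
    """Convert lumen voxels that touch airspace or a foreign lumen to wall.

    The analytic wall thresholds already guarantee separation almost
    everywhere; this pass removes the rare residual contacts (at most a
    voxel-thin layer) so that 26-connected components can never merge
    two cells or a cell with the airspace.  Arrays are modified in
    place.
    """
    big = np.iinfo(cell_labels.dtype).max
    for _ in range(max_iter):
        air_near = ndimage.binary_dilation(air, structure=_CONN26)
        lab_lumen = np.where(lumen, cell_labels, 0)
        max_near = ndimage.maximum_filter(lab_lumen, size=3)
        lab_masked = np.where(lumen, cell_labels, big)
        min_near = ndimage.minimum_filter(lab_masked, size=3)
        bad = lumen & (air_near | (max_near > cell_labels)
                       | (min_near < cell_labels))
        if not bad.any():
            return
        lumen[bad] = False
        wall[bad] = True
        cell_labels[bad] = 0


def generate_phantom(spec: LeafPhantomSpec) -> tuple[ImageStack, GroundTruth]:
    """Rasterise a phantom leaf: image stack plus voxel ground truth.

    Deterministic for a fixed seed.  Raises ``ValueError`` for an
    infeasible spec (cells larger than their band, or an airspace
    target unreachable at the given packing).
    """
    spec.validate()
    g = spec.geometry
    dx, dy, dz = g.as_tuple()
    fx, fy = spec.field_um
    nx, ny = max(4, round(fx / dx)), max(4, round(fy / dy))
    steps = [max(2, round(b / dz)) for b in spec.band_um]
    pad = max(2, round(spec.pad_um / dz))
    b = np.concatenate([[pad], pad + np.cumsum(steps)])
    nz = int(b[4] + pad)
    rng = np.random.default_rng(spec.seed)

    # --- displacement noise for spongy lobedness, on a fixed physical grid
    c = spec.lobe_scale_um
    zmax_phys = spec.thickness_um + 2 * spec.pad_um + 4 * dz
    cx = np.arange(-c, fx + 2 * c, c)
    cy = np.arange(-c, fy + 2 * c, c)
    cz = np.arange(-c, zmax_phys + 2 * c, c)
    amp = spec.lobedness * 0.45 * min(spec.cell_diameter_um.get("spongy", 10.0), 2 * c)
    disp_grid = rng.normal(size=(len(cx), len(cy), len(cz), 2)) * amp
    disp = RegularGridInterpolator((cx, cy, cz), disp_grid, method="linear",
                                   bounds_error=False, fill_value=0.0)

    # --- seed points per cell layer (slab), adaxial → abaxial
    slabs = []  # (tissue_idx, z_lo, z_hi, seeds_xy, label_offset)
    next_label = 1
    for ti, tissue in enumerate(TISSUES):
        layers = spec.layer_count(tissue)
        for (lo, hi) in _split_layers(int(b[ti]), int(b[ti + 1]), layers):
            seeds = _poisson_disc_xy(rng, fx, fy, spec.cell_diameter_um[tissue])
            slabs.append((ti, lo, hi, seeds, next_label))
            next_label += len(seeds)

    # --- nearest-seed assignment per slab; m = half margin to the nearest
    #     inter-cell boundary (Lipschitz-1 lower bound on the distance)
    region = np.zeros((nx, ny, nz), dtype=np.int32)
    m = np.full((nx, ny, nz), np.inf, dtype=np.float32)
    xs = (np.arange(nx) + 0.5) * dx
    ys = (np.arange(ny) + 0.5) * dy
    base_xy = np.stack(np.meshgrid(xs, ys, indexing="ij"), axis=-1).reshape(-1, 2)
    tissue_of_label = np.zeros(next_label, dtype=np.int8)
    for ti, lo, hi, seeds, offset in slabs:
        tissue_of_label[offset:offset + len(seeds)] = ti
        tree = cKDTree(seeds)
        kq = min(2, len(seeds))
        lobed = TISSUES[ti] == "spongy" and spec.lobedness > 0
        for z in range(lo, hi):
            q = base_xy
            if lobed:
                zp = np.full((base_xy.shape[0], 1), (z + 0.5) * dz)
                q = base_xy + disp(np.concatenate([base_xy, zp], axis=1))
            dist, idx = tree.query(q, k=kq)
            if kq == 1:
                region[:, :, z] = (offset + idx).reshape(nx, ny)
            else:
                region[:, :, z] = (offset + idx[:, 0]).reshape(nx, ny)
                m[:, :, z] = (0.5 * (dist[:, 1] - dist[:, 0])).reshape(nx, ny)

    # --- horizontal walls at every slab interface and the leaf surfaces.
    # The outer epidermal walls (periclinal wall + cuticle) are thicker
    # than internal walls, as in real leaves; this also keeps the
    # surfaces detectable at depth where attenuation dims the signal.
    z_phys = (np.arange(nz) + 0.5) * dz
    t2 = spec.wall_thickness_um / 2.0
    t_outer = spec.wall_thickness_um
    horiz = np.zeros(nz, dtype=bool)
    in_leaf_z = np.zeros(nz, dtype=bool)
    for ti, lo, hi, _, _ in slabs:
        zz = z_phys[lo:hi]
        top_t = t_outer if lo == b[0] else t2
        bot_t = t_outer if hi == b[4] else t2
        horiz[lo:hi] |= (zz - lo * dz <= top_t) | (hi * dz - zz <= bot_t)
        in_leaf_z[lo:hi] = True
    in_leaf = np.zeros((nx, ny, nz), dtype=bool)
    in_leaf[:, :, in_leaf_z] = True

    # --- airspace carving per mesophyll band with a non-zero target.
    # Channels follow the inter-cell corridors (small m) at a fixed
    # physical caliber; a smooth selector field decides which corridors
    # are carved, and its threshold is binary-searched to realise the
    # target volume fraction — more airspace means more channels, not
    # unresolvably thin ones.
    air = np.zeros((nx, ny, nz), dtype=bool)
    margin = spec.wall_thickness_um
    h0 = spec.corridor_halfwidth_um
    sel_grid = rng.normal(size=(len(cx), len(cy), len(cz)))
    selector = RegularGridInterpolator((cx, cy, cz), sel_grid, method="linear",
                                       bounds_error=False, fill_value=3.0)
    for ti, tissue in enumerate(TISSUES):
        target = spec.ics_fraction.get(tissue, 0.0)
        if target <= 0:
            continue
        lo, hi = int(b[ti]), int(b[ti + 1])
        band_m = m[:, :, lo:hi]
        zz = z_phys[lo:hi]
        carve_z = (zz - lo * dz > margin) & (hi * dz - zz > margin)
        if not carve_z.any():
            raise ValueError(f"{tissue} band too thin to carve airspace")
        sval = np.empty(band_m.shape, dtype=np.float32)
        for j, z in enumerate(range(lo, hi)):
            zp = np.full((base_xy.shape[0], 1), (z + 0.5) * dz)
            sval[:, :, j] = selector(
                np.concatenate([base_xy, zp], axis=1)).reshape(nx, ny)
        corridor = (band_m <= h0) & carve_z[None, None, :]
        n_band = band_m.size
        if corridor.sum() / n_band < target:
            raise ValueError(
                f"airspace target {target} unreachable in {tissue} at this packing")
        q_lo, q_hi = float(sval.min()) - 1.0, float(sval.max()) + 1.0
        for _ in range(50):
            q = 0.5 * (q_lo + q_hi)
            frac = (corridor & (sval <= q)).sum() / n_band
            if abs(frac - target) <= spec.ics_tolerance:
                break
            if frac < target:
                q_lo = q
            else:
                q_hi = q
        air[:, :, lo:hi] = corridor & (sval <= q)

    wall = in_leaf & ((m <= t2) | horiz[None, None, :]) & ~air
    if air.any():
        # a single-wall shell separates every lumen from airspace
        dist_air = ndimage.distance_transform_edt(~air, sampling=(dx, dy, dz))
        wall |= in_leaf & ~air & (dist_air <= spec.air_wall_um)
    lumen = in_leaf & ~wall & ~air
    cell_labels = np.where(lumen, region, 0).astype(np.int32)
    _closure_repair(cell_labels, lumen, air, wall)

    # --- final ground-truth components: connected lumina are the cells
    min_vox = max(8, round(spec.min_lumen_um3 / g.voxel_volume))
    cc, n_cells = ndimage.label(lumen, structure=_CONN26)
    cc = cc.astype(np.int32)
    counts = np.bincount(cc.ravel())
    tiny = set((np.nonzero(counts[1:] < min_vox)[0] + 1).tolist())
    # lumina thinner than 2 μm along any axis are below the sampling
    # resolution (a real cell is resolvable top and bottom) — reabsorb
    min_ext = [max(3, math.ceil(2.0 / d)) for d in (dx, dy, dz)]
    for lab_i, sl in enumerate(ndimage.find_objects(cc), start=1):
        if sl is not None and any(s.stop - s.start < e for s, e in zip(sl, min_ext)):
            tiny.add(lab_i)
    if tiny:
        kill = np.isin(cc, np.fromiter(tiny, dtype=np.int32))
        wall |= kill
        lumen &= ~kill
        cc[kill] = 0
        cc, n_cells = ndimage.label(lumen, structure=_CONN26)
        cc = cc.astype(np.int32)
    air_cc, n_air = ndimage.label(air, structure=_CONN26)
    air_counts = np.bincount(air_cc.ravel())
    min_air_vox = max(8, round(spec.min_air_um3 / g.voxel_volume))
    tiny_air = np.nonzero(air_counts[1:] < min_air_vox)[0] + 1
    if len(tiny_air):
        kill = np.isin(air_cc, tiny_air)
        wall |= kill
        air &= ~kill
        air_cc[kill] = 0
        air_cc, n_air = ndimage.label(air, structure=_CONN26)
    labels = cc.copy()
    labels[air] = air_cc[air] + n_cells

    boundaries = np.tile(b[None, None, :], (nx, ny, 1)).astype(np.int64)
    bands = TissueBandMap(boundaries=boundaries, nz=nz)

    table = _component_table(labels, g)
    band_codes = np.zeros(nz, dtype=np.int8)
    for i in range(4):
        band_codes[b[i]:b[i + 1]] = i + 1
    tissue_col, class_col = [], []
    nlab = int(labels.max())
    joint = np.bincount(labels.ravel().astype(np.int64) * 5
                        + band_codes[np.newaxis, np.newaxis, :]
                        .repeat(nx, 0).repeat(ny, 1).ravel(),
                        minlength=(nlab + 1) * 5).reshape(nlab + 1, 5)
    for row in table.itertuples():
        l = int(row.label)
        tissue_col.append(TISSUES[int(np.argmax(joint[l, 1:]))])
        class_col.append("cell" if l <= n_cells else "ics")
    table["tissue"] = tissue_col
    table["class"] = class_col
    table["volume_um3"] = table["n_voxels"] * g.voxel_volume
    table["provenance"] = "truth"
    label_volume = CellLabelVolume(labels=labels, table=table, geometry=g)
    truth = GroundTruth(bands=bands, labels=label_volume, wall_mask=wall,
                        geometry=g, spec=copy.deepcopy(spec))

    # --- optics: rasterised scene → blur → depth attenuation → noise
    img = np.full((nx, ny, nz), spec.background_intensity, dtype=np.float32)
    img[lumen] = spec.lumen_intensity
    img[air] = spec.background_intensity
    img[wall] = spec.wall_intensity
    sx, sz = spec.blur_sigma_um
    if sx > 0 or sz > 0:
        img = ndimage.gaussian_filter(img, sigma=(sx / dx, sx / dy, sz / dz))
    if spec.attenuation_per_um > 0:
        img *= np.exp(-spec.attenuation_per_um * z_phys)[None, None, :].astype(np.float32)
    if spec.photon_noise:
        img = rng.poisson(np.clip(img, 0, None)).astype(np.float32)
    if spec.read_noise > 0:
        img += rng.normal(0.0, spec.read_noise, size=img.shape).astype(np.float32)
    voxels = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    stack = ImageStack(voxels=voxels, geometry=g,
                       sample_id=f"phantom_seed{spec.seed}")
    return stack, truth


# ---------------------------------------------------------------------------
# Ground-truth morphometrics: the reference for recovery experiments
# ---------------------------------------------------------------------------

def ground_truth_morphometrics(gt: GroundTruth,
                               geometry: VoxelGeometry | None = None,
                               include_surface: bool = True) -> LeafMorphometrics:
    """Reference morphometrics computed directly from the labels.

    No image processing is involved: thickness comes from the band map,
    airspace fractions from direct voxel counts of the airspace labels,
    densities and volume statistics from the component table, surface
    areas from the true per-cell isosurfaces.  Used as the oracle in
    recovery experiments against the measurement pipeline.
    """
    geometry = geometry or gt.geometry
    bands = gt.bands
    nx, ny = bands.shape_xy
    roi_area_um2 = nx * geometry.dx * ny * geometry.dy
    roi_area_mm2 = roi_area_um2 / 1e6
    th = gt.thickness_um
    mean_th = float(th.mean())
    props = morphometry.tissue_proportions(bands)
    widths = np.diff(bands.boundaries, axis=2).sum(axis=(0, 1)).astype(float)
    band_volume_um3 = dict(zip(TISSUES, widths * geometry.voxel_volume))

    t = gt.labels.table
    incl = morphometry.wall_inclusive_volumes(gt.labels, bands)
    counts, d2, d3 = {}, {}, {}
    vmean, vmin, vmax = {}, {}, {}
    icsf, icsv, sav = {}, {}, {}
    warnings: list[str] = []
    records = gt.cell_records if include_surface else None
    for tissue in TISSUES:
        sel = (t["class"] == "cell") & (t["tissue"] == tissue)
        n = int(sel.sum())
        counts[tissue] = n
        dens = cell_density(n, roi_area_mm2, band_volume_um3[tissue] / 1e9)
        if dens.warning:
            warnings.append(f"{tissue}: {dens.warning}")
        d2[tissue], d3[tissue] = dens.per_mm2, dens.per_mm3
        interior_ids = t.loc[sel & ~t["border"], "label"].astype(int)
        vols = incl.reindex(interior_ids).dropna().to_numpy()
        if len(vols):
            vmean[tissue], vmin[tissue], vmax[tissue] = (
                float(vols.mean()), float(vols.min()), float(vols.max()))
        else:
            vmean[tissue] = vmin[tissue] = vmax[tissue] = float("nan")
        if tissue in MESOPHYLL:
            frac = gt.ics_voxel_fraction(tissue) if n or True else 1.0
            if n == 0:
                frac = 1.0
            icsf[tissue] = frac
            icsv[tissue] = frac * band_volume_um3[tissue]
            if include_surface and n:
                recs = records[records["tissue"] == tissue]
                sav[tissue] = (recs["surface_area_um2"].sum()
                               / band_volume_um3[tissue]) * 1000.0
            else:
                sav[tissue] = float("nan")
    return LeafMorphometrics(
        thickness_mean_um=mean_th,
        thickness_sd_um=float(th.std(ddof=0)),
        thickness_rel_range=float((th.max() - th.min()) / mean_th) if mean_th else 0.0,
        proportions=props,
        cell_count=counts,
        density_per_mm2=d2,
        density_per_mm3=d3,
        cell_volume_mean_um3=vmean,
        cell_volume_min_um3=vmin,
        cell_volume_max_um3=vmax,
        ics_fraction=icsf,
        ics_volume_um3=icsv,
        surface_area_per_volume_mm2_mm3=sav,
        warnings=warnings,
    )
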