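"""Segmentation of cell-wall-stained leaf stacks.

Three stages mirror the measurement workflow for wall-stained z-stacks:

1. :func:`kmeans_threshold` — separate bright wall signal from dark
   lumina/airspace/background by 1-D k-means on voxel intensities.
2. :func:`delineate_tissues` — find the two leaf surfaces per xy column
   and split the interior into the four bands (adaxial epidermis,
   palisade, spongy, abaxial epidermis), automatically or from user
   guide polylines drawn in xz view.
3. :func:`segment_cells` / :func:`classify_components` — label the
   enclosed lumina as cells, split under-segmented components from user
   seed points (watershed on the interior distance transform), and
   classify each component as cell or intercellular space with a tissue
   assignment.

Conventions: voxel indices are 0-based, z-intervals are half-open
``[start, end)``, physical position of a voxel centre is
``index * voxel_size + half voxel``.  Lumina use 26-connectivity
(anisotropic z-spacing makes diagonal connections common); wall
continuity is checked with 6-connectivity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from skimage.segmentation import watershed

from .stack_io import ImageStack, VoxelGeometry

__all__ = [
    "TISSUES",
    "MESOPHYLL",
    "WallMask",
    "TissueBandMap",
    "CellLabelVolume",
    "kmeans_threshold",
    "delineate_tissues",
    "segment_cells",
    "classify_components",
    "count_cells",
]

#: Band order, adaxial → abaxial.  Integer band codes are 1..4 in this
#: order; 0 means outside the leaf.
TISSUES = ("adaxial_epidermis", "palisade", "spongy", "abaxial_epidermis")
MESOPHYLL = ("palisade", "spongy")

_CONN26 = np.ones((3, 3, 3), dtype=bool)


# ---------------------------------------------------------------------------
# Wall mask via 1-D k-means
# ---------------------------------------------------------------------------

@dataclass
class WallMask:
    """Boolean wall-signal mask plus the clustering that produced it."""

    mask: np.ndarray
    threshold: float
    centers: np.ndarray  # sorted ascending

    def __post_init__(self) -> None:
        c = np.sort(np.asarray(self.centers, dtype=float))
        if len(c) >= 2 and not (c[-2] < self.threshold < c[-1]):
            raise ValueError(
                f"threshold {self.threshold} not between top cluster centers {c[-2:]}"
            )
        self.centers = c


def _kmeans_1d(values: np.ndarray, weights: np.ndarray, k: int,
               tol: float = 1e-6, max_iter: int = 300) -> np.ndarray:
    """Weighted 1-D Lloyd's algorithm on distinct values.

    Centers are initialised at evenly spaced quantiles (25th/75th for
    k=2), which is deterministic and, in one dimension, converges to the
    optimal split for well-separated modes.  Ties at a cluster midpoint
    go to the lower cluster.
    """
    order = np.argsort(values)
    v, w = values[order].astype(float), weights[order].astype(float)
    cw = np.cumsum(w)
    total = cw[-1]
    qs = (2 * np.arange(k) + 1) / (2 * k)
    centers = np.array([v[np.searchsorted(cw, q * total)] for q in qs], dtype=float)
    centers = np.unique(centers)
    while len(centers) < k:  # degenerate quantiles: spread within range
        centers = np.unique(np.append(centers, centers[-1] + 1e-9 * (1 + abs(centers[-1]))))
    cum_vw = np.concatenate([[0.0], np.cumsum(v * w)])
    cum_w = np.concatenate([[0.0], cw])
    for _ in range(max_iter):
        mids = 0.5 * (centers[:-1] + centers[1:])
        # boundary index per cluster: values <= mid belong below
        idx = np.searchsorted(v, mids, side="right")
        # a value exactly equal to a midpoint must join the lower cluster
        lo = np.concatenate([[0], idx])
        hi = np.concatenate([idx, [len(v)]])
        new = centers.copy()
        for j in range(k):
            wsum = cum_w[hi[j]] - cum_w[lo[j]]
            if wsum > 0:
                new[j] = (cum_vw[hi[j]] - cum_vw[lo[j]]) / wsum
        if np.max(np.abs(new - centers)) < tol:
            centers = new
            break
        centers = new
    return np.sort(centers)


def kmeans_threshold(stack: ImageStack | np.ndarray, k: int = 2,
                     seed: int | None = None) -> WallMask:
    """Threshold a stack into wall / non-wall by 1-D k-means.

    Wall = voxels assigned to the brightest cluster; the reported
    threshold is the midpoint between the two brightest adjacent
    centers.  The default path is deterministic (fixed quantile
    initialisation), so ``seed`` only matters for future stochastic
    restarts and is accepted for interface stability.

    Raises
    ------
    ValueError
        For ``k < 2`` or a constant-intensity (degenerate) stack.
    """
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    voxels = stack.voxels if isinstance(stack, ImageStack) else np.asarray(stack)
    if voxels.min() == voxels.max():
        raise ValueError("constant-intensity stack cannot be split")
    flat = voxels.ravel()
    if np.issubdtype(flat.dtype, np.integer):
        offset = int(flat.min())
        counts = np.bincount((flat - offset).astype(np.int64))
        values = np.nonzero(counts)[0].astype(float) + offset
        weights = counts[counts > 0].astype(float)
    else:
        values, weights = np.unique(flat, return_counts=True)
    centers = _kmeans_1d(values, weights, k)
    threshold = 0.5 * (centers[-2] + centers[-1])
    # ties at the threshold join the lower (non-wall) cluster
    mask = voxels > threshold
    return WallMask(mask=mask, threshold=float(threshold), centers=centers)


# ---------------------------------------------------------------------------
# Tissue band map
# ---------------------------------------------------------------------------

@dataclass
class TissueBandMap:
    """Per-xy-column z-boundaries of the four tissue bands.

    ``boundaries[x, y]`` holds five half-open z indices: adaxial
    surface, epidermis/palisade, palisade/spongy, spongy/abaxial
    epidermis, abaxial surface.  Band ``i`` (0-based over
    :data:`TISSUES`) occupies ``[boundaries[..., i], boundaries[..., i+1])``.
    """

    boundaries: np.ndarray  # (nx, ny, 5) integer
    nz: int

    def __post_init__(self) -> None:
        b = np.asarray(self.boundaries)
        if b.ndim != 3 or b.shape[2] != 5:
            raise ValueError(f"boundaries must be (nx, ny, 5), got {b.shape}")
        if np.any(np.diff(b, axis=2) <= 0):
            raise ValueError("band boundaries must be strictly increasing in every column")
        if b.min() < 0 or b.max() > self.nz:
            raise ValueError("band boundaries outside the stack z-range")
        self.boundaries = b.astype(np.int64)

    @property
    def shape_xy(self) -> tuple[int, int]:
        return self.boundaries.shape[:2]

    @property
    def top(self) -> np.ndarray:
        """Adaxial surface z-index per column."""
        return self.boundaries[..., 0]

    @property
    def bottom(self) -> np.ndarray:
        """Abaxial surface half-open end z-index per column."""
        return self.boundaries[..., 4]

    def thickness_steps(self) -> np.ndarray:
        return self.bottom - self.top

    def voxel_bands(self) -> np.ndarray:
        """Per-voxel band code volume: 0 outside, 1..4 = TISSUES order."""
        nx, ny = self.shape_xy
        z = np.arange(self.nz)[None, None, :]
        out = np.zeros((nx, ny, self.nz), dtype=np.uint8)
        for i in range(4):
            lo = self.boundaries[..., i][..., None]
            hi = self.boundaries[..., i + 1][..., None]
            out[(z >= lo) & (z < hi)] = i + 1
        return out

    def interior_mask(self) -> np.ndarray:
        z = np.arange(self.nz)[None, None, :]
        return (z >= self.top[..., None]) & (z < self.bottom[..., None])


def _close_wall(mask: np.ndarray, structure_size: tuple[int, int, int]) -> np.ndarray:
    """Morphological closing that does not erode wall at the volume border."""
    pad = tuple((s // 2, s // 2) for s in structure_size)
    padded = np.pad(mask, pad, mode="edge")
    closed = ndimage.binary_closing(padded, structure=np.ones(structure_size, bool))
    crop = tuple(slice(p[0], padded.shape[i] - p[1]) for i, p in enumerate(pad))
    return closed[crop]


def _drop_small(mask: np.ndarray, min_voxels: int) -> np.ndarray:
    """Remove 26-connected components smaller than ``min_voxels``."""
    lab, n = ndimage.label(mask, structure=_CONN26)
    if n == 0:
        return mask
    counts = np.bincount(lab.ravel())
    keep = counts >= min_voxels
    keep[0] = False
    return keep[lab]


def _wall_run_candidates(wall_frac: np.ndarray, z0: int, z1: int,
                         run_threshold: float) -> list[float]:
    """Centers of contiguous high-wall-fraction runs between the surfaces.

    A horizontal cell-layer interface shows up as a run of z-slices that
    are almost entirely wall; the interface plane sits at the run
    center.  Runs touching the surfaces are the surface walls themselves
    and are dropped.
    """
    high = wall_frac > run_threshold
    cands = []
    z = z0
    while z < z1:
        if high[z]:
            start = z
            while z < z1 and high[z]:
                z += 1
            end = z - 1
            if start > z0 and end < z1 - 1:
                cands.append((start + end + 1) / 2.0)
        else:
            z += 1
    return cands


def delineate_tissues(
    stack: ImageStack,
    wall: WallMask,
    mode: str = "automated",
    guides: Mapping[int, np.ndarray] | None = None,
    priors: Sequence[float] = (0.10, 0.40, 0.40, 0.10),
    closing_size: tuple[int, int, int] = (3, 3, 3),
    min_object_voxels: int = 64,
    surface_median: int = 5,
    run_threshold: float = 0.8,
    wall_fraction_floor: float = 0.005,
) -> TissueBandMap:
    """Delineate the four tissue bands from the wall mask.

    Leaf surfaces are the first/last wall signal per xy column along z,
    after removal of small noise components and a light morphological
    closing; surface maps are median-filtered over a small xy window to
    suppress single-column jitter.  Internal boundaries in automated
    mode come from horizontal wall-sheet detection (z-slices that are
    nearly all wall mark cell-layer interfaces) snapped to
    band-thickness priors; in guided mode from user polylines in the xz
    plane (columns ``(x_um, z_um)``, keyed 1..3 for the three internal
    boundaries, interpolated across x and constant in y).

    Raises
    ------
    ValueError
        When no leaf is found (wall fraction below floor) or guides cross.
    """
    mask = np.asarray(wall.mask, bool)
    if mask.shape != stack.voxels.shape:
        raise ValueError("wall mask not aligned with stack")
    if mask.mean() < wall_fraction_floor:
        raise ValueError("no leaf found: wall fraction below floor")
    nx, ny, nz = mask.shape
    if min_object_voxels > 1:
        mask = _drop_small(mask, min_object_voxels)
    mask_clean = mask  # pre-closing: used for the interface-run profile
    if closing_size is not None:
        mask = _close_wall(mask, closing_size)

    has_wall = mask.any(axis=2)
    if has_wall.mean() < 0.5:
        raise ValueError("no leaf found: too few columns with wall signal")
    top = np.argmax(mask, axis=2).astype(np.int64)
    bot1 = nz - np.argmax(mask[:, :, ::-1], axis=2).astype(np.int64)  # half-open
    med_top = int(np.median(top[has_wall]))
    med_bot1 = int(np.median(bot1[has_wall]))
    top[~has_wall] = med_top
    bot1[~has_wall] = med_bot1
    if surface_median and surface_median > 1:
        top = ndimage.median_filter(top, size=surface_median)
        bot1 = ndimage.median_filter(bot1, size=surface_median)
    bot1 = np.maximum(bot1, top + 4)  # at least one voxel per band

    z0g, z1g = int(np.median(top)), int(np.median(bot1))
    cum = np.cumsum(priors)[:3] / np.sum(priors)

    if mode == "guided":
        if not guides:
            raise ValueError("guided mode requires guide polylines")
        g = stack.geometry
        fracs = []
        xs_um = (np.arange(nx) + 0.5) * g.dx
        for k in (1, 2, 3):
            poly = np.asarray(guides[k], dtype=float)
            z_um = np.interp(xs_um, poly[:, 0], poly[:, 1])
            zk = z_um / g.dz  # absolute z index, same for all y
            fracs.append((zk - z0g) / max(z1g - z0g, 1))
        fr = np.stack(fracs, axis=-1)  # (nx, 3)
        if np.any(np.diff(fr, axis=-1) <= 0):
            raise ValueError("guide polylines cross or are out of order")
        fr = fr[:, None, :]  # broadcast over y
    else:
        wall_frac = mask_clean.reshape(-1, nz)[has_wall.ravel()].mean(axis=0)
        cands = _wall_run_candidates(wall_frac, z0g, z1g, run_threshold)
        chosen = []
        span = max(z1g - z0g, 1)
        for ck in cum:
            target = z0g + ck * span
            if cands:
                best = min(cands, key=lambda c: abs(c - target))
                # snap only when the candidate is plausibly this boundary
                if abs(best - target) <= 0.5 * span * min(np.diff([0, *cum, 1])):
                    chosen.append(best)
                    continue
            chosen.append(target)
        if np.any(np.diff(chosen) <= 0):  # collided candidates: fall back
            chosen = [z0g + ck * span for ck in cum]
        fr = (np.asarray(chosen) - z0g) / span
        fr = fr[None, None, :]

    span_col = (bot1 - top).astype(float)[..., None]
    internal = np.rint(top[..., None] + fr * span_col).astype(np.int64)
    boundaries = np.concatenate(
        [top[..., None], internal, bot1[..., None]], axis=-1
    )
    # enforce strict monotonicity within each column
    for i in range(1, 5):
        boundaries[..., i] = np.maximum(boundaries[..., i], boundaries[..., i - 1] + 1)
    boundaries[..., 4] = np.minimum(boundaries[..., 4], nz)
    for i in range(3, -1, -1):
        boundaries[..., i] = np.minimum(boundaries[..., i], boundaries[..., i + 1] - 1)
    if boundaries.min() < 0:
        raise ValueError("leaf too thin for four bands")
    return TissueBandMap(boundaries=boundaries, nz=nz)


# ---------------------------------------------------------------------------
# Cell label volume
# ---------------------------------------------------------------------------

@dataclass
class CellLabelVolume:
    """Integer label per voxel plus a component table.

    Label 0 is wall/background.  The table has one row per component:
    ``label, n_voxels, centroid_{x,y,z}_um, border, provenance`` and —
    after :func:`classify_components` — ``tissue`` and ``class``
    (``cell`` | ``ics``).  Bounding boxes are cached for fast per-cell
    measurement.
    """

    labels: np.ndarray
    table: pd.DataFrame
    geometry: VoxelGeometry

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("label volume must be 3D")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def mask_of(self, label: int) -> np.ndarray:
        return self.labels == label

    def bbox_of(self, label: int) -> tuple[slice, slice, slice]:
        row = self.table.loc[self.table["label"] == label]
        if row.empty:
            raise KeyError(f"label {label} not in component table")
        r = row.iloc[0]
        return (slice(int(r.x0), int(r.x1)), slice(int(r.y0), int(r.y1)),
                slice(int(r.z0), int(r.z1)))

    def labels_of_class(self, klass: str, tissue: str | None = None) -> np.ndarray:
        t = self.table
        if "class" not in t.columns:
            raise ValueError("components not classified yet")
        sel = t["class"] == klass
        if tissue is not None:
            sel &= t["tissue"] == tissue
        return t.loc[sel, "label"].to_numpy()


def _component_table(labels: np.ndarray, geometry: VoxelGeometry,
                     provenance: Mapping[int, str] | None = None) -> pd.DataFrame:
    n = int(labels.max())
    rows = []
    objects = ndimage.find_objects(labels)
    nx, ny, _ = labels.shape
    for lab in range(1, n + 1):
        sl = objects[lab - 1]
        if sl is None:
            continue
        sub = labels[sl] == lab
        nvox = int(sub.sum())
        idx = np.nonzero(sub)
        cx = (idx[0].mean() + sl[0].start + 0.5) * geometry.dx
        cy = (idx[1].mean() + sl[1].start + 0.5) * geometry.dy
        cz = (idx[2].mean() + sl[2].start + 0.5) * geometry.dz
        border = bool(sl[0].start == 0 or sl[0].stop == nx
                      or sl[1].start == 0 or sl[1].stop == ny)
        rows.append({
            "label": lab, "n_voxels": nvox,
            "centroid_x_um": cx, "centroid_y_um": cy, "centroid_z_um": cz,
            "border": border,
            "provenance": (provenance or {}).get(lab, "auto"),
            "x0": sl[0].start, "x1": sl[0].stop,
            "y0": sl[1].start, "y1": sl[1].stop,
            "z0": sl[2].start, "z1": sl[2].stop,
        })
    return pd.DataFrame(rows)


def _relabel_sorted(labels: np.ndarray, geometry: VoxelGeometry,
                    provenance: Mapping[int, str]) -> tuple[np.ndarray, dict[int, str]]:
    """Stable label ids: sort components by centroid (z, then y, then x)."""
    table = _component_table(labels, geometry)
    if table.empty:
        return labels, {}
    order = np.lexsort((table["centroid_x_um"], table["centroid_y_um"],
                        table["centroid_z_um"]))
    old = table["label"].to_numpy()[order]
    remap = np.zeros(int(labels.max()) + 1, dtype=labels.dtype)
    new_prov: dict[int, str] = {}
    for new_lab, old_lab in enumerate(old, start=1):
        remap[old_lab] = new_lab
        new_prov[new_lab] = provenance.get(int(old_lab), "auto")
    return remap[labels], new_prov


def segment_cells(
    wall: WallMask,
    bands: TissueBandMap,
    geometry: VoxelGeometry,
    seeds: Sequence[tuple[float, float, float]] | np.ndarray | None = None,
    closing_size: tuple[int, int, int] = (3, 3, 3),
    min_volume_um3: float = 20.0,
) -> CellLabelVolume:
    """Label enclosed lumina (and airspace) as 26-connected components.

    Non-wall voxels inside the leaf (between the per-column surfaces)
    are grouped; components smaller than ``min_volume_um3`` (no cell
    lumen is that small at any imaging scale) are dropped to wall.  User ``seeds`` — physical μm points, optionally produced by
    semi-automated inspection — that fall inside one component split it
    by watershed on the interior distance transform (anisotropy-aware).
    Components touching the xy stack border are flagged.

    Raises
    ------
    ValueError
        For a seed placed in wall or outside the leaf.
    """
    mask = np.asarray(wall.mask, bool)
    interior = bands.interior_mask()
    wall_closed = _close_wall(mask, closing_size) if closing_size is not None else mask
    open_space = interior & ~wall_closed
    labels, _ = ndimage.label(open_space, structure=_CONN26)
    labels = labels.astype(np.int32)
    if closing_size is not None and labels.max() > 0:
        # the closing is a connectivity veto only: voxels it removed are
        # returned to their nearest component so sizes stay unbiased
        residual = interior & ~mask & (labels == 0)
        if residual.any():
            cap = 1.05 * float(np.linalg.norm(geometry.as_tuple()))
            dist, idx = ndimage.distance_transform_edt(
                labels == 0, sampling=geometry.as_tuple(), return_indices=True)
            nearest = labels[tuple(idx)]
            give_back = residual & (dist <= cap)
            labels[give_back] = nearest[give_back]
    min_voxels = max(1, round(min_volume_um3 / geometry.voxel_volume))
    if labels.max() > 0:
        counts = np.bincount(labels.ravel())
        small = set(np.nonzero(counts < min_voxels)[0].tolist()) - {0}
        # components thinner than 2 μm along any axis are below the
        # sampling resolution and cannot be genuine lumina
        min_ext = [max(3, int(np.ceil(2.0 / d))) for d in geometry.as_tuple()]
        for lab_i, sl in enumerate(ndimage.find_objects(labels), start=1):
            if sl is not None and any(s.stop - s.start < e
                                      for s, e in zip(sl, min_ext)):
                small.add(lab_i)
        if small:
            kill = np.isin(labels, np.fromiter(small, dtype=labels.dtype))
            labels[kill] = 0
    provenance: dict[int, str] = {}

    if seeds is not None and len(seeds):
        pts = np.atleast_2d(np.asarray(seeds, dtype=float))
        vox = np.floor(pts[:, :3] / np.array(geometry.as_tuple())).astype(int)
        shape = np.array(labels.shape)
        if np.any(vox < 0) or np.any(vox >= shape):
            raise ValueError("seed outside the stack")
        seed_labels = labels[vox[:, 0], vox[:, 1], vox[:, 2]]
        inside = bands.interior_mask()[vox[:, 0], vox[:, 1], vox[:, 2]]
        if np.any(~inside):
            raise ValueError("seed outside the leaf")
        if np.any(seed_labels == 0):
            raise ValueError("seed placed in wall")
        next_label = int(labels.max()) + 1
        for comp in np.unique(seed_labels):
            where = seed_labels == comp
            if where.sum() < 2:
                provenance[int(comp)] = "seed"
                continue
            sl = ndimage.find_objects((labels == comp).astype(np.int8))[0]
            sub = labels[sl] == comp
            edt = ndimage.distance_transform_edt(sub, sampling=geometry.as_tuple())
            markers = np.zeros(sub.shape, dtype=np.int32)
            for i, p in enumerate(vox[where], start=1):
                markers[p[0] - sl[0].start, p[1] - sl[1].start, p[2] - sl[2].start] = i
            parts = watershed(-edt, markers=markers, mask=sub)
            region = labels[sl]
            region[sub] = 0
            for i in range(1, int(parts.max()) + 1):
                region[parts == i] = next_label
                provenance[next_label] = "seed"
                next_label += 1
            labels[sl] = region
    labels, provenance = _relabel_sorted(labels, geometry, provenance)
    table = _component_table(labels, geometry, provenance)
    # raw-space connectivity (no closing): components pinched apart by the
    # closing share one raw id, which the classifier uses to tell corridor
    # fragments of the airspace network from genuinely enclosed small cells
    raw_lab, _ = ndimage.label(bands.interior_mask() & ~mask, structure=_CONN26)
    raw_ids = []
    for row in table.itertuples():
        sub = labels[row.x0:row.x1, row.y0:row.y1, row.z0:row.z1] == row.label
        first = np.argwhere(sub)[0]
        raw_ids.append(int(raw_lab[row.x0 + first[0], row.y0 + first[1],
                                   row.z0 + first[2]]))
    table["raw_component"] = raw_ids
    return CellLabelVolume(labels=labels, table=table, geometry=geometry)


def _inplane_solidity(labels: np.ndarray, lab: int,
                      sl: tuple[slice, slice, slice]) -> float:
    """Solidity of the component's largest xy cross-section.

    Area over convex-hull area at the max-area z-slice; lobed airspace
    networks score low, round cells high.
    """
    sub = labels[sl] == lab
    areas = sub.sum(axis=(0, 1))
    zbest = int(np.argmax(areas))
    section = sub[:, :, zbest]
    pts = np.argwhere(section).astype(float)
    if len(pts) < 3:
        return 1.0
    # voxel corners give a hull with nonzero area even for thin sections
    corners = np.concatenate([pts + d for d in
                              ((-0.5, -0.5), (-0.5, 0.5), (0.5, -0.5), (0.5, 0.5))])
    try:
        hull_area = ConvexHull(corners).volume
    except QhullError:
        return 1.0
    return float(min(1.0, len(pts) / hull_area))


def classify_components(
    labels: CellLabelVolume,
    bands: TissueBandMap,
    geometry: VoxelGeometry | None = None,
    cell_volume_ceiling_um3: float | None = None,
    solidity_floor: float = 0.4,
    cell_volume_floor_um3: float | None = None,
) -> CellLabelVolume:
    """Complete the component table with tissue and cell/ICS classes.

    Tissue is the band containing the majority of a component's voxels
    (assessed in 3D, so a cell whose xz appearance is ambiguous is still
    classified by where it lies, matching the practice of judging cell
    identity from paradermal as well as transversal views).  A component
    is intercellular space when it is both much larger than a plausible
    cell (volume above the ceiling; default 8× the median component
    volume) and lobed in-plane (solidity of its largest xy section below
    the floor), or when it reaches the ambient exterior above/below the
    leaf surfaces.  A second pass reclassifies components below the
    minimum plausible cell volume that lie against an airspace
    component: these are corridor fragments pinched off by the wall-gap
    closing, not cells.  Everything else is a cell; all thresholds are
    configurable.
    """
    geometry = geometry or labels.geometry
    lab = labels.labels
    if labels.table.empty or lab.max() == 0:
        raise ValueError("empty label volume")
    band_vol = bands.voxel_bands()
    nlab = int(lab.max())
    # majority band per label via a joint (label, band) histogram
    joint = np.bincount((lab.ravel().astype(np.int64) * 5 + band_vol.ravel()),
                        minlength=(nlab + 1) * 5).reshape(nlab + 1, 5)
    majority = np.argmax(joint[:, 1:], axis=1)  # 0..3 over TISSUES

    # components that leak to the ambient exterior (e.g. stomatal openings)
    exterior = ~bands.interior_mask()
    touch = ndimage.binary_dilation(exterior, structure=_CONN26) & (lab > 0)
    exterior_labels = set(np.unique(lab[touch]))

    table = labels.table.copy()
    vol_um3 = table["n_voxels"].to_numpy() * geometry.voxel_volume
    if cell_volume_ceiling_um3 is None:
        cell_volume_ceiling_um3 = 8.0 * float(np.median(vol_um3))
    if cell_volume_floor_um3 is None:
        cell_volume_floor_um3 = max(50.0, 0.25 * float(np.median(vol_um3)))
    tissues, classes, solidities = [], [], []
    for row, v in zip(table.itertuples(), vol_um3):
        l = int(row.label)
        tissues.append(TISSUES[majority[l]])
        sol = np.nan
        if l in exterior_labels:
            classes.append("ics")
        elif v > cell_volume_ceiling_um3:
            sl = (slice(row.x0, row.x1), slice(row.y0, row.y1), slice(row.z0, row.z1))
            sol = _inplane_solidity(lab, l, sl)
            classes.append("ics" if sol < solidity_floor else "cell")
        else:
            classes.append("cell")
        solidities.append(sol)
    table["tissue"] = tissues
    table["class"] = classes
    table["solidity"] = solidities
    table["volume_um3"] = vol_um3

    # second pass: sub-cell-sized components that the raw (unclosed) wall
    # mask connects to an airspace component are corridor fragments
    if "raw_component" in table.columns:
        ics_raw = set(table.loc[table["class"] == "ics", "raw_component"])
        flip = ((table["class"] == "cell")
                & (table["volume_um3"] < cell_volume_floor_um3)
                & table["raw_component"].isin(ics_raw))
        table.loc[flip, "class"] = "ics"
    return CellLabelVolume(labels=lab, table=table, geometry=geometry)


def count_cells(
    labels: CellLabelVolume,
    tissue: str,
    roi_um: tuple[float, float, float, float] | None = None,
) -> int:
    """Count cell-class components of ``tissue`` with centroid in the ROI.

    ``roi_um`` is ``(x0, x1, y0, y1)`` in μm, half-open; ``None`` means
    the whole footprint.  Border-touching cells are included (density is
    unbiased by truncation; dimension statistics exclude them
    elsewhere).
    """
    if tissue not in TISSUES:
        raise ValueError(f"unknown tissue {tissue!r}")
    t = labels.table
    if "class" not in t.columns:
        raise ValueError("components not classified yet")
    sel = (t["class"] == "cell") & (t["tissue"] == tissue)
    if roi_um is not None:
        x0, x1, y0, y1 = roi_um
        if not (x1 > x0 and y1 > y0):
            raise ValueError("empty roi")
        sel &= ((t["centroid_x_um"] >= x0) & (t["centroid_x_um"] < x1)
                & (t["centroid_y_um"] >= y0) & (t["centroid_y_um"] < y1))
    return int(sel.sum())
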