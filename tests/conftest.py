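"""Shared fixtures: phantom specs and segmentation pipelines.

The standard test phantom is deliberately small (64×64 μm field,
72 μm-thick leaf, ~170 cells) but keeps realistic proportions between
cell diameter, wall thickness and voxel size, so segmentation behaves
as it would on full-size stacks while a full pipeline run stays in the
seconds range.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

import leafmorph as lm


def tiny_spec(**overrides) -> lm.LeafPhantomSpec:
    base = dict(
        field_um=(64.0, 64.0),
        band_um=(12.0, 24.0, 24.0, 12.0),
        cell_diameter_um={"adaxial_epidermis": 16.0, "palisade": 13.0,
                          "spongy": 12.0, "abaxial_epidermis": 14.0},
        geometry=lm.VoxelGeometry(0.4, 0.4, 0.8),
        seed=1,
    )
    base.update(overrides)
    return lm.LeafPhantomSpec(**base)


def noiseless(**overrides) -> lm.LeafPhantomSpec:
    return tiny_spec(blur_sigma_um=(0.0, 0.0), attenuation_per_um=0.0,
                     photon_noise=False, read_noise=0.0, **overrides)


def run_pipeline(spec: lm.LeafPhantomSpec):
    """Phantom → k-means wall → bands → classified labels."""
    stack, truth = lm.generate_phantom(spec)
    wall = lm.kmeans_threshold(stack)
    bands = lm.delineate_tissues(stack, wall, priors=spec.band_um)
    labels = lm.segment_cells(wall, bands, spec.geometry)
    labels = lm.classify_components(labels, bands)
    return stack, truth, wall, bands, labels


def jaccard_scores(truth: lm.GroundTruth, labels: lm.CellLabelVolume) -> np.ndarray:
    """Best-overlap Jaccard per ground-truth cell."""
    gl, el = truth.labels.labels, labels.labels
    out = []
    for cid in truth.labels.labels_of_class("cell"):
        m = gl == cid
        vals, cnts = np.unique(el[m], return_counts=True)
        pos = vals > 0
        if not pos.any():
            out.append(0.0)
            continue
        best = vals[pos][np.argmax(cnts[pos])]
        inter = int(cnts[pos].max())
        union = int(m.sum()) + int((el == best).sum()) - inter
        out.append(inter / union)
    return np.asarray(out)


@pytest.fixture(scope="session")
def noisy_phantom():
    spec = tiny_spec()
    stack, truth = lm.generate_phantom(spec)
    return spec, stack, truth


@pytest.fixture(scope="session")
def noisy_pipeline(noisy_phantom):
    spec, stack, truth = noisy_phantom
    wall = lm.kmeans_threshold(stack)
    bands = lm.delineate_tissues(stack, wall, priors=spec.band_um)
    labels = lm.classify_components(
        lm.segment_cells(wall, bands, spec.geometry), bands)
    return spec, stack, truth, wall, bands, labels


@pytest.fixture(scope="session")
def noiseless_pipeline():
    spec = noiseless()
    return (spec, *run_pipeline(spec))


@pytest.fixture(scope="session")
def seed_battery():
    """Ten noisy phantom seeds, fully segmented and summarised.

    Shared by the recovery and airspace-consistency experiments so the
    expensive generation+segmentation runs once.
    """
    rows = []
    for seed in range(1, 11):
        spec = tiny_spec(seed=seed)
        stack, truth, wall, bands, labels = run_pipeline(spec)
        report = lm.summarize(bands, labels, spec.geometry, include_surface=False)
        gt = lm.ground_truth_morphometrics(truth, include_surface=False)
        jac = jaccard_scores(truth, labels)
        n_gt = len(truth.labels.labels_of_class("cell"))
        n_est = int((labels.table["class"] == "cell").sum())
        rows.append(dict(
            seed=seed,
            n_gt=n_gt,
            n_est=n_est,
            count_err=abs(n_est - n_gt) / n_gt,
            median_jaccard=float(np.median(jac)),
            ics_est=report.ics_fraction["spongy"],
            ics_gt=gt.ics_fraction["spongy"],
            vol_est=report.cell_volume_mean_um3["spongy"],
            vol_gt=gt.cell_volume_mean_um3["spongy"],
            band_dev=max(int(np.abs(bands.boundaries[..., k]
                                    - truth.bands.boundaries[..., k]).max())
                         for k in range(5)),
        ))
    return rows
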