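import math

import numpy as np
import pytest

import leafmorph as lm
from leafmorph import morphometry
from leafmorph.segment import CellLabelVolume, TissueBandMap, _component_table


GEO = lm.VoxelGeometry(0.22, 0.22, 0.8)


def flat_bands(nx, ny, steps, z0=0):
    b = np.cumsum([z0, *steps])
    return TissueBandMap(np.tile(b, (nx, ny, 1)), nz=int(b[-1]) + z0)


def label_volume(mask, geometry, tissue="palisade"):
    lab = mask.astype(np.int32)
    table = _component_table(lab, geometry)
    table["class"] = "cell"
    table["tissue"] = tissue
    table["volume_um3"] = table["n_voxels"] * geometry.voxel_volume
    return CellLabelVolume(lab, table, geometry)


class TestLeafThickness:
    def test_constant_surfaces_closed_form(self):
        bands = flat_bands(32, 32, (28, 66, 66, 28))  # 188 z-steps total
        th = lm.leaf_thickness(bands, GEO)
        assert th.mean_um == pytest.approx(188 * 0.8)
        assert th.sd_um == 0.0
        assert th.rel_range == 0.0

    def test_position_outside_footprint(self):
        bands = flat_bands(16, 16, (4, 8, 8, 4))
        with pytest.raises(ValueError, match="footprint"):
            lm.leaf_thickness(bands, GEO, positions_um=[(1e6, 1e6)])

    def test_mature_preset_thickness_exceeds_young(self):
        assert lm.preset("arabidopsis_mature").thickness_um \
            > lm.preset("arabidopsis_young").thickness_um
        assert lm.preset("arabidopsis_mature").thickness_um >= 150.0


class TestTissueProportions:
    def test_flat_band_fractions(self):
        bands = flat_bands(8, 8, (25, 50, 50, 25))
        props = lm.tissue_proportions(bands)
        assert props["adaxial_epidermis"] == pytest.approx(1 / 6)
        assert props["palisade"] == pytest.approx(1 / 3)
        assert props["spongy"] == pytest.approx(1 / 3)
        assert props["abaxial_epidermis"] == pytest.approx(1 / 6)

    def test_sum_to_one(self, noisy_pipeline):
        *_, bands, _ = noisy_pipeline
        assert sum(lm.tissue_proportions(bands).values()) == pytest.approx(1.0, abs=1e-9)

    def test_recovery_within_002(self, noisy_pipeline):
        spec, stack, truth, wall, bands, labels = noisy_pipeline
        est = lm.tissue_proportions(bands)
        want = lm.tissue_proportions(truth.bands)
        for tissue in lm.TISSUES:
            assert est[tissue] == pytest.approx(want[tissue], abs=0.02)


class TestCellDensity:
    def test_arithmetic(self):
        d = lm.cell_density(100, 0.01)
        assert d.per_mm2 == pytest.approx(10000.0)
        assert d.per_mm3 is None

    def test_per_volume(self):
        d = lm.cell_density(50, 0.01, tissue_volume_mm3=0.001)
        assert d.per_mm3 == pytest.approx(50000.0)

    def test_zero_cells_warns(self):
        assert lm.cell_density(0, 1.0).warning

    def test_bad_area(self):
        with pytest.raises(ValueError):
            lm.cell_density(10, 0.0)


class TestCellDimensions:
    def test_cuboid_closed_form(self):
        mask = np.zeros((14, 14, 24), bool)
        mask[2:12, 2:12, 2:22] = True
        vol = label_volume(mask, GEO)
        rec = lm.cell_dimensions(vol, 1)
        assert rec.volume_um3 == pytest.approx(77.44)
        assert rec.length_um == pytest.approx(16.0)
        assert rec.max_area_um2 == pytest.approx(4.84)
        assert rec.width_um == pytest.approx(2.2 * math.sqrt(2), rel=1e-6)

    def test_sphere_analytic_oracle(self):
        g = lm.VoxelGeometry(0.2, 0.2, 0.2)
        n = 56
        c = n / 2 * 0.2
        idx = (np.indices((n, n, n)) + 0.5) * 0.2
        mask = ((idx[0] - c) ** 2 + (idx[1] - c) ** 2 + (idx[2] - c) ** 2) <= 25.0
        rec = lm.cell_dimensions(label_volume(mask, g), 1)
        assert rec.volume_um3 == pytest.approx(4 / 3 * math.pi * 125, rel=0.05)
        assert rec.surface_area_um2 == pytest.approx(4 * math.pi * 25, rel=0.05)

    def test_single_voxel_flagged(self):
        mask = np.zeros((5, 5, 5), bool)
        mask[2, 2, 2] = True
        rec = lm.cell_dimensions(label_volume(mask, GEO), 1)
        assert rec.volume_um3 == pytest.approx(GEO.voxel_volume)
        assert "below_min_size" in rec.qc

    def test_ics_component_rejected(self, noisy_pipeline):
        *_, labels = noisy_pipeline
        ics_id = int(labels.labels_of_class("ics")[0])
        with pytest.raises(ValueError, match="intercellular"):
            lm.cell_dimensions(labels, ics_id)

    def test_unknown_id(self, noisy_pipeline):
        *_, labels = noisy_pipeline
        with pytest.raises(KeyError):
            lm.cell_dimensions(labels, 10 ** 6)


class TestIcsEstimator:
    def test_exact_fill_gives_zero(self):
        est = lm.intercellular_space_estimate(0.5, 100.0, 2000.0, 100, 1000.0)
        assert est.fraction == pytest.approx(0.0)

    def test_arithmetic_identity(self):
        # V_tissue = 100,000 μm³; 100 cells × 500 μm³ → half airspace
        est = lm.intercellular_space_estimate(1.0, 100.0, 1000.0, 100, 500.0)
        assert est.volume_um3 == pytest.approx(50000.0)
        assert est.fraction == pytest.approx(0.5)

    def test_small_negative_floored_with_warning(self):
        est = lm.intercellular_space_estimate(1.0, 100.0, 1000.0, 100, 1020.0)
        assert est.volume_um3 == 0.0
        assert est.warning

    def test_large_deficit_is_error(self):
        with pytest.raises(ValueError, match="slack"):
            lm.intercellular_space_estimate(1.0, 100.0, 1000.0, 100, 2000.0)

    def test_bad_fraction(self):
        with pytest.raises(ValueError):
            lm.intercellular_space_estimate(0.0, 100.0, 1000.0, 10, 10.0)


class TestSurfaceAreaPerVolume:
    def test_cube_closed_form_and_units(self):
        g = lm.VoxelGeometry(0.2, 0.2, 0.2)
        mask = np.zeros((54, 54, 54), bool)
        mask[2:52, 2:52, 2:52] = True  # 10 μm cube
        rec = lm.cell_dimensions(label_volume(mask, g), 1)
        got = lm.surface_area_per_volume([rec], 10000.0)
        # 600 μm² / 10,000 μm³ = 0.06 μm⁻¹ = 60 mm² mm⁻³ (corners rounded
        # by the isosurface cost a few percent)
        assert got == pytest.approx(60.0, rel=0.05)

    def test_unit_coherence(self):
        g = lm.VoxelGeometry(0.2, 0.2, 0.2)
        mask = np.zeros((24, 24, 24), bool)
        mask[4:20, 4:20, 4:20] = True
        rec = lm.cell_dimensions(label_volume(mask, g), 1)
        in_um = (rec.surface_area_um2 / 5000.0) * 1000.0
        in_mm = (rec.surface_area_um2 * 1e-6) / (5000.0 * 1e-9)
        assert in_um == pytest.approx(in_mm, rel=1e-12)

    def test_empty_records_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            lm.surface_area_per_volume([], 1000.0)

    def test_mature_phantom_order_of_magnitude(self, noisy_pipeline):
        # palisade surface area per tissue volume lands in the tens of
        # mm² mm⁻³, the scale reported for mesophyll near full expansion
        spec, stack, truth, wall, bands, labels = noisy_pipeline
        recs = lm.cell_records(labels, "palisade")
        widths = np.diff(bands.boundaries, axis=2).sum(axis=(0, 1))
        vol = widths[1] * spec.geometry.voxel_volume
        got = lm.surface_area_per_volume(recs, vol)
        assert 10.0 < got < 1000.0


class TestIcsContactFraction:
    def test_no_ics_returns_undefined(self):
        mask = np.zeros((8, 8, 8), bool)
        mask[2:6, 2:6, 2:6] = True
        assert lm.ics_contact_fraction(label_volume(mask, GEO), 1) is None

    def test_embedded_cell_has_zero_contact(self):
        # a cell and a far-away airspace: every face is wall-backed
        g = lm.VoxelGeometry(0.4, 0.4, 0.4)
        lab = np.zeros((40, 12, 12), np.int32)
        lab[2:8, 3:9, 3:9] = 1
        lab[30:38, 3:9, 3:9] = 2
        table = _component_table(lab, g)
        table["class"] = ["cell", "ics"]
        table["tissue"] = "spongy"
        vol = CellLabelVolume(lab, table, g)
        assert lm.ics_contact_fraction(vol, 1, max_gap_um=1.0) == 0.0

    def test_fully_exposed_cell_saturates(self):
        # lumen separated from a surrounding airspace shell by a thin wall
        g = lm.VoxelGeometry(0.4, 0.4, 0.4)
        lab = np.zeros((16, 16, 16), np.int32)
        lab[2:14, 2:14, 2:14] = 2          # airspace shell
        lab[4:12, 4:12, 4:12] = 0          # wall gap
        lab[6:10, 6:10, 6:10] = 1          # the cell
        table = _component_table(lab, g)
        table = table.sort_values("label")
        table["class"] = ["cell", "ics"]
        table["tissue"] = "spongy"
        vol = CellLabelVolume(lab, table, g)
        got = lm.ics_contact_fraction(vol, 1, max_gap_um=1.0)
        assert got == pytest.approx(1.0, abs=0.02)

    def test_phantom_within_tenth_of_truth_adjacency(self, noisy_phantom):
        from scipy import ndimage
        spec, stack, truth = noisy_phantom
        g = spec.geometry
        gl = truth.labels.labels
        ics_mask = np.isin(gl, truth.labels.labels_of_class("ics"))
        t = truth.labels.table
        sel = t[(t["class"] == "cell") & (t["tissue"] == "spongy") & ~t["border"]]
        # independent oracle: voxel-face counting with a dilation-based
        # across-wall reach instead of the distance transform
        gap = 2.0
        reach = tuple(int(np.ceil(gap / d)) for d in g.as_tuple())
        # physically spherical reach, not a chebyshev box
        off = np.meshgrid(*[np.arange(-r, r + 1) * d for r, d in
                            zip(reach, g.as_tuple())], indexing="ij")
        struct = (off[0] ** 2 + off[1] ** 2 + off[2] ** 2) <= gap ** 2
        areas = {0: g.dy * g.dz, 1: g.dx * g.dz, 2: g.dx * g.dy}
        shifts = [(0, (1, 0, 0)), (0, (-1, 0, 0)), (1, (0, 1, 0)),
                  (1, (0, -1, 0)), (2, (0, 0, 1)), (2, (0, 0, -1))]
        checked = 0
        for row in sel.itertuples():
            if checked >= 6:
                break
            cid = int(row.label)
            got = lm.ics_contact_fraction(truth.labels, cid, max_gap_um=gap)
            pad = tuple(r + 2 for r in reach)
            sl = tuple(slice(max(0, s - p), e + p) for s, e, p in
                       ((row.x0, row.x1, pad[0]), (row.y0, row.y1, pad[1]),
                        (row.z0, row.z1, pad[2])))
            cell = gl[sl] == cid
            ics_near = ndimage.binary_dilation(ics_mask[sl], struct)
            total = facing = 0.0
            for axis, shift in shifts:
                out = cell & ~np.roll(cell, shift, axis=axis)
                total += out.sum() * areas[axis]
                near = np.roll(ics_near, shift, axis=axis)
                facing += (out & near).sum() * areas[axis]
            want = facing / total
            assert got == pytest.approx(want, abs=0.1)
            checked += 1
        assert checked > 0


class TestSummarize:
    def test_report_structure_and_export(self, noisy_pipeline, tmp_path):
        spec, stack, truth, wall, bands, labels = noisy_pipeline
        report = lm.summarize(bands, labels, spec.geometry, include_surface=False)
        assert sum(report.proportions.values()) == pytest.approx(1.0, abs=1e-9)
        for tissue in lm.MESOPHYLL:
            assert 0.0 <= report.ics_fraction[tissue] <= 1.0
        rows = report.to_records()
        path = lm.write_measurements(rows, tmp_path / "report.csv",
                                     units=report.UNITS)
        back = lm.read_measurements(path)
        assert len(back) == len(rows)
        got = back.set_index(["variable", "tissue"])["value"]
        assert got[("thickness_mean", "leaf")] == pytest.approx(report.thickness_mean_um)
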