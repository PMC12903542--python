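"""Segmentation and morphometry: fixtures with analytic ground truth."""

from dataclasses import replace

import numpy as np
import pytest

from conftest import make_cell, raster_ellipse
from ctsfna.images import (
    InputError,
    MeasurementError,
    SmearImage,
    assemble_cells,
    measure_nucleus,
    read_smear,
    scan_low_power,
    segment_nuclei,
    segment_red,
    write_smear,
)
from ctsfna.simulate import render_smear


def flat_image(shape=(100, 100), red=100.0, blue=100.0, pixel_size=0.5):
    return SmearImage(
        red=np.full(shape, red), blue=np.full(shape, blue), pixel_size=pixel_size
    )


class TestSegmentNuclei:
    def test_blank_blue_channel_yields_no_nuclei(self):
        labels = segment_nuclei(flat_image(blue=0.0))
        assert labels.max() == 0

    def test_well_separated_nuclei_recovered_with_high_overlap(self, noisefree_config):
        cells = [
            make_cell(center=(x, y), major=10.0, minor=8.0, red=0.0)
            for x, y in [(25, 25), (64, 25), (103, 25), (25, 90), (64, 90), (103, 90)]
        ]
        image, truth = render_smear(cells, noisefree_config)
        labels = segment_nuclei(image)
        assert labels.max() == 6
        for rr, cc in truth.nucleus_masks:
            gt = np.zeros(noisefree_config.shape, dtype=bool)
            gt[rr, cc] = True
            lab_vals = labels[gt]
            lab = np.bincount(lab_vals[lab_vals > 0]).argmax()
            seg = labels == lab
            jaccard = (seg & gt).sum() / (seg | gt).sum()
            assert jaccard >= 0.8

    def test_touching_nuclei_split_into_two(self, noisefree_config):
        # centers 9 um apart with 10-um nuclei: masks touch along one edge
        cells = [
            make_cell(center=(55, 64), major=10.0, minor=9.0, red=0.0),
            make_cell(center=(64.2, 64), major=10.0, minor=9.0, red=0.0),
        ]
        image, _ = render_smear(cells, noisefree_config)
        labels = segment_nuclei(image)
        assert labels.max() == 2

    def test_shape_mismatch_rejected(self):
        with pytest.raises(InputError):
            SmearImage(red=np.zeros((10, 10)), blue=np.zeros((5, 5)), pixel_size=0.5)

    def test_debris_below_minimum_area_removed(self, noisefree_config):
        image, _ = render_smear(
            [make_cell(major=2.5, minor=2.0, red=0.0)], noisefree_config
        )
        assert segment_nuclei(image).max() == 0


class TestMeasureNucleus:
    def test_disc_diameter_and_circularity(self):
        mask = raster_ellipse(10.0, 10.0)
        major, minor, circ = measure_nucleus(mask, 0.5)
        assert major == pytest.approx(10.0, abs=0.5)
        assert circ >= 0.9

    def test_ellipse_major_axis(self):
        major, _, _ = measure_nucleus(raster_ellipse(14.0, 7.0), 0.5)
        assert major == pytest.approx(14.0, abs=0.5)

    def test_perturbed_boundary_lowers_circularity(self, noisefree_config):
        smooth = make_cell(major=12.0, minor=10.0, irregularity=0.0, red=0.0)
        rough = make_cell(major=12.0, minor=10.0, irregularity=0.3, red=0.0)
        vals = []
        for cell in (smooth, rough):
            _, truth = render_smear([cell], noisefree_config)
            mask = np.zeros(noisefree_config.shape, dtype=bool)
            mask[truth.nucleus_masks[0]] = True
            vals.append(measure_nucleus(mask, noisefree_config.pixel_size)[2])
        assert vals[1] < vals[0]

    def test_empty_mask_is_an_error(self):
        with pytest.raises(MeasurementError):
            measure_nucleus(np.zeros((5, 5), dtype=bool), 0.5)

    def test_calibration_equivariance(self):
        # same physical ellipse at two samplings: measured axes agree
        m1, _, _ = measure_nucleus(raster_ellipse(12.0, 8.0, pixel_size=0.5), 0.5)
        m2, _, _ = measure_nucleus(raster_ellipse(12.0, 8.0, pixel_size=1.0), 1.0)
        assert abs(m1 - m2) <= 1.0

    def test_rotation_robustness(self):
        vals = [
            measure_nucleus(raster_ellipse(12.0, 6.0, angle=a), 0.5)[0]
            for a in np.linspace(0, np.pi, 36, endpoint=False)
        ]
        assert (max(vals) - min(vals)) / 12.0 < 0.05


class TestSegmentRed:
    def test_constant_red_channel_gives_empty_mask(self):
        assert not segment_red(flat_image(red=100.0)).any()

    def test_strong_cell_covered_by_mask(self, noisefree_config):
        cell = make_cell(red=1000.0)  # 10x background
        image, truth = render_smear([cell], noisefree_config)
        mask = segment_red(image)
        cyt = np.zeros(noisefree_config.shape, dtype=bool)
        cyt[truth.cytoplasm_masks[0]] = True
        assert (mask & cyt).sum() / cyt.sum() >= 0.9

    def test_full_dilution_erases_signal(self, noisefree_config):
        cfg = replace(noisefree_config, dilution_factor=0.0)
        image, _ = render_smear([make_cell(red=1000.0)], cfg)
        assert not segment_red(image).any()


class TestAssembleCells:
    def test_cell_without_red_is_negative(self, noisefree_config):
        image, _ = render_smear([make_cell(red=0.0)], noisefree_config)
        cells = assemble_cells(segment_nuclei(image), segment_red(image), image)
        assert len(cells) == 1
        assert not cells[0].red_positive
        assert cells[0].median_red == 0.0
        assert cells[0].nc_ratio == 1.0

    def test_uniform_red_gives_exact_median(self, noisefree_config):
        v = 1000.0
        image, _ = render_smear([make_cell(red=v)], noisefree_config)
        cells = assemble_cells(segment_nuclei(image), segment_red(image), image)
        assert cells[0].red_positive
        assert cells[0].median_red == pytest.approx(
            v + noisefree_config.background, abs=1.0
        )

    def test_shared_red_blob_partitioned_without_double_counting(
        self, noisefree_config
    ):
        cells_in = [
            make_cell(center=(56, 64), major=8.0, minor=7.0, red=1000.0),
            make_cell(center=(72, 64), major=8.0, minor=7.0, red=1000.0),
        ]
        image, _ = render_smear(cells_in, noisefree_config)
        nuclei = segment_nuclei(image)
        red_mask = segment_red(image)
        records = assemble_cells(nuclei, red_mask, image, keep_masks=True)
        assert len(records) == 2
        seen = np.zeros(noisefree_config.shape, dtype=int)
        for r in records:
            seen[r.cytoplasm_mask] += 1
        assert seen.max() <= 1  # every red pixel assigned to at most one cell

    def test_median_red_shifts_by_added_constant(self, noisefree_config):
        image, _ = render_smear([make_cell(red=1000.0)], noisefree_config)
        nuclei = segment_nuclei(image)
        red_mask = segment_red(image)
        base = assemble_cells(nuclei, red_mask, image)[0].median_red
        shifted_img = SmearImage(
            red=image.red.astype(float) + 50.0,
            blue=image.blue,
            pixel_size=image.pixel_size,
        )
        shifted = assemble_cells(nuclei, red_mask, shifted_img)[0].median_red
        assert shifted == pytest.approx(base + 50.0, abs=1e-9)


class TestScanLowPower:
    def test_uniform_image_ties_break_row_major(self):
        boxes = scan_low_power(flat_image(shape=(64, 64)), box_size=32, n_top=3)
        assert [b.origin for b in boxes] == [(0, 0), (0, 32), (32, 0)]
        assert len({b.score for b in boxes}) == 1

    def test_red_cluster_tile_ranked_first(self):
        red = np.full((64, 64), 100.0)
        red[40:56, 40:56] = 2000.0
        image = SmearImage(red=red, blue=np.full((64, 64), 100.0), pixel_size=0.5)
        boxes = scan_low_power(image, box_size=32, n_top=4)
        assert boxes[0].origin == (32, 32)

    def test_n_top_clamped_to_tile_count(self):
        boxes = scan_low_power(flat_image(shape=(64, 64)), box_size=32, n_top=99)
        assert len(boxes) == 4

    def test_nonpositive_n_top_rejected(self):
        with pytest.raises(InputError):
            scan_low_power(flat_image(), box_size=32, n_top=0)


class TestTiffRoundTrip:
    def test_write_read_preserves_channels_and_calibration(
        self, tmp_path, noisefree_config
    ):
        image, _ = render_smear([make_cell()], noisefree_config)
        image.slide_id = "S001"
        path = tmp_path / "s1.tiff"
        write_smear(image, path)
        back = read_smear(path)
        assert np.array_equal(back.red, image.red)
        assert np.array_equal(back.blue, image.blue)
        assert back.pixel_size == image.pixel_size
        assert back.slide_id == "S001"
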