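"""Segmentation and per-cell measurement against analytic/ground-truth oracles."""

import numpy as np
import pytest
from skimage.draw import disk

from tgnscreen import (FieldSpec, generate_field, measure_cell,
                       puncta_density, quantify_field, segment_cell_bodies,
                       segment_field, segment_nuclei, segment_tgn,
                       tgn_morphology, FEATURE_NAMES, extract_feature_vector)
from tgnscreen.imaging import NO_TGN, UNDEFINED_RATIO, SegmentationResult
from tgnscreen.simulate import FieldImage


def _disk_image(shape, centers, r, level=200.0, bg=10.0):
    img = np.full(shape, bg)
    for c in centers:
        rr, cc = disk(c, r, shape=shape)
        img[rr, cc] = level
    return img


class TestSegmentNuclei:
    def test_three_disks_three_labels(self):
        img = _disk_image((128, 128), [(30, 30), (30, 90), (90, 60)], 12)
        labels = segment_nuclei(img)
        assert labels.max() == 3

    def test_uniform_image_no_labels(self):
        assert segment_nuclei(np.zeros((64, 64))).max() == 0
        assert segment_nuclei(np.full((64, 64), 7.0)).max() == 0

    def test_min_area_removes_specks(self):
        img = _disk_image((128, 128), [(64, 64)], 12)
        img[5, 5] = 500.0
        assert segment_nuclei(img, min_area=64).max() == 1

    def test_recovers_all_generated_nuclei(self):
        spec = FieldSpec(image_size=(512, 512), n_cells=25, noise_sd=0.0,
                         seed=2)
        img, truth = generate_field(spec)
        labels = segment_nuclei(img.nucleus)
        assert labels.max() == 25


class TestSegmentCellBodies:
    def test_single_body_superset_of_nucleus(self):
        nuc_img = _disk_image((128, 128), [(64, 64)], 10)
        body_img = _disk_image((128, 128), [(64, 64)], 30)
        nuclei = segment_nuclei(nuc_img)
        cells = segment_cell_bodies(body_img, nuclei)
        assert cells.max() == 1
        assert np.all(cells[nuclei == 1] == 1)

    def test_blob_with_two_nuclei_splits_into_two_cells(self):
        nuc_img = _disk_image((128, 192), [(64, 60), (64, 130)], 10)
        body_img = np.full((128, 192), 10.0)
        body_img[30:100, 25:165] = 200.0  # one blob spanning both nuclei
        nuclei = segment_nuclei(nuc_img)
        cells = segment_cell_bodies(body_img, nuclei)
        assert set(np.unique(cells)) == {0, 1, 2}
        for cid in (1, 2):
            inside = set(np.unique(nuclei[cells == cid])) - {0}
            assert inside == {cid}

    def test_jaccard_overlap_with_ground_truth(self, noiseless_field):
        _, img, truth = noiseless_field
        seg = segment_field(img)
        scores = []
        for cid in seg.cell_ids:
            ours = seg.cell_labels == cid
            # match by majority-overlap ground-truth label
            overlap = truth.cell_labels[ours]
            gt_id = np.bincount(overlap[overlap > 0]).argmax()
            gt = truth.cell_labels == gt_id
            scores.append((ours & gt).sum() / (ours | gt).sum())
        assert np.mean(scores) >= 0.95

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            segment_cell_bodies(np.zeros((10, 10)), np.zeros((8, 8), int))


class TestSegmentTgn:
    def test_zero_channel_flags_all_cells(self, noiseless_field):
        _, img, _ = noiseless_field
        blank = FieldImage(img.nucleus, img.body,
                           np.zeros_like(img.tgn), img.cargo)
        seg = segment_field(blank)
        flagged = {cid for cid, reason in seg.excluded if reason == NO_TGN}
        assert flagged == set(seg.cell_ids)

    def test_tgn_area_close_to_designed_fraction(self, noiseless_field):
        spec, img, truth = noiseless_field
        seg = segment_field(img)
        for cid in seg.cell_ids:
            tgn_area = (seg.tgn_labels == cid).sum()
            cell_area = (seg.cell_labels == cid).sum()
            assert tgn_area == pytest.approx(
                spec.tgn_area_fraction * cell_area, rel=0.10)

    def test_straddling_blob_split_by_cell_boundary(self):
        cells = np.zeros((64, 64), np.int32)
        cells[:, :32] = 1
        cells[:, 32:] = 2
        tgn_ch = np.zeros((64, 64))
        tgn_ch[28:36, 28:36] = 100.0  # blob across the boundary
        labels = segment_tgn(tgn_ch, cells)
        assert set(np.unique(labels[28:36, 28:36])) == {1, 2}
        assert np.all(labels[labels > 0] == cells[labels > 0])


class TestMeasureCell:
    def _simple_seg(self):
        cells = np.zeros((64, 64), np.int32)
        rr, cc = disk((32, 32), 25)
        cells[rr, cc] = 1
        nuc = np.zeros_like(cells)
        rr, cc = disk((32, 32), 8)
        nuc[rr, cc] = 1
        tgn = np.zeros_like(cells)
        rr, cc = disk((32, 44), 5)
        tgn[rr, cc] = 1
        tgn[cells == 0] = 0
        return SegmentationResult(nuc, cells, tgn)

    def _field(self, cargo):
        z = np.zeros_like(cargo)
        return FieldImage(z, z, z, cargo)

    def test_uniform_cargo_gives_unit_ratio(self):
        seg = self._simple_seg()
        rec = measure_cell(1, seg, self._field(np.full((64, 64), 42.0)))
        assert rec.translocation_ratio == pytest.approx(1.0)

    def test_designed_two_to_one_ratio(self, noiseless_field):
        _, img, truth = noiseless_field
        cells, _ = quantify_field(img, with_features=False)
        assert np.allclose(cells.translocation_ratio, 2.0, rtol=0.05)

    def test_cargo_entirely_inside_tgn_excluded(self):
        seg = self._simple_seg()
        cargo = np.where(seg.tgn_labels == 1, 100.0, 0.0)
        result = measure_cell(1, seg, self._field(cargo))
        assert result == (None, UNDEFINED_RATIO)

    def test_ratio_scale_invariance(self, noiseless_field):
        """Multiplying the cargo channel by c > 0 leaves every ratio unchanged."""
        _, img, _ = noiseless_field
        base, _ = quantify_field(img, with_features=False)
        scaled_img = FieldImage(img.nucleus, img.body, img.tgn,
                                img.cargo * 3.7, img.pixel_size)
        scaled, _ = quantify_field(scaled_img, with_features=False)
        assert np.allclose(base.translocation_ratio,
                           scaled.translocation_ratio, rtol=1e-9)

    def test_compartment_conservation(self, noiseless_field):
        """tgn_area + cytoplasm_area equals cell_area for every retained cell."""
        _, img, _ = noiseless_field
        seg = segment_field(img)
        for cid in seg.cell_ids:
            cell = seg.cell_labels == cid
            tgn = seg.tgn_labels == cid
            cyto = cell & ~tgn
            assert tgn.sum() + cyto.sum() == cell.sum()


class TestTgnMorphology:
    def test_circle_minimizes_compactness(self):
        m = np.zeros((128, 128), bool)
        rr, cc = disk((64, 64), 50)
        m[rr, cc] = True
        elong, comp, rough, area, perim = tgn_morphology(m)
        assert comp == pytest.approx(1.0, abs=0.05)
        assert elong == pytest.approx(1.0, abs=0.02)
        assert rough == pytest.approx(1.0, abs=0.05)
        assert comp >= 0.95  # compactness ~>= 1 up to discretisation

    def test_square_compactness_analytic(self):
        m = np.zeros((100, 100), bool)
        m[20:80, 20:80] = True
        _, comp, _, _, _ = tgn_morphology(m)
        assert comp == pytest.approx(4.0 / np.pi, abs=0.05)

    def test_rectangle_elongation_and_compactness(self):
        m = np.zeros((120, 120), bool)
        m[10:20, 10:110] = True  # 100 x 10
        elong, comp, _, _, _ = tgn_morphology(m)
        assert elong == pytest.approx(0.10, abs=0.02)
        assert comp == pytest.approx(220 ** 2 / (4 * np.pi * 1000), abs=0.15)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            tgn_morphology(np.zeros((8, 8), bool))


class TestFeatureVector:
    def test_length_constant_and_ordered(self, noiseless_field):
        _, img, _ = noiseless_field
        seg = segment_field(img)
        vecs = [extract_feature_vector(cid, seg, img)
                for cid in seg.cell_ids[:3]]
        for v in vecs:
            assert tuple(v.index) == FEATURE_NAMES
        assert len(FEATURE_NAMES) == 90

    def test_zero_cargo_channel_zeroes_cargo_features(self, noiseless_field):
        _, img, _ = noiseless_field
        seg = segment_field(img)
        blank = FieldImage(img.nucleus, img.body, img.tgn,
                           np.zeros_like(img.cargo))
        v = extract_feature_vector(seg.cell_ids[0], seg, blank)
        assert v["cargo_puncta_count"] == 0
        assert v["cargo_mean_cell"] == 0
        assert v["cargo_positive_area"] == 0

    def test_nucleus_disk_features_analytic(self):
        nuc = np.zeros((64, 64), np.int32)
        rr, cc = disk((32, 32), 12)
        nuc[rr, cc] = 1
        seg = SegmentationResult(nuc, (nuc > 0).astype(np.int32) * 1, nuc * 0)
        z = np.zeros((64, 64))
        v = extract_feature_vector(1, seg, FieldImage(z, z, z, z))
        assert v["nucleus_area"] == pytest.approx(np.pi * 144, rel=0.05)
        assert v["nucleus_eccentricity"] == pytest.approx(0.0, abs=0.1)


class TestPunctaDensity:
    def test_five_puncta_on_fifty_micron_neurite(self):
        # 101-px straight neurite at 0.5 µm/px -> 50 µm skeleton
        cargo = np.zeros((21, 120))
        mask = np.zeros((21, 120), bool)
        mask[9:12, 5:106] = True
        for x in (15, 35, 55, 75, 95):
            cargo[10, x] = 100.0
        d = puncta_density(cargo, mask, pixel_size=0.5, threshold=50.0)
        assert d == pytest.approx(0.1, rel=0.02)

    def test_no_puncta_gives_zero(self):
        mask = np.zeros((11, 60), bool)
        mask[5, 5:55] = True
        assert puncta_density(np.zeros((11, 60)), mask, 0.5,
                              threshold=1.0) == 0.0

    def test_planted_poisson_density_recovered(self, rng):
        # ~lambda puncta per µm on a long straight neurite, noise-free
        lam = 0.08  # per µm at 0.5 µm/px -> p = 0.04 per pixel
        n_px = 2001
        mask = np.zeros((15, n_px + 10), bool)
        mask[7, 5:5 + n_px] = True
        cargo = np.zeros_like(mask, dtype=float)
        xs = np.flatnonzero(rng.random(n_px) < lam * 0.5)
        # enforce min separation so peak detection sees every punctum
        keep = [x for i, x in enumerate(xs) if i == 0 or x - xs[i - 1] > 4]
        for x in keep:
            cargo[7, 5 + x] = 100.0
        length_um = (n_px - 1) * 0.5
        d = puncta_density(cargo, mask, 0.5, threshold=50.0, min_distance=2)
        assert d == pytest.approx(len(keep) / length_um, rel=0.10)

    def test_zero_length_skeleton_rejected(self):
        with pytest.raises(ValueError):
            puncta_density(np.zeros((8, 8)), np.zeros((8, 8), bool), 0.5)
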