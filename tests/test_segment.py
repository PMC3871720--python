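import dataclasses

import numpy as np
import pytest

from lactoscan import (
    SceneParams,
    SegmentationParams,
    classify_rna_objects,
    generate_scene,
    render_channels,
    segment_channel_objects,
    segment_globules,
)
from lactoscan.synthetic import _annulus_arc_pixels, _disk_pixels


def _disk_plane(shape, cx, cy, r, fg=200.0, bg=10.0):
    plane = np.full(shape, bg)
    ys, xs = _disk_pixels(cx, cy, r, shape)
    plane[ys, xs] = fg
    return plane, len(xs)


def _rim_plane(shape, cx, cy, r, fg=200.0, bg=120.0):
    """DIC-like render: bright rim just inside the disk boundary."""
    plane = np.full(shape, bg)
    ys, xs = _annulus_arc_pixels(cx, cy, r - 2.0, r, 0.0, np.pi, shape)
    plane[ys, xs] = fg
    return plane


class TestSegmentGlobules:
    def test_uniform_plane_yields_nothing(self):
        labels, recs = segment_globules(np.full((64, 64), 50.0), SegmentationParams())
        assert recs == []
        assert labels.max() == 0

    @pytest.mark.parametrize("mode", ["gradient", "intensity"])
    def test_single_disk_centroid_and_area(self, mode):
        """One rendered globule of radius 20: centroid within 0.5 px, area
        within 5% of the rasterized-disk pixel count (oracle)."""
        shape = (128, 128)
        plane = _rim_plane(shape, 64.0, 64.0, 20.0)
        params = SegmentationParams(dic_mode=mode, smoothing_sigma=0.0)
        _, recs = segment_globules(plane, params)
        assert len(recs) == 1
        (rec,) = recs
        assert abs(rec.centroid[0] - 64.0) < 0.5
        assert abs(rec.centroid[1] - 64.0) < 0.5
        oracle_area = len(_disk_pixels(64.0, 64.0, 20.0, shape)[0])
        assert rec.area == pytest.approx(oracle_area, rel=0.05)
        assert rec.area == pytest.approx(np.pi * 400, rel=0.05)

    def test_recovers_all_generated_globules(self, clean_scene, clean_stack):
        _, recs = segment_globules(clean_stack.dic, SegmentationParams())
        assert len(recs) == len(clean_scene.globules) == 200

    def test_constant_plane_otsu_warns_not_raises(self, caplog):
        with caplog.at_level("WARNING"):
            _, recs = segment_globules(np.zeros((32, 32)), SegmentationParams())
        assert recs == []
        assert any("Otsu" in m for m in caplog.messages)

    def test_label_map_consistency(self, default_stack):
        labels, recs = segment_globules(default_stack.dic, SegmentationParams())
        assert sum(r.area for r in recs) == np.count_nonzero(labels)
        assert {r.globule_id for r in recs} == set(range(1, len(recs) + 1))


class TestSegmentChannelObjects:
    def test_uniform_plane_yields_nothing(self):
        labels, objs = segment_channel_objects(
            np.full((32, 32), 10.0), 5, SegmentationParams()
        )
        assert objs == []

    def test_min_area_filter(self):
        """Two blobs of 30 and 60 px, min_area 40: only the larger survives."""
        plane = np.full((64, 64), 10.0)
        plane[5:10, 5:11] = 200.0  # 30 px
        plane[30:36, 30:40] = 200.0  # 60 px
        params = SegmentationParams(smoothing_sigma=0.0)
        _, objs = segment_channel_objects(plane, 40, params)
        assert len(objs) == 1
        assert objs[0].area == 60

    def test_integrated_intensity_formula(self):
        """area 50 at value 100 over background 10 integrates to 50*(100-10)."""
        plane = np.full((64, 64), 10.0)
        plane[10:15, 10:20] = 100.0  # 50 px
        params = SegmentationParams(smoothing_sigma=0.0)
        _, objs = segment_channel_objects(plane, 5, params)
        assert len(objs) == 1
        assert objs[0].integrated_intensity == pytest.approx(50 * 90.0)

    def test_monotonic_in_min_area(self, default_stack):
        params = SegmentationParams()
        counts = [
            len(segment_channel_objects(default_stack.rna, a, params)[1])
            for a in (1, 5, 20, 80, 320)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_area_sums_match_label_map(self, default_stack):
        labels, objs = segment_channel_objects(default_stack.rna, 5, SegmentationParams())
        assert sum(o.area for o in objs) == np.count_nonzero(labels)


class TestClassifyRnaObjects:
    @staticmethod
    def _one_object(area_px=10, overlap_px=0, shape=(32, 32)):
        labels = np.zeros(shape, np.int32)
        labels[5, 5 : 5 + area_px] = 1
        dna = np.zeros(shape, bool)
        if overlap_px:
            dna[5, 5 : 5 + overlap_px] = True
        from lactoscan import RnaObject

        obj = RnaObject(
            object_id=1, centroid=(9.5, 5.0), area=float(area_px),
            integrated_intensity=100.0,
        )
        return labels, [obj], dna

    def test_no_dna_overlap_is_crescent(self):
        labels, objs, dna = self._one_object(overlap_px=0)
        params = SegmentationParams(dna_dilation_px=0)
        cands, cells = classify_rna_objects(labels, objs, dna, params)
        assert len(cands) == 1 and not cells
        assert cands[0].kind == "crescent_candidate"

    def test_full_overlap_is_cell(self):
        labels, objs, dna = self._one_object(overlap_px=10)
        params = SegmentationParams(dna_dilation_px=0)
        cands, cells = classify_rna_objects(labels, objs, dna, params)
        assert len(cells) == 1 and not cands
        assert cells[0].dna_area == 10

    def test_boundary_fraction_is_inclusive(self):
        """3/10 px overlap at coloc_fraction 0.3 classifies as a cell."""
        labels, objs, dna = self._one_object(overlap_px=3)
        params = SegmentationParams(dna_dilation_px=0, coloc_fraction=0.3)
        cands, cells = classify_rna_objects(labels, objs, dna, params)
        assert len(cells) == 1 and not cands

    def test_shape_mismatch_raises(self):
        labels, objs, dna = self._one_object()
        with pytest.raises(ValueError, match="shape"):
            classify_rna_objects(labels, objs, dna[:16], SegmentationParams())

    def test_partition_invariant(self, default_stack):
        """Every RNA object lands in exactly one of the two output lists."""
        params = SegmentationParams()
        labels, objs = segment_channel_objects(default_stack.rna, 5, params)
        dna_labels, _ = segment_channel_objects(
            default_stack.dna, 5, params, channel="dna"
        )
        cands, cells = classify_rna_objects(labels, objs, dna_labels > 0, params)
        assert len(cands) + len(cells) == len(objs)
        assert {c.object_id for c in cands} | {c.cell_id for c in cells} == {
            o.object_id for o in objs
        }

    def test_cell_count_monotone_in_coloc_fraction(self, default_stack):
        params = SegmentationParams()
        labels, objs = segment_channel_objects(default_stack.rna, 5, params)
        dna_labels, _ = segment_channel_objects(
            default_stack.dna, 5, params, channel="dna"
        )
        counts = []
        for f in (0.0, 0.2, 0.5, 0.9, 1.0):
            p = SegmentationParams(coloc_fraction=f)
            _, cells = classify_rna_objects(labels, objs, dna_labels > 0, p)
            counts.append(len(cells))
        assert counts == sorted(counts, reverse=True)


class TestGroundTruthAgreement:
    def test_noise_free_counts_and_centroids(self, clean_scene, clean_stack):
        """On a blur-free, noise-free render every object class is recovered
        exactly and centroids agree with the raster ground truth to 0.5 px."""
        from lactoscan import process_stack

        result = process_stack(clean_stack)
        assert len(result.globules) == len(clean_scene.globules)
        assert len(result.crescents) == len(clean_scene.crescents)
        assert len(result.cells) == len(clean_scene.cells)

        from scipy.spatial import cKDTree

        for truth, kind in (
            (clean_scene.globules, result.globules),
            (clean_scene.crescents, result.crescents),
            (clean_scene.cells, result.cells),
        ):
            dist, idx = cKDTree([r.centroid for r in kind]).query(
                [r.centroid for r in truth]
            )
            assert dist.max() <= 0.5
            assert len(set(idx)) == len(truth)
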