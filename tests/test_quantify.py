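import dataclasses
import math

import numpy as np
import pytest

from lactoscan import (
    CellRecord,
    CrescentRecord,
    GlobuleRecord,
    SceneParams,
    SegmentationParams,
    batch_process,
    generate_scene,
    process_stack,
    process_stack_tiled,
    render_channels,
    summarize_scene,
)
from lactoscan.io import write_channel_stack


def _globule(gid):
    return GlobuleRecord(gid, (0.0, 0.0), 100.0, 5.64, 1.0)


def _crescent(cid, linked, intensity=100.0, area=20.0):
    return CrescentRecord(
        crescent_id=cid, centroid=(0.0, 0.0), area=area,
        integrated_intensity=intensity, linked_globule_id=linked,
        link_distance=None if linked is None else 1.0, orphan_flag=linked is None,
    )


def _cell(cid, intensity=100.0, area=20.0):
    return CellRecord(cid, (0.0, 0.0), area, 10.0, intensity)


class TestSummarizeScene:
    def test_incidence_and_zero_cell_share(self):
        globules = [_globule(i) for i in (1, 2, 3)]
        crescents = [_crescent(1, 1), _crescent(2, 2), _crescent(3, 2)]
        s = summarize_scene(globules, crescents, [])
        assert s.pct_globules_with_crescents == pytest.approx(200 / 3)
        assert s.cellular_rna_pct == 0.0
        assert s.exosomal_rna_pct == 100.0

    def test_intensity_attribution_ratio(self):
        s = summarize_scene(
            [_globule(1)],
            [_crescent(1, 1, intensity=700.0)],
            [_cell(1, intensity=300.0)],
        )
        assert s.cellular_rna_pct == pytest.approx(30.0)
        assert s.exosomal_rna_pct == pytest.approx(70.0)

    def test_area_mode_uses_areas(self):
        s = summarize_scene(
            [_globule(1)],
            [_crescent(1, 1, intensity=700.0, area=10.0)],
            [_cell(1, intensity=300.0, area=30.0)],
            mode="area",
        )
        assert s.cellular_rna_pct == pytest.approx(75.0)

    def test_no_globules_reports_missing_not_zero(self):
        s = summarize_scene([], [_crescent(1, None)], [])
        assert math.isnan(s.pct_globules_with_crescents)

    def test_no_rna_objects_reports_missing(self):
        s = summarize_scene([_globule(1)], [], [])
        assert math.isnan(s.cellular_rna_pct)

    def test_multi_crescent_globule_counts_once(self):
        globules = [_globule(1), _globule(2)]
        crescents = [_crescent(1, 1), _crescent(2, 1), _crescent(3, 1)]
        s = summarize_scene(globules, crescents, [])
        assert s.pct_globules_with_crescents == pytest.approx(50.0)

    def test_orphans_counted_in_rna_but_not_incidence(self):
        s = summarize_scene(
            [_globule(1)], [_crescent(1, None, intensity=500.0)],
            [_cell(1, intensity=500.0)],
        )
        assert s.pct_globules_with_crescents == 0.0
        assert s.n_crescents_orphan == 1
        assert s.cellular_rna_pct == pytest.approx(50.0)

    def test_invalid_mode_rejected(self):
        with pytest.raises(ValueError):
            summarize_scene([], [], [], mode="volume")


class TestModeConsistency:
    def test_equal_mean_intensity_modes_agree(self, default_stack):
        """When per-pixel intensities are uniform across objects, intensity-
        and area-weighted attribution agree within one percentage point."""
        params = dataclasses.replace(
            SceneParams(seed=13), cell_rna_amp=150.0, crescent_amp=150.0,
            noise="none", blur_sigma=0.0,
        )
        stack = render_channels(generate_scene(params))
        # no smoothing, so detected masks equal the rendered object pixels
        # and every member pixel carries the same intensity
        seg = SegmentationParams(smoothing_sigma=0.0)
        si = process_stack(stack, seg=seg, mode="intensity").summary
        sa = process_stack(stack, seg=seg, mode="area").summary
        assert si.cellular_rna_pct == pytest.approx(sa.cellular_rna_pct, abs=1.0)


class TestRecovery:
    def test_incidence_and_share_recovery_over_seeds(self):
        """Over 20 seeded default-noise scenes the mean incidence error stays
        within twice the binomial standard error, and the cellular share is
        recovered within 2 percentage points of ground truth."""
        p0, n = 0.06, 200
        se = math.sqrt(p0 * (1 - p0) / n)
        errors, share_errors = [], []
        for seed in range(20):
            scene = generate_scene(SceneParams(seed=100 + seed))
            result = process_stack(render_channels(scene))
            s = result.summary
            errors.append(abs(s.pct_globules_with_crescents / 100 - p0))
            share_errors.append(
                abs(s.cellular_rna_pct - 100 * scene.cellular_share)
            )
        assert np.mean(errors) <= 2 * se
        assert max(share_errors) <= 2.0


class TestTiling:
    def test_single_tile_equals_whole(self, default_stack):
        whole = process_stack(default_stack).summary
        tiled = process_stack_tiled(default_stack, tile_size=512, overlap=64).summary
        assert whole == tiled

    def test_tiled_matches_whole_on_multi_tile_scene(self):
        scene = generate_scene(
            SceneParams(width=1024, height=1024, n_globules=500,
                        globule_radius_lognormal=(5.0, 0.15), n_cells=10, seed=21)
        )
        stack = render_channels(scene)
        # fixed thresholds isolate the tiling machinery from per-tile Otsu
        seg = SegmentationParams(
            threshold_method="fixed", fixed_thresholds={"rna": 30.0, "dna": 30.0}
        )
        whole = process_stack(stack, seg=seg).summary
        tiled = process_stack_tiled(stack, tile_size=400, overlap=64, seg=seg).summary
        assert (whole.n_globules, whole.n_crescents, whole.n_cells) == (
            tiled.n_globules, tiled.n_crescents, tiled.n_cells,
        )
        assert whole.pct_globules_with_crescents == tiled.pct_globules_with_crescents
        # intensity integration uses per-tile background estimates, so the
        # attribution split may differ in the far decimals
        assert whole.cellular_rna_pct == pytest.approx(
            tiled.cellular_rna_pct, abs=0.05
        )


class TestBatchProcess:
    @pytest.fixture()
    def three_images(self, tmp_path):
        paths = []
        for seed in range(3):
            scene = generate_scene(SceneParams(seed=30 + seed, n_globules=60))
            stack = render_channels(scene)
            paths.append(write_channel_stack(stack, tmp_path / f"img{seed}.tif"))
        return paths

    def test_one_row_per_image(self, three_images):
        summaries, objects = batch_process(three_images)
        assert len(summaries) == 3
        assert (summaries["status"] == "ok").all()
        assert set(objects["image_id"]) == {p.stem for p in three_images}

    def test_corrupt_image_isolated(self, three_images, tmp_path):
        bad = tmp_path / "corrupt.tif"
        bad.write_bytes(b"not a tiff at all")
        summaries, _ = batch_process([*three_images, bad])
        assert len(summaries) == 4
        assert (summaries["status"] == "ok").sum() == 3
        assert summaries["status"].str.startswith("failed").sum() == 1

    def test_empty_path_list_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            batch_process([])

    def test_recovered_incidences_monotone(self, tmp_path):
        paths = []
        for i, pct in enumerate((1, 3, 5, 7, 9)):
            scene = generate_scene(
                SceneParams(seed=50 + i, crescent_incidence=2 * pct)  # exact counts
            )
            paths.append(
                write_channel_stack(render_channels(scene), tmp_path / f"p{pct}.tif")
            )
        summaries, _ = batch_process(paths)
        rec = summaries["pct_globules_with_crescents"].to_numpy()
        assert (np.diff(rec) > 0).all()
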