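"""Tracking and per-well kinetic metrics."""

import numpy as np
import pandas as pd
import pytest

from orgscreen.config import ValidationError
from orgscreen.metrics import compute_well_metrics, fold_change, growth_rate_series
from orgscreen.segmentation import LabeledMask
from orgscreen.synthetic import WellImageSet, render_well_stack
from orgscreen.tracking import track_objects


def _mask(arr, frame=0):
    return LabeledMask(labels=np.asarray(arr, np.int32), frame=frame)


def _two_object_mask():
    labels = np.zeros((32, 32), np.int32)
    labels[2:8, 2:8] = 1
    labels[20:26, 20:26] = 2
    return labels


class TestTracking:
    def test_static_masks_identity_links_no_events(self):
        m = _two_object_mask()
        graph = track_objects([_mask(m, 0), _mask(m, 1), _mask(m, 2)])
        assert len(graph.edges) == 4  # 2 objects x 2 transitions
        assert graph.merges == []
        assert graph.disappearances == []
        assert all(src[1] == dst[1] for src, dst in graph.edges)

    def test_two_objects_merging_generate_one_merge_event(self):
        before = _two_object_mask()
        after = np.zeros((32, 32), np.int32)
        after[2:26, 2:26] = 1
        graph = track_objects([_mask(before, 0), _mask(after, 1)])
        assert len(graph.merges) == 1
        ev = graph.merges[0]
        assert ev["frame"] == 1 and sorted(ev["predecessors"]) == [1, 2]

    def test_vanishing_object_recorded_as_disappearance(self):
        before = _two_object_mask()
        after = before.copy()
        after[after == 2] = 0
        graph = track_objects([_mask(before, 0), _mask(after, 1)])
        assert (0, 2) in graph.disappearances

    def test_new_object_recorded_as_appearance(self):
        before = _two_object_mask()
        after = before.copy()
        after[12:16, 12:16] = 3
        graph = track_objects([_mask(before, 0), _mask(after, 1)])
        assert (1, 3) in graph.appearances

    def test_single_frame_warns_and_returns_no_edges(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING):
            graph = track_objects([_mask(_two_object_mask())])
        assert graph.edges == []
        assert len(graph.nodes) == 2

    def test_mismatched_shapes_rejected(self):
        with pytest.raises(ValidationError, match="dimensions"):
            track_objects([_mask(np.zeros((8, 8))), _mask(np.zeros((9, 9)))])

    def test_count_per_frame_matches_masks(self):
        masks = [_mask(_two_object_mask(), 0), _mask(_two_object_mask(), 1)]
        graph = track_objects(masks)
        assert graph.count_per_frame() == {0: 2, 1: 2}


class TestTrackingOnSimulator:
    def test_fusions_tracked_on_truth_masks(self, fusion_case):
        truth, masks, fusion_frames = fusion_case
        graph = track_objects(masks)
        merge_frames = sorted(ev["frame"] for ev in graph.merges)
        assert merge_frames == sorted(fusion_frames)

    def test_merge_conserves_area_within_10pct(self, fusion_case):
        truth, masks, fusion_frames = fusion_case
        graph = track_objects(masks)
        for ev in graph.merges:
            t = ev["frame"]
            succ_area = masks[t].areas_px()[ev["successor"]]
            pred_area = sum(masks[t - 1].areas_px()[p] for p in ev["predecessors"])
            assert succ_area >= 0.9 * pred_area


@pytest.fixture(scope="module")
def fusion_case():
    """Simulated well with at least one fusion; truth masks per frame."""
    from orgscreen.config import SimulationConfig, make_plate_map
    from orgscreen.synthetic import simulate_plate

    cfg = SimulationConfig(seed=15, image_size_px=(160, 160), seeding_density=10,
                           n_timepoints=6, growth_rate_h=0.06, plate_format=96,
                           bubble_rate=0.0, debris_rate=0.0)
    truth = simulate_plate(cfg, make_plate_map(1, 0, [], plate_format=96))
    states = truth.states
    fusion_frames = sorted(
        states[states.parent_ids.astype(str).str.len() > 0].frame.unique()
    )
    assert len(fusion_frames) >= 1, "fixture must schedule at least one fusion"
    _, masks_arr = render_well_stack(truth, "A01")
    masks = [LabeledMask(m.astype(np.int32), frame=t, provenance="truth")
             for t, m in enumerate(masks_arr)]
    return truth, masks, fusion_frames


class TestWellMetrics:
    def _images(self, bf, green=None, blue=None, um_per_px=2.0, times=None):
        n = bf.shape[0]
        return WellImageSet(
            well_id="B02", times_h=times or list(range(n)), bf=bf, blue=blue,
            green=green, um_per_px=um_per_px,
        )

    def test_pixel_count_oracle(self):
        # one 1000-px object at 2 µm/px, green covering 250 px
        labels = np.zeros((64, 64), np.int32)
        labels[:25, :40] = 1  # 1000 px
        green = np.zeros((1, 64, 64))
        green[0, :25, :10] = 1.0  # 250 px inside the mask
        bf = np.full((1, 64, 64), 0.5)
        ts = compute_well_metrics(self._images(bf, green=green), [LabeledMask(labels)])
        row = ts.iloc[0]
        assert row.total_mask_area_um2 == pytest.approx(4000.0)
        assert row.green_area_ratio == pytest.approx(0.25)
        assert row.viable_area_um2 == pytest.approx(3000.0)
        assert row["count"] == 1

    def test_total_equals_count_times_mean(self):
        labels = np.zeros((64, 64), np.int32)
        labels[:10, :10] = 1
        labels[20:40, 20:40] = 2
        bf = np.full((1, 64, 64), 0.5)
        ts = compute_well_metrics(self._images(bf), [LabeledMask(labels)])
        row = ts.iloc[0]
        assert row.total_mask_area_um2 == pytest.approx(row["count"] * row.mean_mask_area_um2)

    def test_empty_mask_flagged_undefined(self):
        bf = np.full((1, 32, 32), 0.5)
        ts = compute_well_metrics(self._images(bf), [LabeledMask(np.zeros((32, 32), np.int32))])
        row = ts.iloc[0]
        assert row["count"] == 0 and row.undefined_ratio
        assert np.isnan(row.green_area_ratio)

    def test_missing_green_zero_filled_with_flag(self):
        labels = np.zeros((32, 32), np.int32)
        labels[:8, :8] = 1
        bf = np.full((1, 32, 32), 0.5)
        ts = compute_well_metrics(self._images(bf), [LabeledMask(labels)])
        row = ts.iloc[0]
        assert row.green_missing and row.total_green_area_um2 == 0.0

    def test_misaligned_masks_rejected(self):
        bf = np.full((2, 32, 32), 0.5)
        with pytest.raises(ValidationError, match="frames"):
            compute_well_metrics(self._images(bf), [LabeledMask(np.zeros((32, 32), np.int32))])

    def test_green_ratios_under_uniform_intensity_rescaling(self):
        # area ratio invariant; intensity ratio scales linearly
        labels = np.zeros((64, 64), np.int32)
        labels[:20, :20] = 1
        green = np.full((1, 64, 64), 0.02)
        green[0, :10, :20] = 0.45
        bf = np.full((1, 64, 64), 0.5)
        ts1 = compute_well_metrics(self._images(bf, green=green), [LabeledMask(labels)])
        ts2 = compute_well_metrics(self._images(bf, green=green * 2.0), [LabeledMask(labels)])
        assert ts2.green_area_ratio.iloc[0] == pytest.approx(ts1.green_area_ratio.iloc[0])
        assert ts2.green_intensity_ratio.iloc[0] == pytest.approx(
            2.0 * ts1.green_intensity_ratio.iloc[0]
        )

    def test_simulator_viable_area_fold_change_matches_truth(self, titration_plate):
        from orgscreen.segmentation import segment_classical

        cfg, pmap, truth, spec = titration_plate
        well = pmap.table.query("role == 'vehicle'").well_id.iloc[0]
        images, _ = render_well_stack(truth, well)
        masks = [segment_classical(images.bf[t], frame=t) for t in range(images.n_frames)]
        ts = compute_well_metrics(images, masks)
        fc = fold_change(ts, "viable_area_um2").iloc[-1]
        tw = truth.per_well_expected
        grp = tw[tw.well_id == well].sort_values("frame")
        fc_truth = grp.viable_area_um2.iloc[-1] / grp.viable_area_um2.iloc[0]
        assert fc == pytest.approx(fc_truth, rel=0.15)


class TestGrowthRates:
    def _ts(self, values, dt=6.0):
        return pd.DataFrame(
            {"well_id": "A01", "frame": range(len(values)),
             "time_h": [i * dt for i in range(len(values))], "metric": values}
        )

    def test_constant_metric_rate_zero(self):
        res = growth_rate_series(self._ts([5.0, 5.0, 5.0]), "metric")
        assert res["mean_log2_per_interval"] == pytest.approx(0.0)

    def test_doubling_each_frame_rate_one(self):
        res = growth_rate_series(self._ts([1.0, 2.0, 4.0, 8.0]), "metric")
        assert res["per_interval_log2"] == pytest.approx([1.0, 1.0, 1.0])
        assert res["mean_log2_per_hour"] == pytest.approx(1 / 6.0)

    def test_zero_at_t0_flagged(self):
        res = growth_rate_series(self._ts([0.0, 1.0]), "metric")
        assert res["undefined"]

    def test_simulator_exponential_rate_recovered(self, rendered_well):
        from orgscreen.segmentation import segment_classical

        cfg, truth, images, tmasks = rendered_well
        masks = [segment_classical(images.bf[t], frame=t) for t in range(images.n_frames)]
        ts = compute_well_metrics(images, masks)
        res = growth_rate_series(ts, "total_mask_area_um2")
        expected = cfg.growth_rate_h / np.log(2)  # log2 area units per hour
        assert res["mean_log2_per_hour"] == pytest.approx(expected, rel=0.10)

    def test_fold_change_is_one_at_t0(self):
        ts = self._ts([3.0, 6.0, 9.0])
        fc = fold_change(ts, "metric")
        assert fc.iloc[0] == 1.0
        assert fc.iloc[-1] == pytest.approx(3.0)
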