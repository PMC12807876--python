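import numpy as np
import pytest

from nemquant.errors import ValidationError
from nemquant.io import ImageStack
from nemquant.nuclei import (
    apply_qc,
    measure_nucleus,
    preprocess,
    roi_traces,
    segment_nuclei,
    track_nuclei,
    tracks_to_table,
)
from nemquant.synth import NoiseSpec, NucleusSpec, SynthScene, synth_nucleus_timelapse


def _pipeline(stack):
    labels = segment_nuclei(preprocess(stack, "ne_marker"))
    tracks = track_nuclei(labels)
    for tr in tracks:
        measure_nucleus(stack, labels, tr)
    return labels, tracks


class TestPreprocess:
    def test_output_range_contract(self, noisy_nucleus):
        stack, _ = noisy_nucleus
        out = preprocess(stack, "ne_marker")
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_planar_gradient_removed_under_flat_foreground(self, rng):
        yy, xx = np.meshgrid(np.linspace(0, 0.4, 64), np.linspace(0, 0.4, 64), indexing="ij")
        img = np.tile(yy + xx, (1, 1, 4, 1, 1))
        img[0, 0, :, 28:36, 28:36] += 1.0  # flat foreground block
        stack = ImageStack(data=img, voxel_size=(1, 1, 1), channel_roles={0: "sensor"})
        out = preprocess(stack, "sensor", gaussian_radius_px=0.5, rollball_radius_px=20)
        fg = out[0, :, 30:34, 30:34].mean()
        bg = out[0, :, 2:10, 2:10].mean()
        assert bg < 0.05 * fg

    def test_constant_channel_rejected(self):
        stack = ImageStack(data=np.zeros((1, 1, 2, 8, 8)), voxel_size=(1, 1, 1),
                           channel_roles={0: "sensor"})
        with pytest.raises(ValidationError, match="dynamic range"):
            preprocess(stack, "sensor")


class TestSegmentation:
    def test_well_separated_nuclei_recovered_with_high_overlap(self):
        scene = SynthScene(
            fov_shape=(20, 200, 200), n_frames=1, seed=6,
            nuclei=[NucleusSpec(centre=(10, 50, 50), semi_axes=(7, 25, 25)),
                    NucleusSpec(centre=(10, 60, 150), semi_axes=(7, 22, 22)),
                    NucleusSpec(centre=(10, 150, 100), semi_axes=(7, 24, 24))],
            noise=NoiseSpec())
        stack, gt = synth_nucleus_timelapse(scene)
        labels = segment_nuclei(preprocess(stack, "ne_marker"))
        found = [l for l in np.unique(labels[0]) if l]
        assert len(found) == 3
        for true_id in (1, 2, 3):
            true = gt.labels[0] == true_id
            best = max(found, key=lambda l: ((labels[0] == l) & true).sum())
            seg = labels[0] == best
            jaccard = (true & seg).sum() / (true | seg).sum()
            assert jaccard > 0.8

    def test_touching_nuclei_split_by_markers(self):
        scene = SynthScene(
            fov_shape=(20, 128, 128), n_frames=1, seed=2,
            nuclei=[NucleusSpec(centre=(10, 64, 42), semi_axes=(7, 20, 20)),
                    NucleusSpec(centre=(10, 64, 86), semi_axes=(7, 20, 20))],
            noise=NoiseSpec())
        stack, _ = synth_nucleus_timelapse(scene)
        labels = segment_nuclei(preprocess(stack, "ne_marker"))
        assert len([l for l in np.unique(labels[0]) if l]) == 2

    def test_blank_frame_yields_no_labels(self):
        blank = np.zeros((1, 8, 32, 32))
        blank[0, :, 5, 5] = 1e-3  # just enough dynamic range to pass validation
        labels = segment_nuclei(blank)
        assert labels.max() == 0


class TestTracking:
    @staticmethod
    def _labels_from_positions(positions_per_frame, shape=(1, 64, 64), r=4):
        frames = []
        for positions in positions_per_frame:
            vol = np.zeros(shape, np.int32)
            for lab, (y, x) in enumerate(positions, start=1):
                vol[0, max(0, y - r):y + r, max(0, x - r):x + r] = lab
            frames.append(vol)
        return np.stack(frames)

    def test_static_object_forms_single_full_length_track(self):
        labels = self._labels_from_positions([[(30, 30)]] * 10)
        tracks = track_nuclei(labels)
        assert len(tracks) == 1
        assert tracks[0].frames == list(range(10))

    def test_two_nearby_objects_keep_their_identities(self):
        # each object moves 4 px, far less than their 24 px separation
        labels = self._labels_from_positions([[(20, 20), (20, 44)], [(24, 20), (24, 44)]])
        tracks = track_nuclei(labels, max_link_px=130)
        assert len(tracks) == 2
        assert all(len(t.frames) == 2 for t in tracks)
        for t in tracks:
            dy = abs(t.centroids[1][1] - t.centroids[0][1])
            dx = abs(t.centroids[1][2] - t.centroids[0][2])
            assert dy <= 5 and dx <= 1

    def test_links_beyond_hard_limit_are_not_made(self):
        labels = self._labels_from_positions([[(10, 10)], [(10, 60)]], shape=(1, 72, 72))
        tracks = track_nuclei(labels, max_link_px=10, jump_link_factor=2.0)
        assert len(tracks) == 2  # 50 px > 10 * 2, so the track ends

    def test_flagged_link_within_factor_records_displacement(self):
        labels = self._labels_from_positions([[(10, 10)], [(10, 40)]], shape=(1, 72, 72))
        tracks = track_nuclei(labels, max_link_px=10, jump_link_factor=4.0)
        assert len(tracks) == 1
        assert tracks[0].max_displacement() == pytest.approx(30.0, abs=0.1)


class TestMeasurement:
    def test_ratiometric_signal_recovers_rim_enrichment(self, noisy_nucleus):
        stack, gt = noisy_nucleus
        _, tracks = _pipeline(stack)
        assert tracks[0].s_ratio[0] == pytest.approx(gt.rim_enrichment[1], rel=0.1)

    def test_uniform_sensor_gives_unit_ratio(self, clean_nucleus):
        stack, _ = clean_nucleus
        flat = ImageStack(data=np.where(stack.data > -1, 0.5, 0.5),
                          voxel_size=stack.voxel_size, channel_roles=stack.channel_roles)
        flat.data[:, 0] = stack.data[:, 0]  # keep the NE marker for segmentation
        labels, tracks = _pipeline(stack)
        tr = track_nuclei(labels)[0]
        measure_nucleus(flat, labels, tr)
        assert tr.s_ratio[0] == pytest.approx(1.0, abs=1e-9)

    def test_ratio_invariant_under_global_sensor_scaling(self, noisy_nucleus):
        stack, _ = noisy_nucleus
        labels, tracks = _pipeline(stack)
        scaled = ImageStack(data=stack.data.copy(), voxel_size=stack.voxel_size,
                            channel_roles=stack.channel_roles)
        scaled.data[:, 1] *= 37.0
        tr = track_nuclei(labels)[0]
        measure_nucleus(scaled, labels, tr)
        assert tr.s_ratio[0] == pytest.approx(tracks[0].s_ratio[0], rel=1e-9)

    def test_volume_within_three_percent_of_analytic_ellipsoid(self):
        scene = SynthScene(
            fov_shape=(24, 96, 96), n_frames=1, seed=8,
            nuclei=[NucleusSpec(centre=(12, 48, 48), semi_axes=(10, 20, 20))],
            noise=NoiseSpec.none())
        stack, gt = synth_nucleus_timelapse(scene)
        # measured on ground-truth labels: voxelization is the only error source
        tr = track_nuclei(gt.labels.astype(np.int32))[0]
        measure_nucleus(stack, gt.labels.astype(np.int32), tr)
        analytic = 4 / 3 * np.pi * 10 * 20 * 20
        assert tr.volume_um3[0] == pytest.approx(analytic, rel=0.03)


class TestQC:
    def test_all_compliant_scene_retains_everything(self):
        scene = SynthScene(
            fov_shape=(20, 300, 300), n_frames=2, seed=5,
            nuclei=[NucleusSpec(centre=(10, 90, 90), semi_axes=(7, 55, 55)),
                    NucleusSpec(centre=(10, 210, 210), semi_axes=(7, 55, 55))],
            noise=NoiseSpec())
        stack, _ = synth_nucleus_timelapse(scene)
        labels, tracks = _pipeline(stack)
        retained, report = apply_qc(tracks, labels)
        assert len(retained) == 2
        assert report.empty

    def test_track_with_gap_excluded_as_broken(self):
        vols = []
        for t in range(3):
            vol = np.zeros((1, 64, 64), np.int32)
            if t != 1:  # object missing in the middle frame
                vol[0, 50:60, 50:60] = 1
            vol[0, 5:25, 5:25] = 2
            vols.append(vol)
        labels = np.stack(vols)
        tracks = track_nuclei(labels)
        for tr in tracks:
            tr.mid_area_px2 = [400.0] * len(tr.frames)  # bypass measurement for this toy
        retained, report = apply_qc(tracks, labels, min_area_px2=50.0, max_jump_px=130.0)
        assert "broken_track" in set(report["reason"])

    def test_unmeasured_track_rejected(self):
        labels = np.zeros((1, 2, 8, 8), np.int32)
        labels[0, :, 2:5, 2:5] = 1
        tracks = track_nuclei(labels)
        with pytest.raises(ValidationError, match="unmeasured"):
            apply_qc(tracks, labels)


class TestRoiTraces:
    def test_lysis_step_and_sensor_decay_visible_in_mip_traces(self):
        scene = SynthScene(
            fov_shape=(16, 96, 96), n_frames=8, seed=0,
            nuclei=[NucleusSpec(centre=(8, 48, 48), semi_axes=(6, 18, 18), lysis_frame=5)],
            noise=NoiseSpec(gaussian_sd=0.005, poisson_scale=300, background_gradient=0.02))
        stack, gt = synth_nucleus_timelapse(scene)
        traces = roi_traces(stack, gt.labels.astype(np.int32))
        lys = traces["nuclear_lysis"]
        assert lys[5] > 3 * lys[4] + 0.05
        assert traces["extranuclear_sensor"][7] < traces["extranuclear_sensor"][4]

    def test_profile_across_enriched_rim_peaks_at_the_boundary(self, clean_nucleus):
        stack, gt = clean_nucleus
        traces = roi_traces(stack, gt.labels.astype(np.int32),
                            profile_line=((48.0, 10.0), (48.0, 48.0)), profile_width_px=20)
        prof = traces["rim_profile"][0]
        # boundary crossing at x ~ 26 (centre 48, semi-axis 22): peak in the rim zone
        assert 12 <= int(np.argmax(prof)) <= 20

    def test_missing_lysis_channel_rejected(self, rng):
        stack = ImageStack(data=rng.random((1, 1, 4, 16, 16)), voxel_size=(1, 1, 1),
                           channel_roles={0: "sensor"})
        with pytest.raises(ValidationError):
            roi_traces(stack, np.zeros((1, 4, 16, 16), np.int32))


def test_tracks_to_table_is_tidy():
    labels = np.zeros((2, 1, 32, 32), np.int32)
    labels[:, 0, 10:20, 10:20] = 1
    tracks = track_nuclei(labels)
    data = np.zeros((2, 2, 1, 32, 32))
    data[:, 0] = 0.5
    data[:, 1] = 0.5
    stack = ImageStack(data=data, voxel_size=(1, 1, 1),
                       channel_roles={0: "ne_marker", 1: "sensor"})
    for tr in tracks:
        measure_nucleus(stack, labels, tr)
    df = tracks_to_table(tracks)
    assert set(df.columns) >= {"track_id", "frame", "volume_um3", "S", "retained"}
    assert len(df) == 2
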