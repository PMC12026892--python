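"""MS2 spot detection, locus selection, tracking, and gap filling."""

import numpy as np
import pytest

from hubburst import ms2
from hubburst.config import MS2Params
from hubburst.nuclei import NucleusTrack
from hubburst.synthetic import _add_gaussian_blob

VZ = (0.3, 0.104, 0.104)


def _spot_volume(center_um, total=5000.0, background=50.0, shape=(16, 48, 48)):
    vol = np.full(shape, background)
    _add_gaussian_blob(vol, center_um, (0.45, 0.15, 0.15), total, VZ)
    return vol


class TestDetection:
    def test_uniform_nucleus_no_candidates(self):
        vol = np.full((8, 32, 32), 42.0)
        mask = np.ones_like(vol, dtype=bool)
        assert ms2.detect_ms2_candidates(vol, mask, VZ) == []

    def test_single_spot_detected_within_half_voxel(self):
        center = np.array([2.4, 2.55, 2.45])
        vol = _spot_volume(center)
        mask = np.ones(vol.shape, dtype=bool)
        cands = ms2.detect_ms2_candidates(vol, mask, VZ)
        sel = ms2.select_locus_spot(cands)
        assert sel is not None
        # lateral localization within half a voxel; axial within half a z step
        err = np.abs(sel.centroid_um - center)
        assert err[1] <= 0.5 * VZ[1] + 1e-9 or err[1] <= 0.06
        assert np.linalg.norm(err) < 0.5 * max(VZ) + 0.05

    def test_background_corrected_intensity_tracks_spot_total(self):
        center = np.array([2.4, 2.5, 2.5])
        weak = ms2.select_locus_spot(
            ms2.detect_ms2_candidates(_spot_volume(center, total=2000),
                                      np.ones((16, 48, 48), bool), VZ)
        )
        strong = ms2.select_locus_spot(
            ms2.detect_ms2_candidates(_spot_volume(center, total=6000),
                                      np.ones((16, 48, 48), bool), VZ)
        )
        assert strong.background_corrected > 2 * weak.background_corrected

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            ms2.detect_ms2_candidates(np.zeros((4, 8, 8)),
                                      np.zeros((4, 8, 8), bool), VZ)


class TestSelection:
    @staticmethod
    def _cand(label, intensity, count=5):
        return ms2.SpotCandidate(
            label=label, centroid_um=np.zeros(3),
            integrated_intensity=intensity,
            background_corrected=intensity, voxel_count=count,
        )

    def test_brightest_wins(self):
        sel = ms2.select_locus_spot([self._cand(1, 10.0), self._cand(2, 7.0)])
        assert sel.label == 1

    def test_empty_list_gives_none(self):
        assert ms2.select_locus_spot([]) is None

    def test_tie_broken_by_volume_then_label(self):
        sel = ms2.select_locus_spot(
            [self._cand(1, 10.0, count=4), self._cand(2, 10.0, count=9)]
        )
        assert sel.label == 2
        sel2 = ms2.select_locus_spot(
            [self._cand(3, 10.0, count=4), self._cand(2, 10.0, count=4)]
        )
        assert sel2.label == 2


def _static_nucleus(n_frames, centroid=(2.0, 2.5, 2.5), radii=(1.5, 1.5, 1.5)):
    tr = NucleusTrack(nucleus_id=0)
    for f in range(n_frames):
        tr.frames.append(f)
        tr.labels[f] = 1
        tr.centroids_um[f] = np.asarray(centroid, dtype=float)
        tr.volumes_um3[f] = 20.0
        tr.radii_um[f] = np.asarray(radii, dtype=float)
    return tr


def _selection(pos, intensity=100.0):
    return ms2.SpotCandidate(label=1, centroid_um=np.asarray(pos, float),
                             integrated_intensity=intensity,
                             background_corrected=intensity, voxel_count=5)


class TestTracking:
    def test_continuous_static_detections_one_segment(self):
        sels = [_selection((2.0, 2.5, 2.5))] * 5
        raw = ms2.track_ms2(sels)
        assert raw.frames == [0, 1, 2, 3, 4]
        assert raw.gaps == []
        assert raw.suspect_frames == []

    def test_single_frame_dropout_is_one_gap(self):
        sels = [_selection((2, 2, 2)), None, _selection((2, 2, 2))]
        raw = ms2.track_ms2(sels)
        assert raw.gaps == [(1, 1)]

    def test_large_jump_flagged(self):
        sels = [_selection((2, 2, 2)), _selection((2, 2, 4.5))]
        raw = ms2.track_ms2(sels, MS2Params(max_step_um=1.0))
        assert raw.suspect_frames == [1]


class TestFillTrack:
    def test_static_gap_interpolates_identical_positions(self):
        sels = [_selection((2.0, 2.5, 2.5)), None, None, _selection((2.0, 2.5, 2.5))]
        raw = ms2.track_ms2(sels)
        filled = ms2.fill_track(raw, _static_nucleus(4))
        for f in (1, 2):
            np.testing.assert_allclose(filled.positions_um[f], (2.0, 2.5, 2.5))
            assert filled.status[f] == "interpolated"

    def test_translation_during_gap_carries_position(self):
        # nucleus translates by delta during the gap; fixed relative position
        tr = NucleusTrack(nucleus_id=0)
        delta = np.array([0.0, 0.6, 0.9])
        for f in range(4):
            tr.frames.append(f)
            tr.labels[f] = 1
            tr.centroids_um[f] = np.array([2.0, 2.5, 2.5]) + delta * f / 3
            tr.volumes_um3[f] = 20.0
            tr.radii_um[f] = np.array([1.5, 1.5, 1.5])
        p0 = tr.centroids_um[0] + np.array([0.2, 0.3, -0.1])
        p3 = tr.centroids_um[3] + np.array([0.2, 0.3, -0.1])
        raw = ms2.track_ms2([_selection(p0), None, None, _selection(p3)])
        filled = ms2.fill_track(raw, tr)
        for f in (1, 2):
            np.testing.assert_allclose(
                filled.positions_um[f],
                tr.centroids_um[f] + np.array([0.2, 0.3, -0.1]),
                atol=1e-12,
            )

    def test_isotropic_size_change_is_exact(self):
        tr = NucleusTrack(nucleus_id=0)
        for f, scale in enumerate((1.0, 1.2, 1.5)):
            tr.frames.append(f)
            tr.labels[f] = 1
            tr.centroids_um[f] = np.array([2.0, 2.5, 2.5])
            tr.volumes_um3[f] = 20.0 * scale**3
            tr.radii_um[f] = np.array([1.0, 1.0, 1.0]) * scale
        offset = np.array([0.2, -0.3, 0.4])
        raw = ms2.track_ms2(
            [_selection(tr.centroids_um[0] + offset), None,
             _selection(tr.centroids_um[2] + offset * 1.5)]
        )
        filled = ms2.fill_track(raw, tr)
        np.testing.assert_allclose(
            filled.positions_um[1], tr.centroids_um[1] + offset * 1.2, atol=1e-12
        )

    def test_extrapolation_limited_by_available_frames(self):
        sels = [None] * 5 + [_selection((2.0, 2.5, 2.5))]
        raw = ms2.track_ms2(sels)
        filled = ms2.fill_track(raw, _static_nucleus(6),
                                MS2Params(max_extrapolate_frames=20))
        ext = [f for f, s in filled.status.items() if s == "extrapolated"]
        assert sorted(ext) == [0, 1, 2, 3, 4]

    def test_extrapolation_capped_at_max_frames(self):
        sels = [None] * 30 + [_selection((2.0, 2.5, 2.5))]
        raw = ms2.track_ms2(sels)
        filled = ms2.fill_track(raw, _static_nucleus(31))
        ext = [f for f, s in filled.status.items() if s == "extrapolated"]
        assert len(ext) == 20
        assert max(ext) == 29

    def test_status_accounting_partitions_frames(self):
        sels = [None, None, _selection((2, 2.5, 2.5)), None,
                _selection((2, 2.5, 2.5)), _selection((2, 2.5, 2.5))]
        raw = ms2.track_ms2(sels)
        filled = ms2.fill_track(raw, _static_nucleus(6))
        n = {s: 0 for s in ("detected", "interpolated", "extrapolated")}
        for s in filled.status.values():
            n[s] += 1
        assert n["detected"] == 3
        assert n["interpolated"] == 1
        assert n["extrapolated"] == 2
        assert sum(n.values()) == len(filled.frames)
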