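"""Generator contracts: dwell sampling, burst waveforms, coupling modes, and
movie-level rendering against analytic expectations."""

import numpy as np
import pandas as pd
import pytest

import hubburst as hb
from hubburst import synthetic
from hubburst.conditions import HUB_ARRIVAL_DWELL_NC14


class TestDwellSampling:
    def test_degenerate_point_mass(self):
        mix = hb.DwellMixture(weights=(1 - 2e-12, 1e-12, 1e-12),
                              means_min=(5.0, 5.0, 5.0), sds_min=(0.0, 0.0, 0.0))
        s = hb.sample_dwell_times(mix, 50, seed=0)
        assert np.allclose(s, 5.0)

    def test_sample_mean_matches_mixture_mean(self):
        mix = hb.DwellMixture(means_min=(0.5, 1.35, 10.04), sds_min=(0.05, 0.1, 0.5))
        n = 10_000
        s = hb.sample_dwell_times(mix, n, seed=3)
        se = np.sqrt(mix.variance / n)
        assert abs(s.mean() - mix.mean) < 4 * se
        assert (s > 0).all()

    def test_seed_determinism(self):
        mix = hb.DwellMixture()
        a = hb.sample_dwell_times(mix, 500, seed=42)
        b = hb.sample_dwell_times(mix, 500, seed=42)
        np.testing.assert_array_equal(a, b)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(weights=(0.5, 0.3, 0.3)),  # weights not summing to 1
            dict(means_min=(0.0, 1.0, 2.0)),  # non-positive mean
            dict(weights=(0.0, 0.5, 0.5)),  # zero weight
        ],
    )
    def test_invalid_mixture_rejected(self, kwargs):
        with pytest.raises(Exception):
            hb.DwellMixture(**kwargs)


class TestBurstWaveform:
    def test_single_noiseless_trapezoid_values(self, dt_min):
        spec = hb.MS2Spec(peak_amplitude=100.0, loading_rate=100.0,
                          plateau_min=1.0, decay_rate_per_min=1.0,
                          decay_shape="linear", inter_burst_interval_min=10.0)
        t = np.arange(0, 4.0, 0.001)
        w = synthetic.burst_waveform(t, [0.0], spec)
        assert w[0] == 0.0
        assert np.isclose(w[t == 0.5][0], 50.0)  # mid-rise
        assert np.isclose(w.max(), 100.0)
        assert np.isclose(np.trapezoid(w, t), 100 * (0.5 + 1.0 + 0.5), rtol=1e-3)

    def test_overlapping_bursts_rejected(self):
        spec = hb.MS2Spec(peak_amplitude=100.0, loading_rate=100.0,
                          plateau_min=2.0, decay_rate_per_min=1.0,
                          inter_burst_interval_min=3.0)
        cfg = hb.SimulationConfig(ms2=spec, n_frames=50)
        with pytest.raises(ValueError, match="overlap"):
            hb.simulate_traces(cfg)

    def test_arrival_coupling_offsets_exceeding_spacing_rejected(self):
        with pytest.raises(Exception, match="overlap"):
            hb.SimulationConfig(
                ms2=hb.MS2Spec(coupling="arrival", hub_arrival_lead_min=5.0,
                               hub_dwell_after_min=5.0,
                               inter_burst_interval_min=6.0)
            )


class TestTraceSimulation:
    def test_lag_zero_hub_trace_tracks_ms2(self):
        cfg = hb.SimulationConfig(
            seed=1, n_frames=200, nucleus=hb.NucleusSpec(count=1),
            ms2=hb.MS2Spec(coupling="lag", lag_min=0.0),
            noise=hb.NoiseSpec(enabled=False),
        )
        tr = hb.simulate_traces(cfg)
        # hub trace is an affine function of the smoothed MS2 trace; with
        # zero lag the two correlate perfectly at lag 0
        res = hb.cross_correlate(tr.ms2[0], tr.hub_intensity[0],
                                 tr.frame_interval_min, max_lag_min=3.0)
        assert res.peak_lag_min == 0.0
        # hub trace carries one extra smoothing pass, so the peak is close to
        # but not exactly 1
        assert res.peak_value > 0.99

    def test_arrival_coupling_lead_is_exact_in_ground_truth(self):
        lead, dwell = HUB_ARRIVAL_DWELL_NC14["sna"]
        cfg = hb.SimulationConfig(
            seed=5, n_frames=800, nucleus=hb.NucleusSpec(count=3),
            ms2=hb.MS2Spec(coupling="arrival", hub_arrival_lead_min=lead,
                           hub_dwell_after_min=dwell,
                           inter_burst_interval_min=46.0,
                           first_burst_start_min=22.0),
            noise=hb.NoiseSpec(enabled=False),
        )
        tr = hb.simulate_traces(cfg)
        truth = tr.truth.hub_intervals.merge(
            tr.truth.bursts, on=["nucleus_id", "burst_index"]
        )
        assert len(truth) > 0
        np.testing.assert_allclose(truth.start_min - truth.on_min, lead)
        np.testing.assert_allclose(truth.off_min - truth.start_min, dwell)

    def test_seed_determinism(self):
        cfg = hb.SimulationConfig(seed=9, n_frames=60)
        a, b = hb.simulate_traces(cfg), hb.simulate_traces(cfg)
        np.testing.assert_array_equal(a.ms2, b.ms2)
        np.testing.assert_array_equal(a.hub_intensity, b.hub_intensity)
        pd.testing.assert_frame_equal(a.truth.bursts, b.truth.bursts)


class TestMovieSimulation:
    def test_noise_off_hubs_off_is_nuclei_on_background(self):
        cfg = hb.SimulationConfig(
            seed=2, n_frames=2, nucleus=hb.NucleusSpec(count=1),
            hubs=hb.HubSpec(density_per_um3=0.0),
            noise=hb.NoiseSpec(enabled=False, background_level=10.0),
        )
        movie, truth = hb.simulate_embryo_movie(cfg)
        ch1 = movie[0, 0]
        vals = np.unique(ch1.round(6))
        # exactly two levels: background and background + nucleoplasm
        assert len(vals) == 2
        assert np.isclose(vals[0], 10.0)
        assert len(truth.hubs) == 0

    def test_hub_count_matches_poisson_expectation(self):
        cfg = hb.SimulationConfig(
            seed=8, n_frames=40, nucleus=hb.NucleusSpec(count=2),
            hubs=hb.HubSpec(density_per_um3=0.25),
            noise=hb.NoiseSpec(enabled=False),
        )
        movie, truth = hb.simulate_embryo_movie(cfg)
        rx, ry, rz = cfg.nucleus.radii_um
        vol = 4 / 3 * np.pi * rx * ry * rz
        expected = cfg.hubs.density_per_um3 * vol
        counts = []
        for f in range(cfg.n_frames):
            on = truth.hubs[(truth.hubs.birth_frame <= f) & (truth.hubs.death_frame >= f)]
            for nid in range(cfg.nucleus.count):
                counts.append(len(on[on.nucleus_id == nid]))
        mean = np.mean(counts)
        # per-frame counts are autocorrelated over a dwell time; allow a
        # generous band around the Poisson stationary mean
        assert abs(mean - expected) < 0.35 * expected + 0.5

    def test_ms2_spot_integrated_intensity_equals_burst_value(self):
        cfg = hb.SimulationConfig(
            seed=4, n_frames=8, nucleus=hb.NucleusSpec(count=1, drift_speed_um_per_min=0),
            hubs=hb.HubSpec(density_per_um3=0.0),
            ms2=hb.MS2Spec(first_burst_start_min=0.0, peak_amplitude=5000.0,
                           loading_rate=20000.0, plateau_min=1.0,
                           decay_rate_per_min=2.0, inter_burst_interval_min=10.0),
            noise=hb.NoiseSpec(enabled=False, background_level=0.0),
        )
        movie, truth = hb.simulate_embryo_movie(cfg)
        # pick a plateau frame; channel 2 = nuclear fill + spot
        f = 4
        assert truth.bursts.iloc[0].start_min == 0.0
        ch2 = movie[f, 1]
        fill = 0.3 * cfg.nucleus.base_intensity
        nuc_mask = movie[f, 0] > 0
        spot_sum = float(ch2.sum()) - fill * int(nuc_mask.sum())
        assert spot_sum == pytest.approx(5000.0, rel=0.02)  # blob truncation

    def test_conservation_every_truth_hub_appears(self):
        cfg = hb.SimulationConfig(seed=6, n_frames=10,
                                  nucleus=hb.NucleusSpec(count=1),
                                  hubs=hb.HubSpec(density_per_um3=0.2))
        movie, truth = hb.simulate_embryo_movie(cfg)
        assert (truth.hubs.death_frame >= truth.hubs.birth_frame).all()
        assert (truth.hubs.birth_frame >= 0).all()
        assert (truth.hubs.death_frame < cfg.n_frames).all()

    def test_seed_determinism_bit_identical(self):
        cfg = hb.SimulationConfig(seed=12, n_frames=3,
                                  nucleus=hb.NucleusSpec(count=1))
        a, _ = hb.simulate_embryo_movie(cfg)
        b, _ = hb.simulate_embryo_movie(cfg)
        np.testing.assert_array_equal(a, b)

    def test_memory_bound_enforced(self):
        cfg = hb.SimulationConfig(shape_zyx=(128, 512, 512))
        with pytest.raises(ValueError, match="memory bound"):
            hb.simulate_embryo_movie(cfg)


class TestPlantedBlobs:
    def test_blob_volume_reports_true_centers(self):
        vol, mask, centers = synthetic.planted_blob_volume(3, seed=1)
        assert centers.shape == (3, 3)
        assert vol.shape == mask.shape
        # blob peaks are where they were planted
        for c in centers:
            idx = tuple(np.round(c / np.array((0.3, 0.104, 0.104))).astype(int))
            assert vol[idx] > 1.5
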