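"""Burst calling, hub-burst linking, cross-correlation, and statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy.ndimage import gaussian_filter1d

import hubburst as hb
from hubburst import bursts as bm
from hubburst.conditions import HUB_ARRIVAL_DWELL_NC14
from hubburst.synthetic import burst_waveform

from conftest import DT_MIN, grid_trapezoid_spec


class TestCallBursts:
    def test_trapezoid_parameters_exact(self, dt_min):
        rise_f, plat_f, fall_f, A = 5, 15, 10, 100.0
        spec = grid_trapezoid_spec(dt_min, rise_f, plat_f, fall_f, A)
        start = 16 * dt_min
        times = np.arange(300) * dt_min
        trace = burst_waveform(times, [start], spec)
        (b,) = hb.call_bursts(trace, dt_min)
        assert b.start_min == pytest.approx(start)
        assert b.amplitude == pytest.approx(A)
        assert b.duration_min == pytest.approx((rise_f + plat_f + fall_f) * dt_min)
        assert b.loading_rate_per_min == pytest.approx(A / (rise_f * dt_min))
        # analytic trapezoid area
        area = A * (rise_f / 2 + plat_f + fall_f / 2) * dt_min
        assert b.output == pytest.approx(area)

    def test_two_trapezoids_and_frequency(self, dt_min):
        spec = grid_trapezoid_spec(dt_min)
        starts = [16 * dt_min, 16 * dt_min + 40 * dt_min]
        times = np.arange(300) * dt_min
        found = hb.call_bursts(burst_waveform(times, starts, spec), dt_min)
        assert len(found) == 2
        assert found[0].is_first and not found[1].is_first
        span = times[-1]
        assert hb.burst_frequency(found, span) == pytest.approx(2 / span)

    def test_flat_trace_no_bursts(self, dt_min):
        assert hb.call_bursts(np.full(50, 7.0), dt_min) == []

    def test_output_additivity_for_noiseless_traces(self, dt_min):
        spec = grid_trapezoid_spec(dt_min)
        starts = [16 * dt_min, 16 * dt_min + 40 * dt_min, 16 * dt_min + 80 * dt_min]
        times = np.arange(360) * dt_min
        trace = burst_waveform(times, starts, spec)
        found = hb.call_bursts(trace, dt_min)
        total = float(np.trapezoid(trace, dx=dt_min))
        # inter-burst residual is ~0; the rolling-minimum baseline sits a hair
        # above zero near burst shoulders, so agreement is to ~1e-4 relative
        assert sum(b.output for b in found) == pytest.approx(total, rel=1e-4)

    def test_noisy_telegraph_recovery(self):
        cfg = hb.SimulationConfig(
            seed=7, n_frames=160, nucleus=hb.NucleusSpec(count=20),
            ms2=hb.MS2Spec(inter_burst_interval_min=5.0, first_burst_start_min=1.0,
                           start_jitter_min=0.8, peak_amplitude=100.0,
                           loading_rate=150.0, plateau_min=0.8,
                           decay_rate_per_min=2.0),
            noise=hb.NoiseSpec(enabled=True, trace_noise_fraction=0.05),
        )
        tr = hb.simulate_traces(cfg)
        matched = total = 0
        for i in range(tr.n_nuclei):
            found = hb.call_bursts(tr.ms2[i], tr.frame_interval_min)
            for _, t in tr.truth.bursts.query(f"nucleus_id=={i}").iterrows():
                total += 1
                for b in found:
                    inter = max(0.0, min(b.end_min, t.end_min) - max(b.start_min, t.start_min))
                    union = max(b.end_min, t.end_min) - min(b.start_min, t.start_min)
                    if inter / union > 0.5:
                        matched += 1
                        break
        assert matched / total >= 0.95

    def test_too_short_trace_rejected(self, dt_min):
        with pytest.raises(ValueError):
            hb.call_bursts(np.array([0, 1, 0.0]), dt_min)


class TestBurstFrequency:
    def test_hand_example(self):
        bursts = [None] * 3  # only the count matters
        assert bm.burst_frequency(bursts, 30.0) == pytest.approx(0.1)

    def test_empty_is_zero_and_bad_span_rejected(self):
        assert bm.burst_frequency([], 10.0) == 0.0
        with pytest.raises(ValueError):
            bm.burst_frequency([], 0.0)


def _arrival_sim(gene="sna", seed=1, count=5):
    lead, dwell = HUB_ARRIVAL_DWELL_NC14[gene]
    ibi = lead + dwell + 3.0
    n_frames = int((25 + 3 * ibi) / DT_MIN)
    cfg = hb.SimulationConfig(
        seed=seed, n_frames=n_frames,
        nucleus=hb.NucleusSpec(count=count),
        ms2=hb.MS2Spec(coupling="arrival", hub_arrival_lead_min=lead,
                       hub_dwell_after_min=dwell, inter_burst_interval_min=ibi,
                       first_burst_start_min=lead + 2.0, n_bursts=3),
        noise=hb.NoiseSpec(enabled=False),
    )
    return hb.simulate_traces(cfg), lead, dwell


class TestLinking:
    def test_arrival_coupling_lead_and_dwell_within_one_frame(self):
        tr, lead, dwell = _arrival_sim()
        leads, dwells = [], []
        for i in range(tr.n_nuclei):
            recs = tr.interaction_records(i)
            found = hb.call_bursts(tr.ms2[i], tr.frame_interval_min, nucleus_id=i)
            for link in hb.link_bursts_to_hubs(found, recs, tr.frame_interval_min):
                if not link.is_first and link.hub_present_at_start:
                    leads.append(link.arrival_lead_min)
                    dwells.append(link.dwell_after_min)
        assert len(leads) >= 2 * tr.n_nuclei
        assert abs(np.mean(leads) - lead) < tr.frame_interval_min
        assert abs(np.mean(dwells) - dwell) < tr.frame_interval_min
        assert all(l >= 0 for l in leads) and all(d >= 0 for d in dwells)

    def test_no_hubs_all_links_false_leads_undefined(self, dt_min):
        spec = grid_trapezoid_spec(dt_min)
        times = np.arange(120) * dt_min
        trace = burst_waveform(times, [16 * dt_min], spec)
        found = hb.call_bursts(trace, dt_min)
        from hubburst.interactions import InteractionRecord

        recs = [
            InteractionRecord(nucleus_id=0, frame=f, time_min=f * dt_min,
                              sphere_mean_intensity=1.0, overlap_volume_um3=0.0,
                              overlap_mean_intensity=np.nan, hub_present=False)
            for f in range(120)
        ]
        (link,) = hb.link_bursts_to_hubs(found, recs, dt_min)
        assert not link.hub_present_at_start
        assert np.isnan(link.arrival_lead_min)
        assert np.isnan(link.dwell_after_min)

    def test_high_mode_is_subset_of_any_mode(self):
        tr, _, _ = _arrival_sim(seed=3, count=3)
        for i in range(tr.n_nuclei):
            recs = tr.interaction_records(i)
            # threshold above every hub intensity: high flags all off
            recs_hi = [
                type(r)(**{**r.__dict__, "high_hub_present": False}) for r in recs
            ]
            found = hb.call_bursts(tr.ms2[i], tr.frame_interval_min, nucleus_id=i)
            any_links = hb.link_bursts_to_hubs(found, recs, tr.frame_interval_min, mode="any")
            hi_links = hb.link_bursts_to_hubs(found, recs_hi, tr.frame_interval_min, mode="high")
            for a, h in zip(any_links, hi_links):
                assert not h.high_hub_at_start
                assert a.hub_present_at_start == h.hub_present_at_start  # unchanged
                if not a.hub_present_at_start:
                    assert np.isnan(a.arrival_lead_min)


class TestHighIntensityThreshold:
    @staticmethod
    def _hub(mi):
        return hb.HubRegion(hub_id=1, frame=0, nucleus_id=0, voxel_count=5,
                            volume_um3=0.02, integrated_intensity=mi * 5,
                            mean_intensity=mi, centroid_um=(0, 0, 0))

    def test_mean_of_two(self):
        assert bm.high_intensity_threshold([self._hub(2.0), self._hub(4.0)]) == 3.0

    def test_single_hub_is_its_own_threshold(self):
        assert bm.high_intensity_threshold([self._hub(2.5)]) == 2.5

    def test_invariant_under_duplication(self):
        hubs = [self._hub(2.0), self._hub(4.0), self._hub(6.0)]
        assert bm.high_intensity_threshold(hubs) == bm.high_intensity_threshold(hubs * 3)


class TestCrossCorrelation:
    def _smooth_trace(self, seed=0, n=400):
        rng = np.random.default_rng(seed)
        return gaussian_filter1d(rng.normal(size=n), 8)

    def test_self_correlation_peaks_at_zero_with_value_one(self, dt_min):
        x = self._smooth_trace()
        res = hb.cross_correlate(x, x, dt_min, max_lag_min=5.0)
        assert res.peak_lag_min == 0.0
        assert res.peak_value == pytest.approx(1.0)

    @pytest.mark.parametrize("shift_frames", [7, -12])
    def test_imposed_shift_recovered_exactly(self, dt_min, shift_frames):
        master = self._smooth_trace(seed=1, n=600)
        n = 400
        ms2 = master[100 : 100 + n]
        hub = master[100 - shift_frames : 100 - shift_frames + n]
        res = hb.cross_correlate(ms2, hub, dt_min, max_lag_min=5.0)
        assert res.peak_lag_min == pytest.approx(shift_frames * dt_min)

    def test_antisymmetry_under_swap(self, dt_min):
        master = self._smooth_trace(seed=2, n=600)
        ms2, hub = master[100:500], master[90:490]
        r1 = hb.cross_correlate(ms2, hub, dt_min, max_lag_min=5.0)
        r2 = hb.cross_correlate(hub, ms2, dt_min, max_lag_min=5.0)
        assert r1.peak_lag_min == pytest.approx(-r2.peak_lag_min)

    def test_anticorrelated_traces_negative_at_zero(self, dt_min):
        x = self._smooth_trace(seed=3)
        res = hb.cross_correlate(x, -x, dt_min, max_lag_min=5.0)
        zero = np.where(res.lags_min == 0.0)[0][0]
        assert res.values[zero] == pytest.approx(-1.0)

    def test_values_bounded(self, dt_min):
        a = self._smooth_trace(seed=4)
        b = self._smooth_trace(seed=5)
        res = hb.cross_correlate(a, b, dt_min)
        assert (res.values <= 1.0 + 1e-12).all()
        assert (res.values >= -1.0 - 1e-12).all()

    def test_zero_variance_returns_none(self, dt_min):
        assert hb.cross_correlate(np.ones(50), np.arange(50.0), dt_min) is None

    def test_cohort_mean_and_sd(self, dt_min):
        x = self._smooth_trace(seed=6)
        r1 = hb.cross_correlate(x, x, dt_min, max_lag_min=2.0)
        r2 = hb.cross_correlate(x, -x, dt_min, max_lag_min=2.0)
        df = bm.cohort_cross_correlation([r1, r2])
        zero = df.loc[df.lag_min == 0.0]
        assert zero["mean"].iloc[0] == pytest.approx(0.0, abs=1e-9)
        assert zero["n"].iloc[0] == 2


def brute_force_u(a, b):
    """Independent oracle: U statistic by exhaustive pair counting."""
    u = 0.0
    for x in a:
        for y in b:
            if x > y:
                u += 1.0
            elif x == y:
                u += 0.5
    return u


class TestGroupCompare:
    def test_identical_groups_not_significant(self):
        g = list(range(10))
        res = hb.group_compare(g, g)
        assert res.p_value > 0.9
        assert res.star == "ns"

    def test_disjoint_groups_u_zero_highly_significant(self):
        a = np.arange(20)
        b = np.arange(100, 120)
        res = hb.group_compare(a, b)
        assert res.mannwhitney_u == 0.0
        assert res.p_value < 0.001
        assert res.star == "***"

    def test_u_equals_pair_counting_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            na, nb = rng.integers(2, 13, 2)
            a = rng.integers(0, 6, na).astype(float)  # ties likely
            b = rng.integers(0, 6, nb).astype(float)
            res = hb.group_compare(a, b)
            assert res.mannwhitney_u == pytest.approx(brute_force_u(a, b))

    @pytest.mark.parametrize(
        "p,star", [(0.2, "ns"), (0.04, "*"), (0.009, "**"), (0.0009, "***")]
    )
    def test_star_coding(self, p, star):
        assert bm.star_code(p) == star


class TestCorrelateBurstParams:
    def _table(self, n=30, slope=2.0, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        dwell = rng.uniform(1, 20, n)
        amp = slope * dwell + 5.0 + rng.normal(0, noise, n)
        return pd.DataFrame(
            dict(dwell_after_min=dwell, pre_burst_intensity=rng.uniform(1, 2, n),
                 amplitude=amp, output=amp * 2, duration_min=rng.uniform(1, 3, n))
        )

    def test_perfect_linear_coupling_r2_one_slope_recovered(self):
        fits = hb.correlate_burst_params(self._table(), "dwell_after_min")
        assert fits["amplitude"].r_squared == pytest.approx(1.0)
        assert fits["amplitude"].slope == pytest.approx(2.0)
        assert fits["amplitude"].significant

    def test_shuffled_predictor_kills_correlation(self):
        rng = np.random.default_rng(1)
        t = self._table(n=200)
        t["dwell_after_min"] = rng.permutation(t["dwell_after_min"].to_numpy())
        fits = hb.correlate_burst_params(t, "dwell_after_min")
        assert fits["amplitude"].r_squared < 0.05

    def test_r2_matches_two_pass_oracle(self):
        t = self._table(noise=8.0, seed=2)
        fits = hb.correlate_burst_params(t, "dwell_after_min")
        x = t["dwell_after_min"].to_numpy()
        y = t["amplitude"].to_numpy()
        r = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
        )
        assert fits["amplitude"].r_squared == pytest.approx(r**2)
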