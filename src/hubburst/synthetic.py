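"""Ground-truthed synthetic inputs for the hub/burst analysis pipeline.

Two fidelities are generated:

* **trace level** (:func:`simulate_traces`) — paired MS2-intensity and
  hub-signal time series on the acquisition frame grid, with either
  *lag coupling* (the hub trace is a smoothed, time-shifted copy of the MS2
  trace — the regime probed by cross-correlation analysis) or *arrival
  coupling* (hub presence switches on a fixed lead before each non-first
  burst and off a fixed dwell after the burst start — the regime probed by
  burst-hub linking);
* **movie level** (:func:`simulate_embryo_movie`) — two-channel 4D volumes
  containing drifting ellipsoidal nuclei with a time-varying nucleoplasmic
  level, sub-nuclear Gaussian hub blobs with mixture-distributed lifetimes,
  and one diffraction-limited MS2 spot per nucleus whose integrated
  intensity follows the burst model, with Poisson-Gaussian camera noise
  applied last.

Every stochastic choice is drawn from a generator seeded by the config, and
everything generated is recorded in a :class:`GroundTruth` so downstream
stages can be scored against what was actually put in.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .config import DwellMixture, MS2Spec, SimulationConfig

__all__ = [
    "GroundTruth",
    "TraceSet",
    "sample_dwell_times",
    "burst_waveform",
    "burst_start_times",
    "simulate_traces",
    "simulate_embryo_movie",
]


@dataclass
class GroundTruth:
    """Record of everything a simulation put into its outputs."""

    #: columns: nucleus_id, hub_id, birth_frame, death_frame, dwell_min,
    #: z_um, y_um, x_um (position in the nucleus frame), amplitude
    hubs: pd.DataFrame = field(default_factory=pd.DataFrame)
    #: true dwell durations in minutes, one per hub event
    dwell_min: np.ndarray = field(default_factory=lambda: np.empty(0))
    #: columns: nucleus_id, burst_index, start_min, peak_min, end_min,
    #: amplitude, loading_rate, output, is_first
    bursts: pd.DataFrame = field(default_factory=pd.DataFrame)
    #: columns: nucleus_id, burst_index, on_min, off_min (arrival coupling)
    hub_intervals: pd.DataFrame = field(default_factory=pd.DataFrame)
    #: columns: nucleus_id, frame, z_um, y_um, x_um (movie-level truth)
    ms2_positions: pd.DataFrame = field(default_factory=pd.DataFrame)
    #: imposed MS2->hub lag in minutes (lag coupling), else 0
    lag_min: float = 0.0

    def validate(self) -> None:
        if len(self.hubs):
            if (self.hubs["death_frame"] < self.hubs["birth_frame"]).any():
                raise ValueError("ground truth hub death before birth")
        if len(self.bursts):
            for _, grp in self.bursts.groupby("nucleus_id"):
                starts = grp["start_min"].to_numpy()
                ends = grp["end_min"].to_numpy()
                order = np.argsort(starts)
                if np.any(ends[order][:-1] > starts[order][1:] + 1e-9):
                    raise ValueError("ground truth bursts overlap")


@dataclass
class TraceSet:
    """Paired per-nucleus time series from :func:`simulate_traces`."""

    times_min: np.ndarray  # (n_frames,)
    ms2: np.ndarray  # (n_nuclei, n_frames)
    hub_intensity: np.ndarray  # (n_nuclei, n_frames)
    hub_present: np.ndarray  # bool (n_nuclei, n_frames)
    #: mean hub intensity inside the interaction sphere when present, NaN
    #: otherwise (mirrors the overlap-intensity column of interaction tables)
    overlap_intensity: np.ndarray
    truth: GroundTruth

    @property
    def n_nuclei(self) -> int:
        return self.ms2.shape[0]

    @property
    def frame_interval_min(self) -> float:
        return float(self.times_min[1] - self.times_min[0])

    def interaction_records(self, nucleus: int):
        """Frame-wise interaction records for one nucleus, ready for run
        extraction and burst-hub linking."""
        from .interactions import InteractionRecord

        dt = self.frame_interval_min
        recs = []
        for f, t in enumerate(self.times_min):
            present = bool(self.hub_present[nucleus, f])
            recs.append(
                InteractionRecord(
                    nucleus_id=nucleus,
                    frame=f,
                    time_min=float(t),
                    sphere_mean_intensity=float(self.hub_intensity[nucleus, f]),
                    overlap_volume_um3=_COUPLED_OVERLAP_UM3 if present else 0.0,
                    overlap_mean_intensity=float(
                        self.overlap_intensity[nucleus, f]
                    ),
                    hub_present=present,
                    high_hub_present=present
                    and self.overlap_intensity[nucleus, f]
                    >= _COUPLED_HUB_INTENSITY,
                )
            )
        return recs


# ---------------------------------------------------------------------------
# dwell-time sampling
# ---------------------------------------------------------------------------


def sample_dwell_times(
    mixture: DwellMixture, n: int, seed: int | np.random.Generator
) -> np.ndarray:
    """Draw ``n`` dwell durations (minutes) from a zero-truncated
    three-component Gaussian mixture.

    Negative draws are resampled within their component, which truncates the
    mixture at zero without re-weighting components.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    weights = np.asarray(mixture.weights, dtype=float)
    means = np.asarray(mixture.means_min, dtype=float)
    sds = np.asarray(mixture.sds_min, dtype=float)

    comps = rng.choice(len(weights), size=n, p=weights)
    samples = rng.normal(means[comps], sds[comps])
    # rejection within component: resample until all positive
    for _ in range(1000):
        bad = samples <= 0
        if not bad.any():
            break
        samples[bad] = rng.normal(means[comps[bad]], sds[comps[bad]])
    else:  # pragma: no cover - means >> sds in any sane configuration
        raise RuntimeError("zero-truncation rejection did not converge")
    return samples


# ---------------------------------------------------------------------------
# burst waveform
# ---------------------------------------------------------------------------


def burst_start_times(spec: MS2Spec, span_min: float, frame_interval_min: float,
                      rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """Burst start times within ``[0, span_min]``, snapped to the frame grid.

    Starts are regular at ``inter_burst_interval_min`` spacing from
    ``first_burst_start_min``, optionally jittered, and always quantized to
    acquisition frames so waveform onsets coincide with sampling times.
    """
    starts = np.arange(spec.first_burst_start_min, span_min,
                       spec.inter_burst_interval_min)
    if spec.n_bursts is not None:
        starts = starts[: spec.n_bursts]
    if spec.start_jitter_min > 0 and rng is not None:
        jitter = rng.normal(0.0, spec.start_jitter_min, size=starts.size)
        # cap jitter at half the slack between waveform span and spacing so
        # jittered bursts can never overlap
        lim = max(0.0, (spec.inter_burst_interval_min - burst_span_min(spec)) / 2)
        starts = starts + np.clip(jitter, -lim, lim)
    starts = np.round(starts / frame_interval_min) * frame_interval_min
    return np.sort(starts[starts >= 0])


def _single_burst(tau: np.ndarray, spec: MS2Spec) -> np.ndarray:
    """Waveform of one burst as a function of time since its start."""
    rise = spec.peak_amplitude / spec.loading_rate
    plateau_end = rise + spec.plateau_min
    out = np.zeros_like(tau, dtype=float)
    up = (tau >= 0) & (tau < rise)
    out[up] = spec.loading_rate * tau[up]
    flat = (tau >= rise) & (tau < plateau_end)
    out[flat] = spec.peak_amplitude
    down = tau >= plateau_end
    if spec.decay_shape == "exponential":
        out[down] = spec.peak_amplitude * np.exp(
            -spec.decay_rate_per_min * (tau[down] - plateau_end)
        )
    else:
        out[down] = spec.peak_amplitude * np.clip(
            1.0 - spec.decay_rate_per_min * (tau[down] - plateau_end), 0.0, None
        )
    return out


def burst_waveform(times_min: np.ndarray, starts_min: np.ndarray,
                   spec: MS2Spec) -> np.ndarray:
    """Deterministic multi-burst MS2 waveform sampled at ``times_min``."""
    times_min = np.asarray(times_min, dtype=float)
    out = np.zeros_like(times_min)
    for s in np.asarray(starts_min, dtype=float):
        out += _single_burst(times_min - s, spec)
    return out


def burst_span_min(spec: MS2Spec) -> float:
    """Full extent of one burst: rise + plateau + decay to 1% of peak."""
    rise = spec.peak_amplitude / spec.loading_rate
    if spec.decay_shape == "exponential":
        fall = -math.log(0.01) / spec.decay_rate_per_min
    else:
        fall = 1.0 / spec.decay_rate_per_min
    return rise + spec.plateau_min + fall


def _check_burst_spacing(spec: MS2Spec) -> None:
    span = burst_span_min(spec)
    if span >= spec.inter_burst_interval_min:
        raise ValueError(
            f"burst waveform spans {span:.2f} min but bursts start every "
            f"{spec.inter_burst_interval_min:.2f} min; bursts would overlap"
        )


def _burst_truth_rows(starts: np.ndarray, spec: MS2Spec, nucleus_id: int) -> list:
    rise = spec.peak_amplitude / spec.loading_rate
    if spec.decay_shape == "exponential":
        fall = -math.log(0.01) / spec.decay_rate_per_min  # to 1% of peak
        area = spec.peak_amplitude * (
            rise / 2 + spec.plateau_min + 1.0 / spec.decay_rate_per_min
        )
    else:
        fall = 1.0 / spec.decay_rate_per_min
        area = spec.peak_amplitude * (rise / 2 + spec.plateau_min + fall / 2)
    rows = []
    for j, s in enumerate(starts):
        rows.append(
            dict(
                nucleus_id=nucleus_id,
                burst_index=j,
                start_min=float(s),
                peak_min=float(s + rise),
                end_min=float(s + rise + spec.plateau_min + fall),
                amplitude=spec.peak_amplitude,
                loading_rate=spec.loading_rate,
                output=area,
                is_first=j == 0,
            )
        )
    return rows


# ---------------------------------------------------------------------------
# trace-level simulation
# ---------------------------------------------------------------------------

#: overlap volume (um^3) written when a coupled hub is present; roughly a
#: 0.3 um-radius hub fully inside the interaction sphere
_COUPLED_OVERLAP_UM3 = 0.11
#: normalized mean hub intensity written when a coupled hub is present
_COUPLED_HUB_INTENSITY = 2.0


def simulate_traces(config: SimulationConfig) -> TraceSet:
    """Generate paired MS2 / hub time series for ``config.nucleus.count``
    nuclei on the acquisition frame grid.

    Coupling modes (``config.ms2.coupling``) are mutually exclusive:

    ``lag``
        The hub-intensity trace is a smoothed copy of the MS2 trace shifted
        by ``lag_min`` (positive lag = hub follows MS2), plus optional noise.
    ``arrival``
        Hub presence switches ON ``hub_arrival_lead_min`` minutes before each
        non-first burst start and OFF ``hub_dwell_after_min`` minutes after
        that burst's start; hub intensity is a constant plateau while present.
    ``none``
        The hub trace is flat background.
    """
    rng = np.random.default_rng(config.seed)
    ms2_spec = config.ms2
    _check_burst_spacing(ms2_spec)
    dt = config.frame_interval_min
    times = config.frame_times_min
    span = float(times[-1]) if len(times) > 1 else dt
    n_nuclei = config.nucleus.count

    ms2 = np.zeros((n_nuclei, config.n_frames))
    hub_int = np.ones((n_nuclei, config.n_frames))
    hub_present = np.zeros((n_nuclei, config.n_frames), dtype=bool)
    overlap_int = np.full((n_nuclei, config.n_frames), np.nan)

    burst_rows: list = []
    interval_rows: list = []

    for i in range(n_nuclei):
        # stagger nuclei by shifting the first burst, keeping starts on-grid
        offset = 0.0
        if n_nuclei > 1 and ms2_spec.start_jitter_min == 0:
            max_shift = max(ms2_spec.inter_burst_interval_min / 2, dt)
            offset = round(rng.uniform(0, max_shift) / dt) * dt
        spec_i = ms2_spec.model_copy(
            update={"first_burst_start_min": ms2_spec.first_burst_start_min + offset}
        )
        starts = burst_start_times(spec_i, span, dt, rng)
        clean = burst_waveform(times, starts, spec_i)
        ms2[i] = clean
        burst_rows.extend(_burst_truth_rows(starts, spec_i, i))

        if ms2_spec.coupling == "lag":
            smoothed = gaussian_filter1d(clean, sigma=2.0, mode="nearest")
            shifted = np.interp(times - ms2_spec.lag_min, times, smoothed)
            hub_int[i] = 1.0 + shifted / max(ms2_spec.peak_amplitude, 1e-12)
            hub_present[i] = hub_int[i] > 1.05
        elif ms2_spec.coupling == "arrival":
            for j, s in enumerate(starts):
                if j == 0:
                    continue
                on = s - ms2_spec.hub_arrival_lead_min
                off = s + ms2_spec.hub_dwell_after_min
                mask = (times >= on - 1e-9) & (times <= off + 1e-9)
                hub_present[i] |= mask
                interval_rows.append(
                    dict(nucleus_id=i, burst_index=j, on_min=float(on),
                         off_min=float(off))
                )
            hub_int[i] = np.where(hub_present[i], _COUPLED_HUB_INTENSITY, 1.0)

        overlap_int[i] = np.where(hub_present[i], _COUPLED_HUB_INTENSITY, np.nan)

    if config.noise.enabled and config.noise.trace_noise_fraction > 0:
        sd = config.noise.trace_noise_fraction * ms2_spec.peak_amplitude
        ms2 = np.clip(ms2 + rng.normal(0, sd, ms2.shape), 0, None)
        hub_sd = config.noise.trace_noise_fraction * 0.2
        hub_int = np.clip(hub_int + rng.normal(0, hub_sd, hub_int.shape), 0, None)

    truth = GroundTruth(
        bursts=pd.DataFrame(burst_rows),
        hub_intervals=pd.DataFrame(interval_rows),
        dwell_min=(
            pd.DataFrame(interval_rows)["off_min"].to_numpy()
            - pd.DataFrame(interval_rows)["on_min"].to_numpy()
            if interval_rows
            else np.empty(0)
        ),
        lag_min=ms2_spec.lag_min if ms2_spec.coupling == "lag" else 0.0,
    )
    truth.validate()
    return TraceSet(
        times_min=times,
        ms2=ms2,
        hub_intensity=hub_int,
        hub_present=hub_present,
        overlap_intensity=overlap_int,
        truth=truth,
    )


def planted_blob_volume(
    k: int,
    seed: int,
    shape_zyx: Tuple[int, int, int] = (16, 64, 64),
    voxel_size_zyx: Tuple[float, float, float] = (0.3, 0.104, 0.104),
    blob_sigma_um: float = 0.15,
    amplitude: float = 1.0,
    min_sep_um: float = 1.2,
    noise_sd: float = 0.02,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mean-normalized nuclear subvolume with ``k`` planted separable blobs.

    Background level 1.0 (the normalized nucleoplasm) plus isotropic
    Gaussian blobs of the given peak ``amplitude``, pairwise separated by at
    least ``min_sep_um``, plus mild Gaussian noise. Returns
    ``(volume, nucleus_mask, centers_um)`` with centers in (z, y, x) um.
    """
    rng = np.random.default_rng(seed)
    vs = np.asarray(voxel_size_zyx)
    extent = (np.asarray(shape_zyx) - 1) * vs
    margin = 4 * blob_sigma_um + 0.2
    centers: List[np.ndarray] = []
    for _ in range(k):
        for _attempt in range(5000):
            c = rng.uniform(margin, extent - margin)
            if all(np.linalg.norm(c - o) >= min_sep_um for o in centers):
                centers.append(c)
                break
        else:
            raise RuntimeError("could not place blobs with the requested separation")
    vol = np.ones(shape_zyx, dtype=float)
    norm = (2 * np.pi) ** 1.5 * blob_sigma_um**3 / float(np.prod(vs))
    for c in centers:
        _add_gaussian_blob(vol, c, blob_sigma_um, amplitude * norm, voxel_size_zyx)
    if noise_sd > 0:
        vol = np.clip(vol + rng.normal(0, noise_sd, vol.shape), 0, None)
    mask = np.ones(shape_zyx, dtype=bool)
    return vol, mask, np.asarray(centers).reshape(-1, 3)


# ---------------------------------------------------------------------------
# movie-level simulation
# ---------------------------------------------------------------------------


def _ellipsoid_mask(shape_zyx, center_um, radii_xyz_um, voxel_zyx):
    """Boolean ellipsoid on the anisotropic grid; voxel centers at idx*size."""
    zz, yy, xx = [
        np.arange(n) * s for n, s in zip(shape_zyx, voxel_zyx)
    ]
    cz, cy, cx = center_um
    rx, ry, rz = radii_xyz_um
    d2 = (
        ((zz - cz) / rz)[:, None, None] ** 2
        + ((yy - cy) / ry)[None, :, None] ** 2
        + ((xx - cx) / rx)[None, None, :] ** 2
    )
    return d2 <= 1.0


def _add_gaussian_blob(volume, center_um, sigma_um, total, voxel_zyx):
    """Add a Gaussian blob whose *sum over voxels* is ``total``.

    ``sigma_um`` may be a scalar (isotropic) or a (z, y, x) tuple. The blob
    is rendered on a +-4 sigma bounding box; the discrete sum equals the
    analytic integral up to truncation and sampling error.
    """
    if np.isscalar(sigma_um):
        sig = np.array([sigma_um] * 3, dtype=float)
    else:
        sig = np.asarray(sigma_um, dtype=float)
    vz, vy, vx = voxel_zyx
    cz, cy, cx = center_um
    lo = [
        max(0, int((c - 4 * s) / v))
        for c, s, v in zip(center_um, sig, voxel_zyx)
    ]
    hi = [
        min(n, int((c + 4 * s) / v) + 2)
        for c, s, v, n in zip(center_um, sig, voxel_zyx, volume.shape)
    ]
    if any(l >= h for l, h in zip(lo, hi)):
        return
    zz = (np.arange(lo[0], hi[0]) * vz - cz) / sig[0]
    yy = (np.arange(lo[1], hi[1]) * vy - cy) / sig[1]
    xx = (np.arange(lo[2], hi[2]) * vx - cx) / sig[2]
    d2 = (
        zz[:, None, None] ** 2 + yy[None, :, None] ** 2 + xx[None, None, :] ** 2
    )
    norm = (2 * np.pi) ** 1.5 * float(np.prod(sig))
    voxel_vol = vz * vy * vx
    blob = total * np.exp(-d2 / 2.0) * voxel_vol / norm
    volume[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] += blob


def _place_nuclei(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Initial nucleus centers (z, y, x in um), non-overlapping, away from
    volume edges (including room for the full drift); retried placement,
    then error."""
    vz, vy, vx = config.voxel_size_zyx
    nz, ny, nx = config.shape_zyx
    extent = np.array([nz * vz, ny * vy, nx * vx])
    rx, ry, rz = config.nucleus.radii_um
    span = config.n_frames * config.frame_interval_min
    drift = config.nucleus.drift_speed_um_per_min * span
    margin = np.array([rz, ry, rx]) * 1.05 + np.array([0.0, drift, drift])
    if np.any(extent <= 2 * margin):
        raise ValueError(
            "volume too small for the configured nucleus radii and drift"
        )
    # leave a resolvable inter-nuclear gap (~40% of a radius), as in the
    # blastoderm where interphase nuclei sit apart
    min_sep = 2.4 * max(rx, ry)
    centers: List[np.ndarray] = []
    for _ in range(config.nucleus.count):
        for _attempt in range(2000):
            c = rng.uniform(margin, extent - margin)
            if all(np.linalg.norm((c - o)[1:]) > min_sep for o in centers):
                centers.append(c)
                break
        else:
            raise RuntimeError(
                "could not place nuclei without overlap; reduce count or radii"
            )
    return np.array(centers)


def _hub_events(config: SimulationConfig, rng: np.random.Generator,
                nucleus_id: int) -> list:
    """Birth-death hub event list for one nucleus over the movie span.

    Births follow a Poisson process whose rate is chosen so the stationary
    mean hub count equals density x nuclear volume; a burn-in of five times
    the longest component mean precedes frame 0 so the process starts near
    stationarity.
    """
    hub = config.hubs
    rx, ry, rz = config.nucleus.radii_um
    vol = 4.0 / 3.0 * np.pi * rx * ry * rz
    mean_dwell = hub.dwell.mean
    rate = hub.density_per_um3 * vol / mean_dwell  # births per minute
    if rate <= 0:
        return []
    span = config.n_frames * config.frame_interval_min
    burn_in = 5.0 * max(hub.dwell.means_min)
    t = -burn_in
    events = []
    hub_id = 0
    while True:
        t += rng.exponential(1.0 / rate)
        if t >= span:
            break
        dwell = float(sample_dwell_times(hub.dwell, 1, rng)[0])
        if t + dwell < 0:
            continue
        # position uniform in the inner 80% of the ellipsoid (nucleus frame)
        while True:
            u = rng.uniform(-1, 1, size=3)
            if np.sum(u**2) <= 1:
                break
        pos = 0.8 * u * np.array([rz, ry, rx])
        amp_scatter = (
            rng.lognormal(mean=0.0, sigma=hub.intensity_cv)
            if hub.intensity_cv > 0
            else 1.0
        )
        events.append(
            dict(
                nucleus_id=nucleus_id,
                hub_id=hub_id,
                t_on_min=float(max(t, 0.0)),
                t_off_min=float(min(t + dwell, span)),
                dwell_min=dwell,
                z_um=float(pos[0]),
                y_um=float(pos[1]),
                x_um=float(pos[2]),
                amp_factor=float(amp_scatter),
            )
        )
        hub_id += 1
    return events


def simulate_embryo_movie(
    config: SimulationConfig,
) -> Tuple[np.ndarray, GroundTruth]:
    """Render a two-channel movie, shape ``(t, c, z, y, x)``, channel 0 =
    tagged transcription factor, channel 1 = MS2/MCP.

    Channel 0 holds ellipsoidal nuclei at the configured nucleoplasmic
    time profile plus isotropic Gaussian hub blobs (peak amplitude =
    ``intensity_mean`` x nucleoplasm level x per-hub scatter). Channel 1
    holds a dimmer nuclear fill plus one MS2 spot per nucleus whose *summed*
    blob intensity equals the burst-model value at that frame.
    Poisson-Gaussian noise is applied last when enabled.
    """
    nvox = int(np.prod(config.shape_zyx))
    if nvox > 256 * 256 * 64:
        raise ValueError("volume exceeds the default memory bound (256x256x64)")
    _check_burst_spacing(config.ms2)
    rng = np.random.default_rng(config.seed)
    dt = config.frame_interval_min
    times = config.frame_times_min
    voxel_zyx = config.voxel_size_zyx
    nuc = config.nucleus
    rx, ry, rz = nuc.radii_um

    centers0 = _place_nuclei(config, rng)
    # coherent constant-velocity drift in xy (blastoderm nuclei flow
    # collectively) with small per-nucleus directional jitter, so nuclei do
    # not collide over the movie
    theta = rng.uniform(0, 2 * np.pi) + rng.normal(0, 0.1, size=nuc.count)
    vel = np.stack(
        [np.zeros_like(theta), np.sin(theta), np.cos(theta)], axis=1
    ) * nuc.drift_speed_um_per_min

    span = max(times[-1], dt)
    profile = nuc.base_intensity * (
        1.0 - nuc.modulation_depth + nuc.modulation_depth * np.sin(np.pi * times / span)
    )

    all_events = []
    for i in range(nuc.count):
        all_events.extend(_hub_events(config, rng, i))

    # per-nucleus MS2 burst schedule (same waveform engine as trace level)
    burst_rows: list = []
    ms2_traces = np.zeros((nuc.count, config.n_frames))
    for i in range(nuc.count):
        offset = 0.0
        if nuc.count > 1:
            offset = round(
                rng.uniform(0, config.ms2.inter_burst_interval_min / 2) / dt
            ) * dt
        spec_i = config.ms2.model_copy(
            update={"first_burst_start_min": config.ms2.first_burst_start_min + offset}
        )
        starts = burst_start_times(spec_i, span, dt, rng)
        ms2_traces[i] = burst_waveform(times, starts, spec_i)
        burst_rows.extend(_burst_truth_rows(starts, spec_i, i))

    # fixed locus position in each nucleus frame, off-center
    locus_rel = np.stack(
        [0.2 * rz * np.ones(nuc.count),
         rng.uniform(-0.3, 0.3, nuc.count) * ry,
         rng.uniform(-0.3, 0.3, nuc.count) * rx],
        axis=1,
    )

    movie = np.zeros((config.n_frames, 2, *config.shape_zyx), dtype=np.float32)
    ms2_pos_rows = []
    hub_rows = []
    for ev in all_events:
        birth = int(np.ceil(ev["t_on_min"] / dt - 1e-9))
        death = min(int(np.floor(ev["t_off_min"] / dt + 1e-9)), config.n_frames - 1)
        if death < birth or birth > config.n_frames - 1:
            continue  # lifetime falls between or beyond frames; never rendered
        hub_rows.append(
            dict(
                nucleus_id=ev["nucleus_id"],
                hub_id=ev["hub_id"],
                birth_frame=birth,
                death_frame=death,
                dwell_min=ev["dwell_min"],
                z_um=ev["z_um"],
                y_um=ev["y_um"],
                x_um=ev["x_um"],
                amplitude=ev["amp_factor"] * config.hubs.intensity_mean,
            )
        )
    observed = {(r["nucleus_id"], r["hub_id"]) for r in hub_rows}
    all_events = [
        ev for ev in all_events if (ev["nucleus_id"], ev["hub_id"]) in observed
    ]

    for f, t in enumerate(times):
        ch_tf = np.full(config.shape_zyx, config.noise.background_level, dtype=float)
        ch_ms2 = np.full(config.shape_zyx, config.noise.background_level, dtype=float)
        for i in range(nuc.count):
            c = centers0[i] + vel[i] * t
            mask = _ellipsoid_mask(config.shape_zyx, c, (rx, ry, rz), voxel_zyx)
            ch_tf[mask] += profile[f]
            ch_ms2[mask] += 0.3 * nuc.base_intensity
            # MS2 spot: integrated intensity = burst model value
            if ms2_traces[i, f] > 0:
                pos = c + locus_rel[i]
                # diffraction-limited spot: PSF-scaled axial elongation
                _add_gaussian_blob(
                    ch_ms2, pos, sigma_um=(0.45, 0.15, 0.15),
                    total=ms2_traces[i, f], voxel_zyx=voxel_zyx,
                )
            ms2_pos_rows.append(
                dict(
                    nucleus_id=i, frame=f,
                    z_um=float(c[0] + locus_rel[i, 0]),
                    y_um=float(c[1] + locus_rel[i, 1]),
                    x_um=float(c[2] + locus_rel[i, 2]),
                )
            )
        for ev in all_events:
            if ev["t_on_min"] - 1e-9 <= t <= ev["t_off_min"] + 1e-9:
                i = ev["nucleus_id"]
                c = centers0[i] + vel[i] * t
                pos = c + np.array([ev["z_um"], ev["y_um"], ev["x_um"]])
                amp = ev["amp_factor"] * config.hubs.intensity_mean
                level = profile[f] if config.hubs.couple_to_nuclear_intensity \
                    else nuc.base_intensity
                peak = amp * level
                sig = config.hubs.blob_sigma_um
                total = peak * (2 * np.pi) ** 1.5 * sig**3 / config.voxel_volume_um3
                _add_gaussian_blob(ch_tf, pos, sig, total, voxel_zyx)
        movie[f, 0] = ch_tf
        movie[f, 1] = ch_ms2

    if config.noise.enabled:
        gain = config.noise.photon_gain
        shot = rng.poisson(np.clip(movie, 0, None) * gain) / gain
        movie = (shot + rng.normal(0, config.noise.read_noise_sd, movie.shape)).astype(
            np.float32
        )
        movie = np.clip(movie, 0, None)

    hubs_df = pd.DataFrame(hub_rows)
    truth = GroundTruth(
        hubs=hubs_df,
        dwell_min=hubs_df["dwell_min"].to_numpy() if len(hubs_df) else np.empty(0),
        bursts=pd.DataFrame(burst_rows),
        ms2_positions=pd.DataFrame(ms2_pos_rows),
    )
    truth.validate()
    return movie, truth
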