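"""Validated configuration models for simulation and analysis runs.

All physical quantities are in micrometres and minutes unless a field name
says otherwise (``frame_interval_s`` is in seconds because acquisition
hardware is specified that way). Frame indices are 0-based. Voxel sizes are
given as ``(dx, dy, dz)``; in-memory arrays are ordered ``(z, y, x)``.
"""

from __future__ import annotations

from typing import Literal, Optional, Sequence, Tuple

import numpy as np
from pydantic import BaseModel, Field, field_validator, model_validator

__all__ = [
    "DwellMixture",
    "NucleusSpec",
    "HubSpec",
    "MS2Spec",
    "NoiseSpec",
    "SimulationConfig",
    "NucleiParams",
    "HubParams",
    "MS2Params",
    "InteractionParams",
    "BurstParams",
    "RunConfig",
]


class DwellMixture(BaseModel):
    """Three-component Gaussian mixture of hub dwell times, in minutes.

    Samples are truncated at zero; component spreads should be small relative
    to the means if the truncation is to be negligible.
    """

    weights: Tuple[float, float, float] = (0.45, 0.35, 0.20)
    means_min: Tuple[float, float, float] = (0.30, 1.35, 10.04)
    sds_min: Tuple[float, float, float] = (0.10, 0.40, 2.00)

    @field_validator("weights")
    @classmethod
    def _weights_valid(cls, v):
        if any(w <= 0 for w in v):
            raise ValueError("mixture weights must be strictly positive")
        if abs(sum(v) - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")
        return v

    @field_validator("means_min")
    @classmethod
    def _means_valid(cls, v):
        if any(m <= 0 for m in v):
            raise ValueError("mixture component means must be positive")
        return v

    @field_validator("sds_min")
    @classmethod
    def _sds_valid(cls, v):
        if any(s < 0 for s in v):
            raise ValueError("mixture component sds must be non-negative")
        return v

    @property
    def mean(self) -> float:
        """Analytic mean of the (untruncated) mixture."""
        return float(np.dot(self.weights, self.means_min))

    @property
    def variance(self) -> float:
        w = np.asarray(self.weights)
        m = np.asarray(self.means_min)
        s = np.asarray(self.sds_min)
        return float(np.sum(w * (s**2 + m**2)) - self.mean**2)


class NucleusSpec(BaseModel):
    count: int = Field(default=3, ge=1)
    radii_um: Tuple[float, float, float] = (1.6, 1.6, 2.2)  # (rx, ry, rz)
    drift_speed_um_per_min: float = Field(default=0.3, ge=0)
    base_intensity: float = Field(default=200.0, gt=0)
    #: peak-to-trough fractional modulation of the nucleoplasmic level over
    #: the cycle (rise then fall, as nuclear import outpaces export and then
    #: reverses).
    modulation_depth: float = Field(default=0.3, ge=0, le=1)


class HubSpec(BaseModel):
    density_per_um3: float = Field(default=0.15, ge=0)
    blob_sigma_um: float = Field(default=0.15, gt=0)
    #: mean hub amplitude as a multiple of the instantaneous nucleoplasmic
    #: intensity; individual hubs scatter lognormally around it.
    intensity_mean: float = Field(default=1.0, gt=0)
    intensity_cv: float = Field(default=0.25, ge=0)
    dwell: DwellMixture = DwellMixture()
    #: when set, hub amplitudes scale linearly with the nucleoplasmic
    #: intensity profile (the regime where hub intensity tracks nuclear
    #: concentration); otherwise amplitudes are constant in time.
    couple_to_nuclear_intensity: bool = True


class MS2Spec(BaseModel):
    """Burst model and hub-coupling parameters for the nascent-transcription
    channel.

    The burst waveform is a linear rise at ``loading_rate`` to
    ``peak_amplitude``, a plateau, then a decay (exponential by default,
    linear for closed-form test waveforms).
    """

    inter_burst_interval_min: float = Field(default=6.0, gt=0)
    first_burst_start_min: float = Field(default=3.0, ge=0)
    peak_amplitude: float = Field(default=100.0, gt=0)
    loading_rate: float = Field(default=100.0, gt=0)  # intensity units / min
    plateau_min: float = Field(default=1.0, ge=0)
    decay_rate_per_min: float = Field(default=2.0, gt=0)
    decay_shape: Literal["exponential", "linear"] = "exponential"
    #: jitter applied to burst start times (sd, minutes); 0 = regular starts
    start_jitter_min: float = Field(default=0.0, ge=0)
    n_bursts: Optional[int] = None  # None = as many as fit in the trace

    # coupling between hub presence/intensity and the MS2 signal
    coupling: Literal["none", "lag", "arrival"] = "none"
    lag_min: float = 0.0  # imposed lag; positive = hub follows MS2
    hub_arrival_lead_min: float = Field(default=0.0, ge=0)
    hub_dwell_after_min: float = Field(default=0.0, ge=0)


class NoiseSpec(BaseModel):
    """Poisson-Gaussian camera noise: shot noise on the photon signal plus
    additive read noise. The trace noise model is a placeholder (the real
    detection chain is not characterised here) and fully configurable."""

    enabled: bool = True
    photon_gain: float = Field(default=1.0, gt=0)  # counts per intensity unit
    read_noise_sd: float = Field(default=2.0, ge=0)
    background_level: float = Field(default=10.0, ge=0)
    #: sd of additive Gaussian noise on trace-level simulations, as a
    #: fraction of the MS2 peak amplitude.
    trace_noise_fraction: float = Field(default=0.05, ge=0)


class SimulationConfig(BaseModel):
    seed: int = 0
    frame_interval_s: float = Field(default=11.56, gt=0)
    n_frames: int = Field(default=100, ge=1)
    voxel_size_um: Tuple[float, float, float] = (0.104, 0.104, 0.3)  # dx,dy,dz
    shape_zyx: Tuple[int, int, int] = (24, 110, 110)
    nucleus: NucleusSpec = NucleusSpec()
    hubs: HubSpec = HubSpec()
    ms2: MS2Spec = MS2Spec()
    noise: NoiseSpec = NoiseSpec()

    @field_validator("voxel_size_um")
    @classmethod
    def _voxels_positive(cls, v):
        if any(x <= 0 for x in v):
            raise ValueError("voxel sizes must be positive")
        return v

    @model_validator(mode="after")
    def _coupling_fits(self):
        ms2 = self.ms2
        if ms2.coupling == "arrival":
            span = ms2.hub_arrival_lead_min + ms2.hub_dwell_after_min
            if span >= ms2.inter_burst_interval_min:
                raise ValueError(
                    "hub arrival lead + dwell after "
                    f"({span:.2f} min) must be smaller than the inter-burst "
                    f"interval ({ms2.inter_burst_interval_min:.2f} min); "
                    "coupled hub events would overlap"
                )
        return self

    @property
    def frame_interval_min(self) -> float:
        return self.frame_interval_s / 60.0

    @property
    def frame_times_min(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_min

    @property
    def voxel_size_zyx(self) -> Tuple[float, float, float]:
        dx, dy, dz = self.voxel_size_um
        return (dz, dy, dx)

    @property
    def voxel_volume_um3(self) -> float:
        dx, dy, dz = self.voxel_size_um
        return dx * dy * dz


# ---------------------------------------------------------------------------
# analysis-stage parameters
# ---------------------------------------------------------------------------


class NucleiParams(BaseModel):
    smooth_sigma_um: float = Field(default=0.5, gt=0)
    min_area_um2: float = Field(default=2.0, ge=0)
    split_touching: bool = True
    maxima_min_distance_um: float = Field(default=2.5, gt=0)
    iou_threshold: float = Field(default=0.5, gt=0, le=1)
    max_gap_slices: int = Field(default=2, ge=0)
    max_displacement_um: float = Field(default=2.0, gt=0)
    min_volume_um3: float = Field(default=5.0, ge=0)


class HubParams(BaseModel):
    #: (x, y, z) half-extents of the median footprint; the default is one
    #: lateral voxel in-plane and a single z-plane (3x3x1)
    median_radius_um: Tuple[float, float, float] = (0.104, 0.104, 0.1)
    erosion_radius_um: float = Field(default=0.15, gt=0)
    #: "otsu" or a fixed residual threshold in normalized-intensity units
    residual_threshold: float | Literal["otsu"] = "otsu"
    #: absolute floor on the residual threshold; guards against Otsu
    #: splitting pure noise in hub-free nuclei.
    min_residual: float = Field(default=0.1, ge=0)
    maxima_min_separation_um: float = Field(default=0.3, gt=0)
    min_voxels: int = Field(default=4, ge=1)


class MS2Params(BaseModel):
    #: (x, y, z) median footprint half-extents; default 3x3x1, single z-plane
    median_radius_um: Tuple[float, float, float] = (0.104, 0.104, 0.1)
    dog_sigma1_um: float = Field(default=0.1, gt=0)
    dog_sigma2_um: float = Field(default=0.3, gt=0)
    percentile: float = Field(default=99.5, gt=0, lt=100)
    max_step_um: float = Field(default=1.0, gt=0)
    max_extrapolate_frames: int = Field(default=20, ge=0)

    @model_validator(mode="after")
    def _sigmas_ordered(self):
        if not self.dog_sigma1_um < self.dog_sigma2_um:
            raise ValueError("difference-of-Gaussians requires sigma1 < sigma2")
        return self


class InteractionParams(BaseModel):
    radius_um: float = Field(default=0.5, gt=0)
    gap_tolerance: int = Field(default=0, ge=0)
    n_mixture_components: int = Field(default=3, ge=1)


class BurstParams(BaseModel):
    smooth_sigma_frames: float = Field(default=1.5, gt=0)
    derivative_k_mad: float = Field(default=2.0, gt=0)
    min_duration_frames: int = Field(default=2, ge=1)
    baseline_window_frames: int = Field(default=20, ge=1)
    #: fraction of burst amplitude used when refining start/end frames on the
    #: raw trace; also the floor applied to noise-scale estimates.
    onset_fraction: float = Field(default=0.02, gt=0, lt=1)
    max_lag_min: Optional[float] = None  # None = half the trace span
    cc_smooth_sigma_frames: float = Field(default=1.5, ge=0)


class RunConfig(BaseModel):
    """Everything a pipeline run needs; serialized alongside its outputs."""

    seed: int = 0
    movie_path: Optional[str] = None
    output_dir: Optional[str] = None
    #: channel indices in the stored movie
    channel_map: dict = {"tf": 0, "ms2": 1}
    frame_interval_s: float = Field(default=11.56, gt=0)
    voxel_size_um: Optional[Tuple[float, float, float]] = None
    nuclei: NucleiParams = NucleiParams()
    hub: HubParams = HubParams()
    ms2: MS2Params = MS2Params()
    interaction: InteractionParams = InteractionParams()
    burst: BurstParams = BurstParams()

    @property
    def frame_interval_min(self) -> float:
        return self.frame_interval_s / 60.0
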