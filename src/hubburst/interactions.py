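"""Hub-locus interaction metrics, dwell-time classification, and survival.

Interaction metrics are measured inside a 0.5 um-radius sphere around the
MS2 spot's weighted centroid. A voxel belongs to the sphere when its center
lies within the radius in *physical* distance, so the anisotropic z step is
handled exactly; partial-voxel weighting is deliberately not used. A "run"
is a maximal stretch of frames with a hub consistently present in the
sphere; run durations feed a three-component Gaussian mixture that splits
interactions into short-, mid-, and long-lived classes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

log = logging.getLogger(__name__)

__all__ = [
    "InteractionRecord",
    "InteractionRun",
    "MixtureFit",
    "sphere_voxels",
    "sphere_metrics",
    "extract_runs",
    "fit_dwell_mixture",
    "survival_curve",
    "DWELL_CLASSES",
]

DWELL_CLASSES = ("short", "mid", "long")


@dataclass(frozen=True)
class InteractionRecord:
    nucleus_id: int
    frame: int
    time_min: float
    sphere_mean_intensity: float  # channel-1 normalized units over the sphere
    overlap_volume_um3: float
    overlap_mean_intensity: float  # NaN when no hub overlaps
    hub_present: bool
    high_hub_present: bool = False
    truncated: bool = False  # sphere clipped by the volume edge


@dataclass(frozen=True)
class InteractionRun:
    nucleus_id: int
    start_frame: int
    end_frame: int
    duration_min: float
    mean_overlap_intensity: float
    dwell_class: str = ""

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame + 1


@dataclass
class MixtureFit:
    weights: np.ndarray
    means_min: np.ndarray  # ascending: short < mid < long
    sds_min: np.ndarray
    responsibilities: np.ndarray  # (n_samples, n_components)
    labels: np.ndarray  # argmax class index per sample
    class_boundaries_min: np.ndarray  # crossing points between components
    seed: int
    converged: bool
    degenerate: bool = False

    def class_names(self) -> List[str]:
        names = DWELL_CLASSES[: len(self.means_min)]
        return [names[i] for i in self.labels]


def sphere_voxels(
    shape_zyx: Tuple[int, int, int],
    center_um: np.ndarray,
    radius_um: float,
    voxel_size_zyx: Tuple[float, float, float],
) -> Tuple[np.ndarray, bool]:
    """Indices of voxels whose centers are within ``radius_um`` of the center.

    Voxel centers sit at ``index * voxel_size``. Only the bounding box of the
    sphere is scanned. Returns ``(indices (n, 3), truncated)`` where
    ``truncated`` flags a sphere clipped by the volume edge.
    """
    center_um = np.asarray(center_um, dtype=float)
    vs = np.asarray(voxel_size_zyx, dtype=float)
    lo_f = (center_um - radius_um) / vs
    hi_f = (center_um + radius_um) / vs
    truncated = bool(np.any(lo_f < 0) or np.any(hi_f > np.asarray(shape_zyx) - 1))
    lo = np.maximum(np.ceil(lo_f - 1e-12).astype(int), 0)
    hi = np.minimum(np.floor(hi_f + 1e-12).astype(int), np.asarray(shape_zyx) - 1)
    if np.any(lo > hi):
        return np.empty((0, 3), dtype=int), truncated
    grids = np.meshgrid(
        *[np.arange(l, h + 1) for l, h in zip(lo, hi)], indexing="ij"
    )
    idx = np.stack([g.ravel() for g in grids], axis=1)
    d2 = np.sum((idx * vs - center_um) ** 2, axis=1)
    return idx[d2 <= radius_um**2 + 1e-12], truncated


def sphere_metrics(
    ch1_normalized: np.ndarray,
    hub_labels: np.ndarray,
    ms2_position_um: np.ndarray,
    voxel_size_zyx: Tuple[float, float, float],
    frame: int,
    frame_interval_min: float,
    nucleus_id: int = 0,
    radius_um: float = 0.5,
    high_intensity_threshold: Optional[float] = None,
) -> InteractionRecord:
    """Hub overlap metrics inside the interaction sphere at one frame.

    ``overlap_mean_intensity`` is the mean channel-1 value over sphere voxels
    carrying a hub label, NaN when no hub overlaps. A sphere clipped by the
    volume edge is computed over its in-bounds voxels and flagged.
    """
    idx, truncated = sphere_voxels(
        ch1_normalized.shape, ms2_position_um, radius_um, voxel_size_zyx
    )
    voxel_vol = float(np.prod(voxel_size_zyx))
    if truncated:
        log.warning(
            "frame %d nucleus %d: interaction sphere truncated by volume edge",
            frame, nucleus_id,
        )
    if len(idx) == 0:
        return InteractionRecord(
            nucleus_id=nucleus_id, frame=frame,
            time_min=frame * frame_interval_min,
            sphere_mean_intensity=np.nan, overlap_volume_um3=0.0,
            overlap_mean_intensity=np.nan, hub_present=False,
            truncated=truncated,
        )
    zz, yy, xx = idx[:, 0], idx[:, 1], idx[:, 2]
    vals = np.asarray(ch1_normalized, dtype=float)[zz, yy, xx]
    in_hub = np.asarray(hub_labels)[zz, yy, xx] > 0
    overlap_volume = float(in_hub.sum()) * voxel_vol
    hub_present = bool(in_hub.any())
    overlap_mean = float(vals[in_hub].mean()) if hub_present else np.nan
    high = bool(
        hub_present
        and high_intensity_threshold is not None
        and overlap_mean >= high_intensity_threshold
    )
    return InteractionRecord(
        nucleus_id=nucleus_id,
        frame=frame,
        time_min=frame * frame_interval_min,
        sphere_mean_intensity=float(vals.mean()),
        overlap_volume_um3=overlap_volume,
        overlap_mean_intensity=overlap_mean,
        hub_present=hub_present,
        high_hub_present=high,
        truncated=truncated,
    )


def extract_runs(
    records: Sequence[InteractionRecord],
    frame_interval_min: float,
    gap_tolerance: int = 0,
    use_high: bool = False,
) -> List[InteractionRun]:
    """Maximal runs of hub presence, allowing up to ``gap_tolerance``
    hub-absent frames inside a run (0 = strictly consistent presence).

    Duration counts the frames in the run: ``(end - start + 1) x interval``.
    """
    recs = sorted(records, key=lambda r: r.frame)
    flag = [(r.high_hub_present if use_high else r.hub_present) for r in recs]
    runs: List[InteractionRun] = []
    start_i = None
    last_on = None
    for i, on in enumerate(flag):
        if on:
            if start_i is None:
                start_i = i
            last_on = i
        elif start_i is not None and i - last_on > gap_tolerance:
            runs.append(_make_run(recs, start_i, last_on, frame_interval_min))
            start_i = None
    if start_i is not None:
        runs.append(_make_run(recs, start_i, last_on, frame_interval_min))
    return runs


def _make_run(recs, i0, i1, dt) -> InteractionRun:
    seg = recs[i0 : i1 + 1]
    overlaps = [r.overlap_mean_intensity for r in seg if r.hub_present]
    return InteractionRun(
        nucleus_id=seg[0].nucleus_id,
        start_frame=seg[0].frame,
        end_frame=seg[-1].frame,
        duration_min=(seg[-1].frame - seg[0].frame + 1) * dt,
        mean_overlap_intensity=float(np.nanmean(overlaps)) if overlaps else np.nan,
    )


def fit_dwell_mixture(
    durations_min: Sequence[float],
    seed: int = 0,
    n_components: int = 3,
    max_iter: int = 500,
) -> MixtureFit:
    """Fit a Gaussian mixture to dwell durations by EM (k-means init, fixed
    seed) and classify each duration by argmax responsibility.

    Components are relabeled ascending by mean so index 0/1/2 map to the
    short/mid/long classes. A sample set with (near-)zero spread is guarded
    by the EM variance floor and flagged ``degenerate``. Non-convergence
    returns the best-so-far fit with ``converged=False``.
    """
    x = np.asarray(durations_min, dtype=float).reshape(-1, 1)
    if x.shape[0] < n_components:
        raise ValueError(f"need at least {n_components} durations to fit")
    gm = GaussianMixture(
        n_components=n_components,
        covariance_type="full",
        max_iter=max_iter,
        n_init=5,
        init_params="kmeans",
        reg_covar=1e-8,
        random_state=seed,
    )
    gm.fit(x)
    order = np.argsort(gm.means_.ravel())
    means = gm.means_.ravel()[order]
    sds = np.sqrt(gm.covariances_.reshape(n_components)[order])
    weights = gm.weights_[order]
    resp = gm.predict_proba(x)[:, order]
    labels = resp.argmax(axis=1)

    spread = means.max() - means.min()
    degenerate = spread < 1e-6 or float(np.ptp(x)) < 1e-12
    if degenerate:
        log.warning("dwell mixture degenerate: effectively one component")

    # empirical decision boundaries between adjacent classes on a fine grid
    boundaries = []
    if not degenerate:
        grid = np.linspace(x.min(), x.max(), 2048).reshape(-1, 1)
        g_labels = gm.predict_proba(grid)[:, order].argmax(axis=1)
        switches = np.nonzero(np.diff(g_labels) != 0)[0]
        boundaries = [float(grid[s + 1, 0]) for s in switches]

    return MixtureFit(
        weights=weights,
        means_min=means,
        sds_min=sds,
        responsibilities=resp,
        labels=labels,
        class_boundaries_min=np.asarray(boundaries),
        seed=seed,
        converged=bool(gm.converged_),
        degenerate=degenerate,
    )


def classify_runs(runs: Sequence[InteractionRun], fit: MixtureFit) -> List[InteractionRun]:
    """Attach mixture class names to runs (same order as the fit samples)."""
    names = fit.class_names()
    if len(names) != len(runs):
        raise ValueError("fit was computed on a different number of runs")
    return [
        InteractionRun(
            nucleus_id=r.nucleus_id,
            start_frame=r.start_frame,
            end_frame=r.end_frame,
            duration_min=r.duration_min,
            mean_overlap_intensity=r.mean_overlap_intensity,
            dwell_class=name,
        )
        for r, name in zip(runs, names)
    ]


def survival_curve(durations_min: Sequence[float]) -> Tuple[np.ndarray, np.ndarray]:
    """Empirical survival S(t) = fraction of runs with duration >= t.

    Returned as a right-continuous step function on the grid {0} plus the
    sorted unique durations; S(0) = 1 always.
    """
    d = np.asarray(durations_min, dtype=float)
    if d.size == 0:
        raise ValueError("survival curve needs at least one duration")
    grid = np.concatenate([[0.0], np.unique(d)])
    surv = np.array([(d >= t).mean() for t in grid])
    return grid, surv
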