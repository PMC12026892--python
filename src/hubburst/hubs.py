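"""Transcription-factor hub detection and per-nucleus hub statistics.

Hubs are local high-concentration regions detected *inside* a nucleus after
normalizing its intensity to the nuclear mean, so "intensity" downstream is
always in normalized units (1.0 = nucleoplasmic average). The detection
recipe: median filter, grayscale erosion, morphological reconstruction by
dilation (seed = eroded, mask = median-filtered), residual = median-filtered
minus reconstructed, residual threshold, local maxima as markers, and a
marker-controlled watershed constrained to the residual mask, followed by a
minimum-size filter. All morphological footprints are specified in
micrometres and converted per-axis to voxels, so the anisotropic z step is
handled explicitly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy import stats
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.morphology import reconstruction
from skimage.segmentation import watershed

from .config import HubParams
from .nuclei import NucleusTrack

log = logging.getLogger(__name__)

__all__ = [
    "HubRegion",
    "HubNucleusStats",
    "normalize_nucleus",
    "detect_hubs",
    "hub_regionprops",
    "hub_nucleus_stats",
]


@dataclass(frozen=True)
class HubRegion:
    hub_id: int
    frame: int
    nucleus_id: int
    voxel_count: int
    volume_um3: float
    integrated_intensity: float  # normalized units x voxels
    mean_intensity: float  # normalized units
    centroid_um: Tuple[float, float, float]  # (z, y, x)


@dataclass(frozen=True)
class HubNucleusStats:
    nucleus_id: int
    frame: int
    hub_count: int
    hub_density_per_um3: float
    mean_hub_intensity: float
    mean_nuclear_intensity: float


def normalize_nucleus(volume: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Divide a channel-1 subvolume by its in-mask mean.

    The result has mean exactly 1 over the mask and is invariant to uniform
    rescaling of the input, which makes downstream hub intensities comparable
    across nuclei and time points.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("nucleus mask is empty")
    mean = float(np.asarray(volume, dtype=float)[mask].mean())
    if mean <= 0:
        raise ValueError("nucleus mean intensity is zero; degenerate input")
    return np.asarray(volume, dtype=float) / mean


def _footprint_um(radii_um, voxel_size_zyx) -> np.ndarray:
    """Axis-aligned box footprint sized in physical units.

    A radius smaller than half the voxel pitch on an axis collapses to a
    single-voxel extent there, so the default footprints stay 3x3x1 on
    grids whose z step is ~3x the lateral pitch.
    """
    if np.isscalar(radii_um):
        radii_um = (radii_um,) * 3
    half = [int(np.floor(r / v + 0.5)) for r, v in zip(radii_um, voxel_size_zyx)]
    if all(h == 0 for h in half):
        half = [0, 1, 1]  # never degenerate to the identity filter
    return np.ones(tuple(2 * h + 1 for h in half), dtype=bool)


def detect_hubs(
    normalized: np.ndarray,
    nucleus_mask: np.ndarray,
    voxel_size_zyx: Tuple[float, float, float],
    params: Optional[HubParams] = None,
) -> np.ndarray:
    """Segment hubs in a mean-normalized nuclear subvolume.

    Returns an int32 label volume; zero hubs is a valid outcome. Raising the
    residual threshold can only shrink the binary mask, so hub count is
    non-increasing in the threshold.
    """
    params = params or HubParams()
    mask = np.asarray(nucleus_mask, dtype=bool)
    img = np.where(mask, np.asarray(normalized, dtype=float), 0.0)

    mr = params.median_radius_um
    med_fp = _footprint_um((mr[2], mr[1], mr[0]), voxel_size_zyx)
    med = ndi.median_filter(img, footprint=med_fp)

    ero_fp = _footprint_um(params.erosion_radius_um, voxel_size_zyx)
    eroded = ndi.grey_erosion(med, footprint=ero_fp)
    recon = reconstruction(eroded, med, method="dilation")
    residual = med - recon
    residual[~mask] = 0.0

    inside = residual[mask]
    if params.residual_threshold == "otsu":
        positive = inside[inside > 0]
        if positive.size < 2 or positive.max() <= params.min_residual:
            return np.zeros(img.shape, dtype=np.int32)
        thr = max(threshold_otsu(positive), params.min_residual)
    else:
        thr = float(params.residual_threshold)
    binary = (residual > thr) & mask
    if not binary.any():
        return np.zeros(img.shape, dtype=np.int32)

    min_sep = [
        max(1, int(round(params.maxima_min_separation_um / v)))
        for v in voxel_size_zyx
    ]
    fp = np.ones(tuple(2 * s + 1 for s in min_sep), dtype=bool)
    # light sub-voxel blur breaks the exact ties the median filter leaves,
    # so each blob contributes one connected plateau of local maxima
    res_s = ndi.gaussian_filter(residual, sigma=0.5)
    max_mask = (res_s == ndi.maximum_filter(res_s, footprint=fp)) & binary
    markers, n_markers = ndi.label(max_mask)
    if n_markers == 0:
        return np.zeros(img.shape, dtype=np.int32)
    labels = watershed(-res_s, markers, mask=binary)

    # size filter, then relabel consecutively for stable downstream ids
    ids, counts = np.unique(labels[labels > 0], return_counts=True)
    keep = ids[counts >= params.min_voxels]
    out = np.zeros(img.shape, dtype=np.int32)
    for new_id, old_id in enumerate(keep, start=1):
        out[labels == old_id] = new_id
    return out


def hub_regionprops(
    hub_labels: np.ndarray,
    normalized: np.ndarray,
    voxel_size_zyx: Tuple[float, float, float],
    frame: int = 0,
    nucleus_id: int = 0,
) -> List[HubRegion]:
    """Integrated/mean intensity, size, and centroid for each hub label."""
    voxel_vol = float(np.prod(voxel_size_zyx))
    scale = np.asarray(voxel_size_zyx)
    out = []
    for hub_id in np.unique(hub_labels[hub_labels > 0]):
        sel = hub_labels == hub_id
        vals = np.asarray(normalized, dtype=float)[sel]
        integrated = float(vals.sum())
        count = int(sel.sum())
        centroid = tuple((np.argwhere(sel).mean(axis=0) * scale).tolist())
        out.append(
            HubRegion(
                hub_id=int(hub_id),
                frame=frame,
                nucleus_id=nucleus_id,
                voxel_count=count,
                volume_um3=count * voxel_vol,
                integrated_intensity=integrated,
                mean_intensity=integrated / count,
                centroid_um=centroid,
            )
        )
    return out


def hub_nucleus_stats(
    hubs: Sequence[HubRegion],
    nuclear_intensity: pd.DataFrame,
) -> Tuple[pd.DataFrame, dict]:
    """Per-(nucleus, frame) hub density/intensity plus correlation summaries.

    ``nuclear_intensity`` must carry columns ``nucleus_id, frame,
    mean_intensity, volume_um3`` (the output of
    :func:`hubburst.nuclei.nucleus_timeseries`). Returns the per-frame stats
    table and Pearson summaries (r^2 and p) of hub density vs nuclear
    intensity and mean hub intensity vs nuclear intensity.
    """
    hub_df = pd.DataFrame(
        [
            dict(
                nucleus_id=h.nucleus_id,
                frame=h.frame,
                mean_intensity=h.mean_intensity,
            )
            for h in hubs
        ]
    )
    rows = []
    for _, nuc in nuclear_intensity.iterrows():
        sel = (
            hub_df[
                (hub_df["nucleus_id"] == nuc["nucleus_id"])
                & (hub_df["frame"] == nuc["frame"])
            ]
            if len(hub_df)
            else hub_df
        )
        count = len(sel)
        rows.append(
            HubNucleusStats(
                nucleus_id=int(nuc["nucleus_id"]),
                frame=int(nuc["frame"]),
                hub_count=count,
                hub_density_per_um3=count / nuc["volume_um3"],
                mean_hub_intensity=(
                    float(sel["mean_intensity"].mean()) if count else np.nan
                ),
                mean_nuclear_intensity=float(nuc["mean_intensity"]),
            )
        )
    stats_df = pd.DataFrame([s.__dict__ for s in rows])

    def _pearson(x, y):
        m = np.isfinite(x) & np.isfinite(y)
        if m.sum() < 3 or np.std(x[m]) == 0 or np.std(y[m]) == 0:
            return dict(r_squared=np.nan, p_value=np.nan)
        r, p = stats.pearsonr(x[m], y[m])
        return dict(r_squared=r**2, p_value=p)

    summaries = {
        "density_vs_nuclear": _pearson(
            stats_df["hub_density_per_um3"].to_numpy(),
            stats_df["mean_nuclear_intensity"].to_numpy(),
        ),
        "hub_intensity_vs_nuclear": _pearson(
            stats_df["mean_hub_intensity"].to_numpy(),
            stats_df["mean_nuclear_intensity"].to_numpy(),
        ),
    }
    return stats_df, summaries
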