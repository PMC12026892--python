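"""Nuclear segmentation, slice stitching, interpolation, and tracking.

The per-slice segmenter here is a deliberately simple intensity-based
stand-in (smoothed Otsu threshold with an optional seeded watershed split);
:func:`stitch_and_interpolate` and :func:`track_nuclei` accept any per-slice
or per-frame label input, so externally produced label volumes (e.g. from a
learned segmenter) can be dropped in unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from skimage.morphology import remove_small_objects
from skimage.segmentation import watershed

from .config import NucleiParams

log = logging.getLogger(__name__)

__all__ = [
    "NucleusTrack",
    "segment_nuclei_slice",
    "segment_nuclei_volume",
    "stitch_and_interpolate",
    "track_nuclei",
    "nucleus_timeseries",
]


@dataclass
class NucleusTrack:
    """One nucleus followed through time.

    ``frames`` is the sorted list of frame indices the nucleus is present in;
    the parallel dicts map frame -> per-frame quantity. ``labels`` holds the
    label value the nucleus carries in that frame's label volume.
    """

    nucleus_id: int
    frames: List[int] = field(default_factory=list)
    labels: Dict[int, int] = field(default_factory=dict)
    centroids_um: Dict[int, np.ndarray] = field(default_factory=dict)  # (z,y,x)
    volumes_um3: Dict[int, float] = field(default_factory=dict)
    #: per-axis equivalent ellipsoid semi-axes (z, y, x), um
    radii_um: Dict[int, np.ndarray] = field(default_factory=dict)

    @property
    def first_frame(self) -> int:
        return self.frames[0]

    @property
    def last_frame(self) -> int:
        return self.frames[-1]

    def covers(self, frame: int) -> bool:
        return frame in self.labels


def segment_nuclei_slice(
    slice_2d: np.ndarray,
    params: Optional[NucleiParams] = None,
    pixel_size_um: Tuple[float, float] = (0.104, 0.104),
    threshold: Optional[float] = None,
) -> np.ndarray:
    """Label nuclear cross-sections in one z-slice.

    Smoothed threshold (Otsu unless a precomputed ``threshold`` is given),
    size filter, and (optionally) a distance-transform seeded watershed to
    split touching cross-sections. A blank slice yields an empty labeling,
    as does a slice whose foreground is not meaningfully brighter than its
    background (an Otsu split of pure noise is not a nucleus).
    """
    params = params or NucleiParams()
    img = np.asarray(slice_2d, dtype=float)
    if img.max() - img.min() < 1e-12:
        return np.zeros(img.shape, dtype=np.int32)
    sigma_px = [params.smooth_sigma_um / s for s in pixel_size_um]
    smoothed = gaussian(img, sigma=sigma_px, preserve_range=True)
    thr = threshold_otsu(smoothed) if threshold is None else threshold
    mask = smoothed > thr
    if not mask.any() or mask.all():
        return np.zeros(img.shape, dtype=np.int32)
    if threshold is None:
        # contrast guard for slices containing only camera noise
        m_fg = smoothed[mask].mean()
        m_bg = smoothed[~mask].mean()
        if m_bg > 0 and m_fg / m_bg < 1.5:
            return np.zeros(img.shape, dtype=np.int32)
    mask = _remove_small_2d(mask, params, pixel_size_um)
    if not mask.any():
        return np.zeros(img.shape, dtype=np.int32)
    if not params.split_touching:
        return cc_label(mask).astype(np.int32)
    dist = ndi.distance_transform_edt(mask, sampling=pixel_size_um)
    # smooth the ridge noise of the EDT so each convex body has one peak
    dist = gaussian(dist, sigma=[0.3 / s for s in pixel_size_um],
                    preserve_range=True)
    min_dist_px = max(1, int(params.maxima_min_distance_um / min(pixel_size_um)))
    peaks = peak_local_max(
        dist, min_distance=min_dist_px, labels=cc_label(mask), exclude_border=False
    )
    if len(peaks) == 0:
        return cc_label(mask).astype(np.int32)
    markers = np.zeros(img.shape, dtype=np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    return watershed(-dist, markers, mask=mask).astype(np.int32)


def _remove_small_2d(mask: np.ndarray, params, pixel_size_um) -> np.ndarray:
    min_px = int(params.min_area_um2 / (pixel_size_um[0] * pixel_size_um[1]))
    if min_px <= 1:
        return mask
    lab = cc_label(mask)
    ids, counts = np.unique(lab[lab > 0], return_counts=True)
    small = set(ids[counts < min_px].tolist())
    if not small:
        return mask
    out = mask.copy()
    out[np.isin(lab, list(small))] = False
    return out


def segment_nuclei_volume(
    volume: np.ndarray,
    params: Optional[NucleiParams] = None,
    voxel_size_zyx: Tuple[float, float, float] = (0.3, 0.104, 0.104),
) -> np.ndarray:
    """Segment a 3D volume slice-by-slice and stitch into 3D labels.

    The threshold is computed once over the whole volume (Otsu on the
    smoothed intensities), which keeps nucleus-free slices from thresholding
    camera noise.
    """
    params = params or NucleiParams()
    vol = np.asarray(volume, dtype=float)
    if vol.max() - vol.min() < 1e-12:
        return np.zeros(vol.shape, dtype=np.int32)
    thr = threshold_otsu(
        gaussian(vol, sigma=[params.smooth_sigma_um / s for s in voxel_size_zyx],
                 preserve_range=True)
    )
    slices = [
        segment_nuclei_slice(vol[z], params, pixel_size_um=voxel_size_zyx[1:],
                             threshold=thr)
        for z in range(vol.shape[0])
    ]
    labels3d = stitch_and_interpolate(np.stack(slices), params)
    return _filter_small_3d(labels3d, params, voxel_size_zyx)


def _filter_small_3d(labels3d, params, voxel_size_zyx):
    voxel_vol = float(np.prod(voxel_size_zyx))
    min_vox = int(params.min_volume_um3 / voxel_vol)
    if min_vox <= 1:
        return labels3d
    out = labels3d.copy()
    ids, counts = np.unique(out[out > 0], return_counts=True)
    for i, n in zip(ids, counts):
        if n < min_vox:
            out[out == i] = 0
    return out


# ---------------------------------------------------------------------------
# stitching and shape interpolation
# ---------------------------------------------------------------------------


def _match_score(a: np.ndarray, b: np.ndarray) -> Tuple[float, float]:
    """(IoU, containment) of two masks; containment = overlap over the
    smaller area, which keeps shrinking polar cross-sections of an ellipsoid
    attached to their nucleus even when the IoU collapses."""
    inter = np.logical_and(a, b).sum()
    if inter == 0:
        return 0.0, 0.0
    union = np.logical_or(a, b).sum()
    return inter / union, inter / min(a.sum(), b.sum())


def _signed_distance(mask: np.ndarray) -> np.ndarray:
    """Positive inside the mask, negative outside (2D)."""
    if mask.all():
        return np.full(mask.shape, 1.0)
    if not mask.any():
        return np.full(mask.shape, -1.0)
    return ndi.distance_transform_edt(mask) - ndi.distance_transform_edt(~mask)


def _interp_masks(m0: np.ndarray, m1: np.ndarray, alphas) -> List[np.ndarray]:
    """Shape interpolation between two 2D masks via their signed distances."""
    d0, d1 = _signed_distance(m0), _signed_distance(m1)
    return [((1 - a) * d0 + a * d1) > 0 for a in alphas]


def stitch_and_interpolate(
    slice_labels: np.ndarray, params: Optional[NucleiParams] = None
) -> np.ndarray:
    """Merge per-slice 2D labelings into a 3D label volume.

    Regions on adjacent slices with IoU >= ``params.iou_threshold`` join the
    same 3D label; a run of <= ``params.max_gap_slices`` missing slices
    inside a nucleus is filled by signed-distance shape interpolation
    between the flanking slices. A region overlapping two existing nuclei is
    assigned to the max-overlap one (logged).
    """
    params = params or NucleiParams()
    slice_labels = np.asarray(slice_labels)
    nz = slice_labels.shape[0]
    out = np.zeros(slice_labels.shape, dtype=np.int32)
    # active nucleus id -> (last z seen, mask at that z)
    active: Dict[int, Tuple[int, np.ndarray]] = {}
    next_id = 1

    for z in range(nz):
        lab = slice_labels[z]
        region_ids = [r for r in np.unique(lab) if r != 0]
        # candidate matches: (iou, region, nucleus)
        cands = []
        for rid in region_ids:
            rmask = lab == rid
            for nid, (last_z, nmask) in active.items():
                if z - last_z > params.max_gap_slices + 1:
                    continue
                iou, cont = _match_score(rmask, nmask)
                if iou >= params.iou_threshold or cont >= 0.8:
                    cands.append((max(iou, cont), rid, nid))
        cands.sort(reverse=True, key=lambda c: c[0])
        used_regions: set = set()
        used_nuclei: set = set()
        assignment: Dict[int, int] = {}
        for i, rid, nid in cands:
            if rid in used_regions:
                log.warning(
                    "slice %d region %d overlaps multiple nuclei; "
                    "assigned to max-overlap", z, rid,
                )
                continue
            if nid in used_nuclei:
                continue
            assignment[rid] = nid
            used_regions.add(rid)
            used_nuclei.add(nid)
        for rid in region_ids:
            rmask = lab == rid
            if rid in assignment:
                nid = assignment[rid]
                last_z, nmask = active[nid]
                gap = z - last_z - 1
                if 0 < gap <= params.max_gap_slices:
                    alphas = [(g + 1) / (gap + 1) for g in range(gap)]
                    for g, m in enumerate(_interp_masks(nmask, rmask, alphas)):
                        fill = m & (out[last_z + 1 + g] == 0)
                        out[last_z + 1 + g][fill] = nid
            else:
                nid = next_id
                next_id += 1
            out[z][rmask] = nid
            active[nid] = (z, rmask)
    return out


# ---------------------------------------------------------------------------
# tracking
# ---------------------------------------------------------------------------


def _frame_regions(labels3d: np.ndarray, voxel_size_zyx) -> pd.DataFrame:
    rows = []
    voxel_vol = float(np.prod(voxel_size_zyx))
    scale = np.asarray(voxel_size_zyx)
    for r in regionprops(labels3d):
        centroid = np.asarray(r.centroid) * scale
        coords = r.coords * scale  # (n, 3) physical
        var = coords.var(axis=0)
        radii = np.sqrt(5.0 * var)  # uniform-ellipsoid moment inversion
        rows.append(
            dict(
                label=r.label,
                centroid=centroid,
                volume_um3=r.num_pixels * voxel_vol,
                radii=np.maximum(radii, 1e-6),
            )
        )
    return pd.DataFrame(rows)


def track_nuclei(
    label_volumes: Sequence[np.ndarray],
    voxel_size_zyx: Tuple[float, float, float],
    params: Optional[NucleiParams] = None,
) -> List[NucleusTrack]:
    """Link nuclei across frames by greedy nearest-centroid assignment.

    Pairs are matched in ascending centroid-distance order; a pair farther
    than ``params.max_displacement_um`` starts a new track. The greedy rule
    means simultaneous position swaps resolve arbitrarily (by distance order)
    and are logged when two assignments are nearly tied.
    """
    params = params or NucleiParams()
    tracks: List[NucleusTrack] = []
    prev: Dict[int, NucleusTrack] = {}  # previous-frame label -> track

    for f, labels3d in enumerate(label_volumes):
        regions = _frame_regions(np.asarray(labels3d), voxel_size_zyx)
        cur: Dict[int, NucleusTrack] = {}
        if len(regions) and prev:
            pairs = []
            for _, reg in regions.iterrows():
                for plabel, track in prev.items():
                    d = np.linalg.norm(
                        reg["centroid"] - track.centroids_um[f - 1]
                    )
                    if d <= params.max_displacement_um:
                        pairs.append((d, int(reg["label"]), plabel))
            pairs.sort(key=lambda p: p[0])
            taken_r: set = set()
            taken_t: set = set()
            for d, rlabel, plabel in pairs:
                if rlabel in taken_r or plabel in taken_t:
                    continue
                track = prev[plabel]
                _append(track, f, rlabel, regions)
                cur[rlabel] = track
                taken_r.add(rlabel)
                taken_t.add(plabel)
        for _, reg in regions.iterrows():
            rlabel = int(reg["label"])
            if rlabel in cur:
                continue
            track = NucleusTrack(nucleus_id=len(tracks))
            _append(track, f, rlabel, regions)
            tracks.append(track)
            cur[rlabel] = track
        prev = cur
    return tracks


def _append(track: NucleusTrack, frame: int, rlabel: int, regions: pd.DataFrame):
    row = regions.loc[regions["label"] == rlabel].iloc[0]
    track.frames.append(frame)
    track.labels[frame] = rlabel
    track.centroids_um[frame] = row["centroid"]
    track.volumes_um3[frame] = float(row["volume_um3"])
    track.radii_um[frame] = row["radii"]


def nucleus_timeseries(
    track: NucleusTrack,
    frames_ch1: Sequence[np.ndarray],
    label_volumes: Sequence[np.ndarray],
) -> pd.DataFrame:
    """Per-frame mean channel-1 intensity and volume for one nucleus track.

    ``frames_ch1`` and ``label_volumes`` are indexed by frame; volume comes
    from the track (mask voxel count x voxel volume).
    """
    rows = []
    for f in track.frames:
        mask = np.asarray(label_volumes[f]) == track.labels[f]
        vals = np.asarray(frames_ch1[f])[mask]
        rows.append(
            dict(
                nucleus_id=track.nucleus_id,
                frame=f,
                mean_intensity=float(vals.mean()) if vals.size else np.nan,
                volume_um3=track.volumes_um3[f],
            )
        )
    return pd.DataFrame(rows)
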