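"""Nascent-transcription (MS2) spot detection, selection, and tracking.

One transcribing locus is assumed per nucleus: each frame's brightest
candidate becomes the locus spot, detections are linked through time, gaps
between bursts are filled by interpolating in *nucleus-relative* coordinates
``r = (pos - nucleus centroid) / nucleus semi-axes`` (which makes the fill
exact under rigid nuclear translation and isotropic size change), and up to
20 frames before the first detection are extrapolated by holding the first
detected ``r`` fixed while the nucleus moves and rescales.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .config import MS2Params
from .hubs import _footprint_um
from .nuclei import NucleusTrack

log = logging.getLogger(__name__)

__all__ = [
    "SpotCandidate",
    "RawTrack",
    "MS2Track",
    "detect_ms2_candidates",
    "select_locus_spot",
    "track_ms2",
    "fill_track",
]


@dataclass(frozen=True)
class SpotCandidate:
    label: int
    centroid_um: np.ndarray  # (z, y, x), intensity-weighted on filtered image
    integrated_intensity: float  # raw-image sum over the component
    #: integrated intensity minus the local nucleoplasmic background
    #: (in-mask median x component size); the burst-calling signal
    background_corrected: float
    voxel_count: int


@dataclass
class RawTrack:
    """Per-frame selected detections with gap bookkeeping."""

    frames: List[int] = field(default_factory=list)
    positions_um: Dict[int, np.ndarray] = field(default_factory=dict)
    intensities: Dict[int, float] = field(default_factory=dict)
    corrected: Dict[int, float] = field(default_factory=dict)
    #: frames where linkage jumped more than max-step (logged, kept as gap)
    suspect_frames: List[int] = field(default_factory=list)

    @property
    def gaps(self) -> List[Tuple[int, int]]:
        """(start, end) inclusive frame ranges with no detection inside the
        span of the track."""
        out = []
        for a, b in zip(self.frames[:-1], self.frames[1:]):
            if b - a > 1:
                out.append((a + 1, b - 1))
        return out


@dataclass
class MS2Track:
    """Gap-filled locus track; statuses partition the covered frames."""

    nucleus_id: int
    frames: List[int] = field(default_factory=list)
    positions_um: Dict[int, np.ndarray] = field(default_factory=dict)
    intensities: Dict[int, float] = field(default_factory=dict)
    corrected: Dict[int, float] = field(default_factory=dict)
    status: Dict[int, str] = field(default_factory=dict)  # detected/interpolated/extrapolated
    first_detection_frame: int = -1

    def to_frame(self, frame_interval_min: float) -> pd.DataFrame:
        rows = []
        for f in self.frames:
            z, y, x = self.positions_um[f]
            rows.append(
                dict(
                    nucleus_id=self.nucleus_id,
                    frame=f,
                    t_min=f * frame_interval_min,
                    z_um=z,
                    y_um=y,
                    x_um=x,
                    intensity=self.intensities.get(f, np.nan),
                    intensity_corrected=self.corrected.get(f, np.nan),
                    status=self.status[f],
                )
            )
        return pd.DataFrame(rows)


def detect_ms2_candidates(
    volume: np.ndarray,
    nucleus_mask: np.ndarray,
    voxel_size_zyx: Tuple[float, float, float],
    params: Optional[MS2Params] = None,
) -> List[SpotCandidate]:
    """Detect bright-spot candidates in a channel-2 nuclear subvolume.

    Median filter, difference-of-Gaussians band-pass (sigmas in um), then a
    percentile threshold on the in-mask filtered distribution; connected
    components above threshold become candidates. A zero-variance filtered
    distribution (e.g. a uniform field) yields no candidates by definition.
    """
    params = params or MS2Params()
    mask = np.asarray(nucleus_mask, dtype=bool)
    if not mask.any():
        raise ValueError("nucleus mask is empty")
    img = np.asarray(volume, dtype=float)

    mr = params.median_radius_um
    med = ndi.median_filter(
        img, footprint=_footprint_um((mr[2], mr[1], mr[0]), voxel_size_zyx)
    )
    s1 = [params.dog_sigma1_um / v for v in voxel_size_zyx]
    s2 = [params.dog_sigma2_um / v for v in voxel_size_zyx]
    dog = ndi.gaussian_filter(med, s1) - ndi.gaussian_filter(med, s2)

    # the nuclear rim is a bright step edge in the band-pass image; exclude a
    # boundary shell (~2 x sigma2) so rim response cannot outshine the locus
    shell = _footprint_um(2 * params.dog_sigma2_um, voxel_size_zyx)
    eroded = ndi.binary_erosion(mask, structure=shell)
    if eroded.any():
        mask = eroded

    inside = dog[mask]
    if inside.max() - inside.min() < 1e-12:
        return []
    thr = np.percentile(inside, params.percentile)
    binary = (dog > thr) & mask
    if not binary.any():
        return []
    labels, n = ndi.label(binary)
    scale = np.asarray(voxel_size_zyx)
    background = float(np.median(img[mask]))
    cands = []
    for lbl in range(1, n + 1):
        sel = labels == lbl
        w = np.clip(dog[sel], 0, None)
        coords = np.argwhere(sel).astype(float)
        if w.sum() > 0:
            centroid = (coords * w[:, None]).sum(axis=0) / w.sum()
        else:
            centroid = coords.mean(axis=0)
        integrated = float(img[sel].sum())
        count = int(sel.sum())
        cands.append(
            SpotCandidate(
                label=lbl,
                centroid_um=centroid * scale,
                integrated_intensity=integrated,
                background_corrected=integrated - count * background,
                voxel_count=count,
            )
        )
    return cands


def select_locus_spot(candidates: Sequence[SpotCandidate]) -> Optional[SpotCandidate]:
    """Pick the likely locus spot: brightest by integrated intensity, ties
    broken by larger voxel count, then lower label id."""
    if not candidates:
        return None
    best = sorted(
        candidates,
        key=lambda c: (-c.integrated_intensity, -c.voxel_count, c.label),
    )
    if (
        len(best) > 1
        and best[0].integrated_intensity == best[1].integrated_intensity
    ):
        log.info("MS2 spot intensity tie; larger-volume candidate chosen")
    return best[0]


def track_ms2(
    selections: Sequence[Optional[SpotCandidate]],
    params: Optional[MS2Params] = None,
) -> RawTrack:
    """Link per-frame locus selections into a raw track.

    Consecutive detections displaced by more than ``params.max_step_um`` are
    flagged suspect (logged); the new detection still enters the track, so a
    genuine relocalization after a long dark gap is kept while the flag lets
    a curation pass revisit it.
    """
    params = params or MS2Params()
    track = RawTrack()
    last_pos = None
    for f, cand in enumerate(selections):
        if cand is None:
            continue
        if last_pos is not None:
            step = float(np.linalg.norm(cand.centroid_um - last_pos))
            if step > params.max_step_um and track.frames and f - track.frames[-1] == 1:
                log.warning("frame %d: MS2 step %.2f um exceeds max-step", f, step)
                track.suspect_frames.append(f)
        track.frames.append(f)
        track.positions_um[f] = np.asarray(cand.centroid_um, dtype=float)
        track.intensities[f] = cand.integrated_intensity
        track.corrected[f] = cand.background_corrected
        last_pos = track.positions_um[f]
    if not track.frames:
        raise ValueError("track requires at least one detection")
    return track


def _relative(pos: np.ndarray, track: NucleusTrack, frame: int) -> np.ndarray:
    return (pos - track.centroids_um[frame]) / track.radii_um[frame]


def _absolute(r: np.ndarray, track: NucleusTrack, frame: int) -> np.ndarray:
    return track.centroids_um[frame] + r * track.radii_um[frame]


def fill_track(
    raw: RawTrack,
    nucleus: NucleusTrack,
    params: Optional[MS2Params] = None,
    apply_edits: Optional[Dict[int, np.ndarray]] = None,
) -> MS2Track:
    """Interpolate gaps and extrapolate pre-appearance frames.

    Gap positions are linear interpolations of the nucleus-relative
    coordinate between flanking detections, mapped back through each frame's
    nucleus geometry; up to ``params.max_extrapolate_frames`` frames before
    the first detection hold the first detected relative coordinate.
    ``apply_edits`` (frame -> absolute position, um) overrides automatic
    positions last, as a reproducible stand-in for manual track curation.
    Frames where the nucleus track is absent are left uncovered (logged).
    """
    params = params or MS2Params()
    out = MS2Track(nucleus_id=nucleus.nucleus_id)
    det_frames = sorted(raw.frames)
    first = det_frames[0]
    out.first_detection_frame = first

    for f in det_frames:
        out.frames.append(f)
        out.positions_um[f] = raw.positions_um[f]
        out.intensities[f] = raw.intensities[f]
        out.corrected[f] = raw.corrected.get(f, np.nan)
        out.status[f] = "detected"

    # interpolate interior gaps in relative coordinates
    for a, b in zip(det_frames[:-1], det_frames[1:]):
        if b - a <= 1:
            continue
        if not (nucleus.covers(a) and nucleus.covers(b)):
            log.warning("nucleus absent at gap flank %d-%d; gap left open", a, b)
            continue
        ra = _relative(raw.positions_um[a], nucleus, a)
        rb = _relative(raw.positions_um[b], nucleus, b)
        for f in range(a + 1, b):
            if not nucleus.covers(f):
                log.warning("nucleus absent at frame %d; frame left uncovered", f)
                continue
            alpha = (f - a) / (b - a)
            r = (1 - alpha) * ra + alpha * rb
            out.frames.append(f)
            out.positions_um[f] = _absolute(r, nucleus, f)
            out.status[f] = "interpolated"

    # extrapolate before first appearance
    if nucleus.covers(first):
        r0 = _relative(raw.positions_um[first], nucleus, first)
        lo = max(first - params.max_extrapolate_frames, 0)
        for f in range(first - 1, lo - 1, -1):
            if not nucleus.covers(f):
                log.warning("nucleus absent at frame %d; extrapolation stops", f)
                break
            out.frames.append(f)
            out.positions_um[f] = _absolute(r0, nucleus, f)
            out.status[f] = "extrapolated"

    if apply_edits:
        for f, pos in apply_edits.items():
            out.positions_um[f] = np.asarray(pos, dtype=float)
            if f not in out.status:
                out.frames.append(f)
                out.status[f] = "detected"

    out.frames.sort()
    n_ext = sum(1 for s in out.status.values() if s == "extrapolated")
    if n_ext > params.max_extrapolate_frames:
        raise AssertionError("extrapolated more frames than allowed")
    return out
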