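"""Transcriptional burst calling and hub-burst statistics.

Bursts are called from MS2 intensity traces via the rate of change of the
Gaussian-smoothed signal: a burst opens at an upward crossing of a
derivative threshold while the signal sits above the local baseline, and
closes when the signal returns to baseline (or a new rise begins after the
derivative has collapsed). Start/end frames are then refined on the raw
trace against a noise-scaled epsilon so that, on noiseless waveforms, burst
boundaries land exactly on the waveform's onset and return-to-baseline
frames.

Cross-correlation sign convention: **positive lag means the hub signal
follows the MS2 signal in time**. Swapping the two traces negates the peak
lag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Literal, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import gaussian_filter1d, minimum_filter1d

from .config import BurstParams
from .hubs import HubRegion
from .interactions import InteractionRecord, InteractionRun, extract_runs

log = logging.getLogger(__name__)

__all__ = [
    "Burst",
    "BurstHubLink",
    "CrossCorrResult",
    "GroupStats",
    "LinearFit",
    "call_bursts",
    "burst_frequency",
    "link_bursts_to_hubs",
    "high_intensity_threshold",
    "cross_correlate",
    "cohort_cross_correlation",
    "group_compare",
    "correlate_burst_params",
    "star_code",
]


@dataclass(frozen=True)
class Burst:
    nucleus_id: int
    index: int
    start_frame: int
    peak_frame: int
    end_frame: int
    start_min: float
    end_min: float
    duration_min: float
    amplitude: float  # peak smoothed intensity - pre-burst baseline
    output: float  # integral of baseline-subtracted intensity, units x min
    loading_rate_per_min: float  # amplitude / (peak - start)
    is_first: bool


@dataclass(frozen=True)
class BurstHubLink:
    nucleus_id: int
    burst_index: int
    is_first: bool
    hub_present_at_start: bool
    high_hub_at_start: bool
    arrival_lead_min: float  # burst start - containing run start; NaN if none
    dwell_after_min: float  # containing run end - burst start; NaN if none
    pre_burst_intensity: float  # mean sphere intensity in the pre-start window


@dataclass
class CrossCorrResult:
    lags_min: np.ndarray
    values: np.ndarray  # normalized, in [-1, 1]
    peak_lag_min: float
    peak_value: float
    #: positive lag = hub signal follows the MS2 signal
    sign_convention: str = "positive lag = hub follows MS2"


@dataclass(frozen=True)
class GroupStats:
    n_a: int
    n_b: int
    mannwhitney_u: float
    p_value: float
    star: str


@dataclass(frozen=True)
class LinearFit:
    n: int
    r_squared: float
    p_value: float
    slope: float
    intercept: float
    significant: bool  # p < 0.05


def star_code(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


# ---------------------------------------------------------------------------
# burst calling
# ---------------------------------------------------------------------------


def call_bursts(
    trace: np.ndarray,
    frame_interval_min: float,
    params: Optional[BurstParams] = None,
    nucleus_id: int = 0,
) -> List[Burst]:
    """Segment an MS2 intensity trace into bursts.

    The derivative threshold is ``k x MAD`` of the smoothed derivative with a
    floor of 5% of the maximum derivative (so noiseless traces, whose MAD can
    be zero, still threshold sensibly). Bursts shorter than
    ``min_duration_frames`` are discarded. A flat trace yields no bursts.
    """
    params = params or BurstParams()
    x = np.asarray(trace, dtype=float)
    n = x.size
    if n < 5:
        raise ValueError("burst calling needs at least 5 frames")
    if np.ptp(x) < 1e-12:
        return []
    dt = frame_interval_min

    sm = gaussian_filter1d(x, params.smooth_sigma_frames, mode="nearest")
    deriv = np.gradient(sm, dt)
    window = min(params.baseline_window_frames, n)
    baseline = minimum_filter1d(sm, size=window, mode="nearest")
    amp_scale = float(np.max(sm - baseline))
    if amp_scale <= 0:
        return []

    noise_sd = 1.4826 * float(np.median(np.abs(x - sm)))
    eps_int = max(params.onset_fraction * amp_scale, 3.0 * noise_sd)
    dmax = float(deriv.max())
    if dmax <= 0:
        return []
    # k x MAD of the derivative, floored (noiseless traces can have MAD 0)
    # and capped (dense bursts inflate the MAD) by fractions of the peak rate
    mad_d = float(np.median(np.abs(deriv - np.median(deriv))))
    theta = float(
        np.clip(params.derivative_k_mad * 1.4826 * mad_d, 0.05 * dmax, 0.3 * dmax)
    )

    above = (deriv > theta) & (sm > baseline + eps_int)
    crossings = np.nonzero(above & ~np.roll(above, 1))[0]
    if above[0]:
        crossings = np.unique(np.concatenate([[0], crossings]))

    bursts: List[Burst] = []
    prev_end = -1
    for s0 in crossings:
        if s0 <= prev_end:
            continue
        end0 = _find_end(sm, deriv, baseline, s0, theta, eps_int)
        start = _refine_start(x, baseline, s0, prev_end, eps_int, noise_sd, amp_scale)
        end = _refine_end(x, baseline, start, end0, eps_int, noise_sd, amp_scale)
        if end - start + 1 < params.min_duration_frames:
            prev_end = max(prev_end, end)
            continue
        base = float(baseline[start])
        seg_sm = sm[start : end + 1]
        amplitude = float(seg_sm.max()) - base
        if amplitude <= 0:
            prev_end = max(prev_end, end)
            continue
        seg_raw = x[start : end + 1]
        eps_peak = max(3.0 * noise_sd, 1e-9 * amp_scale)
        peak_off = int(np.argmax(seg_raw >= seg_raw.max() - eps_peak))
        peak = start + peak_off
        rise_min = max(peak - start, 1) * dt
        output = float(np.trapezoid(np.clip(seg_raw - base, 0, None), dx=dt))
        bursts.append(
            Burst(
                nucleus_id=nucleus_id,
                index=len(bursts),
                start_frame=int(start),
                peak_frame=int(peak),
                end_frame=int(end),
                start_min=start * dt,
                end_min=end * dt,
                duration_min=(end - start) * dt,
                amplitude=amplitude,
                output=output,
                loading_rate_per_min=amplitude / rise_min,
                is_first=len(bursts) == 0,
            )
        )
        prev_end = end
    return bursts


def _find_end(sm, deriv, baseline, s0, theta, eps_int) -> int:
    """First frame after the rise where the signal is back at baseline, or
    where a new rise begins after the derivative has collapsed."""
    n = sm.size
    fell = False
    for j in range(s0 + 1, n):
        if sm[j] <= baseline[j] + eps_int and deriv[j] <= 0:
            return j
        if deriv[j] < -theta:
            fell = True
        elif fell and deriv[j] > theta:
            return j - 1
    return n - 1


def _refine_start(x, baseline, s0, prev_end, eps_int, noise_sd, amp_scale) -> int:
    """Walk left from the derivative crossing to the onset frame: the last
    frame whose raw value sits at the baseline (within a noise epsilon)."""
    eps = max(3.0 * noise_sd, 1e-9 * amp_scale)
    s = s0
    lo = max(prev_end + 1, 0)
    while s > lo and x[s] > baseline[s] + eps:
        if x[s - 1] > x[s] + eps_int:  # climbing the previous burst's tail
            break
        s -= 1
    # smoothing can trip the derivative threshold before the waveform onset;
    # advance to the last at-baseline frame preceding the rise
    n = x.size
    while s + 1 < n and x[s + 1] <= baseline[s + 1] + eps:
        s += 1
    return s


def _refine_end(x, baseline, start, end0, eps_int, noise_sd, amp_scale) -> int:
    """First frame at/after the smoothed end estimate whose raw value has
    returned to baseline; bounded by the next rise."""
    eps = max(3.0 * noise_sd, 1e-9 * amp_scale)
    n = x.size
    peak = start + int(np.argmax(x[start : end0 + 1]))
    for j in range(max(peak, start), n):
        if x[j] <= baseline[j] + eps:
            return j
        if j > end0 and x[j] > x[j - 1] + eps_int:  # next burst rising
            return j - 1
    return n - 1


def burst_frequency(bursts: Sequence[Burst], span_min: float) -> float:
    """Bursts per minute of observed trace span."""
    if span_min <= 0:
        raise ValueError("trace span must be positive")
    return len(bursts) / span_min


# ---------------------------------------------------------------------------
# hub linking
# ---------------------------------------------------------------------------


def high_intensity_threshold(ventral_hubs: Sequence[HubRegion]) -> float:
    """Threshold for 'high-intensity hub': the average mean intensity of a
    ventral hub."""
    if not ventral_hubs:
        raise ValueError("needs at least one ventral hub")
    return float(np.mean([h.mean_intensity for h in ventral_hubs]))


def link_bursts_to_hubs(
    bursts: Sequence[Burst],
    records: Sequence[InteractionRecord],
    frame_interval_min: float,
    mode: Literal["any", "high"] = "any",
    gap_tolerance: int = 0,
    pre_window_frames: int = 5,
) -> List[BurstHubLink]:
    """Relate each burst to hub presence in the interaction sphere.

    Presence at the burst-start frame uses the ``hub_present`` flag (mode
    ``any``) or ``high_hub_present`` (mode ``high``). The arrival lead and
    dwell-after come from the interaction run containing the burst-start
    frame; both are NaN when no hub is present at the start. The pre-burst
    intensity is the mean sphere intensity over the ``pre_window_frames``
    frames before the start.
    """
    by_frame: Dict[int, InteractionRecord] = {r.frame: r for r in records}
    runs = extract_runs(
        records, frame_interval_min, gap_tolerance=gap_tolerance,
        use_high=(mode == "high"),
    )
    links = []
    for b in bursts:
        rec = by_frame.get(b.start_frame)
        if rec is None:
            raise ValueError(f"no interaction record at burst start frame {b.start_frame}")
        present = rec.high_hub_present if mode == "high" else rec.hub_present
        lead = dwell = np.nan
        if present:
            for run in runs:
                if run.start_frame <= b.start_frame <= run.end_frame:
                    lead = b.start_min - run.start_frame * frame_interval_min
                    dwell = run.end_frame * frame_interval_min - b.start_min
                    break
        pre = [
            by_frame[f].sphere_mean_intensity
            for f in range(b.start_frame - pre_window_frames, b.start_frame)
            if f in by_frame
        ]
        links.append(
            BurstHubLink(
                nucleus_id=b.nucleus_id,
                burst_index=b.index,
                is_first=b.is_first,
                hub_present_at_start=bool(rec.hub_present),
                high_hub_at_start=bool(rec.high_hub_present),
                arrival_lead_min=float(lead),
                dwell_after_min=float(dwell),
                pre_burst_intensity=float(np.nanmean(pre)) if pre else np.nan,
            )
        )
    return links


# ---------------------------------------------------------------------------
# cross-correlation
# ---------------------------------------------------------------------------


def cross_correlate(
    ms2_trace: np.ndarray,
    hub_trace: np.ndarray,
    frame_interval_min: float,
    max_lag_min: Optional[float] = None,
    smooth_sigma_frames: float = 1.5,
) -> Optional[CrossCorrResult]:
    """Normalized cross-correlation of paired traces over lags within
    ``+-max_lag_min`` (default: half the trace span).

    Both traces are smoothed identically; at each lag the correlation is the
    Pearson coefficient of the two overlapping windows (the sum is divided by
    the shrinking overlap length ``n - |lag|`` and by the windows' own norms,
    so values are exactly bounded in [-1, 1]). Positive peak lag means the
    hub signal follows the MS2 signal. Zero-variance input is undefined and
    returns ``None`` with a warning.
    """
    a = np.asarray(ms2_trace, dtype=float)
    b = np.asarray(hub_trace, dtype=float)
    if a.shape != b.shape:
        raise ValueError("traces must have equal length")
    n = a.size
    if n < 10:
        raise ValueError("cross-correlation needs at least 10 frames")
    if smooth_sigma_frames > 0:
        a = gaussian_filter1d(a, smooth_sigma_frames, mode="nearest")
        b = gaussian_filter1d(b, smooth_sigma_frames, mode="nearest")
    if np.std(a) < 1e-12 or np.std(b) < 1e-12:
        log.warning("zero-variance trace: cross-correlation undefined")
        return None

    if max_lag_min is None:
        max_lag_min = (n // 2) * frame_interval_min
    max_shift = min(int(round(max_lag_min / frame_interval_min)), n - 3)
    lags = np.arange(-max_shift, max_shift + 1)
    values = np.empty(lags.size)
    for i, lag in enumerate(lags):
        # positive lag: correlate MS2 now with the hub signal |lag| later
        if lag >= 0:
            x, y = a[: n - lag], b[lag:]
        else:
            x, y = a[-lag:], b[: n + lag]
        sx, sy = x.std(), y.std()
        if sx < 1e-12 or sy < 1e-12:
            values[i] = 0.0
            continue
        # Pearson over the overlap: the sum is divided by the shrinking
        # overlap length and the local norms, so values stay in [-1, 1]
        values[i] = float(np.mean((x - x.mean()) * (y - y.mean())) / (sx * sy))
    lags_min = lags * frame_interval_min
    peak = int(np.argmax(values))
    return CrossCorrResult(
        lags_min=lags_min,
        values=values,
        peak_lag_min=float(lags_min[peak]),
        peak_value=float(values[peak]),
    )


def cohort_cross_correlation(
    results: Sequence[CrossCorrResult],
) -> pd.DataFrame:
    """Cohort mean +- sd of per-nucleus cross-correlation curves (curves must
    share the lag grid)."""
    if not results:
        raise ValueError("no cross-correlation results")
    lags = results[0].lags_min
    for r in results[1:]:
        if not np.array_equal(r.lags_min, lags):
            raise ValueError("lag grids differ between nuclei")
    mat = np.stack([r.values for r in results])
    return pd.DataFrame(
        {
            "lag_min": lags,
            "mean": mat.mean(axis=0),
            "sd": mat.std(axis=0, ddof=1) if len(results) > 1 else np.nan,
            "n": len(results),
        }
    )


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------


def group_compare(values_a: Sequence[float], values_b: Sequence[float]) -> GroupStats:
    """Two-sided Mann-Whitney U (normal approximation with tie correction)
    plus the figure-legend star coding."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return GroupStats(
        n_a=a.size,
        n_b=b.size,
        mannwhitney_u=float(res.statistic),
        p_value=float(res.pvalue),
        star=star_code(float(res.pvalue)),
    )


#: burst parameters eligible for predictor regressions
BURST_PARAMETERS = (
    "amplitude",
    "loading_rate_per_min",
    "output",
    "duration_min",
    "frequency_per_min",
)


def correlate_burst_params(
    linked: pd.DataFrame,
    predictor: Literal["dwell_after_min", "pre_burst_intensity"],
) -> Dict[str, LinearFit]:
    """Pearson r^2, p, and least-squares line of each burst parameter against
    a hub predictor, over bursts where the predictor is defined.

    ``linked`` is the join of the burst and link tables (one row per burst,
    carrying both burst parameters and link predictors).
    """
    out: Dict[str, LinearFit] = {}
    for param in BURST_PARAMETERS:
        if param not in linked.columns:
            continue
        x = linked[predictor].to_numpy(dtype=float)
        y = linked[param].to_numpy(dtype=float)
        m = np.isfinite(x) & np.isfinite(y)
        if m.sum() < 3:
            continue
        if np.std(x[m]) == 0 or np.std(y[m]) == 0:
            continue
        fit = stats.linregress(x[m], y[m])
        out[param] = LinearFit(
            n=int(m.sum()),
            r_squared=float(fit.rvalue**2),
            p_value=float(fit.pvalue),
            slope=float(fit.slope),
            intercept=float(fit.intercept),
            significant=bool(fit.pvalue < 0.05),
        )
    return out
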