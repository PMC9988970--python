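"""Motion-artifact detection and MARA-style spline correction.

Abrupt motion spikes are flagged wherever a short moving window shows either
an inflated standard deviation or an inflated peak-to-peak amplitude relative
to the series' robust (MAD-based) SD.  Flagged samples are dilated, merged,
and each artifact segment is corrected by fitting a smoothing spline to the
segment and subtracting it, then re-leveling the residual to the adjacent
clean data so no step discontinuity is introduced at the segment boundaries.
Samples outside the (dilated) segments are returned untouched.

Correction operates on optical density, where motion artifacts are additive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import make_smoothing_spline
from scipy.ndimage import binary_dilation, maximum_filter1d, minimum_filter1d, uniform_filter1d

logger = logging.getLogger(__name__)

__all__ = ["MotionSegments", "detect_motion", "spline_correct", "correct_series"]


@dataclass
class MotionSegments:
    """Artifact intervals for one series, in seconds, half-open, merged."""

    intervals_s: list[tuple[float, float]]
    fs: float
    window_s: float = 1.0
    std_mult: float = 13.5
    amp_mult: float = 5.0
    dilation_s: float = 0.5

    def sample_mask(self, n_samples: int) -> np.ndarray:
        mask = np.zeros(n_samples, dtype=bool)
        for s, e in self.intervals_s:
            i0 = max(int(np.floor(s * self.fs)), 0)
            i1 = min(int(np.ceil(e * self.fs)), n_samples)
            mask[i0:i1] = True
        return mask


def _robust_sd(x: np.ndarray) -> float:
    return 1.4826 * float(np.median(np.abs(x - np.median(x))))


def _mask_to_intervals(mask: np.ndarray, fs: float) -> list[tuple[float, float]]:
    if not mask.any():
        return []
    edges = np.diff(mask.astype(int))
    starts = list(np.where(edges == 1)[0] + 1)
    ends = list(np.where(edges == -1)[0] + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(len(mask))
    return [(s / fs, e / fs) for s, e in zip(starts, ends)]


def detect_motion(
    series: np.ndarray,
    fs: float,
    window_s: float = 1.0,
    std_mult: float = 13.5,
    amp_mult: float = 5.0,
    dilation_s: float = 0.5,
) -> MotionSegments:
    """Flag artifact samples in a single series.

    A sample is flagged when the moving-window SD exceeds ``std_mult`` times
    the series' robust SD, or the within-window peak-to-peak amplitude
    exceeds ``amp_mult`` times the robust SD.  Flags are dilated by
    ``dilation_s`` on each side and overlapping intervals merged.
    """
    x = np.asarray(series, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("series must be finite")
    n = len(x)
    win = max(int(round(window_s * fs)), 2)
    rsd = _robust_sd(x)
    if rsd <= 0:
        rsd = float(x.std()) or 1.0

    m1 = uniform_filter1d(x, win, mode="nearest")
    m2 = uniform_filter1d(x * x, win, mode="nearest")
    mov_sd = np.sqrt(np.maximum(m2 - m1 * m1, 0.0))
    p2p = maximum_filter1d(x, win, mode="nearest") - minimum_filter1d(x, win, mode="nearest")

    flagged = (mov_sd > std_mult * rsd) | (p2p > amp_mult * rsd)
    if flagged.any():
        dil = int(round(dilation_s * fs))
        flagged = binary_dilation(flagged, structure=np.ones(2 * dil + 1, dtype=bool))
    return MotionSegments(_mask_to_intervals(flagged, fs), fs, window_s,
                          std_mult, amp_mult, dilation_s)


def spline_correct(
    series: np.ndarray,
    segments: MotionSegments,
    smoothing: float = 0.99,
) -> np.ndarray:
    """Subtract a smoothing spline inside each artifact segment.

    ``smoothing`` follows the csaps convention p in (0, 1): the spline
    minimizes p * sum (y - f)^2 + (1 - p) * int f''^2 on the sample-index
    grid with csaps' average-spacing normalization (regularization weight
    lambda = (1 - p) / (6 p) for unit spacing), i.e. it tracks the artifact
    trajectory including abrupt steps.  The spline residual is
    re-leveled with a linear offset ramp anchored to the clean data adjacent
    to each boundary, so the output is continuous at segment edges; samples
    outside the (dilated) segments are returned unchanged.

    A segment covering the entire series de-trends it (best-fit line
    removed) and warns: with no clean anchor there is nothing else to do.
    """
    x = np.asarray(series, dtype=float)
    n = len(x)
    fs = segments.fs
    if not segments.intervals_s:
        return x.copy()
    mask = segments.sample_mask(n)
    lam = (1.0 - smoothing) / (6.0 * smoothing)
    out = x.copy()

    if mask.all():
        logger.warning("artifact segment covers the entire series; returning "
                       "de-trended series")
        k = np.arange(n)
        coef = np.polyfit(k, x, 1)
        return x - np.polyval(coef, k)

    for s, e in segments.intervals_s:
        i0 = max(int(np.floor(s * fs)), 0)
        i1 = min(int(np.ceil(e * fs)), n)
        if i1 <= i0:
            continue
        seg = x[i0:i1]
        if i1 - i0 < 4:
            resid = seg - seg.mean()
        else:
            k = np.arange(i1 - i0, dtype=float)
            spl = make_smoothing_spline(k, seg, lam=lam)
            resid = seg - spl(k)
        # anchor the offset ramp to the nearest samples on each side: the
        # corrected segment then joins its neighbours without a step
        lev0 = x[i0 - 1] if i0 > 0 else (x[i1] if i1 < n else seg.mean())
        lev1 = x[i1] if i1 < n else lev0
        ramp = np.linspace(lev0, lev1, i1 - i0)
        out[i0:i1] = resid - 0.5 * (resid[0] + resid[-1]) + ramp
    return out


def correct_series(
    series: np.ndarray,
    fs: float,
    window_s: float = 1.0,
    std_mult: float = 13.5,
    amp_mult: float = 5.0,
    smoothing: float = 0.99,
) -> tuple[np.ndarray, MotionSegments]:
    """Detect and spline-correct in one call (single series)."""
    segs = detect_motion(series, fs, window_s, std_mult, amp_mult)
    return spline_correct(series, segs, smoothing), segs
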