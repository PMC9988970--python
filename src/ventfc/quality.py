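"""Windowed signal-quality metrics and contiguous subsample selection.

Two classic quality measures are computed in short overlapping windows:

* **SCI** (scalp coupling index): zero-lag Pearson correlation between the
  two wavelength signals after band-pass filtering to the cardiac band.
  Good optode-scalp contact couples the cardiac pulse into both wavelengths,
  so SCI near 1 indicates contact, near 0 indicates none.
* **PSP** (peak spectral power): the peak, within the cardiac band, of the
  power spectrum of the normalized cross-correlation of the two filtered
  wavelength signals.  It guards against spuriously high SCI from broadband
  coupling without a spectral cardiac signature.

Each recording is then reduced to the contiguous 2.5-min span with the best
combined quality that avoids signal-dropout segments, and channels without
detectable cardiac pulsation are excluded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal, stats

from .containers import ChannelValidity, RawRecording

logger = logging.getLogger(__name__)

__all__ = [
    "QualityMetrics",
    "SampleWindow",
    "compute_windowed_quality",
    "select_best_subsample",
    "detect_cardiac_channels",
    "apply_manual_exclusions",
    "find_dropout_segments",
    "cardiac_band_hz",
]


def cardiac_band_hz(cardiac_bpm: tuple[float, float] = (90.0, 210.0)) -> tuple[float, float]:
    return (cardiac_bpm[0] / 60.0, cardiac_bpm[1] / 60.0)


@dataclass
class QualityMetrics:
    window_starts_s: np.ndarray        # per window
    sci: np.ndarray                    # (n_windows, n_channels), in [-1, 1]
    psp: np.ndarray                    # (n_windows, n_channels), >= 0
    window_s: float
    overlap: float
    cardiac_band: tuple[float, float]  # Hz
    fs: float
    window_len: int                    # samples
    hop: int                           # samples

    @property
    def n_windows(self) -> int:
        return self.sci.shape[0]


@dataclass
class SampleWindow:
    start: int            # sample index, 0-based
    end: int              # half-open
    score: float
    dropout_free: bool


def _cardiac_sos(band: tuple[float, float], fs: float):
    return signal.butter(3, band, btype="bandpass", fs=fs, output="sos")


def _windowed_view(x: np.ndarray, win: int, hop: int) -> np.ndarray:
    """(n_windows, win, ...) sliding view along axis 0."""
    n = x.shape[0]
    n_win = 1 + (n - win) // hop
    idx = np.arange(win)[None, :] + hop * np.arange(n_win)[:, None]
    return x[idx]


def compute_windowed_quality(
    raw: RawRecording,
    window_s: float = 5.0,
    overlap: float = 0.5,
    cardiac_bpm: tuple[float, float] = (90.0, 210.0),
) -> QualityMetrics:
    """SCI and PSP per window per channel.

    Window and hop sizes are floor(window_s * fs) and
    floor(window_s * fs * (1 - overlap)) samples.  Flat (zero-variance)
    windows yield SCI = PSP = 0.
    """
    fs = raw.fs
    band = cardiac_band_hz(cardiac_bpm)
    if band[1] >= fs / 2:
        raise ValueError("cardiac band upper edge must be below Nyquist")
    win = int(np.floor(window_s * fs))
    hop = int(np.floor(window_s * fs * (1.0 - overlap)))
    if win > raw.n_samples:
        raise ValueError("recording shorter than one quality window")
    if hop < 1:
        raise ValueError("overlap too large: zero hop")

    sos = _cardiac_sos(band, fs)
    # windows: (n_win, win, ch, 2); filter each window independently
    wview = _windowed_view(raw.intensity, win, hop)
    # zero-variance (flat) windows carry no coupling information: SCI/PSP = 0
    flat = (wview.std(axis=1) <= 0).any(axis=2)       # (n_win, ch)
    filt = signal.sosfiltfilt(sos, wview, axis=1)
    mean = filt.mean(axis=1, keepdims=True)
    sd = filt.std(axis=1, keepdims=True)
    zn = (filt - mean) / np.where(sd > 0, sd, 1.0)

    x = zn[:, :, :, 0]
    y = zn[:, :, :, 1]
    sci = np.einsum("wtc,wtc->wc", x, y) / win
    sci = np.clip(sci, -1.0, 1.0)
    sci[flat] = 0.0

    # PSP: power spectrum of the normalized cross-correlation, peak in band
    n_lag = 2 * win - 1
    ham = np.hamming(n_lag)
    freqs = np.fft.rfftfreq(n_lag, d=1.0 / fs)
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    n_win, _, n_ch = x.shape
    psp = np.zeros((n_win, n_ch))
    # cross-correlation via FFT: full xcorr of x and y, normalized by win
    nfft = int(2 ** np.ceil(np.log2(2 * n_lag)))
    fx = np.fft.rfft(x, nfft, axis=1)
    fy = np.fft.rfft(y, nfft, axis=1)
    cc_full = np.fft.irfft(fx * np.conj(fy), nfft, axis=1)
    # reorder lags -(win-1) .. +(win-1)
    cc = np.concatenate([cc_full[:, -(win - 1):, :], cc_full[:, :win, :]], axis=1) / win
    spec = np.abs(np.fft.rfft(cc * ham[None, :, None], axis=1))
    amp = 2.0 * spec / ham.sum()
    psp = (amp[:, in_band, :] ** 2).max(axis=1)
    psp[flat] = 0.0

    starts = hop * np.arange(n_win) / fs
    return QualityMetrics(starts, sci, psp, window_s, overlap, band, fs, win, hop)


def find_dropout_segments(
    raw: RawRecording,
    threshold_frac: float = 0.01,
    min_duration_s: float = 0.5,
) -> np.ndarray:
    """Boolean (n_samples,) mask: any channel in a sustained dropout.

    A dropout is intensity below ``threshold_frac`` of the channel's median
    intensity (either wavelength) sustained for more than ``min_duration_s``.
    """
    inten = raw.intensity
    med = np.median(inten, axis=0)                      # (ch, 2)
    low = (inten < threshold_frac * med[None]).any(axis=2)   # (n, ch)
    min_len = int(np.ceil(min_duration_s * raw.fs))
    mask = np.zeros(raw.n_samples, dtype=bool)
    for ch in range(raw.n_channels):
        col = low[:, ch]
        if not col.any():
            continue
        edges = np.diff(col.astype(int))
        starts = list(np.where(edges == 1)[0] + 1)
        ends = list(np.where(edges == -1)[0] + 1)
        if col[0]:
            starts.insert(0, 0)
        if col[-1]:
            ends.append(len(col))
        for s, e in zip(starts, ends):
            if e - s > min_len:
                mask[s:e] = True
    return mask


def select_best_subsample(
    quality: QualityMetrics,
    raw: RawRecording,
    duration_s: float = 150.0,
    validity: ChannelValidity | None = None,
) -> SampleWindow:
    """Contiguous span of floor(duration_s * fs) samples maximizing quality.

    The score of a span is the mean, over quality windows fully inside the
    span and over non-excluded channels, of rank-normalized SCI plus
    rank-normalized PSP.  Spans overlapping a dropout segment score -inf
    unless no dropout-free span exists, in which case the least-contaminated
    span is returned with a warning.  Ties break to the earliest start.
    """
    fs = raw.fs
    span = int(np.floor(duration_s * fs))
    if span > raw.n_samples:
        raise ValueError("session invalid: recording shorter than the requested subsample")

    ch_mask = validity.valid if validity is not None else np.ones(quality.sci.shape[1], bool)
    if not ch_mask.any():
        ch_mask = np.ones(quality.sci.shape[1], bool)

    def rank_norm(a: np.ndarray) -> np.ndarray:
        flat = stats.rankdata(a, axis=None)
        return ((flat - 1) / max(a.size - 1, 1)).reshape(a.shape)

    wscore = (rank_norm(quality.sci) + rank_norm(quality.psp))[:, ch_mask].mean(axis=1)
    csum = np.concatenate([[0.0], np.cumsum(wscore)])

    drop = find_dropout_segments(raw)
    dsum = np.concatenate([[0], np.cumsum(drop.astype(int))])

    hop, win = quality.hop, quality.window_len
    n_candidates = raw.n_samples - span + 1
    starts = np.arange(n_candidates)
    # windows fully inside [s, s+span): hop*i >= s and hop*i + win <= s+span
    first = np.ceil(starts / hop).astype(int)
    last = np.floor((starts + span - win) / hop).astype(int)  # inclusive
    last = np.minimum(last, quality.n_windows - 1)
    n_cov = np.maximum(last - first + 1, 0)
    with np.errstate(invalid="ignore"):
        scores = np.where(n_cov > 0, (csum[np.minimum(last + 1, quality.n_windows)]
                                      - csum[np.minimum(first, quality.n_windows)])
                          / np.maximum(n_cov, 1), -np.inf)
    drop_counts = dsum[starts + span] - dsum[starts]
    clean = drop_counts == 0
    if clean.any():
        masked = np.where(clean, scores, -np.inf)
        best = int(np.argmax(masked))   # argmax returns first max: earliest tie-break
        return SampleWindow(best, best + span, float(scores[best]), True)
    logger.warning("no dropout-free span of %.1f s; returning least-contaminated span",
                   duration_s)
    order = np.lexsort((-scores, drop_counts))
    best = int(order[0])
    return SampleWindow(best, best + span, float(scores[best]), False)


def detect_cardiac_channels(
    raw: RawRecording,
    sci_threshold: float = 0.7,
    psp_threshold: float = 0.1,
    min_good_window_fraction: float = 0.6,
    peak_factor: float = 2.0,
    quality: QualityMetrics | None = None,
    cardiac_bpm: tuple[float, float] = (90.0, 210.0),
) -> ChannelValidity:
    """Mark channels without detectable cardiac pulsation as invalid.

    A channel is valid iff (a) the fraction of windows with
    SCI >= sci_threshold and PSP >= psp_threshold is at least
    ``min_good_window_fraction`` and (b) its full-span power spectrum has a
    local maximum inside the cardiac band exceeding ``peak_factor`` times the
    band's median power.
    """
    if quality is None:
        quality = compute_windowed_quality(raw, cardiac_bpm=cardiac_bpm)
    band = quality.cardiac_band
    good = (quality.sci >= sci_threshold) & (quality.psp >= psp_threshold)
    frac_ok = good.mean(axis=0) >= min_good_window_fraction

    # Full-subsample spectral check, averaged over the two wavelengths.
    # Power below the cardiac band is high-passed away first: slow
    # hemodynamic power is orders of magnitude larger and would leak a 1/f
    # floor across the short welch segments and bury the cardiac line.
    # Median averaging across welch segments keeps the estimate robust to
    # the broadband power of any motion spikes inside the subsample.
    inten = raw.intensity
    x = inten - inten.mean(axis=0, keepdims=True)
    sd = x.std(axis=0, keepdims=True)
    x = x / np.where(sd > 0, sd, 1.0)
    hp = signal.butter(3, 0.7 * band[0], btype="highpass", fs=raw.fs, output="sos")
    x = signal.sosfiltfilt(hp, x, axis=0)
    nperseg = min(int(12.6 * raw.fs), raw.n_samples)
    freqs, psd = signal.welch(x, fs=raw.fs, nperseg=nperseg, axis=0,
                              average="median")
    psd = psd.mean(axis=2)                      # average wavelengths -> (f, ch)
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    band_psd = psd[in_band]
    peak_ok = np.zeros(raw.n_channels, dtype=bool)
    for ch in range(raw.n_channels):
        col = band_psd[:, ch]
        med = np.median(col)
        peaks, _ = signal.find_peaks(col)
        if len(peaks) and med > 0:
            peak_ok[ch] = col[peaks].max() >= peak_factor * med

    valid = frac_ok & peak_ok
    reason = ["ok" if v else "no_cardiac" for v in valid]
    if not valid.any():
        logger.warning("all channels failed the cardiac-presence check")
    return ChannelValidity(valid, reason)


def apply_manual_exclusions(
    validity: ChannelValidity,
    channels: list[int],
    reason: str = "manual",
    montage=None,
) -> ChannelValidity:
    """Mark the listed channels invalid.  Idempotent: the first recorded
    reason for an already-invalid channel is preserved."""
    out = validity.copy()
    n = len(out.valid)
    for ch in channels:
        if not (0 <= ch < n):
            raise ValueError(f"unknown channel index: {ch}")
        if out.valid[ch]:
            out.valid[ch] = False
            out.reason[ch] = reason
    return out
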