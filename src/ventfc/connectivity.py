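"""Robust-correlation spontaneous functional connectivity (sFC).

Session connectivity is the robust correlation between every valid channel
pair of the 1-Hz hemoglobin series: both series are robustly standardized
(median/MAD), a weighted line fit provides residuals, Tukey bisquare weights
down-weight outlying samples, and the weighted Pearson correlation is
iterated to convergence.  Group summaries average sessions within patient
first (one mean sFC per channel pair per patient), then test sFC != 0 with a
one-sample t-test per pair; pairs observed in too few patients are flagged
low-confidence and excluded.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .containers import ChannelValidity, ConnectivityMatrix, HemoSeries
from .montage import Montage

logger = logging.getLogger(__name__)

__all__ = ["GroupTMap", "robust_correlation", "session_sfc", "group_tmap", "cluster_summary"]

BISQUARE_C = 4.685     # classical bisquare tuning constant
# iteration weights (aggressive: finds the robust fit even under heavy
# contamination); weights are flat at 1 inside FLAT, bisquare-taper to 0 at ZERO
ITER_FLAT, ITER_ZERO = 2.0, BISQUARE_C
# final weights (lenient: computed once from the converged robust fit, so
# clean Gaussian data is left essentially unweighted and the estimate matches
# the classical Pearson correlation)
FINAL_FLAT, FINAL_ZERO = 5.0, 8.0


def _mad_scale(x: np.ndarray) -> float:
    return 1.4826 * float(np.median(np.abs(x - np.median(x))))


def robust_correlation(x: np.ndarray, y: np.ndarray, tol: float = 1e-6,
                       max_iter: int = 50) -> float:
    """Iteratively re-weighted (bisquare) correlation, clamped to [-1, 1].

    Falls back to the classical Pearson correlation (with a warning) when
    either input has zero MAD.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and equally long")
    n = len(x)
    if n < 10:
        raise ValueError("robust correlation needs at least 10 samples")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")

    sx, sy = _mad_scale(x), _mad_scale(y)
    if sx <= 0 or sy <= 0:
        warnings.warn("zero MAD: falling back to classical Pearson correlation")
        sdx, sdy = x.std(), y.std()
        if sdx == 0 or sdy == 0:
            return 0.0
        return float(np.clip(np.corrcoef(x, y)[0, 1], -1.0, 1.0))
    xs = (x - np.median(x)) / sx
    ys = (y - np.median(y)) / sy

    def taper(u: np.ndarray, flat: float, zero: float) -> np.ndarray:
        t_ = np.clip((np.abs(u) - flat) / (zero - flat), 0.0, 1.0)
        return (1 - t_**2) ** 2

    def weighted_r(w: np.ndarray) -> float:
        sw = w.sum()
        mx = (w * xs).sum() / sw
        my = (w * ys).sum() / sw
        cxy = (w * (xs - mx) * (ys - my)).sum() / sw
        vx = (w * (xs - mx) ** 2).sum() / sw
        vy = (w * (ys - my) ** 2).sum() / sw
        if vx <= 0 or vy <= 0:
            return 0.0
        return cxy / np.sqrt(vx * vy)

    # Phase 1: IRLS line fit of y on x with aggressive joint
    # (residual x leverage) bisquare weights — this reliably locks onto the
    # clean-data fit even under heavy contamination.
    w = np.ones(n)
    resid = ys
    s = 1.0
    r_prev = np.inf
    degenerate = None
    for _ in range(max_iter):
        sw = w.sum()
        mx = (w * xs).sum() / sw
        my = (w * ys).sum() / sw
        vx = (w * (xs - mx) ** 2).sum() / sw
        if vx <= 0:
            break
        b = (w * (xs - mx) * (ys - my)).sum() / (sw * vx)
        a = my - b * mx
        resid = ys - (a + b * xs)
        s = _mad_scale(resid)
        if s <= 0:
            # perfect (weighted) linear relation
            degenerate = float(np.sign(b)) if b != 0 else 0.0
            break
        mx_now = (w * xs).sum() / w.sum()
        w = taper(resid / s, ITER_FLAT, ITER_ZERO) * taper(xs - mx_now, ITER_FLAT, ITER_ZERO)
        if w.sum() < 2:
            w = np.ones(n)
        r = weighted_r(w)
        if abs(r - r_prev) < tol:
            break
        r_prev = r
    if degenerate is not None:
        return float(np.clip(degenerate, -1.0, 1.0))

    # Phase 2: final weights from the converged fit, with a wide flat region
    # so typical (clean) samples carry weight exactly 1 and the estimate
    # agrees with the classical Pearson correlation on uncontaminated data,
    # while gross outliers remain fully rejected.
    mx = (w * xs).sum() / w.sum()
    w_final = taper(resid / s, FINAL_FLAT, FINAL_ZERO) * taper(xs - mx, FINAL_FLAT, FINAL_ZERO)
    if w_final.sum() < 2:
        w_final = np.ones(n)
    return float(np.clip(weighted_r(w_final), -1.0, 1.0))


def session_sfc(
    hemo_1hz: HemoSeries,
    validity: ChannelValidity | None = None,
    chromophore: str = "HbT",
    session_label: str = "",
) -> ConnectivityMatrix:
    """Robust correlation for every valid channel pair at 1 Hz."""
    if hemo_1hz.fs != 1.0:
        raise ValueError("connectivity expects 1-Hz series; resample first")
    series = {"HbT": hemo_1hz.hbt, "HbO": hemo_1hz.hbo, "HbR": hemo_1hz.hbr}[chromophore]
    n_ch = series.shape[1]
    validity = validity or ChannelValidity.all_valid(n_ch)
    if validity.valid.sum() < 2:
        raise ValueError("session invalid: fewer than two valid channels")
    vals = np.full((n_ch, n_ch), np.nan)
    np.fill_diagonal(vals, 1.0)
    vals[~validity.valid, :] = np.nan
    vals[:, ~validity.valid] = np.nan
    idx = np.where(validity.valid)[0]
    for a in range(len(idx)):
        for b in range(a + 1, len(idx)):
            i, j = idx[a], idx[b]
            r = robust_correlation(series[:, i], series[:, j])
            vals[i, j] = vals[j, i] = r
    return ConnectivityMatrix(vals, chromophore, validity, hemo_1hz.montage, session_label)


@dataclass
class GroupTMap:
    mean_sfc: np.ndarray       # (ch, ch) mean of patient means
    t: np.ndarray              # (ch, ch)
    df: np.ndarray             # (ch, ch) = n_patients - 1
    p: np.ndarray              # (ch, ch)
    n_patients: np.ndarray     # (ch, ch)
    low_confidence: np.ndarray  # (ch, ch) bool
    chromophore: str
    montage: Montage


def patient_mean_sfc(matrices_by_patient: dict[str, list[ConnectivityMatrix]]) -> dict[str, np.ndarray]:
    """Average sessions within patient, ignoring missing entries."""
    out = {}
    for pid, mats in matrices_by_patient.items():
        stack = np.stack([m.values for m in mats])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            out[pid] = np.nanmean(stack, axis=0)
    return out


def group_tmap(
    matrices_by_patient: dict[str, list[ConnectivityMatrix]],
    min_patients: int = 2,
    chromophore: str = "HbT",
) -> GroupTMap:
    """Per-pair one-sample t-test of patient-mean sFC against zero.

    Patient means use raw correlations (no Fisher z).  Pairs contributed by
    fewer than ``min_patients`` patients are flagged low-confidence and
    reported as missing.
    """
    if len(matrices_by_patient) < 2:
        raise ValueError("group t-map needs at least two patients")
    some = next(iter(matrices_by_patient.values()))[0]
    montage = some.montage
    means = patient_mean_sfc(matrices_by_patient)
    stack = np.stack(list(means.values()))          # (patients, ch, ch)
    n_contrib = np.sum(~np.isnan(stack), axis=0)
    low_conf = n_contrib < min_patients

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(stack, axis=0)
        t, p = stats.ttest_1samp(stack, 0.0, axis=0, nan_policy="omit")
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    for arr in (mean, t, p):
        arr[low_conf] = np.nan
    if np.all(low_conf):
        logger.warning("every channel pair is low-confidence; empty t-map")
    return GroupTMap(mean, t, n_contrib - 1.0, p, n_contrib, low_conf, chromophore, montage)


def cluster_summary(conn: ConnectivityMatrix, clusters: dict | None = None,
                    use_abs: bool = True) -> dict[str, float]:
    """Mean |sFC| (or sFC) over each named cluster's channel pairs.

    Missing entries are skipped; an all-missing cluster yields NaN.
    """
    clusters = clusters if clusters is not None else conn.montage.clusters
    out: dict[str, float] = {}
    for name, pairs in clusters.items():
        vals = np.array([conn.values[i, j] for i, j in pairs], dtype=float)
        if use_abs:
            vals = np.abs(vals)
        if np.all(np.isnan(vals)):
            out[name] = float("nan")
        else:
            out[name] = float(np.nanmean(vals))
    return out
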