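"""Synthetic bedside cohorts: recordings, ventricle-volume trajectories, patients.

The generator emulates the structure of the bedside dataset the analysis is
built for: 10.17 Hz two-wavelength intensity recordings on the 20-channel
neonatal cap, cardiac pulsation drifting within 90-210 bpm, slow (0.01-0.08 Hz)
hemodynamic oscillations with clustered positive / interhemispheric
anti-correlated structure, motion spikes, optode dropout, cardiac-free
channels, and longitudinal ventricle-volume (VV) trajectories with optional
step decreases at CSF-diversion events.  A configurable linear coupling
attenuates the magnitude of the target correlations as VV grows,
|rho| -> max(0, |rho0| - beta * VV), which the slope estimators are meant to
recover with negative sign.

The latent hemodynamic factors are *exactly* decorrelated in-sample
(empirical whitening) before Cholesky mixing, so the realized full-length
correlation matrix equals the target to machine precision at any duration;
downstream estimates still carry natural sampling noise because the pipeline
works on 2.5-min subsamples resampled to 1 Hz.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import linalg, signal

from .containers import GroundTruth, RawRecording, SessionRecord, ConnectivityMatrix, ChannelValidity
from .montage import Montage, default_target_correlation, generate_montage

logger = logging.getLogger(__name__)

__all__ = [
    "RecordingParams",
    "VVTrajectorySpec",
    "CohortSpec",
    "PatientData",
    "simulate_recording",
    "simulate_vv_trajectory",
    "simulate_cohort",
    "simulate_session_records",
    "attenuate_correlation",
    "study_cohort_spec",
]

# OD-equivalent weight of the shared hemodynamic/cardiac attenuation at each
# wavelength (total-hemoglobin-like change affects both positively).
WAVELENGTH_WEIGHTS = (1.0, 1.2)


@dataclass
class RecordingParams:
    """Knobs of a single simulated session (study conditions as defaults)."""

    correlation: np.ndarray | None = None      # target; None -> structured default
    hemo_band_hz: tuple[float, float] = (0.01, 0.08)
    hemo_sd: float = 0.02                      # attenuation (OD) units
    cardiac_amp_frac: float = 0.10             # x hemo_sd
    cardiac_free_rate: float = 0.15            # fraction of channels without pulsation
    heart_rate_hz: tuple[float, float] = (1.5, 3.5)   # 90-210 bpm
    drift_sd: float = 0.01
    motion_rate_per_min: float = 0.5
    motion_amp_range: tuple[float, float] = (5.0, 20.0)  # x hemo_sd
    dropout_rate_per_min: float = 0.02   # per channel; a few events per session
    dropout_duration_s: tuple[float, float] = (1.0, 5.0)
    intensity_baseline: float = 1.0
    intensity_noise_sd: float = 3e-4           # multiplicative, ~OD units
    exact_correlation: bool = True


def _cholesky_or_raise(corr: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.cholesky(corr)
    except np.linalg.LinAlgError:
        eig = np.linalg.eigvalsh(corr)
        raise ValueError(
            f"target correlation matrix is not positive semidefinite "
            f"(smallest eigenvalue {eig.min():.3e})"
        ) from None


def _band_limited_noise(n: int, n_ch: int, fs: float, band: tuple[float, float],
                        rng: np.random.Generator) -> np.ndarray:
    sos = signal.butter(2, band, btype="bandpass", fs=fs, output="sos")
    white = rng.standard_normal((n, n_ch))
    return signal.sosfiltfilt(sos, white, axis=0)


def _exact_correlated_factors(x: np.ndarray, corr: np.ndarray) -> np.ndarray:
    """Whiten realized columns, then mix so the sample correlation == corr."""
    x = x - x.mean(axis=0)
    cov = x.T @ x / x.shape[0]
    lw = np.linalg.cholesky(cov)
    xw = linalg.solve_triangular(lw, x.T, lower=True).T
    lr = _cholesky_or_raise(corr)
    return xw @ lr.T


def simulate_recording(
    montage: Montage,
    duration_s: float = 408.0,
    fs: float = 10.17,
    params: RecordingParams | None = None,
    seed: int = 0,
) -> tuple[RawRecording, GroundTruth]:
    """Simulate one two-wavelength intensity session.

    intensity = baseline * exp(-(hemodynamic + cardiac + drift + motion))
    per wavelength, with dropout intervals replaced by near-zero noise.
    The same seed reproduces the output bit-for-bit.
    """
    params = params or RecordingParams()
    if duration_s < 150:
        raise ValueError("duration_s must be >= 150 s (sessions shorter than the "
                         "2.5-min analysis window are invalid)")
    if fs <= 2 * params.heart_rate_hz[1]:
        raise ValueError("fs must exceed twice the maximum cardiac frequency")

    rng = np.random.default_rng(seed)
    n = int(np.floor(duration_s * fs))
    n_ch = montage.n_channels
    corr = params.correlation
    if corr is None:
        corr = default_target_correlation(montage)
    corr = np.asarray(corr, dtype=float)
    if corr.shape != (n_ch, n_ch):
        raise ValueError("correlation matrix shape does not match montage")

    # latent hemodynamic component with the requested correlation structure
    raw_noise = _band_limited_noise(n, n_ch, fs, params.hemo_band_hz, rng)
    if params.exact_correlation:
        hemo = _exact_correlated_factors(raw_noise, corr)
    else:
        hemo = (raw_noise - raw_noise.mean(0)) / raw_noise.std(0) @ _cholesky_or_raise(corr).T
    hemo *= params.hemo_sd / hemo.std(axis=0, ddof=0)

    # common quasi-periodic cardiac oscillation, slowly drifting frequency
    lo, hi = params.heart_rate_hz
    f0 = rng.uniform(lo + 0.3, hi - 0.5)
    freq = np.clip(f0 + np.cumsum(rng.standard_normal(n)) * 0.01 / np.sqrt(fs), lo, hi)
    phase = 2 * np.pi * np.cumsum(freq) / fs
    cardiac_base = np.sin(phase)
    amp = params.cardiac_amp_frac * params.hemo_sd * rng.uniform(0.7, 1.3, n_ch)
    amp[rng.random(n_ch) < params.cardiac_free_rate] = 0.0
    cardiac = cardiac_base[:, None] * amp[None, :]

    t = np.arange(n) / fs
    u = t / t[-1]
    drift = np.zeros((n, n_ch, 2))
    for w in range(2):
        coefs = rng.normal(0.0, params.drift_sd, size=(2, n_ch))
        drift[:, :, w] = np.outer(u, coefs[0]) + np.outer(u**2, coefs[1])

    # motion spikes: sharp transient + decaying step, shared across channels/wavelengths
    n_events = rng.poisson(params.motion_rate_per_min * duration_s / 60.0)
    spike_times: list[float] = []
    motion = np.zeros((n, n_ch))
    for _ in range(n_events):
        t0 = rng.uniform(5.0, duration_s - 5.0)
        spike_times.append(float(t0))
        a_lo, a_hi = params.motion_amp_range
        base_amp = rng.uniform(a_lo, a_hi) * params.hemo_sd * rng.choice([-1.0, 1.0])
        tau_fast = rng.uniform(0.2, 0.5)
        tau_slow = rng.uniform(2.0, 5.0)
        step_frac = rng.uniform(0.3, 1.0)
        ch_scale = rng.uniform(0.5, 1.5, n_ch)
        dt = t - t0
        shape = np.where(dt >= 0, np.exp(-np.maximum(dt, 0) / tau_fast)
                         + step_frac * np.exp(-np.maximum(dt, 0) / tau_slow), 0.0)
        motion += base_amp * shape[:, None] * ch_scale[None, :]
    spike_times.sort()

    atten_clean = np.empty((n, n_ch, 2))
    for w, wt in enumerate(WAVELENGTH_WEIGHTS):
        atten_clean[:, :, w] = wt * (hemo + cardiac) + drift[:, :, w]
    atten = atten_clean + motion[:, :, None]

    base = params.intensity_baseline
    intensity = base * np.exp(-atten)
    intensity *= 1.0 + params.intensity_noise_sd * rng.standard_normal(intensity.shape)

    # per-channel dropout intervals: optode lifted off the scalp
    dropouts: list[tuple[float, float, int]] = []
    for ch in range(n_ch):
        for _ in range(rng.poisson(params.dropout_rate_per_min * duration_s / 60.0)):
            d = rng.uniform(*params.dropout_duration_s)
            s0 = rng.uniform(0.0, duration_s - d)
            dropouts.append((float(s0), float(s0 + d), ch))
            i0, i1 = int(s0 * fs), int((s0 + d) * fs)
            noise = np.abs(base * (0.003 + 0.001 * rng.standard_normal((i1 - i0, 2))))
            intensity[i0:i1, ch, :] = noise

    rec = RawRecording(intensity, fs, montage, session_label=f"sim-{seed}")
    truth = GroundTruth(
        correlation=corr,
        coupling_slope=0.0,
        motion_spike_times_s=spike_times,
        dropout_intervals_s=sorted(dropouts),
        cardiac_amplitude=amp,
        seed=seed,
        clean_attenuation=atten_clean.astype(np.float32),
    )
    return rec, truth


# ---------------------------------------------------------------------------
# ventricle-volume trajectories


@dataclass
class VVTrajectorySpec:
    """Per-patient VV trajectory: linear growth + noise + diversion steps.

    ``diversion_events`` maps a 0-based session index k to a (step_left,
    step_right) decrease in mL applied *before* session k (i.e. between
    sessions k-1 and k).  Steps are negative for CSF removal.
    """

    n_sessions: int = 4
    baseline_left_ml: float = 10.0
    baseline_right_ml: float = 10.0
    growth_ml_per_week: float = 2.0
    session_interval_weeks: float = 1.0
    # optional per-gap intervals (length n_sessions - 1); overrides the scalar
    session_intervals_weeks: tuple[float, ...] | None = None
    noise_sd_ml: float = 0.0
    diversion_events: dict[int, tuple[float, float]] = field(default_factory=dict)
    floor_ml: float = 0.5
    ga_start_weeks: float = 28.0

    def intervals(self) -> np.ndarray:
        if self.session_intervals_weeks is not None:
            iv = np.asarray(self.session_intervals_weeks, dtype=float)
            if len(iv) != self.n_sessions - 1:
                raise ValueError("session_intervals_weeks must have n_sessions - 1 entries")
            return iv
        return np.full(self.n_sessions - 1, self.session_interval_weeks)


def simulate_vv_trajectory(spec: VVTrajectorySpec, seed: int = 0):
    """Return (vv_left, vv_right, vv_total, ga_weeks) arrays for one patient.

    total == left + right exactly at every session; volumes are truncated at
    ``floor_ml`` (with a logged warning) if a diversion step overshoots.
    """
    rng = np.random.default_rng(seed)
    n = spec.n_sessions
    if n < 2:
        raise ValueError("at least two sessions are required per patient")
    left = np.empty(n)
    right = np.empty(n)
    intervals = spec.intervals()
    ga = spec.ga_start_weeks + np.concatenate([[0.0], np.cumsum(intervals)])
    cur_l, cur_r = spec.baseline_left_ml, spec.baseline_right_ml
    for k in range(n):
        if k > 0:
            cur_l += spec.growth_ml_per_week * intervals[k - 1]
            cur_r += spec.growth_ml_per_week * intervals[k - 1]
        if k in spec.diversion_events:
            dl, dr = spec.diversion_events[k]
            cur_l += dl
            cur_r += dr
        noise_l = rng.normal(0, spec.noise_sd_ml) if spec.noise_sd_ml > 0 else 0.0
        noise_r = rng.normal(0, spec.noise_sd_ml) if spec.noise_sd_ml > 0 else 0.0
        vl, vr = cur_l + noise_l, cur_r + noise_r
        if vl < spec.floor_ml or vr < spec.floor_ml:
            logger.warning("VV truncated to floor (%.2f mL) at session %d", spec.floor_ml, k)
        left[k] = max(vl, spec.floor_ml)
        right[k] = max(vr, spec.floor_ml)
        cur_l = max(cur_l, spec.floor_ml)
        cur_r = max(cur_r, spec.floor_ml)
    return left, right, left + right, ga


# ---------------------------------------------------------------------------
# cohorts


@dataclass
class CohortSpec:
    """One study arm.  Defaults follow the bedside cohort's structure."""

    group: str = "no_diversion"                   # or "diversion"
    n_patients: int = 23
    sessions_range: tuple[int, int] = (2, 8)      # inclusive
    ga_birth_mean_weeks: float = 26.6
    ga_birth_sd_weeks: float = 2.6
    vv_baseline_range_ml: tuple[float, float] = (4.0, 15.0)   # per side
    vv_growth_range_ml_per_week: tuple[float, float] = (0.5, 3.0)
    vv_noise_sd_ml: float = 0.5
    n_diversions_range: tuple[int, int] = (1, 3)  # diversion arm only
    diversion_step_left_ml: float = -9.74
    diversion_step_right_ml: float = -10.20
    diversion_step_sd_ml: float = 2.0
    coupling_slope: float = 0.002                 # beta, |corr| per mL
    interhemi_rule: str = "mean"
    recording: RecordingParams = field(default_factory=RecordingParams)
    duration_s: float = 408.0
    fs: float = 10.17

    def __post_init__(self) -> None:
        if self.sessions_range[0] < 2:
            raise ValueError("patients need at least two valid sessions")


def study_cohort_spec(group: str, **overrides) -> CohortSpec:
    """Spec matching one of the two study arms."""
    if group == "no_diversion":
        spec = CohortSpec(group="no_diversion", n_patients=23, sessions_range=(2, 8))
    elif group == "diversion":
        # severe PHVD: ventricles large enough that repeated ~10 mL/side CSF
        # removals never drive the volume to its floor
        spec = CohortSpec(group="diversion", n_patients=7, sessions_range=(3, 15),
                          vv_baseline_range_ml=(18.0, 40.0))
    else:
        raise ValueError(f"unknown group: {group}")
    return replace(spec, **overrides) if overrides else spec


def attenuate_correlation(corr: np.ndarray, beta: float, vv_left: float,
                          vv_right: float, montage: Montage,
                          interhemi_rule: str = "mean") -> np.ndarray:
    """Session target: |rho| -> max(0, |rho0| - beta * VV_pair), signs kept.

    Within-hemisphere pairs use that hemisphere's VV; interhemispheric pairs
    use the configured combination.  The result is nudged back to positive
    semidefinite (uniform off-diagonal shrinkage) if elementwise attenuation
    broke it, which only occurs for extreme beta * VV.
    """
    n = corr.shape[0]
    vv = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            hemi = montage.pair_hemisphere(i, j) if i != j else "left"
            if hemi == "left":
                vv[i, j] = vv_left
            elif hemi == "right":
                vv[i, j] = vv_right
            else:
                if interhemi_rule == "mean":
                    vv[i, j] = 0.5 * (vv_left + vv_right)
                elif interhemi_rule == "left":
                    vv[i, j] = vv_left
                elif interhemi_rule == "right":
                    vv[i, j] = vv_right
                else:
                    vv[i, j] = vv_left + vv_right
    out = np.sign(corr) * np.maximum(0.0, np.abs(corr) - beta * vv)
    np.fill_diagonal(out, 1.0)
    off = ~np.eye(n, dtype=bool)
    if np.any(np.abs(corr[off]) > 0) and not np.any(np.abs(out[off]) > 0):
        warnings.warn("attenuation drove all off-diagonal correlations to zero")
    eig_min = np.linalg.eigvalsh(out).min()
    if eig_min < 1e-8:
        eps = (1e-8 - eig_min)
        out = (out + eps * np.eye(n)) / (1.0 + eps)
    return out


@dataclass
class PatientData:
    patient_id: str
    group: str
    sessions: list  # list of dicts with keys: recording|connectivity, vv_*, ga_weeks, ...
    truth: dict


def _patient_plan(spec: CohortSpec, rng: np.random.Generator):
    """Shared per-patient design: session count, GA grid, VV trajectory, events."""
    n_sessions = int(rng.integers(spec.sessions_range[0], spec.sessions_range[1] + 1))
    ga_birth = float(np.clip(rng.normal(spec.ga_birth_mean_weeks, spec.ga_birth_sd_weeks),
                             23.0, 32.0))
    events: dict[int, tuple[float, float]] = {}
    if spec.group == "diversion":
        lo, hi = spec.n_diversions_range
        n_events = int(rng.integers(lo, min(hi, max(lo, n_sessions - 1)) + 1))
        candidates = list(range(1, n_sessions))
        rng.shuffle(candidates)
        for k in sorted(candidates[:n_events]):
            events[k] = (
                spec.diversion_step_left_ml + rng.normal(0, spec.diversion_step_sd_ml),
                spec.diversion_step_right_ml + rng.normal(0, spec.diversion_step_sd_ml),
            )
    # post-diversion sessions happen the same day as the event: the gap into
    # an event session is ~30 minutes, so no meaningful VV growth accrues
    intervals = rng.uniform(0.6, 1.4, size=n_sessions - 1)
    for k in events:
        intervals[k - 1] = 0.003
    traj = VVTrajectorySpec(
        n_sessions=n_sessions,
        baseline_left_ml=rng.uniform(*spec.vv_baseline_range_ml),
        baseline_right_ml=rng.uniform(*spec.vv_baseline_range_ml),
        growth_ml_per_week=rng.uniform(*spec.vv_growth_range_ml_per_week),
        session_intervals_weeks=tuple(intervals),
        noise_sd_ml=spec.vv_noise_sd_ml,
        diversion_events=events,
        ga_start_weeks=ga_birth + float(rng.uniform(1.0, 3.0)),
    )
    vv_l, vv_r, vv_t, ga = simulate_vv_trajectory(traj, seed=int(rng.integers(2**31)))
    return n_sessions, ga, vv_l, vv_r, vv_t, events, traj


def simulate_cohort(spec: CohortSpec, seed: int = 0) -> list[PatientData]:
    """Full-fidelity cohort: every session carries a raw intensity recording
    whose latent correlation targets are attenuated by that session's VV."""
    rng = np.random.default_rng(seed)
    montage = generate_montage()
    base_corr = (spec.recording.correlation
                 if spec.recording.correlation is not None
                 else default_target_correlation(montage))
    patients: list[PatientData] = []
    for p in range(spec.n_patients):
        n_sessions, ga, vv_l, vv_r, vv_t, events, traj = _patient_plan(spec, rng)
        pid = f"{spec.group[:3]}-{p + 1:02d}"
        sessions = []
        for k in range(n_sessions):
            target = attenuate_correlation(base_corr, spec.coupling_slope,
                                           vv_l[k], vv_r[k], montage,
                                           spec.interhemi_rule)
            rp = replace(spec.recording, correlation=target)
            rec, truth = simulate_recording(montage, spec.duration_s, spec.fs, rp,
                                            seed=int(rng.integers(2**31)))
            truth.coupling_slope = spec.coupling_slope
            sessions.append({
                "recording": rec,
                "truth": truth,
                "vv_left_ml": vv_l[k],
                "vv_right_ml": vv_r[k],
                "vv_total_ml": vv_t[k],
                "ga_weeks": float(ga[k]),
                "diversion_event_before": k in events,
            })
        patients.append(PatientData(pid, spec.group, sessions,
                                    truth={"coupling_slope": spec.coupling_slope,
                                           "events": events,
                                           "base_correlation": base_corr,
                                           "trajectory": traj}))
    return patients


def simulate_session_records(
    spec: CohortSpec,
    montage: Montage | None = None,
    seed: int = 0,
    n_fc_samples: int = 149,
    base_correlation: np.ndarray | None = None,
) -> list[SessionRecord]:
    """Connectivity-level cohort for statistical recovery/calibration studies.

    Each session's connectivity matrix is the sample Pearson correlation of
    ``n_fc_samples`` draws (the length of a 2.5-min subsample at 1 Hz) from a
    Gaussian with the session's attenuated target correlation — i.e. the
    estimation noise the optical pipeline would hand to the slope stage,
    without the optical simulation cost.
    """
    rng = np.random.default_rng(seed)
    montage = montage or generate_montage()
    if base_correlation is None:
        base_correlation = (spec.recording.correlation
                            if spec.recording.correlation is not None
                            else default_target_correlation(montage))
    n_ch = montage.n_channels
    records: list[SessionRecord] = []
    for p in range(spec.n_patients):
        n_sessions, ga, vv_l, vv_r, vv_t, events, _ = _patient_plan(spec, rng)
        pid = f"{spec.group[:3]}-{p + 1:02d}"
        for k in range(n_sessions):
            target = attenuate_correlation(base_correlation, spec.coupling_slope,
                                           vv_l[k], vv_r[k], montage, spec.interhemi_rule)
            x = rng.standard_normal((n_fc_samples, n_ch)) @ _cholesky_or_raise(target).T
            cm = np.corrcoef(x, rowvar=False)
            conn = ConnectivityMatrix(cm, "HbT", ChannelValidity.all_valid(n_ch),
                                      montage, session_label=f"{pid}-s{k}")
            records.append(SessionRecord(
                patient_id=pid, group=spec.group, ga_weeks=float(ga[k]),
                vv_left_ml=float(vv_l[k]), vv_right_ml=float(vv_r[k]),
                vv_total_ml=float(vv_t[k]), connectivity=conn,
                diversion_event_before=k in events, order_index=k,
            ))
    return records
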