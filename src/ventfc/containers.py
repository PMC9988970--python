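"""In-memory containers shared across the pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .montage import Montage

__all__ = [
    "RawRecording",
    "GroundTruth",
    "ODSeries",
    "HemoSeries",
    "ChannelValidity",
    "ConnectivityMatrix",
    "SessionRecord",
]

VALIDITY_REASONS = ("ok", "no_cardiac", "motion", "dropout", "hardware", "manual")


@dataclass
class RawRecording:
    """Two-wavelength continuous-wave intensity recording.

    ``intensity`` has shape (n_samples, n_channels, 2), arbitrary units,
    expected positive.  The wavelength axis follows ``montage.wavelengths``.
    """

    intensity: np.ndarray
    fs: float
    montage: Montage
    cap_scale: float = 1.0
    session_label: str = ""

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 3 or self.intensity.shape[2] != 2:
            raise ValueError("intensity must have shape (n_samples, n_channels, 2)")
        if self.intensity.shape[1] != self.montage.n_channels:
            raise ValueError("channel count does not match montage")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def n_samples(self) -> int:
        return self.intensity.shape[0]

    @property
    def n_channels(self) -> int:
        return self.intensity.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def slice(self, start: int, stop: int) -> "RawRecording":
        return RawRecording(self.intensity[start:stop].copy(), self.fs, self.montage,
                            self.cap_scale, self.session_label)


@dataclass
class GroundTruth:
    """What the generator injected; consumed only by recovery tests."""

    correlation: np.ndarray                      # target inter-channel correlation
    coupling_slope: float                        # |sFC| attenuation per mL of VV
    motion_spike_times_s: list[float]
    dropout_intervals_s: list[tuple[float, float, int]]  # (start, end, channel)
    cardiac_amplitude: np.ndarray                # per channel, 0 = cardiac-free
    seed: int
    clean_attenuation: np.ndarray | None = None  # (n, ch, 2), artifact-free


@dataclass
class ODSeries:
    """Optical-density change, -ln(I / I_mean), per channel and wavelength."""

    od: np.ndarray            # (n_samples, n_channels, 2)
    reference_intensity: np.ndarray  # (n_channels, 2)
    fs: float
    montage: Montage
    cap_scale: float = 1.0


@dataclass
class HemoSeries:
    """Relative hemoglobin concentration changes (HbO/HbR/HbT)."""

    hbo: np.ndarray           # (n_samples, n_channels)
    hbr: np.ndarray
    fs: float
    montage: Montage
    provenance: dict = field(default_factory=dict)

    @property
    def hbt(self) -> np.ndarray:
        return self.hbo + self.hbr

    @property
    def n_samples(self) -> int:
        return self.hbo.shape[0]


@dataclass
class ChannelValidity:
    valid: np.ndarray                 # bool, per channel
    reason: list[str]                 # per channel, from VALIDITY_REASONS
    low_confidence: np.ndarray | None = None  # cohort-scoped, per channel pair

    @classmethod
    def all_valid(cls, n_channels: int) -> "ChannelValidity":
        return cls(np.ones(n_channels, dtype=bool), ["ok"] * n_channels)

    def copy(self) -> "ChannelValidity":
        return ChannelValidity(self.valid.copy(), list(self.reason),
                               None if self.low_confidence is None else self.low_confidence.copy())


@dataclass
class ConnectivityMatrix:
    """Session-level sFC.  Entries touching invalid channels are NaN, never 0."""

    values: np.ndarray        # (n_channels, n_channels), NaN = missing
    chromophore: str          # "HbT" | "HbO" | "HbR"
    validity: ChannelValidity
    montage: Montage
    session_label: str = ""

    def __post_init__(self) -> None:
        v = self.values
        if v.shape[0] != v.shape[1]:
            raise ValueError("connectivity matrix must be square")


@dataclass
class SessionRecord:
    """One bedside measurement: connectivity + ventricle volumes + context."""

    patient_id: str
    group: str                # "no_diversion" | "diversion"
    ga_weeks: float
    vv_left_ml: float
    vv_right_ml: float
    vv_total_ml: float
    connectivity: ConnectivityMatrix
    diversion_event_before: bool = False
    order_index: int = 0

    def vv_for_pair(self, i: int, j: int, interhemi_rule: str = "mean") -> float:
        """VV used for a channel pair: the pair's own hemisphere, or the
        configured combination for interhemispheric pairs."""
        hemi = self.connectivity.montage.pair_hemisphere(i, j)
        if hemi == "left":
            return self.vv_left_ml
        if hemi == "right":
            return self.vv_right_ml
        if interhemi_rule == "mean":
            return 0.5 * (self.vv_left_ml + self.vv_right_ml)
        if interhemi_rule == "left":
            return self.vv_left_ml
        if interhemi_rule == "right":
            return self.vv_right_ml
        if interhemi_rule == "total":
            return self.vv_total_ml
        raise ValueError(f"unknown interhemi_rule: {interhemi_rule}")
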