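"""Optical density and modified Beer-Lambert law (MBLL) conversion.

Intensity is converted to optical-density change relative to the subsample
mean, dOD(t) = -ln(I(t) / I_mean), then to relative oxygenated (HbO) and
deoxygenated (HbR) hemoglobin concentration changes by solving, per channel
and sample, the 2x2 linear system

    dOD(lambda) = [eps_HbO(lambda) dHbO + eps_HbR(lambda) dHbR] * d_cm * ppf(lambda)

where d is the channel's source-detector distance (nominal separation scaled
to the session's cap size) and ppf the age-appropriate partial pathlength
factor per wavelength (0.1063 at 760 nm, 0.0845 at 850 nm).  The absolute
scale of the ppf only rescales concentration units; it cancels entirely in
correlation-based connectivity, which is why these factors can be used as
opaque multipliers.  Total hemoglobin is HbT = HbO + HbR, exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .containers import HemoSeries, ODSeries, RawRecording
from .montage import Montage

logger = logging.getLogger(__name__)

__all__ = ["MBLLParams", "EXTINCTION_TABLE", "intensity_to_od", "od_to_hemoglobin"]

# Gratzer/Cope hemoglobin extinction coefficients, cm^-1 / (mole/liter),
# as tabulated in the Homer ecosystem.  Keyed by wavelength (nm):
# (eps_HbO, eps_HbR).
EXTINCTION_TABLE = {
    "id": "gratzer-cope-1999",
    760.0: (1486.5865, 3843.707),
    850.0: (2526.391, 1798.643),
}

DEFAULT_PPF = {760.0: 0.1063, 850.0: 0.0845}


@dataclass
class MBLLParams:
    """Conversion constants.  ppf keys must match the montage wavelengths."""

    ppf: dict[float, float] = field(default_factory=lambda: dict(DEFAULT_PPF))
    extinction: dict = field(default_factory=lambda: dict(EXTINCTION_TABLE))
    cap_scale: float = 1.0

    def matrix(self, wavelengths: tuple[float, float]) -> np.ndarray:
        """2x2 system matrix rows ordered by wavelength, columns (HbO, HbR),
        in (mM^-1 cm^-1) after the mole/liter -> mM unit change."""
        rows = []
        for wl in wavelengths:
            if wl not in self.extinction:
                raise ValueError(f"no extinction coefficients tabulated at {wl} nm")
            if wl not in self.ppf:
                raise ValueError(f"no partial pathlength factor for {wl} nm")
            if self.ppf[wl] <= 0:
                raise ValueError("partial pathlength factors must be positive")
            eo, er = self.extinction[wl]
            rows.append((eo / 1000.0, er / 1000.0))   # per mM per cm
        return np.asarray(rows)


def intensity_to_od(raw: RawRecording) -> ODSeries:
    """dOD(t) = -ln(I(t) / I_mean) per channel and wavelength.

    Non-positive samples are replaced by the channel's minimum positive value
    (flagged in the log); an all-nonpositive channel yields NaN OD and should
    be excluded upstream.
    """
    inten = raw.intensity.copy()
    bad = inten <= 0
    if bad.any():
        logger.warning("replacing %d non-positive intensity samples", int(bad.sum()))
        for ch in range(inten.shape[1]):
            for w in range(2):
                col = inten[:, ch, w]
                pos = col[col > 0]
                if len(pos) == 0:
                    logger.warning("channel %d wavelength %d has no positive samples", ch, w)
                    col[:] = np.nan
                else:
                    col[col <= 0] = pos.min()
    ref = inten.mean(axis=0)
    od = -np.log(inten / ref[None])
    return ODSeries(od, ref, raw.fs, raw.montage, raw.cap_scale)


def od_to_hemoglobin(od: ODSeries, params: MBLLParams | None = None,
                     montage: Montage | None = None) -> HemoSeries:
    """Invert the MBLL per channel: (dHbO, dHbR) from the two-wavelength dOD."""
    params = params or MBLLParams(cap_scale=od.cap_scale)
    montage = montage or od.montage
    wavelengths = montage.wavelengths
    eps = params.matrix(wavelengths)             # (2 wl, 2 chromophores)
    cond = np.linalg.cond(eps)
    if not np.isfinite(cond) or cond > 1e8:
        raise ValueError("extinction system is singular or near-singular; "
                         "check wavelength pair and table")

    n, n_ch, _ = od.od.shape
    hbo = np.empty((n, n_ch))
    hbr = np.empty((n, n_ch))
    ppf = np.array([params.ppf[wl] for wl in wavelengths])
    for ch in range(n_ch):
        d_cm = montage.channels[ch].separation_mm * params.cap_scale / 10.0
        a = eps * (d_cm * ppf)[:, None]          # (wl, chromophore)
        sol = np.linalg.solve(a, od.od[:, ch, :].T)
        hbo[:, ch] = sol[0]
        hbr[:, ch] = sol[1]
    prov = {
        "ppf": {wl: params.ppf[wl] for wl in wavelengths},
        "extinction_table": params.extinction["id"],
        "cap_scale": params.cap_scale,
        "distances_mm": [c.separation_mm * params.cap_scale for c in montage.channels],
        "condition_number": float(cond),
    }
    logger.debug("MBLL extinction condition number: %.3f", cond)
    return HemoSeries(hbo, hbr, od.fs, montage, prov)
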