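"""Optode montage geometry for the neonatal high-density fNIRS cap.

The default layout mirrors the bedside acquisition setup: 8 LED sources and
8 detectors over prefrontal/sensorimotor cortex, forming 10 channels of
22 mm nominal separation per hemisphere (20 total), each source emitting at
760 and 850 nm.  Four named channel-pair clusters (left/right x
anterior/posterior) summarize connectivity at an intermediate granularity:
each cluster is a chain of 4 channel pairs over 5 channels and has a
mirror-symmetric counterpart in the other hemisphere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Optode", "Channel", "Montage", "generate_montage", "default_target_correlation"]

DEFAULT_WAVELENGTHS = (760.0, 850.0)
DEFAULT_SEPARATION_MM = 22.0


@dataclass(frozen=True)
class Optode:
    id: str
    pos_mm: tuple[float, float]


@dataclass(frozen=True)
class Channel:
    source: str
    detector: str
    separation_mm: float
    hemisphere: str  # "left" | "right"
    region: str      # "anterior" | "posterior"

    @property
    def name(self) -> str:
        return f"{self.source}-{self.detector}"


@dataclass
class Montage:
    sources: list[Optode]
    detectors: list[Optode]
    channels: list[Channel]
    wavelengths: tuple[float, float] = DEFAULT_WAVELENGTHS
    # cluster name -> list of (channel_index, channel_index) pairs
    clusters: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    def hemisphere_of(self, idx: int) -> str:
        return self.channels[idx].hemisphere

    def pair_hemisphere(self, i: int, j: int) -> str:
        """Hemisphere of a channel *pair*: left/right if both members agree, else 'inter'."""
        hi, hj = self.channels[i].hemisphere, self.channels[j].hemisphere
        return hi if hi == hj else "inter"

    def channel_indices(self, hemisphere: str | None = None) -> list[int]:
        if hemisphere is None:
            return list(range(self.n_channels))
        return [k for k, ch in enumerate(self.channels) if ch.hemisphere == hemisphere]

    def channel_names(self) -> list[str]:
        return [ch.name for ch in self.channels]

    def source_positions(self) -> np.ndarray:
        return np.array([o.pos_mm for o in self.sources], dtype=float)

    def detector_positions(self) -> np.ndarray:
        return np.array([o.pos_mm for o in self.detectors], dtype=float)


def _hemisphere_grid(hemi: str, sep: float, x_sign: float):
    """2x4 checkerboard strip: 4 sources + 4 detectors, 10 links of one grid-step.

    Columns run front (anterior) to back (posterior); the two rows are the
    inferior/superior edge of the strip.  Sources occupy even-parity cells.
    """
    optodes = {}  # (col,row) -> (kind, pos)
    for col in range(4):
        for row in range(2):
            kind = "S" if (col + row) % 2 == 0 else "D"
            # offset from midline so left/right strips do not overlap
            x = x_sign * (sep + col * sep)
            y = row * sep
            optodes[(col, row)] = (kind, (x, y))

    links = []  # (cell_a, cell_b)
    for row in range(2):  # horizontal links within a row
        for col in range(3):
            links.append(((col, row), (col + 1, row)))
    for col in range(4):  # vertical links within a column
        links.append(((col, 0), (col, 1)))
    # Exactly 5 anterior / 5 posterior channels: split on mean column with a
    # row tie-break at the strip's midline.
    channels = []
    for a, b in links:
        mean_col = (a[0] + b[0]) / 2.0
        if mean_col < 1.5:
            region = "anterior"
        elif mean_col > 1.5:
            region = "posterior"
        else:
            region = "anterior" if a[1] == 0 and b[1] == 0 else "posterior"
        channels.append((a, b, region))
    return optodes, channels


def _chain_strip(hemi: str, n_channels: int, sep: float, x_sign: float):
    """Fallback layout for non-default channel counts: alternating S/D chain."""
    optodes = {}
    channels = []
    for k in range(n_channels + 1):
        kind = "S" if k % 2 == 0 else "D"
        optodes[(k, 0)] = (kind, (x_sign * (sep + k * sep * 0.5), 0.0))
    for k in range(n_channels):
        a, b = (k, 0), (k + 1, 0)
        region = "anterior" if k < n_channels / 2 else "posterior"
        if optodes[a][0] == "S":
            channels.append((a, b, region))
        else:
            channels.append((b, a, region))
    return optodes, channels


def generate_montage(
    n_channels_per_hemisphere: int = 10,
    separation_mm: float = DEFAULT_SEPARATION_MM,
    cap_scale: float = 1.0,
    wavelengths: tuple[float, float] = DEFAULT_WAVELENGTHS,
) -> Montage:
    """Build the cap montage.

    ``cap_scale`` scales every optode position (and hence channel separation)
    linearly; it models the family of cap sizes fitted to different head
    circumferences.  The default arguments reproduce the 20-channel bedside
    layout with its four symmetric channel-pair clusters.
    """
    if n_channels_per_hemisphere < 1:
        raise ValueError("n_channels_per_hemisphere must be >= 1")
    if separation_mm <= 0:
        raise ValueError("separation_mm must be positive")
    if cap_scale <= 0:
        raise ValueError("cap_scale must be positive")

    sep = separation_mm * cap_scale
    sources: list[Optode] = []
    detectors: list[Optode] = []
    channels: list[Channel] = []

    for hemi, x_sign in (("left", -1.0), ("right", 1.0)):
        if n_channels_per_hemisphere == 10:
            optodes, links = _hemisphere_grid(hemi, sep, x_sign)
        else:
            optodes, links = _chain_strip(hemi, n_channels_per_hemisphere, sep, x_sign)
        cell_id = {}
        s_i = len(sources)
        d_i = len(detectors)
        for cell, (kind, pos) in sorted(optodes.items()):
            if kind == "S":
                s_i += 1
                oid = f"S{s_i}"
                sources.append(Optode(oid, pos))
            else:
                d_i += 1
                oid = f"D{d_i}"
                detectors.append(Optode(oid, pos))
            cell_id[cell] = oid
        for a, b, region in links:
            src = cell_id[a] if cell_id[a].startswith("S") else cell_id[b]
            det = cell_id[b] if cell_id[b].startswith("D") else cell_id[a]
            channels.append(Channel(src, det, sep, hemi, region))

    clusters: dict[str, list[tuple[int, int]]] = {}
    if n_channels_per_hemisphere == 10:
        for hemi in ("left", "right"):
            for region in ("anterior", "posterior"):
                idx = [k for k, ch in enumerate(channels)
                       if ch.hemisphere == hemi and ch.region == region]
                # chain of 4 channel pairs over the region's 5 channels
                chain = [(idx[k], idx[k + 1]) for k in range(4)]
                clusters[f"{hemi}_{region}"] = chain

    return Montage(sources, detectors, channels, wavelengths, clusters)


def default_target_correlation(
    montage: Montage,
    region_loading: float = 0.6,
    hemisphere_loading: float = 0.45,
) -> np.ndarray:
    """Factor-model target correlation with the structure seen at the bedside.

    Channels load on a shared factor per (hemisphere, region) block with
    weight ``region_loading`` (clustered positive correlations) and on a
    global factor with opposite signs per hemisphere with weight
    ``hemisphere_loading`` (interhemispheric anti-correlations).  Being a
    loading construction, the result is positive semidefinite by design.
    """
    n = montage.n_channels
    blocks = sorted({(ch.hemisphere, ch.region) for ch in montage.channels})
    lam = np.zeros((n, len(blocks) + 1))
    for k, ch in enumerate(montage.channels):
        lam[k, blocks.index((ch.hemisphere, ch.region))] = region_loading
        lam[k, -1] = hemisphere_loading if ch.hemisphere == "left" else -hemisphere_loading
    r = lam @ lam.T
    np.fill_diagonal(r, 1.0)
    return r
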