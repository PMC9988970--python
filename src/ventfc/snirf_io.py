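"""SNIRF container I/O and ventricle label-map volumetry.

SNIRF is the HDF5-based community standard for fNIRS data; this module reads
and writes the subset the pipeline needs (continuous-wave intensity, probe
geometry, per-channel metadata) and round-trips the montage including
hemisphere/region labels, which travel in ``metaDataTags`` as JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import h5py
import numpy as np

from .containers import RawRecording
from .montage import Channel, Montage, Optode

__all__ = ["write_snirf", "read_snirf", "LabelMap", "volume_from_labelmap", "SnirfFormatError"]


class SnirfFormatError(ValueError):
    """Malformed SNIRF container; the message names the missing element."""


def _str(ds) -> str:
    v = ds[()]
    return v.decode() if isinstance(v, bytes) else str(v)


def write_snirf(recording: RawRecording, path: str) -> None:
    """Write a two-wavelength intensity recording as SNIRF v1.0."""
    m = recording.montage
    n, n_ch, _ = recording.intensity.shape
    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data="1.0")
        nirs = f.create_group("/nirs")
        meta = nirs.create_group("metaDataTags")
        meta.create_dataset("SubjectID", data=recording.session_label or "unknown")
        meta.create_dataset("MeasurementDate", data="unknown")
        meta.create_dataset("MeasurementTime", data="unknown")
        meta.create_dataset("LengthUnit", data="mm")
        meta.create_dataset("TimeUnit", data="s")
        meta.create_dataset("FrequencyUnit", data="Hz")
        meta.create_dataset("capScale", data=float(recording.cap_scale))
        aux = {
            "hemispheres": [c.hemisphere for c in m.channels],
            "regions": [c.region for c in m.channels],
            "separations_mm": [c.separation_mm for c in m.channels],
            "clusters": {k: [list(p) for p in v] for k, v in m.clusters.items()},
        }
        meta.create_dataset("channelMetadata", data=json.dumps(aux))

        probe = nirs.create_group("probe")
        probe.create_dataset("wavelengths", data=np.asarray(m.wavelengths, dtype=float))
        probe.create_dataset("sourcePos2D", data=m.source_positions())
        probe.create_dataset("detectorPos2D", data=m.detector_positions())
        probe.create_dataset("sourceLabels",
                             data=np.array([o.id for o in m.sources], dtype="S8"))
        probe.create_dataset("detectorLabels",
                             data=np.array([o.id for o in m.detectors], dtype="S8"))

        data = nirs.create_group("data1")
        flat = recording.intensity.reshape(n, n_ch * 2)
        data.create_dataset("dataTimeSeries", data=flat)
        data.create_dataset("time", data=np.arange(n) / recording.fs)
        src_ids = [o.id for o in m.sources]
        det_ids = [o.id for o in m.detectors]
        k = 0
        for ch in m.channels:
            for wl in (1, 2):
                k += 1
                ml = data.create_group(f"measurementList{k}")
                ml.create_dataset("sourceIndex", data=src_ids.index(ch.source) + 1)
                ml.create_dataset("detectorIndex", data=det_ids.index(ch.detector) + 1)
                ml.create_dataset("wavelengthIndex", data=wl)
                ml.create_dataset("dataType", data=1)
                ml.create_dataset("dataTypeIndex", data=1)


def read_snirf(path: str) -> RawRecording:
    """Read a SNIRF file written by :func:`write_snirf` (or compatible)."""
    with h5py.File(path, "r") as f:
        if "nirs" not in f and "nirs1" not in f:
            raise SnirfFormatError("missing /nirs group")
        nirs = f["nirs"] if "nirs" in f else f["nirs1"]
        probe = nirs.get("probe")
        if probe is None or "wavelengths" not in probe:
            raise SnirfFormatError("missing /nirs/probe/wavelengths")
        wavelengths = tuple(float(w) for w in probe["wavelengths"][()])
        if len(wavelengths) != 2:
            raise SnirfFormatError("exactly two wavelengths are supported")
        data = nirs.get("data1")
        if data is None or "dataTimeSeries" not in data:
            raise SnirfFormatError("missing /nirs/data1/dataTimeSeries")
        ts = np.asarray(data["dataTimeSeries"][()], dtype=float)
        time = np.asarray(data["time"][()], dtype=float)
        if len(time) < 2:
            raise SnirfFormatError("time vector too short")
        dt = np.diff(time)
        if not np.allclose(dt, dt[0], rtol=1e-6):
            raise SnirfFormatError("non-uniform time base")
        fs = 1.0 / dt.mean()

        src_pos = np.asarray(probe["sourcePos2D"][()], dtype=float)
        det_pos = np.asarray(probe["detectorPos2D"][()], dtype=float)
        src_labels = [s.decode() if isinstance(s, bytes) else str(s)
                      for s in probe["sourceLabels"][()]]
        det_labels = [s.decode() if isinstance(s, bytes) else str(s)
                      for s in probe["detectorLabels"][()]]
        sources = [Optode(lbl, tuple(p)) for lbl, p in zip(src_labels, src_pos)]
        detectors = [Optode(lbl, tuple(p)) for lbl, p in zip(det_labels, det_pos)]

        meta = nirs.get("metaDataTags")
        aux = json.loads(_str(meta["channelMetadata"])) if (
            meta is not None and "channelMetadata" in meta) else None
        cap_scale = float(meta["capScale"][()]) if (
            meta is not None and "capScale" in meta) else 1.0
        label = _str(meta["SubjectID"]) if meta is not None and "SubjectID" in meta else ""

        # channels from measurement lists; wavelengthIndex 1 and 2 pair up
        mls = sorted((k for k in data.keys() if k.startswith("measurementList")),
                     key=lambda s: int(s[len("measurementList"):]))
        if not mls:
            raise SnirfFormatError("missing measurementList entries")
        entries = []
        for name in mls:
            g = data[name]
            entries.append((int(g["sourceIndex"][()]), int(g["detectorIndex"][()]),
                            int(g["wavelengthIndex"][()])))
        ch_keys: list[tuple[int, int]] = []
        col_of: dict[tuple[int, int, int], int] = {}
        for col, (si, di, wi) in enumerate(entries):
            col_of[(si, di, wi)] = col
            if (si, di) not in ch_keys:
                ch_keys.append((si, di))
        channels = []
        for k, (si, di) in enumerate(ch_keys):
            sp, dp = src_pos[si - 1], det_pos[di - 1]
            sep = float(np.hypot(*(np.asarray(sp) - np.asarray(dp))))
            hemi = aux["hemispheres"][k] if aux else ("left" if (sp[0] + dp[0]) / 2 < 0
                                                      else "right")
            region = aux["regions"][k] if aux else "anterior"
            if aux and "separations_mm" in aux:
                sep = float(aux["separations_mm"][k])
            channels.append(Channel(src_labels[si - 1], det_labels[di - 1], sep,
                                    hemi, region))
        clusters = ({k: [tuple(p) for p in v] for k, v in aux["clusters"].items()}
                    if aux else {})
        montage = Montage(sources, detectors, channels, wavelengths, clusters)

        n_ch = len(channels)
        inten = np.empty((ts.shape[0], n_ch, 2))
        for k, (si, di) in enumerate(ch_keys):
            for w in (1, 2):
                if (si, di, w) not in col_of:
                    raise SnirfFormatError(
                        f"channel S{si}-D{di} lacks wavelengthIndex {w}")
                inten[:, k, w - 1] = ts[:, col_of[(si, di, w)]]
        return RawRecording(inten, fs, montage, cap_scale, label)


# ---------------------------------------------------------------------------
# 3D ventricle label maps


@dataclass
class LabelMap:
    """Segmentation label map: 0 background, 1 left ventricle, 2 right."""

    labels: np.ndarray              # 3D int array
    voxel_dims_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("label map must be 3-D")
        if any(d <= 0 for d in self.voxel_dims_mm):
            raise ValueError("voxel dimensions must be positive")


def volume_from_labelmap(labelmap: LabelMap) -> tuple[float, float, float]:
    """(vv_left, vv_right, vv_total) in mL from a ventricle label map."""
    labels = labelmap.labels
    unknown = sorted(set(np.unique(labels)) - {0, 1, 2})
    if unknown:
        raise ValueError(f"unknown label values: {unknown}")
    voxel_ml = float(np.prod(labelmap.voxel_dims_mm)) / 1000.0
    left = float(np.count_nonzero(labels == 1)) * voxel_ml
    right = float(np.count_nonzero(labels == 2)) * voxel_ml
    return left, right, left + right
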