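"""End-to-end orchestration: quality -> subsample -> OD -> spline -> MBLL ->
nuisance regression -> 1 Hz -> sFC -> group maps -> slope methods -> case studies.

The pipeline order is fixed and logged; a run is fully determined by its
configuration and seed, and every output file references the configuration
hash that produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .connectivity import group_tmap, session_sfc
from .containers import ChannelValidity, RawRecording, SessionRecord
from .denoise import build_design, regress_nuisance, resample_to_1hz
from .hemodynamics import MBLLParams, intensity_to_od, od_to_hemoglobin
from .motion import detect_motion, spline_correct
from .quality import (apply_manual_exclusions, compute_windowed_quality,
                      detect_cardiac_channels, select_best_subsample)
from .slopes import (case_study_series, diversion_paired_tests, ga_posthoc,
                     slope_lme, slope_ols)
from .synthetic import PatientData, study_cohort_spec, simulate_cohort

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "preprocess_session", "run_pipeline", "records_from_patients"]

PIPELINE_ORDER = ("subsample", "od", "spline", "mbll", "nuisance", "resample",
                  "connectivity")


@dataclass
class PipelineConfig:
    seed: int = 0
    # quality / selection
    window_s: float = 5.0
    overlap: float = 0.5
    cardiac_bpm: tuple[float, float] = (90.0, 210.0)
    subsample_s: float = 150.0
    sci_threshold: float = 0.7
    psp_threshold: float = 0.1
    min_good_window_fraction: float = 0.6
    peak_factor: float = 2.0
    manual_exclusions: tuple[int, ...] = ()
    # motion
    motion_window_s: float = 1.0
    motion_std_mult: float = 13.5
    motion_amp_mult: float = 5.0
    spline_smoothing: float = 0.99
    # hemodynamics / denoise
    ppf_760: float = 0.1063
    ppf_850: float = 0.0845
    cutoff_hz: float = 0.09
    legendre_orders: tuple[int, ...] = (0, 1, 2, 3, 4)
    include_global: bool = True
    chromophore: str = "HbT"
    # group analysis
    interhemi_rule: str = "mean"
    min_patients: dict = field(default_factory=lambda: {"no_diversion": 10, "diversion": 5})
    # simulation (used when no input directory is given)
    simulate: bool = True
    groups: tuple[str, ...] = ("no_diversion", "diversion")
    n_patients: dict = field(default_factory=lambda: {"no_diversion": 23, "diversion": 7})
    duration_s: float = 408.0
    fs: float = 10.17

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        kwargs = {}
        for k, v in raw.items():
            if k not in known:
                raise ValueError(f"unknown config field: {k}")
            kwargs[k] = tuple(v) if isinstance(v, list) else v
        return cls(**kwargs)


def preprocess_session(raw: RawRecording, config: PipelineConfig | None = None):
    """Single-session preprocessing up to the 1-Hz hemoglobin series.

    Returns (hemo_1hz, validity, window, motion_segments); raises ValueError
    for sessions that fail validity (too short, too few usable channels).
    """
    config = config or PipelineConfig()
    quality = compute_windowed_quality(raw, config.window_s, config.overlap,
                                       config.cardiac_bpm)
    window = select_best_subsample(quality, raw, config.subsample_s)
    sub = raw.slice(window.start, window.end)

    validity = detect_cardiac_channels(
        sub, config.sci_threshold, config.psp_threshold,
        config.min_good_window_fraction, config.peak_factor,
        cardiac_bpm=config.cardiac_bpm)
    if config.manual_exclusions:
        validity = apply_manual_exclusions(validity, list(config.manual_exclusions))
    if validity.valid.sum() < 2:
        raise ValueError("session invalid: fewer than two valid channels")

    od = intensity_to_od(sub)
    segments_all = []
    for ch in range(od.od.shape[1]):
        for w in range(2):
            segs = detect_motion(od.od[:, ch, w], od.fs, config.motion_window_s,
                                 config.motion_std_mult, config.motion_amp_mult)
            if segs.intervals_s:
                od.od[:, ch, w] = spline_correct(od.od[:, ch, w], segs,
                                                 config.spline_smoothing)
            segments_all.append({"channel": ch, "wavelength": w,
                                 "intervals_s": segs.intervals_s})

    params = MBLLParams(ppf={760.0: config.ppf_760, 850.0: config.ppf_850},
                        cap_scale=raw.cap_scale)
    hemo = od_to_hemoglobin(od, params)
    design = build_design(hemo.n_samples, hemo.fs, config.cutoff_hz,
                          config.legendre_orders)
    clean = regress_nuisance(hemo, design, config.include_global, validity)
    hemo_1hz = resample_to_1hz(clean)
    return hemo_1hz, validity, window, segments_all


def records_from_patients(patients: list[PatientData],
                          config: PipelineConfig | None = None):
    """Run per-session preprocessing + connectivity over a simulated cohort.

    Sessions failing validity are excluded (and enumerated); patients left
    with fewer than two valid sessions are excluded entirely, mirroring the
    study's exclusion flow.
    """
    config = config or PipelineConfig()
    records: list[SessionRecord] = []
    excluded: list[dict] = []
    for pat in patients:
        pat_records = []
        for k, sess in enumerate(pat.sessions):
            label = f"{pat.patient_id}-s{k}"
            try:
                hemo_1hz, validity, window, _ = preprocess_session(sess["recording"], config)
                conn = session_sfc(hemo_1hz, validity, config.chromophore, label)
            except ValueError as err:
                excluded.append({"session": label, "reason": str(err)})
                continue
            pat_records.append(SessionRecord(
                patient_id=pat.patient_id, group=pat.group,
                ga_weeks=sess["ga_weeks"], vv_left_ml=sess["vv_left_ml"],
                vv_right_ml=sess["vv_right_ml"], vv_total_ml=sess["vv_total_ml"],
                connectivity=conn,
                diversion_event_before=sess["diversion_event_before"],
                order_index=k))
        if len(pat_records) < 2:
            excluded.append({"session": pat.patient_id,
                             "reason": "patient has fewer than two valid sessions"})
            continue
        records.extend(pat_records)
    return records, excluded


def _group_by_patient(records: list[SessionRecord]):
    out: dict[str, list] = {}
    for r in records:
        out.setdefault(r.patient_id, []).append(r.connectivity)
    return out


def analyze_records(records: list[SessionRecord], group: str,
                    config: PipelineConfig | None = None) -> dict:
    """Group-level analysis of one study arm."""
    config = config or PipelineConfig()
    min_pat = config.min_patients.get(group, 2)
    tmap = group_tmap(_group_by_patient(records), min_patients=min_pat,
                      chromophore=config.chromophore)
    low_conf = tmap.low_confidence
    results = {
        "tmap": tmap,
        "slopes": {
            "ols": slope_ols(records, config.interhemi_rule, low_conf),
            "lme": slope_lme(records, False, config.interhemi_rule, low_conf),
            "lme_ga": slope_lme(records, True, config.interhemi_rule, low_conf),
        },
        "ga_posthoc": ga_posthoc(records),
    }
    if group == "diversion":
        results["diversion"] = diversion_paired_tests(records)
        by_pat: dict[str, list[SessionRecord]] = {}
        for r in records:
            by_pat.setdefault(r.patient_id, []).append(r)
        results["case_studies"] = {pid: case_study_series(rs)
                                   for pid, rs in by_pat.items() if len(rs) >= 2}
    return results


def _write_tmap_csv(tmap, path: Path) -> None:
    montage = tmap.montage
    rows = []
    n = montage.n_channels
    for i in range(n):
        for j in range(i + 1, n):
            rows.append({"ch_i": i, "ch_j": j,
                         "hemisphere": montage.pair_hemisphere(i, j),
                         "mean_sfc": tmap.mean_sfc[i, j], "t": tmap.t[i, j],
                         "p": tmap.p[i, j], "n_patients": tmap.n_patients[i, j],
                         "low_confidence": bool(tmap.low_confidence[i, j])})
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.10g")


def run_pipeline(config: PipelineConfig, out_dir: str,
                 patients_by_group: dict[str, list[PatientData]] | None = None) -> dict:
    """Execute the full chain and write per-stage artifacts to ``out_dir``.

    When no cohort is supplied the synthetic generator provides one per
    configured group, seeded from ``config.seed``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    logger.info("pipeline order: %s (config %s)", " -> ".join(PIPELINE_ORDER), chash)

    if patients_by_group is None:
        if not config.simulate:
            raise ValueError("no input cohort supplied and simulation disabled")
        patients_by_group = {}
        for gi, group in enumerate(config.groups):
            spec = study_cohort_spec(group,
                                     n_patients=config.n_patients[group],
                                     duration_s=config.duration_s, fs=config.fs)
            patients_by_group[group] = simulate_cohort(spec, seed=config.seed + gi)

    summary: dict = {"config_hash": chash, "seed": config.seed,
                     "version": __version__, "groups": {}}
    results_all: dict = {}
    for group, patients in patients_by_group.items():
        records, excluded = records_from_patients(patients, config)
        if not records:
            summary["groups"][group] = {"error": "no valid sessions"}
            continue
        res = analyze_records(records, group, config)
        results_all[group] = {"records": records, **res}

        gdir = out / group
        gdir.mkdir(exist_ok=True)
        _write_tmap_csv(res["tmap"], gdir / "tmap.csv")
        for method, sr in res["slopes"].items():
            sr.pairs.to_csv(gdir / f"slopes_{method}_pairs.csv", index=False,
                            float_format="%.10g")
            sr.hemispheres.to_csv(gdir / f"slopes_{method}_hemispheres.csv", index=False,
                                  float_format="%.10g")
        res["ga_posthoc"].to_csv(gdir / "ga_posthoc.csv", index=False,
                                 float_format="%.10g")
        if "diversion" in res:
            res["diversion"]["deltas"].to_csv(gdir / "diversion_deltas.csv", index=False,
                                              float_format="%.10g")
            res["diversion"]["tests"].to_csv(gdir / "diversion_tests.csv", index=False,
                                             float_format="%.10g")
        if "case_studies" in res:
            for pid, cs in res["case_studies"].items():
                cs["table"].to_csv(gdir / f"case_{pid}.csv", index=False,
                                   float_format="%.10g")
        sess_rows = [{
            "patient_id": r.patient_id, "session_idx": r.order_index,
            "ga_weeks": r.ga_weeks, "vv_left_ml": r.vv_left_ml,
            "vv_right_ml": r.vv_right_ml, "vv_total_ml": r.vv_total_ml,
            "diversion_before": r.diversion_event_before, "group": r.group,
        } for r in records]
        pd.DataFrame(sess_rows).to_csv(gdir / "sessions.csv", index=False,
                                       float_format="%.10g")
        with open(gdir / "exclusions.json", "w") as fh:
            json.dump(excluded, fh, indent=2)
        summary["groups"][group] = {
            "n_patients": len({r.patient_id for r in records}),
            "n_sessions": len(records),
            "n_excluded": len(excluded),
        }

    with open(out / "provenance.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    config.save(str(out / "config.yaml"))
    return results_all
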