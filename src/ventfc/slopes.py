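"""Relating |sFC| to ventricle volume: three incremental slope estimators.

The connectivity magnitude |sFC| of each channel pair is regressed on the
ventricle volume (VV) of the pair's hemisphere — interhemispheric pairs use a
configurable combination (default: mean of left and right).  Three estimators
of the |sFC|/VV slope are provided, in increasing sophistication:

1. ``ols_per_patient``: simple linear regression per patient, then a
   one-sample t-test of the patient slopes against zero per pair;
2. ``lme``: linear mixed-effects model |sFC| ~ 1 + VV with a per-patient
   random effect (random VV slope attempted first, intercept-only fallback);
3. ``lme_ga``: as (2) plus a gestational-age fixed effect, separating the
   VV association from shared maturation trends.

Hemisphere-level trends pool the group-level slopes of all within-hemisphere
pairs into a one-sample t-test per hemisphere and method.  Pre/post
CSF-diversion paired comparisons and per-patient longitudinal case-study
tables complete the longitudinal analysis.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .connectivity import cluster_summary
from .containers import SessionRecord
from .montage import Montage

logger = logging.getLogger(__name__)

__all__ = [
    "SlopeResult",
    "abs_sfc",
    "pair_vv",
    "slope_ols",
    "slope_lme",
    "ga_posthoc",
    "diversion_paired_tests",
    "case_study_series",
    "valid_pairs",
]


def abs_sfc(values: np.ndarray) -> np.ndarray:
    """Elementwise |sFC|; missing (NaN) stays missing."""
    return np.abs(values)


def valid_pairs(montage: Montage, hemisphere: str | None = None,
                include_inter: bool = True) -> list[tuple[int, int]]:
    """Upper-triangle channel pairs, optionally restricted by hemisphere."""
    pairs = []
    n = montage.n_channels
    for i in range(n):
        for j in range(i + 1, n):
            hemi = montage.pair_hemisphere(i, j)
            if hemisphere is not None and hemi != hemisphere:
                continue
            if not include_inter and hemi == "inter":
                continue
            pairs.append((i, j))
    return pairs


def pair_vv(records: list[SessionRecord], pair: tuple[int, int],
            interhemi_rule: str = "mean") -> pd.DataFrame:
    """Per-session (|sFC|, VV, GA) tuples for one channel pair.

    Sessions missing the pair's sFC or VV are dropped (logged at debug level).
    """
    i, j = pair
    rows = []
    for rec in records:
        sfc = rec.connectivity.values[i, j]
        if np.isnan(sfc):
            logger.debug("session %s lacks sFC for pair (%d,%d)", rec.patient_id, i, j)
            continue
        vv = rec.vv_for_pair(i, j, interhemi_rule)
        if not np.isfinite(vv):
            logger.debug("session %s lacks VV", rec.patient_id)
            continue
        rows.append({"patient_id": rec.patient_id, "abs_sfc": abs(sfc), "vv_ml": vv,
                     "ga_weeks": rec.ga_weeks})
    return pd.DataFrame(rows, columns=["patient_id", "abs_sfc", "vv_ml", "ga_weeks"])


@dataclass
class SlopeResult:
    method: str
    # one row per channel pair: ch_i, ch_j, hemisphere, slope, se, t, p,
    # n_patients, n_sessions
    pairs: pd.DataFrame
    # one row per hemisphere: hemisphere, slope (mean of pair slopes), t, p, n_pairs
    hemispheres: pd.DataFrame
    interhemi_rule: str = "mean"
    notes: dict = field(default_factory=dict)


def _hemisphere_table(pair_df: pd.DataFrame) -> pd.DataFrame:
    """One-sample t-test over within-hemisphere pair slopes, per hemisphere."""
    rows = []
    for hemi in ("left", "right"):
        sl = pair_df.loc[(pair_df.hemisphere == hemi) & pair_df.slope.notna(), "slope"].to_numpy()
        if len(sl) >= 2:
            t, p = stats.ttest_1samp(sl, 0.0)
        elif len(sl) == 1:
            t, p = np.nan, np.nan
        else:
            t, p = np.nan, np.nan
        rows.append({"hemisphere": hemi, "slope": sl.mean() if len(sl) else np.nan,
                     "t": float(t), "p": float(p), "n_pairs": len(sl)})
    return pd.DataFrame(rows)


def _montage_of(records: list[SessionRecord]) -> Montage:
    return records[0].connectivity.montage


def slope_ols(
    records: list[SessionRecord],
    interhemi_rule: str = "mean",
    low_confidence: np.ndarray | None = None,
    include_inter: bool = True,
) -> SlopeResult:
    """Per-patient simple linear regression of |sFC| on VV.

    Per pair: each contributing patient's OLS slope (patients need >= 2
    sessions with non-constant VV), then a one-sample t-test of patient
    slopes against zero.  The pair's group-level slope is the mean of its
    patient slopes.
    """
    montage = _montage_of(records)
    rows = []
    for (i, j) in valid_pairs(montage, include_inter=include_inter):
        if low_confidence is not None and low_confidence[i, j]:
            continue
        df = pair_vv(records, (i, j), interhemi_rule)
        slopes = []
        n_sessions = 0
        for pid, g in df.groupby("patient_id"):
            if len(g) < 2 or g.vv_ml.nunique() < 2:
                if len(g) >= 2:
                    logger.warning("patient %s has constant VV for pair (%d,%d); dropped",
                                   pid, i, j)
                continue
            b = np.polyfit(g.vv_ml.to_numpy(), g.abs_sfc.to_numpy(), 1)[0]
            slopes.append(b)
            n_sessions += len(g)
        slopes = np.asarray(slopes)
        if len(slopes) >= 2:
            t, p = stats.ttest_1samp(slopes, 0.0)
            se = slopes.std(ddof=1) / np.sqrt(len(slopes))
        else:
            t = p = se = np.nan
        rows.append({"ch_i": i, "ch_j": j, "hemisphere": montage.pair_hemisphere(i, j),
                     "slope": slopes.mean() if len(slopes) else np.nan, "se": se,
                     "t": float(t), "p": float(p),
                     "n_patients": len(slopes), "n_sessions": n_sessions})
    pair_df = pd.DataFrame(rows)
    return SlopeResult("ols_per_patient", pair_df, _hemisphere_table(pair_df), interhemi_rule)


def _fit_mixedlm(df: pd.DataFrame, include_ga: bool):
    """MixedLM |sFC| ~ 1 + VV (+ GA), random VV slope with intercept fallback."""
    import statsmodels.formula.api as smf

    formula = "abs_sfc ~ vv_ml" + (" + ga_weeks" if include_ga else "")
    last_err = None
    for re_formula in ("~vv_ml", None):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = smf.mixedlm(formula, df, groups=df["patient_id"],
                                    re_formula=re_formula)
                fit = model.fit(reml=True, method="lbfgs", maxiter=200)
            if np.isfinite(fit.bse.get("vv_ml", np.nan)):
                return fit, ("random_slope" if re_formula else "random_intercept")
        except Exception as err:  # noqa: BLE001 - non-convergence, singular fits
            last_err = err
            continue
    logger.warning("mixed model failed to converge: %s", last_err)
    return None, "failed"


def slope_lme(
    records: list[SessionRecord],
    include_ga: bool = False,
    interhemi_rule: str = "mean",
    low_confidence: np.ndarray | None = None,
    include_inter: bool = True,
) -> SlopeResult:
    """Linear mixed-effects slope per pair: |sFC| ~ 1 + VV (+ GA), patient
    random effects.  Reports the fixed-effect VV slope with Wald t / p."""
    montage = _montage_of(records)
    if len({r.patient_id for r in records}) < 2:
        raise ValueError("mixed-effects slope needs at least two patients")
    rows = []
    notes = {}
    for (i, j) in valid_pairs(montage, include_inter=include_inter):
        if low_confidence is not None and low_confidence[i, j]:
            continue
        df = pair_vv(records, (i, j), interhemi_rule)
        n_pat = df.patient_id.nunique()
        if n_pat < 2 or len(df) < 6:
            rows.append({"ch_i": i, "ch_j": j,
                         "hemisphere": montage.pair_hemisphere(i, j),
                         "slope": np.nan, "se": np.nan, "t": np.nan, "p": np.nan,
                         "n_patients": n_pat, "n_sessions": len(df)})
            continue
        fit, status = _fit_mixedlm(df, include_ga)
        if fit is None:
            slope = se = t = p = np.nan
        else:
            slope = fit.params["vv_ml"]
            se = fit.bse["vv_ml"]
            t = slope / se if se > 0 else np.nan
            p = fit.pvalues["vv_ml"]
        notes[(i, j)] = status
        rows.append({"ch_i": i, "ch_j": j, "hemisphere": montage.pair_hemisphere(i, j),
                     "slope": slope, "se": se, "t": t, "p": p,
                     "n_patients": n_pat, "n_sessions": len(df)})
    pair_df = pd.DataFrame(rows)
    method = "lme_ga" if include_ga else "lme"
    return SlopeResult(method, pair_df, _hemisphere_table(pair_df), interhemi_rule,
                       {"re_structure": notes})


def ga_posthoc(records: list[SessionRecord]) -> pd.DataFrame:
    """Post-hoc trends across gestational age: VV ~ GA and mean |sFC| ~ GA,
    each with a per-patient random intercept."""
    import statsmodels.formula.api as smf

    rows = []
    df = pd.DataFrame({
        "patient_id": [r.patient_id for r in records],
        "ga_weeks": [r.ga_weeks for r in records],
        "vv_total_ml": [r.vv_total_ml for r in records],
        "mean_abs_sfc": [float(np.nanmean(np.abs(_offdiag(r.connectivity.values))))
                         for r in records],
    })
    for outcome in ("vv_total_ml", "mean_abs_sfc"):
        if df[outcome].nunique() == 1:
            # constant outcome: the GA trend is identically zero
            rows.append({"outcome": outcome, "ga_slope": 0.0, "se": 0.0,
                         "p": 1.0, "n_sessions": len(df)})
            continue
        fit = None
        for method in ("lbfgs", "powell"):
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    fit = smf.mixedlm(f"{outcome} ~ ga_weeks", df,
                                      groups=df["patient_id"]).fit(
                                          reml=True, method=method, maxiter=200)
                if np.isfinite(fit.bse.get("ga_weeks", np.nan)):
                    break
                fit = None
            except (np.linalg.LinAlgError, ValueError) as err:
                logger.warning("GA post-hoc fit for %s failed (%s): %s",
                               outcome, method, err)
                fit = None
        if fit is None:
            rows.append({"outcome": outcome, "ga_slope": np.nan, "se": np.nan,
                         "p": np.nan, "n_sessions": len(df)})
        else:
            rows.append({"outcome": outcome, "ga_slope": fit.params["ga_weeks"],
                         "se": fit.bse["ga_weeks"], "p": fit.pvalues["ga_weeks"],
                         "n_sessions": len(df)})
    return pd.DataFrame(rows)


def _offdiag(m: np.ndarray) -> np.ndarray:
    mask = ~np.eye(m.shape[0], dtype=bool)
    return m[mask]


def diversion_paired_tests(
    records: list[SessionRecord],
    match_window_weeks: float = 0.05,
    clusters: dict | None = None,
) -> dict:
    """Pre/post CSF-diversion paired comparisons.

    For each diversion event (a session flagged ``diversion_event_before``),
    the pre session is the nearest earlier session within
    ``match_window_weeks`` (default ~ same day); the event session itself is
    the post.  Reports per-event deltas of VV (left/right/total) and of the
    four cluster |sFC| summaries, plus group-level paired t-tests.
    """
    by_patient: dict[str, list[SessionRecord]] = {}
    for r in records:
        by_patient.setdefault(r.patient_id, []).append(r)
    deltas = []
    for pid, sess in by_patient.items():
        sess = sorted(sess, key=lambda r: r.ga_weeks)
        for k, post in enumerate(sess):
            if not post.diversion_event_before:
                continue
            if k == 0:
                logger.info("event at first session of %s has no pre session; skipped", pid)
                continue
            pre = sess[k - 1]
            if post.ga_weeks - pre.ga_weeks > match_window_weeks:
                logger.info("no same-day pre session for an event of %s; skipped", pid)
                continue
            row = {
                "patient_id": pid,
                "d_vv_left_ml": post.vv_left_ml - pre.vv_left_ml,
                "d_vv_right_ml": post.vv_right_ml - pre.vv_right_ml,
                "d_vv_total_ml": post.vv_total_ml - pre.vv_total_ml,
            }
            cl_pre = cluster_summary(pre.connectivity, clusters)
            cl_post = cluster_summary(post.connectivity, clusters)
            for name in cl_pre:
                row[f"d_abs_sfc_{name}"] = cl_post[name] - cl_pre[name]
            deltas.append(row)
    delta_df = pd.DataFrame(deltas)
    tests = []
    if len(delta_df):
        for col in [c for c in delta_df.columns if c != "patient_id"]:
            vals = delta_df[col].dropna().to_numpy()
            if len(vals) >= 2:
                t, p = stats.ttest_1samp(vals, 0.0)
            else:
                t, p = np.nan, np.nan
            tests.append({"measure": col, "mean": vals.mean() if len(vals) else np.nan,
                          "sd": vals.std(ddof=1) if len(vals) > 1 else np.nan,
                          "t": float(t), "p": float(p), "n": len(vals)})
    return {"deltas": delta_df, "tests": pd.DataFrame(tests)}


def case_study_series(records: list[SessionRecord], clusters: dict | None = None) -> dict:
    """Longitudinal tidy table for one patient: GA, VV left/right, four
    cluster |sFC| summaries, and diversion-event GA markers."""
    if len(records) < 2:
        raise ValueError("case study needs at least two sessions")
    if len({r.patient_id for r in records}) != 1:
        raise ValueError("case_study_series expects a single patient's records")
    records = sorted(records, key=lambda r: r.ga_weeks)
    rows = []
    events = []
    for r in records:
        row = {"ga_weeks": r.ga_weeks, "vv_left_ml": r.vv_left_ml,
               "vv_right_ml": r.vv_right_ml}
        row.update({f"abs_sfc_{k}": v
                    for k, v in cluster_summary(r.connectivity, clusters).items()})
        rows.append(row)
        if r.diversion_event_before:
            events.append(r.ga_weeks)
    return {"table": pd.DataFrame(rows), "event_ga_weeks": events,
            "patient_id": records[0].patient_id}
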