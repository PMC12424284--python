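"""End-to-end orchestration: recordings -> feature table -> statistics.

These helpers are what the CLI subcommands and the example scripts call;
they keep the stage order honest (extract, log-transform, harmonize,
then infer).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dynamics import (MSEParams, SampEnParams, compute_dynamics,
                       harmonize_sites, log_transform_features)
from .inference import (PLSCResult, efficiency_block, plsc_bootstrap,
                        plsc_fit, plsc_permutation, wm_efficiency)
from .io import (FEATURE_COLUMNS, AnxietyRecord, BehaviorTrial,
                 BreathRecording, FeatureTable, make_feature_table)
from .preprocess import process_recording

logger = logging.getLogger(__name__)


def extract_feature_table(
    recordings: list[BreathRecording],
    low: float = 0.05,
    high: float = 3.0,
    sampen_params: SampEnParams | None = None,
    mse_params: MSEParams | None = None,
    match_length: bool = False,
) -> FeatureTable:
    """16 dynamics features per recording, stacked into a raw table.

    With ``match_length`` the task breath series is truncated to the
    subject's rest breath count before metrics, removing the length bias
    of the entropy estimators at the cost of discarding task breaths.
    """
    series_by_key = {}
    for rec in recordings:
        key = (rec.subject_id, rec.condition)
        try:
            series_by_key[key] = (rec, process_recording(rec, low, high))
        except ValueError as err:
            logger.warning("%s/%s: %s; row excluded", *key, err)
            series_by_key[key] = (rec, None)
    rows = []
    for (subj, cond), (rec, series) in series_by_key.items():
        feats = None
        if series is not None:
            if match_length and cond == "task" and (subj, "rest") in series_by_key:
                rest_series = series_by_key[(subj, "rest")][1]
                n_rest = rest_series.n_breaths if rest_series is not None else None
                if n_rest and series.n_breaths > n_rest:
                    from .preprocess import BreathSeries
                    series = BreathSeries(
                        rate=series.rate[:n_rest], amplitude=series.amplitude[:n_rest],
                        breath_times=series.breath_times[:n_rest],
                        n_pruned=series.n_pruned,
                    )
            try:
                feats = compute_dynamics(series, sampen_params, mse_params)
            except ValueError as err:
                logger.warning("%s/%s: %s; row excluded", subj, cond, err)
        if feats is None:
            # undefined series or metric: keep the row as all-NaN so the
            # listwise missing-data policy drops (and logs) it downstream
            feats = {c: float("nan") for c in FEATURE_COLUMNS}
        rows.append({"subject": subj, "condition": cond, "site": rec.site_id, **feats})
    return make_feature_table(rows)


def mse_profile_table(
    recordings: list[BreathRecording],
    mse_params: MSEParams | None = None,
    series: str = "rate",
    low: float = 0.05,
    high: float = 3.0,
) -> pd.DataFrame:
    """Per-scale multiscale-entropy profiles in long format.

    Columns: subject, condition, scale, sampen — one row per
    coarse-graining scale of the chosen per-breath series.
    """
    from .dynamics import multiscale_entropy

    rows = []
    for rec in recordings:
        s = process_recording(rec, low, high)
        x = s.rate if series == "rate" else s.amplitude
        prof = multiscale_entropy(x, mse_params)
        for tau, value in zip(prof.scales, prof.sampen):
            rows.append({"subject": rec.subject_id, "condition": rec.condition,
                         "scale": int(tau), "sampen": float(value)})
    return pd.DataFrame(rows)


def prepare_features(table: FeatureTable, harmonize: bool = True) -> FeatureTable:
    """raw -> logged (-> harmonized) analysis ladder."""
    logged = log_transform_features(table)
    return harmonize_sites(logged) if harmonize else logged


@dataclass
class PLSCAnalysis:
    result: PLSCResult
    x_names: list[str]
    y_names: list[str]


def anxiety_plsc(
    features: FeatureTable,
    anxiety: list[AnxietyRecord],
    y_block: str = "items",
    n_perm: int = 1000,
    n_boot: int = 1000,
    seed: int | None = None,
) -> PLSCAnalysis:
    """PLSC of resting breathing dynamics against Beck-anxiety scores.

    ``y_block='items'`` uses the 21 item scores (the default: a
    single-column Y admits only one latent variable); ``'total'`` uses
    the summed score. Items constant across the cohort are dropped.
    """
    rest = features.select("rest").drop_incomplete()
    subjects = list(rest.df["subject"])
    by_subj = {a.subject_id: a for a in anxiety}
    missing = [s for s in subjects if s not in by_subj]
    if missing:
        raise ValueError(f"subjects without anxiety scores: {missing}")
    X = rest.features.to_numpy(dtype=float)
    if y_block == "items":
        Y = np.array([by_subj[s].bai_items for s in subjects], dtype=float)
        y_names = [f"item_{j + 1}" for j in range(21)]
        keep = Y.std(axis=0) > 0
        if not keep.all():
            logger.info("dropping %d constant BAI items", int((~keep).sum()))
        Y = Y[:, keep]
        y_names = [nm for nm, k in zip(y_names, keep) if k]
    elif y_block == "total":
        Y = np.array([[by_subj[s].bai_total] for s in subjects], dtype=float)
        y_names = ["bai_total"]
    else:
        raise ValueError(f"unknown y_block {y_block!r}")
    res = plsc_fit(X, Y)
    plsc_permutation(X, Y, res, n_perm=n_perm, seed=seed)
    plsc_bootstrap(X, Y, res, n_boot=n_boot, seed=None if seed is None else seed + 1)
    return PLSCAnalysis(res, list(FEATURE_COLUMNS), y_names)


def efficiency_plsc(
    features: FeatureTable,
    behavior: list[BehaviorTrial],
    n_perm: int = 1000,
    n_boot: int = 1000,
    seed: int | None = None,
) -> PLSCAnalysis:
    """PLSC of task breathing dynamics against N-back efficiency.

    The Y block holds one efficiency column per load (1-, 2-, 3-back),
    speeds pooled.
    """
    task = features.select("task").drop_incomplete()
    eff = efficiency_block(wm_efficiency(behavior))
    subjects = [s for s in task.df["subject"] if s in eff.index]
    if len(subjects) < len(task.df):
        logger.info("dropping %d subjects without behavior", len(task.df) - len(subjects))
    task_df = task.df[task.df["subject"].isin(subjects)]
    X = task_df[list(FEATURE_COLUMNS)].to_numpy(dtype=float)
    Y = eff.loc[subjects].to_numpy(dtype=float)
    res = plsc_fit(X, Y)
    plsc_permutation(X, Y, res, n_perm=n_perm, seed=seed)
    plsc_bootstrap(X, Y, res, n_boot=n_boot, seed=None if seed is None else seed + 1)
    return PLSCAnalysis(res, list(FEATURE_COLUMNS), list(eff.columns))


def plsc_salience_frame(analysis: PLSCAnalysis) -> pd.DataFrame:
    """Long-format salience table with CIs and reliability flags."""
    res = analysis.result
    rows = []
    for block, names, sal, ci, rel in (
        ("X", analysis.x_names, res.x_saliences, res.x_ci, res.x_reliable),
        ("Y", analysis.y_names, res.y_saliences, res.y_ci, res.y_reliable),
    ):
        for j in range(sal.shape[1]):
            for i, nm in enumerate(names):
                rows.append({
                    "block": block, "variable": nm, "lv": j + 1,
                    "salience": sal[i, j],
                    "ci_lo": np.nan if ci is None else ci[i, j, 0],
                    "ci_hi": np.nan if ci is None else ci[i, j, 1],
                    "reliable": False if rel is None else bool(rel[i, j]),
                })
    return pd.DataFrame(rows)


def plsc_summary_frame(analysis: PLSCAnalysis) -> pd.DataFrame:
    res = analysis.result
    return pd.DataFrame({
        "lv": np.arange(res.singular_values.size) + 1,
        "singular_value": res.singular_values,
        "covexp": res.covexp,
        "perm_p": res.perm_p if res.perm_p is not None else np.nan,
    })
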