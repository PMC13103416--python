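"""Comparison of budbreak predictions with observations and the associated
experiments: fit statistics, binary damage validation, chilling phase-shift
sensitivity, and segmented MDST sensitivity slopes.

Residuals are predicted minus observed day of year: negative = early
prediction.  r-squared defaults to the squared Pearson correlation between
predicted and observed (``r2_method='pearson'``); ``'ss'`` gives
1 - SSE/SST about the 1:1 line instead.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .budbreak import BudbreakPrediction, ObservationConvention


@dataclass(frozen=True)
class ObservationRecord:
    site_id: str
    cultivar: str
    season_year: int
    observed_doy: int
    convention: ObservationConvention = ObservationConvention.BBCH07_50


def read_observations(path) -> list[ObservationRecord]:
    """Observations CSV: site_id, cultivar, season_year, observed_doy,
    convention."""
    table = pd.read_csv(path)
    out = []
    for _, row in table.iterrows():
        out.append(
            ObservationRecord(
                site_id=str(row["site_id"]),
                cultivar=str(row["cultivar"]),
                season_year=int(row["season_year"]),
                observed_doy=int(row["observed_doy"]),
                convention=ObservationConvention(row["convention"])
                if "convention" in table.columns
                else ObservationConvention.BBCH07_50,
            )
        )
    return out


def residuals(predicted_doy, observed_doy) -> np.ndarray:
    """predicted - observed, in days."""
    return np.asarray(predicted_doy, float) - np.asarray(observed_doy, float)


@dataclass(frozen=True)
class FitStats:
    n: int
    rmse_days: float
    bias_days: float
    r2: float | None


def fit_stats(predicted_doy, observed_doy, r2_method: str = "pearson"
              ) -> FitStats:
    """Bias (mean residual), RMSE and r-squared of predictions."""
    pred = np.asarray(predicted_doy, dtype=float)
    obs = np.asarray(observed_doy, dtype=float)
    if len(pred) != len(obs):
        raise ValueError("predicted/observed length mismatch")
    if len(pred) == 0:
        raise ValueError("fit_stats requires at least one pair")
    res = residuals(pred, obs)
    bias = float(res.mean())
    rmse = float(np.sqrt((res ** 2).mean()))
    r2 = None
    if len(pred) >= 2:
        if r2_method == "pearson":
            if np.std(pred) == 0.0 or np.std(obs) == 0.0:
                r2 = 1.0 if np.allclose(pred, obs) else None
            else:
                r2 = float(np.corrcoef(pred, obs)[0, 1] ** 2)
        elif r2_method == "ss":
            sst = float(((obs - obs.mean()) ** 2).sum())
            r2 = 1.0 - float((res ** 2).sum()) / sst if sst > 0 else None
        else:
            raise ValueError(f"unknown r2_method {r2_method!r}")
    return FitStats(n=len(pred), rmse_days=rmse, bias_days=bias, r2=r2)


@dataclass(frozen=True)
class DamageConfusion:
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    precision: float
    accuracy: float


def damage_confusion(predicted, recorded) -> DamageConfusion:
    """2x2 confusion of per-season binary damage predictions vs records."""
    pred = np.asarray(predicted, dtype=int)
    rec = np.asarray(recorded, dtype=int)
    if len(pred) != len(rec):
        raise ValueError("predicted/recorded length mismatch")
    tp = int(((pred == 1) & (rec == 1)).sum())
    fp = int(((pred == 1) & (rec == 0)).sum())
    tn = int(((pred == 0) & (rec == 0)).sum())
    fn = int(((pred == 0) & (rec == 1)).sum())

    def ratio(num, den, name):
        if den == 0:
            warnings.warn(f"{name} undefined (zero denominator)",
                          stacklevel=3)
            return math.nan
        return num / den

    return DamageConfusion(
        tp=tp, fp=fp, tn=tn, fn=fn,
        sensitivity=ratio(tp, tp + fn, "sensitivity"),
        specificity=ratio(tn, tn + fp, "specificity"),
        precision=ratio(tp, tp + fp, "precision"),
        accuracy=ratio(tp + tn, tp + fp + tn + fn, "accuracy"),
    )


def match_predictions(predictions: list[BudbreakPrediction],
                      observations: list[ObservationRecord]):
    """Pair predictions with observations on (site, cultivar, season).

    Returns (predicted_doys, observed_doys, n_failed, n_unmatched).
    """
    index = {
        (p.site_id, p.cultivar, p.season_year): p for p in predictions
    }
    pred_doy, obs_doy = [], []
    n_failed = n_unmatched = 0
    for obs in observations:
        pred = index.get((obs.site_id, obs.cultivar, obs.season_year))
        if pred is None:
            n_unmatched += 1
            continue
        if pred.failed:
            n_failed += 1
            continue
        pred_doy.append(pred.doy)
        obs_doy.append(obs.observed_doy)
    return np.array(pred_doy, float), np.array(obs_doy, float), n_failed, n_unmatched


def phase_shift_experiment(
    seasons,
    observations: list[ObservationRecord],
    cultivars,
    shifts=range(-6, 7),
    convention: ObservationConvention = ObservationConvention.BBCH07_50,
    floor=None,
    table=None,
) -> pd.DataFrame:
    """Re-predict budbreak under chill phase shifts and tabulate RMSE.

    ``seasons`` is an iterable of DormantSeason.  Chill is recomputed per
    shift; nothing else changes.  Returns a frame with one row per shift:
    columns ``shift_c``, ``rmse_days``, ``n``.
    """
    from .chill import accumulate_chill
    from .damage import simulate_with_damage
    from .weather import season_hourly_temperatures

    seasons = list(seasons)
    hourly = [season_hourly_temperatures(s) for s in seasons]
    rows = []
    for shift in shifts:
        predictions = []
        for season, hrs in zip(seasons, hourly):
            chill = accumulate_chill(season, shift_c=float(shift),
                                     hourly_temp_c=hrs)
            for cultivar in cultivars:
                run = simulate_with_damage(
                    cultivar, season, chill, convention=convention,
                    floor=floor, table=table,
                )
                predictions.append(run.fdc)
        pred, obs, _, _ = match_predictions(predictions, observations)
        rmse = (fit_stats(pred, obs).rmse_days if len(pred) else math.nan)
        rows.append({"shift_c": float(shift), "rmse_days": rmse,
                     "n": len(pred)})
    return pd.DataFrame(rows)


DEFAULT_SEGMENTS = ((-1.0, 3.0), (3.0, 10.0), (10.0, 12.0))


def sensitivity_slopes(mdst_c, doy, segments=DEFAULT_SEGMENTS) -> dict:
    """Ordinary-least-squares slope of budbreak DOY on MDST, per segment
    and pooled.

    Segment intervals are (lo, hi], except the first which includes its
    lower bound.  Segments with fewer than 3 points are flagged
    ``insufficient`` and carry no slope.
    """
    mdst = np.asarray(mdst_c, dtype=float)
    doy = np.asarray(doy, dtype=float)
    if len(mdst) != len(doy):
        raise ValueError("mdst/doy length mismatch")

    def ols_slope(x, y):
        return float(np.polyfit(x, y, 1)[0])

    out: dict = {"segments": []}
    for i, (lo, hi) in enumerate(segments):
        mask = (mdst > lo) & (mdst <= hi)
        if i == 0:
            mask |= mdst == lo
        entry: dict = {"lo_c": lo, "hi_c": hi, "n": int(mask.sum())}
        if mask.sum() >= 3:
            entry["slope_days_per_c"] = ols_slope(mdst[mask], doy[mask])
        else:
            entry["status"] = "insufficient"
        out["segments"].append(entry)
    if len(mdst) >= 3:
        out["overall_slope_days_per_c"] = ols_slope(mdst, doy)
    out["n"] = len(mdst)
    return out
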