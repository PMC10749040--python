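"""Cross-race dataset construction via marathon calibration.

Each event is calibrated against the marathon with a no-intercept linear fit
on athletes who ran both, refit after discarding the pairs with the largest
relative residuals.  The correlation of the retained pairs ("marathon
correlation") ranks events; each athlete keeps exactly one record, taken from
their highest-ranked event (always the marathon when they ran it).  Records
whose predicted marathon time exceeds a cutoff (default 11 h) are discarded.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InsufficientDataError
from .names import normalize_name

__all__ = [
    "BuildSummary",
    "EventCalibration",
    "build_cross_race",
    "calibrate_event",
    "fit_no_intercept",
    "predict_marathon_time",
]

logger = logging.getLogger(__name__)

MAX_PREDICTED_SECONDS = 39_600.0  # 11 hours, the marathon cut-off


@dataclass(frozen=True)
class EventCalibration:
    """No-intercept calibration of one event against the marathon."""

    event: str
    slope: float
    marathon_correlation: float
    n_shared: int
    n_trimmed: int
    trimmed_names: tuple[str, ...] = ()


@dataclass
class BuildSummary:
    """Counts mirroring the three roles of the dataset-construction table."""

    n_total_results: int
    n_outliers_discarded: int
    n_unique_rows: int
    n_uncalibrated_dropped: int = 0
    calibrations: dict[str, EventCalibration] = field(default_factory=dict)

    def to_text(self) -> str:
        return (
            f"Total no of race results in full data set\t{self.n_total_results}\n"
            f"No of outliers discarded\t{self.n_outliers_discarded}\n"
            f"No of unique rows in cross-race data set\t{self.n_unique_rows}\n"
        )


def fit_no_intercept(pairs) -> float:
    """Least-squares slope through the origin: sum(xy) / sum(x^2)."""
    arr = np.asarray(pairs, dtype=float)
    if arr.size == 0:
        raise InsufficientDataError("no pairs to fit")
    x, y = arr[:, 0], arr[:, 1]
    denom = float(np.dot(x, x))
    if denom == 0.0:
        raise InsufficientDataError("degenerate pairs (all event times zero)")
    return float(np.dot(x, y) / denom)


def calibrate_event(
    pairs,
    keep_frac: float = 0.98,
    event: str = "",
    names=None,
    ratio_denominator: str = "marathon",
    log_scale_correlation: bool = False,
) -> EventCalibration:
    """Two-pass no-intercept calibration with relative-residual trimming.

    A first slope is fit on all pairs; each pair's trimming ratio is
    ``|marathon_time - slope * event_time|`` divided by the marathon time (or
    the event time when ``ratio_denominator='event'``).  The ``ceil(keep_frac
    * n)`` pairs with the lowest ratios are retained; the slope and the
    Pearson correlation are recomputed on the retained pairs.
    """
    if not 0.0 < keep_frac <= 1.0:
        raise ValueError("keep_frac must be in (0, 1]")
    if ratio_denominator not in ("marathon", "event"):
        raise ValueError("ratio_denominator must be 'marathon' or 'event'")
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise InsufficientDataError("need at least 2 shared pairs to calibrate")
    n = arr.shape[0]
    x, y = arr[:, 0], arr[:, 1]

    slope0 = fit_no_intercept(arr)
    denom = y if ratio_denominator == "marathon" else x
    ratio = np.abs(y - slope0 * x) / denom
    n_keep = math.ceil(keep_frac * n)
    order = np.argsort(ratio, kind="stable")
    kept_idx = np.sort(order[:n_keep])
    trimmed_idx = np.sort(order[n_keep:])

    xk, yk = x[kept_idx], y[kept_idx]
    slope = fit_no_intercept(np.column_stack([xk, yk]))
    if log_scale_correlation:
        corr_x, corr_y = np.log(xk), np.log(yk)
    else:
        corr_x, corr_y = xk, yk
    if len(xk) < 2 or np.ptp(corr_x) == 0 or np.ptp(corr_y) == 0:
        corr = float("nan")
    else:
        corr = float(stats.pearsonr(corr_x, corr_y).statistic)

    trimmed_names: tuple[str, ...] = ()
    if names is not None:
        names = list(names)
        trimmed_names = tuple(names[i] for i in trimmed_idx)
    return EventCalibration(
        event=event,
        slope=slope,
        marathon_correlation=corr,
        n_shared=n,
        n_trimmed=n - n_keep,
        trimmed_names=trimmed_names,
    )


def predict_marathon_time(calibration: EventCalibration, event_time: float) -> float:
    """Predicted marathon seconds for a time in the calibrated event."""
    if event_time <= 0:
        raise ValueError("event_time must be positive")
    return calibration.slope * event_time


def build_cross_race(
    results: pd.DataFrame,
    keep_frac: float = 0.98,
    max_predicted_seconds: float = MAX_PREDICTED_SECONDS,
    marathon_event: str = "marathon",
    ratio_denominator: str = "marathon",
) -> tuple[pd.DataFrame, BuildSummary]:
    """Build the one-record-per-athlete cross-race dataset.

    Athletes are identified by normalized full name (same name = same person).
    Every event is calibrated against the marathon; each athlete's record is
    taken from the marathon when they ran it, otherwise from their event with
    the highest marathon correlation (ties: larger shared sample, then
    lexicographic event id).  Events sharing fewer than two runners with the
    marathon cannot be calibrated and are ineligible.  Selected records whose
    predicted marathon time exceeds ``max_predicted_seconds`` are discarded.
    """
    df = results.copy()
    df["_norm"] = df["name"].map(normalize_name)
    if (df["time_seconds"] <= 0).any():
        raise ValueError("race times must be positive")

    marathon_rows = df[df["event"] == marathon_event]
    if marathon_rows.empty:
        raise InsufficientDataError("no marathon results: cannot calibrate")
    # best (lowest) marathon time per athlete for pairing
    mara_time = marathon_rows.groupby("_norm")["time_seconds"].min()

    calibrations: dict[str, EventCalibration] = {
        marathon_event: EventCalibration(
            event=marathon_event,
            slope=1.0,
            marathon_correlation=1.0,
            n_shared=int(mara_time.size),
            n_trimmed=0,
        )
    }
    for event, grp in df[df["event"] != marathon_event].groupby("event"):
        best = grp.groupby("_norm")["time_seconds"].min()
        shared = best.index.intersection(mara_time.index)
        if len(shared) < 2:
            logger.info("event %s shares %d runner(s) with the marathon: uncalibrated",
                        event, len(shared))
            continue
        pairs = np.column_stack([best.loc[shared].to_numpy(), mara_time.loc[shared].to_numpy()])
        calibrations[event] = calibrate_event(
            pairs,
            keep_frac=keep_frac,
            event=event,
            names=list(shared),
            ratio_denominator=ratio_denominator,
        )

    def _rank(event: str):
        cal = calibrations[event]
        corr = cal.marathon_correlation
        if math.isnan(corr):
            corr = -math.inf
        return (corr, cal.n_shared, _NegStr(event))

    chosen_rows: list[int] = []
    n_outliers = 0
    n_uncalibrated = 0
    for name, grp in df.groupby("_norm"):
        eligible = grp[grp["event"].isin(calibrations)]
        if eligible.empty:
            n_uncalibrated += len(grp)
            for idx in grp.index:
                logger.info("discarded %s (%s): event not calibrated",
                            name, df.at[idx, "event"])
            continue
        if (eligible["event"] == marathon_event).any():
            event = marathon_event
        else:
            event = max(eligible["event"].unique(), key=_rank)
        in_event = eligible[eligible["event"] == event]
        idx = in_event["time_seconds"].idxmin()
        predicted = predict_marathon_time(calibrations[event], df.at[idx, "time_seconds"])
        if predicted > max_predicted_seconds:
            n_outliers += 1
            logger.info("discarded %s (%s): predicted marathon time %.0f s > %.0f s",
                        name, event, predicted, max_predicted_seconds)
            continue
        chosen_rows.append(idx)
        df.at[idx, "_predicted"] = predicted

    out = df.loc[chosen_rows].copy()
    out["predicted_marathon_seconds"] = out.pop("_predicted")
    out = out.drop(columns=["_norm"]).reset_index(drop=True)
    summary = BuildSummary(
        n_total_results=len(results),
        n_outliers_discarded=n_outliers,
        n_unique_rows=len(out),
        n_uncalibrated_dropped=n_uncalibrated,
        calibrations=calibrations,
    )
    return out, summary


class _NegStr(str):
    """Orders strings descending inside a max() key (lexicographic tie-break)."""

    def __lt__(self, other):  # noqa: D105
        return str.__gt__(self, other)

    def __gt__(self, other):  # noqa: D105
        return str.__lt__(self, other)
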