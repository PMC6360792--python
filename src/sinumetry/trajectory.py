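"""Per-patient linear trajectories of a ratio measure against scan time.

Serial DRM (or volume-ratio) values of one adult patient are modelled as a
straight line in time,

    y(t) = beta0 + beta1 * t + eps,

fitted by ordinary least squares.  The slope beta1 is the per-patient rate of
sinus-size change (ΔDRM when y is the DRM, ΔVRM for the volume ratio), in
ratio units per year.  Time is measured in decimal years (365.25 days) since
the patient's first scan, so slopes are comparable across patients regardless
of calendar placement; a flat line means unchanged sinus size, a negative
slope means shrinking sinuses, i.e. progressing wall thickening.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import date
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateDesignError, InsufficientDataError
from .measurements import DrmPoint

log = logging.getLogger(__name__)

DAYS_PER_YEAR = 365.25


@dataclass(frozen=True)
class TrajectoryFit:
    """OLS fit of one patient's ratio series against time.

    ``beta1`` is the slope in ratio units per year — ΔDRM (or ΔVRM).
    ``residual_sd`` is sqrt(RSS / (n - 2)) for n > 2 and exactly 0 for n = 2,
    where the line interpolates the two points.
    """

    beta0: float
    beta1: float
    residual_sd: float
    n_points: int
    time_origin: date
    last_date: date


def _coerce_date(d) -> date:
    if isinstance(d, date) and not hasattr(d, "hour"):
        return d
    if isinstance(d, str):
        return date.fromisoformat(d)
    if hasattr(d, "date"):  # datetime / pandas Timestamp: drop time-of-day
        return d.date()
    raise TypeError(f"cannot interpret {d!r} as a calendar date")


def _as_date_value_pairs(points: Iterable) -> list[tuple[date, float]]:
    pairs = []
    for p in points:
        if isinstance(p, DrmPoint):
            pairs.append((p.scan_date, p.drm))
        else:
            d, v = p
            pairs.append((_coerce_date(d), float(v)))
    return pairs


def fit_slope(points: Sequence[DrmPoint] | Sequence[tuple[date, float]]) -> TrajectoryFit:
    """Ordinary least squares of a ratio measure on elapsed time in years.

    Parameters
    ----------
    points:
        At least two (scan_date, value) observations (``DrmPoint`` or plain
        tuples) for one patient, in any order, with at least two distinct
        dates.  Same-day repeat scans are retained.

    Raises
    ------
    InsufficientDataError
        Fewer than two points.
    DegenerateDesignError
        All scan dates identical.
    """
    pairs = _as_date_value_pairs(points)
    if len(pairs) < 2:
        raise InsufficientDataError(
            f"need at least 2 points to fit a slope, got {len(pairs)}")
    pairs.sort(key=lambda p: p[0])
    origin = pairs[0][0]
    t = np.array([(d - origin).days / DAYS_PER_YEAR for d, _ in pairs])
    y = np.array([v for _, v in pairs], dtype=float)
    if np.ptp(t) == 0:
        raise DegenerateDesignError("all scan dates identical; slope undefined")

    # closed-form normal equations for the straight line
    tbar, ybar = t.mean(), y.mean()
    sxx = float(np.sum((t - tbar) ** 2))
    beta1 = float(np.sum((t - tbar) * (y - ybar)) / sxx)
    beta0 = float(ybar - beta1 * tbar)

    n = len(pairs)
    if n == 2:
        residual_sd = 0.0
    else:
        rss = float(np.sum((y - beta0 - beta1 * t) ** 2))
        residual_sd = float(np.sqrt(max(rss, 0.0) / (n - 2)))
    return TrajectoryFit(beta0=beta0, beta1=beta1, residual_sd=residual_sd,
                         n_points=n, time_origin=origin, last_date=pairs[-1][0])


SLOPE_COLUMNS = ("patient_id", "beta0", "beta1_per_year", "residual_sd",
                 "n_points", "first_date", "last_date")


def fit_cohort_slopes(cohort: Mapping[str, Sequence] | pd.DataFrame,
                      *, value_col: str = "drm"
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fit per-patient slopes for a whole cohort.

    ``cohort`` is either a mapping patient_id -> point sequence, or a tidy
    DataFrame with columns ``patient_id``, ``scan_date`` and ``value_col``.

    Returns
    -------
    (slopes, excluded):
        ``slopes`` has one row per fittable patient, ordered by patient_id;
        ``excluded`` reports every patient whose series could not be fitted
        (single scan, identical dates) with the reason — exclusions are
        reported, never silent.
    """
    if isinstance(cohort, pd.DataFrame):
        series: dict[str, list[tuple[date, float]]] = {}
        for pid, g in cohort.groupby("patient_id", sort=True):
            series[str(pid)] = list(zip(g["scan_date"], g[value_col]))
    else:
        series = {str(pid): list(pts) for pid, pts in cohort.items()}

    if not series:
        log.warning("fit_cohort_slopes called on an empty cohort")

    rows, excluded = [], []
    for pid in sorted(series):
        try:
            fit = fit_slope(series[pid])
        except (InsufficientDataError, DegenerateDesignError) as exc:
            excluded.append((pid, str(exc)))
            continue
        rows.append((pid, fit.beta0, fit.beta1, fit.residual_sd,
                     fit.n_points, fit.time_origin, fit.last_date))
    slopes = pd.DataFrame(rows, columns=SLOPE_COLUMNS)
    excl = pd.DataFrame(excluded, columns=["patient_id", "reason"])
    return slopes, excl
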