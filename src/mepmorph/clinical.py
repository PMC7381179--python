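"""Clinical association analyses for the ApEn morphology score.

Three exploratory questions, mirroring how a continuous morphology
score would be used in practice:

1. Is ApEn redundant with the two classically extracted MEP variables
   (latency, peak-to-peak amplitude)?  Quantified by OLS R-squared and
   by a nonparametric mutual-information estimate that also sees
   non-linear dependence.
2. Does ApEn track disability (EDSS, the 0-10 half-step expanded
   disability status scale)?  Each MEP visit is linked to the nearest
   EDSS record within one year, and ApEn distributions are summarised
   per EDSS level.
3. Does baseline ApEn predict 2-year disability progression?  A patient
   progresses when EDSS rises by >= 1.0 from a baseline <= 5.5, or by
   >= 0.5 from a baseline > 5.5, at the follow-up closest to the 2-year
   mark within 1.5-3 years.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import date
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.special import digamma
from scipy.stats import gaussian_kde
from sklearn.linear_model import LinearRegression
from sklearn.metrics import roc_auc_score

logger = logging.getLogger(__name__)

__all__ = [
    "link_edss",
    "select_t1",
    "progression_label",
    "mutual_information",
    "r_squared",
    "bivariate_r_squared",
    "edss_distribution_summary",
    "progression_auc",
]

EDSS_GRID = np.arange(0.0, 10.5, 0.5)


def _as_date(d) -> date:
    if isinstance(d, date):
        return d
    return date.fromisoformat(str(d)[:10])


def _check_edss(value: float) -> float:
    value = float(value)
    if not np.isclose(value * 2.0, round(value * 2.0)) or not 0.0 <= value <= 10.0:
        raise ValueError(f"EDSS must lie on the half-step grid 0..10, got {value}")
    return value


def link_edss(
    visits: pd.DataFrame,
    records: pd.DataFrame,
    window_years: float = 1.0,
) -> dict[str, float]:
    """Map each visit to the nearest EDSS record within +/- window_years.

    ``visits`` needs columns (visit_id, patient_id, date); ``records``
    (patient_id, date, edss).  Equidistant records before and after the
    visit resolve to the earlier one.  Visits with no record inside the
    window are simply absent from the result.
    """
    out: dict[str, float] = {}
    window_days = window_years * 365.25
    by_patient = {pid: g for pid, g in records.groupby("patient_id")}
    for _, visit in visits.iterrows():
        recs = by_patient.get(visit["patient_id"])
        if recs is None:
            continue
        vdate = _as_date(visit["date"])
        best: Optional[tuple[float, float, float]] = None  # (|dt|, signed dt, edss)
        for _, rec in recs.iterrows():
            dt = (_as_date(rec["date"]) - vdate).days
            if abs(dt) > window_days:
                continue
            key = (abs(dt), dt)  # ties: earlier record (negative dt) wins
            if best is None or key < (best[0], best[1]):
                best = (abs(dt), dt, _check_edss(rec["edss"]))
        if best is not None:
            out[visit["visit_id"]] = best[2]
    logger.info("linked %d/%d visits to an EDSS record", len(out), len(visits))
    return out


def select_t1(
    records: pd.DataFrame,
    t0_date,
    window: tuple[float, float] = (1.5, 3.0),
    target_years: float = 2.0,
) -> Optional[tuple[float, float]]:
    """Follow-up EDSS: the record 1.5-3 years after baseline closest to 2 years.

    Returns ``(edss, dt_years)`` or ``None``; equidistant candidates
    resolve to the earlier record.
    """
    t0 = _as_date(t0_date)
    best = None
    for _, rec in records.iterrows():
        dt_years = ((_as_date(rec["date"]) - t0).days) / 365.25
        if not window[0] <= dt_years <= window[1]:
            continue
        key = (abs(dt_years - target_years), dt_years)
        if best is None or key < best[0]:
            best = (key, _check_edss(rec["edss"]), dt_years)
    if best is None:
        return None
    return best[1], best[2]


def progression_label(edss_t0: float, edss_t1: float) -> int:
    """2-year disability progression from a baseline/follow-up EDSS pair.

    Progressed iff the EDSS increased by at least 1.0 from a baseline of
    5.5 or lower, or by at least 0.5 from a baseline above 5.5 (the
    higher baseline leaves less headroom on the scale).
    """
    t0 = _check_edss(edss_t0)
    t1 = _check_edss(edss_t1)
    required = 1.0 if t0 <= 5.5 else 0.5
    return int(t1 - t0 >= required)


def mutual_information(x, y, k: int = 3) -> float:
    """Mutual information between two continuous variables, in nats.

    Kraskov-Stoegbauer-Grassberger k-nearest-neighbour estimator
    (their first variant): with ``eps_i`` twice the Chebyshev distance
    to the k-th neighbour in the joint space, and ``n_x, n_y`` the
    marginal neighbour counts strictly within ``eps_i / 2``,

        MI = digamma(k) + digamma(n) - mean_i[digamma(n_x + 1) + digamma(n_y + 1)]

    The estimator is symmetric in x and y and deterministic; small
    negative estimates (independent data) are clipped to 0 with the raw
    value logged.  Needs at least 50 pairs for a stable estimate.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    n = x.size
    if n < 50:
        raise ValueError(f"mutual_information needs >= 50 pairs, got {n}")
    xy = np.column_stack([x, y])
    tree_xy = cKDTree(xy)
    # distance to the k-th neighbour (excluding self) in the joint space
    dist, _ = tree_xy.query(xy, k=k + 1, p=np.inf)
    eps = dist[:, -1]
    tree_x = cKDTree(x[:, None])
    tree_y = cKDTree(y[:, None])
    nx = np.array(
        [len(tree_x.query_ball_point([xi], r=e, p=np.inf)) - 1 for xi, e in zip(x, np.nextafter(eps, 0))]
    )
    ny = np.array(
        [len(tree_y.query_ball_point([yi], r=e, p=np.inf)) - 1 for yi, e in zip(y, np.nextafter(eps, 0))]
    )
    mi = digamma(k) + digamma(n) - float(np.mean(digamma(nx + 1) + digamma(ny + 1)))
    if mi < 0:
        logger.info("raw MI estimate %.4f nats clipped to 0", mi)
        return 0.0
    return float(mi)


def r_squared(x, y) -> float:
    """OLS coefficient of determination of y regressed on x."""
    return bivariate_r_squared(np.asarray(x, dtype=float).reshape(-1, 1), y)


def bivariate_r_squared(predictors, target) -> float:
    """R-squared of an OLS fit of the target on one or more predictors.

    Used to ask how much of the ApEn score a linear model on latency and
    peak-to-peak amplitude can explain.
    """
    X = np.asarray(predictors, dtype=float)
    if X.ndim == 1:
        X = X.reshape(-1, 1)
    y = np.asarray(target, dtype=float).ravel()
    if y.size < 3:
        raise ValueError("need at least 3 observations")
    if np.var(y) == 0:
        raise ValueError("target has zero variance; R-squared undefined")
    return float(LinearRegression().fit(X, y).score(X, y))


def edss_distribution_summary(
    apen_values,
    edss_values,
    max_edss: float = 7.5,
    density_bandwidth: float = 0.05,
    density_grid: Optional[np.ndarray] = None,
) -> pd.DataFrame:
    """Per-EDSS-level summary of the ApEn distribution (violin-plot data).

    Levels above ``max_edss`` are excluded as too sparse to summarise.
    Each retained level reports n, mean, min, max and a Gaussian kernel
    density (absolute bandwidth 0.05 on the normalised ApEn axis)
    evaluated on ``density_grid`` (default: 101 points over [0, 1]).
    """
    apen_values = np.asarray(apen_values, dtype=float)
    edss_values = np.asarray([_check_edss(v) for v in np.asarray(edss_values, dtype=float)])
    if density_grid is None:
        density_grid = np.linspace(0.0, 1.0, 101)
    keep = edss_values <= max_edss
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("excluded %d traces with EDSS > %.1f", n_dropped, max_edss)
    rows = []
    for level in sorted(np.unique(edss_values[keep])):
        vals = apen_values[keep & (edss_values == level)]
        density: Optional[list] = None
        if vals.size >= 2 and np.std(vals) > 0:
            kde = gaussian_kde(vals, bw_method=density_bandwidth / np.std(vals, ddof=1))
            density = list(kde(density_grid))
        rows.append(
            {
                "edss": float(level),
                "n": int(vals.size),
                "mean": float(vals.mean()),
                "min": float(vals.min()),
                "max": float(vals.max()),
                "density": density,
            }
        )
    return pd.DataFrame(rows)


def progression_auc(feature_values, progressed) -> float:
    """AUC of a single baseline feature for the 2-year progression outcome."""
    y = np.asarray(progressed, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("progression_auc needs both outcome classes present")
    return float(roc_auc_score(y, np.asarray(feature_values, dtype=float)))
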