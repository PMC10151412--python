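"""Local saturation dynamics around isolated pioneers.

A pioneer is an offspring that establishes in empty territory after a long
jump.  Because established individuals never move or die, the occupancy of
the pioneer's interaction disc at any later time can be reconstructed
exactly from the final population (filter by establishment time).  The
ensemble-averaged occupancy curve is well described by logistic growth

    n(dt) = K' / (1 + (K' - 1) exp(-lam * dt)),      n(0) = 1,

with free parameters the growth rate ``lam`` and the fitted plateau ``K'``
(which need not equal the nominal carrying capacity K).  The saturation
time is defined as the time for the fitted curve to reach K' - 1:
``t_sat = (2 / lam) * ln(K' - 1)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .sim_core import RunResult

__all__ = [
    "PioneerTrace",
    "LogisticFit",
    "detect_pioneers",
    "record_local_occupancy",
    "average_traces",
    "logistic_curve",
    "fit_logistic",
    "saturation_time",
]


@dataclass
class PioneerTrace:
    """Occupancy of one pioneer's interaction disc versus time since arrival."""

    pioneer_id: int
    x: float
    y: float
    t_establish: int
    dt: np.ndarray
    count: np.ndarray
    partial: bool = False  # tracking window truncated by end of run


@dataclass
class LogisticFit:
    """Two-parameter logistic fit with n(0) = 1 pinned."""

    lam: float
    K_prime: float
    t_sat: float
    rss: float
    reliable: bool = True


def detect_pioneers(result: RunResult, isolation_radius: float | None = None) -> pd.DataFrame:
    """Survived individuals that landed with zero neighbors, far from everyone.

    Requires a run recorded with ``record_births=True``.  A pioneer had
    ``n_neighbors == 0`` at establishment and no established individual
    within ``isolation_radius`` (default 10 rb) at that moment (individuals
    established earlier in the same generation included).  Founders are
    never pioneers.

    Returns a table with columns ``id, x, y, t`` (establishment time).
    """
    log = result.birth_log
    if log is None:
        raise ValueError("detect_pioneers requires a run with record_births=True")
    rb = result.params.rb
    iso = 10.0 * rb if isolation_radius is None else float(isolation_radius)
    if len(log) == 0:
        return pd.DataFrame({"id": [], "x": [], "y": [], "t": []})
    cand = log[(log["survived"]) & (log["n_neighbors"] == 0)]
    state = result.state
    xs, ys = state.x, state.y
    rows = []
    for _, rec in cand.iterrows():
        j = int(rec["id"])  # individuals 0..j-1 were established before this one
        d2 = (xs[:j] - rec["x"]) ** 2 + (ys[:j] - rec["y"]) ** 2
        if d2.size == 0 or d2.min() > iso * iso:
            rows.append((j, rec["x"], rec["y"], int(rec["t"])))
    return pd.DataFrame(rows, columns=["id", "x", "y", "t"])


def record_local_occupancy(pioneer, result: RunResult, window: int = 200) -> PioneerTrace:
    """Occupancy of the disc of radius rb around a pioneer, per generation.

    ``pioneer`` is a row of :func:`detect_pioneers` (or any mapping with
    ``id, x, y, t``).  The count at dt = 0 is exactly 1 (the pioneer; its
    isolation guarantees no earlier individual is in the disc, and
    same-generation later arrivals are counted from dt = 1).  For dt >= 1
    the count includes every individual established by generation
    ``t + dt``.  The window is truncated at the end of the run, flagged via
    ``partial``.
    """
    state = result.state
    rb = result.params.rb
    pid = int(pioneer["id"])
    px, py, t0 = float(pioneer["x"]), float(pioneer["y"]), int(pioneer["t"])
    t_end = int(result.growth["t"].iloc[-1])
    w = min(window, t_end - t0)
    partial = t0 + window > t_end
    d2 = (state.x - px) ** 2 + (state.y - py) ** 2
    in_disc = d2 <= rb * rb
    tb = state.t_birth[in_disc]
    ids = np.flatnonzero(in_disc)
    dt = np.arange(w + 1)
    count = np.empty(w + 1, dtype=np.int64)
    count[0] = int(np.sum(ids <= pid))
    if w > 0:
        count[1:] = np.searchsorted(np.sort(tb), t0 + dt[1:], side="right")
    return PioneerTrace(pioneer_id=pid, x=px, y=py, t_establish=t0,
                        dt=dt, count=count, partial=partial)


def average_traces(traces) -> pd.DataFrame:
    """Pointwise mean occupancy over aligned traces.

    Returns a table ``dt, mean, n`` with ``n`` the number of traces whose
    window covers each dt (so partial traces contribute what they have).
    """
    traces = list(traces)
    if not traces:
        raise ValueError("average_traces requires at least one trace")
    max_dt = max(tr.dt[-1] for tr in traces)
    total = np.zeros(max_dt + 1)
    n = np.zeros(max_dt + 1, dtype=np.int64)
    for tr in traces:
        w = tr.dt[-1]
        total[: w + 1] += tr.count
        n[: w + 1] += 1
    return pd.DataFrame({"dt": np.arange(max_dt + 1), "mean": total / n, "n": n})


def logistic_curve(dt, lam, K_prime):
    """Logistic occupancy with n(0) = 1 pinned."""
    return K_prime / (1.0 + (K_prime - 1.0) * np.exp(-lam * np.asarray(dt, dtype=float)))


def fit_logistic(dt, count, lam0: float | None = None) -> LogisticFit:
    """Least-squares logistic fit of an occupancy curve.

    The start value n(0) = 1 is pinned (the pioneer), leaving the growth
    rate and the plateau as the two free parameters.  Deterministic given
    the curve: fixed initialization (``lam0`` if given, else 0.3; plateau
    started at the maximum observed count) and a 1e-10 parameter tolerance.
    A fit is flagged unreliable when the curve never levels off (fitted
    plateau well above the largest observation) or the rate collapses to
    its lower bound.
    """
    dt = np.asarray(dt, dtype=float)
    count = np.asarray(count, dtype=float)
    if len(dt) < 4:
        raise ValueError("fit_logistic requires at least 4 points")
    p0 = (lam0 if lam0 is not None else 0.3, max(count.max(), 1.5))
    popt, _ = curve_fit(logistic_curve, dt, count, p0=p0,
                        bounds=([1e-8, 1.0 + 1e-9], [np.inf, np.inf]),
                        xtol=1e-10, ftol=1e-10, maxfev=20000)
    lam, K_prime = float(popt[0]), float(popt[1])
    resid = count - logistic_curve(dt, lam, K_prime)
    reliable = (K_prime <= 1.5 * count.max() + 1.0) and lam > 1e-6
    fit = LogisticFit(lam=lam, K_prime=K_prime, t_sat=math.nan,
                      rss=float(np.sum(resid**2)), reliable=reliable)
    fit.t_sat = saturation_time(fit)
    return fit


def saturation_time(fit: LogisticFit | None = None, *, lam: float | None = None,
                    K_prime: float | None = None) -> float:
    """Closed-form time for the fitted logistic to reach K' - 1.

    Solving n(t) = K' - 1 with n(0) = 1 gives ``t_sat = (2/lam) ln(K'-1)``.
    For K' <= 2 the start value already satisfies the condition and 0 is
    returned.
    """
    if fit is not None:
        lam, K_prime = fit.lam, fit.K_prime
    if lam is None or K_prime is None:
        raise ValueError("provide a LogisticFit or both lam and K_prime")
    if K_prime <= 2.0:
        return 0.0
    return (2.0 / lam) * math.log(K_prime - 1.0)
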