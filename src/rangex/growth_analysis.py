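"""Core-radius growth curves and kernel-exponent inference.

The mass-equivalent radius ``ell(t) = sqrt(M(t) / (pi rho))`` is the radius
of the disc that would hold the whole population at saturation density, and
serves as the estimate of the core radius (``M ~ ell**d``).  Jump-driven
expansions obey a time-doubling self-consistency relation,

    ell(t)**(d + mu)  ~  t * ell(t/2)**(2 d),

linking the core at time t to the satellites seeded around t/2.  Fitting
``t * ell(t/2)**(2d) = B * ell(t)**nu`` on the late half of a trajectory
yields an inferred kernel exponent ``mu_i = nu - d``; deviations of mu_i
from the true mu quantify the departure of the continuum dynamics from the
instant-saturation lattice picture.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ConsistencyFit",
    "mass_equivalent_radius",
    "average_growth_curves",
    "consistency_pairs",
    "infer_kernel_exponent",
    "fit_run",
    "bootstrap_mu_i",
]


@dataclass
class ConsistencyFit:
    """Power-law fit of the time-doubling relation and the implied mu."""

    nu: float
    B: float
    mu_i: float
    n_pairs: int
    ci95: tuple[float, float] | None = None
    n_runs: int | None = None


def mass_equivalent_radius(M, rho: float):
    """``ell = sqrt(M / (pi rho))`` (vectorized)."""
    if rho <= 0:
        raise ValueError(f"density rho must be > 0, got {rho}")
    M = np.asarray(M, dtype=float)
    if np.any(M < 0):
        raise ValueError("population size must be >= 0")
    out = np.sqrt(M / (math.pi * rho))
    return out if out.ndim else float(out)


def average_growth_curves(runs) -> pd.DataFrame:
    """Pointwise ensemble mean of ell(t) on the common integer time grid.

    Curves are truncated at the shortest run.  ``runs`` is an iterable of
    growth tables (columns t, M, ell) or objects carrying one as ``growth``.
    """
    tables = [r.growth if hasattr(r, "growth") else r for r in runs]
    if not tables:
        raise ValueError("average_growth_curves requires at least one run")
    t_max = min(int(g["t"].iloc[-1]) for g in tables)
    t0 = max(int(g["t"].iloc[0]) for g in tables)
    grid = np.arange(t0, t_max + 1)
    ells = []
    Ms = []
    for g in tables:
        t = g["t"].to_numpy()
        sel = (t >= t0) & (t <= t_max)
        if not np.array_equal(t[sel], grid):
            raise ValueError("growth curves must share an integer time grid")
        ells.append(g["ell"].to_numpy()[sel])
        Ms.append(g["M"].to_numpy()[sel])
    return pd.DataFrame({"t": grid, "M": np.mean(Ms, axis=0),
                         "ell": np.mean(ells, axis=0)})


def consistency_pairs(curve: pd.DataFrame, d: int = 2) -> pd.DataFrame:
    """Pairs ``(ell(t), t * ell(t/2)**(2d))`` for even t in the late half.

    Only even integer times with ``t >= t_max / 2`` are used so that t/2
    lies on the recorded grid (no interpolation) and the pre-hierarchy
    transient is excluded.  Returns a table with columns ``t, x, y`` where
    ``x = ell(t)`` and ``y = t * ell(t/2)**(2d)``.
    """
    t = curve["t"].to_numpy().astype(np.int64)
    ell = curve["ell"].to_numpy()
    t0, t_max = int(t[0]), int(t[-1])
    if not np.array_equal(t, np.arange(t0, t_max + 1)):
        raise ValueError("consistency_pairs expects a contiguous integer time grid")
    first = max(2, t_max // 2 + (t_max // 2) % 2)  # first even time in the late half
    sel_t = np.arange(first, t_max + 1, 2)
    sel_t = sel_t[sel_t // 2 >= t0]
    if sel_t.size == 0:
        import warnings

        warnings.warn("trajectory too short for consistency pairs")
        return pd.DataFrame({"t": [], "x": [], "y": []})
    x = ell[sel_t - t0]
    y = sel_t * ell[sel_t // 2 - t0] ** (2 * d)
    return pd.DataFrame({"t": sel_t, "x": x, "y": y})


def infer_kernel_exponent(pairs: pd.DataFrame, d: int = 2) -> ConsistencyFit:
    """OLS of ``log y`` on ``log x``: slope nu, intercept log B, mu_i = nu - d.

    Unweighted least squares in log space; multiplying y by any constant
    overlay factor changes B but never nu.
    """
    x = np.asarray(pairs["x"], dtype=float)
    y = np.asarray(pairs["y"], dtype=float)
    if x.size < 5:
        raise ValueError("infer_kernel_exponent requires at least 5 pairs")
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValueError("consistency pairs must be strictly positive")
    lx, ly = np.log(x), np.log(y)
    if np.ptp(lx) < 1e-12:
        raise ValueError("degenerate x-range: ell(t) does not vary")
    slope, intercept = np.polyfit(lx, ly, 1)
    return ConsistencyFit(nu=float(slope), B=float(math.exp(intercept)),
                          mu_i=float(slope) - d, n_pairs=int(x.size))


def fit_run(run, d: int = 2, min_t: int | None = None) -> ConsistencyFit:
    """Convenience: consistency pairs + exponent fit for one run or curve."""
    curve = run.growth if hasattr(run, "growth") else run
    pairs = consistency_pairs(curve, d=d)
    if min_t is not None:
        pairs = pairs[pairs["t"] >= min_t]
    return infer_kernel_exponent(pairs, d=d)


def bootstrap_mu_i(per_run_mu_i, n_boot: int = 2000, *, seed: int = 0) -> tuple[float, tuple[float, float]]:
    """Bootstrap the mean inferred kernel exponent over runs.

    Resamples the per-run mu_i values with replacement ``n_boot`` times and
    returns ``(mean, (2.5th, 97.5th percentile of bootstrapped means))``.
    Deterministic given the seed.
    """
    vals = np.asarray(per_run_mu_i, dtype=float)
    if vals.size < 2:
        raise ValueError("bootstrap requires at least 2 per-run values")
    if n_boot < 100:
        import warnings

        warnings.warn(f"n_boot={n_boot} is small; the CI will be noisy")
    rng = np.random.default_rng(seed)
    means = rng.choice(vals, size=(n_boot, vals.size), replace=True).mean(axis=1)
    lo, hi = np.percentile(means, [2.5, 97.5])
    return float(vals.mean()), (float(lo), float(hi))
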