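"""Continuum-space individual-based range-expansion engine.

Individuals occupy positions in an unbounded 2D plane.  Each generation every
extant individual draws an independent Poisson(1) offspring count; every
offspring disperses in a uniformly random direction with a distance drawn
from a two-part jump kernel

    J(r) = p / rb                          for r <= rb
    J(r) = (1 - p) * mu * rb**mu / r**(mu+1)   for r > rb,

and establishes only if strictly fewer than K established individuals lie
within the closed disc of radius rb around its landing point.  Established
individuals never move, die, or reproduce at a different rate; the neutral
allele label is inherited exactly (no mutation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from ._engine import NeighborGrid
from .params import SimParams

__all__ = [
    "BirthRecord",
    "PopulationState",
    "RunResult",
    "sample_jump_distance",
    "jump_kernel_cdf",
    "sample_dispersal",
    "count_neighbors",
    "attempt_establishment",
    "init_population",
    "step",
    "run",
]

_TWO_PI = 2.0 * math.pi

#: columns of the tab-separated birth log
BIRTH_LOG_COLUMNS = ["t", "parent_id", "x", "y", "r", "n_neighbors", "survived", "allele", "id"]

#: columns of a position/allele snapshot table
SNAPSHOT_COLUMNS = ["id", "x", "y", "allele", "t_birth"]


# ---------------------------------------------------------------------------
# dispersal kernel

def sample_jump_distance(u, params: SimParams):
    """Invert the jump-kernel CDF at uniform deviate(s) ``u`` in [0, 1).

    The CDF is ``F(r) = p r / rb`` for ``r <= rb`` and
    ``F(r) = 1 - (1-p) (r/rb)**-mu`` beyond, so

        r = u rb / p                          for u < p
        r = rb ((1-u)/(1-p))**(-1/mu)         for u >= p.

    Both branches agree at the seam (``u = p`` gives ``r = rb``); ``p = 0``
    and ``p = 1`` degenerate to the pure tail / pure local cases.
    """
    u = np.asarray(u, dtype=np.float64)
    if np.any(u < 0.0) or np.any(u >= 1.0):
        raise ValueError("uniform deviates must lie in [0, 1)")
    p, rb, mu = params.p, params.rb, params.mu
    r = np.empty_like(u)
    local = u < p
    if p > 0.0:
        r[local] = u[local] * rb / p
    if p < 1.0:
        tail = ~local
        r[tail] = rb * ((1.0 - u[tail]) / (1.0 - p)) ** (-1.0 / mu)
    return r if r.ndim else float(r)


def jump_kernel_cdf(r, params: SimParams):
    """Analytic CDF of the jump kernel (used as the sampling oracle)."""
    r = np.asarray(r, dtype=np.float64)
    p, rb, mu = params.p, params.rb, params.mu
    out = np.where(
        r <= rb,
        np.clip(r, 0.0, None) * p / rb,
        1.0 - (1.0 - p) * np.maximum(r, rb) ** (-mu) * rb**mu,
    )
    return out if out.ndim else float(out)


def sample_dispersal(parent_xy, rng: np.random.Generator, params: SimParams, size: int | None = None):
    """Candidate position(s): parent + r * (cos theta, sin theta).

    ``parent_xy`` is a length-2 sequence; with ``size`` given, returns an
    ``(size, 2)`` array of independent candidates.
    """
    n = 1 if size is None else int(size)
    r = sample_jump_distance(rng.random(n), params)
    theta = rng.random(n) * _TWO_PI
    px, py = float(parent_xy[0]), float(parent_xy[1])
    out = np.column_stack((px + r * np.cos(theta), py + r * np.sin(theta)))
    return out[0] if size is None else out


# ---------------------------------------------------------------------------
# population state

@dataclass
class BirthRecord:
    """Instrumentation record of one duplication attempt.

    ``n_neighbors`` is the count at evaluation time (individuals established
    earlier in the same generation included); values at or above K are
    recorded as K.  ``id`` is the established individual's index, or -1 if
    the offspring died.
    """

    t: int
    parent_id: int
    x: float
    y: float
    r: float
    n_neighbors: int
    survived: bool
    allele: int
    id: int = -1


class PopulationState:
    """Established individuals plus their fixed-radius neighbor index.

    Individual attributes are stored columnar (``x``, ``y``, ``allele``,
    ``t_birth`` numpy arrays of length :attr:`M`); the array index is the
    individual's id.  Individuals are immutable once established and ``M``
    never decreases.
    """

    def __init__(self, params: SimParams):
        self.params = params
        self.t = 0
        self._grid = NeighborGrid(params.rb, capacity=max(4096, 2 * params.n0))

    # -- views -------------------------------------------------------------
    @property
    def M(self) -> int:
        """Current population size."""
        return self._grid.n

    @property
    def x(self) -> np.ndarray:
        return self._grid.x[: self.M]

    @property
    def y(self) -> np.ndarray:
        return self._grid.y[: self.M]

    @property
    def allele(self) -> np.ndarray:
        return self._grid.allele[: self.M]

    @property
    def t_birth(self) -> np.ndarray:
        return self._grid.t_birth[: self.M]

    def snapshot(self) -> pd.DataFrame:
        """Copy of the population as a (id, x, y, allele, t_birth) table."""
        return pd.DataFrame({
            "id": np.arange(self.M),
            "x": self.x.copy(),
            "y": self.y.copy(),
            "allele": self.allele.copy(),
            "t_birth": self.t_birth.copy(),
        })

    def allele_counts(self) -> np.ndarray:
        """Counts per allele label (labels are small non-negative ints)."""
        return np.bincount(self.allele)

    # -- mutation (append-only) --------------------------------------------
    def add_founders(self, xs, ys, alleles):
        """Insert founders with no density check (initialization only)."""
        return self._grid.insert_points(xs, ys, alleles, t_birth=self.t)

    def establish_batch(self, cand_x, cand_y, cand_allele):
        """Sequential density-checked establishment at the current time."""
        return self._grid.establish_sweep(cand_x, cand_y, cand_allele,
                                          self.params.K, self.t)


def count_neighbors(pos, state: PopulationState, rb: float | None = None, limit: int = 0) -> int:
    """Established individuals within the closed disc of radius ``rb`` of ``pos``.

    ``rb`` must equal the grid's cell size (the state's interaction radius);
    it is accepted as an argument for interface symmetry and validated.
    """
    if rb is not None and not math.isclose(rb, state.params.rb):
        raise ValueError("count_neighbors uses the state's interaction radius")
    return state._grid.count(pos[0], pos[1], limit=limit)


def attempt_establishment(pos, allele: int, state: PopulationState,
                          params: SimParams | None = None) -> tuple[bool, BirthRecord]:
    """Attempt to establish one offspring at ``pos``.

    Survives iff fewer than K established individuals (the candidate
    excluded) lie within ``rb`` of ``pos``; on survival the individual is
    appended with ``t_birth`` equal to the current time.  A
    :class:`BirthRecord` is emitted either way.
    """
    params = params or state.params
    survived, ncount = state.establish_batch(
        np.array([pos[0]]), np.array([pos[1]]), np.array([allele]))
    ok = bool(survived[0])
    rec = BirthRecord(t=state.t, parent_id=-1, x=float(pos[0]), y=float(pos[1]),
                      r=math.nan, n_neighbors=int(ncount[0]), survived=ok,
                      allele=int(allele), id=state.M - 1 if ok else -1)
    return ok, rec


# ---------------------------------------------------------------------------
# initialization

def _initial_alleles(n0: int, allele_mode, rng: np.random.Generator) -> np.ndarray:
    if allele_mode == "unique":
        return np.arange(n0, dtype=np.int64)
    if allele_mode == "two_allele_equal":
        k = 2
    elif isinstance(allele_mode, int) and allele_mode >= 1:
        k = allele_mode
    else:
        raise ValueError(f"unknown allele_mode {allele_mode!r}")
    # as-equal-as-possible split; order is irrelevant to every statistic we track
    alleles = np.arange(n0, dtype=np.int64) % k
    if n0 % k:
        import warnings

        warnings.warn(f"n0={n0} not divisible by {k}: allele counts differ by one")
    return alleles


def init_population(params: SimParams, allele_mode="two_allele_equal",
                    rng: np.random.Generator | None = None) -> PopulationState:
    """Gaussian-spread founder population, exempt from the density check.

    ``n0`` founders are placed with independent Gaussian coordinates (mean 0,
    sd ``init_sigma`` = 2 rb by default) at t = 0.  ``allele_mode`` is
    ``"unique"`` (all-distinct labels), ``"two_allele_equal"`` (balanced
    50/50 split, initial global heterozygosity 1/2), or an integer k for a
    balanced k-allele split.
    """
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    state = PopulationState(params)
    n0 = params.n0
    xy = rng.normal(0.0, params.init_sigma, size=(n0, 2))
    alleles = _initial_alleles(n0, allele_mode, rng)
    state.add_founders(xy[:, 0], xy[:, 1], alleles)
    return state


# ---------------------------------------------------------------------------
# reproduction loop

class _BirthLogBuffer:
    """Accumulates per-generation birth arrays; finalized to a DataFrame."""

    def __init__(self):
        self._chunks = []

    def extend(self, t, parent_id, x, y, r, ncount, survived, allele, ids):
        self._chunks.append((t, parent_id, x, y, r, ncount, survived, allele, ids))

    def to_frame(self) -> pd.DataFrame:
        if not self._chunks:
            return pd.DataFrame({c: np.array([]) for c in BIRTH_LOG_COLUMNS})
        cols = {"t": np.concatenate([np.full(len(c[1]), c[0], dtype=np.int64)
                                     for c in self._chunks])}
        for i, name in enumerate(BIRTH_LOG_COLUMNS[1:], start=1):
            cols[name] = np.concatenate([c[i] for c in self._chunks])
        df = pd.DataFrame(cols)
        df["survived"] = df["survived"].astype(bool)
        return df


def step(state: PopulationState, params: SimParams | None = None,
         rng: np.random.Generator | None = None, log: _BirthLogBuffer | None = None) -> PopulationState:
    """Advance the population by one generation (in place).

    Every individual extant at the start of the step draws an independent
    Poisson(1) offspring count; all offspring of the step are shuffled
    uniformly and processed sequentially through dispersal + establishment,
    so an offspring established earlier in the sweep counts toward the
    density check of later offspring.  Time advances by 1.
    """
    params = params or state.params
    if rng is None:
        raise ValueError("step requires an explicit numpy Generator")
    state._grid.compact()  # fold last generation into the cell-sorted layout
    n = state.M
    counts = rng.poisson(1.0, n)
    parents = np.repeat(np.arange(n, dtype=np.int64), counts)
    state.t += 1
    total = parents.size
    if total == 0:
        return state
    parents = parents[rng.permutation(total)]
    r = sample_jump_distance(rng.random(total), params)
    theta = rng.random(total) * _TWO_PI
    cand_x = state.x[parents] + r * np.cos(theta)
    cand_y = state.y[parents] + r * np.sin(theta)
    alleles = state.allele[parents].copy()
    n_before = state.M
    survived, ncount = state.establish_batch(cand_x, cand_y, alleles)
    if log is not None:
        ids = np.full(total, -1, dtype=np.int64)
        ids[survived == 1] = n_before + np.arange(int(survived.sum()))
        log.extend(state.t, parents, cand_x, cand_y, r, ncount.astype(np.int64),
                   survived.astype(np.int64), alleles, ids)
    return state


# ---------------------------------------------------------------------------
# full runs

@dataclass
class RunResult:
    """Everything a single run produced.

    ``growth`` is a table with columns ``t, M, ell`` (and ``H`` when
    heterozygosity tracking is on); ``birth_log`` and ``snapshots`` are
    present only when requested.
    """

    params: SimParams
    seed: int
    status: str
    growth: pd.DataFrame
    state: PopulationState
    birth_log: pd.DataFrame | None = None
    snapshots: list[pd.DataFrame] = field(default_factory=list)

    @property
    def n0(self) -> int:
        return self.params.n0


def _global_het(state: PopulationState) -> float:
    counts = state.allele_counts()
    f = counts / state.M
    return float(1.0 - np.sum(f * f))


def run(params: SimParams, *, allele_mode="two_allele_equal",
        seed: int | None = None, record_births: bool = False,
        track_heterozygosity: bool = True, max_generations: int = 100_000,
        snapshot_times: Iterable[int] = ()) -> RunResult:
    """Run a range expansion until ``M >= m_stop`` (or ``max_generations``).

    Fully reproducible given the seed: a single seeded generator drives
    initialization, offspring numbers, dispersal, and processing order.
    ``snapshot_times`` lists generations at which to store full position
    snapshots; the per-generation (t, M, ell[, H]) growth table is always
    recorded.
    """
    seed = params.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    state = init_population(params, allele_mode, rng)
    log = _BirthLogBuffer() if record_births else None
    snapshot_times = set(int(t) for t in snapshot_times)
    snapshots = []

    rho = params.rho
    ts, Ms, Hs = [], [], []

    def _record():
        ts.append(state.t)
        Ms.append(state.M)
        if track_heterozygosity:
            Hs.append(_global_het(state))
        if state.t in snapshot_times:
            snapshots.append(state.snapshot())

    _record()
    status = "completed"
    if state.M < params.m_stop:
        while True:
            step(state, params, rng, log=log)
            _record()
            if state.M >= params.m_stop:
                break
            if state.t >= max_generations:
                import warnings

                warnings.warn(
                    f"max_generations={max_generations} reached at M={state.M} "
                    f"< m_stop={params.m_stop}; returning partial trajectory")
                status = "max_generations"
                break

    M_arr = np.asarray(Ms, dtype=np.int64)
    growth = pd.DataFrame({
        "t": np.asarray(ts, dtype=np.int64),
        "M": M_arr,
        "ell": np.sqrt(M_arr / (math.pi * rho)),
    })
    if track_heterozygosity:
        growth["H"] = np.asarray(Hs)
    return RunResult(params=params, seed=seed, status=status, growth=growth,
                     state=state, birth_log=log.to_frame() if log else None,
                     snapshots=snapshots)
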