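"""Lattice (deme-based) model with instant saturation and founder-takes-all.

Comparison oracle for the continuum engine: space is a square lattice of
demes with only two states, occupied or empty.  Occupied demes emit
Poisson(1) migrants per generation; each migrant draws a distance from the
pure power-law tail J(r) ~ r**-(mu+1) (r >= 1, lattice units) and a uniform
direction, and the displacement is rounded to the nearest deme.  A migrant
to an empty deme occupies it with the parent deme's allele, instantly and
permanently; a migrant to an occupied deme (including its own source deme)
is discarded.  The first successful migrant therefore "takes all".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["LatticeState", "LatticeResult", "seed_cluster", "lattice_step", "run_lattice"]

_TWO_PI = 2.0 * math.pi


@dataclass
class LatticeState:
    """Occupied demes of the lattice model.

    ``occupied`` maps integer deme coordinates to the allele label; parallel
    coordinate/allele arrays are kept for vectorized migrant generation.
    A deme, once occupied, never changes allele or empties.
    """

    occupied: dict = field(default_factory=dict)
    t: int = 0

    def __post_init__(self):
        self._ix = [k[0] for k in self.occupied]
        self._iy = [k[1] for k in self.occupied]
        self._alleles = list(self.occupied.values())

    @property
    def M(self) -> int:
        return len(self.occupied)

    def allele_array(self) -> np.ndarray:
        return np.asarray(self._alleles, dtype=np.int64)

    def _occupy(self, key, allele):
        self.occupied[key] = allele
        self._ix.append(key[0])
        self._iy.append(key[1])
        self._alleles.append(allele)


def seed_cluster(radius: int = 3, allele_mode="two_allele_equal") -> LatticeState:
    """Filled disc of demes (|x|^2 + |y|^2 <= radius^2) around the origin.

    Mirrors the small, dense founder population of the continuum model.
    Alleles alternate deterministically for ``two_allele_equal`` (as close
    to a balanced split as the disc size allows) or are all distinct for
    ``"unique"``.
    """
    keys = [(ix, iy)
            for ix in range(-radius, radius + 1)
            for iy in range(-radius, radius + 1)
            if ix * ix + iy * iy <= radius * radius]
    if allele_mode == "unique":
        alleles = range(len(keys))
    elif allele_mode == "two_allele_equal":
        alleles = [i % 2 for i in range(len(keys))]
    elif isinstance(allele_mode, int) and allele_mode >= 1:
        alleles = [i % allele_mode for i in range(len(keys))]
    else:
        raise ValueError(f"unknown allele_mode {allele_mode!r}")
    return LatticeState(occupied=dict(zip(keys, alleles)))


def _sample_tail(u: np.ndarray, mu: float) -> np.ndarray:
    # inverse CDF of J(r) = mu r**-(mu+1), r >= 1
    return (1.0 - u) ** (-1.0 / mu)


def lattice_step(state: LatticeState, mu: float, rng: np.random.Generator,
                 log: list | None = None) -> LatticeState:
    """Advance the lattice model by one generation (in place).

    Migrants of the generation are processed in a uniformly random order;
    within-generation occupations block later migrants to the same deme.
    """
    if state.M == 0:
        raise ValueError("lattice_step requires at least one occupied deme")
    n = state.M
    counts = rng.poisson(1.0, n)
    parents = np.repeat(np.arange(n), counts)
    total = parents.size
    state.t += 1
    if total == 0:
        return state
    parents = parents[rng.permutation(total)]
    u = rng.random(total)
    r = _sample_tail(u, mu)
    theta = rng.random(total) * _TWO_PI
    px = np.asarray(state._ix)[parents]
    py = np.asarray(state._iy)[parents]
    tx = np.rint(px + r * np.cos(theta)).astype(np.int64)
    ty = np.rint(py + r * np.sin(theta)).astype(np.int64)
    alleles = np.asarray(state._alleles, dtype=np.int64)[parents]
    occupied = state.occupied
    for j in range(total):
        key = (int(tx[j]), int(ty[j]))
        ok = key not in occupied
        if ok:
            state._occupy(key, int(alleles[j]))
        if log is not None:
            log.append((state.t, key, int(alleles[j]), ok))
    return state


@dataclass
class LatticeResult:
    mu: float
    seed: int
    growth: pd.DataFrame  # t, M, ell[, H]
    state: LatticeState
    log: list | None = None


def run_lattice(mu: float, m_stop: int, allele_mode="two_allele_equal", *,
                seed: int = 0, seed_radius: int = 3, track_heterozygosity: bool = True,
                max_generations: int = 100_000, keep_log: bool = False) -> LatticeResult:
    """Iterate the lattice model until the occupied-deme count reaches m_stop.

    ``M(t)`` is the occupied-deme count and ``ell = sqrt(M/pi)`` the
    mass-equivalent radius (saturation density 1 per deme).  The growth
    table carries the per-generation global heterozygosity over deme alleles
    when tracking is on.
    """
    if mu <= 0:
        raise ValueError(f"mu must be > 0, got {mu}")
    rng = np.random.default_rng(seed)
    state = seed_cluster(seed_radius, allele_mode)
    log: list | None = [] if keep_log else None
    ts, Ms, Hs = [], [], []

    def _record():
        ts.append(state.t)
        Ms.append(state.M)
        if track_heterozygosity:
            counts = np.bincount(state.allele_array())
            f = counts / state.M
            Hs.append(float(1.0 - np.sum(f * f)))

    _record()
    while state.M < m_stop and state.t < max_generations:
        lattice_step(state, mu, rng, log=log)
        _record()

    M_arr = np.asarray(Ms, dtype=np.int64)
    growth = pd.DataFrame({"t": np.asarray(ts, dtype=np.int64), "M": M_arr,
                           "ell": np.sqrt(M_arr / math.pi)})
    if track_heterozygosity:
        growth["H"] = np.asarray(Hs)
    return LatticeResult(mu=mu, seed=seed, growth=growth, state=state, log=log)
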