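"""Simulation parameterization and characteristic time scales.

The model has three consequential parameters once the interaction radius
``rb`` (length unit) and the per-capita reproduction rate (time unit) are
fixed: the kernel exponent ``mu`` controlling the power-law tail of the
dispersal kernel, the local dispersal probability ``p`` (integrated
probability that a jump lands within ``rb`` of the parent), and the local
carrying capacity ``K`` (maximum number of competitors tolerated inside an
interaction disc).  The maximum sustainable density follows as
``rho = K / (pi * rb**2)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

__all__ = ["SimParams", "FastLocalCriterion", "criterion_fast_local"]


@dataclass(frozen=True)
class SimParams:
    """Full parameterization of a continuum range-expansion run.

    Parameters
    ----------
    mu
        Kernel exponent: the dispersal-distance density decays as
        ``r**-(mu + 1)`` beyond the interaction radius.  Must be > 0 so the
        kernel is normalizable.  Smaller ``mu`` means heavier tails.
    p
        Probability that a dispersal event is "local", i.e. lands within
        ``rb`` of the parent.  ``p = 1`` disables long-range jumps entirely;
        ``p = 0`` makes every jump long-range.
    K
        Local carrying capacity: an offspring establishes only if strictly
        fewer than ``K`` established individuals already occupy the closed
        disc of radius ``rb`` around its landing point.
    rb
        Interaction radius; the natural length unit (default 1).
    n0
        Initial population size (default ``10 * K``).
    init_sigma
        Standard deviation of the Gaussian spread of the founders
        (default ``2 * rb``).
    m_stop
        Stop once the population size reaches this value
        (default ``10_000 * n0``).
    seed
        RNG seed recorded in all outputs.
    """

    mu: float
    p: float
    K: int
    rb: float = 1.0
    n0: int = field(default=-1)
    init_sigma: float = field(default=-1.0)
    m_stop: int = field(default=-1)
    seed: int = 0

    #: spatial dimension of the engine; kept symbolic in analysis formulas
    d: int = 2

    def __post_init__(self) -> None:
        if not self.mu > 0:
            raise ValueError(f"kernel exponent mu must be > 0, got {self.mu}")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"local dispersal probability p must lie in [0, 1], got {self.p}")
        if not (isinstance(self.K, (int,)) and self.K >= 1):
            raise ValueError(f"carrying capacity K must be an integer >= 1, got {self.K}")
        if not self.rb > 0:
            raise ValueError(f"interaction radius rb must be > 0, got {self.rb}")
        if self.d != 2:
            raise ValueError("the engine only supports d = 2")
        # fill derived defaults (frozen dataclass: go through __setattr__)
        if self.n0 < 0:
            object.__setattr__(self, "n0", 10 * self.K)
        if self.init_sigma < 0:
            object.__setattr__(self, "init_sigma", 2.0 * self.rb)
        if self.m_stop < 0:
            object.__setattr__(self, "m_stop", 10_000 * self.n0)
        if self.n0 < 1:
            raise ValueError(f"initial population n0 must be >= 1, got {self.n0}")
        if self.m_stop < self.n0:
            raise ValueError(
                f"stopping size m_stop ({self.m_stop}) must be >= initial size n0 ({self.n0})"
            )

    @property
    def rho(self) -> float:
        """Maximum density: ``K / (pi * rb**2)`` individuals per unit area."""
        return self.K / (math.pi * self.rb**2)

    def replace(self, **kwargs) -> "SimParams":
        """Return a copy with the given fields overridden."""
        from dataclasses import replace as _replace

        return _replace(self, **kwargs)


class FastLocalCriterion(NamedTuple):
    """Characteristic time scales of local saturation vs long-range seeding.

    ``tau_s = 1/p`` is the time scale on which a pioneer's interaction disc
    fills with its own locally dispersed descendants; ``tau_j = 1/(K(1-p))``
    is the shortest typical interval between long-range jumps emitted by a
    saturated disc.  Instantaneous-local-dynamics (lattice-model) behavior
    requires ``tau_s << tau_j``, i.e. ``p/(1-p) >> K``; ``p_star = K/(K+1)``
    is the dispersal probability at which the two time scales are equal.
    """

    tau_s: float
    tau_j: float
    ratio: float
    p_star: float


def criterion_fast_local(params: SimParams | None = None, *, p: float | None = None,
                         K: int | None = None) -> FastLocalCriterion:
    """Evaluate the fast-local-dynamics criterion for ``(p, K)``.

    Accepts either a :class:`SimParams` or explicit ``p`` and ``K``.
    ``ratio = tau_j / tau_s = p / ((1 - p) K)`` exceeds 1 only when local
    saturation is fast compared to long-range seeding.
    """
    if params is not None:
        p, K = params.p, params.K
    if p is None or K is None:
        raise ValueError("provide either params or both p and K")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must lie in [0, 1], got {p}")
    if K < 1:
        raise ValueError(f"K must be >= 1, got {K}")
    tau_s = math.inf if p == 0 else 1.0 / p
    tau_j = math.inf if p == 1 else 1.0 / (K * (1.0 - p))
    if p == 0:
        ratio = 0.0
    elif p == 1:
        ratio = math.inf
    else:
        ratio = p / ((1.0 - p) * K)
    p_star = K / (K + 1.0)
    return FastLocalCriterion(tau_s=tau_s, tau_j=tau_j, ratio=ratio, p_star=p_star)
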