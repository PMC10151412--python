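"""Neutral heterozygosity: local (within interaction discs) and global.

Heterozygosity is the probability that two randomly sampled individuals
carry different neutral alleles, ``H = 1 - sum_i f_i**2`` over allele
frequencies f_i.  Locally, H measured inside the interaction disc of an
isolated pioneer detects the breakdown of the founder-takes-all picture:
normalized against ``H_N = 2 (1/K)(1 - 1/K)`` (a full disc containing
exactly one non-founder allele), values above 1 mean a typical disc holds
more than one allele.  Globally, the trajectory of H against the relative
population size M/M0, pooled over replicate runs into logarithmic bins,
distinguishes the diversity-preserving (heavy-tail) and diversity-eroding
kernel regimes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .saturation_analysis import fit_logistic
from .sim_core import RunResult

__all__ = [
    "allele_frequencies",
    "heterozygosity",
    "local_heterozygosity",
    "normalized_local_het",
    "global_het_vs_size",
]


def allele_frequencies(labels) -> pd.Series:
    """Frequencies f_i per allele label over a set of individuals."""
    labels = pd.Series(np.asarray(labels))
    if len(labels) == 0:
        raise ValueError("allele frequencies are undefined for an empty set")
    return labels.value_counts(normalize=True, sort=False)


def heterozygosity(freqs_or_labels) -> float:
    """``H = 1 - sum f_i**2``.

    Accepts allele labels (any hashable dtype) or precomputed frequencies
    (anything array-like summing to 1).  H lies in [0, 1 - 1/a] for a
    distinct alleles and is invariant under relabeling.
    """
    arr = np.asarray(freqs_or_labels)
    if arr.dtype.kind == "f" and arr.ndim == 1 and np.isclose(arr.sum(), 1.0):
        f = arr
    else:
        f = allele_frequencies(arr).to_numpy()
    return float(1.0 - np.sum(np.asarray(f, dtype=float) ** 2))


def local_heterozygosity(pioneer, result: RunResult, when: int | None = None) -> tuple[float, bool]:
    """H over the individuals inside a pioneer's interaction disc.

    ``when`` is the absolute generation at which the disc is evaluated.  By
    default the disc is measured when its occupancy first reaches the fitted
    logistic plateau (K' rounded down), falling back to the end of the run
    if the plateau is never reached.  Returns ``(H, low_n)`` where ``low_n``
    flags discs with fewer than 2 individuals (H = 0 by convention).
    """
    from .saturation_analysis import record_local_occupancy

    state = result.state
    rb = result.params.rb
    px, py, t0 = float(pioneer["x"]), float(pioneer["y"]), int(pioneer["t"])
    t_end = int(result.growth["t"].iloc[-1])
    if when is None:
        trace = record_local_occupancy(pioneer, result)
        when = t_end
        if len(trace.dt) >= 4:
            fit = fit_logistic(trace.dt, trace.count)
            plateau = int(np.floor(fit.K_prime))
            hit = np.flatnonzero(trace.count >= plateau)
            if hit.size:
                when = t0 + int(trace.dt[hit[0]])
    d2 = (state.x - px) ** 2 + (state.y - py) ** 2
    sel = (d2 <= rb * rb) & (state.t_birth <= when)
    labels = state.allele[sel]
    if labels.size < 2:
        return 0.0, True
    return heterozygosity(labels), False


def normalized_local_het(H: float, K: int) -> float:
    """``H / H_N`` with ``H_N = 2 (1/K)(1 - 1/K)``.

    Values above 1 signal that a typical filled disc carries more than one
    non-founder allele, i.e. the breakdown of local founder-takes-all.
    """
    if K < 2:
        raise ValueError(f"normalization requires K >= 2, got {K}")
    H_N = 2.0 * (1.0 / K) * (1.0 - 1.0 / K)
    return H / H_N


def global_het_vs_size(runs, bins_per_decade: int = 20) -> pd.DataFrame:
    """Binned global heterozygosity versus relative population size.

    Pools the per-generation (M/M0, H) points of all runs into log-spaced
    bins of M/M0 (``bins_per_decade`` per decade of the pooled span) and
    reports the within-bin mean, the standard error of that mean, and the
    point count.  Empty bins are dropped.

    ``runs`` is an iterable of :class:`RunResult` (or anything with a
    ``growth`` table carrying M and H and an ``n0``).
    """
    rel, het = [], []
    for r in runs:
        g = r.growth
        if "H" not in g:
            raise ValueError("runs must be tracked with track_heterozygosity=True")
        rel.append(g["M"].to_numpy() / r.n0)
        het.append(g["H"].to_numpy())
    if not rel:
        raise ValueError("global_het_vs_size requires at least one run")
    rel = np.concatenate(rel)
    het = np.concatenate(het)
    lo, hi = np.log10(rel.min()), np.log10(rel.max())
    n_bins = max(1, int(np.ceil((hi - lo) * bins_per_decade)))
    edges = np.logspace(lo, hi, n_bins + 1)
    idx = np.clip(np.digitize(rel, edges) - 1, 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        sel = idx == b
        n = int(sel.sum())
        if n == 0:
            continue
        vals = het[sel]
        sem = float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
        rows.append((float(np.sqrt(edges[b] * edges[b + 1])), float(vals.mean()), sem, n))
    return pd.DataFrame(rows, columns=["M_over_M0", "H_mean", "H_sem", "n"])
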