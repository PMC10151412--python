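"""Numba kernels for the fixed-radius neighbor grid and the establishment sweep.

Established individuals never move or die, so the spatial index only ever
grows.  Two complementary structures back the closed-disc neighbor query
(cells are uniform squares of side ``rb``; a query visits the 3x3 block
around the query point):

* a *compacted* cell-sorted (CSR-style) copy of all individuals established
  up to the last compaction — positions gathered in cell order so a block
  query is three contiguous scans located by lexicographic bisection; and
* an open-addressed hash grid with intrusive per-cell linked lists holding
  only the individuals established *since* the last compaction (a small,
  cache-resident set; the sweep appends here).

Cell coordinates are stored explicitly (no packed keys), so arbitrarily
remote satellites seeded by extreme jumps are handled exactly.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

#: sentinel for an empty hash slot (cell x-coordinates never reach this)
EMPTY = np.int64(2) ** 62


# ---------------------------------------------------------------------------
# hash grid over the not-yet-compacted tail

@njit(cache=True, inline="always")
def _slot_of(cx, cy, table_cx, table_cy):
    """Linear-probe slot for cell (cx, cy): either its slot or the first empty."""
    mask = table_cx.shape[0] - 1
    s = ((cx * np.int64(73856093)) ^ (cy * np.int64(19349663))) & mask
    while True:
        tcx = table_cx[s]
        if tcx == EMPTY or (tcx == cx and table_cy[s] == cy):
            return s
        s = (s + 1) & mask


@njit(cache=True)
def _insert(i, cx, cy, table_cx, table_cy, head, nxt):
    """Prepend individual ``i`` to cell (cx, cy); return 1 if the cell is new."""
    s = _slot_of(cx, cy, table_cx, table_cy)
    if table_cx[s] == EMPTY:
        table_cx[s] = cx
        table_cy[s] = cy
        nxt[i] = -1
        head[s] = i
        return 1
    nxt[i] = head[s]
    head[s] = i
    return 0


@njit(cache=True)
def _rebuild(i0, i1, xs, ys, inv_rb, table_cx, table_cy, head, nxt):
    """Re-insert individuals i0..i1-1 into a cleared table; return the cell count."""
    table_cx[:] = EMPTY
    head[:] = -1
    n_cells = 0
    for i in range(i0, i1):
        cx = np.int64(math.floor(xs[i] * inv_rb))
        cy = np.int64(math.floor(ys[i] * inv_rb))
        n_cells += _insert(i, cx, cy, table_cx, table_cy, head, nxt)
    return n_cells


# ---------------------------------------------------------------------------
# CSR (cell-sorted) part

@njit(cache=True, inline="always")
def _bisect_i64(arr, lo, hi, val):
    """First index in [lo, hi) with arr[index] >= val (arr sorted)."""
    while lo < hi:
        mid = (lo + hi) >> 1
        if arr[mid] < val:
            lo = mid + 1
        else:
            hi = mid
    return lo


@njit(cache=True, inline="always")
def _count_csr(px, py, rb, limit, row_cx, row_cell_start, cell_cy, cell_start,
               s_xy, inv_rb):
    """Closed-disc count over the compacted (cell-sorted) part only.

    Two-level directory: bisect the row of cells with x-index cx+dx in the
    unique-row list, then bisect the cy range within that row's (short,
    contiguous) cell list; individuals of consecutive cells are contiguous,
    so each row contributes one linear scan.  If ``limit > 0`` counting
    stops early once ``limit`` is reached.
    """
    rb2 = rb * rb
    cx = np.int64(math.floor(px * inv_rb))
    cy = np.int64(math.floor(py * inv_rb))
    cnt = 0
    n_rows = row_cx.shape[0]
    for dx in range(-1, 2):
        r = _bisect_i64(row_cx, 0, n_rows, cx + dx)
        if r == n_rows or row_cx[r] != cx + dx:
            continue
        a = _bisect_i64(cell_cy, row_cell_start[r], row_cell_start[r + 1], cy - 1)
        b = _bisect_i64(cell_cy, a, row_cell_start[r + 1], cy + 2)
        if a == b:
            continue
        # branchless hit count over the row's contiguous individuals; the
        # limit is applied between rows, so the clamped return value is
        # min(count, limit) exactly as with per-hit early exit
        row_cnt = 0
        for i in range(cell_start[a], cell_start[b]):
            ddx = s_xy[2 * i] - px
            ddy = s_xy[2 * i + 1] - py
            row_cnt += np.int64(ddx * ddx + ddy * ddy <= rb2)
        cnt += row_cnt
        if limit > 0 and cnt >= limit:
            return limit
    return cnt


@njit(cache=True, inline="always")
def _count_tail(px, py, rb, limit, xs, ys, inv_rb, table_cx, table_cy, head, nxt):
    """Closed-disc count over the not-yet-compacted tail (linked hash grid)."""
    rb2 = rb * rb
    cx = np.int64(math.floor(px * inv_rb))
    cy = np.int64(math.floor(py * inv_rb))
    cnt = 0
    for dx in range(-1, 2):
        for dy in range(-1, 2):
            s = _slot_of(cx + dx, cy + dy, table_cx, table_cy)
            if table_cx[s] == EMPTY:
                continue
            i = head[s]
            while i >= 0:
                ddx = xs[i] - px
                ddy = ys[i] - py
                if ddx * ddx + ddy * ddy <= rb2:
                    cnt += 1
                    if limit > 0 and cnt >= limit:
                        return cnt
                i = nxt[i]
    return cnt


@njit(cache=True)
def _count_disc(px, py, rb, limit,
                row_cx, row_cell_start, cell_cy, cell_start, s_xy,
                xs, ys, inv_rb, table_cx, table_cy, head, nxt):
    """Number of stored individuals with distance <= rb from (px, py).

    Closed disc over both index parts.  If ``limit > 0`` counting stops
    early once ``limit`` is reached (the density check only needs the
    comparison against K).
    """
    cnt = _count_csr(px, py, rb, limit, row_cx, row_cell_start, cell_cy,
                     cell_start, s_xy, inv_rb)
    if limit > 0 and cnt >= limit:
        return cnt
    rem = limit - cnt if limit > 0 else 0
    return cnt + _count_tail(px, py, rb, rem, xs, ys, inv_rb,
                             table_cx, table_cy, head, nxt)


@njit(cache=True)
def _count_static_batch(order, cand_x, cand_y, rb, limit,
                        row_cx, row_cell_start, cell_cy, cell_start, s_xy,
                        inv_rb, out):
    """Static (compacted-part) disc counts for a whole candidate batch.

    The compacted part does not change during a sweep, so these counts are
    order-independent; evaluating them with the candidates visited in cell
    order (``order``) makes consecutive queries hit the same memory.
    """
    for k in range(order.shape[0]):
        j = order[k]
        out[j] = _count_csr(cand_x[j], cand_y[j], rb, limit,
                            row_cx, row_cell_start, cell_cy, cell_start,
                            s_xy, inv_rb)


@njit(cache=True)
def _sweep(j0, cand_x, cand_y, cand_allele, static_count, n, n_cells, t, K, rb, inv_rb,
           xs, ys, alleles, t_birth, nxt, table_cx, table_cy, head,
           survived, ncount, max_cells):
    """Sequentially attempt establishment of candidates ``j0..`` in order.

    ``static_count`` holds each candidate's precomputed disc count over the
    compacted part (clamped at K); the sweep adds the contribution of the
    tail, which includes every offspring established earlier in the same
    sweep, so earlier establishments count toward the density check of
    later offspring.  Pauses (returning the index reached) when the
    individual arrays are full or the hash table load would grow past its
    bound, so the caller can resize and resume.

    Returns ``(j_reached, n, n_cells)``.
    """
    capacity = xs.shape[0]
    total = cand_x.shape[0]
    for j in range(j0, total):
        if n >= capacity or n_cells >= max_cells:
            return j, n, n_cells
        px = cand_x[j]
        py = cand_y[j]
        c = static_count[j]
        if c < K:
            c += _count_tail(px, py, rb, K - c, xs, ys, inv_rb,
                             table_cx, table_cy, head, nxt)
        ncount[j] = c
        if c < K:
            survived[j] = 1
            xs[n] = px
            ys[n] = py
            alleles[n] = cand_allele[j]
            t_birth[n] = t
            cx = np.int64(math.floor(px * inv_rb))
            cy = np.int64(math.floor(py * inv_rb))
            n_cells += _insert(n, cx, cy, table_cx, table_cy, head, nxt)
            n += 1
        else:
            survived[j] = 0
    return total, n, n_cells


def _next_pow2(x: int) -> int:
    return 1 << max(6, int(x - 1).bit_length())


class NeighborGrid:
    """Growable uniform-cell fixed-radius index over immutable 2D points.

    The caller appends points only through :meth:`establish_sweep`
    (density-checked) or :meth:`insert_points` (unchecked bulk insertion,
    used for the founder population).  :meth:`compact` folds the recent
    tail into the cell-sorted layout; callers should invoke it between
    generations (queries are correct either way, compaction only matters
    for speed).
    """

    def __init__(self, rb: float, capacity: int = 4096):
        self.rb = float(rb)
        self.inv_rb = 1.0 / self.rb
        self.capacity = int(capacity)
        self.n = 0
        self.x = np.empty(self.capacity, dtype=np.float64)
        self.y = np.empty(self.capacity, dtype=np.float64)
        self.allele = np.empty(self.capacity, dtype=np.int64)
        self.t_birth = np.empty(self.capacity, dtype=np.int32)
        self._nxt = np.empty(self.capacity, dtype=np.int64)
        self._table_size = _next_pow2(256)
        self._alloc_table()
        self.n_cells = 0
        # compacted (cell-sorted) part, empty to begin with
        self.n_sorted = 0
        self._row_cx = np.empty(0, dtype=np.int64)         # unique cell rows
        self._row_cell_start = np.zeros(1, dtype=np.int64)  # offsets into cell arrays
        self._cell_cy = np.empty(0, dtype=np.int64)        # cy per unique cell
        self._cell_start = np.zeros(1, dtype=np.int64)     # offsets into individuals
        self._s_xy = np.empty(0, dtype=np.float64)  # interleaved (x, y) pairs

    def _alloc_table(self):
        self._table_cx = np.full(self._table_size, EMPTY, dtype=np.int64)
        self._table_cy = np.empty(self._table_size, dtype=np.int64)
        self._head = np.full(self._table_size, -1, dtype=np.int64)

    @property
    def _max_cells(self) -> int:
        # keep the open-addressing load factor at or below 1/4
        return self._table_size // 4

    def _grow_arrays(self, needed: int):
        new_cap = max(needed, int(self.capacity * 1.6) + 1)
        for name in ("x", "y", "allele", "t_birth", "_nxt"):
            old = getattr(self, name)
            new = np.empty(new_cap, dtype=old.dtype)
            new[: self.n] = old[: self.n]
            setattr(self, name, new)
        self.capacity = new_cap

    def _grow_table(self):
        self._table_size *= 2
        self._alloc_table()
        self.n_cells = _rebuild(self.n_sorted, self.n, self.x, self.y, self.inv_rb,
                                self._table_cx, self._table_cy, self._head, self._nxt)

    def compact(self, min_tail: int = 512):
        """Fold the linked-grid tail into the cell-sorted layout.

        A no-op while the tail is shorter than ``min_tail`` (sorting a
        handful of newcomers every generation is not worth the pass over
        the whole population).
        """
        if self.n - self.n_sorted < min_tail:
            return
        cx = np.floor(self.x[: self.n] * self.inv_rb).astype(np.int64)
        cy = np.floor(self.y[: self.n] * self.inv_rb).astype(np.int64)
        order = np.lexsort((cy, cx))
        s_cx = cx[order]
        s_cy = cy[order]
        xy = np.empty(2 * self.n, dtype=np.float64)
        xy[0::2] = self.x[: self.n][order]
        xy[1::2] = self.y[: self.n][order]
        self._s_xy = xy
        # per-cell directory: first individual of each distinct (cx, cy)
        new_cell = np.empty(self.n, dtype=bool)
        new_cell[0] = True
        new_cell[1:] = (s_cx[1:] != s_cx[:-1]) | (s_cy[1:] != s_cy[:-1])
        cell_first = np.flatnonzero(new_cell)
        cell_cx = s_cx[cell_first]
        self._cell_cy = np.ascontiguousarray(s_cy[cell_first])
        self._cell_start = np.append(cell_first, self.n).astype(np.int64)
        # row directory: first cell of each distinct cx
        new_row = np.empty(cell_cx.size, dtype=bool)
        new_row[0] = True
        new_row[1:] = cell_cx[1:] != cell_cx[:-1]
        row_first = np.flatnonzero(new_row)
        self._row_cx = np.ascontiguousarray(cell_cx[row_first])
        self._row_cell_start = np.append(row_first, cell_cx.size).astype(np.int64)
        self.n_sorted = self.n
        self._table_cx[:] = EMPTY
        self._head[:] = -1
        self.n_cells = 0

    def insert_points(self, xs, ys, alleles, t_birth: int):
        """Bulk-insert points without any density check (founders)."""
        m = len(xs)
        if self.n + m > self.capacity:
            self._grow_arrays(self.n + m)
        while self.n_cells + m > self._max_cells:
            self._grow_table()
        sl = slice(self.n, self.n + m)
        self.x[sl] = xs
        self.y[sl] = ys
        self.allele[sl] = alleles
        self.t_birth[sl] = t_birth
        n0 = self.n
        self.n = self.n + m
        self.n_cells = _rebuild(self.n_sorted, self.n, self.x, self.y, self.inv_rb,
                                self._table_cx, self._table_cy, self._head, self._nxt)
        return np.arange(n0, self.n)

    def count(self, px: float, py: float, limit: int = 0) -> int:
        """Closed-disc neighbor count around (px, py); see :func:`_count_disc`."""
        return int(_count_disc(float(px), float(py), self.rb, int(limit),
                               self._row_cx, self._row_cell_start, self._cell_cy,
                               self._cell_start, self._s_xy,
                               self.x, self.y, self.inv_rb,
                               self._table_cx, self._table_cy, self._head, self._nxt))

    def establish_sweep(self, cand_x, cand_y, cand_allele, K: int, t: int):
        """Density-checked sequential establishment of a batch of candidates.

        Returns ``(survived uint8 array, neighbor-count int32 array)``;
        neighbor counts at or above ``K`` are recorded as ``K`` (the check
        only requires the comparison).
        """
        total = len(cand_x)
        survived = np.empty(total, dtype=np.uint8)
        ncount = np.empty(total, dtype=np.int32)
        cand_x = np.ascontiguousarray(cand_x, dtype=np.float64)
        cand_y = np.ascontiguousarray(cand_y, dtype=np.float64)
        cand_allele = np.ascontiguousarray(cand_allele, dtype=np.int64)
        # static part first, visiting candidates in cell order (cache reuse);
        # these counts are independent of the processing order
        ccx = np.floor(cand_x * self.inv_rb).astype(np.int64)
        ccy = np.floor(cand_y * self.inv_rb).astype(np.int64)
        order = np.lexsort((ccy, ccx))
        static_count = np.empty(total, dtype=np.int32)
        _count_static_batch(order, cand_x, cand_y, self.rb, int(K),
                            self._row_cx, self._row_cell_start, self._cell_cy,
                            self._cell_start, self._s_xy, self.inv_rb, static_count)
        j = 0
        while j < total:
            j, self.n, self.n_cells = _sweep(
                j, cand_x, cand_y, cand_allele, static_count,
                self.n, self.n_cells, t,
                int(K), self.rb, self.inv_rb,
                self.x, self.y, self.allele, self.t_birth, self._nxt,
                self._table_cx, self._table_cy, self._head,
                survived, ncount, self._max_cells)
            if j < total:
                if self.n >= self.capacity:
                    self._grow_arrays(self.n + 1)
                if self.n_cells >= self._max_cells:
                    self._grow_table()
        return survived, ncount
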