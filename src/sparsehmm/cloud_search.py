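"""Pruned anti-diagonal flood fill ("cloud search") in linear space.

Starting from a seed cell pair, the forward pass flood-fills the core
Forward recurrence down and to the right one anti-diagonal at a time,
pruning each anti-diagonal in from its two ends once it reaches length
gamma: a cell survives if its match-state value is within alpha of the
best value on its anti-diagonal and within beta of the best value seen so
far anywhere (the X-drop analogue).  A mirrored backward pass runs up and
to the left from the end cell.  The union of the two clouds is trimmed of
protrusions that cannot lie on any begin-to-end path and reoriented into
per-row column intervals, which drive the sparse-matrix stage.

Only three anti-diagonals of DP values are ever resident (a 3-row matrix
recycled mod 3), and each anti-diagonal's bound is stored as just its
lower-left and upper-right cells, so both passes run in linear space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._numerics import NEG_INF, logsumexp2, logsumexp3
from .profile import ProfileHMM, TargetSequence


@dataclass(frozen=True)
class Seed:
    """Begin/end anchor cells for cloud search, 1-based inclusive."""

    ib: int
    jb: int
    ie: int
    je: int
    score: float = float("nan")
    pvalue: float = float("nan")

    def validate(self, m: int, n: int) -> None:
        if not (1 <= self.ib <= self.ie <= m and 1 <= self.jb <= self.je <= n):
            raise ValueError(
                f"seed ({self.ib},{self.jb})-({self.ie},{self.je}) outside "
                f"{m}x{n} matrix")


@dataclass(frozen=True)
class PruneParams:
    """Cloud-search pruning knobs.

    alpha: per-anti-diagonal drop-off in nats; beta: global drop-off in
    nats; gamma: minimum anti-diagonal length before any pruning applies.
    """

    alpha: float = 12.0
    beta: float = 20.0
    gamma: int = 5

    def __post_init__(self):
        if not (self.alpha > 0 and self.beta > 0 and self.gamma >= 1):
            raise ValueError("require alpha > 0, beta > 0, gamma >= 1")


class NonIntersecting(Exception):
    """Forward and backward clouds share no cell."""


@dataclass
class CloudScores:
    best_fwd: float
    best_infwd: float
    best_bkwd: float
    best_inbkwd: float

    def validate(self) -> None:
        if self.best_fwd < self.best_infwd or self.best_bkwd < self.best_inbkwd:
            raise ValueError("running maxima cannot decrease")


class CloudMatrix:
    """Three reusable DP rows indexed by anti-diagonal mod 3.

    The value for implicit-matrix cell (i, j) lives at row (i+j) mod 3,
    column j; writing anti-diagonal d reuses the row that held d-3.
    """

    def __init__(self, width: int):
        self.width = width
        self.m = np.full((3, width), NEG_INF)
        self.i = np.full((3, width), NEG_INF)
        self.d = np.full((3, width), NEG_INF)

    @staticmethod
    def row_for(d: int) -> int:
        return d % 3

    def clear_diag(self, d: int) -> None:
        r = self.row_for(d)
        self.m[r].fill(NEG_INF)
        self.i[r].fill(NEG_INF)
        self.d[r].fill(NEG_INF)

    def set_cell(self, i: int, j: int, vm: float, vi: float, vd: float) -> None:
        r = self.row_for(i + j)
        self.m[r, j] = vm
        self.i[r, j] = vi
        self.d[r, j] = vd

    def get_m(self, i: int, j: int) -> float:
        return float(self.m[self.row_for(i + j), j])


class AntiDiagBounds:
    """Per-anti-diagonal inclusive cell ranges, stored as i-intervals.

    For anti-diagonal d the retained cells are (i, d - i) for
    lo_i <= i <= hi_i; the lower-left bounding cell is (hi_i, d - hi_i)
    and the upper-right cell is (lo_i, d - lo_i) — exactly two cell pairs
    per anti-diagonal.
    """

    def __init__(self):
        self._b: dict[int, tuple[int, int]] = {}

    def set(self, d: int, lo_i: int, hi_i: int) -> None:
        if lo_i > hi_i:
            raise ValueError("empty bound")
        self._b[d] = (lo_i, hi_i)

    def get(self, d: int):
        return self._b.get(d)

    def remove(self, d: int) -> None:
        self._b.pop(d, None)

    @property
    def diagonals(self) -> list[int]:
        return sorted(self._b)

    def __len__(self) -> int:
        return len(self._b)

    def __contains__(self, d: int) -> bool:
        return d in self._b

    def lower_left(self, d: int) -> tuple[int, int]:
        lo, hi = self._b[d]
        return hi, d - hi

    def upper_right(self, d: int) -> tuple[int, int]:
        lo, hi = self._b[d]
        return lo, d - lo

    def cells(self):
        for d in self.diagonals:
            lo, hi = self._b[d]
            for i in range(lo, hi + 1):
                yield i, d - i

    def cell_set(self) -> set:
        return set(self.cells())

    def num_cells(self) -> int:
        return sum(hi - lo + 1 for lo, hi in self._b.values())

    def copy(self) -> "AntiDiagBounds":
        out = AntiDiagBounds()
        out._b = dict(self._b)
        return out


class RowBounds:
    """Per-row inclusive column intervals [left_i, right_i]."""

    def __init__(self, bounds: dict[int, tuple[int, int]] | None = None):
        self._b: dict[int, tuple[int, int]] = dict(bounds or {})
        for i, (l, r) in self._b.items():
            if l > r:
                raise ValueError(f"row {i}: empty interval")

    @classmethod
    def full_matrix(cls, m: int, n: int) -> "RowBounds":
        return cls({i: (0, n) for i in range(0, m + 1)})

    def set(self, i: int, left: int, right: int) -> None:
        if left > right:
            raise ValueError(f"row {i}: empty interval")
        self._b[i] = (left, right)

    def get(self, i: int):
        return self._b.get(i)

    @property
    def rows(self) -> list[int]:
        return sorted(self._b)

    def __contains__(self, i: int) -> bool:
        return i in self._b

    def __len__(self) -> int:
        return len(self._b)

    def cells(self):
        for i in self.rows:
            l, r = self._b[i]
            for j in range(l, r + 1):
                yield i, j

    def cell_set(self) -> set:
        return set(self.cells())

    def num_cells(self) -> int:
        return sum(r - l + 1 for l, r in self._b.values())

    def items(self):
        return ((i, self._b[i]) for i in self.rows)


# ---------------------------------------------------------------------------
# Pruning
# ---------------------------------------------------------------------------

def prune_antidiagonal(
    values: np.ndarray,
    max_d: float,
    max_o: float,
    params: PruneParams,
    length_so_far: int | None = None,
):
    """Apply the two drop-off rules to one anti-diagonal of match values.

    ``values`` are the F^M scores of the cells currently on the
    anti-diagonal, in index order; ``max_d`` is their maximum and ``max_o``
    the best score seen anywhere so far.  Cells are pruned in from the two
    ends only, so the retained range stays contiguous; interior cells below
    threshold survive.  Returns the inclusive retained index range, or
    ``None`` when every cell is pruned (flood fill stops).  Anti-diagonals
    shorter than gamma are never pruned.
    """
    k = len(values)
    if length_so_far is None:
        length_so_far = k
    if length_so_far < params.gamma:
        return (0, k - 1) if k else None
    thr = max(max_d - params.alpha, max_o - params.beta)
    lo, hi = 0, k - 1
    while lo <= hi and values[lo] < thr:
        lo += 1
    while hi >= lo and values[hi] < thr:
        hi -= 1
    if lo > hi:
        return None
    return lo, hi


# ---------------------------------------------------------------------------
# Flood fill passes
# ---------------------------------------------------------------------------

def _core_scores(hmm: ProfileHMM, seq: TargetSequence):
    msc = hmm.match_scores()
    tr = hmm.log_transitions()
    return msc[:, seq.residues], tr  # (m+1, n) match scores by target column


def cloud_search_forward(
    hmm: ProfileHMM,
    seq: TargetSequence,
    seed: Seed,
    params: PruneParams = PruneParams(),
    values_out: dict | None = None,
):
    """Flood fill down-right from the seed begin cell.

    Initializes F^M = F^I = F^D = 0 at (ib, jb) and expands by
    anti-diagonals under the Forward (log-sum) core recurrence, recording
    one bound per anti-diagonal.  Returns ``(bounds, best_fwd, best_infwd)``
    where best_fwd is the best match-state score seen anywhere and
    best_infwd the best seen up to and including the anti-diagonal that
    contains the end cell.
    """
    m, n = hmm.m, seq.n
    seed.validate(m, n)
    emit, tr = _core_scores(hmm, seq)
    cm = CloudMatrix(n + 2)
    bounds = AntiDiagBounds()
    ib, jb, ie, je = seed.ib, seed.jb, seed.ie, seed.je
    d0, d_end = ib + jb, ie + je
    cm.set_cell(ib, jb, 0.0, 0.0, 0.0)
    bounds.set(d0, ib, ib)
    best = 0.0
    best_in = 0.0 if d0 == d_end else None
    prev = (ib, ib)
    prev_d = d0
    prev2 = None
    for d in range(d0 + 1, m + n + 1):
        lo = prev[0]
        hi = prev[1] + 1
        if prev2 is not None:
            lo = min(lo, prev2[0] + 1)
            hi = max(hi, prev2[1] + 1)
        lo = max(lo, ib, d - n)
        hi = min(hi, m, d - jb)
        if lo > hi:
            break
        ii = np.arange(lo, hi + 1)
        jj = d - ii
        r1 = cm.row_for(d - 1)
        r2 = cm.row_for(d - 2)
        # predecessors: (i-1, j-1) on d-2; (i, j-1) and (i-1, j) on d-1
        vm = emit[ii, jj - 1] + logsumexp3(
            cm.m[r2, jj - 1] + tr["mm"][ii - 1],
            cm.i[r2, jj - 1] + tr["im"][ii - 1],
            cm.d[r2, jj - 1] + tr["dm"][ii - 1])
        vi = logsumexp2(cm.m[r1, jj - 1] + tr["mi"][ii],
                        cm.i[r1, jj - 1] + tr["ii"][ii])
        vd = logsumexp2(cm.m[r1, jj] + tr["md"][ii - 1],
                        cm.d[r1, jj] + tr["dd"][ii - 1])
        max_d = float(vm.max())
        best = max(best, max_d)
        keep = prune_antidiagonal(vm, max_d, best, params)
        if keep is None:
            break
        klo, khi = lo + keep[0], lo + keep[1]
        cm.clear_diag(d)
        r = cm.row_for(d)
        sl = slice(keep[0], keep[1] + 1)
        cm.m[r, jj[sl]] = vm[sl]
        cm.i[r, jj[sl]] = vi[sl]
        cm.d[r, jj[sl]] = vd[sl]
        bounds.set(d, klo, khi)
        if values_out is not None:
            for k_ in range(keep[0], keep[1] + 1):
                values_out[(int(ii[k_]), int(jj[k_]))] = float(vm[k_])
        prev2 = prev if prev_d == d - 1 else None
        prev = (klo, khi)
        prev_d = d
        if d == d_end:
            best_in = best
    if best_in is None:
        best_in = best  # pass stopped before reaching the end anti-diagonal
    return bounds, best, best_in


def cloud_search_backward(
    hmm: ProfileHMM,
    seq: TargetSequence,
    seed: Seed,
    params: PruneParams = PruneParams(),
    values_out: dict | None = None,
):
    """Mirror pass: flood fill up-left from the seed end cell."""
    m, n = hmm.m, seq.n
    seed.validate(m, n)
    emit, tr = _core_scores(hmm, seq)
    cm = CloudMatrix(n + 2)
    bounds = AntiDiagBounds()
    ib, jb, ie, je = seed.ib, seed.jb, seed.ie, seed.je
    d0, d_end = ie + je, ib + jb
    cm.set_cell(ie, je, 0.0, 0.0, 0.0)
    bounds.set(d0, ie, ie)
    best = 0.0
    best_in = 0.0 if d0 == d_end else None
    prev = (ie, ie)
    prev_d = d0
    prev2 = None
    for d in range(d0 - 1, 1, -1):
        # successors: (i+1, j+1) on d+2; (i, j+1) and (i+1, j) on d+1
        lo = prev[0] - 1
        hi = prev[1]
        if prev2 is not None:
            lo = min(lo, prev2[0] - 1)
            hi = max(hi, prev2[1] - 1)
        lo = max(lo, 1, d - je)
        hi = min(hi, ie, d - 1)
        if lo > hi:
            break
        ii = np.arange(lo, hi + 1)
        jj = d - ii
        r1 = cm.row_for(d + 1)
        r2 = cm.row_for(d + 2)
        # successor M at (i+1, j+1) emits target residue at column j+1;
        # clipped indices pair with -inf cloud values at the matrix edge
        safe_next = np.minimum(ii + 1, m)
        a = emit[safe_next, np.minimum(jj, n - 1)] + cm.m[r2, jj + 1]
        a[ii + 1 > m] = NEG_INF
        vm = logsumexp3(
            a + tr["mm"][ii],
            cm.i[r1, jj + 1] + tr["mi"][ii],
            cm.d[r1, jj] + tr["md"][ii])
        vi = logsumexp2(a + tr["im"][ii], cm.i[r1, jj + 1] + tr["ii"][ii])
        vd = logsumexp2(a + tr["dm"][ii], cm.d[r1, jj] + tr["dd"][ii])
        max_d = float(vm.max())
        best = max(best, max_d)
        keep = prune_antidiagonal(vm, max_d, best, params)
        if keep is None:
            break
        klo, khi = lo + keep[0], lo + keep[1]
        cm.clear_diag(d)
        r = cm.row_for(d)
        sl = slice(keep[0], keep[1] + 1)
        cm.m[r, jj[sl]] = vm[sl]
        cm.i[r, jj[sl]] = vi[sl]
        cm.d[r, jj[sl]] = vd[sl]
        bounds.set(d, klo, khi)
        if values_out is not None:
            for k_ in range(keep[0], keep[1] + 1):
                values_out[(int(ii[k_]), int(jj[k_]))] = float(vm[k_])
        prev2 = prev if prev_d == d + 1 else None
        prev = (klo, khi)
        prev_d = d
        if d == d_end:
            best_in = best
    if best_in is None:
        best_in = best
    return bounds, best, best_in


# ---------------------------------------------------------------------------
# Union, fallback, trim, reorient
# ---------------------------------------------------------------------------

def cloud_union(fwd: AntiDiagBounds, bkwd: AntiDiagBounds) -> AntiDiagBounds:
    """Covering union of the two clouds, anti-diagonal by anti-diagonal.

    Anti-diagonals present in only one input pass through unchanged.
    Raises :class:`NonIntersecting` when no anti-diagonal has overlapping
    forward and backward intervals (the caller falls back to the seed
    rectangle).
    """
    intersects = False
    out = AntiDiagBounds()
    for d in sorted(set(fwd.diagonals) | set(bkwd.diagonals)):
        a, b = fwd.get(d), bkwd.get(d)
        if a and b:
            if a[0] <= b[1] and b[0] <= a[1]:
                intersects = True
            out.set(d, min(a[0], b[0]), max(a[1], b[1]))
        else:
            lo, hi = a or b
            out.set(d, lo, hi)
    if not intersects:
        raise NonIntersecting("forward and backward clouds share no cell")
    return out


def fallback_rectangle(seed: Seed) -> RowBounds:
    """Rectangular region bounded by the seed begin/end cells."""
    return RowBounds({i: (seed.jb, seed.je)
                      for i in range(seed.ib, seed.ie + 1)})


def _clip_sweep(t: "AntiDiagBounds", use_hull: bool, forward: bool) -> None:
    """One clipping sweep over the bounds, in place.

    ``use_hull``: clip to the covering hull of cells reachable from the
    previous two retained bounds (the interval approximation of graph
    reachability, diagonal steps included).  Otherwise clip against the
    single adjacent bound only, which makes both interval endpoints
    monotone across anti-diagonals and therefore forces row contiguity.
    """
    ds = t.diagonals
    order = ds[1:] if forward else list(reversed(ds[:-1]))
    step = -1 if forward else 1
    for d in order:
        cur = t.get(d)
        if cur is None:
            continue
        p1 = t.get(d + step)
        p2 = t.get(d + 2 * step) if use_hull else None
        lo = hi = None
        if p1 is not None:
            lo, hi = (p1[0], p1[1] + 1) if forward else (p1[0] - 1, p1[1])
        if p2 is not None:
            d2 = (p2[0] + 1, p2[1] + 1) if forward else (p2[0] - 1, p2[1] - 1)
            lo = d2[0] if lo is None else min(lo, d2[0])
            hi = d2[1] if hi is None else max(hi, d2[1])
        if lo is None:
            t.remove(d)
            continue
        nlo, nhi = max(cur[0], lo), min(cur[1], hi)
        if nlo > nhi:
            t.remove(d)
        else:
            t.set(d, nlo, nhi)


def _rows_contiguous(t: "AntiDiagBounds") -> bool:
    left: dict[int, int] = {}
    right: dict[int, int] = {}
    count: dict[int, int] = {}
    for d in t.diagonals:
        lo, hi = t.get(d)
        for i in range(lo, hi + 1):
            left[i] = min(left.get(i, d - i), d - i)
            right[i] = max(right.get(i, d - i), d - i)
            count[i] = count.get(i, 0) + 1
    return all(right[i] - left[i] + 1 == count[i] for i in left)


def trim_cloud(u: AntiDiagBounds) -> AntiDiagBounds:
    """Remove protrusion cells that cannot join begin-to-end paths.

    A forward sweep clips each anti-diagonal bound to the hull of cells
    reachable from the previous two retained bounds; a reverse sweep clips
    to cells that can still reach the following two.  In the rare case
    where the clipped cloud still has a gap inside some matrix row (cells
    whose only support is a diagonal step over a pruned anti-diagonal), a
    stricter pass clips against single adjacent bounds only; that makes
    both interval endpoints monotone across anti-diagonals and therefore
    guarantees one contiguous column run per row — the property the flat
    sparse layout relies on.
    """
    t = u.copy()
    if not t.diagonals:
        return t
    _clip_sweep(t, use_hull=True, forward=True)
    _clip_sweep(t, use_hull=True, forward=False)
    if not _rows_contiguous(t):
        _clip_sweep(t, use_hull=False, forward=True)
        _clip_sweep(t, use_hull=False, forward=False)
    return t


def reorient_to_rows(t: AntiDiagBounds) -> RowBounds:
    """Re-express trimmed anti-diagonal bounds as per-row column intervals.

    The cell set is identical under both representations; a row with a gap
    (which trimming is meant to rule out) raises ``ValueError``.
    """
    left: dict[int, int] = {}
    right: dict[int, int] = {}
    count: dict[int, int] = {}
    for d in t.diagonals:
        lo, hi = t.get(d)
        for i in range(lo, hi + 1):
            j = d - i
            left[i] = min(left.get(i, j), j)
            right[i] = max(right.get(i, j), j)
            count[i] = count.get(i, 0) + 1
    rb = RowBounds()
    for i in sorted(left):
        if right[i] - left[i] + 1 != count[i]:
            raise ValueError(f"row {i} is not contiguous after trimming")
        rb.set(i, left[i], right[i])
    return rb


def cloud_fraction(rb: RowBounds, m: int, n: int) -> float:
    """Fraction of the full (m+1)(n+1) matrix covered by the cloud."""
    return rb.num_cells() / float((m + 1) * (n + 1))
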