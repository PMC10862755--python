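"""Flat-array sparse matrix over row bounds, and sparse Forward/Backward.

The cloud's per-row column intervals are laid out in one flat array, one
slot per (M, I, D) value triple, with padding slots around each row's run
so that every recurrence dependency of every cloud cell — (i-1, j-1),
(i-1, j) and (i, j-1) — resolves to an allocated slot.  Retrieval of the
slot for logical cell (i, j) is ``block_offset[i] + (j - row_offset[i])``.
Padding slots hold the log-space additive identity (-inf, probability
zero) and are never written by the DP, so cells outside the cloud
implicitly contribute zero probability.

With a layout covering the full matrix, sparse Forward/Backward,
posterior decoding and MEA reproduce the dense reference results.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._numerics import (NEG_INF, log_chain_backward, log_chain_forward,
                        logsumexp2, logsumexp4)
from .cloud_search import RowBounds
from .profile import ProfileHMM, TargetSequence
from .reference_dp import Alignment, SpecialParams, _mea_from_grids


@dataclass
class SparseLayout:
    """Offset tables mapping logical (row, column) cells to the flat array.

    ``row_offset[i]`` is the column index of the first allocated slot of
    row i; ``block_offset[i]`` is that slot's flat-array index, so cell
    (i, j) retrieves ``block_offset[i] + (j - row_offset[i])``.  Slot 0 is
    a shared sentinel padding slot serving any lookup outside every
    allocated span (including rows absent from the cloud).
    """

    m: int
    n: int
    rows: list
    active: dict      # row -> (left, right) cloud columns
    alloc: dict       # row -> (aleft, aright) allocated columns
    row_offset: dict  # row -> aleft
    block_offset: dict
    size: int
    n_active: int

    @property
    def n_padding(self) -> int:
        return self.size - self.n_active

    def index(self, i: int, j: int) -> int:
        """Flat slot for logical cell (i, j); sentinel 0 if unallocated."""
        a = self.alloc.get(i)
        if a is None or not (a[0] <= j <= a[1]):
            return 0
        return self.block_offset[i] + (j - self.row_offset[i])

    def is_active(self, i: int, j: int) -> bool:
        a = self.active.get(i)
        return a is not None and a[0] <= j <= a[1]

    def active_cells(self):
        for i in self.rows:
            l, r = self.active[i]
            for j in range(l, r + 1):
                yield i, j


def build_layout(rb: RowBounds, m: int | None = None,
                 n: int | None = None) -> SparseLayout:
    """Build flat-array offsets (plus padding) for a set of row bounds.

    Each row's run is extended one column left (serving its own (i, j-1)
    lookups) and widened to cover the dependency columns of the row below,
    so no DP lookup ever leaves the allocated array.  Rows outside the
    cloud resolve to the shared sentinel slot.
    """
    rows = rb.rows
    if not rows:
        raise ValueError("empty row bounds")
    active = {i: rb.get(i) for i in rows}
    m = rows[-1] if m is None else m
    n = max(r for _, r in active.values()) if n is None else n
    alloc = {}
    for i in rows:
        l, r = active[i]
        aleft, aright = l - 1, r
        below = active.get(i + 1)
        if below is not None:
            # row i serves the (i, j-1) / (i, j) lookups of row i+1
            aleft = min(aleft, below[0] - 1)
            aright = max(aright, below[1])
        alloc[i] = (aleft, aright)
    block_offset = {}
    row_offset = {}
    cur = 1  # slot 0 is the shared sentinel
    for i in rows:
        aleft, aright = alloc[i]
        row_offset[i] = aleft
        block_offset[i] = cur
        cur += aright - aleft + 1
    n_active = sum(r - l + 1 for l, r in active.values())
    return SparseLayout(m=m, n=n, rows=list(rows), active=active, alloc=alloc,
                        row_offset=row_offset, block_offset=block_offset,
                        size=cur, n_active=n_active)


@dataclass
class SparseCells:
    """Flat M/I/D value arrays over a layout (log space), plus the
    per-column special-state rows of the pass that produced them."""

    layout: SparseLayout
    m: np.ndarray
    i: np.ndarray
    d: np.ndarray
    specials: dict = field(default_factory=dict)

    @classmethod
    def zeros(cls, layout: SparseLayout) -> "SparseCells":
        return cls(layout, np.full(layout.size, NEG_INF),
                   np.full(layout.size, NEG_INF), np.full(layout.size, NEG_INF))

    def get(self, state: str, i: int, j: int) -> float:
        return float(getattr(self, state.lower())[self.layout.index(i, j)])

    def padding_is_clean(self) -> bool:
        """True iff every non-active slot still holds -inf."""
        mask = np.ones(self.layout.size, dtype=bool)
        for i, j in self.layout.active_cells():
            mask[self.layout.index(i, j)] = False
        return all(np.all(a[mask] == NEG_INF) for a in (self.m, self.i, self.d))


def _blank(n: int) -> np.ndarray:
    return np.full(n + 2, NEG_INF)


def _store_row(arr: np.ndarray, layout: SparseLayout, i: int,
               vals: np.ndarray, left: int, right: int) -> None:
    b = layout.block_offset[i] + (left - layout.row_offset[i])
    arr[b : b + (right - left + 1)] = vals


def sparse_forward(hmm: ProfileHMM, seq: TargetSequence,
                   layout: SparseLayout) -> tuple[float, SparseCells]:
    """Forward restricted to the cloud; other cells carry zero probability.

    Returns the sparse Forward score in nats and the filled cells (with
    the N/B/E/C special rows attached for posterior decoding).
    """
    m, n = hmm.m, seq.n
    msc = hmm.match_scores()
    tr = hmm.log_transitions()
    sp = SpecialParams.for_model(hmm, n)
    x = seq.residues
    cells = SparseCells.zeros(layout)
    fn = np.arange(n + 1) * sp.loop
    fb = fn + sp.move
    fe = np.full(n + 1, NEG_INF)
    prev_m, prev_i, prev_d = _blank(n), _blank(n), _blank(n)
    prev_row = None
    for i in layout.rows:
        if i == 0 or i > m:
            prev_row = i
            continue
        if prev_row != i - 1:
            prev_m, prev_i, prev_d = _blank(n), _blank(n), _blank(n)
        l, r = layout.active[i]
        l = max(l, 1)
        if l > r:
            prev_row = None
            continue
        jj = np.arange(l, r + 1)
        # prev rows hold column c at slot c+1: (i-1, j-1) -> jj, (i-1, j) -> jj+1
        cur_m = msc[i, x[jj - 1]] + logsumexp4(
            prev_m[jj] + tr["mm"][i - 1],
            prev_i[jj] + tr["im"][i - 1],
            prev_d[jj] + tr["dm"][i - 1],
            fb[jj - 1] + sp.entry[i],
        )
        cur_d = logsumexp2(prev_m[jj + 1] + tr["md"][i - 1],
                           prev_d[jj + 1] + tr["dd"][i - 1])
        cur_i = log_chain_forward(
            np.concatenate([[NEG_INF], cur_m[:-1]]) + tr["mi"][i], tr["ii"][i])
        fe[jj] = logsumexp2(fe[jj], cur_m)
        _store_row(cells.m, layout, i, cur_m, l, r)
        _store_row(cells.i, layout, i, cur_i, l, r)
        _store_row(cells.d, layout, i, cur_d, l, r)
        prev_m, prev_i, prev_d = _blank(n), _blank(n), _blank(n)
        prev_m[jj + 1] = cur_m
        prev_i[jj + 1] = cur_i
        prev_d[jj + 1] = cur_d
        prev_row = i
    fc = log_chain_forward(fe, sp.loop)
    score = float(fc[n] + sp.move)
    cells.specials = {"N": fn, "B": fb, "E": fe, "C": fc}
    return score, cells


def sparse_backward(hmm: ProfileHMM, seq: TargetSequence,
                    layout: SparseLayout) -> tuple[float, SparseCells]:
    """Backward restricted to the cloud; total matches sparse Forward."""
    m, n = hmm.m, seq.n
    msc = hmm.match_scores()
    tr = hmm.log_transitions()
    sp = SpecialParams.for_model(hmm, n)
    x = seq.residues
    cells = SparseCells.zeros(layout)
    bc = sp.move + (n - np.arange(n + 1)) * sp.loop
    be = bc.copy()
    bb = np.full(n + 1, NEG_INF)
    next_m, next_d = _blank(n), _blank(n)
    next_row = None
    for i in reversed(layout.rows):
        if i == 0 or i > m:
            next_row = i
            continue
        if next_row != i + 1:
            next_m, next_d = _blank(n), _blank(n)
        l, r = layout.active[i]
        l = max(l, 0)
        if l > r:
            next_row = None
            continue
        jj = np.arange(l, r + 1)
        # a[j] = emission at column j+1 by node i+1, paired with M(i+1, j+1)
        a = np.full(r - l + 1, NEG_INF)
        if i < m:
            in_range = jj < n
            jr = jj[in_range]
            a[in_range] = msc[i + 1, x[jr]] + next_m[jr + 2]
        cur_d = logsumexp2(a + tr["dm"][i], next_d[jj + 1] + tr["dd"][i])
        cur_i = log_chain_backward(a + tr["im"][i], tr["ii"][i])
        # M -> I uses the same-row right neighbor I(i, j+1)
        ni_shift = np.concatenate([cur_i[1:], [NEG_INF]])
        cur_m = logsumexp4(a + tr["mm"][i], ni_shift + tr["mi"][i],
                           next_d[jj + 1] + tr["md"][i], be[jj])
        valid = jj >= 1
        jv = jj[valid]
        contrib = np.full(n + 1, NEG_INF)
        contrib[jv - 1] = cur_m[valid] + msc[i, x[jv - 1]] + sp.entry[i]
        bb = np.logaddexp(bb, contrib)
        _store_row(cells.m, layout, i, cur_m, l, r)
        _store_row(cells.i, layout, i, cur_i, l, r)
        _store_row(cells.d, layout, i, cur_d, l, r)
        next_m, next_d = _blank(n), _blank(n)
        next_m[jj + 1] = cur_m
        next_d[jj + 1] = cur_d
        next_row = i
    bn = log_chain_backward(bb + sp.move, sp.loop)
    score = float(bn[0])
    cells.specials = {"N": bn, "B": bb, "E": be, "C": bc}
    return score, cells


@dataclass
class SparsePosterior:
    """Posterior cell probabilities over a layout, probability space."""

    layout: SparseLayout
    pm: np.ndarray
    pi: np.ndarray
    pd: np.ndarray
    pn: np.ndarray
    pc: np.ndarray
    total: float

    def get(self, state: str, i: int, j: int) -> float:
        return float(getattr(self, "p" + state.lower())[self.layout.index(i, j)])

    def dense(self):
        """Dense (m+1, n+1) grids; zero outside the cloud."""
        mm, n = self.layout.m, self.layout.n
        out = []
        for arr in (self.pm, self.pi, self.pd):
            g = np.zeros((mm + 1, n + 1))
            for i in self.layout.rows:
                l, r = self.layout.active[i]
                b = self.layout.block_offset[i] + (l - self.layout.row_offset[i])
                g[i, l : r + 1] = arr[b : b + (r - l + 1)]
            out.append(g)
        return out


def sparse_posterior(fwd: SparseCells, bkwd: SparseCells,
                     layout: SparseLayout) -> SparsePosterior:
    """Cellwise fwd*bkwd normalized by total probability; zero off-cloud."""
    n = layout.n
    move = float(np.log(2.0 / (n + 2.0)))
    total = float(fwd.specials["C"][n] + move)
    if not np.isfinite(total):
        z = np.zeros(layout.size)
        zn = np.zeros(n + 1)
        return SparsePosterior(layout, z, z.copy(), z.copy(), zn, zn.copy(),
                               total)
    with np.errstate(over="ignore", invalid="ignore"):
        pm = np.exp(fwd.m + bkwd.m - total)
        pi = np.exp(fwd.i + bkwd.i - total)
        pd = np.exp(fwd.d + bkwd.d - total)
        loop = float(np.log(n / (n + 2.0)))
        fn, fc = fwd.specials["N"], fwd.specials["C"]
        bn, bc = bkwd.specials["N"], bkwd.specials["C"]
        pn = np.zeros(n + 1)
        pc = np.zeros(n + 1)
        pn[1:] = np.exp(fn[:-1] + loop + bn[1:] - total)
        pc[1:] = np.exp(fc[:-1] + loop + bc[1:] - total)
    for a in (pm, pi, pd, pn, pc):
        np.nan_to_num(a, copy=False, nan=0.0, posinf=1.0)
        np.clip(a, 0.0, 1.0, out=a)
    pm[0] = pi[0] = pd[0] = 0.0  # sentinel slot stays zero
    return SparsePosterior(layout, pm, pi, pd, pn, pc, total)


def sparse_mea(post: SparsePosterior, layout: SparseLayout) -> Alignment:
    """Maximum expected accuracy alignment confined to the cloud."""
    pm, pi, pd = post.dense()
    allowed = np.zeros((layout.m + 1, layout.n + 1), dtype=bool)
    for i in layout.rows:
        if i < 1:
            continue
        l, r = layout.active[i]
        allowed[i, max(l, 1) : r + 1] = True
    return _mea_from_grids(pm, pi, pd, allowed=allowed)
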