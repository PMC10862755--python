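"""Full-matrix Forward, Backward, Viterbi, posterior decoding and MEA.

This module computes over the complete (m+1) x (n+1) dynamic-programming
space and serves both as the correctness reference for the sparse
implementation and as the ``--full-dp`` execution path of the pipeline.

Model wrapper: HMMER3-style local alignment with special states
S -> N -> B -> (core) -> E -> C -> T.  Entry into match state i carries
probability 2(m-i+1)/(m(m+1)) (the uniform-fragment-length convention);
exit to E is allowed from every match state with probability one (the
implicit local model); N and C emit flanking residues under the background
with a target-length model loop = n/(n+2), move = 2/(n+2).  There is no J
state: multi-domain paths are out of scope.  All values are natural-log
odds ratios against the background null.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._numerics import (LN2, NEG_INF, log_chain_backward, log_chain_forward,
                        logsumexp2, logsumexp4, max_chain_forward)
from .profile import ProfileHMM, TargetSequence


@dataclass
class SpecialParams:
    """Local-alignment wrapper scores for a given target length."""

    entry: np.ndarray  # (m+1,) log B->M_i
    loop: float        # log N->N == log C->C
    move: float        # log N->B == log C->T

    @classmethod
    def for_model(cls, hmm: ProfileHMM, n: int) -> "SpecialParams":
        m = hmm.m
        entry = np.full(m + 1, NEG_INF)
        entry[1:] = np.log(2.0 * (m - np.arange(1, m + 1) + 1.0) / (m * (m + 1.0)))
        return cls(entry=entry,
                   loop=float(np.log(n / (n + 2.0))),
                   move=float(np.log(2.0 / (n + 2.0))))


@dataclass
class DpMatrices:
    """Dense log-space DP values: three core grids plus special-state rows."""

    fm: np.ndarray
    fi: np.ndarray
    fd: np.ndarray
    specials: dict[str, np.ndarray]
    score: float


@dataclass
class PosteriorMatrix:
    """Per-cell probability of lying on the true alignment path."""

    pm: np.ndarray
    pi: np.ndarray
    pd: np.ndarray
    pn: np.ndarray  # P(residue j emitted by N)
    pc: np.ndarray  # P(residue j emitted by C)
    total: float


@dataclass
class Alignment:
    """A single reported query-target alignment."""

    qstart: int
    qend: int
    tstart: int
    tend: int
    path: list = field(default_factory=list)  # (state, i, j) triples
    posteriors: list = field(default_factory=list)
    score_nats: float = float("nan")
    gain: float = float("nan")
    bits: float = float("nan")
    pvalue: float = float("nan")
    evalue: float = float("nan")

    @property
    def is_empty(self) -> bool:
        return not self.path


def _core_arrays(hmm: ProfileHMM, seq: TargetSequence):
    msc = hmm.match_scores()
    tr = hmm.log_transitions()
    x = seq.residues
    return msc, tr, x


# ---------------------------------------------------------------------------
# Forward / Backward
# ---------------------------------------------------------------------------

def forward_full(hmm: ProfileHMM, seq: TargetSequence) -> DpMatrices:
    """Forward algorithm over the complete matrix (log-sum recurrence)."""
    m, n = hmm.m, seq.n
    msc, tr, x = _core_arrays(hmm, seq)
    sp = SpecialParams.for_model(hmm, n)
    fm = np.full((m + 1, n + 1), NEG_INF)
    fi = np.full((m + 1, n + 1), NEG_INF)
    fd = np.full((m + 1, n + 1), NEG_INF)
    fn = np.arange(n + 1) * sp.loop
    fb = fn + sp.move
    fe = np.full(n + 1, NEG_INF)
    for i in range(1, m + 1):
        pm_, pi_, pd_ = fm[i - 1], fi[i - 1], fd[i - 1]
        fm[i, 1:] = msc[i, x] + logsumexp4(
            pm_[:-1] + tr["mm"][i - 1],
            pi_[:-1] + tr["im"][i - 1],
            pd_[:-1] + tr["dm"][i - 1],
            fb[:-1] + sp.entry[i],
        )
        fd[i, :] = logsumexp2(pm_ + tr["md"][i - 1], pd_ + tr["dd"][i - 1])
        fi[i, 1:] = log_chain_forward(fm[i, :-1] + tr["mi"][i], tr["ii"][i])
        fe = logsumexp2(fe, fm[i])
    fc = log_chain_forward(fe, sp.loop)
    score = float(fc[n] + sp.move)
    return DpMatrices(fm, fi, fd,
                      {"N": fn, "B": fb, "E": fe, "C": fc}, score)


def backward_full(hmm: ProfileHMM, seq: TargetSequence) -> DpMatrices:
    """Backward algorithm; total score equals the Forward total."""
    m, n = hmm.m, seq.n
    msc, tr, x = _core_arrays(hmm, seq)
    sp = SpecialParams.for_model(hmm, n)
    bm = np.full((m + 1, n + 1), NEG_INF)
    bi = np.full((m + 1, n + 1), NEG_INF)
    bd = np.full((m + 1, n + 1), NEG_INF)
    bc = sp.move + (n - np.arange(n + 1)) * sp.loop
    be = bc.copy()
    bb = np.full(n + 1, NEG_INF)
    ninf_row = np.full(n, NEG_INF)
    ninf_full = np.full(n + 1, NEG_INF)
    for i in range(m, 0, -1):
        if i < m:
            # emission of target residue j+1 by node i+1, for j = 0..n-1
            a = msc[i + 1, x] + bm[i + 1, 1:]
            bd_next = bd[i + 1]
        else:
            a = ninf_row
            bd_next = ninf_full
        bi[i, :n] = log_chain_backward(a + tr["im"][i], tr["ii"][i])
        bd[i, :n] = logsumexp2(a + tr["dm"][i], bd_next[:n] + tr["dd"][i])
        bm[i, :n] = logsumexp4(
            a + tr["mm"][i],
            bi[i, 1:] + tr["mi"][i],
            bd_next[:n] + tr["md"][i],
            be[:n],
        )
        bm[i, n] = be[n]  # exit immediately after the last emission
        bb = logsumexp2(bb, np.concatenate(
            [msc[i, x] + bm[i, 1:] + sp.entry[i], [NEG_INF]]))
    bn = log_chain_backward(bb + sp.move, sp.loop)
    score = float(bn[0])
    return DpMatrices(bm, bi, bd,
                      {"N": bn, "B": bb, "E": be, "C": bc}, score)


def forward_score_batch(hmm: ProfileHMM, seqs: np.ndarray) -> np.ndarray:
    """Forward scores for a batch of equal-length digitized sequences.

    ``seqs`` is (n_sequences, L) of residue indices; returns nats.  Used for
    null-score simulation during calibration, where many thousands of
    background sequences must be scored.
    """
    seqs = np.asarray(seqs, dtype=np.int64)
    nb, n = seqs.shape
    m = hmm.m
    msc = hmm.match_scores()
    tr = hmm.log_transitions()
    sp = SpecialParams.for_model(hmm, n)
    xt = seqs.T  # (n, nb)
    fb = (np.arange(n + 1) * sp.loop + sp.move)[:, None]
    prev_m = np.full((n + 1, nb), NEG_INF)
    prev_i = np.full((n + 1, nb), NEG_INF)
    prev_d = np.full((n + 1, nb), NEG_INF)
    fe = np.full((n + 1, nb), NEG_INF)
    for i in range(1, m + 1):
        cur_m = np.full((n + 1, nb), NEG_INF)
        cur_m[1:] = msc[i][xt] + logsumexp4(
            prev_m[:-1] + tr["mm"][i - 1],
            prev_i[:-1] + tr["im"][i - 1],
            prev_d[:-1] + tr["dm"][i - 1],
            fb[:-1] + sp.entry[i],
        )
        cur_d = logsumexp2(prev_m + tr["md"][i - 1], prev_d + tr["dd"][i - 1])
        cur_i = np.full((n + 1, nb), NEG_INF)
        cur_i[1:] = log_chain_forward(cur_m[:-1] + tr["mi"][i], tr["ii"][i])
        fe = logsumexp2(fe, cur_m)
        prev_m, prev_i, prev_d = cur_m, cur_i, cur_d
    fc = log_chain_forward(fe, sp.loop)
    return fc[n] + sp.move


# ---------------------------------------------------------------------------
# Viterbi
# ---------------------------------------------------------------------------

def viterbi_full(hmm: ProfileHMM, seq: TargetSequence) -> Alignment:
    """Highest-probability alignment (max-plus analogue of Forward)."""
    m, n = hmm.m, seq.n
    msc, tr, x = _core_arrays(hmm, seq)
    sp = SpecialParams.for_model(hmm, n)
    vm = np.full((m + 1, n + 1), NEG_INF)
    vi = np.full((m + 1, n + 1), NEG_INF)
    vd = np.full((m + 1, n + 1), NEG_INF)
    vb = np.arange(n + 1) * sp.loop + sp.move
    for i in range(1, m + 1):
        pm_, pi_, pd_ = vm[i - 1], vi[i - 1], vd[i - 1]
        vm[i, 1:] = msc[i, x] + np.maximum.reduce([
            pm_[:-1] + tr["mm"][i - 1],
            pi_[:-1] + tr["im"][i - 1],
            pd_[:-1] + tr["dm"][i - 1],
            vb[:-1] + sp.entry[i],
        ])
        vd[i, :] = np.maximum(pm_ + tr["md"][i - 1], pd_ + tr["dd"][i - 1])
        vi[i, 1:] = max_chain_forward(vm[i, :-1] + tr["mi"][i], tr["ii"][i])
    ve = vm[1:].max(axis=0) if m else np.full(n + 1, NEG_INF)
    vc = max_chain_forward(ve, sp.loop)
    score = float(vc[n] + sp.move)
    if not np.isfinite(score):
        return Alignment(0, 0, 0, 0, score_nats=score)
    path = _traceback_max(hmm, seq, vm, vi, vd, ve, vc, msc, tr, sp)
    aln = _alignment_from_path(path)
    aln.score_nats = score
    aln.bits = score / LN2
    return aln


def _traceback_max(hmm, seq, vm, vi, vd, ve, vc, msc, tr, sp, tol=1e-9):
    n = seq.n
    x = seq.residues
    # find exit column: C[j] either extends C[j-1] or takes E[j]
    j = n
    while j > 0 and not (ve[j] >= vc[j] - tol):
        j -= 1
    i = int(np.argmax(vm[1:, j]) + 1)
    path = []
    state = "M"
    while True:
        path.append((state, i, j))
        if state == "M":
            target = vm[i, j] - msc[i, x[j - 1]]
            cands = [
                ("M", i - 1, j - 1, vm[i - 1, j - 1] + tr["mm"][i - 1]),
                ("D", i - 1, j - 1, vd[i - 1, j - 1] + tr["dm"][i - 1]),
                ("I", i - 1, j - 1, vi[i - 1, j - 1] + tr["im"][i - 1]),
                ("B", i, j, (j - 1) * sp.loop + sp.move + sp.entry[i]),
            ]
        elif state == "I":
            target = vi[i, j]
            cands = [
                ("M", i, j - 1, vm[i, j - 1] + tr["mi"][i]),
                ("I", i, j - 1, vi[i, j - 1] + tr["ii"][i]),
            ]
        else:  # D
            target = vd[i, j]
            cands = [
                ("M", i - 1, j, vm[i - 1, j] + tr["md"][i - 1]),
                ("D", i - 1, j, vd[i - 1, j] + tr["dd"][i - 1]),
            ]
        best = max(c[3] for c in cands)
        for st, ii_, jj_, val in cands:
            if val >= best - tol:
                state, i, j = st, ii_, jj_
                break
        if state == "B":
            break
    path.reverse()
    return path


def _alignment_from_path(path, posteriors=None) -> Alignment:
    core = [(s, i, j) for s, i, j in path if s in ("M", "I", "D")]
    if not core:
        return Alignment(0, 0, 0, 0)
    qs = min(i for s, i, j in core if s != "I")
    qe = max(i for s, i, j in core if s != "I")
    ts = min(j for s, i, j in core if s != "D")
    te = max(j for s, i, j in core if s != "D")
    return Alignment(qs, qe, ts, te, path=core,
                     posteriors=list(posteriors) if posteriors is not None else [])


# ---------------------------------------------------------------------------
# Posterior decoding and MEA
# ---------------------------------------------------------------------------

def posterior_full(fwd: DpMatrices, bkwd: DpMatrices) -> PosteriorMatrix:
    """Combine Forward and Backward into per-cell posteriors."""
    total = fwd.score
    if not np.isfinite(total):
        z = np.zeros_like(fwd.fm)
        zn = np.zeros_like(fwd.specials["N"])
        return PosteriorMatrix(z, z.copy(), z.copy(), zn, zn.copy(), total)
    with np.errstate(over="ignore"):
        pm = np.exp(fwd.fm + bkwd.fm - total)
        pi = np.exp(fwd.fi + bkwd.fi - total)
        pd = np.exp(fwd.fd + bkwd.fd - total)
        fn, bn = fwd.specials["N"], bkwd.specials["N"]
        fc, bc = fwd.specials["C"], bkwd.specials["C"]
        n = fn.size - 1
        loop = np.log(n / (n + 2.0)) if n else NEG_INF
        pn = np.zeros(n + 1)
        pc = np.zeros(n + 1)
        pn[1:] = np.exp(fn[:-1] + loop + bn[1:] - total)
        pc[1:] = np.exp(fc[:-1] + loop + bc[1:] - total)
    for a in (pm, pi, pd, pn, pc):
        np.clip(a, 0.0, 1.0, out=a)
    return PosteriorMatrix(pm, pi, pd, pn, pc, total)


def _gain_chain(source: np.ndarray, gains: np.ndarray) -> np.ndarray:
    """Solve v[j] = gains[j] + max(source[j], v[j-1]), v[-1] = -inf."""
    csum = np.cumsum(gains)
    w = np.maximum.accumulate(source - csum + gains)
    return w + csum


def mea_full(post: PosteriorMatrix) -> Alignment:
    """Maximum expected accuracy alignment from dense posteriors.

    The gain function is the summed posterior of emitting (match/insert)
    cells on the path; silent and special states contribute zero.
    """
    return _mea_from_grids(post.pm, post.pi, post.pd)


def _mea_from_grids(pm, pi, pd, allowed=None) -> Alignment:
    m = pm.shape[0] - 1
    n = pm.shape[1] - 1
    om = np.full((m + 1, n + 1), NEG_INF)
    oi = np.full((m + 1, n + 1), NEG_INF)
    od = np.full((m + 1, n + 1), NEG_INF)
    ob = np.zeros(n + 1)
    for i in range(1, m + 1):
        best_prev = np.maximum.reduce([om[i - 1], oi[i - 1], od[i - 1],
                                       np.broadcast_to(ob, (n + 1,))])
        om[i, 1:] = pm[i, 1:] + best_prev[:-1]
        if allowed is not None:
            om[i, ~allowed[i]] = NEG_INF
        if i >= 2:
            od[i] = np.maximum(om[i - 1], od[i - 1])
            if allowed is not None:
                od[i, ~allowed[i]] = NEG_INF
        if i < m:
            oi[i, 1:] = _gain_chain(om[i, :-1], pi[i, 1:])
            if allowed is not None:
                oi[i, ~allowed[i]] = NEG_INF
    oe = om[1:].max(axis=0) if m else np.full(n + 1, NEG_INF)
    oc = np.maximum.accumulate(oe)
    gain = float(oc[n])
    if not np.isfinite(gain):
        return Alignment(0, 0, 0, 0, gain=gain)
    tol = 1e-9
    j = n
    while j > 0 and not (oe[j] >= oc[j] - tol):
        j -= 1
    i = int(np.argmax(om[1:, j]) + 1)
    path = []
    state = "M"
    while True:
        path.append((state, i, j))
        if state == "M":
            cands = [
                ("M", i - 1, j - 1, om[i - 1, j - 1]),
                ("D", i - 1, j - 1, od[i - 1, j - 1]),
                ("I", i - 1, j - 1, oi[i - 1, j - 1]),
                ("B", i, j, ob[j - 1]),
            ]
            target = om[i, j] - pm[i, j]
        elif state == "I":
            cands = [
                ("M", i, j - 1, om[i, j - 1]),
                ("I", i, j - 1, oi[i, j - 1]),
            ]
            target = oi[i, j] - pi[i, j]
        else:
            cands = [
                ("M", i - 1, j, om[i - 1, j]),
                ("D", i - 1, j, od[i - 1, j]),
            ]
            target = od[i, j]
        best = max(c[3] for c in cands)
        for st, ii_, jj_, val in cands:
            if val >= best - tol:
                state, i, j = st, ii_, jj_
                break
        if state == "B":
            break
    path.reverse()
    posts = [pm[i, j] if s == "M" else (pi[i, j] if s == "I" else pd[i, j])
             for s, i, j in path]
    aln = _alignment_from_path(path, posts)
    aln.gain = gain
    return aln
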