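"""Seed generation: internal k-mer search and external seed files.

The internal seeder mimics the staged prefilter design of fast protein
search tools: (i) candidate diagonals are those carrying two co-diagonal
length-k windows whose profile match scores exceed a threshold; (ii) the
double-hit anchor is extended along the diagonal in both directions with
an X-drop rule and kept if the ungapped segment score passes a second
threshold; (iii) surviving diagonals get a banded gapped local Viterbi
alignment whose endpoints become the cloud-search seed.  It is a
faithful-in-spirit stand-in, not a bit-compatible reimplementation, of an
external prefilter; results from an external aligner can be supplied
instead as an m8-style TSV whose query coordinates must already refer to
profile (consensus) positions.

Default score thresholds are permissive — the pipeline's real gate is the
P-value filter applied to the gapped seed score — so that essentially
every query-target pair receives a calibrated seed score.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ._numerics import NEG_INF, max_chain_forward
from .cloud_search import Seed
from .profile import ProfileHMM, TargetSequence

DEFAULT_K = 6
DEFAULT_KMER_THRESHOLD = 0.0      # nats per k-mer window
DEFAULT_UNGAPPED_THRESHOLD = 0.0  # nats per ungapped segment
DEFAULT_MAX_SEEDS = 1000
XDROP = 20.0                      # nats; ungapped extension drop-off
BAND_WIDTH = 12                   # gapped stage: band half-width around diagonal
MAX_GAPPED_DIAGONALS = 4          # diagonals taken into the gapped stage


@dataclass
class SeedCandidate:
    """One candidate alignment anchor for a query-target pair."""

    query: str
    target: str
    seed: Seed
    ungapped_score: float = float("nan")
    gapped_score: float = float("nan")
    pvalue: float | None = None
    evalue: float | None = None


def _diagonal_double_hits(smat: np.ndarray, k: int, threshold: float):
    """Yield (offset, anchor_start, anchor_end) for diagonals with two
    non-overlapping scoring windows; coordinates are positions along the
    diagonal (0-based)."""
    m, n = smat.shape
    for off in range(-(m - 1), n):
        diag = np.diagonal(smat, offset=off)
        if diag.size < 2 * k:
            continue
        win = np.convolve(diag, np.ones(k), mode="valid")
        hits = np.nonzero(win >= threshold - 1e-12)[0]
        if hits.size < 2:
            continue
        # require two hits separated by at least k (non-overlapping)
        first = hits[0]
        later = hits[hits >= first + k]
        if later.size == 0:
            continue
        yield off, int(first), int(later[0] + k - 1)


def _xdrop_extend(diag: np.ndarray, a0: int, a1: int, xdrop: float):
    """Extend the anchor [a0, a1] outward along the diagonal, X-drop style.

    Returns (start, end, score) of the extended ungapped segment.
    """
    score = float(diag[a0 : a1 + 1].sum())
    best_left = 0.0
    run = 0.0
    best_pos = a0
    pos = a0
    for t in range(a0 - 1, -1, -1):
        run += diag[t]
        if run > best_left:
            best_left, best_pos = run, t
        if run < best_left - xdrop:
            break
    start = best_pos if best_left > 0 else a0
    best_right = 0.0
    run = 0.0
    end_pos = a1
    for t in range(a1 + 1, diag.size):
        run += diag[t]
        if run > best_right:
            best_right, end_pos = run, t
        if run < best_right - xdrop:
            break
    end = end_pos if best_right > 0 else a1
    return start, end, score + max(best_left, 0.0) + max(best_right, 0.0)


def banded_gapped_score(hmm: ProfileHMM, seq: TargetSequence, offset: int,
                        band: int = BAND_WIDTH):
    """Best local gapped alignment within a band around one diagonal.

    Local Smith-Waterman-style maximum over the profile's log-odds scores
    with the profile's own gap transitions; returns (score, Seed) or
    (-inf, None) when nothing scores above zero.
    """
    m, n = hmm.m, seq.n
    msc = hmm.match_scores()
    tr = hmm.log_transitions()
    x = seq.residues
    vm = np.full((m + 1, n + 2), NEG_INF)
    vi = np.full((m + 1, n + 2), NEG_INF)
    vd = np.full((m + 1, n + 2), NEG_INF)
    best = NEG_INF
    best_cell = None
    for i in range(1, m + 1):
        jlo = max(1, i + offset - band)
        jhi = min(n, i + offset + band)
        if jlo > jhi:
            continue
        jj = np.arange(jlo, jhi + 1)
        open_ = np.maximum.reduce([
            np.zeros(jj.size),
            vm[i - 1, jj - 1] + tr["mm"][i - 1],
            vi[i - 1, jj - 1] + tr["im"][i - 1],
            vd[i - 1, jj - 1] + tr["dm"][i - 1]])
        row_m = msc[i, x[jj - 1]] + open_
        vm[i, jj] = row_m
        vd[i, jj] = np.maximum(vm[i - 1, jj] + tr["md"][i - 1],
                               vd[i - 1, jj] + tr["dd"][i - 1])
        src = np.concatenate([[NEG_INF], row_m[:-1]]) + tr["mi"][i]
        vi[i, jj] = max_chain_forward(src, tr["ii"][i])
        k_ = int(np.argmax(row_m))
        if row_m[k_] > best:
            best = float(row_m[k_])
            best_cell = (i, int(jj[k_]))
    if best_cell is None or best <= 0.0:
        return NEG_INF, None
    # traceback from the best match cell to the local start
    i, j = best_cell
    state = "M"
    tol = 1e-9
    ib, jb = i, j
    while True:
        if state == "M":
            ib, jb = i, j
            inner = vm[i, j] - msc[i, x[j - 1]]
            if inner <= tol:
                break
            cands = [("M", i - 1, j - 1, vm[i - 1, j - 1] + tr["mm"][i - 1]),
                     ("D", i - 1, j - 1, vd[i - 1, j - 1] + tr["dm"][i - 1]),
                     ("I", i - 1, j - 1, vi[i - 1, j - 1] + tr["im"][i - 1])]
        elif state == "I":
            cands = [("M", i, j - 1, vm[i, j - 1] + tr["mi"][i]),
                     ("I", i, j - 1, vi[i, j - 1] + tr["ii"][i])]
        else:
            cands = [("M", i - 1, j, vm[i - 1, j] + tr["md"][i - 1]),
                     ("D", i - 1, j, vd[i - 1, j] + tr["dd"][i - 1])]
        top = max(c[3] for c in cands)
        for st, i2, j2, val in cands:
            if val >= top - tol:
                state, i, j = st, i2, j2
                break
    return float(best), Seed(ib, jb, best_cell[0], best_cell[1],
                             score=float(best))


def kmer_seed_search(
    hmm: ProfileHMM,
    seq: TargetSequence,
    k: int = DEFAULT_K,
    kmer_threshold: float = DEFAULT_KMER_THRESHOLD,
    ungapped_threshold: float = DEFAULT_UNGAPPED_THRESHOLD,
    max_seeds: int = DEFAULT_MAX_SEEDS,
    band: int = BAND_WIDTH,
) -> list[SeedCandidate]:
    """Three-stage internal seed search for one query-target pair.

    Returns candidates sorted by gapped score (descending, ties by
    coordinates); empty when the sequences are shorter than 2k or no
    diagonal passes the staged thresholds.
    """
    if k < 3:
        raise ValueError("k must be >= 3")
    m, n = hmm.m, seq.n
    if k > m or k > n:
        return []
    smat = hmm.match_scores()[1:, seq.residues]  # (m, n) log-odds
    cands = []
    for off, a0, a1 in _diagonal_double_hits(smat, k, kmer_threshold):
        diag = np.diagonal(smat, offset=off)
        s0, s1, uscore = _xdrop_extend(diag, a0, a1, XDROP)
        if uscore >= ungapped_threshold:
            cands.append((uscore, off))
    cands.sort(key=lambda t: (-t[0], t[1]))
    out = []
    for uscore, off in cands[:MAX_GAPPED_DIAGONALS]:
        gscore, seed = banded_gapped_score(hmm, seq, off, band)
        if seed is None:
            continue
        out.append(SeedCandidate(query=hmm.name, target=seq.name, seed=seed,
                                 ungapped_score=float(uscore),
                                 gapped_score=float(gscore)))
    out.sort(key=lambda c: (-c.gapped_score, c.seed.ib, c.seed.jb))
    # one candidate per distinct seed; best-scoring first
    uniq = []
    seen = set()
    for c in out:
        key = (c.seed.ib, c.seed.jb, c.seed.ie, c.seed.je)
        if key not in seen:
            seen.add(key)
            uniq.append(c)
    return uniq[:max_seeds]


def best_seed_score(hmm: ProfileHMM, seq: TargetSequence, **kwargs) -> float:
    """Gapped score of the best seed, or -inf when none is found.

    This is the statistic whose null distribution the seed-stage Gumbel
    calibration fits.
    """
    cands = kmer_seed_search(hmm, seq, **kwargs)
    return cands[0].gapped_score if cands else NEG_INF


# ---------------------------------------------------------------------------
# External seed files (m8-style TSV)
# ---------------------------------------------------------------------------

_M8_COLUMNS = ["query", "target", "qstart", "qend", "tstart", "tend", "evalue"]


def read_seed_file(
    path,
    queries: dict[str, ProfileHMM],
    targets: dict[str, TargetSequence],
    db_size: int,
    max_pvalue: float = 0.01,
) -> list[SeedCandidate]:
    """Read external alignment seeds with begin/end coordinates.

    Columns (TSV, no header): query, target, qstart, qend, tstart, tend,
    evalue; coordinates 1-based inclusive, query coordinates in profile
    positions.  E-values are converted to P-values by inverting the
    database-size adjustment, and candidates at or above ``max_pvalue``
    are dropped.
    """
    text = Path(path).read_text().strip()
    if not text:
        return []
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=range(7), names=_M8_COLUMNS)
    out = []
    for row in df.itertuples(index=False):
        if row.query not in queries:
            raise ValueError(f"unknown query id {row.query!r} in seed file")
        if row.target not in targets:
            raise ValueError(f"unknown target id {row.target!r} in seed file")
        if row.qstart > row.qend:
            raise ValueError(
                f"seed for {row.query}/{row.target}: qstart > qend")
        hmm = queries[row.query]
        seq = targets[row.target]
        p = float(row.evalue) / db_size
        if p >= max_pvalue:
            continue
        seed = Seed(int(row.qstart), int(row.tstart),
                    int(row.qend), int(row.tend), pvalue=p)
        seed.validate(hmm.m, seq.n)
        out.append(SeedCandidate(query=row.query, target=row.target,
                                 seed=seed, pvalue=p, evalue=float(row.evalue)))
    out.sort(key=lambda c: (c.pvalue, c.query, c.target))
    return out
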