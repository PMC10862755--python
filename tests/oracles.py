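"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's vectorized dynamic programming:
state paths are enumerated explicitly (tiny inputs), flood fills are done
cell by cell in quadratic space, and cloud reachability is a literal
breadth-first search on the explicit cell set.
"""

import math

import numpy as np

from sparsehmm.reference_dp import SpecialParams


def lse(*vals):
    mx = max(vals)
    if mx == -math.inf:
        return mx
    return mx + math.log(sum(math.exp(v - mx) for v in vals))


def enumerate_paths(hmm, seq):
    """Every legal local-alignment state path with its log-odds.

    Yields (logprob, core_path) where core_path is a list of
    (state, i, j) triples for the M/I/D states visited.
    """
    m, n = hmm.m, seq.n
    msc = hmm.match_scores()
    tr = hmm.log_transitions()
    sp = SpecialParams.for_model(hmm, n)
    x = seq.residues
    out = []

    def extend(i, j, lp, path):
        st = path[-1][0]
        if st == "M":  # exit to E is allowed from any match state
            tail = (n - j) * sp.loop + sp.move
            out.append((lp + tail, list(path)))
        if st == "M":
            t_m, t_i, t_d = tr["mm"][i], tr["mi"][i], tr["md"][i]
        elif st == "I":
            t_m, t_i, t_d = tr["im"][i], tr["ii"][i], -math.inf
        else:
            t_m, t_i, t_d = tr["dm"][i], -math.inf, tr["dd"][i]
        if i < m and j < n and t_m > -math.inf:
            path.append(("M", i + 1, j + 1))
            extend(i + 1, j + 1, lp + t_m + msc[i + 1, x[j]], path)
            path.pop()
        if j < n and i < m and t_i > -math.inf:
            path.append(("I", i, j + 1))
            extend(i, j + 1, lp + t_i, path)
            path.pop()
        if i < m and t_d > -math.inf:
            path.append(("D", i + 1, j))
            extend(i + 1, j, lp + t_d, path)
            path.pop()

    for j0 in range(0, n):
        for i0 in range(1, m + 1):
            lp = j0 * sp.loop + sp.move + sp.entry[i0] + msc[i0, x[j0]]
            path = [("M", i0, j0 + 1)]
            extend(i0, j0 + 1, lp, path)
    return out


def enum_forward(paths):
    return lse(*[lp for lp, _ in paths])


def enum_viterbi(paths):
    return max(lp for lp, _ in paths)


def enum_cell_usage(paths, m, n):
    """Posterior cell-usage probabilities from the enumerated paths."""
    total = math.exp(enum_forward(paths))
    use = {s: np.zeros((m + 1, n + 1)) for s in "MID"}
    for lp, path in paths:
        w = math.exp(lp) / total
        for st, i, j in path:
            use[st][i, j] += w
    return use["M"], use["I"], use["D"]


def enum_best_gain(paths, pm, pi):
    """Best achievable MEA gain over the enumerated paths."""
    return max(
        sum(pm[i, j] if st == "M" else (pi[i, j] if st == "I" else 0.0)
            for st, i, j in path)
        for _, path in paths)


def naive_restricted_fill(hmm, seq, seed, cells):
    """Quadratic-space flood fill of the core Forward recurrence, computing
    only the given cells, initialized to probability one at the seed begin
    cell.  Returns the match-state grid."""
    m, n = hmm.m, seq.n
    msc = hmm.match_scores()
    tr = hmm.log_transitions()
    x = seq.residues
    M = np.full((m + 1, n + 1), -math.inf)
    I = np.full((m + 1, n + 1), -math.inf)
    D = np.full((m + 1, n + 1), -math.inf)
    M[seed.ib, seed.jb] = I[seed.ib, seed.jb] = D[seed.ib, seed.jb] = 0.0
    for (i, j) in sorted(cells, key=lambda c: (c[0] + c[1], c[0])):
        if (i, j) == (seed.ib, seed.jb):
            continue
        M[i, j] = msc[i, x[j - 1]] + lse(
            M[i - 1, j - 1] + tr["mm"][i - 1],
            I[i - 1, j - 1] + tr["im"][i - 1],
            D[i - 1, j - 1] + tr["dm"][i - 1])
        I[i, j] = lse(M[i, j - 1] + tr["mi"][i], I[i, j - 1] + tr["ii"][i])
        D[i, j] = lse(M[i - 1, j] + tr["md"][i - 1],
                      D[i - 1, j] + tr["dd"][i - 1])
    return M


def reachability_oracle(cells, d_first, d_last):
    """Cells on some first-to-last anti-diagonal path: BFS intersection of
    forward-reachable and backward-reachable sets over the explicit cell
    graph (edges: right, down, diagonal)."""
    cs = set(cells)
    fwd = {c for c in cs if c[0] + c[1] == d_first}
    frontier = list(fwd)
    while frontier:
        i, j = frontier.pop()
        for c in ((i + 1, j), (i, j + 1), (i + 1, j + 1)):
            if c in cs and c not in fwd:
                fwd.add(c)
                frontier.append(c)
    bwd = {c for c in cs if c[0] + c[1] == d_last}
    frontier = list(bwd)
    while frontier:
        i, j = frontier.pop()
        for c in ((i - 1, j), (i, j - 1), (i - 1, j - 1)):
            if c in cs and c not in bwd:
                bwd.add(c)
                frontier.append(c)
    return fwd & bwd
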