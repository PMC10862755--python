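"""End-to-end search: seeds -> cloud search -> filters -> sparse FB ->
bias/boundaries/MEA -> E-value-sorted report.

For every query-target candidate the pipeline: finds the best seed (internal
k-mer search, or an external seed file); applies the seed P-value filter;
flood-fills the cloud forward and backward from the seed (falling back to
the seed rectangle when the two clouds do not intersect); applies the cloud
filter, a Forward-score estimate assembled from the two passes' running
maxima; runs sparse Forward/Backward over the trimmed cloud and applies the
Forward filter; and finally decodes posteriors, fixes alignment boundaries,
computes the MEA alignment and the bias-corrected bit score, and reports
E-values against the number of target sequences searched.

``--full-dp`` routes every candidate through the dense reference
implementation instead of cloud search, as an oracle path.
"""

from __future__ import annotations

from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field

import numpy as np

from ._numerics import LN2
from . import cloud_search as cs
from . import reference_dp as ref
from . import seeding
from . import sparse as sp
from . import stats
from .profile import ProfileHMM, TargetSequence
from .reference_dp import Alignment, SpecialParams


@dataclass
class SearchOptions:
    """Everything tunable about a search run."""

    alpha: float = 12.0
    beta: float = 20.0
    gamma: int = 5
    thresholds: stats.FilterThresholds = field(default_factory=stats.FilterThresholds)
    report_evalue: float = 10.0
    full_dp: bool = False
    calibration_samples: int = 1000
    calibration_length: int = 100
    rng_seed: int = 0
    threads: int = 1
    bias: bool = True
    boundary_threshold: float = 0.5
    k: int = seeding.DEFAULT_K
    kmer_threshold: float = seeding.DEFAULT_KMER_THRESHOLD
    ungapped_threshold: float = seeding.DEFAULT_UNGAPPED_THRESHOLD
    max_seeds: int = seeding.DEFAULT_MAX_SEEDS

    @property
    def prune(self) -> cs.PruneParams:
        return cs.PruneParams(self.alpha, self.beta, self.gamma)


@dataclass
class Hit:
    """Per query-target processing record.

    Fields beyond the stage actually reached stay at None; a hit is
    reported only when every filter passed and the E-value clears the
    report threshold.
    """

    query: str
    target: str
    seed: cs.Seed | None = None
    seed_pvalue: float | None = None
    cloud_cells: int | None = None
    cloud_fraction: float | None = None
    fallback: bool = False
    cloud_estimate: float | None = None
    cloud_pvalue: float | None = None
    forward_score: float | None = None
    forward_pvalue: float | None = None
    bias_correction: float | None = None
    bitscore: float | None = None
    evalue: float | None = None
    alignment: Alignment | None = None
    stage: str = "seed"


def _seed_wrapper_offset(hmm: ProfileHMM, seq: TargetSequence,
                         seed: cs.Seed) -> float:
    """Local-model wrapper cost that the core-only cloud scores omit.

    Cloud search starts from probability one at the seed begin cell, so
    its running maxima lack the flanking-state and entry costs of a real
    Forward path: N emissions up to the begin column, the N->B and C->T
    moves, the begin-state entry, the begin cell's own emission, and the
    C-tail beyond the end column.  Adding this constant makes the cloud
    filter estimate directly comparable to the sparse Forward score.
    """
    spp = SpecialParams.for_model(hmm, seq.n)
    msc = hmm.match_scores()
    return float((seed.jb - 1) * spp.loop + 2.0 * spp.move
                 + spp.entry[seed.ib] + msc[seed.ib, seq.residues[seed.jb - 1]]
                 + (seq.n - seed.je) * spp.loop)


def _bracket_spans(aln: Alignment, bounds) -> Alignment:
    """Widen the alignment's target span to bracket the posterior-defined
    aligned region, when one was found."""
    if bounds is None or aln.is_empty:
        return aln
    t0, t1 = bounds
    aln.tstart = min(aln.tstart, t0)
    aln.tend = max(aln.tend, t1)
    return aln


def _process_pair(hmm: ProfileHMM, seq: TargetSequence, calib,
                  options: SearchOptions, db_size: int,
                  external_seed: seeding.SeedCandidate | None = None) -> Hit:
    hit = Hit(query=hmm.name, target=seq.name)
    thr = options.thresholds
    # --- seed stage -------------------------------------------------------
    if external_seed is not None:
        cand = external_seed
        hit.seed = cand.seed
        hit.seed_pvalue = float(cand.pvalue)
    else:
        cands = seeding.kmer_seed_search(
            hmm, seq, k=options.k, kmer_threshold=options.kmer_threshold,
            ungapped_threshold=options.ungapped_threshold,
            max_seeds=options.max_seeds)
        if not cands:
            hit.stage = "seed"
            hit.seed_pvalue = 1.0
            return hit
        cand = cands[0]  # only the best-scoring seed is analyzed
        hit.seed = cand.seed
        hit.seed_pvalue = float(stats.pvalue(cand.gapped_score, calib,
                                             "gapped_max"))
    if hit.seed_pvalue >= thr.seed_p:
        hit.stage = "seed"
        return hit
    m, n = hmm.m, seq.n
    # --- cloud search / full DP -------------------------------------------
    if options.full_dp:
        fwd = ref.forward_full(hmm, seq)
        hit.forward_score = fwd.score
        hit.forward_pvalue = float(stats.pvalue(fwd.score, calib, "forward"))
        hit.cloud_cells = (m + 1) * (n + 1)
        hit.cloud_fraction = 1.0
        if hit.forward_pvalue > thr.forward_p:
            hit.stage = "forward"
            return hit
        bwd = ref.backward_full(hmm, seq)
        post = ref.posterior_full(fwd, bwd)
        aln = ref.mea_full(post)
        bounds = stats.define_boundaries(post, options.boundary_threshold)
        aln = _bracket_spans(aln, bounds)
        score = fwd.score
    else:
        params = options.prune
        fb, best_fwd, best_infwd = cs.cloud_search_forward(hmm, seq, hit.seed,
                                                           params)
        bb, best_bkwd, best_inbkwd = cs.cloud_search_backward(hmm, seq,
                                                              hit.seed, params)
        scores = cs.CloudScores(best_fwd, best_infwd, best_bkwd, best_inbkwd)
        hit.cloud_estimate = (stats.cloud_filter_estimate(scores)
                              + _seed_wrapper_offset(hmm, seq, hit.seed))
        hit.cloud_pvalue = float(stats.pvalue(hit.cloud_estimate, calib,
                                              "forward"))
        if hit.cloud_pvalue > thr.cloud_p:
            hit.stage = "cloud"
            return hit
        try:
            rb = cs.reorient_to_rows(cs.trim_cloud(cs.cloud_union(fb, bb)))
        except cs.NonIntersecting:
            rb = cs.fallback_rectangle(hit.seed)
            hit.fallback = True
        hit.cloud_cells = rb.num_cells()
        hit.cloud_fraction = cs.cloud_fraction(rb, m, n)
        layout = sp.build_layout(rb, m, n)
        score, fcells = sp.sparse_forward(hmm, seq, layout)
        hit.forward_score = score
        hit.forward_pvalue = float(stats.pvalue(score, calib, "forward"))
        if hit.forward_pvalue > thr.forward_p:
            hit.stage = "forward"
            return hit
        _, bcells = sp.sparse_backward(hmm, seq, layout)
        post = sp.sparse_posterior(fcells, bcells, layout)
        aln = sp.sparse_mea(post, layout)
        bounds = stats.define_boundaries(post, options.boundary_threshold)
        aln = _bracket_spans(aln, bounds)
    # --- bias, final score, E-value ---------------------------------------
    if options.bias:
        corrected, corr = stats.bias_correct(aln, post, hmm, seq, score)
    else:
        corrected, corr = score, 0.0
    hit.bias_correction = corr
    final_p = float(stats.pvalue(corrected, calib, "forward"))
    hit.bitscore = corrected / LN2
    hit.evalue = float(stats.evalue(final_p, db_size))
    aln.score_nats = corrected
    aln.bits = hit.bitscore
    aln.pvalue = final_p
    aln.evalue = hit.evalue
    hit.alignment = aln
    hit.stage = "reported" if hit.evalue <= options.report_evalue else "suppressed"
    return hit


def search(
    queries: list[ProfileHMM],
    targets: list[TargetSequence],
    options: SearchOptions = SearchOptions(),
    seed_candidates: list[seeding.SeedCandidate] | None = None,
    return_all: bool = False,
) -> list[Hit]:
    """Search every query against every target.

    ``seed_candidates`` (e.g. from :func:`seeding.read_seed_file`)
    bypasses the internal seeder; pairs without an external seed are then
    skipped, mirroring a prefilter that reported nothing for them.
    Returns reported hits sorted by ascending E-value (all processing
    records when ``return_all``).
    """
    if not queries or targets is None:
        raise ValueError("need at least one query and a target list")
    db_size = len(targets)
    ext = None
    if seed_candidates is not None:
        ext = {}
        for c in seed_candidates:
            ext.setdefault((c.query, c.target), c)
    hits: list[Hit] = []
    for hmm in queries:
        calib = stats.calibrate(
            hmm, n_samples=options.calibration_samples,
            rng_seed=options.rng_seed,
            null_length=options.calibration_length,
            seed_scorer=None if ext is not None else (
                lambda s, h=hmm: seeding.best_seed_score(
                    h, s, k=options.k,
                    kmer_threshold=options.kmer_threshold,
                    ungapped_threshold=options.ungapped_threshold,
                    max_seeds=options.max_seeds)),
        )

        def work(seq: TargetSequence) -> Hit | None:
            if ext is not None:
                c = ext.get((hmm.name, seq.name))
                if c is None:
                    return None
                return _process_pair(hmm, seq, calib, options, db_size,
                                     external_seed=c)
            return _process_pair(hmm, seq, calib, options, db_size)

        if options.threads > 1:
            with ThreadPoolExecutor(max_workers=options.threads) as pool:
                results = list(pool.map(work, targets))
        else:
            results = [work(t) for t in targets]
        for r in results:
            if r is not None:
                hits.append(r)
    if not return_all:
        hits = [h for h in hits if h.stage == "reported"]
    hits.sort(key=lambda h: (h.evalue if h.evalue is not None else np.inf,
                             h.query, h.target))
    return hits


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

REPORT_COLUMNS = ["query", "target", "qstart", "qend", "tstart", "tend",
                  "bitscore", "evalue", "cloud_fraction", "stage"]


def write_report(hits: list[Hit], path, alignments: bool = False) -> None:
    """Tabular (TSV) report, optionally with per-hit alignment blocks."""
    close = False
    if hasattr(path, "write"):
        fh = path
    else:
        fh = open(path, "w")
        close = True
    try:
        fh.write("\t".join(REPORT_COLUMNS) + "\n")
        for h in hits:
            a = h.alignment
            row = [
                h.query, h.target,
                str(a.qstart if a else 0), str(a.qend if a else 0),
                str(a.tstart if a else 0), str(a.tend if a else 0),
                f"{h.bitscore:.2f}" if h.bitscore is not None else "-",
                f"{h.evalue:.3g}" if h.evalue is not None else "-",
                f"{h.cloud_fraction:.4f}" if h.cloud_fraction is not None else "-",
                h.stage,
            ]
            fh.write("\t".join(row) + "\n")
        if alignments:
            for h in hits:
                if h.alignment and not h.alignment.is_empty:
                    fh.write(format_alignment(h) + "\n")
    finally:
        if close:
            fh.close()


def format_alignment(hit: Hit, width: int = 60) -> str:
    """Human-readable alignment block with a per-position posterior band
    (0-9, '*' for >= 0.95)."""
    a = hit.alignment
    lines = [f"# {hit.query} x {hit.target}  bits={hit.bitscore:.2f} "
             f"E={hit.evalue:.3g} q:{a.qstart}-{a.qend} t:{a.tstart}-{a.tend}"]
    states = "".join(s for s, _, _ in a.path)
    posts = "".join(
        "*" if p >= 0.95 else str(int(np.floor(p * 10)))
        for p in (a.posteriors or [0.0] * len(a.path)))
    for off in range(0, len(states), width):
        lines.append("  " + states[off : off + width])
        lines.append("  " + posts[off : off + width])
    return "\n".join(lines)
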