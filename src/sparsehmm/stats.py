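"""Null-score calibration, P/E-values, filters, bias correction, boundaries.

Score statistics follow the standard pHMM conventions: Forward log-odds
scores of non-homologous (background) sequences have an exponential right
tail with a fixed rate of ln 2 per bit (1.0 per nat), and gapped
maximum-score (Viterbi-type) null scores follow a Gumbel with the same
fixed rate; only the location parameter is fitted, by simulation against
shuffled background sequences, per query profile.  P-values follow from
the fitted tails and E-values are P times the number of target sequences
searched.

The filter cascade applies three nominal levels: seed stage P < 0.01,
cloud-filter estimate P <= 1e-3, sparse Forward P <= 1e-4.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._numerics import LN2
from .cloud_search import CloudScores
from .profile import ProfileHMM, TargetSequence
from .reference_dp import Alignment, forward_score_batch

#: fixed tail rate: ln 2 per bit of score, i.e. 1.0 per nat.
LAMBDA_PER_NAT = 1.0

#: fraction of the null sample used to anchor the exponential tail fit
FORWARD_TAIL_MASS = 0.04


@dataclass(frozen=True)
class FilterThresholds:
    """Nominal per-stage P-value cutoffs (seed, cloud filter, Forward)."""

    seed_p: float = 0.01
    cloud_p: float = 1e-3
    forward_p: float = 1e-4

    def __post_init__(self):
        if not (self.seed_p >= self.cloud_p >= self.forward_p > 0):
            raise ValueError("thresholds must satisfy seed >= cloud >= forward > 0")


@dataclass
class ExponentialTail:
    """P(S >= s) = min(1, exp(-lam * (s - tau))) for an exponential tail.

    ``tau`` is the implied location at which P reaches 1; the fit anchors
    the tail at the (1 - tail_mass) sample quantile.
    """

    lam: float
    tau: float

    def pvalue(self, score):
        return np.minimum(1.0, np.exp(-self.lam * (np.asarray(score, dtype=float)
                                                   - self.tau)))


@dataclass
class GumbelTail:
    """P(S >= s) = 1 - exp(-exp(-lam * (s - mu))); a trial that produced
    no score at all (-inf) gets P = 1."""

    lam: float
    mu: float
    support: float = 1.0  # fraction of null trials with any score (metadata)

    def pvalue(self, score):
        s = np.asarray(score, dtype=float)
        with np.errstate(over="ignore"):
            p = -np.expm1(-np.exp(-self.lam * (np.where(np.isfinite(s), s, 0.0)
                                               - self.mu)))
        p = np.where(np.isfinite(s), p, 1.0)
        return np.minimum(1.0, np.maximum(p, np.nextafter(0, 1)))


@dataclass
class NullCalibration:
    """Fitted null-score distributions for one query profile."""

    forward_tail: ExponentialTail
    gapped_max: GumbelTail | None
    n_samples: int
    seed: int
    null_length: int = 100


def fit_exponential_tail(scores: np.ndarray, lam: float = LAMBDA_PER_NAT,
                         tail_mass: float = FORWARD_TAIL_MASS) -> ExponentialTail:
    """Fit the tail location of an exponential with known rate.

    Anchors at the (1 - tail_mass) quantile s0 so that
    P(S >= s) = tail_mass * exp(-lam (s - s0)); returns the equivalent
    location tau = s0 + ln(tail_mass) / lam.
    """
    s = np.sort(np.asarray(scores, dtype=float))
    if s.size < 25:
        raise ValueError("need at least 25 null scores")
    if s[-1] - s[0] < 1e-12:
        raise ValueError("degenerate null sample: all scores equal")
    k = max(int(round(s.size * tail_mass)), 10)
    s0 = s[-k]
    t = k / s.size
    return ExponentialTail(lam=lam, tau=float(s0 + math.log(t) / lam))


GUMBEL_TAIL_MASS = 0.05


def fit_gumbel_location(scores: np.ndarray, lam: float = LAMBDA_PER_NAT,
                        tail_mass: float = GUMBEL_TAIL_MASS) -> GumbelTail:
    """Gumbel location for a known rate, anchored on the upper tail.

    ``scores`` may contain -inf for null trials that produced no score;
    these count toward the sample size but never toward the tail.  The
    location is chosen so the model's exceedance probability at the
    empirical (1 - tail_mass) quantile equals tail_mass, which keeps the
    filter-relevant tail calibrated even when the bulk of the null is not
    Gumbel-shaped.
    """
    s = np.asarray(scores, dtype=float)
    if s.size < 25:
        raise ValueError("need at least 25 null scores")
    finite = s[np.isfinite(s)]
    if finite.size < 25 or finite.max() - finite.min() < 1e-12:
        raise ValueError("degenerate null sample")
    s_all = np.sort(np.where(np.isfinite(s), s, -np.inf))
    k = max(int(round(s.size * tail_mass)), 10)
    s0 = s_all[-k]
    if not np.isfinite(s0):
        raise ValueError("tail quantile is -inf; too few scored null trials")
    t_eff = k / s.size
    mu = s0 + np.log(-np.log1p(-t_eff)) / lam
    return GumbelTail(lam=lam, mu=float(mu),
                      support=float(np.isfinite(s).mean()))


def sample_null_sequences(rng: np.random.Generator, n_samples: int,
                          length: int, alphabet) -> np.ndarray:
    """(n_samples, length) residue indices drawn from the background."""
    return rng.choice(alphabet.size, size=(n_samples, length),
                      p=alphabet.background)


def calibrate(
    hmm: ProfileHMM,
    n_samples: int = 1000,
    rng_seed: int = 0,
    null_length: int = 100,
    seed_scorer=None,
) -> NullCalibration:
    """Simulate shuffled-background nulls and fit both score tails.

    The Forward tail is fitted on full-coverage Forward scores of
    ``n_samples`` background sequences of length ``null_length``; if
    ``seed_scorer`` is given (a callable mapping a TargetSequence to a
    gapped seed score in nats, or -inf when no seed is found), the
    seed-stage Gumbel is fitted on the same nulls.  Deterministic for a
    fixed ``rng_seed``.
    """
    if n_samples < 100:
        raise ValueError("n_samples must be >= 100")
    rng = np.random.default_rng(rng_seed)
    seqs = sample_null_sequences(rng, n_samples, null_length, hmm.alphabet)
    fwd_scores = forward_score_batch(hmm, seqs)
    forward_tail = fit_exponential_tail(fwd_scores)
    gapped = None
    if seed_scorer is not None:
        g = np.array([seed_scorer(TargetSequence(f"null{i}", seqs[i],
                                                 hmm.alphabet))
                      for i in range(n_samples)], dtype=float)
        gapped = fit_gumbel_location(g)
    return NullCalibration(forward_tail=forward_tail, gapped_max=gapped,
                           n_samples=n_samples, seed=rng_seed,
                           null_length=null_length)


def pvalue(score, calib: NullCalibration, kind: str = "forward"):
    """P-value of a score in nats under the fitted null for ``kind``."""
    if kind == "forward":
        return calib.forward_tail.pvalue(score)
    if kind == "gapped_max":
        if calib.gapped_max is None:
            raise ValueError("no gapped-score calibration available")
        return calib.gapped_max.pvalue(score)
    raise ValueError(f"unknown score kind {kind!r}")


def evalue(p, db_size: int):
    """E-value: expected count of null scores this good across the search."""
    return np.asarray(p, dtype=float) * db_size


def pvalue_from_evalue(e, db_size: int):
    """Invert the database-size adjustment of an external E-value."""
    if db_size < 1:
        raise ValueError("db_size must be >= 1")
    return np.asarray(e, dtype=float) / db_size


# ---------------------------------------------------------------------------
# Cloud filter
# ---------------------------------------------------------------------------

def cloud_filter_estimate(cs: CloudScores) -> float:
    """Estimate the total Forward score from the two cloud-search passes.

    Z = best_fwd - best_infwd is the score accumulated by the forward pass
    beyond the seed end anti-diagonal, A = best_bkwd - best_inbkwd the
    mirror quantity; the estimate is A + max(best_infwd, best_inbkwd) + Z.
    """
    cs.validate()
    z = cs.best_fwd - cs.best_infwd
    a = cs.best_bkwd - cs.best_inbkwd
    return a + max(cs.best_infwd, cs.best_inbkwd) + z


# ---------------------------------------------------------------------------
# Filter cascade
# ---------------------------------------------------------------------------

def apply_filters(hits, thresholds: FilterThresholds = FilterThresholds()):
    """Annotate hits with the stage that rejected them, in cascade order.

    Each hit must expose ``seed_pvalue``; ``cloud_pvalue`` and
    ``forward_pvalue`` may be None for stages never reached.  Returns the
    surviving hits; every hit's ``stage`` is set to "seed", "cloud",
    "forward" (the rejecting stage) or "reported".
    """
    survivors = []
    for h in hits:
        if h.seed_pvalue is None or h.seed_pvalue >= thresholds.seed_p:
            h.stage = "seed"
        elif h.cloud_pvalue is not None and h.cloud_pvalue > thresholds.cloud_p:
            h.stage = "cloud"
        elif h.forward_pvalue is not None and h.forward_pvalue > thresholds.forward_p:
            h.stage = "forward"
        else:
            h.stage = "reported"
            survivors.append(h)
    return survivors


# ---------------------------------------------------------------------------
# Bias correction and alignment boundaries
# ---------------------------------------------------------------------------

def bias_correct(aln: Alignment, post, hmm: ProfileHMM,
                 seq: TargetSequence, score_nats: float) -> tuple[float, float]:
    """Composition-bias score adjustment (simplified null2 analogue).

    Builds an alternative null emission distribution as the
    posterior-weighted average of the emission rows used across the
    aligned region, and subtracts the log-odds of the aligned residues
    under that distribution versus the background, clipped below at zero.
    When the weighted emission mix equals the background the correction is
    exactly zero.  Returns (corrected_score, correction).

    ``post`` may be a dense PosteriorMatrix or a SparsePosterior.
    """
    if aln.is_empty:
        return score_nats, 0.0
    if hasattr(post, "dense"):
        pm, pi, _ = post.dense()
    else:
        pm, pi = post.pm, post.pi
    k = hmm.alphabet.size
    i0, i1 = aln.qstart, aln.qend
    j0, j1 = aln.tstart, aln.tend
    sub_m = pm[i0 : i1 + 1, j0 : j1 + 1]
    sub_i = pi[i0 : i1 + 1, j0 : j1 + 1]
    row_w = sub_m.sum(axis=1)
    mix = row_w @ hmm.match_emissions[i0 : i1 + 1]
    wi = sub_i.sum()
    mix = mix + wi * hmm.insert_emissions
    weights = row_w.sum() + wi
    if weights <= 0:
        return score_nats, 0.0
    mix = mix / weights
    bg = hmm.alphabet.background
    res = seq.residues[j0 - 1 : j1]
    res = res[res < k]  # wildcards score zero either way
    with np.errstate(divide="ignore"):
        corr = float(np.sum(np.log(mix[res]) - np.log(bg[res])))
    corr = max(corr, 0.0)
    return score_nats - corr, corr


def define_boundaries(post, threshold: float = 0.5):
    """Aligned-region span from flanking-state posteriors.

    The probability that target column j lies inside the aligned region is
    1 - P(emitted by N) - P(emitted by C); the span runs from the first to
    the last column where this occupancy reaches ``threshold``.  Returns
    (tstart, tend) 1-based inclusive, or None when no column qualifies.
    """
    occ = 1.0 - post.pn - post.pc
    idx = np.nonzero(occ[1:] >= threshold)[0]
    if idx.size == 0:
        return None
    return int(idx[0] + 1), int(idx[-1] + 1)


def bits(score_nats: float) -> float:
    return score_nats / LN2
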