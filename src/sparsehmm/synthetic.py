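"""Synthetic benchmark fixtures: family profiles, divergent homologs
embedded mid-sequence in shuffled decoys, and pure-decoy databases.

The generator emulates, at desk scale, the standard embedded-domain
benchmark construction for protein search tools: each true test sequence is
spliced into the middle of a shuffled unrelated sequence, and the database
is supplemented with pure shuffled decoys.  Decoy source sequences are
drawn i.i.d. from the background composition rather than from a real
protein database, which preserves the statistics that matter for score
calibration while keeping the package self-contained.

Evaluation follows the usual coverage rule: an alignment is a true
positive when it comes from the matching family and covers at least half
of the planted interval; hits on pure decoys are false positives;
cross-family hits on embedded sequences are ignored (neutral).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .profile import AMINO, Alphabet, ProfileHMM, TargetSequence

#: default per-position substitution probability for sampled homologs.
#: Desk-scale profiles (m ~ 50) carry far less information than full-length
#: protein families, so homologs are sampled at ~50% identity: divergent
#: enough that detection is non-trivial, while remaining within the
#: information budget of a short synthetic family.
DEFAULT_DIVERGENCE = 0.5
DEFAULT_INDEL_RATE = 0.02


@dataclass
class BenchmarkSpec:
    """Construction recipe for a desk-scale benchmark."""

    n_families: int = 1
    model_length: tuple[int, int] = (50, 50)
    divergence: float = DEFAULT_DIVERGENCE
    indel_rate: float = DEFAULT_INDEL_RATE
    n_true: int = 20
    n_decoys: int = 200
    decoy_length: tuple[int, int] = (80, 160)
    seed: int = 0

    def __post_init__(self):
        if min(self.n_families, self.n_true, self.n_decoys) < 0:
            raise ValueError("counts must be >= 0")
        if not (0.0 <= self.divergence <= 1.0 and 0.0 <= self.indel_rate <= 1.0):
            raise ValueError("rates must be probabilities")


def make_profile(
    m: int,
    rng: np.random.Generator,
    name: str = "synthfam",
    dominance: float = 0.6,
    alphabet: Alphabet = AMINO,
) -> ProfileHMM:
    """Random family profile with one dominant residue per position.

    Each match state puts probability ``dominance`` (plus its background
    share) on a randomly chosen consensus residue and spreads the rest
    according to the background; transitions favor match-to-match.
    """
    k = alphabet.size
    dom = rng.integers(0, k, size=m)
    match = np.zeros((m + 1, k))
    match[1:] = (1.0 - dominance) * alphabet.background
    match[np.arange(1, m + 1), dom] += dominance
    ones = np.ones(m + 1)
    hmm = ProfileHMM(
        name=name, m=m, match_emissions=match,
        insert_emissions=alphabet.background.copy(),
        t_mm=ones * 0.90, t_mi=ones * 0.05, t_md=ones * 0.05,
        t_im=ones * 0.60, t_ii=ones * 0.40,
        t_dm=ones * 0.70, t_dd=ones * 0.30,
        consensus="".join(alphabet.symbols[c] for c in dom),
        alphabet=alphabet,
    )
    hmm.validate()
    return hmm


def sample_homolog(
    hmm: ProfileHMM,
    divergence: float = DEFAULT_DIVERGENCE,
    indel_rate: float = DEFAULT_INDEL_RATE,
    rng: np.random.Generator | None = None,
    name: str = "homolog",
) -> TargetSequence:
    """Sample a diverged family member from the profile consensus.

    Starting from the consensus, each position is deleted with probability
    ``indel_rate``, substituted by a background draw with probability
    ``divergence``, and followed by a background-composed insertion with
    probability ``indel_rate`` (geometric length, extension 0.4).
    At ``divergence == 0`` and ``indel_rate == 0`` the consensus itself is
    returned.
    """
    rng = np.random.default_rng() if rng is None else rng
    alphabet = hmm.alphabet
    k = alphabet.size
    cons = alphabet.digitize(hmm.consensus)
    out: list[int] = []
    for c in cons:
        if rng.random() < indel_rate:  # deletion
            pass
        elif rng.random() < divergence:
            out.append(int(rng.choice(k, p=alphabet.background)))
        else:
            out.append(int(c))
        if rng.random() < indel_rate:  # insertion burst
            while True:
                out.append(int(rng.choice(k, p=alphabet.background)))
                if rng.random() >= 0.4:
                    break
    if not out:
        out = [int(cons[0])]
    return TargetSequence(name, np.array(out), alphabet)


def random_background_sequence(
    length: int,
    rng: np.random.Generator,
    name: str = "decoy",
    alphabet: Alphabet = AMINO,
) -> TargetSequence:
    res = rng.choice(alphabet.size, size=length, p=alphabet.background)
    return TargetSequence(name, res, alphabet)


def shuffle_sequence(seq: TargetSequence, rng: np.random.Generator) -> TargetSequence:
    """Composition-preserving residue shuffle."""
    res = seq.residues.copy()
    rng.shuffle(res)
    return TargetSequence(seq.name + "-shuffled", res, seq.alphabet)


def embed(
    true_seq: TargetSequence,
    decoy: TargetSequence,
    rng: np.random.Generator | None = None,
) -> tuple[TargetSequence, tuple[int, int]]:
    """Splice ``true_seq`` into the middle of ``decoy``.

    Returns the combined sequence and the planted interval, 1-based
    inclusive.
    """
    mid = decoy.n // 2
    res = np.concatenate([decoy.residues[:mid], true_seq.residues,
                          decoy.residues[mid:]])
    start = mid + 1
    end = mid + true_seq.n
    return TargetSequence(true_seq.name, res, true_seq.alphabet), (start, end)


@dataclass
class Benchmark:
    profiles: list[ProfileHMM]
    targets: list[TargetSequence]
    truth: pd.DataFrame  # target, family, planted_start, planted_end, is_true
    spec: BenchmarkSpec = field(default=None)


def make_benchmark(spec: BenchmarkSpec) -> Benchmark:
    """Build profiles, a labeled target set, and the truth table."""
    rng = np.random.default_rng(spec.seed)
    profiles = []
    targets = []
    rows = []
    for f in range(spec.n_families):
        m = int(rng.integers(spec.model_length[0], spec.model_length[1] + 1))
        fam = f"fam{f:03d}"
        profiles.append(make_profile(m, rng, name=fam))
        for t in range(spec.n_true):
            hom = sample_homolog(profiles[-1], spec.divergence,
                                 spec.indel_rate, rng,
                                 name=f"{fam}-true{t:03d}")
            dlen = int(rng.integers(spec.decoy_length[0], spec.decoy_length[1] + 1))
            decoy = shuffle_sequence(
                random_background_sequence(dlen, rng), rng)
            emb, (ps, pe) = embed(hom, decoy, rng)
            targets.append(emb)
            rows.append((emb.name, fam, ps, pe, True))
    for d in range(spec.n_decoys):
        dlen = int(rng.integers(spec.decoy_length[0], spec.decoy_length[1] + 1))
        decoy = shuffle_sequence(random_background_sequence(dlen, rng), rng)
        decoy.name = f"decoy{d:05d}"
        targets.append(decoy)
        rows.append((decoy.name, "-", 0, 0, False))
    truth = pd.DataFrame(
        rows, columns=["target", "family", "planted_start", "planted_end",
                       "is_true"])
    return Benchmark(profiles, targets, truth, spec)


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

def classify_hits(hits: pd.DataFrame, truth: pd.DataFrame) -> pd.DataFrame:
    """Label each hit TP / FP / neutral under the coverage rule.

    ``hits`` needs columns query, target, tstart, tend, evalue.  A hit is a
    true positive when its query is the target's family and the alignment
    covers >= 50% of the planted interval; any hit on a pure decoy is a
    false positive; everything else is neutral.
    """
    info = truth.set_index("target")
    labels = []
    for row in hits.itertuples():
        rec = info.loc[row.target]
        if not rec.is_true:
            labels.append("FP")
        elif row.query == rec.family:
            plen = rec.planted_end - rec.planted_start + 1
            cov = (min(row.tend, rec.planted_end)
                   - max(row.tstart, rec.planted_start) + 1)
            labels.append("TP" if cov >= 0.5 * plen else "neutral")
        else:
            labels.append("neutral")
    out = hits.copy()
    out["label"] = labels
    return out


def recall0(hits: pd.DataFrame, truth: pd.DataFrame) -> float:
    """Fraction of planted positives with E-value better than the best
    false positive (recall before the first false annotation)."""
    labeled = classify_hits(hits, truth)
    n_true = int(truth["is_true"].sum())
    if n_true == 0:
        return float("nan")
    fp = labeled[labeled["label"] == "FP"]
    cutoff = fp["evalue"].min() if len(fp) else np.inf
    tp = labeled[(labeled["label"] == "TP") & (labeled["evalue"] < cutoff)]
    return len(tp["target"].unique()) / n_true


def recall_curve(hits: pd.DataFrame, truth: pd.DataFrame) -> pd.DataFrame:
    """Recall as a function of false-positive count, by E-value threshold."""
    labeled = classify_hits(hits, truth).sort_values("evalue")
    n_true = max(int(truth["is_true"].sum()), 1)
    seen_tp: set = set()
    n_fp = 0
    rows = []
    for row in labeled.itertuples():
        if row.label == "FP":
            n_fp += 1
        elif row.label == "TP":
            seen_tp.add(row.target)
        rows.append((row.evalue, n_fp, len(seen_tp) / n_true))
    return pd.DataFrame(rows, columns=["evalue", "false_positives", "recall"])
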