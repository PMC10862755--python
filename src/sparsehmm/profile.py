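"""Profile-HMM and target-sequence data model.

A query is a profile hidden Markov model over the 20-letter amino acid
alphabet: per-position match emission distributions, a single shared insert
emission distribution, and the seven core transitions per node
(M->M, M->I, M->D, I->M, I->I, D->M, D->D).  Profiles are read from
HMMER3 ASCII (``HMMER3/f``) files, or built from a single protein sequence
using substitution-matrix conditional probabilities.

Positions are 1-based everywhere: model node ``i`` runs 1..m and target
position ``j`` runs 1..n; row/column 0 of any DP matrix is the begin
boundary.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Align import substitution_matrices

from ._numerics import NEG_INF

AMINO_SYMBOLS = "ACDEFGHIKLMNPQRSTVWY"

# Standard amino-acid background frequencies (Swiss-Prot derived; the same
# null model used throughout the pHMM literature).
_AMINO_BACKGROUND = np.array(
    [
        0.0787945, 0.0151600, 0.0535222, 0.0668298, 0.0397062,
        0.0695071, 0.0229198, 0.0590092, 0.0594422, 0.0963728,
        0.0237718, 0.0414386, 0.0482904, 0.0395639, 0.0540978,
        0.0683364, 0.0540687, 0.0673417, 0.0114135, 0.0304133,
    ]
)

#: residue index used for ambiguity codes (B, Z, X, ...); scored by background
WILDCARD = 20

_AMBIGUOUS = set("BJZXUO*")


class ProfileParseError(ValueError):
    """Raised when a HMMER3 ASCII profile record is malformed."""


@dataclass(frozen=True)
class Alphabet:
    """Residue alphabet with background (null-model) frequencies."""

    symbols: str = AMINO_SYMBOLS
    background: np.ndarray = field(default_factory=lambda: _AMINO_BACKGROUND.copy())

    def __post_init__(self):
        bg = np.asarray(self.background, dtype=float)
        bg = bg / bg.sum()
        object.__setattr__(self, "background", bg)
        if self.size < 2:
            raise ValueError("alphabet needs at least two symbols")
        if abs(self.background.sum() - 1.0) > 1e-9:
            raise ValueError("background must sum to 1")

    @property
    def size(self) -> int:
        return len(self.symbols)

    def index(self, ch: str) -> int:
        ch = ch.upper()
        i = self.symbols.find(ch)
        if i >= 0:
            return i
        if ch in _AMBIGUOUS:
            return WILDCARD
        raise ValueError(f"illegal residue {ch!r}")

    def digitize(self, seq: str) -> np.ndarray:
        return np.array([self.index(c) for c in seq], dtype=np.int64)

    def decode(self, residues: Iterable[int]) -> str:
        return "".join(
            self.symbols[r] if r < self.size else "X" for r in residues
        )


AMINO = Alphabet()


@dataclass
class TargetSequence:
    """A digitized protein sequence.

    ``residues`` holds alphabet indices; ambiguity codes map to the wildcard
    index and are scored with background probability everywhere.
    """

    name: str
    residues: np.ndarray
    alphabet: Alphabet = field(default_factory=lambda: AMINO)

    def __post_init__(self):
        self.residues = np.asarray(self.residues, dtype=np.int64)
        if self.residues.size < 1:
            raise ValueError(f"sequence {self.name!r} is empty")
        if self.residues.min() < 0 or self.residues.max() > WILDCARD:
            raise ValueError(f"sequence {self.name!r} has out-of-range residues")

    @classmethod
    def from_string(cls, name: str, seq: str, alphabet: Alphabet = AMINO):
        return cls(name, alphabet.digitize(seq), alphabet)

    @property
    def n(self) -> int:
        return int(self.residues.size)

    def __len__(self) -> int:
        return self.n

    def __str__(self) -> str:
        return self.alphabet.decode(self.residues)


@dataclass
class ProfileHMM:
    """Core profile HMM.

    Arrays are 1-indexed by model node: row 0 is an unused placeholder so
    that ``match_emissions[i]`` is the emission distribution of match state
    ``M_i`` for i in 1..m.  ``transitions[name][i]`` is the probability of the
    transition leaving node ``i`` (M_i->M_{i+1}, M_i->I_i, ...).  Node m's
    M->M entry is interpreted as the exit into the end state by convention
    and is not used by the local-alignment wrapper, which allows exit from
    every match state.
    """

    name: str
    m: int
    match_emissions: np.ndarray  # (m+1, k)
    insert_emissions: np.ndarray  # (k,)
    t_mm: np.ndarray
    t_mi: np.ndarray
    t_md: np.ndarray
    t_im: np.ndarray
    t_ii: np.ndarray
    t_dm: np.ndarray
    t_dd: np.ndarray
    consensus: str = ""
    alphabet: Alphabet = field(default_factory=lambda: AMINO)
    description: str = ""

    def __post_init__(self):
        if self.m < 1:
            raise ValueError("model length must be >= 1")
        if not self.consensus:
            idx = np.argmax(self.match_emissions[1:], axis=1)
            self.consensus = "".join(self.alphabet.symbols[c] for c in idx)

    # -- validation -------------------------------------------------------
    def validate(self, tol: float = 1e-6) -> None:
        k = self.alphabet.size
        if self.match_emissions.shape != (self.m + 1, k):
            raise ValueError("match emission table has wrong shape")
        rows = self.match_emissions[1:].sum(axis=1)
        if np.any(np.abs(rows - 1.0) > tol):
            raise ValueError("match emission rows must sum to 1")
        if abs(self.insert_emissions.sum() - 1.0) > tol:
            raise ValueError("insert emissions must sum to 1")
        m_out = self.t_mm[1:] + self.t_mi[1:] + self.t_md[1:]
        i_out = self.t_im[1:] + self.t_ii[1:]
        d_out = self.t_dm[1:] + self.t_dd[1:]
        # node m: I_m does not exist and D_m exits deterministically
        for grp, label in ((m_out[:-1], "M"), (i_out[:-1], "I"), (d_out[:-1], "D")):
            if grp.size and np.any(np.abs(grp - 1.0) > tol):
                raise ValueError(f"outgoing transitions from {label} must sum to 1")
        if len(self.consensus) != self.m:
            raise ValueError("consensus length must equal model length")

    # -- log-odds views ---------------------------------------------------
    def match_scores(self) -> np.ndarray:
        """(m+1, k+1) log-odds match emission scores; last column is the
        wildcard residue, scored 0 (background)."""
        k = self.alphabet.size
        out = np.full((self.m + 1, k + 1), NEG_INF)
        with np.errstate(divide="ignore"):
            out[1:, :k] = np.log(self.match_emissions[1:]) - np.log(
                self.alphabet.background
            )
        out[1:, k] = 0.0
        out[0, :] = NEG_INF
        return out

    def log_transitions(self) -> dict[str, np.ndarray]:
        out = {}
        with np.errstate(divide="ignore"):
            for nm in ("t_mm", "t_mi", "t_md", "t_im", "t_ii", "t_dm", "t_dd"):
                out[nm[2:]] = np.log(getattr(self, nm))
        # there is no insert state at the last node
        out["mi"][self.m] = NEG_INF
        out["ii"][self.m] = NEG_INF
        out["im"][self.m] = NEG_INF
        return out

    def consensus_sequence(self) -> TargetSequence:
        return TargetSequence.from_string(self.name + "-consensus", self.consensus,
                                          self.alphabet)


# ---------------------------------------------------------------------------
# HMMER3 ASCII I/O
# ---------------------------------------------------------------------------

def _prob(tok: str, line_no: int) -> float:
    """HMMER3 stores probabilities as negative natural logs; '*' is zero."""
    if tok == "*":
        return 0.0
    try:
        return math.exp(-float(tok))
    except ValueError as exc:
        raise ProfileParseError(f"line {line_no}: bad value {tok!r}") from exc


def read_profiles(path) -> list[ProfileHMM]:
    """Read every record of a HMMER3 ASCII profile file."""
    text = Path(path).read_text()
    return list(_parse_records(text.splitlines()))


def reads_profiles(text: str) -> list[ProfileHMM]:
    return list(_parse_records(text.splitlines()))


def _parse_records(lines: Sequence[str]):
    i = 0
    nlines = len(lines)
    while i < nlines:
        while i < nlines and not lines[i].strip():
            i += 1
        if i >= nlines:
            return
        header = lines[i]
        if not header.startswith("HMMER3"):
            raise ProfileParseError(f"line {i + 1}: expected HMMER3 header, got {header!r}")
        if not header.startswith("HMMER3/f"):
            raise ProfileParseError(f"line {i + 1}: unsupported profile dialect {header.split()[0]!r}")
        i += 1
        name = ""
        desc = ""
        leng = None
        alph = None
        while i < nlines and not lines[i].startswith("HMM "):
            key, _, val = lines[i].partition(" ")
            val = val.strip()
            if key == "NAME":
                name = val
            elif key == "DESC":
                desc = val
            elif key == "LENG":
                leng = int(val)
            elif key == "ALPH":
                alph = val.lower()
            i += 1
        if i >= nlines:
            raise ProfileParseError(f"line {nlines}: truncated record (no HMM line)")
        if leng is None or not name:
            raise ProfileParseError(f"line {i + 1}: header missing NAME or LENG")
        if alph != "amino":
            raise ProfileParseError(f"line {i + 1}: unsupported alphabet {alph!r}")
        i += 2  # skip the two HMM column-header lines
        k = AMINO.size
        # optional COMPO line
        if i < nlines and lines[i].split()[:1] == ["COMPO"]:
            i += 1
        if i + 1 >= nlines:
            raise ProfileParseError(f"line {nlines}: truncated record (node 0)")
        # node 0: insert emissions + transitions
        ins0 = [_prob(t, i + 1) for t in lines[i].split()]
        if len(ins0) != k:
            raise ProfileParseError(f"line {i + 1}: expected {k} insert emissions")
        i += 1
        t0 = [_prob(t, i + 1) for t in lines[i].split()]
        if len(t0) != 7:
            raise ProfileParseError(f"line {i + 1}: expected 7 transitions")
        i += 1

        match = np.zeros((leng + 1, k))
        t = {nm: np.zeros(leng + 1) for nm in
             ("t_mm", "t_mi", "t_md", "t_im", "t_ii", "t_dm", "t_dd")}
        for nm, v in zip(("t_mm", "t_mi", "t_md", "t_im", "t_ii", "t_dm", "t_dd"), t0):
            t[nm][0] = v
        cons = []
        for node in range(1, leng + 1):
            if i + 2 >= nlines + 1 or i >= nlines:
                raise ProfileParseError(f"line {nlines}: truncated record at node {node}")
            toks = lines[i].split()
            if len(toks) < 1 + k or toks[0] != str(node):
                raise ProfileParseError(
                    f"line {i + 1}: expected match line for node {node}")
            match[node] = [_prob(x, i + 1) for x in toks[1 : 1 + k]]
            cons.append(toks[2 + k] if len(toks) > 2 + k else "-")
            i += 1
            if i >= nlines:
                raise ProfileParseError(f"line {nlines}: truncated record at node {node}")
            ins = [_prob(x, i + 1) for x in lines[i].split()]
            if len(ins) != k:
                raise ProfileParseError(f"line {i + 1}: expected {k} insert emissions")
            i += 1
            if i >= nlines:
                raise ProfileParseError(f"line {nlines}: truncated record at node {node}")
            trans = [_prob(x, i + 1) for x in lines[i].split()]
            if len(trans) != 7:
                raise ProfileParseError(f"line {i + 1}: expected 7 transitions")
            for nm, v in zip(("t_mm", "t_mi", "t_md", "t_im", "t_ii", "t_dm", "t_dd"),
                             trans):
                t[nm][node] = v
            i += 1
        if i >= nlines or lines[i].strip() != "//":
            raise ProfileParseError(f"line {min(i + 1, nlines)}: record missing // terminator")
        i += 1
        consensus = "".join(cons)
        if "-" in consensus or len(consensus) != leng:
            consensus = ""
        # renormalize: stored 5-decimal logs leave sums ~1e-5 off unity
        match[1:] /= match[1:].sum(axis=1, keepdims=True)
        ins0 = np.asarray(ins0)
        ins0 /= ins0.sum()
        for node in range(leng):  # node m's groups are boundary conventions
            for grp in (("t_mm", "t_mi", "t_md"), ("t_im", "t_ii"),
                        ("t_dm", "t_dd")):
                tot = sum(t[nm][node + 1] for nm in grp) or 1.0
                for nm in grp:
                    t[nm][node + 1] /= tot
        hmm = ProfileHMM(
            name=name, m=leng, match_emissions=match,
            insert_emissions=np.asarray(ins0), consensus=consensus.upper(),
            description=desc, **t,
        )
        hmm.validate()
        yield hmm


def _fmt(p: float) -> str:
    # whitespace-tokenized readers accept the extra precision, which keeps
    # write-then-read round trips tight (~1e-9)
    if p <= 0.0:
        return "             *"
    return f"{-math.log(p):14.10f}"


def write_profiles(hmms: Iterable[ProfileHMM], path) -> None:
    """Write profiles as HMMER3/f ASCII, readable by HMMER itself."""
    with open(path, "w") as fh:
        for hmm in [hmms] if isinstance(hmms, ProfileHMM) else hmms:
            fh.write(profile_to_text(hmm))


def profile_to_text(hmm: ProfileHMM) -> str:
    k = hmm.alphabet.size
    out = io.StringIO()
    out.write("HMMER3/f [3.4 | sparsehmm]\n")
    out.write(f"NAME  {hmm.name}\n")
    if hmm.description:
        out.write(f"DESC  {hmm.description}\n")
    out.write(f"LENG  {hmm.m}\n")
    out.write("ALPH  amino\n")
    out.write("RF    no\nMM    no\nCONS  yes\nCS    no\nMAP   yes\n")
    out.write("HMM          " + "        ".join(hmm.alphabet.symbols) + "\n")
    out.write("            m->m     m->i     m->d     i->m     i->i     d->m     d->d\n")
    compo = hmm.match_emissions[1:].mean(axis=0)
    out.write("  COMPO   " + " ".join(_fmt(p) for p in compo) + "\n")
    out.write("          " + " ".join(_fmt(p) for p in hmm.insert_emissions) + "\n")
    out.write("          " + " ".join(
        _fmt(p) for p in (hmm.t_mm[0], hmm.t_mi[0], hmm.t_md[0],
                          hmm.t_im[0], hmm.t_ii[0], hmm.t_dm[0], hmm.t_dd[0])) + "\n")
    for i in range(1, hmm.m + 1):
        cons = hmm.consensus[i - 1].lower() if hmm.consensus else "-"
        out.write(f"{i:7d} " + " ".join(_fmt(p) for p in hmm.match_emissions[i]))
        out.write(f" {i:6d} {cons} - - -\n")
        out.write("          " + " ".join(_fmt(p) for p in hmm.insert_emissions) + "\n")
        out.write("          " + " ".join(
            _fmt(p) for p in (hmm.t_mm[i], hmm.t_mi[i], hmm.t_md[i],
                              hmm.t_im[i], hmm.t_ii[i], hmm.t_dm[i], hmm.t_dd[i]))
            + "\n")
    out.write("//\n")
    return out.getvalue()


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path, alphabet: Alphabet = AMINO) -> list[TargetSequence]:
    """Read a protein FASTA file into digitized sequences.

    Lowercase residues are case-folded; ambiguity codes become the wildcard
    residue.  An empty file, or a record with no residues, is an error.
    """
    seqs = []
    for rec in SeqIO.parse(str(path), "fasta"):
        s = str(rec.seq).strip()
        if not s:
            raise ValueError(f"record {rec.id!r} has no residues")
        try:
            seqs.append(TargetSequence.from_string(rec.id, s, alphabet))
        except ValueError as exc:
            raise ValueError(f"record {rec.id!r}: {exc}") from exc
    if not seqs:
        raise ValueError(f"no FASTA records found in {path}")
    return seqs


def write_fasta(seqs: Iterable[TargetSequence], path) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.name}\n")
            text = str(s)
            for off in range(0, len(text), 60):
                fh.write(text[off : off + 60] + "\n")


# ---------------------------------------------------------------------------
# Single sequence -> profile
# ---------------------------------------------------------------------------

_MATRIX_CACHE: dict[str, np.ndarray] = {}


def _conditional_matrix(scoring: str, alphabet: Alphabet) -> np.ndarray:
    """P(c | a) derived from a substitution matrix's implied target
    frequencies: p(c|a) proportional to bg(c) * 2^(S(a,c)/2)."""
    key = scoring.upper()
    if key in _MATRIX_CACHE:
        return _MATRIX_CACHE[key]
    try:
        mat = substitution_matrices.load(key)
    except Exception as exc:
        avail = ", ".join(substitution_matrices.load())
        raise ValueError(
            f"unknown scoring matrix {scoring!r}; available: {avail}") from exc
    k = alphabet.size
    cond = np.zeros((k, k))
    for a in range(k):
        for c in range(k):
            s = mat[alphabet.symbols[a], alphabet.symbols[c]]
            cond[a, c] = alphabet.background[c] * 2.0 ** (s / 2.0)
        cond[a] /= cond[a].sum()
    _MATRIX_CACHE[key] = cond
    return cond


def profile_from_sequence(
    seq: TargetSequence,
    scoring: str = "BLOSUM62",
    gap_open: float = 0.02,
    gap_extend: float = 0.4,
) -> ProfileHMM:
    """Convert a single query sequence to a profile.

    Emissions at position i depend only on the observed residue (conditional
    substitution probabilities); one shared transition 7-tuple applies at
    every position, parameterized by gap open/extend probabilities.
    """
    alphabet = seq.alphabet
    cond = _conditional_matrix(scoring, alphabet)
    m = seq.n
    match = np.zeros((m + 1, alphabet.size))
    for i, r in enumerate(seq.residues, start=1):
        match[i] = alphabet.background if r == WILDCARD else cond[r]
    ones = np.ones(m + 1)
    hmm = ProfileHMM(
        name=seq.name, m=m, match_emissions=match,
        insert_emissions=alphabet.background.copy(),
        t_mm=ones * (1.0 - 2.0 * gap_open), t_mi=ones * gap_open,
        t_md=ones * gap_open, t_im=ones * (1.0 - gap_extend),
        t_ii=ones * gap_extend, t_dm=ones * (1.0 - gap_extend),
        t_dd=ones * gap_extend,
        consensus=str(seq), alphabet=alphabet,
    )
    hmm.validate()
    return hmm
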