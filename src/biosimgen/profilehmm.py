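"""Profile hidden Markov models built from a multiple sequence alignment.

A minimal plan-7-like profile (match/insert/delete states, begin/end, no
flanking states) is estimated from a user-supplied MSA and sampled to
generate homolog-like sequences.  Alignment itself is an input, not a stage:
the model consumes aligned FASTA produced by any aligner.

Columns whose gap fraction is below 0.5 become match states.  Match
emissions are Laplace-smoothed column counts; insert emissions are the
overall residue background; transition probabilities are counted from each
row's implied state path and smoothed with the same pseudocount.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import SeqIO as _BioSeqIO

from .seqio import Alphabet, SequenceRecord, SequenceSet, detect_alphabet

_STATES = ("M", "I", "D")
GAP = "-"


@dataclass
class MSA:
    """Equal-length gapped rows over one alphabet."""

    rows: list[str]
    alphabet: Alphabet

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise ValueError("an MSA needs at least 2 rows")
        self.rows = [r.upper() for r in self.rows]
        width = len(self.rows[0])
        if any(len(r) != width for r in self.rows):
            raise ValueError("MSA rows differ in length")
        allowed = self.alphabet.all_symbols | {GAP}
        for i, r in enumerate(self.rows):
            bad = set(r) - allowed
            if bad:
                raise ValueError(f"MSA row {i}: invalid symbols {sorted(bad)}")

    @property
    def width(self) -> int:
        return len(self.rows[0])


def read_msa(path: str | Path) -> MSA:
    """Load an aligned FASTA file."""
    rows = [str(rec.seq) for rec in _BioSeqIO.parse(str(path), "fasta")]
    if not rows:
        raise ValueError(f"{path}: no alignment rows")
    alphabet = detect_alphabet(r.replace(GAP, "") for r in rows)
    return MSA(rows, alphabet)


@dataclass
class ProfileHMM:
    """Match emissions, insert background and per-position transitions.

    ``transitions[k, s, t]`` is the probability of moving from state ``s`` at
    node ``k`` to target ``t``, with s, t indexing (M, I, D); target M and D
    advance to node k+1, target I stays at node k.  Node 0 is the begin
    state; a move to target M at node ``match_count`` is the end state.
    """

    alphabet: Alphabet
    match_emissions: np.ndarray  # (M, |core|)
    insert_emissions: np.ndarray  # (|core|,)
    transitions: np.ndarray  # (M+1, 3, 3)

    def __post_init__(self) -> None:
        M = self.match_emissions.shape[0]
        if M < 1:
            raise ValueError("profile needs at least one match state")
        if not np.allclose(self.match_emissions.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("match emission rows must sum to 1")
        if abs(self.insert_emissions.sum() - 1.0) > 1e-9:
            raise ValueError("insert emissions must sum to 1")
        sums = self.transitions.sum(axis=2)
        if not np.allclose(sums[sums > 0], 1.0, atol=1e-9):
            raise ValueError("transition rows must sum to 1")

    @property
    def match_count(self) -> int:
        return self.match_emissions.shape[0]

    def consensus(self) -> str:
        core = self.alphabet.core_symbols
        return "".join(core[j] for j in self.match_emissions.argmax(axis=1))

    def to_text(self) -> str:
        """Plain-text state-table serialization."""
        core = self.alphabet.core_symbols
        lines = [f"alphabet\t{self.alphabet.value}",
                 f"match_states\t{self.match_count}",
                 "insert_emissions\t" + "\t".join(
                     f"{v:.10g}" for v in self.insert_emissions)]
        for k in range(self.match_count):
            lines.append(f"match_{k + 1}\t" + "\t".join(
                f"{v:.10g}" for v in self.match_emissions[k]))
        for k in range(self.match_count + 1):
            for si, s in enumerate(_STATES):
                lines.append(f"trans_{k}_{s}\t" + "\t".join(
                    f"{v:.10g}" for v in self.transitions[k, si]))
        return "\n".join(lines) + "\n"


def _state_path(row: str, is_match_col: np.ndarray) -> list[tuple[str, int]]:
    """Implied (state, node) path of one MSA row, begin/end excluded."""
    path: list[tuple[str, int]] = []
    k = 0
    for j, ch in enumerate(row):
        if is_match_col[j]:
            k += 1
            path.append(("M" if ch != GAP else "D", k))
        elif ch != GAP:
            path.append(("I", k))
    return path


def build_profile(msa: MSA, pseudocount: float = 0.1) -> ProfileHMM:
    """Estimate a profile HMM from an MSA with Laplace smoothing."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    core = msa.alphabet.core_symbols
    sym_index = {s: j for j, s in enumerate(core)}
    cols = np.array([[r[j] for r in msa.rows] for j in range(msa.width)])
    gap_frac = (cols == GAP).mean(axis=1)
    is_match = gap_frac < 0.5
    M = int(is_match.sum())
    if M == 0:
        raise ValueError("alignment yields zero match columns")

    emis = np.full((M, len(core)), pseudocount)
    k = 0
    for j in range(msa.width):
        if not is_match[j]:
            continue
        for ch in cols[j]:
            if ch in sym_index:
                emis[k, sym_index[ch]] += 1.0
        k += 1
    emis /= emis.sum(axis=1, keepdims=True)

    bg = np.full(len(core), pseudocount)
    for r in msa.rows:
        for ch in r:
            if ch in sym_index:
                bg[sym_index[ch]] += 1.0
    bg /= bg.sum()

    # transition counts: source node 0..M, source/target in (M, I, D)
    counts = np.zeros((M + 1, 3, 3))
    s_idx = {s: i for i, s in enumerate(_STATES)}
    for row in msa.rows:
        path = [("M", 0)] + _state_path(row, is_match) + [("M", M + 1)]
        for (s, k0), (t, _k1) in zip(path[:-1], path[1:]):
            counts[k0, s_idx[s], s_idx[t]] += 1.0

    trans = counts + pseudocount
    # invalid moves: D target past the last node; I/D sources at begin are
    # smoothed too (harmless: unreachable rows are normalized but never used)
    trans[M, :, s_idx["D"]] = 0.0
    trans /= trans.sum(axis=2, keepdims=True)
    return ProfileHMM(msa.alphabet, emis, bg, trans)


def sample_from_profile(hmm: ProfileHMM, n: int, rng: np.random.Generator,
                        run_tag: str = "hmm") -> SequenceSet:
    """Generate ``n`` ungapped sequences by stochastic begin-to-end traversal."""
    if n < 1:
        raise ValueError("n must be >= 1")
    core = hmm.alphabet.core_symbols
    M = hmm.match_count
    records = []
    for i in range(n):
        out: list[str] = []
        k, s = 0, 0  # begin state behaves like a match state at node 0
        while True:
            t = int(rng.choice(3, p=hmm.transitions[k, s]))
            if t == 1:  # insert at node k
                out.append(core[int(rng.choice(len(core), p=hmm.insert_emissions))])
                s = 1
                continue
            k += 1
            if k > M:
                break
            if t == 0:  # match
                out.append(core[int(rng.choice(len(core), p=hmm.match_emissions[k - 1]))])
            s = t
        if not out:  # all-delete traversal: emit consensus-free retry
            out = [core[int(rng.choice(len(core), p=hmm.insert_emissions))]]
        records.append(SequenceRecord(f"{run_tag}_{i + 1:06d}", "".join(out)))
    return SequenceSet(records, hmm.alphabet)
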