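"""De novo Monte Carlo sequence simulation.

Each input set is summarized by a *blueprint model*: a fitted density of
sequence lengths plus, for every core alphabet symbol, a fitted density of
the per-record symbol fraction.  Sampling the model yields blueprints —
(length, composition vector) pairs — and each blueprint templates one
simulated sequence whose residues are drawn i.i.d. from its composition.
Residue order is deliberately not modelled here; order structure is the
profile-HMM module's job.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .densities import FittedDensity, fit_density, sample_density
from .seqio import Alphabet, SequenceRecord, SequenceSet

_COMPOSITION_RESAMPLE_LIMIT = 100


@dataclass
class Blueprint:
    """Length + composition template for one simulated sequence."""

    length: int
    composition: np.ndarray  # over the alphabet's core symbols

    def __post_init__(self) -> None:
        self.composition = np.asarray(self.composition, dtype=float)
        if self.length < 1:
            raise ValueError("blueprint length must be >= 1")
        if np.any(self.composition < 0):
            raise ValueError("negative composition entry")
        if abs(self.composition.sum() - 1.0) > 1e-9:
            raise ValueError("composition must sum to 1")


@dataclass
class BlueprintModel:
    alphabet: Alphabet
    length_density: FittedDensity
    composition_densities: dict[str, FittedDensity]

    def __post_init__(self) -> None:
        core = set(self.alphabet.core_symbols)
        if set(self.composition_densities) != core:
            raise ValueError("need exactly one composition density per core symbol")


def composition_fractions(seqs: SequenceSet) -> np.ndarray:
    """Per-record core-symbol fractions, ambiguity symbols excluded from denominators."""
    core = seqs.alphabet.core_symbols
    out = np.zeros((len(seqs), len(core)))
    for i, rec in enumerate(seqs):
        counts = np.array([rec.residues.count(s) for s in core], dtype=float)
        total = counts.sum()
        if total == 0:
            raise ValueError(
                f"record {rec.identifier!r} has no unambiguous residues")
        out[i] = counts / total
    return out


def fit_blueprint_model(seqs: SequenceSet) -> BlueprintModel:
    """Fit length and per-symbol composition densities to an input set."""
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences to fit a blueprint model")
    lengths = seqs.lengths()
    length_density = fit_density(lengths, bounds=(1.0, None))
    fracs = composition_fractions(seqs)
    comp_densities = {
        sym: fit_density(fracs[:, j], bounds=(0.0, 1.0))
        for j, sym in enumerate(seqs.alphabet.core_symbols)
    }
    return BlueprintModel(seqs.alphabet, length_density, comp_densities)


def sample_blueprints(model: BlueprintModel, n: int,
                      rng: np.random.Generator) -> list[Blueprint]:
    """Sample ``n`` blueprints: rounded lengths plus renormalized compositions."""
    if n < 1:
        raise ValueError("n must be >= 1")
    lengths = np.maximum(np.rint(sample_density(model.length_density, n, rng)), 1)
    core = model.alphabet.core_symbols
    comp = np.column_stack([
        sample_density(model.composition_densities[s], n, rng) for s in core])
    comp = np.clip(comp, 0.0, None)
    sums = comp.sum(axis=1)
    for _ in range(_COMPOSITION_RESAMPLE_LIMIT):
        bad = np.flatnonzero(sums <= 0)
        if bad.size == 0:
            break
        redraw = np.column_stack([
            sample_density(model.composition_densities[s], bad.size, rng)
            for s in core])
        comp[bad] = np.clip(redraw, 0.0, None)
        sums = comp.sum(axis=1)
    else:
        raise RuntimeError("could not sample a nonzero composition vector")
    comp /= sums[:, None]
    return [Blueprint(int(L), c) for L, c in zip(lengths, comp)]


def generate_sequence(bp: Blueprint, alphabet: Alphabet,
                      rng: np.random.Generator,
                      identifier: str = "sim_000001") -> SequenceRecord:
    """Draw ``bp.length`` residues i.i.d. from the blueprint composition."""
    symbols = np.frombuffer(alphabet.core_symbols.encode(), dtype="S1")
    idx = rng.choice(len(symbols), size=bp.length, p=bp.composition)
    residues = symbols[idx].tobytes().decode()
    return SequenceRecord(identifier, residues)


def simulate_sequences(model: BlueprintModel, n: int, rng: np.random.Generator,
                       run_tag: str = "sim") -> SequenceSet:
    """Simulate ``n`` sequences from a fitted blueprint model."""
    if n < 1:
        raise ValueError("n must be >= 1")
    blueprints = sample_blueprints(model, n, rng)
    records = [
        generate_sequence(bp, model.alphabet, rng, f"{run_tag}_{i + 1:06d}")
        for i, bp in enumerate(blueprints)
    ]
    return SequenceSet(records, model.alphabet)


def pooled_symbol_frequencies(seqs: SequenceSet) -> np.ndarray:
    """Residue frequencies pooled over all records (core symbols only)."""
    core = seqs.alphabet.core_symbols
    counts = np.zeros(len(core))
    for rec in seqs:
        for j, s in enumerate(core):
            counts[j] += rec.residues.count(s)
    return counts / counts.sum()
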