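"""Deterministic synthetic-data generators.

Every capability of the simulator is testable without downloads: sequence
families are drawn from Dirichlet composition laws with optional implanted
motifs, and ground-truth correlated feature matrices come from a Gaussian
copula sampler implemented independently of the simulation path (shared
math, separate code), so it can serve as the copula oracle.

RNG streams are namespaced per operation so adding a fixture never perturbs
existing seeded outputs.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .seqio import Alphabet, FeatureMatrix, SequenceRecord, SequenceSet


def _rng(seed: int, namespace: str) -> np.random.Generator:
    # crc32 keying makes streams stable across processes (unlike hash())
    return np.random.default_rng(np.random.SeedSequence(
        [seed, zlib.crc32(namespace.encode()) % (2 ** 31)]))


@dataclass
class FamilySpec:
    """Parameters of a synthetic sequence family."""

    alphabet: Alphabet = Alphabet.DNA
    n: int = 50
    length_law: str = "lognormal"        # lognormal | uniform | fixed
    length_params: tuple = (5.0, 0.3)    # law-specific
    concentration: tuple | None = None   # Dirichlet over core symbols
    motif: str | None = None
    motif_mutation_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.motif_mutation_rate <= 1.0:
            raise ValueError("mutation rate must be in [0, 1]")
        if self.concentration is not None and len(self.concentration) != len(
                self.alphabet.core_symbols):
            raise ValueError("concentration length must match core alphabet size")


def _sample_length(spec: FamilySpec, rng: np.random.Generator) -> int:
    if spec.length_law == "lognormal":
        mu, sigma = spec.length_params
        return max(1, int(round(rng.lognormal(mu, sigma))))
    if spec.length_law == "uniform":
        lo, hi = spec.length_params
        return int(rng.integers(int(lo), int(hi) + 1))
    if spec.length_law == "fixed":
        return int(spec.length_params[0])
    raise ValueError(f"unknown length law {spec.length_law!r}")


def make_sequence_family(spec: FamilySpec) -> SequenceSet:
    """Generate ``spec.n`` records with Dirichlet-drawn per-record compositions."""
    rng = _rng(spec.seed, "sequence_family")
    core = spec.alphabet.core_symbols
    conc = np.asarray(spec.concentration if spec.concentration is not None
                      else [5.0] * len(core), dtype=float)
    records = []
    for i in range(spec.n):
        length = _sample_length(spec, rng)
        if spec.motif and len(spec.motif) > length:
            raise ValueError("motif longer than sampled sequence length")
        comp = rng.dirichlet(conc)
        idx = rng.choice(len(core), size=length, p=comp)
        residues = list(core[j] for j in idx)
        if spec.motif:
            start = int(rng.integers(0, length - len(spec.motif) + 1))
            for k, ch in enumerate(spec.motif.upper()):
                if rng.random() < spec.motif_mutation_rate:
                    choices = [c for c in core if c != ch]
                    residues[start + k] = choices[int(rng.integers(len(choices)))]
                else:
                    residues[start + k] = ch
        records.append(SequenceRecord(f"fam_{i + 1:04d}", "".join(residues)))
    return SequenceSet(records, spec.alphabet)


@dataclass
class MarginalSpec:
    """A named scipy-style 1-D marginal for ground-truth feature generation."""

    law: str = "normal"          # normal | exponential | mixture | uniform
    params: tuple = (0.0, 1.0)

    def ppf(self, u: np.ndarray) -> np.ndarray:
        if self.law == "normal":
            return stats.norm.ppf(u, *self.params)
        if self.law == "exponential":
            return stats.expon.ppf(u, scale=self.params[0])
        if self.law == "uniform":
            lo, hi = self.params
            return lo + (hi - lo) * u
        if self.law == "mixture":
            # two-component normal mixture; params = (mu1, sd1, mu2, sd2, w1)
            mu1, sd1, mu2, sd2, w1 = self.params
            grid = np.linspace(min(mu1 - 6 * sd1, mu2 - 6 * sd2),
                               max(mu1 + 6 * sd1, mu2 + 6 * sd2), 4096)
            cdf = w1 * stats.norm.cdf(grid, mu1, sd1) + \
                (1 - w1) * stats.norm.cdf(grid, mu2, sd2)
            return np.interp(u, cdf, grid)
        raise ValueError(f"unknown marginal law {self.law!r}")


def make_correlated_features(n: int, R: np.ndarray,
                             marginals: list[MarginalSpec],
                             seed: int = 0,
                             names: list[str] | None = None) -> FeatureMatrix:
    """Ground-truth Gaussian-copula sampler (independent of the simulator path)."""
    R = np.asarray(R, dtype=float)
    p = R.shape[0]
    if R.shape != (p, p) or len(marginals) != p:
        raise ValueError("R must be p x p with one marginal per feature")
    vals = np.linalg.eigvalsh(R)
    if vals.min() < -1e-10:
        raise ValueError("R is not positive semi-definite")
    rng = _rng(seed, "correlated_features")
    L = np.linalg.cholesky(R + 1e-12 * np.eye(p))
    z = rng.standard_normal((n, p)) @ L.T
    u = np.clip(stats.norm.cdf(z), 1e-12, 1 - 1e-12)
    values = np.column_stack([m.ppf(u[:, j]) for j, m in enumerate(marginals)])
    names = names or [f"f{j + 1}" for j in range(p)]
    ids = [f"fix_{i + 1:06d}" for i in range(n)]
    return FeatureMatrix(ids, names, values)


def make_two_class_family(n_per_class: int = 150, seed: int = 0,
                          shift: float = 1.0) -> tuple[SequenceSet, SequenceSet]:
    """Two protein families with different composition biases (classifier tests)."""
    core = Alphabet.PROTEIN.core_symbols
    base = np.full(len(core), 3.0)
    conc_a = base.copy()
    conc_b = base.copy()
    # class A enriched in hydrophobic residues, class B in charged ones
    for aa in "AILMFV":
        conc_a[core.index(aa)] += 4.0 * shift
    for aa in "DEKR":
        conc_b[core.index(aa)] += 6.0 * shift
    spec_a = FamilySpec(Alphabet.PROTEIN, n_per_class, "lognormal", (4.0, 0.25),
                        tuple(conc_a), seed=seed * 2 + 1)
    spec_b = FamilySpec(Alphabet.PROTEIN, n_per_class, "lognormal", (4.0, 0.25),
                        tuple(conc_b), seed=seed * 2 + 2)
    return make_sequence_family(spec_a), make_sequence_family(spec_b)
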