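"""Sequence-to-feature projection.

Maps sequence sets into numerical feature space so that simulated sequences
can be filtered for feature-space fidelity:

* pseudo-amino-acid composition: the 20 residue frequencies augmented with
  lambda sequence-order correlation factors computed from standardized
  physicochemical scales (hydrophobicity, hydrophilicity, side-chain mass),
  normalized to a probability vector of length 20 + lambda;
* mean dinucleotide property values over all overlapping windows, against a
  bundled table of conformational/thermodynamic properties (a reduced
  literature selection; full catalogs load from a user TSV in the same
  dialect);
* GC content.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .seqio import Alphabet, FeatureMatrix, SequenceSet

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"

# Classical pseudo-amino-acid composition scales (raw, standardized on use):
# hydrophobicity, hydrophilicity (Hopp-Woods) and side-chain mass.
HYDROPHOBICITY = {
    "A": 0.62, "R": -2.53, "N": -0.78, "D": -0.90, "C": 0.29, "Q": -0.85,
    "E": -0.74, "G": 0.48, "H": -0.40, "I": 1.38, "L": 1.06, "K": -1.50,
    "M": 0.64, "F": 1.19, "P": 0.12, "S": -0.18, "T": -0.05, "W": 0.81,
    "Y": 0.26, "V": 1.08,
}
HYDROPHILICITY = {
    "A": -0.5, "R": 3.0, "N": 0.2, "D": 3.0, "C": -1.0, "Q": 0.2,
    "E": 3.0, "G": 0.0, "H": -0.5, "I": -1.8, "L": -1.8, "K": 3.0,
    "M": -1.3, "F": -2.5, "P": 0.0, "S": 0.3, "T": -0.4, "W": -3.4,
    "Y": -2.3, "V": -1.5,
}
SIDE_CHAIN_MASS = {
    "A": 15.0, "R": 101.0, "N": 58.0, "D": 59.0, "C": 47.0, "Q": 72.0,
    "E": 73.0, "G": 1.0, "H": 82.0, "I": 57.0, "L": 57.0, "K": 73.0,
    "M": 75.0, "F": 91.0, "P": 42.0, "S": 31.0, "T": 45.0, "W": 130.0,
    "Y": 107.0, "V": 43.0,
}

DINUCLEOTIDES = [a + b for a in "ACGT" for b in "ACGT"]


@dataclass
class AAPropertyScale:
    """A named 20-value amino-acid scale, optionally standardized to mean 0, SD 1."""

    name: str
    values: dict[str, float]
    standardized: bool = False

    def standardize(self) -> "AAPropertyScale":
        arr = np.array([self.values[a] for a in AA_ORDER])
        std = (arr - arr.mean()) / arr.std(ddof=0)
        return AAPropertyScale(self.name, dict(zip(AA_ORDER, std)), True)


def default_scales() -> list[AAPropertyScale]:
    return [
        AAPropertyScale("hydrophobicity", HYDROPHOBICITY).standardize(),
        AAPropertyScale("hydrophilicity", HYDROPHILICITY).standardize(),
        AAPropertyScale("side_chain_mass", SIDE_CHAIN_MASS).standardize(),
    ]


@dataclass
class PseudoAAConfig:
    """Sequence-order depth lambda (1..10), weight w, and the property scales."""

    lam: int = 4
    w: float = 0.05
    scales: list[AAPropertyScale] = field(default_factory=default_scales)

    def __post_init__(self) -> None:
        if not 1 <= self.lam <= 10:
            raise ValueError("lambda must be in 1..10")
        if self.w <= 0:
            raise ValueError("weight w must be > 0")
        self.scales = [s if s.standardized else s.standardize() for s in self.scales]


@dataclass
class DinucPropertyTable:
    """Per-property values for the 16 dinucleotides (DNA-keyed; U maps to T)."""

    values: dict[str, dict[str, float]]

    def __post_init__(self) -> None:
        for name, row in self.values.items():
            if set(row) != set(DINUCLEOTIDES):
                raise ValueError(f"property {name!r}: needs exactly 16 dinucleotides")
            if not all(np.isfinite(list(row.values()))):
                raise ValueError(f"property {name!r}: non-finite value")

    @property
    def names(self) -> list[str]:
        return list(self.values)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DinucPropertyTable":
        """Load the documented dialect: header 'property<TAB>AA<TAB>...<TAB>TT'."""
        df = pd.read_csv(path, sep="\t", index_col=0)
        missing = set(DINUCLEOTIDES) - set(df.columns)
        if missing:
            raise ValueError(f"{path}: missing dinucleotide columns {sorted(missing)}")
        return cls({str(name): {d: float(df.loc[name, d]) for d in DINUCLEOTIDES}
                    for name in df.index})

    @classmethod
    def bundled(cls) -> "DinucPropertyTable":
        ref = resources.files("biosimgen").joinpath("data/dinuc_properties.tsv")
        with resources.as_file(ref) as path:
            return cls.from_tsv(path)


def pseudo_aa(seq: str, cfg: PseudoAAConfig | None = None) -> np.ndarray:
    """Pseudo-amino-acid composition vector of length 20 + lambda.

    Components 1..20 are f_u / (sum f + w * sum theta); components 20+j are
    w * theta_j / (same denominator), where theta_j averages the coupling
    Theta(R_i, R_{i+j}) over the sequence and Theta is the mean squared
    difference of the standardized scale values.  The vector sums to 1.
    """
    cfg = cfg or PseudoAAConfig()
    seq = seq.upper().replace("X", "")
    L = len(seq)
    if L <= cfg.lam:
        raise ValueError(
            f"sequence length {L} must exceed lambda={cfg.lam} after removing X")
    bad = set(seq) - set(AA_ORDER)
    if bad:
        raise ValueError(f"invalid amino acids {sorted(bad)}")

    scale_mat = np.array([[s.values[a] for a in seq] for s in cfg.scales])
    freqs = np.array([seq.count(a) for a in AA_ORDER], dtype=float) / L

    thetas = np.empty(cfg.lam)
    for j in range(1, cfg.lam + 1):
        diffs = scale_mat[:, j:] - scale_mat[:, :-j]
        thetas[j - 1] = np.mean(np.mean(diffs ** 2, axis=0))
    denom = freqs.sum() + cfg.w * thetas.sum()
    return np.concatenate([freqs, cfg.w * thetas]) / denom


def pseudo_aa_names(lam: int) -> list[str]:
    return [f"pseAA_{a}" for a in AA_ORDER] + [
        f"pseAA_theta{j}" for j in range(1, lam + 1)]


def _dna_key(dinuc: str) -> str:
    return dinuc.replace("U", "T")


def dinuc_features(seq: str, table: DinucPropertyTable,
                   properties: list[str] | None = None) -> np.ndarray:
    """Mean property value over all valid overlapping dinucleotide windows.

    Windows containing N are skipped; U is mapped to T for table lookup.
    """
    properties = properties or table.names
    unknown = set(properties) - set(table.names)
    if unknown:
        raise ValueError(f"unknown properties {sorted(unknown)}")
    seq = seq.upper()
    if len(seq) < 2:
        raise ValueError("need length >= 2 for dinucleotide features")
    windows = [_dna_key(seq[i:i + 2]) for i in range(len(seq) - 1)]
    windows = [w for w in windows if "N" not in w]
    if not windows:
        raise ValueError("no valid dinucleotide windows (all contain N)")
    out = np.empty(len(properties))
    for j, name in enumerate(properties):
        row = table.values[name]
        out[j] = np.mean([row[w] for w in windows])
    return out


def gc_content(seq: str) -> float:
    """(G + C) / (A + C + G + T/U); ambiguous N excluded from the denominator."""
    seq = seq.upper()
    if not seq:
        raise ValueError("empty sequence")
    gc = seq.count("G") + seq.count("C")
    denom = gc + seq.count("A") + seq.count("T") + seq.count("U")
    if denom == 0:
        raise ValueError("no unambiguous nucleotides")
    return gc / denom


@dataclass
class FeatureSpec:
    """What to extract: any combination compatible with the set's alphabet."""

    pseaa: PseudoAAConfig | None = None
    dinuc_properties: list[str] | None = None
    dinuc_table: DinucPropertyTable | None = None
    gc: bool = False

    @classmethod
    def parse(cls, tokens: list[str],
              table: DinucPropertyTable | None = None) -> "FeatureSpec":
        """Parse CLI-style tokens: 'pseaa:4:0.05', 'dinuc:twist,roll', 'gc'."""
        spec = cls()
        for tok in tokens:
            parts = tok.split(":")
            if parts[0] == "pseaa":
                lam = int(parts[1]) if len(parts) > 1 else 4
                w = float(parts[2]) if len(parts) > 2 else 0.05
                spec.pseaa = PseudoAAConfig(lam=lam, w=w)
            elif parts[0] == "dinuc":
                spec.dinuc_table = table or DinucPropertyTable.bundled()
                spec.dinuc_properties = (parts[1].split(",") if len(parts) > 1
                                         else spec.dinuc_table.names)
            elif parts[0] == "gc":
                spec.gc = True
            else:
                raise ValueError(f"unknown feature token {tok!r}")
        return spec

    def is_empty(self) -> bool:
        return self.pseaa is None and self.dinuc_properties is None and not self.gc


def extract_features(seqs: SequenceSet, spec: FeatureSpec) -> FeatureMatrix:
    """One feature row per record, with named columns per extractor."""
    if spec.is_empty():
        raise ValueError("empty feature specification")
    is_nuc = seqs.alphabet in (Alphabet.DNA, Alphabet.RNA)
    if spec.pseaa is not None and is_nuc:
        raise ValueError("pseudo-AA features require protein sequences")
    if (spec.dinuc_properties is not None or spec.gc) and not is_nuc:
        raise ValueError("dinucleotide/GC features require nucleotide sequences")

    names: list[str] = []
    if spec.pseaa is not None:
        names += pseudo_aa_names(spec.pseaa.lam)
    if spec.dinuc_properties is not None:
        names += spec.dinuc_properties
    if spec.gc:
        names += ["gc"]

    rows = np.empty((len(seqs), len(names)))
    for i, rec in enumerate(seqs):
        parts = []
        if spec.pseaa is not None:
            parts.append(pseudo_aa(rec.residues, spec.pseaa))
        if spec.dinuc_properties is not None:
            parts.append(dinuc_features(rec.residues, spec.dinuc_table,
                                        spec.dinuc_properties))
        if spec.gc:
            parts.append(np.array([gc_content(rec.residues)]))
        rows[i] = np.concatenate(parts)
    return FeatureMatrix([r.identifier for r in seqs], names, rows)
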