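"""Sequence and feature-table I/O.

Reads and writes the formats the simulator accepts: multi-record FASTA or
one-sequence-per-line plain text for DNA/RNA/protein sequences, and delimited
numeric tables (TSV/CSV) for feature matrices.  All sequence input is
validated against a detected alphabet; feature tables must be rectangular,
fully numeric and free of missing values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO as _BioSeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

logger = logging.getLogger(__name__)


class Alphabet(str, Enum):
    DNA = "DNA"
    RNA = "RNA"
    PROTEIN = "PROTEIN"

    @property
    def core_symbols(self) -> str:
        """Symbols used for composition modelling (ambiguity codes excluded)."""
        return _CORE[self]

    @property
    def all_symbols(self) -> frozenset[str]:
        return _FULL[self]

    @property
    def ambiguous(self) -> str:
        return "N" if self in (Alphabet.DNA, Alphabet.RNA) else "X"


_CORE = {
    Alphabet.DNA: "ACGT",
    Alphabet.RNA: "ACGU",
    Alphabet.PROTEIN: "ACDEFGHIKLMNPQRSTVWY",
}
_FULL = {
    Alphabet.DNA: frozenset("ACGTN"),
    Alphabet.RNA: frozenset("ACGUN"),
    Alphabet.PROTEIN: frozenset("ACDEFGHIKLMNPQRSTVWYX"),
}


@dataclass
class SequenceRecord:
    """One identified sequence: residues are uppercase symbols of an alphabet."""

    identifier: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"record {self.identifier!r}: empty sequence")
        self.residues = self.residues.upper()

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class SequenceSet:
    """An ordered collection of records sharing one alphabet."""

    records: list[SequenceRecord]
    alphabet: Alphabet

    def __post_init__(self) -> None:
        seen: set[str] = set()
        allowed = self.alphabet.all_symbols
        for rec in self.records:
            if rec.identifier in seen:
                raise ValueError(f"duplicate identifier {rec.identifier!r}")
            seen.add(rec.identifier)
            bad = set(rec.residues) - allowed
            if bad:
                raise ValueError(
                    f"record {rec.identifier!r}: symbol(s) {sorted(bad)} outside "
                    f"{self.alphabet.value} alphabet"
                )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def lengths(self) -> np.ndarray:
        return np.array([len(r) for r in self.records], dtype=float)

    def sequences(self) -> list[str]:
        return [r.residues for r in self.records]


@dataclass
class FeatureMatrix:
    """n samples x p named features, finite values only."""

    row_ids: list[str]
    feature_names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        n, p = self.values.shape
        if p < 1:
            raise ValueError("at least one feature required")
        if len(self.row_ids) != n or len(self.feature_names) != p:
            raise ValueError("row_ids/feature_names lengths do not match values shape")
        if len(set(self.feature_names)) != p:
            raise ValueError("duplicate feature names")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite values in feature matrix")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.feature_names.index(name)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_ids, columns=self.feature_names)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FeatureMatrix":
        return cls(
            row_ids=[str(i) for i in df.index],
            feature_names=[str(c) for c in df.columns],
            values=df.to_numpy(dtype=float),
        )


def detect_alphabet(residue_strings: Iterable[str]) -> Alphabet:
    """Classify the pooled symbol set: DNA > RNA > PROTEIN precedence.

    DNA if symbols are within {A,C,G,T,N}; RNA if within {A,C,G,U,N} and a U
    is present; otherwise protein if within the 20 amino-acid letters + X.
    """
    pooled: set[str] = set()
    n_nonempty = 0
    for s in residue_strings:
        if s:
            n_nonempty += 1
            pooled |= set(s.upper())
    if n_nonempty == 0:
        raise ValueError("no non-empty sequences supplied")

    fits = [a for a in (Alphabet.DNA, Alphabet.RNA, Alphabet.PROTEIN)
            if pooled <= a.all_symbols]
    if not fits:
        bad = pooled - (Alphabet.DNA.all_symbols | Alphabet.RNA.all_symbols
                        | Alphabet.PROTEIN.all_symbols)
        raise ValueError(f"symbols {sorted(bad) or sorted(pooled)} fit no alphabet")
    if Alphabet.RNA in fits and "U" in pooled:
        return Alphabet.RNA
    if len(fits) > 1:
        logger.info("alphabet ambiguous (%s); resolved to %s by precedence",
                    [a.value for a in fits], fits[0].value)
    return fits[0]


def read_sequences(path: str | Path, format: str = "auto") -> SequenceSet:
    """Read FASTA or one-sequence-per-line text into a validated SequenceSet.

    ``format='auto'`` sniffs a leading '>' for FASTA.  Plain-line records get
    ordinal identifiers ``seq_0001`` ...  Residues are uppercased; the
    alphabet is detected from the pooled symbols.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise ValueError(f"{path}: empty input file")
    if format == "auto":
        format = "fasta" if text.lstrip().startswith(">") else "lines"

    records: list[SequenceRecord] = []
    if format == "fasta":
        for rec in _BioSeqIO.parse(str(path), "fasta"):
            records.append(SequenceRecord(rec.id, str(rec.seq), rec.description))
    elif format == "lines":
        idx = 0
        for line in text.splitlines():
            line = line.strip()
            if not line:
                continue
            idx += 1
            records.append(SequenceRecord(f"seq_{idx:04d}", line))
    else:
        raise ValueError(f"unknown sequence format {format!r}")
    if not records:
        raise ValueError(f"{path}: no sequences found")
    alphabet = detect_alphabet(r.residues for r in records)
    return SequenceSet(records, alphabet)


def write_sequences(seqs: SequenceSet, path: str | Path, format: str = "fasta",
                    width: int = 70) -> None:
    """Write FASTA (wrapped at ``width`` columns) or plain line format."""
    path = Path(path)
    if format == "fasta":
        with path.open("w") as fh:
            for rec in seqs:
                header = rec.identifier
                if rec.description and rec.description != rec.identifier:
                    header = rec.description
                fh.write(f">{header}\n")
                for i in range(0, len(rec.residues), width):
                    fh.write(rec.residues[i:i + width] + "\n")
    elif format == "lines":
        path.write_text("".join(r.residues + "\n" for r in seqs))
    else:
        raise ValueError(f"unknown sequence format {format!r}")


def read_feature_table(path: str | Path, delimiter: str = "\t",
                       header: bool = True, row_ids: bool = False) -> FeatureMatrix:
    """Read a rectangular numeric table; any non-numeric cell is an error.

    ``header`` takes feature names from the first row, otherwise names are
    generated ``f1..fp``.  ``row_ids`` treats the first column as sample
    identifiers.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=delimiter, header=0 if header else None,
                     index_col=0 if row_ids else None, dtype=str,
                     skip_blank_lines=True)
    if df.empty:
        raise ValueError(f"{path}: empty table")
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        for i, cell in enumerate(df.iloc[:, j]):
            try:
                v = float(cell)
            except (TypeError, ValueError):
                raise ValueError(
                    f"{path}: non-numeric cell {cell!r} at row {i + 1}, "
                    f"column {col!r}") from None
            if not np.isfinite(v):
                raise ValueError(
                    f"{path}: missing/non-finite value at row {i + 1}, column {col!r}")
            values[i, j] = v
    names = [str(c) for c in df.columns] if header else [
        f"f{j + 1}" for j in range(df.shape[1])]
    ids = [str(i) for i in df.index] if row_ids else [
        f"row_{i + 1}" for i in range(df.shape[0])]
    return FeatureMatrix(ids, names, values)


def write_feature_table(fm: FeatureMatrix, path: str | Path, delimiter: str = "\t",
                        row_ids: bool = False) -> None:
    df = fm.to_frame()
    df.to_csv(path, sep=delimiter, index=row_ids, float_format="%.12g")


def to_biopython(seqs: SequenceSet) -> list[_BioSeqRecord]:
    """Convert to Biopython records (interop convenience)."""
    return [_BioSeqRecord(Seq(r.residues), id=r.identifier,
                          description=r.description) for r in seqs]
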