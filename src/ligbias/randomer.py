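"""Positional nucleotide composition of randomized-region libraries.

For a ligation study with a randomized oligo pool, the "input" library is the
pool as synthesized and the "output" library is what survived adaptor
ligation. A position shows no ligase preference when the input-normalized
nucleotide percentage RNnp = 25 * f_out / f_in equals 25, i.e. RNnp - 25 = 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from ._seq import to_rna

NUCLEOTIDES = ("A", "C", "G", "U")


@dataclass
class PositionalFrequencyMatrix:
    """Percent nucleotide frequency per 1-based position of a fixed region."""

    frequencies: pd.DataFrame  # index: position 1..L, columns A C G U, percent
    n_sequences: int

    @property
    def length(self) -> int:
        return len(self.frequencies)

    def to_tsv(self, path: str | Path) -> None:
        self.frequencies.to_csv(path, sep="\t", index_label="position")


@dataclass
class EnrichmentMatrix:
    """RNnp - 25 in percentage points; NaN marks undefined cells (f_in = 0)."""

    values: pd.DataFrame
    rnnp: pd.DataFrame

    def to_tsv(self, path: str | Path) -> None:
        self.values.to_csv(path, sep="\t", index_label="position", na_rep="NA")


def positional_frequency(sequences: Iterable[str]) -> PositionalFrequencyMatrix:
    """Column-wise nucleotide percentages of an equal-length sequence set."""
    seqs = [to_rna(s) for s in sequences]
    if not seqs:
        raise ValueError("empty sequence set")
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise ValueError("sequences have unequal lengths")
    arr = np.frombuffer("".join(seqs).encode(), dtype="S1").reshape(len(seqs), length)
    counts = {n: (arr == n.encode()).sum(axis=0) for n in NUCLEOTIDES}
    covered = sum(counts.values())
    if not (covered == len(seqs)).all():
        raise ValueError("sequences contain characters outside ACGU")
    freq = pd.DataFrame(
        {n: 100.0 * counts[n] / len(seqs) for n in NUCLEOTIDES},
        index=pd.RangeIndex(1, length + 1, name="position"),
    )
    return PositionalFrequencyMatrix(frequencies=freq, n_sequences=len(seqs))


def positional_enrichment(
    output: PositionalFrequencyMatrix, input: PositionalFrequencyMatrix
) -> EnrichmentMatrix:
    """Input-normalized enrichment RNnp - 25 per position and nucleotide.

    Cells where the input frequency is 0 but the output is positive are
    undefined and reported as NaN rather than dropped; 0/0 cells are also NaN.
    """
    if output.frequencies.shape != input.frequencies.shape:
        raise ValueError("output and input matrices have different dimensions")
    f_out = output.frequencies
    f_in = input.frequencies
    with np.errstate(divide="ignore", invalid="ignore"):
        rnnp = 25.0 * f_out / f_in
    rnnp = rnnp.where(f_in > 0)
    return EnrichmentMatrix(values=rnnp - 25.0, rnnp=rnnp)
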