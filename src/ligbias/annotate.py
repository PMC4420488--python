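"""Zero-mismatch read annotation and normalized read tables.

A trimmed read is annotated iff it equals a reference-pool sequence exactly
and full-length (after T->U mapping); everything else is counted once as
unannotated. Counts are converted to "normalized reads" by dividing by the
normalization factor (total annotated reads / number of unique pool
sequences), so an equimolar pool has an expected normalized value of 1 for
every sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from ._seq import to_rna
from .pool import ReferencePool


@dataclass
class CountTable:
    """Per-id annotated counts plus the unannotated remainder."""

    counts: dict[str, int]
    unannotated: int = 0

    def __post_init__(self) -> None:
        if self.unannotated < 0 or any(c < 0 for c in self.counts.values()):
            raise ValueError("counts must be non-negative")

    @property
    def annotated_total(self) -> int:
        return sum(self.counts.values())

    @property
    def total_reads(self) -> int:
        return self.annotated_total + self.unannotated


def annotate_reads(trimmed_reads: Iterable[str], pool: ReferencePool) -> CountTable:
    """Count reads by exact full-length equality to pool sequences."""
    if len(pool) == 0:
        raise ValueError("reference pool is empty")
    index = pool.sequence_index()
    counts = {e.id: 0 for e in pool}
    unannotated = 0
    for read in trimmed_reads:
        hit = index.get(to_rna(read))
        if hit is None:
            unannotated += 1
        else:
            counts[hit] += 1
    return CountTable(counts=counts, unannotated=unannotated)


@dataclass
class NormalizedTable:
    """Normalized reads and expectation-relative ratios for one library.

    ``normalized_reads`` = count / normalization_factor where the factor is
    annotated_total / pool size; ``expected`` = N * c_i / sum(c) so that the
    mean expected value is 1; ``ratio`` = normalized / expected.
    """

    table: pd.DataFrame  # index: id; columns: count, normalized_reads, expected, ratio
    normalization_factor: float

    @property
    def ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def normalized_reads(self) -> pd.Series:
        return self.table["normalized_reads"]

    @property
    def expected(self) -> pd.Series:
        return self.table["expected"]

    @property
    def ratios(self) -> pd.Series:
        return self.table["ratio"]

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index_label="id")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "NormalizedTable":
        df = pd.read_csv(path, sep="\t", index_col="id")
        factor = float(df["count"].sum()) / len(df)
        return cls(table=df, normalization_factor=factor)


def normalize(counts: CountTable, pool: ReferencePool) -> NormalizedTable:
    """Turn annotated counts into normalized reads and expectation ratios."""
    annotated = counts.annotated_total
    if annotated == 0:
        raise ValueError("no annotated reads; cannot normalize")
    n = len(pool)
    factor = annotated / n
    conc = pool.concentrations
    total_conc = sum(conc.values())
    rows = []
    for e in pool:
        c = counts.counts.get(e.id, 0)
        normalized = c / factor
        expected = n * e.concentration / total_conc
        rows.append((e.id, c, normalized, expected, normalized / expected))
    df = pd.DataFrame(
        rows, columns=["id", "count", "normalized_reads", "expected", "ratio"]
    ).set_index("id")
    return NormalizedTable(table=df, normalization_factor=factor)


def average_replicates(tables: Sequence[NormalizedTable]) -> NormalizedTable:
    """Arithmetic mean of normalized reads across replicate libraries.

    Id sets and expected values must agree; counts are summed for reference
    (the averaged normalized values are what downstream metrics use).
    """
    if len(tables) < 2:
        raise ValueError("need at least two replicate tables")
    first = tables[0].table
    ids = list(first.index)
    frames = [first]
    for t in tables[1:]:
        df = t.table
        if list(df.index) != ids:
            if set(df.index) != set(ids):
                raise ValueError("replicate tables have different id sets")
            df = df.loc[ids]
        if not (df["expected"].values == first["expected"].values).all():
            raise ValueError("replicate tables have different expected values")
        frames.append(df)
    norm = sum(f["normalized_reads"] for f in frames) / len(frames)
    count = sum(f["count"] for f in frames)
    df = pd.DataFrame(
        {
            "count": count,
            "normalized_reads": norm,
            "expected": first["expected"],
            "ratio": norm / first["expected"],
        },
        index=first.index,
    )
    factor = sum(t.normalization_factor for t in tables) / len(tables)
    return NormalizedTable(table=df, normalization_factor=factor)
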