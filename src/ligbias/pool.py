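"""Defined reference pools of small RNA sequences.

A reference pool is the ground truth of a defined-mix sequencing experiment:
a set of uniquely named, unique ~20-25 nt RNA sequences, each present at a
known relative concentration (1 everywhere for an equimolar mix such as the
miRXplore Universal Reference).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO

from ._seq import validate_rna


@dataclass(frozen=True)
class PoolEntry:
    id: str
    sequence: str  # RNA alphabet
    concentration: float = 1.0


@dataclass
class ReferencePool:
    """Named unique RNA sequences with relative concentrations.

    Invariants: ids unique, sequences unique and non-empty, concentrations
    positive. Duplicated sequences are rejected with a report naming every
    colliding id because exact-match annotation would otherwise be ambiguous.
    """

    entries: list[PoolEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [e.id for e in self.entries]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate ids in reference pool: {dupes}")
        by_seq: dict[str, list[str]] = {}
        for e in self.entries:
            if not e.sequence:
                raise ValueError(f"empty sequence for id {e.id!r}")
            if e.concentration <= 0:
                raise ValueError(f"non-positive concentration for id {e.id!r}")
            by_seq.setdefault(e.sequence, []).append(e.id)
        collisions = {s: ids for s, ids in by_seq.items() if len(ids) > 1}
        if collisions:
            report = "; ".join(
                f"{' and '.join(ids)} share {s}" for s, ids in collisions.items()
            )
            raise ValueError(f"duplicate sequences in reference pool: {report}")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def ids(self) -> list[str]:
        return [e.id for e in self.entries]

    @property
    def sequences(self) -> dict[str, str]:
        return {e.id: e.sequence for e in self.entries}

    @property
    def concentrations(self) -> dict[str, float]:
        return {e.id: e.concentration for e in self.entries}

    def sequence_index(self) -> dict[str, str]:
        """Map sequence -> id (well defined because sequences are unique)."""
        return {e.sequence: e.id for e in self.entries}


def load_concentrations(path: str | Path) -> dict[str, float]:
    """Read a two-column TSV (id, concentration)."""
    out: dict[str, float] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0].lower() in ("id", "name") and len(out) == 0:
                continue  # header
            if len(fields) < 2:
                raise ValueError(f"malformed concentration line: {line!r}")
            out[fields[0]] = float(fields[1])
    return out


def load_reference_pool(
    path: str | Path, concentrations: str | Path | Mapping[str, float] | None = None
) -> ReferencePool:
    """Load a reference pool from FASTA, with optional concentration TSV.

    Sequences are converted T->U; ids present in the concentration table must
    be a subset of the FASTA ids; ids without an entry default to 1.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    if concentrations is None:
        conc: Mapping[str, float] = {}
    elif isinstance(concentrations, Mapping):
        conc = concentrations
    else:
        conc = load_concentrations(concentrations)
    fasta_ids = {r.id for r in records}
    unknown = set(conc) - fasta_ids
    if unknown:
        raise ValueError(f"concentration table ids not in FASTA: {sorted(unknown)}")
    entries = [
        PoolEntry(
            id=r.id,
            sequence=validate_rna(str(r.seq), context=f"record {r.id!r}"),
            concentration=float(conc.get(r.id, 1.0)),
        )
        for r in records
    ]
    return ReferencePool(entries)


def pool_from_sequences(
    sequences: Mapping[str, str] | Iterable[tuple[str, str]],
    concentrations: Mapping[str, float] | None = None,
) -> ReferencePool:
    items = sequences.items() if isinstance(sequences, Mapping) else sequences
    conc = concentrations or {}
    return ReferencePool(
        [
            PoolEntry(id=i, sequence=validate_rna(s, context=f"record {i!r}"),
                      concentration=float(conc.get(i, 1.0)))
            for i, s in items
        ]
    )
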