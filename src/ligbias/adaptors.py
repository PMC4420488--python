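"""Adaptor specifications and exact-match adaptor trimming.

An adaptor is a defined oligonucleotide, optionally carrying one maximal run
of N characters marking a randomized region (6 nt in all the library designs
this package models). Trimming locates the insert-proximal *defined* flank of
the adaptor by exact substring search and removes the adaptor together with
any randomized bases lying between the insert and the matched flank.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

from ._seq import to_rna, validate_adaptor_alphabet

MIN_FLANK = 4  # shorter exact-match anchors are too ambiguous to trim on

THREE_PRIME = "three_prime"
FIVE_PRIME = "five_prime"


@dataclass(frozen=True)
class AdaptorSpec:
    """One adaptor: side, sequence over ACGUTN with at most one N-run.

    ``alphabet`` records the synthesis chemistry (the 3' adaptor is DNA, the
    5' adaptor RNA); all matching and folding is done after T->U mapping.
    """

    side: str
    sequence: str
    alphabet: str = "RNA"
    name: str = "adaptor"

    def __post_init__(self) -> None:
        if self.side not in (THREE_PRIME, FIVE_PRIME):
            raise ValueError(f"side must be {THREE_PRIME!r} or {FIVE_PRIME!r}")
        seq = validate_adaptor_alphabet(self.sequence, context=f"adaptor {self.name!r}")
        object.__setattr__(self, "sequence", seq)
        if len(re.findall("N+", seq)) > 1:
            raise ValueError(f"adaptor {self.name!r} has more than one N-run")
        if not seq.replace("N", ""):
            raise ValueError(f"adaptor {self.name!r} has no defined bases")

    @property
    def rna_sequence(self) -> str:
        return to_rna(self.sequence)

    @property
    def n_run(self) -> tuple[int, int] | None:
        """(start, end) of the randomized region, or None."""
        m = re.search("N+", self.sequence)
        return (m.start(), m.end()) if m else None

    @property
    def n_run_length(self) -> int:
        span = self.n_run
        return span[1] - span[0] if span else 0

    def fill_random_region(self, fill: str) -> str:
        """Concrete RNA sequence with the N-run replaced by ``fill``."""
        span = self.n_run
        if span is None:
            if fill:
                raise ValueError("adaptor has no randomized region to fill")
            return self.rna_sequence
        if len(fill) != self.n_run_length:
            raise ValueError(
                f"fill length {len(fill)} != randomized region length {self.n_run_length}"
            )
        s = self.rna_sequence
        return s[: span[0]] + to_rna(fill) + s[span[1] :]

    def trim_anchor(self) -> tuple[str, int]:
        """Insert-proximal defined flank used for trimming.

        Returns (flank in RNA alphabet, number of randomized bases sitting
        between the insert and the flank). For a 3' adaptor the insert-proximal
        side is the adaptor's 5' end; for a 5' adaptor it is the 3' end. When
        the N-run abuts the insert, the first defined segment beyond it is the
        anchor and the N bases are removed alongside it.
        """
        seq = self.rna_sequence
        span = self.n_run
        if self.side == THREE_PRIME:
            if span is None:
                flank, gap = seq, 0
            elif span[0] == 0:  # randomized region abuts the insert
                after = seq[span[1] :]
                flank = re.match("[^N]*", after).group(0)
                gap = self.n_run_length
            else:
                flank, gap = seq[: span[0]], 0
        else:
            if span is None:
                flank, gap = seq, 0
            elif span[1] == len(seq):
                before = seq[: span[0]]
                flank = re.search("[^N]*$", before).group(0)
                gap = self.n_run_length
            else:
                flank, gap = seq[span[1] :], 0
        if len(flank) < MIN_FLANK:
            raise ValueError(
                f"adaptor {self.name!r}: defined flank {flank!r} shorter than "
                f"{MIN_FLANK} nt is too ambiguous to trim on"
            )
        return flank, gap


def load_adaptor(path: str | Path, side: str, alphabet: str = "RNA") -> AdaptorSpec:
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise ValueError(f"expected exactly one adaptor record in {path}")
    r = records[0]
    return AdaptorSpec(side=side, sequence=str(r.seq), alphabet=alphabet, name=r.id)


@dataclass(frozen=True)
class TrimResult:
    insert: str
    trimmed3: bool
    trimmed5: bool

    @property
    def ok(self) -> bool:
        return self.trimmed3 and self.trimmed5


def trim_read(
    read: str,
    three_prime: AdaptorSpec | None,
    five_prime: AdaptorSpec | None = None,
) -> TrimResult:
    """Trim one read; reads that miss a required adaptor are flagged untrimmed.

    The 3' anchor is located by the *rightmost* exact occurrence (the
    occurrence proximal to the adaptor side), the 5' anchor by the leftmost,
    so inserts that happen to contain a flank internally are not truncated.
    """
    seq = to_rna(read)
    t3 = t5 = True
    if five_prime is not None:
        if five_prime.side != FIVE_PRIME:
            raise ValueError("five_prime argument must have side five_prime")
        flank, gap = five_prime.trim_anchor()
        pos = seq.find(flank)
        if pos < 0:
            t5 = False
        else:
            seq = seq[pos + len(flank) + gap :]
    if three_prime is not None:
        if three_prime.side != THREE_PRIME:
            raise ValueError("three_prime argument must have side three_prime")
        flank, gap = three_prime.trim_anchor()
        pos = seq.rfind(flank)
        if pos < 0:
            t3 = False
        else:
            seq = seq[: max(pos - gap, 0)]
    return TrimResult(insert=seq, trimmed3=t3, trimmed5=t5)


def trim_adaptors(
    reads: Iterable[str],
    three_prime: AdaptorSpec | None,
    five_prime: AdaptorSpec | None = None,
) -> tuple[list[str], list[TrimResult]]:
    """Trim a read set. Returns (inserts of fully trimmed reads, full report).

    Reads with no adaptor match are excluded from the returned inserts (and
    hence from annotation) but appear in the report.
    """
    report = [trim_read(r, three_prime, five_prime) for r in reads]
    inserts = [t.insert for t in report if t.ok]
    return inserts, report


def attach_adaptors(
    insert: str,
    three_prime: AdaptorSpec | None,
    five_prime: AdaptorSpec | None = None,
    fill3: str = "",
    fill5: str = "",
) -> str:
    """Inverse of trimming: build the full-length read for a given insert."""
    seq = to_rna(insert)
    if five_prime is not None:
        seq = five_prime.fill_random_region(fill5) + seq
    if three_prime is not None:
        seq = seq + three_prime.fill_random_region(fill3)
    return seq


def read_sequences(path: str | Path, fmt: str | None = None) -> list[str]:
    """Read sequences from FASTA or FASTQ (qualities ignored)."""
    path = Path(path)
    if fmt is None:
        fmt = "fastq" if path.suffix.lower() in (".fq", ".fastq") else "fasta"
    return [str(r.seq) for r in SeqIO.parse(str(path), fmt)]


def _first_defined_segment(seq: str) -> str:
    return re.match("[^N]*", seq).group(0)


def adaptor_pair_summary(adaptors: Sequence[AdaptorSpec]) -> str:
    return " + ".join(f"{a.name}({a.side})" for a in adaptors)
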