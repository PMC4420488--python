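"""Small sequence-alphabet helpers shared across modules.

All internal comparisons and folding happen in the RNA alphabet; DNA input
(including DNA adaptors) is mapped T->U on entry.
"""

from __future__ import annotations

RNA_BASES = frozenset("ACGU")
ADAPTOR_BASES = frozenset("ACGUTN")

_COMPLEMENT = str.maketrans("ACGU", "UGCA")


def to_rna(seq: str) -> str:
    """Uppercase and map T->U."""
    return seq.upper().replace("T", "U")


def validate_rna(seq: str, *, context: str = "sequence") -> str:
    seq = to_rna(seq)
    bad = set(seq) - RNA_BASES
    if bad:
        raise ValueError(f"{context} contains non-ACGU(T) characters: {sorted(bad)}")
    return seq


def validate_adaptor_alphabet(seq: str, *, context: str = "adaptor") -> str:
    s = seq.upper()
    bad = set(s) - ADAPTOR_BASES
    if bad:
        raise ValueError(f"{context} contains characters outside ACGUTN: {sorted(bad)}")
    return s


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement in the RNA alphabet (T treated as U)."""
    return to_rna(seq).translate(_COMPLEMENT)[::-1]
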