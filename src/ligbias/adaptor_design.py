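"""Construction of bias-reducing adaptor variants.

Three families of designs:

* C3-style 5' adaptors whose 3'-terminal k bases are the reverse complement
  of the 3' adaptor's first k bases, so the two adaptors can pair across the
  insert and steer the 5'-ligation cofold toward a loop junction;
* randomized adaptors carrying an N-run either at the insert-proximal end or
  internally (MidRand-style), ligated as a pool of variants;
* per-target designed 5' adaptors: a complementary window against one
  specific substrate chosen so the cofold junction lands in a requested state
  pair (by default a loop on both sides — the "break in the loop" geometry
  that T4 RNA ligase 1 favors).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from ._seq import reverse_complement, to_rna
from .adaptors import FIVE_PRIME, THREE_PRIME, AdaptorSpec
from .folding import FoldingBackend
from .structure import (
    LOOP_UNPAIRED,
    CategoryTable,
    CofoldResult,
    DEFAULT_CATEGORY_TABLE,
    cofold_pair,
)


def make_c3_adaptor(
    five_prime_adaptor: AdaptorSpec, three_prime_adaptor: AdaptorSpec, k: int = 7
) -> AdaptorSpec:
    """5' adaptor whose last k bases complement the 3' adaptor's first k bases.

    The 3'-terminal k bases of the 5' adaptor are *replaced* by the reverse
    complement (RNA alphabet) of the 3' adaptor's first k defined bases.
    """
    a3 = three_prime_adaptor.rna_sequence
    a5 = five_prime_adaptor.rna_sequence
    if k < 1 or k > len(a3):
        raise ValueError(f"k={k} exceeds the 3' adaptor length {len(a3)}")
    if k > len(a5):
        raise ValueError(f"k={k} exceeds the 5' adaptor length {len(a5)}")
    if "N" in a3[:k]:
        raise ValueError("3' adaptor prefix within k must be defined (no N)")
    suffix = reverse_complement(a3[:k])
    return AdaptorSpec(
        side=FIVE_PRIME,
        sequence=a5[: len(a5) - k] + suffix,
        alphabet="RNA",
        name=f"{five_prime_adaptor.name}-C3",
    )


def make_randomized_adaptor(
    adaptor: AdaptorSpec, n: int = 6, placement: str | int = "end_proximal"
) -> AdaptorSpec:
    """Insert an N-run of length n into a defined adaptor.

    ``placement`` is ``"end_proximal"`` (the insert-proximal end: the 5' end
    of a 3' adaptor, the 3' end of a 5' adaptor) or an integer 0-based offset
    for an internal randomized region (MidRand-style). The insert-distal side
    must keep at least 4 defined bases so the trimmer has an anchor.
    """
    if adaptor.n_run is not None:
        raise ValueError("adaptor already has a randomized region")
    seq = adaptor.sequence
    if n == 0:
        return adaptor
    if n < 0:
        raise ValueError("n must be >= 0")
    if placement == "end_proximal":
        pos = 0 if adaptor.side == THREE_PRIME else len(seq)
    else:
        pos = int(placement)
        if not 0 <= pos <= len(seq):
            raise ValueError(f"placement {pos} outside adaptor bounds")
    new_seq = seq[:pos] + "N" * n + seq[pos:]
    spec = AdaptorSpec(
        side=adaptor.side,
        sequence=new_seq,
        alphabet=adaptor.alphabet,
        name=f"{adaptor.name}-rand{n}@{pos}",
    )
    spec.trim_anchor()  # validates the defined flank; raises if < 4 nt
    return spec


@dataclass
class DesignRequest:
    """Targeted 5'-adaptor design against one substrate.

    ``target`` is the molecule present at the 5' ligation step: the RNA with
    the 3'-adaptor sequence already appended. The complementary window slides
    over offsets 2..6 (1-based) of the target so at least one target base
    stays unpaired on the junction side, leaving room for the loop geometry.
    """

    base_adaptor: AdaptorSpec
    target: str
    desired_states: tuple[str, str] = (LOOP_UNPAIRED, LOOP_UNPAIRED)
    complement_length: int = 7
    offsets: tuple[int, ...] = (2, 3, 4, 5, 6)


@dataclass
class DesignResult:
    adaptor: AdaptorSpec
    cofold: CofoldResult
    offset: int
    met: bool
    candidates: list = field(default_factory=list)


def design_targeted_adaptor(
    request: DesignRequest,
    backend: FoldingBackend | None = None,
    table: CategoryTable = DEFAULT_CATEGORY_TABLE,
) -> DesignResult:
    """Search complementary windows until the requested junction states form.

    For each window offset w, the reverse complement of target[w .. w+L-1]
    (1-based, L = complement_length) is appended to the base adaptor's 3' end;
    the candidate is cofolded with the target (adaptor as molecule A) and its
    junction is classified. The first candidate whose accepted cofold matches
    the requested state pair wins; if none does, the candidate with the lowest
    dimer MFE is returned flagged unmet, along with all candidates.
    """
    target = to_rna(request.target)
    L = request.complement_length
    if len(target) < 12:
        raise ValueError("target must be at least 12 nt")
    base = request.base_adaptor.rna_sequence
    if "N" in base:
        raise ValueError("base adaptor must be fully defined")
    candidates = []
    for w in request.offsets:
        if w + L - 1 > len(target):
            continue
        window = target[w - 1 : w + L - 1]
        candidate = AdaptorSpec(
            side=FIVE_PRIME,
            sequence=base + reverse_complement(window),
            alphabet="RNA",
            name=f"{request.base_adaptor.name}-design@w{w}",
        )
        cf = cofold_pair(candidate.rna_sequence, target, backend, table)
        met = cf.accepted and (
            (cf.category.state_a, cf.category.state_b) == request.desired_states
        )
        candidates.append((candidate, cf, w, met))
        if met:
            return DesignResult(
                adaptor=candidate, cofold=cf, offset=w, met=True, candidates=candidates
            )
    best = min(candidates, key=lambda c: c[1].mfe_ab)
    return DesignResult(
        adaptor=best[0], cofold=best[1], offset=best[2], met=False, candidates=candidates
    )
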