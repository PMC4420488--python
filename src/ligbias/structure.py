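"""Cofold junction classification and per-sequence folding attributes.

The joint MFE structure of a ligation substrate pair (molecule A 5' of the
junction, molecule B 3' of it) is written in dual dot-bracket notation with
'&' marking the junction. A cofold is *accepted* — treated as a real
interaction — only when the dimer MFE is below the MFE of each molecule
folded alone. Accepted cofolds are classified by the state of the two
junction-flanking bases (A's last base, B's first base), each of which is one
of four terminal states:

* ``exterior_unpaired`` — unpaired and enclosed by no base pair,
* ``loop_unpaired``     — unpaired inside a loop (enclosed by some pair),
* ``paired_intra``      — paired with a partner in the same molecule,
* ``paired_inter``      — paired with a partner across the junction.

The 4 x 4 state combinations give 16 junction categories. The integer ids are
a configurable bijection; the shipped default assigns ids 1..16 row-major in
the state order above. Note that in pseudoknot-free structures 4 of the 16
combinations — (exterior, loop), (loop, exterior), (exterior, inter) and
(inter, exterior) — cannot occur, because any pair enclosing one junction
base from across the junction necessarily encloses the other.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from ._seq import to_rna
from .adaptors import FIVE_PRIME, THREE_PRIME, AdaptorSpec
from .folding import (
    FoldingBackend,
    FoldResult,
    count_terminal_unpaired,
    default_pair_backend,
    default_single_backend,
)
from .pool import ReferencePool

EXTERIOR_UNPAIRED = "exterior_unpaired"
LOOP_UNPAIRED = "loop_unpaired"
PAIRED_INTRA = "paired_intra"
PAIRED_INTER = "paired_inter"
STATE_ORDER = (EXTERIOR_UNPAIRED, LOOP_UNPAIRED, PAIRED_INTRA, PAIRED_INTER)

#: State pairs that cannot occur in a pseudoknot-free dual structure.
IMPOSSIBLE_STATE_PAIRS = frozenset(
    {
        (EXTERIOR_UNPAIRED, LOOP_UNPAIRED),
        (LOOP_UNPAIRED, EXTERIOR_UNPAIRED),
        (EXTERIOR_UNPAIRED, PAIRED_INTER),
        (PAIRED_INTER, EXTERIOR_UNPAIRED),
    }
)


class CategoryTable:
    """Bijective mapping (state_a, state_b) -> category id in 1..16."""

    def __init__(self, mapping: Mapping[tuple[str, str], int] | None = None):
        if mapping is None:
            mapping = {
                (a, b): 4 * ia + ib + 1
                for ia, a in enumerate(STATE_ORDER)
                for ib, b in enumerate(STATE_ORDER)
            }
        mapping = dict(mapping)
        expected_keys = {(a, b) for a in STATE_ORDER for b in STATE_ORDER}
        if set(mapping) != expected_keys:
            raise ValueError("mapping must cover all 16 state pairs")
        if sorted(mapping.values()) != list(range(1, 17)):
            raise ValueError("mapping must be a bijection onto 1..16")
        self._map = mapping
        self._inverse = {v: k for k, v in mapping.items()}

    def id_of(self, state_a: str, state_b: str) -> int:
        return self._map[(state_a, state_b)]

    def states_of(self, category_id: int) -> tuple[str, str]:
        return self._inverse[category_id]

    def items(self):
        return self._map.items()


DEFAULT_CATEGORY_TABLE = CategoryTable()


@dataclass(frozen=True)
class JunctionCategory:
    state_a: str
    state_b: str
    category_id: int


@dataclass(frozen=True)
class CofoldResult:
    """Two-molecule MFE structure plus the acceptance call and category."""

    seq_a: str
    seq_b: str
    dot_bracket: str  # dual notation with '&'
    mfe_ab: float
    mfe_a: float
    mfe_b: float
    accepted: bool
    category: JunctionCategory | None


def _pair_map(dual: str) -> tuple[str, int, dict[int, int]]:
    """Parse dual dot-bracket; return (structure w/o '&', cut index, pairs)."""
    if dual.count("&") != 1:
        raise ValueError("dual dot-bracket must contain exactly one '&'")
    cut = dual.index("&")
    db = dual.replace("&", "")
    if cut == 0 or cut == len(db):
        raise ValueError("'&' must separate two non-empty molecules")
    stack: list[int] = []
    pairs: dict[int, int] = {}
    for i, ch in enumerate(db):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise ValueError("unbalanced dual dot-bracket")
            j = stack.pop()
            pairs[i], pairs[j] = j, i
        elif ch != ".":
            raise ValueError(f"invalid character {ch!r} in dual dot-bracket")
    if stack:
        raise ValueError("unbalanced dual dot-bracket")
    return db, cut, pairs


def _terminal_state(idx: int, cut: int, db: str, pairs: dict[int, int]) -> str:
    if db[idx] != ".":
        partner = pairs[idx]
        same_side = (idx < cut) == (partner < cut)
        return PAIRED_INTRA if same_side else PAIRED_INTER
    enclosed = any(i < idx < j for i, j in pairs.items() if i < j)
    return LOOP_UNPAIRED if enclosed else EXTERIOR_UNPAIRED


def classify_junction(
    dual_dot_bracket: str, table: CategoryTable = DEFAULT_CATEGORY_TABLE
) -> JunctionCategory:
    """Classify the two junction-flanking bases of a dual dot-bracket."""
    db, cut, pairs = _pair_map(dual_dot_bracket)
    state_a = _terminal_state(cut - 1, cut, db, pairs)
    state_b = _terminal_state(cut, cut, db, pairs)
    return JunctionCategory(state_a, state_b, table.id_of(state_a, state_b))


def fold_single(sequence: str, backend: FoldingBackend | None = None) -> FoldResult:
    """Single-molecule MFE structure (default-settings predictor)."""
    backend = backend or default_single_backend()
    return backend.fold(sequence)


def cofold_pair(
    seq_a: str,
    seq_b: str,
    backend: FoldingBackend | None = None,
    table: CategoryTable = DEFAULT_CATEGORY_TABLE,
) -> CofoldResult:
    """Cofold A with B, apply the acceptance rule, classify if accepted.

    The cofold is accepted only when the dimer MFE is strictly below the MFE
    of either molecule alone; a junction category is reported only for
    accepted cofolds.
    """
    backend = backend or default_pair_backend()
    a, b = to_rna(seq_a), to_rna(seq_b)
    dual, mfe_ab = backend.cofold(a, b)
    mfe_a = backend.fold(a).mfe
    mfe_b = backend.fold(b).mfe
    accepted = mfe_ab < min(mfe_a, mfe_b)
    category = classify_junction(dual, table) if accepted else None
    return CofoldResult(
        seq_a=a,
        seq_b=b,
        dot_bracket=dual,
        mfe_ab=mfe_ab,
        mfe_a=mfe_a,
        mfe_b=mfe_b,
        accepted=accepted,
        category=category,
    )


def category_distribution(cofolds: Iterable[CofoldResult]) -> tuple[dict[int, float], int]:
    """Percentage of accepted cofolds per category id; rejected count aside."""
    counts: dict[int, int] = {}
    rejected = 0
    for cf in cofolds:
        if cf.accepted:
            counts[cf.category.category_id] = counts.get(cf.category.category_id, 0) + 1
        else:
            rejected += 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError(f"no accepted cofolds ({rejected} rejected)")
    return {cat: 100.0 * c / total for cat, c in sorted(counts.items())}, rejected


def enrichment(
    subset_pct: Mapping, all_pct: Mapping
) -> dict:
    """Signed enrichment fraction (subset - all) / all per category or group.

    Categories absent from the reference distribution (all = 0) are reported
    as NaN, never dropped.
    """
    out = {}
    for key in set(subset_pct) | set(all_pct):
        s = subset_pct.get(key, 0.0)
        a = all_pct.get(key, 0.0)
        out[key] = (s - a) / a if a > 0 else math.nan
    return out


# enrichment thresholds, as fractions: an attribute class is unfavorable at
# -10% or worse for every attribute kind; the favorable threshold is +20% for
# cofold categories and +5% for single-molecule fold groups.
UNFAVORABLE_MAX = -0.10
FAVORABLE_MIN = {"cofold": 0.20, "contrafold": 0.05}

FAVORABLE = "favorable"
NEUTRAL = "neutral"
UNFAVORABLE = "unfavorable"


def favorability_call(e: float, attribute_kind: str) -> str:
    """Map an enrichment fraction to favorable / neutral / unfavorable."""
    if attribute_kind not in FAVORABLE_MIN:
        raise ValueError("attribute_kind must be 'cofold' or 'contrafold'")
    if math.isnan(e):
        return NEUTRAL
    if e <= UNFAVORABLE_MAX:
        return UNFAVORABLE
    if e >= FAVORABLE_MIN[attribute_kind]:
        return FAVORABLE
    return NEUTRAL


#: Label used for cofolds that fail the acceptance rule.
REJECTED = "rejected"

ATTRIBUTE_SLOTS = ("fold3", "fold5", "cofold3", "cofold5")
_SLOT_KIND = {
    "fold3": "contrafold",
    "fold5": "contrafold",
    "cofold3": "cofold",
    "cofold5": "cofold",
}


class FavorabilityTable:
    """Per-attribute-slot mapping from category/group label to a call.

    Labels are junction category ids (cofold slots) or terminal unpaired-base
    groups, i.e. an int or ``"no pairing"`` (fold slots). Labels with no entry
    are treated as neutral with a warning.
    """

    def __init__(self, calls: Mapping[str, Mapping] | None = None):
        calls = calls or {}
        unknown = set(calls) - set(ATTRIBUTE_SLOTS)
        if unknown:
            raise ValueError(f"unknown attribute slots: {sorted(unknown)}")
        self._calls = {slot: dict(calls.get(slot, {})) for slot in ATTRIBUTE_SLOTS}
        for slot, m in self._calls.items():
            bad = set(m.values()) - {FAVORABLE, NEUTRAL, UNFAVORABLE}
            if bad:
                raise ValueError(f"invalid calls in slot {slot}: {sorted(bad)}")

    @classmethod
    def from_enrichment(cls, tables: Mapping[str, Mapping]) -> "FavorabilityTable":
        """Build calls from enrichment fractions using the slot thresholds."""
        calls = {
            slot: {
                label: favorability_call(e, _SLOT_KIND[slot])
                for label, e in tables.get(slot, {}).items()
            }
            for slot in ATTRIBUTE_SLOTS
        }
        return cls(calls)

    def call(self, slot: str, label) -> str:
        m = self._calls[slot]
        if label not in m:
            warnings.warn(
                f"no favorability entry for {slot} label {label!r}; treating as neutral",
                stacklevel=2,
            )
            return NEUTRAL
        return m[label]


@dataclass(frozen=True)
class AttributeVector:
    """Four folding attributes of one pool sequence and their calls.

    3' attributes are computed on the bare sequence (terminal fold group at
    the 3' end; cofold of the sequence with the 3' adaptor). 5' attributes are
    computed on the sequence with the 3'-adaptor sequence appended, mirroring
    the molecule present at the 5'-ligation step.
    """

    id: str
    fold3_class: int | str
    fold5_class: int | str
    cofold3_category: int | str  # category id, or "rejected"
    cofold5_category: int | str
    calls: tuple[str, str, str, str]  # per ATTRIBUTE_SLOTS order

    @property
    def n_unfavorable(self) -> int:
        return sum(c == UNFAVORABLE for c in self.calls)


def _defined_rna(adaptor: AdaptorSpec) -> str:
    if adaptor.n_run is not None:
        raise ValueError(
            f"adaptor {adaptor.name!r} has a randomized region; attribute "
            "analysis needs a concrete adaptor (fill the N-run first)"
        )
    return adaptor.rna_sequence


def attribute_vectors(
    pool: ReferencePool,
    adaptor3: AdaptorSpec,
    adaptor5: AdaptorSpec,
    favorability: FavorabilityTable,
    single_backend: FoldingBackend | None = None,
    pair_backend: FoldingBackend | None = None,
    table: CategoryTable = DEFAULT_CATEGORY_TABLE,
) -> list[AttributeVector]:
    """Compute the 4-slot attribute vector for every pool sequence.

    Cofold orientation follows the ligation chemistry: for the 3' ligation the
    RNA is molecule A and the 3' adaptor molecule B; for the 5' ligation the
    5' adaptor is molecule A and the RNA-3'-adaptor hybrid molecule B.
    """
    if adaptor3.side != THREE_PRIME or adaptor5.side != FIVE_PRIME:
        raise ValueError("adaptor3/adaptor5 must have matching sides")
    single_backend = single_backend or default_single_backend()
    pair_backend = pair_backend or default_pair_backend()
    a3 = _defined_rna(adaptor3)
    a5 = _defined_rna(adaptor5)
    out = []
    for entry in pool:
        mirna = entry.sequence
        hybrid = mirna + a3
        fold3 = count_terminal_unpaired(single_backend.fold(mirna), "three_prime")
        fold5 = count_terminal_unpaired(single_backend.fold(hybrid), "five_prime")
        cf3 = cofold_pair(mirna, a3, pair_backend, table)
        cf5 = cofold_pair(a5, hybrid, pair_backend, table)
        c3 = cf3.category.category_id if cf3.accepted else REJECTED
        c5 = cf5.category.category_id if cf5.accepted else REJECTED
        calls = (
            favorability.call("fold3", fold3),
            favorability.call("fold5", fold5),
            favorability.call("cofold3", c3),
            favorability.call("cofold5", c5),
        )
        out.append(
            AttributeVector(
                id=entry.id,
                fold3_class=fold3,
                fold5_class=fold5,
                cofold3_category=c3,
                cofold5_category=c5,
                calls=calls,
            )
        )
    return out


def attributes_to_frame(vectors: Sequence[AttributeVector]) -> pd.DataFrame:
    rows = [
        {
            "id": v.id,
            "fold3": v.fold3_class,
            "fold5": v.fold5_class,
            "cofold3_cat": v.cofold3_category,
            "cofold5_cat": v.cofold5_category,
            "fold3_call": v.calls[0],
            "fold5_call": v.calls[1],
            "cofold3_call": v.calls[2],
            "cofold5_call": v.calls[3],
            "n_unfavorable": v.n_unfavorable,
        }
        for v in vectors
    ]
    return pd.DataFrame(rows).set_index("id")
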