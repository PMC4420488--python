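"""Synthetic defined pools and reads under a planted ligation-efficiency model.

The generator emulates a defined-mix small RNA sequencing experiment end to
end: a pool of unique 20-25 nt RNA sequences at known concentrations, a
per-molecule ligation efficiency that depends only on the four folding
attributes (3'/5' terminal structure of the molecule, 3'/5' cofold junction
category with the adaptors), multinomial sampling of reads proportional to
concentration x efficiency, and adaptor attachment with uniformly drawn
randomized-region fills. Because the efficiency model is planted, every
pipeline stage can be tested against exact ground truth without downloads.

Efficiency is multiplicative across the four attribute slots: each slot
contributes a multiplier by its favorability call (defaults 2.0 favorable,
1.0 neutral, 0.15 unfavorable), the simplest model consistent with a
cumulative effect of unfavorable attributes on representation.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .adaptors import AdaptorSpec, attach_adaptors
from .folding import FoldingBackend
from .pool import PoolEntry, ReferencePool
from .structure import (
    AttributeVector,
    CategoryTable,
    DEFAULT_CATEGORY_TABLE,
    FAVORABLE,
    FavorabilityTable,
    LOOP_UNPAIRED,
    NEUTRAL,
    PAIRED_INTER,
    PAIRED_INTRA,
    REJECTED,
    UNFAVORABLE,
    attribute_vectors,
)

#: Defined single-sequence adaptor pair used as the default study condition.
#: These are synthetic stand-ins with the layout of standard small RNA
#: library adaptors (pre-adenylated DNA on the 3' side, RNA on the 5' side),
#: not the oligos of any particular kit.
DEFAULT_ADAPTOR3 = AdaptorSpec(
    side="three_prime",
    sequence="AGATCGGAAGAGCACACGTCT",
    alphabet="DNA",
    name="synthetic-A1-3p",
)
DEFAULT_ADAPTOR5 = AdaptorSpec(
    side="five_prime",
    sequence="GUUCAGAGUUCUACAGUCCGACGAUC",
    alphabet="RNA",
    name="synthetic-A1-5p",
)

DEFAULT_MULTIPLIERS: dict[str, float] = {
    UNFAVORABLE: 0.15,
    NEUTRAL: 1.0,
    FAVORABLE: 2.0,
}


def _default_favorability(table: CategoryTable = DEFAULT_CATEGORY_TABLE) -> FavorabilityTable:
    """Planted favorability mirroring the known ligase structure preferences.

    Terminal-fold slots: a blocked (0 free bases) terminus is unfavorable,
    long free ends (>= 3 bases) favorable; a fully unstructured molecule is
    unfavorable for the 5' ligation but neutral for the 3' one. Cofold slots:
    loop-junction geometries (a break in a loop) are favorable, junctions
    buried in or flanking stems are unfavorable.
    """
    fold_common: dict = {0: UNFAVORABLE}
    fold_common.update({k: NEUTRAL for k in (1, 2)})
    fold_common.update({k: FAVORABLE for k in range(3, 61)})
    fold3 = dict(fold_common, **{"no pairing": NEUTRAL})
    fold5 = dict(fold_common, **{"no pairing": UNFAVORABLE})

    # Loop-break geometry (both junction bases free inside a loop) is the
    # ligase's preferred substrate; a junction whose flanking base sits in a
    # stem (paired intra- or intermolecularly) is a bulge/nick geometry and
    # unfavorable; fully exterior junctions are neutral.
    paired = {PAIRED_INTRA, PAIRED_INTER}
    cofold: dict = {REJECTED: NEUTRAL}
    for (sa, sb), cat_id in table.items():
        if sa in paired or sb in paired:
            cofold[cat_id] = UNFAVORABLE
        elif sa == LOOP_UNPAIRED and sb == LOOP_UNPAIRED:
            cofold[cat_id] = FAVORABLE
        else:
            cofold[cat_id] = NEUTRAL
    return FavorabilityTable(
        {"fold3": fold3, "fold5": fold5, "cofold3": cofold, "cofold5": cofold}
    )


DEFAULT_FAVORABILITY = _default_favorability()


@dataclass
class SimConfig:
    """Study conditions for one simulated library."""

    pool_size: int = 200
    insert_length: tuple[int, int] = (20, 25)
    mix: str = "equimolar"  # or "spread"
    spread_fold: float = 500.0
    adaptor3: AdaptorSpec = field(default_factory=lambda: DEFAULT_ADAPTOR3)
    adaptor5: AdaptorSpec = field(default_factory=lambda: DEFAULT_ADAPTOR5)
    multipliers: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_MULTIPLIERS))
    total_reads: int = 2_000_000
    seed: int = 0
    error_rate: float = 0.0  # uniform substitution rate; 0 keeps annotation exact

    def __post_init__(self) -> None:
        if self.pool_size < 1:
            raise ValueError("pool_size must be >= 1")
        if self.mix not in ("equimolar", "spread"):
            raise ValueError("mix must be 'equimolar' or 'spread'")
        if any(m <= 0 for m in self.multipliers.values()):
            raise ValueError("multipliers must be positive")
        if self.total_reads < self.pool_size:
            raise ValueError("total_reads must be >= pool_size")
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must be in [0, 1)")


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, independent RNG substream derived from one top-level seed."""
    key = zlib.crc32(name.encode()) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, key]))


def generate_pool(
    config: SimConfig,
    favorability: FavorabilityTable = DEFAULT_FAVORABILITY,
    single_backend: FoldingBackend | None = None,
    pair_backend: FoldingBackend | None = None,
) -> tuple[ReferencePool, list[AttributeVector]]:
    """Random unique pool plus attribute vectors against the configured adaptors.

    Deterministic for a fixed seed. Raises if the requested number of unique
    sequences cannot be produced in bounded attempts.
    """
    rng = substream(config.seed, "pool")
    lo, hi = config.insert_length
    seqs: list[str] = []
    seen: set[str] = set()
    attempts = 0
    while len(seqs) < config.pool_size:
        attempts += 1
        if attempts > 100 * config.pool_size:
            raise RuntimeError("could not generate enough unique sequences")
        length = int(rng.integers(lo, hi + 1))
        s = "".join(rng.choice(["A", "C", "G", "U"], size=length))
        if s not in seen:
            seen.add(s)
            seqs.append(s)
    if config.mix == "equimolar":
        conc = np.ones(config.pool_size)
    else:
        conc = np.geomspace(1.0, config.spread_fold, config.pool_size)
        rng.shuffle(conc)
    pool = ReferencePool(
        [
            PoolEntry(id=f"syn{i:04d}", sequence=s, concentration=float(c))
            for i, (s, c) in enumerate(zip(seqs, conc))
        ]
    )
    attrs = attribute_vectors(
        pool,
        config.adaptor3,
        config.adaptor5,
        favorability,
        single_backend=single_backend,
        pair_backend=pair_backend,
    )
    return pool, attrs


def planted_efficiency(
    attrs: AttributeVector, params: Mapping[str, float] | None = None
) -> float:
    """Multiplicative efficiency over the four favorability calls."""
    params = params or DEFAULT_MULTIPLIERS
    e = 1.0
    for call in attrs.calls:
        e *= params[call]
    return e


def efficiencies_for(
    attrs: Sequence[AttributeVector], params: Mapping[str, float] | None = None
) -> dict[str, float]:
    return {a.id: planted_efficiency(a, params) for a in attrs}


def simulate_counts(
    pool: ReferencePool,
    efficiencies: Mapping[str, float],
    total_reads: int,
    seed: int,
) -> dict[str, int]:
    """Multinomial read counts with p_i proportional to c_i * e_i."""
    ids = pool.ids
    conc = pool.concentrations
    weights = np.array([conc[i] * efficiencies[i] for i in ids], dtype=float)
    if weights.sum() <= 0:
        raise ValueError("degenerate probability vector (sum of c_i * e_i is 0)")
    p = weights / weights.sum()
    rng = substream(seed, "counts")
    draws = rng.multinomial(total_reads, p)
    return dict(zip(ids, (int(d) for d in draws)))


def simulate_library(
    pool: ReferencePool,
    efficiencies: Mapping[str, float],
    config: SimConfig,
    fastq_path: str | Path | None = None,
) -> tuple[list[str], pd.DataFrame]:
    """Full simulated library: adaptor-attached reads plus the truth table.

    Reads carry the 5' adaptor, the insert and the 3' adaptor, with any
    randomized regions filled uniformly at random per read. The truth table
    records concentration, planted efficiency, expected sampling probability,
    drawn count and the seed.
    """
    counts = simulate_counts(pool, efficiencies, config.total_reads, config.seed)
    rng = substream(config.seed, "fills")
    err_rng = substream(config.seed, "errors")
    bases = np.array(list("ACGU"))
    n3 = config.adaptor3.n_run_length
    n5 = config.adaptor5.n_run_length
    reads: list[str] = []
    for entry in pool:
        for _ in range(counts[entry.id]):
            fill3 = "".join(rng.choice(bases, size=n3)) if n3 else ""
            fill5 = "".join(rng.choice(bases, size=n5)) if n5 else ""
            read = attach_adaptors(
                entry.sequence, config.adaptor3, config.adaptor5, fill3=fill3, fill5=fill5
            )
            if config.error_rate > 0:
                arr = np.array(list(read))
                hit = err_rng.random(arr.size) < config.error_rate
                if hit.any():
                    arr[hit] = err_rng.choice(bases, size=int(hit.sum()))
                    read = "".join(arr)
            reads.append(read)
    conc = pool.concentrations
    weights = {i: conc[i] * efficiencies[i] for i in pool.ids}
    total_w = sum(weights.values())
    truth = pd.DataFrame(
        {
            "concentration": [conc[i] for i in pool.ids],
            "efficiency": [efficiencies[i] for i in pool.ids],
            "expected_p": [weights[i] / total_w for i in pool.ids],
            "count": [counts[i] for i in pool.ids],
            "seed": config.seed,
        },
        index=pd.Index(pool.ids, name="id"),
    )
    if fastq_path is not None:
        write_fastq(reads, fastq_path)
    return reads, truth


def write_fastq(reads: Sequence[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, r in enumerate(reads):
            fh.write(f"@read{i}\n{r}\n+\n{'I' * len(r)}\n")


def variant_efficiencies(
    pool: ReferencePool,
    adaptor3: AdaptorSpec,
    adaptor5: AdaptorSpec,
    n_variants: int,
    seed: int,
    favorability: FavorabilityTable = DEFAULT_FAVORABILITY,
    multipliers: Mapping[str, float] | None = None,
    single_backend: FoldingBackend | None = None,
    pair_backend: FoldingBackend | None = None,
) -> pd.DataFrame:
    """Planted efficiencies for each of n random fills of randomized adaptors.

    Models a randomized-adaptor pool: each variant is one concrete fill of the
    N-runs; a molecule's effective efficiency under the pooled adaptors is the
    mean over variants (every molecule can sample every variant).
    """
    rng = substream(seed, "variants")
    bases = np.array(list("ACGU"))
    cols = {}
    for v in range(n_variants):
        fill3 = "".join(rng.choice(bases, size=adaptor3.n_run_length))
        fill5 = "".join(rng.choice(bases, size=adaptor5.n_run_length))
        a3 = AdaptorSpec(
            side="three_prime",
            sequence=adaptor3.fill_random_region(fill3),
            alphabet=adaptor3.alphabet,
            name=f"{adaptor3.name}-v{v}",
        )
        a5 = AdaptorSpec(
            side="five_prime",
            sequence=adaptor5.fill_random_region(fill5),
            alphabet=adaptor5.alphabet,
            name=f"{adaptor5.name}-v{v}",
        )
        attrs = attribute_vectors(
            pool, a3, a5, favorability,
            single_backend=single_backend, pair_backend=pair_backend,
        )
        e = efficiencies_for(attrs, multipliers)
        cols[f"variant_{v}"] = [e[i] for i in pool.ids]
    return pd.DataFrame(cols, index=pd.Index(pool.ids, name="id"))
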