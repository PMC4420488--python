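"""Secondary-structure prediction backends.

Two engines sit behind one minimal contract (one MFE structure, one energy,
for a single molecule or a two-molecule "dimer" written in dual dot-bracket
notation with '&' at the junction):

* :class:`ViennaBackend` — ViennaRNA thermodynamic folding. Pair folding for
  ligation-substrate analysis is configured at 25 degC with the 1999 Turner
  parameters; single-molecule prediction defaults to the engine's default
  settings (37 degC, Turner 2004).
* :class:`StackingBackend` — a deliberately simple base-pair + stacking score
  with an exact dynamic program and a brute-force structure enumerator, used
  as an independent oracle and for dependency-free runs.

Energies are kcal/mol for Vienna and arbitrary negative units for the toy
model; only ordering matters for the acceptance rule.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass

from ._seq import validate_rna

_WOBBLE = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}
MIN_HAIRPIN = 3  # minimum unpaired bases closing an intramolecular hairpin


@dataclass(frozen=True)
class FoldResult:
    """Single-molecule MFE structure."""

    sequence: str
    dot_bracket: str
    mfe: float

    def __post_init__(self) -> None:
        if len(self.dot_bracket) != len(self.sequence):
            raise ValueError("structure length does not match sequence")
        depth = 0
        for ch in self.dot_bracket:
            if ch == "(":
                depth += 1
            elif ch == ")":
                depth -= 1
                if depth < 0:
                    raise ValueError("unbalanced dot-bracket")
            elif ch != ".":
                raise ValueError(f"invalid dot-bracket character {ch!r}")
        if depth != 0:
            raise ValueError("unbalanced dot-bracket")


def count_terminal_unpaired(fold: FoldResult, end: str) -> int | str:
    """Length of the terminal run of unpaired bases, or ``"no pairing"``.

    A molecule whose MFE structure contains no pair at all is its own group
    ("no pairing") rather than the trivial count of its full length, because
    fully unstructured RNAs behave differently as ligation substrates than
    structured RNAs with long free ends.
    """
    if end not in ("five_prime", "three_prime"):
        raise ValueError("end must be 'five_prime' or 'three_prime'")
    db = fold.dot_bracket
    if "(" not in db:
        return "no pairing"
    run = db[::-1] if end == "three_prime" else db
    k = 0
    for ch in run:
        if ch != ".":
            break
        k += 1
    return k


class FoldingBackend:
    """Contract: fold one molecule or one ordered pair; return one structure."""

    def fold(self, sequence: str) -> FoldResult:
        raise NotImplementedError

    def cofold(self, seq_a: str, seq_b: str) -> tuple[str, float]:
        """Return (dual dot-bracket with '&', dimer MFE)."""
        raise NotImplementedError


class ViennaBackend(FoldingBackend):
    """ViennaRNA MFE folding at a configurable temperature / parameter set.

    ``parameters`` is one of ``"turner2004"`` (engine default) or
    ``"turner1999"``. Parameter tables are process-global in the engine, so
    the backend re-loads them only when a different set was active.
    """

    _active_params: str | None = None

    def __init__(self, temperature: float = 37.0, parameters: str = "turner2004"):
        if parameters not in ("turner1999", "turner2004"):
            raise ValueError(f"unknown parameter set {parameters!r}")
        self.temperature = float(temperature)
        self.parameters = parameters

    def _model(self):
        import RNA

        if ViennaBackend._active_params != self.parameters:
            if self.parameters == "turner1999":
                RNA.params_load_RNA_Turner1999()
            else:
                RNA.params_load_RNA_Turner2004()
            ViennaBackend._active_params = self.parameters
        md = RNA.md()
        md.temperature = self.temperature
        return RNA, md

    def fold(self, sequence: str) -> FoldResult:
        seq = validate_rna(sequence)
        if not seq:
            raise ValueError("cannot fold an empty sequence")
        RNA, md = self._model()
        fc = RNA.fold_compound(seq, md)
        db, mfe = fc.mfe()
        return FoldResult(sequence=seq, dot_bracket=db, mfe=float(mfe))

    def cofold(self, seq_a: str, seq_b: str) -> tuple[str, float]:
        a = validate_rna(seq_a, context="molecule A")
        b = validate_rna(seq_b, context="molecule B")
        if not a or not b:
            raise ValueError("cannot cofold an empty sequence")
        RNA, md = self._model()
        fc = RNA.fold_compound(f"{a}&{b}", md)
        db, mfe = fc.mfe_dimer()
        return db[: len(a)] + "&" + db[len(a) :], float(mfe)


def default_single_backend() -> ViennaBackend:
    """Default-settings single-molecule predictor."""
    return ViennaBackend()


def default_pair_backend() -> ViennaBackend:
    """Pair folding at 25 degC with the 1999 Turner parameter set."""
    return ViennaBackend(temperature=25.0, parameters="turner1999")


class StackingBackend(FoldingBackend):
    """Exact folding under a toy pair + stacking energy model.

    Every Watson-Crick or G.U pair scores ``pair_energy``; every stacked pair
    (a pair (i, j) whose inner neighbour (i+1, j-1) is also paired) adds
    ``stack_energy``. Intramolecular hairpins must enclose at least
    ``MIN_HAIRPIN`` unpaired bases; pairs across the molecule junction are
    exempt, as in two-molecule folding. Pseudoknots are excluded. The dynamic
    program returns the exact optimum of this model, which makes the backend
    checkable against brute-force enumeration.
    """

    def __init__(self, pair_energy: float = -1.0, stack_energy: float = -1.0):
        self.pair_energy = float(pair_energy)
        self.stack_energy = float(stack_energy)

    # -- model ------------------------------------------------------------
    def _pairable(self, seq: str, i: int, j: int, cut: int) -> bool:
        if (seq[i], seq[j]) not in _WOBBLE:
            return False
        if cut is not None and i < cut <= j:
            return True  # intermolecular pair: no hairpin constraint
        return j - i - 1 >= MIN_HAIRPIN

    def _solve(self, seq: str, cut: int | None) -> tuple[str, float]:
        n = len(seq)
        INF = float("inf")

        @functools.lru_cache(maxsize=None)
        def paired(i: int, j: int) -> float:
            if not self._pairable(seq, i, j, cut):
                return INF
            inner = best(i + 1, j - 1) if i + 1 <= j - 1 else 0.0
            e = self.pair_energy + inner
            if i + 1 < j - 1:
                p_in = paired(i + 1, j - 1)
                if p_in < INF:
                    e = min(e, self.pair_energy + p_in + self.stack_energy)
            return e

        @functools.lru_cache(maxsize=None)
        def best(i: int, j: int) -> float:
            if i >= j:
                return 0.0
            e = best(i + 1, j)
            for k in range(i + 1, j + 1):
                pk = paired(i, k)
                if pk < INF:
                    e = min(e, pk + best(k + 1, j))
            return e

        structure = ["."] * n

        def trace_paired(i: int, j: int) -> None:
            structure[i], structure[j] = "(", ")"
            if i + 1 > j - 1:
                return
            target = paired(i, j) - self.pair_energy
            if (
                i + 1 < j - 1
                and paired(i + 1, j - 1) < INF
                and abs(paired(i + 1, j - 1) + self.stack_energy - target) < 1e-9
            ):
                trace_paired(i + 1, j - 1)
            else:
                trace_best(i + 1, j - 1)

        def trace_best(i: int, j: int) -> None:
            while i < j:
                if abs(best(i, j) - best(i + 1, j)) < 1e-9:
                    i += 1  # leaving i unpaired already achieves the optimum
                    continue
                for k in range(i + 1, j + 1):
                    pk = paired(i, k)
                    if pk < INF and abs(pk + best(k + 1, j) - best(i, j)) < 1e-9:
                        trace_paired(i, k)
                        i = k + 1
                        break

        mfe = best(0, n - 1)
        trace_best(0, n - 1)
        return "".join(structure), mfe

    # -- backend contract --------------------------------------------------
    def fold(self, sequence: str) -> FoldResult:
        seq = validate_rna(sequence)
        if not seq:
            raise ValueError("cannot fold an empty sequence")
        db, mfe = self._solve(seq, cut=None)
        return FoldResult(sequence=seq, dot_bracket=db, mfe=mfe)

    def cofold(self, seq_a: str, seq_b: str) -> tuple[str, float]:
        a = validate_rna(seq_a, context="molecule A")
        b = validate_rna(seq_b, context="molecule B")
        if not a or not b:
            raise ValueError("cannot cofold an empty sequence")
        db, mfe = self._solve(a + b, cut=len(a))
        return db[: len(a)] + "&" + db[len(a) :], mfe

    # -- independent oracle -------------------------------------------------
    def enumerate_structures(self, seq: str, cut: int | None = None):
        """Yield every pseudoknot-free pair set as a tuple of (i, j) pairs.

        Brute force; intended for short sequences in oracle tests.
        """

        @functools.lru_cache(maxsize=None)
        def structs(i: int, j: int):
            if i >= j:
                return ((),)
            out = list(structs(i + 1, j))
            for k in range(i + 1, j + 1):
                if self._pairable(seq, i, k, cut):
                    for inner in structs(i + 1, k - 1):
                        for outer in structs(k + 1, j):
                            out.append(((i, k),) + inner + outer)
            return tuple(out)

        yield from structs(0, len(seq) - 1)

    def score_pairs(self, pairs) -> float:
        """Energy of an explicit pair set under the model."""
        pair_set = set(pairs)
        e = self.pair_energy * len(pair_set)
        for i, j in pair_set:
            if (i + 1, j - 1) in pair_set:
                e += self.stack_energy
        return e

    def brute_force_mfe(self, seq_a: str, seq_b: str | None = None) -> float:
        """Minimum energy by exhaustive enumeration (the oracle)."""
        if seq_b is None:
            seq, cut = validate_rna(seq_a), None
        else:
            a, b = validate_rna(seq_a), validate_rna(seq_b)
            seq, cut = a + b, len(a)
        return min(self.score_pairs(p) for p in self.enumerate_structures(seq, cut))
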