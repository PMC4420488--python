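# Methods

## Normalization model

A defined pool is a set of `N` uniquely named, unique RNA sequences with
relative concentrations `c_i > 0`. Reads are trimmed of adaptors and
annotated only by exact, full-length, zero-mismatch equality to a pool
sequence (after T→U mapping); anything else counts once as unannotated.
Because pool sequences are unique, a read can match at most one entry, so
annotation is single-valued and the conservation identity
`annotated + unannotated = total` holds by construction.

Counts convert to normalized reads by dividing by the normalization factor
`annotated_total / N`, which forces the mean normalized value over the pool
to be exactly 1. The expected value is `expected_i = N c_i / Σc`, the unique
scaling that (a) reduces to 1 everywhere for an equimolar pool and (b) keeps
the mean expectation at 1 for non-equimolar mixes. All bias metrics operate
on the ratio `r_i = normalized_i / expected_i`.

Replicate libraries are combined by the arithmetic mean of normalized reads
per sequence; expected values must agree exactly across replicates.

## Trimming

Each adaptor is a sequence over `{A,C,G,U,T,N}` with at most one maximal
N-run marking a randomized region. The trimmer anchors on the
insert-proximal *defined* flank (for a 3' adaptor the segment 5' of the
N-run, or the first defined segment after an insert-proximal N-run, in which
case the randomized bases are removed together with the anchor) and locates
it by exact substring search — rightmost occurrence for the 3' adaptor,
leftmost for the 5' adaptor, so that inserts containing a flank copy
internally are not truncated. Anchors shorter than 4 nt are rejected as too
ambiguous. Reads that miss a required anchor are flagged untrimmed and
excluded from annotation rather than guessed at. Partial adaptor matches at
read ends are not attempted; a full anchor match is required.

## Folding and junction classification

Single-molecule structure and two-molecule (cofold) structure go through a
pluggable backend contract: one MFE structure and one energy per call, with
dimers written in dual dot-bracket notation (`&` at the junction between A's
last and B's first base). Two backends ship:

* **ViennaRNA** (default). Pair folding is configured at 25 °C with the 1999
  Turner parameter set; single-molecule prediction uses the engine's default
  settings. DNA adaptors are folded as RNA after T→U mapping; this treats the
  3' DNA adaptor with an RNA energy model, a deliberate approximation that
  keeps both ligation steps in one thermodynamic frame.
* **StackingBackend**, an exact dynamic program for a deliberately simple
  model (−1 per Watson-Crick/G·U pair, −1 per stacked pair, hairpins ≥ 3 nt
  intramolecularly, no constraint across the junction, no pseudoknots). Its
  optimum is verifiable against brute-force enumeration of all structures,
  which the test suite does exhaustively for every 2-letter pair of combined
  length ≤ 10; it also serves dependency-free runs.

A cofold is **accepted** as a real interaction only when the dimer MFE is
strictly below the MFE of each molecule folded alone. The monomer reference
energies are plain MFEs; no duplex-initiation correction is applied, so the
rule is a pure energy comparison under one parameter set. Only the single
canonical MFE structure is used — no ensemble or suboptimal analysis.

Accepted cofolds are classified by the states of the two junction-flanking
bases. Each base is `exterior_unpaired` (dot enclosed by no pair),
`loop_unpaired` (dot enclosed by at least one pair), `paired_intra`
(partner on its own side of the junction) or `paired_inter` (partner across
the junction); the 4×4 combinations give 16 categories. The integer ids are
a configurable bijection; the shipped default numbers the pairs row-major in
the state order above. In pseudoknot-free structures exactly four
combinations — (exterior, loop), (loop, exterior), (exterior, inter),
(inter, exterior) — are geometrically impossible, because any pair that
encloses one junction base from across the junction necessarily encloses the
other; with the default numbering these are ids 2, 4, 5 and 13. If a
specific published numbering must be reproduced, the mapping table is the
single place to recalibrate.

Terminal structure of a single molecule is summarised as the length of the
terminal run of unpaired bases at the ligated end, except that a completely
pair-free structure forms its own group, "no pairing" — unstructured RNAs
behave differently as ligase substrates than structured RNAs with free ends,
so conflating them with "many free bases" would blur the attribute.

## Enrichment and favorability

Composition enrichment for randomized-region libraries is the
input-normalized nucleotide percentage `RNnp = 25 · f_out / f_in` reported
as `RNnp − 25` percentage points, so 0 means no preference; cells with zero
input frequency are reported as explicit NA. Category/group enrichment is
the signed fraction `E = (subset − all)/all`, again with NA for empty
reference classes.

An attribute class is called **unfavorable** when `E ≤ −0.10`, **favorable**
when `E ≥ +0.20` (cofold categories) or `E ≥ +0.05` (single-molecule fold
groups), otherwise neutral. Per sequence, four attribute slots are filled:
3'-terminal fold group and 3' cofold category on the bare molecule (molecule
A, adaptor B), and 5'-terminal fold group and 5' cofold category on the
molecule with the 3'-adaptor sequence appended (5' adaptor as molecule A) —
the species actually present at the 5'-ligation step. `n_unfavorable ∈ 0..4`
groups the pool for the cumulative-bias analysis. Labels missing from a
favorability table fall back to neutral with a warning; rejected cofolds are
their own label.

## Adaptor design

* **C3-style**: the 5' adaptor's 3'-terminal k bases (default 7) are replaced
  by the reverse complement of the 3' adaptor's first k bases, enabling a
  cross-insert duplex that favors loop-junction cofolds.
* **Randomized**: one N-run (default 6 nt), insert-proximal or internal
  (MidRand-style); construction validates that the trimmer retains a ≥ 4 nt
  defined anchor.
* **Targeted**: for one substrate (RNA + 3'-adaptor), windows of length 7 at
  offsets 2..6 from the substrate's 5' end are reverse-complemented onto the
  base adaptor's 3' end; candidates are cofolded and classified, and the
  first one achieving the requested junction state pair (default: loop on
  both sides) is returned. Offsets start at 2 so at least one substrate base
  stays unpaired at the junction, leaving room for the loop geometry. If no
  candidate qualifies, the lowest-energy candidate is returned flagged
  unmet, with all candidates attached. Design complementarity is
  Watson-Crick only, though the folding backend may add G·U pairs when
  evaluating.

## Synthetic data generator

The generator emulates a defined-pool calibration experiment: unique random
RNA sequences of 20–25 nt (defaults: 200 sequences, equimolar; optionally a
geometric 500-fold concentration spread), a defined adaptor pair (synthetic
stand-ins with the standard layout: 21 nt DNA 3' adaptor, 26 nt RNA 5'
adaptor), and a planted efficiency `e_i` equal to the product of one
multiplier per attribute call (defaults 2.0 favorable / 1.0 neutral / 0.15
unfavorable). Counts are multinomial with `p_i ∝ c_i e_i` at 2×10⁶ reads by
default; reads are adaptor-attached with uniform N-run fills. A substitution
error knob exists but defaults to 0 so zero-mismatch annotation stays exact.
All randomness derives from one seed through named substreams, so pool,
counts, fills and errors are independently reproducible.

The planted favorability table encodes the qualitative ligase preferences:
loop-break junction geometries favorable, junctions with a base-paired
flanking base unfavorable, blocked (0 free bases) termini unfavorable, long
free ends favorable, fully unstructured molecules unfavorable for the 5'
ligation and neutral for the 3'. It was fixed so that the simulated
single-sequence-adaptor baseline shows bias of the magnitude defined-pool
experiments report (tens of percent of sequences >10-fold under-represented,
~4 log10 ratio spread, all 0–4 unfavorable-attribute groups populated).

What the simulation does **not** model: ligase kinetics, PCR amplification
bias, sequencing error profiles, partial adaptor ligation products, or
ensemble folding. Passing recovery tests therefore demonstrates that the
pipeline is correct and self-consistent, not that the planted multipliers
are biologically calibrated.

### A note on rank-recovery ceilings

Because planted efficiencies are products of three multiplier values, a
200-sequence pool carries only ~11–15 distinct `e_i`; Spearman correlation
with average-rank tie handling then has a hard ceiling below 1 against any
untied response (≈ 0.983 at the default conditions). Observed rank agreement
between normalized reads and planted efficiency reaches this ceiling to four
decimals at 2×10⁶ reads, i.e. the ordering is recovered perfectly; the
residual gap from 1 is a property of the tie structure, not of the pipeline.

## Numerical choices

* Within-2-fold is the closed interval `[0.5, 2]`; >10-fold-under is strict
  `r < 0.1`, and `r = 0` (zero reads) counts there as the limit of
  under-representation while being excluded from the log-spread.
* Mann-Whitney comparisons are two-tailed; the exact null distribution is
  used when both groups have ≤ 8 values and the pooled sample is tie-free,
  otherwise the normal approximation with average-rank tie correction.
* Replicate discrepancy counts pairs with max/min ≥ 2; a pair with exactly
  one zero is discrepant by definition, double zeros are excluded.
* MFE ties inside a backend resolve to the backend's single canonical
  structure (the toy DP prefers leaving a base unpaired on exact ties).
* Empty inputs, zero annotated reads, ragged randomized regions, degenerate
  probability vectors and non-bijective category tables all raise rather
  than warn.

## Scale of shipped analyses

The test suite and the acceptance script run entirely on synthetic data: the
property battery at pools of ≤ 50 sequences, the recovery study at the
generator's default conditions (200 sequences, 2×10⁶ sampled reads, 16
randomized-adaptor variants). Analysis of a real defined-pool experiment
(hundreds of unique sequences, each cofolded against each adaptor) uses the
same code paths and scales linearly in pool size × adaptor variants.
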