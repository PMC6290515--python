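# Methods

## Problem and model

`flexscan` ranks homologs of a query protein by how attractive they are as
expression targets: close in sequence, low in intrinsic disorder. Two
per-hit statistics feed one hybrid score.

**Disorder content (IDS).** Given a per-residue disorder trace
*s₁…s_l* ∈ [0, 1], IDS is the percentage of residues with *s_r* strictly
above a threshold (default 0.5). The inequality is strict: a residue
scoring exactly at the threshold counts as ordered. IDS is displayed in
percent but enters FLEX as a fraction; both facts are fixed by requiring
FLEX ∈ [0, 1] and by reproducing the reference score table (see tests).

**Homology (E-value).** Each library sequence is aligned to the query by
optimal affine-gap Smith–Waterman (BLOSUM62; a gap of length *k* costs
`gap_open + k·gap_extend`, defaults 11/1). Significance uses the
Karlin–Altschul database model `E = K·m·n·exp(−λS)` with *m* the query
length and *n* the **total** residue count of the library, so E-values are
comparable across subjects as in database search. λ = 0.267, K = 0.041 —
the published gapped BLOSUM62/11/1 constants — make the engine
deterministic; numeric agreement with NCBI BLAST's E-values is not
promised (BLAST applies edge corrections and composition adjustments),
though raw scores agree exactly with blastp when its composition-based
statistics and SEG filtering are off, which the optional external adapter
therefore disables. A library entry equal to the query (same accession or
identical residues) is the *self hit*: its E-value is set to exactly 0 and
it always ranks first.

**FLEX.** `FLEX = (1−η)·t(E) + η·(1 − IDS/100)` with
`t(E) = 1 − 0.99^((−log₁₀E)²)` and `t(0) = 1` as the limiting convention
for self hits. The transform's base-10 logarithm, the fractional IDS and
the `t(0)=1` convention are each pinned by closed-form reproduction of the
reference table at 4 decimal places (acceptance suite). `t` is sigmoidal
in −log₁₀E: near-linear between E = 10⁻³ and 10⁻¹⁴, with tails
approaching 0 (E→1) and 1 (E→0). For E ≥ 1 the squared exponent keeps
t ∈ [0, 1] without clamping; t rises again for E > 1, which the E-value
threshold (always ≪ 1) keeps out of scope. The priority coefficient η
defaults to 0.5 (equal weighting); η = 1 ranks purely by intrinsic order.

A **superior homolog** is a hit whose FLEX strictly exceeds the query's
under the same η; screen summaries count them and bin their IDS
improvements (query IDS − hit IDS) in 5-point bins.

## Disorder prediction is pluggable

Dedicated disorder predictors (IUPred and kin) estimate pairwise
interaction energy from sequence; reimplementing one is out of scope here.
The built-in default is a deliberately simple composition heuristic: over
a centered window (101 residues in `long` mode, 25 in `short`, truncated
at the termini),

```
score = clamp01( 0.45 − 0.12·mean_KD_hydropathy + 0.5·|mean_net_charge| )
```

with Kyte–Doolittle hydropathy and K/R = +1, D/E = −1 charges. The
constants are calibrated so low-complexity polar/charged stretches
(poly-E/K/S/P) score above 0.5 and hydrophobic cores below it. It captures
the composition signal real predictors exploit but claims no accuracy
parity with them; quantities that depend on absolute predictor output
(e.g. a specific protein's published IDS under IUPred) are reproducible
only with that predictor's own scores, which can be supplied as
per-accession score files (`<accession>.scores`, one score or
`index score` per line) and then drive IDS, FLEX and trace alignment
unchanged.

## Polyprotein virtual processing

A hit on an unprocessed viral polyprotein is mapped to the mature peptide
(chain) with maximal residue overlap with the hit's subject interval; ties
go to the smaller start, and with no overlapping chain the whole sequence
is used with a logged warning. IDS is recomputed over the selected
fragment only; the hit's E-value is kept as computed on the full subject —
re-aligning against the fragment would change the search statistics
mid-run. Chain tables are local TSVs mirroring UniProt CHAIN features
(1-based inclusive coordinates throughout); no remote annotation retrieval.

## Trace alignment

The multiple aligner is progressive: pairwise global affine alignments
(BLOSUM62, gap open 10, extend 0.1) give distances (1 − fractional
identity), average-linkage (UPGMA) clustering gives the guide tree, and
profiles merge by affine profile–profile dynamic programming whose column
score is the mean cross-pair substitution score (gap characters contribute
0). Output is deterministic for a fixed input order; since aligner
defaults are convention-bound, alignment-dependent outputs such as segment
boundaries are conventions of this package, not universal values.

Projection places each row's trace at its non-gap columns; gap cells score
exactly 0.0 so gaps are visible in overlaid traces. The 0.0 value is
knowingly overloaded (gap vs. genuinely ordered residue); the gap mask is
kept alongside the matrix for consumers that need the distinction. Segment
reports list maximal runs of query residues above the IDS threshold in
1-based query residue coordinates, each with the mean fraction of other
rows disordered over the same columns; runs below a cross-row fraction of
0.5 are flagged as deletion candidates.

## Synthetic data generator

Test inputs are homolog families with designed architecture: an ancestor
drawn block-wise from a disordered pool {E,K,S,P,Q,G} and an ordered pool
{L,I,V,F,W,Y,A,M}, and descendants derived by per-residue point
substitutions (within the block's pool, preserving architecture) and
single-residue indels. Score profiles emulate predictor output at
0.8 ± 0.1 (disordered) and 0.2 ± 0.1 (ordered), uniform noise, clamped —
the 0.1 half-width keeps every score on the correct side of the 0.5
threshold, so ground-truth IDS equals block arithmetic exactly. The pools
are chosen so the built-in heuristic separates blocks cleanly; this is a
documented calibration coupling between fixtures and predictor. One
integer seed drives everything (per-accession profile streams are derived
via CRC32, keeping them process-independent).

What the generator does **not** emulate: realistic substitution processes
(no matrix-driven mutation, no rate heterogeneity, no domain-level
rearrangements), realistic disorder score shapes (real traces oscillate
near the threshold; block profiles do not), or database-scale composition
diversity. Passing tests therefore demonstrate the correctness of the
statistics and plumbing on controlled input, not predictor accuracy or
BLAST-equality on natural proteomes.

### Study conditions

The acceptance run screens a 400-residue query (30% + 15% disordered
termini around an ordered core; overall true IDS 45%) against its family
of eight descendants at 5% substitutions and 1% indels — desk-scale
conditions chosen to mirror a single-protein screen with a custom library;
E-value threshold 10⁻¹⁰, at most 100 hits, η = 0.5, all defaults.

## Numerical and design choices

- Identity and similarity percentages use the full alignment length
  (including gap columns) as denominator; similarity counts columns whose
  substitution score is positive.
- Equal E-values (and equal FLEX/IDS) tie-break by accession, so reports
  are byte-reproducible.
- X/B/Z are scored by BLOSUM62's ambiguity rows; U (absent from the
  matrix) scores 0 against everything — tolerated, never rewarded.
- FLEX prints at 4 decimals, IDS at 3, E-values as 2-decimal scientific
  notation; full precision is kept internally.
- The report TSV is recomputable row-by-row: FLEX re-derives from the
  printed E-value and IDS columns within print precision.
- Config files are YAML mirroring the CLI flags; explicit CLI values win.

## Known limitations

- The built-in E-values use fixed Karlin–Altschul constants with no
  length/edge corrections; they are internally consistent (e.g. doubling
  the library doubles E) but not interchangeable with NCBI BLAST's.
- The heuristic predictor misreads sequences whose disorder is not
  composition-driven (e.g. conditionally folded regions).
- The progressive aligner has no iterative refinement; pathological guide
  trees can propagate early gap placement errors.
- Reference-table FLEX values are reproduced from printed inputs to one
  unit in the fourth decimal: the printed IDS and E-value columns are
  themselves rounded, which caps the achievable agreement.
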