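# flexscan

Screen homologs of a query protein for **intrinsic structural order**.

Intrinsically disordered regions make proteins hard to express, purify and
crystallise. When a target resists structural work, a close homolog with
less disorder is often the practical way forward, and dispensable
disordered segments can be truncated from the expression construct.
`flexscan` automates that reasoning: it searches a FASTA library for
homologs of a query, predicts per-residue intrinsic disorder for every hit,
summarises each hit's disorder content, and ranks hits by a hybrid score
that balances homology strength against structural order.

## The statistics

For a per-residue disorder trace *s₁ … s_l* (each *s_r* ∈ [0, 1]), the
**intrinsic disorder score** is the percentage of residues strictly above a
threshold (default 0.5):

```
IDS = 100 · #{ r : s_r > 0.5 } / l
```

Homology strength enters through the Karlin–Altschul E-value of the optimal
local alignment, `E = K·m·n·exp(−λ·S)`, mapped onto [0, 1] by a sigmoidal
transform that converges the extreme low-E range while resolving the
middle:

```
t(E) = 1 − 0.99^((−log₁₀ E)²),     t(0) = 1  (self hits)
```

The **FLEX score** is the weighted average of the two components, with the
priority coefficient η ∈ [0, 1] shifting the weight from homology (η → 0)
to intrinsic order (η → 1):

```
FLEX = (1 − η) · t(E) + η · (1 − IDS/100)          ∈ [0, 1]
```

A hit whose FLEX score exceeds the query's own is a *superior homolog*:
about as close, but more ordered — a better bet for the bench.

The built-in disorder predictor is a windowed composition heuristic
(hydropathy + net charge); genuine output from an external predictor such
as IUPred can be injected per accession via plain score files and drives
every downstream statistic unchanged. Viral polyprotein hits can be
virtually processed with a chain table so IDS is computed on the mature
peptide the hit overlaps. A trace-alignment module projects disorder
traces onto a multiple alignment (gap cells score exactly 0.0) and reports
which disordered segments of the query are conserved and which are
deletion candidates.

## Worked example

```python
from flexscan import FlexParams, flex_score, evalue_transform

# a close but highly disordered hit vs a weaker but fully ordered hit
close_disordered = dict(ids_pct=70.0, evalue=3.8e-28)
weak_ordered     = dict(ids_pct=0.0,  evalue=5.2e-11)
for eta in (0.1, 0.9):
    a = flex_score(params=FlexParams(eta=eta), **close_disordered)
    b = flex_score(params=FlexParams(eta=eta), **weak_ordered)
    print(eta, round(a, 4), round(b, 4))
```

prints

```
0.1 0.9295 0.6891
0.9 0.3699 0.9655
```

— at η = 0.1 the near-identical hit wins on homology; at η = 0.9 the fully
ordered hit wins on structure. `examples/` holds one narrative script per
capability (screening, scoring, trace alignment, polyprotein processing);
each builds a small input, runs the method and explains what it printed.

From the shell:

```
flexscan fixtures --seed 5 --out fam/
flexscan scan --query fam/family.fasta --db fam/family.fasta \
    --out run/ --evalue-threshold 1e-10 --flex-coefficient 0.5 \
    --score-dir fam/
flexscan compare --query fam/family.fasta --db fam/family.fasta \
    --out run/ --ids FAM5A,FAM5D1 --evalue-threshold 1e-5 --score-dir fam/
```

`scan` writes a ranked TSV (identifier, gene id, species, identity,
similarity, E-value, IDS, FLEX — the query row first with E-value 0);
`compare` writes the aligned FASTA, the projected trace matrix and the
disorder-segment report.

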