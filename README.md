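# mitodate

Molecular divergence estimation and dating for mitochondrial genomes,
built for the kind of question raised by the two Indonesian coelacanth
(*Latimeria*) lineages: how different are two mitogenomes, where on the
tree did their differences arise, and when did the lineages split?

The package implements the full chain as a reusable library with a thin
CLI:

- **Distances and indels** — uncorrected (p-) distances under pairwise
  deletion, per-gene distance tables via gap-aware annotation mapping,
  base-difference counts, and maximal-indel summaries.
- **Protein-level mapping** — translation under the vertebrate
  mitochondrial code (NCBI table 2) and amino-acid replacement tables,
  with three-taxon parsimony assigning each replacement to a terminal or
  internal branch.
- **Maximum likelihood** — GTR+Γ+I via Felsenstein's pruning algorithm
  with pattern compression, NJ starting trees, NNI search, nonparametric
  bootstrap confidence intervals for branch lengths, and a bootstrap test
  of rate equality between two branches.
- **Dating** — a penalized-likelihood chronogram under the correlated-rate
  model (quadratic roughness penalty λ·Σ(r_i − r_parent)² on adjacent
  branch rates, soft fossil-calibration windows), and a relaxed
  lognormal-clock MCMC with a Yule prior and normal calibration priors,
  summarized by posterior medians, HPD intervals and ESS.
- **Synthetic data** — a generator that evolves annotated mitogenome-like
  alignments on known trees and chronograms, so every stage is testable
  against planted truth.

## Worked example

The bundled dataset holds the 35 amino-acid replacement columns observed
among three key mitogenomes (the new Papua specimen, the Manado specimen
GQ911586, and *L. chalumnae* AP012199) across the ND1, ND2 and COI
proteins. Three-taxon parsimony assigns each replacement to a branch:

```python
from mitodate.datasets import (latimeria_aa_replacements, TAXON_PAPUA,
                               TAXON_MANADO, TAXON_CHALUMNAE)
from mitodate.mitoprotein import assign_branches

table = latimeria_aa_replacements()
counts = assign_branches(table, TAXON_PAPUA, TAXON_MANADO, TAXON_CHALUMNAE)
print(f"variable amino-acid positions: {table.n_columns}")
print(f"events on the Papua branch:    {counts.tip_a}")
print(f"events on the GQ911586 branch: {counts.tip_b}")
print(f"events on the internal branch: {counts.internal}")
```

```
variable amino-acid positions: 35
events on the Papua branch:    6
events on the GQ911586 branch: 5
events on the internal branch: 24
```

Of the 35 replacements separating the Indonesian pair from
*L. chalumnae*, 24 accumulated on the internal branch between the two
main clades, and the 11 differences between the two Indonesian genomes
split almost evenly (6 vs 5) across their terminal branches — the pattern
expected if both lineages evolve at the same rate.

From the shell, a full synthetic dataset and its per-gene distance table:

```sh
$ mitodate simulate --scenario latimeria --seed 7 --out demo
wrote demo/alignment.fasta (27 x 16448)
$ mitodate distances --aln demo/alignment.fasta --ref Manado \
    --ann demo/genes.tsv --pairs Papua:Manado --out demo/d.csv
wrote demo/d.csv (17 rows)
```

|     gene | p_distance | n_compared | n_diff |
|---------:|-----------:|-----------:|-------:|
| tRNA-Phe |     0.0299 |         67 |      2 |
|      12S |     0.0137 |        950 |     13 |
|      16S |     0.0077 |       1698 |     13 |
|      ND1 |     0.0144 |        975 |     14 |

Each row is one annotated feature; `n_compared` counts columns where both
sequences have an unambiguous base (pairwise deletion), so the
new-specimen analogue contributes only its sequenced half-genome.

Dating runs the same way (`mitodate mltree`, `mitodate date-pl`,
`mitodate date-mcmc`), or as one pipeline from a YAML config with
`mitodate run-all`.

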