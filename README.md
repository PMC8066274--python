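# virotyper

Community profiling for shotgun viromes (virus-like-particle metagenomes).
Given the standard 12-column tabular outputs of protein- and nucleotide-level
alignment searches, the package identifies reads taxonomically in two stages,
builds genome-length-normalized virotype abundance tables, and computes the
community statistics an aquatic-virology study needs: alpha diversity, NMDS
ordination with fitted gradient vectors, hierarchical clustering, pairwise
chi-square comparisons, scaffold-level taxonomy by protein majority vote, and
functional (KEGG/COG/AMG) and host-range profiles.

It is aimed at microbial ecologists who already ran the heavy external steps
(read trimming, DIAMOND/BLAST searches, assembly, viral detection, read
mapping) and need a tested, reproducible implementation of everything that
comes after. A synthetic community generator with known ground truth makes
every stage verifiable without any sequence data.

## The model

A *virotype* is the closest known reference genome (a RefSeq ID) a read or
scaffold can be assigned to. Identification is two-staged:

1. protein stage — a read is assigned to the best hit (highest bit score,
   ties by e-value, then subject ID) among hits with identity ≥ 35%,
   e-value ≤ 10⁻⁵ and bit score ≥ 50;
2. nucleotide stage — reads without a qualifying protein hit are assigned
   from genome-level hits with e-value ≤ 10⁻⁵ and bit score ≥ 50; the rest
   are not identified as viral.

Raw counts nᵢ over-represent long genomes (at equal particle concentration a
genome twice as long contributes twice the DNA), so per sample:

    Lₛ = (1/N) Σᵢ Lᵢ        (mean genome length over the N virotypes present)
    Sᵢ = Lₛ / Lᵢ            (normalization coefficient)
    nkᵢ = nᵢ · Sᵢ           (length-normalized count)

which conserves Σᵢ nkᵢ·Lᵢ = Lₛ·Σᵢ nᵢ and makes normalized counts proportional
to particle abundances. Downstream statistics use the 95% *dominant pool*
(the minimal set of top virotypes reaching 95% of a sample's normalized
counts), Shannon H = −Σ p ln p, the Gini–Simpson index 1 − Σ p², the
bias-corrected Chao1 estimator S + f₁(f₁−1)/(2(f₂+1)), Kruskal stress-1
NMDS on Euclidean distances of relative-abundance + 0–1-ranged profiles,
UPGMA/complete-linkage clustering, and Bonferroni-corrected Pearson
chi-square tests. Scaffolds get the virotype with the most protein votes,
ties broken by the highest percent identity.

## Worked example

The `analysis/` scripts run the whole study on the synthetic community
(seed 42: 4 samples × 100 virotypes × 10⁵ reads, ~90% unidentifiable):

```
$ python analysis/01_simulate.py
simulated 400,000 reads across 4 samples
  protein-identifiable: 36,197; nucleotide-only: 3,899; unidentifiable: 359,904

$ python analysis/02_assign_reads.py
S1: 9,930/100,000 reads viral (9.93%)
...

$ python analysis/03_normalize_abundance.py
S1: mean genome 107,714 bp; dominant pool keeps 68/100 virotypes; normalized
counts vs planted abundance r = 0.9970
...

$ python analysis/04_diversity_ordination.py
    species_richness  shannon  simpson  chao1
S1              68.0    3.742    0.961   68.0
...
NMDS stress-1: 6.175e-07
pairwise chi-square: 6/6 pairs differ (Bonferroni p <= 0.05)
```

The percent-viral figures land in the ~10% range real viromes show; the
normalized counts recover the planted particle abundances at r ≈ 0.996–0.998
(raw counts instead track abundance × genome length — the bias the
normalization exists to remove); near-zero stress reflects only four samples
being ordinated. Scripts 05–06 assign scaffolds (100% recovery with planted
unanimous majorities) and build KEGG/COG/AMG and host-phylum profiles.

A `virotyper` console command exposes the same stages
(`simulate`, `assign`, `normalize`, `stats`, `run-all`).

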