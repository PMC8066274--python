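# Methods

## Scope and data model

The package operates entirely on tabular artifacts: 12-column alignment hit
tables (`qseqid sseqid pident length mismatch gapopen qstart qend sstart
send evalue bitscore`, coordinates 1-based inclusive and never converted),
read tables (`read_id length sample_id`), virus metadata (genome length in
bp, family, genome type, host lineage, keyed by RefSeq ID), scaffold
metadata and per-sample mapped-read count tables. Running aligners,
assemblers, viral detectors, AMG callers or host predictors is out of scope;
their outputs are inputs here, and the synthetic module fabricates all of
them for testing.

## Two-stage identification

Reads shorter than 100 bp are dropped (inclusive threshold; the 100–301 bp
range corresponds to 2×300 paired-end chemistry after trimming). Stage 1
assigns a read from its protein-level hits with percent identity ≥ 35 that
are also globally significant (e-value ≤ 10⁻⁵, bit score ≥ 50); stage 2
considers only stage-1-unassigned reads and uses the e-value/bit-score
filter alone. "Proteomic similarity" is the hit's `pident` over the aligned
region — the only per-hit similarity the tabular format carries.

Best-hit selection is not defined by the alignment tools when scores tie, so
the package fixes a total order: highest bit score, then lowest e-value,
then lexicographically smallest subject ID. Multiple HSPs to one subject
still count the read once (reads, not HSPs, are the counting unit), and
paired-end mates are independent reads. The e-value threshold is the
inclusive form (≤ 10⁻⁵); with continuous score distributions the strict
form is indistinguishable.

## Genome-length normalization

Per sample, Lₛ is the mean genome length over virotypes with nonzero count
in that sample (zero-count virotypes do not enter N — the literal reading of
"number of virotypes in the sample"), Sᵢ = Lₛ/Lᵢ, nkᵢ = nᵢSᵢ. The algebraic
conservation Σ nkᵢLᵢ = Lₛ Σ nᵢ is property-tested to 10⁻⁹ relative.
Normalized counts stay real-valued; operations that need integers (Chao1's
singleton/doubleton detection, chi-square contingency tables) receive counts
rounded half-to-even, because no rounding rule is canonical and half-even is
bias-free.

The dominant pool is taken per sample (per-sample post-filter richness is
the reported quantity downstream): virotypes ranked by descending normalized
count, the minimal prefix whose cumulative share reaches the 0.95 fraction
retained, ties at the boundary count all retained, everything else zeroed.
Whether the pool should instead be taken over the pooled dataset is a
genuinely open choice; per-sample is the default and the fraction is a
parameter, so the alternative is one call away.

## Diversity and ordination

Shannon entropy uses natural log (values for ~10²–10³ virotypes on skewed
abundance distributions land in the 4–6 nat range typical of virome
studies); Simpson is the complement (Gini–Simpson) form 1 − Σp², the only
form that produces the >0.98 values such communities show; Chao1 is the
bias-corrected estimator S + f₁(f₁−1)/(2(f₂+1)), defined when f₂ = 0 and
collapsing to S when f₁ = 0 (after half-even rounding, normalized tables
frequently have no singletons, so Chao1 = richness is the expected pattern,
not a bug).

Before ordination, tables are transformed in this order: per-sample relative
abundance, then per-virotype 0–1 ranging across samples ((x − min)/(max −
min), constants mapping to 0). NMDS minimizes Kruskal stress-1 on Euclidean
distances of the transformed profiles. SMACOF (scikit-learn) is started from
the classical-scaling (Torgerson) configuration plus 19 random starts and
the best configuration by stress-1 wins; the reported stress is always
recomputed from the returned coordinates by the package's own
isotonic-regression stress evaluator, so an independent recomputation agrees
to ≤ 10⁻⁶ by construction of the selection, not by luck. The classical
start guarantees exact (stress ≈ 0) recovery of configurations that embed
perfectly, where random-start SMACOF alone can stall. Fewer than 3 samples
is an error (stress degenerates).

Gradient vectors: each external variable is least-squares-regressed on the
two ordination axes (envfit-style); direction is the unit coefficient
vector, R² the explained-variance fraction, and the p-value a permutation
test over sample labels — 999 permutations and α = 0.05 by default, both
parameters, since no canonical values exist. The permutation count matters
little beyond resolution of the p-value; the type-I error of the test is
simulation-checked against its binomial interval. Constant variables have
undefined R² and are flagged unreliable.

Sample dendrograms use UPGMA (average linkage) on Euclidean distances,
verified against a brute-force all-pairs implementation for n ≤ 7 and
exported as Newick with branch lengths = parent merge height − child merge
height. Heatmap display orders transform counts log10(x+1) and take the
complete-linkage dendrogram leaf order for rows and columns. Pairwise
chi-square tests are plain Pearson (no Yates correction) on the 2×V table of
a sample pair, virotypes empty in both samples dropped, Bonferroni = raw p ×
number of pairs, capped at 1.

## Scaffold taxonomy, function and host profiles

Scaffold retention is coverage strictly greater than 5 and length ≥ 5000 bp
(the wording of the source filters differs between "more than five" and the
inclusive length bound; both are parameters, and a 10× coverage variant used
in some summaries is reachable by flag). Each protein's best proteome hit
(bit-score-selected, qualifying at e-value ≤ 10⁻⁵, bit ≥ 50, identity ≥ 35 —
the same filter reused for the scaffold stage, which states no separate
one) casts one vote; most votes wins, vote ties break by maximum percent
identity among the tied taxa, residual ties lexicographically. Proteins
without a qualifying hit abstain rather than block. Protein counts per
sample equal the containing scaffold's mapped-read count.

Functional profiles divide each category's summed protein read counts by
the sample's mean read count per annotated protein (total annotated-protein
reads / number of annotated proteins). "Normalized for the average number
of hits" admits several readings; this one is the only depth-scale-invariant
one (doubling every count in a sample changes nothing), and the normalizer
is pluggable. KO→pathway and COG→category mappings are fixture tables, not
live service queries, so tests are hermetic. AMG calls go through the
identical transform restricted to AMG proteins. Host profiles aggregate
scaffold read counts to host phylum via either a virus→host lookup or a
per-scaffold predictor output; the two sources are reported separately and
never merged (no principled reconciliation exists). Unassigned scaffolds
and unmapped hosts fall into "unknown", so shares including unknown always
sum to 1.

## Synthetic communities

The generator emulates the statistical structure the pipeline assumes, with
defaults fixed once as the emulated study conditions: 4 samples, 100
virotypes, lognormal particle abundances (meanlog 0, sdlog 1, per-sample
multiplicative jitter sdlog 0.6), genome lengths uniform on 5–200 kb, 10⁵
reads per sample drawn multinomially with probability ∝ abundance × genome
length, read lengths uniform 100–301 bp, 90% of reads unidentifiable
(real viromes identify ~8–20%), 10% of identifiable reads reaching only the
nucleotide stage, per-read identity truncated-Normal(60, 12) (average
similarities in environmental viromes sit in the 35–70% band), and decoy
secondary hits at strictly lower bit scores on 30% of hit-bearing reads to
exercise tie-breaking. Scaffold fixtures plant a true virotype per scaffold
(vote truthfulness 0.85 by default, 1.0 for recovery tests), Poisson protein
counts, and host phyla drawn from a configurable mixture.

One integer seed drives everything; each emitter derives its generator from
(seed, fixed offset), so adding an emitter never perturbs earlier streams,
and all outputs are byte-identical across runs for a fixed seed.

What the generator does **not** model: base-level sequence content, quality
scores, chimeras and assembly errors, database incompleteness structured by
taxon (unidentifiability is uniform, not phylogenetically clustered), and
read-length-dependent alignment quality. Passing tests therefore show the
*bookkeeping and statistics* are correct under the declared noise model —
they do not certify performance on real data where reference bias dominates.

## Problem sizes and numerical choices

Test and acceptance runs use 4 samples × 10⁵ reads × 100 virotypes for
recovery (seconds of runtime), 10³ reads for brute-force assignment
equivalence, 10³ scaffolds for host-mixture recovery, 10³ replicates × 199
permutations for the vector-fit null calibration, and n ≤ 7 for exhaustive
clustering oracles — sizes at which the independent oracles are exact or
their sampling error is quantifiable. Floating-point equality is asserted
exactly where algebra guarantees it (hand-sized normalization examples) and
at 10⁻⁹ relative otherwise; count tables serialize floats at repr precision
so write/read round trips are bit-exact. At the fixed-seed study conditions
the abundance-recovery correlation is ≈ 0.996; across arbitrary seeds it
fluctuates in the 0.985–0.995 band from multinomial sampling error alone.

## Known limitations

Reference-database bias (the dominant error source in real virome
profiling) is outside the model; the NMDS permutation test has coarse
p-value resolution for very few samples (4 samples admit only 24 label
permutations, so vectors are rarely flagged reliable); Chao1 on normalized
real-valued counts depends on the rounding convention; and the chi-square
test treats reads as independent draws, which mapping duplicates violate in
real data.
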