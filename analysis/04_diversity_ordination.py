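#!/usr/bin/env python
"""Diversity, NMDS ordination with gradient vectors, clustering, chi-square.

Alpha diversity (richness, Shannon, Simpson, Chao1) is computed on the
dominant-pool table; samples are ordinated by non-metric MDS on the relative-
abundance + 0-1-ranged profiles, with family gradient vectors and diversity
indices fitted onto the plane; a UPGMA dendrogram and pairwise chi-square
tests (Bonferroni-corrected) complete the comparison.
"""

from pathlib import Path

from virotyper import abundance, stats, tabular

BASE = Path(__file__).resolve().parent.parent / "results"
SCRATCH = Path(__file__).resolve().parent.parent / "scratch"
SEED = 42


def main() -> None:
    pooled = tabular.read_count_table(BASE / "counts_dominant_pool.tsv")
    metadata = tabular.read_virus_metadata(SCRATCH / "synthetic" / "metadata.tsv")

    div = stats.diversity_table(pooled)
    div.to_csv(BASE / "diversity.tsv", sep="\t")
    print(div.round(3))

    transformed = stats.ordination_transform(pooled)
    ordination = stats.nmds(transformed, seed=SEED)
    print(f"NMDS stress-1: {ordination.stress:.4g}")

    families = abundance.aggregate_families(pooled, metadata)
    variables = families.T.join(div[["species_richness", "shannon", "simpson"]])
    vectors = stats.fit_vectors(ordination, variables, seed=SEED)
    ordination.coordinates.to_csv(BASE / "nmds_coordinates.tsv", sep="\t")
    vectors.to_csv(BASE / "nmds_vectors.tsv", sep="\t")
    reliable = vectors[vectors["reliable"]].index.tolist()
    print(f"reliable gradient vectors (p <= 0.05): {reliable or 'none'}")

    _, _, newick = stats.cluster_samples(transformed, method="average")
    tabular.write_newick(newick, BASE / "sample_dendrogram.nwk")
    print(f"UPGMA dendrogram: {newick}")

    tests = stats.pairwise_chisq(abundance.round_half_even(pooled))
    tests.to_csv(BASE / "pairwise_chisq.tsv", sep="\t", index=False)
    n_sig = int((tests["p_bonferroni"] <= 0.05).sum())
    print(f"pairwise chi-square: {n_sig}/{len(tests)} pairs differ "
          f"(Bonferroni p <= 0.05)")


if __name__ == "__main__":
    main()
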