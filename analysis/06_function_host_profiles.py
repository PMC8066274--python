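#!/usr/bin/env python
"""Functional-category, AMG and host-range profiles of the scaffold community.

Proteins are annotated against the KO and COG fixture databases, read counts
are aggregated into depth-invariant category profiles, AMG calls are folded
into KEGG pathway groups, and scaffold counts are aggregated to host phylum
shares by the virus-host lookup route.  Profiles are clustered with the same
machinery as the taxonomic tables.
"""

from pathlib import Path

from virotyper import functions, scaffolds as sc, stats
from virotyper.synthetic import CommunitySpec, emit_scaffold_fixtures, simulate_community

SEED = 42
OUT = Path(__file__).resolve().parent.parent / "results" / "profiles"


def main() -> None:
    spec = CommunitySpec(seed=SEED)
    truth, _ = simulate_community(spec)
    fx = emit_scaffold_fixtures(truth, spec)
    OUT.mkdir(parents=True, exist_ok=True)

    protein_counts = sc.protein_count_table(fx.scaffold_counts, fx.scaffold_proteins)

    ko_notes = functions.annotate_proteins(fx.function_hits)
    kegg = functions.category_profile(ko_notes, protein_counts, fx.ko_to_pathway)
    kegg.to_csv(OUT / "kegg_pathway_profile.tsv", sep="\t")
    print(f"KEGG profile: {kegg.shape[0]} pathway groups, "
          f"{len(ko_notes)} annotated proteins")

    cog_notes = functions.annotate_proteins(fx.cog_hits)
    cog = functions.category_profile(cog_notes, protein_counts, fx.cog_to_category)
    cog.to_csv(OUT / "cog_category_profile.tsv", sep="\t")
    print(f"COG profile: {cog.shape[0]} categories")

    amg = functions.amg_profile(fx.amg_calls, protein_counts, fx.ko_to_pathway)
    amg.to_csv(OUT / "amg_profile.tsv", sep="\t")
    print(f"AMG profile: {amg.shape[0]} pathway groups from "
          f"{len(fx.amg_calls)} AMG calls")

    assigned = sc.assign_scaffolds(fx.scaffold_proteins, fx.proteome_hits)
    host = functions.host_profile(dict(assigned), fx.scaffold_counts,
                                  virus_host=fx.virus_host)
    host.to_csv(OUT / "host_shares.tsv", sep="\t")
    print("host phylum shares (per sample):")
    print(host.round(3))

    # one code path for every profile comparison: reuse the stats machinery
    _, _, newick = stats.cluster_samples(amg, method="average")
    (OUT / "amg_dendrogram.nwk").write_text(newick + "\n")
    print(f"AMG-profile UPGMA dendrogram: {newick}")


if __name__ == "__main__":
    main()
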