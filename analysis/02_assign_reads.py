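#!/usr/bin/env python
"""Two-stage taxonomic identification of the simulated reads.

Reads are filtered to >= 100 bp, compared against the protein hit table
(identity >= 35%, e-value <= 1e-5, bit score >= 50) and, when unassigned,
against the nucleotide hit table (e-value <= 1e-5, bit score >= 50).  The
raw virotype x sample count table and per-sample viral percentages are
written to results/.
"""

from pathlib import Path

import pandas as pd

from virotyper import reads as rt, tabular

BASE = Path(__file__).resolve().parent.parent / "results"
SCRATCH = Path(__file__).resolve().parent.parent / "scratch"


def main() -> None:
    BASE.mkdir(parents=True, exist_ok=True)
    read_table = rt.filter_reads(tabular.read_reads_table(SCRATCH / "synthetic" / "reads.tsv"))
    protein = tabular.read_hit_frame(SCRATCH / "synthetic" / "protein_hits.tsv")
    nucleotide = tabular.read_hit_frame(SCRATCH / "synthetic" / "nucleotide_hits.tsv")

    assignments, tallies = {}, []
    for sample, group in read_table.groupby("sample_id"):
        ids = set(group["read_id"])
        assigned, unidentified = rt.assign_sample(
            protein[protein["qseqid"].isin(ids)],
            nucleotide[nucleotide["qseqid"].isin(ids)], ids)
        assignments[sample] = assigned
        pct = rt.percent_viral(len(ids), len(assigned))
        tallies.append({"sample": sample, "reads": len(ids),
                        "viral_reads": len(assigned), "percent_viral": pct})
        print(f"{sample}: {len(assigned):,}/{len(ids):,} reads viral ({pct}%)")

    counts = rt.build_count_table(assignments)
    tabular.write_count_table(counts, BASE / "counts_raw.tsv")
    pd.DataFrame(tallies).to_csv(BASE / "read_tallies.tsv", sep="\t", index=False)
    print(f"count table: {counts.shape[0]} virotypes x {counts.shape[1]} samples "
          f"-> {BASE / 'counts_raw.tsv'}")


if __name__ == "__main__":
    main()
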