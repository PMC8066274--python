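"""Two-stage taxonomic identification of reads and virotype counting.

Stage 1 compares reads against a viral proteome database and keeps hits with
percent identity >= 35 (and globally significant e-value <= 1e-5, bit score
>= 50).  Reads without a qualifying protein hit fall through to stage 2, a
nucleotide search against complete viral genomes filtered on e-value <= 1e-5
and bit score >= 50.  Reads failing both stages are not identified as viral.

Best-hit selection among qualifying hits: highest bit score, then lowest
e-value, then lexicographically smallest subject ID — a deterministic total
order, since the alignment tools themselves do not guarantee one.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import pandas as pd

from .tabular import hits_to_frame

DEFAULT_MIN_IDENTITY = 35.0
DEFAULT_EVALUE_MAX = 1e-5
DEFAULT_BIT_MIN = 50.0


def filter_reads(reads: pd.DataFrame, min_len: int = 100) -> pd.DataFrame:
    """Keep reads of at least ``min_len`` bp (inclusive), order preserved."""
    return reads[reads["length"] >= min_len].reset_index(drop=True)


def best_hit_per_query(hits: pd.DataFrame) -> pd.DataFrame:
    """One row per query: highest bit score, ties by e-value then subject ID."""
    ordered = hits.sort_values(
        ["bitscore", "evalue", "sseqid"],
        ascending=[False, True, True],
        kind="stable",
    )
    return ordered.drop_duplicates("qseqid", keep="first")


def stage1_assign(
    protein_hits,
    reads: Iterable[str],
    min_identity: float = DEFAULT_MIN_IDENTITY,
    evalue_max: float = DEFAULT_EVALUE_MAX,
    bit_min: float = DEFAULT_BIT_MIN,
) -> tuple[dict[str, str], set[str]]:
    """Protein-level assignment; returns (read -> subject, unassigned reads).

    A read is assigned iff it has at least one hit with identity >=
    ``min_identity`` that is also globally significant (e-value, bit score).
    Unassigned reads are the candidates for stage 2.
    """
    frame = hits_to_frame(protein_hits)
    qualifying = frame[
        (frame["pident"] >= min_identity)
        & (frame["evalue"] <= evalue_max)
        & (frame["bitscore"] >= bit_min)
    ]
    best = best_hit_per_query(qualifying)
    assigned = dict(zip(best["qseqid"], best["sseqid"]))
    unassigned = {r for r in reads if r not in assigned}
    return assigned, unassigned


def stage2_assign(
    nucleotide_hits,
    unassigned: Iterable[str],
    evalue_max: float = DEFAULT_EVALUE_MAX,
    bit_min: float = DEFAULT_BIT_MIN,
    stage1_assigned: Iterable[str] | None = None,
) -> tuple[dict[str, str], set[str]]:
    """Nucleotide-level assignment of stage-1-unassigned reads.

    Returns (read -> subject, unidentified reads).  Passing a read already
    assigned in stage 1 violates stage exclusivity and raises ``ValueError``.
    """
    unassigned = set(unassigned)
    if stage1_assigned is not None:
        overlap = unassigned & set(stage1_assigned)
        if overlap:
            raise ValueError(
                f"stage-1-assigned reads offered to stage 2: {sorted(overlap)[:5]}"
            )
    frame = hits_to_frame(nucleotide_hits)
    considered = frame[frame["qseqid"].isin(unassigned)]
    qualifying = considered[
        (considered["evalue"] <= evalue_max) & (considered["bitscore"] >= bit_min)
    ]
    best = best_hit_per_query(qualifying)
    assigned = dict(zip(best["qseqid"], best["sseqid"]))
    unidentified = unassigned - assigned.keys()
    return assigned, unidentified


def assign_sample(
    protein_hits,
    nucleotide_hits,
    reads: Iterable[str],
    min_identity: float = DEFAULT_MIN_IDENTITY,
    evalue_max: float = DEFAULT_EVALUE_MAX,
    bit_min: float = DEFAULT_BIT_MIN,
) -> tuple[dict[str, str], set[str]]:
    """Run both stages for one sample's reads; returns (assignments, unidentified)."""
    stage1, unassigned = stage1_assign(protein_hits, reads, min_identity, evalue_max, bit_min)
    stage2, unidentified = stage2_assign(
        nucleotide_hits, unassigned, evalue_max, bit_min, stage1_assigned=stage1
    )
    merged = dict(stage1)
    merged.update(stage2)
    return merged, unidentified


def build_count_table(assignments: Mapping[str, Mapping[str, str]]) -> pd.DataFrame:
    """Virotype x sample count table from per-sample read -> virotype maps.

    Samples with no assigned reads keep an all-zero column; the grand total
    equals the number of assigned reads.
    """
    samples = list(assignments)
    counts: dict[str, pd.Series] = {}
    for sample in samples:
        mapping = assignments[sample]
        counts[sample] = pd.Series(list(mapping.values()), dtype=object).value_counts()
    table = pd.DataFrame(counts).fillna(0).astype(int)
    table = table.reindex(columns=samples)
    table.index.name = "virotype"
    return table.sort_index()


def percent_viral(n_reads_total: int, n_reads_viral: int) -> float:
    """Percentage of reads identified as viral, to two decimals."""
    if n_reads_total <= 0:
        raise ValueError("total read count must be positive")
    return round(100.0 * n_reads_viral / n_reads_total, 2)
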