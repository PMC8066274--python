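"""Scaffold-level taxonomy: filtering, majority-vote assignment, counting.

Assembled scaffolds are retained when total coverage exceeds 5x (strict) and
length is at least 5000 bp (inclusive).  Each predicted protein on a scaffold
casts one vote — its best qualifying proteome hit (e-value <= 1e-5, bit score
>= 50, identity >= 35%) selected by bit score.  The scaffold's virotype is
the subject with the most votes; vote ties are broken by the highest percent
identity among the tied subjects' hits, then by the lexicographically
smallest reference ID.  Proteins without a qualifying hit abstain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .reads import best_hit_per_query
from .tabular import hits_to_frame

DEFAULT_MIN_COVERAGE = 5.0
DEFAULT_MIN_LENGTH = 5000


@dataclass
class ScaffoldAnnotation:
    scaffold_id: str
    length: int
    total_coverage: float
    protein_best_hits: list[tuple[str, str, float]] = field(default_factory=list)
    # (protein_id, subject_id, percent_identity)
    assigned_virotype: str | None = None
    per_sample_read_counts: dict[str, int] = field(default_factory=dict)


def filter_scaffolds(
    scaffolds: pd.DataFrame,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    min_length: int = DEFAULT_MIN_LENGTH,
) -> pd.DataFrame:
    """Retain scaffolds with coverage > min_coverage and length >= min_length."""
    keep = (scaffolds["coverage"] > min_coverage) & (scaffolds["length"] >= min_length)
    return scaffolds[keep].reset_index(drop=True)


def protein_best_hits(
    hits,
    evalue_max: float = 1e-5,
    bit_min: float = 50.0,
    min_identity: float = 35.0,
) -> pd.DataFrame:
    """One qualifying best hit per protein, selected by bit score."""
    frame = hits_to_frame(hits)
    qualifying = frame[
        (frame["evalue"] <= evalue_max)
        & (frame["bitscore"] >= bit_min)
        & (frame["pident"] >= min_identity)
    ]
    return best_hit_per_query(qualifying)


def assign_scaffold_virotype(votes: list[tuple[str, float]]) -> str | None:
    """Majority-vote virotype from (subject_id, percent_identity) votes.

    Returns None when no protein cast a vote.  Ties on vote count are broken
    by the maximum identity among each tied subject's votes, then by the
    smallest subject ID.
    """
    if not votes:
        return None
    tally: dict[str, list[float]] = {}
    for subject, identity in votes:
        tally.setdefault(subject, []).append(identity)
    # sort key: most votes, then highest max identity, then lexicographic
    ranked = sorted(
        tally.items(), key=lambda kv: (-len(kv[1]), -max(kv[1]), kv[0])
    )
    return ranked[0][0]


def assign_scaffolds(
    scaffold_proteins: pd.DataFrame,
    hits,
    evalue_max: float = 1e-5,
    bit_min: float = 50.0,
    min_identity: float = 35.0,
) -> pd.Series:
    """Assign a virotype to every scaffold from its proteins' proteome hits.

    ``scaffold_proteins`` maps protein_id -> scaffold_id (columns
    ``protein_id``, ``scaffold_id``).  Returns a Series indexed by scaffold
    with the assigned virotype or None.
    """
    best = protein_best_hits(hits, evalue_max, bit_min, min_identity)
    by_protein = dict(zip(best["qseqid"], zip(best["sseqid"], best["pident"])))
    assignments: dict[str, str | None] = {}
    for scaffold, group in scaffold_proteins.groupby("scaffold_id"):
        votes = [by_protein[p] for p in group["protein_id"] if p in by_protein]
        assignments[scaffold] = assign_scaffold_virotype(votes)
    return pd.Series(assignments, name="virotype")


def scaffold_count_table(mapped_counts: pd.DataFrame) -> pd.DataFrame:
    """Validate a scaffold x sample read-mapping count table."""
    if (mapped_counts.to_numpy() < 0).any():
        raise ValueError("negative mapped-read counts")
    return mapped_counts.astype(int)


def protein_count_table(
    scaffold_counts: pd.DataFrame, scaffold_proteins: pd.DataFrame
) -> pd.DataFrame:
    """Protein x sample counts: each protein inherits its scaffold's counts."""
    counts = scaffold_count_table(scaffold_counts)
    mapping = scaffold_proteins.set_index("protein_id")["scaffold_id"]
    missing = set(mapping) - set(counts.index)
    if missing:
        raise KeyError(f"proteins on scaffolds without counts: {sorted(missing)[:5]}")
    out = counts.loc[mapping.to_numpy()]
    out.index = mapping.index
    return out
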