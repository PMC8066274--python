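"""Genome-length normalization of virotype counts and downstream filtering.

Raw read counts over-represent long genomes: at equal particle concentration
a virus with a genome twice as long contributes twice the DNA.  Counts are
therefore rescaled per sample by S_i = L_s / L_i, where L_s is the mean
genome length over the virotypes present (count > 0) in the sample and L_i
the genome length of virotype i.  The normalized count is nk_i = n_i * S_i,
which satisfies the conservation law sum(nk_i * L_i) = L_s * sum(n_i).

After normalization, per-sample profiles are reduced to the dominant pool:
the minimal set of top virotypes whose cumulative share reaches 95% of the
sample, with boundary ties all retained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class NormalizationContext:
    """Per-sample normalization state: mean genome length and coefficients."""

    sample_id: str
    mean_genome_length: float
    coefficients: pd.Series  # S_i = L_s / L_i, indexed by virotype


def normalize_counts(
    table: pd.DataFrame, metadata: pd.DataFrame
) -> tuple[pd.DataFrame, dict[str, NormalizationContext]]:
    """Rescale a virotype x sample count table by genome length.

    ``metadata`` must carry a genome_length for every virotype counted in a
    sample; a missing length raises a ``KeyError`` naming the virotype.
    """
    lengths = metadata["genome_length"]
    normalized = table.astype(float).copy()
    contexts: dict[str, NormalizationContext] = {}
    for sample in table.columns:
        counts = table[sample]
        present = counts.index[counts > 0]
        missing = [v for v in present if v not in lengths.index]
        if missing:
            raise KeyError(f"no genome length for counted virotype(s): {missing}")
        if len(present) == 0:
            contexts[sample] = NormalizationContext(sample, float("nan"), pd.Series(dtype=float))
            continue
        li = lengths.loc[present].astype(float)
        ls = float(li.mean())
        si = ls / li
        normalized.loc[present, sample] = counts.loc[present].astype(float) * si
        contexts[sample] = NormalizationContext(sample, ls, si)
    return normalized, contexts


def dominant_pool(table: pd.DataFrame, fraction: float = 0.95) -> pd.DataFrame:
    """Keep, per sample, the top virotypes reaching ``fraction`` of the counts.

    Virotypes are ranked by descending count; the minimal prefix whose
    cumulative share is >= ``fraction`` is retained and ties at the boundary
    count are all kept.  Dropped virotypes are zeroed.  An all-zero sample is
    returned unchanged with a warning.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    out = table.astype(float).copy()
    for sample in table.columns:
        counts = out[sample]
        total = counts.sum()
        if total == 0:
            warnings.warn(f"sample {sample!r} has no counts; left unchanged")
            continue
        ranked = counts.sort_values(ascending=False, kind="stable")
        cumshare = ranked.cumsum() / total
        cutoff_pos = int(np.searchsorted(cumshare.to_numpy(), fraction))
        cutoff_pos = min(cutoff_pos, len(ranked) - 1)
        boundary_count = ranked.iloc[cutoff_pos]
        keep = counts >= boundary_count
        # ties at the boundary are all retained; everything below is zeroed
        out.loc[~keep, sample] = 0.0
    return out


def aggregate_families(
    table: pd.DataFrame, metadata: pd.DataFrame, total: bool = False
) -> pd.DataFrame:
    """Family x sample percentage table.

    Per sample, a family's percentage is 100 * (sum of member virotype
    counts) / (sum of all counts); columns sum to 100.  With ``total=True``
    a cross-sample "Total" column holding the row sums is appended.
    """
    families = metadata["family"].reindex(table.index).fillna("unclassified")
    grouped = table.groupby(families.to_numpy()).sum()
    grouped.index.name = "family"
    pct = 100.0 * grouped / grouped.sum(axis=0)
    if total:
        pct["Total"] = pct.sum(axis=1)
    return pct


def add_total_column(percentages: pd.DataFrame) -> pd.DataFrame:
    """Append a "Total" column summing per-sample percentages across samples."""
    out = percentages.copy()
    out["Total"] = percentages.sum(axis=1)
    return out


def round_half_even(table: pd.DataFrame | pd.Series) -> pd.DataFrame | pd.Series:
    """Round normalized (real) counts to integers, half to even.

    Integer counts are required by estimators that detect singletons and
    doubletons (Chao1) and by contingency-table tests.
    """
    return np.rint(table).astype(int)
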