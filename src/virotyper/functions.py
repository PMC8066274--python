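"""Functional-category and host-range profiles of viral scaffold communities.

Predicted viral proteins are annotated against a function database (KEGG
orthology identifiers or COG entries) by their best qualifying hit (e-value
<= 1e-5, bit score >= 50, identity >= 35%).  Per-sample category counts sum
the read counts of member proteins and are normalized by the average number
of hits on annotated proteins in the sample — i.e. divided by
(total annotated-protein reads / number of annotated proteins) — which makes
the profile invariant to sequencing depth.  Auxiliary metabolic genes (AMGs)
go through the same transform restricted to the AMG-called proteins.

Host profiles aggregate per-scaffold read counts to host phylum, via either
a virus->host lookup table or an external per-scaffold host prediction;
scaffolds without an assigned virotype or a mapped host fall into "unknown",
so shares (including unknown) sum to 1 per sample.
"""

from __future__ import annotations

import logging
import warnings
from typing import Mapping

import pandas as pd

from .scaffolds import protein_best_hits

logger = logging.getLogger(__name__)

UNCLASSIFIED = "unclassified"
UNKNOWN = "unknown"


def annotate_proteins(
    hits,
    evalue_max: float = 1e-5,
    bit_min: float = 50.0,
    min_identity: float = 35.0,
) -> dict[str, str]:
    """protein_id -> function identifier from best qualifying hits."""
    best = protein_best_hits(hits, evalue_max, bit_min, min_identity)
    return dict(zip(best["qseqid"], best["sseqid"]))


def category_profile(
    annotations: Mapping[str, str],
    protein_counts: pd.DataFrame,
    category_map: Mapping[str, str],
) -> pd.DataFrame:
    """Category x sample normalized-count profile.

    ``annotations`` maps protein -> function identifier; ``category_map``
    maps identifier -> category (unmapped identifiers fall into
    "unclassified").  Normalization divides each category's summed read count
    by the sample's mean read count per annotated protein.
    """
    annotated = [p for p in annotations if p in protein_counts.index]
    if not annotated:
        warnings.warn("no annotated proteins with counts; empty profile")
        return pd.DataFrame(columns=protein_counts.columns)
    categories = {}
    for protein in annotated:
        ident = annotations[protein]
        cat = category_map.get(ident)
        if cat is None:
            logger.info("identifier %s not in category map; using %s", ident, UNCLASSIFIED)
            cat = UNCLASSIFIED
        categories[protein] = cat
    counts = protein_counts.loc[annotated]
    cat_series = pd.Series(categories).loc[annotated]
    grouped = counts.groupby(cat_series.to_numpy()).sum()
    grouped.index.name = "category"
    totals = counts.sum(axis=0)
    mean_per_protein = totals / len(annotated)
    normalized = grouped.div(mean_per_protein.where(mean_per_protein > 0), axis=1)
    empty = totals == 0
    if empty.any():
        warnings.warn(f"samples with zero annotated-protein reads: {list(totals.index[empty])}")
        normalized.loc[:, empty] = 0.0
    return normalized


def amg_profile(
    amg_calls: pd.DataFrame,
    protein_counts: pd.DataFrame,
    ko_to_pathway: Mapping[str, str],
) -> pd.DataFrame:
    """AMG category x sample profile (the category transform on AMG proteins).

    ``amg_calls`` has columns ``protein_id`` and ``ko``.
    """
    annotations = dict(zip(amg_calls["protein_id"], amg_calls["ko"]))
    return category_profile(annotations, protein_counts, ko_to_pathway)


def _phylum(lineage: str) -> str:
    # lineages are ';'-separated, superkingdom first, phylum second
    parts = [p.strip() for p in str(lineage).split(";") if p.strip()]
    if not parts or parts[0].lower() == UNKNOWN:
        return UNKNOWN
    return parts[1] if len(parts) > 1 else parts[0]


def host_profile(
    scaffold_virotypes: Mapping[str, str | None],
    scaffold_counts: pd.DataFrame,
    virus_host: Mapping[str, str] | None = None,
    scaffold_host: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Host-phylum x sample share table from one prediction source.

    Exactly one of ``virus_host`` (virotype -> host lineage, the lookup-table
    route) or ``scaffold_host`` (scaffold -> host lineage, the predictor
    route) must be given.  Shares per sample, "unknown" included, sum to 1.
    """
    if (virus_host is None) == (scaffold_host is None):
        raise ValueError("provide exactly one of virus_host or scaffold_host")
    hosts = {}
    for scaffold in scaffold_counts.index:
        if scaffold_host is not None:
            lineage = scaffold_host.get(scaffold)
        else:
            virotype = scaffold_virotypes.get(scaffold)
            lineage = None if virotype is None else virus_host.get(virotype)
        hosts[scaffold] = UNKNOWN if lineage is None else _phylum(lineage)
    host_series = pd.Series(hosts).loc[scaffold_counts.index]
    grouped = scaffold_counts.groupby(host_series.to_numpy()).sum()
    grouped.index.name = "host"
    totals = grouped.sum(axis=0)
    if (totals == 0).any():
        raise ValueError("sample with zero scaffold counts has no host shares")
    return grouped / totals
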