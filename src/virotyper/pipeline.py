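"""End-to-end orchestration: from hit tables to statistics, with a manifest.

A run consumes the tabular inputs (read table, protein and nucleotide hit
tables, virus metadata), executes identification, normalization, dominant-
pool filtering, family aggregation, and community statistics, and writes
every stage output plus a manifest with SHA-256 checksums.  Identical config
and seed give byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

from . import abundance, reads as read_taxonomy, stats, tabular

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    reads_path: str
    protein_hits_path: str
    nucleotide_hits_path: str
    metadata_path: str
    out_dir: str
    min_read_length: int = 100
    min_identity: float = 35.0
    evalue_max: float = 1e-5
    bit_min: float = 50.0
    pool_fraction: float = 0.95
    seed: int = 0
    run_ordination: bool = True
    thresholds_logged: dict = field(default_factory=dict)

    def validate(self) -> None:
        for name in ("reads_path", "protein_hits_path", "nucleotide_hits_path",
                     "metadata_path"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p}")
        if not 0 < self.pool_fraction <= 1:
            raise ValueError("pool_fraction must be in (0, 1]")
        if not 0 <= self.min_identity <= 100:
            raise ValueError("min_identity must be in [0, 100]")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all read-level stages; returns the manifest dict."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger.info("thresholds: %s", {k: v for k, v in asdict(config).items()
                                   if k not in {"thresholds_logged"}})

    reads = tabular.read_reads_table(config.reads_path)
    reads = read_taxonomy.filter_reads(reads, config.min_read_length)
    protein_hits = tabular.read_hit_frame(config.protein_hits_path)
    nucleotide_hits = tabular.read_hit_frame(config.nucleotide_hits_path)
    metadata = tabular.read_virus_metadata(config.metadata_path)

    assignments = {}
    tallies = {}
    for sample, group in reads.groupby("sample_id", sort=True):
        ids = set(group["read_id"])
        p_sub = protein_hits[protein_hits["qseqid"].isin(ids)]
        n_sub = nucleotide_hits[nucleotide_hits["qseqid"].isin(ids)]
        assigned, unidentified = read_taxonomy.assign_sample(
            p_sub, n_sub, ids, config.min_identity, config.evalue_max, config.bit_min
        )
        assignments[sample] = assigned
        tallies[sample] = {
            "reads": len(ids),
            "assigned": len(assigned),
            "percent_viral": read_taxonomy.percent_viral(len(ids), len(assigned)),
        }
        logger.info("sample %s: %d/%d reads assigned", sample, len(assigned), len(ids))

    counts = read_taxonomy.build_count_table(assignments)
    normalized, _ = abundance.normalize_counts(counts, metadata)
    pooled = abundance.dominant_pool(normalized, config.pool_fraction)
    families = abundance.aggregate_families(pooled, metadata, total=True)
    div = stats.diversity_table(pooled)

    tabular.write_count_table(counts, out / "counts_raw.tsv")
    tabular.write_count_table(normalized, out / "counts_normalized.tsv")
    tabular.write_count_table(pooled, out / "counts_dominant_pool.tsv")
    families.to_csv(out / "family_percentages.tsv", sep="\t")
    div.to_csv(out / "diversity.tsv", sep="\t")

    outputs = ["counts_raw.tsv", "counts_normalized.tsv",
               "counts_dominant_pool.tsv", "family_percentages.tsv", "diversity.tsv"]

    if config.run_ordination and counts.shape[1] >= 3:
        transformed = stats.ordination_transform(pooled)
        ordination = stats.nmds(transformed, seed=config.seed)
        ordination.coordinates.to_csv(out / "nmds_coordinates.tsv", sep="\t")
        (out / "nmds_stress.txt").write_text(f"{ordination.stress!r}\n")
        _, _, newick = stats.cluster_samples(transformed, method="average")
        tabular.write_newick(newick, out / "sample_dendrogram.nwk")
        tests = stats.pairwise_chisq(abundance.round_half_even(pooled))
        tests.to_csv(out / "pairwise_chisq.tsv", sep="\t", index=False)
        outputs += ["nmds_coordinates.tsv", "nmds_stress.txt",
                    "sample_dendrogram.nwk", "pairwise_chisq.tsv"]

    manifest = {
        "seed": config.seed,
        "tallies": tallies,
        "outputs": {name: _sha256(out / name) for name in outputs},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
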