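"""Synthetic virome communities with known ground truth.

The generator emulates the statistical structure the pipeline assumes about
real shotgun viromes: per-sample virotype particle abundances are lognormal;
the probability a read originates from a virotype is proportional to
abundance x genome length (longer genomes contribute more DNA at equal
particle concentration); a large fraction of reads matches nothing in the
reference databases; identifiable reads carry an alignment whose identity is
noisy (truncated Normal(60, 12), in the range of average similarities seen
in environmental viromes); a minority of identifiable reads hit only the
nucleotide database (genomes without annotated proteomes); and decoy
secondary hits with strictly lower bit scores exercise best-hit tie-breaks.

It does not simulate base-level sequence content, quality scores, or
assembly artifacts — scaffold fixtures are fabricated directly with planted
majorities and hosts.

One integer seed drives everything; each emitter derives its own stream from
(seed, fixed offset), so adding an emitter never perturbs earlier outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tabular import HIT_COLUMNS

FAMILY_POOL = [
    ("Siphoviridae", 0.40), ("Podoviridae", 0.25), ("Myoviridae", 0.15),
    ("Lavidaviridae", 0.05), ("Phycodnaviridae", 0.05), ("Mimiviridae", 0.03),
    ("unclassified", 0.07),
]

HOST_POOL = [
    ("Bacteria;Proteobacteria", 0.40), ("Bacteria;Cyanobacteria", 0.30),
    ("Bacteria;Bacteroidetes", 0.15), ("Bacteria;Actinobacteria", 0.10),
    ("Bacteria;Firmicutes", 0.05),
]

KO_POOL = [f"K{i:05d}" for i in range(1, 31)]
PATHWAY_POOL = [
    "Carbohydrate metabolism", "Amino acid metabolism",
    "Glycan biosynthesis and metabolism", "Metabolism of cofactors and vitamins",
    "Energy metabolism", "Replication and repair",
]
COG_POOL = [f"COG{i:04d}" for i in range(1, 21)]
COG_CATEGORIES = ["J", "K", "L", "M", "O", "R", "S", "X"]


@dataclass
class CommunitySpec:
    """Parameters of a synthetic virome study.

    Defaults describe the emulated study conditions: four samples, one
    hundred virotypes with lognormal particle abundances, 10^5 reads per
    sample of which ~90% are unidentifiable against the references (real
    viromes identify only ~8–20% of reads), and 10% of identifiable reads
    reaching only the nucleotide stage.
    """

    n_virotypes: int = 100
    n_samples: int = 4
    meanlog: float = 0.0
    sdlog: float = 1.0                    # lognormal spread of particle abundances
    sample_sdlog: float = 0.6             # per-sample multiplicative jitter
    genome_length_range: tuple[int, int] = (5_000, 200_000)
    reads_per_sample: int = 100_000
    read_length_range: tuple[int, int] = (100, 301)
    unidentifiable_fraction: float = 0.9
    stage2_fraction: float = 0.1
    identity_mu: float = 60.0
    identity_sigma: float = 12.0
    decoy_rate: float = 0.3
    n_scaffolds: int = 80
    proteins_per_scaffold: float = 12.0   # mean, Poisson + 1
    majority_rate: float = 0.85           # per-protein chance of voting truthfully
    host_pool: tuple = tuple(HOST_POOL)
    genome_lengths: tuple[int, ...] | None = None   # explicit lengths override the range
    seed: int = 0

    def validate(self) -> None:
        if self.n_virotypes < 1:
            raise ValueError("n_virotypes must be >= 1")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        for name in ("unidentifiable_fraction", "stage2_fraction", "decoy_rate",
                     "majority_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.genome_length_range[0] < 1:
            raise ValueError("minimum genome length must be >= 1")
        if self.read_length_range[0] < 1:
            raise ValueError("minimum read length must be >= 1")
        if self.genome_lengths is not None and len(self.genome_lengths) != self.n_virotypes:
            raise ValueError("genome_lengths must list one length per virotype")


@dataclass
class GroundTruth:
    """Everything the tests need to verify recovery of the planted community."""

    virotype_ids: list[str]
    genome_lengths: np.ndarray                 # bp, per virotype
    abundance: pd.DataFrame                    # samples x virotypes, relative particle abundance
    expected_read_share: pd.DataFrame          # samples x virotypes, prop. to abundance*length
    reads: pd.DataFrame                        # read_id, sample_id, length, true_virotype, tier
    hosts: dict[str, str] = field(default_factory=dict)    # virotype -> host lineage
    scaffolds: pd.DataFrame | None = None      # scaffold truth, filled by emit_scaffold_fixtures


def _rng(spec: CommunitySpec, offset: int) -> np.random.Generator:
    return np.random.default_rng([spec.seed, offset])


def _truncated_normal(rng, mu, sigma, lo, hi, size):
    out = rng.normal(mu, sigma, size)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mu, sigma, int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def simulate_community(spec: CommunitySpec) -> tuple[GroundTruth, pd.DataFrame]:
    """Draw a community and its reads; returns (truth, virus metadata table).

    Read counts per virotype are multinomial with probabilities proportional
    to particle abundance x genome length.  Deterministic for a fixed seed.
    """
    spec.validate()
    rng = _rng(spec, 0)
    n = spec.n_virotypes
    ids = [f"NC_9{i:05d}" for i in range(n)]
    if spec.genome_lengths is not None:
        lengths = np.asarray(spec.genome_lengths, dtype=int)
    else:
        lengths = rng.integers(spec.genome_length_range[0], spec.genome_length_range[1] + 1, n)

    base = rng.lognormal(spec.meanlog, spec.sdlog, n)
    samples = [f"S{j + 1}" for j in range(spec.n_samples)]
    ab_rows = []
    for _ in samples:
        a = base * rng.lognormal(0.0, spec.sample_sdlog, n)
        ab_rows.append(a / a.sum())
    abundance = pd.DataFrame(ab_rows, index=samples, columns=ids)

    weighted = abundance * lengths
    share = weighted.div(weighted.sum(axis=1), axis=0)

    read_rows = []
    for s in samples:
        counts = rng.multinomial(spec.reads_per_sample, share.loc[s].to_numpy())
        true_v = np.repeat(np.arange(n), counts)
        rng.shuffle(true_v)
        m = true_v.size
        lens = rng.integers(spec.read_length_range[0], spec.read_length_range[1] + 1, m)
        u = rng.random(m)
        tier = np.where(
            u < spec.unidentifiable_fraction, "none",
            np.where(rng.random(m) < spec.stage2_fraction, "nucleotide", "protein"),
        )
        read_rows.append(pd.DataFrame({
            "read_id": [f"{s}_r{i}" for i in range(m)],
            "sample_id": s,
            "length": lens,
            "true_virotype": [ids[v] for v in true_v],
            "tier": tier,
        }))
    reads = pd.concat(read_rows, ignore_index=True)

    fam_names = [f for f, _ in FAMILY_POOL]
    fam_p = np.array([p for _, p in FAMILY_POOL])
    families = rng.choice(fam_names, size=n, p=fam_p / fam_p.sum())
    host_names = [h for h, _ in spec.host_pool]
    host_p = np.array([p for _, p in spec.host_pool], dtype=float)
    hosts_arr = rng.choice(host_names, size=n, p=host_p / host_p.sum())
    metadata = pd.DataFrame({
        "refseq_id": ids,
        "genome_length": lengths,
        "family": families,
        "genome_type": "dsDNA",
        "host_lineage": hosts_arr,
    }).set_index("refseq_id")

    truth = GroundTruth(
        virotype_ids=ids,
        genome_lengths=lengths,
        abundance=abundance,
        expected_read_share=share,
        reads=reads,
        hosts=dict(zip(ids, hosts_arr)),
    )
    return truth, metadata


def _hit_frame(qseqid, sseqid, pident, length, evalue, bitscore) -> pd.DataFrame:
    m = len(qseqid)
    length = np.asarray(length, dtype=int)
    frame = pd.DataFrame({
        "qseqid": qseqid,
        "sseqid": sseqid,
        "pident": np.round(np.asarray(pident, dtype=float), 1),
        "length": length,
        "mismatch": np.zeros(m, dtype=int),
        "gapopen": np.zeros(m, dtype=int),
        "qstart": np.ones(m, dtype=int),
        "qend": length,
        "sstart": np.ones(m, dtype=int),
        "send": length,
        "evalue": np.asarray(evalue, dtype=float),
        "bitscore": np.round(np.asarray(bitscore, dtype=float), 1),
    })
    return frame[HIT_COLUMNS]


def emit_hit_tables(
    truth: GroundTruth, spec: CommunitySpec
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Fabricate (protein hit table, nucleotide hit table, read table).

    Unidentifiable reads appear in neither table; the stage-2 tier appears
    only in the nucleotide table.  Every read's top-bit-score hit names its
    true virotype; decoy hits point elsewhere with strictly lower bit scores.
    """
    rng = _rng(spec, 1)
    reads = truth.reads
    n_vir = len(truth.virotype_ids)
    id_arr = np.array(truth.virotype_ids)

    def decoys(sub: pd.DataFrame, primary_bit: np.ndarray) -> pd.DataFrame:
        take = rng.random(len(sub)) < spec.decoy_rate
        if not take.any() or n_vir < 2:
            return _hit_frame([], [], [], [], [], [])
        sub = sub[take]
        pbit = primary_bit[take]
        true_idx = np.searchsorted(id_arr, sub["true_virotype"].to_numpy())
        shift = rng.integers(1, n_vir, len(sub))
        decoy_subject = id_arr[(true_idx + shift) % n_vir]
        identity = _truncated_normal(rng, spec.identity_mu, spec.identity_sigma, 0, 100, len(sub))
        bits = pbit - rng.uniform(1.0, 10.0, len(sub))  # strictly below the true hit
        ev = 10.0 ** (-rng.uniform(5.0, 20.0, len(sub)))
        return _hit_frame(sub["read_id"], decoy_subject, identity,
                          np.maximum(1, sub["length"] // 3), ev, np.maximum(bits, 0.0))

    prot = reads[reads["tier"] == "protein"]
    identity = _truncated_normal(rng, spec.identity_mu, spec.identity_sigma, 0, 100, len(prot))
    bit = 50.0 + 0.9 * identity + rng.exponential(5.0, len(prot))
    evalue = 10.0 ** (-rng.uniform(6.0, 25.0, len(prot)))
    protein_hits = _hit_frame(prot["read_id"], prot["true_virotype"], identity,
                              np.maximum(1, prot["length"] // 3), evalue, bit)
    protein_hits = pd.concat(
        [protein_hits, decoys(prot, bit)], ignore_index=True
    )

    nuc = reads[reads["tier"] == "nucleotide"]
    n_identity = rng.uniform(70.0, 100.0, len(nuc))
    n_bit = rng.uniform(51.0, 150.0, len(nuc))
    n_evalue = 10.0 ** (-rng.uniform(6.0, 20.0, len(nuc)))
    nucleotide_hits = _hit_frame(nuc["read_id"], nuc["true_virotype"], n_identity,
                                 nuc["length"], n_evalue, n_bit)
    nucleotide_hits = pd.concat(
        [nucleotide_hits, decoys(nuc, n_bit)], ignore_index=True
    )

    read_table = reads[["read_id", "length", "sample_id"]].copy()
    return protein_hits, nucleotide_hits, read_table


@dataclass
class ScaffoldFixtures:
    """Fabricated inputs for the scaffold / function / host stages."""

    scaffolds: pd.DataFrame          # scaffold_id, length, coverage, true_virotype, true_host
    scaffold_proteins: pd.DataFrame  # protein_id, scaffold_id
    scaffold_counts: pd.DataFrame    # scaffold x sample mapped-read counts
    proteome_hits: pd.DataFrame      # proteins vs viral proteome DB
    function_hits: pd.DataFrame      # proteins vs KO function DB
    cog_hits: pd.DataFrame           # proteins vs COG DB
    amg_calls: pd.DataFrame          # protein_id, ko
    ko_to_pathway: dict[str, str]
    cog_to_category: dict[str, str]
    virus_host: dict[str, str]       # refseq_id -> host lineage


def emit_scaffold_fixtures(truth: GroundTruth, spec: CommunitySpec) -> ScaffoldFixtures:
    """Fabricate scaffold metadata, counts, protein hit tables and mappings.

    Each scaffold's proteins vote for its true virotype with probability
    ``majority_rate`` (1.0 plants a unanimous, strict majority).
    """
    rng = _rng(spec, 2)
    n_vir = len(truth.virotype_ids)
    id_arr = np.array(truth.virotype_ids)
    samples = list(truth.abundance.index)
    base_p = truth.abundance.mean(axis=0).to_numpy()
    base_p = base_p / base_p.sum()

    rows, prot_rows = [], []
    counts = {}
    proteome, functional, cog, amg = [], [], [], []
    ko_to_pathway = {ko: PATHWAY_POOL[i % len(PATHWAY_POOL)] for i, ko in enumerate(KO_POOL)}
    cog_to_category = {c: COG_CATEGORIES[i % len(COG_CATEGORIES)] for i, c in enumerate(COG_POOL)}

    for s_idx in range(spec.n_scaffolds):
        sid = f"SCF{s_idx:04d}"
        v_idx = rng.choice(n_vir, p=base_p)
        virotype = id_arr[v_idx]
        length = int(rng.integers(5_000, 100_001))
        coverage = float(np.round(rng.lognormal(2.5, 0.7), 2))
        rows.append({"scaffold_id": sid, "length": length, "coverage": coverage,
                     "true_virotype": virotype, "true_host": truth.hosts[virotype]})

        p_samples = truth.abundance[virotype].to_numpy()
        p_samples = p_samples / p_samples.sum()
        total_reads = max(1, int(coverage * length / 300))
        counts[sid] = rng.multinomial(total_reads, p_samples)

        n_prot = 1 + int(rng.poisson(max(spec.proteins_per_scaffold - 1, 0)))
        for p_idx in range(n_prot):
            pid = f"{sid}_p{p_idx}"
            prot_rows.append({"protein_id": pid, "scaffold_id": sid})
            identity = float(_truncated_normal(rng, spec.identity_mu, spec.identity_sigma,
                                               0, 100, 1)[0])
            if rng.random() < spec.majority_rate or n_vir < 2:
                subject = virotype
            else:
                subject = id_arr[(v_idx + int(rng.integers(1, n_vir))) % n_vir]
            bit = 50.0 + 0.9 * identity + float(rng.exponential(5.0))
            ev = 10.0 ** (-float(rng.uniform(6.0, 25.0)))
            proteome.append((pid, subject, identity, 150, ev, bit))

            if rng.random() < 0.6:   # hit in the KO function database
                ko = KO_POOL[int(rng.integers(0, len(KO_POOL)))]
                f_ident = float(_truncated_normal(rng, spec.identity_mu, spec.identity_sigma,
                                                  0, 100, 1)[0])
                functional.append((pid, ko, f_ident, 150,
                                   10.0 ** (-float(rng.uniform(6.0, 25.0))),
                                   50.0 + 0.9 * f_ident))
                if rng.random() < 0.25:
                    amg.append({"protein_id": pid, "ko": ko})
            if rng.random() < 0.6:   # hit in the COG database
                cg = COG_POOL[int(rng.integers(0, len(COG_POOL)))]
                c_ident = float(_truncated_normal(rng, spec.identity_mu, spec.identity_sigma,
                                                  0, 100, 1)[0])
                cog.append((pid, cg, c_ident, 150,
                            10.0 ** (-float(rng.uniform(6.0, 25.0))),
                            50.0 + 0.9 * c_ident))

    def to_frame(tuples):
        if not tuples:
            return _hit_frame([], [], [], [], [], [])
        q, s, pi, ln, ev, bi = zip(*tuples)
        return _hit_frame(list(q), list(s), list(pi), list(ln), list(ev), list(bi))

    scaffolds = pd.DataFrame(rows)
    truth.scaffolds = scaffolds
    scaffold_counts = pd.DataFrame(counts, index=samples).T
    scaffold_counts.index.name = "scaffold_id"
    return ScaffoldFixtures(
        scaffolds=scaffolds,
        scaffold_proteins=pd.DataFrame(prot_rows),
        scaffold_counts=scaffold_counts,
        proteome_hits=to_frame(proteome),
        function_hits=to_frame(functional),
        cog_hits=to_frame(cog),
        amg_calls=pd.DataFrame(amg, columns=["protein_id", "ko"]),
        ko_to_pathway=ko_to_pathway,
        cog_to_category=cog_to_category,
        virus_host=dict(truth.hosts),
    )
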