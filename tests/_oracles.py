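"""Independent brute-force oracles used to cross-check pipeline operations.

These deliberately share no code with the package: naive agglomerative
clustering by exhaustive pairwise scans, pool-adjacent-violators for the
stress-1 disparities, and a per-read threshold scan for assignments.
"""

from __future__ import annotations

import numpy as np


def naive_linkage_order(points: np.ndarray, method: str) -> list[list[int]]:
    """Agglomerative clustering by exhaustive scan; returns merge history.

    Each history entry is the sorted member list of the newly formed cluster.
    ``method`` is 'average' (UPGMA) or 'complete'.
    """
    n = len(points)
    d = np.sqrt(((points[:, None, :] - points[None, :, :]) ** 2).sum(-1))
    clusters: dict[int, list[int]] = {i: [i] for i in range(n)}
    history = []
    heights = []
    next_id = n
    while len(clusters) > 1:
        best = None
        keys = sorted(clusters)
        for i_pos, a in enumerate(keys):
            for b in keys[i_pos + 1:]:
                pairs = [(x, y) for x in clusters[a] for y in clusters[b]]
                dists = [d[x, y] for x, y in pairs]
                dist = np.mean(dists) if method == "average" else np.max(dists)
                if best is None or dist < best[0]:
                    best = (dist, a, b)
        dist, a, b = best
        merged = sorted(clusters.pop(a) + clusters.pop(b))
        clusters[next_id] = merged
        history.append(merged)
        heights.append(dist)
        next_id += 1
    return history, heights


def pava_nondecreasing(y: np.ndarray, weights: np.ndarray | None = None) -> np.ndarray:
    """Pool-adjacent-violators: least-squares non-decreasing fit to y."""
    y = np.asarray(y, dtype=float)
    w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float)
    blocks = [[y[i] * w[i], w[i], [i]] for i in range(len(y))]
    merged: list = []
    for block in blocks:
        merged.append(block)
        while len(merged) > 1 and merged[-2][0] / merged[-2][1] > merged[-1][0] / merged[-1][1]:
            s, wsum, idx = merged.pop()
            merged[-1][0] += s
            merged[-1][1] += wsum
            merged[-1][2] += idx
    out = np.empty_like(y)
    for s, wsum, idx in merged:
        out[idx] = s / wsum
    return out


def stress1_oracle(dissimilarities: np.ndarray, coordinates: np.ndarray) -> float:
    """Kruskal stress-1 recomputed from scratch with hand-rolled PAVA."""
    from scipy.spatial.distance import pdist

    d_in = dissimilarities
    d_conf = pdist(coordinates)
    order = np.argsort(d_in, kind="stable")
    dhat = np.empty_like(d_conf)
    dhat[order] = pava_nondecreasing(d_conf[order])
    return float(np.sqrt(((d_conf - dhat) ** 2).sum() / (d_conf**2).sum()))


def brute_force_assign(
    protein_hits, nucleotide_hits, read_ids,
    min_identity=35.0, evalue_max=1e-5, bit_min=50.0,
):
    """Per-read exhaustive scan applying the two-stage thresholds."""
    by_read_p: dict[str, list] = {}
    for h in protein_hits.itertuples(index=False):
        by_read_p.setdefault(h.qseqid, []).append(h)
    by_read_n: dict[str, list] = {}
    for h in nucleotide_hits.itertuples(index=False):
        by_read_n.setdefault(h.qseqid, []).append(h)
    assigned = {}
    unidentified = set()
    for read in read_ids:
        stage1 = [h for h in by_read_p.get(read, [])
                  if h.pident >= min_identity and h.evalue <= evalue_max
                  and h.bitscore >= bit_min]
        if stage1:
            best = min(stage1, key=lambda h: (-h.bitscore, h.evalue, h.sseqid))
            assigned[read] = best.sseqid
            continue
        stage2 = [h for h in by_read_n.get(read, [])
                  if h.evalue <= evalue_max and h.bitscore >= bit_min]
        if stage2:
            best = min(stage2, key=lambda h: (-h.bitscore, h.evalue, h.sseqid))
            assigned[read] = best.sseqid
        else:
            unidentified.add(read)
    return assigned, unidentified


def brute_force_scaffold_vote(votes):
    """Enumerate all (taxon, votes, max identity) triples and pick the winner."""
    if not votes:
        return None
    triples = {}
    for subject, ident in votes:
        n, m = triples.get(subject, (0, -1.0))
        triples[subject] = (n + 1, max(m, ident))
    best = None
    for subject, (n, m) in triples.items():
        key = (-n, -m, subject)
        if best is None or key < best[0]:
            best = (key, subject)
    return best[1]
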