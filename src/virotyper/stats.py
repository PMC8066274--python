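"""Community statistics: alpha diversity, ordination, clustering, tests.

Alpha diversity uses the ecology conventions: Shannon entropy in nats,
the Gini–Simpson index 1 - sum(p^2), and the bias-corrected Chao1 richness
estimator S + f1(f1-1) / (2(f2+1)) (defined even when no doubletons exist).

Ordination is non-metric multidimensional scaling (Kruskal stress-1) on
Euclidean distances of the transformed profiles; gradient vectors for
external variables are fitted by least squares on the ordination axes with
permutation p-values, in the manner of vegan's envfit.  Sample dendrograms
use UPGMA (average linkage); heatmap row/column orders use complete linkage
on log10(x+1) transformed counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage, to_tree
from scipy.spatial.distance import pdist, squareform
from scipy.stats import chi2_contingency
from sklearn.isotonic import IsotonicRegression
from sklearn.manifold import smacof


@dataclass(frozen=True)
class DiversityProfile:
    species_richness: int
    shannon: float   # nats
    simpson: float   # Gini–Simpson, in [0, 1)
    chao1: float     # >= richness


@dataclass(frozen=True)
class OrdinationResult:
    coordinates: pd.DataFrame      # samples x k
    stress: float                  # Kruskal stress-1
    fitted_vectors: pd.DataFrame | None = None


def diversity(counts) -> DiversityProfile:
    """Alpha-diversity profile of one sample's (integer-valued) counts."""
    x = np.asarray(counts, dtype=float)
    if (x < 0).any():
        raise ValueError("negative counts")
    x = x[x > 0]
    if x.size == 0:
        raise ValueError("all-zero sample has no diversity")
    p = x / x.sum()
    shannon = float(-(p * np.log(p)).sum())
    simpson = float(1.0 - (p**2).sum())
    richness = int(x.size)
    rounded = np.rint(x).astype(int)
    f1 = int((rounded == 1).sum())
    f2 = int((rounded == 2).sum())
    chao1 = richness + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    return DiversityProfile(richness, shannon, simpson, chao1)


def diversity_table(table: pd.DataFrame) -> pd.DataFrame:
    """Per-sample diversity profiles for a virotype x sample table."""
    rows = {}
    for sample in table.columns:
        d = diversity(table[sample].to_numpy())
        rows[sample] = {
            "species_richness": d.species_richness,
            "shannon": d.shannon,
            "simpson": d.simpson,
            "chao1": d.chao1,
        }
    return pd.DataFrame(rows).T


def relative_abundance(table: pd.DataFrame) -> pd.DataFrame:
    """Per-sample relative abundances (columns sum to 1)."""
    sums = table.sum(axis=0)
    if (sums == 0).any():
        raise ValueError("cannot take relative abundance of an all-zero sample")
    return table / sums


def range01(table: pd.DataFrame) -> pd.DataFrame:
    """Range each virotype across samples to [0, 1]; constants map to 0."""
    if table.shape[1] < 2:
        raise ValueError("ranging requires at least two samples")
    lo = table.min(axis=1)
    span = table.max(axis=1) - lo
    out = table.astype(float).sub(lo, axis=0)
    nonconst = span > 0
    out.loc[nonconst] = out.loc[nonconst].div(span[nonconst], axis=0)
    out.loc[~nonconst] = 0.0
    return out


def ordination_transform(table: pd.DataFrame) -> pd.DataFrame:
    """The pre-ordination transform: relative abundance, then 0–1 ranging."""
    return range01(relative_abundance(table))


def stress1(dissimilarities: np.ndarray, coordinates: np.ndarray) -> float:
    """Kruskal stress-1 of a configuration against input dissimilarities.

    Disparities are the isotonic (monotone non-decreasing) regression of the
    configuration distances on the dissimilarity ranks.
    """
    d_in = squareform(dissimilarities, checks=False) if dissimilarities.ndim == 2 else dissimilarities
    d_conf = pdist(coordinates)
    order = np.argsort(d_in, kind="stable")
    iso = IsotonicRegression(increasing=True)
    dhat = np.empty_like(d_conf)
    dhat[order] = iso.fit_transform(np.arange(order.size), d_conf[order])
    denom = float((d_conf**2).sum())
    if denom == 0:
        return 0.0
    return float(np.sqrt(((d_conf - dhat) ** 2).sum() / denom))


def _classical_scaling(dist: np.ndarray, k: int) -> np.ndarray:
    """Torgerson's classical metric scaling, used as one SMACOF start."""
    n = dist.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (dist**2) @ j
    vals, vecs = np.linalg.eigh(b)
    idx = np.argsort(vals)[::-1][:k]
    vals = np.clip(vals[idx], 0, None)
    return vecs[:, idx] * np.sqrt(vals)


def nmds(
    table: pd.DataFrame,
    k: int = 2,
    seed: int = 0,
    n_starts: int = 20,
    max_iter: int = 500,
) -> OrdinationResult:
    """Non-metric MDS of samples (columns) on Euclidean distances.

    ``table`` should already be transformed (see :func:`ordination_transform`).
    SMACOF is run from the classical-scaling configuration plus ``n_starts - 1``
    random starts; the configuration with the lowest stress-1 wins.
    Deterministic for a fixed seed.
    """
    if table.shape[1] < 3:
        raise ValueError("NMDS needs at least 3 samples")
    x = table.T.to_numpy(dtype=float)  # samples as points
    dist = squareform(pdist(x))
    candidates = []
    init = _classical_scaling(dist, k)
    emb, _ = smacof(
        dist, metric=False, n_components=k, init=init, n_init=1,
        max_iter=max_iter, eps=1e-12, random_state=seed, normalized_stress=True,
    )
    candidates.append(emb)
    if n_starts > 1:
        emb, _ = smacof(
            dist, metric=False, n_components=k, n_init=n_starts - 1,
            max_iter=max_iter, eps=1e-12, random_state=seed, normalized_stress=True,
        )
        candidates.append(emb)
    best = min(candidates, key=lambda c: stress1(dist, c))
    coords = pd.DataFrame(
        best, index=table.columns, columns=[f"NMDS{i + 1}" for i in range(k)]
    )
    return OrdinationResult(coordinates=coords, stress=stress1(dist, best))


def fit_vectors(
    ordination: OrdinationResult,
    variables: pd.DataFrame,
    n_permutations: int = 999,
    seed: int = 0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Fit gradient vectors of external variables onto ordination axes.

    Each variable is regressed on the axes by least squares; the direction is
    the unit-normalized coefficient vector and R^2 the explained-variance
    fraction.  The p-value permutes sample labels (``n_permutations`` draws);
    a vector is flagged reliable when p <= ``alpha``.  Constant variables are
    undefined and flagged unreliable.
    """
    coords = ordination.coordinates
    common = coords.index.intersection(variables.index)
    if len(common) != len(coords.index):
        raise ValueError("variables must provide one value per ordinated sample")
    xc = coords.loc[common].to_numpy() - coords.loc[common].to_numpy().mean(axis=0)
    hat = xc @ np.linalg.pinv(xc)
    rng = np.random.default_rng(seed)
    rows = {}
    k = coords.shape[1]
    for name in variables.columns:
        y = variables.loc[common, name].to_numpy(dtype=float)
        yc = y - y.mean()
        sst = float((yc**2).sum())
        if sst == 0:
            rows[name] = dict(
                **{f"axis{i+1}": np.nan for i in range(k)},
                r_squared=np.nan, p_value=np.nan, reliable=False,
            )
            continue
        beta = np.linalg.lstsq(xc, yc, rcond=None)[0]
        r2 = float(((hat @ yc) ** 2).sum() / sst)
        direction = beta / np.linalg.norm(beta) if np.linalg.norm(beta) > 0 else beta
        perms = np.array([rng.permutation(yc) for _ in range(n_permutations)]).T
        r2_null = ((hat @ perms) ** 2).sum(axis=0) / (perms**2).sum(axis=0)
        p = float((1 + (r2_null >= r2).sum()) / (n_permutations + 1))
        rows[name] = dict(
            **{f"axis{i+1}": direction[i] for i in range(k)},
            r_squared=r2, p_value=p, reliable=bool(p <= alpha),
        )
    return pd.DataFrame(rows).T


def linkage_to_newick(z: np.ndarray, labels: list[str]) -> str:
    """Newick serialization of a scipy linkage matrix.

    Branch lengths are parent merge height minus child merge height (leaves
    sit at height 0), so root-to-leaf path lengths equal the merge heights.
    """

    def recurse(node, parent_height):
        if node.is_leaf():
            return f"{labels[node.id]}:{parent_height:g}"
        inner = ",".join(recurse(c, node.dist) for c in (node.left, node.right))
        if parent_height is None:
            return f"({inner});"
        return f"({inner}):{parent_height - node.dist:g}"

    root = to_tree(z)
    return recurse(root, None)


def cluster_samples(table: pd.DataFrame, method: str = "average"):
    """Hierarchical clustering of samples (columns) on Euclidean distances.

    Returns (linkage matrix, labels, newick).  The default ``average`` method
    is UPGMA; merges are deterministic (scipy resolves equal distances by
    cluster index).
    """
    if table.shape[1] < 2:
        raise ValueError("clustering needs at least 2 samples")
    x = table.T.to_numpy(dtype=float)
    z = linkage(x, method=method, metric="euclidean")
    labels = list(table.columns)
    return z, labels, linkage_to_newick(z, labels)


def heatmap_order(table: pd.DataFrame):
    """Row and column display orders for a count heatmap.

    Counts are transformed log10(x + 1); rows and columns are each ordered by
    the leaf order of a complete-linkage dendrogram on Euclidean distances.
    Returns (row_order, col_order, transformed table).
    """
    logged = np.log10(table.astype(float) + 1.0)
    row_order = [table.index[i] for i in leaves_list(linkage(logged.to_numpy(), method="complete"))] \
        if table.shape[0] > 1 else list(table.index)
    col_order = [table.columns[i] for i in leaves_list(linkage(logged.T.to_numpy(), method="complete"))] \
        if table.shape[1] > 1 else list(table.columns)
    return row_order, col_order, logged


def pairwise_chisq(
    table: pd.DataFrame, pairs: list[tuple[str, str]] | None = None
) -> pd.DataFrame:
    """Pearson chi-square tests of virotype composition between sample pairs.

    Counts are rounded half-to-even to integers; virotypes absent from both
    samples of a pair are dropped.  Bonferroni multiplies raw p-values by the
    number of pairs tested (capped at 1).
    """
    if pairs is None:
        pairs = list(combinations(table.columns, 2))
    rows = []
    for s1, s2 in pairs:
        sub = np.rint(table[[s1, s2]].to_numpy(dtype=float)).astype(int)
        sub = sub[sub.sum(axis=1) > 0]
        if (sub.sum(axis=0) == 0).any():
            raise ValueError(f"pair ({s1}, {s2}) includes a zero-sum sample")
        if sub.shape[0] < 2:
            chi2, p, dof = 0.0, 1.0, 0
        else:
            chi2, p, dof, _ = chi2_contingency(sub.T, correction=False)
        rows.append({"sample_a": s1, "sample_b": s2, "chi2": float(chi2),
                     "df": int(dof), "p_raw": float(p),
                     "p_bonferroni": float(min(1.0, p * len(pairs)))})
    return pd.DataFrame(rows)
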