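"""Phenotype-convergence analyses of predicted fluxomes.

Dimension reduction (PCA, t-SNE), shared-nearest-neighbor modularity
clustering, cluster composition/stage summaries, per-sample gene-set
enrichment (ssGSEA-style running-sum scores), and flux-vs-stress-marker
correlations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE
from sklearn.neighbors import NearestNeighbors

from .containers import as_expression
from .errors import InputError, ParameterError


@dataclass
class Embedding2D:
    """2D sample embedding with the settings that produced it."""

    coordinates: pd.DataFrame  # sample x (tsne1, tsne2)
    seed: int
    perplexity: float


@dataclass
class ClusterReport:
    """Per-cluster composition over (cancer type, status) and stage."""

    labels: pd.Series
    composition: pd.DataFrame        # cluster x (type, status) counts
    stage_distribution: pd.DataFrame  # cluster x stage counts (NA tallied)
    n_clusters: int
    stage_chi2_p: float | None = None


def top_principal_components(matrix: pd.DataFrame, n_components: int) -> pd.DataFrame:
    """Column-centered PCA scores ordered by decreasing explained variance.

    Component signs are fixed so the largest-magnitude feature loading of
    each component is positive, making the scores deterministic.
    """
    X = np.asarray(matrix, dtype=float)
    if n_components > min(X.shape):
        raise ParameterError(
            f"n_components={n_components} exceeds min(n_samples, n_features)={min(X.shape)}"
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    for c in range(n_components):
        loading = pca.components_[c]
        if loading[np.argmax(np.abs(loading))] < 0:
            scores[:, c] = -scores[:, c]
    index = matrix.index if isinstance(matrix, pd.DataFrame) else pd.RangeIndex(X.shape[0])
    return pd.DataFrame(scores, index=index,
                        columns=[f"PC{i + 1}" for i in range(n_components)])


def tsne_embed(matrix: pd.DataFrame, seed: int = 42, perplexity: float = 30.0) -> Embedding2D:
    """2D t-SNE embedding of a sample x feature matrix; deterministic given seed."""
    X = np.asarray(matrix, dtype=float)
    if X.shape[0] <= 3 * perplexity:
        raise ParameterError(
            f"need more than 3*perplexity={3 * perplexity:g} samples, got {X.shape[0]}"
        )
    emb = TSNE(n_components=2, perplexity=perplexity, random_state=seed,
               init="pca").fit_transform(X)
    index = matrix.index if isinstance(matrix, pd.DataFrame) else pd.RangeIndex(X.shape[0])
    coords = pd.DataFrame(emb, index=index, columns=["tsne1", "tsne2"])
    return Embedding2D(coordinates=coords, seed=seed, perplexity=perplexity)


def knn_cluster(
    pc_scores: pd.DataFrame,
    k_neighbors: int = 20,
    resolution: float = 0.8,
    seed: int = 42,
    prune: float = 1.0 / 15.0,
) -> pd.Series:
    """Shared-nearest-neighbor modularity clustering on Euclidean distances.

    A k-nearest-neighbor graph is built on the score matrix, edges are
    reweighted by the Jaccard overlap of neighborhoods (weights below
    ``prune`` dropped), and communities are found by resolution-weighted
    modularity optimization.  Deterministic given ``seed``.
    """
    X = np.asarray(pc_scores, dtype=float)
    index = pc_scores.index if isinstance(pc_scores, pd.DataFrame) else pd.RangeIndex(X.shape[0])
    n = X.shape[0]
    if k_neighbors >= n:
        raise ParameterError(f"k_neighbors={k_neighbors} must be < n_samples={n}")
    if np.allclose(X, X[0]):
        warnings.warn("all samples identical; returning a single cluster", stacklevel=2)
        return pd.Series(0, index=index, name="cluster")

    nn = NearestNeighbors(n_neighbors=k_neighbors).fit(X)
    neigh = nn.kneighbors(return_distance=False)
    neigh_sets = [set(row) | {i} for i, row in enumerate(neigh)]
    edges, weights = [], []
    for i in range(n):
        for j in neigh[i]:
            j = int(j)
            if j <= i:
                continue
            jac = len(neigh_sets[i] & neigh_sets[j]) / len(neigh_sets[i] | neigh_sets[j])
            if jac >= prune:
                edges.append((i, j))
                weights.append(jac)
    graph = ig.Graph(n=n, edges=edges)
    graph.es["weight"] = weights
    part = leidenalg.find_partition(
        graph, leidenalg.RBConfigurationVertexPartition,
        weights="weight", resolution_parameter=resolution, seed=seed,
    )
    return pd.Series(part.membership, index=index, name="cluster")


def cluster_stage_distribution(labels: pd.Series, metadata: pd.DataFrame) -> ClusterReport:
    """Per-cluster composition over (cancer type, status) and cancer stage.

    Missing stages are tallied as NA.  Stage-vs-cluster enrichment is
    assessed with a chi-square test on the non-NA contingency table when
    it is well formed (otherwise the p-value is None with a warning).
    """
    metadata = metadata.reindex(labels.index)
    comp = pd.crosstab(
        labels, [metadata.get("cancer_type", pd.Series("NA", index=labels.index)),
                 metadata.get("status", pd.Series("NA", index=labels.index))]
    )
    stage = metadata.get("stage")
    if stage is None:
        stage = pd.Series(pd.NA, index=labels.index)
    stage = stage.astype("object").where(stage.notna(), "NA")
    stage_tab = pd.crosstab(labels, stage)
    chi2_p: float | None = None
    observed = stage_tab.drop(columns=["NA"], errors="ignore")
    if observed.shape[0] >= 2 and observed.shape[1] >= 2 and observed.to_numpy().sum() > 0:
        chi2_p = float(stats.chi2_contingency(observed.to_numpy() + 0.0).pvalue)
    else:
        warnings.warn("stage metadata too sparse for a chi-square test", stacklevel=2)
    return ClusterReport(
        labels=labels, composition=comp, stage_distribution=stage_tab,
        n_clusters=int(labels.nunique()), stage_chi2_p=chi2_p,
    )


def ssgsea_scores(expression, gene_sets: dict[str, list[str]],
                  alpha: float = 0.75) -> pd.DataFrame:
    """Per-sample enrichment scores (ssGSEA-style running sum).

    For each sample, genes are ranked by descending expression; the score
    of a gene set is the sum over rank positions of the difference between
    the weighted in-set cumulative fraction (weights ``|rank statistic|^alpha``,
    rank statistic = descending-rank weight n..1) and the unweighted
    out-of-set cumulative fraction.  Depending only on ranks, scores are
    invariant under strictly increasing transforms of a sample's values.
    Sets with no overlap with the matrix get NA with a warning.
    """
    if alpha < 0:
        raise ParameterError("alpha must be non-negative")
    expr = as_expression(expression)
    values = expr.values
    genes = values.index.to_numpy()
    n = len(genes)
    scores = pd.DataFrame(np.nan, index=values.columns, columns=list(gene_sets))
    memberships = {}
    for name, members in gene_sets.items():
        mask = np.isin(genes, list(members))
        if not mask.any():
            warnings.warn(f"gene set {name!r} shares no genes with the matrix; score NA",
                          stacklevel=2)
            memberships[name] = None
        else:
            memberships[name] = mask
    rank_stat = np.arange(n, 0, -1, dtype=float)  # weight n for the top-ranked gene
    weights_full = np.abs(rank_stat) ** alpha
    for sample in values.columns:
        order = np.argsort(-values[sample].to_numpy(), kind="stable")
        w = weights_full  # position-based weights after sorting
        for name, mask in memberships.items():
            if mask is None:
                continue
            in_set = mask[order]
            n_in = int(in_set.sum())
            if n_in == n:
                cum_out = np.zeros(n)
            else:
                cum_out = np.cumsum(~in_set) / (n - n_in)
            w_in = np.where(in_set, w, 0.0)
            cum_in = np.cumsum(w_in) / w_in.sum()
            scores.loc[sample, name] = float(np.sum(cum_in - cum_out))
    return scores


def flux_stress_correlation(flux: pd.DataFrame, scores: pd.DataFrame) -> pd.DataFrame:
    """Spearman correlation of each module's flux with each gene-set score.

    Computed over the samples shared by the two tables (at least 3
    required); rows follow the flux modules, columns the score sets.
    """
    shared = flux.index.intersection(scores.index)
    if len(shared) < 3:
        raise InputError(f"need >=3 shared samples, got {len(shared)}")
    F = flux.loc[shared]
    E = scores.loc[shared]
    out = pd.DataFrame(index=flux.columns, columns=scores.columns, dtype=float)
    for s in scores.columns:
        rho = [stats.spearmanr(F[m], E[s]).statistic for m in flux.columns]
        out[s] = rho
    return out
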