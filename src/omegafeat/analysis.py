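"""Feature-matrix analysis: normalization, clustering, reduction.

Fifteen algorithms: two normalizations (z-score with population sd,
min-max), ten clustering methods (k-means, mini-batch k-means, Gaussian
mixture, agglomerative, spectral, Markov clustering, hierarchical tree
cut, affinity propagation, mean shift, DBSCAN) and three dimensionality
reductions (PCA, t-SNE, LDA).  Markov clustering is implemented in-repo
(expansion/inflation matrix iteration); everything else delegates to
scikit-learn / scipy behind a uniform seeded interface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .records import FeatureMatrix


@dataclass
class AnalysisResult:
    kind: str  # cluster | reduction | normalization
    algorithm: str
    params: dict = field(default_factory=dict)
    seed: int | None = None
    cluster_ids: np.ndarray | None = None   # per-sample, -1 = noise
    embedding: FeatureMatrix | None = None
    matrix: FeatureMatrix | None = None


NORMALIZATIONS = ["zscore", "minmax"]
CLUSTERING_ALGORITHMS = [
    "kmeans", "minibatch_kmeans", "gaussian_mixture",
    "hierarchical_agglomerative", "spectral", "markov_clustering",
    "hclust_tree_cut", "affinity_propagation", "mean_shift", "dbscan",
]
REDUCTION_ALGORITHMS = ["pca", "tsne", "lda"]
ANALYSIS_ALGORITHMS = NORMALIZATIONS + CLUSTERING_ALGORITHMS + REDUCTION_ALGORITHMS


# --------------------------------------------------------------------------
# normalization
# --------------------------------------------------------------------------

def normalize(matrix: FeatureMatrix, method: str = "zscore") -> FeatureMatrix:
    """Column-wise rescaling.

    ``zscore`` maps each column to mean 0 / population sd 1 (idempotent);
    ``minmax`` maps each column onto [0, 1].  Constant columns map to
    zeros under both rules, so no division by zero occurs.
    """
    x = matrix.values
    if x.size == 0:
        raise ValueError("empty matrix")
    if method == "zscore":
        if x.shape[0] < 2:
            raise ValueError("zscore needs >= 2 samples")
        mu = x.mean(axis=0)
        sd = x.std(axis=0)  # population sd
        out = np.where(sd > 0, (x - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    elif method == "minmax":
        lo = x.min(axis=0)
        span = x.max(axis=0) - lo
        out = np.where(span > 0, (x - lo) / np.where(span > 0, span, 1.0), 0.0)
    else:
        raise ValueError(f"unknown normalization {method!r}")
    return matrix.with_values(out)


# --------------------------------------------------------------------------
# Markov clustering (in-repo implementation)
# --------------------------------------------------------------------------

def markov_cluster(
    similarity: np.ndarray,
    inflation: float = 2.0,
    expansion: int = 2,
    prune: float = 1e-5,
    max_iter: int = 200,
    tol: float = 1e-8,
) -> np.ndarray:
    """Markov clustering on a non-negative similarity matrix.

    Iterates column-normalize -> expand (matrix power) -> inflate
    (elementwise power, renormalize) -> prune until the flow matrix
    converges; attractor rows then define the clusters.
    """
    m = np.asarray(similarity, dtype=float).copy()
    if m.shape[0] != m.shape[1]:
        raise ValueError("similarity matrix must be square")
    n = m.shape[0]
    np.fill_diagonal(m, np.maximum(m.diagonal(), 1e-12))  # self loops

    def colnorm(a: np.ndarray) -> np.ndarray:
        s = a.sum(axis=0)
        s[s == 0] = 1.0
        return a / s

    m = colnorm(m)
    for _ in range(max_iter):
        prev = m
        m = np.linalg.matrix_power(m, expansion)
        m = colnorm(np.power(m, inflation))
        m[m < prune] = 0.0
        m = colnorm(m)
        if np.abs(m - prev).max() < tol:
            break
    # attractors: nodes with positive flow on their own row
    labels = np.full(n, -1, dtype=int)
    cluster = 0
    for i in range(n):
        if m[i, i] > 0 and labels[i] == -1:
            members = np.nonzero(m[i] > 0)[0]
            existing = {labels[j] for j in members if labels[j] != -1}
            if existing:
                lab = min(existing)
            else:
                lab = cluster
                cluster += 1
            labels[i] = lab
            for j in members:
                labels[j] = lab
    for i in range(n):  # unattached nodes join their strongest column
        if labels[i] == -1:
            j = int(np.argmax(m[:, i]))
            labels[i] = labels[j] if labels[j] != -1 else cluster
            if labels[i] == cluster:
                cluster += 1
    # relabel consecutively in order of first appearance
    remap: dict[int, int] = {}
    out = np.empty(n, dtype=int)
    for i, lab in enumerate(labels):
        if lab not in remap:
            remap[lab] = len(remap)
        out[i] = remap[lab]
    return out


# --------------------------------------------------------------------------
# clustering front end
# --------------------------------------------------------------------------

def cluster(
    matrix: FeatureMatrix,
    algorithm: str,
    params: dict | None = None,
    seed: int = 0,
) -> AnalysisResult:
    """Run one of the ten clustering algorithms; deterministic per seed."""
    from sklearn import cluster as skc
    from sklearn.mixture import GaussianMixture

    params = dict(params or {})
    x = matrix.values
    n = x.shape[0]
    if not np.isfinite(x).all():
        raise ValueError("non-finite values in feature matrix")
    k = int(params.pop("n_clusters", min(2, n)))
    if k > n:
        raise ValueError(f"n_clusters={k} exceeds sample count {n}")
    if algorithm == "kmeans":
        labels = skc.KMeans(
            n_clusters=k, n_init=10, random_state=seed, **params
        ).fit_predict(x)
    elif algorithm == "minibatch_kmeans":
        labels = skc.MiniBatchKMeans(
            n_clusters=k, n_init=10, random_state=seed, **params
        ).fit_predict(x)
    elif algorithm == "gaussian_mixture":
        labels = GaussianMixture(
            n_components=k, random_state=seed, **params
        ).fit_predict(x)
    elif algorithm == "hierarchical_agglomerative":
        labels = skc.AgglomerativeClustering(n_clusters=k, **params).fit_predict(x)
    elif algorithm == "spectral":
        gamma = params.pop("gamma", 1.0 / max(1, x.shape[1]))
        labels = skc.SpectralClustering(
            n_clusters=k, affinity="rbf", gamma=gamma,
            random_state=seed, **params,
        ).fit_predict(x)
    elif algorithm == "markov_clustering":
        gamma = params.pop("gamma", 1.0 / max(1, x.shape[1]))
        d2 = squareform(pdist(x, metric="sqeuclidean")) if n > 1 else np.zeros((1, 1))
        sim = np.exp(-gamma * d2)
        labels = markov_cluster(sim, **params)
    elif algorithm == "hclust_tree_cut":
        if n < 2:
            labels = np.zeros(n, dtype=int)
        else:
            link = hierarchy.linkage(x, method=params.pop("method", "ward"))
            labels = hierarchy.cut_tree(link, n_clusters=k).ravel()
    elif algorithm == "affinity_propagation":
        labels = skc.AffinityPropagation(
            random_state=seed, **params
        ).fit_predict(x)
    elif algorithm == "mean_shift":
        labels = skc.MeanShift(**params).fit_predict(x)
    elif algorithm == "dbscan":
        labels = skc.DBSCAN(**params).fit_predict(x)
    else:
        raise ValueError(f"unknown clustering algorithm {algorithm!r}")
    return AnalysisResult(
        "cluster", algorithm, params, seed, cluster_ids=np.asarray(labels, dtype=int)
    )


# --------------------------------------------------------------------------
# dimensionality reduction
# --------------------------------------------------------------------------

def reduce(
    matrix: FeatureMatrix,
    algorithm: str,
    n_components: int = 2,
    seed: int = 0,
    labels: list[str] | None = None,
) -> AnalysisResult:
    """PCA / t-SNE / LDA embedding of the samples.

    LDA requires labels (taken from the matrix when not given) and at
    most ``classes - 1`` components; PCA additionally records the
    explained-variance ratios in ``params``.
    """
    from sklearn.decomposition import PCA
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
    from sklearn.manifold import TSNE

    x = matrix.values
    if n_components > x.shape[1]:
        raise ValueError("n_components exceeds feature count")
    info: dict = {}
    if algorithm == "pca":
        model = PCA(n_components=n_components, random_state=seed)
        emb = model.fit_transform(x)
        info["explained_variance_ratio"] = model.explained_variance_ratio_.tolist()
    elif algorithm == "tsne":
        perplexity = min(30.0, max(1.0, (x.shape[0] - 1) / 3.0))
        model = TSNE(
            n_components=n_components, random_state=seed,
            perplexity=perplexity, init="pca",
        )
        emb = model.fit_transform(x)
        info["perplexity"] = perplexity
    elif algorithm == "lda":
        labs = labels if labels is not None else matrix.labels
        if labs is None:
            raise ValueError("LDA requires labels")
        classes = sorted(set(labs))
        if n_components > len(classes) - 1:
            raise ValueError(
                f"LDA supports at most {len(classes) - 1} components here"
            )
        model = LinearDiscriminantAnalysis(n_components=n_components)
        emb = model.fit_transform(x, labs)
    else:
        raise ValueError(f"unknown reduction algorithm {algorithm!r}")
    names = [f"{algorithm.upper()}{i + 1}" for i in range(n_components)]
    out = FeatureMatrix(
        np.asarray(emb, dtype=float), matrix.sample_ids, names, matrix.labels
    )
    return AnalysisResult("reduction", algorithm, info, seed, embedding=out)


def run_analysis(
    matrix: FeatureMatrix, algorithm: str, params: dict | None = None, seed: int = 0
) -> AnalysisResult:
    """Uniform entry point over all fifteen analysis algorithms."""
    params = dict(params or {})
    if algorithm in NORMALIZATIONS:
        return AnalysisResult(
            "normalization", algorithm, params, seed,
            matrix=normalize(matrix, algorithm),
        )
    if algorithm in CLUSTERING_ALGORITHMS:
        return cluster(matrix, algorithm, params, seed)
    if algorithm in REDUCTION_ALGORITHMS:
        return reduce(matrix, algorithm, seed=seed, **params)
    raise ValueError(f"unknown analysis algorithm {algorithm!r}")
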