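"""Unsupervised cluster-quality evaluation via kNN accuracy, plus t-SNE.

kNN accuracy scores a feature space by how often a point's k nearest
Euclidean neighbours vote for its true cluster label — compound identity
for replicate clustering, MoA class for mechanism clustering.  Majority-vote
ties are broken in favour of the tied class containing the closest
neighbour, which is deterministic and order-independent.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.neighbors import NearestNeighbors

from .profiles import ProfileMatrix


@dataclass
class ClusterEvalResult:
    feature_type_name: str
    task: str  # "replicates" or "moa"
    knn_accuracy: float
    k: int
    n_points: int
    n_classes: int
    exclude_self: bool

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def knn_accuracy(
    X: np.ndarray,
    labels: Sequence,
    k: int = 5,
    exclude_self: bool = False,
    metric: str = "euclidean",
) -> float:
    """Fraction of points whose k-nearest-neighbour majority label is correct.

    With ``exclude_self=False`` (mirroring a classifier fit and queried on
    the same set) the query point itself counts among its neighbours; with
    ``exclude_self=True`` the vote is leave-one-out.
    """
    X = np.asarray(X, dtype=np.float64)
    labels = np.asarray(labels)
    if k < 1:
        raise ValueError("k must be >= 1")
    n = X.shape[0]
    needed = k + 1 if exclude_self else k
    if n < needed:
        raise ValueError(f"need at least {needed} rows for k={k}")
    if len(set(labels.tolist())) < 2:
        raise ValueError("labels are degenerate (fewer than 2 classes)")

    nn = NearestNeighbors(n_neighbors=k + 1 if exclude_self else k, metric=metric)
    nn.fit(X)
    _, idx = nn.kneighbors(X)
    if exclude_self:
        # drop the query point itself; for duplicate rows the query may not
        # come first, so remove by index explicitly
        pruned = np.empty((n, k), dtype=int)
        for i in range(n):
            row = idx[i][idx[i] != i][:k]
            if row.size < k:  # all-duplicate corner: self absent from idx
                row = idx[i][:k]
            pruned[i] = row
        idx = pruned

    correct = 0
    for i in range(n):
        votes = labels[idx[i]]
        counts = Counter(votes.tolist())
        top = max(counts.values())
        tied = {lab for lab, c in counts.items() if c == top}
        if len(tied) == 1:
            pred = tied.pop()
        else:  # nearest neighbour among tied classes decides
            pred = next(lab for lab in votes.tolist() if lab in tied)
        correct += pred == labels[i]
    return correct / n


def replicate_clustering_eval(
    features: ProfileMatrix,
    k: int = 5,
    exclude_self: bool = False,
    feature_type_name: str = "features",
) -> ClusterEvalResult:
    """Replicate clustering: labels are compound ids of CP replicate rows.

    The caller restricts ``features`` to test-split compounds beforehand.
    Compounds with a single replicate can never be voted correctly under
    leave-one-out; they trigger a warning but stay in the denominator.
    """
    labels = features.compound_ids
    if exclude_self:
        singles = [c for c, n in Counter(labels).items() if n == 1]
        if singles:
            warnings.warn(
                f"{len(singles)} compounds have a single replicate and cannot "
                "be correctly voted with exclude_self=True",
                stacklevel=2,
            )
    acc = knn_accuracy(features.values, labels, k=k, exclude_self=exclude_self)
    return ClusterEvalResult(
        feature_type_name, "replicates", acc, k,
        features.n_rows, len(set(labels)), exclude_self,
    )


def moa_clustering_eval(
    features: ProfileMatrix,
    moa: dict[str, str],
    top_m: int = 9,
    k: int = 5,
    exclude_self: bool = False,
    feature_type_name: str = "features",
) -> ClusterEvalResult:
    """MoA clustering on compound-level features.

    Restricts to the ``top_m`` most-populated annotated MoA classes among the
    given compounds (ties broken by class name for determinism) and scores
    kNN accuracy with MoA class labels.
    """
    annotated = [(c, moa[c]) for c in features.compound_ids if c in moa]
    counts = Counter(lab for _, lab in annotated)
    if len(counts) < 2:
        raise ValueError("need at least 2 annotated MoA classes")
    if len(counts) < top_m:
        warnings.warn(
            f"only {len(counts)} MoA classes available (top_m={top_m}); using all",
            stacklevel=2,
        )
    keep = {
        lab for lab, _ in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[:top_m]
    }
    cids = [c for c, lab in annotated if lab in keep]
    labels = [moa[c] for c in cids]
    sub = features.rows_for(cids)
    # align label order with row order of the subset
    labels = [moa[c] for c in sub.compound_ids]
    acc = knn_accuracy(sub.values, labels, k=k, exclude_self=exclude_self)
    return ClusterEvalResult(
        feature_type_name, "moa", acc, k, sub.n_rows, len(keep), exclude_self
    )


def embed_2d(
    X: np.ndarray, perplexity: float = 10.0, seed: int = 0
) -> np.ndarray:
    """2-D t-SNE coordinates (init='random', learning_rate='auto')."""
    from sklearn.manifold import TSNE

    X = np.asarray(X, dtype=np.float64)
    if X.shape[0] <= 3 * perplexity:
        raise ValueError(
            f"need more than {int(3 * perplexity)} points for perplexity {perplexity}"
        )
    tsne = TSNE(
        n_components=2,
        perplexity=perplexity,
        init="random",
        learning_rate="auto",
        random_state=seed,
    )
    return tsne.fit_transform(X)


def scatter_2d(coords: np.ndarray, labels: Sequence, path: str) -> None:
    """Scatter plot of 2-D coordinates coloured by label, saved to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = np.asarray(labels)
    fig, ax = plt.subplots(figsize=(6, 5))
    for lab in np.unique(labels):
        m = labels == lab
        ax.scatter(coords[m, 0], coords[m, 1], s=8, label=str(lab))
    if len(np.unique(labels)) <= 12:
        ax.legend(fontsize=7, markerscale=2)
    ax.set_xticks([])
    ax.set_yticks([])
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
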