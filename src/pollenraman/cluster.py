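"""Joint hierarchical cluster analysis of pixel spectra (HCA).

Pixels from one or many grain images are pooled and clustered with the
Pearson dissimilarity d = 1 − r and Ward linkage (Ward.D2 convention:
Lance–Williams updates on squared dissimilarities).  Cutting the tree at k
groups yields per-image false-color label maps and k shared cluster mean
spectra, which later seed the curve-resolution step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .core import HyperspectralImage

__all__ = [
    "ClusterResult",
    "CLUSTER_COLORS",
    "pearson_distance",
    "ward_tree",
    "cut_clusters",
    "hca_images",
]

#: rendering palette for clusters 1..5 (dark blue, light blue, purple,
#: orange, red), extended cyclically for larger k
CLUSTER_COLORS = ("#1f3b8f", "#7fc4e8", "#8b5fbf", "#f28e2b", "#d62728")


@dataclass
class ClusterResult:
    k: int
    labels: list[np.ndarray]            # per image, 0 = not retained
    linkage_matrix: np.ndarray          # scipy (n-1, 4) merge tree
    mean_spectra: np.ndarray            # (k, n_channels)
    counts: np.ndarray                  # pixels per cluster
    colors: tuple[str, ...]
    subsampled: bool = False
    meta: dict = field(default_factory=dict)

    def pooled_labels(self, images: list[HyperspectralImage]) -> np.ndarray:
        """Labels of retained pixels only, concatenated across images."""
        return np.concatenate(
            [lab[im.mask] for lab, im in zip(self.labels, images)])


def pearson_distance(spectra: np.ndarray) -> np.ndarray:
    """Pairwise Pearson dissimilarity matrix d(i,j) = 1 − r(i,j).

    Symmetric, zero diagonal, values in [0, 2].  Invariant under per-row
    affine intensity transforms aI + b with a > 0.
    """
    X = np.asarray(spectra, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least 2 spectra")
    sd = X.std(axis=1)
    if np.any(sd == 0):
        bad = int(np.nonzero(sd == 0)[0][0])
        raise ValueError(f"constant spectrum (zero variance) at pixel {bad}")
    d = 1.0 - np.corrcoef(X)
    d = np.clip((d + d.T) / 2.0, 0.0, 2.0)
    np.fill_diagonal(d, 0.0)
    return d


def ward_tree(dist: np.ndarray) -> np.ndarray:
    """Agglomerative merge sequence under the Ward criterion.

    Lance–Williams recursion on squared dissimilarities applied to the
    supplied matrix (the Ward.D2 convention); merge heights are
    non-decreasing.  Returns the scipy linkage matrix.
    """
    d = np.asarray(dist, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    return linkage(squareform(d, checks=False), method="ward")


def cut_clusters(tree: np.ndarray, k: int) -> np.ndarray:
    """Cut the tree into k groups; labels 1..k ordered by decreasing size."""
    n = tree.shape[0] + 1
    if not (1 <= k <= n):
        raise ValueError(f"k={k} out of range 1..{n}")
    raw = fcluster(tree, t=k, criterion="maxclust")
    return _canonicalize(raw)


def _canonicalize(raw: np.ndarray) -> np.ndarray:
    """Renumber labels 1..k by decreasing cluster size (ties: first seen)."""
    uniq, first, counts = np.unique(raw, return_index=True, return_counts=True)
    order = np.lexsort((first, -counts))
    remap = {int(uniq[o]): rank + 1 for rank, o in enumerate(order)}
    return np.array([remap[int(v)] for v in raw], dtype=int)


def hca_images(images: "list[HyperspectralImage] | HyperspectralImage",
               k: int = 5, max_exact_n: int = 20_000,
               seed: int = 0) -> ClusterResult:
    """Joint HCA of all retained pixels across images.

    If the pooled pixel count exceeds ``max_exact_n``, a seeded random
    subsample is clustered exactly and the remaining pixels are assigned to
    the nearest cluster mean by Pearson dissimilarity (flagged in the
    result).  Cluster means are arithmetic means of all member spectra.
    """
    if isinstance(images, HyperspectralImage):
        images = [images]
    axis0 = images[0].axis.values
    for im in images[1:]:
        if len(im.axis) != len(axis0) or not np.allclose(im.axis.values, axis0):
            raise ValueError("images must share one wavenumber axis")
    pooled = np.concatenate([im.retained_matrix() for im in images])
    n = pooled.shape[0]
    if n < k:
        raise ValueError(f"only {n} retained pixels for k={k}")

    subsampled = n > max_exact_n
    if subsampled:
        rng = np.random.default_rng(seed)
        idx = np.sort(rng.choice(n, size=max_exact_n, replace=False))
        tree = ward_tree(pearson_distance(pooled[idx]))
        sub_labels = cut_clusters(tree, k)
        means = np.stack([pooled[idx][sub_labels == c].mean(axis=0)
                          for c in range(1, k + 1)])
        labels_all = _assign_nearest(pooled, means)
        labels_all[idx] = sub_labels
        labels_all = _canonicalize(labels_all)
    else:
        tree = ward_tree(pearson_distance(pooled))
        labels_all = cut_clusters(tree, k)

    means = np.stack([pooled[labels_all == c].mean(axis=0)
                      for c in range(1, k + 1)])
    counts = np.array([(labels_all == c).sum() for c in range(1, k + 1)])

    per_image = []
    start = 0
    for im in images:
        lab = np.zeros(im.n_pixels, dtype=int)
        nret = int(im.mask.sum())
        lab[im.mask] = labels_all[start:start + nret]
        per_image.append(lab)
        start += nret
    colors = tuple(CLUSTER_COLORS[i % len(CLUSTER_COLORS)] for i in range(k))
    return ClusterResult(k=k, labels=per_image, linkage_matrix=tree,
                         mean_spectra=means, counts=counts, colors=colors,
                         subsampled=subsampled,
                         meta={"n_pooled": int(n), "max_exact_n": max_exact_n,
                               "seed": seed})


def _assign_nearest(X: np.ndarray, means: np.ndarray) -> np.ndarray:
    """Assign each row of X to the nearest mean by Pearson dissimilarity."""
    Xc = X - X.mean(axis=1, keepdims=True)
    Mc = means - means.mean(axis=1, keepdims=True)
    Xn = Xc / np.linalg.norm(Xc, axis=1, keepdims=True)
    Mn = Mc / np.linalg.norm(Mc, axis=1, keepdims=True)
    r = Xn @ Mn.T
    return np.argmax(r, axis=1) + 1
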