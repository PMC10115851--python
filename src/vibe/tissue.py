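"""K-means tissue segmentation of a skull-stripped slice.

Once the brain has been extracted, the three major tissue classes —
cerebrospinal fluid, gray matter and white matter — separate well in
intensity alone, so a plain K-means (K = 3) on the masked pixel
intensities recovers them.  Clusters are mapped to tissue names by
sorting the cluster centers under the declared contrast convention:
T1-like contrast orders CSF darkest and white matter brightest, T2-like
the reverse.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .errors import DegenerateClusterError, GeometryError, UndefinedMetricError
from .evaluation import OverlapCounts, dice as _dice, jaccard as _jaccard

__all__ = ["TissueLabelImage", "evaluate_tissues", "kmeans_tissues",
           "TISSUE_LABELS"]

#: label values of a TissueLabelImage
TISSUE_LABELS = {"background": 0, "csf": 1, "gray": 2, "white": 3}

#: cluster-center order (ascending intensity) -> tissue label, per contrast
_ORDER = {
    "t1_like": (TISSUE_LABELS["csf"], TISSUE_LABELS["gray"], TISSUE_LABELS["white"]),
    "t2_like": (TISSUE_LABELS["white"], TISSUE_LABELS["gray"], TISSUE_LABELS["csf"]),
}


@dataclass
class TissueLabelImage:
    """Per-pixel tissue labels (0 background, 1 CSF, 2 gray, 3 white)."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.uint8)
        if not np.all(np.isin(np.unique(self.labels), list(TISSUE_LABELS.values()))):
            raise GeometryError("tissue labels must be in {0, 1, 2, 3}")


def kmeans_tissues(
    stripped_slice: np.ndarray,
    mask_slice: np.ndarray,
    k: int = 3,
    seed: int = 0,
    contrast: str = "t1_like",
    tol: float = 1e-6,
    max_iter: int = 300,
):
    """Cluster masked pixel intensities into ``k`` tissue classes.

    K-means on the 1D intensity feature with k-means++ initialization at
    a fixed seed; background pixels never enter the clustering.  Returns
    ``(TissueLabelImage, centers)`` with centers in ascending intensity
    order.  Relabelling clusters by center order makes the output
    invariant to the arbitrary label permutation of the initialization.
    """
    img = np.asarray(stripped_slice, dtype=np.float64)
    mask = np.asarray(mask_slice) > 0
    if img.shape != mask.shape:
        raise GeometryError("slice and mask shapes differ")
    if not np.any(mask):
        raise DegenerateClusterError("mask is empty; nothing to cluster")
    if contrast not in _ORDER:
        raise GeometryError(f"unknown contrast convention {contrast!r}")
    values = img[mask]
    if np.unique(values).size < k:
        raise DegenerateClusterError(
            f"mask contains fewer than k={k} distinct intensities"
        )
    km = KMeans(n_clusters=k, init="k-means++", n_init=10,
                random_state=int(seed) % (2 ** 31 - 1), tol=tol, max_iter=max_iter)
    assignments = km.fit_predict(values.reshape(-1, 1))
    centers = km.cluster_centers_.ravel()
    order = np.argsort(centers)  # ascending intensity
    if k == 3:
        tissue_of_rank = _ORDER[contrast]
    else:
        tissue_of_rank = tuple(range(1, k + 1))
    rank_of_cluster = np.empty(k, dtype=int)
    rank_of_cluster[order] = np.arange(k)
    labels = np.zeros(img.shape, dtype=np.uint8)
    labels[mask] = np.asarray(tissue_of_rank)[rank_of_cluster[assignments]]
    return TissueLabelImage(labels), np.sort(centers)


def evaluate_tissues(pred: TissueLabelImage, truth: TissueLabelImage):
    """Per-class one-vs-rest Dice and Jaccard.

    Classes absent from the truth are reported as missing (None) rather
    than scored.  Returns ``{class_name: {"dice": ..., "jaccard": ...}}``.
    """
    p, t = pred.labels, truth.labels
    if p.shape != t.shape:
        raise GeometryError("prediction and truth label images differ in shape")
    out = {}
    for name, value in TISSUE_LABELS.items():
        if name == "background":
            continue
        if not np.any(t == value):
            out[name] = None
            continue
        counts = OverlapCounts.from_masks(p == value, t == value)
        try:
            out[name] = {"dice": _dice(counts), "jaccard": _jaccard(counts)}
        except UndefinedMetricError:
            out[name] = None
    return out
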