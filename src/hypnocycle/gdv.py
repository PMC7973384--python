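"""Generalized discrimination value (GDV): separability of labeled point clouds.

The GDV scores how well the classes of a labeled embedding separate in its
feature space.  Each dimension is z-scored over all points and rescaled by
0.5, then

    GDV = (1 / sqrt(D)) * [ mean_l  d̄(C_l)  −  mean_{l<m}  d̄(C_l, C_m) ]

where d̄(C_l) is the mean Euclidean distance between points of class l and
d̄(C_l, C_m) the mean distance between points of different classes.  Under
this convention a GDV of 0 indicates non-separable classes (intra- and
inter-class distances look alike) and −1 corresponds to perfect class
separation.  The z-scoring makes the value invariant to global translation
and uniform scaling of the cloud.

The index is useful layer-by-layer: feeding the same samples through the
layers of a trained network and computing a GDV per layer profiles where
the network's representation becomes class-separable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist, pdist

from .errors import DegenerateInputError

logger = logging.getLogger(__name__)

#: Rescaling applied to each z-scored dimension; 0.5 reproduces the
#: convention that perfect separation approaches −1.
ZSCORE_RESCALE = 0.5


@dataclass
class LabeledEmbedding:
    """N×D point cloud with per-point class labels.

    Points may be network-layer activations or any feature vectors; labels
    are arbitrary hashables (typically ints or stage names).
    """

    points: np.ndarray
    labels: np.ndarray
    layer_name: str = ""

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.points.ndim != 2:
            raise ValueError("points must be an N x D matrix")
        if self.labels.shape != (self.points.shape[0],):
            raise ValueError("labels length must equal number of points")

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.labels)


@dataclass
class GdvProfile:
    """GDV per layer, in network order (input → output)."""

    layer_names: list[str]
    gdv_values: np.ndarray

    def __post_init__(self):
        self.gdv_values = np.asarray(self.gdv_values, dtype=float)
        if len(self.layer_names) != self.gdv_values.size:
            raise ValueError("one GDV value per layer name required")


def _check_embedding(emb: LabeledEmbedding) -> list[np.ndarray]:
    if not np.all(np.isfinite(emb.points)):
        raise ValueError("embedding contains non-finite values")
    classes = emb.classes
    if classes.size < 2:
        raise ValueError("GDV requires at least 2 classes")
    groups = [np.flatnonzero(emb.labels == c) for c in classes]
    for c, g in zip(classes, groups):
        if g.size < 2:
            raise ValueError(f"class {c!r} has fewer than 2 points; GDV undefined")
    return groups


def gdv(embedding: LabeledEmbedding, rescale: float = ZSCORE_RESCALE) -> float:
    """Compute the generalized discrimination value of a labeled embedding.

    Dimensions with zero variance carry no geometry after z-scoring and are
    dropped with a logged warning; if every dimension is constant the input
    is degenerate.

    Raises
    ------
    ValueError
        If any class has fewer than 2 points, or values are non-finite.
    DegenerateInputError
        If all dimensions have zero variance.
    """
    groups = _check_embedding(embedding)
    x = embedding.points
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    keep = sd > 0
    if not keep.any():
        raise DegenerateInputError("all dimensions have zero variance; GDV undefined")
    if not keep.all():
        logger.warning("dropping %d zero-variance dimension(s) before z-scoring",
                       int((~keep).sum()))
    z = rescale * (x[:, keep] - mu[keep]) / sd[keep]
    d_eff = int(keep.sum())

    intra = np.array([pdist(z[g]).mean() for g in groups])
    inter = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            inter.append(cdist(z[groups[i]], z[groups[j]]).mean())
    return float((intra.mean() - np.mean(inter)) / np.sqrt(d_eff))


def gdv_profile(embeddings: list[LabeledEmbedding], rescale: float = ZSCORE_RESCALE) -> GdvProfile:
    """GDV per layer for the same samples observed at successive layers.

    All embeddings must carry identical label vectors (same samples, in the
    same order, through different layers).
    """
    if not embeddings:
        raise ValueError("need at least one embedding")
    ref = embeddings[0].labels
    for emb in embeddings[1:]:
        if emb.labels.shape != ref.shape or not np.array_equal(emb.labels, ref):
            raise ValueError("all embeddings must share the same label vector")
    names = [emb.layer_name or f"layer{i}" for i, emb in enumerate(embeddings)]
    values = np.array([gdv(emb, rescale=rescale) for emb in embeddings])
    return GdvProfile(layer_names=names, gdv_values=values)
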