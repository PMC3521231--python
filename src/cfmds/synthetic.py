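"""Synthetic datasets with the structural properties the tool is tested on.

Three generators cover the regimes that matter for classical MDS and its
divide-and-conquer approximation:

* :func:`make_embeddable` — points drawn in a low-dimensional Euclidean
  space together with their exact distance matrix, on which classical MDS
  must recover every distance to numerical precision;
* :func:`make_clustered` — a Gaussian mixture in a higher-dimensional
  ambient space, emulating clustered expression profiles; its ``skew``
  parameter warps one axis exponentially to raise the skewness (PMSC) of
  the inter-object distance distribution, reproducing the regime where
  MaxMin sampling outperforms Random;
* :func:`features_to_distances` — the Euclidean dissimilarity matrix of a
  feature table (the only built-in metric, being the one classical MDS
  models).

Everything is deterministic given ``seed``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .core_mds import DissimilarityMatrix
from .errors import ValidationError

#: Cluster centers are drawn from N(0, (CENTER_SCALE * cluster_spread)^2 I):
#: five-fold the within-cluster spread gives clearly separated clusters.
CENTER_SCALE = 5.0


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic dataset.

    ``latent_dim`` is the true dimensionality of embeddable point clouds;
    ``ambient_dim`` the feature-space dimensionality of clustered data;
    ``cluster_spread`` the within-cluster standard deviation; ``skew`` (>= 0,
    0 = symmetric) the strength of the exponential warp applied to the first
    coordinate.
    """

    n: int = 2000
    ambient_dim: int = 20
    latent_dim: int = 2
    n_clusters: int = 5
    cluster_spread: float = 1.0
    skew: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValidationError(f"n={self.n} must be >= 2")
        if self.latent_dim > self.ambient_dim:
            raise ValidationError(
                f"latent_dim={self.latent_dim} exceeds ambient_dim={self.ambient_dim}"
            )
        if not 1 <= self.n_clusters <= self.n:
            raise ValidationError(f"n_clusters={self.n_clusters} out of range")
        if self.cluster_spread <= 0:
            raise ValidationError("cluster_spread must be positive")


def make_embeddable(spec: SyntheticSpec) -> tuple[np.ndarray, DissimilarityMatrix]:
    """Points in ``latent_dim`` dimensions and their exact distance matrix.

    Classical MDS at ``m = latent_dim`` recovers the returned matrix exactly
    (up to numerical tolerance), which makes this the canonical fixture for
    exact-recovery checks.
    """
    rng = np.random.default_rng(spec.seed)
    points = rng.standard_normal((spec.n, spec.latent_dim))
    D = DissimilarityMatrix(squareform(pdist(points)))
    return points, D


def make_clustered(spec: SyntheticSpec) -> np.ndarray:
    """Gaussian-mixture feature table of shape ``(n, ambient_dim)``.

    ``n_clusters`` centers are drawn from an isotropic Gaussian of scale
    ``CENTER_SCALE * cluster_spread``; points are assigned to clusters
    uniformly and jittered by ``cluster_spread``. With ``skew > 0`` the
    first coordinate ``x`` is remapped to ``(exp(skew * z) - 1) / skew``
    (``z`` the standardized coordinate), a monotone warp that stretches the
    right tail and increases the PMSC of the distance distribution.
    """
    rng = np.random.default_rng(spec.seed)
    centers = rng.normal(
        scale=CENTER_SCALE * spec.cluster_spread,
        size=(spec.n_clusters, spec.ambient_dim),
    )
    labels = rng.integers(spec.n_clusters, size=spec.n)
    X = centers[labels] + rng.normal(scale=spec.cluster_spread,
                                     size=(spec.n, spec.ambient_dim))
    if spec.skew != 0:
        x0 = X[:, 0]
        z = (x0 - x0.mean()) / x0.std()
        X[:, 0] = x0.std() * (np.expm1(spec.skew * z) / spec.skew) + x0.mean()
    return X


def features_to_distances(
    X: np.ndarray, metric: str = "euclidean", ids: tuple[str, ...] = ()
) -> DissimilarityMatrix:
    """Full pairwise dissimilarity matrix of a feature table."""
    if metric != "euclidean":
        raise ValidationError(f"unsupported metric {metric!r}; only 'euclidean'")
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2:
        raise ValidationError(f"feature table must be 2-D, got shape {X.shape}")
    if X.shape[0] < 2:
        raise ValidationError(f"need at least 2 rows, got {X.shape[0]}")
    bad = np.flatnonzero(~np.all(np.isfinite(X), axis=1))
    if bad.size:
        raise ValidationError(
            f"missing/non-finite values in rows {[int(i) for i in bad[:10]]}"
        )
    return DissimilarityMatrix(squareform(pdist(X)), ids)
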