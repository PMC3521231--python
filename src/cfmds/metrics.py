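"""Distance-preservation statistics for comparing embeddings.

Accuracy of an approximate embedding is measured against a reference by the
Pearson correlation of the two all-pairs Euclidean distance vectors: a value
near 1 means the approximation preserves the same inter-object geometry.
Two further summaries characterize a distance distribution itself:

* PMSC, Pearson's median skewness coefficient, ``3 * (mean - median) / sd``
  — asymmetry of the distribution;
* CV, coefficient of variation, ``sd / mean`` — normalized dispersion.

Both use the sample standard deviation (``ddof=1``) and accept any numeric
vector, the canonical input being the pairwise-distance vector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist

from .core_mds import Embedding
from .errors import NumericError, ValidationError


@dataclass
class AccuracyReport:
    """Summary emitted by the ``evaluate`` front end."""

    pearson_r: float
    n_pairs: int
    pmsc: float
    cv: float


def pairwise_distance_vector(e: Embedding) -> np.ndarray:
    """Euclidean distances of all unordered pairs, lexicographic (i < j) order."""
    if e.n < 2:
        raise ValidationError(f"need at least 2 objects, got n={e.n}")
    return pdist(e.coords)


def distance_correlation(
    a: Embedding,
    b: Embedding,
    *,
    max_pairs: int | None = None,
    seed: int = 0,
) -> float:
    """Pearson correlation of the pairwise-distance vectors of ``a`` and ``b``.

    Rows of ``b`` are re-aligned to ``a``'s id order before pairing, so the
    statistic is independent of row order and invariant under rigid
    transforms of either embedding. ``max_pairs`` enables seeded subsampling
    of pairs for very large ``n`` (off by default).
    """
    if sorted(a.ids) != sorted(b.ids):
        raise ValidationError("embeddings have different object ids")
    pos_b = {obj: k for k, obj in enumerate(b.ids)}
    order = [pos_b[obj] for obj in a.ids]
    va = pairwise_distance_vector(a)
    vb = pairwise_distance_vector(Embedding(coords=b.coords[order], ids=a.ids))
    if max_pairs is not None and len(va) > max_pairs:
        idx = np.random.default_rng(seed).choice(len(va), size=max_pairs, replace=False)
        va, vb = va[idx], vb[idx]
    if np.std(va) == 0 or np.std(vb) == 0:
        raise NumericError("correlation undefined: a distance vector has zero variance")
    return float(np.corrcoef(va, vb)[0, 1])


def pmsc(x: np.ndarray) -> float:
    """Pearson's median skewness coefficient, ``3 * (mean - median) / sd``."""
    x = np.asarray(x, dtype=np.float64)
    if x.size < 2:
        raise ValidationError(f"need at least 2 values, got {x.size}")
    sd = float(np.std(x, ddof=1))
    if sd == 0:
        raise NumericError("PMSC undefined: zero standard deviation")
    return float(3.0 * (np.mean(x) - np.median(x)) / sd)


def cv(x: np.ndarray) -> float:
    """Coefficient of variation, ``sd / mean`` (sample standard deviation)."""
    x = np.asarray(x, dtype=np.float64)
    if x.size < 2:
        raise ValidationError(f"need at least 2 values, got {x.size}")
    mean = float(np.mean(x))
    if mean == 0:
        raise NumericError("CV undefined: zero mean")
    return float(np.std(x, ddof=1) / mean)


def accuracy_report(a: Embedding, b: Embedding, distances: np.ndarray | None = None,
                    **corr_kwargs) -> AccuracyReport:
    """Correlation between two embeddings plus PMSC/CV of a distance vector.

    PMSC and CV are computed on ``distances`` when given (e.g. the original
    dissimilarities), otherwise on ``a``'s pairwise-distance vector.
    """
    r = distance_correlation(a, b, **corr_kwargs)
    vec = np.asarray(distances, dtype=np.float64).ravel() if distances is not None \
        else pairwise_distance_vector(a)
    return AccuracyReport(
        pearson_r=r,
        n_pairs=a.n * (a.n - 1) // 2,
        pmsc=pmsc(vec),
        cv=cv(vec),
    )
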