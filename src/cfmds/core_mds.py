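"""Exact classical (Torgerson) multidimensional scaling.

Classical MDS turns an ``n x n`` dissimilarity matrix ``D`` into ``m``-dimensional
coordinates whose pairwise Euclidean distances approximate ``D`` as well as a
rank-``m`` inner-product model can. The pipeline is the textbook one:

1. square the dissimilarities elementwise, ``D2 = [d_ij**2]``;
2. double-center with ``J = I - n**-1 * 1`` to obtain the Gram matrix
   ``B = -1/2 * J @ D2 @ J``;
3. take the ``m`` algebraically largest eigenpairs of ``B``;
4. scale each eigenvector by the square root of its eigenvalue.

When ``D`` is exactly the Euclidean distance matrix of points in ``R^m`` the
procedure recovers those points up to rotation, reflection and translation.
Negative eigenvalues (non-Euclidean dissimilarities) are clamped to zero with
a warning, the standard Torgerson practice.

All numerics are double precision.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .errors import MdsWarning, NumericError, ParameterError, ValidationError

#: Relative tolerance under which a matrix is accepted as symmetric
#: (and silently symmetrized as (D + D.T) / 2).
SYMMETRY_RTOL = 1e-8


def _default_ids(n: int) -> tuple[str, ...]:
    return tuple(f"obj_{i}" for i in range(n))


@dataclass
class DissimilarityMatrix:
    """A validated square, symmetric, nonnegative, zero-diagonal matrix.

    Parameters
    ----------
    values
        ``n x n`` array of pairwise dissimilarities (unitless).
    ids
        Ordered object identifiers; defaults to ``obj_0 .. obj_{n-1}``.
    """

    values: np.ndarray
    ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValidationError(
                f"dissimilarity matrix must be square, got shape {v.shape}"
            )
        n = v.shape[0]
        if n < 2:
            raise ValidationError(f"need at least 2 objects, got n={n}")
        if not np.all(np.isfinite(v)):
            i, j = np.argwhere(~np.isfinite(v))[0]
            raise ValidationError(f"non-finite entry at ({i}, {j})")
        scale = max(1.0, float(np.abs(v).max()))
        asym = np.abs(v - v.T)
        if asym.max() > SYMMETRY_RTOL * scale:
            i, j = np.unravel_index(np.argmax(asym), asym.shape)
            raise ValidationError(
                f"matrix is asymmetric beyond tolerance: entry ({i}, {j})="
                f"{v[i, j]!r} but ({j}, {i})={v[j, i]!r}"
            )
        v = (v + v.T) / 2.0
        diag = np.abs(np.diag(v))
        if diag.max() > SYMMETRY_RTOL * scale:
            i = int(np.argmax(diag))
            raise ValidationError(f"diagonal entry ({i}, {i})={v[i, i]!r} is not zero")
        np.fill_diagonal(v, 0.0)
        if v.min() < 0:
            i, j = np.argwhere(v < 0)[0]
            raise ValidationError(f"negative dissimilarity at ({i}, {j})={v[i, j]!r}")
        self.values = v
        if not self.ids:
            self.ids = _default_ids(n)
        else:
            self.ids = tuple(str(x) for x in self.ids)
            if len(self.ids) != n:
                raise ValidationError(
                    f"{len(self.ids)} ids for a {n}x{n} matrix"
                )

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def submatrix(self, indices) -> "DissimilarityMatrix":
        """Principal submatrix restricted to ``indices`` (order preserved)."""
        idx = np.asarray(indices, dtype=np.intp)
        return DissimilarityMatrix(
            self.values[np.ix_(idx, idx)], tuple(self.ids[i] for i in idx)
        )


@dataclass
class GramMatrix:
    """Double-centered squared dissimilarities (inner-product matrix ``B``)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValidationError(f"Gram matrix must be square, got shape {v.shape}")
        n = v.shape[0]
        tol = 1e-6 * n * max(1.0, float(np.abs(v).max()))
        if np.abs(v.sum(axis=0)).max() > tol or np.abs(v.sum(axis=1)).max() > tol:
            raise ValidationError("Gram matrix rows/columns do not sum to zero")
        self.values = (v + v.T) / 2.0

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class EigenSpectrum:
    """Top eigenpairs of a Gram matrix, eigenvalues non-increasing."""

    eigenvalues: np.ndarray  # shape (m,), descending
    eigenvectors: np.ndarray  # shape (n, m), unit-norm columns

    @property
    def n_positive(self) -> int:
        return int(np.sum(self.eigenvalues > 0))


@dataclass
class Embedding:
    """``n x m`` coordinates with object ids.

    ``eigenvalues`` is populated when the embedding comes straight out of
    classical MDS and is ``None`` for transformed embeddings. ``meta`` carries
    run metadata (partition plan, warnings, residuals) for pipeline outputs.
    """

    coords: np.ndarray
    ids: tuple[str, ...] = ()
    eigenvalues: np.ndarray | None = None
    meta: dict | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        c = np.asarray(self.coords, dtype=np.float64)
        if c.ndim != 2:
            raise ValidationError(f"coordinates must be 2-D, got shape {c.shape}")
        if c.shape[1] < 1:
            raise ValidationError("embedding dimension m must be >= 1")
        self.coords = c
        if not self.ids:
            self.ids = _default_ids(c.shape[0])
        else:
            self.ids = tuple(str(x) for x in self.ids)
            if len(self.ids) != c.shape[0]:
                raise ValidationError(
                    f"{len(self.ids)} ids for {c.shape[0]} coordinate rows"
                )

    @property
    def n(self) -> int:
        return self.coords.shape[0]

    @property
    def dim(self) -> int:
        return self.coords.shape[1]


def square_elements(D: DissimilarityMatrix) -> np.ndarray:
    """Elementwise square of the dissimilarities, ``D2[i, j] = d_ij**2``."""
    return D.values**2


def double_center(D2: np.ndarray) -> GramMatrix:
    """Double-center squared dissimilarities: ``B = -1/2 * J @ D2 @ J``.

    ``J = I - n**-1 * 1`` is the centering matrix (``1`` is the all-ones
    matrix). Implemented by subtracting row means, column means and adding
    the grand mean, which is algebraically identical and avoids forming J.
    """
    D2 = np.asarray(D2, dtype=np.float64)
    if D2.ndim != 2 or D2.shape[0] != D2.shape[1]:
        raise ValidationError(f"squared matrix must be square, got shape {D2.shape}")
    row = D2.mean(axis=1, keepdims=True)
    col = D2.mean(axis=0, keepdims=True)
    grand = D2.mean()
    B = -0.5 * (D2 - row - col + grand)
    return GramMatrix(B)


def _canonicalize_signs(vectors: np.ndarray) -> np.ndarray:
    """Flip each column so its largest-magnitude entry is positive.

    Makes eigenvector output reproducible across linear-algebra backends;
    ties in magnitude resolve to the smallest row index.
    """
    out = vectors.copy()
    for k in range(out.shape[1]):
        pivot = int(np.argmax(np.abs(out[:, k])))
        if out[pivot, k] < 0:
            out[:, k] = -out[:, k]
    return out


def top_eigenpairs(B: GramMatrix, m: int) -> EigenSpectrum:
    """The ``m`` algebraically largest eigenpairs of ``B``, descending.

    Emits an :class:`~cfmds.errors.MdsWarning` when fewer than ``m`` of the
    returned eigenvalues are positive (non-Euclidean input or m too large).
    """
    n = B.n
    if not 1 <= m <= n:
        raise ParameterError(f"m={m} must satisfy 1 <= m <= n={n}")
    vals, vecs = scipy.linalg.eigh(B.values, subset_by_index=[n - m, n - 1])
    order = np.argsort(vals)[::-1]  # eigh returns ascending
    vals = vals[order]
    vecs = _canonicalize_signs(vecs[:, order])
    if np.any(vals <= 0):
        warnings.warn(
            f"only {int(np.sum(vals > 0))} of the top {m} eigenvalues are "
            "positive; the input is not exactly embeddable in m dimensions",
            MdsWarning,
            stacklevel=2,
        )
    return EigenSpectrum(eigenvalues=vals, eigenvectors=vecs)


def classical_mds(D: DissimilarityMatrix, m: int = 2) -> Embedding:
    """One-shot classical MDS of ``D`` into ``m`` dimensions.

    Coordinates are ``e_k * sqrt(lambda_k)`` for the top-``m`` eigenpairs of
    the double-centered Gram matrix. Negative eigenvalues among the top ``m``
    are clamped to zero (their coordinate columns are zero) with a warning.

    Raises
    ------
    ParameterError
        If ``m`` is outside ``[1, n - 1]``.
    NumericError
        If no positive eigenvalue exists (e.g. the zero matrix).
    """
    n = D.n
    if not 1 <= m <= n - 1:
        raise ParameterError(f"m={m} must satisfy 1 <= m <= n-1={n - 1}")
    spectrum = top_eigenpairs(double_center(square_elements(D)), m)
    vals = spectrum.eigenvalues
    if np.all(vals <= 0):
        raise NumericError(
            "no positive spectrum: all top-m eigenvalues are <= 0, "
            "the dissimilarities admit no classical MDS embedding"
        )
    clamped = np.maximum(vals, 0.0)
    coords = spectrum.eigenvectors * np.sqrt(clamped)
    return Embedding(coords=coords, ids=D.ids, eigenvalues=clamped)
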