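"""Shared fixtures and independent brute-force oracles."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

from cfmds import DissimilarityMatrix


def brute_force_classical_mds(D: np.ndarray, m: int) -> np.ndarray:
    """Independent reference: explicit centering matrix + full eigh.

    Deliberately built straight from the defining matrix formulas (forming J
    explicitly, full eigendecomposition) rather than sharing any code path
    with the implementation under test.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    D2 = D**2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    w, V = np.linalg.eigh(B)
    idx = np.argsort(w)[::-1][:m]
    lam = np.clip(w[idx], 0.0, None)
    return V[:, idx] * np.sqrt(lam)


def check_maxmin_greedy(D: np.ndarray, subset: list, selection: list) -> None:
    """Verify a MaxMin selection step by step against exhaustive search.

    Independent of the seeded first draw: accepts whatever first point the
    selection starts with and checks every subsequent pick maximizes the
    minimum distance to the already-chosen set, ties to smallest index.
    """
    assert selection[0] in subset
    chosen = [selection[0]]
    for pick in selection[1:]:
        unused = [g for g in subset if g not in chosen]
        gains = {g: min(D[g, c] for c in chosen) for g in unused}
        best = max(gains.values())
        winners = sorted(g for g, v in gains.items() if v == best)
        assert pick == winners[0], (
            f"pick {pick} but exhaustive search expects {winners[0]}"
        )
        chosen.append(pick)


def random_point_matrix(n: int, dim: int, seed: int):
    """Points in R^dim and their exact Euclidean DissimilarityMatrix."""
    pts = np.random.default_rng(seed).standard_normal((n, dim))
    return pts, DissimilarityMatrix(squareform(pdist(pts)))


@pytest.fixture
def small_matrix():
    """A fixed valid 4x4 dissimilarity matrix from 2-D points."""
    _, D = random_point_matrix(4, 2, seed=42)
    return D
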