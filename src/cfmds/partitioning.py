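"""Random decomposition into subsets and anchor sampling.

The divide-and-conquer mode first assigns the ``n`` objects at random to
``p`` near-equal subsets (the induced principal submatrices are the diagonal
blocks ``D_1 .. D_p``), then samples ``s`` anchor objects from each subset.
Pooling the anchors yields the ``(s*p) x (s*p)`` alignment matrix ``M_align``
whose embedding later serves as the common frame the per-block embeddings
are stitched into.

Two sampling strategies are provided:

* ``random`` — uniform sampling without replacement;
* ``maxmin`` — greedy farthest-point selection: after a seeded uniform first
  pick, each new anchor maximizes, over all unused subset members, the
  minimum dissimilarity to the anchors already chosen. MaxMin favours
  anchors that are far apart, which helps on skewed or dispersed data.

One user-facing seed drives everything through independent derived streams
(numpy ``SeedSequence`` spawn keys), so switching the sampling strategy does
not perturb the partition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_mds import DissimilarityMatrix
from .errors import ParameterError, ValidationError

# spawn-key tags for the independent random streams derived from one seed
_PARTITION_STREAM = 0
_SAMPLING_STREAM = 1


def _rng(seed: int, *tags: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=tags))


def subset_seed(seed: int, subset_index: int) -> int:
    """Deterministic per-subset sampling seed derived from the shared seed."""
    ss = np.random.SeedSequence(int(seed), spawn_key=(_SAMPLING_STREAM, subset_index))
    return int(ss.generate_state(1, np.uint32)[0]) & 0x7FFFFFFF


@dataclass
class PartitionPlan:
    """Mode decision plus the partition and sampling parameters.

    ``subsets`` are disjoint ordered lists of global object indices covering
    ``0 .. n-1``; sizes differ by at most one (larger subsets first).
    """

    mode: str  # "one_shot" | "divide_and_conquer"
    p: int
    subsets: list[list[int]]
    s: int
    sampling: str  # "random" | "maxmin"
    seed: int

    def __post_init__(self) -> None:
        if self.mode not in ("one_shot", "divide_and_conquer"):
            raise ParameterError(f"unknown mode {self.mode!r}")
        if self.sampling not in ("random", "maxmin"):
            raise ParameterError(f"unknown sampling {self.sampling!r}")
        sizes = [len(sub) for sub in self.subsets]
        if len(sizes) != self.p:
            raise ParameterError(f"plan has {len(sizes)} subsets but p={self.p}")
        if self.mode == "divide_and_conquer":
            if max(sizes) - min(sizes) > 1:
                raise ParameterError("subset sizes must differ by at most 1")
            if not 1 <= self.s <= min(sizes):
                raise ParameterError(
                    f"s={self.s} must satisfy 1 <= s <= min subset size {min(sizes)}"
                )
        flat = sorted(i for sub in self.subsets for i in sub)
        if flat != list(range(len(flat))):
            raise ParameterError("subsets must partition 0..n-1 without overlap")

    @property
    def n(self) -> int:
        return sum(len(sub) for sub in self.subsets)

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "p": self.p,
            "s": self.s,
            "sampling": self.sampling,
            "seed": self.seed,
            "subset_sizes": [len(sub) for sub in self.subsets],
        }


@dataclass
class AnchorSet:
    """Per-subset anchor indices and the pooled alignment matrix."""

    anchor_indices: list[list[int]]
    m_align: DissimilarityMatrix = field(repr=False)


def random_partition(n: int, p: int, seed: int) -> list[list[int]]:
    """Randomly split ``0..n-1`` into ``p`` near-equal ordered subsets.

    A seeded uniform permutation is cut into contiguous chunks of size
    ``ceil(n/p)`` or ``floor(n/p)`` (larger chunks first). Deterministic
    given ``seed``.
    """
    if not 1 <= p <= n:
        raise ParameterError(f"p={p} must satisfy 1 <= p <= n={n}")
    perm = _rng(seed, _PARTITION_STREAM).permutation(n)
    base, rem = divmod(n, p)
    subsets: list[list[int]] = []
    start = 0
    for i in range(p):
        size = base + (1 if i < rem else 0)
        subsets.append([int(x) for x in perm[start : start + size]])
        start += size
    return subsets


def sample_random(subset: list[int], s: int, seed: int) -> list[int]:
    """Uniform sample of ``s`` distinct members of ``subset``, seeded."""
    if not 1 <= s <= len(subset):
        raise ParameterError(f"s={s} must satisfy 1 <= s <= |subset|={len(subset)}")
    picks = _rng(seed, _SAMPLING_STREAM).choice(len(subset), size=s, replace=False)
    return [subset[int(i)] for i in picks]


def sample_maxmin(
    D: DissimilarityMatrix, subset: list[int], s: int, seed: int
) -> list[int]:
    """Greedy farthest-point (MaxMin) sample of ``s`` members of ``subset``.

    The first anchor is a seeded uniform draw; every later anchor is the
    unused subset member whose minimum dissimilarity to the already-chosen
    anchors is largest. Ties break toward the smallest global index, making
    the output deterministic given the seed.
    """
    if not 1 <= s <= len(subset):
        raise ParameterError(f"s={s} must satisfy 1 <= s <= |subset|={len(subset)}")
    members = np.asarray(subset, dtype=np.intp)
    first = int(_rng(seed, _SAMPLING_STREAM).integers(len(members)))
    chosen_local = [first]
    used = np.zeros(len(members), dtype=bool)
    used[first] = True
    # min dissimilarity from each member to the chosen set so far
    mindist = D.values[members, members[first]].copy()
    for _ in range(1, s):
        masked = np.where(used, -np.inf, mindist)
        best = masked.max()
        ties = np.flatnonzero(masked == best)
        nxt = int(ties[np.argmin(members[ties])])  # smallest global index wins
        chosen_local.append(nxt)
        used[nxt] = True
        np.minimum(mindist, D.values[members, members[nxt]], out=mindist)
    return [int(members[i]) for i in chosen_local]


def build_alignment_matrix(
    D: DissimilarityMatrix, anchors: list[list[int]]
) -> AnchorSet:
    """Pool per-subset anchors into the ``(s*p) x (s*p)`` matrix ``M_align``.

    Rows and columns follow the concatenation of the anchor lists in subset
    order, so block ``i`` of ``M_align`` is the anchor submatrix of ``D_i``.
    """
    pooled = [i for sub in anchors for i in sub]
    if len(set(pooled)) != len(pooled):
        seen: set[int] = set()
        dup = next(i for i in pooled if i in seen or seen.add(i))
        raise ValidationError(f"anchor index {dup} appears in more than one list")
    m_align = D.submatrix(pooled)
    return AnchorSet(anchor_indices=[list(sub) for sub in anchors], m_align=m_align)
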