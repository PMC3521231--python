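"""Divide-and-conquer MDS: per-block embedding, alignment and combination.

Each diagonal block ``D_i`` of the partitioned dissimilarity matrix is
embedded independently with classical MDS (``dMDS_i``), and the pooled
anchor matrix ``M_align`` is embedded once (``mMDS``). Because every block
embedding lives in its own arbitrary rotation/reflection/translation of the
reduced space, the anchors shared between ``dMDS_i`` and ``mMDS`` are used
to fit a least-squares map ``A_i`` from the block frame onto the common
anchor frame; applying ``A_i`` to all of ``dMDS_i`` gives ``newdMDS_i``,
and concatenating the transformed blocks (restored to the original object
order) yields the approximate global embedding.

The map is affine by default: each block embedding is centered on its own
subset centroid while the anchor embedding is centered on the pooled anchor
centroid, so a translation component is required for the frames to match
exactly. ``linear_only=True`` drops the translation and fits a pure linear
map (the literal least-squares formulation), which is retained as an option.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core_mds import DissimilarityMatrix, Embedding, classical_mds
from .errors import MdsWarning, ParameterError, ValidationError
from .partitioning import (
    AnchorSet,
    PartitionPlan,
    build_alignment_matrix,
    random_partition,
    sample_maxmin,
    sample_random,
    subset_seed,
)

#: Default number of anchors sampled per subset when none is requested;
#: matches the settings used for genome-scale matrices.
DEFAULT_S = 100


@dataclass
class MemoryBudget:
    """Largest number of objects the one-shot path may process at once.

    Stands in for automatic device-memory detection: ``n <= max_objects``
    runs one-shot, anything larger is divided. Both the block size and the
    pooled anchor matrix are kept within the same cap.
    """

    max_objects: int

    def __post_init__(self) -> None:
        if self.max_objects < 2:
            raise ParameterError(f"max_objects={self.max_objects} must be >= 2")


@dataclass
class AlignmentTransform:
    """Affine map ``x -> linear @ x + translation`` on coordinate rows."""

    linear: np.ndarray  # (m, m), acts on column coordinate vectors
    translation: np.ndarray  # (m,), zero in linear-only mode

    def __post_init__(self) -> None:
        self.linear = np.asarray(self.linear, dtype=np.float64)
        self.translation = np.asarray(self.translation, dtype=np.float64)
        m = self.linear.shape[0]
        if self.linear.shape != (m, m) or self.translation.shape != (m,):
            raise ValidationError(
                f"inconsistent transform shapes {self.linear.shape} / "
                f"{self.translation.shape}"
            )
        if not (np.all(np.isfinite(self.linear)) and np.all(np.isfinite(self.translation))):
            raise ValidationError("transform has non-finite entries")


def choose_plan(
    n: int,
    budget: MemoryBudget,
    *,
    p: int | None = None,
    s: int | None = None,
    sampling: str = "random",
    seed: int = 0,
    default_s: int = DEFAULT_S,
) -> PartitionPlan:
    """Pick the operating mode and the partition/sampling parameters.

    Without overrides: one-shot whenever ``n <= max_objects``; otherwise the
    number of subsets starts at ``ceil(n / max_objects)`` and grows until
    both the block size ``ceil(n/p)`` and the pooled anchor count ``s*p``
    fit the budget, with ``s = min(default_s, floor(n/p))``. Explicit ``p``
    or ``s`` overrides force divide-and-conquer and win over auto-derivation.
    """
    if n < 2:
        raise ParameterError(f"need at least 2 objects, got n={n}")
    if p is None and s is None and n <= budget.max_objects:
        return PartitionPlan(
            mode="one_shot",
            p=1,
            subsets=[list(range(n))],
            s=n,
            sampling=sampling,
            seed=seed,
        )
    if p is not None:
        if not 1 <= p <= n:
            raise ParameterError(f"p={p} must satisfy 1 <= p <= n={n}")
        s_eff = s if s is not None else min(default_s, n // p)
        if not 1 <= s_eff <= n // p:
            raise ParameterError(
                f"s={s_eff} must satisfy 1 <= s <= floor(n/p)={n // p}"
            )
        p_eff = p
    else:
        p_eff = max(1, -(-n // budget.max_objects))  # ceil
        while True:
            s_eff = s if s is not None else min(default_s, n // p_eff)
            if s_eff > n // p_eff:
                raise ParameterError(
                    f"s={s_eff} exceeds floor(n/p)={n // p_eff} at p={p_eff}"
                )
            if -(-n // p_eff) <= budget.max_objects and s_eff * p_eff <= budget.max_objects:
                break
            if p_eff >= n:
                raise ParameterError(
                    f"no divide-and-conquer plan fits max_objects="
                    f"{budget.max_objects} for n={n}; raise the budget"
                )
            p_eff += 1
    return PartitionPlan(
        mode="divide_and_conquer",
        p=p_eff,
        subsets=random_partition(n, p_eff, seed),
        s=s_eff,
        sampling=sampling,
        seed=seed,
    )


def solve_alignment(
    source: Embedding,
    target: Embedding,
    *,
    affine: bool = True,
    residual_warn: float | None = None,
) -> AlignmentTransform:
    """Least-squares map taking ``source`` anchor coordinates onto ``target``.

    Minimizes the Frobenius norm of ``transform(source) - target``. With
    ``affine=True`` the source is augmented with a constant component so a
    translation is fitted jointly; otherwise the map is purely linear. Rank
    deficiency yields the minimum-norm solution. If ``residual_warn`` is
    given, a warning is emitted when the RMS residual per anchor exceeds it.
    """
    if source.coords.shape != target.coords.shape:
        raise ValidationError(
            f"shape mismatch: source {source.coords.shape} vs "
            f"target {target.coords.shape}"
        )
    s, m = source.coords.shape
    A = source.coords
    if affine:
        A = np.hstack([A, np.ones((s, 1))])
    W, _, _, _ = np.linalg.lstsq(A, target.coords, rcond=None)
    linear = W[:m].T
    translation = W[m] if affine else np.zeros(m)
    if residual_warn is not None:
        rms = float(np.sqrt(np.mean((A @ W - target.coords) ** 2)))
        if rms > residual_warn:
            warnings.warn(
                f"alignment RMS residual {rms:.3g} exceeds {residual_warn:.3g}",
                MdsWarning,
                stacklevel=2,
            )
    return AlignmentTransform(linear=linear, translation=translation)


def apply_transform(t: AlignmentTransform, e: Embedding) -> Embedding:
    """Map every coordinate row by the linear part, then translate."""
    if e.dim != t.linear.shape[0]:
        raise ValidationError(
            f"transform is {t.linear.shape[0]}-D but embedding is {e.dim}-D"
        )
    return Embedding(coords=e.coords @ t.linear.T + t.translation, ids=e.ids)


def _alignment_rms(t: AlignmentTransform, source: Embedding, target: Embedding) -> float:
    fitted = source.coords @ t.linear.T + t.translation
    return float(np.sqrt(np.mean((fitted - target.coords) ** 2)))


def dnc_mds(
    D: DissimilarityMatrix,
    m: int,
    plan: PartitionPlan,
    *,
    linear_only: bool = False,
) -> Embedding:
    """Divide-and-conquer classical MDS following ``plan``.

    Runs partition -> anchor sampling -> per-block classical MDS -> MDS of
    ``M_align`` -> per-block least-squares alignment -> transformation ->
    combination, restoring the original object order. A plan in one-shot
    mode delegates to :func:`~cfmds.core_mds.classical_mds`. The returned
    embedding's ``meta`` records the plan, alignment residuals and any
    warnings raised along the way.
    """
    if plan.n != D.n:
        raise ParameterError(f"plan covers {plan.n} objects but D has {D.n}")
    meta: dict = {"plan": plan.to_dict(), "m": m, "linear_only": bool(linear_only)}
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", MdsWarning)
        if plan.mode == "one_shot":
            result = classical_mds(D, m)
            out = Embedding(coords=result.coords, ids=result.ids,
                            eigenvalues=result.eigenvalues)
        else:
            out = _dnc_run(D, m, plan, linear_only, meta)
    meta["warnings"] = [str(w.message) for w in caught]
    out.meta = meta
    return out


def _dnc_run(
    D: DissimilarityMatrix,
    m: int,
    plan: PartitionPlan,
    linear_only: bool,
    meta: dict,
) -> Embedding:
    for i, sub in enumerate(plan.subsets):
        if len(sub) < m + 1:
            raise ParameterError(
                f"subset {i} has {len(sub)} objects but m={m} needs at least "
                f"{m + 1}; use a smaller m or fewer partitions"
            )
    anchors: list[list[int]] = []
    for i, sub in enumerate(plan.subsets):
        seed_i = subset_seed(plan.seed, i)
        if plan.sampling == "random":
            anchors.append(sample_random(sub, plan.s, seed_i))
        else:
            anchors.append(sample_maxmin(D, sub, plan.s, seed_i))
    anchor_set: AnchorSet = build_alignment_matrix(D, anchors)

    mmds = classical_mds(anchor_set.m_align, m)  # common anchor frame
    block_coords = np.empty((D.n, m))
    residuals: list[float] = []
    offset = 0
    for i, sub in enumerate(plan.subsets):
        dmds_i = classical_mds(D.submatrix(sub), m)
        local_pos = {g: k for k, g in enumerate(sub)}
        sub_rows = [local_pos[g] for g in anchors[i]]
        sub_dmds = Embedding(
            coords=dmds_i.coords[sub_rows],
            ids=tuple(dmds_i.ids[r] for r in sub_rows),
        )
        mmds_i = Embedding(
            coords=mmds.coords[offset : offset + plan.s],
            ids=mmds.ids[offset : offset + plan.s],
        )
        offset += plan.s
        t = solve_alignment(sub_dmds, mmds_i, affine=not linear_only)
        residuals.append(_alignment_rms(t, sub_dmds, mmds_i))
        block_coords[np.asarray(sub, dtype=np.intp)] = (
            dmds_i.coords @ t.linear.T + t.translation
        )
    meta["alignment_rms"] = residuals
    return Embedding(coords=block_coords, ids=D.ids)
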