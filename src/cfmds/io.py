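"""Delimited-text readers/writers and the end-to-end pipeline.

All on-disk formats are plain delimited text (TSV/CSV/whitespace):

* dissimilarity matrices — optional header row and id column;
* feature tables — rows are objects, columns numeric features;
* coordinates — ``id`` column plus ``dim_1 .. dim_m``, written with 17
  significant digits so a write/read round trip is bit-identical.

``run_pipeline`` glues everything together: read, optionally convert
features to distances, choose the operating mode against the memory budget,
embed, write coordinates and a YAML metadata sidecar.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import yaml

from .core_mds import DissimilarityMatrix, Embedding
from .errors import CfmdsError, ParameterError, ValidationError
from .metrics import cv as _cv, pmsc as _pmsc
from .stitching import DEFAULT_S, MemoryBudget, choose_plan, dnc_mds
from .synthetic import features_to_distances

log = logging.getLogger("cfmds")


class IOFailure(CfmdsError):
    exit_code = 4


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def _sniff_delimiter(line: str) -> str | None:
    if "\t" in line:
        return "\t"
    if "," in line:
        return ","
    return None  # any whitespace


def _load_rows(path, delimiter: str | None) -> list[list[str]]:
    try:
        text = Path(path).read_text()
    except OSError as exc:
        raise IOFailure(f"cannot read {path}: {exc}") from exc
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ValidationError(f"{path} is empty")
    delim = delimiter or _sniff_delimiter(lines[0])
    return [
        [tok.strip() for tok in (ln.split(delim) if delim else ln.split())]
        for ln in lines
    ]


def _split_table(
    rows: list[list[str]], header: bool | None
) -> tuple[list[str] | None, list[str] | None, list[list[str]]]:
    """Separate optional header row and id column from the numeric body."""
    if header is None:
        # probe tokens after the first: a non-numeric leading token alone
        # indicates an id column, not a header row
        probe = rows[0][1:] if len(rows[0]) > 1 else rows[0]
        header = not all(_is_number(t) for t in probe)
    col_names = rows[0] if header else None
    body = rows[1:] if header else rows
    if not body:
        raise ValidationError("no data rows after header")
    has_id_col = any(not _is_number(r[0]) for r in body)
    row_ids = [r[0] for r in body] if has_id_col else None
    if has_id_col:
        body = [r[1:] for r in body]
        if col_names is not None and len(col_names) == len(body[0]) + 1:
            col_names = col_names[1:]
    return col_names, row_ids, body


def _to_array(body: list[list[str]], what: str) -> np.ndarray:
    width = len(body[0])
    for i, r in enumerate(body):
        if len(r) != width:
            raise ValidationError(
                f"{what}: row {i} has {len(r)} columns, expected {width}"
            )
        for j, tok in enumerate(r):
            if not _is_number(tok):
                raise ValidationError(
                    f"{what}: non-numeric value {tok!r} at row {i}, column {j}"
                )
    return np.array([[float(t) for t in r] for r in body], dtype=np.float64)


def read_matrix(
    path, delimiter: str | None = None, header: bool | None = None
) -> DissimilarityMatrix:
    """Read and validate a square dissimilarity matrix.

    Object ids come from the header row when present, else the id column,
    else ``obj_0 .. obj_{n-1}``. Delimiter is auto-detected (tab, comma,
    whitespace) unless given; ``header=None`` auto-detects a header row.
    """
    col_names, row_ids, body = _split_table(_load_rows(path, delimiter), header)
    values = _to_array(body, f"matrix {path}")
    ids = tuple(col_names) if col_names else tuple(row_ids) if row_ids else ()
    return DissimilarityMatrix(values, ids)


def read_features(
    path, delimiter: str | None = None, header: bool | None = None
) -> tuple[np.ndarray, tuple[str, ...]]:
    """Read an objects x features numeric table; returns (array, row ids)."""
    _, row_ids, body = _split_table(_load_rows(path, delimiter), header)
    X = _to_array(body, f"feature table {path}")
    ids = tuple(row_ids) if row_ids else tuple(f"obj_{i}" for i in range(len(X)))
    return X, ids


def write_matrix(D: DissimilarityMatrix, path, delimiter: str = "\t") -> None:
    with open(path, "w") as fh:
        fh.write(delimiter.join(D.ids) + "\n")
        for row in D.values:
            fh.write(delimiter.join(f"{x:.17g}" for x in row) + "\n")


def write_features(X: np.ndarray, ids, path, delimiter: str = "\t") -> None:
    with open(path, "w") as fh:
        fh.write(delimiter.join(["id"] + [f"f_{j}" for j in range(X.shape[1])]) + "\n")
        for obj, row in zip(ids, X):
            fh.write(delimiter.join([str(obj)] + [f"{x:.17g}" for x in row]) + "\n")


def write_embedding(e: Embedding, path, delimiter: str = "\t") -> None:
    """Write coordinates as ``id dim_1 .. dim_m`` delimited text."""
    if e.n == 0:
        raise ValidationError("refusing to write an empty embedding")
    try:
        with open(path, "w") as fh:
            header = ["id"] + [f"dim_{k + 1}" for k in range(e.dim)]
            fh.write(delimiter.join(header) + "\n")
            for obj, row in zip(e.ids, e.coords):
                fh.write(delimiter.join([str(obj)] + [f"{x:.17g}" for x in row]) + "\n")
    except OSError as exc:
        raise IOFailure(f"cannot write {path}: {exc}") from exc


def read_embedding(path, delimiter: str | None = None) -> Embedding:
    """Read coordinates written by :func:`write_embedding` (or compatible)."""
    _, row_ids, body = _split_table(_load_rows(path, delimiter), None)
    coords = _to_array(body, f"coordinates {path}")
    ids = tuple(row_ids) if row_ids else ()
    return Embedding(coords=coords, ids=ids)


@dataclass
class RunConfig:
    """Everything needed to reproduce an ``embed`` run."""

    input_path: str
    output_path: str
    input_type: str = "distances"  # "distances" | "features"
    metric: str = "euclidean"
    dims: int = 2
    mode: str = "auto"  # "auto" | "oneshot" | "dnc"
    p: int | None = None
    s: int | None = None
    sampling: str = "random"
    linear_only: bool = False
    max_objects: int = 5000
    seed: int = 0
    delimiter: str | None = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.input_type not in ("distances", "features"):
            raise ParameterError(f"unknown input_type {self.input_type!r}")
        if self.mode not in ("auto", "oneshot", "dnc"):
            raise ParameterError(f"unknown mode {self.mode!r}")


def _distance_summary(e: Embedding, max_pairs: int = 100_000, seed: int = 0) -> dict:
    """PMSC/CV of the embedded distances, pair-subsampled for large n."""
    n = e.n
    if n * (n - 1) // 2 <= max_pairs:
        from .metrics import pairwise_distance_vector

        vec = pairwise_distance_vector(e)
    else:
        rng = np.random.default_rng(seed)
        i = rng.integers(0, n, size=max_pairs)
        j = rng.integers(0, n - 1, size=max_pairs)
        j = np.where(j >= i, j + 1, j)  # exclude self-pairs
        vec = np.linalg.norm(e.coords[i] - e.coords[j], axis=1)
    return {"pmsc": _pmsc(vec), "cv": _cv(vec)}


def run_pipeline(cfg: RunConfig) -> Embedding:
    """Read -> (features -> distances) -> plan -> embed -> write + sidecar."""
    logging.basicConfig(level=cfg.log_level, format="%(levelname)s %(message)s")
    if cfg.input_type == "features":
        X, ids = read_features(cfg.input_path, cfg.delimiter)
        D = features_to_distances(X, cfg.metric, ids)
    else:
        D = read_matrix(cfg.input_path, cfg.delimiter)
    budget = MemoryBudget(cfg.max_objects)
    if cfg.mode == "oneshot":
        plan = choose_plan(D.n, MemoryBudget(max(D.n, 2)), sampling=cfg.sampling,
                           seed=cfg.seed)
    elif cfg.mode == "dnc":
        p = cfg.p if cfg.p is not None else max(2, -(-D.n // cfg.max_objects))
        plan = choose_plan(D.n, budget, p=p, s=cfg.s, sampling=cfg.sampling,
                           seed=cfg.seed)
    else:
        plan = choose_plan(D.n, budget, p=cfg.p, s=cfg.s, sampling=cfg.sampling,
                           seed=cfg.seed)
    log.info("plan: mode=%s p=%d s=%d sampling=%s", plan.mode, plan.p, plan.s,
             plan.sampling)
    result = dnc_mds(D, cfg.dims, plan, linear_only=cfg.linear_only)
    for w in result.meta.get("warnings", []):
        log.warning("%s", w)
    write_embedding(result, cfg.output_path)
    sidecar = {
        "config": asdict(cfg),
        "plan": result.meta["plan"],
        "warnings": result.meta.get("warnings", []),
        "alignment_rms": result.meta.get("alignment_rms"),
        "distance_summary": _distance_summary(result, seed=cfg.seed),
    }
    meta_path = str(cfg.output_path) + ".meta.yaml"
    with open(meta_path, "w") as fh:
        yaml.safe_dump(sidecar, fh, sort_keys=False)
    log.info("wrote %s and %s", cfg.output_path, meta_path)
    return result
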