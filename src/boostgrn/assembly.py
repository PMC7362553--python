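"""Global edge ranking: L2 normalization of per-target confidences.

Each target's regression subproblem is solved independently, so its raw
split counts live on an arbitrary per-target scale.  Dividing every target
column by its Euclidean norm puts all subproblems on a common scale; the
normalized (or prior-fused / variance-scaled) matrix is then flattened into
one globally ranked directed edge list.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError

_STAGES = ("raw", "normalized", "prior_fused", "variance_scaled")


@dataclass
class ConfidenceMatrix:
    """Regulator x target nonnegative edge confidences at a pipeline stage.

    Stage progresses raw -> normalized -> (prior_fused) -> variance_scaled;
    entries where regulator and target are the same gene are always zero.
    """

    regulator_ids: list[str]
    target_ids: list[str]
    W: np.ndarray
    stage: str = "raw"

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        if self.stage not in _STAGES:
            raise ValidationError(f"unknown stage {self.stage!r}")
        if self.W.shape != (len(self.regulator_ids), len(self.target_ids)):
            raise ValidationError(
                f"W shape {self.W.shape} does not match axis labels"
            )
        if not np.all(np.isfinite(self.W)):
            raise ValidationError("non-finite confidence value")
        if np.any(self.W < 0):
            raise ValidationError("negative confidence value")
        tpos = {t: j for j, t in enumerate(self.target_ids)}
        for i, r in enumerate(self.regulator_ids):
            j = tpos.get(r)
            if j is not None and self.W[i, j] != 0:
                raise ValidationError(f"nonzero self-confidence for gene {r!r}")


@dataclass
class RankedEdgeList:
    """Directed edges in descending score order with a deterministic total
    order (ties broken by regulator id, then target id, ascending)."""

    entries: list[tuple[str, str, float]]

    def __post_init__(self) -> None:
        for reg, tgt, _ in self.entries:
            if reg == tgt:
                raise ValidationError(f"self-edge {reg!r} in ranked list")
        scores = [s for _, _, s in self.entries]
        if any(a < b for a, b in zip(scores, scores[1:])):
            raise ValidationError("scores are not non-increasing")


def normalize_l2(conf: ConfidenceMatrix) -> ConfidenceMatrix:
    """Divide each target column by its Euclidean norm over regulators.

    All-zero columns (a target no regulator ever split on) stay all-zero
    rather than becoming NaN.  Idempotent on nonzero normalized columns.
    """
    if conf.stage != "raw":
        raise ValidationError(f"normalize_l2 expects stage 'raw', got {conf.stage!r}")
    norms = np.sqrt((conf.W**2).sum(axis=0))
    safe = np.where(norms > 0, norms, 1.0)
    return ConfidenceMatrix(
        regulator_ids=list(conf.regulator_ids),
        target_ids=list(conf.target_ids),
        W=conf.W / safe,
        stage="normalized",
    )


def rank_edges(conf: ConfidenceMatrix) -> RankedEdgeList:
    """Flatten a confidence matrix into the global directed-edge ranking.

    Every ordered (regulator, target) pair with distinct genes is scored;
    sorting is by score descending, then (regulator_id, target_id)
    lexicographic ascending for a deterministic total order.
    """
    if conf.stage == "raw":
        raise ValidationError("rank_edges expects a normalized or later stage")
    entries = [
        (r, t, float(conf.W[i, j]))
        for i, r in enumerate(conf.regulator_ids)
        for j, t in enumerate(conf.target_ids)
        if r != t
    ]
    entries.sort(key=lambda e: (-e[2], e[0], e[1]))
    return RankedEdgeList(entries=entries)
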