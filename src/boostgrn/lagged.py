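"""Decay-weighted lagged feature construction.

For each target gene the inference problem becomes a supervised regression:
the response is the target's expression at time t and the regressors are,
for every candidate regulator, the geometrically decayed accumulation of its
expression over the k previous time points,

    u = sum_{j=1..k} x(t-j) * delta**(j-1),

so the most recent lag enters with weight 1 and older lags are down-weighted
by the decay factor delta in [0, 1].  With k=1 (or delta=0 and k=2) this
reduces to the classical single-lag construction in which the target at t
is explained by the regulators at t-1 only.

Lags never cross replicate-series boundaries; the first k time points of
each series serve only as lag context and never as responses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ValidationError
from .io import ExpressionDataset


@dataclass(frozen=True)
class LagConfig:
    """Lag-accumulation settings.

    Parameters
    ----------
    k
        Number of previous time points accumulated (>= 1).  Default 2.
    delta
        Geometric decay factor in [0, 1] applied to older lags.  Default 0.45.
    """

    k: int = 2
    delta: float = 0.45

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValidationError(f"k must be >= 1, got {self.k}")
        if not 0.0 <= self.delta <= 1.0:
            raise ValidationError(f"delta must be in [0, 1], got {self.delta}")


@dataclass
class LaggedDataset:
    """Per-target supervised regression problem.

    ``X[r, :]`` rows are decay-accumulated regulator values; ``y`` is the
    target's expression at the corresponding (later) time point.  The target
    gene is never among its own regressors.
    """

    target_id: str
    regulator_ids: list[str]
    X: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        if self.target_id in self.regulator_ids:
            raise ValidationError("target gene appears among its own regressors")
        if self.X.shape != (len(self.y), len(self.regulator_ids)):
            raise ValidationError(
                f"X shape {self.X.shape} inconsistent with y ({len(self.y)}) "
                f"and regulators ({len(self.regulator_ids)})"
            )
        if not (np.all(np.isfinite(self.X)) and np.all(np.isfinite(self.y))):
            raise ValidationError("non-finite value in lagged dataset")

    @property
    def n_samples(self) -> int:
        return len(self.y)


def accumulate(lagged_slices: Sequence[np.ndarray], delta: float) -> np.ndarray:
    """Decay-weighted sum of lag slices, most recent first.

    Returns ``sum_j lagged_slices[j] * delta**j`` (0-based j), i.e. the most
    recent slice has weight 1 and each step back decays by ``delta``.
    """
    if not 0.0 <= delta <= 1.0:
        raise ValidationError(f"delta must be in [0, 1], got {delta}")
    slices = [np.asarray(z, dtype=float) for z in lagged_slices]
    if not slices:
        raise ValidationError("need at least one lag slice")
    n = slices[0].shape
    if any(z.shape != n for z in slices):
        raise ValidationError("lag slices have mismatched lengths")
    out = np.zeros_like(slices[0])
    for j, z in enumerate(slices):
        out += z * delta**j
    return out


def build_lagged_dataset(
    data: ExpressionDataset, target_id: str, cfg: LagConfig
) -> LaggedDataset:
    """Assemble the supervised problem for one target gene.

    For each series and each 0-based time index t in {k, ..., T-1} emits one
    sample: response = target expression at t; regressor row = decayed
    accumulation of each candidate regulator over t-1, ..., t-k.  Samples
    from different series are concatenated in series order.
    """
    gene_ids = data.gene_ids
    if target_id not in gene_ids:
        raise ValidationError(f"unknown target gene {target_id!r}")
    target_col = gene_ids.index(target_id)
    regulator_ids = [r for r in data.regulator_ids if r != target_id]
    reg_cols = [gene_ids.index(r) for r in regulator_ids]
    k, delta = cfg.k, cfg.delta

    X_parts, y_parts = [], []
    for sidx, series in enumerate(data.series):
        T = series.n_timepoints
        if T <= k:
            raise ValidationError(
                f"series {sidx} has {T} time points; needs more than k={k}"
            )
        V = series.values[:, reg_cols]
        # vectorized over response times t = k .. T-1: lag j covers rows t-j
        acc = np.zeros((T - k, len(reg_cols)))
        for j in range(1, k + 1):
            acc += V[k - j : T - j, :] * delta ** (j - 1)
        X_parts.append(acc)
        y_parts.append(series.values[k:, target_col])

    return LaggedDataset(
        target_id=target_id,
        regulator_ids=regulator_ids,
        X=np.vstack(X_parts),
        y=np.concatenate(y_parts),
    )
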