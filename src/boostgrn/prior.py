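"""Knockout-prior fusion and regulator-variance reweighting.

Knockout experiments carry direction information: if deleting gene i
significantly changes gene j's expression relative to j's spread across all
knockout experiments, the edge i -> j gains support.  The significance
factor is the absolute z-score

    I_ij = |x_ij - mean_j| / sd_j,

where x_ij is gene j's expression after knocking out gene i and mean_j /
sd_j are taken over gene j's column across all knockout experiments.  Edge
confidences are multiplied elementwise by I.

A second, expression-only reweighting encodes regulator hubness: a
regulator whose confidence profile across targets has high variance holds a
few strong edges (regulatory networks are sparse), so each regulator row is
scaled by its own weight variance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .assembly import ConfidenceMatrix
from .errors import ValidationError
from .io import KnockoutMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PriorConfig:
    """Prior-fusion settings.

    ``fuse_knockout`` (the p_r switch) enables the knockout significance
    factor; ``sd_mode`` picks the sample (n-1) or population (n) standard
    deviation; ``exclude_self_knockout`` drops gene j's own knockout row
    from its column statistics (a self-knockout forces expression to ~0 and
    can inflate the spread); ``apply_variance_update`` toggles the
    regulator-variance reweighting.
    """

    fuse_knockout: bool = False
    sd_mode: str = "sample"
    exclude_self_knockout: bool = False
    apply_variance_update: bool = True

    def __post_init__(self) -> None:
        if self.sd_mode not in ("sample", "population"):
            raise ValidationError(f"sd_mode must be sample|population, got {self.sd_mode!r}")


@dataclass
class PriorMatrix:
    """Knockout significance factors I_ij (regulator x target, >= 0)."""

    regulator_ids: list[str]
    target_ids: list[str]
    I: np.ndarray

    def __post_init__(self) -> None:
        self.I = np.asarray(self.I, dtype=float)
        if self.I.shape != (len(self.regulator_ids), len(self.target_ids)):
            raise ValidationError("prior matrix shape does not match axis labels")
        if np.any(self.I < 0) or not np.all(np.isfinite(self.I)):
            raise ValidationError("prior factors must be finite and nonnegative")


def compute_prior(
    ko: KnockoutMatrix | None,
    regulator_ids: Sequence[str],
    target_ids: Sequence[str],
    cfg: PriorConfig,
) -> PriorMatrix:
    """Build the significance-factor matrix from knockout expression.

    With fusion off the prior is the identity (all ones).  With fusion on,
    I_ij is the absolute z-score of x_ij within gene j's knockout column;
    regulators without a knockout row get the neutral factor 1, as does any
    gene whose column has zero spread (logged).  Self-pairs are 0: they are
    never scored.
    """
    regulator_ids = list(regulator_ids)
    target_ids = list(target_ids)
    n_r, n_t = len(regulator_ids), len(target_ids)
    I = np.ones((n_r, n_t))

    if cfg.fuse_knockout:
        if ko is None or len(ko.knocked_gene_ids) < 2:
            raise ValidationError(
                "knockout fusion needs a knockout matrix with at least 2 experiments"
            )
        ko_row = {g: i for i, g in enumerate(ko.knocked_gene_ids)}
        ko_col = {g: j for j, g in enumerate(ko.measured_gene_ids)}
        ddof = 1 if cfg.sd_mode == "sample" else 0
        for j, tgt in enumerate(target_ids):
            cj = ko_col.get(tgt)
            if cj is None:
                continue  # gene never measured: neutral column
            col = ko.values[:, cj]
            mask = np.ones(len(col), dtype=bool)
            if cfg.exclude_self_knockout and tgt in ko_row:
                mask[ko_row[tgt]] = False
            used = col[mask]
            if len(used) < 2:
                continue
            sd = float(np.std(used, ddof=ddof))
            if sd == 0.0:
                logger.warning(
                    "gene %r has zero knockout spread; neutral prior column", tgt
                )
                continue
            mean = float(np.mean(used))
            for i, reg in enumerate(regulator_ids):
                ri = ko_row.get(reg)
                if ri is not None:
                    I[i, j] = abs(ko.values[ri, cj] - mean) / sd

    # self-pairs are never scored
    tpos = {t: j for j, t in enumerate(target_ids)}
    for i, reg in enumerate(regulator_ids):
        j = tpos.get(reg)
        if j is not None:
            I[i, j] = 0.0
    return PriorMatrix(regulator_ids=regulator_ids, target_ids=target_ids, I=I)


def fuse_prior(conf: ConfidenceMatrix, prior: PriorMatrix) -> ConfidenceMatrix:
    """Elevate edge confidences by the knockout significance factors
    (elementwise product)."""
    if conf.stage != "normalized":
        raise ValidationError(f"fuse_prior expects stage 'normalized', got {conf.stage!r}")
    if (
        conf.regulator_ids != prior.regulator_ids
        or conf.target_ids != prior.target_ids
    ):
        raise ValidationError("confidence and prior matrices have mismatched axes")
    return ConfidenceMatrix(
        regulator_ids=list(conf.regulator_ids),
        target_ids=list(conf.target_ids),
        W=conf.W * prior.I,
        stage="prior_fused",
    )


def variance_update(conf: ConfidenceMatrix) -> ConfidenceMatrix:
    """Scale each regulator's row by the variance of its own weights.

    The variance (population convention) is taken over targets j != i of the
    weights as they stand entering this step; every weight in the row is
    then multiplied by it.  A regulator with a few strong edges among many
    near-zero ones gains rank over one with uniform mid-level weights.
    """
    if conf.stage not in ("normalized", "prior_fused"):
        raise ValidationError(
            f"variance_update expects normalized or prior_fused stage, got {conf.stage!r}"
        )
    W = conf.W.copy()
    tpos = {t: j for j, t in enumerate(conf.target_ids)}
    for i, reg in enumerate(conf.regulator_ids):
        j_self = tpos.get(reg)
        mask = np.ones(W.shape[1], dtype=bool)
        if j_self is not None:
            mask[j_self] = False
        row = W[i, mask]
        # a constant row has exactly zero variance; avoid rounding residue
        var = 0.0 if row.size == 0 or np.ptp(row) == 0.0 else float(np.var(row))
        W[i, :] *= var
    return ConfidenceMatrix(
        regulator_ids=list(conf.regulator_ids),
        target_ids=list(conf.target_ids),
        W=W,
        stage="variance_scaled",
    )
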