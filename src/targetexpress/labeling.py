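"""True-Target / False-Target label construction from a perturbation
experiment's differential-expression table, and experiment eligibility.

Two labelling modes exist:

``fdr``
    TT = predicted, measured, repressed (log2FC < 0) and significant
    (FDR < 0.1); FT = predicted, measured, FDR > 0.2 irrespective of
    direction.  Inequalities are strict.
``topk``
    TT = the k most down-regulated predicted transcripts (t < 0,
    ascending t); FT = the k measured predicted transcripts with
    |t| < t_null closest to zero.  Used when two platforms must be
    compared on an equal footing.

Predicted targets that were not measured in the experiment are excluded
entirely; everything predicted-and-measured is partitioned into
TT / FT / unlabeled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal

from .errors import DomainError, ValidationError
from .iodata import DiffExprRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LabelSet:
    """Partition of predicted-and-measured transcripts."""

    tt: frozenset[str]
    ft: frozenset[str]
    unlabeled: frozenset[str]

    def __post_init__(self) -> None:
        if self.tt & self.ft or self.tt & self.unlabeled or self.ft & self.unlabeled:
            raise ValidationError("TT, FT and unlabeled sets must be disjoint")

    @property
    def universe(self) -> frozenset[str]:
        return self.tt | self.ft | self.unlabeled


@dataclass(frozen=True)
class LabelConfig:
    mode: Literal["fdr", "topk"] = "fdr"
    fdr_tt: float = 0.1
    fdr_ft: float = 0.2
    k: int = 250
    t_null: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.fdr_tt <= self.fdr_ft <= 1:
            raise ValidationError(
                f"need 0 < fdr_tt <= fdr_ft <= 1, got ({self.fdr_tt}, {self.fdr_ft})"
            )
        if self.k < 1:
            raise ValidationError(f"k must be >= 1, got {self.k}")


def assign_labels_fdr(
    diff: Iterable[DiffExprRecord],
    predicted: set[str],
    cfg: LabelConfig = LabelConfig(),
) -> LabelSet:
    """FDR-band labelling (the training-time definition)."""
    if not predicted:
        raise DomainError("empty predicted-target set")
    if cfg.mode != "fdr":
        raise DomainError(f"assign_labels_fdr called with mode {cfg.mode!r}")
    tt, ft, other = set(), set(), set()
    for rec in diff:
        if rec.transcript_id not in predicted:
            continue
        if rec.log2fc < 0 and rec.fdr < cfg.fdr_tt:
            tt.add(rec.transcript_id)
        elif rec.fdr > cfg.fdr_ft:
            ft.add(rec.transcript_id)
        else:
            other.add(rec.transcript_id)
    return LabelSet(frozenset(tt), frozenset(ft), frozenset(other))


def assign_labels_topk(
    diff: Iterable[DiffExprRecord],
    predicted: set[str],
    cfg: LabelConfig = LabelConfig(mode="topk"),
) -> LabelSet:
    """Top-k labelling: k most down-regulated as TT, k least-changing as FT.

    Ties at the k-th value are broken lexicographically on transcript id
    so the partition is deterministic.  If fewer than k candidates exist
    on either side, all available are used with a warning.
    """
    if not predicted:
        raise DomainError("empty predicted-target set")
    if cfg.mode != "topk":
        raise DomainError(f"assign_labels_topk called with mode {cfg.mode!r}")
    measured = [r for r in diff if r.transcript_id in predicted]
    down = sorted(
        (r for r in measured if r.t < 0), key=lambda r: (r.t, r.transcript_id)
    )
    if len(down) < cfg.k:
        logger.warning("only %d down-regulated candidates for k=%d", len(down), cfg.k)
    tt = {r.transcript_id for r in down[: cfg.k]}
    null = sorted(
        (r for r in measured
         if abs(r.t) < cfg.t_null and r.transcript_id not in tt),
        key=lambda r: (abs(r.t), r.transcript_id),
    )
    if len(null) < cfg.k:
        logger.warning("only %d non-changing candidates for k=%d", len(null), cfg.k)
    ft = {r.transcript_id for r in null[: cfg.k]}
    other = {r.transcript_id for r in measured} - tt - ft
    return LabelSet(frozenset(tt), frozenset(ft), frozenset(other))


def assign_labels(
    diff: Iterable[DiffExprRecord], predicted: set[str], cfg: LabelConfig
) -> LabelSet:
    """Dispatch on ``cfg.mode``."""
    if cfg.mode == "fdr":
        return assign_labels_fdr(diff, predicted, cfg)
    return assign_labels_topk(diff, predicted, cfg)


def experiment_eligible(
    labels: LabelSet, seed_qc_pass: bool, min_tt: int = 20
) -> bool:
    """An experiment trains an ensemble member iff it shows a clean seed
    enrichment signal and has at least `min_tt` True Targets."""
    return bool(seed_qc_pass) and len(labels.tt) >= min_tt
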