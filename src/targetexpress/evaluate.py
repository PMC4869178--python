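"""Evaluation machinery: ROC/AUC, operating points, baseline predictors,
experiment-level leave-one-out cross-validation, and the paired
one-sided Wilcoxon comparison of method AUC vectors.

AUC is computed by the Mann-Whitney rank formula (ties count 1/2), i.e.
the probability that a random positive outranks a random negative.  The
operating point is the ROC point closest to the top-left corner
(sensitivity = specificity = 1).  The optional 95% CI uses DeLong's
variance estimator.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata
from sklearn.metrics import roc_curve

from .errors import DomainError
from .features import (FEATURE_NAMES, FeatureMatrix, restrict_features)
from .iodata import SCORE_NAMES, ExpressionProfile
from .model import SvmConfig, predict_consensus, train_ensemble

logger = logging.getLogger(__name__)


@dataclass
class RocResult:
    auc: float
    points: list[tuple[float, float]]           # (sensitivity, specificity)
    operating_point: tuple[float, float, float]  # (sens, spec, threshold)
    ci95: tuple[float, float] | None = None


def _mann_whitney_auc(pos: np.ndarray, neg: np.ndarray) -> float:
    # rank-sum form: numerator is exact in floats (sums of half-integers)
    ranks = rankdata(np.concatenate([pos, neg]), method="average")
    n1, n2 = len(pos), len(neg)
    r_pos = ranks[:n1].sum()
    return (r_pos - n1 * (n1 + 1) / 2.0) / (n1 * n2)


def roc_auc(
    scores: Mapping[str, float],
    labels: Mapping[str, int],
    ci: bool = False,
) -> RocResult:
    """ROC curve and AUC for scores against +1/-1 labels.

    Only ids present in both mappings are used; ties between a positive
    and a negative score count one half.
    """
    ids = [i for i in scores if i in labels]
    if not ids:
        raise DomainError("no id is both scored and labeled")
    s = np.array([scores[i] for i in ids], dtype=float)
    y = np.array([labels[i] for i in ids])
    pos, neg = s[y == 1], s[y == -1]
    if len(pos) == 0 or len(neg) == 0:
        raise DomainError("need at least one positive and one negative label")
    auc = _mann_whitney_auc(pos, neg)

    fpr, tpr, thr = roc_curve(y, s, drop_intermediate=False)
    points = [(float(se), float(1.0 - fp)) for fp, se in zip(fpr, tpr)]
    k = _operating_index(points)
    op = (points[k][0], points[k][1], float(thr[k]))
    ci95 = _delong_ci(pos, neg, auc) if ci else None
    return RocResult(float(auc), points, op, ci95)


def _operating_index(points: Sequence[tuple[float, float]]) -> int:
    best, best_d = 0, math.inf
    for i, (se, sp) in enumerate(points):
        d = math.hypot(1.0 - se, 1.0 - sp)
        if d < best_d - 1e-12 or (abs(d - best_d) <= 1e-12
                                  and se > points[best][0]):
            best, best_d = i, d
    return best


def operating_point(points: Sequence[tuple[float, float]]) -> tuple[float, float]:
    """ROC point minimising distance to (sens=1, spec=1); ties favour
    the higher sensitivity."""
    if not points:
        raise DomainError("empty ROC point list")
    se, sp = points[_operating_index(points)]
    return (se, sp)


def _delong_ci(pos: np.ndarray, neg: np.ndarray, auc: float,
               level: float = 0.95) -> tuple[float, float]:
    # DeLong structural components
    m, n = len(pos), len(neg)
    v10 = np.array([(np.sum(p > neg) + 0.5 * np.sum(p == neg)) / n for p in pos])
    v01 = np.array([(np.sum(pos > q) + 0.5 * np.sum(pos == q)) / m for q in neg])
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + \
          (np.var(v01, ddof=1) / n if n > 1 else 0.0)
    z = norm.ppf(0.5 + level / 2.0)
    half = z * math.sqrt(max(var, 0.0))
    return (max(0.0, auc - half), min(1.0, auc + half))


def intersect_baseline(
    scores: Mapping[str, float], expr: ExpressionProfile
) -> dict[str, float]:
    """The median-intersect baseline: keep a target's score only if its
    expression exceeds the median of the whole profile.

    The median is taken over every value in the profile (the whole
    array, not just the targets); retention is strictly greater; an
    even-length profile uses the midpoint of the two central values.
    """
    if len(expr) == 0:
        raise DomainError("empty expression profile")
    med = float(np.median(list(expr.values.values())))
    kept = {t: s for t, s in scores.items() if t in expr and expr[t] > med}
    if not kept:
        logger.warning("intersect baseline removed every target")
    return kept


def sum_baseline(matrix: FeatureMatrix, methods: set[str]) -> dict[str, float]:
    """Per-transcript sum of selected rank-scaled score columns
    (imputed scores contribute their neutral 0)."""
    if not methods:
        raise DomainError("methods must be non-empty")
    unknown = methods - set(SCORE_NAMES)
    if unknown:
        raise DomainError(f"unknown score columns: {sorted(unknown)}")
    total = matrix.data[list(methods)].sum(axis=1)
    return dict(zip(matrix.transcript_ids, total.tolist()))


def paired_wilcoxon(auc_a: Sequence[float], auc_b: Sequence[float]) -> float:
    """One-sided paired Wilcoxon signed-rank p for alternative A > B.

    Zero differences are dropped (standard signed-rank convention); the
    tail probability is exact (dynamic programming over the 2^n sign
    assignments of the observed |difference| ranks, tied ranks included)
    for n <= 25, and a normal approximation with tie correction above.
    All-zero differences degenerate to p = 1 with a warning.
    """
    a, b = np.asarray(auc_a, float), np.asarray(auc_b, float)
    if len(a) != len(b):
        raise DomainError("paired vectors must have equal length")
    if len(a) < 3:
        raise DomainError("need at least 3 pairs")
    d = a - b
    d = d[d != 0.0]
    if len(d) == 0:
        logger.warning("all paired differences are zero; p = 1")
        return 1.0
    ranks = rankdata(np.abs(d), method="average")
    w_plus = float(ranks[d > 0].sum())
    n = len(d)
    if n <= 25:
        return _exact_signed_rank_tail(ranks, w_plus)
    # normal approximation with tie correction
    mu = n * (n + 1) / 4.0
    tie_term = 0.0
    _, counts = np.unique(np.abs(d), return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / 48.0
    sigma = math.sqrt(n * (n + 1) * (2 * n + 1) / 24.0 - tie_term)
    z = (w_plus - mu - 0.5) / sigma  # continuity correction
    return float(norm.sf(z))


def _exact_signed_rank_tail(ranks: np.ndarray, w_plus: float) -> float:
    # work on doubled ranks so tied (half-integer) ranks become integers
    doubled = np.round(ranks * 2).astype(int)
    target = int(round(w_plus * 2))
    total = int(doubled.sum())
    # dp[s] = number of sign assignments with doubled W+ == s
    dp = np.zeros(total + 1, dtype=float)
    dp[0] = 1.0
    for r in doubled:
        dp[r:] = dp[r:] + dp[:-r] if r > 0 else dp[r:] * 2
    return float(dp[target:].sum() / 2 ** len(doubled))


@dataclass
class CvReport:
    """AUC per (left-out experiment, method) and paired comparisons."""

    auc: pd.DataFrame  # index experiment_id, columns method spec

    def compare(self, method_a: str, method_b: str) -> float:
        """One-sided p that method A's AUCs exceed method B's, paired
        by left-out experiment."""
        return paired_wilcoxon(self.auc[method_a].to_numpy(),
                               self.auc[method_b].to_numpy())


@dataclass
class Experiment:
    """One perturbation experiment prepared for cross-validation:
    a labeled feature matrix, the full expression profile it came from,
    and the seed-enrichment QC verdict."""

    experiment_id: str
    matrix: FeatureMatrix
    expression: ExpressionProfile
    qc_pass: bool = True


def _parse_method(spec: str) -> tuple[str, set[str]]:
    kind, _, cols = spec.partition(":")
    if kind not in ("raw", "intersect", "sum", "te"):
        raise DomainError(f"unknown method spec {spec!r}")
    if kind == "te" and cols in ("", "all"):
        return kind, set(SCORE_NAMES)
    names = set(cols.split("+")) if cols else set()
    unknown = names - set(SCORE_NAMES)
    if not names or unknown:
        raise DomainError(f"bad score columns in method spec {spec!r}")
    return kind, names


def _method_scores(
    kind: str,
    cols: set[str],
    exp: Experiment,
    others: list[Experiment],
    cfg: SvmConfig,
    min_tt: int,
) -> dict[str, float]:
    mat = exp.matrix
    if kind in ("raw", "sum"):
        return sum_baseline(mat, cols)
    if kind == "intersect":
        base = sum_baseline(mat, cols)
        kept = intersect_baseline(base, exp.expression)
        # removed targets rank below every retained one
        floor = (min(kept.values()) if kept else 0.0) - 1.0
        return {t: kept.get(t, floor) for t in base}
    # kind == "te": train on the other experiments, restricted to cols
    train = [(restrict_features(o.matrix, cols), o.qc_pass) for o in others]
    ens = train_ensemble(train, cfg=cfg, min_tt=min_tt)
    return predict_consensus(ens, restrict_features(mat, cols))


def loocv(
    experiments: Iterable[Experiment],
    methods: Sequence[str],
    cfg: SvmConfig = SvmConfig(),
    min_tt: int = 20,
) -> CvReport:
    """Leave-one-experiment-out cross-validation.

    For each eligible experiment, an ensemble is trained on the others
    and every method spec is scored on the held-out experiment's
    labeled transcripts.  Method specs: ``raw:<col>``,
    ``intersect:<col>``, ``sum:<col>+<col>``, ``te:<col>[+...]`` or
    ``te:all``.
    """
    exps = list(experiments)
    eligible = [
        e for e in exps
        if e.qc_pass and int((e.matrix.y() == 1).sum()) >= min_tt
    ]
    if len(eligible) < 2:
        raise DomainError(
            f"need >= 2 eligible experiments, have {len(eligible)}"
        )
    parsed = [(spec, *_parse_method(spec)) for spec in methods]
    rows = {}
    for e in eligible:
        others = [o for o in eligible if o.experiment_id != e.experiment_id]
        labels = dict(zip(e.matrix.transcript_ids, e.matrix.y().tolist()))
        rows[e.experiment_id] = {
            spec: roc_auc(
                _method_scores(kind, cols, e, others, cfg, min_tt), labels
            ).auc
            for spec, kind, cols in parsed
        }
    return CvReport(pd.DataFrame.from_dict(rows, orient="index")[list(methods)])
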