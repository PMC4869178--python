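"""Feature construction: rank + min-max scaling to [-1, +1] with neutral
imputation, and assembly of the 7-column matrix the SVMs consume.

Each feature (six prediction scores plus one expression value) is ranked
within its column (average ranks for ties) and the ranks are min-max
mapped to [-1, +1].  Missing scores take the min-max centre, 0 — neutral
for a radial-kernel SVM trained on this scale.  Ranking makes the matrix
invariant to any monotone transform of the inputs, which is what lets
one model consume microarray log-intensities, RPKM or counts
interchangeably.

``RankScaler`` packages the same transform as a scikit-learn
transformer so it composes with pipelines.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import ConfigError, DomainError, EmptyResultError
from .iodata import SCORE_NAMES, ExpressionProfile, PredictionRecord
from .labeling import LabelSet

#: Column order of the feature matrix.  Expression is always last.
FEATURE_NAMES: tuple[str, ...] = SCORE_NAMES + ("expression",)

#: Default orientation: larger scaled value = stronger predicted
#: targeting.  Total Context+ is negated (more negative raw score means
#: stronger repression); every other score already points that way.
DEFAULT_ORIENTATION: dict[str, int] = {name: 1 for name in FEATURE_NAMES}
DEFAULT_ORIENTATION["context_plus"] = -1


def rank_scale(values: Sequence[float | None]) -> np.ndarray:
    """Rank then min-max scale one feature column to [-1, +1].

    Non-missing values are replaced by their average-tie rank, then
    affinely mapped so the minimum rank lands on -1 and the maximum on
    +1.  Missing values map to the centre, 0.  A constant column (all
    non-missing values equal) also maps to 0.
    """
    arr = np.array(
        [np.nan if v is None else float(v) for v in values], dtype=float
    )
    present = ~np.isnan(arr)
    if not present.any():
        raise DomainError("all values missing; cannot rank-scale")
    out = np.zeros(len(arr), dtype=float)
    ranks = rankdata(arr[present], method="average")
    lo, hi = ranks.min(), ranks.max()
    if hi > lo:
        out[present] = 2.0 * (ranks - lo) / (hi - lo) - 1.0
    return out


class RankScaler(BaseEstimator, TransformerMixin):
    """Column-wise rank + min-max scaling to [-1, +1], NaN -> 0.

    Stateless by design: the scaling is defined within each matrix it is
    applied to (training and evaluation matrices are each ranked
    internally), so ``fit`` only records the column count.
    """

    def fit(self, X, y=None):  # noqa: D102 - sklearn signature
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise DomainError("expected a 2-D array")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:  # noqa: D102
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != getattr(self, "n_features_in_", X.shape[1]):
            raise DomainError("column count differs from fit")
        return np.column_stack([rank_scale(col) for col in X.T])


@dataclass
class FeatureMatrix:
    """The scaled 7-feature matrix for one cellular context.

    Attributes
    ----------
    data : DataFrame, index transcript_id, columns FEATURE_NAMES,
        every entry in [-1, +1].
    imputed : boolean DataFrame of the same shape; True where the raw
        score was missing (entry is exactly 0 there).
    labels : optional Series of +1 (TT) / -1 (FT) indexed like `data`.
    experiment_id : provenance tag.
    """

    data: pd.DataFrame
    imputed: pd.DataFrame
    labels: pd.Series | None = None
    experiment_id: str = ""

    def __post_init__(self) -> None:
        if list(self.data.columns) != list(FEATURE_NAMES):
            raise DomainError(f"columns must be {FEATURE_NAMES}")
        if not self.data.index.is_unique:
            raise DomainError("duplicate transcript ids in feature matrix")
        if self.labels is not None:
            missing = set(self.labels.index) - set(self.data.index)
            if missing:
                raise DomainError(f"labeled ids without rows: {sorted(missing)[:5]}")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def transcript_ids(self) -> list[str]:
        return list(self.data.index)

    def y(self) -> np.ndarray:
        if self.labels is None:
            raise DomainError("matrix has no labels")
        return self.labels.loc[self.data.index].to_numpy()


def build_matrix(
    preds: Iterable[PredictionRecord],
    expr: ExpressionProfile,
    labels: LabelSet | None = None,
    orientation: Mapping[str, int] | None = None,
    experiment_id: str = "",
) -> FeatureMatrix:
    """Assemble and scale the feature matrix for one context.

    Rows are transcripts with at least one prediction score AND an
    expression value AND, when `labels` is given (training mode), a
    TT/FT label.  Orientation is applied to the raw scores before
    ranking; each column is then rank-scaled independently within this
    matrix.
    """
    orient = dict(DEFAULT_ORIENTATION)
    if orientation:
        orient.update(orientation)

    preds = list(preds)
    if not preds:
        raise DomainError("no prediction records")
    if len(expr) == 0:
        raise DomainError("empty expression profile")

    rows: dict[str, dict[str, float | None]] = {}
    for rec in preds:
        if rec.transcript_id in rows:
            raise DomainError(f"duplicate transcript {rec.transcript_id!r}")
        rows[rec.transcript_id] = rec.scores()

    ids = [t for t in rows if t in expr]
    if not ids:
        raise EmptyResultError("no predicted transcript has an expression value")
    if labels is not None:
        labeled = labels.tt | labels.ft
        ids = [t for t in ids if t in labeled]
        if not ids:
            raise EmptyResultError(
                "no predicted+measured transcript carries a TT/FT label"
            )

    raw = pd.DataFrame(
        {name: [rows[t][name] for t in ids] for name in SCORE_NAMES},
        index=pd.Index(ids, name="transcript_id"),
        dtype=float,
    )
    raw["expression"] = [expr[t] for t in ids]
    imputed = raw.isna()
    imputed["expression"] = False

    scaled = pd.DataFrame(index=raw.index, columns=list(FEATURE_NAMES), dtype=float)
    for name in FEATURE_NAMES:
        col = raw[name].to_numpy() * orient[name]
        if np.isnan(col).all():
            # a method absent from the whole table: entirely neutral
            scaled[name] = 0.0
            continue
        scaled[name] = rank_scale([None if np.isnan(v) else v for v in col])

    lab = None
    if labels is not None:
        lab = pd.Series(
            [1 if t in labels.tt else -1 for t in ids], index=scaled.index, dtype=int
        )
    return FeatureMatrix(scaled, imputed, lab, experiment_id)


def restrict_features(matrix: FeatureMatrix, keep: set[str]) -> FeatureMatrix:
    """Zero out score columns not in `keep` (single-method variants).

    Expression is always kept.  The shape never changes: excluded
    columns are set to the neutral value 0 and flagged imputed, exactly
    as a missing score would be.
    """
    unknown = keep - set(FEATURE_NAMES)
    if unknown:
        raise ConfigError(f"unknown feature names: {sorted(unknown)}")
    keep = set(keep) | {"expression"}
    if not keep & set(SCORE_NAMES):
        raise ConfigError("keep must retain at least one score column")
    data = matrix.data.copy()
    imputed = matrix.imputed.copy()
    for name in FEATURE_NAMES:
        if name not in keep:
            data[name] = 0.0
            imputed[name] = True
    return FeatureMatrix(data, imputed, matrix.labels, matrix.experiment_id)
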