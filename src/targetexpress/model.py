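"""The class-weighted RBF-SVM ensemble.

One support-vector machine is trained per eligible perturbation
experiment on its scaled feature matrix, with per-class penalties that
equalise the influence of the (rare) True Targets and the (abundant)
False Targets:

    c1 = (1/n1) / (1/n1 + 1/n2),   c2 = (1/n2) / (1/n1 + 1/n2)

where n1 = |TT| and n2 = |FT|, so c1 + c2 = 1 and c1*n1 = c2*n2.  Each
class's soft-margin penalty is cost * c_k.

At prediction time the signed decision values of all members are summed;
this consensus is the final score, positive meaning predicted true
target in the supplied expression context.  A ``vote`` mode (sum of
member class votes, each +/-1) exists for comparison.

``TargetExpressEnsemble`` is a scikit-learn style classifier:
``fit(X, y, groups=...)`` trains one member per group,
``decision_function`` returns the consensus.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import joblib
import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from .errors import ContractError, DomainError, ModelIOError
from .features import FEATURE_NAMES, FeatureMatrix
from .labeling import experiment_eligible

_PERSIST_VERSION = 1


@dataclass(frozen=True)
class SvmConfig:
    """Kernel-machine settings.  gamma defaults to 1/7 (one over the
    number of features) and inputs are never re-scaled: the matrix is
    already rank/min-max normalised."""

    gamma: float = 1.0 / 7.0
    cost: float = 1.0
    kernel: str = "rbf"
    scale_inputs: bool = False

    def __post_init__(self) -> None:
        if self.gamma <= 0 or self.cost <= 0:
            raise DomainError("gamma and cost must be positive")
        if self.kernel != "rbf":
            raise DomainError("only the radial kernel is supported")
        if self.scale_inputs:
            raise DomainError("inputs are pre-scaled; scale_inputs is fixed False")


@dataclass(frozen=True)
class ClassWeights:
    n1: int
    n2: int
    c1: float
    c2: float


def class_weights(n1: int, n2: int) -> ClassWeights:
    """Inverse-class-size weights normalised to sum to one."""
    if n1 < 1 or n2 < 1:
        raise DomainError(f"class counts must be >= 1, got ({n1}, {n2})")
    denom = 1.0 / n1 + 1.0 / n2
    return ClassWeights(n1, n2, (1.0 / n1) / denom, (1.0 / n2) / denom)


class TargetExpressEnsemble(BaseEstimator, ClassifierMixin):
    """Ensemble of class-weighted radial-kernel SVMs, one per experiment.

    Parameters
    ----------
    gamma, cost : RBF kernel width and soft-margin cost (both shared by
        every member).
    min_tt : minimum number of positive (TT) examples a group needs to
        contribute a member.
    mode : ``"decision"`` sums signed continuous decision values
        (default); ``"vote"`` sums hard +/-1 votes.

    Attributes
    ----------
    members_ : list of (group_id, fitted SVC).
    feature_names_ : column order every member expects.
    skipped_ : mapping group_id -> reason, for ineligible groups.
    """

    def __init__(self, gamma: float = 1.0 / 7.0, cost: float = 1.0,
                 min_tt: int = 20, mode: Literal["decision", "vote"] = "decision"):
        self.gamma = gamma
        self.cost = cost
        self.min_tt = min_tt
        self.mode = mode

    def fit(self, X, y, groups=None, qc_pass: Mapping[str, bool] | None = None,
            feature_names: Sequence[str] | None = None):
        """Train one member per group.

        X : (n_samples, n_features) scaled matrix; y : +1/-1 labels;
        groups : per-row experiment ids (a single group if omitted);
        qc_pass : optional per-group seed-enrichment QC flags — groups
        that fail are skipped, as are groups with fewer than `min_tt`
        positives or a single class.
        """
        cfg = SvmConfig(gamma=self.gamma, cost=self.cost)
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2:
            raise DomainError("X must be 2-D")
        if set(np.unique(y)) - {-1, 1}:
            raise DomainError("labels must be +1 (TT) / -1 (FT)")
        if groups is None:
            groups = np.zeros(len(y), dtype=int)
        groups = np.asarray(groups)
        qc_pass = dict(qc_pass or {})

        self.feature_names_ = (
            list(feature_names) if feature_names is not None
            else list(FEATURE_NAMES)[: X.shape[1]]
        )
        self.members_: list[tuple[str, SVC]] = []
        self.skipped_: dict[str, str] = {}
        for gid in sorted(set(groups.tolist()), key=str):
            mask = groups == gid
            yg = y[mask]
            n1 = int((yg == 1).sum())
            n2 = int((yg == -1).sum())
            if not qc_pass.get(gid, True):
                self.skipped_[str(gid)] = "seed-enrichment QC failed"
                continue
            if n1 < self.min_tt:
                self.skipped_[str(gid)] = f"only {n1} TT (< {self.min_tt})"
                continue
            if n2 == 0:
                self.skipped_[str(gid)] = "no FT examples"
                continue
            self.members_.append((str(gid), _fit_member(X[mask], yg, cfg)))
        if not self.members_:
            raise DomainError(
                "no eligible experiment to train on; reasons: "
                + "; ".join(f"{k}: {v}" for k, v in self.skipped_.items())
            )
        self.classes_ = np.array([-1, 1])
        self.config_ = cfg
        return self

    def decision_function(self, X) -> np.ndarray:
        """Consensus score: sum of member decision values (or votes)."""
        check_is_fitted(self, "members_")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != len(self.feature_names_):
            raise ContractError(
                f"expected {len(self.feature_names_)} feature columns "
                f"({self.feature_names_}), got shape {X.shape}"
            )
        total = np.zeros(X.shape[0])
        for _, svc in self.members_:
            d = svc.decision_function(X)
            total += np.sign(d) if self.mode == "vote" else d
        return total

    def predict(self, X) -> np.ndarray:
        """+1 where the consensus is positive, else -1."""
        return np.where(self.decision_function(X) > 0, 1, -1)

    @property
    def n_members_(self) -> int:
        check_is_fitted(self, "members_")
        return len(self.members_)


def _fit_member(X: np.ndarray, y: np.ndarray, cfg: SvmConfig) -> SVC:
    w = class_weights(int((y == 1).sum()), int((y == -1).sum()))
    svc = SVC(kernel="rbf", gamma=cfg.gamma, C=cfg.cost,
              class_weight={1: w.c1, -1: w.c2})
    svc.fit(X, y)
    # sklearn orients decision_function toward classes_[1]; with labels
    # {-1, +1} positive decision values are the TT side already.
    return svc


def train_member(matrix: FeatureMatrix, cfg: SvmConfig = SvmConfig()) -> SVC:
    """Fit a single weighted SVM on one labeled feature matrix."""
    y = matrix.y()
    if len(set(y.tolist())) < 2:
        raise DomainError("training matrix contains a single class")
    return _fit_member(matrix.data.to_numpy(), y, cfg)


def member_decision(svc: SVC, matrix: FeatureMatrix) -> dict[str, float]:
    """Signed decision values of one member on a matrix."""
    d = svc.decision_function(matrix.data.to_numpy())
    return dict(zip(matrix.transcript_ids, d.tolist()))


def train_ensemble(
    experiments: Iterable[tuple[FeatureMatrix, bool]],
    cfg: SvmConfig = SvmConfig(),
    min_tt: int = 20,
    mode: Literal["decision", "vote"] = "decision",
) -> TargetExpressEnsemble:
    """Train the ensemble from (labeled matrix, seed-QC flag) pairs.

    Eligibility follows :func:`labeling.experiment_eligible`: QC pass
    and at least `min_tt` True Targets.  Ineligible experiments are
    skipped (recorded in ``skipped_``); zero eligible is an error.
    """
    experiments = list(experiments)
    if not experiments:
        raise DomainError("no experiments supplied")
    Xs, ys, gs, qc = [], [], [], {}
    for i, (mat, qc_flag) in enumerate(experiments):
        gid = mat.experiment_id or f"experiment_{i}"
        y = mat.y()
        qc[gid] = bool(qc_flag)
        Xs.append(mat.data.to_numpy())
        ys.append(y)
        gs.append(np.full(len(y), gid, dtype=object))
    ens = TargetExpressEnsemble(gamma=cfg.gamma, cost=cfg.cost,
                                min_tt=min_tt, mode=mode)
    ens.fit(np.vstack(Xs), np.concatenate(ys), groups=np.concatenate(gs),
            qc_pass=qc, feature_names=list(FEATURE_NAMES))
    return ens


def predict_consensus(
    ensemble: TargetExpressEnsemble, matrix: FeatureMatrix
) -> dict[str, float]:
    """Consensus score per transcript; positive = predicted true target."""
    if list(matrix.data.columns) != list(ensemble.feature_names_):
        raise ContractError(
            f"feature order mismatch: model expects {ensemble.feature_names_}, "
            f"matrix has {list(matrix.data.columns)}"
        )
    scores = ensemble.decision_function(matrix.data.to_numpy())
    return dict(zip(matrix.transcript_ids, scores.tolist()))


def save_ensemble(ensemble: TargetExpressEnsemble, path: str) -> None:
    """Persist a fitted ensemble (joblib) with version + feature order."""
    check_is_fitted(ensemble, "members_")
    payload = {
        "format_version": _PERSIST_VERSION,
        "feature_names": list(ensemble.feature_names_),
        "params": ensemble.get_params(),
        "members": ensemble.members_,
        "skipped": ensemble.skipped_,
    }
    joblib.dump(payload, path)


def load_ensemble(path: str) -> TargetExpressEnsemble:
    """Load a persisted ensemble; errors on truncation, missing
    metadata, or a format-version mismatch."""
    try:
        payload = joblib.load(path)
    except Exception as exc:  # joblib raises various unpickling errors
        raise ModelIOError(f"cannot read model file {path!r}: {exc}") from exc
    if not isinstance(payload, dict):
        raise ModelIOError(f"{path!r} is not a TargetExpress model file")
    if payload.get("format_version") != _PERSIST_VERSION:
        raise ModelIOError(
            f"model format version {payload.get('format_version')!r} "
            f"unsupported (expected {_PERSIST_VERSION})"
        )
    if "feature_names" not in payload or not payload["feature_names"]:
        raise ModelIOError(f"{path!r} lacks feature-order metadata")
    ens = TargetExpressEnsemble(**payload["params"])
    ens.feature_names_ = list(payload["feature_names"])
    ens.members_ = payload["members"]
    ens.skipped_ = payload.get("skipped", {})
    ens.classes_ = np.array([-1, 1])
    ens.config_ = SvmConfig(gamma=ens.gamma, cost=ens.cost)
    return ens
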