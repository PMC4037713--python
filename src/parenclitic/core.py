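"""Pairwise reference models and single-subject parenclitic networks.

The parenclitic representation turns one subject — a vector of scalar
features with no time axis — into a weighted network.  Nodes are features;
the edge joining features *i* and *j* measures how far the subject's
``(x_i, x_j)`` pair deviates from the relationship those two features show
in a reference population.  The reference relationship in each feature-pair
plane is an ordinary-least-squares line, and the deviation is the absolute
z-score of the subject's residual against the spread of the training
residuals.  Atypical subjects produce dense, hub-dominated networks;
typical subjects produce sparse, homogeneous ones.

This module owns the model fitting (:func:`fit_pair_model`,
:func:`fit_reference_models`) and the network construction
(:func:`edge_weight`, :func:`build_network`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Relative tolerance below which a predictor spread or residual spread is
#: treated as zero (scaled by the data magnitude, floored at 1).
DEGENERACY_RTOL = 1e-12

#: Minimum number of training instances: 2 fix a line, 1 residual d.o.f.
MIN_TRAIN = 3

COMBINE_RULES = ("mean", "max", "min")
ZSCORE_MODES = ("signed", "absolute")

# Edge status codes for ParencliticNetwork.edge_status
STATUS_ABSENT = 0
STATUS_ONE_DIRECTION = 1
STATUS_VALID = 2
STATUS_LABELS = {
    STATUS_ABSENT: "absent",
    STATUS_ONE_DIRECTION: "one-direction-degenerate",
    STATUS_VALID: "valid",
}
STATUS_CODES = {v: k for k, v in STATUS_LABELS.items()}


def _check_unique(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate {what} ids: {dup}")
    return ids


@dataclass
class ExpressionDataset:
    """Instances × features numeric matrix with ids and optional labels.

    Rows are instances (subjects, or time steps in the leave-one-out
    design); columns are features (genes, clinical variables).  Values are
    assumed pre-normalized; non-finite entries are rejected.
    """

    values: np.ndarray
    instance_ids: list[str]
    feature_ids: list[str]
    class_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values contain non-finite entries")
        self.instance_ids = _check_unique(self.instance_ids, "instance")
        self.feature_ids = _check_unique(self.feature_ids, "feature")
        n, f = self.values.shape
        if len(self.instance_ids) != n:
            raise ValueError("instance_ids length does not match values")
        if len(self.feature_ids) != f:
            raise ValueError("feature_ids length does not match values")
        if n < 1:
            raise ValueError("need at least one instance")
        if f < 2:
            raise ValueError("need at least two features")
        if self.class_labels is not None:
            self.class_labels = [str(c) for c in self.class_labels]
            if len(self.class_labels) != n:
                raise ValueError("class_labels length does not match values")

    # -- conveniences -----------------------------------------------------

    @property
    def n_instances(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def instance_vector(self, instance_id: str) -> np.ndarray:
        return self.values[self.instance_ids.index(str(instance_id))].copy()

    def select_instances(self, keep) -> "ExpressionDataset":
        """Subset instances by ids, integer indices or a boolean mask."""
        idx = _selector_indices(self, keep)
        labels = (
            [self.class_labels[i] for i in idx] if self.class_labels else None
        )
        return ExpressionDataset(
            self.values[idx],
            [self.instance_ids[i] for i in idx],
            list(self.feature_ids),
            labels,
        )

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, class_labels: Sequence[str] | None = None
    ) -> "ExpressionDataset":
        return cls(
            df.to_numpy(dtype=float),
            [str(i) for i in df.index],
            [str(c) for c in df.columns],
            list(class_labels) if class_labels is not None else None,
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values.copy(), index=self.instance_ids, columns=self.feature_ids
        )


def _selector_indices(dataset: ExpressionDataset, keep) -> list[int]:
    if keep is None:
        return list(range(dataset.n_instances))
    arr = np.asarray(keep)
    if arr.dtype == bool:
        if arr.shape != (dataset.n_instances,):
            raise ValueError("boolean selector has wrong length")
        return list(np.flatnonzero(arr))
    if np.issubdtype(arr.dtype, np.integer):
        return [int(i) for i in arr]
    return [dataset.instance_ids.index(str(i)) for i in arr]


@dataclass
class PairModel:
    """Directional linear reference model for one ordered feature pair.

    Predicts the response feature from the predictor feature via
    ``x_j ≈ slope · x_i + intercept``; ``residual_std`` is the sample
    standard deviation of the signed training residuals and is the z-score
    denominator.  ``abs_residual_mean/std`` support the alternative
    standardization of absolute distances.
    """

    source_feature: str
    target_feature: str
    slope: float
    intercept: float
    residual_std: float
    n_train: int
    degenerate: bool
    abs_residual_mean: float = 0.0
    abs_residual_std: float = 0.0
    ddof: int = 1
    predictor_degenerate: bool = False
    scale_tol: float = DEGENERACY_RTOL

    def predict(self, x_source: float) -> float:
        return self.slope * x_source + self.intercept

    def usable(self, mode: str = "signed") -> bool:
        """Whether this direction can contribute a finite z-score."""
        if mode == "signed":
            return not self.degenerate
        if mode == "absolute":
            return (not self.predictor_degenerate) and (
                self.abs_residual_std > self.scale_tol
            )
        raise ValueError(f"unknown z-score mode: {mode!r}")

    def zscore(self, x_source: float, x_target: float, mode: str = "signed") -> float:
        """Absolute z-score of the subject's deviation in this plane."""
        d = abs(x_target - self.predict(x_source))
        if mode == "signed":
            return d / self.residual_std
        if mode == "absolute":
            return abs(d - self.abs_residual_mean) / self.abs_residual_std
        raise ValueError(f"unknown z-score mode: {mode!r}")


def fit_pair_model(
    x,
    y,
    *,
    source_feature: str = "x",
    target_feature: str = "y",
    ddof: int = 1,
) -> PairModel:
    """Ordinary-least-squares line of ``y`` on ``x`` plus residual spread.

    Minimizes the sum of squared vertical residuals.  With a constant
    predictor the model is flagged degenerate and falls back to
    ``slope = 0, intercept = mean(y)``; a (near-)perfect fit is likewise
    degenerate because its residual spread cannot standardize anything.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.shape != x.shape:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = x.size
    if n < MIN_TRAIN:
        raise ValueError(
            f"insufficient training instances: need >= {MIN_TRAIN}, got {n}"
        )
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite training values")

    xm = x.mean()
    ym = y.mean()
    xc = x - xm
    sxx = float(xc @ xc)
    x_tol = DEGENERACY_RTOL * max(1.0, float(np.abs(x).max()))
    predictor_degenerate = np.sqrt(sxx / (n - 1)) <= x_tol
    if predictor_degenerate:
        slope, intercept = 0.0, float(ym)
    else:
        slope = float(xc @ (y - ym)) / sxx
        intercept = float(ym - slope * xm)

    resid = y - (slope * x + intercept)
    residual_std = float(np.std(resid, ddof=ddof))
    abs_resid = np.abs(resid)
    y_tol = DEGENERACY_RTOL * max(1.0, float(np.abs(y).max()))
    return PairModel(
        source_feature=source_feature,
        target_feature=target_feature,
        slope=slope,
        intercept=intercept,
        residual_std=residual_std,
        n_train=n,
        degenerate=bool(predictor_degenerate or residual_std <= y_tol),
        abs_residual_mean=float(abs_resid.mean()),
        abs_residual_std=float(np.std(abs_resid, ddof=ddof)),
        ddof=ddof,
        predictor_degenerate=bool(predictor_degenerate),
        scale_tol=y_tol,
    )


@dataclass
class ReferenceModelSet:
    """All n_f(n_f − 1) directional pair models fitted on one instance set.

    Stored as dense (f × f) coefficient matrices indexed
    ``[predictor, response]``; :meth:`pair_model` materializes a single
    :class:`PairModel` and :attr:`models` the full ordered-pair dict.
    """

    feature_ids: list[str]
    slope: np.ndarray
    intercept: np.ndarray
    residual_std: np.ndarray
    degenerate: np.ndarray
    abs_residual_mean: np.ndarray
    abs_residual_std: np.ndarray
    predictor_degenerate: np.ndarray  # per feature, as predictor
    response_tol: np.ndarray  # per feature, as response
    n_train: int
    ddof: int = 1
    training_scope: str = "all"

    def __post_init__(self) -> None:
        f = len(self.feature_ids)
        for name in ("slope", "intercept", "residual_std", "degenerate"):
            if getattr(self, name).shape != (f, f):
                raise ValueError(f"{name} must be an {f}x{f} matrix")

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def _index(self, feature_id: str) -> int:
        return self.feature_ids.index(str(feature_id))

    def available(self, mode: str = "signed") -> np.ndarray:
        """Boolean (f × f) matrix of directions usable in ``mode``."""
        if mode == "signed":
            avail = ~self.degenerate
        elif mode == "absolute":
            avail = (~self.predictor_degenerate[:, None]) & (
                self.abs_residual_std > self.response_tol[None, :]
            )
        else:
            raise ValueError(f"unknown z-score mode: {mode!r}")
        avail = avail.copy()
        np.fill_diagonal(avail, False)
        return avail

    def pair_model(self, source_feature: str, target_feature: str) -> PairModel:
        i = self._index(source_feature)
        j = self._index(target_feature)
        if i == j:
            raise KeyError("pair models are defined for distinct features only")
        return PairModel(
            source_feature=self.feature_ids[i],
            target_feature=self.feature_ids[j],
            slope=float(self.slope[i, j]),
            intercept=float(self.intercept[i, j]),
            residual_std=float(self.residual_std[i, j]),
            n_train=self.n_train,
            degenerate=bool(self.degenerate[i, j]),
            abs_residual_mean=float(self.abs_residual_mean[i, j]),
            abs_residual_std=float(self.abs_residual_std[i, j]),
            ddof=self.ddof,
            predictor_degenerate=bool(self.predictor_degenerate[i]),
            scale_tol=float(self.response_tol[j]),
        )

    @property
    def models(self) -> dict[tuple[str, str], PairModel]:
        """Dict over all ordered pairs; O(f²) objects, built on demand."""
        out: dict[tuple[str, str], PairModel] = {}
        for i, fi in enumerate(self.feature_ids):
            for j, fj in enumerate(self.feature_ids):
                if i != j:
                    out[(fi, fj)] = self.pair_model(fi, fj)
        return out

    def __len__(self) -> int:
        f = self.n_features
        return f * (f - 1)


def fit_reference_models(
    dataset: ExpressionDataset,
    include=None,
    *,
    ddof: int = 1,
    training_scope: str | None = None,
) -> ReferenceModelSet:
    """Fit all ordered-pair OLS reference models on the selected instances.

    ``include`` may be None (all instances), a sequence of instance ids,
    integer indices, or a boolean mask.  Vectorized over pairs; each entry
    agrees with :func:`fit_pair_model` on the same data.
    """
    idx = _selector_indices(dataset, include)
    X = dataset.values[idx]
    n = X.shape[0]
    if n < MIN_TRAIN:
        raise ValueError(
            f"insufficient training instances: need >= {MIN_TRAIN}, got {n}"
        )
    m = X.mean(axis=0)
    Xc = X - m
    S = Xc.T @ Xc  # cross-product sums; diag = per-feature sum of squares
    ss = np.diag(S).copy()
    feat_tol = DEGENERACY_RTOL * np.maximum(1.0, np.abs(X).max(axis=0))
    pred_degen = np.sqrt(ss / (n - 1)) <= feat_tol

    with np.errstate(divide="ignore", invalid="ignore"):
        slope = S / ss[:, None]
    slope[pred_degen, :] = 0.0
    intercept = m[None, :] - slope * m[:, None]

    # Signed residual tensor R[t, i, j] = resid of instance t in plane i→j.
    R = Xc[:, None, :] - slope[None, :, :] * Xc[:, :, None]
    residual_std = np.std(R, axis=0, ddof=ddof)
    absR = np.abs(R)
    abs_mean = absR.mean(axis=0)
    abs_std = np.std(absR, axis=0, ddof=ddof)

    degenerate = pred_degen[:, None] | (residual_std <= feat_tol[None, :])
    np.fill_diagonal(degenerate, True)

    if training_scope is None:
        if include is None:
            training_scope = f"all {n} instances"
        else:
            training_scope = f"{n} selected instances"
    return ReferenceModelSet(
        feature_ids=list(dataset.feature_ids),
        slope=slope,
        intercept=intercept,
        residual_std=residual_std,
        degenerate=degenerate,
        abs_residual_mean=abs_mean,
        abs_residual_std=abs_std,
        predictor_degenerate=pred_degen,
        response_tol=feat_tol,
        n_train=n,
        ddof=ddof,
        training_scope=training_scope,
    )


def edge_weight(
    model_ij: PairModel,
    model_ji: PairModel,
    x_i: float,
    x_j: float,
    combine: str = "mean",
    mode: str = "signed",
) -> float:
    """Combine the two directional z-scores of one feature pair."""
    w, _ = edge_weight_with_status(model_ij, model_ji, x_i, x_j, combine, mode)
    return w


def edge_weight_with_status(
    model_ij: PairModel,
    model_ji: PairModel,
    x_i: float,
    x_j: float,
    combine: str = "mean",
    mode: str = "signed",
) -> tuple[float, int]:
    """As :func:`edge_weight`, also reporting the edge status code."""
    if combine not in COMBINE_RULES:
        raise ValueError(f"unknown combine rule: {combine!r}")
    if not (
        model_ij.source_feature == model_ji.target_feature
        and model_ij.target_feature == model_ji.source_feature
    ):
        raise ValueError("models are not the two directions of one pair")
    if not (np.isfinite(x_i) and np.isfinite(x_j)):
        raise ValueError("subject values must be finite")

    scores = []
    if model_ij.usable(mode):
        scores.append(model_ij.zscore(x_i, x_j, mode))
    if model_ji.usable(mode):
        scores.append(model_ji.zscore(x_j, x_i, mode))
    if not scores:
        logger.warning(
            "both directions degenerate for pair (%s, %s); edge absent",
            model_ij.source_feature,
            model_ij.target_feature,
        )
        return 0.0, STATUS_ABSENT
    if combine == "mean":
        w = sum(scores) / len(scores)
    elif combine == "max":
        w = max(scores)
    else:
        w = min(scores)
    status = STATUS_VALID if len(scores) == 2 else STATUS_ONE_DIRECTION
    return float(w), status


@dataclass
class ParencliticNetwork:
    """One subject's symmetric non-negative deviation network.

    ``weights`` are dimensionless absolute z-scores; ``edge_status`` flags
    per pair whether both, one or neither direction contributed.
    """

    subject_id: str
    feature_ids: list[str]
    weights: np.ndarray
    edge_status: np.ndarray

    def __post_init__(self) -> None:
        self.feature_ids = _check_unique(self.feature_ids, "feature")
        f = len(self.feature_ids)
        self.weights = np.asarray(self.weights, dtype=float)
        self.edge_status = np.asarray(self.edge_status, dtype=np.int8)
        if self.weights.shape != (f, f) or self.edge_status.shape != (f, f):
            raise ValueError(f"weights/edge_status must be {f}x{f}")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("weights contain non-finite entries")
        if not np.array_equal(self.weights, self.weights.T):
            raise ValueError("weight matrix must be symmetric")
        if np.any(self.weights < 0):
            raise ValueError("weights must be non-negative")
        if np.any(np.diag(self.weights) != 0):
            raise ValueError("diagonal must be zero")

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def _index(self, feature_id: str) -> int:
        return self.feature_ids.index(str(feature_id))

    def weight(self, i: str, j: str) -> float:
        return float(self.weights[self._index(i), self._index(j)])

    def status(self, i: str, j: str) -> str:
        return STATUS_LABELS[int(self.edge_status[self._index(i), self._index(j)])]

    def edges(self, min_weight: float = 0.0):
        """Yield (source, target, weight, status) over positive-weight pairs,
        sorted by (source, target) id."""
        rows = []
        for i in range(self.n_features):
            for j in range(i + 1, self.n_features):
                w = self.weights[i, j]
                if w > 0 and w >= min_weight:
                    rows.append(
                        (
                            self.feature_ids[i],
                            self.feature_ids[j],
                            float(w),
                            STATUS_LABELS[int(self.edge_status[i, j])],
                        )
                    )
        rows.sort(key=lambda r: (r[0], r[1]))
        return rows

    def to_networkx(self, min_weight: float = 0.0):
        """Graph over all features; edges are positive-weight pairs
        (optionally at least ``min_weight``), with weight/status attrs."""
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.feature_ids)
        for src, tgt, w, st in self.edges(min_weight):
            g.add_edge(src, tgt, weight=w, status=st)
        return g

    def subnetwork(self, keep_ids: Sequence[str]) -> "ParencliticNetwork":
        idx = [self._index(i) for i in keep_ids]
        return ParencliticNetwork(
            subject_id=self.subject_id,
            feature_ids=[self.feature_ids[i] for i in idx],
            weights=self.weights[np.ix_(idx, idx)],
            edge_status=self.edge_status[np.ix_(idx, idx)],
        )

    def edge_dataframe(self, min_weight: float = 0.0) -> pd.DataFrame:
        return pd.DataFrame(
            self.edges(min_weight), columns=["source", "target", "weight", "status"]
        )


def _align_subject(subject, feature_ids: Sequence[str]) -> np.ndarray:
    if isinstance(subject, pd.Series):
        subject = subject.to_dict()
    if isinstance(subject, Mapping):
        missing = [f for f in feature_ids if f not in subject]
        extra = [f for f in subject if f not in set(feature_ids)]
        if missing or extra:
            raise ValueError(
                f"subject features do not match models (missing={missing}, "
                f"extra={extra})"
            )
        x = np.array([float(subject[f]) for f in feature_ids])
    else:
        x = np.asarray(subject, dtype=float)
        if x.shape != (len(feature_ids),):
            raise ValueError(
                f"subject vector length {x.shape} does not match "
                f"{len(feature_ids)} model features"
            )
    if not np.all(np.isfinite(x)):
        raise ValueError("subject values must be finite")
    return x


def build_network(
    subject_features,
    models: ReferenceModelSet,
    combine: str = "mean",
    *,
    mode: str = "signed",
    subject_id: str = "subject",
) -> ParencliticNetwork:
    """Build one subject's parenclitic network against a reference set.

    ``subject_features`` is a vector aligned with ``models.feature_ids``
    or a mapping/Series keyed by feature id.  Each unordered pair combines
    its two directional z-scores with ``combine`` (mean by default);
    degenerate directions are dropped, fully degenerate pairs become
    weight-0 "absent" edges.
    """
    if combine not in COMBINE_RULES:
        raise ValueError(f"unknown combine rule: {combine!r}")
    x = _align_subject(subject_features, models.feature_ids)
    f = models.n_features

    pred = models.slope * x[:, None] + models.intercept  # [i, j]: E[x_j | x_i]
    D = np.abs(x[None, :] - pred)
    avail = models.available(mode)
    with np.errstate(divide="ignore", invalid="ignore"):
        if mode == "signed":
            Z = D / models.residual_std
        else:
            Z = np.abs(D - models.abs_residual_mean) / models.abs_residual_std
    Z = np.where(avail, Z, 0.0)

    a = avail.astype(float)
    cnt = a + a.T
    if combine == "mean":
        Wsum = Z + Z.T  # exactly symmetric
        with np.errstate(invalid="ignore"):
            W = np.where(cnt > 0, Wsum / np.maximum(cnt, 1.0), 0.0)
    elif combine == "max":
        W = np.maximum(Z, Z.T)
        W = np.where(cnt > 0, W, 0.0)
    else:  # min over available directions
        Zm = np.where(avail, Z, np.inf)
        W = np.minimum(Zm, Zm.T)
        W = np.where(cnt > 0, W, 0.0)
    np.fill_diagonal(W, 0.0)

    status = np.where(
        cnt >= 2, STATUS_VALID, np.where(cnt == 1, STATUS_ONE_DIRECTION, STATUS_ABSENT)
    ).astype(np.int8)
    np.fill_diagonal(status, STATUS_ABSENT)

    n_absent = int(np.sum((status == STATUS_ABSENT)[np.triu_indices(f, k=1)]))
    if n_absent:
        logger.warning(
            "subject %s: %d feature pair(s) fully degenerate; edges absent",
            subject_id,
            n_absent,
        )
    return ParencliticNetwork(
        subject_id=str(subject_id),
        feature_ids=list(models.feature_ids),
        weights=W,
        edge_status=status,
    )
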