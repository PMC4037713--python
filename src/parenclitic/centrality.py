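"""α-centrality and topological summaries of parenclitic networks.

α-centrality solves ``x = αWx + e``: a node's centrality is α times the
weighted sum of its neighbours' centralities plus an exogenous term *e*
(all ones by default).  For the solution to exist and stay non-negative,
α must be below the reciprocal of the spectral radius of W; the default
places it at 90% of that bound.  Hubs — the high-centrality nodes — are
the features whose pairwise relationships deviate most broadly from the
reference models.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .core import (
    STATUS_ABSENT,
    STATUS_LABELS,
    ParencliticNetwork,
)

logger = logging.getLogger(__name__)


@dataclass
class CentralityResult:
    """α-centrality scores with the α used and normalization convention."""

    feature_ids: list[str]
    scores: np.ndarray
    alpha: float
    alpha_fraction: float
    normalized: bool
    residual: float  # ‖x − (αWx + e)‖∞ of the unnormalized solution

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.feature_ids),):
            raise ValueError("scores length does not match feature_ids")

    def score(self, feature_id: str) -> float:
        return float(self.scores[self.feature_ids.index(str(feature_id))])

    def to_dataframe(self) -> pd.DataFrame:
        order = ranked(self)
        df = pd.DataFrame(order, columns=["feature_id", "centrality"])
        df["rank"] = np.arange(1, len(order) + 1)
        return df


def _as_matrix(network) -> tuple[np.ndarray, list[str]]:
    if isinstance(network, ParencliticNetwork):
        return network.weights, network.feature_ids
    W = np.asarray(network, dtype=float)
    return W, [f"n{i}" for i in range(W.shape[0])]


def spectral_radius(network) -> float:
    """Largest absolute eigenvalue of the (symmetric) weight matrix."""
    W, _ = _as_matrix(network)
    if W.size == 0:
        return 0.0
    if not np.allclose(W, W.T):
        raise ValueError("weight matrix must be symmetric")
    return float(np.max(np.abs(np.linalg.eigvalsh(W))))


def alpha_centrality(
    network,
    alpha_fraction: float = 0.9,
    exogenous: np.ndarray | None = None,
    *,
    alpha: float | None = None,
    normalized: bool = True,
) -> CentralityResult:
    """Solve ``x = αWx + e`` on a parenclitic network.

    By default ``α = alpha_fraction / λ_max(W)`` with ``alpha_fraction``
    strictly inside (0, 1), which guarantees an invertible, entrywise
    non-negative Neumann series.  Pass ``alpha`` to fix α directly.  The
    solution is normalized so the top node scores 1 (when any score is
    positive).
    """
    W, feature_ids = _as_matrix(network)
    n = W.shape[0]
    if W.shape != (n, n) or not np.all(np.isfinite(W)):
        raise ValueError("weight matrix must be square and finite")
    if n and not np.array_equal(W, W.T):
        raise ValueError("weight matrix must be symmetric")

    lam = spectral_radius(W) if n else 0.0
    if alpha is None:
        if not 0.0 < alpha_fraction < 1.0:
            raise ValueError("alpha_fraction must be in (0, 1)")
        # W = 0 has no spectral constraint; any fixed α gives x = e.
        alpha = alpha_fraction / lam if lam > 0 else alpha_fraction
    else:
        alpha = float(alpha)
        alpha_fraction = alpha * lam

    e = np.ones(n) if exogenous is None else np.asarray(exogenous, dtype=float)
    if e.shape != (n,):
        raise ValueError("exogenous vector has wrong length")

    M = np.eye(n) - alpha * W
    x = np.linalg.solve(M, e) if n else e.copy()
    if n:
        # one step of iterative refinement tightens the fixed point
        x = x + np.linalg.solve(M, e - M @ x)
    residual = float(np.max(np.abs(x - (alpha * (W @ x) + e)))) if n else 0.0

    if normalized and n and x.max() > 0:
        x = x / x.max()
    return CentralityResult(
        feature_ids=list(feature_ids),
        scores=x,
        alpha=float(alpha),
        alpha_fraction=float(alpha_fraction),
        normalized=normalized,
        residual=residual,
    )


def ranked(result: CentralityResult) -> list[tuple[str, float]]:
    """Full ranking, descending score, ties by lexicographic feature id."""
    pairs = list(zip(result.feature_ids, (float(s) for s in result.scores)))
    pairs.sort(key=lambda p: (-p[1], p[0]))
    return pairs


def top_k(result: CentralityResult, k: int = 20) -> list[tuple[str, float]]:
    """The k most central features (deterministic tie-break)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    order = ranked(result)
    if k > len(order):
        logger.warning(
            "k=%d exceeds the %d available features; returning all", k, len(order)
        )
        return order
    return order[:k]


def threshold_network(
    network: ParencliticNetwork, min_weight: float, *, strict: bool = False
) -> ParencliticNetwork:
    """Zero out edges below ``min_weight`` (weight ≥ threshold kept).

    ``strict=True`` keeps strictly greater weights instead — the display
    convention of some figures; immaterial for continuous weights.
    """
    if min_weight < 0:
        raise ValueError("min_weight must be >= 0")
    keep = (
        network.weights > min_weight if strict else network.weights >= min_weight
    )
    W = np.where(keep, network.weights, 0.0)
    np.fill_diagonal(W, 0.0)
    status = network.edge_status.copy()
    status[(network.weights > 0) & ~keep] = STATUS_ABSENT
    return ParencliticNetwork(
        subject_id=network.subject_id,
        feature_ids=list(network.feature_ids),
        weights=W,
        edge_status=status,
    )


def giant_component(network: ParencliticNetwork) -> ParencliticNetwork:
    """Restrict to the largest connected component of positive-weight edges.

    Isolated nodes are dropped; size ties resolve to the component holding
    the lexicographically smallest feature id.  A network with no edges
    yields an empty result.
    """
    g = network.to_networkx()
    g.remove_nodes_from([n for n in list(g.nodes) if g.degree(n) == 0])
    if g.number_of_nodes() == 0:
        logger.warning(
            "subject %s: network has no positive-weight edges; "
            "giant component is empty",
            network.subject_id,
        )
        return ParencliticNetwork(
            subject_id=network.subject_id,
            feature_ids=[],
            weights=np.zeros((0, 0)),
            edge_status=np.zeros((0, 0), dtype=np.int8),
        )
    comp = min(nx.connected_components(g), key=lambda c: (-len(c), min(c)))
    keep = [f for f in network.feature_ids if f in comp]
    return network.subnetwork(keep)


def link_density(network: ParencliticNetwork, min_weight: float = 0.0) -> float:
    """Fraction of feature pairs joined by an edge of weight ≥ min_weight.

    An edge exists where the weight is positive; the denominator is the
    number of unordered feature pairs.
    """
    f = network.n_features
    if f < 2:
        raise ValueError("link density requires at least two features")
    iu = np.triu_indices(f, k=1)
    w = network.weights[iu]
    qualifying = int(np.sum((w > 0) & (w >= min_weight)))
    return qualifying / (f * (f - 1) / 2)
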