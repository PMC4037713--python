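"""In-silico validation dataset: linear trends, noise, planted anomalies.

Each feature *j* evolves linearly with the instance index *t* (1-based):
``value[t, j] = a_j·t + b_j + ζ``, with per-feature coefficients ``a_j``,
``b_j`` drawn once from a normal distribution and per-entry noise ζ drawn
from N(0, noise_std²).  The shared linear trend makes every feature pair
strongly correlated across instances; the noise emulates natural
expression variability.  Planted perturbations then shift chosen entries
of one "abnormal" instance — by default features 5 and 10 of instance 10
are incremented by 2 — so the leave-one-out pipeline should flag exactly
those features as hubs of that instance's network.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .core import ExpressionDataset

#: Default planted anomalies: (instance, feature, delta), all 1-based.
DEFAULT_PERTURBATIONS: tuple[tuple[int, int, float], ...] = (
    (10, 5, 2.0),
    (10, 10, 2.0),
)


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic expression generator.

    ``slope_params`` / ``intercept_params`` are (mean, std) of the normal
    distribution the per-feature coefficients are drawn from; ``noise_std``
    scales the per-entry Gaussian noise.  Perturbation indices are 1-based
    so "instance 10, feature 5" reads literally.
    """

    n_instances: int = 10
    n_features: int = 20
    slope_params: tuple[float, float] = (0.0, 1.0)
    intercept_params: tuple[float, float] = (0.0, 1.0)
    noise_std: float = 1.0
    perturbations: Sequence[tuple[int, int, float]] = DEFAULT_PERTURBATIONS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_instances < 3:
            raise ValueError("n_instances must be >= 3")
        if self.n_features < 2:
            raise ValueError("n_features must be >= 2")
        if self.noise_std < 0:
            raise ValueError("noise_std must be >= 0")
        for s in (self.slope_params, self.intercept_params):
            if len(s) != 2 or s[1] < 0:
                raise ValueError("coefficient params must be (mean, std>=0)")
        for inst, feat, _ in self.perturbations:
            if not 1 <= inst <= self.n_instances:
                raise ValueError(f"perturbation instance {inst} out of range")
            if not 1 <= feat <= self.n_features:
                raise ValueError(f"perturbation feature {feat} out of range")


def _pad_ids(prefix: str, n: int) -> list[str]:
    width = max(2, len(str(n)))
    return [f"{prefix}{i:0{width}d}" for i in range(1, n + 1)]


def generate_synthetic(
    spec: SyntheticSpec,
    trend: Callable[[np.ndarray, np.ndarray, np.ndarray], np.ndarray] | None = None,
) -> ExpressionDataset:
    """Generate the synthetic dataset described by ``spec``.

    ``trend(t, slopes, intercepts)`` may replace the default linear form
    ``slopes·t + intercepts``; it receives the 1-based instance index
    column vector ``t`` of shape (n_instances, 1) and per-feature
    coefficient rows, and must return the (n_instances, n_features) trend.
    Identical seeds reproduce the dataset bit-for-bit, and the noise draw
    is independent of the perturbation list, so a run with perturbations
    differs from one without exactly at the perturbed entries.
    """
    rng = np.random.default_rng(spec.seed)
    n, f = spec.n_instances, spec.n_features
    slopes = rng.normal(*spec.slope_params, size=f)
    intercepts = rng.normal(*spec.intercept_params, size=f)
    noise = rng.normal(0.0, 1.0, size=(n, f)) * spec.noise_std

    t = np.arange(1, n + 1, dtype=float)[:, None]
    if trend is None:
        values = slopes[None, :] * t + intercepts[None, :]
    else:
        values = np.asarray(trend(t, slopes, intercepts), dtype=float)
        if values.shape != (n, f):
            raise ValueError("trend callback returned wrong shape")
    values = values + noise
    for inst, feat, delta in spec.perturbations:
        values[inst - 1, feat - 1] += delta

    return ExpressionDataset(
        values=values,
        instance_ids=_pad_ids("T", n),
        feature_ids=_pad_ids("F", f),
    )
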