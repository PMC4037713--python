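"""Study orchestration: leave-one-out over instances, or class references.

Two designs are supported, both producing one network (plus centrality
ranking and density summary) per analyzed instance:

* :func:`loo_networks` — the time-series design: to analyze instance τ,
  reference models are fitted on **all other** instances, so τ's network
  shows the deviations specific to τ.
* :func:`class_networks` — the general labeled-population design: models
  are fitted on the members of one class and an unlabeled subject is
  scored against them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import __version__
from .centrality import CentralityResult, alpha_centrality, link_density, top_k
from .core import (
    ExpressionDataset,
    MIN_TRAIN,
    ParencliticNetwork,
    build_network,
    fit_reference_models,
)


@dataclass
class InstanceResult:
    """Network, centrality and summaries for one analyzed instance."""

    instance_id: str
    network: ParencliticNetwork
    centrality: CentralityResult
    ranking: list[tuple[str, float]]
    density: float


@dataclass
class PipelineResult:
    """Ordered per-instance results plus the reproducibility snapshot."""

    results: dict[str, InstanceResult]
    config: dict
    version: str = __version__

    def __iter__(self):
        return iter(self.results.values())

    def __getitem__(self, instance_id: str) -> InstanceResult:
        return self.results[instance_id]

    def summary_rows(self) -> list[dict]:
        rows = []
        for r in self:
            top_id, top_score = r.ranking[0] if r.ranking else ("", float("nan"))
            rows.append(
                {
                    "instance": r.instance_id,
                    "density": r.density,
                    "top_feature": top_id,
                    "top_centrality": top_score,
                }
            )
        return rows


def _analyze(
    network: ParencliticNetwork,
    alpha_fraction: float,
    k: int,
    density_threshold: float,
) -> InstanceResult:
    cent = alpha_centrality(network, alpha_fraction=alpha_fraction)
    return InstanceResult(
        instance_id=network.subject_id,
        network=network,
        centrality=cent,
        ranking=top_k(cent, min(k, network.n_features)),
        density=link_density(network, density_threshold),
    )


def loo_networks(
    dataset: ExpressionDataset,
    combine: str = "mean",
    alpha_fraction: float = 0.9,
    k: int = 20,
    density_threshold: float = 1.5,
    *,
    ddof: int = 1,
    mode: str = "signed",
) -> PipelineResult:
    """Leave-one-out design: one network per instance.

    For each instance τ, reference models are fitted on the remaining
    instances only — no value of τ influences its own reference — and τ's
    vector is scored against them.
    """
    n = dataset.n_instances
    if n < MIN_TRAIN + 1:
        raise ValueError(
            f"leave-one-out needs >= {MIN_TRAIN + 1} instances, got {n}"
        )
    results: dict[str, InstanceResult] = {}
    mask = np.ones(n, dtype=bool)
    for tau, inst_id in enumerate(dataset.instance_ids):
        mask[:] = True
        mask[tau] = False
        models = fit_reference_models(
            dataset,
            mask,
            ddof=ddof,
            training_scope=f"exclude instance {inst_id}",
        )
        net = build_network(
            dataset.values[tau], models, combine, mode=mode, subject_id=inst_id
        )
        results[inst_id] = _analyze(net, alpha_fraction, k, density_threshold)
    config = {
        "design": "leave-one-out",
        "combine": combine,
        "alpha_fraction": alpha_fraction,
        "k": k,
        "density_threshold": density_threshold,
        "ddof": ddof,
        "zscore_mode": mode,
        "n_instances": n,
        "n_features": dataset.n_features,
    }
    return PipelineResult(results=results, config=config)


def class_networks(
    train: ExpressionDataset,
    subject,
    target_class: str,
    combine: str = "mean",
    *,
    subject_id: str = "subject",
    ddof: int = 1,
    mode: str = "signed",
) -> ParencliticNetwork:
    """Score an unlabeled subject against one class's reference models.

    The models are fitted on the training instances labeled
    ``target_class`` (at least 3 required).  Evaluating the same subject
    against several classes — one call per class — yields one network per
    class, whose summary statistics (density, hubs) can then be compared.
    """
    if train.class_labels is None:
        raise ValueError("training dataset has no class labels")
    members = [
        i for i, c in enumerate(train.class_labels) if c == str(target_class)
    ]
    if str(target_class) not in set(train.class_labels):
        raise ValueError(f"unknown class: {target_class!r}")
    if len(members) < MIN_TRAIN:
        raise ValueError(
            f"class {target_class!r} has {len(members)} members; "
            f"need >= {MIN_TRAIN}"
        )
    models = fit_reference_models(
        train,
        members,
        ddof=ddof,
        training_scope=f"class={target_class}",
    )
    return build_network(subject, models, combine, mode=mode, subject_id=subject_id)
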