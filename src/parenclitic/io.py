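"""Readers and writers: expression matrices, networks, centralities, configs.

All writers use stable orderings so outputs are byte-reproducible, and
everything written can be read back by this module.  Matrix parsing is
strict: any cell that does not parse as a finite number is a hard error
naming its row and column — the method assumes complete data.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .centrality import CentralityResult
from .core import (
    STATUS_CODES,
    STATUS_LABELS,
    STATUS_VALID,
    ExpressionDataset,
    ParencliticNetwork,
)

_DELIMITERS = {".csv": ",", ".tsv": "\t", ".txt": "\t"}


def _delimiter(path: Path) -> str:
    try:
        return _DELIMITERS[path.suffix.lower()]
    except KeyError:
        raise ValueError(
            f"cannot infer delimiter from extension {path.suffix!r}; "
            "use .csv or .tsv"
        ) from None


def read_matrix(
    path,
    transpose: bool = False,
    *,
    label_column: str | None = None,
) -> ExpressionDataset:
    """Read an instances × features matrix from CSV/TSV.

    First row holds feature ids, first column instance ids; pass
    ``transpose=True`` for files with the opposite orientation.
    ``label_column`` names a column carrying per-instance class labels
    (incompatible with ``transpose``).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(
        path, sep=_delimiter(path), index_col=0, dtype=str, keep_default_na=False
    )
    if transpose:
        if label_column is not None:
            raise ValueError("label_column is not supported with transpose")
        df = df.T
    df.index = df.index.map(str)
    df.columns = df.columns.map(str)
    labels = None
    if label_column is not None:
        if label_column not in df.columns:
            raise ValueError(f"label column {label_column!r} not found")
        labels = [str(v) for v in df[label_column]]
        df = df.drop(columns=[label_column])

    if df.index.duplicated().any():
        dup = sorted(df.index[df.index.duplicated()])
        raise ValueError(f"duplicate instance ids in {path.name}: {dup}")
    if df.columns.duplicated().any():
        dup = sorted(df.columns[df.columns.duplicated()])
        raise ValueError(f"duplicate feature ids in {path.name}: {dup}")

    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = ~np.isfinite(numeric.to_numpy(dtype=float))
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValueError(
            f"non-numeric or non-finite cell in {path.name} at "
            f"instance {df.index[r]!r}, feature {df.columns[c]!r}: "
            f"{df.iat[r, c]!r}"
        )
    return ExpressionDataset.from_dataframe(numeric, class_labels=labels)


def write_matrix(dataset: ExpressionDataset, path) -> Path:
    """Write a dataset as CSV/TSV (delimiter from the extension)."""
    path = Path(path)
    dataset.to_dataframe().to_csv(path, sep=_delimiter(path))
    return path


def write_network(
    network: ParencliticNetwork,
    path,
    format: str | None = None,
    min_weight_display: float = 0.0,
    *,
    centrality: CentralityResult | None = None,
) -> Path:
    """Write a network as GraphML or a TSV edge list.

    ``min_weight_display`` drops lighter edges from the written file (a
    display convention; the in-memory network is untouched).  A
    :class:`CentralityResult` adds an ``alpha_centrality`` node attribute
    to GraphML output.
    """
    path = Path(path)
    if format is None:
        format = "graphml" if path.suffix.lower() == ".graphml" else "edgelist"
    if format == "graphml":
        g = network.to_networkx(min_weight_display)
        if centrality is not None:
            for fid, score in zip(centrality.feature_ids, centrality.scores):
                if fid in g:
                    g.nodes[fid]["alpha_centrality"] = float(score)
        nx.write_graphml(g, path)
    elif format == "edgelist":
        network.edge_dataframe(min_weight_display).to_csv(
            path, sep="\t", index=False
        )
    else:
        raise ValueError(f"unknown network format: {format!r}")
    return path


def read_network(path, subject_id: str | None = None) -> ParencliticNetwork:
    """Read a GraphML file written by :func:`write_network`."""
    path = Path(path)
    g = nx.read_graphml(path)
    ids = [str(n) for n in g.nodes]
    idx = {f: i for i, f in enumerate(ids)}
    f = len(ids)
    W = np.zeros((f, f))
    status = np.zeros((f, f), dtype=np.int8)
    for u, v, data in g.edges(data=True):
        w = float(data.get("weight", 0.0))
        st = STATUS_CODES.get(str(data.get("status", "valid")), STATUS_VALID)
        i, j = idx[str(u)], idx[str(v)]
        W[i, j] = W[j, i] = w
        status[i, j] = status[j, i] = st
    return ParencliticNetwork(
        subject_id=str(subject_id or path.stem),
        feature_ids=ids,
        weights=W,
        edge_status=status,
    )


def write_centrality(result: CentralityResult, path) -> Path:
    """Write a centrality table (feature_id, centrality, rank) as CSV."""
    path = Path(path)
    result.to_dataframe().to_csv(path, index=False)
    return path


@dataclass
class RunConfig:
    """Validated snapshot of one pipeline run's settings."""

    input: str = ""
    transpose: bool = False
    combine: str = "mean"
    ddof: int = 1
    zscore_mode: str = "signed"
    alpha_fraction: float = 0.9
    k: int = 20
    density_threshold: float = 1.5
    display_threshold: float = 0.0
    seed: int = 0
    out_dir: str = "."

    def __post_init__(self) -> None:
        from .core import COMBINE_RULES, ZSCORE_MODES

        if self.combine not in COMBINE_RULES:
            raise ValueError(f"combine must be one of {COMBINE_RULES}")
        if self.zscore_mode not in ZSCORE_MODES:
            raise ValueError(f"zscore_mode must be one of {ZSCORE_MODES}")
        if not 0.0 < self.alpha_fraction < 1.0:
            raise ValueError("alpha_fraction must be in (0, 1)")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.density_threshold < 0 or self.display_threshold < 0:
            raise ValueError("thresholds must be >= 0")
        if self.ddof not in (0, 1):
            raise ValueError("ddof must be 0 or 1")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)
        return path
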