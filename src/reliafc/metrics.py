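"""Weighted degree centrality and network-level mean connectivity.

Degree centrality of a node in a weighted undirected graph is the sum of
its edge weights to all other nodes; here weights are Fisher-z values of
reliability-filtered absolute correlations, so Dc >= 0.  Network-level
summaries average the edge weights inside one network or between two
networks; zeros produced by the reliability filter stay in the mean by
default (zero encodes "unreliable", and dropping zeros would make the
denominators subject-specific).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .clustering import NetworkPartition
from .regions import NETWORK_PAIRS, NETWORKS
from .reliability import FilteredConnectome

__all__ = [
    "degree_centrality",
    "network_mean_fc",
    "degree_table",
    "network_fc_table",
    "network_edge_masks",
]


def _matrix_of(connectome: FilteredConnectome | np.ndarray) -> np.ndarray:
    values = (
        connectome.values
        if isinstance(connectome, FilteredConnectome)
        else np.asarray(connectome, dtype=float)
    )
    if not np.allclose(values, values.T, atol=1e-12):
        raise ValueError("connectome matrix must be symmetric")
    return values


def degree_centrality(connectome: FilteredConnectome | np.ndarray) -> np.ndarray:
    """Dc(i) = sum_{j != i} w(i, j) for every node."""
    values = _matrix_of(connectome)
    work = values.copy()
    np.fill_diagonal(work, 0.0)
    return work.sum(axis=1)


def _label_indices(partition: NetworkPartition) -> dict[str, np.ndarray]:
    if not partition.is_labeled:
        raise ValueError("partition must be labeled to define network edge sets")
    labels = np.asarray(partition.labels, dtype=object)
    return {net: np.flatnonzero(labels == net) for net in NETWORKS}


def network_edge_masks(partition: NetworkPartition) -> dict[tuple[str, str], np.ndarray]:
    """Boolean p x p masks (upper triangle) for the six network edge sets.

    The three within-network and three between-network sets are disjoint
    and jointly cover all p*(p-1)/2 edges.
    """
    idx = _label_indices(partition)
    p = len(partition.region_names)
    masks = {}
    for net in NETWORKS:
        mask = np.zeros((p, p), dtype=bool)
        mask[np.ix_(idx[net], idx[net])] = True
        masks[(net, net)] = np.triu(mask, 1)
    for a, b in NETWORK_PAIRS:
        mask = np.zeros((p, p), dtype=bool)
        mask[np.ix_(idx[a], idx[b])] = True
        mask[np.ix_(idx[b], idx[a])] = True
        masks[(a, b)] = np.triu(mask, 1)
    return masks


def network_mean_fc(
    connectome: FilteredConnectome | np.ndarray,
    partition: NetworkPartition,
    net_a: str,
    net_b: str | None = None,
    include_zeros: bool = True,
) -> float:
    """Mean edge weight within ``net_a`` or between ``net_a`` and ``net_b``."""
    values = _matrix_of(connectome)
    net_b = net_a if net_b is None else net_b
    idx = _label_indices(partition)
    if net_a == net_b and len(idx[net_a]) < 2:
        raise ValueError(f"network {net_a} has fewer than 2 regions")
    key = (net_a, net_b)
    if net_a != net_b and key not in NETWORK_PAIRS:
        key = (net_b, net_a)
    mask = network_edge_masks(partition)[key]
    edge_vals = values[mask]
    if not include_zeros:
        edge_vals = edge_vals[edge_vals != 0.0]
        if edge_vals.size == 0:
            return 0.0
    return float(edge_vals.mean())


def degree_table(connectomes: list[FilteredConnectome]) -> pd.DataFrame:
    """Subjects x regions table of Dc values."""
    rows = {c.subject_id: degree_centrality(c) for c in connectomes}
    names = connectomes[0].region_names
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=list(names))
    frame.index.name = "subject_id"
    return frame


def network_fc_table(
    connectomes: list[FilteredConnectome],
    partition: NetworkPartition,
    include_zeros: bool = True,
) -> pd.DataFrame:
    """Subjects x 6 table of within/between network mean FC (Fisher-z)."""
    columns = [f"{n}-{n}" for n in NETWORKS] + [f"{a}-{b}" for a, b in NETWORK_PAIRS]
    rows = {}
    for c in connectomes:
        rows[c.subject_id] = [
            network_mean_fc(c, partition, *key.split("-"), include_zeros=include_zeros)
            for key in columns
        ]
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=columns)
    frame.index.name = "subject_id"
    return frame
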