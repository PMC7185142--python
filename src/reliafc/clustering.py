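"""Hierarchical network partitioning of the 43 regions.

The group-mean absolute-correlation matrix is converted to the distance
``d(i, j) = 1 - |r(i, j)|`` and clustered agglomeratively (average linkage
by default), then the tree is cut into exactly three clusters.  Cluster
labels are matched to the reference DN/CN/AN networks by the label
permutation maximizing total overlap — an automated, reproducible
replacement for assignment by visual inspection.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .connectivity import ConnectivityMatrix
from .regions import NETWORKS, REFERENCE_LABELS, REGION_NAMES

__all__ = [
    "NetworkPartition",
    "reference_partition",
    "hierarchical_partition",
    "match_to_reference",
    "partition_shift",
]

LINKAGE_METHODS = ("average", "complete", "ward")


@dataclass
class NetworkPartition:
    """Assignment of each region to a cluster and (optionally) a network.

    ``clusters`` holds 0-based cluster ids; ``labels`` holds DN/CN/AN names
    once the partition has been matched to the reference (or for the
    reference itself).  ``overlap`` records, per network, how many regions
    the matched clustering shares with the reference.
    """

    region_names: tuple[str, ...]
    clusters: np.ndarray
    labels: np.ndarray | None = None
    source: str = "clustered"
    linkage_tree: np.ndarray | None = None
    overlap: dict[str, int] | None = None
    tie_flag: bool = False

    def __post_init__(self) -> None:
        self.clusters = np.asarray(self.clusters)
        if len(self.clusters) != len(self.region_names):
            raise ValueError("every region needs exactly one cluster assignment")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=object)
            if len(self.labels) != len(self.region_names):
                raise ValueError("every region needs exactly one label")

    @property
    def n_clusters(self) -> int:
        return len(np.unique(self.clusters))

    @property
    def is_labeled(self) -> bool:
        return self.labels is not None

    def assignment(self) -> dict[str, str]:
        if not self.is_labeled:
            raise ValueError("partition has no network labels yet")
        return dict(zip(self.region_names, self.labels))

    def members(self, label: str) -> list[str]:
        return [r for r, lab in zip(self.region_names, self.labels) if lab == label]

    def to_frame(self) -> pd.DataFrame:
        data = {"region": self.region_names, "cluster": self.clusters}
        if self.is_labeled:
            data["network"] = self.labels
        frame = pd.DataFrame(data)
        frame["source"] = self.source
        return frame

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def tree_to_json(self, path) -> None:
        if self.linkage_tree is None:
            raise ValueError("partition has no linkage tree")
        payload = {
            "linkage": [
                {"merge": [int(a), int(b)], "height": float(h), "size": int(s)}
                for a, b, h, s in self.linkage_tree
            ]
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
            fh.write("\n")


def reference_partition() -> NetworkPartition:
    """The shipped task-defined DN/CN/AN labeling as a partition object."""
    labels = np.array([REFERENCE_LABELS[r] for r in REGION_NAMES], dtype=object)
    clusters = np.array([NETWORKS.index(lab) for lab in labels])
    return NetworkPartition(
        region_names=REGION_NAMES, clusters=clusters, labels=labels, source="reference"
    )


def hierarchical_partition(
    mean_matrix: ConnectivityMatrix, k: int = 3, method: str = "average"
) -> NetworkPartition:
    """Cut the agglomerative tree of ``1 - |r|`` distances into k clusters."""
    p = mean_matrix.n_regions
    if not 1 <= k <= p:
        raise ValueError(f"k must lie in [1, {p}], got {k}")
    if method not in LINKAGE_METHODS:
        raise ValueError(f"linkage method must be one of {LINKAGE_METHODS}")
    dist = 1.0 - mean_matrix.values
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    tree = linkage(condensed, method=method)
    flat = fcluster(tree, t=k, criterion="maxclust")
    # relabel cluster ids by lowest member region index for determinism
    order = {}
    for cid in flat:
        if cid not in order:
            order[cid] = len(order)
    clusters = np.array([order[c] for c in flat])
    tag = mean_matrix.tag or "unknown"
    return NetworkPartition(
        region_names=mean_matrix.region_names,
        clusters=clusters,
        source=f"clustered:{tag}",
        linkage_tree=tree,
    )


def match_to_reference(
    partition: NetworkPartition, reference: NetworkPartition | None = None
) -> NetworkPartition:
    """Label clusters DN/CN/AN by the overlap-maximizing permutation.

    All 3! = 6 assignments of the three network names to the three clusters
    are enumerated and the one with the largest total overlap with the
    reference labeling wins; ties go to the first permutation in
    lexicographic order and are flagged.
    """
    if reference is None:
        reference = reference_partition()
    if partition.region_names != reference.region_names:
        raise ValueError("partitions must cover the same regions in the same order")
    if not reference.is_labeled:
        raise ValueError("reference partition must be labeled")
    if partition.n_clusters != len(NETWORKS):
        raise ValueError(
            f"expected exactly {len(NETWORKS)} clusters, got {partition.n_clusters}"
        )
    ref_labels = np.asarray(reference.labels, dtype=object)
    cluster_ids = np.unique(partition.clusters)
    best_perm = None
    best_total = -1
    tie = False
    for perm in itertools.permutations(NETWORKS):
        mapping = dict(zip(cluster_ids, perm))
        labels = np.array([mapping[c] for c in partition.clusters], dtype=object)
        total = int(np.sum(labels == ref_labels))
        if total > best_total:
            best_total, best_perm, tie = total, perm, False
        elif total == best_total:
            tie = True
    mapping = dict(zip(cluster_ids, best_perm))
    labels = np.array([mapping[c] for c in partition.clusters], dtype=object)
    overlap = {
        net: int(np.sum((labels == net) & (ref_labels == net))) for net in NETWORKS
    }
    return NetworkPartition(
        region_names=partition.region_names,
        clusters=partition.clusters.copy(),
        labels=labels,
        source=partition.source,
        linkage_tree=partition.linkage_tree,
        overlap=overlap,
        tie_flag=tie,
    )


def partition_shift(
    a: NetworkPartition, b: NetworkPartition
) -> list[tuple[str, str, str]]:
    """Regions whose network label differs between two labeled partitions."""
    if not (a.is_labeled and b.is_labeled):
        raise ValueError("both partitions must be labeled")
    if a.region_names != b.region_names:
        raise ValueError("partitions must cover the same regions in the same order")
    return [
        (region, la, lb)
        for region, la, lb in zip(a.region_names, a.labels, b.labels)
        if la != lb
    ]
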