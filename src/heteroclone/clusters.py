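"""Named sample clusters with per-cluster membership thresholds.

A mutation is taken to truly exist in a cluster when it is called in at
least ``min_support[cluster]`` of the cluster's samples.  When a threshold
is not given it defaults to ``max(2, ceil(|cluster| / 2))`` — for cluster
sizes 6/2/3 this yields the 3-of-P1, 2-of-P2, 2-of-M rule used for the
multi-region HGSC case this package models.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import yaml

__all__ = ["ClusterScheme", "default_min_support", "read_cluster_yaml", "write_cluster_yaml"]


def default_min_support(size: int) -> int:
    return min(size, max(2, math.ceil(size / 2)))


@dataclass
class ClusterScheme:
    clusters: dict[str, list[str]]
    min_support: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for name, members in self.clusters.items():
            if not members:
                raise ValueError(f"cluster {name!r} is empty")
            dup = seen & set(members)
            if dup:
                raise ValueError(f"samples {sorted(dup)} appear in more than one cluster")
            seen.update(members)
        for name, members in self.clusters.items():
            ms = self.min_support.get(name)
            if ms is None:
                self.min_support[name] = default_min_support(len(members))
            elif not 1 <= ms <= len(members):
                raise ValueError(
                    f"min_support[{name!r}]={ms} outside [1, {len(members)}]"
                )

    @property
    def samples(self) -> list[str]:
        return [s for members in self.clusters.values() for s in members]

    def cluster_of(self, sample: str) -> str | None:
        for name, members in self.clusters.items():
            if sample in members:
                return name
        return None

    def partition(self) -> frozenset[frozenset[str]]:
        """Label-free view for comparing schemes."""
        return frozenset(frozenset(m) for m in self.clusters.values())


def read_cluster_yaml(path) -> ClusterScheme:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "clusters" not in doc:
        raise ValueError(f"{path}: expected a mapping with a 'clusters' key")
    clusters = {str(k): [str(s) for s in v] for k, v in doc["clusters"].items()}
    min_support = {str(k): int(v) for k, v in (doc.get("min_support") or {}).items()}
    return ClusterScheme(clusters=clusters, min_support=min_support)


def write_cluster_yaml(scheme: ClusterScheme, path) -> None:
    doc = {"clusters": scheme.clusters, "min_support": scheme.min_support}
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
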