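"""Mutation group classification and driver-table utilities.

A mutation is deemed present in a cluster when its call count among the
cluster's samples reaches the cluster's support threshold; it is then
labeled Common (present in all clusters), Shared (in >= 2 but not all,
with the cluster set recorded), Cluster-specific (exactly one cluster) or
Sample-specific (below every cluster threshold — even if the raw calls
touch several scattered samples).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .clusters import ClusterScheme
from .matrix import MutationMatrix

__all__ = [
    "ClusterPresence",
    "ClassificationResult",
    "DamagingVote",
    "cluster_presence",
    "classify_mutations",
    "group_percentages",
    "proportion_percent",
    "damaging_fraction",
    "normalized_af_fold_change",
    "load_candidate_drivers",
]

LABELS = ["Common", "Shared", "Cluster-specific", "Sample-specific"]


@dataclass
class ClusterPresence:
    """Binary clusters x loci matrix: support count >= min_support."""

    df: pd.DataFrame  # index: cluster labels, columns: locus ids

    @property
    def clusters(self) -> list[str]:
        return list(self.df.index)

    @property
    def loci(self) -> list[str]:
        return list(self.df.columns)


@dataclass
class ClassificationResult:
    table: pd.DataFrame  # columns: locus, label, clusters (comma-joined set)
    counts: dict[str, int]

    def label_of(self, locus: str) -> str:
        row = self.table[self.table["locus"] == locus]
        return row["label"].iloc[0] if len(row) else ""

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def cluster_presence(matrix: MutationMatrix, scheme: ClusterScheme) -> ClusterPresence:
    unknown = set(scheme.samples) - set(matrix.samples)
    if unknown:
        raise ValueError(f"cluster scheme references unknown sample(s) {sorted(unknown)}")
    rows = {}
    for name, members in scheme.clusters.items():
        support = matrix.df.loc[members].sum(axis=0)
        rows[name] = (support >= scheme.min_support[name]).astype(int)
    return ClusterPresence(pd.DataFrame(rows).T[matrix.loci])


def classify_mutations(presence: ClusterPresence) -> ClassificationResult:
    """Assign each locus to Common/Shared/Cluster-specific/Sample-specific."""
    n_clusters = len(presence.clusters)
    if n_clusters < 2:
        raise ValueError("classification needs at least 2 clusters")
    records = []
    for locus in presence.loci:
        hit = [c for c in presence.clusters if presence.df.at[c, locus] == 1]
        if len(hit) == n_clusters:
            label, cl = "Common", ""
        elif len(hit) >= 2:
            label, cl = "Shared", ",".join(sorted(hit))
        elif len(hit) == 1:
            label, cl = "Cluster-specific", hit[0]
        else:
            label, cl = "Sample-specific", ""
        records.append({"locus": locus, "label": label, "clusters": cl})
    table = pd.DataFrame(records, columns=["locus", "label", "clusters"])
    counts = {lab: int((table["label"] == lab).sum()) for lab in LABELS}
    return ClassificationResult(table=table, counts=counts)


def group_percentages(counts: dict[str, int]) -> dict[str, int]:
    """Whole-percent share of each group among all classified mutations."""
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no classified mutations")
    return {lab: round(100 * n / total) for lab, n in counts.items()}


def proportion_percent(numerator: int, denominator: int) -> float:
    """Percentage a/b as printed in cohort-comparison summaries (e.g. 3 of 20 -> 15.0)."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return 100.0 * numerator / denominator


@dataclass
class DamagingVote:
    """Damaging-prediction vote: damaging algorithms / available algorithms."""

    n_damaging: int
    n_available: int

    @property
    def fraction(self) -> float | None:
        if self.n_available == 0:
            return None  # N/A: no applicable algorithm (e.g. stop-gains)
        return self.n_damaging / self.n_available

    def __str__(self) -> str:
        if self.n_available == 0:
            return "N/A"
        return f"{self.n_damaging}/{self.n_available}"


def damaging_fraction(verdicts: list[tuple[bool, bool]]) -> DamagingVote:
    """Aggregate per-algorithm (available, damaging) verdicts for one locus."""
    n_avail = sum(1 for avail, _ in verdicts if avail)
    n_dam = sum(1 for avail, dam in verdicts if avail and dam)
    return DamagingVote(n_damaging=n_dam, n_available=n_avail)


def normalized_af_fold_change(
    af: pd.DataFrame,
    target_samples: list[str],
    comparator_samples: list[str],
) -> pd.Series:
    """Per-locus fold change of normalized allele fractions.

    ``af`` is loci x samples with entries in [0, 1].  Each sample's column
    is first divided by that sample's mean allele fraction over the
    validated somatic loci (a per-sample purity correction), then the fold
    change is the arithmetic mean of normalized values over the target
    samples divided by the mean over the comparator samples.  A zero
    comparator mean yields ``inf`` rather than an exception.
    """
    if set(target_samples) & set(comparator_samples):
        raise ValueError("target and comparator sample sets must be disjoint")
    arr = af[list(target_samples) + list(comparator_samples)]
    means = arr.mean(axis=0)
    zero = means[means == 0]
    if len(zero):
        raise ValueError(
            f"sample(s) {list(zero.index)} have all-zero allele fractions; "
            "normalizer undefined"
        )
    norm = arr / means
    t = norm[list(target_samples)].mean(axis=1)
    c = norm[list(comparator_samples)].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = t / c
    fold[(c == 0) & (t > 0)] = np.inf
    fold[(c == 0) & (t == 0)] = np.nan
    return fold


def load_candidate_drivers() -> pd.DataFrame:
    """Bundled candidate-driver mutation list for the multi-region HGSC case.

    Columns: group, chrom, pos, ref, alt, gene, aa_change, n_damaging,
    n_available, cosmic.  Stop-gain records carry no damaging vote (the
    prediction algorithms only score missense changes) and have NA counts.
    """
    ref = importlib.resources.files("heteroclone.data") / "candidate_drivers_hgsc.tsv"
    with importlib.resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    df["n_damaging"] = df["n_damaging"].astype("Int64")
    df["n_available"] = df["n_available"].astype("Int64")
    return df
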