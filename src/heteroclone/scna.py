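"""Somatic copy-number segment weighting and cluster-consensus classification.

Per-sample segments (log2 tumor/normal ratios) are harmonized onto the
breakpoint union across samples, each harmonized region is scored
``delta * max(log10 L, 1)`` (L = region length in bp; delta = +1 amplified,
-1 deleted, 0 neutral at the +/-0.2 log2 cutoffs, boundaries inclusive),
and the resulting samples x regions weight matrix feeds the same Pearson
distance / tree machinery as the mutation matrix.  Cluster consensus
requires unanimity: a cluster is amplified/deleted at a region only when
every member sample is; mixed clusters are discordant and excluded from
the Common/Shared/Specific agreement count.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import pandas as pd

from .clusters import ClusterScheme

logger = logging.getLogger(__name__)

__all__ = [
    "Region",
    "RegionWeightMatrix",
    "harmonize_regions",
    "call_delta",
    "segment_weight",
    "build_weight_matrix",
    "cluster_segment_status",
    "classify_segments",
    "summarize_segments",
]

Region = tuple[str, int, int]  # chrom, start, end (1-based inclusive)

AMP_CUT = 0.2
DEL_CUT = -0.2


@dataclass
class RegionWeightMatrix:
    """Samples x harmonized regions; entries delta * max(log10 L, 1)."""

    w: pd.DataFrame        # index: samples, columns: region id strings
    regions: list[Region]  # aligned with w.columns
    delta: pd.DataFrame    # same shape as w, entries in {-1, 0, +1}

    @property
    def samples(self) -> list[str]:
        return list(self.w.index)


def _region_id(r: Region) -> str:
    return f"{r[0]}:{r[1]}-{r[2]}"


def harmonize_regions(profiles: pd.DataFrame) -> list[Region]:
    """Partition each covered chromosome at the union of all breakpoints.

    ``profiles`` has columns sample, chrom, start, end, log2_ratio.
    Returns maximal disjoint intervals such that every input segment is a
    union of returned regions.
    """
    if profiles.empty:
        return []
    regions: list[Region] = []
    for chrom, grp in profiles.groupby("chrom", sort=False):
        points = sorted(set(grp["start"]) | set(grp["end"] + 1))
        for a, b in zip(points[:-1], points[1:]):
            lo, hi = a, b - 1
            covered = ((grp["start"] <= lo) & (grp["end"] >= hi)).any()
            if covered:
                regions.append((str(chrom), int(lo), int(hi)))
    regions.sort(key=lambda r: (r[0], r[1]))
    return regions


def call_delta(log2_ratio: float, amp_cut: float = AMP_CUT,
               del_cut: float = DEL_CUT) -> int:
    """+1 amplified (log2 >= amp_cut), -1 deleted (log2 <= del_cut), else 0."""
    if amp_cut <= del_cut:
        raise ValueError(f"amp_cut {amp_cut} must exceed del_cut {del_cut}")
    if not math.isfinite(log2_ratio):
        raise ValueError("non-finite log2 ratio")
    if log2_ratio >= amp_cut:
        return 1
    if log2_ratio <= del_cut:
        return -1
    return 0


def segment_weight(length_bp: int, delta: int) -> float:
    """delta * max(log10 L, 1): direction times floored log segment length."""
    if length_bp < 1:
        raise ValueError("segment length must be >= 1 bp")
    return delta * max(math.log10(length_bp), 1.0)


def build_weight_matrix(
    profiles: pd.DataFrame,
    regions: list[Region] | None = None,
    amp_cut: float = AMP_CUT,
    del_cut: float = DEL_CUT,
    drop_neutral: bool = True,
) -> RegionWeightMatrix:
    """Score every (sample, harmonized region) with the segment-weight formula.

    Regions with no segment data for a sample score 0 (count logged).  By
    default only regions altered (delta != 0) in at least one sample are
    kept as matrix columns; neutral-everywhere regions carry no signal.
    """
    if regions is None:
        regions = harmonize_regions(profiles)
    samples = list(dict.fromkeys(profiles["sample"]))
    delta = pd.DataFrame(0, index=samples, columns=[_region_id(r) for r in regions],
                         dtype=int)
    w = pd.DataFrame(0.0, index=samples, columns=delta.columns)
    n_nodata = 0
    by_sample = {s: g for s, g in profiles.groupby("sample", sort=False)}
    for r in regions:
        chrom, lo, hi = r
        rid = _region_id(r)
        length = hi - lo + 1
        for s in samples:
            g = by_sample[s]
            seg = g[(g["chrom"] == chrom) & (g["start"] <= lo) & (g["end"] >= hi)]
            if seg.empty:
                n_nodata += 1
                continue
            dl = call_delta(float(seg["log2_ratio"].iloc[0]), amp_cut, del_cut)
            delta.at[s, rid] = dl
            w.at[s, rid] = segment_weight(length, dl)
    if n_nodata:
        logger.info("%d (sample, region) pairs without segment data scored 0", n_nodata)
    if drop_neutral:
        keep = [c for c in w.columns if (delta[c] != 0).any()]
        kept_regions = [r for r in regions if _region_id(r) in set(keep)]
        return RegionWeightMatrix(w=w[keep], regions=kept_regions, delta=delta[keep])
    return RegionWeightMatrix(w=w, regions=regions, delta=delta)


def cluster_segment_status(wm: RegionWeightMatrix,
                           scheme: ClusterScheme) -> pd.DataFrame:
    """Per-region, per-cluster consensus status.

    amplified / deleted / neutral require unanimity of the cluster's
    member deltas; any disagreement makes the cluster discordant at that
    region (neglected downstream).
    """
    missing = set(scheme.samples) - set(wm.samples)
    if missing:
        raise ValueError(f"cluster scheme references unknown sample(s) {sorted(missing)}")
    out = {}
    for name, members in scheme.clusters.items():
        sub = wm.delta.loc[members]
        col = []
        for rid in wm.delta.columns:
            vals = set(sub[rid])
            if vals == {1}:
                col.append("amplified")
            elif vals == {-1}:
                col.append("deleted")
            elif vals == {0}:
                col.append("neutral")
            else:
                col.append("discordant")
        out[name] = col
    return pd.DataFrame(out, index=wm.delta.columns).T  # clusters x regions


_DIRECTION = {"amplified": "amp", "deleted": "del"}


def classify_segments(status: pd.DataFrame) -> pd.DataFrame:
    """Label each region Common / Shared(set) / Specific(cluster) / none.

    Discordant clusters are excluded from the agreement count.  Common:
    every cluster shares one non-neutral status.  Shared: a proper subset
    of >= 2 clusters shares it (ties between amplified and deleted subsets
    of equal size go to amplified).  Specific: exactly one cluster is
    non-neutral genome-wide at the region.
    """
    clusters = list(status.index)
    if len(clusters) < 2:
        raise ValueError("need >= 2 clusters")
    records = []
    for rid in status.columns:
        col = status[rid]
        amp = [c for c in clusters if col[c] == "amplified"]
        dele = [c for c in clusters if col[c] == "deleted"]
        label, direction, cset = "none", "", ""
        if len(amp) == len(clusters):
            label, direction = "Common", "amp"
        elif len(dele) == len(clusters):
            label, direction = "Common", "del"
        else:
            bigger, dir_ = (amp, "amp") if len(amp) >= len(dele) else (dele, "del")
            if len(bigger) >= 2:
                label, direction, cset = "Shared", dir_, ",".join(sorted(bigger))
            elif len(amp) + len(dele) == 1:
                only = (amp + dele)[0]
                label = "Specific"
                direction = "amp" if amp else "del"
                cset = only
        records.append({"region": rid, "label": label,
                        "direction": direction, "clusters": cset})
    return pd.DataFrame(records, columns=["region", "label", "direction", "clusters"])


def summarize_segments(labels: pd.DataFrame, regions: list[Region]) -> pd.DataFrame:
    """Segment count and total span (bp) per (label, direction).

    Adjacent same-label harmonized regions are NOT merged; each region
    counts once (the package's own spanning convention).
    """
    span = {_region_id(r): r[2] - r[1] + 1 for r in regions}
    rows = []
    for (label, direction), grp in labels.groupby(["label", "direction"]):
        if label == "none":
            continue
        total = int(sum(span.get(rid, 0) for rid in grp["region"]))
        rows.append({"label": label, "direction": direction,
                     "n_segments": len(grp), "span_bp": total})
    return pd.DataFrame(rows, columns=["label", "direction", "n_segments", "span_bp"])
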