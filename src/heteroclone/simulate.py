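"""Clonal-evolution simulator for multi-region tumor sequencing data.

Emulates a multi-region high-grade serous ovarian carcinoma: sample
clusters arranged on a ladder tree (default two primary clusters P1/P2
plus a metastatic cluster M, topology ((P1, M), P2) — the metastatic
cluster diverging late from P1's ancestor), mutation budgets per category
(trunk/common, shared between cluster pairs, cluster-specific,
sample-specific), branch-level copy-number segments, and discovery-phase
call noise (false-negative dropout of true calls, false-positive calls on
a decoy pool of artifact-prone candidate sites plus truth-absent pairs).

Every stochastic draw flows from the single integer ``seed`` via
per-stage child generators, so identical parameters reproduce
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .clusters import ClusterScheme, default_min_support
from .io import write_mutation_table, write_seg, write_newick, write_cluster_yaml
from .matrix import locus_id
from .phylo import SampleTree, TreeNode
from .validation import VALIDATION_COLUMNS, write_validation_table

__all__ = [
    "SimParams",
    "SimTruth",
    "DEFAULT_GENOME",
    "simulate_truth",
    "simulate_observed_calls",
    "simulate_validation_table",
    "expected_mutation_labels",
    "expected_segment_labels",
    "write_simulation",
]

#: hg19 autosomes + X, lengths rounded to the Mb
DEFAULT_GENOME: tuple[tuple[str, int], ...] = (
    ("chr1", 249_000_000), ("chr2", 243_000_000), ("chr3", 198_000_000),
    ("chr4", 191_000_000), ("chr5", 181_000_000), ("chr6", 171_000_000),
    ("chr7", 159_000_000), ("chr8", 146_000_000), ("chr9", 141_000_000),
    ("chr10", 136_000_000), ("chr11", 135_000_000), ("chr12", 134_000_000),
    ("chr13", 115_000_000), ("chr14", 107_000_000), ("chr15", 103_000_000),
    ("chr16", 90_000_000), ("chr17", 81_000_000), ("chr18", 78_000_000),
    ("chr19", 59_000_000), ("chr20", 63_000_000), ("chr21", 48_000_000),
    ("chr22", 51_000_000), ("chrX", 155_000_000),
)

_BASES = np.array(list("ACGT"))
_EFFECTS = ("missense", "nonsense", "splice")
_EFFECT_P = (0.8, 0.1, 0.1)


@dataclass
class SimParams:
    """Study-condition knobs of the simulator.

    Defaults mirror the multi-region HGSC case this package models:
    11 tumor samples in clusters of 6 (P1), 3 (M) and 2 (P2); mutation
    budgets 19 common / 82 shared(P1, M) / 39+11+54 cluster-specific /
    10 per-sample private; 6% false-negative and 1% false-positive call
    rates; ~90x discovery and ~9,647x validation coverage; tumor purity
    0.7.  ``fp_locus_pool`` sizes the caller's negative candidate
    universe so the validation assay's negative:positive pair ratio
    matches the one jointly implied by the printed precision/FNR/FPR.
    """

    cluster_labels: tuple[str, ...] = ("P1", "M", "P2")
    samples_per_cluster: tuple[int, ...] = (6, 3, 2)
    n_common: int = 19
    n_shared: dict[tuple[str, str], int] = field(
        default_factory=lambda: {("P1", "M"): 82})
    n_cluster_specific: dict[str, int] = field(
        default_factory=lambda: {"P1": 39, "M": 11, "P2": 54})
    n_sample_specific_per_sample: int = 10
    fn_rate: float = 0.06
    fp_rate: float = 0.01
    fp_locus_pool: int = 740
    wes_depth_mean: float = 90.0
    validation_depth_mean: float = 9647.0
    purity: float | dict[str, float] = 0.7
    cna_segments_per_branch: int = 4
    cna_min_length: int = 2_000_000
    cna_max_length: int = 20_000_000
    amp_log2: float = 0.58
    del_log2: float = -1.0
    seq_error: float = 0.001
    genome_model: tuple[tuple[str, int], ...] = DEFAULT_GENOME
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.cluster_labels) < 2:
            raise ValueError("classification needs at least 2 clusters")
        if len(self.samples_per_cluster) != len(self.cluster_labels):
            raise ValueError("samples_per_cluster must match cluster_labels")
        if any(n < 1 for n in self.samples_per_cluster):
            raise ValueError("every cluster must contain at least one sample")
        for name, rate in (("fn_rate", self.fn_rate), ("fp_rate", self.fp_rate),
                           ("seq_error", self.seq_error)):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name}={rate} outside [0, 1]")
        counts = [self.n_common, self.n_sample_specific_per_sample,
                  self.fp_locus_pool, self.cna_segments_per_branch,
                  *self.n_shared.values(), *self.n_cluster_specific.values()]
        if any(c < 0 for c in counts):
            raise ValueError("mutation/segment budgets must be >= 0")
        known = set(self.cluster_labels)
        for pair in self.n_shared:
            if not set(pair) <= known or len(set(pair)) < 2:
                raise ValueError(f"invalid shared cluster pair {pair}")
        for c in self.n_cluster_specific:
            if c not in known:
                raise ValueError(f"unknown cluster {c!r} in n_cluster_specific")

    @property
    def samples(self) -> list[str]:
        return [f"{c}_{i + 1}" for c, n in
                zip(self.cluster_labels, self.samples_per_cluster)
                for i in range(n)]

    def purity_of(self, sample: str) -> float:
        if isinstance(self.purity, dict):
            return self.purity[sample]
        return float(self.purity)

    def to_yaml(self, path) -> None:
        doc = dataclasses.asdict(self)
        doc["cluster_labels"] = list(self.cluster_labels)
        doc["samples_per_cluster"] = list(self.samples_per_cluster)
        doc["n_shared"] = {"|".join(k): v for k, v in self.n_shared.items()}
        doc["genome_model"] = [[c, int(l)] for c, l in self.genome_model]
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimParams":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        doc["cluster_labels"] = tuple(doc["cluster_labels"])
        doc["samples_per_cluster"] = tuple(doc["samples_per_cluster"])
        doc["n_shared"] = {tuple(k.split("|")): v for k, v in doc["n_shared"].items()}
        doc["genome_model"] = tuple((c, int(l)) for c, l in doc["genome_model"])
        return cls(**doc)


@dataclass
class SimTruth:
    """Ground truth of one simulated tumor."""

    params: SimParams
    samples: list[str]
    sample_cluster: dict[str, str]
    presence: pd.DataFrame       # samples x loci, binary
    locus_category: dict[str, tuple[str, tuple[str, ...]]]
    locus_info: pd.DataFrame     # per locus: chrom, pos, ref, alt, gene, effect
    decoy_info: pd.DataFrame     # same columns for the decoy pool
    true_vaf: pd.DataFrame       # samples x loci, expected allele fractions
    true_tree: SampleTree
    branch_samples: dict[str, tuple[str, ...]]
    true_segments: dict[str, list[tuple[str, int, int, str]]]

    def scheme(self) -> ClusterScheme:
        clusters = {c: [s for s in self.samples if self.sample_cluster[s] == c]
                    for c in self.params.cluster_labels}
        return ClusterScheme(
            clusters=clusters,
            min_support={c: default_min_support(len(m)) for c, m in clusters.items()},
        )


def _draw_loci(rng: np.random.Generator, n: int, params: SimParams,
               taken: set[tuple], prefix: str) -> pd.DataFrame:
    chroms = [c for c, _ in params.genome_model]
    lengths = np.array([l for _, l in params.genome_model], dtype=float)
    p = lengths / lengths.sum()
    rows = []
    while len(rows) < n:
        ci = rng.choice(len(chroms), p=p)
        pos = int(rng.integers(1, lengths[ci] + 1))
        ref = str(rng.choice(_BASES))
        alt = str(rng.choice(_BASES[_BASES != ref]))
        key = (chroms[ci], pos, ref, alt)
        if key in taken:
            continue
        taken.add(key)
        effect = str(rng.choice(_EFFECTS, p=_EFFECT_P))
        rows.append({"chrom": chroms[ci], "pos": pos, "ref": ref, "alt": alt,
                     "gene": f"{prefix}{len(taken):05d}", "effect": effect})
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "gene", "effect"])


def _build_tree(params: SimParams) -> tuple[SampleTree, dict[str, tuple[str, ...]]]:
    """Ladder tree over clusters (join order = cluster_labels order)."""
    labels = params.cluster_labels
    cluster_members = {c: [f"{c}_{i + 1}" for i in range(n)]
                       for c, n in zip(labels, params.samples_per_cluster)}
    cluster_nodes = {}
    for c, members in cluster_members.items():
        leaves = [TreeNode(name=s, length=0.2) for s in members]
        if len(leaves) == 1:
            node = leaves[0]
            node.length = 0.0
            node.height = 0.0
            node = TreeNode(children=[node], height=0.2)
            node.children[0].length = 0.2
        else:
            node = TreeNode(children=leaves, height=0.2)
        cluster_nodes[c] = node
    node = cluster_nodes[labels[0]]
    branch_samples: dict[str, tuple[str, ...]] = {}
    prefix = list(cluster_members[labels[0]])
    for i, c in enumerate(labels[1:], start=1):
        h = 0.2 + 0.2 * i
        other = cluster_nodes[c]
        node.length = h - node.height
        other.length = h - other.height
        node = TreeNode(children=[node, other], height=h)
        prefix.extend(cluster_members[c])
        if i < len(labels) - 1:
            clade = tuple(labels[: i + 1])
            branch_samples["clade:" + "+".join(clade)] = tuple(prefix)
    branch_samples["trunk"] = tuple(s for c in labels for s in cluster_members[c])
    for c, members in cluster_members.items():
        branch_samples[f"cluster:{c}"] = tuple(members)
    return SampleTree(root=node, rooted=True), branch_samples


def _plant_segments(rng: np.random.Generator, params: SimParams,
                    branches: list[str]) -> dict[str, list[tuple[str, int, int, str]]]:
    """Globally non-overlapping CNA segments, so per-sample profiles stay disjoint."""
    chroms = [c for c, _ in params.genome_model]
    lengths = {c: l for c, l in params.genome_model}
    p = np.array([lengths[c] for c in chroms], dtype=float)
    p /= p.sum()
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    out: dict[str, list[tuple[str, int, int, str]]] = {}
    for branch in branches:
        segs = []
        for _ in range(params.cna_segments_per_branch):
            for _attempt in range(1000):
                chrom = chroms[int(rng.choice(len(chroms), p=p))]
                seg_len = int(rng.integers(params.cna_min_length,
                                           params.cna_max_length + 1))
                if seg_len >= lengths[chrom]:
                    continue
                start = int(rng.integers(1, lengths[chrom] - seg_len + 1))
                end = start + seg_len - 1
                if any(s <= end and start <= e for s, e in placed[chrom]):
                    continue
                placed[chrom].append((start, end))
                direction = "amp" if rng.random() < 0.5 else "del"
                segs.append((chrom, start, end, direction))
                break
            else:  # pragma: no cover - genome far larger than requested segments
                raise RuntimeError("could not place non-overlapping CNA segment")
        out[branch] = segs
    return out


def simulate_truth(params: SimParams) -> SimTruth:
    """Plant the mutation categories, VAFs, tree and CNA segments."""
    rng = np.random.default_rng([params.seed, 0])
    samples = params.samples
    sample_cluster = {s: c for c, n in
                      zip(params.cluster_labels, params.samples_per_cluster)
                      for s in [f"{c}_{i + 1}" for i in range(n)]}

    taken: set[tuple] = set()
    budget: list[tuple[str, tuple[str, ...]]] = []
    budget += [("common", ())] * params.n_common
    for pair, n in params.n_shared.items():
        budget += [("shared", tuple(sorted(pair)))] * n
    for c, n in params.n_cluster_specific.items():
        budget += [("cluster_specific", (c,))] * n
    for s in samples:
        budget += [("sample_specific", (s,))] * params.n_sample_specific_per_sample

    info = _draw_loci(rng, len(budget), params, taken, "GENE")
    decoy_info = _draw_loci(rng, params.fp_locus_pool, params, taken, "DCY")
    loci = [locus_id(r.chrom, r.pos, r.ref, r.alt) for r in info.itertuples()]
    info = info.copy()
    info.index = loci
    decoy_info = decoy_info.copy()
    decoy_info.index = [locus_id(r.chrom, r.pos, r.ref, r.alt)
                        for r in decoy_info.itertuples()]

    presence = pd.DataFrame(0, index=samples, columns=loci, dtype=int)
    locus_category: dict[str, tuple[str, tuple[str, ...]]] = {}
    for locus, (kind, detail) in zip(loci, budget):
        locus_category[locus] = (kind, detail)
        if kind == "common":
            carriers = samples
        elif kind == "shared":
            carriers = [s for s in samples if sample_cluster[s] in detail]
        elif kind == "cluster_specific":
            carriers = [s for s in samples if sample_cluster[s] == detail[0]]
        else:
            carriers = list(detail)
        presence.loc[carriers, locus] = 1

    purity = np.array([params.purity_of(s) for s in samples])
    # diploid heterozygous clonal model: VAF = purity * cell fraction / 2
    true_vaf = presence.mul(purity / 2.0, axis=0)

    tree, branch_samples = _build_tree(params)
    true_segments = _plant_segments(rng, params, list(branch_samples))
    return SimTruth(
        params=params, samples=samples, sample_cluster=sample_cluster,
        presence=presence, locus_category=locus_category, locus_info=info,
        decoy_info=decoy_info, true_vaf=true_vaf, true_tree=tree,
        branch_samples=branch_samples, true_segments=true_segments,
    )


def _depth_alt(rng, n, depth_mean, vafs):
    depth = np.maximum(rng.poisson(depth_mean, size=n), 1)
    alt = rng.binomial(depth, vafs)
    return depth, alt


def simulate_observed_calls(truth: SimTruth,
                            params: SimParams) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Noisy discovery-phase calls and per-sample SEG profiles.

    Each true presence drops out with probability ``fn_rate``; each
    truth-absent (sample, candidate locus) pair — candidate loci being the
    true loci plus the decoy pool — is falsely called with probability
    ``fp_rate``.  Depths are Poisson around ``wes_depth_mean``; alt reads
    binomial around the expected VAF (false calls carry a low artifact
    allele fraction).
    """
    if list(truth.samples) != params.samples:
        raise ValueError("sample sets of truth and params differ")
    rng = np.random.default_rng([params.seed, 1])
    samples = truth.samples
    loci = list(truth.presence.columns)
    pres = truth.presence.to_numpy()

    keep = (rng.random(pres.shape) >= params.fn_rate) & (pres == 1)
    fp_true = (rng.random(pres.shape) < params.fp_rate) & (pres == 0)
    n_decoy = len(truth.decoy_info)
    fp_decoy = rng.random((len(samples), n_decoy)) < params.fp_rate

    artifact_vaf = 0.10  # allele fraction mimicked by systematic artifacts
    rows = []
    all_info = pd.concat([truth.locus_info, truth.decoy_info])
    vaf_arr = truth.true_vaf.to_numpy()

    def emit(si: int, locus: str, vaf: float) -> None:
        depth = max(int(rng.poisson(params.wes_depth_mean)), 1)
        alt = int(rng.binomial(depth, vaf))
        alt = max(alt, 1)  # a call implies at least one supporting read
        r = all_info.loc[locus]
        rows.append({
            "sample": samples[si], "chrom": r["chrom"], "pos": int(r["pos"]),
            "ref": r["ref"], "alt": r["alt"], "gene": r["gene"],
            "effect": r["effect"], "alt_count": alt, "depth": depth,
        })

    for si in range(len(samples)):
        for li in np.nonzero(keep[si])[0]:
            emit(si, loci[li], vaf_arr[si, li])
        for li in np.nonzero(fp_true[si])[0]:
            emit(si, loci[li], artifact_vaf)
        for di in np.nonzero(fp_decoy[si])[0]:
            emit(si, truth.decoy_info.index[di], artifact_vaf)
    calls = pd.DataFrame(
        rows, columns=["sample", "chrom", "pos", "ref", "alt", "gene",
                       "effect", "alt_count", "depth"])

    seg_rows = []
    chrom_len = dict(params.genome_model)
    for s in samples:
        planted: dict[str, list[tuple[int, int, float]]] = {c: [] for c in chrom_len}
        for branch, members in truth.branch_samples.items():
            if s not in members:
                continue
            for chrom, start, end, direction in truth.true_segments[branch]:
                log2 = params.amp_log2 if direction == "amp" else params.del_log2
                planted[chrom].append((start, end, log2))
        for chrom, length in params.genome_model:
            segs = sorted(planted[chrom])
            cursor = 1
            for start, end, log2 in segs:
                if start > cursor:
                    seg_rows.append((s, chrom, cursor, start - 1, 0.0))
                seg_rows.append((s, chrom, start, end, log2))
                cursor = end + 1
            if cursor <= length:
                seg_rows.append((s, chrom, cursor, length, 0.0))
    segments = pd.DataFrame(
        seg_rows, columns=["sample", "chrom", "start", "end", "log2_ratio"])
    return calls, segments


def simulate_validation_table(
    truth: SimTruth,
    observed: pd.DataFrame,
    params: SimParams,
    loci: list[str] | None = None,
) -> pd.DataFrame:
    """Deep-resequencing assay over the caller's candidate universe.

    Default panel = true loci plus the decoy pool (every site the
    discovery caller evaluated); a custom panel must stay inside that
    universe or the observed calls.  Deep depths are Poisson around
    ``validation_depth_mean`` for tumor and normal; alt reads binomial
    around the true VAF with a small sequencing-error floor.
    """
    rng = np.random.default_rng([params.seed, 2])
    universe = set(truth.presence.columns) | set(truth.decoy_info.index)
    observed_ids = {locus_id(c, int(p), r, a) for c, p, r, a in
                    zip(observed["chrom"], observed["pos"],
                        observed["ref"], observed["alt"])}
    if loci is None:
        panel = list(truth.presence.columns) + list(truth.decoy_info.index)
    else:
        bad = [l for l in loci if l not in universe and l not in observed_ids]
        if bad:
            raise ValueError(f"requested locus/loci absent from truth and observed: {bad[:5]}")
        panel = list(loci)
    samples = truth.samples
    n = len(panel) * len(samples)
    vafs = np.empty(n)
    for i, locus in enumerate(panel):
        for j, s in enumerate(samples):
            if locus in truth.true_vaf.columns:
                v = float(truth.true_vaf.at[s, locus])
            else:
                v = 0.0
            vafs[i * len(samples) + j] = max(v, params.seq_error)
    tumor_depth = np.maximum(rng.poisson(params.validation_depth_mean, size=n), 1)
    normal_depth = np.maximum(rng.poisson(params.validation_depth_mean, size=n), 1)
    alt = rng.binomial(tumor_depth, vafs)
    table = pd.DataFrame({
        "locus": np.repeat(panel, len(samples)),
        "sample": np.tile(samples, len(panel)),
        "tumor_depth": tumor_depth,
        "normal_depth": normal_depth,
        "alt_fraction": alt / tumor_depth,
    })
    return table[VALIDATION_COLUMNS]


def expected_mutation_labels(truth: SimTruth) -> dict[str, tuple[str, str]]:
    """Planted category of each locus mapped through the classification rules."""
    out = {}
    n_clusters = len(truth.params.cluster_labels)
    for locus, (kind, detail) in truth.locus_category.items():
        if kind == "common":
            out[locus] = ("Common", "")
        elif kind == "shared":
            if len(detail) == n_clusters:
                out[locus] = ("Common", "")
            else:
                out[locus] = ("Shared", ",".join(sorted(detail)))
        elif kind == "cluster_specific":
            out[locus] = ("Cluster-specific", detail[0])
        else:
            out[locus] = ("Sample-specific", "")
    return out


def expected_segment_labels(truth: SimTruth) -> dict[tuple[str, int, int], tuple[str, str, str]]:
    """Planted branch of each CNA segment mapped to Common/Shared/Specific."""
    n_clusters = len(truth.params.cluster_labels)
    out = {}
    for branch, segs in truth.true_segments.items():
        if branch == "trunk":
            label, cset = "Common", ""
        elif branch.startswith("clade:"):
            clusters = branch.split(":", 1)[1].split("+")
            if len(clusters) == n_clusters:
                label, cset = "Common", ""
            else:
                label, cset = "Shared", ",".join(sorted(clusters))
        else:
            label, cset = "Specific", branch.split(":", 1)[1]
        for chrom, start, end, direction in segs:
            out[(chrom, start, end)] = (label, direction, cset)
    return out


def write_simulation(truth: SimTruth, calls: pd.DataFrame, segments: pd.DataFrame,
                     validation: pd.DataFrame | None, outdir) -> dict[str, str]:
    """Write mutation TSV, SEG, validation TSV, truth JSON, params YAML, clusters YAML."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "mutations": str(out / "mutations.tsv"),
        "segments": str(out / "segments.seg"),
        "clusters": str(out / "clusters.yaml"),
        "params": str(out / "sim_params.yaml"),
        "truth": str(out / "truth.json"),
    }
    write_mutation_table(calls, paths["mutations"])
    write_seg(segments, paths["segments"])
    write_cluster_yaml(truth.scheme(), paths["clusters"])
    truth.params.to_yaml(paths["params"])
    if validation is not None:
        paths["validation"] = str(out / "validation.tsv")
        write_validation_table(validation, paths["validation"])
    doc = {
        "samples": truth.samples,
        "sample_cluster": truth.sample_cluster,
        "locus_category": {l: [k, list(d)] for l, (k, d) in truth.locus_category.items()},
        "tree_newick": truth.true_tree.to_newick(),
        "true_segments": {b: [list(s) for s in segs]
                          for b, segs in truth.true_segments.items()},
    }
    with open(paths["truth"], "w") as fh:
        json.dump(doc, fh, indent=1)
    write_newick(truth.true_tree, out / "true_tree.nwk")
    return paths
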