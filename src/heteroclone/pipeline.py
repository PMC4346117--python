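"""End-to-end orchestration: calls + segments + clusters -> trees, labels, reports.

Stages: effect filter -> binary matrix -> presence filter -> Pearson
distance -> NJ + UPGMA trees (clusters either supplied or cut from the
UPGMA tree) -> mutation classification; optionally the SCNA weight-matrix
tree and segment classification, and the validation-concordance report.
A manifest records the configuration and the record count at every stage.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .clusters import ClusterScheme, read_cluster_yaml, write_cluster_yaml
from .io import read_mutation_table, read_seg, write_newick
from .matrix import build_binary_matrix, filter_effects, filter_present_loci
from .phylo import cut_clusters, neighbor_joining, pearson_distance, upgma
from .classify import classify_mutations, cluster_presence, group_percentages
from .scna import (build_weight_matrix, classify_segments,
                   cluster_segment_status, summarize_segments)
from .validation import (apply_assessability_filter, compare_calls,
                         read_validation_table)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    mutation_table: str
    out_dir: str
    seg_file: str | None = None
    validation_table: str | None = None
    cluster_yaml: str | None = None
    tree_cut_k: int | None = None       # derive clusters from the UPGMA tree
    effect_filter: bool = True
    presence_filter: bool = True
    normal_samples: list[str] = field(default_factory=list)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(**doc)


def run_pipeline(config: RunConfig) -> dict:
    """Run all configured stages; returns (and writes) the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": {k: v for k, v in vars(config).items()},
                      "version": __version__, "stages": {}}
    written: list[Path] = []

    def emit(name: str, writer) -> None:
        path = out / name
        writer(path)
        written.append(path)

    def stage(name: str, fn):
        try:
            result = fn()
        except Exception as exc:
            for p in written:  # no partial outputs on failure
                p.unlink(missing_ok=True)
            raise PipelineError(name, exc) from exc
        return result

    calls = stage("read_mutations", lambda: read_mutation_table(config.mutation_table))
    manifest["stages"]["calls_in"] = len(calls)

    if config.effect_filter:
        calls = stage("effect_filter", lambda: filter_effects(calls))
    manifest["stages"]["calls_after_effect_filter"] = len(calls)

    scheme: ClusterScheme | None = None
    if config.cluster_yaml:
        scheme = stage("read_clusters", lambda: read_cluster_yaml(config.cluster_yaml))

    samples = sorted(set(calls["sample"]) | set(config.normal_samples)
                     | (set(scheme.samples) if scheme else set()))
    tumor_samples = [s for s in samples if s not in set(config.normal_samples)]
    mat = stage("binary_matrix", lambda: build_binary_matrix(calls, samples))
    manifest["stages"]["loci_in_matrix"] = len(mat.loci)
    if config.presence_filter:
        mat = stage("presence_filter", lambda: filter_present_loci(mat, tumor_samples))
    manifest["stages"]["loci_after_presence_filter"] = len(mat.loci)

    dm = stage("pearson_distance", lambda: pearson_distance(mat.df))
    emit("mutation_distance.tsv", dm.to_tsv)
    nj = stage("nj_tree", lambda: neighbor_joining(dm))
    emit("mutation_tree_nj.nwk", lambda p: write_newick(nj, p))
    up = stage("upgma_tree", lambda: upgma(dm))
    emit("mutation_tree_upgma.nwk", lambda p: write_newick(up, p))

    if scheme is None:
        if config.tree_cut_k is None:
            raise PipelineError("clusters", ValueError(
                "provide cluster_yaml or tree_cut_k"))
        if config.tree_cut_k < 2:
            raise PipelineError("clusters", ValueError("tree_cut_k must be >= 2"))
        k = config.tree_cut_k
        scheme = stage("tree_cut", lambda: cut_clusters(up, k))
        emit("derived_clusters.yaml", lambda p: write_cluster_yaml(scheme, p))
    manifest["stages"]["clusters"] = {c: len(m) for c, m in scheme.clusters.items()}

    pres = stage("cluster_presence", lambda: cluster_presence(mat, scheme))
    result = stage("classify_mutations", lambda: classify_mutations(pres))
    emit("mutation_classification.tsv", result.to_tsv)
    manifest["stages"]["mutation_group_counts"] = result.counts
    manifest["stages"]["mutation_group_percent"] = group_percentages(result.counts)

    if config.seg_file:
        profiles = stage("read_seg", lambda: read_seg(config.seg_file))
        wm = stage("weight_matrix", lambda: build_weight_matrix(profiles))
        emit("scna_weight_matrix.tsv",
             lambda p: wm.w.to_csv(p, sep="\t", index_label="sample"))
        manifest["stages"]["scna_regions"] = len(wm.regions)
        scna_dm = stage("scna_distance", lambda: pearson_distance(wm.w))
        emit("scna_distance.tsv", scna_dm.to_tsv)
        scna_nj = stage("scna_nj_tree", lambda: neighbor_joining(scna_dm))
        emit("scna_tree_nj.nwk", lambda p: write_newick(scna_nj, p))
        status = stage("segment_status", lambda: cluster_segment_status(wm, scheme))
        seg_labels = stage("classify_segments", lambda: classify_segments(status))
        emit("segment_classification.tsv",
             lambda p: seg_labels.to_csv(p, sep="\t", index=False))
        summary = summarize_segments(seg_labels, wm.regions)
        emit("segment_summary.tsv", lambda p: summary.to_csv(p, sep="\t", index=False))
        manifest["stages"]["segment_label_counts"] = {
            f"{r.label}/{r.direction}": int(r.n_segments)
            for r in summary.itertuples()}
    else:
        logger.info("no SEG file configured; SCNA stages skipped")
        manifest["stages"]["scna"] = "skipped"

    if config.validation_table:
        vt = stage("read_validation", lambda: read_validation_table(config.validation_table))
        filt = stage("assessability_filter", lambda: apply_assessability_filter(vt))
        manifest["stages"]["validation_pairs_assessable"] = len(filt)
        report = stage("compare_calls", lambda: compare_calls(calls, filt))
        emit("validation_report.json", report.to_json)
        manifest["stages"]["validation_report"] = report.to_dict()

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
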