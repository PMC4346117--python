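"""Readers and writers for the formats the pipeline touches.

Mutation calls travel as a pandas DataFrame with columns
``sample, chrom, pos, ref, alt, gene, effect, alt_count, depth``
(1-based inclusive coordinates; a locus is identified by chrom/pos/ref/alt
so distinct substitutions at one position are distinct loci; chromosome
labels are opaque strings, no "chr" normalization).  Segment profiles are
a DataFrame with ``sample, chrom, start, end, log2_ratio``.  All readers
are total on their dialects: malformed input raises :class:`ParseError`
naming the line, never a silent partial table.
"""

from __future__ import annotations

import pandas as pd

from .clusters import ClusterScheme, read_cluster_yaml, write_cluster_yaml  # noqa: F401
from .phylo import SampleTree

__all__ = [
    "ParseError",
    "MUTATION_COLUMNS",
    "EFFECT_CATEGORIES",
    "read_mutation_table",
    "write_mutation_table",
    "read_vcf_minimal",
    "read_seg",
    "write_seg",
    "write_newick",
    "read_cluster_yaml",
    "write_cluster_yaml",
]

MUTATION_COLUMNS = [
    "sample", "chrom", "pos", "ref", "alt", "gene", "effect", "alt_count", "depth",
]

EFFECT_CATEGORIES = {
    "missense", "nonsense", "splice", "synonymous",
    "intronic", "intergenic", "near-gene", "other",
}


class ParseError(ValueError):
    """Malformed input file; message names the file and line."""


def read_mutation_table(path) -> pd.DataFrame:
    """Read the tab-separated mutation-call table.

    Duplicate (sample, locus) rows and alt_count > depth are rejected with
    the offending line number.
    """
    rows = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        missing = [c for c in MUTATION_COLUMNS if c not in header]
        if missing:
            raise ParseError(f"{path}: missing column(s) {missing}")
        col = {c: header.index(c) for c in MUTATION_COLUMNS}
        seen: dict[tuple, int] = {}
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < len(header):
                raise ParseError(f"{path}:{lineno}: expected {len(header)} fields")
            try:
                pos = int(parts[col["pos"]])
                alt_count = int(parts[col["alt_count"]])
                depth = int(parts[col["depth"]])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric field ({exc})") from None
            if pos < 1:
                raise ParseError(f"{path}:{lineno}: pos must be >= 1")
            if alt_count < 0 or alt_count > depth:
                raise ParseError(
                    f"{path}:{lineno}: alt_count {alt_count} outside [0, depth={depth}]"
                )
            key = (parts[col["sample"]], parts[col["chrom"]], pos,
                   parts[col["ref"]], parts[col["alt"]])
            if key in seen:
                raise ParseError(
                    f"{path}:{lineno}: duplicate call for sample/locus "
                    f"{key} (first at line {seen[key]})"
                )
            seen[key] = lineno
            rows.append({
                "sample": parts[col["sample"]],
                "chrom": parts[col["chrom"]],
                "pos": pos,
                "ref": parts[col["ref"]],
                "alt": parts[col["alt"]],
                "gene": parts[col["gene"]],
                "effect": parts[col["effect"]],
                "alt_count": alt_count,
                "depth": depth,
            })
    return pd.DataFrame(rows, columns=MUTATION_COLUMNS)


def write_mutation_table(calls: pd.DataFrame, path) -> None:
    calls.to_csv(path, sep="\t", index=False, columns=MUTATION_COLUMNS)


_VCF_EFFECT_MAP = {
    "missense_variant": "missense",
    "stop_gained": "nonsense",
    "stop_lost": "nonsense",
    "splice_acceptor_variant": "splice",
    "splice_donor_variant": "splice",
    "splice_region_variant": "splice",
    "synonymous_variant": "synonymous",
    "intron_variant": "intronic",
    "intergenic_region": "intergenic",
    "intergenic_variant": "intergenic",
    "upstream_gene_variant": "near-gene",
    "downstream_gene_variant": "near-gene",
}


def read_vcf_minimal(path) -> pd.DataFrame:
    """Minimal multi-sample VCF reader.

    Emits one call per (sample, site, alt allele) where the genotype
    carries that non-reference allele; multi-allelic sites are split.
    Effect is taken from the first ANN/CSQ annotation when present,
    otherwise "other".  AD/DP feed alt_count/depth when present.
    """
    import pysam

    try:
        vf = pysam.VariantFile(str(path))
    except Exception as exc:  # pragma: no cover - pysam error text varies
        raise ParseError(f"{path}: malformed VCF ({exc})") from None
    rows = []
    with vf:
        for rec in vf:
            alts = rec.alts or ()
            ann_effects = _ann_effects(rec, len(alts))
            for sample in rec.samples:
                sdata = rec.samples[sample]
                gt = sdata.get("GT") or ()
                alt_indices = sorted({a for a in gt if a not in (None, 0)})
                for ai in alt_indices:
                    alt = alts[ai - 1]
                    ad = sdata.get("AD")
                    alt_count = int(ad[ai]) if ad is not None and ad[ai] is not None else 0
                    dp = sdata.get("DP")
                    if dp is None and ad is not None:
                        dp = sum(x or 0 for x in ad)
                    depth = int(dp) if dp is not None else alt_count
                    rows.append({
                        "sample": sample,
                        "chrom": rec.chrom,
                        "pos": rec.pos,
                        "ref": rec.ref,
                        "alt": alt,
                        "gene": (rec.info["GENE"] if "GENE" in rec.header.info
                                 and "GENE" in rec.info else ""),
                        "effect": ann_effects[ai - 1],
                        "alt_count": alt_count,
                        "depth": max(depth, alt_count),
                    })
    return pd.DataFrame(rows, columns=MUTATION_COLUMNS)


def _ann_effects(rec, n_alts: int) -> list[str]:
    raw = None
    for tag in ("ANN", "CSQ"):
        if tag in rec.header.info and tag in rec.info:
            raw = rec.info[tag]
            break
    effects = ["other"] * n_alts
    if raw is None:
        return effects
    if isinstance(raw, str):
        raw = (raw,)
    for entry in raw:
        fields = entry.split("|")
        if len(fields) < 2:
            continue
        allele, effect = fields[0], fields[1].split("&")[0]
        for i, alt in enumerate(rec.alts):
            if alt == allele and effects[i] == "other":
                effects[i] = _VCF_EFFECT_MAP.get(effect, "other")
    return effects


SEG_COLUMNS = ["sample", "chrom", "start", "end", "log2_ratio"]
_SEG_ALIASES = {
    "sample": ["sample", "ID", "Sample"],
    "chrom": ["chrom", "chromosome", "chr"],
    "start": ["start", "loc.start"],
    "end": ["end", "loc.end"],
    "log2_ratio": ["log2_ratio", "seg.mean", "seg_mean"],
}


def read_seg(path) -> pd.DataFrame:
    """Read a SEG file (CBS output dialect) into a segment DataFrame.

    Coordinates are 1-based inclusive.  Overlapping segments within one
    sample/chromosome, or end < start, are errors.
    """
    raw = pd.read_csv(path, sep="\t")
    cols = {}
    for canon, aliases in _SEG_ALIASES.items():
        found = next((a for a in aliases if a in raw.columns), None)
        if found is None:
            raise ParseError(f"{path}: missing column for {canon!r} (any of {aliases})")
        cols[found] = canon
    seg = raw.rename(columns=cols)[SEG_COLUMNS].copy()
    try:
        seg["start"] = seg["start"].astype(int)
        seg["end"] = seg["end"].astype(int)
        seg["log2_ratio"] = seg["log2_ratio"].astype(float)
    except (TypeError, ValueError) as exc:
        raise ParseError(f"{path}: non-numeric coordinate or ratio ({exc})") from None
    bad = seg[seg["end"] < seg["start"]]
    if not bad.empty:
        i = bad.index[0]
        raise ParseError(f"{path}: segment end < start at data row {i + 1}")
    for (sample, chrom), grp in seg.groupby(["sample", "chrom"], sort=False):
        g = grp.sort_values("start")
        prev_end = None
        for _, row in g.iterrows():
            if prev_end is not None and row["start"] <= prev_end:
                raise ParseError(
                    f"{path}: overlapping segments for {sample} {chrom} "
                    f"(at start {row['start']} <= previous end {prev_end})"
                )
            prev_end = row["end"]
    return seg


def write_seg(segments: pd.DataFrame, path) -> None:
    out = segments.rename(columns={"log2_ratio": "seg.mean",
                                   "start": "loc.start", "end": "loc.end"})
    out.to_csv(path, sep="\t", index=False)


def write_newick(tree: SampleTree, path, precision: int = 6) -> None:
    """Write standard Newick with branch lengths.

    Unrooted NJ trees are serialized with their trifurcating root.
    Duplicate leaf labels are rejected.
    """
    names = tree.leaf_names()
    if len(names) != len(set(names)):
        raise ValueError("duplicate leaf labels in tree")
    with open(path, "w") as fh:
        fh.write(tree.to_newick(precision=precision) + "\n")
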