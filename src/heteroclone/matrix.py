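"""Binary samples x loci mutation matrix construction and filtering.

Point mutations are converted to binary data (0 = no mutation, 1 =
somatic mutation) per sample; the resulting matrix drives both the
phylogeny (via the Pearson distance) and the mutation classification.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import EFFECT_CATEGORIES

logger = logging.getLogger(__name__)

__all__ = [
    "MutationMatrix",
    "EXCLUDED_EFFECTS",
    "locus_id",
    "filter_effects",
    "build_binary_matrix",
    "filter_present_loci",
]

#: effect classes excluded before matrix construction (non-coding or silent)
EXCLUDED_EFFECTS = frozenset({"synonymous", "intronic", "intergenic", "near-gene"})


def locus_id(chrom, pos, ref, alt) -> str:
    return f"{chrom}:{pos}:{ref}>{alt}"


@dataclass
class MutationMatrix:
    """Binary presence matrix; rows = samples, columns = locus ids."""

    df: pd.DataFrame  # index: samples, columns: locus ids, values in {0, 1}

    def __post_init__(self) -> None:
        vals = self.df.to_numpy()
        if vals.size and not np.isin(vals, (0, 1)).all():
            raise ValueError("matrix entries must be 0 or 1")
        if self.df.index.duplicated().any() or self.df.columns.duplicated().any():
            raise ValueError("duplicate sample or locus labels")

    @property
    def samples(self) -> list[str]:
        return list(self.df.index)

    @property
    def loci(self) -> list[str]:
        return list(self.df.columns)

    def to_tsv(self, path) -> None:
        # loci as rows for easier eyeballing of long matrices
        self.df.T.to_csv(path, sep="\t", index_label="locus")

    @classmethod
    def from_tsv(cls, path) -> "MutationMatrix":
        df = pd.read_csv(path, sep="\t", index_col="locus").T
        df.index.name = None
        return cls(df.astype(int))


def filter_effects(calls: pd.DataFrame,
                   excluded: frozenset[str] = EXCLUDED_EFFECTS) -> pd.DataFrame:
    """Drop silent / non-coding calls; row order preserved.

    Unknown effect categories are retained (and logged) rather than
    silently discarded.
    """
    unknown = set(calls["effect"]) - EFFECT_CATEGORIES
    if unknown:
        logger.info("retaining %d call(s) with unknown effect categories %s",
                    calls["effect"].isin(unknown).sum(), sorted(unknown))
    return calls[~calls["effect"].isin(excluded)].copy()


def build_binary_matrix(calls: pd.DataFrame, samples: list[str]) -> MutationMatrix:
    """Entry (s, locus) = 1 iff a call for the locus exists in sample s.

    Loci are ordered by (chrom, pos, ref, alt); duplicate calls saturate
    at 1, so the construction is idempotent and order-invariant.  Samples
    without calls (e.g. normals included for rooting) get all-zero rows.
    """
    unknown = set(calls["sample"]) - set(samples)
    if unknown:
        raise ValueError(f"calls reference unknown sample(s) {sorted(unknown)}")
    keys = sorted(
        {(c, int(p), r, a) for c, p, r, a in
         zip(calls["chrom"], calls["pos"], calls["ref"], calls["alt"])}
    )
    loci = [locus_id(*k) for k in keys]
    df = pd.DataFrame(0, index=list(samples), columns=loci, dtype=int)
    if len(calls):
        ids = [locus_id(c, int(p), r, a) for c, p, r, a in
               zip(calls["chrom"], calls["pos"], calls["ref"], calls["alt"])]
        for s, l in zip(calls["sample"], ids):
            df.at[s, l] = 1
    return MutationMatrix(df)


def filter_present_loci(matrix: MutationMatrix, tumor_samples: list[str]) -> MutationMatrix:
    """Keep loci found at least once among the tumor samples."""
    if not tumor_samples:
        raise ValueError("tumor_samples must be non-empty")
    missing = set(tumor_samples) - set(matrix.samples)
    if missing:
        raise ValueError(f"unknown tumor sample(s) {sorted(missing)}")
    support = matrix.df.loc[list(tumor_samples)].sum(axis=0)
    keep = support[support >= 1].index
    return MutationMatrix(matrix.df[keep].copy())
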