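"""Concordance of discovery (WES) calls with deep-resequencing validation.

The unit of evaluation is the (locus, sample) pair: a locus called in one
sample is a negative test in every other assayed sample, which is the only
reading under which a high precision and a ~1% false-positive rate can
coexist (most assayed pairs are true negatives).  A pair is assessable
when both tumor and normal deep coverage reach the depth floor; it is
validated somatic when the deep tumor allele fraction strictly exceeds
the AF threshold.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict

import pandas as pd

from .matrix import locus_id

logger = logging.getLogger(__name__)

__all__ = [
    "VALIDATION_COLUMNS",
    "ValidationReport",
    "apply_assessability_filter",
    "compare_calls",
    "read_validation_table",
    "write_validation_table",
]

VALIDATION_COLUMNS = [
    "locus", "sample", "tumor_depth", "normal_depth", "alt_fraction",
]

MIN_DEPTH = 500
MIN_AF = 0.05


def read_validation_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"locus": str, "sample": str})
    missing = [c for c in VALIDATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    return df


def write_validation_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def apply_assessability_filter(
    table: pd.DataFrame,
    min_depth: int = MIN_DEPTH,
    min_af: float = MIN_AF,
) -> pd.DataFrame:
    """Keep pairs with >= min_depth reads in BOTH tissues; flag somatic status.

    Adds a boolean ``validated_somatic`` column: deep tumor allele
    fraction strictly greater than ``min_af`` (a pair at exactly the
    threshold is retained but counts as not somatic).
    """
    ok = (table["tumor_depth"] >= min_depth) & (table["normal_depth"] >= min_depth)
    dropped = int((~ok).sum())
    if dropped:
        logger.info("assessability filter dropped %d of %d pairs", dropped, len(table))
    out = table[ok].copy()
    out["validated_somatic"] = out["alt_fraction"] > min_af
    return out


@dataclass
class ValidationReport:
    n_assessable: int
    tp: int
    fp: int
    fn: int
    tn: int
    n_unassayed_calls: int = 0

    def _rate(self, num: int, den: int) -> float | None:
        return num / den if den else None

    @property
    def precision(self) -> float | None:
        return self._rate(self.tp, self.tp + self.fp)

    @property
    def fnr(self) -> float | None:
        return self._rate(self.fn, self.tp + self.fn)

    @property
    def fpr(self) -> float | None:
        return self._rate(self.fp, self.fp + self.tn)

    def to_dict(self) -> dict:
        d = asdict(self)
        for k in ("precision", "fnr", "fpr"):
            v = getattr(self, k)
            d[k] = v if v is not None else "N/A"
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def __str__(self) -> str:
        def pct(v):
            return "N/A" if v is None else f"{100 * v:.1f}%"
        return (
            f"assessable pairs: {self.n_assessable}\n"
            f"tp={self.tp} fp={self.fp} fn={self.fn} tn={self.tn}\n"
            f"precision={pct(self.precision)} fnr={pct(self.fnr)} fpr={pct(self.fpr)}"
        )


def compare_calls(wes_calls: pd.DataFrame, validated: pd.DataFrame) -> ValidationReport:
    """Confusion matrix of WES calls against the filtered validation table.

    ``validated`` must already carry ``validated_somatic`` (run
    :func:`apply_assessability_filter` first).  WES calls at pairs never
    assayed are excluded and counted separately.
    """
    if "validated_somatic" not in validated.columns:
        raise ValueError("validation table not filtered; run apply_assessability_filter")
    called = {
        (locus_id(c, int(p), r, a), s)
        for c, p, r, a, s in zip(
            wes_calls["chrom"], wes_calls["pos"], wes_calls["ref"],
            wes_calls["alt"], wes_calls["sample"])
    }
    assayed = set(zip(validated["locus"], validated["sample"]))
    unassayed = len(called - assayed)
    if unassayed:
        logger.warning("%d WES-called pair(s) never assayed; excluded", unassayed)
    tp = fp = fn = tn = 0
    for locus, sample, somatic in zip(
            validated["locus"], validated["sample"], validated["validated_somatic"]):
        was_called = (locus, sample) in called
        if was_called and somatic:
            tp += 1
        elif was_called:
            fp += 1
        elif somatic:
            fn += 1
        else:
            tn += 1
    return ValidationReport(
        n_assessable=len(validated), tp=tp, fp=fp, fn=fn, tn=tn,
        n_unassayed_calls=unassayed,
    )
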