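"""Exonic and intronic FPKM computation and the expression filters.

FPKM(g, s) = counts(g, s) * 1e9 / (library_total(s) * length_bp(g)), where the
library total is the number of reads mapped to the same region class (exonic
reads for gene-body FPKM, intron-mapped reads for pre-mRNA FPKM) and the
length is the region length sum of the gene's representative transcript.

Filters follow the literal printed thresholds with strict "<" comparisons:
genes below 0.00015 mean FPKM are excluded from expression analyses, and
intronic quantification drops genes with mean intron FPKM < 0.01 or intron
length < 30 bp (a sub-30 bp intron makes intronic FPKM meaningless, so the
default eliminates on either condition; ``rule="both"`` requires both).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "FpkmMatrix",
    "compute_fpkm",
    "filter_min_expression",
    "filter_intron_quality",
]

MIN_EXPRESSION_FPKM = 0.00015
MIN_INTRON_FPKM = 0.01
MIN_INTRON_LENGTH_BP = 30


@dataclass
class CountMatrix:
    """Genes x samples read counts for one region class.

    ``totals`` are per-sample region-mapped library totals; when absent they
    default to the column sums (self-contained toy inputs).
    """

    region: str
    counts: pd.DataFrame
    totals: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.region not in ("exonic", "intronic"):
            raise ValueError(f"unknown region {self.region!r}")
        if (self.counts.values < 0).any():
            raise ValueError("negative read counts")
        if self.totals is not None:
            self.totals = self.totals.astype(float).reindex(self.counts.columns)
            if self.totals.isna().any():
                missing = self.totals[self.totals.isna()].index.tolist()
                raise ValueError(f"library totals missing for samples {missing}")

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    def library_totals(self) -> pd.Series:
        if self.totals is not None:
            return self.totals
        return self.counts.sum(axis=0).astype(float)


@dataclass
class FpkmMatrix:
    """Genes x samples FPKM values for one region class."""

    region: str
    values: pd.DataFrame

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns


def compute_fpkm(counts: CountMatrix, lengths: pd.DataFrame | pd.Series) -> FpkmMatrix:
    """Length- and depth-normalize a count matrix to FPKM.

    ``lengths`` is the gene-length table (or a Series of bp); the column used
    matches the count region.  Exonic genes must have positive length; genes
    with zero intron length get NaN intron FPKM and are left for the intron
    quality filter to remove.
    """
    if isinstance(lengths, pd.DataFrame):
        col = "exon_length_bp" if counts.region == "exonic" else "intron_length_bp"
        length_bp = lengths[col]
    else:
        length_bp = lengths
    length_bp = length_bp.reindex(counts.genes).astype(float)
    if length_bp.isna().any():
        missing = length_bp[length_bp.isna()].index.tolist()[:5]
        raise ValueError(f"missing {counts.region} lengths for genes {missing}")
    if counts.region == "exonic" and (length_bp <= 0).any():
        bad = length_bp[length_bp <= 0].index.tolist()[:5]
        raise ValueError(f"non-positive exon length for genes {bad}")

    totals = counts.library_totals()
    if (totals <= 0).any():
        bad = totals[totals <= 0].index.tolist()
        raise ValueError(f"non-positive library total for samples {bad}")

    with np.errstate(divide="ignore", invalid="ignore"):
        values = counts.counts.astype(float) * 1e9
        values = values.div(totals, axis=1).div(length_bp, axis=0)
    values = values.where(np.isfinite(values))  # zero intron length -> NaN
    return FpkmMatrix(region=counts.region, values=values)


def filter_min_expression(
    fpkm: FpkmMatrix | pd.DataFrame,
    threshold: float = MIN_EXPRESSION_FPKM,
    samples: pd.Index | list[str] | None = None,
) -> pd.Index:
    """Genes retained by the minimum-expression filter.

    A gene is removed when its mean FPKM over the selected samples is strictly
    below ``threshold``; the boundary value itself is retained.
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    values = fpkm.values if isinstance(fpkm, FpkmMatrix) else fpkm
    if samples is not None:
        values = values[list(samples)]
    summary = values.mean(axis=1)
    return summary.index[~(summary < threshold)]


def filter_intron_quality(
    fpkm: FpkmMatrix | pd.DataFrame,
    lengths: pd.DataFrame | pd.Series,
    min_fpkm: float = MIN_INTRON_FPKM,
    min_len_bp: int = MIN_INTRON_LENGTH_BP,
    samples: pd.Index | list[str] | None = None,
    rule: str = "any",
) -> pd.Index:
    """Genes retained by the intronic-quality filter.

    With ``rule="any"`` (default) a gene is eliminated when mean intron FPKM
    < ``min_fpkm`` OR intron length < ``min_len_bp``; ``rule="both"`` requires
    both conditions.  Undefined intron FPKM (zero intron length) counts as
    failing the FPKM condition.
    """
    if rule not in ("any", "both"):
        raise ValueError(f"unknown rule {rule!r}")
    values = fpkm.values if isinstance(fpkm, FpkmMatrix) else fpkm
    if samples is not None:
        values = values[list(samples)]
    if isinstance(lengths, pd.DataFrame):
        length_bp = lengths["intron_length_bp"]
    else:
        length_bp = lengths
    length_bp = length_bp.reindex(values.index).astype(float)

    summary = values.mean(axis=1)
    low_fpkm = (summary < min_fpkm) | summary.isna()
    short = length_bp < min_len_bp
    eliminated = (low_fpkm | short) if rule == "any" else (low_fpkm & short)
    return values.index[~eliminated]
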