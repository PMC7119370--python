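"""RIP-seq enrichment scoring and bound-gene calling.

The enrichment value of a gene for one bait (the immunoprecipitated protein)
is its FPKM in the pulldown library divided by its FPKM in the matched input
total-RNA library.  Genes below 0.1 FPKM in *both* libraries are too poorly
measured to score and are excluded; genes with zero input FPKM are excluded
as undefined divisions.  Enrichment is computed per replicate experiment
first and then aggregated (mean or median); a gene is called bound when its
aggregated enrichment strictly exceeds the threshold (default 1.5).  The IgG
bait has no specific capture, so its enrichment distribution centers at one
and serves as a negative control.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RIP_MIN_FPKM",
    "BOUND_THRESHOLD",
    "compute_enrichment",
    "aggregate_replicates",
    "classify_bound",
    "enrichment_table",
]

RIP_MIN_FPKM = 0.1
BOUND_THRESHOLD = 1.5


def compute_enrichment(
    input_fpkm: float, rip_fpkm: float, min_fpkm: float = RIP_MIN_FPKM
) -> float:
    """Enrichment of one gene in one experiment, or NaN when excluded.

    Excluded when both FPKMs are strictly below ``min_fpkm``, or when the
    input FPKM is zero (undefined division).
    """
    if input_fpkm < 0 or rip_fpkm < 0:
        raise ValueError("FPKM values must be non-negative")
    if input_fpkm < min_fpkm and rip_fpkm < min_fpkm:
        return math.nan
    if input_fpkm == 0:
        return math.nan
    return rip_fpkm / input_fpkm


def aggregate_replicates(values: Sequence[float], statistic: str = "mean") -> float:
    """Mean or median over the defined (non-NaN) replicate enrichment values."""
    if statistic not in ("mean", "median"):
        raise ValueError(f"unknown statistic {statistic!r}")
    arr = np.asarray(list(values), dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        return math.nan
    return float(np.mean(arr) if statistic == "mean" else np.median(arr))


def classify_bound(aggregate: float, threshold: float = BOUND_THRESHOLD) -> bool | None:
    """True when the aggregated enrichment strictly exceeds the threshold.

    Undefined aggregates (NaN) return None and never enter bound sets.
    """
    if aggregate is None or math.isnan(aggregate):
        return None
    return bool(aggregate > threshold)


def enrichment_table(
    input_fpkm: pd.DataFrame,
    rip_fpkm: pd.DataFrame,
    min_fpkm: float = RIP_MIN_FPKM,
    statistic: str = "mean",
    threshold: float = BOUND_THRESHOLD,
) -> pd.DataFrame:
    """Per-gene enrichment table for one bait.

    ``input_fpkm`` and ``rip_fpkm`` hold one column per replicate experiment,
    paired by position.  Per-replicate enrichments are computed with the dual
    abundance filter, then aggregated; columns: ``input_fpkm`` and
    ``rip_fpkm`` (replicate means, descriptive), per-replicate
    ``enrichment_r*``, ``enrichment``, ``n_defined`` and ``bound``
    (nullable boolean).
    """
    if input_fpkm.shape[1] != rip_fpkm.shape[1]:
        raise ValueError("input and RIP matrices must have the same replicate count")
    rip_fpkm = rip_fpkm.reindex(input_fpkm.index)
    inp = input_fpkm.to_numpy(dtype=float)
    rip = rip_fpkm.to_numpy(dtype=float)
    if (inp < 0).any() or (rip < 0).any():
        raise ValueError("FPKM values must be non-negative")

    with np.errstate(divide="ignore", invalid="ignore"):
        enr = rip / inp
    excluded = ((inp < min_fpkm) & (rip < min_fpkm)) | (inp == 0)
    enr = np.where(excluded, np.nan, enr)

    if statistic not in ("mean", "median"):
        raise ValueError(f"unknown statistic {statistic!r}")
    n_defined = (~np.isnan(enr)).sum(axis=1)
    agg = np.full(enr.shape[0], np.nan)
    defined = n_defined > 0
    if defined.any():
        func = np.nanmean if statistic == "mean" else np.nanmedian
        agg[defined] = func(enr[defined], axis=1)

    out = pd.DataFrame(
        {
            "input_fpkm": inp.mean(axis=1),
            "rip_fpkm": rip.mean(axis=1),
        },
        index=input_fpkm.index.rename("gene_id"),
    )
    for i in range(enr.shape[1]):
        out[f"enrichment_r{i + 1}"] = enr[:, i]
    out["enrichment"] = agg
    out["n_defined"] = n_defined
    out["bound"] = pd.array(
        [None if math.isnan(a) else a > threshold for a in agg], dtype="boolean"
    )
    return out
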