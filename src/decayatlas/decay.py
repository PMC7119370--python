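"""mRNA half-life estimation from an actinomycin-D chase series.

Transcription shutoff makes libraries shrink in absolute terms while
sequencing depth stays fixed, so per-sample FPKMs are first normalized to a
stable reference mRNA (Rplp0-like).  The reference-normalized values are
averaged per timepoint over replicates, scaled so the 0 h mean equals one,
and log-transformed; ordinary least squares of ln(level) on chase time gives
an intercept and slope from which the half-life follows as

    t_half = ln(0.5 / e^intercept) / slope = (ln 0.5 - intercept) / slope.

Estimates outside (0, 50] h are flagged as unreliable and excluded, as are
profiles whose timepoint means are not strictly positive (log undefined).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .quantify import FpkmMatrix

__all__ = [
    "STATUS_OK",
    "STATUS_NONPOSITIVE",
    "STATUS_OVER_CAP",
    "STATUS_UNUSABLE",
    "ChaseProfile",
    "HalfLifeEstimate",
    "normalize_to_reference",
    "build_chase_profile",
    "fit_decay",
    "half_life_from_fit",
    "apply_half_life_bounds",
    "estimate_half_lives",
]

HALF_LIFE_CAP_H = 50.0

STATUS_OK = "ok"
STATUS_NONPOSITIVE = "excluded_nonpositive"
STATUS_OVER_CAP = "excluded_over_cap"
STATUS_UNUSABLE = "excluded_unusable"


@dataclass(frozen=True)
class ChaseProfile:
    """Reference-normalized, 0 h-scaled chase series for one gene."""

    gene_id: str
    timepoints_h: tuple[float, ...]
    means: tuple[float, ...]  # per-timepoint replicate means of ratios
    scaled: tuple[float, ...]  # means divided by the 0 h mean

    @property
    def usable(self) -> bool:
        return all(v > 0 for v in self.means)


@dataclass(frozen=True)
class HalfLifeEstimate:
    gene_id: str
    intercept: float
    slope: float
    half_life_h: float
    status: str


def normalize_to_reference(
    fpkm: FpkmMatrix | pd.DataFrame, reference_gene: str
) -> pd.DataFrame:
    """Divide every gene's FPKM by the reference gene's FPKM per sample."""
    values = fpkm.values if isinstance(fpkm, FpkmMatrix) else fpkm
    if reference_gene not in values.index:
        raise ValueError(f"reference gene {reference_gene!r} absent from FPKM matrix")
    ref = values.loc[reference_gene]
    bad = ref.index[~(ref > 0)]
    if len(bad):
        raise ValueError(
            f"reference gene {reference_gene!r} has non-positive FPKM in "
            f"sample(s) {bad.tolist()}"
        )
    return values.div(ref, axis=1)


def build_chase_profile(
    ratios: pd.DataFrame, manifest: pd.DataFrame, gene_id: str, condition: str | None = None
) -> ChaseProfile:
    """Per-timepoint replicate means, scaled to the 0 h mean, for one gene."""
    means, timepoints = _timepoint_means(ratios.loc[[gene_id]], manifest, condition)
    m = means.iloc[0]
    scaled = _scale_to_zero_hour(means, timepoints).iloc[0]
    return ChaseProfile(
        gene_id=gene_id,
        timepoints_h=tuple(timepoints),
        means=tuple(float(v) for v in m),
        scaled=tuple(float(v) for v in scaled),
    )


def _chase_samples(manifest: pd.DataFrame, condition: str | None) -> pd.DataFrame:
    sel = manifest[manifest["assay"] == "chase"] if "assay" in manifest.columns else manifest
    if condition is not None:
        sel = sel[sel["condition"] == condition]
    if sel.empty:
        raise ValueError(f"no chase samples for condition {condition!r}")
    return sel


def _timepoint_means(
    ratios: pd.DataFrame, manifest: pd.DataFrame, condition: str | None
) -> tuple[pd.DataFrame, list[float]]:
    sel = _chase_samples(manifest, condition)
    timepoints = sorted(sel["timepoint_h"].unique())
    if 0.0 not in timepoints:
        raise ValueError("chase design lacks a 0 h timepoint")
    cols = {}
    for t in timepoints:
        samples = sel.loc[sel["timepoint_h"] == t, "sample_id"].tolist()
        missing = [s for s in samples if s not in ratios.columns]
        if missing:
            raise ValueError(f"samples {missing} missing from ratio matrix")
        cols[t] = ratios[samples].mean(axis=1)
    return pd.DataFrame(cols), [float(t) for t in timepoints]


def _scale_to_zero_hour(means: pd.DataFrame, timepoints: list[float]) -> pd.DataFrame:
    with np.errstate(divide="ignore", invalid="ignore"):
        scaled = means.div(means[0.0], axis=0)
    return scaled


def fit_decay(profile: ChaseProfile) -> tuple[float, float]:
    """OLS of ln(scaled level) on time for one profile -> (intercept, slope)."""
    if not profile.usable:
        raise ValueError(f"profile {profile.gene_id!r} has non-positive values")
    t = np.asarray(profile.timepoints_h, dtype=float)
    if len(np.unique(t)) < 2:
        raise ValueError("need at least two distinct timepoints")
    y = np.log(np.asarray(profile.scaled, dtype=float))
    intercept, slope = _ols(t, y[None, :])
    return float(intercept[0]), float(slope[0])


def _ols(t: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise least squares of y (genes x timepoints) on t."""
    tbar = t.mean()
    dt = t - tbar
    slope = (y * dt).sum(axis=1) / (dt**2).sum()
    intercept = y.mean(axis=1) - slope * tbar
    return intercept, slope


def half_life_from_fit(intercept: float, slope: float) -> float:
    """Half-life from the regression: (ln 0.5 - intercept) / slope.

    A zero slope (no measurable decay) maps to an infinite half-life, which
    the bounds rule then flags as over the cap.
    """
    if slope == 0:
        return math.inf
    return (math.log(0.5) - intercept) / slope


def apply_half_life_bounds(
    estimate: HalfLifeEstimate, cap_h: float = HALF_LIFE_CAP_H
) -> HalfLifeEstimate:
    """Flag estimates outside (0, cap] as unreliable."""
    if estimate.status == STATUS_UNUSABLE:
        return estimate
    hl = estimate.half_life_h
    if not np.isfinite(hl) or hl > cap_h:
        status = STATUS_OVER_CAP
    elif hl <= 0:
        status = STATUS_NONPOSITIVE
    else:
        status = STATUS_OK
    return HalfLifeEstimate(
        gene_id=estimate.gene_id,
        intercept=estimate.intercept,
        slope=estimate.slope,
        half_life_h=hl,
        status=status,
    )


def estimate_half_lives(
    fpkm: FpkmMatrix | pd.DataFrame,
    manifest: pd.DataFrame,
    reference_gene: str,
    condition: str | None = None,
    cap_h: float = HALF_LIFE_CAP_H,
    genes: pd.Index | list[str] | None = None,
) -> pd.DataFrame:
    """Half-life table for every gene of one chase series.

    Returns a DataFrame indexed by gene_id with columns ``intercept``,
    ``slope``, ``half_life_h`` and ``status``.  The regression runs on the
    per-timepoint means of reference-normalized FPKMs, after scaling the
    series to its 0 h value.
    """
    ratios = normalize_to_reference(fpkm, reference_gene)
    if genes is not None:
        ratios = ratios.loc[list(genes)]
    means, timepoints = _timepoint_means(ratios, manifest, condition)
    scaled = _scale_to_zero_hour(means, timepoints)

    usable = (means > 0).all(axis=1).to_numpy()
    t = np.asarray(timepoints, dtype=float)
    y = np.full(scaled.shape, np.nan)
    y[usable] = np.log(scaled.to_numpy()[usable])
    intercept, slope = _ols(t, y)

    with np.errstate(divide="ignore", invalid="ignore"):
        half_life = (math.log(0.5) - intercept) / slope
    half_life = np.where(slope == 0, np.inf, half_life)

    status = np.full(len(scaled), STATUS_OK, dtype=object)
    status[~usable] = STATUS_UNUSABLE
    over = usable & (~np.isfinite(half_life) | (half_life > cap_h))
    nonpos = usable & np.isfinite(half_life) & (half_life <= 0)
    status[over] = STATUS_OVER_CAP
    status[nonpos] = STATUS_NONPOSITIVE

    return pd.DataFrame(
        {
            "intercept": intercept,
            "slope": slope,
            "half_life_h": half_life,
            "status": status,
        },
        index=scaled.index.rename("gene_id"),
    )
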