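"""Integration of the expression, half-life, RIP and pre-mRNA layers.

This module joins the per-gene outputs of the upstream stages and implements
the analyses that relate them: fold-change classification of steady-state
expression (knockout / control, 2-fold), stability classification of
half-life ratios (> 2.0 stabilized, < 0.5 destabilized), steady-state
reconstruction (predicted level = half-life x intron FPKM, since steady-state
abundance = synthesis rate / decay rate and intron reads proxy the synthesis
rate), rank-order tables, Spearman/Pearson correlations, Wilcoxon rank-sum /
signed-rank group comparisons, and the three-way overlap of stabilized genes
with the per-bait bound sets.

Genes excluded at any upstream stage propagate as "unavailable" instead of
being dropped, so per-stage attrition stays auditable.
"""

from __future__ import annotations

import itertools
import math
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EXPRESSION_FOLD",
    "STABILITY_FOLD",
    "classify_expression_change",
    "classify_stability_change",
    "predict_steady_state",
    "correlate",
    "group_compare",
    "exact_rank_sum_p",
    "overlap_sets",
    "rank_order_table",
    "benjamini_hochberg",
    "build_integration_table",
    "integration_report",
]

EXPRESSION_FOLD = 2.0
STABILITY_FOLD = 2.0
EXACT_RANK_SUM_MAX_N = 10


def classify_expression_change(
    fpkm_control: float, fpkm_ko: float, fold: float = EXPRESSION_FOLD
) -> str:
    """"increased" when ko/control > fold, "decreased" when < 1/fold (strict)."""
    if fpkm_control < 0 or fpkm_ko < 0:
        raise ValueError("FPKM values must be non-negative")
    if fpkm_control == 0 or math.isnan(fpkm_control) or math.isnan(fpkm_ko):
        return "unavailable"
    ratio = fpkm_ko / fpkm_control
    if ratio > fold:
        return "increased"
    if ratio < 1.0 / fold:
        return "decreased"
    return "unchanged"


def classify_stability_change(
    hl_control: float,
    hl_ko: float,
    status_control: str = "ok",
    status_ko: str = "ok",
    fold: float = STABILITY_FOLD,
) -> str:
    """"stabilized" when the knockout/control half-life ratio exceeds ``fold``,
    "destabilized" below ``1/fold``; defined only when both estimates are ok."""
    if status_control != "ok" or status_ko != "ok":
        return "unavailable"
    if math.isnan(hl_control) or math.isnan(hl_ko) or hl_control <= 0:
        return "unavailable"
    ratio = hl_ko / hl_control
    if ratio > fold:
        return "stabilized"
    if ratio < 1.0 / fold:
        return "destabilized"
    return "unchanged"


def predict_steady_state(half_life_h: float, intron_fpkm: float) -> float:
    """Reconstructed steady-state level: half-life x intron FPKM (pre-mRNA
    level standing in for the synthesis rate).  NaN inputs stay NaN."""
    if math.isnan(half_life_h) or math.isnan(intron_fpkm):
        return math.nan
    if half_life_h < 0 or intron_fpkm < 0:
        raise ValueError("inputs must be non-negative")
    return half_life_h * intron_fpkm


def correlate(
    x: Sequence[float], y: Sequence[float], method: str = "spearman"
) -> tuple[float, float]:
    """Spearman (average-rank ties) or Pearson correlation with two-sided p.

    NaN pairs are dropped; fewer than 3 defined pairs is an error; a constant
    vector yields (nan, nan).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError("need at least 3 defined pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return math.nan, math.nan
    if method == "spearman":
        rho, p = stats.spearmanr(x, y)
    elif method == "pearson":
        rho, p = stats.pearsonr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(rho), float(p)


def exact_rank_sum_p(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sided exact Wilcoxon rank-sum p by enumeration over labelings.

    The rank sum W of group a (average ranks under ties) is compared against
    its distribution over all C(n_a + n_b, n_a) relabelings of the pooled
    sample; p is the fraction of labelings at least as far from E[W] as the
    observed value.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    n_a = len(a)
    w_obs = ranks[:n_a].sum()
    mu = ranks.mean() * n_a
    d_obs = abs(w_obs - mu)
    count = 0
    total = 0
    for combo in itertools.combinations(range(len(pooled)), n_a):
        w = ranks[list(combo)].sum()
        if abs(w - mu) >= d_obs - 1e-12:
            count += 1
        total += 1
    return count / total


def group_compare(
    a: Sequence[float],
    b: Sequence[float],
    test: str = "rank_sum",
) -> float:
    """Two-sided Wilcoxon group comparison p-value.

    ``rank_sum`` compares two independent groups: exact enumeration when the
    combined size is at most 10, normal approximation with tie correction
    otherwise.  ``signed_rank`` compares paired samples of equal length;
    identical pairs (all zero differences) return p = 1.
    """
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if test == "rank_sum":
        if a.size + b.size <= EXACT_RANK_SUM_MAX_N:
            return exact_rank_sum_p(a, b)
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        return float(res.pvalue)
    if test == "signed_rank":
        if a.size != b.size:
            raise ValueError("signed_rank requires paired samples")
        diffs = a - b
        if np.all(diffs == 0):
            return 1.0
        res = stats.wilcoxon(a, b, alternative="two-sided")
        return float(res.pvalue)
    raise ValueError(f"unknown test {test!r}")


def overlap_sets(
    stabilized: Iterable[str], bound_by: Mapping[str, Iterable[str]]
) -> dict[str, int]:
    """Three-way Venn region counts of stabilized-and-bound gene sets.

    The three sets are the intersections of the stabilized genes with each
    bait's bound set; keys are underscore-joined bait combinations plus
    ``stabilized_total`` and per-bait totals.
    """
    stab = set(stabilized)
    baits = list(bound_by)
    if len(baits) != 3:
        raise ValueError("overlap_sets expects exactly three baits")
    sets = {bait: stab & set(genes) for bait, genes in bound_by.items()}
    counts: dict[str, int] = {"stabilized_total": len(stab)}
    for bait in baits:
        counts[f"{bait}_total"] = len(sets[bait])
    a, b, c = (sets[bait] for bait in baits)
    regions = {
        f"{baits[0]}_only": a - b - c,
        f"{baits[1]}_only": b - a - c,
        f"{baits[2]}_only": c - a - b,
        f"{baits[0]}_{baits[1]}": (a & b) - c,
        f"{baits[0]}_{baits[2]}": (a & c) - b,
        f"{baits[1]}_{baits[2]}": (b & c) - a,
        f"{baits[0]}_{baits[1]}_{baits[2]}": a & b & c,
    }
    counts.update({k: len(v) for k, v in regions.items()})
    return counts


def rank_order_table(values: pd.Series) -> pd.DataFrame:
    """Stable ascending rank-order table of a per-gene statistic.

    NaN values are dropped; ties keep input order (stable sort); ``rank`` is
    1-based.
    """
    defined = values.dropna()
    ordered = defined.sort_values(kind="stable")
    return pd.DataFrame(
        {"value": ordered.to_numpy(), "rank": np.arange(1, len(ordered) + 1)},
        index=ordered.index,
    )


def benjamini_hochberg(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (FDR)."""
    return stats.false_discovery_control(np.asarray(pvalues, dtype=float), method="bh")


def build_integration_table(
    fpkm_control: pd.Series,
    fpkm_ko: pd.Series,
    halflives_control: pd.DataFrame,
    halflives_ko: pd.DataFrame,
    rip_tables: Mapping[str, pd.DataFrame],
    intron_fpkm_control: pd.Series | None = None,
    intron_fpkm_ko: pd.Series | None = None,
    categories: pd.Series | None = None,
    expression_fold: float = EXPRESSION_FOLD,
    stability_fold: float = STABILITY_FOLD,
) -> pd.DataFrame:
    """Per-gene joined view across all layers.

    Inputs are per-gene summaries (FPKM means per condition, half-life tables
    with status, per-bait enrichment tables, intron FPKM means); the result
    is indexed by the union of genes with class labels, enrichments, and the
    reconstructed steady-state level per condition.
    """
    genes = fpkm_control.index.union(fpkm_ko.index)
    out = pd.DataFrame(index=genes.rename("gene_id"))
    out["fpkm_control"] = fpkm_control.reindex(genes)
    out["fpkm_ko"] = fpkm_ko.reindex(genes)
    out["expression_class"] = [
        "unavailable"
        if math.isnan(c) or math.isnan(k)
        else classify_expression_change(c, k, expression_fold)
        for c, k in zip(out["fpkm_control"], out["fpkm_ko"])
    ]

    for label, table in (("control", halflives_control), ("ko", halflives_ko)):
        out[f"half_life_{label}"] = table["half_life_h"].reindex(genes)
        out[f"half_life_status_{label}"] = (
            table["status"].reindex(genes).fillna("excluded_unusable")
        )
    out["stability_class"] = [
        classify_stability_change(hc, hk, sc, sk, stability_fold)
        for hc, hk, sc, sk in zip(
            out["half_life_control"].fillna(math.nan),
            out["half_life_ko"].fillna(math.nan),
            out["half_life_status_control"],
            out["half_life_status_ko"],
        )
    ]

    for bait, table in rip_tables.items():
        out[f"enrichment_{bait}"] = table["enrichment"].reindex(genes)
        out[f"bound_{bait}"] = table["bound"].reindex(genes)

    for label, intron in (
        ("control", intron_fpkm_control),
        ("ko", intron_fpkm_ko),
    ):
        if intron is None:
            continue
        out[f"intron_fpkm_{label}"] = intron.reindex(genes)
        hl = out[f"half_life_{label}"].where(
            out[f"half_life_status_{label}"] == "ok"
        )
        out[f"predicted_level_{label}"] = hl * out[f"intron_fpkm_{label}"]

    if categories is not None:
        out["category"] = categories.reindex(genes)
    return out


def integration_report(
    table: pd.DataFrame,
    baits: Sequence[str] = ("ccr4not", "brf1", "ago2"),
    correlation_bait: str = "ccr4not",
) -> dict:
    """Summary statistics of an integration table.

    Tallies the classification columns, computes the headline Spearman
    correlations (enrichment vs half-life, enrichment vs expression,
    half-life vs expression), the rank-sum comparison of enrichment between
    stabilized and unchanged genes, the log-log Pearson correlation of
    reconstructed vs measured steady-state levels, and the stabilized x bound
    Venn counts.
    """
    report: dict = {
        "n_genes": int(len(table)),
        "expression_class_counts": table["expression_class"].value_counts().to_dict(),
        "stability_class_counts": table["stability_class"].value_counts().to_dict(),
    }

    enr = table.get(f"enrichment_{correlation_bait}")
    hl = table["half_life_control"].where(table["half_life_status_control"] == "ok")
    fpkm = table["fpkm_control"]
    correlations = {}
    if enr is not None:
        correlations["enrichment_vs_half_life"] = correlate(enr, hl, "spearman")
        correlations["enrichment_vs_fpkm"] = correlate(enr, fpkm, "spearman")
    correlations["half_life_vs_fpkm"] = correlate(hl, fpkm, "spearman")
    report["spearman"] = {
        k: {"rho": v[0], "p": v[1]} for k, v in correlations.items()
    }

    if enr is not None:
        stab = enr[(table["stability_class"] == "stabilized") & enr.notna()]
        unch = enr[(table["stability_class"] == "unchanged") & enr.notna()]
        if len(stab) and len(unch):
            report["stabilized_vs_unchanged"] = {
                "median_enrichment_stabilized": float(stab.median()),
                "median_enrichment_unchanged": float(unch.median()),
                "rank_sum_p": group_compare(stab, unch, "rank_sum"),
            }

    if "predicted_level_control" in table.columns:
        pred = table["predicted_level_control"]
        meas = table["fpkm_control"]
        keep = pred.notna() & meas.notna() & (pred > 0) & (meas > 0)
        if keep.sum() >= 3:
            rho, p = correlate(
                np.log(pred[keep]), np.log(meas[keep]), "pearson"
            )
            report["steady_state_reconstruction"] = {
                "pearson_r_loglog": rho,
                "p": p,
                "n": int(keep.sum()),
            }

    bound_cols = {b: f"bound_{b}" for b in baits if f"bound_{b}" in table.columns}
    if len(bound_cols) == 3:
        stabilized = set(table.index[table["stability_class"] == "stabilized"])
        bound_by = {
            b: set(table.index[table[col].fillna(False).astype(bool)])
            for b, col in bound_cols.items()
        }
        report["venn_stabilized_bound"] = overlap_sets(stabilized, bound_by)
    return report
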