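"""Synthetic transcriptome-kinetics generator.

Emulates the data a liver transcription-shutoff study produces, so the whole
pipeline can be exercised without deposited sequencing data:

* per-gene first-order kinetics: synthesis rate ``k_syn`` and a decay rate
  split into a basal component and a CCR4-NOT-dependent component
  (``k_dec = k_dec_basal + k_dec_ccr4``, true half-life ``ln2 / k_dec``);
* an actinomycin-D chase: after transcription shutoff every mRNA decays as
  ``m0 * exp(-k_dec * t)``; libraries are compositional (each sample is
  renormalized to a fixed sequencing depth), so absolute decay is only
  recoverable through a stable reference gene (Rplp0-like);
* knockout of the deadenylase scaffold: the CCR4-NOT decay component is
  removed, optionally with a secondary transcription change
  (``ko_syn_multiplier``);
* RIP capture per bait (ccr4not / brf1 / ago2 / igg): pulldown weight is
  abundance x (background + affinity); IgG has zero affinity everywhere;
* intron (pre-mRNA) reads proportional to the current synthesis rate, drawn
  from the steady-state (0 h) libraries only;
* replicate structure 4/3/3 (control) and 4/4/5 (knockout) at 0/4/8 h, with
  Poisson or negative-binomial count noise, or exact expected counts
  (``mode="expectation"``) for oracle tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .quantify import CountMatrix

__all__ = [
    "BAITS",
    "TrueGeneParams",
    "SimulationConfig",
    "SimulatedDataset",
    "steady_state_level",
    "chase_abundance",
    "apply_knockout",
    "rip_expected_share",
    "expected_enrichment",
    "generate_gene_params",
    "simulate_dataset",
    "truth_table",
]

BAITS = ("ccr4not", "brf1", "ago2", "igg")

DEFAULT_REPLICATES: dict[str, dict[float, int]] = {
    "control": {0.0: 4, 4.0: 3, 8.0: 3},
    "ko": {0.0: 4, 4.0: 4, 8.0: 5},
}


@dataclass(frozen=True)
class TrueGeneParams:
    """Ground-truth kinetic parameters for one gene.

    ``abundance0`` optionally pins the steady-state abundance directly; it is
    used for the reference gene, whose half-life may be infinite (ideally
    stable), where ``k_syn / k_dec`` is undefined.
    """

    gene_id: str
    k_syn: float
    k_dec_basal: float
    k_dec_ccr4: float
    exon_length_bp: int
    intron_length_bp: int
    capture: Mapping[str, float] = field(default_factory=dict)
    is_reference: bool = False
    ko_syn_multiplier: float = 1.0
    abundance0: float | None = None

    def __post_init__(self) -> None:
        if self.k_syn < 0:
            raise ValueError(f"{self.gene_id}: negative synthesis rate")
        if self.k_dec_basal < 0 or self.k_dec_ccr4 < 0:
            raise ValueError(f"{self.gene_id}: negative decay component")
        if self.k_dec == 0 and self.abundance0 is None:
            raise ValueError(
                f"{self.gene_id}: zero total decay rate requires an explicit abundance0"
            )
        if self.ko_syn_multiplier < 0:
            raise ValueError(f"{self.gene_id}: negative ko_syn_multiplier")
        if any(a < 0 for a in self.capture.values()):
            raise ValueError(f"{self.gene_id}: negative capture affinity")

    @property
    def k_dec(self) -> float:
        return self.k_dec_basal + self.k_dec_ccr4

    @property
    def half_life_h(self) -> float:
        return math.inf if self.k_dec == 0 else math.log(2.0) / self.k_dec

    @property
    def steady_state(self) -> float:
        if self.abundance0 is not None:
            return self.abundance0
        return steady_state_level(self.k_syn, self.k_dec)

    def affinity(self, bait: str) -> float:
        return float(self.capture.get(bait, 0.0))


def steady_state_level(k_syn: float, k_dec: float) -> float:
    """Steady-state abundance: synthesis rate divided by decay rate."""
    if k_dec <= 0:
        raise ValueError("steady state requires a positive decay rate")
    return k_syn / k_dec


def chase_abundance(m0: float, k_dec: float, t: float) -> float:
    """First-order decay after transcription shutoff: ``m0 * exp(-k_dec t)``."""
    if t < 0:
        raise ValueError("chase time must be non-negative")
    if m0 < 0:
        raise ValueError("abundance must be non-negative")
    return m0 * math.exp(-k_dec * t)


def apply_knockout(params: TrueGeneParams) -> TrueGeneParams:
    """Knockout of the deadenylase scaffold for one gene.

    Removes the complex-dependent decay component and applies the secondary
    transcription change; the reference gene (no CCR4-NOT component) keeps
    identical kinetics when its multiplier is 1.
    """
    return replace(
        params,
        k_dec_ccr4=0.0,
        k_syn=params.k_syn * params.ko_syn_multiplier,
        ko_syn_multiplier=1.0,
    )


def rip_expected_share(abundance: float, affinity: float, background: float) -> float:
    """Unnormalized pulldown weight of one gene: abundance x (background + affinity)."""
    if abundance < 0 or affinity < 0 or background < 0:
        raise ValueError("rip_expected_share arguments must be non-negative")
    return abundance * (background + affinity)


def expected_enrichment(
    truth: Sequence[TrueGeneParams], bait: str, background: float
) -> pd.Series:
    """Closed-form expectation-mode enrichment per gene for one bait.

    Sequencing renormalizes both libraries to fixed depth, so the expected
    RIP-FPKM / input-FPKM ratio is ``(background + affinity)`` divided by its
    abundance-x-length-weighted mean over the transcriptome.
    """
    w = np.array([p.steady_state * p.exon_length_bp for p in truth])
    cap = np.array([background + p.affinity(bait) for p in truth])
    wmean = float((w * cap).sum() / w.sum())
    return pd.Series(cap / wmean, index=[p.gene_id for p in truth], name=bait)


@dataclass(frozen=True)
class SimulationConfig:
    """Study design and noise model for one simulated dataset."""

    seed: int = 0
    depth: float = 5e6
    intron_depth_fraction: float = 0.05
    timepoints_h: tuple[float, ...] = (0.0, 4.0, 8.0)
    replicates: Mapping[str, Mapping[float, int]] = field(
        default_factory=lambda: {c: dict(t) for c, t in DEFAULT_REPLICATES.items()}
    )
    rip_replicates: int = 3
    dispersion: float = 0.0
    mode: str = "expectation"
    capture_background: float = 0.1

    def __post_init__(self) -> None:
        if self.mode not in ("expectation", "sampled"):
            raise ValueError(f"unknown simulation mode {self.mode!r}")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")


@dataclass
class SimulatedDataset:
    """Bundle of count matrices, manifest and ground truth for one run."""

    exonic: CountMatrix
    intronic: CountMatrix
    manifest: pd.DataFrame
    truth: pd.DataFrame
    gene_lengths: pd.DataFrame
    config: SimulationConfig


def generate_gene_params(
    n_genes: int = 1000,
    seed: int = 0,
    half_life_range_h: tuple[float, float] = (0.5, 40.0),
    target_fraction: float = 0.2,
    couple_binding_to_decay: bool = True,
    target_ccr4_frac_range: tuple[float, float] = (0.55, 0.95),
    nontarget_ccr4_frac_max: float = 0.35,
    affinity_range: tuple[float, float] = (1.5, 4.0),
    brf1_prob: float = 0.6,
    ago2_prob: float = 0.6,
    k_syn_log_mean: float = 1.0,
    k_syn_log_sigma: float = 1.0,
    exon_length_range_bp: tuple[int, int] = (500, 5000),
    intron_length_range_bp: tuple[int, int] = (200, 20000),
    ko_syn_multiplier: float = 1.0,
    reference_gene: str = "Rplp0",
    reference_half_life_h: float = math.inf,
) -> list[TrueGeneParams]:
    """Draw ground-truth kinetics for ``n_genes`` genes plus a stable reference.

    Total true half-lives are log-uniform over ``half_life_range_h``.  A
    ``target_fraction`` of genes are CCR4-NOT targets: a dominant fraction
    (``target_ccr4_frac_range``) of their decay rate is complex-dependent, so
    their knockout/control half-life ratio 1/(1-f) exceeds 2; non-targets stay
    below the 2-fold stabilization threshold.  With
    ``couple_binding_to_decay`` target status is sampled with probability
    proportional to the decay rate, reproducing the observed coupling of short
    half-life, high RIP enrichment and low expression.  Capture affinities of
    targets scale with their complex dependence; BRF1 and AGO2 each cover a
    random, overlapping subset of targets; IgG captures nothing specifically.

    The reference gene is appended last, highly expressed and stable
    (infinite half-life by default; pass a finite ``reference_half_life_h`` to
    study normalization bias from residual reference decay).
    """
    rng = np.random.default_rng(seed)
    lo, hi = half_life_range_h
    t_half = np.exp(rng.uniform(math.log(lo), math.log(hi), n_genes))
    k_dec = math.log(2.0) / t_half

    n_targets = int(round(target_fraction * n_genes))
    if couple_binding_to_decay:
        p = k_dec / k_dec.sum()
        target_idx = rng.choice(n_genes, size=n_targets, replace=False, p=p)
    else:
        target_idx = rng.choice(n_genes, size=n_targets, replace=False)
    is_target = np.zeros(n_genes, dtype=bool)
    is_target[target_idx] = True

    f_lo, f_hi = target_ccr4_frac_range
    frac = np.where(
        is_target,
        rng.uniform(f_lo, f_hi, n_genes),
        rng.uniform(0.0, nontarget_ccr4_frac_max, n_genes),
    )
    k_ccr4 = frac * k_dec
    k_basal = k_dec - k_ccr4

    a_lo, a_hi = affinity_range
    aff_scale = (frac - f_lo) / (f_hi - f_lo)
    aff_ccr4 = np.where(is_target, a_lo + (a_hi - a_lo) * aff_scale, 0.0)
    has_brf1 = is_target & (rng.random(n_genes) < brf1_prob)
    has_ago2 = is_target & (rng.random(n_genes) < ago2_prob)
    aff_brf1 = np.where(has_brf1, rng.uniform(a_lo, a_hi, n_genes), 0.0)
    aff_ago2 = np.where(has_ago2, rng.uniform(a_lo, a_hi, n_genes), 0.0)

    k_syn = rng.lognormal(k_syn_log_mean, k_syn_log_sigma, n_genes)
    exon_len = rng.integers(*exon_length_range_bp, size=n_genes, endpoint=True)
    intron_len = rng.integers(*intron_length_range_bp, size=n_genes, endpoint=True)

    width = max(4, len(str(n_genes)))
    genes = [
        TrueGeneParams(
            gene_id=f"g{i + 1:0{width}d}",
            k_syn=float(k_syn[i]),
            k_dec_basal=float(k_basal[i]),
            k_dec_ccr4=float(k_ccr4[i]),
            exon_length_bp=int(exon_len[i]),
            intron_length_bp=int(intron_len[i]),
            capture={
                "ccr4not": float(aff_ccr4[i]),
                "brf1": float(aff_brf1[i]),
                "ago2": float(aff_ago2[i]),
            },
            ko_syn_multiplier=float(ko_syn_multiplier),
        )
        for i in range(n_genes)
    ]

    # Rplp0-like reference: abundant, stable, not a CCR4-NOT target.
    ref_k_dec = 0.0 if math.isinf(reference_half_life_h) else math.log(2.0) / reference_half_life_h
    median_ss = float(np.median(k_syn / k_dec))
    genes.append(
        TrueGeneParams(
            gene_id=reference_gene,
            k_syn=float(np.median(k_syn)),
            k_dec_basal=ref_k_dec,
            k_dec_ccr4=0.0,
            exon_length_bp=1000,
            intron_length_bp=2000,
            capture={},
            is_reference=True,
            abundance0=20.0 * median_ss,
        )
    )
    return genes


def truth_table(truth: Sequence[TrueGeneParams], background: float = 0.1) -> pd.DataFrame:
    """Ground truth as a DataFrame, with derived half-lives, the knockout
    stability ratio and closed-form expected enrichment per bait."""
    enr = {b: expected_enrichment(truth, b, background) for b in BAITS}
    rows = []
    for p in truth:
        ko = apply_knockout(p)
        rows.append(
            {
                "gene_id": p.gene_id,
                "k_syn": p.k_syn,
                "k_dec_basal": p.k_dec_basal,
                "k_dec_ccr4": p.k_dec_ccr4,
                "k_dec": p.k_dec,
                "half_life_h": p.half_life_h,
                "half_life_ko_h": ko.half_life_h,
                "stability_ratio": (
                    math.inf if p.k_dec_basal == 0 else p.k_dec / p.k_dec_basal
                ),
                "steady_state": p.steady_state,
                "steady_state_ko": ko.steady_state,
                "exon_length_bp": p.exon_length_bp,
                "intron_length_bp": p.intron_length_bp,
                "is_reference": p.is_reference,
                "ko_syn_multiplier": p.ko_syn_multiplier,
                **{f"affinity_{b}": p.affinity(b) for b in BAITS},
                **{f"expected_enrichment_{b}": enr[b][p.gene_id] for b in BAITS},
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")


def _draw_counts(
    expected: np.ndarray, rng: np.random.Generator, mode: str, dispersion: float
) -> np.ndarray:
    if mode == "expectation":
        return expected
    if dispersion == 0.0:
        return rng.poisson(expected).astype(float)
    # Gamma-Poisson mixture: Var = mu + dispersion * mu^2.
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, expected / shape)
    return rng.poisson(lam).astype(float)


def simulate_dataset(
    truth: Sequence[TrueGeneParams], config: SimulationConfig
) -> SimulatedDataset:
    """Generate all count matrices the pipeline consumes.

    Exonic chase counts cover both genotypes at every timepoint/replicate;
    intronic counts are produced for the 0 h (steady-state) libraries; RIP
    counts comprise paired input and pulldown libraries (``rip_replicates``
    each) per bait from control livers.  Per-sample expected counts are
    compositional: proportional to abundance x exon length, renormalized to
    the configured depth.  Deterministic given the seed.
    """
    truth = list(truth)
    if not any(p.is_reference for p in truth):
        raise ValueError("ground truth must contain a reference gene")
    rng = np.random.default_rng(config.seed)
    genes = [p.gene_id for p in truth]
    exon_len = np.array([p.exon_length_bp for p in truth], dtype=float)
    intron_len = np.array([p.intron_length_bp for p in truth], dtype=float)
    ko = [apply_knockout(p) for p in truth]

    def _chase_abundances(params: Sequence[TrueGeneParams], t: float) -> np.ndarray:
        return np.array([chase_abundance(p.steady_state, p.k_dec, t) for p in params])

    columns: dict[str, np.ndarray] = {}
    manifest_rows: list[dict] = []
    intron_columns: dict[str, np.ndarray] = {}

    def _expected(weights: np.ndarray, depth: float) -> np.ndarray:
        total = weights.sum()
        if total <= 0:
            raise ValueError("zero total expected reads in a sample")
        return depth * weights / total

    for condition in ("control", "ko"):
        params = truth if condition == "control" else ko
        syn = np.array([p.k_syn for p in params])
        reps = config.replicates[condition]
        for t in config.timepoints_h:
            abundance = _chase_abundances(params, t)
            exp_exonic = _expected(abundance * exon_len, config.depth)
            exp_intron = None
            if t == 0.0:
                exp_intron = _expected(
                    syn * intron_len, config.depth * config.intron_depth_fraction
                )
            for r in range(1, int(reps[t]) + 1):
                sample_id = f"{condition}_{t:g}h_r{r}"
                columns[sample_id] = _draw_counts(
                    exp_exonic, rng, config.mode, config.dispersion
                )
                manifest_rows.append(
                    {
                        "sample_id": sample_id,
                        "condition": condition,
                        "assay": "chase",
                        "bait": "",
                        "timepoint_h": t,
                        "replicate": r,
                    }
                )
                if exp_intron is not None:
                    intron_columns[sample_id] = _draw_counts(
                        exp_intron, rng, config.mode, config.dispersion
                    )

    # RIP experiments use steady-state control livers.
    abundance0 = np.array([p.steady_state for p in truth])
    exp_input = _expected(abundance0 * exon_len, config.depth)
    for r in range(1, config.rip_replicates + 1):
        sample_id = f"rip_input_r{r}"
        columns[sample_id] = _draw_counts(exp_input, rng, config.mode, config.dispersion)
        manifest_rows.append(
            {
                "sample_id": sample_id,
                "condition": "control",
                "assay": "rip_input",
                "bait": "",
                "timepoint_h": 0.0,
                "replicate": r,
            }
        )
    for bait in BAITS:
        cap = np.array(
            [config.capture_background + p.affinity(bait) for p in truth]
        )
        exp_rip = _expected(abundance0 * exon_len * cap, config.depth)
        for r in range(1, config.rip_replicates + 1):
            sample_id = f"rip_{bait}_r{r}"
            columns[sample_id] = _draw_counts(exp_rip, rng, config.mode, config.dispersion)
            manifest_rows.append(
                {
                    "sample_id": sample_id,
                    "condition": "control",
                    "assay": "rip",
                    "bait": bait,
                    "timepoint_h": 0.0,
                    "replicate": r,
                }
            )

    exonic_df = pd.DataFrame(columns, index=pd.Index(genes, name="gene_id"))
    intronic_df = pd.DataFrame(intron_columns, index=pd.Index(genes, name="gene_id"))
    manifest = pd.DataFrame(manifest_rows)
    manifest["library_total"] = manifest["sample_id"].map(exonic_df.sum(axis=0))

    lengths = pd.DataFrame(
        {
            "exon_length_bp": exon_len.astype(int),
            "intron_length_bp": intron_len.astype(int),
        },
        index=pd.Index(genes, name="gene_id"),
    )
    return SimulatedDataset(
        exonic=CountMatrix(region="exonic", counts=exonic_df),
        intronic=CountMatrix(region="intronic", counts=intronic_df),
        manifest=manifest,
        truth=truth_table(truth, background=config.capture_background),
        gene_lengths=lengths,
        config=config,
    )
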