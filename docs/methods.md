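# Methods

## Decay model and half-life estimation

Each mRNA is assumed to follow first-order kinetics: synthesis at constant
rate `k_syn` (molecules·h⁻¹) and degradation at rate `k_dec` (h⁻¹), so the
steady-state abundance is `k_syn / k_dec` and, after transcription shutoff,
abundance decays as `m₀·exp(−k_dec·t)` with half-life `t½ = ln2 / k_dec`.
The decay rate is decomposed into a basal component and a
deadenylase-complex–dependent component, `k_dec = k_basal + k_ccr4`; a
scaffold knockout removes the second component, so the true knockout/control
half-life ratio is `(k_basal + k_ccr4) / k_basal`, optionally accompanied by
a secondary transcription change (`ko_syn_multiplier` on `k_syn`).

Sequencing is compositional: a library measures relative, not absolute,
abundance.  During a chase the total mRNA pool shrinks while read depth
stays fixed, so FPKMs of decaying genes are inflated sample by sample.  The
estimator therefore divides every FPKM by the FPKM of a stable reference
mRNA in the same sample, averages the ratios per timepoint over replicates
(the regression runs on the three timepoint means, not on individual
replicates), scales the series to its 0 h mean, and fits ordinary least
squares of `ln(level)` on time.  Natural log is fixed by the half-life
formula `t½ = ln(0.5 / e^intercept) / slope = (ln 0.5 − intercept)/slope`.
Although the 0 h scaling forces the first point to one, the intercept is
still estimated; it absorbs residual offset and the formula corrects for it.

Quality rules: a profile with any non-positive timepoint mean is unusable
(log undefined); fitted half-lives ≤ 0 h (rising series) or > 50 h are
excluded as unreliable, and a slope of exactly zero maps to the over-cap
exclusion as the limit of an infinite half-life.  All thresholds
(`0.00015` minimum mean FPKM; intron filter `0.01` FPKM / `30` bp; RIP dual
`0.1` FPKM; bound `> 1.5`; fold changes `2.0`; cap `50` h) are strict
comparisons at the printed values and are configurable in `RunConfig`.

## RIP enrichment

Enrichment of gene *g* for bait *b* is `FPKM_RIP(g) / FPKM_input(g)`,
computed per replicate experiment and then aggregated (mean by default,
median available), rather than aggregating FPKMs first — replicate
enrichment values are what the aggregation statistics describe.  A replicate
value is undefined when both FPKMs are below 0.1 (too poorly measured) or
when the input FPKM is zero (undefined division, treated conservatively
rather than as infinite enrichment); a gene is excluded only when no
replicate yields a defined value.  IgG-bound genes are not subtracted from
bait-bound sets (the IgG control is reported descriptively); an explicit
subtraction can be done on the returned tables if desired.

## Synthetic-data generator

The generator emulates the features of the real experiment that the
estimators rely on, with the replicate design 4/3/3 (control) and 4/4/5
(knockout) at 0/4/8 h and three RIP replicates per bait:

- **Compositional counts.** Expected exonic reads are proportional to
  abundance × exon length, renormalized per sample to a fixed depth
  (5×10⁶ by default).  This reproduces the fact that absolute decay is
  invisible without a reference gene: doubling every synthesis rate leaves
  all FPKMs unchanged.
- **Reference gene.** An Rplp0-like gene is highly expressed (20× the median
  steady state) and ideally stable by default (infinite true half-life).
  The idealization is deliberate: reference normalization recovers
  `k_dec − k_ref`, so any residual reference decay biases long half-lives
  upward (with a 300 h reference, ≈ 15 % at t½ = 40 h).  The noiseless
  recovery guarantees below hold for the ideal reference;
  `reference_half_life_h` accepts finite values to study that bias, which
  also afflicts the real experiment's assumption that the reference is
  stable over the 8 h chase.
- **Kinetics.** Total true half-lives are log-uniform on [0.5, 40] h.
  A configurable fraction of genes (default 0.2) are complex targets: the
  complex-dependent share of their decay rate is uniform on [0.55, 0.95]
  (knockout stabilization ratio 2.2–20), non-targets at most 0.35 (ratio
  ≤ 1.54).  The gap around the 2-fold threshold keeps the truth
  unambiguous.  Target status is sampled with probability proportional to
  the decay rate ("binding-coupled decay"), which induces the empirically
  observed sign structure: enrichment anticorrelates with half-life and
  with expression, half-life correlates with expression.  Synthesis rates
  are log-normal and independent of decay.
- **RIP capture.** Pulldown weight = abundance × (background + affinity),
  renormalized to depth; expected enrichment is therefore
  `(background + affinity)` over its abundance-weighted mean.  Target
  affinities (1.5–4) scale with the complex-dependent decay share; BRF1 and
  AGO2 each cover a random 60 % of targets, giving partially overlapping
  bound sets; IgG has zero affinity everywhere, so its expected enrichment
  is exactly one for every gene.
- **Pre-mRNA.** Intron-mapped reads are generated for the steady-state (0 h)
  libraries only, proportional to the current synthesis rate × intron
  length — pre-mRNA profiling uses steady-state libraries, not the chase.
- **Noise.** `mode="expectation"` emits exact expected (real-valued) counts
  for oracle tests; `mode="sampled"` draws Poisson counts, or gamma-Poisson
  (negative binomial, `Var = μ + φμ²`) when a dispersion φ > 0 is set.
  Everything is deterministic given the seed.

What the generator does **not** emulate — and what passing tests therefore
do not show about real data: fragment-level coverage and mappability,
isoform mixtures, batch effects between libraries, partial knockout
efficiency, cell-type heterogeneity of whole-tissue RNA, secondary
transcriptional programs beyond a per-gene synthesis multiplier, and any
deviation from first-order decay (e.g. age-dependent or biphasic decay).
Recovery accuracy on this generator is a correctness check of the
estimators, not a performance claim about tissue RNA-seq.

## Statistics

Spearman (average ranks for ties) and Pearson correlations and the
asymptotic, tie-corrected Wilcoxon tests delegate to scipy.  The exact
small-sample rank-sum test (combined n ≤ 10) is computed in-package by
enumeration over all C(n_a+n_b, n_a) relabelings, with the two-sided
p-value defined as the fraction of labelings whose rank sum is at least as
far from its expectation as observed; a paired comparison of identical
vectors returns p = 1.  No multiple-testing correction is applied by
default (raw p-values are reported); a Benjamini–Hochberg helper exists for
per-gene differential-expression screens.

## Numerical choices and degenerate inputs

- Gene lengths use 0-based half-open intervals; abutting exons produce zero
  intron length, and such genes get undefined intron FPKM, removed by the
  intron filter.  Representative transcripts: smallest support level
  (missing level ranks last), then longest transcript, then lexicographic
  id — deterministic under permutation.
- Library totals default to column sums when no manifest total is supplied.
- The intron filter eliminates on *either* low FPKM or short length by
  default (`rule="both"` restores the conjunctive reading): a < 30 bp intron
  makes intron FPKM meaningless regardless of its value.
- Two-timepoint designs reduce to the closed form `t·ln2 / ln(M₀/M_t)`.
- Pipeline problem sizes in tests and the acceptance script (200–2,000
  genes, depth 5×10⁶) were chosen as the smallest sizes at which every
  property is measured with comfortable margin; all stages are vectorized
  and run in seconds.

## Known limitations

Three chase timepoints give no degrees of freedom for lack-of-fit
diagnostics, and no confidence intervals are attached to half-lives.  The
bound/unbound call is a hard threshold on a continuous enrichment; near-1.5
genes are call-unstable under sampling noise.  Stability classification
requires both half-lives to pass the (0, 50] window, which censors the
slowest-decaying genes precisely in the knockout where stabilization pushes
them over the cap — the real analysis shares this censoring.
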