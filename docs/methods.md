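# Methods

This note documents the statistical procedures implemented in `refstab`,
the defaults and numerical choices, what the synthetic generator does and
does not emulate, and known limitations.

## From Cq to relative quantities

A quantification cycle (Cq) is the PCR cycle at which fluorescence crosses
the detection threshold. Entries with no amplification by the final cycle
(`max_cycles`, default 40) are *missing*. Present values must lie in
(0, max_cycles]; gene and sample identifiers must be unique.

**QC filtering.** A sample is kept iff RQI > `rqi_min` (default 7,
strict) and `ratio_low` ≤ A260/280 ≤ `ratio_high` (defaults 1.9–2.1,
inclusive). Missing QC fields reject with reason `missing_qc` by default
(`missing_policy="keep"` available). The partition is exhaustive and
disjoint and every rejection carries machine-readable reason codes.

**Technical replicates** (same tissue/treatment/temperature/week/bio_rep)
are averaged arithmetically over their *present* Cq values before any
analysis; a group that is entirely missing stays missing. Replicates
disagreeing by more than 1.0 cycle (configurable) trigger a warning, never
an error — typical instrument repeatability is well below one cycle, but
no standard prescribes a hard rule.

**Relative quantities.** With per-gene amplification factor
A_g ∈ (1, 3] (default 2.0 = 100% efficiency; per-gene values can come from
an efficiency table or from standard curves), q_gs = A_g^(Cq_cal − Cq_gs)
with the calibrator being the gene's minimum-Cq sample (so max_s q_gs = 1;
a named calibrator is configurable). Missing-value policy before the
transform: `drop` (default) removes any sample with an incomplete gene
profile, since both stability algorithms need complete matrices; `impute`
fills missing entries at `max_cycles`, treating them as detection-limit
censoring.

**Standard curves** are ordinary least squares of mean Cq on log10
dilution (≥ 3 distinct levels; non-negative slopes rejected), giving
E(%) = (10^(−1/slope) − 1) × 100 and the amplification factor 1 + E/100.

**Distribution summaries** report per-gene n, min, 5th/25th/50th/75th/95th
percentiles and max over present values, with percentiles by linear
interpolation between order statistics (numpy's `method="linear"`), chosen
because box-plot conventions vary and this one is the common default.

## geNorm

All logarithms are base 2 and all standard deviations use the n−1
denominator (the algorithm's conventional choices). On the log2 quantity
matrix:

- V_jk = SD_s(log2 q_js − log2 q_ks); M_j = Σ_{k≠j} V_jk / (G−1), defined
  for G ≥ 3.
- Stepwise exclusion removes the highest-M gene and recomputes M until two
  genes remain. Those two cannot be ranked against each other (their M
  values are identical by construction — each equals their mutual V), so
  they are reported as a tied pair with rank 1.5 each. Exact ties in the
  maximal M (within 1e−12) exclude the gene *latest* in input order; the
  rule is arbitrary but deterministic and documented.
- NF_n is the per-sample geometric mean of the n most stable genes;
  V_n/n+1 = SD_s(log2 NF_n − log2 NF_{n+1}) for n = 2..G−1.
- Gene-count recommendation: the smallest n with V_n/n+1 ≤ 0.15 (cutoff
  configurable). Because the field also reads a sub-cutoff V_n/n+1 as
  licensing an *optional* (n+1)-th gene, the result exposes both readings:
  `recommended_n` (strict minimum) and `optional_extra_n` (largest m such
  that every V_k/k+1 with k < m is under the cutoff). If nothing meets the
  cutoff the full panel is recommended with a warning flag.
- M classification: ≤ 0.5 stable; for heterogeneous panels values in
  (0.5, 1] are still acceptable.

Scale invariance (per-gene rescaling), sample-permutation invariance and
agreement with an independent brute-force implementation to 1e−10 on
random matrices are asserted in the test suite.

## NormFinder

Log2 expression within group g follows a two-way layout per gene i and
sample j: y_igj = α_ig + β_gj + ε_igj with ε_igj ~ N(0, σ²_ig). After
two-way centering within the group, residual sums of squares
z_ig = Σ_j R²_igj/(n_g − 1) are bias-corrected into unbiased variance
estimates:

    σ̂²_ig = (z_ig − Ŝ_g/G²) · G/(G−2),   Ŝ_g = (G/(G−1)) Σ_i z_ig.

(E[z_ig] = σ²_ig (G−2)/G + Σ_k σ²_kg / G², so the correction is exactly
unbiased; the test suite confirms this over 10,000 simulated datasets.)
Negative estimates are floored at 0 for the stability computation; the
un-floored estimates are available (`floor=False`) because a bias check
must average raw values.

Differential group effects d̂_ig are the two-way-centred G × Γ matrix of
group means (unweighted over groups, so Σ_i d̂_ig = 0 per group holds even
for unbalanced designs). Their dispersion in excess of sampling noise
estimates the between-group effect variance

    τ̂² = max(0, Σ_{i,g} d̂²_ig/((G−1)(Γ−1)) − mean_{i,g}(σ̂²_ig/n_g)),

effects are shrunk by τ̂²/(τ̂² + σ̂²_ig/n_g), and the per-gene-per-group
stability ρ_ig = |d̃_ig| + sqrt((σ̂²_ig/n_g)·τ̂²/(τ̂² + σ̂²_ig/n_g)) is
averaged over groups. With a single group (or `groups=None`) the stability
is sqrt(max(0, σ̂²_i)).

**τ̂² = 0 boundary.** When τ̂² = 0 every ρ_ig collapses to 0 and the
grouped ranking is vacuous; the implementation then falls back to the
ungrouped stability and flags the result (`fallback_ungrouped`), which
preserves a usable ranking.

**Resolution limit.** Genes whose true variance is far below the panel's
average cannot be reliably ordered *among themselves*: the shared
column-mean noise contributed by the noisy genes enters every z_ig, and
very small σ̂² frequently floor to 0 (ties). The estimator reliably
separates quiet genes from noisy ones — which is the question the method
answers — but the internal order of near-tied quiet genes is unstable, and
the tests assert only the former.

Requirements: G ≥ 3 (the correction divides by G−2), ≥ 3 samples
ungrouped, and every group with n_g ≥ 2.

## Consensus ranking

Each method's ordering becomes weights 1..G (ties share the mean of the
spanned integers; geNorm's final pair enters as a tie at 1.5). The
consensus score is the geometric mean of a gene's weights across methods
and the final order sorts it ascending. GM ties break by mean per-method
weight, then by input order — published tables occasionally disagree with
their own per-method rankings here, so no tie policy can reproduce every
table and ours is simply deterministic.

## Synthetic data generator

`simulate` draws y_igj = b_gj + d_ig + ε_igj (sample effect b shared by
all genes, SD `sample_effect_sd` = 1.0 log2 units, emulating RNA-input and
RT-efficiency variation; optional zero-sum group effects d; per-gene noise
ε) and maps to Cq = baseline_i − y/log2(A_i), adds N(0, 0.1) cycles per
technical replicate, and censors values beyond `max_cycles` = 40 (plus an
optional random `missing_rate`). Defaults mirror the emulated study:

- design: 24 condition cells (leaves/stems × ±PGPR × weeks 4/6/8 at 20 °C;
  flowers/seeds × ±PGPR × weeks 6/8; uninoculated leaves at 15 and 25 °C ×
  weeks 4/6), 3 biological × 2 technical replicates → 144 wells;
- per-gene baseline Cq spanning ~11.6 (18S rRNA) to ~33 (EF-1a), matching
  the wide abundance range such panels show;
- per-gene log2 noise SD ladder {0.05, 0.1, 0.3, 0.5, 0.7, 0.9, 1.1, 1.3,
  1.5, 1.7}, assigned so the implied stability order matches the consensus
  order reported for the emulated study's full panel (CAC and α-tubulin
  quietest, α-actin noisiest);
- QC metadata RQI ~ U(7, 10) and A260/280 ~ U(1.9, 2.1) so that default
  data passes QC (ranges are configurable for QC tests).

Ground truth (`SyntheticTruth`) carries the generative config, the latent
log-expression matrix and the true stability order (ascending noise SD +
mean |d|), and generation is bit-reproducible from config + seed.

What the generator does **not** emulate: amplification stochasticity at
low copy number (Poisson/Monte-Carlo PCR effects), inhibitor-induced
efficiency shifts, correlated noise between genes beyond the shared sample
effect, plate/batch effects, or non-Gaussian outliers. Passing recovery
tests therefore show the estimators work when their model holds; they do
not certify behaviour under model violations.

## Problem sizes used in the validation suite

Oracle equivalence runs 100 random matrices up to 6 genes × 12 samples;
the unbiasedness check uses 10,000 one-group datasets of 6 genes × 8
samples; ground-truth recovery uses 200 seeds of the full 24-cell design;
the null calibration uses 300 seeds with single technical replicates.
These sizes give Monte-Carlo error comfortably below the asserted margins
while keeping the default test run fast.

## Known limitations

- The published stability values of the study this design emulates (e.g.
  M = 0.74 for the best pair over all samples) derive from raw Cq data
  that was never deposited, so they cannot be recomputed; only the
  decision logic and in-text worked examples are reproducible.
- geNorm's M conflates co-regulation with stability: a co-regulated gene
  pair can rank artificially well. The synthetic generator can plant such
  pairs via group effects, but no automatic co-regulation diagnostic is
  provided.
- Efficiency correction assumes a single per-gene amplification factor;
  per-sample efficiency variation is not modelled.
- The pipeline treats panels independently; no multiplicity adjustment is
  applied across panels (the underlying methods define none).
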