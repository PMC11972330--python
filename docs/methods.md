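# Methods

## Screening model

The screen treats each gene as a pair of T-point expression series, one per
condition, on the log2(TPM+1) scale, and ranks genes by how dissimilar the
two series are. There is no parametric model of expression: significance is
defined *relative to the cohort* — a gene is called by a metric when its
distance sits in the top 1 % of that metric's empirical distance distribution
across all screened genes. This makes the screen scale-free and
assumption-light, at the cost of a fixed selection budget: each metric calls
exactly ⌊0.01·N⌋ genes when distances are tie-free, regardless of how many
genes truly diverge. If more than ~1 % of screened genes carry real signal,
the excess cannot be called (see *Limitations*).

Stages and their contracts:

1. **TPM normalization.** `tpm_g = (count_g/len_kb_g) / Σ_g'(count_g'/len_kb_g') × 10⁶`
   per sample; columns sum to 10⁶ exactly. Expression is `log2(tpm+1)`.
   No between-sample normalization beyond TPM (no TMM/size factors) — the
   joint minmax scaling later removes per-gene affine effects anyway.
2. **Profile pairs.** Replicates are collapsed per condition × timepoint by
   the arithmetic mean of log2(TPM+1) (median available). Mean-of-logs is the
   minimal-assumption reduction when replicate counts differ between
   conditions (4 vs 2 here); it weights each replicate equally on the scale
   the screen operates on.
3. **Variance filter.** Sample variance (denominator 2T−1) of the pooled 2T
   values must be strictly greater than 0.1 log2-units². Sample (not
   population) variance is the conventional default; with 2T = 14 the two
   differ by the factor 14/13 ≈ 1.08, so the choice matters only for genes
   within ~8 % of the threshold. A constant-pair "degenerate" flag covers
   threshold-0 runs: such pairs are excluded from screening with a logged
   count rather than scaled to NaN.
4. **Joint minmax scaling.** `E' = (E − E_min)/(E_max − E_min)` with extrema
   over the pooled 2T values. Scaling jointly (not per series) preserves the
   WT/KO relationship; scaling at all makes every downstream metric invariant
   to positive affine transforms of the raw pair, which the suite verifies
   end-to-end.
5. **Empirical selection.** The self-inclusive tail probability
   `p(g) = #{g′: d(g′) ≥ d(g)}/N` unifies "1 % highest distances" with
   "p < 0.01": with continuous distances, `p ≤ 0.01` selects exactly
   ⌊0.01·N⌋ genes, the top gene has p = 1/N, and tied genes share one p and
   are selected all-or-none (so a tie group straddling the cutoff is dropped
   entirely — selection never exceeds the budget). The empirical survival
   function is used directly; no kernel density estimate enters the decision
   path, since a bandwidth would be an unanchored free parameter.
6. **Consensus.** Genes significant in ≥1 metric are compiled and sorted by
   (number of significant metrics desc, mean p asc, gene id asc) — a total,
   deterministic order. Metrics that return no value for a gene are treated
   as non-significant and logged.

## The twelve metrics

All metrics operate on the scaled pair x (WT), y (KO); free parameters are in
`MetricParams`, recorded in the distance-table header. Defaults for T = 7:

| metric | definition | parameters (default) |
|---|---|---|
| euclidean | √Σ(xᵢ−yᵢ)² | — |
| sts | √Σ(slopeᵢ(y)−slopeᵢ(x))², slopes over the actual time grid | — |
| dtw | min-cost monotone warping path, local cost \|xᵢ−yⱼ\|, steps {↓,→,↘}, no window, no normalization | — |
| tam | from the optimal DTW path: n_h/p + n_v/p + (1−n_d/p) ∈ [0,2] | diagonal-preferred backtrack |
| acf | √Σₖ(ρ̂ₓ(k)−ρ̂_y(k))², biased autocorrelations | max lag T−2 = 5 |
| fourier | √Σₖ\|Xₖ−Yₖ\|² over first n DFT coefficients | n = ⌊T/2⌋+1 = 4 |
| cdm | (C(x⊕y)+C(y⊕x)) / (2(C(x)+C(y))) on 8-symbol quantized series | lzma (raw LZMA2, preset 9) |
| cid | euclidean × (max(CE)+ε)/(min(CE)+ε), CE = √Σ(Δz)² | ε = 1e−12 |
| cor | √(2(1−ρ)), Pearson ρ; constant series → ρ := 0 | — |
| per | √Σₖ(Pₓ(k)−P_y(k))², P(k)=\|Zₖ\|²/T, DC excluded | K = ⌊T/2⌋ = 3 |
| int.per | Σₖ\|Fₓ(k)−F_y(k)\|, F = normalized cumulative periodogram; zero-power series → uniform ramp | K = 3 |
| frechet | discrete Fréchet (Eiter–Mannila recursion), cost \|xᵢ−yⱼ\| | value-only embedding |

Numerical and design notes:

- **TAM tie-break.** TAM depends on which optimal path is taken. The path is
  fixed by diagonal-preferred backtracking (ties: diagonal, then vertical,
  then horizontal), computed on the lexicographically ordered argument pair —
  the ordering makes TAM exactly symmetric, which plain transposition of the
  cost matrix does not guarantee when vertical/horizontal ties occur.
- **Fréchet embedding.** Default is value-only: scaled values span [0,1]
  while time spans days, so a 2-D (time, value) embedding would be dominated
  by the time axis. The 2-D option exists for callers who rescale time.
- **CDM.** Series are quantized into 8 uniform bins over [0,1], one byte per
  point, and compressed with a raw LZMA2 stream at preset 9 (64 KiB
  dictionary — far larger than any input, so lengths are content-determined;
  the headerless raw format avoids a fixed ~60-byte container overhead that
  would swamp the signal at T = 7). A deflate (zlib level 9) option exists.
  CDM(x,x) > 0 by construction — it is a shared-information ratio, not a
  metric with identity — and at T = 7 its resolution is very coarse (heavily
  tied values, so the all-or-none tie rule usually selects few or no genes).
  It is retained for completeness of the family.
- **Constant-series conventions.** acf: ρ̂ := 0 at all lags; cor: ρ := 0
  (d = √2); int.per: F := uniform ramp. These keep every metric NaN-free on
  any pair that passes the variance filter.
- **Vectorization.** The gene × metric table uses vectorized numpy/FFT paths
  for the eight closed-form metrics, per-gene O(T²) dynamic programs for
  dtw/tam/frechet, and a compressed-length cache keyed on the quantized byte
  string for cdm. A 62,710-gene, 12-metric table takes ~10 s on one CPU; the
  table path is tested to match the per-pair definitions exactly.

## Synthetic data generator

The generator emulates the screen's target regime: a 7-point two-week time
course (default grid 0, 2, 4, 6, 9, 11, 14 days — a plausible reconstruction,
configurable), 4 WT and 2 KO replicates, ~log2(TPM+1) expression with a small
planted fraction of condition-divergent genes.

- **Latent trajectories** (linear TPM scale): baseline uniform in [0.5, 5]
  TPM; null genes are 60 % flat, 15 % sigmoid, 15 % ramp, 10 % pulse —
  mostly static transcriptomes with a dynamic minority, typical of bulk
  differentiation courses. Activation is a logistic
  `b + A/(1+exp(−k(t−t₀)))` with k = 1/day and plateau A log-uniform in
  [10, 1000] TPM, mimicking sequential-activation (HOX-like) onset profiles
  without asserting any biology.
- **Planted effects** modify the KO trajectory only: *delay* evaluates the
  template at t − delay_shift (default 4 days ≈ two early grid steps);
  *attenuation* multiplies the plateau by 0.3 on the linear scale;
  *suppression* flattens KO to baseline; *ectopic* keeps WT flat while KO
  activates. Null genes share one latent trajectory in both conditions.
- **Counts mode** draws negative-binomial counts (dispersion 10) around
  TPM-proportional means scaled by lognormal library sizes (mean 2×10⁷,
  cv 0.2), plus per-sample lognormal jitter of sd `noise_sd_log` on the
  latent TPM. Exercises the full normalization path, including TPM's
  invariance to depth.
- **Expression mode** emits log2(TPM+1) plus Gaussian noise of sd
  `noise_sd_log` directly, so the screen can be tested in isolation; with
  zero noise, null genes give exactly zero distance under every metric with
  identity.

What the generator does *not* emulate: clone-to-clone batch structure,
count overdispersion heterogeneity across genes, transcript isoforms, or any
correlation between genes. Passing tests therefore demonstrate the pipeline's
contracts and its behavior under idealized noise, not performance on real
organoid data.

## Problem sizes used in the checks

The self-checks run at the sizes that make their property sharp while staying
desk-sized: oracle equivalence on 240 random pairs at T ≤ 5 (exhaustive
enumeration is exponential in T); selection cardinality at N = 10,000
(⌊0.01·N⌋ = 100 exactly); null calibration at N = 5,000; planted-signal
recovery at N = 2,000 with 50 planted genes over 10 seeds; and one full
62,710-profile run matching the target scale of a whole-transcriptome screen.

## Limitations

- The 1 % empirical rule bounds per-metric calls at ⌊0.01·N⌋. In the
  planted-recovery setting (50 planted among ~800 filtered genes, i.e. ~6 %
  true signal), each metric can call at most 8 genes, so recall against the
  full planted set is structurally capped (measured: ~0.49 of planted genes
  reach ≥1-metric significance, ~0.08 reach ≥6; per-metric precision is near
  1). This is a property of the method, not of the implementation: the screen
  is a *top-divergence ranker*, not a complete detector, and behaves exactly
  as designed when the signal fraction exceeds the tail budget.
- Consensus counts are not calibrated error rates: the 12 metrics are highly
  correlated, so "significant in k metrics" has no simple null distribution.
  The union bound (≤12 %) on ≥1-metric calls under the null is the only
  distribution-free guarantee, and in practice the null fraction is ~5 %.
- Replicate aggregation before distance computation discards within-timepoint
  variance; a gene with noisy replicates and a gene with consistent ones are
  screened identically.
- T = 7 is short for the spectral and autocorrelation metrics (3 Fourier
  frequencies, 5 lags) and very short for cdm; these metrics contribute
  diversity to the consensus rather than standalone power.
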