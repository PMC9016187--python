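# Methods

## Statistical model

Two-sample summary-data MR assumes each instrument j satisfies, to first
order,

    β̂_Xj ~ N(γ_j, se²_Xj)          (SNP–exposure association)
    β̂_Yj ~ N(β γ_j + α_j, se²_Yj)  (SNP–outcome association)

with β the causal effect of interest and α_j a possible direct
(pleiotropic) effect. A valid instrument has α_j = 0; the estimators
differ in which violations they tolerate. All estimators act on the Wald
ratios θ̂_j = β̂_Yj/β̂_Xj with first-order SE σ_j = se_Yj/|β̂_Xj| (the
no-measurement-error approximation; a second-order SE including the
exposure term is available behind a flag, default off, because with
F ≳ 100 the correction is negligible).

### Estimator details and numerical choices

* **IVW.** Ratio form with w_j = σ_j⁻². Default model is multiplicative
  random effects: SE_fixed × max(1, √(Q/(J−1))), which reduces exactly to
  the fixed-effect model when Q ≤ J−1. Both models are exposed; the floor
  at 1 never narrows the fixed-effect interval. CIs use the normal 97.5%
  quantile; p-values are two-sided normal Wald tests floored at 1e-300.
* **MR-Egger.** Weighted regression (weights se_Yj⁻²) with intercept,
  after orienting all instruments to positive exposure effects (flipping
  both betas, which leaves ratios invariant). The regression is fitted via
  statsmodels WLS; the residual variance (overdispersion) scale is floored
  at 1; slope and intercept use t inference with J−2 df. The t reference
  (rather than normal) is required for the intercept test to be exact at
  small J, and is verified against the published-value consistency check
  (intercept/SE of 3.053e-5/5.354e-5 at J = 23 → p = 0.575).
* **Weighted median.** Standardized cumulative weights
  s_j = (Σ_{i≤j} w_i − w_j/2)/Σ w_i over the sorted ratios; linear
  interpolation at s = 0.5. SE from a parametric bootstrap
  (θ_j* ~ N(θ̂_j, σ_j), weights held fixed, default 1000 draws, seeded).
* **Mode estimators.** Gaussian kernel density over {θ̂_j} with weights
  uniform (simple) or σ_j⁻² (weighted), bandwidth
  h = φ·0.9·min(sd, MAD·1.4826)·J^(−1/5) (φ default 1), evaluated on a
  512-point grid spanning [min−3h, max+3h]; argmax ties break toward the
  smaller ratio (first maximum on the ascending grid). Degenerate spread
  (h = 0) returns the weighted median of the ratios, which then equals the
  repeated value. SE by the same parametric bootstrap.
* **Cochran's Q** uses the fixed-effect IVW estimate as reference and
  χ²_{J−1}; this parameterization reproduces the published p = 0.085 at
  Q = 31.591 with 22 df.
* **MR-PRESSO.** Leave-one-out IVW slopes as per-SNP references; observed
  weighted RSS compared against simulations under the fitted no-pleiotropy
  model; empirical p-values use (1 + #exceedances)/(K + 1) smoothing, so
  the global p can never fall below 1/(K+1). Outlier p-values are
  Bonferroni-multiplied by J (α default 0.05, K default 1000). The
  distortion test is implemented as a random-subset comparison: the shift
  in the IVW estimate caused by removing the flagged SNPs is ranked
  against shifts from removing equally many randomly chosen SNPs. The
  published distortion procedure is under-specified for a summary-level
  reimplementation; this permutation-style variant is this package's
  convention and is documented as such.
* **Leave-one-out stability flag** (this package's convention): stable iff
  every reduced estimate keeps the full estimate's sign and every reduced
  CI overlaps the full CI.

### Selection pipeline

Fixed stage order: significance filter (strict p < 5×10⁻⁸ by default) →
greedy LD clumping (accept the smallest p, remove r² ≥ 0.1 neighbours;
ties broken by snp_id so results are row-order invariant; distance-window
fallback of 250 kb when no LD table is supplied; LD is always consumed
precomputed, never estimated from genotypes) → harmonization → F ≥ 10
screen → Steiger filter. Per-SNP variance explained uses
r² = β̂²/(β̂² + n·se²), which needs only printed columns; the
allele-frequency form 2·eaf(1−eaf)·β̂² is available by option. The Steiger
filter is the plain r² comparison (keep iff r²_exposure > r²_outcome).
Palindromic SNPs are resolved by allele frequency only when both
frequencies lie outside 0.5 ± 0.08 (window configurable) and are dropped
otherwise, including whenever a frequency is missing. Every input SNP
appears exactly once in the harmonization log.

## Synthetic data: what it emulates and what it does not

The generator reproduces the *statistical* structure of a two-sample
design: independent instruments, per-study sampling noise with
se = sd_resid/√(2 n maf(1−maf)), consistent p-values, configurable
pleiotropy (balanced or directional, on a fraction of SNPs), reverse-causal
SNPs (primary effect drawn on the outcome side with a back-propagated
exposure effect sized at half the outcome z-score, so the SNP clears
exposure-side screening but fails the Steiger comparison), outlier shifts
in units of se_Y, and allele-coding scrambles for harmonization testing.
One seeded stream with a fixed draw order (maf → γ → α → reverse selection
→ exposure noise → outcome noise → alleles → scramble) makes output tables
byte-reproducible. A `noise_scale` multiplier on the sampling noise (SEs
unchanged) supports exact degenerate checks.

It does **not** emulate LD between instruments, winner's curse from
in-sample selection, sample overlap between studies, allele-frequency
estimation error, or liability-scale subtleties of binary traits. Passing
tests therefore demonstrate correctness of the algorithms under the
stated sampling model, not robustness to those real-data complications.

### The study-sized scenario

`paper_like_scenario()` mirrors the motivating design: a case-control
exposure GWAS of 5,539 cases / 20,169 controls on the log-odds scale
(SE multiplier 1/√(φ(1−φ)) with case fraction φ ≈ 0.215) and a
463,010-person biobank outcome with 1,178 cases scanned by a *linear*
model on the 0/1 phenotype (SE multiplier √(φ(1−φ)) ≈ 0.050). The linear
outcome scale is deliberate: biobank scans of rare binary endpoints are
typically linear-model association studies, and only on that scale do the
emulated per-SNP outcome SEs (~1.2×10⁻⁴) combine to the ~7.5×10⁻⁵ pooled
IVW standard error and odds ratios of order 1.0003 that characterize this
regime. True SNP-exposure effects are drawn from N(0.34, 0.08²) truncated
below at 0.20, giving 23 instruments that all clear p < 5×10⁻⁸ and F ≥ 10
(mean F ≈ 180, mean exposure r² ≈ 0.007) and pass Steiger by construction.

## Simulation study sizes

The validation harness uses 500 replicates for effect recovery and null
calibration (Monte-Carlo SE of a 5% rejection rate ≈ 1%), 200 for the
pleiotropy robustness ordering, 100 for MR-PRESSO recovery (K = 1000
simulations each), and 20 for the deterministic Steiger construction —
sizes chosen so each Monte-Carlo band is comfortably wider than its
sampling noise while the whole battery runs in well under a minute.

## Known limitations and open choices

* The Wald-ratio SE default ignores exposure-side noise (NOME); fine for
  F ≳ 50, optimistic below that. The F ≥ 10 screen bounds the damage.
* Correlated instruments are out of scope: the IVW/Egger forms assume
  independent SNPs, and clumping is the only defence offered.
* MR-PRESSO's distortion test follows this package's random-subset
  definition (above), not the original's exact resampling scheme.
* The mode estimators use bootstrap SEs; analytic (delta-method) SEs are
  not offered.
* Reported odds-ratio columns exponentiate the estimate regardless of the
  outcome scan's scale; when the outcome GWAS is a linear scan of a binary
  trait (as in the emulated design) these are risk-difference
  exponentials, interpretable only near 1.
* When several estimates tie in p-value sorting or the kernel argmax, the
  documented deterministic tie-breaks (snp_id order, smaller ratio) are
  applied; they are conventions, not statistical claims.
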