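# Methods

## Model and assumptions

The unit of analysis is one gene: m variants measured on N⁺ cases and
N⁻ controls as minor-allele dosages in {0, 1, 2}. The population
quantity attached to variant i is Dᵢ = fᵢ⁺ − fᵢ⁻, the case/control
difference in minor allele frequencies; its sample analogue is
D̂ᵢ = Cᵢ⁺/(2N⁺) − Cᵢ⁻/(2N⁻) with Cᵢ± the stratum allele counts. All
inference is marginal per variant: no covariates, no relatedness, and —
in the simulation model — no linkage disequilibrium (variants
independent, Hardy-Weinberg within each stratum).

### Step 1: gene-based tests

Two weighted tests over the vector D̂:

* burden: Q_bw = Σ wᵢ D̂ᵢ. Asymptotic null Q_bw ~ N(0, Σ wᵢ² v̂ᵢ),
  two-sided p-value, with the pooled-frequency (score-test style)
  null variance v̂ᵢ = f̂ᵢ(1−f̂ᵢ)(1/(2N⁺) + 1/(2N⁻)). Two-sided
  because risk-decreasing variants are in scope.
* variance-component (SKAT-type): Q_sw = Σ wᵢ D̂ᵢ². Asymptotic null
  Σ (wᵢ v̂ᵢ) χ²₁ with independent chi-squares; upper-tail p-value.

Weights are the Beta(1, 25) density at the variant's MAF,
wᵢ = 25 (1 − fᵢ)²⁴ ∈ [0, 25]. By default the MAF is the pooled sample
estimate f̂ᵢ — the only quantity a real-data analysis can observe; an
explicit weight vector (e.g. from true simulation MAFs) can be passed
instead. Monomorphic variants get weight 25 (f̂ = 0) but contribute
zero to every statistic and null variance; a fully monomorphic gene
returns p = 1 with a warning.

The chi-square-mixture tail is evaluated by Imhof's inversion integral
(numerical quadrature of the exact characteristic-function inversion);
this is the default because four-moment matching to a non-central
chi-square, also provided (`method="moment"`), errs by 10–20% for
p ≤ 0.002, which matters when p-values are reported. The moment
approximation *is* used as the default gate inside the bootstrap loop,
where only the comparison p < α matters and its few-percent error near
α = 0.01 is immaterial against thousands of inversions per gene. Both
methods reduce to the exact χ²₁ tail for a single polymorphic variant.

### Step 2: post-hoc statistics and ranking

For genes with Step-1 p < α, each variant gets a naive statistic T̂ᵢ:
D̂ᵢ (family "D", aligned with the burden test) or D̂ᵢ² (family "D2",
aligned with the variance-component test). Variants are ranked by
|T̂ᵢ|, rank 1 strongest; absolute value keeps risk-decreasing causal
variants rankable. Ties get midranks.

Because rare-variant statistics live on the lattice k/(2N), exact ties
are common, including at the top of the ranking. The "top-k causal"
metric therefore uses expected credit: if a tie spans the k-th
position, the replicate scores the hypergeometric probability that a
uniformly random tie-break fills the remaining slots with causal
variants only (1 when all tied variants are causal, 0 when too few of
them are). This is deterministic, independent of variant order, and
equal in expectation to any randomized tie-breaking procedure; an
all-or-nothing rule would systematically deflate the metric (by about
half a point in the worked scenario below, where ~1% of significant
replicates have a causal/neutral tie at the top).

### The bootstrap winner's-curse correction

Conditioning on Step-1 significance biases T̂ᵢ away from zero. The
correction estimates that selection bias from the data themselves:

1. Draw a bootstrap sample with replacement, separately within cases
   and controls, of sizes exactly N⁺ and N⁻. The subjects drawn zero
   times form the residual sample; each stratum retains on average a
   fraction (1 − 1/N)^N ≈ e⁻¹ ≈ 0.368 of its subjects there.
2. Recompute the same GBT on the bootstrap sample (weights re-derived
   from the bootstrap sample's pooled MAFs, mirroring what the original
   analysis did; freezing the original weights is available as an
   option). Keep the replicate only if it is significant at the same α
   as Step 1 — the selection event must be reproduced inside the
   resample for the bias to be the *conditional* one.
3. For kept replicates record bias_b(T̂ᵢ) = T̂ᵢ,b* − T̂ᵢ,bᴿ, the
   bootstrap-sample statistic minus the residual-sample statistic.
   Residual statistics use the residual sample's own case/control
   counts; frequency differences are scale-free in N so no reweighting
   is needed.
4. Adjust by the per-variant median over kept replicates, clamped at
   zero: T̂ᵢ,adj = max(T̂ᵢ − median_b bias_b, 0) for T̂ᵢ > 0,
   min(…, 0) for T̂ᵢ < 0, and 0 stays 0. The clamp guarantees
   sign(T̂adj) ∈ {0, sign(T̂)}; the median (rather than the mean,
   also available) is robust to the long tail that conditioning
   produces.

If no bootstrap replicate is significant the naive statistics are
returned flagged unadjusted. A bootstrap replicate whose residual
stratum is empty is redrawn and does not count toward B; with
thousands of subjects this is unreachable (probability N⁻ᴺ per
stratum), and it is guarded mainly for toy-sized inputs.

B defaults to 1,000. The reproduction runs use B = 200: the per-variant
median is already stable there (top-rank metrics move by < 0.5 points
between B = 200 and B = 1,000 in the worked scenario).

## Simulated data

A scenario fixes per-variant population MAFs f and allelic relative
risks λ, plus N⁺ = N⁻ = 1,500 and the Step-1 α. Controls sit at the
population frequency and cases at f⁺ = λf / (1 + (λ−1)f) — the
rare-disease allelic relative-risk mapping, chosen because no disease
prevalence is specified anywhere in the design and because it makes
neutral variants (λ = 1) *exactly* null. Genotypes are subject-level
independent Binomial(2, f±) draws, so the bootstrap can resample
subjects.

The canonical grid crosses 10 MAF architectures of a 10-variant gene
(all-rare at 0.0001 or 0.001; one common neutral variant at 0.05 or
0.01 plus 9 rare; two common — one neutral, one risk-increasing — plus
8 rare) with 5 relative-risk mixes (risk-increasing : neutral :
risk-decreasing percentages 20:80:0, 50:50:0, 80:20:0, 20:60:20,
0:100:0), 50 scenarios in all. A causal variant's λ is tied to its
MAF: (0.05, 1.2), (0.01, 1.5), (0.001, 2), (0.0001, 8), reciprocals
for risk-decreasing. Variants are laid out causal-rares first, then
common variant(s), then neutral rares; in the two-common architecture
the designated common risk variant consumes one risk-increasing slot
when the mix provides one (in the all-null mix it is neutral like
everything else).

Closed-form truth per variant: E[D̂ᵢ] = fᵢ⁺ − fᵢ⁻ and
E[D̂ᵢ²] = (fᵢ⁺ − fᵢ⁻)² + Var(D̂ᵢ) with
Var(D̂ᵢ) = fᵢ⁺(1−fᵢ⁺)/(2N⁺) + fᵢ⁻(1−fᵢ⁻)/(2N⁻) (binomial allele
counts under HWE). These are verified against brute-force Monte-Carlo
moments in the tests.

Seeding is counter-based: replicate r of a study uses
SeedSequence(master, r), so any single replicate is reproducible
without regenerating its predecessors; the bootstrap for a significant
replicate continues that replicate's stream.

What the generator does **not** emulate: linkage disequilibrium,
population structure, covariates, genotyping error, quantitative
traits, and variable gene sizes. Passing tests therefore demonstrate
the selection-bias mechanism and its correction under independence;
they do not certify behaviour under correlated genotypes, where the
per-variant bias acquires covariance terms that this implementation's
diagnostic (below) deliberately omits.

## Evaluation machinery

A study simulates n replicates of one scenario, gates each on Step 1,
and aggregates over the significant replicates only (the conditioning
is the phenomenon under study): per-variant bias = mean(T̂ − E[T]),
MSE = mean((T̂ − E[T])²), mean ranks, and top-1 / top-2 causal
proportions, all before and after adjustment. Step-1 power is the
fraction of all replicates with p < α.

The gene-level bias decomposition used as a diagnostic predicts, for
independent variants,

    Bias(T̂ᵢ) = Bias(Q)/Var(Q) · wᵢ · Var(Tᵢ),

i.e. the observed gene-statistic bias propagates to each variant in
proportion to weight × sampling variance. Var(Tᵢ) uses the closed form
above for family D and the normal-approximation variance
4μ²σ² + 2σ⁴ for family D2. This explains the headline pathology: the
common neutral variant has by far the largest Var(Dᵢ), hence absorbs
the largest share of the selection bias.

Cross-scenario summaries pool variant-by-scenario cells within each
(test, statistic, α) group: the fraction of cells whose |bias| (or
MSE) decreased after adjustment, the median improvement among improved
cells, the median decline among worsened ones, and their ratio —
optionally stratified by Step-1 power band (0–0.05, 0.05–0.2, 0.2–0.5,
0.5–1). Scenarios with fewer than two significant replicates are
excluded; empty strata render as "–". Improvement is measured on
|bias| so that it is well defined for negative-bias variants.

## Problem sizes used by the test suite

The worked low-power scenario (five rare risk variants at RR 8, one
common neutral variant, burden/α = 0.01, Step-1 power ≈ 12%) is run at
its full 10,000 replicates with B = 200 — a few minutes on one CPU.
The cross-scenario study is run at a reduced scale chosen to keep the
whole suite interactive: 500 replicates per scenario and B = 100,
over all 50 scenarios and all four test/α configurations, with the
moment-matching gate for the variance-component runs. Calibration
checks (type-I error, null unbiasedness, funnel relation between bias
and power) use 2,000–10,000 replicates of single scenarios.

## Known limitations

* P-values are purely asymptotic. At MAF ≤ 1e-3 the allele counts are
  tiny and the true null distributions are discrete, which makes both
  tests mildly conservative on rare-only genes (empirical size ≈ 0.008
  to 0.009 at nominal 0.01 in our calibration runs); calibration is
  tight when at least one common variant carries part of the null
  variance. Per-gene p-values for rare-only genes should be read as
  approximations.
* The bias decomposition diagnostic drops the covariance terms and so
  only applies to (approximately) independent variants.
* The correction reduces, but does not eliminate, the conditional
  bias; with very low Step-1 power the median is taken over few
  significant bootstraps and becomes noisy.
* Adjusted statistics carry no standard errors or p-values: inference
  after selection and adjustment is a harder problem than point
  de-biasing and is out of scope here.
* In the worked scenario the adjusted *top-two* causal proportion
  settles near 40% — clearly above its naive ~8% but below the ~47%
  the adjusted top-one metric reaches; the value is insensitive to B,
  to signed versus absolute ranking, and to tie handling.
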