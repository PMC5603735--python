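# wincurse

Winner's-curse correction for post-hoc single-variant statistics after
gene-based rare-variant association tests.

## The problem

Case-control sequencing studies test rare variation gene by gene,
aggregating the per-variant signal into a gene-based test (GBT) such as
a weighted burden test or a SKAT-type variance-component test. When a
gene comes out significant, the natural next question — *which* variant
drives the signal, and how big is its effect? — is usually answered
with naive single-marker statistics computed on the same data. Because
those statistics are only examined *conditional on the gene having
passed the significance threshold*, they overstate the evidence: the
winner's curse. The distortion is worst exactly where gene-based
testing is most needed (low power), and it is differential — relatively
common non-causal variants are inflated the most, so they can be ranked
ahead of the truly causal rare variants.

`wincurse` implements a two-step analysis with a stratified-bootstrap
bias correction:

1. **Step 1** — test the gene with a weighted burden statistic
   Q_bw = Σᵢ wᵢ D̂ᵢ or a variance-component statistic
   Q_sw = Σᵢ wᵢ D̂ᵢ², where D̂ᵢ = f̂ᵢ⁺ − f̂ᵢ⁻ is the case/control
   difference in sample minor allele frequencies and
   wᵢ = 25 (1 − fᵢ)²⁴ is the Beta(1, 25) density weight. P-values are
   asymptotic (normal for Q_bw; a chi-square mixture tail, evaluated by
   Imhof's inversion integral, for Q_sw). Stop unless p < α.
2. **Step 2** — compute per-variant statistics T̂ᵢ (D̂ᵢ or D̂ᵢ²), then
   estimate their selection bias by resampling: draw B stratified
   bootstrap samples (N⁺ cases, N⁻ controls, with replacement within
   stratum); the subjects never drawn form the *residual sample*
   (≈ e⁻¹ ≈ 37% of each stratum). For every bootstrap sample on which
   the GBT is again significant, record
   bias_b(T̂ᵢ) = T̂ᵢ,b* − T̂ᵢ,bᴿ, and adjust

   T̂ᵢ,adj = max(T̂ᵢ − median_b bias_b(T̂ᵢ), 0) if T̂ᵢ > 0 (min(…, 0) if T̂ᵢ < 0),

   so the adjusted estimate can shrink to zero but never cross it.

The package also ships the full simulation framework used to quantify
what the correction buys: a 50-scenario grid of minor-allele-frequency
architectures × relative-risk mixes with closed-form expected values,
plus evaluation machinery for Step-1 power, conditional bias, MSE and
variant-ranking metrics.

## Worked example

```python
from wincurse import GeneAssociationModel, lowpower_scenario, simulate_gene

# one replicate of the worked low-power scenario: SNPs 1-5 are rare
# (MAF 0.0001) risk variants with relative risk 8, SNP 6 is a common
# (MAF 0.01) neutral variant, SNPs 7-10 are rare neutral variants
geno, truth = simulate_gene(lowpower_scenario(), seed=20)

model = GeneAssociationModel.from_genotypes(geno, gene_id="demo-gene")
res = model.fit(test="burden", alpha=0.01, n_bootstrap=500, seed=20)
print(res.summary())
```

```
Two-step gene-based association analysis
============================================
Gene:        demo-gene
Subjects:    1500 cases / 1500 controls
Variants:    10
Step 1 test: burden  Q = 0.1922  p = 0.001568  (alpha = 0.01)
Bootstrap:   500 replicates, 359 significant

variant family     naive  adjusted  bias_estimate  n_significant_bootstraps  rank_naive  rank_adjusted
     v1      D     0.001 0.0009074      9.256e-05                       359         4.5              4
     v2      D  0.001333 0.0009488      0.0003846                       359         2.5              2
     v3      D     0.001 0.0008993      0.0001007                       359         4.5              5
     v4      D  0.001333 0.0009311      0.0004022                       359         2.5              3
     v5      D 0.0003333         0      0.0003333                       359           7            8.5
     v6      D  0.002667  0.001065       0.001602                       359           1              1
     v7      D         0         0              0                       359           9            8.5
     v8      D         0         0              0                       359           9            8.5
     v9      D 0.0006667 0.0005841      8.257e-05                       359           6            6
    v10      D         0         0              0                       359           9            8.5
```

The gene clears Step 1 (p ≈ 0.0016 < 0.01). Naively, the common
neutral variant v6 tops the ranking with D̂ = 0.00267 — almost four
times its true value of 0. The bootstrap attributes by far the largest
selection bias to it (0.0016, versus ≈ 1e-4 for most rare variants)
and shrinks it to 0.00107, while the causal variants v1–v4 lose little.
Averaged over many replicates this demotes common neutral variants and
roughly halves the conditional bias of every variant (see the
simulation study below).

A command-line surface mirrors the library:
`wincurse simulate | test | adjust | evaluate | reproduce` (see
`wincurse --help`); real data enter as VCF 4.2 or a dosage TSV plus a
phenotype table and a gene-set table.

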