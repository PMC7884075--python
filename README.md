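# polyarch

Polygenic-architecture analysis of quantitative traits from GWAS summary
statistics, packaged with a synthetic-data harness so the whole pipeline is
testable end to end without any external download.

What it does:

- **`polyarch.synthdata`** — genotype panels (latent AR(1) per LD block,
  thresholded to diploid dosages), point-normal / point-t causal
  architectures with optional per-megabase "clumpy" placement
  (Beta(α, α/ρ)), phenotypes at a target SNP heritability, and a fast path
  that simulates marginal z-scores per LD block directly
  (`z ~ MVN(√N·Rβ, R)`, optional χ² inflation λ).
- **`polyarch.gwas`** — log-transform + covariate residualization,
  repeated-measure cleaning (10×IQR, then 4 sd), per-variant linear
  association with MAF/missingness filters, strict MAF/INFO filtering.
- **`polyarch.ashcore`** — empirical-Bayes point-mass-plus-normal mixture on
  (beta, se) pairs with a null-favouring penalty; SQUAREM-accelerated EM
  with a monotone penalized-log-likelihood trace; the point-mass weight is
  the per-bin null proportion pi0.
- **`polyarch.polygenicity`** — windowed LD scores with small-sample
  adjustment, ntile LD-score binning with per-bin mean χ², pi0 and a
  χ²-tail fraction, univariate LD-score regression with iterative weights
  (slope, intercept, implied h²), a simulated reference-curve library over
  a (π1, λ) grid, and two causal-fraction estimators: matching the three
  observed bin curves against the library (inflation estimated from the
  intercept, statistics deflated by it) with log-scale grid refinement,
  and a parametric fit of the non-null fraction vs LD score with an
  inflation-absorbing intercept.
- **`polyarch.heritability`** — cM-gap genome blocks, HESS-style local h²
  from summary statistics and block LD (truncated-eigenvalue
  pseudoinverse), cumulative-h² curves, pathway h² by block overlap, and
  BED-style interval subtraction.
- **`polyarch.enrichment`** — greedy p-value clumping, anchor-greedy 0.1 cM
  lead merging, 100 kb gene windows, Fisher 2×2 and exact Poisson-rate
  pathway enrichment, and matched null SNP sets (MAF × LD score × gene
  distance deciles).
- **`polyarch.nonlinearity`** — dominance (dosage vs dosage+genotype-class
  indicators), pairwise epistasis (two-locus main effects vs full
  interaction), and stratified paired-difference Z tests.
- **`polyarch.pipeline`** — declarative experiment config, an end-to-end
  architecture report, and text-format round-trip validation.

File formats are plain text throughout: plink2 `.glm.linear`-style TSV for
association results, ldsc `.l2.ldscore`-style TSV for LD scores, BED3+name
for intervals, GMT for gene sets.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the property-based acceptance criteria
(π1 recovery within factor 2, null calibration, inflation robustness,
LD-score-regression identities, the mixture oracle, exhaustive Fisher
equivalence, local-h² recovery, non-additivity calibration, and the
direction checks); it shares one simulated reference library across
criteria and takes a few minutes. The rest of the suite is fast.

## CLI

```sh
polyarch simulate --pi1 0.003 --h2 0.3 --n-individuals 20000 \
    --n-variants 50000 --seed 1 --out sim.glm.linear.tsv
polyarch ldsc --assoc sim.glm.linear.tsv \
    --ldscores sim.glm.linear.tsv.l2.ldscore --n-individuals 20000
polyarch bins --assoc sim.glm.linear.tsv \
    --ldscores sim.glm.linear.tsv.l2.ldscore --bins 200 --out bins.tsv
polyarch ash --assoc sim.glm.linear.tsv
polyarch bed-subtract --a regions.bed --b exclude.bed --out kept.bed
polyarch report --config experiment.json --out-dir out/
```

`polyarch report` composes simulation → binning → LD-score regression →
π1 estimation from a single JSON config (see
`polyarch.pipeline.ExperimentConfig`) and stamps every artifact with the
config hash and seed.
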