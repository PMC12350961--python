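# fidlong

Analysis toolkit for the genetic link between **translational fidelity**
and **longevity** in yeast segregant panels (BY × RM recombinant haploid
progeny), built around Orgel's error-catastrophe model of aging.

It is aimed at quantitative geneticists and aging researchers who want a
tested, scriptable reimplementation of this analysis — from raw
plate-reader and luminometer tables to QTL intervals — plus a
synthetic-data generator so every stage runs and is testable with no
external downloads.

## The model and the pipeline

Orgel's model posits that translation errors corrupt the translation
machinery itself: with baseline error rate *E* and amplification
constant α > 1, the aggregate error rate follows

    e_{t+1} = E + α e_t ,   e_0 = E ,

and death occurs when *e* reaches a critical level *D*, giving a maximum
lifespan

    Lifespan(E) = (ln((α−1)D + E) − ln E) / ln α .

Because *E* is evolutionarily confined to a narrow band [L, U] and other
causes of death truncate lifespans below this cap, feasible
(*E*, lifespan) pairs fill a trapezoid with a concave hypotenuse — and
the fidelity-longevity anticorrelation is only visible among long-lived
individuals. The package's **removal scan** quantifies this: it
recomputes the two-tailed Spearman correlation after discarding
increasing fractions of the shortest-lived samples, with bootstrap
standard errors and Bonferroni adjustment across the fraction grid.

Around that core, the package implements:

- `fidlong.orgel_model` — cohort simulation (uniform rejection sampling
  of the trapezoid), replicated removal-scan studies, parameter sweeps;
- `fidlong.cls_pipeline` — chronological lifespan (CLS) from outgrowth
  OD600 curves: background subtraction, CV ≤ 0.2 replicate filters,
  doubling time δ = ln2·(t₂−t₁)/(ln X₂ − ln X₁) over the exponential OD
  window, time-to-threshold with 12-h extrapolation, survival fractions
  S_n = 2^(−(t_n−t₂)/δ₂), and the survival integral (trapezoid area
  over aging days) as the CLS;
- `fidlong.luciferase` — translation error rates from dual-luciferase
  tables: RLU gates, Renilla-normalized Firefly activities, two-level
  CV filtering, the mutant/wildtype ratio of ratios, and the 10⁻²
  plausibility cutoff;
- `fidlong.qtl_mapping` — LOD = −n·ln(1−r²)/(2 ln 10) linkage scans,
  permutation thresholds (mean + 3 SD), peak calling, 95% Bayesian
  credible intervals, interval overlap and combined-LOD SNP selection,
  allele-effect summaries;
- `fidlong.heritability` — broad-sense H² = σ²G/(σ²G+σ²E) from replicate
  variance components and narrow-sense h² = σ²A/(σ²A+σ²EV) by kinship
  REML, both with delete-one-strain jackknife SEs;
- `fidlong.stats_correlation` — empirical and allele-stratified removal
  scans, percent-change arithmetic, KS/Lilliefors normality checks,
  strain-effect ANOVA;
- `fidlong.synthetic_data` — seeded generators for genotypes, coupled
  traits with a planted pleiotropic locus, growth-curve plates and RLU
  tables, with ground truth serialized beside every dataset.

## Worked example

Replicated cohort simulation (1000 cohorts of 400 samples, α = 1.5,
D = 0.06, L = 5×10⁻⁴, U = 1.5×10⁻³):

```python
from fidlong.orgel_model import OrgelParams, simulate_study

study = simulate_study(OrgelParams.methods_variant(), n=400, reps=1000, seed=0)
print(study[["fraction_removed", "n_kept", "mean_rho", "median_p_adjusted"]])
```

```
 fraction_removed  n_kept  mean_rho  median_p_adjusted
              0.0     400   -0.1362             0.0528
              0.1     360   -0.1498             0.0436
              0.2     320   -0.1655             0.0279
              0.3     280   -0.1879             0.0163
              0.4     240   -0.2131             0.0085
              0.5     200   -0.2484             0.0038
              0.9      40   -0.5052             0.0066
```

On the full cohort the correlation is not significant (median
Bonferroni-adjusted P ≈ 0.053 > 0.05); after removing 40% of the
shortest-lived samples it is (P ≈ 0.0085), and the mean Spearman ρ
strengthens monotonically until the sample size collapses at 90%
removal.

The assay pipelines round-trip the generator's ground truth:

```python
from fidlong import synthetic_data as sd
from fidlong.cls_pipeline import estimate_cls
from fidlong.luciferase import estimate_error_rates

cfg = sd.SynthConfig(n_strains=5, n_chromosomes=2, markers_per_chromosome=5)
data = sd.generate_all(cfg, seed=0)
cls_tab, _ = estimate_cls(data["plate"])
ter_tab = estimate_error_rates(data["rlu"])
```

```
 strain  cls_mean  error_rate   cls_planted  E_planted
seg0000   7.97283 0.000780764       8.62136 0.000771127
seg0001   7.61244  0.00118098       7.95188  0.00118188
seg0003   8.51406 0.000661244       8.76924 0.000632776
```

Error rates are recovered to ~1% at the default 5% replicate noise (and
exactly in the noise-free limit). Recovered CLS sits a few percent below
the planted survival integral because the minimal-doubling-time
statistic is deliberately conservative under measurement noise; ranks
and downstream correlations are unaffected, and the noise-free
round-trip agrees to better than 0.1%.

A console script mirrors the library (`fidlong simulate`, `fidlong cls`,
`fidlong ter`, `fidlong qtl`, `fidlong herit`, `fidlong correlate`,
`fidlong synth`); see `fidlong --help`.

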