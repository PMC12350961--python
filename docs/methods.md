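# Methods

## Error-catastrophe model

The aggregate translation error rate evolves as `e_{t+1} = E + α e_t`
with `e_0 = E`. For α > 1 this grows without bound (closed form
`e_t = E(α^{t+1} − 1)/(α − 1)`), and the time for `e` to climb from `E`
to the lethal level `D` gives the maximum lifespan

    Lifespan(E) = (ln((α−1)D + E) − ln E)/ln α .

The continuous formula and the discrete recurrence differ by at most
one time step (an off-by-one between "time of the reading at D" and
"number of steps taken"); the test suite asserts this over random
parameter draws. The α ≤ 1 regime, in which the error rate converges to
E/(1−α) instead of diverging, is outside the model's scope.

Default constants: α = 1.5, D = 0.06 errors/codon, L = 5×10⁻⁴,
U = 2×10⁻³. Two published values of U circulate (2×10⁻³ and 1.5×10⁻³);
`OrgelParams` defaults to the former and exposes the latter as
`OrgelParams.methods_variant()` / `U_METHODS`. Empirically, only the
1.5×10⁻³ variant reproduces the full qualitative pattern in which the
whole-cohort correlation is **not** significant while the 40%-removal
correlation is; under U = 2×10⁻³ the full cohort is already
significantly anticorrelated at n = 400. The acceptance script
therefore reports the 40%-removal P under U = 2×10⁻³ (where it is
significant either way) and the 0%-removal P under the 1.5×10⁻³
variant.

**Cohort sampling.** Cohorts are uniform over
{(E, y): L ≤ E ≤ U, 0 ≤ y ≤ Lifespan(E)} by rejection sampling in the
bounding box [L, U] × [0, Lifespan(L)]. This is exactly uniform and
avoids quadrature of the concave hypotenuse; acceptance rate ≈ 0.8 at
the default constants. A chi-square uniformity test on a 10×10 grid is
part of the suite.

**Removal scan.** For each fraction f in {0, 0.1, …, 0.9} the
`ceil((1−f)·n)` longest-lived samples are kept (stable sort by lifespan
then input order, so ties are deterministic; the rule maps 235 → 118 at
f = 0.5 and 235 → 24 at f = 0.9). Spearman's two-tailed test uses the
asymptotic t approximation with average ranks, except for n ≤ 9 where
the null is enumerated exactly over all n! rank assignments. The
Bonferroni multiplier is the size of the fraction grid (10 by default).
Bootstrap SEs resample kept pairs with replacement (100 draws by
default; 0 disables). Replicated studies report both the median
adjusted P per fraction and the proportion of replicates significant at
0.05, since a single published P track could be either aggregation.

## Chronological lifespan

Time unit: minutes. Readings every 10 min for 12 h (720 min); the "12"
in the extrapolation formula is read as 12 h for dimensional
consistency with δ in minutes. The pipeline per biological replicate:

1. subtract the per-timepoint mean of the plate's cell-free blank wells
   (negative values retained — CLS is invariant to any constant plate
   offset, which the suite asserts);
2. CV-filter technical replicates on the OD at t = 50 min: if
   CV > 0.2, drop the value farthest from the mean of the others
   (ties → lowest index) and retest once; still failing → discard the
   replicate set. For k > 3 replicates up to ⌊k/3⌋ drops are allowed;
3. average kept technical curves; compute the doubling time over all
   ordered point pairs with background-corrected OD inside [0.2, 0.5]
   and X₂ > X₁, reduced by the **min** statistic (mean/median are
   options). The window applies to background-corrected, un-normalized
   OD — doubling time is computed before the t = 50 normalization — a
   convention switchable via `ClsConfig.window_on_normalized`;
4. t_n is the first sampled grid time at which the t50-normalized OD
   reaches 0.3 (no interpolation); cultures that never cross within the
   horizon are extrapolated with
   `t_n = 720 + (ln 0.3 − ln X₇₂₀)·δ/ln 2`, where δ falls back to the
   day-2 value when the day's own window never fills;
5. S_n = 2^(−(t_n − t₂)/δ₂); S at the reference day is exactly 1;
   S_n > 1 (t_n < t₂) is allowed and flagged rather than clamped, since
   clamping would silently bias the CLS downward;
6. CLS = trapezoid area of S over aging days {2, 4, 6, 9, 12, 15}.

Biological-replicate CLS values pass the same CV filter before
averaging; a replicate whose technical set is discarded is dropped, and
strains with no surviving replicate are omitted (recorded in the audit
trail). Ties among "most different" replicates break toward the lowest
index.

Note on the min statistic: under measurement noise the minimum pairwise
doubling time is biased low, which lowers recovered CLS a few percent
below the planted truth at the default noise level. This is a property
of the chosen estimator (ranks are preserved); the noise-free
round-trip recovers the planted survival integral to < 10⁻³ relative
error.

## Translation error rate

Gates (inclusive): mutant Firefly RLU in [5×10², 10⁴], wildtype Firefly
≥ 10⁶, Renilla in [5×10⁶, 10⁸] for both reporters. Gating precedes all
averaging. Activities are Firefly/Renilla; technical then biological
replicates are CV-filtered at 0.2. The strain error rate is the **ratio
of strain-averaged activities** (mutant over wildtype); the per-pair
rates from index-matched biological replicates are used only for the
SD (the pairing is a documented convention — no physical pairing
exists). Rates above 10⁻² are treated as assay failures and flagged;
a strain failing either reporter entirely yields no estimate rather
than a partial one. The error rate is scale-invariant in the raw RLUs.

## QTL mapping

LOD per marker: `−n·ln(1−r²)/(2 ln 10)` with r the Pearson correlation
between the 0/1 allele coding (0 = BY, 1 = RM) and the trait over the
pairs non-missing at that marker (pairwise deletion; n set per marker).
Monomorphic markers are flagged undefined; |r| = 1 maps to +inf.

Permutation thresholds shuffle the phenotype-to-strain assignment.
Default mode `genomewide_max` takes mean + 3 SD of the per-permutation
maximum LOD (family-wise control, the field standard); `per_marker`
applies mean + 3 SD marker-wise for fidelity to the literal protocol
wording — the published description is ambiguous between the two. When
n! ≤ n_perm all assignments are enumerated exactly.

The 95% credible interval emulates the ranked-weight `bayesint`
construction: posterior weights ∝ 10^LOD normalized over the
chromosome, markers accumulated in decreasing-weight order until
coverage, interval spanning the accumulated set expanded by one
flanking marker per side. Exact numerical parity with the R
implementation is not claimed. Combined LOD across two traits is the
plain sum (the combination rule is otherwise unspecified); ties break
toward the lower position. Coordinates are 1-based closed intervals in
memory; BED exports use 0-based half-open convention for the file only.

## Heritability

Broad-sense H²: k = 2 replicates per strain are drawn (seeded) to unify
sample size; one-way random-effects method-of-moments components give
σ²E = within-strain mean square and σ²G = (between − within)/k, with
negative σ²G clamped to zero (clamping flagged). A REML option through
a random-intercept mixed model is provided and agrees with the moment
estimator on synthetic data (asserted). H² is invariant to shifting and
positive rescaling of the trait.

Narrow-sense h²: kinship K = ZZᵀ/m from column-standardized genotypes
(missing calls mean-imputed, monomorphic markers dropped; duplicating
markers leaves K, and hence h², unchanged). The model y = μ + g + ε
with cov(g) = σ²A·K is fit by restricted maximum likelihood profiled
over δ = σ²EV/σ²A on the spectral decomposition of K: a 100-point grid
over ln δ ∈ [−12, 12] followed by bounded refinement, so the returned
optimum is at least as good as the grid (asserted as a verification
hook); hitting the grid boundary is flagged. This is equivalent in
expectation to ridge-regression BLUP on the markers; numerical parity
with any particular GBLUP package is not claimed. SEs for both
estimators use the delete-one-strain jackknife,
`SE = sqrt(((n−1)/n)·Σ(θ₋ᵢ − θ̄)²)`, skipping (and flagging)
leave-one-out sets on which the statistic is undefined.

## Empirical correlation analyses

The joint table is an inner join of the CLS and error-rate tables on
strain id. Removal is keyed to ascending mean CLS with ties broken by
strain id. Allele-stratified scans filter strains satisfying all
(marker, allele) conditions before scanning. Percent change is
100·(reference − new)/reference, so reductions are positive; the
asymmetry pc(a,b) = −pc(b,a)·b/a is documented and tested. The KS
normality check fits the normal's parameters from the data and warns
that the resulting P is anti-conservative; a Lilliefors-corrected
variant is provided. The strain-effect ANOVA is a standard one-way
unbalanced decomposition, returning +inf F when the within-strain mean
square is zero (cross-checked against an independent ANOVA routine in
the suite).

## Synthetic data generator

The generator emulates a BY × RM haploid segregant panel and defines
the study conditions under which all properties are tested.

- **Genotypes**: per chromosome, first marker Bernoulli(0.5), later
  markers flip parent with probability 0.1 per interval; 16 chromosomes
  × 30 markers at 25 kb spacing, 120 strains by default (large enough
  for linkage power, small enough for seconds-scale runs).
- **Traits**: E = clip(μ_E + planted effects + N(0, σ_E), L, U) with
  μ_E = (L+U)/2 and σ_E = 0.15(U−L); other-cause lifespan uniform on
  [0, Lifespan(L)] plus planted lifespan effects; realized lifespan is
  the minimum of other-cause and the error-catastrophe cap — exactly
  the trapezoid geometry. The default planted locus (middle of
  chromosome 10) is pleiotropic: the RM allele lowers E by 0.3(U−L)
  and adds 4 model time units (~30% of lifespan variance) to the
  other-cause lifespan. The direct lifespan effect is needed because
  coupling through the cap alone is far below linkage-scan power on
  half a panel: selecting the long-lived half both attenuates the
  effect (conditioning on the trait) and depletes the BY allele, so
  only a major-effect locus remains the genome-wide peak there — the
  regime the empirical analysis operates in.
- **Survival schedules**: half-life in days = 1 + lifespan, giving
  survival integrals of ~6–9 for typical strains on the day grid
  {2, …, 15}, matching realistic assay scales.
- **Growth curves**: background-corrected OD is a pure exponential at
  doubling time 90 min, scaled so the t50-normalized curve crosses 0.3
  exactly at the planted time, which is snapped to the 10-min sampling
  grid; days crossing past the 12-h horizon exercise the extrapolation
  path, where the t50 offset makes extrapolated t_n exact only to
  ~0.6% in S_n — negligible in the integral because such days carry
  little survival weight. Exponential-to-ceiling growth is used rather
  than logistic because the survival arithmetic assumes exponential
  outgrowth. Additive Gaussian OD noise (sd 0.002 by default).
- **RLU tables**: Renilla ≈ 2×10⁷, wildtype Firefly = 0.15·Renilla,
  mutant Firefly = E·0.15·Renilla, each with lognormal noise at 5% CV;
  ≥ 99% of default-scale draws pass the RLU gates, so gate-attrition
  behavior is opt-in rather than accidental. Noise-free draws
  round-trip E exactly.
- One master seed spawns all child seeds; every generated dataset
  carries its ground truth.

What the generator does **not** emulate: real yeast recombination maps
or marker ascertainment, diploid genetics, epistasis, lag-phase or
logistic growth dynamics, batch effects, or the heavy-tailed replicate
noise of real luminometry. Passing round-trip tests therefore
demonstrates correctness of the estimators under the stated model, not
robustness to every artifact of real plates.

## Problem sizes

The default test-suite and acceptance-script workloads are sized for
seconds-to-minutes runs on one CPU: 1000-replicate cohort studies of
n = 400; 100-seed linkage-recovery studies on 120 × 480 panels;
500-strain heritability recovery; 8-strain noise-free round-trip
plates. All are the package's own defaults and can be scaled up via
function arguments.

## Known limitations

- The min-statistic doubling time is biased low under noise (by
  design, following the main-figure convention); mean/median variants
  are provided.
- The credible-interval construction emulates, but is not bit-identical
  to, the R `bayesint` ranked-weight algorithm.
- h² estimates on panels with near-singular kinship (no residual noise)
  sit at the optimizer bound and are flagged rather than refined.
- Exact Spearman enumeration is limited to n ≤ 9 (9! null assignments);
  beyond that the asymptotic approximation is used.
- The real study's heritabilities and QTL coordinates depend on the
  original strain data and external package internals; this package
  reproduces the methodology and its synthetic-data behavior, not those
  specific values.
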