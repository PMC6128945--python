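# Methods

This document specifies the statistical models, algorithms, parameter
conventions and numerical choices implemented in basinflow, and the
assumptions and limitations of each stage.

## 1. Genotype data model

Genotypes are diploid, biallelic SNPs stored as an integer matrix of
alternate-allele dosages (0, 1, 2; −1 for missing) of shape
individuals × loci. Each SNP carries a locus identifier (the RAD locus or
contig it came from) and a within-locus position. Input is VCF (parsed
with cyvcf2) plus a four-column, headerless, tab-separated population
map: individual, population, latitude, longitude. Populations are
ordered by first appearance in the popmap.

`filter_loci(G, min_pops, min_ind_frac)` retains loci genotyped in at
least `min_pops` populations and, within every retained population, in at
least a fraction `min_ind_frac` of its individuals.

## 2. Population statistics

For each population, `pop_stats` reports the number of polymorphic sites
P, nucleotide diversity π per SNP site, observed heterozygosity H_o,
expected heterozygosity H_e with the small-sample correction
2n/(2n−1) (n = number of called diploids), and the inbreeding
coefficient F_IS computed as a ratio of sums over loci,
F_IS = 1 − Σ H_o,l / Σ H_e,l. π equals H_e under this estimator.

Pairwise F_ST uses the Weir–Cockerham (1984) variance-components
estimator combined across loci as a ratio of sums (Σa / Σ(a+b+c)), which
is less biased than averaging per-locus ratios. Significance is assessed
by permuting individuals between the two populations; the p-value uses
the add-one rule p = (1 + #{F_perm ≥ F_obs}) / (n_perm + 1).

Assumptions: unlinked biallelic SNPs, random mating within populations
for H_e, missing data missing at random.

## 3. Folded joint site-frequency spectrum

The three-group joint SFS counts sites by their alternate-allele counts
(i, j, k) in the north, central and south groups. Because ancestral
states are unknown, the spectrum is folded on the **global** minor
allele: any cell whose pooled count exceeds half the pooled haploid
sample size is complemented on all three axes, and exact-half ties are
split 50/50 between the two complementary cells. The monomorphic corners
are masked, i.e. inference conditions on polymorphism. Folding is
idempotent.

Missing data are removed by projection: sites where any group has fewer
called haploids than its target size are dropped; at the remaining
sites each group's allele count is replaced by its hypergeometric
expectation over draws of the target haploids from the called ones
(`mode="project"`, real-valued mass), or by one seeded hypergeometric
draw (`mode="subsample"`, integer counts). One SNP per locus is retained
(`thin_one_snp_per_locus`, first- or random-SNP rule) so sites are
approximately unlinked, as the composite likelihood assumes.

## 4. Demographic models

Six variants (A–F) of one fixed topology for three groups: the southern
lineage diverges first at `t_div2` and the north/central lineages
diverge at `t_div1` (0 < t_div1 ≤ t_div2, both in generations before
present). Sizes `theta_n, theta_c, theta_s, theta_nc, theta_anc` are
diploid effective sizes of the five branches (north, central, south,
north-central ancestor, root). Migration is symmetric within a pair and
expressed as the backward per-lineage per-generation probability that a
lineage's parent came from the other deme:

| model | m_nc (N↔C, after t_div1) | m_cs (C↔S, after t_div1) | m_anc (NC↔S, between splits) |
|---|---|---|---|
| A | ● | ● | ● |
| B | ● | | ● |
| C | ● | ● | |
| D | | | ● |
| E | ● | | |
| F | | | |

Rates not active under a variant must be zero. The number of free
parameters k is 6 (four sizes plus two times; `theta_s` is fixed, see
§5) plus the number of active migration rates.

### Coalescent engine

The engine simulates genealogies under the structured coalescent with
piecewise-constant demes (numba-compiled kernels). In a deme of diploid
size N, c lineages coalesce at rate c(c−1)/(4N) per generation; each
lineage migrates at its deme's backward rate; at epoch boundaries
lineages are remapped to ancestral demes. Waiting times are exponential
(continuous-time approximation). The engine accepts any deme count, so
the synthetic generator can nest six sampled localities inside the
three-group history.

The expected folded SFS under a model is estimated by branch-length
weighting: each branch of each simulated genealogy contributes mass
equal to its length to its descendant configuration (the one-mutation,
infinite-sites weighting), and the accumulated array is folded, masked
and normalized. This is exact in the limit of many genealogies for loci
short enough that recurrent mutation is negligible.

The engine is cross-validated in the test suite against msprime
(spectra agree within Monte-Carlo noise for migration-free and
migration-bearing variants) and against analytic results (E[T_MRCA] = 2N
for a pair; the folded neutral single-deme spectrum ∝ 1/i + 1/(n−i)).

## 5. Composite-likelihood fitting

The observed folded SFS **x** is modeled as multinomial over unmasked
cells with probabilities p(θ) from the engine, giving the composite
log-likelihood lnL(θ) = Σ x_c ln max(p_c(θ), p_min). The floor
p_min (default 1/(10·n_sims)) guards cells where the Monte-Carlo
estimate of a small probability is zero. Because linked sites violate
multinomial independence, lnL is a composite likelihood: valid for point
estimation and model ranking, but its curvature understates uncertainty
— hence parametric-bootstrap intervals (§6).

`theta_s` is not estimated from the SFS. It is fixed from the southern
group's nucleotide diversity via Watterson/Tajima's identity
Ne = π/(4μ) (`ne_from_pi`), anchoring the model's absolute scale; all
other sizes and times are estimated relative to data plus this anchor.

### Optimization

`fit_model` maximizes lnL by replicated expectation–conditional-
maximization (ECM) in log-parameter space:

- **Multistart profile.** Replicate r starts `t_div2` on a log-spaced
  grid spanning the time bounds (trimmed one decade at each end),
  `t_div1 = t_div2/8`, all sizes at the `theta_s` anchor, and migration
  rates alternating between the geometric center of their bounds and the
  lower bound — the latter so every migration model also explores the
  regime of its nested variant, keeping fitted lnL monotone under
  nesting up to optimizer noise.
- **Cycle structure.** Each replicate runs `ecm_min_cycles` to
  `ecm_max_cycles` cycles of one-parameter golden-section searches over
  the full log-bounds, accepting only improvements, with a replicate-
  fixed simulation seed (common random numbers make the surface
  deterministic within a replicate). The first cycle holds the split
  times fixed so sizes adapt before times move; without this, arbitrary
  starts collapse `t_div1` toward zero, merging two populations.
  `t_div1 ≤ t_div2` is enforced by clipping the search interval.
- **Re-ranking and polish.** Replicate endpoints are re-scored on one
  shared, model-independent surface with `polish_n_sims` simulations,
  and the winner is refined by alternating coordinate cycles with
  Nelder–Mead (`polish_maxfev` evaluations) in clipped log coordinates.
- **Final evaluation.** Optionally (`final_n_sims`) the maximized lnL is
  re-evaluated once on a larger, model-independent common surface so lnL
  values are comparable across models in an AIC table. Both the polished
  and the pre-polish candidates are evaluated and the better kept, since
  polish gains on the noisy selection surface do not always survive
  re-evaluation.

All seeds derive deterministically from `InferenceConfig.seed`; fits are
exactly reproducible.

### Nested model batteries

Fitting each model of a nested family independently and comparing AICs
is unreliable at moderate simulation budgets: the scatter in attained
lnL between optimization runs on Monte-Carlo surfaces is tens of units
— far beyond the 2-unit AIC resolution — so a richer model routinely
scores *below* a model it nests, which exact maximum likelihood forbids.
`fit_battery` fits models in the given order and passes each fitted
optimum forward as an extra starting candidate (`extra_starts`) to every
later model whose active migration set is a superset (absent rates enter
at their lower bound). Extra starts skip the ECM stage and join the
candidate pool at re-ranking, so with models listed in order of
increasing complexity the fitted lnL values satisfy the nesting
inequality up to final-surface Monte-Carlo noise, and ΔAIC differences
between nested variants reflect fit, not optimizer luck. Two practical
notes for AIC work at desk scale: the lnL noise of a final common-seed
evaluation falls roughly as 1/√n_sims (standard deviation of several
lnL units at 2·10⁴ simulations, ~1.5 at 10⁵), so `final_n_sims` of 10⁵
or more is needed before ΔAIC < 2 is resolvable; and any spectrum used
to *generate* data for calibration or simulation studies must itself be
far more precise than the fitting surfaces, since its Monte-Carlo noise
is a genuine, fittable signal shared by every data set drawn from it.

### Defaults and bounds

Sizes and times: 1e2–1e7 (diploids; generations). Migration rates:
1e-9–1e-2 per generation. Defaults: 10 replicates, 5000 simulations per
evaluation, 2–10 ECM cycles with relative stopping tolerance 1e-6,
20 golden-section iterations, polish budget 200 evaluations. μ defaults
to 3.5e-9 per bp per generation and generation time to 1 year
(`generations_to_years` converts fitted times).

## 6. Model comparison and uncertainty

`model_table` computes AIC = 2k − 2 lnL, ΔAIC relative to the minimum,
Akaike weights ω ∝ exp(−ΔAIC/2) (normalized to 1), and flags the
statistically equivalent set ΔAIC < 2. `model_average` forms
ω-weighted parameter averages; a parameter absent from some models is
averaged over the models containing it with renormalized weights,
optionally restricted to the ΔAIC < 2 set.

`parametric_bootstrap` resimulates the observed number of sites from the
expected spectrum at the point estimates and refits each replicate with
the same estimator. The generating spectrum is computed at
max(50000, polish_n_sims) simulations: it must be far more precise than
a fitting surface, because its Monte-Carlo noise would enter every
bootstrap data set as one shared distortion. Intervals are
**bias-corrected pivotal** intervals on the log scale: with l_b the log
refitted estimates, the estimated bias is mean(l_b) − ln θ̂ and
CI = exp(2 ln θ̂ − mean(l_b) ± t_{B−1,0.975} · s), where s is the
sample standard deviation of l_b inflated by sqrt(1 + 1/B). The
reflection cancels first-order estimator bias, which matters here: at
moderate simulation counts the Monte-Carlo composite-likelihood
estimator is measurably biased (upward for sizes and the shallow split
time in calibration runs), and the refits reproduce that bias. The
Student-t/sd form is used instead of raw refit percentiles because at
the small refit counts that are affordable (B ≈ 10) the empirical
2.5/97.5 percentiles collapse to the sample extremes — for B normal
draws these span only about ±1.5 s — and systematically undercover.
More than 20% refit failures aborts with an error.

## 7. Isolation by resistance

A resistance scenario assigns a per-cell resistance raster:

- `flat` — all suitable cells cost 1 (isolation by distance).
- `slope` — cost 1 + slope in degrees (Horn's 3×3 operator).
- `basin_barrier` — cost 1 inside basins; the two cell rows flanking a
  basin boundary cost R (the barrier burn-in).
- `habitat` — suitable classes cost 1, other natural classes R,
  non-natural classes 2R.
- `lithology` — suitable classes cost 1, others R.

Rasters use ESRI ASCII grid format (NaN for nodata in memory). Focal
points snap to the nearest valid cell within 2 cells. The landscape is a
4-neighbor lattice; the conductance of the edge between adjacent cells
is the reciprocal of the mean of their resistances. Pairwise effective
resistance between focal cells is computed exactly by grounding one node
and solving the reduced Laplacian with a sparse LU factorization —
equivalent to the circuit-theory (Circuitscape-style) pairwise mode.
Disconnected focal pairs raise an error.

`scan_profile` evaluates a scenario over the fixed 23-value grid
R ∈ {2.5, 5, 7.5, 10, 25, …, 1e6}, regressing the genetic distance
matrix on each resistance-distance matrix by single-predictor MMRR, and
returns the R maximizing r² (ties resolve to the smallest R; `flat` and
`slope` have no R and return a single row).

Limitations: 4-neighbor connectivity (no diagonal moves), single
all-to-all resistance mode, no current maps.

## 8. Matrix regression (MMRR)

Distance matrices are unfolded to their strict lower triangle (row-major
order, i > j). Predictors and response are standardized by default.
Coefficients are ordinary least squares; significance of each
coefficient (t-statistic) and of the overall fit (F-statistic) is
assessed by permuting rows and columns of the response matrix jointly
(Mantel-style), with add-one p-values. Exactly collinear predictors
raise an error naming the offending pair. The estimator follows the
scikit-learn interface (`MMRR().fit(X, y)` with fitted attributes
`coef_`, `pvalues_`, `r_squared_`, …); `mmrr()` is a functional wrapper.

`backward_select` drops the least significant predictor until all
remaining p-values are below α (default 0.05), refitting and re-testing
at each step, and reports retained terms, rejected terms with their
final-test p-values, and whether only the intercept survives.
Permutation tests are seeded and reproducible.

Assumptions: the permutation scheme accounts for the non-independence
of distance-matrix entries, but p-values remain approximate; matrices
must share the same population labels and order.

## 9. Synthetic data generator

`SyntheticStudySpec` defines a miniature study emulating the target
sampling design: six localities (TAJU, BELI / PHUE, SALI, BONI / ORCE)
of 5–6 diploids nested in three genetic groups, ~10k short loci, 5%
missing genotypes. Genotypes are simulated under a six-deme refinement
of the three-group history: within-group migration (`m_within`) keeps
within-group F_ST low while the two splits and weak between-group flow
produce strong between-lineage differentiation — qualitatively matching
a strongly fragmented, relictual population structure. The landscape is
a 48×48 grid with three river basins separated by wavy divides, a
habitat mosaic (suitable patches guaranteed at the localities), a
lithology raster and a gently ridged elevation field. `make_matrix_set`
builds distance-matrix regression problems with known coefficients for
calibrating MMRR.

The generator does **not** emulate ddRAD locus dropout, allele dropout,
sequencing error, or any real geography; it provides structurally
faithful inputs with known truth for validation.

## 10. Numerical choices

- All optimization is in log10 parameter space; bounds are enforced by
  clipping.
- Golden-section search is used for conditional maximization because the
  Monte-Carlo surface is noisy but unimodal along coordinates under
  common random numbers.
- Per-evaluation common random numbers (fixed kernel seed per replicate)
  make the likelihood surface deterministic, converting a stochastic
  optimization into a deterministic one at the cost of surface bias that
  the re-ranking and final-evaluation stages mitigate.
- Seeds everywhere derive from user seeds through
  `numpy.random.SeedSequence` and stay below 2^31.
- Sparse Laplacian solves use scipy's LU factorization; the dense
  pseudo-inverse is avoided (graph Laplacians have a null direction that
  default pseudo-inverse cutoffs handle poorly at small grid sizes).
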