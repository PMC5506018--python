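# Methods

## The design and the statistical model

triadkit targets the hybrid family-based design for maternally expressed
disease: *case-parent triads* (affected mother M, father F, child C, all
genotyped) combined with *control-mother dyads* (unaffected mother and
child, father not collected). At a biallelic SNP every genotype is coded as
the dose g ∈ {0, 1, 2} of the declared variant allele — the low-frequency
allele named in the map file, not inferred from the data, so the coding
cannot flip between subsets or strata.

The disease model is multiplicative on the mother's risk:

    P(disease | g_M, g_C, E) = f0 · R_{g_C} · S_{g_M} · I_{g_M}^{E}

with fetal relative risks R_1, R_2, maternal relative risks S_1, S_2
(dose 0 as reference, R_0 = S_0 = 1), and optional maternal
gene–environment multipliers I_1, I_2 active when the binary exposure E is
present. Parents are assumed to mate randomly with genotypes in
Hardy–Weinberg proportions, and transmission is Mendelian.

### The hybrid likelihood

Conditioning a triad on the mother being a case gives, over the 15
Mendelian-compatible ordered cells (g_M, g_F, g_C),

    P(cell | case) ∝ μ_{M(g_M, g_F)} · w(g_M, g_F) · T(g_C | g_M, g_F) · R_{g_C} · S_{g_M}

- μ_1..μ_6: the frequencies of the six unordered parental mating types,
  free simplex-constrained nuisance parameters shared between the two arms
  (HWE is *not* imposed on μ in the fit; it is only the generative truth of
  the simulator).
- w: the mating-symmetry weight (1/2 for heterogeneous ordered pairs, 1
  for equal-genotype pairs) — the assumption that which parent carries
  which genotype is exchangeable in the population.
- T: Mendelian transmission, e.g. T(1 | 1, 1) = 1/2.

The baseline f0 cancels in the conditioning, so case data alone identify
R and S given μ. Control dyads contribute

    P(g_M, g_C | control) ∝ Σ_{g_F} μ_{M(g_M, g_F)} · w · T(g_C | g_M, g_F)

over the 7 compatible mother-child cells: the unobserved father is
marginalized *analytically* inside the likelihood (exact; no EM is needed
because fathers are missing by design, not at random), and controls carry
no R or S terms — the rare-disease assumption that unaffected families are
representative of the source population. With a baseline risk of ~5 % and
relative risks below ~2 this approximation distorts control cell
probabilities by well under 1 %.

Both arms are multinomial with totals fixed by the sampling design, so the
conditional multinomial likelihood is used rather than a free-intercept
Poisson surrogate — the relative-risk MLEs coincide and no intercept
nuisance parameters are introduced.

### Estimation and inference

Maximization is quasi-Newton (BFGS) on unconstrained parameters: log
relative risks and multinomial logits of μ, with an analytic gradient
(the multinomial score reduces to residual sums within genotype classes
and mating types). Convergence is judged by the gradient norm at the final
point (tolerance 1e-6 relative to the sample size; BFGS's "precision-loss"
stop at an interior optimum is accepted when the analytic gradient
vanishes), with an L-BFGS-B polish as fallback. Starting values are zero
log-RRs and mating-type logits matched to the observed margins. The
covariance of the estimates is the inverse observed information (numerical
Hessian, ridge-regularized at 1e-8 if ill-conditioned); ORs are
exp(estimate) with Wald 95 % intervals.

Each parameter block gets a likelihood-ratio test on 2 df: fetal
(H0: R_1 = R_2 = 1) and maternal (H0: S_1 = S_2 = 1), by refitting the
nested model. A genotype class with zero count support leaves its RR
unidentified; the entry is flagged undefined and rendered `-` rather than
raising, matching how such cells are reported in practice. On exact
expected counts the fit recovers generating parameters to better than
1e-6 relative error; at 2,000 + 2,000 families the median bias of ln R_2
is below 0.02 with Wald coverage ≈ 0.95 (both are regression-tested).

### Severity subtypes and G×E

Subtype fits re-run the hybrid model with only the mild or severe case
triads against *all* control dyads. The maternal G×E LRT uses case triads
only (the exposure-stratified conditional likelihood needs no controls):
the full model frees μ and (S_1, S_2) per exposure stratum with the fetal
block shared; the reduced model shares (S_1, S_2) too; 2·Δℓ is referred to
χ²(2) — the 2 df being the two maternal interaction parameters. Freeing
the fetal block across strata as well was rejected because the test is a
*maternal* interaction test and the 2-df convention is what printed
interaction χ²/p pairs in this literature are consistent with. When
p < α, triad-only per-stratum fits report the stratified maternal ORs.

## Single-locus machinery

- **HWE**: Pearson goodness-of-fit of the three genotype cells against
  expectations from the sample allele frequency, 1 df (one estimated
  parameter). Monomorphic samples return NaN, flagged, not an error.
- **Contingency tests**: Pearson χ² without continuity correction is the
  default (continuity correction would not reproduce classical reported
  values such as p = 0.006 for a 67/165 vs 59/255 split). Substitution
  rule, read literally from its classical statement: Monte-Carlo p (10,000
  random fixed-margin tables via Patefield sampling, seeded) when > 20 %
  of expected cells lie in [1, 5); Fisher's exact probability when any
  expected cell is < 1. For 2×2 tables Fisher serves both branches. For
  r×c tables with an expected cell < 1 the Monte-Carlo branch stands in
  for the impractical exact r×c enumeration.
- **Fisher 2×2**: two-sided by the point-probability rule — sum of all
  hypergeometric outcomes with probability ≤ the observed one, ties within
  relative 1e-7 included.
- **Dominant/recessive ORs**: cross-product ratio on the collapsed 2×2
  with Woolf (log-OR normal) intervals; any zero cell marks the OR
  undefined (`-`) while the p-value is still reported.
- **FDR**: Benjamini–Hochberg step-up, applied per results table by
  default; the family is configurable since test-family definitions vary.

## TDT

Each parent of a QC-passed case triad contributes one (transmitted,
untransmitted) pair — two per triad, so a SNP's transmission table totals
2n. Homozygous parents fill diagonal cells, reported for completeness but
uninformative; the statistic is McNemar's (b − c)²/(b + c) on the
discordant counts from heterozygous parents, 1 df, no continuity
correction. In the doubly ambiguous configuration (both parents and child
heterozygous) the two allele-assignment resolutions yield the same
aggregate pair multiset {(ref, var), (var, ref)}, so the table is
well-defined without arbitrary choices.

## Power

For a design of n_T triads and n_D dyads under an alternative
(q, R_1, R_2, S_1, S_2): exact cell probabilities give expected counts;
the all-RRs-at-1 null model (μ free) is fitted to those expected counts;
the noncentrality is λ = 2(ℓ_alt − ℓ_null), where ℓ_alt is available in
closed form because expected counts are exactly realizable by the full
model. Power is P(χ²_df(λ) > χ²_df,1−α), default df = 4 (two fetal + two
maternal parameters). λ is exactly linear in a common multiplier on
(n_T, n_D). A Monte-Carlo cross-check samples multinomial cell counts and
runs the actual LRT; TDT power uses the same cell law with the McNemar
noncentrality.

**Scalar "effect size" mapping.** A single number like 1.5 must be mapped
onto the four RR parameters. The default is log-additive on *both* blocks
(R_1 = S_1 = 1.5, R_2 = S_2 = 2.25): the 4-df LRT tests both blocks
jointly, and this is the only scalar reading under which the canonical
220-triad + 300-dyad design attains ≥ 0.90 power across risk-allele
frequencies 0.10–0.36 (minimum 0.938 at q = 0.10) while the TDT sits near
0.7 — the relationship such designs are chosen for. Fetal-only,
maternal-only and dominant mappings are available; fetal-only log-additive,
for instance, yields only ~0.46 minimum power at this design size.

## The synthetic-data generator

The generator emulates the target study's sampling: parents drawn
Binomial(2, q) (HWE, random mating), Mendelian child, exposure
Bernoulli(prev), disease by the multiplicative model, then *rejection
sampling* — families are drawn until the case-triad and control-dyad
quotas fill, which is exact for a conditional-on-status design and bounded
by a configurable attempt cap (raising a configuration error on
unachievable settings such as f0 = 0). Defaults mirror the study scale:
256 case triads (mild fraction 39/256) + 360 control dyads (1,488
subjects), f0 = 0.05 (≈ the reported ~5.2 % population incidence of
preeclampsia in China), exposure prevalence 0.37 (the observed share of
case mothers with pre-pregnancy BMI ≥ 24 kg/m²), risk-allele frequencies
configurable in the study's 0.10–0.36 range (default 0.25).

Corruption is injected after sampling: each member genotype is set missing
with probability 0.02, and each child's genotype is replaced by a uniform
random dose with probability 0.005 (typical PCR/TaqMan failure and error
scales). A corrupted child may remain Mendelian-consistent by chance, so
QC is validated as "detected ⊆ injected" with exact bookkeeping in the
truth record; missingness-based exclusions match the injection count
exactly. Covariates (BMI consistent with the latent exposure via truncated
normals around the 24 kg/m² threshold, education, maternal age) are simple
parametric draws sufficient to exercise the descriptive statistics; they
are not calibrated to published cohort moments.

What the generator does *not* emulate — and hence what passing tests do
not establish about real data: linkage disequilibrium between SNPs,
population stratification or assortative mating (μ truly HWE here),
parent-of-origin effects, genotyping error in parents, informative
missingness, and covariate–genotype correlation beyond the built-in
exposure interaction.

## QC conventions

Families are excluded per SNP (a family failing one SNP remains in the
others' analyses), first for any missing member genotype, then for
Mendelian inconsistency — triads against the 15-cell compatibility table,
dyads against the two detectable opposite-homozygote pairs (0,2)/(2,0).
Applying the Mendelian rule to control dyads is a deliberate choice for
symmetry of data cleaning across arms, even though published analyses of
such designs rarely state whether control dyads were screened; the
exclusion is tallied separately so the effect is visible in the QC report.
qc_filter is idempotent.

## Numerical conventions and degenerate inputs

- Missing dose sentinel −1; operations that require complete genotypes
  raise on it rather than guessing.
- TDT with b + c = 0 and HWE on monomorphic samples return flagged
  undefined results, not exceptions; degenerate contingency margins raise.
- Monte-Carlo p-values use the (1 + #{T_sim ≥ T_obs}) / (reps + 1)
  estimator with an explicit seed; default 10,000 replicates.
- All reported simulations and tests use fixed seeds; problem sizes in the
  test suite (e.g. 200 recovery replicates at 2,000 + 2,000 families,
  ~500-replicate calibration batches, 1,000-replicate Monte-Carlo power)
  were chosen as the smallest giving Monte-Carlo error comfortably inside
  the asserted tolerances.

## Known limitations

- No sex-chromosome or multi-allelic support; no imputation (families are
  excluded instead, as is standard for these designs).
- Wald intervals and 2-df block LRTs can disagree near boundaries (zero
  cells); the package reports `-` rather than profile-likelihood
  intervals.
- The G×E test models maternal interaction only; fetal G×E would need a
  different full model.
- The maternal×fetal genotype interaction (logistic-regression style) is
  out of scope.
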