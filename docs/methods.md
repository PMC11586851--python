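# Methods

This note records the models implemented in `rfieval`, the defaults chosen
where the design was genuinely open, and what the synthetic herd does and
does not emulate.

## Phenotype derivation

**Energy-corrected milk.** ECM = 0.327·MY + 12.95·FY + 7.2·PY (kg). When
only fat/protein percentages are available, yields are percentage × MY/100.
The function is linear and rejects negative inputs.

**Daily-record quality control.** Cows need at least 30 daily records each
of body weight, dry-matter intake and ECM inside the test window (days in
milk 100–240) or they are dropped entirely. Per animal and trait, the trait
is regressed on DIM by OLS and days whose residual deviates from the mean
residual by more than 3 SD are flagged. Flagged days where the DMI *and*
milk-yield residuals both exceed 3 SD in the same direction are retained —
those are biological events (e.g. estrus, illness recovery), not meter
errors. Removal is per trait stream; the biological-event exception
protects the day in every stream, since the event is real. An animal/trait
with zero residual variance gets no removals.

**Trait summaries.** Averages are taken over each trait's kept days. ΔBW
(the cow model's growth energy sink) is, by default, the per-animal OLS line
of BW on DIM evaluated at the last minus the first kept day — robust to
single-day scale noise; a raw-endpoint mode is available. The published
summary tables are ambiguous about whether ΔBW is a total or a daily rate;
both readings are obtainable (total by default, rate = total / span).
Metabolic body weight is BW^0.75 (exponent configurable), averaged over the
available weighings.

**RFI regressions.** Heifer RFI is fitted separately within each trial
(the trial mean is the model's µ), requiring at least 5 animals per trial.
Cow RFI is one OLS across the herd with trial (26 levels) and lactation
(2 levels) as fixed factors plus DIM, DIM², age, age², BW, ECM and ΔBW;
when an animal has records in both lactations only the first-lactation
record enters. Factors use reference-level dummy coding; residuals — and
hence RFI — are invariant to that choice. Rank-deficient designs fail with
the collinear columns named.

## Relationship matrices

**Pedigree A.** Tabular method on a parents-first pedigree: a_ii = 1 + F_i,
F_i = a(sire, dam)/2, a_ij = (a(j, sire) + a(j, dam))/2, unknown parents
contributing zero (unrelated, non-inbred base). Pedigree depth is truncated
at 10 generations of ancestors from the anchor animals before building.

**SNP quality control.** In order: sex chromosomes dropped; SNPs with call
rate below 95% dropped (exactly 95% is kept — the rule is "less than");
SNPs with minor allele frequency below 5% dropped (5.0% kept); animals with
call rate below 95% dropped. Residual missing genotypes are mean-imputed as
2p_j. Phasing/imputation with external tools is out of scope.

**Genomic G.** VanRaden: G = (M − 2P)(M − 2P)′ / (2Σ p_j(1−p_j)), genotypes
coded 0/1/2. Base-population allele frequencies are unobservable, so the
default P uses observed frequencies in the genotyped set; external
frequencies can be supplied (the G-vs-A agreement test uses founder
frequencies, which match A's base definition). Because duplicates or clones
make raw G singular, `stabilize` adds ε = 0.01 to the diagonal by default,
or blends 0.95·G + 0.05·A.

## REML

Average-information REML, re-implemented (no external mixed-model binary).
With one record per animal the relationship matrix is eigendecomposed once
(A = UDU′); in the rotated basis the univariate likelihood, score, AI
matrix and EM update are all O(n) per iteration. The bivariate model with
complete records decomposes the same way into per-animal 2×2 blocks with
covariance d_iK + R; animals missing one trait fall back to a dense
P-matrix implementation (records stacked trait-major, residual covariance
linking only the two records of the same animal). A regression test
verifies the block likelihood equals the explicitly stacked Kronecker form.

Step control: the AI step is halved until it stays inside the parameter
space (variances positive, R positive definite, K allowed to touch the PSD
boundary) *and* does not decrease the restricted log-likelihood; if no such
step exists the univariate model takes an EM-REML step (monotone by
construction) and the bivariate model a likelihood-guarded scaled-gradient
step. Convergence: relative parameter change < 1e-8 or scaled gradient
norm < 1e-6/n; maximum 200 iterations, non-convergence raises with the full
trajectory attached. A vanishing additive variance is flagged as a boundary
estimate, not an error; an indefinite converged K is projected to the
nearest PSD matrix and flagged.

The asymptotic covariance of the estimates is the inverse AI matrix at
convergence. SEs of derived parameters (h², r_g) are the SD of the
parameter across 100,000 draws from N(θ̂, AI⁻¹); draws with invalid
components are rejected and counted, and more than 50% rejection aborts
(the Gaussian approximation is then meaningless, e.g. at boundary fits).
A delta-method h² SE is also provided.

The bivariate fixed effects are per-trait means only, matching the
two-stage design: RFI is already adjusted for its fixed effects, so the
variance-component model carries only µ, the animal effect and the
residual.

## GBLUP

Two-step, verbatim: variance components from the pedigree-based fit are
frozen, then the training mixed model equations are solved with
λ = σe²/σa² on G_TT⁻¹. C22 denotes the animal block of the inverse
coefficient matrix, so PEV_i = C22_ii·σe². Indirect prediction is
û_P = G_PT G_TT⁻¹ û_T. The prediction (co)variance quadratic form
G_PT G_TT⁻¹ (G_TT σa² − C22 σe²) G_TT⁻¹ G_TP is not yet unitless; each
animal is normalised by g_ii·σa² — the standard reliability
Var(û)/Var(u) — and the result must land in [0, 1] (violations beyond 1e-6
raise, signalling a mismatched C22/G pairing). Training reliabilities use
the standard PEV form 1 − C22_ii σe²/(g_ii σa²). Dense symmetric solves
throughout; training sets here are at most a few thousand animals.

## Cohort analyses

Candidates are grouped by male-line ancestry shared with the training set:
Group 1 shares sires, Group 2 only grandsires, Group 3 only
great-grandsires, Group 4 none. Only sire-line male ancestors are compared
by default (the groups are defined through male ancestors); an option adds
maternal-line males. Shared sets are compared as sets over the whole
training population. Candidates whose three-generation male-line chain hits
an unknown parent are excluded and reported.

Close relatives are training animals with genomic relationship ≥ 0.45
(first-degree allowing ±0.05 estimation error; the threshold is inclusive).
The reliability-vs-relatives curve is rel = a·(n+1)^b by deterministic
multi-start nonlinear least squares; the +1 offset keeps zero-relative
animals in the fit.

Re-ranking uses efficiency classes per life stage: the lowest floor(0.10·n)
RFI breeding values are "most efficient", the highest floor(0.10·n) "least",
the rest "medium" (cutoffs configurable; ties broken by stable animal-id
order). The cross-tab reports row percentages per heifer class.

## Synthetic herd

The generator reproduces the statistical structure the analysis assumes:

- multi-generation pedigree with a small sire fraction per generation
  (default 8% of males), creating the paternal half-sib families the group
  analyses need; sexes 50/50;
- genotypes by Mendelian gene dropping from founder frequencies drawn in
  the configured MAF range, coded 0/1/2;
- true breeding values drawn from N(0, A ⊗ K) — from the relationship
  matrix, not from marker effects, so REML parameter recovery is a clean
  test of the estimation model;
- cow daily records over DIM 100–240 built from the same covariates the
  cow RFI model fits (trial with 26 levels, lactation with 2 levels at the
  published 2,118/420 mix, DIM and age polynomials, BW, ECM, ΔBW) plus the
  animal's RFI deviation and day noise; heifer trials of 70 d with biweekly
  weighings, growth slopes around 1.09 kg/d and ages in 206–437 d;
- variance components default to the published cow RFI values (additive
  1.16, residual 1.55 kg² DM/d²) and a heifer/cow genetic correlation of
  0.42. The heifer additive variance is not printed in the source study;
  the default splits the published heifer phenotypic variance (SD 0.86)
  at the cow heritability 0.43, giving 0.318/0.4216 — chosen once and
  documented here;
- a configured fraction of days (default 2%) is perturbed beyond the 3-SD
  rule, split across DMI-only, BW-only, ECM-only and same-direction
  DMI+MY co-outliers, so the QC exception path is exercised.

Day-level noise is uniform on [−√3σ, √3σ]: same variance as a Gaussian of
SD σ but bounded strictly inside 3σ, so clean days can never trip the
outlier rule and the injected outliers are exactly the ground truth. Real
meters have heavier tails; the trade is intentional, making QC behaviour
deterministic under test. The generator also omits autocorrelated day
effects (the analysis averages over the period, so serial correlation is
not identifiable from its model), pregnancy, body-condition dynamics and
raw feeding-event streams. Passing tests therefore demonstrate correctness
of the estimation machinery under the stated model, not robustness to
every artefact of real barn data.

Trial-size distributions and the sire-family structure of the real herd are
not published; the defaults above are documented choices, not inferences.

## Problem sizes and reproducibility

The replicate recovery studies run 50 univariate replicates at 2,000
animals (3 generations) and 30 bivariate replicates at 1,500 animals —
sizes matching the published cohorts while keeping a full study in the
minutes range on one CPU. Replicate k uses seed (base + k), so any
replicate reproduces in isolation; the pipeline expands one run seed into
per-stage seeds through a fixed SeedSequence scheme, and a run directory
archives its config, seed and content-hashed outputs.

## Known limitations

- The cow RFI model omits energy sinks the source model also omits
  (pregnancy, body-condition change, locomotion).
- Reliability approximations assume the fixed variance components are
  correct; no propagation of their estimation error into reliabilities.
- The dense bivariate path scales as O(n³) per iteration and is meant for
  herds up to a few thousand records.
- Single-step evaluation (H-matrix), SNP-effect back-solving and
  deregressed proofs are out of scope.
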