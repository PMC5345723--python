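# Methods

This note documents the statistical model, the estimation algorithm, the
synthetic-data generator and the numerical conventions implemented in
`singlestep`, together with the design choices that were genuinely open
and the package's known limitations.

## 1. The bivariate animal model

For trees i = 1..n with up to two trait records each, the model is

    y = X b + Z1 a + Z2 u + e

* `y` — stacked phenotypes, each trait independently centred and scaled
  (z-score with the sample SD, ddof = 1; switchable to the population SD).
  Scaling constants are retained for back-transformation. Standardization
  puts the two traits on a common footing in the bivariate fit; all
  derived ratios (h², r_G, accuracy) are scale-free.
* `X b` — one intercept per trait.
* `a ~ N(0, Σa ⊗ K)` — additive genetic effects (breeding values) for
  every individual in the kernel's id set, parents included. `Σa` is an
  unstructured 2×2; `K` is A, or H, or any PD relationship matrix.
* `u ~ N(0, Σu ⊗ I)` — random block effects with diagonal `Σu`
  (2 parameters). The trial is a randomized block design; blocks are
  environmental, so no cross-trait block covariance is fitted.
* `e ~ N(0, Σe ⊗ I)` — residuals with unstructured 2×2 `Σe` applied per
  tree over its observed traits. A tree with a single-trait record
  contributes through the corresponding 1×1 residual block
  (missing-at-random handling by observation pattern, not row deletion).

Free (co)variance parameters: 3 (additive) + 2 (block) + 3 (residual)
= 8; the AIC is `−2ℓ_R + 2·8`. The solver is written for a generic trait
count and is exercised with one and two traits.

## 2. REML estimation

The restricted log-likelihood is evaluated through Henderson's mixed-model
equations (MME): with `W = [X Z1 Z2]`, `C = W'R⁻¹W + diag(0, Σa⁻¹⊗K⁻¹,
Σu⁻¹⊗I)`,

    −2 ℓ_R = (n_obs − rank X) log 2π + log|R| + log|G| + log|C| + y'Py.

Only `K⁻¹` enters, never `K` itself — the reason the single-step inverse
identity matters. The coefficient matrix is factored densely (Cholesky);
at the package's design scale (~2 000 trees, ~4 500 equations) one
factorization plus inverse takes a few seconds on one core.

Updates are average-information (AI) steps:

* Scores use the standard MME identities
  `Z'PZ = G⁻¹ − G⁻¹C^{uu}G⁻¹` (random-effect structures) and
  `P = R⁻¹ − R⁻¹WC⁻¹W'R⁻¹` (residual structures), so each iteration needs
  one `C⁻¹` and a handful of traces.
* The AI matrix is `AI_ij = ½ w_i' P w_j` with working variates
  `w_i = V̇_i P y`, each `P w_j` obtained by one extra MME solve against
  the existing factor.
* **Safeguards.** If a plain AI step leaves the feasible region or fails
  to improve the likelihood, the step is Levenberg–Marquardt-damped
  (`AI + λ·diag-scale·I`, λ escalating) and halved; proposals are
  projected back to feasibility (eigenvalue floor 1e-8 for Σa and Σe,
  plain floor for block variances). A damped AI step degrades gracefully
  into a short gradient-ascent step, which is always uphill, so the
  iteration cannot diverge. This fills the role an EM fallback plays in
  classical AI-REML implementations with less machinery.
* **Boundaries.** A variance pinned at its floor whose score points
  outward is frozen out of the Newton system for that iteration
  (active-set reduction). Without this, a boundary component (e.g. a
  block variance estimated at zero) makes the joint step crawl;
  with it, convergence is quadratic in the remaining parameters.
* **Convergence** when |Δℓ| < 1e-8 and the largest parameter change,
  relative to the largest parameter magnitude (floored at 1e-3), is
  < 1e-6; both tolerances and the iteration cap (200) are configurable.
  Non-convergence is flagged on the result, not raised.
* **Starting values**: half the phenotypic (co)variance each to additive
  and residual, 5 % of the trait variances to blocks.
* Standard errors are `sqrt(diag(AI⁻¹))` at the optimum; they are
  meaningless for parameters at a boundary.

The solver is validated against three independent oracles in the test
suite: a direct dense-V evaluation of the restricted likelihood,
numerical differentiation of the likelihood against the analytic score,
and the closed-form balanced one-way ANOVA estimator, which balanced
half-sib REML must reproduce to the solver's convergence tolerance.

BLUPs at fixed components solve the same MME once; prediction SEs are
square roots of the corresponding diagonal entries of `C⁻¹` (direct
inversion at this scale).

## 3. Relationship matrices

* **A** by the tabular method with inbreeding propagated; `A⁻¹`
  assembled sparsely from Henderson's rules using Mendelian-sampling
  variances `d_i = 1 − 0.25(1+F_dam) − 0.25(1+F_sire)` (unknown-parent
  terms dropped), with parental F taken from the tabular diagonal.
  Parents referenced but never declared are auto-inserted as founders
  with a warning; unknown-parent encodings default to {"", "0", "NA"}.
* **G** (VanRaden): allele frequencies from the genotyped set itself
  (the genotyped population is the genomic base population), centred
  scores with missing entries zeroed (mean imputation), denominator
  `2Σp_j(1−p_j)`. Markers monomorphic in the genotyped set are excluded
  up front (they contribute zero to numerator and denominator; excluding
  them makes the degenerate case an explicit error). MAF and call-rate
  filters exist but default to off.
* **Scaling** solves the 2×2 system matching `Avg(diag G)` and `Avg(G)`
  to the A22 targets. `Avg(·)` unqualified is read as the mean over all
  n² elements (diagonal included) — the plainest reading; the
  off-diagonal-only convention is a switch, and the two coincide as n
  grows. A spread-free G (diagonal average equal to overall average)
  makes the system singular and raises with advice to skip scaling.
* **Blending** `G_w = wG* + (1−w)A22`, default w = 0.95, guarantees an
  invertible genomic block.
* **H** is assembled densely (its genotyped block is exactly `G_w`);
  `H⁻¹ = A⁻¹ + (G_w⁻¹ − A22⁻¹)` in the genotyped block. The two routes
  are cross-checked against each other (dense inverse agreement to 1e-6
  on random 200-individual instances).

All matrices carry explicit ordered id lists; nothing positional crosses
a module boundary.

## 4. The synthetic trial generator

The generator emulates the structure of a provenance–progeny OP trial:
maternal parents assigned to provenances; family sizes Poisson(7.9)
truncated to [1, 12]; offspring randomized over 6 blocks; trait targets
h² = 0.3 / 0.6 with block-variance fractions 0.05 / 0.01 and zero genetic
correlation. Defaults scale to ~214 families / ~43 provenances / up to
6 716 SNPs and down to test size.

Hidden structure, invisible to the recorded (dams-only) pedigree:

* **Full-sibs** — within a family, each offspring reuses an existing
  pollen donor with probability `full_sib_proportion` (default 0.2),
  otherwise draws a fresh donor; reuse creates full-sib sets.
* **Selfs** — with probability `selfing_rate` (default 0.05) the mother
  is the pollen parent (offspring F = 0.5).
* **Maternal coancestry** — each mother's two parents are drawn (without
  replacement) from an unobserved per-provenance grandparental pool of
  size ≈ 1/`provenance_relatedness`, giving same-provenance mothers a
  mean additive relationship equal to the target (default 0.05). Using an
  explicit ancestral generation keeps genotypes and kinship mutually
  consistent, rather than perturbing A directly.
* **Recording errors** — with probability `pedigree_error_rate` (default
  0.02) an offspring's recorded dam is replaced by another mother.

Genotypes are produced by gene drop: founder alleles Bernoulli(p_j) with
p_j ~ U(0.05, 0.5), Mendelian transmission through the true pedigree.
Offspring are the genotyped candidates; mothers are not genotyped, as in
the emulated trial.

**Breeding values** come in two generative modes:

* `genetic_mode="marker"` (default): per-marker additive effects are
  drawn (trait-correlated to give the target r_G), scaled so the founder
  HWE additive variance hits the target, and summed over each
  individual's centred gene-dropped dosages. Trait covariance then tracks
  *realized* genomic relationships, as it does in real data where the
  panel tags the causal variation. This is the mode under which genomic
  information genuinely improves model fit: the pedigree expectation A is
  only an approximation to the true covariance kernel, and H recovers the
  difference.
* `genetic_mode="pedigree"`: breeding values follow the
  Mendelian-sampling recursion on the true pedigree (equivalent to a
  Cholesky of the true numerator matrix in pedigree order) — the exact
  generative assumption of the pedigree animal model. This mode is the
  right oracle for REML parameter-recovery tests. Note its flip side:
  because the true kernel *is* the pedigree matrix, marker-derived
  relationships can only add noise around it, and a single-step model is
  then expected to fit slightly *worse* than the (true-)pedigree model —
  so this mode cannot, even in principle, reproduce the fit improvements
  genomic data show on real trials. That asymmetry is why the marker mode
  is the default.

Phenotypes are `mean + sd·(a + u_block + e)` on a latent standardized
scale with `σ²a + σ²e = 1` per trait; the raw means/SDs are cosmetic and
removed again by standardization.

What the generator does **not** emulate: linkage and LD structure (markers
segregate independently), selection, multi-site G×E, dominance and
epistasis, spatial field trends, and genotyping error. Passing tests on
synthetic data therefore demonstrate the correctness of the machinery and
the direction of the headline effects, not the magnitudes real data would
give.

## 5. The genotyping-effort experiment

Efforts 0/25/50/75/100 %. Per replicate at intermediate efforts,
`round((1 − effort/100)·n_f)` members of each family's genotyped set are
removed uniformly at random (half-up rounding, so a family of eight loses
exactly 6/4/2; proportional removal preserves the effort semantics for
other family sizes). G is rebuilt on the retained subset — allele
frequencies recomputed there, since the genotyped set defines the genomic
base — then rescaled, blended and combined per replicate. Efforts 0 and
100 are deterministic (single replicate). One master seed spawns
per-replicate seeds deterministically; seeds are recorded in the outputs.
Non-converged replicates are flagged, logged and excluded from
aggregates.

Breeding-value accuracies for all scenarios are computed at variance
components fixed to the full-genotyping estimates (taken as the most
accurate), in three classes: maternal parents, genotyped progeny,
non-genotyped progeny; an empty class reports not-applicable. The
accuracy uses the square-root form `r̂ = √(1 − SE²/((1+F)σ̂²a))` with
pedigree-based F; the non-root (reliability-style) form is available
behind a flag — no numeric anchor distinguishes them in the reference
material, and the square-root form is the standard prediction-error
derivation. Negative values under the root are clamped to zero with a
warning (they occur when the PEV exceeds the usable additive variance,
e.g. weakly connected mothers).

Rankings (mothers and progeny separately) are compared to the
pedigree-only baseline by Spearman ρ (average-rank ties) and by overlap
of the top 5 % (k = ceil(0.05·n), ties broken deterministically by id).

Relationship-group descriptives classify every unordered pair by the
*recorded* pedigree — identity, parent–parent, parent–offspring,
half-sib/within-family, unrelated — and report mean/SD/range per group
plus the overall mean/variance and the Pearson correlation with a
reference matrix, both over the upper triangle including the diagonal
(documented, switchable).

## 6. Scale of the shipped study configurations

The default test-suite and example configurations run a scaled study —
roughly 80 families (≈600 trees), 1 000 markers and 5 replicates per
intermediate effort; the parameter-recovery check uses ≈250 families
(≈2 000 trees) and 20 replicate trials. The full emulated-trial scale
(214 families / 1 694 trees / 6 716 SNPs / 30 replicates) runs through
exactly the same code paths, only longer.

## 7. Known limitations and open edges

* At desk scale the pedigree-only h² estimate from a few dozen half-sib
  families carries large sampling noise — far larger than the modest
  upward bias the default hidden-relatedness levels induce (mean
  within-family relationship a few points above the assumed 0.25). The
  h² gap between pedigree-only and single-step analyses is positive in
  expectation but any single study can show the opposite ordering; the
  fit-quality (AIC), accuracy and ranking trends are, by contrast,
  stable per study. Detecting the h² trend reliably requires either
  many replicate datasets or stronger hidden relatedness.
* The REML solver factors the MME densely; beyond ~10⁴ equations a
  sparse or iterative formulation would be needed.
* No τ/ω weighting or APY-style approximations of H⁻¹; no metafounders;
  single VanRaden-method-1 G only.
* The VCF reader maps GT to reference-allele dosage and skips
  multiallelic records with a warning; it is a convenience path, not a
  variant-QC tool.
* AIC values are comparable only within a run convention: the parameter
  count is the number of free (co)variance parameters (8 bivariate),
  matching the common REML-AIC convention.
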