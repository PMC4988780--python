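# Methods

## Statistical model

### Censoring-aware analyte preprocessing

Multiplex immunoassays report a lower limit of quantification (LLOQ) per
analyte; values recorded below it are left-censored, not missing. The
preprocessing order is fixed: (1) triage by the censored fraction among
non-missing measurements — strictly above 90% the analyte is dropped,
strictly below 10% it is analyzed by ordinary least squares, anything in
between (boundaries inclusive) by a censored Gaussian (tobit) model;
(2) below-LLOQ values are imputed at LLOQ/2; (3) all values pass through
the rank-based inverse normal transform Φ⁻¹((r − ½)/m) with average ranks
for ties. The tie rule matters: every half-LLOQ imputation is an exact
tie, so all censored observations map to one transformed value, and the
censored-likelihood handles them through the censoring mask rather than
through that value. Because the transform forces an exactly Gaussian
marginal, the tobit normality assumption holds by construction. The
truncation value is c = min(transformed uncensored) − 10⁻¹⁰; the censoring
mask is taken from the below-LLOQ indicator, never re-derived by comparing
transformed values to c.

When a censored analyte later serves as a covariate (trio models, variance
reports), censored entries are replaced by the conditional expectation of
a normal truncated above at c: μᵢ − σ·φ(αᵢ)/Φ(αᵢ) with αᵢ = (c − μᵢ)/σ
from a tobit fit on the covariate design. The Mills ratio is evaluated in
log space (`log_ndtr`), which stays accurate far beyond the range where
Φ(α) underflows, so no asymptotic fallback is required.

### Association engines

OLS uses the closed-form normal equations with σ̂² = RSS/(n − p); aliased
design columns are dropped by pivoted QR with a warning. The tobit
log-likelihood

ℓ(β, σ) = Σ_uncens [log φ((yᵢ − xᵢβ)/σ) − log σ] + Σ_cens log Φ((c − xᵢβ)/σ)

is maximized in (β, log σ) by BFGS with the analytic gradient, initialized
from OLS on the transformed values, then polished by damped Newton steps
on the observed information until the gradient inf-norm falls below 10⁻⁶
(the convergence criterion); standard errors come from the inverse
observed information. Logistic regression delegates to statsmodels' Newton
MLE; runaway coefficients (perfect separation) are flagged non-converged.
Inference is Wald throughout: p = 2Φ(−|β̂/se|).

Genome-wide scans take complete cases per variant on the dosage. For
linear-mode analytes with complete dosages the scan runs through the
Frisch–Waugh–Lovell residual regression (residualize y and all dosage
columns on the covariate design once, then one slope per variant), which
is algebraically identical to per-variant refits and is what keeps a
2,000-variant × 3-analyte null calibration run in the test suite at a few
seconds. Monomorphic-in-sample variants return β = 0, p = 1, flagged.

### Meta-analysis and conditioning

Per-cohort (β, p) pairs become signed z-scores z = sign(β)·|Φ⁻¹(p/2)|
(evaluated from log p below ~10⁻²⁸⁰ so extreme associations keep accurate
z) and combine as Z = (n₁z₁ + n₂z₂)/(n₁ + n₂), meta-p = 2Φ(−|Z|). This
arithmetic-mean weighting is implemented exactly as the source analysis
used it. It is **not** the classical Stouffer statistic: its null variance
is below 1, so it is conservative whenever the cohorts differ in size
(verified over a grid in the tests, and visible as a ~0.5% rejection rate
at nominal α = 5% in the null calibration). The classical √n-weighted
variant is available via `method="classical"`; the conservative form
remains the default for fidelity. A log₁₀ meta-p column accompanies every
table because combined p-values can undershoot the float range.

Genome-wide significance defaults to 8×10⁻¹⁰ (strict inequality) and is
deliberately a configuration constant, with a helper computing
0.05/(variants × analytes) for a user's own panel. Replication of a
cohort-A discovery requires p_B < 0.05/m_A (m_A = discovery count) *and*
sign agreement. Recursive conditioning pools candidates with marginal
meta-p < 10⁻⁸ (a separate, looser constant than the significance call),
selects the top marginal hit, then repeatedly refits every remaining
candidate per cohort with **all** previously selected dosages in the
design, accepting the best candidate while its conditional meta-p beats
0.05/T for T remaining candidates. Conditioning on all selected variants
(not only the first) follows the forward-regression framing; candidates
with dosage r² > 0.99 against a selected variant are skipped as numerical
duplicates. Ties break by meta-p, then |Z|, then variant id. A variant is
"local" to an analyte when it lies within 1 Mb of the encoding gene's
interval on the same chromosome (distance zero inside the gene), else
"distant".

### Trio causal classification

Under the Mendelian-randomization premise that genotype causes molecular
and clinical variation (never the reverse), five directed models over a
(SNP g, biomarker B, phenotype D) trio imply distinct conditional
(in)dependence patterns. Four slopes are read off three regressions per
cohort — b₁ (g in D ~ g + C), b₃ and b₂ (g and B in D ~ g + B + C), b₅
(g in B ~ g + D + C) — meta-combined with the same signed-Z scheme, and
declared nonzero when meta-p < α (default 0.01). Testing b₂ doubles for
the biomarker–disease conditional dependence in both directions, so no
fourth regression is needed. The decision table formalizes the verbal
d-separation statements (S = significant, order b₁, b₃, b₂, b₅):

| b₁ | b₃ | b₂ | b₅ | category |
|----|----|----|----|----------|
| S | · | S | S | causal |
| S | S | S | · | reactive |
| S | S | · | S | independent |
| · | S | S | S | collide |
| S | S | S | S | complete |
| anything else | | | | other |

Each row was checked against d-separation on its DAG. Treating meta-p ≥ α
as evidence of conditional independence is accept-the-null logic inherited
from the procedure, not endorsed: the battery p-values are always emitted
so margins can be judged, and at realistic sizes confusion flows toward
"complete" (a power direction) rather than between causal and reactive.
Binary phenotypes use logistic models in the phenotype-response
regressions; the non-collapsibility of odds ratios means b₃ is not exactly
zero under a mediated graph with a binary outcome — a known caveat. The
biomarker PC1 covariate is excluded from the biomarker-response model
(M3) to avoid conditioning a response on a function of itself. Percent
emphysema may be log-transformed (log(x + 0.1)) before modeling; FEV₁
%-predicted enters untransformed.

### Biomarker PC1 covariate

PC1 is computed on the standardized transformed panel (tobit analytes
conditional-expectation-filled) *without* residualizing on covariates, and
then screened: under the `auto` policy it is included as a scan covariate
only when no clinical covariate associates with it at p < 0.05/(number of
covariate terms). Residualizing first would make PC1 orthogonal to the
covariates by construction and the screen vacuous; computing it plain lets
the screen distinguish a latent batch-like factor (include) from structure
the covariates already carry (exclude). Inclusion is decided per cohort.

## Synthetic cohorts

The generator emulates the data layout and statistical structure the
pipeline assumes: two cohorts (defaults n₁ = 750, n₂ = 590 — the study
sizes this pipeline shape targets) on a shared variant panel with MAFs
uniform on [0.01, 0.5], Hardy–Weinberg genotypes, and LD as block-copying
(each block member copies the seed haplotype with probability ρ, giving
r² ≈ ρ², exactly 1 at ρ = 1). Covariates resemble an older smoking cohort
(age ~ N(66, 8), BMI ~ N(28, 5), pack-years truncated N(50, 25) at ≥ 10,
30% current smokers, uniform sites). Each analyte is a unit-variance
latent Gaussian: effect sizes are *variance fractions* (a causal variant
with fraction f and frequency p gets slope √(f/(2p(1−p)))), plus covariate,
cell-count and batch loadings, with the residual absorbing the remainder.
The raw assay value is exp(latent + log 100) and the LLOQ sits at a
configured quantile of the raw distribution, so the censored fraction —
and hence the triage class — is controlled exactly. Log-normal raw scale
with quantile censoring was chosen because the inverse normal transform
makes the association scale insensitive to any monotone choice here.

Phenotypes are generated under a chosen trio graph. Where the disease
responds to the biomarker (causal, complete), it responds to the
biomarker's rank-based normal scores — the scale the analysis models —
rather than the raw latent: generating from the latent leaks a residual
SNP→disease signal of order the rank-transform noise, which at n ≈ 1,340
is large enough to misclassify causal trios as complete. This is a
deliberate convention, equivalent up to a monotone rescale of the
biomarker. Reactive and null graphs regenerate the biomarker without its
genetic edge; collide attenuates the existing biomarker by √(1 − λ²) and
adds λ·standardized(D).

What the generator does **not** emulate: population structure and
admixture, realistic gene annotation, assay batch/plate layout beyond a
single latent factor, genotyping error, and relatedness. Passing tests
therefore demonstrate correctness of the statistical machinery under the
assumed model, not robustness to confounding that real cohorts carry.

All randomness flows from the single config seed through
`numpy.random.SeedSequence` spawning (panel → per-cohort → per-component);
there is no global random state, and equal seeds give byte-identical
studies.

## Numerical choices and defaults

- Triage boundaries: "<10%" and ">90%" are strict, so exactly 10% or 90%
  censored goes to tobit (literal reading of the rules).
- Tobit: optimized in (β, log σ) for an unconstrained search; convergence
  requires gradient inf-norm < 10⁻⁶ and σ̂ > 10⁻⁸; non-converged scan
  results carry a flag and are excluded from meta-analysis.
- Genotype PCs: standardized dosages (missing set to the variant mean —
  mean imputation is used *only* inside PCA; scans use complete cases),
  residualized on the covariate design, SVD; sign fixed so the
  largest-magnitude loading is positive; the number of PCs used downstream
  is configuration (default 1) with eigenvalues emitted for a scree
  decision.
- Site enters designs as one-hot indicators against the first alphabetical
  level; with a single site no indicator is emitted.
- Filter attribution order is missingness → MAF → HWE for reporting; the
  kept set is the intersection, so variant order cannot change it.
- HWE is the standard exact conditional test (sum of heterozygote-count
  probabilities not exceeding the observed one), matching the common GWAS
  toolchain; monomorphic tables return p = 1.
- Association tables are written at 17 significant digits and read back
  with round-trip float parsing, so TSV round trips are bitwise.
- Default problem sizes in the test suite (e.g. 2,000-variant null scans,
  100-replicate conditioning and trio batteries, 500-replicate bias runs)
  are chosen so the statistical assertions have comfortable margins while
  the whole suite runs in well under a minute.

## Known limitations

- Exactly two cohorts; generalizing the weights is trivial but untested
  here, and heterogeneity statistics (I², Q) are out of scope.
- The meta statistic is conservative by design (see above); users wanting
  nominal calibration should pass `method="classical"`.
- Missing biomarker values (distinct from below-LLOQ) are treated as
  missing and excluded per regression, not as censored.
- Binary-phenotype trio tests inherit odds-ratio non-collapsibility.
- X-chromosome dosage conventions are not implemented (autosomal panels).
- PLINK import covers text `.ped`/`.map` only; the counted allele is the
  observed minor allele (ties break to the lexicographically greater), so
  allele alignment against an external reference is the caller's job.
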