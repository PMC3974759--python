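# Methods

## The statistical engine

Every filter in the cascade is a univariate association test computed from
centered sums of one predictor and one response:

* slope test: β̂ = S_xy/S_xx, se(β̂)² = (S_yy − β̂·S_xy)/((n−2)·S_xx),
  t = β̂/se, two-sided p from the t distribution with n−2 df;
* correlation test: r = S_xy/√(S_xx·S_yy), t = r·√((n−2)/(1−r²)).

The two are the same test; the implementation computes both from the same
sums so the identity holds numerically (pinned at 10⁻¹² relative in the
suite). Genotypes enter as additive 0/1/2 dosages of the coded (alternate)
allele, so the effect is assumed linear in allele count. No covariates are
fitted; the model assumes approximately normal residuals, which the
log-transform of the percent-viable phenotype is meant to serve.

Numerical conventions:

* **Missingness** — listwise deletion per test; a test needs n ≥ 3 complete
  cases (n − 2 ≥ 1 df) or it is an error for scalar calls and a flagged
  never-passing entry in vectorized scans.
* **Degenerate inputs** — a zero-variance predictor (monomorphic SNP, flat
  expression) or constant response yields a flagged record with β̂ = 0 and
  p = 1 instead of an exception, so genome-wide scans never abort. Variance
  is "zero" below a floor of n·(ε·max(1, max|x|))²·4 with ε the float64
  machine epsilon, which absorbs rounding in centered sums of constant
  columns.
* **Perfect fits** — residual sum of squares ≤ 10⁻¹⁴·S_yy is treated as an
  exact linear relationship: p is reported as the smallest positive double
  with a `perfect_fit` flag rather than 0, keeping downstream log-p
  arithmetic finite.
* **Thresholds** — loose gates (steps 1, 2, 5; replication entities) use
  strict inequality p < α; strict gates (steps 3, 4, 6; replication pairs)
  use non-strict p ≤ α. Ties at exactly 0.05 or 10⁻⁴ resolve accordingly.
  Defaults α_loose = 0.05, α_strict = 10⁻⁴; no multiple-testing correction
  is applied beyond these fixed thresholds.
* **Log base** — the phenotype log base (default: natural log, recorded in
  file metadata) is an affine rescaling, so every t and p downstream is
  base-invariant. The suite checks p-value agreement across bases e/2/10 at
  10⁻¹² relative on a 58-sample cohort. One caveat: p-values are computed
  through the t-distribution tail, which amplifies the ~10⁻¹⁴ relative float
  noise in t by a factor ≈ t²; for astronomically small p (t ≳ 25, p below
  ~10⁻¹⁰⁰, reachable only at n ≫ 100 with strong planted effects) cross-base
  agreement degrades to ~10⁻¹¹ relative. The triad *set* is unaffected.

## The cascade

Concentrations are processed fully independently and their triad lists
unioned; the unique summary deduplicates by (SNP, miRNA, gene) across
concentrations. Survivor sets are nested by construction (a step only ever
tests entities that survived the steps it depends on), and the join that
assembles triads requires all six memberships simultaneously — it is tested
exactly against brute-force cross-product enumeration. Gene–miRNA and
SNP–gene associations are computed directly from the input matrices rather
than looked up in a precomputed eQTL/target database; the statistical
contract (negative sign, p ≤ 10⁻⁴) is the same. An optional minor-allele-
frequency floor can exclude rare SNPs before steps 4–6; it defaults to 0 (no
filter). SNPs are tested against all survivor genes — the data model carries
no genomic coordinates, so no cis-window restriction is available.

One behavioural note for interpreting null-cohort runs: steps 3–6 test
entities *selected* by earlier steps for association with the same
phenotype. Conditional on that selection, survivors are mutually correlated,
so conditional pass rates at later steps exceed the unconditional nominal
rate even on null data — a property of sequential filtering, not
miscalibration. The suite therefore calibrates each test on unselected
inputs (where the exact t-test attains its nominal level under the Gaussian
null) and separately verifies that full-cascade false discoveries are
essentially absent (mean final triads per null run, computed by the
acceptance test and script).

## Phenotyping

Percent viability is 100 × mean(treated replicates)/mean(control
replicates) — a ratio of means, since control wells are plate-level in the
assay — and is scale-invariant in the plate readings. Values above 100
(treated outgrowing control) are retained. The regression phenotype is the
element-wise log; raw per-plate background normalization is not modelled
(the ratio is taken on raw readings). Dose-response summaries report the
median (midpoint of central order statistics for even rosters) and range per
concentration.

## The synthetic-cohort generator

The generator emulates the structure of an LCL pharmacogenomics study:
n = 58 samples, genome-wide biallelic SNPs (desk-scale default 5000),
13 000 gene expression traits, 201 expressed miRNAs, and viability
phenotypes at 3, 5, 7 and 10 μM. Genotypes are drawn per SNP as
Binomial(2, f) with f uniform on (0.05, 0.5]; expression is generated
directly on log scale.

Each planted triad follows a linear structural model with standardized
parents (genotype standardized by its population moments 2f, 2f(1−f); each
mediator by its analytic population SD) and i.i.d. Gaussian residuals of SD
`noise_sd` (default 1):

    miRNA = e_qm·z(SNP) + ε
    gene  = e_qg·z(SNP) + e_mg·std(miRNA) + ε
    log-viability_c = e_gp·dose_scaling[c]·std(gene) + ε

with defaults e_qg = 0.8, e_qm = 0.8, e_mg = −0.8 (repression; enforced
negative whenever triads are planted), e_gp = 0.8. `dose_scaling` defaults
to concentration/5 μM, i.e. (0.6, 1.0, 1.4, 2.0): phenotype effects grow
with dose, so inter-individual spread is larger at higher concentrations, as
observed in such assays. The structural log-viability is mapped affinely
onto a realistic percent scale (per-dose medians falling linearly 88% → 56%
from 3 to 10 μM, ln-scale SD growing 0.10 → 0.30); affine maps change no
p-value, so this is presentation only. Non-planted features are pure noise.
All randomness flows from a single seed through named substreams per matrix,
and a fixed seed reproduces the cohort bit-for-bit.

Two consequences of this model are worth stating because the test suite
measures them:

* **Path cancellation.** The marginal standardized slope of a planted gene
  on its SNP is the composite e_qg + e_mg·e_qm/√(e_qm² + noise_sd²) — direct
  path plus indirect path through the repressive miRNA. With the default
  signs (+0.8, +0.8, −0.8) the indirect path (−0.50) cancels half the direct
  one, leaving a composite of ≈ 0.30 (marginal SNP–gene correlation ≈ 0.25).
  `composite_snp_gene_slope` exposes the closed form, and the suite verifies
  the fitted slope converges to it at n = 2000.
* **Cross-triad dilution.** All planted genes feed one shared phenotype, so
  with k triads each SNP's marginal correlation with the phenotype is
  bounded by ≈ 0.25/√k. At k = 5 and n = 500 the step-6 gate at p ≤ 10⁻⁴
  (|t| ≥ 3.9 against an expected t ≈ 2.5) almost never passes, so
  multi-triad designs have near-zero full-cascade recovery while
  single-triad designs are recovered most of the time. Both rates are
  computed by the acceptance suite and `scripts/acceptance.py`
  (`planted_triad_recovery_pct`, `single_planted_triad_recovery_pct`);
  the package reports the measured values rather than adjusting the
  generator to mask the property.

What the generator does **not** emulate: linkage disequilibrium and real
allele-frequency spectra, population stratification, array probe/batch
effects, pleiotropy (one SNP/miRNA/gene per triad, for unambiguous truth
bookkeeping), heavy-tailed or skewed phenotype noise. Passing tests
therefore demonstrate correctness of the statistics and the pipeline on
idealized Gaussian structure, not robustness to real-data artefacts.

## Replication and screening choices

* Entity replication accepts association at **any** concentration in the
  second cohort (p < 0.05) and records the replicating dose per entity; the
  alternative (same concentration only) is stricter but was not adopted
  because dose-response curves shift between cohorts.
* Pair replication requires the discovery sign (negative) at the strict
  threshold, mirroring the mixed pattern real cross-population tables show
  (loose entity replication, strict pair replication).
* The allele-frequency screen interprets "more than 30% difference" as
  absolute difference of coded-allele frequencies > 0.30 (relative change is
  undefined near zero). With allele labels supplied, swapped ref/alt coding
  is detected and harmonized by complementing the frequency; strand-ambiguous
  (A/T, C/G) label mismatches are excluded with a warning because swap and
  strand-flip are indistinguishable. The screen is symmetric in the two
  cohorts.
* GI50 panel evaluation correlates expression with −log₁₀(GI50) (larger =
  more sensitive); input files store raw molar GI50 and the transform is
  internal. Curve fitting to estimate GI50 is out of scope; values are
  consumed as given.

## File formats and reproducibility

TSV is the canonical dialect (sample rows, feature columns, `NA`/blank for
missing); genotypes may also be read from a minimal GT-only VCF and written
as one with synthetic coordinates. Data matrices are written at 10
significant digits; statistic tables write p-values in scientific notation
at 6 significant digits — all comparisons happen on full-precision in-memory
values. Every written file carries `#`-prefixed provenance lines (package
version, config SHA-256, seed), and pipeline runs emit a JSON manifest with
a checksum per output; rerunning an identical config and seed reproduces
every byte. Sample alignment across matrices is by identifier, never by row
position.

## Problem sizes used by the shipped checks

The test suite and acceptance script run the cascade at desk scale: null
calibration on twenty 58-sample cohorts with 2000 genes, 200 miRNAs and
5000 SNPs; recovery studies on ten 500-sample cohorts with 300 genes, 60
miRNAs and 150 SNPs; the engine oracle on 100 random fixtures of 10–80
observations. These sizes exercise every code path (the scans are
vectorized, so larger matrices change runtime, not behaviour) while keeping
the full suite in the tens of seconds.

## Known limitations

No mixed models, kinship or population-structure correction; no covariates;
no multiple-testing correction beyond the fixed thresholds; no LD-aware
interpretation of SNP hits (correlated SNPs yield correlated triads); the
replication module assumes shared feature identifiers between cohorts and
reports — rather than resolves — missing candidates.
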