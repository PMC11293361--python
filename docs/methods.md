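# Methods

## ctDNA detection model

The caller works on consensus (post-UMI) molecule counts at a
patient-specific set of tracked somatic sites. At site *i*, with depth
*d_i* molecules, per-molecule background error rate *e_i*, allele factor
*c_i*, and ctDNA fraction *f*, the alt count is modeled

    k_i ~ Poisson(d_i (e_i + c_i f)),   f in [0, 1].

The rate is linear in *f*: a plasma molecule drawn at site *i* is
tumor-derived with probability ~*c_i f* (with *c_i* = 0.5 for a
heterozygous variant in a diploid genome — overridable per site where copy
number alters the expectation) and otherwise produces an alt read only by
error. This linear-in-*f* Poisson form is the minimal model consistent
with ultra-deep counting of independent molecules; it ignores overlapping
biological sources of alt molecules (e.g. clonal hematopoiesis), which a
real assay must filter upstream.

**Site test.** The per-site p-value is the inclusive upper tail
P(X ≥ k_i) under X ~ Poisson(d_i e_i), so k = 0 always gives p = 1 and a
zero background rate with observed alt molecules gives p = 0. Sites with
p < 0.05 are *significant sites*.

**Fraction estimate.** The log-likelihood
ℓ(f) = Σ_i [k_i ln(d_i(e_i + c_i f)) − d_i(e_i + c_i f)] is concave in
*f*; its score is strictly decreasing, so the constrained MLE is found by
boundary checks at f = 0, 1 and otherwise a Brent root of the score
(xtol 1e-12). A fine-grid search (step 1e-6) is kept in the test suite as
an independent oracle. When some e_i = 0 with k_i > 0, ℓ(0) would be −∞;
those rates are floored at 1e-9 with a warning.

**Sample test.** Λ = 2(ℓ(f̂) − ℓ(0)) ≥ 0. Because f = 0 sits on the
boundary of the parameter space, the null distribution of Λ is the 50:50
mixture of a point mass at zero and χ²₁; the reported sample p-value is
½·P(χ²₁ ≥ Λ) when f̂ > 0 and 1 otherwise. A flag
(`boundary_mixture=False`) switches to the plain χ²₁ tail, which is
exactly twice as large.

**Positivity rule.** MRD-positive iff at least 2 significant sites *and*
sample p < 0.005. The conjunction makes the rule conservative: on
background-only samples the empirical false-positive rate sits below the
0.005 sample-level threshold (verified on 2000 simulated nulls in the
acceptance suite).

**Limit of detection.** Monte Carlo over 25 log-spaced fractions in
[1e-7, 1e-3] (configurable): at each grid fraction, samples are simulated
from the model and run through the full caller; the LoD is the smallest
grid fraction with detection probability ≥ 0.95. The same seed is reused
at every grid point (paired replicates), which removes most grid-to-grid
Monte-Carlo noise and makes depth/panel-size monotonicity checks sharp. A
panel that never reaches the target (e.g. a single-site panel, which can
never satisfy the two-site rule) returns an explicit "above grid"
sentinel. A 50-site panel at 30000x with e = 1e-5 lands at ~3e-5, the
order of magnitude reported for per-patient tumor-informed panels
(0.0009%–0.0032%).

**Longitudinal summaries.** Per patient, fold reduction =
f(baseline) / max(f(pre-surgery), floor), with floor defaulting to 1e-7
(intended as panel LoD / 10) so that samples estimated at exactly zero
give a large finite fold rather than infinity. Group contrast is the
ratio of group median fold reductions. "Mean tumor molecules" has no
closed published definition; it is implemented as the mean alt molecule
count over tracked sites and labeled as such.

**Variant selection.** Somatic calls are kept if supporting reads ≥ 5,
VAF ≥ 3%, no elevated population frequency, and tumor/normal AF ratio ≥ 3
with not both AFs > 10% (normal AF 0 counts as infinite ratio). The panel
takes the top-VAF variants (ties broken by genomic position) up to 50
sites; smaller panels are allowed, zero eligible variants is an error
(undesignable patient). Coordinates are 1-based inclusive (VCF
convention).

## Simon two-stage design

Stage 1 enrolls n1; the trial stops for futility if responses ≤ r1.
PET(p) = B(r1; n1, p). EN(p) = n1 + (1 − PET(p))(n − n1). Rejection
("active") requires strictly more than r responses among n, evaluated by
exact convolution P(X1 > r1, X1 + X2 > r) with X1 ~ Bin(n1, p),
X2 ~ Bin(n − n1, p). The optimal-design search enumerates (n1, r1, n, r)
up to n_max, keeps designs with attained alpha ≤ alpha_max and power ≥
1 − beta_max, and minimizes EN(p0), breaking ties by smaller n then n1 —
the standard optimality convention. For (p0, p1, α, β) = (0.10, 0.30,
0.05, 0.10) the search returns (2/18, 6/35) with PET 73.4%, EN 22.5,
alpha 4.74%, power 90.2%.

## Exact contingency tests

Two-sided Fisher p-values are defined by summation of all tables (fixed
margins) whose probability is at most that of the observed table, with a
relative tie tolerance of 1e-7 — the R `fisher.test` convention. This
choice is deliberate: it reproduces the printed two-decimal p-values of
the cohort's baseline table (smoking 0.04, gender 0.02, PS 0.12,
histology 0.18, N stage 0.59, T stage 0.06), whereas the "doubling"
convention does not. The 2×2 case delegates to
`scipy.stats.fisher_exact`, which implements exactly this convention; the
r×c Freeman–Halton generalization is an in-package depth-first
enumeration in log space, bounded at 36 cells / total n 200 (beyond that
it raises and suggests Monte Carlo). Reported tables round half-up to two
decimals.

Two published rows do *not* reproduce from their printed counts (staging
modality prints 0.18 but computes to 0.61; EGFR subtype prints 0.33 but
computes to 0.51) — most likely transcription artifacts in the source
table; the reproduction tests assert only the internally consistent rows.
The age comparison uses Welch's t from the published group summaries
(means, sds, ns), since raw ages were not published; the resulting p
(0.43) matches the printed 0.42 only to the first decimal, and is
excluded from the strict checks.

Diagnostic metrics treat *non-response* (nMPR) as the condition-positive
class, because ctDNA positivity is used to predict inferior pathological
response. Ratios with empty denominators are reported as explicit "k/0"
strings (`None` numerically), never as silent NaN — the all-negative-call
timepoint yields the documented "PPV 0/0" case.

## TCR clonotypes and expansion

Contigs must be productive, high-confidence and full-length with a valid
barcode and chain in {TRA, TRB}; cells lacking a productive alpha/beta
pair are excluded. The clonotype key is the paired (chain, V gene, J
gene, CDR3 nucleotide) tuple for both chains — nucleotide-level by
default, with a flag for amino-acid keys. Cells with two productive
alphas keep the highest-UMI alpha (the 10x convention); cells with
*conflicting* duplicate betas are dropped as ambiguous (likely doublets)
and counted. Clone size is counted table-wide while each cell is
attributed to its own subtype, so a clone spanning subtypes contributes
to both — this is what makes cross-subtype expansion correlation
informative. The expanded ratio of a subtype is the fraction of its cells
in clonotypes of size ≥ 3 (threshold configurable; in practice ≥ 10 cells
for exhausted CD8 clones, ≥ 3 for Treg clones, which expand less). The
expansion correlation is Pearson's r between per-clonotype log1p cell
counts of two subtypes, computed across clonotypes (a per-patient variant
would also be defensible; the per-clonotype form is the one implemented
and tested).

## Signature scoring

ssGSEA: genes ranked by expression within a sample (descending, stable
ties); the score is Σ_j [P_in^w(j) − P_out(j)], where P_in^w is the
cumulative rank^0.25-weighted fraction of set members and P_out the
unweighted cumulative fraction of non-members. It depends only on ranks,
hence is invariant under strictly monotone transforms; no cross-sample
normalization is applied by default (a min-max flag exists) because the
downstream median split is scale-invariant. A kernel-CDF setting
sometimes quoted alongside ssGSEA applies to a different GSVA mode and is
intentionally not part of this score. Median split: stratum "high" iff
score > cohort median, ties to "low", so the high stratum strictly
exceeds the median. The module score for cell matrices is the Seurat
AddModuleScore construction (24 expression bins, 100 controls per set
gene, controls excluding the set genes, seeded); an optional
`bin_means` argument lets callers bin on reference means.

Cell QC (droplet data): keep cells with total UMI in [1000, 40000],
detected genes in [600, 5000], mitochondrial fraction strictly < 10%;
then drop genes detected in fewer than 200 surviving cells. Cells are
filtered before genes, and the order matters.

## Synthetic data

The generator produces inputs with the statistical structure the pipeline
assumes, at the study's scale:

- **Panels**: 50 sites per patient (one published patient had a 20-site
  panel; the size is configurable). Consensus depth is negative binomial
  with mean 5000 and size 20 — consistent with a 100,000x raw-depth
  target at a few percent molecule conversion. Background error rates are
  log-normal with median 1e-4 and log-sd 1.0, spanning ~1e-6–1e-3
  (duplex-to-UMI regimes, consistent with LoDs near 1e-5); the true
  per-site magnitudes of any particular commercial assay are not public,
  so these defaults are configurable and not claimed to match one.
- **Longitudinal cohorts**: per-patient baseline fractions log-normal
  (median 1e-3); responders decay through multipliers (1, 0.1, 0.01,
  1e-3, 0, 0) over (baseline, after cycles 1–3, pre-surgery,
  post-surgery) — clearing entirely by pre-surgery — while nonresponders
  decay to 1% of baseline, echoing the observation that both groups drop
  substantially but responders far more deeply. Response labels are
  assigned deterministically (first ⌈mix·n⌉ patients), so a seed fixes
  group sizes exactly.
- **Repertoires**: clone sizes zeta-distributed (exponent 2.5, capped at
  200) within each subtype; each clonotype gets distinct alpha/beta V/J
  and CDR3nt; every member cell emits one productive, high-confidence,
  full-length contig per chain. The all-singletons limit and a forced
  dominant clone are available for tests.
- **Expression cohorts**: 2000 genes × 200 samples, log-scale Gaussian
  noise (sd 1); signature genes upshifted by 2 sd in the (alternating)
  high stratum; survival exponential with baseline hazard 0.1, hazard
  ratio 2.5 for the high stratum, censoring hazard 0.02.

Randomness: one root seed; per-patient child streams come from
`SeedSequence([seed, crc32(patient_id)])`, so adding a patient never
perturbs the others, and fixed seeds give byte-identical outputs (the
end-to-end pipeline writes files compared byte-for-byte in the tests).

What the simulations do *not* emulate: read-level errors and their
sequence context, UMI collapse, clonal hematopoiesis, tumor growth
dynamics, batch effects and library-size variation in expression data,
doublets beyond the conflicting-beta case. Passing tests therefore
demonstrate correctness of the statistical machinery under the stated
models, not assay-level performance on real plasma or real droplet data.

## Problem sizes in the checked claims

The statistical acceptance checks run at: 2000 null samples (FPR of the
positivity rule), 500 replicates × 3 fractions (bias of f̂ at 1e-4, 1e-3,
5e-3 with 50 sites at depth 5000, e = 1e-4), 100 random instances for the
optimizer-vs-grid oracle (grid step 1e-6, agreement 1e-5), 200 paired
replicates per LoD grid point, and a 12-patient end-to-end run. These
sizes give Monte-Carlo standard errors comfortably inside the asserted
tolerances while keeping the whole suite fast.

## Known limitations

- The proprietary likelihood and per-site error estimation of commercial
  tumor-informed assays are not public; this package implements the
  minimal published model (Poisson site test, ML fraction, LRT,
  two-site/0.005 rule) and makes no claim of bit-level equivalence.
- Whether published per-patient LoDs are analytic or simulated is
  unstated; only the Monte-Carlo estimator is provided.
- Exact r×c enumeration is exponential in table size; beyond the bounds
  it refuses rather than silently approximating.
- The external-validation expression cohorts behind the signature's
  clinical claims are not packaged; signature/survival checks here are
  property-based on synthetic cohorts.
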